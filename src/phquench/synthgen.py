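"""Synthetic generators emulating the upstream simulation outputs.

The downstream analysis stages consume (i) binary protonation
trajectories of coupled titratable residues at fixed pH, (ii) Gaussian
vertical-energy series for electronic states, (iii) collective-variable
samples drawn under a known positive boost potential, and (iv) rigid
point-charge pigment pairs.  Each generator here produces one of these
with a known ground truth, so every estimator in the pipeline can be
validated against an exact oracle.

The titration generator uses an Ising-like pairwise model expressed in
pH units: with s_i = 1 meaning protonated,

    beta*E(s) / ln(10) = sum_i (1 - s_i) (pKa_int,i - pH)
                         + sum_{i<j} w_ij (1 - s_i)(1 - s_j)

so an isolated site titrates along the Henderson-Hasselbalch curve with
midpoint pKa_int, and a positive coupling w_ij penalizes joint
deprotonation of a pair (the mechanism behind nonmonotonic titration
curves of strongly coupled acidic residues).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .coupling import TransitionChargeSet

LN10 = math.log(10.0)

__all__ = [
    "SiteModel",
    "ProtonationTrajectory",
    "EnergySeries",
    "BiasedSample",
    "simulate_coupled_titration",
    "exact_titration",
    "simulate_energy_series",
    "simulate_biased_samples",
    "make_toy_pigment_pair",
]


@dataclass(frozen=True)
class SiteModel:
    """One titratable site plus its pairwise couplings.

    Parameters
    ----------
    site_id : str
        Residue label, e.g. ``"E114"``.
    residue_class : {"GLU", "ASP"}
        Residue type; fixes the water-reference pKa used downstream
        (Glu 4.3, Asp 3.9).
    pka_int : float
        Intrinsic midpoint pH of the isolated site.
    couplings : mapping of str -> float
        Interaction w_ij (pH units, dimensionless in the exponent) with
        other sites, applied when both members of the pair are
        deprotonated.  Symmetry across the model is validated by the
        simulators.
    """

    site_id: str
    residue_class: str = "GLU"
    pka_int: float = 4.3
    couplings: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residue_class not in ("GLU", "ASP"):
            raise ValueError(f"residue_class must be GLU or ASP, got {self.residue_class!r}")
        if not np.isfinite(self.pka_int):
            raise ValueError("pka_int must be finite")


@dataclass
class ProtonationTrajectory:
    """Binary protonation record of several sites at one pH.

    ``states`` is a (n_frames, n_sites) uint8 matrix, 1 = protonated.
    ``dt_ps`` is the time separating successive protonation-change
    attempts (one attempt per frame).
    """

    pH: float
    dt_ps: float
    sites: list[str]
    states: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ValueError("states must be a nonempty frame x site matrix")
        if self.states.shape[1] != len(self.sites):
            raise ValueError("site list and state matrix disagree on site count")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states entries must be 0/1")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    def column(self, site_id: str) -> np.ndarray:
        try:
            j = self.sites.index(site_id)
        except ValueError:
            raise KeyError(f"site {site_id!r} not in trajectory (has {self.sites})") from None
        return self.states[:, j]


@dataclass
class EnergySeries:
    """Vertical-energy samples (cm^-1) of one electronic state."""

    state_label: str
    values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("an energy series needs at least 2 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("energy series contains non-finite values")


@dataclass
class BiasedSample:
    """Collective-variable samples with their per-frame boost potential."""

    cv_values: np.ndarray
    boost: np.ndarray
    truth_pmf: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.cv_values = np.asarray(self.cv_values, dtype=float)
        self.boost = np.asarray(self.boost, dtype=float)
        if self.cv_values.shape[0] != self.boost.shape[0]:
            raise ValueError("cv_values and boost must have equal length")
        if (self.boost < 0).any():
            raise ValueError("boost potential must be nonnegative")


# ---------------------------------------------------------------------------
# titration model internals
# ---------------------------------------------------------------------------

def _validate_model(model: Sequence[SiteModel]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Return (site ids, intrinsic pKas, symmetric coupling matrix)."""
    sites = [m.site_id for m in model]
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate site ids in model")
    index = {s: i for i, s in enumerate(sites)}
    pkas = np.array([m.pka_int for m in model], dtype=float)
    w = np.zeros((len(sites), len(sites)))
    for m in model:
        for other, wij in m.couplings.items():
            if other not in index:
                raise ValueError(f"coupling of {m.site_id} references unknown site {other!r}")
            w[index[m.site_id], index[other]] = wij
    if not np.allclose(w, w.T):
        # fill one-sided declarations symmetrically, reject contradictions
        both = (w != 0) & (w.T != 0)
        if not np.allclose(w[both], w.T[both]):
            raise ValueError("couplings declared asymmetrically with conflicting values")
        w = np.where(w != 0, w, w.T)
    return sites, pkas, w


def _state_energy(s: np.ndarray, pH: float, pkas: np.ndarray, w: np.ndarray) -> float:
    """Dimensionless energy beta*E / ln10 of one binary microstate."""
    d = 1.0 - s  # deprotonation indicator
    field_term = float(d @ (pkas - pH))
    pair_term = 0.5 * float(d @ w @ d)  # w symmetric, diagonal zero
    return field_term + pair_term


def simulate_coupled_titration(
    model: Sequence[SiteModel],
    pH: float,
    n_frames: int,
    seed: int,
    dt_ps: float = 200.0,
) -> ProtonationTrajectory:
    """Metropolis Monte Carlo over binary protonation microstates.

    One single-site flip is attempted per frame (mirroring the periodic
    single-exchange attempts of discrete constant-pH MD); the visited
    state is recorded every frame, frame 0 being the initial state.
    The initial state is drawn from the independent-site
    Henderson-Hasselbalch probabilities.

    Returns a :class:`ProtonationTrajectory`; bit-reproducible per seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    sites, pkas, w = _validate_model(model)
    n = len(sites)
    rng = np.random.default_rng(seed)

    p_init = 1.0 / (1.0 + 10.0 ** (pH - pkas))  # independent-site protonated prob
    s = (rng.random(n) < p_init).astype(float)

    states = np.empty((n_frames, n), dtype=np.uint8)
    states[0] = s
    # precompute per-frame site choices and uniforms for speed
    flips = rng.integers(0, n, size=n_frames)
    us = rng.random(n_frames)
    d = 1.0 - s
    for t in range(1, n_frames):
        i = flips[t]
        # energy change of flipping site i (in beta*E/ln10 units)
        di_new = 1.0 - d[i]
        delta = (di_new - d[i]) * ((pkas[i] - pH) + w[i] @ d)
        if delta <= 0 or us[t] < math.exp(-LN10 * delta):
            d[i] = di_new
        states[t] = (1.0 - d).astype(np.uint8)
    return ProtonationTrajectory(pH=pH, dt_ps=dt_ps, sites=list(sites), states=states, seed=seed)


def exact_titration(model: Sequence[SiteModel], pH: float) -> dict[str, float]:
    """Exact per-site protonated fractions by exhaustive enumeration.

    Boltzmann-averages s_i over all 2^N microstates of the pairwise
    model; the independent oracle for the Monte Carlo simulator and for
    Hill-fit recovery.  Limited to 20 sites.
    """
    sites, pkas, w = _validate_model(model)
    n = len(sites)
    if n > 20:
        raise ValueError(f"exact enumeration limited to 20 sites, got {n}")
    z = 0.0
    mean_s = np.zeros(n)
    for bits in itertools.product((0.0, 1.0), repeat=n):
        s = np.array(bits)
        e = _state_energy(s, pH, pkas, w)
        wgt = math.exp(-LN10 * e)
        z += wgt
        mean_s += wgt * s
    mean_s /= z
    return dict(zip(sites, mean_s))


def simulate_energy_series(
    mean: float, sd: float, n: int, seed: int, state_label: str = "LE"
) -> EnergySeries:
    """I.i.d. Gaussian vertical-energy samples (cm^-1).

    Gaussian fluctuations are the premise of the linear-response
    treatment downstream, so the generator is exactly matched to the
    estimator's assumptions.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    return EnergySeries(state_label=state_label, values=rng.normal(mean, sd, size=n), seed=seed)


def simulate_biased_samples(
    truth_pmf: tuple[np.ndarray, np.ndarray],
    boost_rule: Callable[[np.ndarray], np.ndarray],
    n: int,
    seed: int,
    temperature: float = 300.0,
    boost_sd: float = 0.0,
) -> BiasedSample:
    """Draw collective-variable samples from a boosted free-energy surface.

    ``truth_pmf`` is a tabulated surface ``(grid, F)`` in kcal/mol.  The
    boost ``dV = boost_rule(grid) >= 0`` is *added* to the surface, as
    in accelerated-MD sampling, so the biased density on the grid is
    proportional to ``exp(-beta (F + dV))`` — a boost that is largest in
    the wells flattens the sampled landscape.  Samples are drawn
    cell-wise (categorical over the grid, uniform jitter within a cell)
    and each frame records its boost.  When ``boost_sd > 0`` the
    recorded boost fluctuates as a Gaussian around the rule — the regime
    in which second-order cumulant reweighting is exact — and the
    sampling density carries the matching ``exp(-beta^2 sd^2 / 2)``
    correction so that the generative model stays self-consistent with
    exponential reweighting.
    """
    from .constants import K_B_KCAL

    grid, f_true = (np.asarray(a, dtype=float) for a in truth_pmf)
    if grid.ndim != 1 or grid.shape != f_true.shape:
        raise ValueError("truth_pmf must be a 1-D (grid, F) pair of equal length")
    beta = 1.0 / (K_B_KCAL * temperature)
    dv_mean = np.asarray(boost_rule(grid), dtype=float)
    if (dv_mean < 0).any():
        raise ValueError("boost_rule must be nonnegative everywhere sampled")
    log_p = -beta * (f_true + dv_mean) - 0.5 * (beta * boost_sd) ** 2
    log_p -= log_p.max()
    p = np.exp(log_p)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(grid.size, size=n, p=p)
    half = 0.5 * float(np.median(np.diff(grid))) if grid.size > 1 else 0.0
    cv = grid[idx] + rng.uniform(-half, half, size=n)
    boost = dv_mean[idx]
    if boost_sd > 0:
        boost = boost + rng.normal(0.0, boost_sd, size=n)
        boost = np.clip(boost, 0.0, None)

    def _pmf(x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), grid, f_true)

    return BiasedSample(cv_values=cv, boost=boost, truth_pmf=_pmf)


def make_toy_pigment_pair(
    separation: float,
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    charge_pattern: Sequence[tuple[str, Sequence[float], float]] = (("X", (0.0, 0.0, 0.0), 1.0),),
) -> tuple[TransitionChargeSet, TransitionChargeSet]:
    """Two rigid copies of a point-charge pattern at a given separation.

    The first set sits at the origin; the second is rotated by the
    intrinsic z-y-x Euler angles ``orientation`` (radians) and displaced
    by ``separation`` along +x.  ``charge_pattern`` lists
    ``(atom_name, local_xyz, transition_charge_e)`` rows.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    names = [a for a, _, _ in charge_pattern]
    local = np.array([xyz for _, xyz, _ in charge_pattern], dtype=float)
    q = np.array([c for _, _, c in charge_pattern], dtype=float)

    a, b, g = orientation
    rz = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]])
    ry = np.array([[math.cos(b), 0, math.sin(b)], [0, 1, 0], [-math.sin(b), 0, math.cos(b)]])
    rx = np.array([[1, 0, 0], [0, math.cos(g), -math.sin(g)], [0, math.sin(g), math.cos(g)]])
    rot = rz @ ry @ rx

    pos_a = local
    pos_b = local @ rot.T + np.array([separation, 0.0, 0.0])
    dists = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    if (dists < 0.5).any():
        i, j = np.unravel_index(np.argmin(dists), dists.shape)
        raise ValueError(
            f"overlapping atoms: {names[i]} (set A) and {names[j]} (set B) at {dists[i, j]:.3f} A"
        )
    set_a = TransitionChargeSet("pigA", names, pos_a, q, state_label="toy")
    set_b = TransitionChargeSet("pigB", names, pos_b, q, state_label="toy")
    return set_a, set_b
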