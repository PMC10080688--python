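"""Titration curves, Hill fits, blocked-bootstrap pKa errors, sensor calls.

A site's titration curve is the protonated fraction f(pH) averaged over
constant-pH trajectories.  The curve is fitted to the Hill equation
written for the protonated fraction (decreasing with pH),

    f(pH) = 1 / (1 + 10^{n (pH - pKa)})

by bounded nonlinear least squares.  Errors on pKa and n are two times
the standard deviation over blocked-bootstrap replicates, blocks being
resampled with replacement within each pH trajectory so that the error
estimate respects the autocorrelation of the underlying dynamics.

A residue qualifies as a lumenal pH-sensor candidate when its fitted
pKa is shifted more than one unit above the water reference of its
residue class (Glu 4.3, Asp 3.9); sites whose curve is nonmonotonic
beyond noise (the signature of strong coupling to neighbouring sites)
are flagged as coupled rather than force-fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .synthgen import ProtonationTrajectory

__all__ = [
    "WATER_REFERENCE_PKA",
    "TitrationCurve",
    "HillFit",
    "HillTitration",
    "protonation_fraction",
    "build_curve",
    "fit_hill",
    "blocked_bootstrap_pka",
    "classify_sensor",
]

#: Water-reference pKa values of the two acidic residue classes.
WATER_REFERENCE_PKA = {"GLU": 4.3, "ASP": 3.9}


@dataclass
class TitrationCurve:
    """Protonated fraction versus pH for one site."""

    site_id: str
    ph_values: np.ndarray
    fractions: np.ndarray
    errors: np.ndarray | None = None
    n_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.ph_values.ndim != 1 or self.ph_values.shape != self.fractions.shape:
            raise ValueError("ph_values and fractions must be equal-length 1-D arrays")
        if not (np.diff(self.ph_values) > 0).all():
            raise ValueError("pH values must be strictly increasing")
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
        if self.n_frames is not None:
            self.n_frames = np.asarray(self.n_frames, dtype=int)

    def point_errors(self) -> np.ndarray:
        """Per-point uncertainties: given errors, else binomial SE, else 0.01."""
        if self.errors is not None:
            return self.errors
        if self.n_frames is not None:
            f = self.fractions
            return np.sqrt(np.clip(f * (1 - f), 1e-4, None) / np.maximum(self.n_frames, 1))
        return np.full_like(self.fractions, 0.01)


@dataclass
class HillFit:
    """Point estimates (and optional 2x bootstrap SEs) of the Hill parameters."""

    pka: float
    n_hill: float
    pka_err: float = 0.0
    n_err: float = 0.0
    converged: bool = True
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.converged and not self.n_hill > 0:
            raise ValueError("a converged fit requires n_hill > 0")
        if self.pka_err < 0 or self.n_err < 0:
            raise ValueError("errors must be nonnegative")


def protonation_fraction(traj: ProtonationTrajectory, site_id: str) -> float:
    """Mean of the binary protonation column of one site; in [0, 1]."""
    return float(traj.column(site_id).mean())


def build_curve(
    trajs_per_ph: Mapping[float, ProtonationTrajectory | Sequence[ProtonationTrajectory]],
    site_id: str,
) -> TitrationCurve:
    """Assemble a titration curve, averaging replicas at each pH."""
    phs = sorted(trajs_per_ph)
    fracs, nframes = [], []
    for ph in phs:
        trajs = trajs_per_ph[ph]
        if isinstance(trajs, ProtonationTrajectory):
            trajs = [trajs]
        fracs.append(float(np.mean([protonation_fraction(t, site_id) for t in trajs])))
        nframes.append(int(sum(t.n_frames for t in trajs)))
    return TitrationCurve(site_id, np.array(phs, float), np.array(fracs), n_frames=np.array(nframes))


def _hill(ph: np.ndarray, pka: float, n: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (n * (ph - pka)))


class HillTitration(BaseEstimator):
    """Bounded least-squares fit of the Hill equation to a titration curve.

    Parameters
    ----------
    n_bounds : (float, float)
        Box for the Hill coefficient; default (1e-3, 10).
    pka_bounds : (float, float)
        Box for the midpoint; default (0, 14).
    check_monotonic : bool
        When true (default), a curve whose increase between consecutive
        pH points exceeds twice the pooled point error is declared
        nonmonotonic and the fit is marked non-converged instead of
        raising — the behaviour wanted for strongly coupled sites.
    min_range : float
        Minimum spread of the fractions below which the curve carries no
        midpoint information and the fit is marked non-converged.

    Attributes
    ----------
    pka_, n_hill_ : float
        Fitted midpoint and Hill coefficient.
    converged_ : bool
    residuals_ : ndarray
    """

    def __init__(
        self,
        n_bounds: tuple[float, float] = (1e-3, 10.0),
        pka_bounds: tuple[float, float] = (0.0, 14.0),
        check_monotonic: bool = True,
        min_range: float = 0.05,
    ):
        self.n_bounds = n_bounds
        self.pka_bounds = pka_bounds
        self.check_monotonic = check_monotonic
        self.min_range = min_range

    def fit(self, X, y=None):
        """Fit to a :class:`TitrationCurve`, or to (pH array, fraction array)."""
        if isinstance(X, TitrationCurve):
            curve = X
        else:
            ph = np.asarray(X, dtype=float).ravel()
            curve = TitrationCurve("", ph, np.asarray(y, dtype=float))
        ph, f = curve.ph_values, curve.fractions
        usable = np.isfinite(f)
        if usable.sum() < 3:
            raise ValueError("need at least 3 usable pH points")
        ph, f = ph[usable], f[usable]
        errs = curve.point_errors()[usable]

        self.converged_ = True
        if self.check_monotonic:
            rises = np.diff(f)
            pooled = np.sqrt(errs[:-1] ** 2 + errs[1:] ** 2)
            if (rises > 2.0 * np.maximum(pooled, 1e-12)).any():
                self.converged_ = False
        if f.max() - f.min() < self.min_range:
            self.converged_ = False

        # initial guess: pKa at the half-maximum crossing, n = 1
        pka0 = float(np.interp(0.5, f[::-1], ph[::-1])) if f[0] > 0.5 > f[-1] else float(
            ph[np.argmin(np.abs(f - 0.5))]
        )
        pka0 = float(np.clip(pka0, *self.pka_bounds))
        lo = (self.pka_bounds[0], self.n_bounds[0])
        hi = (self.pka_bounds[1], self.n_bounds[1])
        try:
            res = least_squares(
                lambda p: _hill(ph, p[0], p[1]) - f, x0=[pka0, 1.0], bounds=(lo, hi)
            )
            self.pka_ = float(res.x[0])
            self.n_hill_ = float(res.x[1])
            self.residuals_ = res.fun
            if not res.success:
                self.converged_ = False
        except Exception:
            self.pka_, self.n_hill_, self.residuals_ = float("nan"), float("nan"), None
            self.converged_ = False
        if self.converged_ and self.n_hill_ <= 2 * self.n_bounds[0]:
            self.converged_ = False  # flat-curve degenerate solution
        return self

    def to_hill_fit(self, site_id: str = "") -> HillFit:
        n = self.n_hill_ if (self.converged_ or self.n_hill_ > 0) else 1.0
        return HillFit(pka=self.pka_, n_hill=n, converged=self.converged_, site_id=site_id)


def fit_hill(curve: TitrationCurve, **kwargs) -> HillFit:
    """Functional wrapper over :class:`HillTitration`."""
    est = HillTitration(**kwargs).fit(curve)
    return est.to_hill_fit(site_id=curve.site_id)


def blocked_bootstrap_pka(
    trajs_per_ph: Mapping[float, ProtonationTrajectory | Sequence[ProtonationTrajectory]],
    site_id: str,
    block_length: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> HillFit:
    """Hill fit with 2x standard errors from a blocked bootstrap.

    Whole non-overlapping blocks of ``block_length`` frames are
    resampled with replacement within every pH trajectory (each replica
    separately); each replicate recomputes the per-pH protonated
    fractions and refits the Hill curve.  Reported errors are twice the
    standard deviation of the replicate parameters.  Replicates whose
    fit fails are dropped; the point estimate comes from the original
    (unresampled) curve.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    norm = {
        ph: [t] if isinstance(t, ProtonationTrajectory) else list(t)
        for ph, t in trajs_per_ph.items()
    }
    shortest = min(t.n_frames for ts in norm.values() for t in ts)
    if not 1 <= block_length <= shortest:
        raise ValueError(f"block_length must be in [1, {shortest}]")

    # pre-slice each trajectory's site column into complete blocks
    blocks: dict[float, list[np.ndarray]] = {}
    for ph, ts in norm.items():
        per_traj = []
        for t in ts:
            col = t.column(site_id).astype(float)
            nb = col.size // block_length
            per_traj.append(col[: nb * block_length].reshape(nb, block_length))
        blocks[ph] = per_traj

    rng = np.random.default_rng(seed)
    phs = sorted(norm)
    pkas, ns = [], []
    frac_reps = {ph: [] for ph in phs}
    for _ in range(n_boot):
        fracs = []
        for ph in phs:
            reps = []
            for blk in blocks[ph]:
                pick = rng.integers(0, blk.shape[0], size=blk.shape[0])
                reps.append(blk[pick].mean())
            fracs.append(np.mean(reps))
            frac_reps[ph].append(fracs[-1])
        try:
            est = HillTitration(check_monotonic=False).fit(
                np.array(phs, float), np.clip(fracs, 0, 1)
            )
        except ValueError:
            continue
        if est.converged_:
            pkas.append(est.pka_)
            ns.append(est.n_hill_)
    def _two_sd(vals: list[float]) -> float:
        if len(vals) < 2 or np.ptp(vals) < 1e-12:  # identical replicates
            return 0.0
        return 2.0 * float(np.std(vals, ddof=1))

    pka_err = _two_sd(pkas)
    n_err = _two_sd(ns)

    # point fit on the original curve, with per-point errors taken from the
    # blocked replicates (one bootstrap SE each) so the nonmonotonicity test
    # respects the chain's autocorrelation rather than assuming i.i.d. frames
    curve = build_curve(norm, site_id)
    curve.errors = np.array(
        [max(0.5 * _two_sd(frac_reps[ph]), 5e-4) for ph in phs], dtype=float
    )
    point = fit_hill(curve)
    return HillFit(
        pka=point.pka,
        n_hill=point.n_hill,
        pka_err=pka_err,
        n_err=n_err,
        converged=point.converged,
        site_id=site_id,
    )


def classify_sensor(fit: HillFit, residue_class: str) -> str:
    """Classify a site from its Hill fit.

    ``sensor_candidate`` — converged fit with pKa shifted more than one
    unit above the residue class's water reference; ``non_sensor`` —
    converged with a smaller shift; ``coupled_undetermined`` — the fit
    did not converge (nonmonotonic / degenerate curve, typical of
    strongly coupled sites).
    """
    if residue_class not in WATER_REFERENCE_PKA:
        raise ValueError(f"residue_class must be one of {sorted(WATER_REFERENCE_PKA)}")
    if not fit.converged:
        return "coupled_undetermined"
    shift = fit.pka - WATER_REFERENCE_PKA[residue_class]
    return "sensor_candidate" if shift > 1.0 else "non_sensor"
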