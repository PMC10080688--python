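"""Excitonic couplings from atomic transition charges (TrEsp).

The Coulomb coupling between two transition densities is approximated by
atom-centered transition charges:

    V_raw = K_e * sum_ij q_i q_j / r_ij        [cm^-1]

with K_e = 116140 cm^-1 A e^-2 (vacuum interaction; medium screening is
absorbed into the empirical rescale factor).  The conventional empirical
rescaling of carotenoid-chlorophyll couplings (factor 3.7) is applied as
an attenuation, V = V_raw / rescale; the convention is an explicit
argument so the opposite reading can be selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import K_E_CM_ANG

__all__ = ["TransitionChargeSet", "tresp_coupling", "ensemble_couplings", "dipole_coupling"]


@dataclass
class TransitionChargeSet:
    """Atom names, positions (A) and transition charges (e) of one pigment state."""

    pigment_id: str
    names: list[str]
    positions: np.ndarray
    charges: np.ndarray
    state_label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        if self.positions.shape[0] < 1:
            raise ValueError("a charge set needs at least one atom")
        if self.positions.shape != (self.charges.size, 3):
            raise ValueError("positions must be (n_atoms, 3) matching charges")
        if not np.isfinite(self.positions).all() or not np.isfinite(self.charges).all():
            raise ValueError("positions and charges must be finite")

    @property
    def transition_dipole(self) -> np.ndarray:
        """Transition dipole sum(q_i r_i), e*A."""
        return self.charges @ self.positions

    @property
    def center(self) -> np.ndarray:
        """Charge-magnitude-weighted center, or centroid if all charges vanish."""
        wgt = np.abs(self.charges)
        if wgt.sum() == 0:
            return self.positions.mean(axis=0)
        return (wgt @ self.positions) / wgt.sum()


def tresp_coupling(
    a: TransitionChargeSet,
    b: TransitionChargeSet,
    rescale: float = 3.7,
    divide: bool = True,
) -> float:
    """TrEsp point-charge coupling between two pigments, cm^-1.

    Full double sum over atom pairs; raises if any interatomic distance
    across the sets falls below 0.5 A.  ``rescale`` (default 3.7) is
    applied as division when ``divide`` is true, multiplication
    otherwise.
    """
    if rescale <= 0:
        raise ValueError("rescale must be positive")
    diff = a.positions[:, None, :] - b.positions[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    if (r < 0.5).any():
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"atom clash between {a.pigment_id}:{a.names[i]} and "
            f"{b.pigment_id}:{b.names[j]} (r = {r[i, j]:.3f} A)"
        )
    v_raw = K_E_CM_ANG * float(a.charges @ (1.0 / r) @ b.charges)
    return v_raw / rescale if divide else v_raw * rescale


def dipole_coupling(a: TransitionChargeSet, b: TransitionChargeSet) -> float:
    """Ideal transition-dipole interaction of the two charge sets, cm^-1.

    Far-field reference: the point-dipole formula evaluated with the
    dipoles and centers implied by the same charges (no rescaling).
    """
    mu_a, mu_b = a.transition_dipole, b.transition_dipole
    rvec = b.center - a.center
    r = float(np.linalg.norm(rvec))
    if r == 0:
        raise ValueError("coincident charge centers")
    rhat = rvec / r
    return K_E_CM_ANG * float(mu_a @ mu_b - 3.0 * (mu_a @ rhat) * (mu_b @ rhat)) / r**3


def ensemble_couplings(
    frames: Sequence[tuple[TransitionChargeSet, TransitionChargeSet]],
    rescale: float = 3.7,
    divide: bool = True,
) -> dict:
    """Per-frame TrEsp couplings with mean and t-based 95% CI.

    Returns ``{"values", "mean", "ci95"}``; ``ci95`` is the half-width
    of the two-sided Student-t interval on the mean (0 for one frame or
    zero variance).
    """
    from scipy import stats

    if len(frames) < 1:
        raise ValueError("need at least one frame")
    values = np.array([tresp_coupling(a, b, rescale=rescale, divide=divide) for a, b in frames])
    mean = float(values.mean())
    if values.size > 1 and values.std(ddof=1) > 0:
        half = float(
            stats.t.ppf(0.975, values.size - 1) * values.std(ddof=1) / np.sqrt(values.size)
        )
    else:
        half = 0.0
    return {"values": values, "mean": mean, "ci95": half}
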