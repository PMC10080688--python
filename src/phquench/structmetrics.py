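"""Geometric observables of the carotenoid-chlorophyll quenching site.

A local right-handed frame is anchored on the chlorin ring of the
chlorophyll: origin at the Mg ion, z normal to the least-squares plane
of the four ring nitrogens, x along the in-plane projection of a
designated N-to-N direction.  Carotenoid displacement is the
mass-weighted center of the conjugated (isoprenic) chain expressed in
that frame; its in-plane scatter over an ensemble is summarized by a
covariance ellipse at a chosen coverage.  Bond-length alternation
(BLA) — mean single-bond length minus mean double-bond length along the
conjugated chain — indexes pi-delocalization of the carotenoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "ChlorinFrame",
    "ConjugatedChain",
    "build_chlorin_frame",
    "com_displacement",
    "coverage_ellipse",
    "bla",
]


@dataclass
class ChlorinFrame:
    """Orthonormal right-handed frame anchored at the chlorophyll Mg."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis, atol=1e-8):
            raise ValueError("frame must be right-handed (z = x cross y)")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express lab-frame points in this frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return pts @ np.stack([self.x_axis, self.y_axis, self.z_axis]).T


@dataclass
class ConjugatedChain:
    """Ordered atom positions of a conjugated chain plus its bond pattern.

    ``pattern`` holds one flag per bond between consecutive atoms:
    "s" (single) or "d" (double).
    """

    positions: np.ndarray
    pattern: Sequence[str]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 4:
            raise ValueError("a conjugated chain needs at least 4 atoms")
        if len(self.pattern) != self.positions.shape[0] - 1:
            raise ValueError("pattern must list one flag per bond (n_atoms - 1)")
        if set(self.pattern) - {"s", "d"}:
            raise ValueError("pattern flags must be 's' or 'd'")


def build_chlorin_frame(
    mg: np.ndarray, ring_nitrogens: np.ndarray, x_pair: tuple[int, int] = (0, 2)
) -> ChlorinFrame:
    """Frame from the Mg position and the four chlorin-ring nitrogens.

    z is the normal of the least-squares plane through the nitrogens
    (oriented to make the frame construction deterministic: positive
    component along the first-to-second N cross first-to-third N);
    x is the projection of the designated N->N direction (``x_pair``
    indices into the nitrogen order, default first to third) onto that
    plane; y completes the right-handed triad.  The origin is the Mg,
    which need not lie in the ring plane.
    """
    mg = np.asarray(mg, dtype=float)
    ns = np.atleast_2d(np.asarray(ring_nitrogens, dtype=float))
    if ns.shape != (4, 3):
        raise ValueError("need exactly 4 nitrogen positions")
    centered = ns - ns.mean(axis=0)
    # least-squares plane normal = smallest right singular vector
    _, svals, vt = np.linalg.svd(centered)
    if svals[1] < 1e-8:
        raise ValueError("nitrogens are collinear; plane undefined")
    z = vt[2]
    ref = np.cross(ns[1] - ns[0], ns[2] - ns[0])
    if np.dot(z, ref) < 0:
        z = -z
    i, j = x_pair
    direction = ns[j] - ns[i]
    x = direction - np.dot(direction, z) * z
    norm = np.linalg.norm(x)
    if norm < 1e-10:
        raise ValueError("designated N->N direction is normal to the ring plane")
    x = x / norm
    y = np.cross(z, x)
    return ChlorinFrame(origin=mg, x_axis=x, y_axis=y, z_axis=z)


def com_displacement(
    positions: np.ndarray, masses: np.ndarray, frame: ChlorinFrame
) -> tuple[float, float]:
    """In-plane (x, y) displacement of the mass-weighted centroid, angstrom."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    m = np.asarray(masses, dtype=float)
    if pos.shape[0] == 0:
        raise ValueError("empty atom set")
    if m.shape[0] != pos.shape[0] or (m <= 0).any():
        raise ValueError("need one positive mass per atom")
    com = (m @ pos) / m.sum()
    local = frame.to_local(com)[0]
    return float(local[0]), float(local[1])


def coverage_ellipse(
    points: np.ndarray, coverage: float = 0.40
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Covariance ellipse enclosing a nominal fraction of Gaussian data.

    Returns ``(center, semi_axes, orientation_rad, degenerate)``.  The
    semi-axes are sqrt(eigenvalue x q) with q the chi-square(2 dof)
    quantile at ``coverage``; orientation is the angle of the major
    axis.  A singular covariance sets the degenerate flag (the minor
    axis collapses to 0).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 two-dimensional points")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    vals, vecs = np.linalg.eigh(cov)
    degenerate = bool(vals[0] <= 1e-12 * max(vals[1], 1.0))
    q = chi2.ppf(coverage, df=2)
    semi = np.sqrt(np.clip(vals[::-1], 0, None) * q)  # major first
    major = vecs[:, 1]
    angle = float(np.arctan2(major[1], major[0]))
    return center, semi, angle, degenerate


def bla(chain: ConjugatedChain) -> float:
    """Bond-length alternation: mean single minus mean double bond, angstrom."""
    lengths = np.linalg.norm(np.diff(chain.positions, axis=0), axis=1)
    flags = np.array(chain.pattern)
    singles = lengths[flags == "s"]
    doubles = lengths[flags == "d"]
    if singles.size == 0 or doubles.size == 0:
        raise ValueError("pattern must contain at least one single and one double bond")
    return float(singles.mean() - doubles.mean())
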