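"""Conformational landscape: tICA projection, density clustering,
free-energy reweighting of boosted sampling, and representative frames.

tICA (time-lagged independent component analysis) finds the linear
combinations of input features that decorrelate slowest: with
mean-centered data X, instantaneous covariance C(0) and symmetrized
lagged covariance C(tau), the components solve the generalized
eigenproblem C(tau) v = lambda C(0) v.  The top eigenvectors span the
slow subspace onto which all trajectories are projected; clusters of
the projections (HDBSCAN, with a noise label) identify the metastable
conformations, each carrying the protonation-microstate composition of
its member frames.

Free energies over the projected space are recovered from boosted
(accelerated-MD-style) sampling by second-order cumulant reweighting:

    F(bin) = -kT [ ln p_biased(bin) + beta <dV>_bin
                   + beta^2 var(dV)_bin / 2 ] + C

which is exact when the boost dV is Gaussian within each bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import HDBSCAN

from .constants import K_B_KCAL

__all__ = [
    "FeatureMatrix",
    "TICA",
    "ClusterSet",
    "Pmf",
    "fit_tica",
    "cluster_density",
    "reweight_pmf",
    "stratified_sample",
    "representative_frame",
]


@dataclass
class FeatureMatrix:
    """Frames x features matrix with provenance for each frame.

    ``pms`` (protonation-microstate label), ``replica`` and ``time_ps``
    are optional per-frame annotations carried through clustering.
    Dihedral angles are expected to enter as sin/cos pairs so that all
    columns are aperiodic.
    """

    values: np.ndarray
    feature_names: list[str] | None = None
    pms: np.ndarray | None = None
    replica: np.ndarray | None = None
    time_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        if self.feature_names is not None and len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match column count")
        for attr in ("pms", "replica", "time_ps"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != self.values.shape[0]:
                    raise ValueError(f"{attr} must have one entry per frame")
                setattr(self, attr, v)


class TICA(BaseEstimator, TransformerMixin):
    """Time-lagged independent component analysis.

    Covariances are estimated symmetrically over the lagged frame pairs
    (t, t+lag):  C(0) = (Xl'Xl + Xr'Xr)/2m and
    C(tau) = (Xl'Xr + Xr'Xl)/2m, which makes C(tau) symmetric by
    construction and keeps eigenvalues in [-1, 1].  A small ridge,
    ``ridge * trace(C0)/n_features``, is added to C(0) because sin/cos
    feature sets are commonly near-collinear.  Eigenvectors returned by
    the generalized solver are C(0)-orthonormal, so training projections
    have unit variance per component.

    Parameters
    ----------
    lag : int
        Lag in frames.
    n_dims : int
        Components kept, by descending eigenvalue.  Default 2.
    ridge : float
        Relative ridge on C(0); default 1e-6.

    Attributes
    ----------
    means_, eigenvalues_, components_ : fitted quantities;
    ``components_`` has shape (n_features, n_dims).
    """

    def __init__(self, lag: int = 1, n_dims: int = 2, ridge: float = 1e-6):
        self.lag = lag
        self.n_dims = n_dims
        self.ridge = ridge

    def _matrix(self, X) -> tuple[np.ndarray, list[str] | None]:
        if isinstance(X, FeatureMatrix):
            return X.values, X.feature_names
        return np.atleast_2d(np.asarray(X, dtype=float)), None

    def fit(self, X, y=None):
        values, names = self._matrix(X)
        n, d = values.shape
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if n <= self.lag + d:
            raise ValueError("need more frames than lag + n_features")
        self.means_ = values.mean(axis=0)
        xc = values - self.means_
        xl, xr = xc[: n - self.lag], xc[self.lag:]
        m = n - self.lag
        c0 = (xl.T @ xl + xr.T @ xr) / (2.0 * m)
        ctau = (xl.T @ xr + xr.T @ xl) / (2.0 * m)
        reg = self.ridge * np.trace(c0) / d
        c0r = c0 + reg * np.eye(d)
        try:
            vals, vecs = eigh(ctau, c0r)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises rarely here
            raise np.linalg.LinAlgError(
                f"C(0) not positive definite even with ridge {reg:.3e}; "
                "features are exactly degenerate"
            ) from exc
        order = np.argsort(vals)[::-1]
        self.eigenvalues_ = vals[order]
        self.components_ = vecs[:, order[: self.n_dims]]
        self.feature_names_ = names
        self.c0_ = c0
        self.ctau_ = ctau
        return self

    def transform(self, X) -> np.ndarray:
        values, names = self._matrix(X)
        if names is not None and self.feature_names_ is not None and names != self.feature_names_:
            raise ValueError("feature names do not match the fitted model")
        if values.shape[1] != self.means_.size:
            raise ValueError("feature count does not match the fitted model")
        return (values - self.means_) @ self.components_


def fit_tica(X, lag: int, n_dims: int = 2, ridge: float = 1e-6) -> TICA:
    """Functional wrapper: fitted :class:`TICA` model."""
    return TICA(lag=lag, n_dims=n_dims, ridge=ridge).fit(X)


@dataclass
class ClusterSet:
    """Cluster labels per frame (-1 = noise) plus per-frame pMS provenance."""

    labels: np.ndarray
    pms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.pms is not None:
            self.pms = np.asarray(self.pms)
            if self.pms.shape[0] != self.labels.shape[0]:
                raise ValueError("pms must have one entry per frame")

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in set(self.labels.tolist()) if c != -1)

    @property
    def sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in self.cluster_ids}

    def composition(self, cluster: int) -> dict[str, float]:
        """pMS composition fractions of one cluster (sum to 1)."""
        if self.pms is None:
            raise ValueError("no pMS provenance attached")
        mask = self.labels == cluster
        if not mask.any():
            raise ValueError(f"cluster {cluster} is empty")
        vals, counts = np.unique(self.pms[mask], return_counts=True)
        total = counts.sum()
        return {str(v): float(c) / total for v, c in zip(vals, counts)}

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def cluster_density(
    projections: np.ndarray,
    min_cluster_size: int | None = None,
    min_samples: int | None = None,
    pms: Sequence[str] | None = None,
) -> ClusterSet:
    """Hierarchical density-based clustering (HDBSCAN) of the projections.

    ``min_cluster_size`` defaults to 0.5% of the frames (at least 5).
    Points in no density mode get the noise label -1; an all-noise
    result returns an empty :class:`ClusterSet` with a warning.
    """
    pts = np.atleast_2d(np.asarray(projections, dtype=float))
    n = pts.shape[0]
    if min_cluster_size is None:
        min_cluster_size = max(5, int(round(0.005 * n)))
    if n < min_cluster_size:
        raise ValueError("fewer points than min_cluster_size")
    model = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=min_samples, copy=True)
    labels = model.fit_predict(pts)
    if (labels == -1).all():
        warnings.warn("all points classified as noise; empty cluster set", stacklevel=2)
    return ClusterSet(labels=labels, pms=None if pms is None else np.asarray(pms))


@dataclass
class Pmf:
    """Binned free-energy surface, kcal/mol, minimum shifted to zero.

    ``free_energy`` is NaN on unoccupied or under-occupied bins;
    ``reliable`` marks bins with at least ``n_min`` frames.
    Works for 1-D profiles and 2-D surfaces alike.
    """

    edges: list[np.ndarray]
    free_energy: np.ndarray
    counts: np.ndarray
    reliable: np.ndarray

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


def reweight_pmf(
    projections: np.ndarray,
    boost: np.ndarray | None,
    bins: int | Sequence = 50,
    temperature: float = 300.0,
    n_min: int = 10,
) -> Pmf:
    """Second-order-cumulant reweighted free energy over binned projections.

    ``projections`` may be 1-D (a profile) or (n, d); ``boost`` is the
    per-frame bias in kcal/mol (``None`` or zeros for unbiased data, in
    which case the result is the plain histogram free energy).  Bins
    with fewer than ``n_min`` frames are marked unreliable and excluded
    from the minimum shift.
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, d = pts.shape
    if n == 0:
        raise ValueError("no samples")
    if boost is None:
        boost = np.zeros(n)
    boost = np.asarray(boost, dtype=float)
    if boost.shape != (n,):
        raise ValueError("boost must align with projections")
    kt = K_B_KCAL * temperature
    beta = 1.0 / kt

    counts, edges = np.histogramdd(pts, bins=bins)
    counts = counts.astype(int)
    # bin index of each frame
    idx = tuple(
        np.clip(np.searchsorted(edges[k], pts[:, k], side="right") - 1, 0, counts.shape[k] - 1)
        for k in range(d)
    )
    flat = np.ravel_multi_index(idx, counts.shape)
    nbins = counts.size
    cnt = np.bincount(flat, minlength=nbins).astype(float)
    s1 = np.bincount(flat, weights=boost, minlength=nbins)
    s2 = np.bincount(flat, weights=boost**2, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dv = s1 / cnt
        var_dv = s2 / cnt - mean_dv**2
        logp = np.log(cnt / cnt.sum())
        f = -kt * (logp + beta * mean_dv + 0.5 * beta**2 * np.clip(var_dv, 0, None))
    f = f.reshape(counts.shape)
    reliable = counts >= n_min
    occupied_reliable = reliable & (counts > 0)
    if not occupied_reliable.any():
        raise ValueError("no reliably occupied bins")
    f = f - f[occupied_reliable].min()
    f[~occupied_reliable] = np.nan
    return Pmf(edges=list(edges), free_energy=f, counts=counts, reliable=reliable)


def stratified_sample(
    clusters: ClusterSet, n_per_cluster: int, seed: int = 0
) -> dict[int, np.ndarray]:
    """Per-cluster random frame draws preserving pMS composition.

    Counts per pMS stratum follow largest-remainder rounding of
    composition x n; draws are uniform without replacement within each
    stratum, falling back to with-replacement (with a warning) if a
    stratum is smaller than its allocation.
    """
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    if clusters.pms is None:
        raise ValueError("stratified sampling needs pMS provenance")
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for c in clusters.cluster_ids:
        comp = clusters.composition(c)
        strata = sorted(comp)  # deterministic order
        quotas = {s: comp[s] * n_per_cluster for s in strata}
        alloc = {s: int(np.floor(quotas[s])) for s in strata}
        short = n_per_cluster - sum(alloc.values())
        by_rem = sorted(strata, key=lambda s: (-(quotas[s] - alloc[s]), s))
        for s in by_rem[:short]:
            alloc[s] += 1
        picks = []
        members = clusters.members(c)
        for s in strata:
            pool = members[clusters.pms[members] == s]
            k = alloc[s]
            if k == 0:
                continue
            if k > pool.size:
                warnings.warn(
                    f"cluster {c} stratum {s!r}: {pool.size} frames for allocation {k}; "
                    "sampling with replacement",
                    stacklevel=2,
                )
                picks.append(rng.choice(pool, size=k, replace=True))
            else:
                picks.append(rng.choice(pool, size=k, replace=False))
        out[c] = np.sort(np.concatenate(picks))
    return out


def representative_frame(clusters: ClusterSet, projections: np.ndarray) -> dict[int, int]:
    """Per cluster, the frame closest (Euclidean) to the cluster mean.

    Ties go to the lowest frame index.
    """
    pts = np.atleast_2d(np.asarray(projections, dtype=float))
    if pts.shape[0] == 1 and clusters.labels.size > 1:
        pts = np.asarray(projections, dtype=float)[:, None]
    out: dict[int, int] = {}
    for c in clusters.cluster_ids:
        members = clusters.members(c)
        sub = pts[members]
        dist = np.linalg.norm(sub - sub.mean(axis=0), axis=1)
        out[c] = int(members[np.argmin(dist)])  # argmin returns first minimum
    return out
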