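"""Protonation microstates of a residue triad and their Markov network.

Each frame of a constant-pH trajectory assigns the triad (by default
E114/E227/E233) a k-letter label over {P, D} — P for protonated, D for
deprotonated — giving 2^k protonation microstates.  A discrete Markov
model over these labels is estimated by sliding-window transition
counting at a lag, giving the transition probabilities and the state
populations that summarize the pH-dependent protonation pattern.
Pairwise coupling between sites is diagnosed from the Pearson
correlation of their windowed protonation fractions: positively
correlated sites protonate and deprotonate together, negatively
correlated sites share a proton (one protonated exactly when the other
is not).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .synthgen import ProtonationTrajectory

__all__ = [
    "MicrostateSeries",
    "MicrostateNetwork",
    "MarkovStateModel",
    "encode_microstates",
    "decode_microstates",
    "windowed_fractions",
    "correlation_coupling",
    "estimate_network",
    "dominant_states",
]


@dataclass
class MicrostateSeries:
    """Per-frame P/D labels of a fixed-order site triad (or k-ad)."""

    labels: list[str]
    site_order: list[str]
    pH: float | None = None

    def __post_init__(self) -> None:
        k = len(self.site_order)
        for lab in self.labels:
            if len(lab) != k or set(lab) - {"P", "D"}:
                raise ValueError(f"bad microstate label {lab!r} for {k} sites")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class MicrostateNetwork:
    """Row-stochastic transition matrix and populations over microstates."""

    states: list[str]
    transition_matrix: np.ndarray
    populations: np.ndarray
    counts: np.ndarray
    lag: int = 1

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        self.counts = np.asarray(self.counts)
        rows = self.transition_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if (self.populations < 0).any() or abs(self.populations.sum() - 1.0) > 1e-10:
            raise ValueError("populations must be a probability vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def stationary_distribution(self) -> np.ndarray:
        """Dominant left eigenvector of T, normalized to a probability vector."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmax(vals.real))
        pi = np.abs(vecs[:, i].real)
        return pi / pi.sum()

    def to_graph(self):
        """Directed networkx graph with population/probability attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for s, p in zip(self.states, self.populations):
            g.add_node(s, population=float(p))
        for i, si in enumerate(self.states):
            for j, sj in enumerate(self.states):
                if self.counts[i, j] > 0:
                    g.add_edge(
                        si, sj,
                        count=int(self.counts[i, j]),
                        probability=float(self.transition_matrix[i, j]),
                    )
        return g


def encode_microstates(traj: ProtonationTrajectory, triad: list[str]) -> MicrostateSeries:
    """Per-frame P/D labels of the given sites, in the given order (1 -> P)."""
    cols = np.stack([traj.column(s) for s in triad], axis=1)
    lut = np.array(["D", "P"])
    labels = ["".join(row) for row in lut[cols]]
    return MicrostateSeries(labels=labels, site_order=list(triad), pH=traj.pH)


def decode_microstates(series: MicrostateSeries) -> np.ndarray:
    """Inverse of :func:`encode_microstates`: (frames, k) binary matrix."""
    return np.array([[1 if c == "P" else 0 for c in lab] for lab in series.labels], dtype=np.uint8)


def windowed_fractions(traj: ProtonationTrajectory, site_id: str, window: int) -> np.ndarray:
    """Non-overlapping window means of a site's protonation; tail dropped."""
    if window < 1:
        raise ValueError("window must be >= 1")
    col = traj.column(site_id).astype(float)
    if window > col.size:
        raise ValueError(f"window ({window}) exceeds trajectory length ({col.size})")
    nw = col.size // window
    return col[: nw * window].reshape(nw, window).mean(axis=1)


def correlation_coupling(
    frac_a: np.ndarray, frac_b: np.ndarray, threshold: float = 0.3
) -> tuple[str, float]:
    """Classify the coupling of two windowed-fraction series by Pearson r.

    Returns ``(verdict, r)`` with verdict in {"positive", "negative",
    "undetermined"}; zero-variance input yields ("undetermined", nan).
    """
    a = np.asarray(frac_a, dtype=float)
    b = np.asarray(frac_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 windows")
    if a.std() == 0 or b.std() == 0:
        return "undetermined", float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    if r > threshold:
        return "positive", r
    if r < -threshold:
        return "negative", r
    return "undetermined", r


class MarkovStateModel(BaseEstimator):
    """Discrete Markov model over microstate labels at a fixed lag.

    Transition counts use every frame pair ``(t, t + lag)`` (sliding
    window).  States in the declared alphabet that are never visited are
    retained with a self-transition of 1 and population 0, so networks
    estimated at different pH values share a common state space.
    Populations are empirical visit frequencies (the stationary
    eigenvector is available separately on the fitted network).

    Parameters
    ----------
    lag : int
        Lag in frames; default 1.
    alphabet : list of str or None
        Full state list; inferred as {P,D}^k from the first label when
        omitted.
    symmetrize : bool
        Count each pair in both directions (detailed-balance estimate);
        off by default.
    """

    def __init__(self, lag: int = 1, alphabet: list[str] | None = None, symmetrize: bool = False):
        self.lag = lag
        self.alphabet = alphabet
        self.symmetrize = symmetrize

    def fit(self, X: MicrostateSeries | list[str], y=None):
        labels = X.labels if isinstance(X, MicrostateSeries) else list(X)
        if len(labels) == 0:
            raise ValueError("empty microstate series")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if len(labels) <= self.lag:
            raise ValueError("series must be longer than the lag")
        if self.alphabet is None:
            k = len(labels[0])
            states = ["".join(t) for t in itertools.product("PD", repeat=k)]
            states = sorted(states)
        else:
            states = list(self.alphabet)
        index = {s: i for i, s in enumerate(states)}
        seq = np.array([index[lab] for lab in labels])
        n = len(states)
        counts = np.zeros((n, n), dtype=np.int64)
        np.add.at(counts, (seq[: -self.lag], seq[self.lag:]), 1)
        if self.symmetrize:
            counts = counts + counts.T
        t = counts.astype(float)
        rowsums = t.sum(axis=1)
        visited = rowsums > 0
        t[visited] /= rowsums[visited, None]
        t[~visited] = np.eye(n)[~visited]  # unvisited: self-transition 1
        pops = np.bincount(seq, minlength=n).astype(float)
        pops /= pops.sum()
        self.states_ = states
        self.transition_matrix_ = t
        self.counts_ = counts
        self.populations_ = pops
        return self

    def network_(self) -> MicrostateNetwork:
        return MicrostateNetwork(
            states=self.states_,
            transition_matrix=self.transition_matrix_,
            populations=self.populations_,
            counts=self.counts_,
            lag=self.lag,
        )


def estimate_network(
    series: MicrostateSeries | list[str],
    lag: int = 1,
    alphabet: list[str] | None = None,
    symmetrize: bool = False,
) -> MicrostateNetwork:
    """Functional wrapper over :class:`MarkovStateModel`."""
    return MarkovStateModel(lag=lag, alphabet=alphabet, symmetrize=symmetrize).fit(series).network_()


def dominant_states(network: MicrostateNetwork, top_k: int = 3) -> list[tuple[str, float]]:
    """Microstates ranked by population, ties broken alphabetically."""
    order = sorted(zip(network.states, network.populations), key=lambda sp: (-sp[1], sp[0]))
    return [(s, float(p)) for s, p in order[:top_k]]
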