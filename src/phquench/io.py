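"""Plain-text readers and writers for the pipeline's data types.

Everything round-trips through small CSV/XYZ files so runs stay
inspectable and diff-able:

* protonation trajectories — ``frame,time_ps,<site...>`` CSV with 0/1
  entries and a ``# pH=<v> seed=<v>`` comment line;
* energy series — ``index,energy_cm1`` CSV;
* transition-charge sets — one ``atom,x,y,z,q`` CSV per pigment, or an
  XYZ file paired with an ``atom_index,q_e`` CSV;
* feature matrices — feature columns plus ``pms,replica,time_ps``
  provenance columns;
* microstate networks — node CSV ``state,population`` and edge CSV
  ``from,to,count,probability`` (optional GraphML via networkx).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import TransitionChargeSet
from .landscape import FeatureMatrix
from .microstates import MicrostateNetwork
from .synthgen import EnergySeries, ProtonationTrajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_energy_series",
    "read_energy_series",
    "write_charge_set",
    "read_charge_set",
    "read_charge_set_xyz",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_network",
    "read_network",
]

_PROVENANCE = ("pms", "replica", "time_ps")


def write_trajectory(traj: ProtonationTrajectory, path: str | Path) -> None:
    path = Path(path)
    seed = traj.seed if traj.seed is not None else -1
    header = f"# pH={traj.pH} seed={seed} dt_ps={traj.dt_ps}\n"
    frames = np.arange(traj.n_frames)
    df = pd.DataFrame(traj.states, columns=traj.sites)
    df.insert(0, "time_ps", frames * traj.dt_ps)
    df.insert(0, "frame", frames)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_trajectory(path: str | Path) -> ProtonationTrajectory:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    sites = [c for c in df.columns if c not in ("frame", "time_ps")]
    seed = int(meta.get("seed", -1))
    return ProtonationTrajectory(
        pH=float(meta.get("pH", float("nan"))),
        dt_ps=float(meta.get("dt_ps", df["time_ps"].diff().median() if "time_ps" in df else 1.0)),
        sites=sites,
        states=df[sites].to_numpy(),
        seed=None if seed < 0 else seed,
    )


def write_energy_series(series: EnergySeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# state={series.state_label} seed={series.seed if series.seed is not None else -1}\n")
        pd.DataFrame(
            {"index": np.arange(series.values.size), "energy_cm1": series.values}
        ).to_csv(fh, index=False)


def read_energy_series(path: str | Path) -> EnergySeries:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    seed = int(meta.get("seed", -1))
    return EnergySeries(
        state_label=meta.get("state", ""),
        values=df["energy_cm1"].to_numpy(),
        seed=None if seed < 0 else seed,
    )


def write_charge_set(cs: TransitionChargeSet, path: str | Path) -> None:
    """Single-file form: ``atom,x,y,z,q`` CSV with pigment/state comment."""
    with open(path, "w") as fh:
        fh.write(f"# pigment={cs.pigment_id} state={cs.state_label}\n")
        pd.DataFrame(
            {
                "atom": cs.names,
                "x": cs.positions[:, 0],
                "y": cs.positions[:, 1],
                "z": cs.positions[:, 2],
                "q": cs.charges,
            }
        ).to_csv(fh, index=False)


def read_charge_set(path: str | Path) -> TransitionChargeSet:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return TransitionChargeSet(
        pigment_id=meta.get("pigment", Path(path).stem),
        names=df["atom"].astype(str).tolist(),
        positions=df[["x", "y", "z"]].to_numpy(),
        charges=df["q"].to_numpy(),
        state_label=meta.get("state", ""),
    )


def read_charge_set_xyz(
    xyz_path: str | Path, charge_csv: str | Path, pigment_id: str = "", state_label: str = ""
) -> TransitionChargeSet:
    """XYZ coordinates plus an ``atom_index,q_e`` CSV in matching order."""
    lines = Path(xyz_path).read_text().splitlines()
    n = int(lines[0].split()[0])
    rows = [ln.split() for ln in lines[2 : 2 + n]]
    names = [r[0] for r in rows]
    pos = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    qdf = pd.read_csv(charge_csv).sort_values("atom_index")
    if len(qdf) != n:
        raise ValueError("charge CSV and XYZ atom counts differ")
    return TransitionChargeSet(
        pigment_id=pigment_id or Path(xyz_path).stem,
        names=names,
        positions=pos,
        charges=qdf["q_e"].to_numpy(),
        state_label=state_label,
    )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    names = fm.feature_names or [f"f{i}" for i in range(fm.values.shape[1])]
    df = pd.DataFrame(fm.values, columns=names)
    for col in _PROVENANCE:
        v = getattr(fm, col)
        if v is not None:
            df[col] = v
    df.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    prov = {c: df[c].to_numpy() for c in _PROVENANCE if c in df.columns}
    feat = [c for c in df.columns if c not in _PROVENANCE]
    return FeatureMatrix(
        values=df[feat].to_numpy(dtype=float),
        feature_names=feat,
        pms=prov.get("pms"),
        replica=prov.get("replica"),
        time_ps=prov.get("time_ps"),
    )


def write_network(net: MicrostateNetwork, out_dir: str | Path, graphml: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"state": net.states, "population": net.populations}).to_csv(
        out / "nodes.csv", index=False
    )
    rows = []
    for i, si in enumerate(net.states):
        for j, sj in enumerate(net.states):
            if net.counts[i, j] > 0:
                rows.append(
                    {
                        "from": si,
                        "to": sj,
                        "count": int(net.counts[i, j]),
                        "probability": net.transition_matrix[i, j],
                    }
                )
    pd.DataFrame(rows, columns=["from", "to", "count", "probability"]).to_csv(
        out / "edges.csv", index=False
    )
    if graphml:
        import networkx as nx

        nx.write_graphml(net.to_graph(), out / "network.graphml")


def read_network(out_dir: str | Path, lag: int = 1) -> MicrostateNetwork:
    out = Path(out_dir)
    nodes = pd.read_csv(out / "nodes.csv")
    edges = pd.read_csv(out / "edges.csv")
    states = nodes["state"].astype(str).tolist()
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    counts = np.zeros((n, n), dtype=np.int64)
    for _, row in edges.iterrows():
        counts[index[str(row["from"])], index[str(row["to"])]] = int(row["count"])
    t = counts.astype(float)
    rowsums = t.sum(axis=1)
    visited = rowsums > 0
    t[visited] /= rowsums[visited, None]
    t[~visited] = np.eye(n)[~visited]
    return MicrostateNetwork(
        states=states,
        transition_matrix=t,
        populations=nodes["population"].to_numpy(),
        counts=counts,
        lag=lag,
    )
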