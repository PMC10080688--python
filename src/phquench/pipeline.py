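"""End-to-end orchestration of the synthetic pH-quenching pipeline.

``run_all`` executes the stages in dependency order on fully synthetic
inputs — titration (constant-pH emulation, Hill fits, sensor calls),
microstate Markov networks, conformational landscape (tICA + density
clustering + boost reweighting), quenching-site geometry, TrEsp
couplings, and Marcus/lifetime energetics — writing plain-text outputs
plus a JSON summary into a run directory.  All randomness derives from
one master seed through a fixed splitting rule, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import coupling as cpl
from . import energetics as en
from . import io as pio
from . import landscape as ls
from . import microstates as ms
from . import structmetrics as sm
from . import synthgen as sg
from . import titration as ti

__all__ = ["ConfigError", "demo_config", "validate_config", "stage_seed", "run_all"]

_STAGES = (
    "synthgen",
    "titration",
    "microstates",
    "landscape",
    "structmetrics",
    "coupling",
    "energetics",
)


class ConfigError(ValueError):
    """Raised before any compute when a run config fails validation."""


def demo_config(seed: int = 1) -> dict[str, Any]:
    """The default fully synthetic study configuration.

    Emulates six constant-pH ensembles (pH 3..8, two replicas of 600
    frames each) of a coupled acidic triad plus two independently
    titrating controls, a three-microstate conformational landscape
    with a known boost, and cluster-level LE/CT energetics seeded from
    the published cluster observables.
    """
    return {
        "seed": int(seed),
        "temperature": 300.0,
        "titration": {
            "ph_values": [3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "n_frames": 600,
            "n_replicas": 2,
            "block_frames": 30,
            "n_boot": 500,
            "sites": [
                {"site_id": "E114", "residue_class": "GLU", "pka_int": 4.5,
                 "couplings": {"E227": 3.0, "E233": 3.0}},
                {"site_id": "E227", "residue_class": "GLU", "pka_int": 4.2, "couplings": {}},
                {"site_id": "E233", "residue_class": "GLU", "pka_int": 6.3, "couplings": {}},
                {"site_id": "D118", "residue_class": "ASP", "pka_int": 4.7, "couplings": {}},
                {"site_id": "E232", "residue_class": "GLU", "pka_int": 4.5, "couplings": {}},
            ],
            "triad": ["E114", "E227", "E233"],
        },
        "microstates": {"lag": 10, "window": 30},
        "landscape": {
            "n_frames_per_pms": 1500,
            "pms_groups": ["PPD", "PDP", "DPP"],
            "lag": 10,
            "n_dims": 2,
            "min_cluster_frac": 0.02,
            "n_per_cluster": 30,
            "pmf_bins": 40,
            "boost_mean_kcal": 2.0,
            "boost_sd_kcal": 0.5,
        },
        "coupling": {"n_frames": 200, "rescale": 3.7, "separations": {"CL_low_pH": 5.4, "CL_high_pH": 6.0}},
        "energetics": {
            "n_samples": 30,
            "clusters": {
                "CL2": {"e_le": 15582.0, "e_ct": 20656.0, "sd_le": 683.0, "sd_ct": 873.0, "v": 292.0},
                "CL5": {"e_le": 15689.0, "e_ct": 20887.0, "sd_le": 517.0, "sd_ct": 1240.0, "v": 199.0},
            },
            # (lambda, dG) in cm^-1 per named set; the CT reorganization
            # energy dominates the spread between literature estimates
            "lambda_sets": {
                "LHCII_like": [2500.0, 1560.0],
                "CP29_like": [3000.0, 1040.0],
            },
        },
    }


def validate_config(config: dict[str, Any]) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in config or not isinstance(config["seed"], int):
        raise ConfigError("config requires an explicit integer 'seed'")
    for section in ("titration", "microstates", "landscape", "coupling", "energetics"):
        if section not in config:
            raise ConfigError(f"config missing section {section!r}")
    tit = config["titration"]
    for key in ("ph_values", "n_frames", "sites", "triad", "n_boot", "block_frames"):
        if key not in tit:
            raise ConfigError(f"titration section missing {key!r}")
    declared = {s["site_id"] for s in tit["sites"]}
    if not set(tit["triad"]) <= declared:
        raise ConfigError("triad references undeclared sites")


def config_hash(config: dict[str, Any]) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed split from the master seed."""
    k = _STAGES.index(stage)
    return int(np.random.SeedSequence((master_seed, k)).generate_state(1)[0] % 2**31)


def _site_models(site_specs: list[dict]) -> list[sg.SiteModel]:
    return [
        sg.SiteModel(
            site_id=s["site_id"],
            residue_class=s["residue_class"],
            pka_int=s["pka_int"],
            couplings=dict(s.get("couplings", {})),
        )
        for s in site_specs
    ]


def _landscape_fixture(cfg: dict, seed: int):
    """AR(1) dynamics around pMS-specific centers in a 5-feature space.

    Two features are slow (long correlation time, pMS-dependent means);
    three are fast noise — so the slow subspace is known by
    construction.
    """
    rng = np.random.default_rng(seed)
    groups = cfg["pms_groups"]
    n = cfg["n_frames_per_pms"]
    centers = {g: rng.normal(0.0, 4.0, size=2) for g in groups}
    blocks, pms = [], []
    for g in groups:
        slow = np.empty((n, 2))
        phi, noise = 0.98, 0.25
        slow[0] = centers[g]
        eps = rng.normal(0.0, noise, size=(n, 2))
        for t in range(1, n):
            slow[t] = centers[g] + phi * (slow[t - 1] - centers[g]) + eps[t]
        fast = rng.normal(0.0, 1.0, size=(n, 3))
        blocks.append(np.hstack([slow, fast]))
        pms.extend([g] * n)
    values = np.vstack(blocks)
    names = ["d_helixAB", "d_helixD_E233", "x_fast1", "x_fast2", "x_fast3"]
    boost = np.clip(
        rng.normal(cfg["boost_mean_kcal"], cfg["boost_sd_kcal"], size=values.shape[0]), 0.0, None
    )
    return ls.FeatureMatrix(values=values, feature_names=names, pms=np.array(pms)), boost


def _geometry_fixture(cluster_ids, seed: int):
    """Toy quenching-site geometries: chlorin frame + per-cluster chains."""
    rng = np.random.default_rng(seed)
    nitrogens = np.array([[2.0, 0, 0], [0, 2.0, 0], [-2.0, 0, 0], [0, -2.0, 0]])
    frame = sm.build_chlorin_frame(np.zeros(3), nitrogens)
    out = {}
    for k, c in enumerate(cluster_ids):
        # conjugated chain of 11 atoms along y, displaced along x per cluster
        base_x = 3.0 + 1.5 * k
        ys = np.linspace(-6.0, 6.0, 11)
        bond = np.tile([1.42, 1.36], 6)[:10]
        ys = np.concatenate([[0.0], np.cumsum(bond)])
        ys -= ys.mean()
        n_frames = 40
        disp, blas = [], []
        for _ in range(n_frames):
            jitter = rng.normal(0.0, 0.15, size=(11, 3))
            chain = np.stack([np.full(11, base_x), ys, np.zeros(11)], axis=1) + jitter
            masses = np.full(11, 12.011)
            disp.append(sm.com_displacement(chain, masses, frame))
            blas.append(sm.bla(sm.ConjugatedChain(chain, ["s", "d"] * 5)))
        out[c] = {"displacements": np.array(disp), "bla": np.array(blas)}
    return frame, out


def run_all(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run every stage; returns the summary dict (also written as JSON)."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config["seed"]
    chash = config_hash(config)
    temperature = float(config.get("temperature", 300.0))
    summary: dict[str, Any] = {"config_hash": chash, "seed": master}

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        (d / "meta.json").write_text(
            json.dumps({"config_hash": chash, "seed": stage_seed(master, name)}, sort_keys=True)
        )
        return d

    # --- synthgen + titration -------------------------------------------
    tcfg = config["titration"]
    models = _site_models(tcfg["sites"])
    seed0 = stage_seed(master, "synthgen")
    d_syn = stage_dir("synthgen")
    trajs: dict[float, list[sg.ProtonationTrajectory]] = {}
    for i, ph in enumerate(tcfg["ph_values"]):
        reps = []
        for r in range(tcfg.get("n_replicas", 1)):
            t = sg.simulate_coupled_titration(
                models, ph, tcfg["n_frames"], seed=seed0 + 100 * i + r
            )
            pio.write_trajectory(t, d_syn / f"traj_pH{ph:g}_rep{r}.csv")
            reps.append(t)
        trajs[ph] = reps

    d_tit = stage_dir("titration")
    tseed = stage_seed(master, "titration")
    fits = {}
    rows = []
    for m in models:
        fit = ti.blocked_bootstrap_pka(
            trajs, m.site_id, block_length=tcfg["block_frames"],
            n_boot=tcfg["n_boot"], seed=tseed,
        )
        verdict = ti.classify_sensor(fit, m.residue_class)
        fits[m.site_id] = fit
        rows.append(
            {
                "site": m.site_id,
                "residue_class": m.residue_class,
                "pka": fit.pka,
                "pka_err": fit.pka_err,
                "n_hill": fit.n_hill,
                "n_err": fit.n_err,
                "converged": fit.converged,
                "classification": verdict,
            }
        )
        curve = ti.build_curve(trajs, m.site_id)
        pd.DataFrame(
            {"pH": curve.ph_values, "fraction": curve.fractions, "n_frames": curve.n_frames}
        ).to_csv(d_tit / f"curve_{m.site_id}.csv", index=False)
    fits_df = pd.DataFrame(rows)
    fits_df.to_csv(d_tit / "fits.csv", index=False)
    summary["titration"] = {
        r["site"]: {"pka": None if not r["converged"] else round(r["pka"], 3),
                    "classification": r["classification"]}
        for r in rows
    }

    # --- microstates -----------------------------------------------------
    mcfg = config["microstates"]
    d_ms = stage_dir("microstates")
    triad = tcfg["triad"]
    dominant = {}
    for ph, reps in trajs.items():
        labels: list[str] = []
        for t in reps:
            series = ms.encode_microstates(t, triad)
            labels.extend(series.labels)
        merged = ms.MicrostateSeries(labels=labels, site_order=triad, pH=ph)
        net = ms.estimate_network(merged, lag=mcfg["lag"])
        pio.write_network(net, d_ms / f"net_pH{ph:g}")
        dominant[f"{ph:g}"] = [s for s, _ in ms.dominant_states(net, top_k=3)]
    summary["microstates"] = {"dominant_per_pH": dominant}

    # --- landscape -------------------------------------------------------
    lcfg = config["landscape"]
    d_ls = stage_dir("landscape")
    lseed = stage_seed(master, "landscape")
    fm, boost = _landscape_fixture(lcfg, lseed)
    pio.write_feature_matrix(fm, d_ls / "features.csv")
    tica = ls.fit_tica(fm, lag=lcfg["lag"], n_dims=lcfg["n_dims"])
    proj = tica.transform(fm)
    mcs = max(5, int(round(lcfg["min_cluster_frac"] * proj.shape[0])))
    clusters = ls.cluster_density(proj, min_cluster_size=mcs, pms=fm.pms)
    pd.DataFrame({"frame": np.arange(proj.shape[0]), "label": clusters.labels}).to_csv(
        d_ls / "labels.csv", index=False
    )
    pd.DataFrame(proj, columns=[f"tic{i+1}" for i in range(proj.shape[1])]).to_csv(
        d_ls / "projections.csv", index=False
    )
    pmf = ls.reweight_pmf(proj, boost, bins=lcfg["pmf_bins"], temperature=temperature)
    np.savetxt(d_ls / "pmf.csv", np.nan_to_num(pmf.free_energy, nan=-1.0), delimiter=",")
    picks = ls.stratified_sample(clusters, lcfg["n_per_cluster"], seed=lseed + 1)
    reps_frames = ls.representative_frame(clusters, proj)
    pd.DataFrame(
        [{"cluster": c, "representative_frame": f} for c, f in sorted(reps_frames.items())]
    ).to_csv(d_ls / "representatives.csv", index=False)
    summary["landscape"] = {
        "n_clusters": len(clusters.cluster_ids),
        "cluster_sizes": {str(c): s for c, s in clusters.sizes.items()},
        "composition": {str(c): clusters.composition(c) for c in clusters.cluster_ids},
        "samples_per_cluster": {str(c): len(v) for c, v in picks.items()},
    }

    # --- structmetrics ---------------------------------------------------
    d_sm = stage_dir("structmetrics")
    sseed = stage_seed(master, "structmetrics")
    cluster_names = sorted(config["coupling"]["separations"])
    frame, geo = _geometry_fixture(cluster_names, sseed)
    geo_rows = []
    for c, data in geo.items():
        center, semi, angle, _ = sm.coverage_ellipse(data["displacements"], coverage=0.40)
        geo_rows.append(
            {
                "cluster": c,
                "com_x": data["displacements"][:, 0].mean(),
                "com_y": data["displacements"][:, 1].mean(),
                "ellipse_major_A": semi[0],
                "ellipse_minor_A": semi[1],
                "ellipse_angle_rad": angle,
                "bla_A": data["bla"].mean(),
            }
        )
    pd.DataFrame(geo_rows).to_csv(d_sm / "geometry.csv", index=False)
    summary["structmetrics"] = {
        r["cluster"]: {"com_x": round(r["com_x"], 3), "bla_A": round(r["bla_A"], 4)}
        for r in geo_rows
    }

    # --- coupling --------------------------------------------------------
    ccfg = config["coupling"]
    d_cp = stage_dir("coupling")
    cseed = stage_seed(master, "coupling")
    rng = np.random.default_rng(cseed)
    pattern = [("C1", (0.0, 0.8, 0.0), 0.35), ("C2", (0.0, -0.8, 0.0), -0.35)]
    coupling_rows = []
    vbar = {}
    for c, sep in sorted(ccfg["separations"].items()):
        frames = []
        for _ in range(ccfg["n_frames"]):
            jitter = float(rng.normal(0.0, 0.15))
            frames.append(sg.make_toy_pigment_pair(sep + jitter, charge_pattern=pattern))
        res = cpl.ensemble_couplings(frames, rescale=ccfg["rescale"])
        vbar[c] = res["mean"]
        coupling_rows.append(
            {"cluster": c, "V_mean_cm1": res["mean"], "V_ci95_cm1": res["ci95"],
             "n_frames": ccfg["n_frames"], "rescale": ccfg["rescale"], "convention": "divide"}
        )
    pd.DataFrame(coupling_rows).to_csv(d_cp / "couplings.csv", index=False)
    summary["coupling"] = {c: round(v, 2) for c, v in vbar.items()}

    # --- energetics ------------------------------------------------------
    ecfg = config["energetics"]
    d_en = stage_dir("energetics")
    eseed = stage_seed(master, "energetics")
    lam_sets = {k: (float(v[0]), float(v[1])) for k, v in ecfg["lambda_sets"].items()}
    couplings = {}
    marcus_rows = []
    for i, (c, pars) in enumerate(sorted(ecfg["clusters"].items())):
        le = sg.simulate_energy_series(
            pars["e_le"], pars["sd_le"], ecfg["n_samples"], seed=eseed + 2 * i, state_label="LE"
        )
        ct = sg.simulate_energy_series(
            pars["e_ct"], pars["sd_ct"], ecfg["n_samples"], seed=eseed + 2 * i + 1, state_label="CT"
        )
        pio.write_energy_series(le, d_en / f"E_LE_{c}.csv")
        pio.write_energy_series(ct, d_en / f"E_CT_{c}.csv")
        mp = en.linear_response(le, ct, temperature=temperature)
        couplings[c] = float(pars["v"])
        marcus_rows.append(
            {"cluster": c, "E_LE": mp.e_le_mean, "E_CT": mp.e_ct_mean, "gap": mp.e_ct_mean - mp.e_le_mean,
             "lambda_LE": mp.lambda_le, "lambda_CT": mp.lambda_ct, "lambda_eff": mp.lambda_eff,
             "dG": mp.delta_g}
        )
    pd.DataFrame(marcus_rows).to_csv(d_en / "linear_response.csv", index=False)
    # data-derived effective set: mean lambda_eff and dG across clusters
    lam_eff = float(np.mean([r["lambda_eff"] for r in marcus_rows]))
    dg_eff = float(np.mean([r["dG"] for r in marcus_rows]))
    lam_sets = {"effective": (lam_eff, dg_eff), **lam_sets}
    table = en.rate_table(couplings, lam_sets, temperature=temperature)
    table.to_csv(d_en / "rates.csv", index=False)
    summary["energetics"] = {
        "gaps_cm1": {r["cluster"]: round(r["gap"], 1) for r in marcus_rows},
        "rate_table_rows": len(table),
        "kcs_1e9_per_s": {
            f"{row.cluster}/{row.set}": round(row.kcs_per_s / 1e9, 3) for row in table.itertuples()
        },
        "tau_ps": {f"{row.cluster}/{row.set}": round(row.tau_ps, 1) for row in table.itertuples()},
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
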