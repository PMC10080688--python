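"""Marcus charge-separation energetics and the excitation-lifetime model.

Driving forces and reorganization energies come from the fluctuations of
the vertical energies of the locally excited (LE) and charge-transfer
(CT) states in the linear-response approximation:

    lambda_X = sigma_X^2 / (2 k_B T),     G_X = <E_X> - lambda_X,
    dG = G_CT - G_LE,
    lambda_eff = var(E_CT - E_LE) / (2 k_B T)   (paired samples)

The nonadiabatic high-temperature Marcus rate for LE -> CT charge
separation is

    k_cs = (2 pi / hbar) V^2 (4 pi lambda k_B T)^(-1/2)
           exp(-(dG + lambda)^2 / (4 lambda k_B T))

with everything in cm^-1 (hbar = 5.3088e-12 cm^-1 s makes the rate come
out in s^-1).  The complex-level excitation lifetime uses a
coarse-grained scheme: one excited manifold (the quenching chlorophyll
in fast equilibrium with the pool, carrying weight p_quencher on the
quencher) feeding a CT state that recombines to the ground state, with
intrinsic chlorophyll decay in parallel.  The mean lifetime is the time
integral of the total survival probability, available in closed form
from the 2x2 rate matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import HBAR_CM_S, K_B_CM, T_DEFAULT
from .synthgen import EnergySeries

__all__ = [
    "MarcusParameters",
    "KineticScheme",
    "TABLE_REFERENCE",
    "linear_response",
    "marcus_rate",
    "back_rate",
    "excitation_lifetime",
    "rate_table",
]

#: Published cluster-level observables used as pipeline inputs when real
#: QM/MM ensembles are unavailable: mean vertical energies with 95% CI
#: half-widths (cm^-1, 30 samples per cluster) and LE-CT couplings
#: (cm^-1) for the low-pH (CL2) and high-pH (CL5) conformational
#: clusters of the L1 lutein / Chl a612 pair.
TABLE_REFERENCE = {
    "CL2": {"E_LE": 15582.0, "E_LE_ci": 255.0, "E_CT": 20656.0, "E_CT_ci": 326.0,
            "V": 292.0, "V_ci": 61.0, "n_samples": 30},
    "CL5": {"E_LE": 15689.0, "E_LE_ci": 193.0, "E_CT": 20887.0, "E_CT_ci": 463.0,
            "V": 199.0, "V_ci": 46.0, "n_samples": 30},
}


@dataclass
class MarcusParameters:
    """Linear-response energetics of the LE/CT pair (cm^-1, cm^-2)."""

    e_le_mean: float
    e_ct_mean: float
    sigma2_le: float
    sigma2_ct: float
    lambda_le: float
    lambda_ct: float
    g_le: float
    g_ct: float
    delta_g: float
    temperature: float
    sigma2_gap: float = float("nan")
    lambda_eff: float = float("nan")

    def __post_init__(self) -> None:
        for lam in (self.lambda_le, self.lambda_ct):
            if lam < 0:
                raise ValueError("reorganization energies must be nonnegative")
        if abs(self.delta_g - (self.g_ct - self.g_le)) > 1e-6:
            raise ValueError("delta_g must equal g_ct - g_le")


@dataclass
class KineticScheme:
    """Rates of the coarse-grained quenching scheme (all s^-1).

    ``p_quencher`` is the equilibrium excited-state weight on the
    quenching chlorophyll (1/8 for equal partition over an
    eight-chlorophyll pool); the initial excitation is likewise equally
    partitioned, i.e. fully in the excited manifold.
    """

    k_cs: float
    k_back: float = 0.0
    k_rec: float = 1.0e11          # CT recombination, (10 ps)^-1
    k_intr: float = 0.25e9         # intrinsic Chl decay, (4 ns)^-1
    n_pool: int = 8
    p_quencher: float | None = None

    def __post_init__(self) -> None:
        if self.p_quencher is None:
            self.p_quencher = 1.0 / self.n_pool
        for r in (self.k_cs, self.k_back, self.k_rec, self.k_intr):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.p_quencher <= 1.0:
            raise ValueError("p_quencher must lie in [0, 1]")


def linear_response(
    series_le: EnergySeries,
    series_ct: EnergySeries,
    temperature: float = T_DEFAULT,
    paired: bool = True,
) -> MarcusParameters:
    """Linear-response free energies and reorganization energies.

    With ``paired=True`` (default) the two series must be sampled on the
    same frames; the effective reorganization energy is then computed
    from the variance of the CT-LE gap.  Unpaired input with
    ``paired=True`` is a data error; with ``paired=False`` gap
    statistics are reported as NaN.
    """
    kbt = K_B_CM * temperature
    e_le, e_ct = series_le.values, series_ct.values
    s2_le = float(np.var(e_le, ddof=1))
    s2_ct = float(np.var(e_ct, ddof=1))
    lam_le = s2_le / (2 * kbt)
    lam_ct = s2_ct / (2 * kbt)
    g_le = float(e_le.mean()) - lam_le
    g_ct = float(e_ct.mean()) - lam_ct
    s2_gap = lam_eff = float("nan")
    if paired:
        if e_le.size != e_ct.size:
            raise ValueError("paired gap statistics need equal-length series")
        s2_gap = float(np.var(e_ct - e_le, ddof=1))
        lam_eff = s2_gap / (2 * kbt)
    return MarcusParameters(
        e_le_mean=float(e_le.mean()),
        e_ct_mean=float(e_ct.mean()),
        sigma2_le=s2_le,
        sigma2_ct=s2_ct,
        lambda_le=lam_le,
        lambda_ct=lam_ct,
        g_le=g_le,
        g_ct=g_ct,
        delta_g=g_ct - g_le,
        temperature=temperature,
        sigma2_gap=s2_gap,
        lambda_eff=lam_eff,
    )


def marcus_rate(
    v: float, delta_g: float, lam: float, temperature: float = T_DEFAULT
) -> float:
    """Nonadiabatic Marcus charge-separation rate, s^-1.

    ``v``, ``delta_g`` and ``lam`` in cm^-1.
    """
    if lam <= 0:
        raise ValueError("reorganization energy must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kbt = K_B_CM * temperature
    pref = (2.0 * math.pi / HBAR_CM_S) * v**2 / math.sqrt(4.0 * math.pi * lam * kbt)
    return pref * math.exp(-((delta_g + lam) ** 2) / (4.0 * lam * kbt))


def back_rate(k_cs: float, delta_g: float, temperature: float = T_DEFAULT) -> float:
    """Detailed-balance reverse rate of the LE -> CT step, s^-1.

    k_back = k_cs exp(dG / k_B T) with dG = G_CT - G_LE: an uphill
    forward step implies k_back > k_cs.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return k_cs * math.exp(delta_g / (K_B_CM * temperature))


def excitation_lifetime(scheme: KineticScheme) -> float:
    """Mean excitation lifetime of the complex, ps (closed form).

    Integrates the total survival probability of the two-state master
    equation {excited manifold, CT} starting from a fully excited
    manifold:

        tau = (k_back + k_rec + p k_cs)
              / ((k_intr + p k_cs)(k_back + k_rec) - k_back p k_cs)
    """
    p = scheme.p_quencher
    a = scheme.k_intr + p * scheme.k_cs          # excited-manifold total loss
    b = scheme.k_back
    c = p * scheme.k_cs
    d = scheme.k_back + scheme.k_rec
    det = a * d - b * c
    if det <= 0:
        raise ZeroDivisionError("no decay channel: survival integral diverges")
    return 1e12 * (d + c) / det


def survival_trace(scheme: KineticScheme, t_ps: np.ndarray) -> np.ndarray:
    """Total survival probability at the given times (ps); for checks/plots."""
    m = np.array(
        [
            [-(scheme.k_intr + scheme.p_quencher * scheme.k_cs), scheme.k_back],
            [scheme.p_quencher * scheme.k_cs, -(scheme.k_back + scheme.k_rec)],
        ]
    )
    x0 = np.array([1.0, 0.0])
    vals, vecs = np.linalg.eig(m)
    coef = np.linalg.solve(vecs, x0)
    t_s = np.asarray(t_ps, dtype=float) * 1e-12
    traj = (vecs @ (coef[:, None] * np.exp(vals[:, None] * t_s[None, :]))).real
    return traj.sum(axis=0)


def rate_table(
    couplings: dict[str, float],
    lambda_sets: dict[str, tuple[float, float]],
    temperature: float = T_DEFAULT,
    scheme: KineticScheme | None = None,
    reversible: bool = True,
) -> pd.DataFrame:
    """Marcus rates and lifetimes for every cluster x parameter set.

    ``couplings`` maps cluster label to V (cm^-1); ``lambda_sets`` maps
    a set name to (lambda, dG), both cm^-1.  ``scheme`` provides the
    non-Marcus rates (defaults: (10 ps)^-1 recombination, (4 ns)^-1
    intrinsic decay, 8-chlorophyll pool); ``reversible`` switches the
    detailed-balance back rate on (default) or off.
    """
    base = scheme if scheme is not None else KineticScheme(k_cs=0.0)
    rows = []
    for cluster, v in couplings.items():
        for set_name, (lam, dg) in lambda_sets.items():
            k = marcus_rate(v, dg, lam, temperature)
            kb = back_rate(k, dg, temperature) if reversible else 0.0
            sch = replace(base, k_cs=k, k_back=kb)
            rows.append(
                {
                    "cluster": cluster,
                    "set": set_name,
                    "V_cm1": v,
                    "lambda_cm1": lam,
                    "dG_cm1": dg,
                    "kcs_per_s": k,
                    "tau_ps": excitation_lifetime(sch),
                }
            )
    return pd.DataFrame(rows)
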