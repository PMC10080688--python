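"""Hill fits, blocked-bootstrap errors and sensor classification."""

import numpy as np
import pytest

from phquench.synthgen import ProtonationTrajectory, SiteModel, exact_titration, simulate_coupled_titration
from phquench.titration import (
    HillFit,
    TitrationCurve,
    blocked_bootstrap_pka,
    build_curve,
    classify_sensor,
    fit_hill,
    protonation_fraction,
)


def _traj(column, site="S", ph=5.0):
    states = np.asarray(column, dtype=np.uint8)[:, None]
    return ProtonationTrajectory(pH=ph, dt_ps=1.0, sites=[site], states=states)


def _hill_curve(pka, n, phs):
    phs = np.asarray(phs, dtype=float)
    return TitrationCurve("S", phs, 1.0 / (1.0 + 10.0 ** (n * (phs - pka))))


class TestProtonationFraction:
    def test_all_ones(self):
        assert protonation_fraction(_traj(np.ones(10)), "S") == 1.0

    def test_alternating(self):
        assert protonation_fraction(_traj([0, 1] * 5), "S") == 0.5

    def test_unknown_site(self):
        with pytest.raises(KeyError):
            protonation_fraction(_traj(np.ones(4)), "E999")

    def test_matches_exact_oracle_at_midpoint(self, single_site):
        traj = simulate_coupled_titration(single_site, 5.0, 30_000, seed=5)
        target = exact_titration(single_site, 5.0)["E1"]
        assert protonation_fraction(traj, "E1") == pytest.approx(target, abs=0.02)


class TestHillFit:
    def test_noiseless_self_consistency(self):
        """Exact Hill points are recovered to 1e-6 in both parameters."""
        fit = fit_hill(_hill_curve(5.4, 1.0, np.arange(3.0, 8.5)))
        assert fit.converged
        assert fit.pka == pytest.approx(5.4, abs=1e-6)
        assert fit.n_hill == pytest.approx(1.0, abs=1e-6)

    def test_flat_curve_not_converged(self):
        curve = TitrationCurve("S", np.arange(3.0, 9.0), np.full(6, 0.5))
        assert not fit_hill(curve).converged

    def test_oracle_curve_recovery(self):
        """Hill fit of the enumeration oracle recovers the intrinsic pKa."""
        model = [SiteModel("E227", pka_int=5.7)]
        phs = np.arange(3.0, 9.0)
        fracs = [exact_titration(model, ph)["E227"] for ph in phs]
        fit = fit_hill(TitrationCurve("E227", phs, fracs))
        assert fit.pka == pytest.approx(5.7, abs=1e-4)

    def test_nonmonotonic_curve_flagged(self):
        """An up-and-down curve beyond noise is marked not converged."""
        phs = np.arange(3.0, 9.0)
        f = np.array([0.9, 0.55, 0.75, 0.6, 0.2, 0.05])
        fit = fit_hill(TitrationCurve("E114", phs, f, errors=np.full(6, 0.01)))
        assert not fit.converged

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 usable"):
            fit_hill(TitrationCurve("S", [4.0, 5.0], [0.8, 0.2]))

    def test_hill_curve_is_decreasing_for_positive_n(self):
        phs = np.linspace(0, 14, 200)
        f = 1.0 / (1.0 + 10.0 ** (2.3 * (phs - 6.0)))
        assert np.all(np.diff(f) < 0)

    def test_parameter_recovery_under_sampling_noise(self, single_site):
        """Median |pKa_hat - 5.0| over seeds of 6-pH, 600-frame data is small."""
        errs = []
        for seed in range(20):
            trajs = {
                ph: simulate_coupled_titration(single_site, ph, 600, seed=seed * 10 + int(ph))
                for ph in np.arange(3.0, 9.0)
            }
            fit = fit_hill(build_curve(trajs, "E1"))
            if fit.converged:
                errs.append(abs(fit.pka - 5.0))
        assert np.median(errs) < 0.15


class TestBlockedBootstrap:
    def _constant_trajs(self):
        return {
            ph: _traj(np.full(200, 1 if ph < 5 else 0), site="S", ph=ph)
            for ph in [3.0, 4.0, 5.0, 6.0, 7.0]
        }

    def test_zero_variance_gives_zero_errors(self):
        trajs = {
            ph: _traj((np.random.default_rng(0).random(400) < f).astype(int) * 0
                      + (1 if f > 0.5 else 0), site="S", ph=ph)
            for ph, f in zip([3.0, 4.0, 5.0, 6.0, 7.0, 8.0], [1, 1, 1, 0, 0, 0])
        }
        fit = blocked_bootstrap_pka(trajs, "S", block_length=10, n_boot=50, seed=0)
        assert fit.pka_err == 0.0 and fit.n_err == 0.0

    def test_iid_frames_insensitive_to_block_length(self, single_site):
        """Without autocorrelation, block length must not matter much."""
        rng = np.random.default_rng(42)
        trajs = {
            ph: _traj(
                (rng.random(2000) < 1 / (1 + 10 ** (ph - 5.0))).astype(int), site="E1", ph=ph
            )
            for ph in np.arange(3.0, 9.0)
        }
        e1 = blocked_bootstrap_pka(trajs, "E1", 1, n_boot=300, seed=1).pka_err
        e10 = blocked_bootstrap_pka(trajs, "E1", 10, n_boot=300, seed=2).pka_err
        assert e10 == pytest.approx(e1, rel=0.25)

    @staticmethod
    def _sticky_trajs(seed, n=3000, decorrelation=0.05):
        """Occupancy with positive autocorrelation (sticky 2-state chain).

        Stay probability 1 - decorrelation*(...) gives lag-1
        autocorrelation 1 - decorrelation, i.e. correlation time ~ 20
        frames at the default.
        """
        rng = np.random.default_rng(seed)
        out = {}
        for ph in np.arange(3.0, 9.0):
            p = 1.0 / (1.0 + 10.0 ** (ph - 5.0))
            a, b = decorrelation * (1 - p), decorrelation * p  # 1->0, 0->1 rates
            col = np.empty(n, dtype=int)
            col[0] = rng.random() < p
            u = rng.random(n)
            for t in range(1, n):
                flip = u[t] < (a if col[t - 1] else b)
                col[t] = 1 - col[t - 1] if flip else col[t - 1]
            out[ph] = _traj(col, site="E1", ph=ph)
        return out

    def test_correlated_frames_need_blocking(self):
        """On positively autocorrelated occupancy, long blocks give larger,
        honest errors; 1-frame blocks underestimate them."""
        trajs = self._sticky_trajs(seed=500)
        e_short = blocked_bootstrap_pka(trajs, "E1", 1, n_boot=200, seed=3).pka_err
        e_long = blocked_bootstrap_pka(trajs, "E1", 300, n_boot=200, seed=4).pka_err
        assert e_long > 2.0 * e_short
        # honest: the blocked 2x SE should bracket the seed-to-seed spread
        point_pkas = [
            fit_hill(build_curve(self._sticky_trajs(seed=9000 + rep), "E1")).pka
            for rep in range(25)
        ]
        truth_2sd = 2.0 * np.std(point_pkas, ddof=1)
        assert 0.4 * truth_2sd < e_long < 2.5 * truth_2sd

    def test_bootstrap_error_scales_with_sample_size(self):
        """On i.i.d. frames the pKa error shrinks roughly as 1/sqrt(n)."""
        rng = np.random.default_rng(7)

        def make(n):
            return {
                ph: _traj((rng.random(n) < 1 / (1 + 10 ** (ph - 5.0))).astype(int),
                          site="E1", ph=ph)
                for ph in np.arange(3.0, 9.0)
            }

        e_small = blocked_bootstrap_pka(make(500), "E1", 10, n_boot=300, seed=5).pka_err
        e_large = blocked_bootstrap_pka(make(8000), "E1", 10, n_boot=300, seed=6).pka_err
        assert e_small / e_large == pytest.approx(4.0, rel=0.4)

    def test_bad_block_length(self):
        trajs = {ph: _traj(np.ones(50), ph=ph) for ph in [4.0, 5.0, 6.0]}
        with pytest.raises(ValueError, match="block_length"):
            blocked_bootstrap_pka(trajs, "S", 100, n_boot=10, seed=0)


class TestClassifySensor:
    def test_small_shift_aspartate(self):
        fit = HillFit(pka=4.7, n_hill=1.0)
        assert classify_sensor(fit, "ASP") == "non_sensor"

    def test_shifted_glutamate(self):
        fit = HillFit(pka=5.7, n_hill=1.0)
        assert classify_sensor(fit, "GLU") == "sensor_candidate"

    def test_unconverged_is_coupled(self):
        fit = HillFit(pka=float("nan"), n_hill=1.0, converged=False)
        assert classify_sensor(fit, "GLU") == "coupled_undetermined"

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            classify_sensor(HillFit(pka=5.0, n_hill=1.0), "LYS")
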