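"""Irreversible 2TCM forward/inverse, K1max screen and FUR."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fdgir.cohort import (CohortSpec, default_frame_schedule, draw_feng,
                          generate_tissue)
from fdgir.feng import FengParameters, feng_eval
from fdgir.kinetics import (KineticParameters, compute_fur, derive_ki,
                            fit_2tcm, k1max, plausibility_screen,
                            simulate_2tcm)
from fdgir.tac import TimeActivityCurve

TRUTH = FengParameters(tau=1.7, a1=560.0, a2=16.0, a3=11.0,
                       l1=-3.5, l2=-0.12, l3=-0.006)
FRAMES = default_frame_schedule()


def _dense_input(t_end=100.0):
    grid = np.arange(0.0, t_end + 1e-9, 0.02)
    return TimeActivityCurve(grid, feng_eval(TRUTH, grid))


class TestSimulate:
    def test_k1_zero_gives_pure_vascular(self):
        inp = _dense_input()
        kin = KineticParameters(k1=0.0, k2=0.1, k3=0.05)
        tis = simulate_2tcm(inp, kin, FRAMES)
        from fdgir.kinetics import _frame_average
        expected = _frame_average(inp.times, kin.vb * inp.activities,
                                  FRAMES)
        np.testing.assert_allclose(tis.activities, expected, atol=1e-12)

    def test_equilibrium_ratio_with_constant_input(self):
        # k3 = 0, constant input: tissue/plasma -> (1-vb)*K1/k2 + vb
        t = np.arange(0.0, 400.0 + 1e-9, 0.5)
        inp = TimeActivityCurve(t, np.full_like(t, 10.0))
        kin = KineticParameters(k1=0.1, k2=0.2, k3=0.0)
        frames = np.array([[360.0, 370.0], [375.0, 385.0], [390.0, 400.0]])
        tis = simulate_2tcm(inp, kin, frames)
        ratio = tis.activities[-1] / 10.0
        assert ratio == pytest.approx((1 - kin.vb) * 0.5 + kin.vb, rel=1e-4)

    def test_matches_stiff_ode_oracle(self):
        """Analytic convolution vs independent ODE integration (< 0.1%)."""
        inp = _dense_input()
        kin = KineticParameters(k1=0.08, k2=0.15, k3=0.05)

        def cp(t):
            return np.interp(t, inp.times, inp.activities)

        def rhs(t, y):
            cf, cb = y
            return [kin.k1 * cp(t) - (kin.k2 + kin.k3) * cf, kin.k3 * cf]

        frames = FRAMES[4:]  # skip sub-grid early frames for the oracle
        mids = frames.mean(axis=1)
        sol = solve_ivp(rhs, (0.0, 100.0), [0.0, 0.0], method="LSODA",
                        t_eval=mids, rtol=1e-10, atol=1e-12, max_step=0.25)
        ode_pet = (1 - kin.vb) * sol.y.sum(axis=0) + kin.vb * cp(mids)

        # compare instantaneous model (tiny frames) against the ODE values
        tiny = np.column_stack([mids - 0.01, mids + 0.01])
        ours = simulate_2tcm(inp, kin, tiny)
        rel = np.abs(ours.activities - ode_pet) / np.max(ode_pet)
        assert np.max(rel) < 1e-3

    def test_input_must_cover_frames(self):
        inp = _dense_input(t_end=50.0)
        with pytest.raises(ValueError):
            simulate_2tcm(inp, KineticParameters(0.1, 0.1, 0.05), FRAMES)


class TestFit:
    def test_noiseless_recovery(self):
        inp = _dense_input()
        kin = KineticParameters(k1=0.08, k2=0.15, k3=0.05)
        tis = simulate_2tcm(inp, kin, FRAMES)
        fit = fit_2tcm(tis, inp, frames=FRAMES)
        assert fit.k1 == pytest.approx(kin.k1, rel=1e-2)
        assert fit.k2 == pytest.approx(kin.k2, rel=1e-2)
        assert fit.k3 == pytest.approx(kin.k3, rel=1e-2)
        assert fit.converged and not fit.at_bound

    def test_zero_k1_hits_lower_bound(self):
        inp = _dense_input()
        tis = simulate_2tcm(inp, KineticParameters(0.0, 0.1, 0.05), FRAMES)
        fit = fit_2tcm(tis, inp, frames=FRAMES)
        assert fit.k1 == pytest.approx(0.0, abs=1e-6)
        assert "k1" in fit.at_bound

    def test_multistart_agrees(self):
        inp = _dense_input()
        kin = KineticParameters(k1=0.1, k2=0.2, k3=0.04)
        tis = simulate_2tcm(inp, kin, FRAMES)
        fits = [fit_2tcm(tis, inp, frames=FRAMES, starts=(s,))
                for s in ((0.05, 0.3, 0.02), (0.2, 0.8, 0.08),
                          (0.4, 2.0, 0.15))]
        k1s = [f.k1 for f in fits]
        assert np.ptp(k1s) < 1e-4


class TestDeriveKi:
    def test_canonical_arithmetic(self):
        assert derive_ki(0.1, 0.2, 0.05) == pytest.approx(0.02)

    def test_printed_variant_differs(self):
        # the alternative convention divides by K1 + k2 instead of k2 + k3
        assert derive_ki(0.1, 0.2, 0.05, convention="printed") == \
            pytest.approx(0.1 * 0.05 / 0.3)

    def test_no_trapping_no_influx(self):
        assert derive_ki(0.1, 0.2, 0.0) == 0.0

    def test_no_efflux_full_trapping(self):
        assert derive_ki(0.1, 0.0, 0.05) == pytest.approx(0.1)

    def test_ki_bounded_by_k1_and_monotone_in_k3(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k1, k2, k3 = rng.uniform(0.01, 1.0, 3)
            ki = derive_ki(k1, k2, k3)
            assert ki <= k1 + 1e-12
        base = derive_ki(0.1, 0.2, 0.05)
        assert derive_ki(0.1, 0.2, 0.06) > base


class TestK1Max:
    def test_arithmetic(self):
        c = k1max(0.5, 0.4)
        assert c.cpf == pytest.approx(0.30)
        assert c.k1max == pytest.approx(0.30)
        assert c.extraction == 1.0

    def test_zero_hematocrit_limit(self):
        assert k1max(0.5, 1e-9).k1max == pytest.approx(0.5)

    def test_out_of_range_hematocrit_errors(self):
        with pytest.raises(ValueError):
            k1max(0.5, 1.2)


class TestScreen:
    def test_zero_counts_when_all_below(self):
        fits = {"s1": {"roi": KineticParameters(0.1, 0.2, 0.05)}}
        cons = {"s1": k1max(0.5, 0.4)}
        df = plausibility_screen(fits, cons)
        assert df.loc[df.subject == "TOTAL", "n_over_before"].item() == 0

    def test_subject_counted_once_across_rois(self):
        fits = {"s1": {f"roi{i}": KineticParameters(0.1, 0.2, 0.05)
                       for i in range(3)}}
        fits["s1"]["roi3"] = KineticParameters(0.9, 0.2, 0.05)
        cons = {"s1": k1max(0.5, 0.4)}
        df = plausibility_screen(fits, cons)
        total = df[df.subject == "TOTAL"].iloc[0]
        assert total["n_over_before"] == 1
        assert total["any_over_before"] == 1


class TestFur:
    def test_constant_tissue(self):
        t = np.arange(0.0, 101.0, 1.0)
        inp = TimeActivityCurve(t, np.full_like(t, 2.0))  # AUC(0,T) = 2T
        tis = TimeActivityCurve([60.0, 80.0, 100.0], [6.0, 6.0, 6.0],
                                label="tissue")
        res = compute_fur(tis, inp)
        expected = np.mean([6.0 / (2 * 60), 6.0 / (2 * 80), 6.0 / (2 * 100)])
        assert res.fur == pytest.approx(expected, rel=1e-6)

    def test_halves_when_input_doubles(self):
        t = np.arange(0.0, 101.0, 1.0)
        inp = TimeActivityCurve(t, np.exp(-0.01 * t) * 10)
        inp2 = inp.with_values(activities=inp.activities * 2)
        tis = TimeActivityCurve([70.0, 85.0, 100.0], [5.0, 5.5, 6.0],
                                label="tissue")
        f1 = compute_fur(tis, inp).fur
        f2 = compute_fur(tis, inp2).fur
        assert f2 == pytest.approx(f1 / 2, rel=1e-9)

    def test_joint_rescale_invariant(self):
        t = np.arange(0.0, 101.0, 1.0)
        inp = TimeActivityCurve(t, np.exp(-0.01 * t) * 10)
        tis = TimeActivityCurve([70.0, 85.0, 100.0], [5.0, 5.5, 6.0],
                                label="tissue")
        s = 3.3
        f1 = compute_fur(tis, inp).fur
        f2 = compute_fur(tis.with_values(activities=tis.activities * s),
                         inp.with_values(activities=inp.activities * s)).fur
        assert f2 == pytest.approx(f1, rel=1e-12)

    def test_window_filters_frames(self):
        t = np.arange(0.0, 101.0, 1.0)
        inp = TimeActivityCurve(t, np.full_like(t, 2.0))
        tis = TimeActivityCurve([10.0, 60.0, 100.0], [1.0, 6.0, 6.0],
                                label="tissue")
        res = compute_fur(tis, inp, window=(50.0, 100.0))
        assert len(res.per_frame) == 2

    def test_rank_correlation_with_true_ki(self):
        """FUR orders subjects like the true net influx constant."""
        from scipy import stats
        spec = CohortSpec(n_subjects=25, seed=31)
        furs, kis = [], []
        for i in range(spec.n_subjects):
            rng = np.random.default_rng([31, i])
            truth = draw_feng(spec, rng)
            kin = KineticParameters(k1=rng.uniform(*spec.k1_range),
                                    k2=rng.uniform(*spec.k2_range),
                                    k3=rng.uniform(*spec.k3_range))
            tis = generate_tissue(truth, kin, FRAMES, noise_sd=0.03, rng=rng)
            grid = np.arange(0.0, 100.0 + 1e-9, 0.05)
            inp = TimeActivityCurve(grid, feng_eval(truth, grid))
            furs.append(compute_fur(tis, inp, window=(60.0, 100.0)).fur)
            kis.append(kin.ki)
        rho = stats.spearmanr(furs, kis).statistic
        assert rho > 0.9
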