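import numpy as np
import pytest

from g4kit.coupling_karplus import (
    CouplingSet,
    KarplusParams,
    fit_pseudorotation,
    karplus_j,
    load_karplus_params,
    predict_couplings,
    read_coupling_table,
    simulate_couplings,
)


@pytest.fixture(scope="module")
def params():
    return load_karplus_params("default")


class TestKarplusJ:
    @pytest.mark.parametrize(
        "theta,expected",
        [(90.0, 5.88), (0.0, 40.61 - 4.22 + 5.88), (180.0, 40.61 + 4.22 + 5.88)],
    )
    def test_special_angles(self, theta, expected):
        assert karplus_j(theta, (40.61, -4.22, 5.88)) == pytest.approx(expected, abs=1e-9)


class TestPredict:
    def test_constant_model(self):
        p = KarplusParams(
            name="const",
            coeffs={"F2'-H1'": (0.0, 0.0, 5.0)},
            theta_maps={"F2'-H1'": (1, 1.0, 0.0)},
        )
        for P in (0, 90, 200):
            cs = predict_couplings(P, 38.0, p)
            assert cs.values["F2'-H1'"][0] == pytest.approx(5.0)

    def test_planar_ring_fixed(self, params):
        a = predict_couplings(10.0, 0.0, params)
        b = predict_couplings(250.0, 0.0, params)
        for path in a.values:
            assert a.values[path][0] == pytest.approx(b.values[path][0], abs=1e-9)

    def test_slope_changes_sign_at_extremum(self, params):
        # J(F2'-H1') along P at fixed tau_m: finite-difference slope must
        # change sign exactly where cos(theta) is extremal (brute force)
        tau = 38.0
        js = [
            predict_couplings(P, tau, params, paths=("F2'-H1'",)).values["F2'-H1'"][0]
            for P in range(0, 181)
        ]
        slopes = np.sign(np.diff(js))
        assert len(set(slopes[slopes != 0])) == 2  # both rising and falling

    def test_missing_path_errors(self, params):
        with pytest.raises(ValueError, match="lacks"):
            predict_couplings(10, 38, params, paths=("bogus",))

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            KarplusParams(name="x", coeffs={"p": (1, 1, 1)}, theta_maps={"p": (1, 0.0, 0.0)})


class TestSimulate:
    def test_zero_noise_equals_prediction(self, params):
        sim = simulate_couplings(55, 35, params, 0.0, seed=4)
        pred = predict_couplings(55, 35, params)
        for path in pred.values:
            assert sim.values[path][0] == pytest.approx(pred.values[path][0], abs=1e-12)

    def test_seed_determinism(self, params):
        a = simulate_couplings(55, 35, params, 0.5, seed=11)
        b = simulate_couplings(55, 35, params, 0.5, seed=11)
        assert a.values == b.values

    def test_sample_mean_clt(self, params):
        # 10^4 draws of one path: sample mean within 3 SE of prediction
        pred = predict_couplings(120, 38, params, paths=("F2'-H3'",)).values["F2'-H3'"][0]
        sd = 0.5
        n = 10_000
        draws = [
            simulate_couplings(120, 38, params, sd, seed=s, paths=("F2'-H3'",)).values["F2'-H3'"][0]
            for s in range(n)
        ]
        se = sd / np.sqrt(n)
        assert abs(np.mean(draws) - pred) < 3 * se

    def test_truncated_at_zero(self):
        p = KarplusParams(
            name="tiny", coeffs={"p": (0.0, 0.0, 0.01)}, theta_maps={"p": (1, 1.0, 0.0)}
        )
        for s in range(50):
            j, _ = simulate_couplings(10, 38, p, 1.0, seed=s, paths=("p",)).values["p"]
            assert j >= 0.0


class TestFit:
    def test_self_consistency(self, params):
        obs = CouplingSet(
            values={p: (j, 0.3) for p, (j, _) in predict_couplings(20, 38, params).values.items()}
        )
        fit = fit_pseudorotation(obs, params)
        assert abs(fit.best[0] - 20) <= 1.0
        assert abs(fit.best[1] - 38) <= 1.0

    def test_zero_noise_exhaustive_recovery(self, params):
        for P in range(0, 360, 40):
            for tau in (27.0, 36.0, 44.0):
                obs = simulate_couplings(P, tau, params, 0.0, seed=0)
                fit = fit_pseudorotation(obs, params, p_step=2.0, tau_step=1.0)
                dp = min(abs(fit.best[0] - P), 360 - abs(fit.best[0] - P))
                assert dp <= 2.0, (P, tau, fit.best)
                assert abs(fit.best[1] - tau) <= 1.0

    def test_compatible_shrinks_with_k(self, params):
        obs = simulate_couplings(60, 36, params, 0.3, seed=8)
        sizes = [
            len(fit_pseudorotation(obs, params, p_step=3.0, k=k).compatible)
            for k in (3.0, 2.0, 1.0, 0.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_chisq_invariant_under_path_relabeling(self, params):
        obs = simulate_couplings(60, 36, params, 0.3, seed=8)
        fit1 = fit_pseudorotation(obs, params, p_step=5.0)
        shuffled = CouplingSet(values=dict(reversed(list(obs.values.items()))))
        fit2 = fit_pseudorotation(shuffled, params, p_step=5.0)
        assert np.allclose(fit1.chisq, fit2.chisq)

    def test_degenerate_two_intervals(self):
        # one H-H path alone cannot distinguish N from S pseudorotamers:
        # construct an observation hit exactly by two disjoint P regions
        p = KarplusParams(
            name="hh",
            coeffs={"H1'-H2'": (10.2, -0.8, 0.0)},
            theta_maps={"H1'-H2'": (1, 1.0, 121.4)},
        )
        obs = CouplingSet(values={"H1'-H2'": (predict_couplings(60, 38, p).values["H1'-H2'"][0], 0.2)})
        fit = fit_pseudorotation(obs, p, p_step=1.0, k=1.0)
        assert len(fit.p_intervals) == 2
        # the true node lies in one interval, its mirror in the other
        (a0, a1), (b0, b1) = fit.p_intervals
        assert a0 <= 60.0 <= a1
        assert b0 <= 228.0 <= b1

    def test_empty_compatible_flagged(self, params):
        obs = CouplingSet(values={"F2'-H1'": (200.0, 0.001)})  # impossible J
        fit = fit_pseudorotation(obs, params)
        assert fit.no_solution_at_k
        assert fit.p_intervals == []
        assert fit.best is not None

    def test_monte_carlo_recovery(self, params):
        # noise-propagation bound: sigma_P ~ sigma_J / |dJ/dP| aggregated
        # over paths, evaluated by finite differences (independent oracle)
        true_p, true_tau, sd = 55.0, 35.0, 0.3
        eps = 0.5
        grads = []
        for path in params.coeffs:
            j_hi = predict_couplings(true_p + eps, true_tau, params, (path,)).values[path][0]
            j_lo = predict_couplings(true_p - eps, true_tau, params, (path,)).values[path][0]
            grads.append((j_hi - j_lo) / (2 * eps))
        sigma_p = sd / np.sqrt(np.sum(np.square(grads)))
        errs = []
        for seed in range(100):
            obs = simulate_couplings(true_p, true_tau, params, sd, seed=seed)
            fit = fit_pseudorotation(obs, params, p_step=2.0, k=2.0)
            errs.append(min(abs(fit.best[0] - true_p), 360 - abs(fit.best[0] - true_p)))
        median_err = float(np.median(errs))
        assert median_err <= 2.0 + 3.0 * sigma_p, (median_err, sigma_p)


class TestIO:
    def test_read_coupling_table(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("path\tJ_Hz\tsigma_Hz\nF2'-H1'\t12.5\t0.3\nF2'-H3'\t21.0\t0.4\n")
        cs = read_coupling_table(p)
        assert cs.values["F2'-H1'"] == (12.5, 0.3)

    def test_empty_table_raises(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            read_coupling_table(p)

    def test_negative_j_rejected(self):
        with pytest.raises(ValueError):
            CouplingSet(values={"F2'-H1'": (-1.0, 0.3)})
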