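import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from stemtaper import taper_models as tm
from stemtaper.stem_geometry import K

from conftest import RECOVERY_BETAS, model_rows


class TestPredictDiameter:
    def test_metcalf_breast_height_identity(self):
        spec = tm.get_model("metcalf")
        for b1 in (0.01, 0.05, 0.2):
            assert tm.predict_diameter(spec, [b1], 37.0, 18.0, 1.3) == \
                pytest.approx(37.0, rel=1e-14)

    def test_lee_vanishing_exponent(self):
        spec = tm.get_model("lee")
        for h in (0.1, 5.0, 15.0):
            assert tm.predict_diameter(spec, [1, 1, 0, 0, 0], 30.0, 20.0, h) \
                == pytest.approx(30.0)

    def test_lee_linear_case(self):
        spec = tm.get_model("lee")
        assert tm.predict_diameter(spec, [1, 1, 0, 0, 1], 30.0, 20.0, 10.0) \
            == pytest.approx(15.0)

    def test_negative_prediction_clipped(self):
        spec = tm.get_model("lee")
        # a negative leading coefficient forces a negative raw diameter
        val = tm.predict_diameter(spec, [-1, 1, 0, 0, 1], 30.0, 20.0, 10.0)
        assert val == 0.0

    def test_h_at_or_above_ht_rejected(self):
        spec = tm.get_model("lee")
        with pytest.raises(tm.TaperDomainError):
            tm.predict_diameter(spec, RECOVERY_BETAS["lee"], 30.0, 20.0, 20.0)

    def test_low_total_height_rejected(self):
        spec = tm.get_model("lee")
        with pytest.raises(ValueError):
            tm.predict_diameter(spec, RECOVERY_BETAS["lee"], 30.0, 1.2, 0.5)

    def test_nonfinite_raises_domain_error(self):
        spec = tm.get_model("biging")
        # exp(-b0/b1) with b1 -> 0- makes the log argument non-positive
        with pytest.raises(tm.TaperDomainError):
            tm.predict_diameter(spec, [1.0, -1e-9], 30.0, 20.0, 10.0)

    def test_registry_arity(self):
        expected = {"demaerschalk": 4, "biging": 2, "bi": 7, "lee": 5,
                    "kozak": 9, "metcalf": 1}
        for name, n in expected.items():
            assert tm.get_model(name).n_params == n

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            tm.get_model("nonexistent")


class TestGaussNewton:
    def test_metcalf_exact_recovery(self):
        rows = model_rows("metcalf", (0.05,), n_trees=20, per_tree=10)
        fit = tm.gauss_newton_fit(tm.get_model("metcalf"), rows, inits=[0.2])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(0.05, rel=1e-6)
        assert fit.sse < 1e-16

    @pytest.mark.parametrize("name", list(RECOVERY_BETAS))
    def test_all_models_noise_free_recovery(self, name):
        truth = np.asarray(RECOVERY_BETAS[name], float)
        rows = model_rows(name, truth)
        # bi and kozak are recoverable only from nearby starts
        pert = 1.03 if name in ("bi", "kozak") else 1.08
        fit = tm.gauss_newton_fit(tm.get_model(name), rows, inits=truth * pert)
        assert fit.converged, fit.message
        rel = np.abs(fit.beta - truth) / np.maximum(np.abs(truth), 1e-12)
        assert np.max(rel) < 1e-5

    def test_lee_noisy_recovery_within_3_se(self):
        truth = np.asarray(RECOVERY_BETAS["lee"])
        rows = model_rows("lee", truth, n_trees=125, per_tree=12,
                          noise_sd=0.3, seed=7)
        assert len(rows) == 1500
        spec = tm.get_model("lee")
        fit = tm.gauss_newton_fit(spec, rows, inits=truth * 1.05)
        assert fit.converged
        # linearised standard errors from the Jacobian at the solution
        J = tm._jacobian(spec, fit.beta, rows["dbh"].to_numpy(),
                         rows["ht"].to_numpy(), rows["h"].to_numpy())
        sigma2 = fit.sse / (fit.n_obs - spec.n_params)
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(fit.beta - truth) < 3 * se)

    def test_bi_on_lee_data_does_not_raise(self):
        rows = model_rows("lee", RECOVERY_BETAS["lee"], noise_sd=0.5, seed=3)
        fit = tm.gauss_newton_fit(tm.get_model("bi"), rows)
        assert isinstance(fit.converged, bool)
        if fit.converged:
            assert math.isfinite(fit.aicc)
        else:
            assert fit.aicc is None

    def test_too_few_rows_rejected(self):
        rows = model_rows("lee", RECOVERY_BETAS["lee"]).head(4)
        with pytest.raises(ValueError):
            tm.gauss_newton_fit(tm.get_model("lee"), rows)

    def test_nonfinite_start_flags_not_raises(self):
        rows = model_rows("lee", RECOVERY_BETAS["lee"])
        fit = tm.gauss_newton_fit(tm.get_model("biging"), rows,
                                  inits=[1.0, -1e-12])
        assert not fit.converged
        assert fit.aicc is None

    def test_oracle_equivalence_with_scipy(self):
        """Converged GN solutions match a general-purpose least-squares
        minimiser run from the same starting values."""
        for name in ("lee", "metcalf", "biging", "demaerschalk"):
            truth = np.asarray(RECOVERY_BETAS[name], float)
            rows = model_rows(name, truth, noise_sd=0.3, seed=11)
            spec = tm.get_model(name)
            inits = truth * 1.05
            fit = tm.gauss_newton_fit(spec, rows, inits=inits)
            assert fit.converged

            dbh = rows["dbh"].to_numpy()
            ht = rows["ht"].to_numpy()
            h = rows["h"].to_numpy()
            d = rows["d"].to_numpy()
            res = least_squares(
                lambda b: d - tm._raw_predict(spec, b, dbh, ht, h), inits,
                method="lm", xtol=1e-14, ftol=1e-14)
            sse_ref = float(res.fun @ res.fun)
            assert fit.sse == pytest.approx(sse_ref, rel=1e-6)


class TestAicc:
    def test_penalty_monotone_in_params(self):
        scores = [tm.aicc(50.0, 200, k) for k in range(1, 8)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_monotone_in_sse(self):
        assert tm.aicc(60.0, 200, 3) > tm.aicc(50.0, 200, 3)

    def test_closed_form_value(self):
        # sse = n kills the log term; 2k + 2k(k+1)/(n-k-1) with k=2, n=100
        assert tm.aicc(100.0, 100, 1) == pytest.approx(4 + 12 / 97, rel=1e-12)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            tm.aicc(10.0, 5, 4)
        with pytest.raises(ValueError):
            tm.aicc(0.0, 100, 1)


def _fit(name, forest, sse, n=500, converged=True):
    spec = tm.get_model(name)
    score = tm.aicc(sse, n, spec.n_params) if converged else None
    return tm.TaperFit(spec, forest, np.zeros(spec.n_params), sse, n,
                       converged, 5, score)


class TestSelectBestModel:
    def test_majority_winner(self):
        fits = [
            _fit("lee", "cerrado", 50.0), _fit("kozak", "cerrado", 80.0),
            _fit("lee", "rainforest", 50.0), _fit("kozak", "rainforest", 80.0),
            _fit("lee", "semideciduous", 90.0),
            _fit("kozak", "semideciduous", 40.0),
        ]
        tally = tm.select_best_model(fits)
        assert tally.overall_best == ("lee",)
        assert tally.counts == {"lee": 2, "kozak": 1}
        assert sum(tally.counts.values()) == 3
        assert not tally.ties

    def test_two_forest_winner_pattern(self):
        # one forest won by A, two by B -> B overall
        fits = [
            _fit("kozak", "cerrado", 40.0), _fit("lee", "cerrado", 50.0),
            _fit("lee", "semideciduous", 40.0),
            _fit("kozak", "semideciduous", 50.0),
            _fit("lee", "rainforest", 40.0), _fit("kozak", "rainforest", 50.0),
        ]
        tally = tm.select_best_model(fits)
        assert tally.winners["cerrado"] == ("kozak",)
        assert tally.overall_best == ("lee",)

    def test_nonconverged_excluded(self):
        fits = [_fit("lee", "cerrado", 50.0),
                _fit("bi", "cerrado", 1.0, converged=False)]
        tally = tm.select_best_model(fits)
        assert tally.winners["cerrado"] == ("lee",)

    def test_forest_without_convergence_reported(self):
        fits = [_fit("bi", "cerrado", 1.0, converged=False)]
        tally = tm.select_best_model(fits)
        assert tally.excluded_forests == ["cerrado"]
        assert tally.overall_best == ()

    def test_tie_credits_both_and_flags(self):
        a = _fit("lee", "cerrado", 50.0)
        b = _fit("biging", "cerrado", 50.0)
        b.aicc = a.aicc + 1e-9
        tally = tm.select_best_model([a, b])
        assert set(tally.winners["cerrado"]) == {"lee", "biging"}
        assert tally.ties == ["cerrado"]
        assert tally.counts == {"lee": 1, "biging": 1}


class TestTaperVolume:
    def metcalf_closed_form(self, b1, dbh, lo, hi):
        return K * dbh**2 / (2 * b1) * (
            math.exp(-2 * b1 * (lo - 1.3)) - math.exp(-2 * b1 * (hi - 1.3)))

    def test_metcalf_analytic_oracle(self):
        spec = tm.get_model("metcalf")
        got = tm.taper_volume(spec, [0.05], 30.0, 20.0, 15.0, 0.1)
        want = self.metcalf_closed_form(0.05, 30.0, 0.1, 15.0)
        assert got == pytest.approx(want, abs=1e-8)

    def test_zero_span(self):
        spec = tm.get_model("lee")
        assert tm.taper_volume(spec, RECOVERY_BETAS["lee"], 30.0, 20.0,
                               5.0, 5.0) == 0.0

    def test_additivity(self):
        spec = tm.get_model("lee")
        beta = RECOVERY_BETAS["lee"]
        v1 = tm.taper_volume(spec, beta, 30.0, 20.0, 7.0, 0.1)
        v2 = tm.taper_volume(spec, beta, 30.0, 20.0, 15.0, 7.0)
        v12 = tm.taper_volume(spec, beta, 30.0, 20.0, 15.0, 0.1)
        assert v1 + v2 == pytest.approx(v12, abs=1e-9)

    def test_invalid_bounds_rejected(self):
        spec = tm.get_model("lee")
        with pytest.raises(ValueError):
            tm.taper_volume(spec, RECOVERY_BETAS["lee"], 30.0, 20.0, 5.0, 0.05)
        with pytest.raises(ValueError):
            tm.taper_volume(spec, RECOVERY_BETAS["lee"], 30.0, 20.0, 25.0, 0.1)

    def test_batch_matches_adaptive(self):
        spec = tm.get_model("lee")
        beta = np.asarray(RECOVERY_BETAS["lee"])
        dbh = np.array([12.0, 30.0, 55.0])
        ht = np.array([10.0, 18.0, 26.0])
        hu = np.array([4.0, 9.0, 20.0])
        batch = tm.taper_volume_batch(spec, beta, dbh, ht, hu)
        for i in range(3):
            ref = tm.taper_volume(spec, beta, dbh[i], ht[i], hu[i])
            assert batch[i] == pytest.approx(ref, abs=1e-9)

    def test_fitted_volume_close_to_smalian_truth(self):
        """Low-residual fits integrate to within 2% of the Smalian ground
        truth of finely sampled stems."""
        from stemtaper.stem_geometry import (StemMeasurement, StemProfile,
                                             accumulated_volume_profile)

        spec = tm.get_model("lee")
        truth = np.asarray(RECOVERY_BETAS["lee"])
        rows = model_rows("lee", truth, noise_sd=0.2, seed=5)
        fit = tm.gauss_newton_fit(spec, rows, inits=truth * 1.05)
        assert fit.converged
        resid_sd = math.sqrt(fit.sse / fit.n_obs)
        assert resid_sd < 0.3

        for dbh, ht in ((20.0, 14.0), (45.0, 24.0)):
            hs = np.arange(0.1, 0.92 * ht, 0.01)
            ds = tm.predict_diameter(spec, truth, dbh, ht, hs)
            stem = StemProfile("s", tuple(
                StemMeasurement(h, d) for h, d in zip(hs, ds)))
            smalian = accumulated_volume_profile(stem, ht)[-2].vac
            fitted = tm.taper_volume(spec, fit.beta, dbh, ht, hs[-1], 0.1)
            assert fitted == pytest.approx(smalian, rel=0.02)
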