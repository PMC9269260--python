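"""Standardization, elastic-net fitting, correlation and reporting."""

import numpy as np
import pandas as pd
import pytest

from keykin.errors import (
    DegenerateColumnError,
    DegenerateInputError,
    FittingError,
    InsufficientDataError,
)
from keykin.features import PREDICTOR_COLUMNS
from keykin.regression import (
    NetFit,
    fit_elastic_net,
    outcome_correlation,
    parse_report,
    report,
    report_to_json,
    standardize,
)
from keykin.simulate import planted_cohort_table

from _oracles import closed_form_ridge


def _ztable(n=49, r2=0.85, seed=0):
    table, beta = planted_cohort_table(n=n, r2=r2, seed=seed)
    z, _ = standardize(table, columns=[c for c in table.columns if c != "pianist_id"])
    return z, beta


class TestStandardize:
    def test_three_point_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, _ = standardize(df)
        assert np.allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(3, 2, 30)})
        z1, _ = standardize(df)
        z2, _ = standardize(z1)
        assert np.allclose(z1["a"], z2["a"], atol=1e-12)

    def test_posthoc_moments(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(5, 7, (40, 3)), columns=list("abc"))
        z, params = standardize(df)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)
        back = params.inverse(z)
        assert np.allclose(back.to_numpy(), df.to_numpy(), atol=1e-10)

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(DegenerateColumnError, match="flat"):
            standardize(df)


class TestFitElasticNet:
    def test_unpenalized_recovers_exact_linear_model(self):
        """alpha = 0 on noiseless y = X beta: coefficients within 1e-6, R2 = 1."""
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((60, 12)), columns=list(PREDICTOR_COLUMNS))
        beta = np.zeros(12)
        beta[[0, 5]] = [0.8, -0.5]
        z = X.copy()
        z["y"] = X.to_numpy() @ beta
        fit = fit_elastic_net(z, "y", alphas=[0.0], l1_ratios=[0.5], seed=0)
        assert np.allclose(fit.coef.to_numpy(), beta, atol=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_total_shrinkage_limit(self):
        z, _ = _ztable(seed=3)
        fit = fit_elastic_net(z, "fastest_ioi", alphas=[1e6], l1_ratios=[0.5], seed=0)
        assert np.allclose(fit.coef.to_numpy(), 0.0)
        assert fit.r2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_ridge_at_l1_zero(self):
        """l1_ratio = 0 agrees with the closed-form ridge solution."""
        z, _ = _ztable(seed=4)
        alpha = 0.3
        fit = fit_elastic_net(z, "fastest_ioi", alphas=[alpha], l1_ratios=[0.0], seed=0)
        b, intercept = closed_form_ridge(z[list(PREDICTOR_COLUMNS)], z["fastest_ioi"],
                                         alpha)
        assert np.allclose(fit.coef.to_numpy(), b, atol=1e-6)
        assert fit.intercept == pytest.approx(intercept, abs=1e-6)

    def test_planted_effects_recovered(self):
        """n = 49, three planted effects + nine irrelevant predictors at
        true R2 = 0.85: fitted signs correct, R2 close to truth."""
        z, beta = _ztable(seed=5)
        fit = fit_elastic_net(z, "fastest_ioi", seed=0)
        for pred, b in beta["fastest_ioi"].items():
            if b != 0:
                assert np.sign(fit.coef[pred]) == np.sign(b)
        assert abs(fit.r2 - 0.85) < 0.15

    def test_in_sample_r2_nonincreasing_in_alpha(self):
        z, _ = _ztable(seed=6)
        r2s = [fit_elastic_net(z, "loudness_balance", alphas=[a], l1_ratios=[0.5],
                               seed=0).r2
               for a in [1e-3, 1e-2, 1e-1, 0.3, 1.0, 3.0]]
        assert all(a >= b - 1e-10 for a, b in zip(r2s, r2s[1:]))

    def test_predictor_permutation_equivariance(self):
        """At fixed hyperparameters, permuting predictor columns permutes the
        coefficients and leaves predictions unchanged."""
        z, _ = _ztable(seed=7)
        perm = list(np.random.default_rng(0).permutation(list(PREDICTOR_COLUMNS)))
        fit = fit_elastic_net(z, "fastest_ioi", alphas=[0.05], l1_ratios=[0.7], seed=0)
        fit_p = fit_elastic_net(z, "fastest_ioi", predictors=perm,
                                alphas=[0.05], l1_ratios=[0.7], seed=0)
        assert np.allclose(fit_p.coef[list(PREDICTOR_COLUMNS)].to_numpy(),
                           fit.coef.to_numpy(), atol=1e-8)
        assert np.allclose(fit_p.predict(z), fit.predict(z), atol=1e-8)

    def test_row_order_invariance_at_fixed_hyperparameters(self):
        z, _ = _ztable(seed=8)
        shuffled = z.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit = fit_elastic_net(z, "fastest_ioi", alphas=[0.05], l1_ratios=[0.7], seed=0)
        fit_s = fit_elastic_net(shuffled, "fastest_ioi", alphas=[0.05],
                                l1_ratios=[0.7], seed=0)
        assert np.allclose(fit_s.coef.to_numpy(), fit.coef.to_numpy(), atol=1e-8)

    def test_tie_breaks_toward_larger_alpha(self):
        # duplicate alphas give exactly tied CV scores; the larger must win
        z, _ = _ztable(seed=9)
        fit = fit_elastic_net(z, "fastest_ioi", alphas=[0.05, 0.05 + 1e-12],
                              l1_ratios=[0.5], seed=0)
        assert fit.alpha == pytest.approx(0.05 + 1e-12)

    def test_empty_grid_rejected(self):
        z, _ = _ztable(seed=10)
        with pytest.raises(FittingError):
            fit_elastic_net(z, "fastest_ioi", alphas=[], l1_ratios=[0.5])


class TestOutcomeCorrelation:
    def test_identity(self):
        y = np.arange(10.0)
        res = outcome_correlation(y, y)
        assert res.r == pytest.approx(1.0)

    def test_orthogonal_contrast(self):
        res = outcome_correlation([1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0])
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_p_value_from_t_distribution(self):
        rng = np.random.default_rng(11)
        a, b = rng.standard_normal(49), rng.standard_normal(49)
        res = outcome_correlation(a, b)
        from scipy import stats
        t = res.r * np.sqrt(47 / (1 - res.r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df=47), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            outcome_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            outcome_correlation([1.0, 2.0], [2.0, 1.0])


class TestReport:
    def _zero_fit(self):
        return NetFit(outcome="fastest_ioi",
                      coef=pd.Series(0.0, index=list(PREDICTOR_COLUMNS)),
                      intercept=0.0, alpha=1e6, l1_ratio=0.5, r2=0.0, cv_r2=-0.1)

    def test_all_zero_fit(self):
        df = report([self._zero_fit()])
        assert (df.loc["fastest_ioi", list(PREDICTOR_COLUMNS)] == 0.0).all()
        assert df.loc["fastest_ioi", "r2"] == 0.0

    def test_json_round_trip(self, tmp_path):
        z, _ = _ztable(seed=12)
        fits = [fit_elastic_net(z, out, alphas=[0.05], l1_ratios=[0.6], seed=0)
                for out in ("fastest_ioi", "loudness_balance")]
        path = tmp_path / "report.json"
        report_to_json(fits, path)
        parsed = parse_report(path)
        for orig, back in zip(fits, parsed):
            assert back.outcome == orig.outcome
            assert np.allclose(back.coef[orig.coef.index].to_numpy(),
                               orig.coef.to_numpy())
            for attr in ("intercept", "alpha", "l1_ratio", "r2", "cv_r2"):
                assert getattr(back, attr) == pytest.approx(getattr(orig, attr))
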