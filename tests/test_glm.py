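"""Logistic myelination model: IRLS fit, separation handling, d50."""

import numpy as np
import pytest
import statsmodels.api as sm

from myelotrace.glm import (
    LAYER1_GLM_COEFFICIENTS,
    NoInformationError,
    SeparationError,
    d50,
    fit_myelination_glm,
    irls_logistic,
    predict_probability,
    reference_fit,
)
from myelotrace.synth import simulate_glm_dataset


class TestIRLS:
    def test_intercept_only_closed_form(self):
        # balanced outcomes: log-odds of one half is exactly 0
        X = np.ones((10, 1))
        y = np.array([0.0] * 5 + [1.0] * 5)
        beta, _, _, _, converged = irls_logistic(X, y, np.ones(10))
        assert converged
        assert beta[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_grid_on_tiny_instance(self):
        """IRLS equals the grid-search maximum of the Bernoulli log likelihood."""
        rng = np.random.default_rng(11)
        diam = rng.uniform(0.2, 1.2, size=25)
        y = (rng.uniform(size=25) < 1 / (1 + np.exp(-(-2.0 + 4.0 * diam)))).astype(float)
        X = np.column_stack([np.ones(25), diam])
        beta, *_ = irls_logistic(X, y, np.ones(25))

        def loglik(b0, bd):
            mu = 1 / (1 + np.exp(-(b0 + bd * diam)))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            return np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

        # coarse-to-fine exhaustive grid search, final resolution 2e-4
        b0s = np.linspace(-10, 10, 201)
        bds = np.linspace(-10, 20, 301)
        for _ in range(4):
            ll = np.array([[loglik(a, b) for b in bds] for a in b0s])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            best = (b0s[i], bds[j])
            span0 = (b0s[1] - b0s[0]) * 2
            spand = (bds[1] - bds[0]) * 2
            b0s = np.linspace(best[0] - span0, best[0] + span0, 41)
            bds = np.linspace(best[1] - spand, best[1] + spand, 41)
        assert beta[0] == pytest.approx(best[0], abs=1e-3)
        assert beta[1] == pytest.approx(best[1], abs=1e-3)

    def test_matches_statsmodels_glm(self):
        data = simulate_glm_dataset(n=2000, seed=5)
        fit = fit_myelination_glm(data)
        diam = np.array([d for d, _, _ in data])
        subs = [s for _, s, _ in data]
        y = np.array([r for _, _, r in data])
        X = np.column_stack(
            [np.ones_like(diam), diam]
            + [[1.0 if s == t else 0.0 for s in subs] for t in ("VM", "PO", "RBP4", "NXPH4")]
        )
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        mine = [fit.coefficients[t] for t in fit.terms]
        np.testing.assert_allclose(mine, ref.params, rtol=1e-6)
        ses = [fit.standard_errors[t] for t in fit.terms]
        np.testing.assert_allclose(ses, ref.bse, rtol=1e-4)


class TestFit:
    def test_parameter_recovery_bias_shrinks_with_n(self):
        """Coefficient bias decreases from n=2,000 to n=20,000 (mean over seeds)."""
        true_bd = LAYER1_GLM_COEFFICIENTS["diam"][0]

        def mean_abs_bias(n, seeds):
            errs = []
            for s in seeds:
                fit = fit_myelination_glm(simulate_glm_dataset(n=n, seed=s))
                errs.append(fit.coefficients["diam"] - true_bd)
            return abs(np.mean(errs))

        seeds = range(101, 109)
        assert mean_abs_bias(20000, seeds) < mean_abs_bias(2000, seeds) + 0.05

    def test_fractional_site_responses_accepted(self):
        rng = np.random.default_rng(3)
        data = []
        weights = []
        for _ in range(400):
            d = rng.uniform(0.2, 1.2)
            s = rng.choice(["PV", "VM"])
            k = rng.integers(2, 4)
            p = 1 / (1 + np.exp(-(-3.044 + 5.836 * d)))
            data.append((d, str(s), float(rng.binomial(k, p)) / k))
            weights.append(float(k))
        fit = fit_myelination_glm(data, weights=weights)
        assert fit.converged
        assert fit.coefficients["diam"] > 0

    def test_single_class_response_rejected(self):
        data = [(0.5, "PV", 0.0), (0.6, "VM", 0.0), (0.7, "PV", 0.0)]
        with pytest.raises(NoInformationError):
            fit_myelination_glm(data)

    def test_collinear_design_rejected(self):
        # one diameter value makes diam collinear with the intercept
        data = [(0.5, "PV", 1.0), (0.5, "PV", 0.0), (0.5, "VM", 1.0), (0.5, "VM", 0.0)]
        with pytest.raises(np.linalg.LinAlgError):
            fit_myelination_glm(data)


@pytest.fixture(scope="module")
def separated_fit():
    base = simulate_glm_dataset(n=1500, seed=9, subtypes=("PV", "VM", "NTSR1"))
    data = [(d, s, 0.0 if s == "NTSR1" else y) for d, s, y in base]
    return fit_myelination_glm(data)


@pytest.fixture(scope="module")
def pub():
    return reference_fit()


class TestSeparation:
    def test_all_zero_subtype_is_flagged(self, separated_fit):
        assert "type_NTSR1" in separated_fit.separation_flags
        # divergent but reported as-is
        assert separated_fit.coefficients["type_NTSR1"] < -10

    def test_fit_completes_for_other_subtypes(self, separated_fit):
        assert abs(separated_fit.coefficients["diam"] - 5.836) < 1.5

    def test_d50_raises_for_flagged_subtype(self, separated_fit):
        with pytest.raises(SeparationError):
            d50(separated_fit, "NTSR1")

    def test_d50_defined_for_clean_subtype(self, separated_fit):
        est = d50(separated_fit, "PV")
        assert 0.3 < est.d50 < 0.8


class TestD50:
    @pytest.mark.parametrize(
        "subtype,expected",
        [("PV", 0.522), ("VM", 0.514), ("PO", 0.604), ("RBP4", 0.695), ("NXPH4", 0.773)],
    )
    def test_published_coefficients_reproduce_printed_values(self, pub, subtype, expected):
        assert d50(pub, subtype).d50 == pytest.approx(expected, abs=5e-4)

    def test_subtype_ordering(self, pub):
        vals = {s: d50(pub, s).d50 for s in ("PV", "VM", "PO", "RBP4", "NXPH4")}
        assert abs(vals["PV"] - vals["VM"]) < 0.02
        assert max(vals["PV"], vals["VM"]) < vals["PO"] < vals["RBP4"] < vals["NXPH4"]

    def test_algebraic_identity_at_one_micron(self):
        fit = reference_fit(
            {"(Intercept)": (-3.0, 0.1), "diam": (5.0, 0.1), "type_VM": (-2.0, 0.1)}
        )
        assert d50(fit, "VM").d50 == pytest.approx(1.0)

    def test_interval_brackets_estimate(self, pub):
        est = d50(pub, "PV")
        lo, hi = est.interval
        assert lo <= est.d50 <= hi

    def test_probability_at_d50_is_half(self, pub):
        for s in ("PV", "PO"):
            est = d50(pub, s)
            assert predict_probability(pub, est.d50, s) == pytest.approx(0.5)


class TestPredict:
    def test_zero_diameter_reference(self):
        fit = reference_fit()
        assert predict_probability(fit, 0.0, "PV") == pytest.approx(0.0455, abs=5e-4)

    def test_large_diameter_near_certain(self):
        fit = reference_fit()
        assert predict_probability(fit, 2.0, "PV") > 0.99

    def test_strictly_increasing_in_diameter(self):
        fit = reference_fit()
        probs = [predict_probability(fit, x, "VM") for x in np.linspace(0.1, 1.5, 30)]
        assert np.all(np.diff(probs) > 0)
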