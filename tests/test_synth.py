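"""Synthetic-data generators: determinism, structure, oracle agreement."""

import numpy as np
import pytest

from myelotrace.coverage import compute_plm, extract_gaps
from myelotrace.diameter import fwhm
from myelotrace.glm import LAYER1_GLM_COEFFICIENTS
from myelotrace.synth import (
    DEFAULT_SUBTYPE_PARAMS,
    RemodelingParams,
    SubtypeParams,
    default_glm_coefficients,
    gen_axon_population,
    gen_intensity_profiles,
    gen_longitudinal,
    simulate_glm_dataset,
)


class TestAxonPopulation:
    def test_zero_axons(self):
        traces, anns, table = gen_axon_population(n_per_subtype=0, seed=0)
        assert traces == [] and anns == [] and table.empty

    def test_deterministic_given_seed(self):
        out1 = gen_axon_population(n_per_subtype=5, seed=33)
        out2 = gen_axon_population(n_per_subtype=5, seed=33)
        assert out1[2].equals(out2[2])
        assert [(a.axon_id, a.s_start, a.s_end) for a in out1[1]] == [
            (a.axon_id, a.s_start, a.s_end) for a in out2[1]
        ]

    def test_saturating_diameter_coefficient_myelinates_everything(self):
        coefs = {"(Intercept)": 0.0, "diam": 100.0}
        params = [DEFAULT_SUBTYPE_PARAMS["PV"]]
        _, _, table = gen_axon_population(params, coefs, n_per_subtype=50, seed=1)
        assert table["myelinated"].all()

    def test_proportion_myelinated_follows_d50_ordering(self):
        """Empirical myelination proportions are monotone in the subtype
        d50 ordering of the generative model (PV ≈ VM > PO > RBP4 > NXPH4)."""
        subs = ["PV", "VM", "PO", "RBP4", "NXPH4"]
        params = [DEFAULT_SUBTYPE_PARAMS[s] for s in subs]
        _, _, table = gen_axon_population(params, n_per_subtype=2000, seed=2)
        prop = table.groupby("subtype")["myelinated"].mean()
        assert min(prop["PV"], prop["VM"]) > prop["PO"] > prop["RBP4"] > prop["NXPH4"]

    def test_gap_structure_respects_nodal_partition(self):
        params = [DEFAULT_SUBTYPE_PARAMS["PV"]]
        traces, anns, _ = gen_axon_population(params, n_per_subtype=200, seed=3)
        by_axon = {}
        for a in anns:
            by_axon.setdefault(a.axon_id, []).append(a)
        gaps = [g for anns_ in by_axon.values() for g in extract_gaps(sorted(anns_, key=lambda a: a.s_start))]
        assert gaps, "generator produced no gaps"
        nodal = [g for g in gaps if g.nodal]
        for g in nodal:
            assert g.length <= 5.0
        for g in gaps:
            if not g.nodal:
                assert 5.0 < g.length <= 150.0
        # generative nodal fraction recovered within binomial error
        frac = len(nodal) / len(gaps)
        p = DEFAULT_SUBTYPE_PARAMS["PV"].p_nodal
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / len(gaps))

    def test_no_jitter_never_exceeds_100(self):
        traces, anns, _ = gen_axon_population(
            [DEFAULT_SUBTYPE_PARAMS["PV"]], n_per_subtype=100, seed=4, jitter_sd=0.0
        )
        by_axon = {}
        for a in anns:
            by_axon.setdefault(a.axon_id, []).append(a)
        for t in traces:
            prof = compute_plm(t, by_axon.get(t.axon_id, []))
            assert prof.plm <= 100.0
            assert 100.0 * prof.myelinated_length / prof.total_length <= 100.0 + 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SubtypeParams(subtype="PV", diameter_mean=-1.0, diameter_sd=0.1, beta_type=0.0)
        with pytest.raises(ValueError):
            SubtypeParams(
                subtype="PV",
                diameter_mean=0.6,
                diameter_sd=0.1,
                beta_type=0.0,
                nodal_gap_range=(1.0, 7.0),
            )


class TestIntensityProfiles:
    def test_noiseless_box_recovers_diameter(self):
        prof = gen_intensity_profiles([0.6], psf_sigma=0.0, noise_sd=0.0)[0]
        spacing = prof.positions[1] - prof.positions[0]
        assert fwhm(prof) == pytest.approx(0.6, abs=spacing)

    def test_narrow_box_approaches_psf_width(self):
        # width ≪ σ: the box acts as a delta and FWHM → 2√(2 ln 2)·σ
        sigma = 0.3
        prof = gen_intensity_profiles([0.01], psf_sigma=sigma, noise_sd=0.0, samples_per_um=200)[0]
        assert fwhm(prof) == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, rel=0.01)

    def test_matches_numerical_convolution_oracle(self):
        """Mean FWHM over noisy profiles agrees with a dense numerical
        convolution + exact half-max search oracle within 10%."""
        d, sigma = 0.6, 0.1
        profiles = gen_intensity_profiles(
            [d] * 50, psf_sigma=sigma, noise_sd=0.05, seed=8
        )
        measured = np.mean([fwhm(p) for p in profiles])

        # oracle: dense grid convolution of the box with the Gaussian
        dx = 1e-4
        x = np.arange(-2.0, 2.0, dx)
        box = ((x >= -d / 2) & (x <= d / 2)).astype(float)
        kern = np.exp(-(x**2) / (2 * sigma**2))
        kern /= kern.sum()
        conv = np.convolve(box, kern, mode="same")
        half = conv.max() / 2
        above = np.where(conv >= half)[0]
        oracle = (above[-1] - above[0]) * dx
        assert measured == pytest.approx(oracle, rel=0.10)

    def test_deterministic(self):
        a = gen_intensity_profiles([0.5], noise_sd=0.05, seed=5)[0]
        b = gen_intensity_profiles([0.5], noise_sd=0.05, seed=5)[0]
        np.testing.assert_array_equal(a.values, b.values)


class TestLongitudinal:
    def test_noiseless_linear_form(self):
        rem = RemodelingParams(gain_at_zero=20, loss_at_full=10, noise_sd=0, pivot=50)
        recs = gen_longitudinal([0.0, 99.0], rem, seed=0)
        assert recs[0].plm_recovery == pytest.approx(20.0)
        assert recs[1].plm_recovery == pytest.approx(89.2)

    def test_no_remodeling_no_noise_is_identity(self):
        rem = RemodelingParams(gain_at_zero=0, loss_at_full=0, noise_sd=0)
        recs = gen_longitudinal([0.0, 25.0, 75.0], rem, seed=0)
        assert [r.plm_recovery for r in recs] == [0.0, 25.0, 75.0]
        assert recs[0].status == "excluded_always_unmyelinated"

    def test_deterministic(self):
        rem = RemodelingParams()
        a = gen_longitudinal([10.0] * 20, rem, seed=6)
        b = gen_longitudinal([10.0] * 20, rem, seed=6)
        assert a == b

    def test_weak_axons_gain_strong_axons_lose(self):
        rem = RemodelingParams(gain_at_zero=20, loss_at_full=10, noise_sd=5, pivot=50)
        recs = gen_longitudinal(list(np.linspace(1, 99, 200)), rem, seed=7)
        deltas = np.array([r.plm_recovery - r.plm_baseline for r in recs])
        baselines = np.array([r.plm_baseline for r in recs])
        assert deltas[baselines < 25].mean() > 0
        assert deltas[baselines > 75].mean() < 0


def test_simulate_glm_dataset_statistics():
    data = simulate_glm_dataset(n=5000, seed=10)
    diam = np.array([d for d, _, _ in data])
    assert 0.2 <= diam.min() and diam.max() <= 1.2
    subs = {s for _, s, _ in data}
    assert subs == {"PV", "VM", "PO", "RBP4", "NXPH4"}
    # overall myelination rate should be far from degenerate
    y = np.array([r for _, _, r in data])
    assert 0.2 < y.mean() < 0.8


def test_default_coefficients_are_point_estimates():
    coefs = default_glm_coefficients()
    assert coefs["diam"] == LAYER1_GLM_COEFFICIENTS["diam"][0]
    assert coefs["(Intercept)"] == LAYER1_GLM_COEFFICIENTS["(Intercept)"][0]
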