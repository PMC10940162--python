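"""Convolution-basis counting: PDF estimation, basis construction,
mixture fitting, aggregation and calibration diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from minusend import counting, simulate
from minusend.counting import NmerMixture


@pytest.fixture(scope="module")
def monomer_pdf(monomer_sample):
    return counting.estimate_pdf(monomer_sample.intensities)


@pytest.fixture(scope="module")
def basis(monomer_pdf):
    return counting.build_nmer_basis(monomer_pdf, n_max=8)


class TestEstimatePdf:
    def test_density_normalized(self, monomer_sample):
        pdf = counting.estimate_pdf(monomer_sample.intensities)
        assert pdf.density.sum() * pdf.width == pytest.approx(1.0,
                                                              abs=1e-9)

    def test_equal_samples_single_bin(self):
        pdf = counting.estimate_pdf(np.full(100, 3.0), binning=10)
        assert (pdf.density > 0).sum() == 1

    def test_too_few_samples_names_floor(self):
        with pytest.raises(ValueError, match="50"):
            counting.estimate_pdf(np.ones(10))

    def test_ecdf_close_to_true_cdf(self, monomer_model):
        ds = simulate.gen_monomer_intensities(monomer_model, 100_000,
                                              seed=51)
        x = np.sort(ds.intensities)
        sigma2 = np.log1p(monomer_model.cv ** 2)
        mu = np.log(monomer_model.mean) - sigma2 / 2
        true_cdf = stats.lognorm.cdf(x, s=np.sqrt(sigma2),
                                     scale=np.exp(mu))
        ecdf = np.arange(1, x.size + 1) / x.size
        assert np.max(np.abs(ecdf - true_cdf)) < 0.01

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), n=st.integers(60, 500))
    def test_normalization_property(self, seed, n):
        x = np.random.default_rng(seed).gamma(2.0, 10.0, n)
        pdf = counting.estimate_pdf(x)
        assert pdf.density.sum() * pdf.width == pytest.approx(1.0,
                                                              abs=1e-9)


class TestNmerBasis:
    def test_delta_monomer_gives_delta_members(self):
        edges = np.linspace(0, 20.0, 41)  # width 0.5
        dens = np.zeros(40)
        dens[19] = 1 / 0.5  # all mass in the bin centred at 9.75
        pdf = counting.IntensityPDF(edges, dens, n_samples=100)
        mu = pdf.mean()
        basis = counting.build_nmer_basis(pdf, n_max=3)
        for n in (1, 2, 3):
            m = basis.pdfs[n]
            peak = m.centers[np.argmax(m.density)]
            assert abs(peak - n * mu) <= m.width
            # all mass within one bin of N x the monomer mean
            near = np.abs(m.centers - n * mu) <= m.width
            assert m.density[~near].sum() * m.width < 1e-9

    def test_members_normalized(self, basis):
        for n, pdf in basis.pdfs.items():
            assert pdf.density.sum() * pdf.width == pytest.approx(
                1.0, abs=1e-6)

    def test_moment_identities(self, monomer_pdf, basis):
        m1, v1 = monomer_pdf.mean(), monomer_pdf.var()
        for n in range(1, 9):
            member = basis.pdfs[n]
            assert abs(member.mean() - n * m1) <= monomer_pdf.width / 2
            assert member.var() == pytest.approx(n * v1, rel=0.02)

    def test_fft_matches_direct_convolution(self, monomer_sample):
        pdf = counting.estimate_pdf(monomer_sample.intensities,
                                    binning=256)
        b_fft = counting.build_nmer_basis(pdf, 4, method="fft")
        b_dir = counting.build_nmer_basis(pdf, 4, method="direct")
        for n in (2, 3, 4):
            assert np.max(np.abs(b_fft.pdfs[n].density
                                 - b_dir.pdfs[n].density)) < 1e-8


class TestFitMixture:
    def test_monomer_only_recovers_w1(self, monomer_model, basis):
        ds = simulate.gen_monomer_intensities(monomer_model, 10_000,
                                              seed=52)
        fit = counting.fit_mixture(ds.intensities, basis)
        assert fit.weights[1] >= 0.9

    def test_two_component_recovery(self, monomer_model, basis):
        true_w = {1: 0.5, 4: 0.5}
        scen = simulate.OligomerScenario(weights=true_w, p_active=1.0,
                                         n_puncta=20_000, seed=53)
        olig = simulate.gen_oligomer_dataset(scen, monomer_model)
        fit = counting.fit_mixture(olig.intensities, basis)
        for n, w in true_w.items():
            assert abs(fit.weights[n] - w) <= 0.07

    def test_weights_sum_to_one_nonnegative(self, monomer_model, basis):
        scen = simulate.scenario_bimodal_gcp3(n_puncta=5000, seed=54)
        olig = simulate.gen_oligomer_dataset(scen, monomer_model)
        fit = counting.fit_mixture(olig.intensities, basis)
        w = np.array(list(fit.weights.values()))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_overlap_raises(self, basis):
        top = basis.bin_edges[-1]
        with pytest.raises(ValueError, match="overlap"):
            counting.fit_mixture(np.full(200, top * 50), basis)

    def test_fitted_curve_is_weighted_member_sum(self, monomer_model,
                                                 monomer_sample):
        scen = simulate.scenario_bimodal_gcp3(n_puncta=10_000, seed=55)
        olig = simulate.gen_oligomer_dataset(scen, monomer_model)
        est = NmerMixture(monomer=monomer_sample.intensities,
                          n_max=8).fit(olig.intensities)
        total = est.predict_density()
        manual = sum(est.weights_[n] * est.basis_.pdfs[n].density
                     for n in range(1, 9))
        np.testing.assert_allclose(total, manual, atol=1e-12)

    def test_scale_invariance(self, monomer_model):
        # rescaling all intensities (a.u. gauge freedom) leaves weights
        scen = simulate.OligomerScenario(weights={1: 0.5, 4: 0.5},
                                         n_puncta=10_000, seed=56)
        olig = simulate.gen_oligomer_dataset(scen, monomer_model)
        mono = simulate.gen_monomer_intensities(monomer_model, 10_000,
                                                seed=57)
        w_ref = NmerMixture(monomer=mono.intensities, binning=200
                            ).fit(olig.intensities).weights_
        scale = 7.3
        w_scaled = NmerMixture(monomer=mono.intensities * scale,
                               binning=200
                               ).fit(olig.intensities * scale).weights_
        for n in range(1, 9):
            assert w_scaled[n] == pytest.approx(w_ref[n], abs=1e-9)


class TestEndToEndRecovery:
    TRUE_W = {1: 0.4, 2: 0.1, 4: 0.35, 6: 0.15}

    def _l1(self, weights):
        return sum(abs(weights.get(n, 0.0) - self.TRUE_W.get(n, 0.0))
                   for n in range(1, 9))

    def test_full_pipeline_l1(self, monomer_model, monomer_sample):
        scen = simulate.OligomerScenario(weights=self.TRUE_W,
                                         p_active=1.0, n_puncta=20_000,
                                         seed=58)
        olig = simulate.gen_oligomer_dataset(scen, monomer_model)
        est = NmerMixture(monomer=monomer_sample.intensities,
                          n_max=8).fit(olig.intensities)
        assert self._l1(est.weights_) < 0.15

    def test_error_decreases_with_sample_size(self, monomer_model):
        true_w = {1: 0.4, 4: 0.6}  # separated by >= 2 sizes
        mean_err = {}
        for n in (1_000, 10_000, 100_000):
            errs = []
            for seed in range(20):
                mono = simulate.gen_monomer_intensities(
                    monomer_model, 10_000, seed=600 + seed)
                basis = counting.build_nmer_basis(
                    counting.estimate_pdf(mono.intensities), 8)
                olig = simulate.gen_oligomer_dataset(
                    simulate.OligomerScenario(weights=true_w,
                                              n_puncta=n,
                                              seed=700 + seed),
                    monomer_model)
                fit = counting.fit_mixture(olig.intensities, basis)
                errs.append(sum(abs(fit.weights.get(k, 0)
                                    - true_w.get(k, 0))
                                for k in range(1, 9)))
            mean_err[n] = np.mean(errs)
        assert mean_err[1_000] > mean_err[10_000] > mean_err[100_000]


class TestAggregateAndDiagnostics:
    def _fit(self, weights):
        return counting.MixtureFit(weights=weights, residual=0.0,
                                   n_samples=100)

    def test_single_fit_sd_zero(self):
        agg = counting.aggregate_weights([self._fit({1: 0.3, 2: 0.7})])
        assert agg.loc[1, "mean"] == 0.3
        assert (agg["sd"] == 0).all()

    def test_two_fits_hand_arithmetic(self):
        agg = counting.aggregate_weights(
            [self._fit({2: 0.4, 1: 0.6}), self._fit({2: 0.6, 1: 0.4})])
        assert agg.loc[2, "mean"] == pytest.approx(0.5)
        assert agg.loc[2, "sd"] == pytest.approx(np.sqrt(2) * 0.1,
                                                 abs=1e-6)

    def test_missing_sizes_count_as_zero(self):
        agg = counting.aggregate_weights(
            [self._fit({1: 1.0}), self._fit({3: 1.0})])
        assert agg.loc[3, "mean"] == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            counting.aggregate_weights([])

    def test_identical_samples_ratio_one(self):
        x = np.linspace(1, 2, 100)
        r = counting.brightness_ratio(x, x, seed=0)
        assert r.ratio == 1.0

    def test_ideal_dimer_ratio_two(self, monomer_model):
        mono = simulate.gen_monomer_intensities(monomer_model, 50_000,
                                                seed=61)
        dim = simulate.gen_oligomer_dataset(
            simulate.OligomerScenario(weights={2: 1.0}, p_active=1.0,
                                      n_puncta=50_000, seed=62),
            monomer_model)
        r = counting.brightness_ratio(dim.intensities, mono.intensities,
                                      seed=63)
        assert abs(r.ratio - 2.0) < 3 * r.se

    def test_partial_maturation_dimer_closed_form(self, monomer_model):
        # E[k | k>=1], k ~ Binom(2, 0.7): 2*0.7 / (1 - 0.3^2)
        expected = 1.4 / 0.91
        mono = simulate.gen_monomer_intensities(monomer_model, 50_000,
                                                seed=64)
        dim = simulate.gen_oligomer_dataset(
            simulate.OligomerScenario(weights={2: 1.0}, p_active=0.7,
                                      n_puncta=50_000, seed=65),
            monomer_model)
        r = counting.brightness_ratio(dim.intensities, mono.intensities,
                                      seed=66)
        assert abs(r.ratio - expected) < 3 * r.se

    def test_normalize_active_intensities(self):
        classes = {"released": [2.0, 4.0], "bound": [3.0]}
        out, summary = counting.normalize_active_intensities(classes, 2.0)
        np.testing.assert_allclose(out["released"], [1.0, 2.0])
        assert summary.loc["released", "mean"] == pytest.approx(1.5)

    def test_null_classes_center_on_one(self, monomer_model):
        rng = np.random.default_rng(67)
        pop = simulate.gen_monomer_intensities(monomer_model, 3000,
                                               seed=68).intensities
        ref = pop.mean()
        classes = {f"c{i}": rng.choice(pop, 300) for i in range(3)}
        _, summary = counting.normalize_active_intensities(classes, ref)
        for _, row in summary.iterrows():
            assert abs(row["mean"] - 1.0) < 3 * row["sem"]

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            counting.normalize_active_intensities({"a": [1.0]}, 0.0)


class TestSklearnInterface:
    def test_get_set_params_roundtrip(self, monomer_sample):
        est = NmerMixture(monomer=monomer_sample.intensities, n_max=6)
        params = est.get_params()
        assert params["n_max"] == 6
        est.set_params(n_max=4)
        assert est.n_max == 4

    def test_clone_and_column_vector_input(self, monomer_model,
                                           monomer_sample):
        from sklearn.base import clone

        olig = simulate.gen_oligomer_dataset(
            simulate.OligomerScenario(weights={2: 1.0}, n_puncta=2000,
                                      seed=69), monomer_model)
        est = NmerMixture(monomer=monomer_sample.intensities, n_max=4)
        w1 = clone(est).fit(olig.intensities).weights_
        w2 = clone(est).fit(olig.intensities[:, None]).weights_
        assert w1 == w2
        assert sum(w1.values()) == pytest.approx(1.0)
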