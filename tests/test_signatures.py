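import numpy as np
import pytest
from sklearn.svm import SVC, SVR

from mikern import (
    AbundanceTable,
    MKLWeights,
    Signature,
    average_signatures,
    clin_kernel,
    clr_transform,
    crbf_kernel,
    flin_multivariate,
    hyperplane_weights,
    replace_zeros,
    select_top_fraction,
    signature_from_clin_svm,
    signature_longitudinal,
    signature_spatial_aggregate,
    simulate_longitudinal,
    SimulationConfig,
    svm_train,
    TimeSeriesTable,
)

from conftest import make_positive_table


def _planted_single_feature(seed=0, n=40, d=12, shift=6.0):
    """Only taxon 0 separates the classes on the clr scale."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = rng.lognormal(mean=1.0, sigma=0.3, size=(n, d))
    x[y == 1, 0] *= np.exp(shift)
    table = AbundanceTable(x, [f"s{i}" for i in range(n)],
                           [f"t{j}" for j in range(d)])
    return table, y


class TestClinSignature:
    def test_importance_concentrates_on_the_planted_feature(self):
        # features fixed directly on the clr scale: only column 0 varies
        # between samples, every other column is identical everywhere
        rng = np.random.default_rng(0)
        n, d = 40, 12
        y = np.repeat([0, 1], n // 2)
        z = np.tile(rng.normal(size=d), (n, 1))
        z[:, 0] = rng.normal(size=n) + np.where(y == 1, 3.0, -3.0)
        from mikern import KernelMatrix
        K = KernelMatrix(z @ z.T, [f"s{i}" for i in range(n)], {"name": "clin"})
        model = svm_train(K, y, cost=10.0)
        sig = signature_from_clin_svm(model, z, [f"t{j}" for j in range(d)])
        assert sig.importances[0] > 0.9
        assert sig.importances.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(sig.importances >= 0)

    @pytest.mark.parametrize("cost", [0.1, 1.0, 10.0])
    def test_dual_expansion_matches_primal_linear_svm(self, cost):
        table, y = _planted_single_feature(seed=3, shift=2.0)
        clr = clr_transform(table)
        model = svm_train(clin_kernel(table), y, cost=cost)
        w_dual = hyperplane_weights(model, clr)
        primal = SVC(C=cost, kernel="linear").fit(clr, y)
        np.testing.assert_allclose(w_dual, primal.coef_[0], rtol=1e-5, atol=1e-8)

    def test_regression_dual_matches_primal(self):
        rng = np.random.default_rng(5)
        table = make_positive_table(rng, n=30, d=8)
        clr = clr_transform(table)
        y = clr @ rng.normal(size=8) + rng.normal(scale=0.1, size=30)
        model = svm_train(clin_kernel(table), y, task="regression", cost=1.0)
        w_dual = hyperplane_weights(model, clr)
        primal = SVR(C=1.0, kernel="linear").fit(clr, y)
        np.testing.assert_allclose(w_dual, primal.coef_[0], rtol=1e-5, atol=1e-8)

    def test_non_linear_kernel_refused(self):
        table, y = _planted_single_feature()
        model = svm_train(crbf_kernel(table, 0.1), y)
        with pytest.raises(ValueError, match="linear"):
            signature_from_clin_svm(model, clr_transform(table), table.taxon_ids)

    def test_signature_invariant_to_per_sample_rescaling(self):
        table, y = _planted_single_feature(seed=7, shift=2.0)
        rng = np.random.default_rng(8)
        scaled = table.with_values(table.values * rng.uniform(0.5, 2.0,
                                                              (table.n_samples, 1)))
        s1 = signature_from_clin_svm(svm_train(clin_kernel(table), y, cost=1.0),
                                     clr_transform(table), table.taxon_ids)
        s2 = signature_from_clin_svm(svm_train(clin_kernel(scaled), y, cost=1.0),
                                     clr_transform(scaled), scaled.taxon_ids)
        np.testing.assert_allclose(s1.importances, s2.importances, atol=1e-8)


class TestSpatialAggregation:
    def _sig(self, raw, taxa=None):
        raw = np.asarray(raw, dtype=float)
        taxa = taxa or [f"t{j}" for j in range(raw.size)]
        return Signature(taxa, raw / raw.sum(), raw=raw)

    def test_single_site_identity(self):
        sig = self._sig([4.0, 1.0, 0.0])
        out = signature_spatial_aggregate([sig], MKLWeights(np.array([1.0])))
        np.testing.assert_allclose(out.importances, sig.importances)

    def test_identical_sites_half_half(self):
        sig = self._sig([2.0, 3.0, 5.0])
        out = signature_spatial_aggregate([sig, sig],
                                          MKLWeights(np.array([0.5, 0.5])))
        np.testing.assert_allclose(out.importances, sig.importances)

    def test_degenerate_weight_ignores_noise_site(self):
        signal = self._sig([9.0, 1.0])
        noise = self._sig([1.0, 9.0])
        out = signature_spatial_aggregate(
            [signal, noise], MKLWeights(np.array([1.0, 0.0])))
        np.testing.assert_allclose(out.importances, signal.importances)

    def test_union_with_zero_fill_warns(self):
        a = self._sig([1.0, 1.0], taxa=["t1", "t2"])
        b = self._sig([2.0], taxa=["t3"])
        with pytest.warns(UserWarning, match="union"):
            out = signature_spatial_aggregate([a, b],
                                              MKLWeights(np.array([0.5, 0.5])))
        assert out.taxon_ids == ["t1", "t2", "t3"]
        assert out.importances.sum() == pytest.approx(1.0)


class TestLongitudinalSignature:
    def test_single_timepoint_reduces_to_clin_signature(self):
        table, y = _planted_single_feature(shift=2.0)
        clr = clr_transform(table)
        ts = TimeSeriesTable(clr[:, :, None], table.sample_ids, table.taxon_ids,
                             [0.0])
        model = svm_train(flin_multivariate(ts, dt=1.0), y, cost=1.0)
        sig_long = signature_longitudinal(model, ts.flattened(), table.taxon_ids, 1)
        model_clin = svm_train(clin_kernel(table), y, cost=1.0)
        sig_clin = signature_from_clin_svm(model_clin, clr, table.taxon_ids)
        np.testing.assert_allclose(sig_long.importances, sig_clin.importances,
                                   atol=1e-8)

    def test_signal_at_last_timepoint_ranks_planted_taxon_first(self):
        from mikern import clr_timeseries
        res = simulate_longitudinal(SimulationConfig(
            n_individuals=60, n_taxa=30, n_informative=1, effect_size=4.0,
            informative_indices=[2], n_timepoints=3, informative_timepoints=[3],
            seed=9))
        ts = clr_timeseries(res.timeseries)
        model = svm_train(flin_multivariate(ts), res.y, cost=1.0)
        sig = signature_longitudinal(model, ts.flattened(), ts.taxon_ids,
                                     ts.n_timepoints)
        assert sig.ranking()[0][0] == ts.taxon_ids[2]
        assert sig.importances.sum() == pytest.approx(1.0, abs=1e-10)

    def test_layout_mismatch_rejected(self):
        table, y = _planted_single_feature()
        clr = clr_transform(table)
        ts = TimeSeriesTable(clr[:, :, None], table.sample_ids, table.taxon_ids,
                             [0.0])
        model = svm_train(flin_multivariate(ts, dt=1.0), y)
        with pytest.raises(ValueError, match="layout"):
            signature_longitudinal(model, ts.flattened(), table.taxon_ids, 5)


class TestTopFraction:
    def test_full_fraction_keeps_everything(self):
        sig = Signature([f"t{j}" for j in range(10)], np.full(10, 0.1))
        subset, share = select_top_fraction(sig, 1.0)
        assert len(subset.taxon_ids) == 10
        assert share == pytest.approx(1.0)

    def test_uniform_importances_five_percent(self):
        sig = Signature([f"t{j:03d}" for j in range(100)], np.full(100, 0.01))
        subset, share = select_top_fraction(sig, 0.05)
        assert len(subset.taxon_ids) == 5
        assert share == pytest.approx(0.05)
        # lexical tie-break: the first five ids
        assert subset.taxon_ids == [f"t{j:03d}" for j in range(5)]

    def test_skewed_signature_concentrates_share(self):
        raw = np.full(200, 0.01)
        raw[:10] = 10.0  # 10 planted taxa dominate
        sig = Signature([f"t{j:03d}" for j in range(200)], raw / raw.sum(), raw=raw)
        subset, share = select_top_fraction(sig, 0.05)
        assert len(subset.taxon_ids) == 10
        assert share > 0.9


class TestAveraging:
    def test_mean_and_stderr_across_replicates(self):
        taxa = ["a", "b"]
        sigs = [Signature(taxa, np.array([0.6, 0.4])),
                Signature(taxa, np.array([0.8, 0.2]))]
        avg = average_signatures(sigs)
        np.testing.assert_allclose(avg.importances, [0.7, 0.3])
        np.testing.assert_allclose(avg.stderr, np.std([[0.6, 0.8], [0.4, 0.2]],
                                                      axis=1, ddof=1) / np.sqrt(2))
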