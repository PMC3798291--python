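"""Induction calling, permutation FDR and cross-dataset comparison."""

import numpy as np
import pandas as pd
import pytest

import actikin as ak
from actikin.detection import (
    DetectionParams,
    call_induced,
    compute_logfc,
    crossdataset_correlation,
    estimate_fdr_by_permutation,
)
from actikin.error_model import ErrorModel, ZMatrix, compute_z, fit_error_model


def _zmatrix(rows, timepoints=(1, 4, 8, 24)):
    ids = [f"ps{i}" for i in range(len(rows))]
    z = pd.DataFrame(rows, index=ids, columns=list(timepoints))
    m0 = pd.Series(8.0, index=ids)
    return ZMatrix(z=z, control_mean=m0, timepoint_means=z * 0 + 8.0)


def _presence(index, count, n_samples=18):
    flags = np.zeros((len(index), n_samples), dtype=int)
    flags[:, :count] = 1
    return pd.DataFrame(flags, index=index,
                        columns=[f"s{i}" for i in range(n_samples)])


class TestCallInduced:
    def test_any_timepoint_threshold(self):
        z = _zmatrix([[6, 1, 1, 1], [1, 1, 1, 1], [5.1, 0, 0, 0]])
        calls = call_induced(z, _presence(z.z.index, 18))
        assert calls["induced"].tolist() == [True, False, True]

    def test_presence_filter_vetoes_high_z(self):
        """Z=10 but present on only 2 arrays is not induced (min 3)."""
        z = _zmatrix([[10, 0, 0, 0]])
        calls = call_induced(z, _presence(z.z.index, 2))
        assert not calls["induced"].any()
        calls3 = call_induced(z, _presence(z.z.index, 3))
        assert calls3["induced"].all()

    def test_two_sided_mode_catches_downregulation(self):
        z = _zmatrix([[-8, -2, 0, 0]])
        pres = _presence(z.z.index, 18)
        assert not call_induced(z, pres)["induced"].any()
        assert call_induced(z, pres, DetectionParams(two_sided=True))["induced"].all()

    def test_peak_timepoint_is_argmax(self):
        z = _zmatrix([[2, 9, 4, 1]])
        calls = call_induced(z, _presence(z.z.index, 18))
        assert calls["peak_timepoint"].iloc[0] == 4
        assert calls["max_z"].iloc[0] == 9

    def test_threshold_monotonicity(self, study_dataset):
        """Raising the Z threshold can only shrink the induced set."""
        ds = study_dataset
        model = fit_error_model(ds.expression, ds.design)
        z = compute_z(ds.expression, ds.design, model)
        sets = []
        for thr in (3.0, 5.0, 8.0, 12.0):
            calls = call_induced(z, ds.presence, DetectionParams(z_threshold=thr))
            sets.append(set(calls.index[calls["induced"]]))
        for small, large in zip(sets[1:], sets[:-1]):
            assert small <= large

    def test_recovery_against_truth(self, study_dataset, study_calls):
        """>=95% of planted induced probe sets called; truth FDR <=5%."""
        truth = study_dataset.truth.probesets
        calls = study_calls
        induced_true = truth.index[truth["induced"]]
        sensitivity = calls.loc[induced_true, "induced"].mean()
        called = calls.index[calls["induced"]]
        fdr = (~truth.loc[called, "induced"]).mean() if len(called) else 0.0
        assert sensitivity >= 0.95
        assert fdr <= 0.05


class TestPermutationFdr:
    def test_fdr_is_mean_null_over_observed(self, study_dataset):
        ds = study_dataset
        est = estimate_fdr_by_permutation(
            ds.expression, ds.design, ds.presence, DetectionParams(seed=11)
        )
        assert est.n_permutations == 25
        assert est.fdr == pytest.approx(
            np.mean(est.null_positive_counts) / est.observed_positives
        )

    def test_below_paper_bound_on_planted_data(self, study_dataset):
        ds = study_dataset
        est = estimate_fdr_by_permutation(
            ds.expression, ds.design, ds.presence, DetectionParams(seed=11)
        )
        assert est.observed_positives > 0
        assert est.fdr < 0.05

    def test_seeded_determinism(self, study_dataset):
        ds = study_dataset
        runs = [
            estimate_fdr_by_permutation(
                ds.expression, ds.design, ds.presence, DetectionParams(seed=11)
            )
            for _ in range(2)
        ]
        assert runs[0].null_positive_counts == runs[1].null_positive_counts

    def test_zero_observed_warns_and_reports_zero(self, study_dataset):
        ds = study_dataset
        params = DetectionParams(z_threshold=1e9, seed=11, n_permutations=5)
        with pytest.warns(UserWarning, match="no observed positives"):
            est = estimate_fdr_by_permutation(
                ds.expression, ds.design, ds.presence, params
            )
        assert est.fdr == 0.0

    @pytest.mark.filterwarnings("ignore:no observed positives")
    def test_exchangeability_under_null(self):
        """On null data, observed and permutation null counts look alike."""
        from scipy.stats import ks_2samp

        observed, nulls = [], []
        for seed in range(12):
            cfg = ak.SimConfig(n_genes=400, multi_probeset_frac=0.0, seed=100 + seed)
            ds = ak.simulate_null(cfg)
            est = estimate_fdr_by_permutation(
                ds.expression, ds.design, ds.presence,
                DetectionParams(seed=seed, n_permutations=10),
            )
            observed.append(est.observed_positives)
            nulls.extend(est.null_positive_counts)
        if len(set(observed)) == 1 and set(nulls) == set(observed):
            return  # identical degenerate samples: trivially exchangeable
        assert ks_2samp(observed, nulls).pvalue > 0.01


class TestLogFc:
    def test_logfc_identity_and_shift(self):
        design = pd.Series([0, 0, 4], index=["c1", "c2", "t4"])
        expr = pd.DataFrame({"c1": [8.0, 5.0], "c2": [8.0, 5.0],
                             "t4": [10.0, 5.0]}, index=["up", "flat"])
        lf = compute_logfc(expr, design)
        assert lf.loc["up", 4] == pytest.approx(2.0)
        assert lf.loc["flat", 4] == pytest.approx(0.0)

    def test_logfc_equals_z_times_sd(self, study_dataset):
        """Algebraic cross-check: logFC = Z * sd(control mean), cellwise."""
        ds = study_dataset
        model = fit_error_model(ds.expression, ds.design)
        z = compute_z(ds.expression, ds.design, model)
        lf = compute_logfc(ds.expression, ds.design)
        rebuilt = z.z.mul(z.sd_at_control, axis=0)
        assert np.allclose(lf.to_numpy(), rebuilt.to_numpy(), atol=1e-10)


class TestCrossDataset:
    def test_identical_vectors(self):
        lf = pd.DataFrame({4: [1.0, 2.0, 3.0]}, index=list("abc"))
        assert crossdataset_correlation(lf, lf, list("abc"), 4) == pytest.approx(1.0)

    def test_negated_vector(self):
        lf = pd.DataFrame({4: [1.0, 2.0, 3.0]}, index=list("abc"))
        assert crossdataset_correlation(lf, -lf, list("abc"), 4) == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        a = pd.DataFrame({4: [1.0, 2.0, 3.0]}, index=list("abc"))
        b = pd.DataFrame({4: [1.0, 1.0, 1.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="variance"):
            crossdataset_correlation(a, b, list("abc"), 4)

    def test_too_few_shared_ids(self):
        lf = pd.DataFrame({4: [1.0, 2.0]}, index=list("ab"))
        with pytest.raises(ValueError, match=">=3"):
            crossdataset_correlation(lf, lf, list("ab"), 4)

    def test_shared_biology_replicates_across_strains(self):
        """Two noise realisations of one truth correlate strongly at peak."""
        cfg = ak.SimConfig(n_genes=600, multi_probeset_frac=0.0, seed=1)
        a = ak.simulate_timecourse(cfg)
        b = ak.simulate_from_truth(a.truth, cfg, seed=2)
        lfa = compute_logfc(a.expression, a.design)
        lfb = compute_logfc(b.expression, b.design)
        truth = a.truth.probesets
        induced = truth.index[truth["induced"]]
        lfc_cols = a.truth.lfc_columns()
        peak_t = int(
            truth.loc[induced, lfc_cols].mean().idxmax().split("_")[1].rstrip("h")
        )
        r = crossdataset_correlation(lfa, lfb, induced, peak_t)
        assert r > 0.8
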