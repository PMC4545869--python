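import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ewasrf import (
    MethylationDataset,
    adjust_batch,
    beta_matrix_to_m,
    filter_detection,
    probe_accounting,
    recode_outliers,
    remove_sex_chromosomes,
    remove_snp_probes,
    run_qc,
)
from ewasrf.errors import DegenerateInputError, MissingAnnotationError


def _dataset(beta, detection=None):
    probes = [f"cg{i:05d}" for i in range(beta.shape[0])]
    samples = [f"S{i}" for i in range(beta.shape[1])]
    det = None if detection is None else pd.DataFrame(detection, index=probes,
                                                      columns=samples)
    return MethylationDataset(
        beta=pd.DataFrame(beta, index=probes, columns=samples),
        detection_p=det)


class TestDetectionFilter:
    def test_boundary_is_strict(self):
        """10 samples: failing in 2 (20%) removes; failing in exactly 1
        (10%, not strictly greater) retains."""
        beta = np.full((2, 10), 0.5)
        det = np.full((2, 10), 0.001)
        det[0, :2] = 0.5   # fails in 2/10
        det[1, 0] = 0.5    # fails in 1/10
        ds = _dataset(beta, det)
        kept, removed = filter_detection(ds)
        assert removed == ["cg00000"]
        assert list(kept.probe_ids) == ["cg00001"]

    def test_matches_bruteforce_row_scan(self):
        rng = np.random.default_rng(0)
        det = np.where(rng.random((100, 20)) < 0.12, 0.5, 0.001)
        ds = _dataset(np.full((100, 20), 0.5), det)
        kept, removed = filter_detection(ds)
        expected_removed = [ds.probe_ids[i] for i in range(100)
                            if sum(det[i] > 0.01) / 20 > 0.10]
        assert removed == expected_removed
        assert set(kept.probe_ids) | set(removed) == set(ds.probe_ids)

    def test_requires_detection_matrix(self):
        ds = _dataset(np.full((3, 4), 0.5))
        with pytest.raises(DegenerateInputError):
            filter_detection(ds)


class TestAnnotationFilters:
    def _manifest(self, chroms, snp=None):
        n = len(chroms)
        return pd.DataFrame({
            "CHR": chroms,
            "SNP_flag": snp if snp is not None else [False] * n,
        }, index=[f"cg{i:05d}" for i in range(n)])

    def test_sex_probes_removed_exactly(self):
        ds = _dataset(np.full((5, 4), 0.5))
        man = self._manifest(["1", "X", "Y", "X", "22"])
        kept, removed = remove_sex_chromosomes(ds, man)
        assert removed == ["cg00001", "cg00002", "cg00003"]
        assert kept.n_probes == 2

    def test_no_sex_probes_identity(self):
        ds = _dataset(np.full((3, 4), 0.5))
        kept, removed = remove_sex_chromosomes(ds, self._manifest(["1", "2", "3"]))
        assert removed == [] and list(kept.probe_ids) == list(ds.probe_ids)

    def test_snp_flag_removal_and_identity(self):
        ds = _dataset(np.full((4, 4), 0.5))
        man = self._manifest(["1"] * 4, snp=[False, True, False, True])
        kept, removed = remove_snp_probes(ds, man)
        assert removed == ["cg00001", "cg00003"]
        kept2, removed2 = remove_snp_probes(kept, man)
        assert removed2 == []

    def test_unannotated_probe_named_in_error(self):
        ds = _dataset(np.full((3, 4), 0.5))
        man = self._manifest(["1", "2"])
        with pytest.raises(MissingAnnotationError, match="cg00002"):
            remove_sex_chromosomes(ds, man)

    def test_generator_truth_recovered(self, small_sim):
        _, (ds, manifest, _, _, truth) = small_sim
        _, sex_removed = remove_sex_chromosomes(ds, manifest)
        assert set(sex_removed) == truth.sex_probes
        _, snp_removed = remove_snp_probes(ds, manifest)
        assert set(snp_removed) == truth.snp_probes


class TestProbeAccounting:
    def test_published_funnel(self):
        remaining, report = probe_accounting(383_998, sex_removed=9_650,
                                             snp_removed=119_888)
        assert remaining == 254_460
        assert report.n_remaining == 254_460

    def test_no_removals(self):
        assert probe_accounting(100, 0, 0)[0] == 100

    def test_matches_set_difference_oracle(self):
        rng = np.random.default_rng(1)
        probes = set(range(500))
        sex = set(rng.choice(500, 60, replace=False))
        snp = set(rng.choice(sorted(probes - sex), 90, replace=False))
        remaining, _ = probe_accounting(len(probes), len(sex), len(snp))
        assert remaining == len(probes - sex - snp)

    def test_inconsistent_funnel_rejected(self):
        with pytest.raises(ValueError):
            probe_accounting(100, 80, 30)


class TestFullFunnel:
    def test_report_reconciles_and_samples_untouched(self, small_sim):
        _, (ds, manifest, _, _, _) = small_sim
        clean, report = run_qc(ds, manifest)
        assert report.n_entry - report.n_detection_removed \
            - report.n_sex_removed - report.n_snp_removed == clean.n_probes
        assert list(clean.sample_ids) == list(ds.sample_ids)
        removed_all = (set(report.detection_removed) | set(report.sex_removed)
                       | set(report.snp_removed))
        assert removed_all.isdisjoint(set(clean.probe_ids))


class TestAdjustBatch:
    def test_constant_offset_aligned(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(20, 30))
        m[:, 15:] += 1.0
        dfm = pd.DataFrame(m, index=[f"p{i}" for i in range(20)],
                           columns=[f"s{i}" for i in range(30)])
        batches = [1] * 15 + [2] * 15
        adj = adjust_batch(dfm, batches)
        means = adj.T.groupby(pd.Series(batches, index=adj.columns)).mean().T
        assert np.allclose(means[1], means[2], atol=1e-9)

    def test_single_batch_identity(self):
        dfm = pd.DataFrame(np.random.default_rng(3).normal(size=(5, 8)))
        pd.testing.assert_frame_equal(adjust_batch(dfm, [1] * 8), dfm)

    def test_singleton_batch_rejected_unless_location_only(self):
        dfm = pd.DataFrame(np.random.default_rng(4).normal(size=(5, 4)))
        with pytest.raises(ValueError, match="singleton"):
            adjust_batch(dfm, [1, 1, 1, 2])
        adjust_batch(dfm, [1, 1, 1, 2], location_only=True)  # allowed

    def test_batch_term_removed_on_simulated_shift(self, small_sim):
        """After location-scale alignment, a per-probe ANOVA on batch should
        be non-significant for at least 95% of null probes."""
        _, (ds, _, pheno, _, truth) = small_sim
        special = truth.informative_probes | truth.sex_probes | truth.snp_probes
        null_probes = [p for p in ds.probe_ids if p not in special]
        m = beta_matrix_to_m(ds.beta.loc[null_probes])
        adj = adjust_batch(m, pheno.loc[m.columns, "batch"])
        b = pheno.loc[m.columns, "batch"].to_numpy()
        pvals = np.array([stats.f_oneway(row[b == 1], row[b == 2]).pvalue
                          for row in adj.to_numpy()])
        # NaN p = no between-batch variation left at all: non-significant
        assert np.mean(pvals < 0.05) <= 0.05


class TestRecodeOutliers:
    def test_constant_probe_untouched(self):
        dfm = pd.DataFrame(np.full((3, 50), 1.7))
        out, recoded = recode_outliers(dfm, [0] * 25 + [1] * 25)
        assert recoded == []
        assert not out.isna().any().any()

    def test_extreme_value_recoded(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=100)
        vals[17] = vals.mean() + 10 * vals.std()
        dfm = pd.DataFrame(vals.reshape(1, -1), index=["p0"],
                           columns=[f"s{i}" for i in range(100)])
        out, recoded = recode_outliers(dfm, [0] * 100, fence_k=3.0)
        # quantile oracle: the planted cell is outside the Tukey fence
        q1, q3 = np.percentile(vals, [25, 75])
        assert vals[17] > q3 + 3 * (q3 - q1)
        assert ("p0", "s17") in recoded
        assert np.isnan(out.loc["p0", "s17"])

    def test_huge_fence_is_identity(self):
        rng = np.random.default_rng(6)
        dfm = pd.DataFrame(rng.normal(size=(10, 40)))
        out, recoded = recode_outliers(dfm, [0] * 20 + [1] * 20, fence_k=1e9)
        assert recoded == []
        pd.testing.assert_frame_equal(out, dfm)
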