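import numpy as np
import pytest
from scipy.stats import spearmanr

from cfcnv.covmatrix import (
    BiasCorrectionConfig,
    CoverageProfile,
    assemble_matrix,
    correct_bias,
    count_coverage,
    normalize_rows,
    prune_windows,
    sample_qc,
)
from cfcnv.windows import ChromSizes, make_windows, mask_windows


def profile(values, sample_id="s", mean_depth=0.2, **kw):
    values = np.asarray(values, dtype=float)
    return CoverageProfile(sample_id, values, np.arange(len(values)),
                           mean_depth=mean_depth, **kw)


class TestCountCoverage:
    def test_per_base_sum(self):
        ws = make_windows(ChromSizes([("A", 5)]), 5)
        records = [("A", i, i + 1, d) for i, d in enumerate([1, 1, 2, 0, 3])]
        p = count_coverage(ws, records)
        assert p.values[0] == pytest.approx(7)

    def test_constant_depth_record(self):
        ws = make_windows(ChromSizes([("A", 10_000)]), 10_000)
        p = count_coverage(ws, [("A", 0, 10_000, 2.0)])
        assert p.values[0] == pytest.approx(20_000)
        assert p.mean_depth == pytest.approx(2.0)

    def test_record_split_across_windows(self):
        ws = make_windows(ChromSizes([("A", 20_000)]), 10_000)
        p = count_coverage(ws, [("A", 5_000, 15_000, 1.0)])
        assert p.values[0] == pytest.approx(5_000)
        assert p.values[1] == pytest.approx(5_000)

    def test_masked_windows_omitted(self):
        ws = make_windows(ChromSizes([("A", 20_000)]), 10_000)
        ws = mask_windows(ws, [("A", 0, 10_000)], 0.5)
        p = count_coverage(ws, [("A", 0, 20_000, 1.0)])
        assert list(p.window_indices) == [1]
        assert p.values[0] == pytest.approx(10_000)
        assert p.mean_depth == pytest.approx(1.0)  # unmasked genome only

    def test_negative_depth_rejected(self):
        ws = make_windows(ChromSizes([("A", 100)]), 100)
        with pytest.raises(ValueError, match="negative depth"):
            count_coverage(ws, [("A", 0, 10, -1.0)])

    def test_out_of_bounds_record_rejected(self):
        ws = make_windows(ChromSizes([("A", 100)]), 100)
        with pytest.raises(ValueError, match="beyond chromosome"):
            count_coverage(ws, [("A", 90, 110, 1.0)])

    def test_mass_conservation(self):
        rng = np.random.default_rng(42)
        ws = make_windows(ChromSizes([("A", 10_000), ("B", 7_000)]), 1_000)
        records = []
        for chrom, length in [("A", 10_000), ("B", 7_000)]:
            pos = 0
            while pos < length:
                step = int(rng.integers(1, 900))
                end = min(pos + step, length)
                records.append((chrom, pos, end, float(rng.integers(0, 5))))
                pos = end
        p = count_coverage(ws, records)
        total = sum(d * (e - s) for _, s, e, d in records)
        assert p.values.sum() == pytest.approx(total)


class TestSampleQC:
    def test_low_coverage_fails(self):
        r = sample_qc(profile([1.0], mean_depth=0.14, n_unique_reads=7_000_000))
        assert not r.passed and r.reasons == ["low_coverage"]

    def test_boundary_mean_depth_passes(self):
        r = sample_qc(profile([1.0], mean_depth=0.15, n_unique_reads=7_000_000))
        assert r.passed

    def test_boundary_reads_fail(self):
        r = sample_qc(profile([1.0], mean_depth=0.2, n_unique_reads=5_999_999))
        assert not r.passed and r.reasons == ["low_reads"]
        r2 = sample_qc(profile([1.0], mean_depth=0.2, n_unique_reads=6_000_000))
        assert r2.passed

    def test_missing_reads_warns_and_skips(self):
        with pytest.warns(UserWarning, match="read-count check skipped"):
            r = sample_qc(profile([1.0], mean_depth=0.2))
        assert r.passed

    def test_sets_qc_pass_flag(self):
        p = profile([1.0], mean_depth=0.1, n_unique_reads=7_000_000)
        sample_qc(p)
        assert p.qc_pass is False


class TestCorrectBias:
    def test_gc_trend_flattened(self):
        rng = np.random.default_rng(0)
        n = 2000
        gc = rng.beta(5, 5, n)
        f = 1.0 + 1.6 * (0.25 - (gc - 0.45) ** 2)  # smooth unimodal in gc
        p = profile(1500.0 * f)
        out = correct_bias(p, gc, np.ones(n))
        assert out.stage == "corrected"
        assert np.abs(out.values / out.values.mean() - 1).max() < 1e-3

    def test_constant_tracks_identity(self):
        rng = np.random.default_rng(1)
        p = profile(rng.uniform(900, 1100, 500))
        out = correct_bias(p, np.full(500, 0.4), np.ones(500))
        np.testing.assert_allclose(out.values, p.values, rtol=1e-12)

    def test_mappability_trend_flattened(self):
        rng = np.random.default_rng(2)
        n = 2000
        mp = rng.uniform(0.5, 1.0, n)
        p = profile(1500.0 * (0.5 + 0.5 * mp))
        out = correct_bias(p, np.full(n, 0.4), mp)
        assert np.abs(out.values / out.values.mean() - 1).max() < 1e-3

    def test_mean_preserved(self):
        rng = np.random.default_rng(3)
        n = 1000
        gc = rng.beta(5, 5, n)
        vals = rng.poisson(2000 * (1.0 + 0.8 * (0.25 - (gc - 0.45) ** 2)), n)
        p = profile(vals.astype(float))
        out = correct_bias(p, gc, np.ones(n))
        assert out.values.mean() == pytest.approx(p.values.mean(), rel=1e-9)

    def test_reduces_gc_spearman_on_noisy_input(self):
        rng = np.random.default_rng(4)
        n = 3000
        gc = rng.beta(5, 5, n)
        vals = rng.poisson(2000 * (1.0 + 1.6 * (0.25 - (gc - 0.45) ** 2)), n)
        p = profile(vals.astype(float))
        out = correct_bias(p, gc, np.ones(n))
        before = abs(spearmanr(p.values, gc).statistic)
        after = abs(spearmanr(out.values, gc).statistic)
        assert after < before
        assert after < 0.05

    def test_near_identity_when_unbiased(self):
        rng = np.random.default_rng(5)
        n = 3000
        gc = rng.beta(5, 5, n)
        vals = rng.poisson(2000, n).astype(float)
        p = profile(vals)
        out = correct_bias(p, gc, np.ones(n))
        assert np.abs(out.values / p.values - 1).max() < 0.05

    def test_too_few_windows_refused(self):
        rng = np.random.default_rng(6)
        p = profile(rng.uniform(10, 20, 30))
        with pytest.raises(ValueError, match="refused"):
            correct_bias(p, rng.beta(5, 5, 30), np.ones(30))

    def test_low_mappability_windows_excluded_from_gc_fit_but_corrected(self):
        rng = np.random.default_rng(7)
        n = 1000
        gc = rng.beta(5, 5, n)
        mp = np.ones(n)
        mp[:100] = 0.6
        f = 1.0 + 1.6 * (0.25 - (gc - 0.45) ** 2)
        vals = 1500.0 * f
        vals[:100] *= 0.5  # mappability-depressed coverage
        out = correct_bias(profile(vals), gc, mp)
        assert len(out.values) == n
        assert np.isfinite(out.values).all()

    def test_requires_raw_stage(self):
        p = profile(np.ones(100))
        p.stage = "corrected"
        with pytest.raises(ValueError, match="raw"):
            correct_bias(p, np.full(100, 0.4), np.ones(100))


class TestAssembleMatrix:
    def test_shape(self):
        ps = [profile(np.arange(4) + i, sample_id=f"s{i}") for i in range(3)]
        m = assemble_matrix(ps, [0, 1, 0])
        assert m.values.shape == (3, 4)
        assert m.sample_ids == ["s0", "s1", "s2"]

    def test_failing_profile_excluded(self):
        ps = [profile(np.ones(4), sample_id=f"s{i}") for i in range(3)]
        ps[1].qc_pass = False
        m = assemble_matrix(ps, {"s0": 0, "s1": 1, "s2": 1})
        assert m.values.shape == (2, 4)
        assert m.sample_ids == ["s0", "s2"]

    def test_window_mismatch_rejected(self):
        ps = [profile(np.ones(4), sample_id="a"), profile(np.ones(5), sample_id="b")]
        with pytest.raises(ValueError, match="window-set mismatch"):
            assemble_matrix(ps, {"a": 0, "b": 1})

    def test_missing_label_rejected(self):
        ps = [profile(np.ones(4), sample_id="a")]
        with pytest.raises(ValueError, match="label missing"):
            assemble_matrix(ps, {"b": 0})


class TestNormalizeRows:
    def test_simple_row(self, matrix_factory):
        m = matrix_factory([[2, 4, 6], [1, 1, 1]], stage="raw")
        out = normalize_rows(m)
        np.testing.assert_allclose(out.values[0], [0.5, 1.0, 1.5])
        assert out.stage == "normalized"

    def test_scale_invariance(self, matrix_factory):
        a = normalize_rows(matrix_factory([[0.1, 0.2, 0.3]], labels=[0], stage="raw"))
        b = normalize_rows(matrix_factory([[1, 2, 3]], labels=[0], stage="raw"))
        np.testing.assert_allclose(a.values, b.values)

    def test_identity_row(self, matrix_factory):
        out = normalize_rows(matrix_factory([[1, 1, 1, 1]], labels=[0], stage="raw"))
        np.testing.assert_allclose(out.values[0], 1.0)

    def test_row_means_are_one(self, matrix_factory):
        rng = np.random.default_rng(0)
        m = matrix_factory(rng.uniform(0.5, 2.0, (7, 20)), stage="raw")
        out = normalize_rows(m)
        np.testing.assert_allclose(out.values.mean(axis=1), 1.0, rtol=1e-12)

    def test_idempotent_on_own_output(self, matrix_factory):
        rng = np.random.default_rng(1)
        m = matrix_factory(rng.uniform(0.5, 2.0, (5, 12)), stage="raw")
        once = normalize_rows(m)
        twice = normalize_rows(
            matrix_factory(once.values.copy(), labels=once.labels, stage="raw")
        )
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_zero_row_rejected(self, matrix_factory):
        m = matrix_factory([[0, 0, 0], [1, 1, 1]], stage="raw")
        with pytest.raises(ValueError, match="s0"):
            normalize_rows(m)


def prune_oracle(values, labels, dropout_frac=0.8, dropout_value=0.1, mean_diff=0.01):
    """Brute-force per-column re-computation of both pruning rules."""
    n, m = values.shape
    keep, reasons = [], {}
    for j in range(m):
        col = values[:, j]
        n_low = sum(1 for v in col if v < dropout_value)
        rule1 = n_low / n > dropout_frac
        mean0 = np.mean([v for v, l in zip(col, labels) if l == 0])
        mean1 = np.mean([v for v, l in zip(col, labels) if l == 1])
        rule2 = round(abs(mean0 - mean1), 12) < mean_diff
        if rule1:
            reasons[j] = "dropout_rule"
        elif rule2:
            reasons[j] = "mean_diff_rule"
        else:
            keep.append(j)
    return keep, reasons


class TestPruneWindows:
    def test_boundary_fraction_not_dropped(self, matrix_factory):
        # 4/5 = 0.8 exactly, not > 0.8 -> rule 1 keeps; means differ enough
        col = np.array([0.05, 0.05, 0.05, 0.05, 0.5])
        values = np.column_stack([col, np.linspace(0.5, 1.5, 5)])
        m = matrix_factory(values, labels=[0, 1, 0, 1, 0])
        out, report = prune_windows(m)
        reasons = dict(report.dropped)
        assert 0 not in [i for i, r in report.dropped if r == "dropout_rule"]

    def test_all_low_column_dropped_as_dropout(self, matrix_factory):
        values = np.column_stack([np.full(5, 0.05), np.linspace(0.5, 1.5, 5)])
        m = matrix_factory(values, labels=[0, 1, 0, 1, 0])
        out, report = prune_windows(m)
        assert (0, "dropout_rule") in report.dropped

    def test_similar_means_dropped(self, matrix_factory):
        # label-0 mean 1.000, label-1 mean 1.005 -> |diff| = 0.005 < 0.01
        values = np.array([[1.000, 0.2], [1.005, 0.9], [1.000, 0.2], [1.005, 0.9]])
        m = matrix_factory(values, labels=[0, 1, 0, 1])
        out, report = prune_windows(m)
        assert (0, "mean_diff_rule") in report.dropped
        assert out.n_windows == 1

    def test_boundary_mean_diff_kept(self, matrix_factory):
        # |diff| exactly 0.01 is not < 0.01
        values = np.array([[1.00, 0.2], [1.01, 0.9], [1.00, 0.2], [1.01, 0.9]])
        m = matrix_factory(values, labels=[0, 1, 0, 1])
        out, report = prune_windows(m)
        assert 0 not in dict(report.dropped)

    def test_single_class_rejected(self, matrix_factory):
        m = matrix_factory(np.ones((3, 4)), labels=[1, 1, 1])
        with pytest.raises(ValueError, match="both classes"):
            prune_windows(m)

    def test_report_accounts_for_every_window(self, matrix_factory):
        rng = np.random.default_rng(5)
        m = matrix_factory(rng.uniform(0, 2, (20, 50)))
        out, report = prune_windows(m)
        assert report.n_initial == 50
        assert report.n_retained == out.n_windows
        assert report.n_retained + len(report.dropped) == 50

    def test_requires_normalized_stage(self, matrix_factory):
        m = matrix_factory(np.ones((4, 3)), stage="raw")
        with pytest.raises(ValueError, match="normalized"):
            prune_windows(m)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bruteforce_oracle(self, matrix_factory, seed):
        rng = np.random.default_rng(seed)
        values = rng.choice([0.0, 0.05, 0.5, 1.0, 1.005, 2.0], size=(50, 200))
        labels = rng.permutation(np.arange(50) % 2)
        m = matrix_factory(values, labels=labels)
        out, report = prune_windows(m)
        keep, reasons = prune_oracle(values, labels)
        assert list(out.window_indices) == keep
        assert dict(report.dropped) == reasons
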