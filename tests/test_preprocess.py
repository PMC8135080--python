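import numpy as np
import pandas as pd
import pytest
from scipy import stats

from platemark.cohort import CohortDesign, generate_cohort
from platemark.preprocess import (
    filter_by_coverage,
    impute_downshifted,
    normalize_columns,
    run_all_contrasts,
    summarize_de,
    t_test_per_protein,
)


def _pooled_t(a, b):
    """Independent closed-form pooled-variance t-test (oracle)."""
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


class TestNormalizeColumns:
    def test_medians_equalized(self, small_cohort):
        matrix, _ = small_cohort
        out = normalize_columns(matrix.values)
        medians = out.median(axis=0)
        assert np.allclose(medians, medians.iloc[0])

    def test_idempotent(self, small_cohort):
        matrix, _ = small_cohort
        once = normalize_columns(matrix.values)
        twice = normalize_columns(once, already_log2=True)
        pd.testing.assert_frame_equal(once, twice)

    def test_shifted_column_recentered(self, small_cohort):
        """A +3 log2 shift of one column is removed by centering: the result
        matches the reference normalization up to the (constant) change in
        the global median target."""
        matrix, _ = small_cohort
        log2 = np.log2(matrix.values)
        ref = normalize_columns(log2, already_log2=True)
        shifted = log2.copy()
        shifted.iloc[:, 0] += 3.0
        out = normalize_columns(shifted, already_log2=True)
        diff = (out - ref).to_numpy()
        assert np.allclose(diff, diff[0, 0], atol=1e-12)
        assert abs(diff[0, 0]) < 0.5  # target moved far less than the shift

    def test_all_missing_column_errors(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="s2"):
            normalize_columns(df, already_log2=True)

    def test_nonpositive_raw_errors(self):
        df = pd.DataFrame({"s1": [1.0, -2.0]})
        with pytest.raises(ValueError, match="positive"):
            normalize_columns(df)


class TestImputeDownshifted:
    def test_no_missing_unchanged(self, small_cohort, rng):
        matrix, _ = small_cohort
        log2 = np.log2(matrix.values)
        out = impute_downshifted(log2, rng)
        pd.testing.assert_frame_equal(out, log2)

    def test_observed_cells_untouched(self, rng):
        log2 = pd.DataFrame(rng.normal(20, 2, (200, 6)))
        holed = log2.mask(rng.random(log2.shape) < 0.2)
        out = impute_downshifted(holed, np.random.default_rng(1))
        obs = holed.notna()
        assert np.array_equal(out[obs].to_numpy(), holed[obs].to_numpy(), equal_nan=True)
        assert not out.isna().any().any()

    def test_downshift_mean(self, rng):
        """Imputed mean ~ col_mean - 1.8*col_sd over >=1000 imputed cells."""
        log2 = pd.DataFrame(rng.normal(20, 2, (2000, 4)))
        holed = log2.mask(rng.random(log2.shape) < 0.3)
        out = impute_downshifted(holed, np.random.default_rng(2))
        col = holed.columns[0]
        miss = holed[col].isna()
        assert miss.sum() >= 500
        mu, sd = holed[col].mean(), holed[col].std(ddof=1)
        assert out.loc[miss, col].mean() == pytest.approx(mu - 1.8 * sd, abs=0.1 * sd)

    def test_deterministic(self, rng):
        log2 = pd.DataFrame(rng.normal(20, 2, (100, 5)))
        holed = log2.mask(rng.random(log2.shape) < 0.2)
        a = impute_downshifted(holed, np.random.default_rng(9))
        b = impute_downshifted(holed, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_observed_errors(self):
        df = pd.DataFrame({"s1": [1.0, np.nan, np.nan]})
        with pytest.raises(ValueError, match="s1"):
            impute_downshifted(df, np.random.default_rng(0))


class TestTTest:
    def test_frozen_example(self):
        """a=[1,2,3,4], b=[3,4,5,6]: |t|=2.1909, p=0.0710 (pooled formula)."""
        values = pd.DataFrame(
            [[1, 2, 3, 4, 3, 4, 5, 6]],
            index=["prot"],
            columns=[f"s{i}" for i in range(8)],
            dtype=float,
        )
        group = pd.Series(["Ctrl"] * 4 + ["MCI"] * 4, index=values.columns)
        cmp = t_test_per_protein(values, group, ("Ctrl", "MCI"))
        row = cmp.table.loc["prot"]
        assert row["t"] == pytest.approx(2.1908902300206643, abs=1e-12)
        assert row["p"] == pytest.approx(0.07098765432098762, abs=1e-12)
        assert row["log2fc"] == pytest.approx(2.0)
        assert row["direction"] == "up"

    def test_identical_groups(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
            index=["prot"],
            columns=[f"s{i}" for i in range(6)],
        )
        group = pd.Series(["Ctrl"] * 3 + ["AD"] * 3, index=values.columns)
        row = t_test_per_protein(values, group, ("Ctrl", "AD")).table.loc["prot"]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_matches_closed_form_on_random_inputs(self, rng):
        """Implementation vs independent pooled-variance oracle, 1e-10."""
        for _ in range(100):
            na, nb = rng.integers(3, 8, size=2)
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            values = pd.DataFrame(
                [np.r_[a, b]], index=["p1"], columns=[f"s{i}" for i in range(na + nb)]
            )
            group = pd.Series(["Ctrl"] * na + ["MCI"] * nb, index=values.columns)
            row = t_test_per_protein(values, group, ("Ctrl", "MCI")).table.loc["p1"]
            t_exp, p_exp = _pooled_t(a, b)
            assert row["t"] == pytest.approx(t_exp, abs=1e-10)
            assert row["p"] == pytest.approx(p_exp, abs=1e-10)

    def test_unknown_group_errors(self, small_cohort):
        matrix, _ = small_cohort
        with pytest.raises(ValueError):
            t_test_per_protein(np.log2(matrix.values), matrix.group, ("Ctrl", "XX"))

    def test_planted_cluster1_protein_significant(self, small_cohort):
        matrix, truth = small_cohort
        log2 = np.log2(matrix.values)
        pid = next(p for p, c in truth.cluster_assignment.items() if c == 1)
        for contrast in (("Ctrl", "MCI"), ("Ctrl", "AD")):
            row = t_test_per_protein(log2, matrix.group, contrast).table.loc[pid]
            assert row["p"] < 0.001
            assert row["direction"] == "down"

    def test_direction_matches_sign(self, small_cohort):
        matrix, _ = small_cohort
        table = t_test_per_protein(
            np.log2(matrix.values), matrix.group, ("Ctrl", "AD")
        ).table
        assert (
            (table["direction"] == "up") == (table["log2fc"] > 0)
        ).all()


class TestSummarizeDE:
    def test_counts_add_up(self, small_cohort):
        matrix, _ = small_cohort
        comparisons = run_all_contrasts(np.log2(matrix.values), matrix.group)
        s = summarize_de(comparisons)
        assert (s.counts["n_up"] + s.counts["n_down"] == s.counts["n_sig"]).all()

    def test_overlap_subset_of_each(self, small_cohort):
        matrix, _ = small_cohort
        s = summarize_de(run_all_contrasts(np.log2(matrix.values), matrix.group))
        assert s.overlap_ctrl <= s.significant["MCI_vs_Ctrl"]
        assert s.overlap_ctrl <= s.significant["AD_vs_Ctrl"]
        assert s.union_ctrl <= s.union_all

    def test_recovery_of_planted(self, default_cohort):
        """Union captures >=95% of planted DE proteins at default effects."""
        matrix, truth = default_cohort
        values = normalize_columns(matrix.values)
        s = summarize_de(run_all_contrasts(values, matrix.group))
        recovered = len(truth.de_union & s.union_all) / len(truth.de_union)
        assert recovered >= 0.95

    def test_null_calibration(self):
        """Zero effects: ~5% false positives per contrast, 10 reps pooled."""
        rates = []
        for seed in range(10):
            d = CohortDesign(
                n_proteins=1000, n_cluster1=0, n_cluster2=0, n_cluster3=0,
                panel_size=0, n_corr=0, effect_size=0.0, target_corr=0.0, seed=seed,
            )
            matrix, _ = generate_cohort(d)
            values = normalize_columns(matrix.values)
            for c in run_all_contrasts(values, matrix.group):
                rates.append((c.table["p"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_mismatched_universe_errors(self, small_cohort):
        matrix, _ = small_cohort
        log2 = np.log2(matrix.values)
        c1 = t_test_per_protein(log2, matrix.group, ("Ctrl", "MCI"))
        c2 = t_test_per_protein(log2.iloc[:10], matrix.group, ("Ctrl", "AD"))
        with pytest.raises(ValueError, match="universe"):
            summarize_de([c1, c2])


class TestFilterByCoverage:
    def test_drops_low_coverage(self, small_cohort, rng):
        matrix, _ = small_cohort
        values = matrix.values.copy()
        pid = values.index[0]
        ctrl = matrix.samples_in("Ctrl")
        values.loc[pid, ctrl[:4]] = np.nan  # 5/9 Ctrl observed < 70%
        from platemark.cohort import ProteomeMatrix

        pm = ProteomeMatrix(values, matrix.group, matrix.mmse)
        out = filter_by_coverage(pm, 0.7)
        assert pid not in out.values.index
        assert len(out.values) == len(values) - 1

    def test_keeps_complete(self, small_cohort):
        matrix, _ = small_cohort
        out = filter_by_coverage(matrix, 0.7)
        assert out.values.shape == matrix.values.shape
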