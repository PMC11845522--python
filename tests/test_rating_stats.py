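"""Rating-table statistics: summaries, insufficiency, ANOVA, agreement."""

from itertools import combinations

import numpy as np
import pytest

from labnorm import (
    RatingRecord,
    anova_posthoc,
    anova_posthoc_groups,
    insufficiency_rate,
    interrater_agreement,
    summarize_methods,
    total_coregistrations,
    welch_t,
)

RATERS = ("EK", "RB", "JG")


def make_table(grades_by_method: dict, n_datasets: int, raters=RATERS) -> list:
    """Build a rating table where ``grades_by_method[m]`` is a flat list of
    len(raters) * n_datasets grades laid out dataset-major."""
    records = []
    for method, grades in grades_by_method.items():
        assert len(grades) == n_datasets * len(raters)
        it = iter(grades)
        for d in range(n_datasets):
            for r in raters:
                records.append(RatingRecord(f"d{d:03d}", method, r, next(it)))
    return records


def grades_with_insufficient(n_total: int, n_insufficient: int) -> list:
    return [5.0] * n_insufficient + [2.0] * (n_total - n_insufficient)


def exact_moment_group(mean: float, sd: float, n: int) -> np.ndarray:
    """A sample with exactly the requested mean and sample SD (ddof=1)."""
    base = np.arange(n, dtype=float)
    z = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * z


class TestSummaries:
    def test_constant_group(self):
        recs = make_table({"TIE": [2.0] * 9}, 3)
        (s,) = summarize_methods(recs)
        assert (s.n, s.mean, s.sd) == (9, 2.0, 0.0)

    def test_two_value_sample_sd(self):
        recs = [RatingRecord("d0", "EL", "a", 1.0), RatingRecord("d1", "EL", "a", 3.0)]
        (s,) = summarize_methods(recs)
        assert s.mean == 2.0
        assert s.sd == pytest.approx(np.sqrt(2.0))

    def test_reproduces_constructed_moments(self):
        grades = [1.5] * 200 + [3.0] * 259  # arbitrary but fixed mixture
        recs = make_table({"TIE": grades}, 153)
        (s,) = summarize_methods(recs)
        assert s.mean == pytest.approx(np.mean(grades))
        assert s.sd == pytest.approx(np.std(grades, ddof=1))


class TestInsufficiency:
    def test_seventeen_of_459(self):
        recs = make_table({"3P": grades_with_insufficient(459, 17)}, 153)
        count, percent = insufficiency_rate(recs, "3P")
        assert count == 17
        assert round(percent, 2) == 3.70

    def test_zero_and_full(self):
        recs = make_table({"TIE": [2.0] * 6, "EL": [6.0] * 6}, 2)
        assert insufficiency_rate(recs, "TIE") == (0, 0.0)
        assert insufficiency_rate(recs, "EL") == (6, 100.0)

    def test_half_steps_at_or_above_cutoff_count(self):
        recs = make_table({"TIE": [5.5, 5.0, 4.5, 2.0, 1.0, 6.0]}, 2)
        count, _ = insufficiency_rate(recs, "TIE")
        assert count == 3  # 5.5, 5.0, 6.0 but not 4.5

    def test_count_monotone_in_cutoff(self):
        recs = make_table({"TIE": [1.0, 2.5, 4.0, 4.5, 5.0, 6.0]}, 2)
        counts = [insufficiency_rate(recs, "TIE", cutoff=c)[0] for c in (6.0, 5.0, 4.0, 1.0)]
        assert counts == sorted(counts)
        assert all(0 <= insufficiency_rate(recs, "TIE", cutoff=c)[1] <= 100 for c in (1.0, 5.0, 6.0))


class TestAnovaPosthoc:
    def test_identical_groups_null_case(self):
        groups = {m: [2.0, 2.0, 3.0, 3.0] for m in ("A", "B", "C", "D")}
        res = anova_posthoc_groups(groups)
        assert res.f_statistic == pytest.approx(0.0)
        assert all(c.cohens_d == pytest.approx(0.0) for c in res.comparisons)
        assert all(c.p_bonferroni == 1.0 for c in res.comparisons)

    def test_printed_group_moments_reproduce_effect_size(self):
        # groups constructed to carry the published per-method mean +/- SD
        groups = {
            "TIE": exact_moment_group(2.21, 1.15, 153),
            "3P": exact_moment_group(2.58, 0.61, 153),
            "EL": exact_moment_group(3.42, 1.06, 153),
            "ANTS": exact_moment_group(3.49, 1.26, 153),
        }
        res = anova_posthoc_groups(groups)
        d = {(c.method_a, c.method_b): c.cohens_d for c in res.comparisons}
        assert round(abs(d[("TIE", "ANTS")]), 2) == 1.22
        assert round(abs(d[("3P", "ANTS")]), 2) == 0.87
        assert round(abs(d[("TIE", "3P")]), 2) == 0.35
        assert res.df_between == 3 and res.df_within == 608

    def test_unit_effect_two_groups(self):
        groups = {"A": exact_moment_group(0.0, 1.0, 50), "B": exact_moment_group(1.0, 1.0, 50)}
        res = anova_posthoc_groups(groups)
        assert res.comparisons[0].cohens_d == pytest.approx(-1.0)

    def test_f_invariant_to_affine_grade_change(self, rng):
        groups = {m: rng.normal(loc, 1.0, 30) for m, loc in (("A", 0.0), ("B", 0.4), ("C", 1.0))}
        f0 = anova_posthoc_groups(groups).f_statistic
        shifted = {m: 5.0 + 2.0 * g for m, g in groups.items()}
        assert anova_posthoc_groups(shifted).f_statistic == pytest.approx(f0, rel=1e-12)

    def test_bonferroni_at_least_raw_and_capped(self, rng):
        groups = {m: rng.normal(0.0, 1.0, 20) for m in "ABCD"}
        res = anova_posthoc_groups(groups)
        assert all(0.0 < c.p_bonferroni <= 1.0 for c in res.comparisons)
        assert all(c.family_size == 6 for c in res.comparisons)

    def test_dataset_mean_pooling_dimensions(self):
        # 153 datasets x 3 raters x 4 methods -> 153 observations per method
        grades = {m: [2.0, 3.0, 4.0] * 153 for m in ("3P", "TIE", "EL", "ANTS")}
        recs = make_table(grades, 153)
        res = anova_posthoc(recs, pooling="dataset_mean")
        assert res.df_within == 4 * 153 - 4
        res_pooled = anova_posthoc(recs, pooling="ratings")
        assert res_pooled.df_within == 4 * 459 - 4

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_posthoc_groups({"A": [1.0], "B": [1.0, 2.0]})


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert abs(t) == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert df == pytest.approx(4.0)

    def test_large_shift_is_overwhelming(self, rng):
        a = rng.normal(0.0, 1.0, 10_000)
        b = rng.normal(1.0, 1.0, 10_000)
        _, _, p = welch_t(a, b)
        assert p < 1e-10

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestInterrater:
    @staticmethod
    def table_from_vectors(vecs: dict) -> list:
        n = len(next(iter(vecs.values())))
        return [
            RatingRecord(f"d{i:02d}", "TIE", rater, float(v[i]))
            for rater, v in vecs.items()
            for i in range(n)
        ]

    def test_perfect_agreement(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = interrater_agreement(self.table_from_vectors({"a": v, "b": v}))
        row = df.iloc[0]
        assert row.spearman_rho == pytest.approx(1.0)
        assert row.kendall_tau == pytest.approx(1.0)

    def test_perfect_disagreement(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = interrater_agreement(self.table_from_vectors({"a": v, "b": v[::-1]}))
        row = df.iloc[0]
        assert row.spearman_rho == pytest.approx(-1.0)
        assert row.kendall_tau == pytest.approx(-1.0)

    def test_tau_b_matches_pair_enumeration_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 3.0, 2.0, 4.0]
        df = interrater_agreement(self.table_from_vectors({"a": x, "b": y}))
        # brute-force concordant/discordant pair count with tie correction
        nc = nd = tx = ty = 0
        for i, j in combinations(range(4), 2):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
        expected = (nc - nd) / np.sqrt((nc + nd + tx) * (nc + nd + ty))
        assert df.iloc[0].kendall_tau == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_rejected(self):
        recs = self.table_from_vectors({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="share only"):
            interrater_agreement(recs)


def test_total_coregistrations_counts_dataset_method_pairs():
    grades = {m: [2.0, 3.0, 4.0] * 153 for m in ("3P", "TIE", "EL", "ANTS")}
    recs = make_table(grades, 153)
    assert total_coregistrations(recs) == 612
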