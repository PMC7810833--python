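import math

import numpy as np
import pytest
from scipy import stats as sps

from nacmap import stats as nstats
from nacmap.connectivity import Adjacency
from nacmap.records import SubjectRecord

from conftest import random_adjacency


def adjacency_from_edges(edges, n):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return Adjacency(a=a)


class TestDistributionChisq:
    def test_identical_distribution_gives_zero(self):
        edges = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        scores = np.repeat([0.1, 0.3, 0.6, 0.9], 25)  # 25 per bin
        ref = np.array([0.25, 0.25, 0.25, 0.25])
        chi2, df, p = nstats.distribution_chisq(scores, ref, edges)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_extreme_case(self):
        # all 388 region scores in one of two equiprobable bins: chi2 = n
        edges = np.array([0.0, 0.5, 1.0])
        scores = np.full(388, 0.25)
        chi2, df, p = nstats.distribution_chisq(scores, np.array([0.5, 0.5]), edges)
        assert chi2 == pytest.approx(388.0)
        assert df == 1

    def test_matches_brute_force_formula(self, rng):
        edges = nstats.default_bin_edges(0.1)
        scores = rng.uniform(0, 1, 200)
        ref = np.full(10, 0.1)
        chi2, df, p = nstats.distribution_chisq(scores, ref, edges)
        observed, _ = np.histogram(scores, edges)
        expected = ref * 200
        assert chi2 == pytest.approx(((observed - expected) ** 2 / expected).sum(), abs=1e-10)
        assert p == pytest.approx(sps.chi2.sf(chi2, df), abs=1e-12)

    def test_small_expected_bins_are_merged(self):
        edges = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        ref = np.array([0.01, 0.49, 0.49, 0.01])  # outer bins expect < 5
        scores = np.repeat([0.3, 0.6], 50)
        chi2, df, p = nstats.distribution_chisq(scores, ref, edges)
        assert df == 1  # 4 bins merged down to 2

    def test_degenerate_binning_errors(self):
        edges = np.array([0.0, 0.5, 1.0])
        with pytest.raises(ValueError, match="2 bins"):
            nstats.distribution_chisq(
                np.full(4, 0.25), np.array([0.5, 0.5]), edges
            )

    def test_matched_reference_widens_window(self):
        records = [
            SubjectRecord(subject_id=f"c{i}", age=20.0 + i, sex="M", group="control")
            for i in range(12)
        ]
        scores = np.tile(np.linspace(0.1, 1.0, 30), (12, 1))
        subject = SubjectRecord(subject_id="p", age=80.0, sex="M", group="patient")
        edges = nstats.default_bin_edges()
        props, n_matched = nstats.matched_reference(scores, records, subject, edges)
        assert n_matched >= 10  # fell back to a wider window
        assert props.sum() == pytest.approx(1.0)


class TestCountComparison:
    def test_identical_samples_give_p_one(self):
        out = nstats.count_comparison([1, 2, 3, 4], [1, 2, 3, 4])
        assert abs(out["z"]) < 1e-12
        assert out["p"] == pytest.approx(1.0)

    def test_exact_rank_arithmetic_on_separated_samples(self):
        # {1..10} vs {11..20}: W = 55, mu = 105, var = 100*21/12 = 175
        out = nstats.count_comparison(list(range(1, 11)), list(range(11, 21)))
        assert out["z"] == pytest.approx(-50 / math.sqrt(175), abs=1e-12)
        assert out["median_a"] == 5.5 and out["median_b"] == 15.5

    def test_antisymmetric_under_group_swap(self, rng):
        x = rng.integers(0, 30, 12).tolist()
        y = rng.integers(0, 30, 15).tolist()
        a = nstats.count_comparison(x, y)
        b = nstats.count_comparison(y, x)
        assert a["z"] == pytest.approx(-b["z"], abs=1e-12)

    def test_all_tied_values(self):
        out = nstats.count_comparison([5, 5, 5], [5, 5])
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_matches_scipy_tie_corrected_normal_approximation(self, rng):
        x = rng.integers(0, 10, 14).tolist()
        y = rng.integers(0, 10, 18).tolist()
        out = nstats.count_comparison(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert out["p"] == pytest.approx(ref.pvalue, abs=1e-10)


class TestSpearman:
    def test_monotone_relationship(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 4, 9, 16, 30, 100]
        r, p = nstats.spearman(x, y)
        assert r == pytest.approx(1.0)

    def test_partial_reduces_to_plain_with_orthogonal_covariate(self):
        x = np.arange(1.0, 10.0)
        y = x**2
        covar = np.abs(x - 5.0)  # rank-orthogonal to x and y by symmetry
        r_plain, _ = nstats.spearman(x, y)
        r_part, _ = nstats.spearman_partial(x, y, covar)
        assert r_part == pytest.approx(r_plain, abs=1e-12)

    def test_tied_fixture_matches_brute_force_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0, 6.0, 7.0]

        def midranks(v):
            v = np.asarray(v)
            out = np.empty(len(v))
            for i, val in enumerate(v):
                less = (v < val).sum()
                eq = (v == val).sum()
                out[i] = less + (eq + 1) / 2.0
            return out

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        r, _ = nstats.spearman(x, y)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_partial_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        c = 0.3 * x + rng.normal(size=25)
        r, p = nstats.spearman_partial(x, y, c)
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "c": c}), x="x", y="y", covar="c",
            method="spearman",
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            nstats.spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestConnectionPercentage:
    def test_clique_is_hundred_percent(self):
        a = adjacency_from_edges([(0, 1), (0, 2), (1, 2)], 5)
        assert nstats.connection_percentage(a, [0, 1, 2]) == pytest.approx(100.0)

    def test_two_of_three_possible_edges(self):
        a = adjacency_from_edges([(1, 2), (2, 3)], 5)
        assert nstats.connection_percentage(a, [1, 2, 3]) == pytest.approx(100 * 2 / 3)

    def test_empty_subgraph_is_zero(self):
        a = adjacency_from_edges([(0, 4)], 5)
        assert nstats.connection_percentage(a, [1, 2, 3]) == 0.0

    def test_undefined_below_two_regions(self):
        a = adjacency_from_edges([(0, 1)], 3)
        assert nstats.connection_percentage(a, [0]) is None


class TestKappa:
    def test_perfect_agreement(self):
        labels = [0, 1, 0, 1, 1, 0]
        assert nstats.cohen_kappa(labels, labels) == pytest.approx(1.0)

    def test_hand_computed_confusion_fixture(self):
        # 388 regions: 20 both-abnormal, 348 both-normal, 10+10 discordant
        a = np.zeros(388, dtype=int)
        b = np.zeros(388, dtype=int)
        a[:30] = 1  # 20 shared + 10 only-a
        b[:20] = 1
        b[30:40] = 1  # 10 only-b
        po = 368 / 388
        pe = (30 / 388) ** 2 + (358 / 388) ** 2
        expected = (po - pe) / (1 - pe)
        assert expected == pytest.approx(0.639, abs=5e-4)
        assert nstats.cohen_kappa(a, b) == pytest.approx(expected, abs=1e-12)

    def test_independent_labelings_near_zero(self, rng):
        a = rng.integers(0, 2, 5000)
        b = rng.integers(0, 2, 5000)
        assert abs(nstats.cohen_kappa(a, b)) < 0.05

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        assert nstats.cohen_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_identical_constant_labelings(self):
        assert nstats.cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0


class TestDmnEnrichment:
    def test_case_fractions(self):
        dmn = list(range(100))
        regions = list(range(19)) + list(range(200, 214))  # 19 of 33 in DMN
        out = nstats.dmn_enrichment(regions, dmn, 388)
        assert out["observed_pct"] == pytest.approx(57.6, abs=0.1)
        assert out["expected_pct"] == pytest.approx(25.8, abs=0.05)
        regions = list(range(26)) + list(range(200, 215))  # 26 of 41
        out = nstats.dmn_enrichment(regions, dmn, 388)
        assert out["observed_pct"] == pytest.approx(63.4, abs=0.1)

    def test_exactly_expected_proportion_gives_zero_chi2(self):
        # 25 of 97 regions in DMN: expected count 97 * 100/388 = 25 exactly
        dmn = list(range(100))
        regions = list(range(25)) + list(range(200, 272))
        out = nstats.dmn_enrichment(regions, dmn, 388)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            nstats.dmn_enrichment([], list(range(100)), 388)


class TestEdgesAncova:
    def test_identical_groups_give_null_f(self, rng):
        edges = np.tile(rng.integers(5000, 7000, 10), 2).astype(float)
        group = ["control"] * 10 + ["patient"] * 10
        age = np.tile(np.linspace(20, 70, 10), 2)
        out = nstats.edges_ancova(edges, group, age)
        assert out["F_group"] == pytest.approx(0.0, abs=1e-10)

    def test_pure_group_offset_is_overwhelming(self):
        age = np.tile(np.linspace(20, 70, 8), 2)
        edges = np.concatenate([np.full(8, 6000.0), np.full(8, 6500.0)])
        edges += 0.01 * age  # noiseless apart from the age trend
        group = ["control"] * 8 + ["patient"] * 8
        out = nstats.edges_ancova(edges, group, age)
        assert out["p_group"] < 1e-10

    def test_matches_rss_ratio_oracle(self, rng):
        n = 12
        age = rng.uniform(20, 70, n)
        group = np.array(["control"] * 6 + ["patient"] * 6)
        edges = 6000 + 10 * age + 300 * (group == "patient") + rng.normal(0, 50, n)
        out = nstats.edges_ancova(edges, group.tolist(), age)

        g = (group == "patient").astype(float)

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, edges, rcond=None)
            return ((edges - X @ beta) ** 2).sum()

        ones = np.ones(n)
        rss_age = rss(np.column_stack([ones, age]))
        rss_add = rss(np.column_stack([ones, g, age]))
        rss_full = rss(np.column_stack([ones, g, age, g * age]))
        f_group = (rss_age - rss_add) / (rss_add / (n - 3))
        f_int = (rss_add - rss_full) / (rss_full / (n - 4))
        assert out["F_group"] == pytest.approx(f_group, abs=1e-8)
        assert out["F_interaction"] == pytest.approx(f_int, abs=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            nstats.edges_ancova([1.0] * 8, ["control"] * 8, list(range(8)))


class TestReportAssembly:
    def test_counts_match_inputs(self, rng):
        adj = random_adjacency(rng, 30)
        ar0 = frozenset({1, 2, 3, 10})
        ar1 = frozenset({2, 3, 11})
        rep = nstats.subject_report("s1", adj, ar0, ar1, list(range(8)), 30)
        assert rep.n_ar0 == 4 and rep.n_ar1 == 3
        assert -1 <= rep.kappa <= 1
        assert rep.dmn_ar0["n_regions"] == 4

    def test_noiseless_duration_relation_has_unit_partial_r(self, rng):
        import pandas as pd

        n = 20
        duration = np.linspace(1, 20, n)
        age = rng.permutation(np.linspace(25, 65, n))  # independent of duration
        patients = pd.DataFrame(
            {
                "n_ar0": 5 + duration,  # strictly increasing in duration
                "n_ar1": rng.integers(0, 20, n),
                "connection_percentage": rng.uniform(0, 100, n),
                "duration_years": duration,
                "n_aeds": rng.integers(1, 5, n),
                "qolie31": rng.uniform(30, 90, n),
                "lsss": rng.uniform(10, 70, n),
                "age": age,
            }
        )
        table = nstats.clinical_correlations(patients)
        row = table[(table.outcome == "n_ar0") & (table.predictor == "duration_years")]
        assert row["r"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert row["method"].iloc[0] == "partial_spearman_age"

    def test_shuffled_clinical_columns_rarely_significant(self, rng):
        n = 20
        n_ar0 = rng.integers(0, 30, n).astype(float)
        qolie = rng.uniform(30, 90, n)
        n_sig = 0
        for _ in range(100):
            shuffled = rng.permutation(qolie)
            _, p = nstats.spearman(n_ar0, shuffled)
            n_sig += p < 0.05
        assert n_sig <= 10  # >= 90% of shuffles are non-significant
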