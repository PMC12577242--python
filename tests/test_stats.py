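import itertools
import warnings

import numpy as np
import pytest
from scipy import special

from tcrars.exceptions import ParameterError, UndefinedStatisticError
from tcrars.repertoire_io import ClinicalRecord, Cohort
from tcrars.ars import ARSRecord
from tcrars.stats import (
    TOTAL,
    activity_report,
    anova_tukey,
    auc_mann_whitney,
    benjamini_hochberg,
    jgene_enrichment,
    jgene_usage,
    motif_features,
    pearson,
    spearman,
    t_test_independent,
)

from conftest import make_repertoire


def brute_force_auc(values, labels):
    """Exhaustive pair counting: (wins + ties/2) / (n_pos * n_neg)."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    s = sum(1.0 if p > n else (0.5 if p == n else 0.0)
            for p, n in itertools.product(pos, neg))
    return s / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_and_constant(self):
        assert auc_mann_whitney([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
        assert auc_mann_whitney([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_interleaved_example(self):
        assert auc_mann_whitney([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n = int(rng.integers(4, 50))
            values = rng.integers(0, 8, size=n).astype(float)  # many ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert auc_mann_whitney(values, labels) == pytest.approx(
                brute_force_auc(values, labels), abs=1e-12
            )

    def test_negation_symmetry(self):
        rng = np.random.default_rng(2)
        v = rng.random(30)
        l = (rng.random(30) < 0.5).astype(int)
        l[0], l[1] = 0, 1
        assert auc_mann_whitney(-v, l) == pytest.approx(
            1 - auc_mann_whitney(v, l), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            auc_mann_whitney([1, 2], [1, 1])


def welch_p_manual(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * special.stdtr(df, -abs(t))


class TestTTest:
    def test_identical_samples(self):
        r = t_test_independent([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_swap_flips_sign(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0, 9.0]
        r1, r2 = t_test_independent(a, b), t_test_independent(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_closed_form_welch(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(0, 1, size=int(rng.integers(3, 20)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 20)))
            r = t_test_independent(a, b)
            t, p = welch_p_manual(a, b)
            assert r.statistic == pytest.approx(t, abs=1e-9)
            assert r.p_value == pytest.approx(p, abs=1e-9)

    def test_student_degenerate_falls_back_to_welch(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = t_test_independent([1.0, 1.0, 1.0], [2.0, 2.0], variant="student")
        assert r.extra["variant"] == "welch"


class TestCorrelations:
    def test_linear_and_monotone(self):
        x = np.arange(1.0, 11.0)
        assert pearson(x, 2 * x).statistic == pytest.approx(1.0)
        sp = spearman(x, np.exp(x))
        assert sp.statistic == pytest.approx(1.0)
        assert pearson(x, np.exp(x)).statistic < 1.0
        assert pearson(x, -x).statistic == pytest.approx(-1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_invariances(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(25), rng.random(25)
        assert pearson(3 * x + 2, y).statistic == pytest.approx(
            pearson(x, y).statistic, abs=1e-12
        )
        assert spearman(np.exp(x), y).statistic == pytest.approx(
            spearman(x, y).statistic, abs=1e-12
        )

    def test_p_values_match_t_transform(self):
        rng = np.random.default_rng(9)
        for _ in range(15):
            n = int(rng.integers(5, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r = pearson(x, y)
            t = r.statistic * np.sqrt((n - 2) / (1 - r.statistic**2))
            p = 2 * special.stdtr(n - 2, -abs(t))
            assert r.p_value == pytest.approx(p, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnovaTukey:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        r = anova_tukey([g, g, g])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_pairwise_row_count(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=5) for _ in range(4)]
        r = anova_tukey(groups)
        assert len(r.extra["tukey"]) == 4 * 3 // 2

    def test_outlier_group_drives_significance(self):
        rng = np.random.default_rng(2)
        g1 = rng.normal(0, 0.1, 10)
        g2 = rng.normal(0, 0.1, 10)
        g3 = rng.normal(10, 0.1, 10)
        r = anova_tukey([g1, g2, g3], labels=["a", "b", "c"])
        tk = r.extra["tukey"].set_index(["group_a", "group_b"])
        assert tk.loc[("a", "c"), "p_adj"] < 0.001
        assert tk.loc[("b", "c"), "p_adj"] < 0.001
        assert tk.loc[("a", "b"), "p_adj"] > 0.05

    def test_matches_statsmodels_tukey(self):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, size=8) for m in (0, 0.5, 2)]
        r = anova_tukey(groups, labels=["g0", "g1", "g2"])
        data = np.concatenate(groups)
        labs = np.repeat(["g0", "g1", "g2"], 8)
        ref = sm.pairwise_tukeyhsd(data, labs)
        ours = r.extra["tukey"]["p_adj"].to_numpy()
        assert np.allclose(ours, ref.pvalues, atol=1e-6)

    def test_tukey_adjusted_not_below_raw_t(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, size=10) for m in (0, 0.3, 0.8)]
        r = anova_tukey(groups, labels=["0", "1", "2"])
        for _, row in r.extra["tukey"].iterrows():
            i, j = int(row.group_a), int(row.group_b)
            raw = t_test_independent(groups[i], groups[j], variant="student").p_value
            assert row.p_adj >= raw - 1e-9

    def test_small_group_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropping"):
            r = anova_tukey([[1.0, 2.0], [3.0, 4.0], [9.0]])
        assert r.group_sizes == (2, 2)


def test_benjamini_hochberg_known_example():
    p = np.array([0.01, 0.04, 0.03, 0.005])
    adj = benjamini_hochberg(p)
    # sorted p: .005, .01, .03, .04 -> adjusted: .02, .02, .04, .04
    assert adj[np.argsort(p)] == pytest.approx([0.02, 0.02, 0.04, 0.04])


class TestMotifFeatures:
    def _rep(self):
        return make_repertoire(
            "s", "case",
            [("CAFFF", "TRBV2*01", "TRBJ1-1*01", 0.6),
             ("CASSF", "TRBV2*01", "TRBJ1-1*01", 0.4)],
        )

    def test_containment_and_weighted(self):
        feats = {f.motif: f for f in motif_features(self._rep(), ["AFF"])}
        assert feats["AFF"].containment_fraction == pytest.approx(0.5)
        assert feats["AFF"].weighted_frequency == pytest.approx(0.6)

    def test_gapped_match_requires_fixed_positions(self):
        # C*SF requires C, any, S, F; neither CAFFF nor CASSF has a window
        # satisfying all three fixed positions (CASS fails s3, ASSF fails s0)
        feats = {f.motif: f for f in motif_features(self._rep(), ["C*SF"])}
        assert feats["C*SF"].containment_fraction == 0.0
        # the wildcard genuinely matches any residue
        feats = {f.motif: f for f in motif_features(self._rep(), ["C*SS"])}
        assert feats["C*SS"].containment_fraction == pytest.approx(0.5)

    def test_absent_motif_zero(self):
        feats = {f.motif: f for f in motif_features(self._rep(), ["WWW"])}
        assert feats["WWW"].containment_fraction == 0.0
        assert feats["WWW"].weighted_frequency == 0.0

    def test_total_sum_vs_union(self):
        rep = make_repertoire(
            "s", "case",
            [("CAFFLFFF", "TRBV2*01", "TRBJ1-1*01", 0.5),
             ("CASSYEQF", "TRBV2*01", "TRBJ1-1*01", 0.5)],
        )
        s = {f.motif: f for f in motif_features(rep, ["AFF", "LFF"], total_mode="sum")}
        u = {f.motif: f for f in motif_features(rep, ["AFF", "LFF"], total_mode="union")}
        # both motifs occur in the same (first) sequence
        assert s[TOTAL].weighted_frequency == pytest.approx(1.0)
        assert u[TOTAL].weighted_frequency == pytest.approx(0.5)
        assert s[TOTAL].containment_fraction == pytest.approx(0.5)

    def test_empty_motif_list(self):
        assert motif_features(self._rep(), []) == []


class TestJGene:
    def test_single_gene_usage(self):
        rep = make_repertoire(
            "s", "case",
            [("CADSF", "TRBV2*01", "TRBJ1-1*01", 0.7),
             ("CAYTF", "TRBV2*01", "TRBJ1-1*01", 0.3)],
        )
        assert jgene_usage(rep, ["TRBJ1-1*01"])["TRBJ1-1*01"] == pytest.approx(1.0)

    def test_usage_conservation_over_panel(self):
        rep = make_repertoire(
            "s", "case",
            [("CADSF", "TRBV2*01", "TRBJ1-1*01", 0.7),
             ("CAYTF", "TRBV2*01", "TRBJ2-2*01", 0.3)],
        )
        u = jgene_usage(rep, ["TRBJ1-1*01", "TRBJ2-2*01"])
        assert sum(u.values()) == pytest.approx(1.0)
        u2 = jgene_usage(rep, ["TRBJ1-1*01", "TRBJ2-2*01"], weighted=False)
        assert sum(u2.values()) == pytest.approx(1.0)

    def test_absent_gene_skipped(self):
        reps = [
            make_repertoire(f"p{i}", "case", [("CADSF", "TRBV2*01", "TRBJ1-1*01", 1.0)])
            for i in range(2)
        ] + [
            make_repertoire(f"h{i}", "control", [("CADSF", "TRBV2*01", "TRBJ1-1*01", 1.0)])
            for i in range(2)
        ]
        out = jgene_enrichment(Cohort(reps), ["TRBJ9-9*01"])
        assert out["TRBJ9-9*01"].p_value is None


class TestActivityReport:
    @staticmethod
    def _cohort_like(n=40, seed=0, shuffle=False):
        """ARS stands in for a burden-tracking score; no training needed."""
        rng = np.random.default_rng(seed)
        burden = rng.uniform(0.05, 0.25, size=n)
        a = 3.5 * burden + rng.normal(0, 0.1, size=n)
        ars = burden + rng.normal(0, 0.01, size=n)
        if shuffle:
            ars = rng.permutation(ars)
        records, clinical = [], {}
        med = np.median(a)
        qs = np.quantile(a, [0.2, 0.4, 0.6, 0.8])
        for i in range(n):
            sid = f"p{i}"
            records.append(ARSRecord(sid, "case", float(ars[i]), 100))
            clinical[sid] = ClinicalRecord(
                sledai=int(round(max(0, 10 * a[i]))),
                c3=float(120 - 40 * a[i] + rng.normal(0, 8)),
                c4=float(30 - 10 * a[i] + rng.normal(0, 3)),
                dsdna_positive=bool(a[i] > med),
                damage_count=int(np.searchsorted(qs, a[i])),
            )
        return records, clinical

    def test_signs_follow_construction(self):
        records, clinical = self._cohort_like()
        rep = activity_report(records, clinical)
        assert rep["spearman_sledai"].statistic > 0
        assert rep["spearman_c3"].statistic < 0
        assert rep["active_vs_silent"].statistic > 0
        assert rep["damage_anova"].p_value < 0.05

    def test_permuted_scores_attenuate(self):
        records, clinical = self._cohort_like(shuffle=True, seed=1)
        rep = activity_report(records, clinical)
        assert abs(rep["spearman_sledai"].statistic) < 0.2

    def test_missing_covariate_skips_only_that_analysis(self):
        records, clinical = self._cohort_like(n=10)
        for rec in clinical.values():
            rec.c4 = None
        rep = activity_report(records, clinical)
        assert rep["pearson_c4"] is None
        assert rep["pearson_sledai"] is not None
        assert any("c4" in n for n in rep["notes"])
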