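"""Motif-frequency repertoire features and the evaluation statistics layer.

Provides the rank-based Mann-Whitney formulation of ROC AUC, independent
t-tests (Welch by default), Pearson/Spearman correlation, one-way ANOVA
with Tukey HSD post-hoc, frequency-weighted J-gene usage enrichment, and
the composite disease-activity report relating the per-subject risk score
to SLEDAI, activity status, anti-dsDNA, accumulated tissue damage, and
complement C3/C4.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ParameterError, UndefinedStatisticError
from .repertoire_io import ClinicalRecord, Cohort, Repertoire

TOTAL = "TOTAL"


@dataclass
class MotifFeature:
    """Per-subject motif burden: containment and clone-weighted frequency."""

    subject_id: str
    motif: str
    containment_fraction: float
    weighted_frequency: float


@dataclass
class StatReport:
    name: str
    statistic: float
    p_value: float | None
    group_sizes: tuple[int, ...]
    extra: dict = field(default_factory=dict)


# --------------------------------------------------------------- features
def motif_regex(motif: str) -> re.Pattern:
    """Compile a contiguous or gapped motif ('*' matches any residue)."""
    return re.compile("".join("." if c == "*" else re.escape(c) for c in motif))


def motif_features(
    rep: Repertoire, motifs, total_mode: str = "sum"
) -> list[MotifFeature]:
    """Motif burden features for one (representative) repertoire.

    For each motif: the fraction of sequences containing it and the summed
    clone frequency of those sequences.  A TOTAL row aggregates the selected
    motifs — weighted_frequency as the sum of per-motif weighted frequencies
    (``total_mode='sum'``; co-occurring sequences counted once per motif) or
    as the union accounting (``'union'``); containment TOTAL is always the
    fraction of sequences containing at least one motif.
    """
    if total_mode not in ("sum", "union"):
        raise ParameterError("total_mode must be 'sum' or 'union'")
    out: list[MotifFeature] = []
    if not motifs:
        return out
    n = len(rep.clonotypes)
    seqs = [c.junction_aa for c in rep.clonotypes]
    freqs = np.array([c.frequency for c in rep.clonotypes])
    any_hit = np.zeros(n, dtype=bool)
    weighted_sum = 0.0
    for motif in motifs:
        pat = motif_regex(motif)
        hits = np.array([pat.search(s) is not None for s in seqs])
        any_hit |= hits
        wf = float(freqs[hits].sum())
        weighted_sum += wf
        out.append(MotifFeature(rep.subject_id, motif, float(hits.mean()), wf))
    total_wf = weighted_sum if total_mode == "sum" else float(freqs[any_hit].sum())
    out.append(MotifFeature(rep.subject_id, TOTAL, float(any_hit.mean()), total_wf))
    return out


# ------------------------------------------------------------- statistics
def auc_mann_whitney(values, labels) -> float:
    """ROC AUC via the Mann-Whitney pair-counting statistic.

    AUC = (#(case > control) + 0.5 * #ties) / (n_case * n_control),
    computed with midranks.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ParameterError("both labels must be present to compute AUC")
    ranks = sps.rankdata(values)
    r_pos = ranks[labels == 1].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def t_test_independent(a, b, variant: str = "welch") -> StatReport:
    """Two-sided independent-samples t-test (Welch by default).

    A degenerate pooled variance under the Student variant falls back to
    Welch with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each sample needs at least 2 observations")
    if variant not in ("welch", "student"):
        raise ParameterError("variant must be 'welch' or 'student'")
    if variant == "student" and a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        warnings.warn("degenerate variance: falling back to Welch")
        variant = "welch"
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    if np.isnan(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    return StatReport(
        name=f"t_test_{variant}",
        statistic=float(t),
        p_value=float(p),
        group_sizes=(len(a), len(b)),
        extra={"variant": variant},
    )


def _check_corr_input(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("correlation needs two equal-length vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("correlation inputs must be finite")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    return x, y


def pearson(x, y) -> StatReport:
    x, y = _check_corr_input(x, y)
    r, p = sps.pearsonr(x, y)
    return StatReport("pearson", float(r), float(p), (len(x),))


def spearman(x, y) -> StatReport:
    x, y = _check_corr_input(x, y)
    rho, p = sps.spearmanr(x, y)
    return StatReport("spearman", float(rho), float(p), (len(x),))


def anova_tukey(groups, labels=None) -> StatReport:
    """One-way ANOVA with a full pairwise Tukey HSD table.

    Groups with fewer than two observations are dropped with a warning.
    """
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    kept, kept_labels = [], []
    for g, lab in zip(groups, labels):
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            warnings.warn(f"ANOVA: dropping group {lab!r} with < 2 observations")
            continue
        kept.append(g)
        kept_labels.append(lab)
    if len(kept) < 2:
        raise ParameterError("ANOVA needs at least two groups with >= 2 observations")
    f, p = sps.f_oneway(*kept)
    if np.isnan(f):  # zero within- and between-group variance
        f, p = 0.0, 1.0
    hsd = sps.tukey_hsd(*kept)
    rows = []
    k = len(kept)
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group_a": kept_labels[i],
                    "group_b": kept_labels[j],
                    "diff": float(np.mean(kept[i]) - np.mean(kept[j])),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return StatReport(
        name="anova_oneway",
        statistic=float(f),
        p_value=float(p),
        group_sizes=tuple(len(g) for g in kept),
        extra={"tukey": pd.DataFrame(rows)},
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ------------------------------------------------------------ repertoire-level
def jgene_usage(rep: Repertoire, j_calls, weighted: bool = True) -> dict[str, float]:
    """Usage of each J gene of interest in one repertoire.

    ``weighted=True`` weights clonotypes by clone frequency; ``False`` uses
    the clone-count fraction, which is far less variable when the clone-size
    spectrum is heavy-tailed (a single dominant clone then cannot swing the
    statistic).
    """
    usage = {j: 0.0 for j in j_calls}
    w = 1.0 / max(len(rep.clonotypes), 1)
    for c in rep.clonotypes:
        if c.j_call in usage:
            usage[c.j_call] += c.frequency if weighted else w
    return usage


def jgene_enrichment(
    cohort: Cohort, j_calls, weighted: bool = True
) -> dict[str, StatReport]:
    """Case-vs-control t-test of per-subject J-gene usage, per gene."""
    rows = {j: {"case": [], "control": []} for j in j_calls}
    for rep in cohort:
        u = jgene_usage(rep, j_calls, weighted)
        for j in j_calls:
            rows[j][rep.label].append(u[j])
    out: dict[str, StatReport] = {}
    for j in j_calls:
        case, ctrl = rows[j]["case"], rows[j]["control"]
        if max(case, default=0.0) == 0.0 and max(ctrl, default=0.0) == 0.0:
            out[j] = StatReport(
                "jgene_usage", 0.0, None, (len(case), len(ctrl)),
                extra={"note": "gene absent everywhere; test skipped"},
            )
            continue
        rep_stat = t_test_independent(case, ctrl)
        rep_stat.name = "jgene_usage"
        rep_stat.extra.update(
            mean_case=float(np.mean(case)), mean_control=float(np.mean(ctrl))
        )
        out[j] = rep_stat
    return out


# ----------------------------------------------------------- activity report
def activity_report(
    ars_records, clinical: dict[str, ClinicalRecord]
) -> dict[str, StatReport | None]:
    """Relate per-subject risk scores to clinical disease-activity markers.

    Six analyses over case subjects matched to clinical records: Pearson and
    Spearman of score vs SLEDAI, Active-vs-Silent t-test (Active iff
    SLEDAI >= 5), dsDNA+/- t-test, one-way ANOVA (+Tukey) across damage
    counts, and correlations of score vs C3 and vs C4.  Analyses with fewer
    than 3 matched subjects (or fewer than 2 per group) are skipped and
    reported as None with a note in ``'notes'``.
    """
    recs = [r for r in ars_records if r.label == "case" and r.subject_id in clinical]
    notes: list[str] = []
    out: dict[str, StatReport | None] = {}

    def _pairs(attr):
        xs, ys = [], []
        for r in recs:
            v = getattr(clinical[r.subject_id], attr)
            if v is not None:
                xs.append(r.ars)
                ys.append(float(v))
        return np.array(xs), np.array(ys)

    def _corrs(attr, key):
        x, y = _pairs(attr)
        if len(x) < 3 or np.std(y) == 0.0:
            notes.append(f"{key}: skipped (insufficient or degenerate data)")
            out[f"pearson_{key}"] = out[f"spearman_{key}"] = None
            return
        out[f"pearson_{key}"] = pearson(x, y)
        out[f"spearman_{key}"] = spearman(x, y)

    _corrs("sledai", "sledai")
    _corrs("c3", "c3")
    _corrs("c4", "c4")

    active = [r.ars for r in recs if clinical[r.subject_id].is_active is True]
    silent = [r.ars for r in recs if clinical[r.subject_id].is_active is False]
    if len(active) >= 2 and len(silent) >= 2:
        rep_stat = t_test_independent(active, silent)
        rep_stat.name = "active_vs_silent"
        out["active_vs_silent"] = rep_stat
    else:
        notes.append("active_vs_silent: skipped (a group has < 2 subjects)")
        out["active_vs_silent"] = None

    dsp = [r.ars for r in recs if clinical[r.subject_id].dsdna_positive is True]
    dsn = [r.ars for r in recs if clinical[r.subject_id].dsdna_positive is False]
    if len(dsp) >= 2 and len(dsn) >= 2:
        rep_stat = t_test_independent(dsp, dsn)
        rep_stat.name = "dsdna_pos_vs_neg"
        out["dsdna_pos_vs_neg"] = rep_stat
    else:
        notes.append("dsdna: skipped (a group has < 2 subjects)")
        out["dsdna_pos_vs_neg"] = None

    dmg: dict[int, list[float]] = {}
    for r in recs:
        d = clinical[r.subject_id].damage_count
        if d is not None:
            dmg.setdefault(int(d), []).append(r.ars)
    groups = [dmg[k] for k in sorted(dmg)]
    if sum(len(g) >= 2 for g in groups) >= 2:
        out["damage_anova"] = anova_tukey(
            groups, labels=[str(k) for k in sorted(dmg)]
        )
    else:
        notes.append("damage_anova: skipped (< 2 usable groups)")
        out["damage_anova"] = None

    out["notes"] = notes  # type: ignore[assignment]
    out["n_matched"] = len(recs)  # type: ignore[assignment]
    return out
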