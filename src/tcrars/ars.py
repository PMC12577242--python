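"""Autoimmune Risk Score: per-subject aggregation of TCR-level scores.

The ARS of a subject is the unweighted arithmetic mean of the classifier's
probabilities over the subject's representative clonotype set (aggregators
``top_k_mean`` and ``weighted_mean`` are exposed as alternatives).
Individual-level k-fold cross-validation re-trains the classifier per fold
on the pooled TCRs of the fold's training subjects, so every subject's ARS
is computed out of fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import ModelConfig, TCRClassifier
from .encoding import Vocabulary, build_vocabulary, encode_batch
from .exceptions import ParameterError
from .repertoire_io import Clonotype, Cohort, Repertoire, pool_training_tcrs
from .stats import auc_mann_whitney


@dataclass
class ARSRecord:
    subject_id: str
    label: str
    ars: float
    n_tcrs_scored: int


@dataclass
class CVResult:
    fold_aucs: list[float]
    ars_records: list[ARSRecord]
    fold_of_subject: dict[str, int] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def _score_repertoire(model: TCRClassifier, rep: Repertoire) -> np.ndarray:
    genes = None
    if model.uses_gene:
        col = model._gene_column()
        genes = [getattr(c, col) for c in rep.clonotypes]
    toks, gvec = encode_batch(
        [c.junction_aa for c in rep.clonotypes], model.vocab, genes
    )
    return model.predict_tokens(toks, gvec)


def compute_ars(
    model: TCRClassifier,
    rep: Repertoire,
    vocab: Vocabulary | None = None,
    aggregator: str = "mean",
    top_k: int | None = None,
) -> ARSRecord:
    """Aggregate per-TCR probabilities over the representative set.

    The default aggregator is the unweighted mean, which is invariant to
    clonotype ordering and to rescaling of clone frequencies.
    """
    if len(rep) == 0:
        raise ParameterError(f"{rep.subject_id}: empty repertoire")
    if vocab is not None:
        model.require_vocab(vocab)
    scores = _score_repertoire(model, rep)
    if aggregator == "mean":
        ars = float(scores.mean())
    elif aggregator == "top_k_mean":
        k = min(top_k or len(scores), len(scores))
        ars = float(np.sort(scores)[::-1][:k].mean())
    elif aggregator == "weighted_mean":
        freqs = np.array([c.frequency for c in rep.clonotypes])
        ars = float((scores * freqs).sum() / freqs.sum())
    else:
        raise ParameterError(f"unknown aggregator: {aggregator!r}")
    return ARSRecord(rep.subject_id, rep.label, ars, len(scores))


def crossvalidate_individual_level(
    cohort: Cohort,
    k: int = 5,
    feature_mode: str = "cdr3+vgene",
    cfg: ModelConfig | None = None,
    seed: int = 0,
    aggregator: str = "mean",
) -> CVResult:
    """Subject-level stratified k-fold cross-validation of the ARS.

    Per fold: pool the training subjects' representative TCRs, build the
    vocabulary and train a fresh classifier from them, then compute ARS for
    the held-out subjects and the fold's case-vs-control ARS AUC.
    """
    labels = np.array([1 if r.label == "case" else 0 for r in cohort])
    for lab in (0, 1):
        if (labels == lab).sum() < k:
            raise ParameterError(f"need >= {k} subjects per label for {k}-fold CV")
    cfg = cfg or ModelConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reps = cohort.repertoires
    records: list[ARSRecord] = []
    fold_aucs: list[float] = []
    fold_of: dict[str, int] = {}
    max_len = max(
        len(c.junction_aa) for r in cohort for c in r.clonotypes
    )
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(reps)), labels)):
        train_cohort = Cohort([reps[i] for i in tr])
        pool = pool_training_tcrs(train_cohort, feature_mode)
        vocab = build_vocabulary(pool, feature_mode, max_len=max_len)
        fold_cfg = ModelConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        model = TCRClassifier(fold_cfg, vocab, feature_mode).fit(pool)
        fold_records = [
            compute_ars(model, reps[i], aggregator=aggregator) for i in va
        ]
        records.extend(fold_records)
        for i in va:
            fold_of[reps[i].subject_id] = fold
        fold_aucs.append(
            auc_mann_whitney(
                [r.ars for r in fold_records],
                [1 if r.label == "case" else 0 for r in fold_records],
            )
        )
    return CVResult(fold_aucs=fold_aucs, ars_records=records, fold_of_subject=fold_of)


def harmonize_cv_ars(cv: CVResult) -> list[ARSRecord]:
    """Calibrate out-of-fold ARS to a common healthy baseline.

    Each fold's classifier is a separate training run with its own score
    calibration; pooling raw out-of-fold scores therefore mixes per-fold
    offsets into between-subject comparisons.  Subtracting, per fold, the
    mean ARS of that fold's held-out controls re-expresses every score as
    elevation above the healthy baseline, making scores comparable across
    folds.  Harmonized scores are offsets and may be slightly negative.
    """
    fold_ctrl: dict[int, list[float]] = {}
    for r in cv.ars_records:
        if r.label == "control":
            fold_ctrl.setdefault(cv.fold_of_subject[r.subject_id], []).append(r.ars)
    if not fold_ctrl:
        raise ParameterError("no control subjects to define the baseline")
    offsets = {f: float(np.mean(v)) for f, v in fold_ctrl.items()}
    out = []
    for r in cv.ars_records:
        off = offsets.get(cv.fold_of_subject[r.subject_id])
        if off is None:
            continue
        out.append(ARSRecord(r.subject_id, r.label, r.ars - off, r.n_tcrs_scored))
    return out


def select_top_sequences(
    model: TCRClassifier, rep: Repertoire, m: int = 2000
) -> list[tuple[Clonotype, float]]:
    """The m highest-probability TCRs of a repertoire, descending.

    Ties are broken lexicographically on the junction so selection is
    deterministic.
    """
    if m <= 0:
        raise ParameterError("m must be positive")
    scores = _score_repertoire(model, rep)
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], rep.clonotypes[i].junction_aa)
    )[:m]
    return [(rep.clonotypes[i], float(scores[i])) for i in order]


def export_top_sequences(selection, path) -> None:
    """Write a selection to TSV (junction_aa, v_call, j_call, score)."""
    if not selection:
        raise ParameterError("selection is empty")
    with open(path, "w") as fh:
        fh.write("junction_aa\tv_call\tj_call\tscore\n")
        for clono, score in selection:
            fh.write(f"{clono.junction_aa}\t{clono.v_call}\t{clono.j_call}\t{score:.6f}\n")
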