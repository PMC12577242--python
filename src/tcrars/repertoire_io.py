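"""Repertoire ingestion, quality control, representative selection and splits.

Repertoires arrive either as AIRR Rearrangement TSV (columns ``junction_aa``,
``v_call``, ``j_call`` and one of ``duplicate_count``/``frequency``) or as a
minimal "simple" TSV dialect (``cdr3``, ``v``, ``j``, ``freq``).  Counts are
converted to within-repertoire frequencies summing to one.  Quality control
retains canonical-alphabet junctions of plausible length; the representative
set is the n most frequent clonotypes, and cohorts are split train/validation
at the individual level with label stratification so that no subject's TCRs
leak across the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .encoding import AA_ALPHABET, v_family_of
from .exceptions import (
    EmptyRepertoireError,
    FormatError,
    ParameterError,
    StratificationError,
)

logger = logging.getLogger(__name__)

_CANONICAL = set(AA_ALPHABET)

AIRR_COLUMNS = ("junction_aa", "v_call", "j_call")
SIMPLE_COLUMNS = ("cdr3", "v", "j", "freq")


@dataclass(frozen=True)
class Clonotype:
    """One TCRβ rearrangement with its within-repertoire relative frequency."""

    junction_aa: str
    v_call: str
    j_call: str
    frequency: float
    v_family: str = ""

    def __post_init__(self):
        if not self.v_family:
            object.__setattr__(self, "v_family", v_family_of(self.v_call))


@dataclass
class ClinicalRecord:
    """Per-subject clinical covariates; missing values are None, never imputed.

    ``damage_count`` counts affected tissue types among skin, joint, blood,
    kidney and brain (0-4).  Disease activity is derived, not stored: a
    subject is Active iff SLEDAI >= 5.
    """

    sledai: int | None = None
    c3: float | None = None
    c4: float | None = None
    dsdna_positive: bool | None = None
    damage_count: int | None = None

    ACTIVITY_CUTOFF = 5

    @property
    def is_active(self) -> bool | None:
        if self.sledai is None:
            return None
        return self.sledai >= self.ACTIVITY_CUTOFF


@dataclass
class Repertoire:
    subject_id: str
    label: str  # "case" | "control"
    clonotypes: list[Clonotype]
    clinical: ClinicalRecord | None = None

    def __len__(self) -> int:
        return len(self.clonotypes)


@dataclass
class Cohort:
    repertoires: list[Repertoire] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.subject_id for r in self.repertoires]
        if len(ids) != len(set(ids)):
            raise ParameterError("duplicate subject_id in cohort")

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self):
        return iter(self.repertoires)

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.repertoires]

    def labels(self) -> list[str]:
        return [r.label for r in self.repertoires]


def _normalize(freqs: np.ndarray) -> np.ndarray:
    total = float(freqs.sum())
    if total <= 0:
        raise EmptyRepertoireError("total clone frequency is zero")
    return freqs / total


def read_repertoire(
    path, dialect: str = "airr", subject_id: str | None = None, label: str = "case"
) -> Repertoire:
    """Read one repertoire file into a :class:`Repertoire`.

    Counts (``duplicate_count``) take precedence over a ``frequency`` column
    when both are present; either is renormalised to sum to one.  Row order
    is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path} is empty")
    if dialect == "airr":
        for col in AIRR_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"{path}: missing required AIRR column {col!r}")
        if "duplicate_count" in df.columns:
            weights = pd.to_numeric(df["duplicate_count"]).to_numpy(float)
        elif "frequency" in df.columns:
            weights = pd.to_numeric(df["frequency"]).to_numpy(float)
        else:
            raise FormatError(
                f"{path}: AIRR dialect requires duplicate_count or frequency"
            )
        junc, v, j = df["junction_aa"], df["v_call"], df["j_call"]
    elif dialect == "simple":
        for col in SIMPLE_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        weights = pd.to_numeric(df["freq"]).to_numpy(float)
        junc, v, j = df["cdr3"], df["v"], df["j"]
    else:
        raise ParameterError(f"unknown dialect: {dialect!r}")
    if len(df) == 0:
        raise EmptyRepertoireError(f"{path} contains no rearrangements")
    freqs = _normalize(weights)
    clonotypes = [
        Clonotype(junction_aa=str(s), v_call=str(vv), j_call=str(jj), frequency=float(f))
        for s, vv, jj, f in zip(junc, v, j, freqs)
    ]
    return Repertoire(
        subject_id=subject_id or path.stem, label=label, clonotypes=clonotypes
    )


def write_repertoire(rep: Repertoire, path, dialect: str = "airr") -> None:
    """Serialise a repertoire; inverse of :func:`read_repertoire` (round-trips)."""
    rows = {
        "junction_aa" if dialect == "airr" else "cdr3": [c.junction_aa for c in rep.clonotypes],
        "v_call" if dialect == "airr" else "v": [c.v_call for c in rep.clonotypes],
        "j_call" if dialect == "airr" else "j": [c.j_call for c in rep.clonotypes],
        "frequency" if dialect == "airr" else "freq": [
            repr(c.frequency) for c in rep.clonotypes
        ],
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def qc_filter(
    rep: Repertoire, min_len: int = 6, max_len: int = 30
) -> Repertoire:
    """Quality-control a repertoire.

    Retains clonotypes whose junction is entirely canonical-alphabet, of
    length within [min_len, max_len], with positive frequency; survivors are
    renormalised.  Filter counts are logged.
    """
    kept, n_alpha, n_len, n_freq = [], 0, 0, 0
    for c in rep.clonotypes:
        if not set(c.junction_aa) <= _CANONICAL or not c.junction_aa:
            n_alpha += 1
        elif not (min_len <= len(c.junction_aa) <= max_len):
            n_len += 1
        elif c.frequency <= 0:
            n_freq += 1
        else:
            kept.append(c)
    if not kept:
        raise EmptyRepertoireError(
            f"{rep.subject_id}: no clonotypes survive quality control"
        )
    logger.info(
        "%s: QC removed %d non-canonical, %d out-of-length, %d zero-frequency",
        rep.subject_id, n_alpha, n_len, n_freq,
    )
    freqs = _normalize(np.array([c.frequency for c in kept]))
    kept = [replace(c, frequency=float(f)) for c, f in zip(kept, freqs)]
    return Repertoire(rep.subject_id, rep.label, kept, rep.clinical)


def select_representative(rep: Repertoire, n: int = 2000) -> Repertoire:
    """Keep the n most frequent clonotypes (the representative set).

    Ties are broken lexicographically on junction then V call, so selection
    is deterministic; survivors are renormalised and returned sorted by
    descending frequency.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    ranked = sorted(
        rep.clonotypes, key=lambda c: (-c.frequency, c.junction_aa, c.v_call)
    )[:n]
    freqs = _normalize(np.array([c.frequency for c in ranked]))
    ranked = [replace(c, frequency=float(f)) for c, f in zip(ranked, freqs)]
    return Repertoire(rep.subject_id, rep.label, ranked, rep.clinical)


def split_cohort(
    cohort: Cohort, train_fraction: float = 0.8, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Individual-level stratified train/validation split (default 4:1)."""
    labels = cohort.labels()
    uniq = set(labels)
    if len(uniq) < 2 or min(labels.count(u) for u in uniq) < 2:
        raise StratificationError("need at least two subjects per label to split")
    idx = np.arange(len(cohort))
    tr, va = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    reps = cohort.repertoires
    return (
        Cohort([reps[i] for i in sorted(tr)]),
        Cohort([reps[i] for i in sorted(va)]),
    )


def pool_training_tcrs(train: Cohort, feature_mode: str = "cdr3+vgene") -> pd.DataFrame:
    """Pool representative TCRs from all training subjects into one table.

    One row per (subject, clonotype) with the binary label inherited from the
    donor (case=1).  Exact within-subject duplicates are collapsed; identical
    TCRs contributed by donors of opposite labels are both retained — the
    pooled construction accepts noisy instance labels.
    """
    if len(train) == 0:
        raise ParameterError("empty training cohort")
    rows = []
    for rep in train:
        for c in rep.clonotypes:
            rows.append(
                (rep.subject_id, c.junction_aa, c.v_call, c.v_family, c.j_call,
                 c.frequency, 1 if rep.label == "case" else 0)
            )
    df = pd.DataFrame(
        rows,
        columns=["subject_id", "junction_aa", "v_call", "v_family", "j_call",
                 "frequency", "label"],
    )
    df = df.drop_duplicates(subset=["subject_id", "junction_aa", "v_call", "j_call"])
    if feature_mode == "cdr3":
        df = df.drop(columns=["v_call", "v_family"]).assign(v_call="", v_family="")
    return df.reset_index(drop=True)


_TRUTHY = {"1", "true", "yes", "pos", "positive", "y", "t"}
_FALSY = {"0", "false", "no", "neg", "negative", "n", "f"}


def _parse_bool(x) -> bool | None:
    if pd.isna(x):
        return None
    s = str(x).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise FormatError(f"cannot parse boolean value {x!r}")


def read_clinical(path) -> dict[str, ClinicalRecord]:
    """Read the clinical covariate CSV into subject_id -> ClinicalRecord.

    Missing covariates (absent column or empty cell) are stored as None.
    """
    df = pd.read_csv(path, dtype=str)
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: missing subject_id column")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"{path}: duplicated subject_id {dup!r}")

    def _num(row, col, cast):
        if col not in df.columns or pd.isna(row[col]) or str(row[col]).strip() == "":
            return None
        return cast(float(row[col]))

    out: dict[str, ClinicalRecord] = {}
    for _, row in df.iterrows():
        out[str(row["subject_id"])] = ClinicalRecord(
            sledai=_num(row, "sledai", lambda v: int(round(v))),
            c3=_num(row, "c3", float),
            c4=_num(row, "c4", float),
            dsdna_positive=_parse_bool(row["dsdna"]) if "dsdna" in df.columns else None,
            damage_count=_num(row, "damage_count", lambda v: int(round(v))),
        )
    return out


def attach_clinical(cohort: Cohort, clinical: dict[str, ClinicalRecord]) -> None:
    """Attach clinical records to matching subjects in place."""
    for rep in cohort:
        rep.clinical = clinical.get(rep.subject_id, rep.clinical)


def read_cohort(in_dir, dialect: str = "airr") -> Cohort:
    """Read a cohort directory: one repertoire TSV per subject + clinical.csv.

    Subject labels come from the ``label`` column of clinical.csv; clinical
    covariates are attached to the matching repertoires.
    """
    in_dir = Path(in_dir)
    clin_path = in_dir / "clinical.csv"
    if not clin_path.exists():
        raise FormatError(f"{in_dir}: clinical.csv not found")
    df = pd.read_csv(clin_path, dtype=str)
    labels = dict(zip(df["subject_id"], df.get("label", "case")))
    clinical = read_clinical(clin_path)
    reps = []
    for sid, label in labels.items():
        rep = read_repertoire(in_dir / f"{sid}.tsv", dialect, subject_id=sid, label=label)
        rep.clinical = clinical.get(sid)
        reps.append(rep)
    return Cohort(reps)


def prepare_cohort(
    cohort: Cohort,
    min_len: int = 6,
    max_len: int = 30,
    n_representative: int = 2000,
) -> Cohort:
    """QC-filter then representative-select every repertoire of a cohort."""
    return Cohort(
        [
            select_representative(qc_filter(r, min_len, max_len), n_representative)
            for r in cohort
        ]
    )
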