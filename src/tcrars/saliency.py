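"""Occlusion saliency: mask 3-mers and gapped mers, score the deltas.

Every window of a high-scoring CDR3 is occluded by writing the shared
padding/mask token (0) over the window's residues — for contiguous ``XXX``
all three positions; for gapped ``X*XX`` / ``XX*X`` only the X positions,
leaving the wildcard untouched — and the motif's contribution is the drop
in classifier probability, delta = P(original) - P(masked).  Deltas are
aggregated per distinct motif (mean over occurrences, configurable to
median), essential motifs are those in the top quantile of aggregated
deltas that also recur at least ``min_count`` times, and occurrences are
profiled positionally over front/mid/tail thirds of the unpadded junction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .classifier import TCRClassifier
from .encoding import EncodedTCR, encode_batch
from .exceptions import ParameterError

#: pattern name -> (window span, masked offsets within the window,
#:                  wildcard offsets within the window)
PATTERNS: dict[str, tuple[int, tuple[int, ...], tuple[int, ...]]] = {
    "XXX": (3, (0, 1, 2), ()),
    "X*XX": (4, (0, 2, 3), (1,)),
    "XX*X": (4, (0, 1, 3), (2,)),
}


@dataclass(frozen=True)
class MaskSpec:
    """A single occlusion window on the unpadded junction."""

    offset: int
    pattern: str

    @property
    def span(self) -> int:
        return PATTERNS[self.pattern][0]

    @property
    def masked_positions(self) -> tuple[int, ...]:
        return tuple(self.offset + k for k in PATTERNS[self.pattern][1])


@dataclass
class Occurrence:
    motif: str
    delta: float
    start: int
    length: int  # unpadded junction length


@dataclass
class MotifRecord:
    motif: str
    pattern: str
    mean_delta: float
    occurrence_count: int
    selected: bool = False


@dataclass
class PositionalProfile:
    """Per-motif positional saliency and front/mid/tail occurrence fractions.

    Segment boundaries are floor(L/3) and floor(2L/3) of the unpadded length,
    and an occurrence belongs to the segment containing its start index.
    """

    position_matrix: dict[str, np.ndarray] = field(default_factory=dict)
    segment_fractions: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def enumerate_masks(junction: str, pattern: str) -> list[tuple[MaskSpec, str]]:
    """All valid occlusion windows of ``pattern`` over a junction.

    Returns |junction| - span + 1 specs (empty when shorter than the span)
    with the motif string read off the masked positions, '*' at wildcards.
    """
    span, masked, wild = PATTERNS[pattern]
    out = []
    for off in range(len(junction) - span + 1):
        window = junction[off: off + span]
        motif = "".join(
            "*" if k in wild else window[k] for k in range(span)
        )
        out.append((MaskSpec(offset=off, pattern=pattern), motif))
    return out


def apply_mask(enc: EncodedTCR, spec: MaskSpec) -> EncodedTCR:
    """Zero the masked token positions (shifted by pad_len); pure function."""
    n = len(enc.tokens) - enc.pad_len
    if spec.offset < 0 or spec.offset + spec.span > n:
        raise ParameterError(
            f"mask {spec} out of range for junction of length {n}"
        )
    out = enc.copy()
    for pos in spec.masked_positions:
        out.tokens[enc.pad_len + pos] = 0
    return out


def occurrence_delta(model: TCRClassifier, enc: EncodedTCR, spec: MaskSpec) -> float:
    """delta = P(original) - P(masked) for one occlusion window."""
    masked = apply_mask(enc, spec)
    probs = model.predict_encoded([enc, masked])
    return float(probs[0] - probs[1])


def scan_sequences(
    model: TCRClassifier,
    sequences,
    genes=None,
    patterns=("XXX", "X*XX", "XX*X"),
    batch_size: int = 4096,
) -> dict[str, list[Occurrence]]:
    """Batched occlusion scan of many junctions.

    ``sequences`` is a list of junction strings; ``genes`` the matching gene
    labels when the model uses its gene branch.  Returns occurrences (motif,
    delta, start, length) per pattern.  Equivalent to calling
    :func:`occurrence_delta` per window, but scores masked variants in large
    batches.
    """
    vocab = model.vocab
    toks, gvec = encode_batch(sequences, vocab, genes if model.uses_gene else None)
    base = model.predict_tokens(toks, gvec, batch_size)
    out: dict[str, list[Occurrence]] = {p: [] for p in patterns}
    masked_rows, masked_genes, owners = [], [], []
    for si, seq in enumerate(sequences):
        pad = vocab.max_len - len(seq)
        for pattern in patterns:
            for spec, motif in enumerate_masks(seq, pattern):
                row = toks[si].copy()
                for pos in spec.masked_positions:
                    row[pad + pos] = 0
                masked_rows.append(row)
                if gvec is not None:
                    masked_genes.append(gvec[si])
                owners.append((pattern, motif, spec.offset, len(seq), si))
    if not masked_rows:
        return out
    mtoks = np.stack(masked_rows)
    mg = np.array(masked_genes, dtype=np.int64) if gvec is not None else None
    mprobs = model.predict_tokens(mtoks, mg, batch_size)
    for (pattern, motif, off, length, si), mp in zip(owners, mprobs):
        out[pattern].append(
            Occurrence(motif=motif, delta=float(base[si] - mp), start=off, length=length)
        )
    return out


def aggregate_motif_scores(
    occurrences: list[Occurrence], pattern: str, aggregate: str = "mean"
) -> list[MotifRecord]:
    """Collapse occurrences into per-motif records (mean delta, count)."""
    if not occurrences:
        raise ParameterError("no occurrences to aggregate")
    if aggregate not in ("mean", "median"):
        raise ParameterError("aggregate must be 'mean' or 'median'")
    groups: dict[str, list[float]] = defaultdict(list)
    for occ in occurrences:
        groups[occ.motif].append(occ.delta)
    agg = np.mean if aggregate == "mean" else np.median
    return [
        MotifRecord(motif=m, pattern=pattern, mean_delta=float(agg(ds)),
                    occurrence_count=len(ds))
        for m, ds in sorted(groups.items())
    ]


def select_essential(
    records: list[MotifRecord], top_quantile: float = 0.015, min_count: int = 300
) -> list[MotifRecord]:
    """Mark motifs in the top score quantile that recur at least min_count times.

    The quantile is computed over distinct motifs' aggregated deltas.
    Returns the selected records (records are flagged in place as well),
    sorted by descending mean delta.
    """
    if not 0.0 < top_quantile < 1.0:
        raise ParameterError("top_quantile must lie in (0, 1)")
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    deltas = np.array([r.mean_delta for r in records])
    threshold = float(np.quantile(deltas, 1.0 - top_quantile))
    selected = []
    for r in records:
        r.selected = r.mean_delta >= threshold and r.occurrence_count >= min_count
        if r.selected:
            selected.append(r)
    return sorted(selected, key=lambda r: -r.mean_delta)


def positional_profile(
    selected: list[MotifRecord], occurrences: list[Occurrence], max_len: int | None = None
) -> PositionalProfile:
    """Positional saliency and segment occupancy for the selected motifs."""
    if not selected:
        raise ParameterError("no selected motifs to profile")
    motifs = {r.motif for r in selected}
    if max_len is None:
        max_len = max((o.length for o in occurrences), default=0)
    profile = PositionalProfile()
    pos_sum: dict[str, np.ndarray] = {m: np.zeros(max_len) for m in motifs}
    pos_cnt: dict[str, np.ndarray] = {m: np.zeros(max_len) for m in motifs}
    seg_cnt: dict[str, np.ndarray] = {m: np.zeros(3) for m in motifs}
    for occ in occurrences:
        if occ.motif not in motifs:
            continue
        pos_sum[occ.motif][occ.start] += occ.delta
        pos_cnt[occ.motif][occ.start] += 1
        front, mid = occ.length // 3, (2 * occ.length) // 3
        seg = 0 if occ.start < front else (1 if occ.start < mid else 2)
        seg_cnt[occ.motif][seg] += 1
    for m in motifs:
        with np.errstate(invalid="ignore"):
            profile.position_matrix[m] = np.where(
                pos_cnt[m] > 0, pos_sum[m] / np.maximum(pos_cnt[m], 1), np.nan
            )
        total = seg_cnt[m].sum()
        fr = seg_cnt[m] / total if total else np.full(3, np.nan)
        profile.segment_fractions[m] = (float(fr[0]), float(fr[1]), float(fr[2]))
    return profile


def mine_motifs(
    model: TCRClassifier,
    case_sequences,
    case_genes=None,
    patterns=("XXX", "X*XX", "XX*X"),
    top_quantile: float = 0.015,
    min_counts: dict[str, int] | None = None,
    aggregate: str = "mean",
) -> dict[str, dict]:
    """End-to-end motif mining over the analyzed case sequences.

    ``min_counts`` maps pattern -> minimum occurrence count (defaults:
    300 for XXX, 20 for the gapped patterns).  Returns, per pattern, the
    full record list, the selected essential motifs, and their positional
    profile.
    """
    if min_counts is None:
        min_counts = {"XXX": 300, "X*XX": 20, "XX*X": 20}
    occ = scan_sequences(model, case_sequences, case_genes, patterns)
    result: dict[str, dict] = {}
    for pattern in patterns:
        records = aggregate_motif_scores(occ[pattern], pattern, aggregate)
        selected = select_essential(
            records, top_quantile, min_counts.get(pattern, 20)
        )
        profile = (
            positional_profile(selected, occ[pattern]) if selected else PositionalProfile()
        )
        result[pattern] = {
            "records": records,
            "selected": selected,
            "profile": profile,
            "occurrences": occ[pattern],
        }
    return result
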