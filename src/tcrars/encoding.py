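"""Tokenisation of CDR3 amino-acid sequences and categorical gene encoding.

CDR3 junctions are mapped to fixed-length integer vectors with *leading*
zero padding; index 0 is reserved jointly for padding and for occlusion
masking, so that zeroing a token genuinely nullifies the residue.  Gene
features (V call or V family) are encoded as a single categorical index
against a vocabulary built from training data only, with an explicit UNK
entry for labels unseen at training time.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

import numpy as np

from .exceptions import FormatError, ParameterError

#: Canonical amino-acid alphabet, alphabetical order.  Index i+1 encodes
#: AA_ALPHABET[i]; index 0 is padding/mask.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Sentinel label for unknown / malformed genes.
UNK = "<UNK>"

_AA_INDEX = {aa: i + 1 for i, aa in enumerate(AA_ALPHABET)}

_VFAM_RE = re.compile(r"^(TRBV\d+)")


def v_family_of(v_call: str) -> str:
    """Reduce a V gene-allele call to its gene family.

    ``TRBV12-3*01 -> TRBV12``; ``TRBV20-1 -> TRBV20``.  Malformed calls map
    to the UNK sentinel (total function; callers may log).
    """
    m = _VFAM_RE.match(str(v_call).strip())
    return m.group(1) if m else UNK


@dataclass(frozen=True)
class Vocabulary:
    """Token and gene vocabularies plus the global padded length.

    ``aa_index`` is fixed (alphabetical, 1-based); ``gene_index`` enumerates
    gene labels seen in training, with UNK at index 0.
    """

    gene_index: dict[str, int]
    max_len: int
    aa_index: dict[str, int] = field(default_factory=lambda: dict(_AA_INDEX))

    def __post_init__(self) -> None:
        if self.max_len <= 0:
            raise ParameterError("max_len must be positive")
        if UNK not in self.gene_index:
            raise ParameterError("gene_index must contain the UNK entry")

    @property
    def n_tokens(self) -> int:
        """Size of the token embedding table (20 residues + padding)."""
        return len(self.aa_index) + 1

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    def to_json(self) -> str:
        return json.dumps(
            {"gene_index": self.gene_index, "max_len": self.max_len},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        return cls(gene_index=dict(d["gene_index"]), max_len=int(d["max_len"]))

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class EncodedTCR:
    """A pre-padded token vector plus optional gene index.

    ``tokens[pad_len:]`` are all nonzero before any masking;
    ``pad_len = max_len - len(junction_aa)``.
    """

    tokens: np.ndarray
    gene: int | None
    pad_len: int

    def copy(self) -> "EncodedTCR":
        return EncodedTCR(self.tokens.copy(), self.gene, self.pad_len)


def build_vocabulary(pool, feature_mode: str, max_len: int | None = None) -> Vocabulary:
    """Build the vocabulary from a pooled training table.

    Parameters
    ----------
    pool : pandas.DataFrame
        Must carry ``junction_aa``; the gene column used depends on
        ``feature_mode`` (``v_call`` for ``cdr3+vgene``, ``v_family`` for
        ``cdr3+vfamily``; ignored for ``cdr3``).
    max_len : int, optional
        Global padded length.  Defaults to the longest training junction.
    """
    if len(pool) == 0:
        raise ParameterError("cannot build a vocabulary from an empty pool")
    longest = int(pool["junction_aa"].str.len().max())
    if max_len is None:
        max_len = longest
    elif longest > max_len:
        raise ParameterError(
            f"training junction of length {longest} exceeds max_len={max_len}; "
            "increase max_len"
        )
    gene_index: dict[str, int] = {UNK: 0}
    if feature_mode == "cdr3+vgene":
        col = "v_call"
    elif feature_mode == "cdr3+vfamily":
        col = "v_family"
    elif feature_mode == "cdr3":
        col = None
    else:
        raise ParameterError(f"unknown feature_mode: {feature_mode!r}")
    if col is not None:
        for g in sorted(pool[col].astype(str).unique()):
            gene_index[g] = len(gene_index)
    return Vocabulary(gene_index=gene_index, max_len=max_len)


def encode_cdr3(junction_aa: str, vocab: Vocabulary, gene: str | None = None) -> EncodedTCR:
    """Encode one junction (and optionally its gene label) against ``vocab``."""
    n = len(junction_aa)
    if n > vocab.max_len:
        raise ParameterError(
            f"junction of length {n} exceeds vocabulary max_len={vocab.max_len}"
        )
    pad = vocab.max_len - n
    tokens = np.zeros(vocab.max_len, dtype=np.int64)
    for i, c in enumerate(junction_aa):
        idx = vocab.aa_index.get(c)
        if idx is None:
            raise FormatError(f"non-canonical residue {c!r} in junction {junction_aa!r}")
        tokens[pad + i] = idx
    g = encode_gene(gene, vocab) if gene is not None else None
    return EncodedTCR(tokens=tokens, gene=g, pad_len=pad)


def decode_cdr3(enc: EncodedTCR, vocab: Vocabulary) -> str:
    """Inverse of :func:`encode_cdr3`, ignoring padding (and masked zeros)."""
    rev = {v: k for k, v in vocab.aa_index.items()}
    return "".join(rev[t] for t in enc.tokens.tolist() if t != 0)


def encode_gene(label: str, vocab: Vocabulary) -> int:
    """Total mapping from gene label to vocabulary index (UNK if unseen)."""
    return vocab.gene_index.get(str(label), vocab.gene_index[UNK])


def encode_batch(
    junctions, vocab: Vocabulary, genes=None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Vectorised encoding of many junctions into a (B, max_len) token matrix."""
    toks = np.zeros((len(junctions), vocab.max_len), dtype=np.int64)
    for i, j in enumerate(junctions):
        toks[i] = encode_cdr3(j, vocab).tokens
    gvec = None
    if genes is not None:
        gvec = np.array([encode_gene(g, vocab) for g in genes], dtype=np.int64)
    return toks, gvec
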