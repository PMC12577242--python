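import numpy as np
import pandas as pd
import pytest

from tcrars.classifier import ModelConfig, TCRClassifier
from tcrars.encoding import Vocabulary, build_vocabulary
from tcrars.repertoire_io import Clonotype, Cohort, Repertoire


def make_repertoire(subject_id, label, rows):
    """rows: iterable of (junction, v_call, j_call, freq)."""
    total = sum(r[3] for r in rows)
    return Repertoire(
        subject_id,
        label,
        [
            Clonotype(junction_aa=j, v_call=v, j_call=jj, frequency=f / total)
            for j, v, jj, f in rows
        ],
    )


@pytest.fixture
def toy_pool():
    rng = np.random.default_rng(0)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    for i in range(40):
        junc = "C" + "".join(rng.choice(letters[1:], size=10)) + "F"
        rows.append(
            {
                "subject_id": f"s{i % 4}",
                "junction_aa": junc,
                "v_call": f"TRBV{(i % 5) + 1}-1*01",
                "v_family": f"TRBV{(i % 5) + 1}",
                "j_call": "TRBJ1-1*01",
                "frequency": 0.1,
                "label": i % 2,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def small_vocab(toy_pool):
    return build_vocabulary(toy_pool, "cdr3+vgene", max_len=16)


TINY_CFG = dict(
    embed_dim=6, conv_blocks=2, conv_channels=8, kernel_size=3, lstm_layers=2,
    lstm_hidden=4, dropout=0.0, gene_embed_dim=3, dense_dim=8, seed=7,
)


@pytest.fixture
def tiny_model(small_vocab):
    """Small untrained classifier; deterministic scoring."""
    return TCRClassifier(ModelConfig(**TINY_CFG), small_vocab, "cdr3+vgene")


@pytest.fixture
def zero_head_model(small_vocab):
    """Classifier with a zeroed output layer: scores exactly 0.5 everywhere."""
    m = TCRClassifier(ModelConfig(**TINY_CFG), small_vocab, "cdr3+vgene")
    m.net.params["out_W"][:] = 0.0
    m.net.params["out_b"][:] = 0.0
    return m
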