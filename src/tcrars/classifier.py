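"""TCR-level binary classifier: CNN + BiLSTM over tokenised CDR3s.

The scorer consumes a pre-padded token vector (sequence branch) and an
optional categorical gene index (gene branch).  The sequence embedding is
read by two parallel branches — a stack of residually connected 1-D
convolution blocks pooled with a global position-wise max, and a stack of
bidirectional LSTM layers with inter-layer dropout summarised by the final
hidden states — whose summaries are concatenated with the flattened gene
embedding and pushed through a dense layer to a single logistic score in
[0, 1].  Training minimises class-weighted binary cross-entropy with Adam
and early stopping on a held-out slice of the pooled TCR table.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _nn
from .encoding import EncodedTCR, Vocabulary, encode_batch
from .exceptions import ParameterError, VocabularyMismatchError

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Hyperparameters of the TCR classifier.

    The topology (four residual convolution blocks; three bidirectional
    recurrent layers with dropout; gene embedding flattened and concatenated;
    dense head with logistic output) is fixed by the architecture contract;
    the widths below are package defaults sized for single-CPU training and
    are all configurable.
    """

    embed_dim: int = 16
    conv_blocks: int = 4
    conv_channels: int = 32
    kernel_size: int = 3
    lstm_layers: int = 3
    lstm_hidden: int = 16
    dropout: float = 0.2
    gene_embed_dim: int = 8
    dense_dim: int = 32
    learning_rate: float = 2e-3
    epochs: int = 8
    batch_size: int = 256
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 2
    max_train_tcrs: int | None = None
    restore_best: bool = True

    @classmethod
    def for_mining(cls, **overrides) -> "ModelConfig":
        """Training profile for occlusion saliency.

        Subject-level discrimination saturates within a couple of epochs,
        but per-motif carrier confidence — what occlusion deltas measure —
        keeps sharpening afterwards, and inter-layer dropout blurs it for
        gapped (wildcard) patterns.  This profile therefore trains longer,
        on the full pool, without dropout, and keeps the final epoch's
        parameters.
        """
        base = dict(
            dropout=0.0, epochs=8, batch_size=128, patience=10**6,
            max_train_tcrs=None, restore_best=False,
        )
        base.update(overrides)
        return cls(**base)

    def __post_init__(self):
        if self.conv_blocks < 1 or self.lstm_layers < 1:
            raise ParameterError("conv_blocks and lstm_layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must lie in [0, 1)")


@dataclass
class TrainingReport:
    epoch_train_loss: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


class TCRClassifier:
    """A (possibly trained) TCR scorer bound to a vocabulary."""

    def __init__(self, cfg: ModelConfig, vocab: Vocabulary, feature_mode: str):
        self.cfg = cfg
        self.vocab = vocab
        self.feature_mode = feature_mode
        self.vocab_hash = vocab.content_hash()
        use_gene = feature_mode in ("cdr3+vgene", "cdr3+vfamily")
        if feature_mode == "cdr3" and cfg.gene_embed_dim > 0:
            warnings.warn(
                "feature_mode='cdr3': gene branch disabled despite gene_embed_dim > 0"
            )
        self.net = _nn.Network(
            n_tokens=vocab.n_tokens,
            n_genes=vocab.n_genes,
            embed_dim=cfg.embed_dim,
            conv_blocks=cfg.conv_blocks,
            conv_channels=cfg.conv_channels,
            kernel_size=cfg.kernel_size,
            lstm_layers=cfg.lstm_layers,
            lstm_hidden=cfg.lstm_hidden,
            dropout=cfg.dropout,
            gene_embed_dim=cfg.gene_embed_dim,
            dense_dim=cfg.dense_dim,
            use_gene=use_gene,
            seed=cfg.seed,
        )
        self.report = TrainingReport()

    # ------------------------------------------------------------ helpers
    @property
    def uses_gene(self) -> bool:
        return self.net.use_gene

    def _gene_column(self) -> str | None:
        return {
            "cdr3": None, "cdr3+vgene": "v_call", "cdr3+vfamily": "v_family"
        }[self.feature_mode]

    def require_vocab(self, vocab: Vocabulary) -> None:
        if vocab.content_hash() != self.vocab_hash:
            raise VocabularyMismatchError(
                "input was encoded against a different vocabulary than the model's"
            )

    def encode_pool(self, pool) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
        col = self._gene_column()
        genes = pool[col].astype(str).tolist() if (col and self.uses_gene) else None
        toks, gvec = encode_batch(pool["junction_aa"].tolist(), self.vocab, genes)
        y = pool["label"].to_numpy(dtype=float)
        return toks, gvec, y

    # ----------------------------------------------------------- scoring
    def predict_tokens(self, tokens, genes=None, batch_size: int = 4096) -> np.ndarray:
        """Score token matrices; order-preserving, batch-size invariant."""
        out = np.empty(len(tokens))
        for s in range(0, len(tokens), batch_size):
            sl = slice(s, s + batch_size)
            g = genes[sl] if genes is not None else None
            out[sl], _ = self.net.forward(tokens[sl], g, train=False)
        return out

    def predict_encoded(self, batch: list[EncodedTCR], batch_size: int = 4096) -> np.ndarray:
        """Score a batch of :class:`EncodedTCR` (probabilities in [0, 1])."""
        toks = np.stack([e.tokens for e in batch])
        genes = None
        if self.uses_gene:
            genes = np.array(
                [e.gene if e.gene is not None else 0 for e in batch], dtype=np.int64
            )
        return self.predict_tokens(toks, genes, batch_size)

    # ----------------------------------------------------------- training
    def fit(self, pool) -> "TCRClassifier":
        """Train on a pooled, labeled TCR table (pandas DataFrame).

        Requires both labels.  Class imbalance is handled with
        inverse-frequency loss weights; a stratified ``val_fraction`` slice
        of the pool is held out for early stopping.
        """
        cfg = self.cfg
        labels = set(pool["label"].unique().tolist())
        if labels != {0, 1}:
            raise ParameterError("training pool must contain both labels 0 and 1")
        rng = np.random.default_rng(cfg.seed)
        toks, genes, y = self.encode_pool(pool)
        n = len(y)
        if cfg.max_train_tcrs is not None and n > cfg.max_train_tcrs:
            keep = rng.choice(n, size=cfg.max_train_tcrs, replace=False)
            toks, y = toks[keep], y[keep]
            genes = genes[keep] if genes is not None else None
            n = cfg.max_train_tcrs
        # early-stopping slice (val_fraction 0 disables it: monitor train loss)
        order = rng.permutation(n)
        val_n = max(2, int(round(cfg.val_fraction * n))) if cfg.val_fraction > 0 else 0
        val_idx, tr_idx = order[:val_n], order[val_n:]
        if len({int(v) for v in y[tr_idx]}) < 2 or len(tr_idx) == 0:
            tr_idx, val_idx = order, order[:val_n]
        n_pos = max(y[tr_idx].sum(), 1.0)
        n_neg = max(len(tr_idx) - y[tr_idx].sum(), 1.0)
        w_pos = len(tr_idx) / (2.0 * n_pos)
        w_neg = len(tr_idx) / (2.0 * n_neg)

        opt = _nn.Adam(self.net.params, lr=cfg.learning_rate)
        best_val = np.inf
        best_params = None
        bad_epochs = 0
        for epoch in range(cfg.epochs):
            perm = rng.permutation(len(tr_idx))
            losses = []
            for s in range(0, len(perm), cfg.batch_size):
                b = tr_idx[perm[s: s + cfg.batch_size]]
                gb = genes[b] if genes is not None else None
                probs, cache = self.net.forward(
                    toks[b], gb, train=True, rng=rng, want_cache=True
                )
                wb = np.where(y[b] == 1.0, w_pos, w_neg)
                loss, dlogit = _nn.weighted_bce(probs, y[b], wb)
                grads = self.net.backward(cache, dlogit)
                opt.step(self.net.params, grads)
                losses.append(loss)
            self.report.epoch_train_loss.append(float(np.mean(losses)))
            if val_n > 0:
                vg = genes[val_idx] if genes is not None else None
                vp = self.predict_tokens(toks[val_idx], vg)
                wv = np.where(y[val_idx] == 1.0, w_pos, w_neg)
                vloss, _ = _nn.weighted_bce(vp, y[val_idx], wv)
            else:
                vloss = self.report.epoch_train_loss[-1]
            self.report.epoch_val_loss.append(float(vloss))
            logger.info(
                "epoch %d: train loss %.4f, val loss %.4f",
                epoch, self.report.epoch_train_loss[-1], vloss,
            )
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_params = {k: v.copy() for k, v in self.net.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > cfg.patience:
                    self.report.stopped_epoch = epoch
                    break
        if cfg.restore_best and best_params is not None:
            self.net.params = best_params
        return self

    # ------------------------------------------------------ serialisation
    def save(self, path) -> None:
        """Single-archive checkpoint: parameters + config + vocabulary."""
        meta = json.dumps(
            {
                "config": asdict(self.cfg),
                "feature_mode": self.feature_mode,
                "vocab": json.loads(self.vocab.to_json()),
                "vocab_hash": self.vocab_hash,
            }
        )
        np.savez(
            path,
            __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
            **{f"param/{k}": v for k, v in self.net.params.items()},
        )

    @classmethod
    def load(cls, path) -> "TCRClassifier":
        with np.load(path if str(path).endswith(".npz") else f"{path}") as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {
                k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")
            }
        vocab = Vocabulary.from_json(json.dumps(meta["vocab"]))
        model = cls(ModelConfig(**meta["config"]), vocab, meta["feature_mode"])
        model.net.params = params
        return model


def build_model(cfg: ModelConfig, vocab: Vocabulary, feature_mode: str) -> TCRClassifier:
    """Construct an untrained classifier (seeded, deterministic init)."""
    return TCRClassifier(cfg, vocab, feature_mode)


def train_model(model: TCRClassifier, pool, cfg: ModelConfig | None = None) -> TCRClassifier:
    """Train ``model`` on the pooled TCR table; returns the trained model."""
    if cfg is not None:
        model.cfg = cfg
    return model.fit(pool)


def predict_tcr_batch(model: TCRClassifier, batch: list[EncodedTCR]) -> np.ndarray:
    return model.predict_encoded(batch)


def evaluate_tcr_level(model: TCRClassifier, pool) -> float:
    """Held-out TCR-level ROC AUC of the model's scores."""
    from .stats import auc_mann_whitney

    toks, genes, y = model.encode_pool(pool)
    scores = model.predict_tokens(toks, genes)
    return auc_mann_whitney(scores, y.astype(int))
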