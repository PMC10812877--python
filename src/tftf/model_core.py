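"""The TFTF network: embeddings, Balancer, transformer stack, classifier.

Architecture summary
--------------------
Token streams (DNA 3-mers, one stream per omic signal) are embedded into
dimension 8. The Balancer — two transformer blocks over the *sum* of DNA and
omic embeddings, a CLS pooling, and a 2-neuron head passed through
``Weight(x) = 1 + tanh(x)`` — produces one DNA weight and one omic weight per
input, each in (0, 2). The final input embedding is

    w_dna * E_dna + w_omic * sum(E_omics) + E_pos

followed by four transformer blocks (8 heads of dimension 16, post-norm
residual blocks, ReLU feed-forward) and a small fully connected classifier
emitting two outputs (x1, x2). The Confidence Score is x1 - x2; the default
hard label is positive iff the score exceeds 0.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import stats

from .autodiff import (
    Adam,
    Tensor,
    cross_entropy,
    embedding,
    layer_norm,
    no_grad,
    softmax,
)
from .serialize import savez_deterministic
from .tokenization import SignalBinning, Vocabulary, INPUT_LEN


def balancer_weight_activation(x):
    """Weight(x) = 1 + tanh(x): maps a head pre-activation into (0, 2)."""
    return 1.0 + np.tanh(x)


@dataclass
class ModelConfig:
    k: int = 3
    embed_dim: int = 8
    input_len: int = INPUT_LEN
    n_heads: int = 8
    head_dim: int = 16
    balancer_blocks: int = 2
    transformer_blocks: int = 4
    ffn_hidden: int = 32
    classifier_hidden: int = 16
    n_omics: int = 1
    signal_bins: int = 36
    seed: int = 0
    dtype: str = "float32"
    # whether the position embedding enters the Balancer input (default: it
    # is added only after modality re-scaling)
    balancer_sees_position: bool = False

    def __post_init__(self):
        if min(self.embed_dim, self.n_heads, self.head_dim, self.ffn_hidden) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.input_len < 101:
            raise ValueError("input_len must be >= 101 (CLS + 99 tokens + SEP)")
        if self.n_omics < 0:
            raise ValueError("n_omics must be >= 0")


@dataclass
class Prediction:
    """Classifier outputs and the derived Confidence Score."""

    x1: float
    x2: float
    confidence: float
    label: bool

    @classmethod
    def from_outputs(cls, x1: float, x2: float, threshold: float = 0.0) -> "Prediction":
        conf = x1 - x2
        return cls(float(x1), float(x2), float(conf), bool(conf > threshold))


def _trunc_normal(rng, shape, std=0.02):
    # truncated at 2 sigma, the usual BERT-style initialisation
    return stats.truncnorm.rvs(-2.0, 2.0, scale=std, size=shape, random_state=rng)


class TFTFModel:
    """Multimodal transformer with a Balancer modality-weighting layer."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary | None = None,
                 binning: SignalBinning | None = None):
        self.config = config
        self.vocab = vocab or Vocabulary(k=config.k)
        self.binning = binning or SignalBinning(n_bins=config.signal_bins)
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- parameters ---------------------------------------------------------
    def _add(self, name, array):
        dt = np.dtype(self.config.dtype)
        self.params[name] = Tensor(np.asarray(array, dtype=dt), requires_grad=True)

    def _init_block(self, rng, prefix):
        c = self.config
        d, h = c.embed_dim, c.n_heads * c.head_dim
        for w in ("Wq", "Wk", "Wv"):
            self._add(f"{prefix}/{w}", _trunc_normal(rng, (d, h)))
            self._add(f"{prefix}/b{w[1]}", np.zeros(h))
        self._add(f"{prefix}/Wo", _trunc_normal(rng, (h, d)))
        self._add(f"{prefix}/bo", np.zeros(d))
        self._add(f"{prefix}/ln1_g", np.ones(d))
        self._add(f"{prefix}/ln1_b", np.zeros(d))
        self._add(f"{prefix}/W1", _trunc_normal(rng, (d, c.ffn_hidden)))
        self._add(f"{prefix}/b1", np.zeros(c.ffn_hidden))
        self._add(f"{prefix}/W2", _trunc_normal(rng, (c.ffn_hidden, d)))
        self._add(f"{prefix}/b2", np.zeros(d))
        self._add(f"{prefix}/ln2_g", np.ones(d))
        self._add(f"{prefix}/ln2_b", np.zeros(d))

    def _init_params(self):
        c = self.config
        rng = np.random.default_rng(c.seed)
        self._add("emb/dna", _trunc_normal(rng, (len(self.vocab), c.embed_dim)))
        for j in range(c.n_omics):
            self._add(f"emb/omic{j}", _trunc_normal(rng, (self.binning.vocab_size, c.embed_dim)))
        self._add("emb/pos", _trunc_normal(rng, (c.input_len, c.embed_dim)))
        for b in range(c.balancer_blocks):
            self._init_block(rng, f"bal{b}")
        self._add("bal_head/W", _trunc_normal(rng, (c.embed_dim, 2)))
        self._add("bal_head/b", np.zeros(2))
        for b in range(c.transformer_blocks):
            self._init_block(rng, f"trf{b}")
        self._add("clf/W1", _trunc_normal(rng, (c.embed_dim, c.classifier_hidden)))
        self._add("clf/b1", np.zeros(c.classifier_hidden))
        self._add("clf/W2", _trunc_normal(rng, (c.classifier_hidden, 2)))
        self._add("clf/b2", np.zeros(2))

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def transformer_parameter_count(self) -> int:
        """Trainable parameters in the 4-block transformer layer."""
        return sum(p.data.size for k, p in self.params.items() if k.startswith("trf"))

    # -- forward ------------------------------------------------------------
    def _block(self, x: Tensor, prefix: str, keep: np.ndarray, maps: list | None):
        c = self.config
        p = self.params
        B, L, D = x.shape
        H, dh = c.n_heads, c.head_dim

        def heads(name, scale=None):
            t = x.matmul(p[f"{prefix}/{name}"]) + p[f"{prefix}/b{name[1]}"]
            if scale is not None:
                t = t * scale  # scale q here: cheaper than scaling L x L scores
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)  # (B,H,L,dh)

        q = heads("Wq", 1.0 / math.sqrt(dh))
        k, v = heads("Wk"), heads("Wv")
        scores = q.matmul(k.transpose(0, 1, 3, 2))
        attn = softmax(scores, axis=-1, keep=keep)  # (B,H,L,L), PAD columns 0
        if maps is not None:
            maps.append(attn.data.copy())
        ctx = attn.matmul(v).transpose(0, 2, 1, 3).reshape(B, L, H * dh)
        out = ctx.matmul(p[f"{prefix}/Wo"]) + p[f"{prefix}/bo"]
        # post-norm residual placement, as in the original transformer
        x = layer_norm(x + out, p[f"{prefix}/ln1_g"], p[f"{prefix}/ln1_b"])
        h = (x.matmul(p[f"{prefix}/W1"]) + p[f"{prefix}/b1"]).relu()
        h = h.matmul(p[f"{prefix}/W2"]) + p[f"{prefix}/b2"]
        return layer_norm(x + h, p[f"{prefix}/ln2_g"], p[f"{prefix}/ln2_b"])

    def embed(self, batch: dict):
        """Embedding lookups: DNA, per-omic, and position embeddings."""
        c = self.config
        e_dna = embedding(self.params["emb/dna"], batch["dna"])
        e_omics = [
            embedding(self.params[f"emb/omic{j}"], batch["omics"][j])
            for j in range(c.n_omics)
        ]
        return e_dna, e_omics, self.params["emb/pos"]

    def balancer(self, e_dna: Tensor, e_omic_sum: Tensor | None, keep: np.ndarray,
                 e_pos: Tensor | None = None):
        """Per-input modality weights, each in (0, 2); (1, 0) in DNA-only mode."""
        B = e_dna.shape[0]
        if e_omic_sum is None:  # n_omics == 0: DNA-only architecture
            one = Tensor(np.ones(B, dtype=e_dna.data.dtype))
            zero = Tensor(np.zeros(B, dtype=e_dna.data.dtype))
            return one, zero, np.stack([one.data, zero.data], axis=1)
        x = e_dna + e_omic_sum
        if self.config.balancer_sees_position and e_pos is not None:
            x = x + e_pos
        for b in range(self.config.balancer_blocks):
            x = self._block(x, f"bal{b}", keep, None)
        cls = x.select(0, axis=1)  # (B, D)
        pre = cls.matmul(self.params["bal_head/W"]) + self.params["bal_head/b"]
        w = pre.tanh() + 1.0  # Weight(x) = 1 + tanh(x), range (0, 2)
        return w.select(0, axis=1), w.select(1, axis=1), w.data.copy()

    def forward(self, batch: dict, collect_attention: bool = False,
                balancer_override: tuple | None = None):
        """Run the network.

        Returns (logits Tensor (B,2), balancer weights (B,2) ndarray,
        attention maps: list over transformer blocks of (B,H,L,L) arrays when
        ``collect_attention`` else None).

        ``balancer_override=(w_dna, w_omic)`` freezes the modality weights —
        (1, 0) reproduces DNA-only prediction from a multimodally trained
        model.
        """
        c = self.config
        B = batch["dna"].shape[0]
        # PAD positions are masked out of attention (zero weight post-softmax)
        keep = (~batch["mask"])[:, None, None, :]

        e_dna, e_omics, pos = self.embed(batch)
        e_omic_sum = None
        if e_omics:
            e_omic_sum = e_omics[0]
            for e in e_omics[1:]:
                e_omic_sum = e_omic_sum + e

        if balancer_override is not None:
            wd_v, wo_v = balancer_override
            dt = np.dtype(c.dtype)
            w_dna = Tensor(np.full(B, wd_v, dtype=dt))
            w_omic = Tensor(np.full(B, wo_v, dtype=dt))
            weights = np.stack([w_dna.data, w_omic.data], axis=1)
        else:
            w_dna, w_omic, weights = self.balancer(e_dna, e_omic_sum, keep, pos)

        x = w_dna.reshape(B, 1, 1) * e_dna
        if e_omic_sum is not None:
            x = x + w_omic.reshape(B, 1, 1) * e_omic_sum
        x = x + pos.reshape(1, c.input_len, c.embed_dim)

        maps = [] if collect_attention else None
        for b in range(c.transformer_blocks):
            x = self._block(x, f"trf{b}", keep, maps)

        cls = x.select(0, axis=1)
        h = (cls.matmul(self.params["clf/W1"]) + self.params["clf/b1"]).relu()
        logits = h.matmul(self.params["clf/W2"]) + self.params["clf/b2"]
        return logits, weights, maps

    # -- inference ------------------------------------------------------------
    def predict(self, batch: dict, threshold: float = 0.0,
                balancer_override: tuple | None = None,
                batch_size: int = 256, collect_attention: bool = False):
        """Batched no-grad inference; returns (predictions, weights, maps)."""
        preds, weights_all, maps_all = [], [], []
        n = batch["dna"].shape[0]
        with no_grad():
            for lo in range(0, n, batch_size):
                hi = min(lo + batch_size, n)
                sub = {
                    "dna": batch["dna"][lo:hi],
                    "omics": batch["omics"][:, lo:hi] if self.config.n_omics else batch["omics"],
                    "mask": batch["mask"][lo:hi],
                }
                logits, w, maps = self.forward(
                    sub, collect_attention=collect_attention,
                    balancer_override=balancer_override,
                )
                for x1, x2 in logits.data:
                    preds.append(Prediction.from_outputs(x1, x2, threshold))
                weights_all.append(w)
                if collect_attention:
                    maps_all.append(maps)
        weights = np.concatenate(weights_all) if weights_all else np.zeros((0, 2))
        if collect_attention and maps_all:
            n_blocks = len(maps_all[0])
            maps = [np.concatenate([m[b] for m in maps_all]) for b in range(n_blocks)]
        else:
            maps = None
        return preds, weights, maps

    def confidences(self, batch: dict, **kw) -> np.ndarray:
        preds, _, _ = self.predict(batch, **kw)
        return np.array([p.confidence for p in preds])

    # -- checkpointing ----------------------------------------------------------
    def save(self, path) -> None:
        """One archive: parameter state + config + vocabulary + binning."""
        meta = json.dumps(
            {
                "config": asdict(self.config),
                "vocab": self.vocab.to_json(),
                "binning": self.binning.to_json(),
            }
        )
        arrays = {k.replace("/", "__"): p.data for k, p in self.params.items()}
        savez_deterministic(
            path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays
        )

    @classmethod
    def load(cls, path) -> "TFTFModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(
                ModelConfig(**meta["config"]),
                Vocabulary.from_json(meta["vocab"]),
                SignalBinning.from_json(meta["binning"]),
            )
            for k in model.params:
                model.params[k].data = z[k.replace("/", "__")].copy()
        return model


def loss_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Cross-entropy of (x1, x2) against labels in {1, 2} (1 = positive)."""
    labels = np.asarray(labels)
    if not np.isin(labels, (1, 2)).all():
        raise ValueError("labels must be in {1, 2}")
    return cross_entropy(logits, labels - 1)
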