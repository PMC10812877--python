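"""Tokenization: overlapping DNA k-mers and categorical signal bins.

A 101-bp window becomes 99 stride-1 3-mers; the aligned per-bp signal keeps
its central 99 values and each value is mapped to one of 36 intensity
categories. Both streams are framed as CLS + 99 tokens + SEP and padded to a
fixed model input length of 128.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

PAD, CLS, SEP = "[PAD]", "[CLS]", "[SEP]"
SPECIALS = (PAD, CLS, SEP)

WINDOW = 101  # bp per sample
INPUT_LEN = 128  # model input length (token positions)


@dataclass
class Vocabulary:
    """Dense, stable token-id maps for k-mers plus CLS/SEP/PAD."""

    k: int = 3
    token_to_id: dict = field(default_factory=dict)
    id_to_token: list = field(default_factory=list)

    def __post_init__(self):
        if not self.token_to_id:
            tokens = list(SPECIALS) + [
                "".join(p) for p in itertools.product("ACGT", repeat=self.k)
            ]
            self.id_to_token = tokens
            self.token_to_id = {t: i for i, t in enumerate(tokens)}

    def __len__(self):
        return len(self.id_to_token)

    @property
    def pad_id(self):
        return self.token_to_id[PAD]

    @property
    def cls_id(self):
        return self.token_to_id[CLS]

    @property
    def sep_id(self):
        return self.token_to_id[SEP]

    def encode_kmer(self, kmer: str) -> int:
        """Id of a k-mer; any k-mer with a non-ACGT base maps to the PAD id
        (a neutral lookup) — callers flag windows with many such k-mers."""
        return self.token_to_id.get(kmer, self.pad_id)

    def to_json(self) -> dict:
        return {"k": self.k}

    @classmethod
    def from_json(cls, d: dict) -> "Vocabulary":
        return cls(k=d["k"])


@dataclass
class SignalBinning:
    """Monotone mapping of signal values to ``n_bins`` intensity categories.

    Values are clipped to [0, vmax] and cut by log-spaced internal edges, so
    resolution is fine at low signal and saturating peaks share top bins.
    Category c maps to token id c + 3 (after PAD/CLS/SEP).
    """

    n_bins: int = 36
    vmax: float = 50.0
    vmin_edge: float = 0.1
    edges: np.ndarray = None

    def __post_init__(self):
        if self.edges is None:
            self.edges = np.geomspace(self.vmin_edge, self.vmax, self.n_bins - 1)
        self.edges = np.asarray(self.edges, dtype=np.float64)
        if len(self.edges) != self.n_bins - 1:
            raise ValueError("need n_bins - 1 internal edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def vocab_size(self) -> int:
        return self.n_bins + 3

    def categorize(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64)
        if np.any(values < 0):
            warnings.warn("negative signal values clipped to 0")
            values = np.maximum(values, 0.0)
        values = np.minimum(values, self.vmax)
        # category = number of edges <= value, so the clip at vmax (= last
        # edge) lands saturating values in the top category
        return np.searchsorted(self.edges, values, side="right")

    def to_json(self) -> dict:
        return {"n_bins": self.n_bins, "vmax": self.vmax, "edges": self.edges.tolist()}

    @classmethod
    def from_json(cls, d: dict) -> "SignalBinning":
        return cls(n_bins=d["n_bins"], vmax=d["vmax"], edges=np.asarray(d["edges"]))


@dataclass
class TokenizedInput:
    """Parallel fixed-length token streams for one sample."""

    dna_ids: np.ndarray  # (128,)
    omic_ids: list  # one (128,) array per omic
    pad_mask: np.ndarray  # (128,) bool, True at PAD positions
    ambiguous_frac: float = 0.0  # fraction of k-mers containing non-ACGT bases


def tokenize_dna(seq: str, k: int = 3) -> list:
    """Overlapping stride-1 k-mers of ``seq`` (no special tokens)."""
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    seq = seq.upper()
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def bin_signal(values: np.ndarray, binning: SignalBinning) -> np.ndarray:
    """Map a 101-value window to 99 category tokens (central values only)."""
    values = np.asarray(values)
    if len(values) != WINDOW:
        raise ValueError(f"expected {WINDOW} per-bp values, got {len(values)}")
    return binning.categorize(values[1:-1])


def assemble_input(
    dna_tokens: list,
    omic_token_streams: list,
    vocab: Vocabulary,
    target_len: int = INPUT_LEN,
) -> TokenizedInput:
    """Frame streams as CLS + tokens + SEP, pad to ``target_len``.

    DNA tokens are k-mer strings; omic streams are integer category arrays.
    All streams share the same content length and pad structure.
    """
    n = len(dna_tokens)
    for s in omic_token_streams:
        if len(s) != n:
            raise ValueError("stream length mismatch between DNA and signal tokens")
    if n + 2 > target_len:
        raise ValueError(f"{n} tokens do not fit input length {target_len}")

    dna_ids = np.full(target_len, vocab.pad_id, dtype=np.int64)
    dna_ids[0] = vocab.cls_id
    kmer_ids = [vocab.encode_kmer(t) for t in dna_tokens]
    ambiguous = sum(t not in vocab.token_to_id for t in dna_tokens)
    dna_ids[1 : n + 1] = kmer_ids
    dna_ids[n + 1] = vocab.sep_id

    omic_ids = []
    for s in omic_token_streams:
        # signal vocabulary shares the special-token layout: PAD 0, CLS 1, SEP 2
        ids = np.zeros(target_len, dtype=np.int64)
        ids[0] = 1
        ids[1 : n + 1] = np.asarray(s, dtype=np.int64) + 3
        ids[n + 1] = 2
        omic_ids.append(ids)

    pad_mask = np.zeros(target_len, dtype=bool)
    pad_mask[n + 2 :] = True
    return TokenizedInput(dna_ids, omic_ids, pad_mask, ambiguous / max(n, 1))


def encode_window(
    seq: str,
    signals: list,
    vocab: Vocabulary,
    binning: SignalBinning,
    target_len: int = INPUT_LEN,
) -> TokenizedInput:
    """Full pipeline for one 101-bp window and its aligned signal vectors."""
    return assemble_input(
        tokenize_dna(seq, vocab.k),
        [bin_signal(v, binning) for v in signals],
        vocab,
        target_len,
    )


def encode_batch(
    seqs: list,
    signal_lists: list,
    vocab: Vocabulary,
    binning: SignalBinning,
    target_len: int = INPUT_LEN,
) -> dict:
    """Vectorized batch: returns dna (B,L), omics (n_omics,B,L), mask (B,L),
    ambiguous_frac (B,)."""
    toks = [
        encode_window(s, sig, vocab, binning, target_len)
        for s, sig in zip(seqs, signal_lists)
    ]
    n_omics = len(toks[0].omic_ids) if toks else 0
    return {
        "dna": np.stack([t.dna_ids for t in toks]) if toks else np.zeros((0, target_len), int),
        "omics": np.stack(
            [np.stack([t.omic_ids[j] for t in toks]) for j in range(n_omics)]
        )
        if n_omics
        else np.zeros((0, len(toks), target_len), int),
        "mask": np.stack([t.pad_mask for t in toks]) if toks else np.zeros((0, target_len), bool),
        "ambiguous_frac": np.array([t.ambiguous_frac for t in toks]),
    }
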