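"""Attention-based interpretation: per-token attention scores and the
in-motif vs out-of-motif attention fold change (ASFC).

The attention score of token j in one head is the column-j sum of the
row-softmaxed attention matrix — the total attention mass all L query
positions place on j — so the scores of a head always sum to L. The ASFC of
a sample is the mean over heads of (summed score inside the motif region) /
(summed score outside it); special tokens (CLS/SEP/PAD) are excluded from
both sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_CONTENT_TOKENS = 99  # k-mer tokens of a 101-bp window


@dataclass
class AttentionProfile:
    """Per-head, per-token attention scores for one sample."""

    scores: np.ndarray  # (n_heads, L)

    @property
    def n_heads(self):
        return self.scores.shape[0]

    @property
    def input_len(self):
        return self.scores.shape[1]


def attention_scores(maps, block: int = -1) -> AttentionProfile:
    """Column sums of the row-stochastic attention matrix, per head.

    ``maps`` is the list of per-block attention arrays returned by the
    forward pass; each block holds an (n_heads, L, L) matrix for a single
    sample (or (1, n_heads, L, L), which is squeezed). The default block is
    the last transformer block.
    """
    if not -len(maps) <= block < len(maps):
        raise IndexError(f"block {block} out of range for {len(maps)} blocks")
    m = np.asarray(maps[block])
    if m.ndim == 4:
        if m.shape[0] != 1:
            raise ValueError("attention_scores expects a single sample")
        m = m[0]
    return AttentionProfile(m.sum(axis=-2))  # sum over query rows


def content_positions(n_tokens: int = N_CONTENT_TOKENS) -> np.ndarray:
    """Stream positions of the k-mer tokens (CLS is 0, SEP is n_tokens+1)."""
    return np.arange(1, n_tokens + 1)


def motif_token_positions(
    window_start: int, motif_start: int, motif_len: int, k: int = 3
) -> np.ndarray:
    """Stream positions of k-mers overlapping a motif occurrence.

    Coordinates are genomic; the k-mer at window offset i covers bases
    [i, i+k) and sits at stream position i+1 (after CLS).
    """
    off = motif_start - window_start
    lo = max(0, off - k + 1)
    hi = min(N_CONTENT_TOKENS - 1, off + motif_len - 1)
    if hi < lo:
        return np.array([], dtype=int)
    return np.arange(lo, hi + 1) + 1


def asfc(
    profile: AttentionProfile,
    motif_positions,
    valid_positions=None,
    normalized: bool = False,
) -> float:
    """Attention-score fold change between motif and non-motif tokens.

    Literal form: mean over heads of sum_in / sum_out. The ``normalized``
    variant uses mean_in / mean_out instead, which is invariant to the size
    of the motif region under uniform attention.
    """
    if valid_positions is None:
        valid_positions = content_positions()
    valid = np.asarray(sorted(set(int(p) for p in valid_positions)))
    m = np.asarray(sorted(set(int(p) for p in motif_positions)))
    m = m[np.isin(m, valid)]
    if m.size == 0:
        raise ValueError("motif region is empty within the valid positions")
    out = valid[~np.isin(valid, m)]
    if out.size == 0:
        raise ValueError("motif region covers all valid positions; ASFC undefined")
    ratios = []
    for h in range(profile.n_heads):
        s_in = profile.scores[h, m].sum()
        s_out = profile.scores[h, out].sum()
        if normalized:
            s_in /= m.size
            s_out /= out.size
        ratios.append(s_in / s_out)
    return float(np.mean(ratios))


def profiles_to_frame(profiles: list, sample_ids=None):
    """Long-format DataFrame (sample, head, position, score) for CSV export."""
    import pandas as pd

    rows = []
    for si, prof in enumerate(profiles):
        sid = sample_ids[si] if sample_ids is not None else si
        for h in range(prof.n_heads):
            for j in range(prof.input_len):
                rows.append((sid, h, j, float(prof.scores[h, j])))
    return pd.DataFrame(rows, columns=["sample", "head", "position", "score"])
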