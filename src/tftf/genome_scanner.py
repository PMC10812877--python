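"""Genome-wide TFBS detection by sliding-window classification.

A chromosome is tiled with 101-bp windows every 30 bp; every window is
tokenized and classified, and detections are accounted at the peak level:
all windows overlapping the same truth peak count as ONE positive unit (a
true positive is credited once, no matter how many of its windows fire),
while each window outside all peaks is its own negative unit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval
from .tokenization import encode_batch


@dataclass
class ScanConfig:
    window: int = 101
    stride: int = 30
    threshold: float = 0.0
    chroms: list | None = None
    max_ambiguous: float = 0.1  # skip windows with more ambiguous k-mers
    batch_size: int = 256

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def tile(chrom_length: int, config: ScanConfig) -> list:
    """Window start positions 0, stride, 2*stride, ...

    Count = floor((chrom_length - window) / stride) + 1; empty (with a
    warning) when the chromosome is shorter than one window.
    """
    if chrom_length < config.window:
        warnings.warn(f"chromosome length {chrom_length} < window {config.window}")
        return []
    n = (chrom_length - config.window) // config.stride + 1
    return [i * config.stride for i in range(n)]


@dataclass
class ScanResult:
    windows: list  # GenomicInterval per scored window
    confidences: np.ndarray
    truth_peaks: list  # Peak
    window_peaks: list  # per window: tuple of overlapped truth-peak indices
    n_skipped: int = 0

    @property
    def n_peaks(self) -> int:
        return len(self.truth_peaks)

    def counts(self, threshold: float) -> dict:
        """Peak-level TP/FN, window-level FP/TN at a Confidence cut-off."""
        called = self.confidences > threshold
        hit = np.zeros(self.n_peaks, dtype=bool)
        fp = tn = 0
        for i, peaks in enumerate(self.window_peaks):
            if peaks:
                if called[i]:
                    for pi in peaks:  # a window spanning 2 peaks credits both
                        hit[pi] = True
            else:
                if called[i]:
                    fp += 1
                else:
                    tn += 1
        tp = int(hit.sum())
        return {
            "tp": tp,
            "fn": self.n_peaks - tp,
            "fp": fp,
            "tn": tn,
            "recall": tp / self.n_peaks if self.n_peaks else 0.0,
            "precision": tp / (tp + fp) if tp + fp else 0.0,
        }

    def unit_scores(self):
        """(scores, labels) over scan units for threshold sweeps.

        Positive units are truth peaks, scored by the max confidence of
        their overlapping windows (peaks with no scored window get the
        global minimum minus 1, i.e. never called); negative units are the
        windows outside all peaks with their own confidences.
        """
        floor = (self.confidences.min() if len(self.confidences) else 0.0) - 1.0
        pos = np.full(self.n_peaks, floor)
        neg = []
        for i, peaks in enumerate(self.window_peaks):
            if peaks:
                for pi in peaks:
                    pos[pi] = max(pos[pi], self.confidences[i])
            else:
                neg.append(self.confidences[i])
        scores = np.concatenate([pos, np.asarray(neg)])
        labels = np.concatenate([np.ones(self.n_peaks, bool), np.zeros(len(neg), bool)])
        return scores, labels


def _overlap_index(windows: list, peaks: list) -> list:
    """Per window, the indices of truth peaks it overlaps (>= 1 bp)."""
    by_chrom: dict = {}
    for pi, p in enumerate(peaks):
        by_chrom.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end, pi))
    for lst in by_chrom.values():
        lst.sort()
    out = []
    for w in windows:
        hits = []
        for s, e, pi in by_chrom.get(w.chrom, ()):
            if s >= w.end:
                break
            if e > w.start:
                hits.append(pi)
        out.append(tuple(hits))
    return out


def scan(model, genome: dict, tracks: dict, truth_peaks: list, config: ScanConfig) -> ScanResult:
    """Tile, tokenize and classify every window of the selected chromosomes.

    ``tracks`` maps omic name -> track with .query(chrom, start, end) or a
    SignalTrack. Windows with too many ambiguous bases are skipped and
    counted. Window order is deterministic, so FP lists are reproducible.
    """
    omics = sorted(tracks)
    chroms = config.chroms or sorted(genome)
    windows, seqs, sigs = [], [], []
    for chrom in chroms:
        for start in tile(len(genome[chrom]), config):
            iv = GenomicInterval(chrom, start, start + config.window)
            windows.append(iv)
            seqs.append(genome[chrom][iv.start : iv.end])
            sigs.append([_query(tracks[o], chrom, iv.start, iv.end) for o in omics])

    data = encode_batch(seqs, sigs, model.vocab, model.binning)
    keep = data["ambiguous_frac"] <= config.max_ambiguous
    n_skipped = int((~keep).sum())
    if n_skipped:
        idx = np.flatnonzero(keep)
        windows = [windows[i] for i in idx]
        data = {
            "dna": data["dna"][idx],
            "omics": data["omics"][:, idx] if data["omics"].size else data["omics"],
            "mask": data["mask"][idx],
        }
    conf = model.confidences(data, batch_size=config.batch_size)
    return ScanResult(
        windows, conf, truth_peaks, _overlap_index(windows, truth_peaks), n_skipped
    )


def _query(track, chrom, start, end):
    from .genomic_io import SignalTrack

    if isinstance(track, SignalTrack):
        if track.chrom != chrom:
            return np.zeros(end - start, dtype=np.float32)
        return track.query(start, end)
    return track.query(chrom, start, end)


def threshold_table(result: ScanResult, thresholds=None) -> pd.DataFrame:
    """(threshold, recall, precision, TP, FP) rows; cut-offs 0, 5 and 10 are
    always included."""
    thr = sorted(set([0.0, 5.0, 10.0] + [float(t) for t in (thresholds or [])]))
    rows = []
    for t in thr:
        c = result.counts(t)
        rows.append(
            {"threshold": t, "recall": c["recall"], "precision": c["precision"],
             "tp": c["tp"], "fp": c["fp"]}
        )
    return pd.DataFrame(rows)


def write_scan_outputs(result: ScanResult, outdir, threshold: float = 0.0) -> None:
    """BED6 of positive windows plus a JSON summary."""
    from pathlib import Path

    from .genomic_io import write_predictions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    called = result.confidences > threshold
    records = [
        (w, float(c), True)
        for w, c, ok in zip(result.windows, result.confidences, called)
        if ok
    ]
    write_predictions(outdir / "hits.bed", records)
    summary = {"threshold": threshold, "n_windows": len(result.windows),
               "n_skipped": result.n_skipped, **result.counts(threshold)}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
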