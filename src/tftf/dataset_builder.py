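"""Construction of labeled training cohorts from peaks, genome and tracks.

Positives are the 101-bp windows flanking peak centers, one sample per
(window, cell). Negatives are sampled uniformly from the genome outside all
marked peak regions and at least a margin (default 2 kb) away from every
marked-region boundary; each negative borrows the signal of one randomly
chosen training cell. ANSR (Additional Negative Sampling Regions) are
training-cell binding sites that are *not* bound in the test cell — the hard
negatives that measure cell-type specificity. Augmentation shifts each
positive window start by ±1..7 bp (15 windows per peak in total).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genomic_io import GenomicInterval, Peak, write_fasta, write_peaks, write_bedgraph
from .tokenization import WINDOW

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass
class Sample:
    """One 101-bp window with aligned per-omic signal and a label."""

    interval: GenomicInterval
    seq: str
    signals: list  # one length-101 array per omic
    label: str  # positive / negative
    cohort: str  # train_pos / train_neg / ansr / test_pos / test_neg
    cell_id: str = ""
    enrichment: float = 0.0

    def __post_init__(self):
        if len(self.seq) != self.interval.length:
            raise ValueError("sequence length does not match interval")
        for v in self.signals:
            if len(v) != self.interval.length:
                raise ValueError("signal vector length does not match interval")


@dataclass
class CohortSpec:
    train_cells: list
    test_cell: str
    validation_cell: str | None = None
    margin: int = 2000
    neg_ratio: int = 1
    augment: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.neg_ratio < 1:
            raise ValueError("negatives-per-positive ratio must be >= 1")


def window_around(peak: Peak) -> GenomicInterval:
    """The 101-bp window flanking the peak center: floor((a+b)/2) - 50."""
    c = (peak.interval.start + peak.interval.end) // 2
    return GenomicInterval(peak.interval.chrom, c - 50, c - 50 + WINDOW)


def positive_windows(peaks: list, chrom_sizes: dict) -> list:
    """Per-(window, cell) positive intervals.

    Identical windows from different cells each yield one cell-tagged entry
    (they later receive that cell's own signal); duplicates within a cell are
    unioned. Windows falling off a chromosome edge are skipped with a warning.
    Returns (interval, cell_id, enrichment) tuples.
    """
    if not peaks:
        raise ValueError("no peaks given")
    out, seen = [], set()
    skipped = 0
    for p in peaks:
        c = (p.interval.start + p.interval.end) // 2
        start = c - 50
        size = chrom_sizes[p.interval.chrom]
        if start < 0 or start + WINDOW > size:
            skipped += 1
            continue
        iv = GenomicInterval(p.interval.chrom, start, start + WINDOW)
        key = (iv, p.cell_id)
        if key in seen:
            continue
        seen.add(key)
        out.append((iv, p.cell_id, p.enrichment))
    if skipped:
        warnings.warn(f"{skipped} peak window(s) off chromosome edge; skipped")
    return out


def _eligible_intervals(chrom_sizes: dict, marked: list, margin: int, length: int):
    """Per-chromosome intervals of legal negative-window starts."""
    out = {}
    for chrom, size in chrom_sizes.items():
        blocks = sorted(
            (max(0, iv.start - margin), iv.end + margin)
            for iv in marked
            if iv.chrom == chrom
        )
        merged = []
        for s, e in blocks:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        free, pos = [], 0
        for s, e in merged:
            if s > pos:
                free.append((pos, s))
            pos = max(pos, e)
        if pos < size:
            free.append((pos, size))
        # a start is legal if the whole window stays inside the free stretch
        starts = [(s, e - length + 1) for s, e in free if e - s >= length]
        if starts:
            out[chrom] = starts
    return out


def sample_negatives(
    chrom_sizes: dict,
    marked: list,
    n: int,
    margin: int = 2000,
    length: int = WINDOW,
    seed: int | np.random.Generator = 0,
) -> list:
    """Uniform draw of ``n`` distinct window starts from the eligible space.

    The eligible space is computed exactly by interval subtraction (marked
    regions inflated by ``margin`` on both sides), so the draw is uniform over
    all legal starts and the call terminates even in dense genomes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return []
    elig = _eligible_intervals(chrom_sizes, marked, margin, length)
    chroms = sorted(elig)
    sizes = np.array(
        [sum(e - s for s, e in elig[c]) for c in chroms], dtype=np.int64
    )
    total = int(sizes.sum())
    if total < n:
        raise ValueError(
            f"only {total} eligible negative start position(s) exist; {n} requested"
        )
    offsets = rng.choice(total, size=n, replace=False)
    offsets.sort()
    cum = np.concatenate([[0], np.cumsum(sizes)])
    out = []
    for off in offsets:
        ci = int(np.searchsorted(cum, off, side="right") - 1)
        rem = int(off - cum[ci])
        for s, e in elig[chroms[ci]]:
            if rem < e - s:
                out.append(GenomicInterval(chroms[ci], s + rem, s + rem + length))
                break
            rem -= e - s
    return out


def build_ansr(train_cells_peaks: list, test_cell_peaks: list, chrom_sizes: dict) -> list:
    """Windows of training-cell peaks that do not overlap any test-cell peak.

    These regions are binding sites elsewhere but not in the test cell, so
    they are labeled negative (cohort 'ansr'). Returns unique intervals.
    """
    test_ivs = [p.interval for p in test_cell_peaks]
    out, seen = [], set()
    for iv, _cell, _enr in positive_windows(train_cells_peaks, chrom_sizes):
        if iv in seen:
            continue
        seen.add(iv)
        if not any(iv.overlaps(t) for t in test_ivs):
            out.append(iv)
    if not out:
        warnings.warn("ANSR cohort is empty (all training-cell sites bound in test cell)")
    return out


def augment(peak: Peak, chrom_size: int | None = None) -> list:
    """The original window plus 14 windows shifted by ±1..7 bp (15 total).

    Shifts that would leave the chromosome are dropped with a warning.
    """
    c = (peak.interval.start + peak.interval.end) // 2
    starts = [c - 50] + [c - 50 + d * i for i in range(1, 8) for d in (1, -1)]
    out, dropped = [], 0
    for s in starts:
        if s < 0 or (chrom_size is not None and s + WINDOW > chrom_size):
            dropped += 1
            continue
        out.append(GenomicInterval(peak.interval.chrom, s, s + WINDOW))
    if dropped:
        warnings.warn(f"{dropped} augmented window(s) off chromosome edge; dropped")
    return out


# ---------------------------------------------------------------------------
# cohort assembly against an in-memory world (genome dict + per-cell tracks)


@dataclass
class Cohort:
    """Labeled samples for one cross-cell experiment."""

    train: list  # positives + negatives of the training cells
    test_pos: list
    test_neg: list
    ansr: list
    spec: CohortSpec
    manifest: dict = field(default_factory=dict)

    def all_samples(self):
        return self.train + self.test_pos + self.test_neg + self.ansr


def _extract(genome: dict, tracks: dict, cell: str, iv: GenomicInterval, omics: list):
    seq = genome[iv.chrom][iv.start : iv.end]
    sig = [tracks[cell][o].query(iv.start, iv.end) for o in omics]
    return seq, sig


def build_cohort(
    genome: dict,
    peaks_by_cell: dict,
    tracks: dict,
    spec: CohortSpec,
    omics: list | None = None,
) -> Cohort:
    """Assemble a cross-cell cohort.

    ``genome``: {chrom: sequence}; ``peaks_by_cell``: {cell: [Peak]};
    ``tracks``: {cell: {omic_name: SignalTrack-like with .query}}.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    if omics is None:
        omics = sorted(next(iter(tracks.values())))

    train_peaks = [p for c in spec.train_cells for p in peaks_by_cell[c]]
    test_peaks = peaks_by_cell[spec.test_cell]

    # positives: one sample per (window, cell); optional +-7 bp augmentation
    train = []
    for iv, cell, enr in positive_windows(train_peaks, chrom_sizes):
        ivs = [iv]
        if spec.augment:
            ivs = augment(
                Peak(GenomicInterval(iv.chrom, iv.start, iv.end), enr, cell),
                chrom_sizes[iv.chrom],
            )
        for w in ivs:
            seq, sig = _extract(genome, tracks, cell, w, omics)
            train.append(Sample(w, seq, sig, POSITIVE, "train_pos", cell, enr))
    n_pos = len(train)

    # marked regions: union of ALL cohort cells' peaks (train + test)
    marked = [p.interval for cell in (list(spec.train_cells) + [spec.test_cell])
              for p in peaks_by_cell[cell]]

    n_neg = spec.neg_ratio * n_pos
    for iv in sample_negatives(chrom_sizes, marked, n_neg, spec.margin, seed=rng):
        cell = spec.train_cells[rng.integers(len(spec.train_cells))]
        seq, sig = _extract(genome, tracks, cell, iv, omics)
        train.append(Sample(iv, seq, sig, NEGATIVE, "train_neg", cell))

    # held-out test cell: positives + matched negatives + ANSR
    test_pos = []
    for iv, cell, enr in positive_windows(test_peaks, chrom_sizes):
        seq, sig = _extract(genome, tracks, spec.test_cell, iv, omics)
        test_pos.append(Sample(iv, seq, sig, POSITIVE, "test_pos", cell, enr))
    test_neg = []
    for iv in sample_negatives(chrom_sizes, marked, len(test_pos), spec.margin, seed=rng):
        seq, sig = _extract(genome, tracks, spec.test_cell, iv, omics)
        test_neg.append(Sample(iv, seq, sig, NEGATIVE, "test_neg", spec.test_cell))
    ansr = []
    for iv in build_ansr(train_peaks, test_peaks, chrom_sizes):
        seq, sig = _extract(genome, tracks, spec.test_cell, iv, omics)
        ansr.append(Sample(iv, seq, sig, NEGATIVE, "ansr", spec.test_cell))

    manifest = {
        "train_cells": list(spec.train_cells),
        "test_cell": spec.test_cell,
        "seed": spec.seed,
        "margin": spec.margin,
        "neg_ratio": spec.neg_ratio,
        "augment": spec.augment,
        "omics": omics,
        "counts": {
            "train_pos": n_pos,
            "train_neg": len(train) - n_pos,
            "test_pos": len(test_pos),
            "test_neg": len(test_neg),
            "ansr": len(ansr),
        },
    }
    return Cohort(train, test_pos, test_neg, ansr, spec, manifest)


def export_audit(cohort: Cohort, outdir) -> None:
    """Write BED + FASTA + per-omic bedGraph-style dumps of all samples."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = cohort.all_samples()
    with open(outdir / "samples.bed", "w") as fh:
        for s in samples:
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                f"\t{s.cohort}:{s.cell_id or '.'}\t{s.enrichment:g}\t.\n"
            )
    write_fasta(
        outdir / "samples.fa",
        {
            f"{s.cohort}|{s.cell_id or '.'}|{s.interval.chrom}:{s.interval.start}-{s.interval.end}": s.seq
            for s in samples
        },
    )
    omics = cohort.manifest.get("omics", [])
    for j, omic in enumerate(omics):
        with open(outdir / f"samples.{omic}.bedgraph", "w") as fh:
            for s in samples:
                for i, v in enumerate(s.signals[j]):
                    fh.write(
                        f"{s.interval.chrom}\t{s.interval.start + i}"
                        f"\t{s.interval.start + i + 1}\t{v:g}\n"
                    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
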