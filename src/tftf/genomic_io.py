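"""Readers/writers for the standard genomic formats the tool touches.

All internal coordinates are 0-based half-open (BED convention). Strand is
ignored throughout: the model operates on fixed windows around peak centers
and the forward-strand sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO


class FormatError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise FormatError(f"negative start: {self}")
        if self.end <= self.start:
            raise FormatError(f"empty or inverted interval: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> int:
        """Gap between intervals (0 if they overlap or touch)."""
        if self.chrom != other.chrom:
            raise ValueError("distance across chromosomes is undefined")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class Peak:
    """A called binding-site interval with an optional enrichment score."""

    interval: GenomicInterval
    enrichment: float = 0.0
    cell_id: str = ""

    def __post_init__(self):
        if self.enrichment < 0:
            raise FormatError(f"negative enrichment: {self.enrichment}")


@dataclass
class SignalTrack:
    """Per-bp signal values (−log10 P scale) over one covered range.

    Queries outside the covered range return 0.
    """

    chrom: str
    values: np.ndarray
    start: int = 0

    def query(self, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=np.float32)
        lo = max(start, self.start)
        hi = min(end, self.start + len(self.values))
        if hi > lo:
            out[lo - start : hi - start] = self.values[lo - self.start : hi - self.start]
        return out


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict:
    """Read a FASTA file into {name: uppercase sequence}.

    Non-ACGT letters are preserved (masking is handled downstream at
    tokenization time).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r} in {path}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(path, sequences: dict, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# BED / narrowPeak


def read_peaks(path, cell_id: str = "", score_col: int | None = None) -> list:
    """Read BED/narrowPeak intervals into Peaks.

    ``score_col`` selects the 0-based column used as enrichment. By default
    narrowPeak files (>= 7 columns) use column 6 (signalValue) and plain BED
    with >= 5 columns uses column 4 (score); 3-column BED gets enrichment 0.
    """
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start")
            col = score_col
            if col is None:
                col = 6 if len(cols) >= 7 else (4 if len(cols) >= 5 else None)
            enrichment = float(cols[col]) if col is not None and col < len(cols) else 0.0
            peaks.append(Peak(GenomicInterval(chrom, start, end), enrichment, cell_id))
    return peaks


def write_peaks(path, peaks: list) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start)):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.cell_id or '.'}"
                f"\t{float(p.enrichment)!r}\t.\n"
            )


# --------------------------------------------------------------------------
# bedGraph (canonical per-bp signal format here) and optional bigWig


class BedGraphTrack:
    """A loaded bedGraph file, queryable per chromosome.

    Gaps are filled with 0; a query on an absent chromosome warns and
    returns zeros.
    """

    def __init__(self, path):
        self._chroms = {}
        starts, ends, vals, cur = [], [], [], None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                c, s, e, v = line.split("\t")[:4]
                if c != cur:
                    if cur is not None:
                        self._store(cur, starts, ends, vals)
                    starts, ends, vals, cur = [], [], [], c
                starts.append(int(s))
                ends.append(int(e))
                vals.append(float(v))
        if cur is not None:
            self._store(cur, starts, ends, vals)

    def _store(self, chrom, starts, ends, vals):
        order = np.argsort(np.asarray(starts))
        prev = self._chroms.get(chrom)
        s = np.asarray(starts, dtype=np.int64)[order]
        e = np.asarray(ends, dtype=np.int64)[order]
        v = np.asarray(vals, dtype=np.float32)[order]
        if prev is not None:  # chromosome split across the file
            s = np.concatenate([prev[0], s])
            e = np.concatenate([prev[1], e])
            v = np.concatenate([prev[2], v])
            order = np.argsort(s)
            s, e, v = s[order], e[order], v[order]
        self._chroms[chrom] = (s, e, v)

    def chroms(self):
        return list(self._chroms)

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=np.float32)
        if chrom not in self._chroms:
            warnings.warn(f"chromosome {chrom!r} absent from signal track; returning zeros")
            return out
        s, e, v = self._chroms[chrom]
        i = np.searchsorted(e, start, side="right")
        while i < len(s) and s[i] < end:
            lo, hi = max(s[i], start), min(e[i], end)
            if hi > lo:
                out[lo - start : hi - start] = v[i]
            i += 1
        return out


_TRACK_CACHE: dict = {}


def open_signal(path):
    """Open a signal file (bedGraph, or bigWig when pyBigWig is available)."""
    path = str(path)
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        try:
            import pyBigWig  # optional
        except ImportError as exc:  # pragma: no cover
            raise ImportError("bigWig input requires pyBigWig") from exc
        return _BigWigTrack(pyBigWig.open(path))
    return BedGraphTrack(path)


class _BigWigTrack:  # pragma: no cover - exercised only when pyBigWig present
    def __init__(self, bw):
        self._bw = bw

    def query(self, chrom, start, end):
        if chrom not in self._bw.chroms():
            warnings.warn(f"chromosome {chrom!r} absent from bigWig; returning zeros")
            return np.zeros(end - start, dtype=np.float32)
        vals = np.asarray(self._bw.values(chrom, start, end), dtype=np.float32)
        return np.nan_to_num(vals, nan=0.0)


def read_signal(path, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-bp values over [start, end); gaps and absent chromosomes are 0."""
    key = str(path)
    if key not in _TRACK_CACHE:
        _TRACK_CACHE[key] = open_signal(path)
    return _TRACK_CACHE[key].query(chrom, start, end)


def write_bedgraph(path, chrom: str, values: np.ndarray, start: int = 0) -> None:
    """Write per-bp values, run-length collapsing equal neighbours.

    Values are written with shortest round-tripping decimals so a float32
    track survives a write/read cycle bit-exactly.
    """
    values = np.asarray(values, dtype=np.float32)
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        breaks = np.flatnonzero(values[1:] != values[:-1]) + 1
        edges = np.concatenate([[0], breaks, [len(values)]])
        for lo, hi in zip(edges[:-1], edges[1:]):
            v = np.format_float_positional(values[lo], unique=True, trim="0")
            fh.write(f"{chrom}\t{start + lo}\t{start + hi}\t{v}\n")


# --------------------------------------------------------------------------
# prediction output


def write_predictions(path, records: list) -> None:
    """Write (interval, confidence, label) records as BED6.

    Score column is the Confidence Score; the name column carries the hard
    label. Input is sorted by (chrom, start) on write.
    """
    records = sorted(records, key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    with open(path, "w") as fh:
        for iv, conf, label in records:
            name = "pos" if label else "neg"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{conf!r}\t.\n")


def read_predictions(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            c, s, e, name, score, _ = line.split("\t")
            out.append((GenomicInterval(c, int(s), int(e)), float(score), name == "pos"))
    return out
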