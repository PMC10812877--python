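"""Self-contained synthetic multi-cell-type worlds for end-to-end testing.

A world is one random chromosome shared by several "cell types". A fixed
motif is planted at every candidate site; each cell type binds each site
independently with a configurable probability (cell-type specificity), and
decoy motif occurrences are never bound in any cell. Each cell's signal
track is i.i.d. exponential background noise plus a Gaussian bump (lognormal
height) centered on each of *its* bound sites — unbound-in-this-cell sites
get background only. By construction a decoy's DNA context is
indistinguishable from a true site's, so sequence alone cannot resolve
cell-type-specific binding, while the signal can.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genomic_io import GenomicInterval, Peak, SignalTrack, write_fasta, write_peaks, write_bedgraph

# a fixed 19-mer standing in for the CTCF core motif
DEFAULT_MOTIF = "TGGCCACCAGGGGGCGCTA"


@dataclass
class WorldConfig:
    genome_length: int = 4_000_000
    gc: float = 0.41
    motif: str = DEFAULT_MOTIF
    n_cell_types: int = 4
    n_sites: int = 400
    p_bind: float = 0.6
    n_decoys: int = 200
    peak_halfwidth: int = 100  # truth peaks span center +- halfwidth
    min_gap: int = 500  # minimum distance between element centers
    bump_sigma: float = 60.0  # bp width of the signal bump
    bump_log_mu: float = 2.0  # lognormal log-mean of bump heights
    bump_log_sigma: float = 0.5
    noise_scale: float = 1.0  # exponential background noise scale
    omics: tuple = ("h3k4me3",)
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_bind <= 1):
            raise ValueError("p_bind must be in (0, 1]")
        if self.n_cell_types < 1 or self.n_sites < 1:
            raise ValueError("need at least one cell type and one site")


@dataclass
class World:
    config: WorldConfig
    genome: dict  # {chrom: sequence}
    cells: list  # cell-type names
    site_centers: np.ndarray
    decoy_centers: np.ndarray
    bound: np.ndarray  # (n_cells, n_sites) bool
    peaks_by_cell: dict  # {cell: [Peak]}
    tracks: dict  # {cell: {omic: SignalTrack}}
    bump_heights: np.ndarray  # (n_cells, n_sites) 0 where unbound

    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, outdir) -> None:
        """FASTA + per-cell BED + per-cell/omic bedGraph + truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", self.genome)
        for cell in self.cells:
            write_peaks(outdir / f"{cell}.peaks.bed", self.peaks_by_cell[cell])
            for omic in self.config.omics:
                tr = self.tracks[cell][omic]
                write_bedgraph(outdir / f"{cell}.{omic}.bedgraph", tr.chrom, tr.values)
        truth = {
            "config": {**asdict(self.config), "omics": list(self.config.omics)},
            "cells": self.cells,
            "site_centers": self.site_centers.tolist(),
            "decoy_centers": self.decoy_centers.tolist(),
            "bound": self.bound.astype(int).tolist(),
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


def _random_genome(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _place_elements(rng, config: WorldConfig) -> np.ndarray:
    """Non-overlapping element centers, min_gap apart, clear of the edges."""
    n = config.n_sites + config.n_decoys
    edge = config.peak_halfwidth + len(config.motif) + 2100  # room for margins
    lo, hi = edge, config.genome_length - edge
    if hi <= lo:
        raise ValueError("genome too short for any site")
    for attempt in range(20):
        cand = np.sort(rng.integers(lo, hi, size=max(4 * n, 64)))
        kept = [cand[0]]
        for c in cand[1:]:
            if c - kept[-1] >= config.min_gap:
                kept.append(c)
        if len(kept) >= n:
            kept = np.asarray(kept[:n])
            return kept[rng.permutation(n)]
    raise ValueError(
        f"could not place {n} elements with min gap {config.min_gap} "
        f"in a {config.genome_length} bp genome"
    )


def generate(config: WorldConfig) -> World:
    """Build a world deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    seq = list(_random_genome(rng, config.genome_length, config.gc))

    centers = _place_elements(rng, config)
    site_centers = np.sort(centers[: config.n_sites])
    decoy_centers = np.sort(centers[config.n_sites :])

    motif = config.motif.upper()
    half = len(motif) // 2
    for c in np.concatenate([site_centers, decoy_centers]):
        seq[c - half : c - half + len(motif)] = motif
    genome = {config.chrom: "".join(seq)}

    cells = [f"cell{i}" for i in range(config.n_cell_types)]
    bound = rng.random((config.n_cell_types, config.n_sites)) < config.p_bind
    heights = np.where(
        bound,
        rng.lognormal(config.bump_log_mu, config.bump_log_sigma, bound.shape),
        0.0,
    )

    peaks_by_cell, tracks = {}, {}
    hw = config.peak_halfwidth
    span = int(4 * config.bump_sigma)
    xs = np.arange(-span, span + 1)
    bump_shape = np.exp(-(xs**2) / (2 * config.bump_sigma**2))
    for ci, cell in enumerate(cells):
        peaks = [
            Peak(GenomicInterval(config.chrom, c - hw, c + hw + 1), heights[ci, si], cell)
            for si, c in enumerate(site_centers)
            if bound[ci, si]
        ]
        peaks_by_cell[cell] = peaks
        tracks[cell] = {}
        for omic in config.omics:
            vals = rng.exponential(config.noise_scale, config.genome_length).astype(
                np.float32
            )
            for si, c in enumerate(site_centers):
                if bound[ci, si]:
                    lo, hi = c - span, c + span + 1
                    vals[lo:hi] += (heights[ci, si] * bump_shape).astype(np.float32)
            tracks[cell][omic] = SignalTrack(config.chrom, vals)

    return World(
        config, genome, cells, site_centers, decoy_centers, bound,
        peaks_by_cell, tracks, heights,
    )


def ansr_difficulty(world: World) -> int:
    """Number of sites bound in >= 1 cell but not in all cells.

    These cross-cell-inconsistent sites are the population ANSR samples are
    drawn from; with one cell type the count is 0 by definition.
    """
    if world.bound.shape[0] < 2:
        return 0
    per_site = world.bound.sum(axis=0)
    return int(((per_site >= 1) & (per_site < world.bound.shape[0])).sum())


def load_world_files(indir):
    """Read back a written world as (genome, peaks_by_cell, tracks, truth).

    Tracks are returned as SignalTrack objects so the result plugs straight
    into dataset_builder.build_cohort.
    """
    from .genomic_io import read_fasta, read_peaks, BedGraphTrack

    indir = Path(indir)
    with open(indir / "truth.json") as fh:
        truth = json.load(fh)
    genome = read_fasta(indir / "genome.fa")
    chrom = truth["config"]["chrom"]
    peaks_by_cell, tracks = {}, {}
    for cell in truth["cells"]:
        peaks_by_cell[cell] = read_peaks(indir / f"{cell}.peaks.bed", cell_id=cell)
        tracks[cell] = {}
        for omic in truth["config"]["omics"]:
            bg = BedGraphTrack(indir / f"{cell}.{omic}.bedgraph")
            tracks[cell][omic] = SignalTrack(chrom, bg.query(chrom, 0, len(genome[chrom])))
    return genome, peaks_by_cell, tracks, truth
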