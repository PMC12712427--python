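"""Sliding-window binning, normalization, per-gene signal and metaprofiles.

The genome is segmented into fixed-width bins laid on a sliding grid
(default 1-kb bins every 500 bp, so interior bases fall in two bins).
Per-sample bin counts are coverage mass (value x overlap length, i.e.
per-base accumulation), normalized by the sample's library total to a
configurable scale, then averaged across replicates per genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ChromSizes, CoverageTrack, GenomicInterval, ValidationError
from .samples import Manifest

__all__ = [
    "BinGrid",
    "make_bins",
    "bin_counts",
    "normalize",
    "average_replicates",
    "BinSignalMatrix",
    "build_bin_matrix",
    "gene_signal",
    "Metaprofile",
    "metaprofile",
]


@dataclass(frozen=True)
class BinGrid:
    """Sliding-window bin layout: per chrom, bin starts every ``step`` bp.

    Only full-length bins are kept (a bin whose end would exceed the
    chromosome is dropped), so the gain/loss threshold is comparable
    across all bins.
    """

    bin_size: int
    step: int
    starts: Mapping[str, np.ndarray]  # chrom -> sorted bin start positions

    @property
    def chroms(self) -> list[str]:
        return list(self.starts)

    @property
    def n_bins(self) -> int:
        return sum(len(s) for s in self.starts.values())

    def chrom_offsets(self) -> dict[str, int]:
        """Offset of each chromosome's first bin in the concatenated order."""
        offsets, pos = {}, 0
        for chrom, starts in self.starts.items():
            offsets[chrom] = pos
            pos += len(starts)
        return offsets

    def frame(self) -> pd.DataFrame:
        rows = []
        for chrom, starts in self.starts.items():
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + self.bin_size}
                )
            )
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(rows, ignore_index=True)

    def overlapping_bin_indices(self, interval: GenomicInterval) -> np.ndarray:
        """Concatenated-order indices of bins overlapping ``interval``."""
        if interval.chrom not in self.starts:
            return np.array([], dtype=np.int64)
        starts = self.starts[interval.chrom]
        mask = (starts < interval.end) & (starts + self.bin_size > interval.start)
        return np.nonzero(mask)[0] + self.chrom_offsets()[interval.chrom]


def make_bins(chrom_sizes: ChromSizes, bin_size: int = 1000, step: int = 500) -> BinGrid:
    """Lay a sliding-window grid over every chromosome."""
    if not (0 < step <= bin_size):
        raise ValueError(f"require 0 < step <= bin_size, got step={step}, bin_size={bin_size}")
    starts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        if length < bin_size:
            starts[chrom] = np.array([], dtype=np.int64)
        else:
            n = (length - bin_size) // step + 1
            starts[chrom] = np.arange(n, dtype=np.int64) * step
    return BinGrid(bin_size=bin_size, step=step, starts=starts)


def _cumulative_mass(starts: np.ndarray, ends: np.ndarray, values: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Coverage mass of the track restricted to [0, x) for each query x.

    Exact per-base accumulation in closed form, relying on the track
    invariant that records are sorted and non-overlapping.
    """
    if len(starts) == 0:
        return np.zeros(len(x))
    seg_len = ends - starts
    cum = np.concatenate(([0.0], np.cumsum(values * seg_len)))
    k = np.searchsorted(starts, x, side="right") - 1
    kc = np.clip(k, 0, None)
    partial = values[kc] * np.clip(x - starts[kc], 0, seg_len[kc])
    return cum[kc] + np.where(k >= 0, partial, 0.0)


def bin_counts(track: CoverageTrack, grid: BinGrid) -> np.ndarray:
    """Raw signal per bin: sum over records of value x overlap length.

    Equivalent to accumulating the per-base coverage over each bin.
    Bins in chromosomes absent from the track get 0.
    """
    out = np.zeros(grid.n_bins)
    offsets = grid.chrom_offsets()
    for chrom, bin_starts in grid.starts.items():
        if len(bin_starts) == 0 or chrom not in track:
            continue
        s, e, v = track.arrays(chrom)
        lo = _cumulative_mass(s, e, v, bin_starts)
        hi = _cumulative_mass(s, e, v, bin_starts + grid.bin_size)
        out[offsets[chrom]: offsets[chrom] + len(bin_starts)] = hi - lo
    return out


def normalize(counts: np.ndarray, library_total: float, scale: float = 1e6) -> np.ndarray:
    """Library-size normalization: count / library_total x scale."""
    if library_total <= 0:
        raise ValueError(f"library_total must be > 0, got {library_total}")
    return np.asarray(counts, dtype=np.float64) / float(library_total) * float(scale)


def average_replicates(
    sample_values: pd.DataFrame, manifest: Manifest, antibody: str = "mark"
) -> pd.DataFrame:
    """Unweighted arithmetic mean of replicate columns per genotype.

    ``sample_values`` columns are sample_ids; the manifest maps them to
    genotypes. Supports any number of replicates >= 1.
    """
    out = {}
    for genotype in manifest.genotypes():
        samples = [s.sample_id for s in manifest.select(genotype=genotype, antibody=antibody)]
        samples = [s for s in samples if s in sample_values.columns]
        if not samples:
            raise KeyError(f"no {antibody!r} samples for genotype {genotype!r} in matrix")
        out[genotype] = sample_values[samples].mean(axis=1)
    return pd.DataFrame(out)


@dataclass
class BinSignalMatrix:
    """Normalized per-bin signal per sample plus genotype means."""

    grid: BinGrid
    samples: pd.DataFrame        # columns: sample_ids; rows: bins (concatenated order)
    genotype_means: pd.DataFrame  # columns: genotypes
    manifest: Manifest
    scale: float
    bins: pd.DataFrame = field(default=None)  # chrom/start/end, aligned to rows

    def __post_init__(self):
        if self.bins is None:
            self.bins = self.grid.frame()

    def frame(self) -> pd.DataFrame:
        """Bins + per-sample values + genotype means, one wide table."""
        return pd.concat(
            [self.bins.reset_index(drop=True),
             self.samples.reset_index(drop=True),
             self.genotype_means.add_prefix("mean_").reset_index(drop=True)],
            axis=1,
        )


def build_bin_matrix(
    tracks: Mapping[str, CoverageTrack],
    manifest: Manifest,
    grid: BinGrid,
    scale: float = 1e6,
    antibody: str = "mark",
) -> BinSignalMatrix:
    """Bin, normalize and replicate-average the mark tracks of a manifest."""
    columns = {}
    for info in manifest.select(antibody=antibody):
        if info.sample_id not in tracks:
            raise KeyError(f"manifest sample {info.sample_id!r} missing from tracks")
        counts = bin_counts(tracks[info.sample_id], grid)
        columns[info.sample_id] = normalize(counts, info.library_total, scale)
    samples = pd.DataFrame(columns)
    means = average_replicates(samples, manifest, antibody=antibody)
    return BinSignalMatrix(grid=grid, samples=samples, genotype_means=means,
                           manifest=manifest, scale=scale)


def gene_signal(
    tracks: Mapping[str, CoverageTrack],
    manifest: Manifest,
    genes: Sequence[GenomicInterval],
    chrom_sizes: ChromSizes,
    flank: int = 500,
    scale: float = 1e6,
    antibody: str = "mark",
) -> pd.DataFrame:
    """Aggregate normalized signal per gene body plus flanks, per genotype.

    For each replicate, normalized coverage is summed over
    [start - flank, end + flank) clipped to the chromosome, then
    replicates are averaged per genotype. Returns genes x genotypes.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    gene_ids = []
    windows: list[tuple[str, int, int]] = []
    for i, gene in enumerate(genes):
        chrom_sizes.validate_interval(gene)
        lo = max(0, gene.start - flank)
        hi = min(chrom_sizes[gene.chrom], gene.end + flank)
        gene_ids.append(gene.name if gene.name is not None else f"feature_{i}")
        windows.append((gene.chrom, lo, hi))

    columns = {}
    for info in manifest.select(antibody=antibody):
        track = tracks[info.sample_id]
        vals = np.zeros(len(windows))
        for j, (chrom, lo, hi) in enumerate(windows):
            if chrom not in track:
                continue
            s, e, v = track.arrays(chrom)
            vals[j] = _cumulative_mass(s, e, v, np.array([hi]))[0] - _cumulative_mass(
                s, e, v, np.array([lo])
            )[0]
        columns[info.sample_id] = normalize(vals, info.library_total, scale)
    samples = pd.DataFrame(columns, index=gene_ids)
    means = average_replicates(samples, manifest, antibody=antibody)
    means.index = pd.Index(gene_ids, name="gene_id")
    return means


@dataclass
class Metaprofile:
    """Mean signal as a function of offset from a set of anchor midpoints."""

    offsets: np.ndarray  # window start offsets, -flank .. flank - resolution
    values: np.ndarray   # mean per-bp signal per offset window
    n_anchors: int       # anchors actually used
    n_excluded: int      # anchors dropped because their window left the chrom

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "signal": self.values})


def metaprofile(
    track: CoverageTrack,
    anchors: Sequence[GenomicInterval],
    chrom_sizes: ChromSizes,
    flank: int = 5000,
    resolution: int = 100,
    library_total: float | None = None,
    scale: float = 1e6,
) -> Metaprofile:
    """Anchor-centered mean coverage profile over +/- ``flank`` bp.

    The anchor point is the interval midpoint. Anchors whose window
    [mid - flank, mid + flank) exceeds chromosome bounds are excluded
    (not zero-padded) and counted in ``n_excluded``. Values are mean
    per-bp coverage per ``resolution``-bp offset window, optionally
    library-normalized.
    """
    if flank <= 0 or resolution <= 0 or flank % resolution != 0:
        raise ValueError("flank must be a positive multiple of resolution")
    n_windows = 2 * flank // resolution
    offsets = -flank + np.arange(n_windows, dtype=np.int64) * resolution
    total = np.zeros(n_windows)
    used = excluded = 0
    for anchor in anchors:
        if anchor.chrom not in chrom_sizes:
            raise ValidationError(f"anchor on unknown chrom {anchor.chrom!r}")
        mid = anchor.midpoint
        lo, hi = mid - flank, mid + flank
        if lo < 0 or hi > chrom_sizes[anchor.chrom]:
            excluded += 1
            continue
        edges = np.arange(lo, hi + resolution, resolution, dtype=np.int64)
        if anchor.chrom in track:
            s, e, v = track.arrays(anchor.chrom)
            mass = _cumulative_mass(s, e, v, edges)
            total += np.diff(mass) / resolution
        used += 1
    if used == 0:
        raise ValueError("no usable anchors (all excluded or none supplied)")
    values = total / used
    if library_total is not None:
        values = normalize(values, library_total, scale)
    return Metaprofile(offsets=offsets, values=values, n_anchors=used, n_excluded=excluded)
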