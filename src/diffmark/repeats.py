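"""Tandem-repeat unit discovery and motif density scanning.

Interstitial telomeric repeat (ITR) arrays are near-perfect tandem
stacks of a short telobox unit (plant telomere repeat TTTAGGG and its
rotations, e.g. TAGGGTT). The unit finder here is a deliberately simple
tandem k-mer heuristic: a k-mer immediately followed by an identical
copy is direct evidence of a period-k tandem. It recovers a single
dominant unit from an array; it is not a structural-hierarchy
decomposition of higher-order repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval

__all__ = [
    "canonical_rotation",
    "RepeatUnitReport",
    "dominant_repeat_unit",
    "MotifDensityTrack",
    "count_motif_occurrences",
    "motif_density",
    "region_repeat_overlap",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation of ``unit``.

    All phases of the same tandem array (TAGGGTT, AGGGTTT, ...) share
    one canonical rotation, so unit identity is phase-independent.
    """
    if not unit:
        raise ValueError("empty unit")
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


@dataclass
class RepeatUnitReport:
    unit: str                 # most frequent tandem k-mer (as observed)
    k: int
    canonical_rotation: str
    tandem_count: int         # positions i with seq[i:i+k] == seq[i+k:i+2k] for this unit class
    fraction: float           # fraction of the region covered by tandem copies of the unit
    is_dominant: bool         # fraction >= min_fraction


def dominant_repeat_unit(
    sequence: str, k_min: int = 5, k_max: int = 12, min_fraction: float = 0.2
) -> RepeatUnitReport:
    """Find the dominant short tandem-repeat unit of a sequence.

    For each k in [k_min, k_max], positions where a k-mer is immediately
    followed by an identical k-mer count as tandem evidence; evidence is
    pooled over rotations of the same unit (canonical-rotation classes).
    The winner is the class with the most evidence; ties break toward
    smaller k, then lexicographically smaller canonical unit. Windows
    containing N are ignored. A report with ``fraction`` below
    ``min_fraction`` is flagged not dominant.
    """
    seq = sequence.upper()
    if k_min < 1 or k_min > k_max:
        raise ValueError("require 1 <= k_min <= k_max")
    if len(seq) < 2 * k_max:
        raise ValueError(f"sequence length {len(seq)} < 2*k_max = {2 * k_max}")

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")

    best: tuple[int, int, str] | None = None  # (-count, k, canonical)
    best_positions: np.ndarray | None = None
    for k in range(k_min, k_max + 1):
        n = len(seq) - 2 * k + 1
        if n <= 0:
            continue
        # position i is tandem evidence when seq[i:i+k] == seq[i+k:i+2k]
        eq = np.ones(n, dtype=bool)
        ok = np.ones(n, dtype=bool)
        for j in range(k):
            eq &= arr[j: j + n] == arr[j + k: j + k + n]
            ok &= valid[j: j + n] & valid[j + k: j + k + n]
        hits = np.nonzero(eq & ok)[0]
        if len(hits) == 0:
            continue
        classes: dict[str, list[int]] = {}
        for i in hits:
            canon = canonical_rotation(seq[i: i + k])
            classes.setdefault(canon, []).append(int(i))
        for canon, positions in classes.items():
            key = (-len(positions), k, canon)
            if best is None or key < best:
                best = key
                best_positions = np.array(positions)

    if best is None:
        return RepeatUnitReport(unit="", k=0, canonical_rotation="", tandem_count=0,
                                fraction=0.0, is_dominant=False)
    count, k, canon = -best[0], best[1], best[2]
    # bases covered by at least one tandem pair of the winning class
    covered = np.zeros(len(seq) + 1, dtype=np.int64)
    covered[best_positions] += 1
    covered[np.minimum(best_positions + 2 * k, len(seq))] -= 1
    fraction = float(np.count_nonzero(np.cumsum(covered[:-1]) > 0)) / len(seq)
    unit = seq[best_positions[0]: best_positions[0] + k]
    return RepeatUnitReport(unit=unit, k=k, canonical_rotation=canon,
                            tandem_count=count, fraction=fraction,
                            is_dominant=fraction >= min_fraction)


def count_motif_occurrences(sequence: str, motif: str) -> int:
    """Occurrences of ``motif`` in ``sequence``, overlapping matches allowed."""
    count, start = 0, 0
    while True:
        idx = sequence.find(motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def _match_starts(sequence: str, motif: str) -> list[int]:
    starts, pos = [], 0
    while True:
        idx = sequence.find(motif, pos)
        if idx < 0:
            return starts
        starts.append(idx)
        pos = idx + 1


@dataclass
class MotifDensityTrack:
    """Motif occurrence counts in fixed non-overlapping windows per chrom."""

    motif: str
    window: int
    strand: str                       # "forward" or "both"
    counts: Mapping[str, np.ndarray]  # chrom -> count per window

    def window_interval(self, chrom: str, idx: int) -> GenomicInterval:
        return GenomicInterval(chrom, idx * self.window, (idx + 1) * self.window)

    def frame(self) -> pd.DataFrame:
        rows = []
        for chrom, counts in self.counts.items():
            starts = np.arange(len(counts), dtype=np.int64) * self.window
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": starts + self.window,
                "count": counts,
            }))
        return pd.concat(rows, ignore_index=True)


def motif_density(
    sequences: Mapping[str, str], motif: str = "TAGGGTT",
    window: int = 200, strand: str = "forward",
) -> MotifDensityTrack:
    """Count motif occurrences per fixed genomic window.

    Overlapping matches are counted (tandem arrays place a copy of the
    motif at every repeat phase). A match belongs to the window
    containing its start position; half-open windows tile each
    chromosome, the last (possibly short) window included. With
    ``strand="both"`` reverse-complement matches are added.
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if len(motif) >= window:
        raise ValueError("motif must be shorter than the window")
    if strand not in ("forward", "both"):
        raise ValueError(f"strand must be 'forward' or 'both', got {strand!r}")
    queries = [motif]
    if strand == "both":
        rc = reverse_complement(motif)
        if rc != motif:
            queries.append(rc)
    counts: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        seq = seq.upper()
        n_windows = max(1, -(-len(seq) // window))
        c = np.zeros(n_windows, dtype=np.int64)
        for query in queries:
            for start in _match_starts(seq, query):
                c[start // window] += 1
        counts[chrom] = c
    return MotifDensityTrack(motif=motif, window=window, strand=strand, counts=counts)


def region_repeat_overlap(
    regions: Sequence[GenomicInterval] | pd.DataFrame,
    track: MotifDensityTrack,
    density_threshold: float,
) -> pd.DataFrame:
    """Mean motif count per window inside each region, with a dense flag.

    Windows overlapping the region (any overlap) contribute. A region is
    flagged telobox-dense when its mean count per window >= threshold.
    """
    if isinstance(regions, pd.DataFrame):
        intervals = [
            GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            for _, row in regions.iterrows()
        ]
    else:
        intervals = list(regions)
    rows = []
    for iv in intervals:
        counts = track.counts.get(iv.chrom)
        if counts is None:
            density = 0.0
        else:
            lo = iv.start // track.window
            hi = -(-iv.end // track.window)  # ceil
            hi = min(hi, len(counts))
            density = float(counts[lo:hi].mean()) if hi > lo else 0.0
        rows.append({
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "mean_count_per_window": density,
            "telobox_dense": density >= density_threshold,
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "mean_count_per_window", "telobox_dense"])
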