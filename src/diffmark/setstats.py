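"""Marked-gene sets, set intersections and overlap statistics.

A gene is "marked" when at least one peak overlaps it. Overlaps between
gene sets are tested with the upper-tail hypergeometric distribution
(enrichment), summarized by fold enrichment
(overlap / n_query) / (n_term / n_universe), and corrected for multiple
testing with Benjamini-Hochberg. The universe must always be supplied
explicitly: p-values are universe-sensitive and silently inferring it
from a union of sets would not be reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval

__all__ = [
    "assign_peaks_to_genes",
    "MarkedGeneSets",
    "intersect_sets",
    "OverlapTest",
    "hypergeom_overlap",
    "overlap_test",
    "fold_enrichment",
    "bh_adjust",
]


def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    min_overlap: int = 1,
    flank: int = 0,
) -> set[str]:
    """Genes overlapped by >= ``min_overlap`` bp of any peak.

    By default only the gene body counts; ``flank`` widens each gene by
    that many bp on both sides (e.g. to include promoters). Returns a
    set of gene names.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for peak in peaks:
        by_chrom.setdefault(peak.chrom, []).append((peak.start, peak.end))
    marked: set[str] = set()
    for i, gene in enumerate(genes):
        gid = gene.name if gene.name is not None else f"feature_{i}"
        lo = max(0, gene.start - flank)
        hi = gene.end + flank
        for ps, pe in by_chrom.get(gene.chrom, ()):
            if min(hi, pe) - max(lo, ps) >= min_overlap:
                marked.add(gid)
                break
    return marked


@dataclass
class MarkedGeneSets:
    """Per-genotype marked-gene sets over an explicit gene universe."""

    sets: Mapping[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        for label, members in self.sets.items():
            extra = set(members) - self.universe
            if extra:
                raise ValueError(
                    f"set {label!r} has {len(extra)} members outside the universe "
                    f"(e.g. {sorted(extra)[:3]})"
                )


def intersect_sets(sets: Mapping[str, set[str]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclusive membership-partition (UpSet) counts plus pairwise overlaps.

    Every element of the union is assigned to exactly one membership
    signature, so signature counts sum to the union size. Also returns
    the pairwise intersection counts used for Venn diagrams.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    labels = list(sets)
    union = set().union(*sets.values())
    if not union:
        raise ValueError("all sets empty")
    signatures: dict[tuple[bool, ...], int] = {}
    for element in union:
        sig = tuple(element in sets[label] for label in labels)
        signatures[sig] = signatures.get(sig, 0) + 1
    upset_rows = [
        {**{label: present for label, present in zip(labels, sig)}, "count": count}
        for sig, count in sorted(signatures.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    upset = pd.DataFrame(upset_rows, columns=labels + ["count"])
    pair_rows = [
        {"set_a": a, "set_b": b, "overlap": len(sets[a] & sets[b]),
         "only_a": len(sets[a] - sets[b]), "only_b": len(sets[b] - sets[a])}
        for i, a in enumerate(labels) for b in labels[i + 1:]
    ]
    pairwise = pd.DataFrame(pair_rows, columns=["set_a", "set_b", "overlap", "only_a", "only_b"])
    return upset, pairwise


def _check_overlap_bounds(n_query: int, n_set: int, overlap: int, n_universe: int) -> None:
    if not (0 <= n_query <= n_universe and 0 <= n_set <= n_universe):
        raise ValueError("set sizes must lie within the universe")
    if overlap > min(n_query, n_set) or overlap < max(0, n_query + n_set - n_universe):
        raise ValueError(
            f"impossible overlap {overlap} for n_query={n_query}, "
            f"n_set={n_set}, N={n_universe}"
        )


def hypergeom_overlap(n_query: int, n_set: int, overlap: int, n_universe: int) -> float:
    """Upper-tail hypergeometric overlap p-value, P[X >= overlap].

    X counts the intersection of a random ``n_query``-subset of an
    ``n_universe`` universe with a fixed ``n_set``-subset. The tail is
    evaluated in log space and exponentiated, so extreme enrichments
    stay finite instead of underflowing to 0 prematurely.
    """
    _check_overlap_bounds(n_query, n_set, overlap, n_universe)
    if overlap == 0:
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(overlap - 1, n_universe, n_set, n_query)))


def fold_enrichment(overlap: int, n_query: int, n_term: int, n_universe: int) -> float:
    """(overlap / n_query) / (n_term / n_universe); > 1 = over-represented."""
    if n_query <= 0 or n_term <= 0 or n_universe <= 0:
        raise ValueError("n_query, n_term and n_universe must be > 0")
    return (overlap / n_query) / (n_term / n_universe)


@dataclass
class OverlapTest:
    n_query: int
    n_set: int
    overlap: int
    n_universe: int
    p_hyper: float
    fold_enrichment: float
    p_adjusted: float | None = None


def overlap_test(query: set[str], term: set[str], universe: set[str]) -> OverlapTest:
    """Hypergeometric enrichment + fold enrichment for two concrete sets."""
    if not universe:
        raise ValueError("empty universe")
    q, t = query & universe, term & universe
    overlap = len(q & t)
    return OverlapTest(
        n_query=len(q), n_set=len(t), overlap=overlap, n_universe=len(universe),
        p_hyper=hypergeom_overlap(len(q), len(t), overlap, len(universe)),
        fold_enrichment=fold_enrichment(overlap, len(q), len(t), len(universe))
        if q and t else 0.0,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
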