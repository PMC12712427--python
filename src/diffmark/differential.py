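"""Per-bin genotype deltas, gain/loss classification and summaries.

A bin is a *gain* bin when the normalized genotype-mean signal
difference (A minus B) exceeds the gain threshold, a *loss* bin when it
falls below the loss threshold; both inequalities are strict, so a delta
exactly at a threshold is *unchanged*. Defaults are +0.5 / -0.5 in the
normalized units produced by the binning stage; the thresholds are
configurable because they are coupled to the normalization scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinSignalMatrix

__all__ = [
    "GAIN", "LOSS", "UNCHANGED",
    "bin_diff", "classify_deltas", "classify_bins",
    "DiffSummary", "summarize", "merge_regions",
    "gene_delta", "CorrelationResult", "gene_delta_correlation",
]

GAIN = "gain"
LOSS = "loss"
UNCHANGED = "unchanged"


def bin_diff(matrix: BinSignalMatrix, genotype_a: str, genotype_b: str) -> pd.DataFrame:
    """Per-bin delta = mean(genotype_a) - mean(genotype_b).

    Sign convention: positive delta means more signal in ``genotype_a``.
    """
    for g in (genotype_a, genotype_b):
        if g not in matrix.genotype_means.columns:
            raise KeyError(f"unknown genotype {g!r}")
    out = matrix.bins.copy().reset_index(drop=True)
    out["delta"] = (
        matrix.genotype_means[genotype_a].to_numpy()
        - matrix.genotype_means[genotype_b].to_numpy()
    )
    return out


def classify_deltas(
    deltas: np.ndarray, gain_threshold: float = 0.5, loss_threshold: float = -0.5
) -> np.ndarray:
    """Classify deltas into gain/loss/unchanged with strict thresholds."""
    if not gain_threshold > loss_threshold:
        raise ValueError(
            f"gain_threshold ({gain_threshold}) must exceed loss_threshold ({loss_threshold})"
        )
    deltas = np.asarray(deltas, dtype=np.float64)
    calls = np.full(deltas.shape, UNCHANGED, dtype=object)
    calls[deltas > gain_threshold] = GAIN
    calls[deltas < loss_threshold] = LOSS
    return calls


def classify_bins(
    diff: pd.DataFrame, gain_threshold: float = 0.5, loss_threshold: float = -0.5
) -> pd.DataFrame:
    """Attach a {gain, loss, unchanged} call to each bin delta row."""
    out = diff.copy()
    out["call"] = classify_deltas(out["delta"].to_numpy(), gain_threshold, loss_threshold)
    return out


@dataclass
class DiffSummary:
    contrast: str
    per_chrom: pd.DataFrame  # index chrom; columns gain/loss/unchanged
    n_gain: int
    n_loss: int
    n_unchanged: int
    gain_loss_ratio: float  # inf when losses == 0 and gains > 0; NaN when both 0

    @property
    def n_bins(self) -> int:
        return self.n_gain + self.n_loss + self.n_unchanged


def summarize(calls: pd.DataFrame, contrast: str = "") -> DiffSummary:
    """Genome and per-chromosome gain/loss/unchanged counts and ratio.

    With a sliding grid (step < bin size) neighbouring bins overlap, so
    a contiguous changed region contributes several counted bins.
    """
    per_chrom = (
        calls.pivot_table(index="chrom", columns="call", values="start", aggfunc="count")
        .reindex(columns=[GAIN, LOSS, UNCHANGED])
        .fillna(0)
        .astype(int)
    )
    per_chrom.columns.name = None
    n_gain = int(per_chrom[GAIN].sum())
    n_loss = int(per_chrom[LOSS].sum())
    n_unch = int(per_chrom[UNCHANGED].sum())
    if n_loss > 0:
        ratio = n_gain / n_loss
    elif n_gain > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")
    return DiffSummary(contrast, per_chrom, n_gain, n_loss, n_unch, ratio)


def merge_regions(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/book-ended same-call gain or loss bins.

    Returns maximal regions (chrom, start, end, call, n_bins,
    mean_delta); unchanged bins are not merged. Mean delta is the
    unweighted mean over member bins.
    """
    rows = []
    changed = calls[calls["call"] != UNCHANGED].sort_values(["chrom", "start"])
    for (chrom, call), group in changed.groupby(["chrom", "call"], sort=True):
        cur_start = cur_end = None
        deltas: list[float] = []
        for _, row in group.iterrows():
            if cur_start is None:
                cur_start, cur_end, deltas = row["start"], row["end"], [row["delta"]]
            elif row["start"] <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, row["end"])
                deltas.append(row["delta"])
            else:
                rows.append((chrom, cur_start, cur_end, call, len(deltas), float(np.mean(deltas))))
                cur_start, cur_end, deltas = row["start"], row["end"], [row["delta"]]
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, call, len(deltas), float(np.mean(deltas))))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "call", "n_bins", "mean_delta"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def gene_delta(gene_signal: pd.DataFrame, genotype_a: str, genotype_b: str) -> pd.Series:
    """Per-gene signal delta (A minus B) from a gene-signal table."""
    for g in (genotype_a, genotype_b):
        if g not in gene_signal.columns:
            raise KeyError(f"unknown genotype {g!r}")
    delta = gene_signal[genotype_a] - gene_signal[genotype_b]
    delta.name = f"{genotype_a}-{genotype_b}"
    return delta


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_genes: int
    n_dropped: int
    table: pd.DataFrame  # gene_id, delta_a, delta_b (plot-ready)


def gene_delta_correlation(deltas_a: pd.Series, deltas_b: pd.Series) -> CorrelationResult:
    """Pearson correlation of per-gene deltas between two contrasts.

    The two series must cover the same gene universe; genes with a
    missing value in either contrast are dropped and counted. The
    correlation is computed on all remaining genes, untransformed and
    untrimmed (outlier exclusion is a plotting concern, never applied
    before computing r).
    """
    if set(deltas_a.index) != set(deltas_b.index):
        raise ValueError("contrasts must share the same gene universe")
    table = pd.DataFrame({"delta_a": deltas_a, "delta_b": deltas_b.reindex(deltas_a.index)})
    clean = table.dropna()
    n_dropped = len(table) - len(clean)
    if len(clean) < 3:
        raise ValueError(f"need >= 3 shared genes with values, got {len(clean)}")
    r, p = stats.pearsonr(clean["delta_a"], clean["delta_b"])
    clean = clean.reset_index().rename(columns={"index": "gene_id"})
    return CorrelationResult(r=float(r), p_value=float(p), n_genes=len(clean),
                             n_dropped=n_dropped, table=clean)
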