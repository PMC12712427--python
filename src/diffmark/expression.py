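"""Expression integration: DEG thresholds, PCA on log counts, and
DEG-by-mark-change cross-tabulation.

Differential-expression fitting itself is upstream (the module consumes
per-gene log2 fold change / FDR tables); here a gene is a DEG when
FDR < 0.01 and |log2FC| > 1, both strict. PCA is run on log-transformed
counts (natural log, pseudocount 1; the loading-selection rule below is
invariant to the log base), and per-component "high-loading" genes are
those whose |loading| exceeds three times the SD of that component's
loading vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .setstats import bh_adjust, fold_enrichment, hypergeom_overlap

__all__ = [
    "call_degs",
    "PCAResult",
    "pca_counts",
    "select_high_loading_genes",
    "separating_component",
    "crosstab_deg_mark",
]

REQUIRED_DEG_COLUMNS = ("gene_id", "log2FC", "FDR")


def call_degs(
    table: pd.DataFrame, fdr_max: float = 0.01, min_abs_log2fc: float = 1.0
) -> pd.DataFrame:
    """Call differentially expressed genes from a (gene_id, log2FC, FDR) table.

    A gene is a DEG iff FDR < ``fdr_max`` and |log2FC| > ``min_abs_log2fc``
    (both inequalities strict, so boundary values are not DEGs).
    Returns the DEG rows with a ``direction`` column ("up"/"down").
    """
    missing = [c for c in REQUIRED_DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    if table["gene_id"].duplicated().any():
        raise ValueError("DEG table has duplicate gene_ids")
    fdr = table["FDR"].to_numpy(dtype=float)
    if np.any((fdr < 0) | (fdr > 1)):
        raise ValueError("FDR values must lie in [0, 1]")
    lfc = table["log2FC"].to_numpy(dtype=float)
    is_deg = (fdr < fdr_max) & (np.abs(lfc) > min_abs_log2fc)
    out = table.loc[is_deg, list(REQUIRED_DEG_COLUMNS)].copy()
    out["direction"] = np.where(out["log2FC"] > 0, "up", "down")
    return out.reset_index(drop=True)


@dataclass
class PCAResult:
    scores: pd.DataFrame     # samples x components
    loadings: pd.DataFrame   # genes x components
    variance_explained: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> PCAResult:
    """PCA of a genes x samples count matrix on log-transformed counts.

    Counts are log(count + pseudocount) transformed (natural log),
    centered per gene, and decomposed by SVD with samples as
    observations. Loadings columns are orthonormal; variance explained
    is nonincreasing. Component signs are fixed deterministically: the
    largest-magnitude loading of each component is made positive.
    A constant matrix yields all-zero scores, not an error.
    """
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    gene_ids = [str(g) for g in counts.index]
    sample_ids = [str(s) for s in counts.columns]
    x = np.log(counts.to_numpy(dtype=float) + pseudocount).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    n = x.shape[0]
    var = (s ** 2) / max(n - 1, 1)
    comp_names = [f"PC{j + 1}" for j in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=sample_ids, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=gene_ids, columns=comp_names),
        variance_explained=var,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
    )


def select_high_loading_genes(
    pca: PCAResult, component: str | int, sd_multiple: float = 3.0,
    about_zero: bool = False,
) -> set[str]:
    """Genes whose |loading| exceeds ``sd_multiple`` x SD of the component.

    SD is the sample standard deviation of the component's loading
    vector about its mean (set ``about_zero=True`` for SD about zero).
    The inequality is strict. A degenerate component (SD == 0) returns
    an empty set with a warning.
    """
    if isinstance(component, int):
        component = f"PC{component}"
    if component not in pca.loadings.columns:
        raise KeyError(f"unknown component {component!r}")
    loadings = pca.loadings[component].to_numpy()
    if about_zero:
        sd = float(np.sqrt(np.sum(loadings ** 2) / max(len(loadings) - 1, 1)))
    else:
        sd = float(np.std(loadings, ddof=1)) if len(loadings) > 1 else 0.0
    if sd == 0.0:
        warnings.warn(f"component {component} has zero loading SD; no genes selected")
        return set()
    threshold = sd_multiple * sd
    return {g for g, l in zip(pca.gene_ids, loadings) if abs(l) > threshold}


def separating_component(
    pca: PCAResult, sample_groups: dict[str, str], group: str,
) -> str:
    """Component whose scores best separate ``group`` samples from the rest.

    Separation is the squared mean-score difference between the group
    and the remaining samples divided by the pooled within-group score
    variance (+ a small floor), evaluated per component.
    """
    labels = np.array([sample_groups[s] for s in pca.sample_ids])
    mask = labels == group
    if mask.all() or not mask.any():
        raise ValueError(f"group {group!r} must be a strict subset of samples")
    best_comp, best_stat = None, -np.inf
    for comp in pca.scores.columns:
        s = pca.scores[comp].to_numpy()
        between = (s[mask].mean() - s[~mask].mean()) ** 2
        within = (np.var(s[mask]) * mask.sum() + np.var(s[~mask]) * (~mask).sum()) / len(s)
        stat = between / (within + 1e-12)
        if stat > best_stat:
            best_comp, best_stat = comp, stat
    return best_comp


def crosstab_deg_mark(
    degs: pd.DataFrame, gene_mark_calls: pd.Series | dict[str, str]
) -> pd.DataFrame:
    """Cross-tabulate DEG direction against per-gene mark-change calls.

    ``degs`` is the output of :func:`call_degs`; ``gene_mark_calls``
    maps gene_id -> {"gain", "loss", "unchanged"} and defines the
    universe (genes with mark information). Returns one row per
    (direction, mark_call) cell with counts, hypergeometric enrichment
    p, fold enrichment and BH-adjusted p across the six cells. Cell
    counts sum to the number of DEGs that have mark information.
    """
    calls = pd.Series(gene_mark_calls)
    if calls.empty:
        raise ValueError("empty gene universe")
    universe = set(calls.index.astype(str))
    calls.index = calls.index.astype(str)
    rows = []
    for direction in ("up", "down"):
        query = set(degs.loc[degs["direction"] == direction, "gene_id"].astype(str)) & universe
        for mark_call in ("gain", "loss", "unchanged"):
            term = set(calls.index[calls == mark_call])
            overlap = len(query & term)
            if query and term:
                p = hypergeom_overlap(len(query), len(term), overlap, len(universe))
                fe = fold_enrichment(overlap, len(query), len(term), len(universe))
            else:
                p, fe = 1.0, float("nan")
            rows.append({
                "direction": direction, "mark_call": mark_call,
                "n_deg": len(query), "n_mark": len(term), "overlap": overlap,
                "fold_enrichment": fe, "p_hyper": p,
            })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_hyper"].to_numpy())
    return out
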