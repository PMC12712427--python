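"""Synthetic data generator with known planted truth.

Emulates the statistical structure the analysis assumes, at desk scale:

* a toy genome (default 2 chromosomes x 300 kb) with uniformly spaced
  2-kb genes and one pericentromeric interstitial telomeric repeat
  (ITR): an exact tandem array of a telobox unit (default TAGGGTT);
* multi-genotype, multi-replicate mark + control coverage. Expected
  mark coverage is depth x a piecewise level: background everywhere,
  a marked level over marked genes (multiplied by a per-genotype effect
  over the effect-gene subset), and an ectopic level over the ITR in
  genotypes that gain it. Reads are drawn per 100-bp segment from a
  Poisson (the pipeline consumes coverage, not reads), and each sample
  gets a library-size jitter factor (0.5-2x) so normalization is a
  load-bearing, testable step;
* a negative-binomial count matrix (genes x samples) with genotype
  structure and planted log2 effects on DE genes, plus a synthetic
  stand-in for an upstream differential-expression result table.

Everything is deterministic under a fixed seed, and a zero-noise
("expectation") mode makes every downstream stage exactly invertible
to the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import BinGrid, bin_counts, normalize
from .core import ChromSizes, CoverageTrack, GenomicInterval
from .differential import classify_deltas
from .samples import Manifest, SampleInfo

__all__ = [
    "ConfigError",
    "GenotypeEffect",
    "SimConfig",
    "SimTruth",
    "ToyDataset",
    "build_toy_genome",
    "expected_level",
    "signal_area",
    "expected_track",
    "simulate_coverage",
    "simulate_peaks",
    "simulate_counts_matrix",
    "simulate_deg_table",
    "calibrated_scale",
    "expected_bin_values",
    "planted_bin_calls",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class GenotypeEffect:
    """Per-genotype planted effect.

    gene_effect multiplies the marked level over the effect-gene subset
    (1.0 = no change, 2.0 = domain-level gain, 0.5 = loss).
    itr_level is the absolute ectopic mark level at the ITR in units of
    the marked level (0.0 = background only, 1.0 = fully marked).
    """

    gene_effect: float = 1.0
    itr_level: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic dataset; defaults are the study conditions
    the test suite and demo run under."""

    seed: int = 0
    chroms: tuple[tuple[str, int], ...] = (("chr1", 300_000), ("chr2", 300_000))
    n_genes: int = 100
    gene_length: int = 2_000
    gene_spacing: int = 5_500   # slot pitch; multiple of the bin step
    gene_offset: int = 200      # first slot start; deliberately off the bin grid
    itr_chrom: str = "chr1"
    itr_start: int = 145_000
    telobox: str = "TAGGGTT"
    telobox_copies: int = 1_428  # ~10 kb array
    effects: tuple[tuple[str, GenotypeEffect], ...] = (
        ("WT", GenotypeEffect(1.0, 0.0)),
        ("dek", GenotypeEffect(2.0, 1.0)),
        ("lhp1", GenotypeEffect(0.5, 0.0)),
    )
    baseline_genotype: str = "WT"
    replicates: int = 2
    depth: float = 30.0            # mean mark-library depth, reads per bp at marked level
    background_level: float = 0.2  # mark level outside marked features
    marked_level: float = 1.0
    marked_fraction: float = 0.4   # fraction of genes carrying the mark at baseline
    n_effect_genes: int = 20       # marked genes subject to genotype effects
    segment: int = 100             # Poisson noise granularity, bp
    noise: str = "poisson"         # "poisson" or "none" (expectation mode)
    jitter: tuple[float, float] = (0.5, 2.0)  # library-size factor range
    n_expr_genes: int = 1_000
    expr_replicates: int = 3
    expr_mean: float = 100.0
    nb_dispersion: float = 0.1
    de_log2fc: float = -2.5        # planted expression effect on DE genes
    de_genotype: str = "dek"

    @property
    def genotypes(self) -> list[str]:
        return [g for g, _ in self.effects]

    def effect(self, genotype: str) -> GenotypeEffect:
        for g, eff in self.effects:
            if g == genotype:
                return eff
        raise ConfigError(f"unknown genotype {genotype!r}")

    @property
    def itr(self) -> GenomicInterval:
        length = len(self.telobox) * self.telobox_copies
        return GenomicInterval(self.itr_chrom, self.itr_start, self.itr_start + length)

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(dict(self.chroms))

    def validate(self) -> None:
        errors = []
        if self.depth <= 0:
            errors.append("depth must be > 0")
        if not (0 < self.background_level < self.marked_level):
            errors.append("require 0 < background_level < marked_level")
        if self.replicates < 1 or self.expr_replicates < 1:
            errors.append("replicates must be >= 1")
        if not self.telobox or set(self.telobox.upper()) - set("ACGT"):
            errors.append("telobox unit must be non-empty ACGT")
        for g, eff in self.effects:
            if eff.gene_effect <= 0 or eff.itr_level < 0:
                errors.append(f"effects for {g!r} must be positive")
        if self.baseline_genotype not in self.genotypes:
            errors.append(f"baseline genotype {self.baseline_genotype!r} not in effects")
        if self.de_genotype not in self.genotypes:
            errors.append(f"de_genotype {self.de_genotype!r} not in effects")
        sizes = dict(self.chroms)
        if self.itr_chrom not in sizes:
            errors.append(f"ITR chrom {self.itr_chrom!r} not among chroms")
        elif self.itr.end > sizes[self.itr_chrom]:
            errors.append("ITR exceeds its chromosome")
        if self.n_expr_genes < self.n_genes:
            errors.append("n_expr_genes must be >= n_genes")
        if not (0 < self.jitter[0] <= self.jitter[1]):
            errors.append("jitter bounds must satisfy 0 < lo <= hi")
        if self.noise not in ("poisson", "none"):
            errors.append(f"unknown noise model {self.noise!r}")
        if errors:
            raise ConfigError("; ".join(errors))

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per purpose."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


def _gene_id(i: int) -> str:
    return f"g{i + 1:04d}"


@dataclass
class SimTruth:
    """Planted ground truth, derivable deterministically from the config."""

    genes: list[GenomicInterval]
    marked_genes: set[str]
    effect_genes: set[str]
    itr: GenomicInterval
    de_genes: dict[str, float]  # gene_id -> signed planted log2 fold change

    def gene_by_id(self) -> dict[str, GenomicInterval]:
        return {g.name: g for g in self.genes}


@dataclass
class ToyDataset:
    sequences: dict[str, str]
    genes: list[GenomicInterval]
    chrom_sizes: ChromSizes
    truth: SimTruth
    config: SimConfig


def build_toy_genome(config: SimConfig) -> ToyDataset:
    """Random background genome + tandem ITR array + uniformly spaced genes.

    Genes are placed on a fixed slot grid (pitch ``gene_spacing``,
    first slot at ``gene_offset``), skipping slots that would overlap
    the ITR; a packing that cannot fit ``n_genes`` raises
    :class:`ConfigError`.
    """
    config.validate()
    sizes = dict(config.chroms)
    rng = config.rng(0)
    sequences: dict[str, str] = {}
    for chrom, length in config.chroms:
        seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
        sequences[chrom] = seq
    itr = config.itr
    unit = config.telobox.upper()
    array = unit * config.telobox_copies
    s = sequences[itr.chrom]
    sequences[itr.chrom] = s[: itr.start] + array + s[itr.end:]

    # gene slots, round-robin-free: fill chromosomes in order with an even split
    n_chroms = len(config.chroms)
    per_chrom = [config.n_genes // n_chroms] * n_chroms
    for i in range(config.n_genes % n_chroms):
        per_chrom[i] += 1
    genes: list[GenomicInterval] = []
    idx = 0
    for (chrom, length), want in zip(config.chroms, per_chrom):
        placed = 0
        start = config.gene_offset
        while placed < want and start + config.gene_length <= length:
            gene = GenomicInterval(chrom, start, start + config.gene_length)
            if chrom != itr.chrom or gene.overlap_length(itr) == 0:
                genes.append(GenomicInterval(chrom, start, start + config.gene_length,
                                             name=_gene_id(idx)))
                idx += 1
                placed += 1
            start += config.gene_spacing
        if placed < want:
            raise ConfigError(
                f"cannot place {want} genes on {chrom} (length {length}, "
                f"spacing {config.gene_spacing}, ITR at {itr.start}-{itr.end})"
            )

    pick = config.rng(1)
    n_marked = int(round(config.marked_fraction * config.n_genes))
    if config.n_effect_genes > n_marked:
        raise ConfigError(
            f"n_effect_genes ({config.n_effect_genes}) exceeds marked genes ({n_marked})"
        )
    gene_ids = [g.name for g in genes]
    marked = sorted(pick.choice(gene_ids, size=n_marked, replace=False))
    effect = sorted(pick.choice(marked, size=config.n_effect_genes, replace=False))
    de_genes = {g: config.de_log2fc for g in effect}
    truth = SimTruth(genes=genes, marked_genes=set(marked), effect_genes=set(effect),
                     itr=itr, de_genes=de_genes)
    return ToyDataset(sequences=sequences, genes=genes,
                      chrom_sizes=config.chrom_sizes(), truth=truth, config=config)


def expected_level(config: SimConfig, truth: SimTruth, genotype: str) -> dict[str, np.ndarray]:
    """Per-bp expected mark level (units of depth) for one genotype."""
    eff = config.effect(genotype)
    levels = {chrom: np.full(length, config.background_level)
              for chrom, length in config.chroms}
    for gene in truth.genes:
        if gene.name not in truth.marked_genes:
            continue
        lvl = config.marked_level
        if gene.name in truth.effect_genes:
            lvl *= eff.gene_effect
        levels[gene.chrom][gene.start: gene.end] = lvl
    itr_lvl = eff.itr_level * config.marked_level
    if itr_lvl > config.background_level:
        levels[truth.itr.chrom][truth.itr.start: truth.itr.end] = itr_lvl
    return levels


def signal_area(config: SimConfig, truth: SimTruth, genotype: str) -> float:
    """Integral of the expected level over the genome (total reads / depth)."""
    return float(sum(l.sum() for l in expected_level(config, truth, genotype).values()))


def _segment_rates(config: SimConfig, levels: Mapping[str, np.ndarray]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Expected reads per segment: lambda = depth x sum(level over segment)."""
    out = {}
    m = config.segment
    for chrom, level in levels.items():
        n_seg = -(-len(level) // m)
        pad = n_seg * m - len(level)
        padded = np.concatenate([level, np.zeros(pad)]) if pad else level
        lam = config.depth * padded.reshape(n_seg, m).sum(axis=1)
        starts = np.arange(n_seg, dtype=np.int64) * m
        ends = np.minimum(starts + m, len(level))
        out[chrom] = (starts, ends, lam)
    return out


def expected_track(config: SimConfig, truth: SimTruth, genotype: str,
                   antibody: str = "mark") -> CoverageTrack:
    """Noise-free coverage track whose values are expected per-segment reads."""
    if antibody == "mark":
        levels = expected_level(config, truth, genotype)
    else:
        levels = {chrom: np.full(length, config.marked_level)
                  for chrom, length in config.chroms}
    data = _segment_rates(config, levels)
    return CoverageTrack(data, config.chrom_sizes())


def simulate_coverage(config: SimConfig, truth: SimTruth) -> tuple[dict[str, CoverageTrack], Manifest]:
    """Mark + control tracks per genotype per replicate, with a manifest.

    Per sample: a library-size factor is drawn log-uniformly from the
    jitter range, per-segment reads are Poisson around factor x expected
    (or exactly expected x factor in ``noise="none"`` mode), and the
    manifest records the realized library total (sum of track values).
    """
    config.validate()
    rng = config.rng(2)
    chrom_sizes = config.chrom_sizes()
    control_levels = {chrom: np.full(length, config.marked_level)
                      for chrom, length in config.chroms}
    tracks: dict[str, CoverageTrack] = {}
    infos: list[SampleInfo] = []
    for genotype in config.genotypes:
        mark_levels = expected_level(config, truth, genotype)
        for antibody, levels in (("mark", mark_levels), ("control", control_levels)):
            rates = _segment_rates(config, levels)
            for rep in range(1, config.replicates + 1):
                lo, hi = config.jitter
                factor = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                data = {}
                total = 0.0
                for chrom, (starts, ends, lam) in rates.items():
                    expected = lam * factor
                    if config.noise == "poisson":
                        values = rng.poisson(expected).astype(np.float64)
                    else:
                        values = expected.copy()
                    total += float(values.sum())
                    keep = values > 0
                    data[chrom] = (starts[keep], ends[keep], values[keep])
                sample_id = f"{genotype}_{antibody}_r{rep}"
                tracks[sample_id] = CoverageTrack(data, chrom_sizes)
                infos.append(SampleInfo(sample_id=sample_id, genotype=genotype,
                                        antibody=antibody, replicate=rep,
                                        library_total=total, seed=config.seed))
    return tracks, Manifest(infos)


def simulate_peaks(config: SimConfig, truth: SimTruth) -> dict[str, list[GenomicInterval]]:
    """Per-genotype reproducible-peak stand-ins.

    Peak calling is upstream of this package; the synthetic peaks are
    the marked gene bodies (genes retain a peak as long as their level
    stays above background) plus the ITR in genotypes where the ectopic
    level exceeds background.
    """
    peaks: dict[str, list[GenomicInterval]] = {}
    for genotype in config.genotypes:
        eff = config.effect(genotype)
        out = []
        for gene in truth.genes:
            if gene.name not in truth.marked_genes:
                continue
            lvl = config.marked_level * (
                eff.gene_effect if gene.name in truth.effect_genes else 1.0
            )
            if lvl > config.background_level:
                out.append(GenomicInterval(gene.chrom, gene.start, gene.end,
                                           name=f"{genotype}_peak_{gene.name}"))
        if eff.itr_level * config.marked_level > config.background_level:
            out.append(GenomicInterval(truth.itr.chrom, truth.itr.start, truth.itr.end,
                                       name=f"{genotype}_peak_itr"))
        peaks[genotype] = out
    return peaks


def _expr_gene_ids(config: SimConfig) -> list[str]:
    return [_gene_id(i) for i in range(config.n_expr_genes)]


def simulate_counts_matrix(
    config: SimConfig, truth: SimTruth | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Negative-binomial count matrix (genes x samples) with planted DE.

    The expression universe has ``n_expr_genes`` genes; the first
    ``n_genes`` ids coincide with the toy genome's annotated genes so
    mark calls and expression can be integrated. Per-gene base means
    are log-normal around ``expr_mean``; DE genes are shifted by their
    planted log2 effect in ``de_genotype`` samples; counts are NB with
    the configured dispersion.
    """
    config.validate()
    if len(config.genotypes) < 2 or config.expr_replicates < 2:
        raise ConfigError("need >= 2 genotypes and >= 2 replicates for a count matrix")
    if truth is None:
        truth = build_toy_genome(config).truth
    gene_ids = _expr_gene_ids(config)
    rng = config.rng(3)
    base = rng.lognormal(mean=np.log(config.expr_mean), sigma=1.0, size=len(gene_ids))
    de = dict(truth.de_genes)
    shift = np.array([2.0 ** de.get(g, 0.0) for g in gene_ids])
    n_nb = 1.0 / config.nb_dispersion
    columns = {}
    for genotype in config.genotypes:
        mu = base * shift if genotype == config.de_genotype else base
        p = n_nb / (n_nb + mu)
        for rep in range(1, config.expr_replicates + 1):
            columns[f"{genotype}_rna_r{rep}"] = rng.negative_binomial(n_nb, p)
    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return counts, de


def simulate_deg_table(
    config: SimConfig, truth: SimTruth, genotype: str | None = None
) -> pd.DataFrame:
    """Synthetic stand-in for an upstream differential-expression fit.

    Produces a (gene_id, log2FC, FDR) table for ``genotype`` vs the
    baseline: planted DE genes get their signed log2 effect plus small
    noise and vanishing FDR; null genes get near-zero log2FC and a
    uniform FDR.
    """
    config.validate()
    genotype = genotype or config.de_genotype
    if genotype not in config.genotypes:
        raise ConfigError(f"unknown genotype {genotype!r}")
    gene_ids = _expr_gene_ids(config)
    rng = config.rng(4)
    is_de = np.array([g in truth.de_genes for g in gene_ids]) if genotype == config.de_genotype \
        else np.zeros(len(gene_ids), dtype=bool)
    planted = np.array([truth.de_genes.get(g, 0.0) for g in gene_ids])
    log2fc = np.where(is_de, planted + rng.normal(0, 0.1, len(gene_ids)),
                      rng.normal(0, 0.2, len(gene_ids)))
    fdr = np.where(is_de, 10.0 ** (-rng.uniform(6, 30, len(gene_ids))),
                   rng.uniform(0, 1, len(gene_ids)))
    return pd.DataFrame({"gene_id": gene_ids, "log2FC": log2fc, "FDR": fdr})


def calibrated_scale(
    config: SimConfig, truth: SimTruth, genotype: str,
    baseline: str | None = None, target_delta: float = 1.0, bin_size: int = 1000,
) -> float:
    """Normalization scale at which the planted effect-gene delta hits target.

    Closed form from the generator's expectations: a bin fully inside an
    effect gene has expected normalized value
    scale x bin_mass / total_reads with bin_mass = level x bin_size x
    segment x depth and total_reads = depth x signal area, so the scale
    that makes the genotype-vs-baseline delta equal ``target_delta``
    follows directly. Used by the demo so the default +/-0.5
    thresholds sit at half the planted effect.
    """
    baseline = baseline or config.baseline_genotype
    lvl_a = config.marked_level * config.effect(genotype).gene_effect
    lvl_b = config.marked_level * config.effect(baseline).gene_effect
    area_a = signal_area(config, truth, genotype)
    area_b = signal_area(config, truth, baseline)
    per_bp = lvl_a / area_a - lvl_b / area_b
    if per_bp == 0:
        raise ConfigError(f"no planted effect difference between {genotype} and {baseline}")
    delta_scale1 = bin_size * config.segment * per_bp
    return abs(target_delta / delta_scale1)


def expected_bin_values(
    config: SimConfig, truth: SimTruth, genotype: str, grid: BinGrid, scale: float,
) -> np.ndarray:
    """Expected normalized per-bin signal (ratio of expectations)."""
    track = expected_track(config, truth, genotype)
    return normalize(bin_counts(track, grid), track.total_value(), scale)


def planted_bin_calls(
    config: SimConfig, truth: SimTruth, grid: BinGrid, scale: float,
    genotype: str, baseline: str | None = None,
    gain_threshold: float = 0.5, loss_threshold: float = -0.5,
) -> pd.DataFrame:
    """Ground-truth bin calls: classify the noise-free expected deltas."""
    baseline = baseline or config.baseline_genotype
    delta = (expected_bin_values(config, truth, genotype, grid, scale)
             - expected_bin_values(config, truth, baseline, grid, scale))
    out = grid.frame()
    out["delta"] = delta
    out["call"] = classify_deltas(delta, gain_threshold, loss_threshold)
    return out
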