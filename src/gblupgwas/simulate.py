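"""Synthetic genotype panels and phenotypes with a planted QTL.

The generator emulates a diploid SNP panel with block linkage
disequilibrium and a quantitative trait of controlled heritability:

* Genotypes: each individual carries two independent haplotypes.  Within a
  haplotype block of consecutive markers, the alleles share a latent
  Gaussian factor with correlation ``within_block_corr``, thresholded at
  the per-marker allele frequency (a Gaussian copula).  Blocks are
  independent and never span chromosomes; positions sit on a regular grid.
* Phenotypes: y = mu + QTL term + optional polygenic term + residual.  The
  QTL effect is specified in trait-standard-deviation units; the polygenic
  term spreads the remaining genetic variance over all other markers; the
  residual is scaled so the realized heritability matches the target.

Defaults mirror a small horse GWAS panel: 630 individuals and a trait
heritability of 0.56.  All randomness flows from a single integer seed,
so identical configurations give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import GenotypePanel, center_genotypes

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_genotypes_tsv",
    "write_map_tsv",
    "write_phenotypes_tsv",
    "write_truth_tsv",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one simulated data set."""

    n_individuals: int = 630
    n_markers: int = 1000
    n_chromosomes: int = 2
    ld_block_size: int = 5
    within_block_corr: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    qtl_index: int | None = None
    qtl_effect: float = 0.0
    h2_target: float = 0.56
    polygenic_background: bool = True
    mean: float = 0.0
    bp_spacing: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_markers < 1:
            raise ValueError("need at least 2 individuals and 1 marker")
        if self.n_chromosomes < 1 or self.n_chromosomes > self.n_markers:
            raise ValueError("invalid number of chromosomes")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.h2_target < 1.0):
            raise ValueError("h2_target must be in [0, 1)")
        if self.qtl_index is not None and not (0 <= self.qtl_index < self.n_markers):
            raise ValueError("qtl_index out of range")


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype, for recovery tests."""

    qtl_index: int | None
    qtl_effect: float
    realized_h2: float
    allele_freq: np.ndarray
    marker_effects: np.ndarray
    var_genetic: float
    var_residual: float
    sigma2_a_marker: float  # realized per-marker effect variance of the polygenic term


def _chromosome_labels(n_markers: int, n_chromosomes: int) -> np.ndarray:
    sizes = [len(c) for c in np.array_split(np.arange(n_markers), n_chromosomes)]
    return np.repeat([str(i + 1) for i in range(n_chromosomes)], sizes)


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Draw a diploid dosage panel with Gaussian-copula block LD."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers
    maf = rng.uniform(*config.maf_range, size=m)
    thresh = stats.norm.ppf(maf)
    chrom = _chromosome_labels(m, config.n_chromosomes)
    rho = config.within_block_corr

    dosage = np.zeros((n, m))
    for _hap in range(2):
        latent = np.empty((n, m))
        # blocks are runs of ld_block_size markers within one chromosome
        start = 0
        for c in pd.unique(chrom):
            c_len = int(np.sum(chrom == c))
            for b0 in range(start, start + c_len, config.ld_block_size):
                b1 = min(b0 + config.ld_block_size, start + c_len)
                shared = rng.standard_normal((n, 1))
                eps = rng.standard_normal((n, b1 - b0))
                latent[:, b0:b1] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
            start += c_len
        dosage += latent < thresh

    positions = np.empty(m, dtype=np.int64)
    start = 0
    for c in pd.unique(chrom):
        c_len = int(np.sum(chrom == c))
        positions[start : start + c_len] = (np.arange(c_len) + 1) * config.bp_spacing
        start += c_len

    return GenotypePanel(
        dosages=dosage,
        marker_ids=[f"snp{j:05d}" for j in range(m)],
        chromosome=chrom,
        position_bp=positions,
        individual_ids=[f"ind{i:05d}" for i in range(n)],
    )


def simulate_phenotypes(
    panel: GenotypePanel,
    qtl: tuple[int, float] | None = None,
    h2_target: float = 0.56,
    polygenic_background: bool = True,
    seed: int = 0,
    mean: float = 0.0,
) -> tuple[np.ndarray, SimTruth]:
    """Simulate y = mu + QTL + polygenic + residual at a target heritability.

    The QTL effect is in trait-sd units (total phenotypic variance is close
    to 1).  The polygenic term receives the genetic variance left over after
    the QTL; the residual is rescaled empirically so the realized h2 matches
    ``h2_target`` closely.  A nonzero QTL effect with ``h2_target = 0`` is
    contradictory and raises.
    """
    rng = np.random.default_rng(seed)
    n, m = panel.n_individuals, panel.n_markers
    Z = center_genotypes(panel)

    qtl_index, qtl_effect = (None, 0.0) if qtl is None else (int(qtl[0]), float(qtl[1]))
    if qtl_effect != 0.0 and h2_target == 0.0:
        raise ValueError("h2_target = 0 contradicts a nonzero QTL effect")
    if qtl_index is not None and not (0 <= qtl_index < m):
        raise ValueError("qtl_index out of range")

    effects = np.zeros(m)
    g_qtl = np.zeros(n)
    if qtl_index is not None and qtl_effect != 0.0:
        effects[qtl_index] = qtl_effect
        g_qtl = qtl_effect * Z[:, qtl_index]
    var_qtl = float(np.var(g_qtl))
    if var_qtl > h2_target and h2_target > 0.0:
        raise ValueError(
            f"QTL alone explains {var_qtl:.3f} of variance, more than "
            f"h2_target = {h2_target}"
        )

    sigma2_a_marker = 0.0
    g_poly = np.zeros(n)
    if polygenic_background and h2_target > 0.0:
        target = h2_target - var_qtl
        u = rng.standard_normal(m)
        if qtl_index is not None:
            u[qtl_index] = 0.0
        raw = Z @ u
        sd_raw = float(np.std(raw))
        if target > 0.0 and sd_raw > 0.0:
            scale = np.sqrt(target) / sd_raw
            u *= scale
            g_poly = raw * scale
            sigma2_a_marker = scale * scale
            effects += u

    g = g_qtl + g_poly
    var_g = float(np.var(g))
    e = rng.standard_normal(n)
    if var_g > 0.0 and 0.0 < h2_target < 1.0:
        sigma_e = np.sqrt(var_g * (1.0 - h2_target) / h2_target)
    else:
        sigma_e = 1.0
    e = e / np.std(e) * sigma_e
    var_e = float(np.var(e))

    y = mean + g + e
    realized_h2 = var_g / (var_g + var_e) if var_g + var_e > 0.0 else 0.0
    truth = SimTruth(
        qtl_index=qtl_index,
        qtl_effect=qtl_effect,
        realized_h2=realized_h2,
        allele_freq=panel.allele_freq.copy(),
        marker_effects=effects,
        var_genetic=var_g,
        var_residual=var_e,
        sigma2_a_marker=sigma2_a_marker,
    )
    return y, truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypePanel, np.ndarray, SimTruth]:
    """Genotypes plus phenotypes from one config (phenotype seed = seed + 1)."""
    panel = simulate_genotypes(config)
    qtl = None
    if config.qtl_index is not None and config.qtl_effect != 0.0:
        qtl = (config.qtl_index, config.qtl_effect)
    y, truth = simulate_phenotypes(
        panel,
        qtl=qtl,
        h2_target=config.h2_target,
        polygenic_background=config.polygenic_background,
        seed=config.seed + 1,
        mean=config.mean,
    )
    return panel, y, truth


# ---------------------------------------------------------------------------
# Writers (same TSV dialects model_core reads)
# ---------------------------------------------------------------------------

def write_genotypes_tsv(panel: GenotypePanel, path) -> None:
    ids = panel.individual_ids or [f"ind{i:05d}" for i in range(panel.n_individuals)]
    df = pd.DataFrame(panel.dosages, columns=panel.marker_ids)
    df = df.astype("Int64")
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_map_tsv(panel: GenotypePanel, path) -> None:
    panel.marker_map.to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(individual_ids, y, path, trait: str = "trait") -> None:
    pd.DataFrame({"id": individual_ids, trait: y}).to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: SimTruth, panel: GenotypePanel, path) -> None:
    """Sidecar table: per-marker true effects plus scalar truth as comments."""
    header = (
        f"# qtl_index={truth.qtl_index}\tqtl_effect={truth.qtl_effect}\t"
        f"realized_h2={truth.realized_h2:.6f}\tvar_genetic={truth.var_genetic:.6f}\t"
        f"var_residual={truth.var_residual:.6f}\n"
    )
    df = pd.DataFrame(
        {
            "id": panel.marker_ids,
            "allele_freq": truth.allele_freq,
            "true_effect": truth.marker_effects,
        }
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
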