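"""Synthetic genotype/phenotype simulator with family structure and local LD.

The generator emulates the structure a marker-based predictor exploits:

* founders drawn per marker from Binomial(2, p_j) with p_j ~ U(maf_range);
* local LD induced by a first-order Markov copying process along each
  chromosome (an allele is copied from the previous marker with probability
  ``ld_rho``, otherwise drawn fresh);
* within-family kinship created by gene-dropping: each offspring inherits one
  recombination-free chromosome copy from each of two founder parents;
* a minority of causal loci with additive effects plus pairwise epistatic
  (centered-product) interactions, rescaled to a target heritability;
* uniform missingness and, optionally, extra appended markers that each
  violate one QC criterion.

Phenotypes are standardized to mean 0 / variance 1 over the cohort at
simulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .genotype_io import GenotypeMatrix, MarkerMap, PhenotypeTable

import pandas as pd


@dataclass
class SimConfig:
    n_families: int = 40
    offspring_per_family: int = 8
    n_founders_per_family: int = 2
    n_markers: int = 2000
    n_chromosomes: int = 10
    ld_rho: float = 0.3          # adjacent-marker copy probability in [0,1)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_additive: int = 20
    n_causal_epistatic_pairs: int = 5
    h2: float = 0.7              # genetic fraction of phenotypic variance
    missing_rate: float = 0.02
    qc_fail_markers: int = 0
    equal_additive_effects: bool = False  # unit effects instead of N(0,1)
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1 or self.n_markers < 1 or self.n_chromosomes < 1:
            raise ConfigError("need >=1 family, marker and chromosome")
        if self.n_founders_per_family < 2 and self.offspring_per_family > 0:
            raise ConfigError("gene-dropping needs >=2 founders per family")
        if self.n_founders_per_family < 1:
            raise ConfigError("need >=1 founder per family")
        if not (0 <= self.ld_rho < 1):
            raise ConfigError("ld_rho must be in [0,1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.h2 <= 1):
            raise ConfigError("h2 must be in [0,1]")
        if self.n_causal_additive + 2 * self.n_causal_epistatic_pairs > self.n_markers:
            raise ConfigError("more causal loci than markers")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0,1)")

    @property
    def n_samples(self) -> int:
        return self.n_families * (self.n_founders_per_family + self.offspring_per_family)


@dataclass
class SimTruth:
    causal_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    causal_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    epistatic_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    genetic_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    family_ids: np.ndarray = field(default_factory=lambda: np.empty(0, object))


def _chromosome_sizes(n_markers: int, n_chromosomes: int) -> list[int]:
    base = n_markers // n_chromosomes
    sizes = [base] * n_chromosomes
    for c in range(n_markers - base * n_chromosomes):
        sizes[c] += 1
    return [s for s in sizes if s > 0]


def _draw_haplotype(rng: np.random.Generator, p: np.ndarray, sizes: list[int],
                    ld_rho: float) -> np.ndarray:
    """One founder haplotype: Markov copying chain restarted per chromosome."""
    hap = np.empty(p.size, dtype=np.int8)
    start = 0
    for size in sizes:
        fresh = rng.random(size) < p[start:start + size]
        copy = rng.random(size) < ld_rho
        copy[0] = False
        hap[start] = fresh[0]
        for j in range(1, size):
            hap[start + j] = hap[start + j - 1] if copy[j] else fresh[j]
        start += size
    return hap


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate the genotype panel; the returned truth carries family labels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sizes = _chromosome_sizes(cfg.n_markers, cfg.n_chromosomes)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)

    sample_ids: list[str] = []
    family_ids: list[str] = []
    hap_rows: list[tuple[np.ndarray, np.ndarray]] = []
    for fam in range(cfg.n_families):
        fam_label = f"F{fam:03d}"
        founders = []
        for k in range(cfg.n_founders_per_family):
            h1 = _draw_haplotype(rng, p, sizes, cfg.ld_rho)
            h2 = _draw_haplotype(rng, p, sizes, cfg.ld_rho)
            founders.append((h1, h2))
            sample_ids.append(f"{fam_label}_P{k}")
            family_ids.append(fam_label)
            hap_rows.append((h1, h2))
        for o in range(cfg.offspring_per_family):
            pa, pb = rng.choice(cfg.n_founders_per_family, size=2, replace=False)
            child = []
            for parent in (founders[pa], founders[pb]):
                hap = np.empty(cfg.n_markers, dtype=np.int8)
                start = 0
                for size in sizes:  # one whole chromosome copy per parent
                    which = rng.integers(2)
                    hap[start:start + size] = parent[which][start:start + size]
                    start += size
                child.append(hap)
            sample_ids.append(f"{fam_label}_O{o}")
            family_ids.append(fam_label)
            hap_rows.append((child[0], child[1]))

    dosages = np.array([h1 + h2 for h1, h2 in hap_rows], dtype=float)

    # chromosome-ordered marker map, 10 kb spacing
    chroms, positions = [], []
    for c, size in enumerate(sizes, start=1):
        chroms.extend([str(c)] * size)
        positions.extend(10_000 * (j + 1) for j in range(size))

    if cfg.qc_fail_markers:
        extra = _qc_failing_columns(rng, cfg.qc_fail_markers, dosages.shape[0])
        dosages = np.hstack([dosages, extra])
        last_chrom, last_pos = chroms[-1], positions[-1]
        for j in range(cfg.qc_fail_markers):
            chroms.append(last_chrom)
            positions.append(last_pos + 10_000 * (j + 1))

    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        # keep every marker observable: never blank a full column
        for j in np.where(mask.all(axis=0))[0]:
            mask[rng.integers(dosages.shape[0]), j] = False
        dosages = dosages.copy()
        dosages[mask] = np.nan

    n_total = dosages.shape[1]
    mmap = MarkerMap(
        ids=np.array([f"snp{j}" for j in range(n_total)], dtype=object),
        chromosomes=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
    )
    g = GenotypeMatrix(dosages, sample_ids, mmap)
    truth = SimTruth(family_ids=np.array(family_ids, dtype=object))
    return g, truth


def _qc_failing_columns(rng: np.random.Generator, k: int, n: int) -> np.ndarray:
    """k columns that each violate one QC criterion (cycling through three)."""
    cols = np.empty((n, k))
    for j in range(k):
        kind = j % 3
        if kind == 0:  # call rate 0.5
            col = rng.binomial(2, 0.3, size=n).astype(float)
            col[rng.permutation(n)[: n // 2]] = np.nan
        elif kind == 1:  # MAF below any reasonable floor
            col = np.zeros(n)
            col[rng.integers(n)] = 1.0  # single het -> maf ~ 1/(2n)
        else:  # HWE: half AA / half aa, no heterozygotes
            col = np.zeros(n)
            col[: n // 2] = 2.0
            col = col[rng.permutation(n)]
        cols[:, j] = col
    return cols


def simulate_phenotype(
    g: GenotypeMatrix, cfg: SimConfig, truth: SimTruth | None = None,
    trait: str = "trait",
) -> tuple[PhenotypeTable, SimTruth]:
    """Additive + pairwise-epistatic genetic values at target heritability.

    Genetic value g_i = sum_k a_k x_ik + sum_(i,j) b_ij (x_i - mean)(x_j - mean)
    with effects drawn N(0,1) and the genetic / noise components rescaled so
    var(genetic)/var(total) = h2. The phenotype is standardized to mean 0,
    variance 1 over the cohort.
    """
    cfg.validate()
    n_causal = cfg.n_causal_additive + 2 * cfg.n_causal_epistatic_pairs
    if cfg.h2 == 1.0 and n_causal == 0:
        raise ConfigError("h2=1 requires at least one causal locus")
    truth = truth or SimTruth()
    rng = np.random.default_rng(cfg.seed + 1_000_003)

    n, m_total = g.dosages.shape
    m_core = min(cfg.n_markers, m_total)  # appended QC-fail columns never causal
    X = g.dosages[:, :m_core].copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(~np.isfinite(X))
    X[nan_r, nan_c] = col_mean[nan_c]

    idx = rng.permutation(m_core)[:n_causal]
    add_idx = idx[: cfg.n_causal_additive]
    epi_idx = idx[cfg.n_causal_additive:]
    a = (np.ones(cfg.n_causal_additive) if cfg.equal_additive_effects
         else rng.standard_normal(cfg.n_causal_additive))
    genetic = X[:, add_idx] @ a if cfg.n_causal_additive else np.zeros(n)

    pairs: list[tuple[int, int, float]] = []
    Xc = X - X.mean(axis=0)
    for k in range(cfg.n_causal_epistatic_pairs):
        i, j = int(epi_idx[2 * k]), int(epi_idx[2 * k + 1])
        b = float(rng.standard_normal())
        genetic = genetic + b * Xc[:, i] * Xc[:, j]
        pairs.append((i, j, b))

    noise = rng.standard_normal(n)
    var_g = genetic.var()
    var_e = noise.var()
    if cfg.h2 > 0 and var_g > 0:
        genetic = genetic * np.sqrt(cfg.h2 / var_g)
    else:
        genetic = np.zeros(n)
    noise = noise * np.sqrt((1.0 - cfg.h2) / var_e) if cfg.h2 < 1 else np.zeros(n)

    y = genetic + noise
    mu, sd = y.mean(), y.std()
    if sd == 0:
        raise ConfigError("degenerate phenotype: zero variance")
    y = (y - mu) / sd
    genetic_std = (genetic - genetic.mean()) / sd

    truth.causal_indices = np.sort(add_idx)
    truth.causal_effects = a[np.argsort(add_idx)]
    truth.epistatic_pairs = pairs
    truth.genetic_values = genetic_std
    table = PhenotypeTable(pd.DataFrame({trait: y}, index=list(g.sample_ids)))
    return table, truth


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Genotypes + phenotype in one call (shared truth)."""
    g, truth = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotype(g, cfg, truth)
    return g, pheno, truth
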