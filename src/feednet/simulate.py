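"""Synthetic populations for the feed-efficiency analysis pipeline.

Generates beef-cattle-like data with the statistical structure the
downstream stages assume: biallelic dosages with block LD, base traits
(daily feed intake FI, average daily gain ADG, final weight FW) with a
target genetic correlation structure and moderate heritability, the
fixed-effect design of a multi-year fattening test (contemporary-group
year, dam-age class, twinning, final-age covariate), and a synthetic
gene annotation. Defaults emulate a population of 789 genotyped
Charolais young bulls: trait means/SDs FI 10.63 +/- 1.23 kg DM/d,
ADG 1.44 +/- 0.19 kg/d, FW 695 +/- 87 kg; heritabilities 0.35; genetic
correlations r_g(FI,ADG) = 0.44, r_g(FI,FW) = 0.76, r_g(ADG,FW) = 0.80.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    BASE_TRAITS,
    ConfigError,
    GenotypeMatrix,
)

__all__ = [
    "SimConfig",
    "SimPopulation",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_annotation",
    "simulate_population",
    "DEFAULT_GENETIC_CORR",
    "TRAIT_MEANS",
    "TRAIT_SDS",
]

TRAIT_MEANS = {"FI": 10.63, "ADG": 1.44, "FW": 695.0}
TRAIT_SDS = {"FI": 1.23, "ADG": 0.19, "FW": 87.0}

#: genetic correlations among the recorded base traits (pedigree-scale
#: estimates for French Charolais young bulls)
DEFAULT_GENETIC_CORR = pd.DataFrame(
    [[1.00, 0.44, 0.76], [0.44, 1.00, 0.80], [0.76, 0.80, 1.00]],
    index=list(BASE_TRAITS),
    columns=list(BASE_TRAITS),
)

_DAM_AGE_LABELS = ["3", "4", "5", "6+"]


def _default_h2():
    return {t: 0.35 for t in BASE_TRAITS}


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    The defaults are the study conditions the generator emulates
    (sample size, trait scales, fixed-effect structure); see the
    methods note for the rationale behind each.
    """

    n_individuals: int = 789
    n_variants: int = 20000
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 300
    heritabilities: dict = field(default_factory=_default_h2)
    genetic_corr: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_GENETIC_CORR.copy()
    )
    n_years: int = 22
    dam_age_classes: int = 4
    twinning_rate: float = 0.04
    test_days: float = 180.0
    final_age_mean: float = 455.0
    final_age_sd: float = 10.0
    ld_block_size: int = 10
    ld_strength: float = 0.8
    n_chromosomes: int = 29
    #: fraction of causal variants private to a single trait (0 = fully
    #: pleiotropic architecture)
    private_causal_fraction: float = 0.0
    #: optional number of sire families; None = unstructured population
    sire_families: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_causal > self.n_variants:
            raise ConfigError("n_causal cannot exceed n_variants")
        corr = np.asarray(self.genetic_corr, dtype=float)
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ConfigError("genetic_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ConfigError("genetic_corr must be positive semi-definite")
        for t, h2 in self.heritabilities.items():
            if not (0.0 <= h2 <= 1.0):
                raise ConfigError(f"heritability of {t} outside [0, 1]: {h2}")
        if not (0.0 <= self.twinning_rate <= 1.0):
            raise ConfigError("twinning_rate must be a probability")

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["genetic_corr"] = np.asarray(self.genetic_corr).tolist()
        d["genetic_corr_traits"] = list(self.genetic_corr.columns)
        d["maf_range"] = list(self.maf_range)
        return json.dumps(d, indent=2, default=float)


@dataclass
class SimPopulation:
    """A simulated population plus the ground truth behind it."""

    genotypes: GenotypeMatrix
    true_breeding_values: pd.DataFrame
    traits: pd.DataFrame
    annotation: pd.DataFrame
    causal_ids: list
    causal_effects: pd.DataFrame
    config: SimConfig


# -------------------------------------------------------------- genotypes

def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple = (0.05, 0.5),
    ld_block_size: int = 10,
    seed: int = 0,
    ld_strength: float = 0.8,
    n_chromosomes: int = 29,
    sire_families: Optional[int] = None,
) -> GenotypeMatrix:
    """Simulate biallelic dosages with block linkage disequilibrium.

    Haplotypes are built by latent-uniform copying: within an LD block
    each haplotype either copies its latent draw from the previous
    variant (probability ``ld_strength``) or redraws it, so marginal
    allele frequencies are exact and adjacent variants are positively
    correlated. Blocks never span chromosome boundaries. With
    ``sire_families`` set, each individual inherits one intact paternal
    haplotype from its family's sire.
    """
    if n < 2 or m < 1:
        raise ConfigError("need n >= 2 individuals and m >= 1 variants")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {maf_range}")
    if not (0.0 <= ld_strength < 1.0):
        raise ConfigError("ld_strength must be in [0, 1)")
    rng = np.random.default_rng(seed)

    mafs = rng.uniform(lo, hi, size=m)
    n_chrom = min(n_chromosomes, m)
    chrom_sizes = [len(a) for a in np.array_split(np.arange(m), n_chrom)]
    chroms, positions = [], []
    for c, size in enumerate(chrom_sizes, start=1):
        chroms.extend([str(c)] * size)
        positions.extend(np.cumsum(rng.integers(500, 1500, size=size)).tolist())

    def _haplotypes(n_hap: int) -> np.ndarray:
        """(n_hap, m) binary haplotypes via latent-uniform copying."""
        hap = np.empty((n_hap, m), dtype=np.int8)
        u = np.empty(n_hap)
        j0 = 0
        for size in chrom_sizes:
            for j in range(j0, j0 + size):
                fresh = rng.uniform(size=n_hap)
                if j == j0 or (j - j0) % ld_block_size == 0:
                    u = fresh
                else:
                    keep = rng.uniform(size=n_hap) < ld_strength
                    u = np.where(keep, u, fresh)
                hap[:, j] = (u < mafs[j]).astype(np.int8)
            j0 += size
        return hap

    if sire_families:
        sire_haps = _haplotypes(2 * sire_families)
        maternal = _haplotypes(n)
        fam = rng.integers(0, sire_families, size=n)
        which = rng.integers(0, 2, size=n)
        paternal = sire_haps[2 * fam + which]
        dosages = (paternal + maternal).astype(float)
    else:
        haps = _haplotypes(2 * n)
        dosages = (haps[0::2] + haps[1::2]).astype(float)

    variants = pd.DataFrame(
        {
            "variant_id": [f"SNP{i + 1:07d}" for i in range(m)],
            "chrom": chroms,
            "pos": positions,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


# ----------------------------------------------------------------- traits

def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition (handles rank deficiency)."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_traits(g: GenotypeMatrix, cfg: SimConfig):
    """Simulate base-trait phenotypes on top of a genotype matrix.

    Returns ``(traits, true_breeding_values, causal_ids, causal_effects)``.

    Per trait, phenotype = mean + fixed effects + genetic value +
    residual. Causal effects are drawn from a multivariate normal across
    traits with correlation ``cfg.genetic_corr`` (complete pleiotropy
    unless ``private_causal_fraction`` > 0); genetic values are scaled
    so that the realized genetic variance is exactly h2 * sigma_P^2 and
    residuals are drawn with variance (1 - h2) * sigma_P^2. The table
    carries initial/final weights and the test duration so ADG and
    metabolic mid-test weight are derivable downstream.
    """
    traits = list(cfg.genetic_corr.columns)
    missing = [t for t in BASE_TRAITS if t not in traits]
    if missing:
        raise ConfigError(f"genetic_corr must cover base traits, missing {missing}")
    corr = np.asarray(cfg.genetic_corr, dtype=float)
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ConfigError("genetic_corr must be positive semi-definite")

    n, m = g.n_individuals, g.n_variants
    n_traits = len(traits)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    causal_idx = np.sort(rng.choice(m, size=cfg.n_causal, replace=False))
    causal_ids = g.variants["variant_id"].to_numpy()[causal_idx].tolist()

    # effects: MVN rows with the target cross-trait correlation
    raw = rng.standard_normal((cfg.n_causal, n_traits))
    effects = raw @ _psd_factor(corr).T
    if cfg.private_causal_fraction > 0:
        n_priv = int(round(cfg.private_causal_fraction * cfg.n_causal))
        priv = rng.choice(cfg.n_causal, size=n_priv, replace=False)
        owner = rng.integers(0, n_traits, size=n_priv)
        mask = np.ones((cfg.n_causal, n_traits))
        mask[priv, :] = 0.0
        mask[priv, owner] = 1.0
        effects = effects * mask

    x_causal = np.nan_to_num(g.dosages[:, causal_idx])
    g_raw = x_causal @ effects  # (n, n_traits)

    sds = np.array([TRAIT_SDS.get(t, 1.0) for t in traits])
    means = np.array([TRAIT_MEANS.get(t, 0.0) for t in traits])
    h2 = np.array([cfg.heritabilities.get(t, 0.35) for t in traits])

    tbv = np.zeros_like(g_raw)
    for j in range(n_traits):
        sd_g = g_raw[:, j].std()
        if h2[j] > 0 and sd_g > 0:
            tbv[:, j] = (g_raw[:, j] - g_raw[:, j].mean()) * (
                np.sqrt(h2[j]) * sds[j] / sd_g
            )
    resid = rng.standard_normal((n, n_traits)) * (np.sqrt(1.0 - h2) * sds)

    # fixed-effect design: class effects ~ N(0, (0.5 sigma_P)^2)
    year = rng.integers(0, cfg.n_years, size=n)
    dam = rng.integers(0, cfg.dam_age_classes, size=n)
    twin = rng.uniform(size=n) < cfg.twinning_rate
    final_age = rng.normal(cfg.final_age_mean, cfg.final_age_sd, size=n)

    year_eff = rng.standard_normal((cfg.n_years, n_traits)) * (0.5 * sds)
    dam_eff = rng.standard_normal((cfg.dam_age_classes, n_traits)) * (0.5 * sds)
    twin_eff = -0.3 * sds  # twins grow slower and eat less
    age_slope = 0.25 * sds / cfg.final_age_sd
    fixed = (
        year_eff[year]
        + dam_eff[dam]
        + np.outer(twin.astype(float), twin_eff)
        + np.outer(final_age - cfg.final_age_mean, age_slope)
    )

    pheno = means + fixed + tbv + resid
    ptab = pd.DataFrame(pheno, columns=traits)

    dam_labels = [_DAM_AGE_LABELS[min(d, len(_DAM_AGE_LABELS) - 1)] for d in dam]
    out = pd.DataFrame(
        {
            "animal_id": [f"IND{i + 1:06d}" for i in range(n)],
            "initial_weight": ptab["FW"] - ptab["ADG"] * cfg.test_days,
            "final_weight": ptab["FW"],
            "test_days": cfg.test_days,
            "FI": ptab["FI"],
            "year": [f"Y{y + 1:02d}" for y in year],
            "dam_age_class": dam_labels,
            "twinning": twin,
            "final_age": final_age,
        }
    )
    tbv_df = pd.DataFrame(tbv, columns=traits)
    tbv_df.insert(0, "animal_id", out["animal_id"])
    eff_df = pd.DataFrame(effects, columns=traits)
    eff_df.insert(0, "variant_id", causal_ids)
    return out, tbv_df, causal_ids, eff_df


# ------------------------------------------------------------- annotation

def simulate_annotation(
    g: GenotypeMatrix, n_genes: int, coverage_fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Place non-overlapping gene intervals over the simulated genome.

    Genes are distributed across chromosomes proportionally to variant
    counts; within each chromosome one gene is placed per equal-width
    window at a random offset, sized so that about ``coverage_fraction``
    of variants fall inside a gene.
    """
    if not (0.0 < coverage_fraction <= 1.0):
        raise ConfigError("coverage_fraction must be in (0, 1]")
    if n_genes > g.n_variants:
        raise ConfigError("n_genes cannot exceed the number of variants")
    if n_genes < 1:
        raise ConfigError("need at least one gene")
    rng = np.random.default_rng(seed)
    var = g.variants

    chrom_order = var["chrom"].drop_duplicates().tolist()
    counts = var["chrom"].value_counts()
    sizes = np.array([counts[c] for c in chrom_order], dtype=float)
    # largest-remainder allocation of genes to chromosomes
    quota = n_genes * sizes / sizes.sum()
    alloc = np.floor(quota).astype(int)
    rem = n_genes - alloc.sum()
    if rem > 0:
        order = np.argsort(-(quota - alloc))
        alloc[order[:rem]] += 1

    rows = []
    gid = 0
    for c, n_g in zip(chrom_order, alloc):
        if n_g == 0:
            continue
        pos = var.loc[var["chrom"] == c, "pos"].to_numpy()
        m_c = len(pos)
        windows = np.array_split(np.arange(m_c), n_g)
        for w in windows:
            if len(w) == 0:
                continue
            span = max(1, int(round(coverage_fraction * len(w))))
            span = min(span, len(w))
            off = rng.integers(0, len(w) - span + 1)
            i0, i1 = w[off], w[off + span - 1]
            gid += 1
            rows.append((f"GENE{gid:06d}", c, int(pos[i0]), int(pos[i1]), "+"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# -------------------------------------------------------------- population

def simulate_population(cfg: SimConfig, n_genes: int = None,
                        gene_coverage: float = 0.35) -> SimPopulation:
    """Simulate genotypes, traits, and annotation in one deterministic call."""
    g = simulate_genotypes(
        cfg.n_individuals,
        cfg.n_variants,
        cfg.maf_range,
        cfg.ld_block_size,
        seed=np.random.SeedSequence([cfg.seed, 0]).generate_state(1)[0],
        ld_strength=cfg.ld_strength,
        n_chromosomes=cfg.n_chromosomes,
        sire_families=cfg.sire_families,
    )
    traits, tbv, causal_ids, effects = simulate_traits(g, cfg)
    if n_genes is None:
        n_genes = max(1, cfg.n_variants // 25)
    ann = simulate_annotation(
        g, n_genes, gene_coverage,
        seed=np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0],
    )
    return SimPopulation(
        genotypes=g,
        true_breeding_values=tbv,
        traits=traits,
        annotation=ann,
        causal_ids=causal_ids,
        causal_effects=effects,
        config=cfg,
    )
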