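"""Post-AWM quantitative genetics: z-score genomic correlations and
SNP-subset heritability contrasts.

The *genomic correlation* between two traits is the Pearson correlation
of their standardized SNP effects (z-scores) over the AWM's variant
rows — a summary-statistic proxy for genetic correlation restricted to
the co-associated variant set.

The *heritability contrast* asks how much phenotypic variance the
AWM-selected SNPs capture relative to an equally sized random panel:
GREML is run on a GRM built from each panel and the two SNP
heritabilities are reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .awm import AWMatrix
from .containers import GenotypeMatrix, ValidationError, VarianceComponents
from .gwas import compute_grm, fit_null_reml

__all__ = [
    "genomic_correlation",
    "greml_h2",
    "heritability_contrast",
    "HeritabilityContrast",
]


@dataclass
class HeritabilityContrast:
    trait: str
    selected: VarianceComponents
    random: VarianceComponents
    n_snps: int
    seed: int
    random_ids: list


def genomic_correlation(awm: AWMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlations of z-score columns over AWM rows."""
    if awm.n_variants < 3:
        raise ValidationError(
            f"genomic correlation needs >= 3 AWM rows, got {awm.n_variants}"
        )
    if len(awm.retained_traits) < 2:
        raise ValidationError("genomic correlation needs >= 2 retained traits")
    z = awm.z[awm.retained_traits].to_numpy(dtype=float)
    r = np.corrcoef(z, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=awm.retained_traits, columns=awm.retained_traits)


def greml_h2(
    y: np.ndarray, g: GenotypeMatrix, snp_subset
) -> VarianceComponents:
    """SNP heritability from a GRM built on ``snp_subset`` only."""
    ids = list(snp_subset)
    if len(ids) == 0:
        raise ValidationError("SNP subset is empty")
    grm = compute_grm(g, variant_ids=ids)
    return fit_null_reml(np.asarray(y, dtype=float), grm)


def heritability_contrast(
    y: np.ndarray,
    g: GenotypeMatrix,
    selected,
    seed: int = 0,
    trait: str = "",
    maf_matched: bool = False,
) -> HeritabilityContrast:
    """GREML heritability of a selected SNP panel vs a random control panel.

    The control panel is an equal-size draw (without replacement,
    seeded) from the variants outside the selected panel; with
    ``maf_matched`` the draw is stratified on deciles of the selected
    panel's MAF distribution.
    """
    sel = list(dict.fromkeys(selected))
    if len(sel) == 0:
        raise ValidationError("selected panel is empty")
    all_ids = g.variants["variant_id"].tolist()
    remaining = [v for v in all_ids if v not in set(sel)]
    if len(remaining) < len(sel):
        raise ValidationError(
            f"only {len(remaining)} non-selected variants remain; "
            f"cannot draw a control panel of {len(sel)}"
        )
    rng = np.random.default_rng(seed)
    if maf_matched:
        # greedy nearest-MAF matching without replacement, in a random
        # order so ties do not bias toward genome position
        maf = pd.Series(g.maf(), index=all_ids)
        pool = pd.Series(maf[remaining].to_numpy(),
                         index=remaining).sample(frac=1.0, random_state=seed)
        pool = pool.sort_values(kind="mergesort")
        random_ids = []
        for target in rng.permutation(maf[sel].to_numpy()):
            j = int(np.searchsorted(pool.to_numpy(), target))
            j = min(j, len(pool) - 1)
            if j > 0 and abs(pool.iloc[j - 1] - target) <= abs(pool.iloc[j] - target):
                j -= 1
            random_ids.append(pool.index[j])
            pool = pool.drop(pool.index[j])
    else:
        random_ids = rng.choice(remaining, size=len(sel), replace=False).tolist()

    return HeritabilityContrast(
        trait=trait,
        selected=greml_h2(y, g, sel),
        random=greml_h2(y, g, random_ids),
        n_snps=len(sel),
        seed=seed,
        random_ids=random_ids,
    )
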