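"""Shared data containers and error types.

The pipeline passes a small number of in-memory objects between stages:
a dosage matrix with variant metadata (:class:`GenotypeMatrix`), plain
pandas DataFrames for phenotype tables and gene annotation, and
:class:`VarianceComponents` for REML output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeednetError",
    "ConfigError",
    "DataFormatError",
    "NumericalError",
    "ValidationError",
    "GenotypeMatrix",
    "GRM",
    "VarianceComponents",
    "TRAITS",
    "BASE_TRAITS",
]

#: the six analysis traits, in canonical order
TRAITS = ("RFI", "RG", "FE", "FI", "FW", "ADG")

#: directly simulated / recorded traits; the others derive from them
BASE_TRAITS = ("FI", "ADG", "FW")


class FeednetError(Exception):
    """Base class; carries the CLI exit code."""

    exit_code = 1


class ConfigError(FeednetError):
    """Invalid configuration or parameter value."""

    exit_code = 2


class DataFormatError(FeednetError):
    """Malformed input file."""

    exit_code = 3


class NumericalError(FeednetError):
    """Numerical failure (non-convergence, degenerate system)."""

    exit_code = 4


class ValidationError(FeednetError):
    """Input data violates a documented precondition."""

    exit_code = 3


@dataclass
class GenotypeMatrix:
    """Individuals x variants allele dosages with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_variants)`` float array of counts of the A1
        allele, in ``[0, 2]``; ``NaN`` marks a missing genotype.
        Imputed (fractional) dosages are allowed.
    variants
        DataFrame with columns ``variant_id, chrom, pos, a1, a2``
        (positions 1-based).
    samples
        Individual identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D array")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValidationError(
                f"variant table has {len(self.variants)} rows but dosage "
                f"matrix has {self.dosages.shape[1]} columns"
            )
        if self.samples is None or len(self.samples) == 0:
            self.samples = [f"IND{i + 1:06d}" for i in range(self.dosages.shape[0])]
        if len(self.samples) != self.dosages.shape[0]:
            raise ValidationError("sample list length does not match dosage rows")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-variant A1 allele frequency (missing dosages ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        """Return a copy restricted to ``variant_ids`` (original order kept)."""
        wanted = set(variant_ids)
        mask = self.variants["variant_id"].isin(wanted).to_numpy()
        if mask.sum() == 0:
            raise ValidationError("variant subset is empty")
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            variants=self.variants.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
        )


@dataclass
class GRM:
    """Genomic relationship matrix (VanRaden method 1)."""

    matrix: np.ndarray
    n_snps_used: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VarianceComponents:
    """REML variance components for ``y = 1mu + u + e``.

    ``h2 = sigma_u2 / (sigma_u2 + sigma_e2)`` is the SNP heritability of
    the GRM used in the fit; ``se_h2`` is a delta-method standard error
    from the average-information matrix.
    """

    sigma_u2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool = True
    n_iter: int = 0
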