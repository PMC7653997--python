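"""Variant QC, genomic relationships, REML, and mixed-model association.

The association model per variant is

    y = 1*mu + x*b + u + e,   u ~ N(0, G su2),  e ~ N(0, I se2)

where ``y`` is a precorrected trait, ``x`` the allele dosage, ``G`` the
genomic relationship matrix (VanRaden method 1), and ``(su2, se2)`` are
variance components estimated once under the null model ``y = mu + u + e``
and then held fixed for every variant test (the standard MLMA scheme).
Tests use the eigendecomposition of G: rotating by its eigenvectors
diagonalizes the covariance, so each variant is a weighted least-squares
fit costing O(n).

The REML fit profiles the restricted likelihood down to the single
heritability parameter ``h2 = su2/(su2 + se2)`` on the eigenvalue scale
and maximizes it by bounded scalar search — exact for one random
effect. Standard errors come from the average-information (Fisher)
matrix at the optimum via the delta method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .containers import (
    GRM,
    GenotypeMatrix,
    NumericalError,
    ValidationError,
    VarianceComponents,
)

__all__ = [
    "QCThresholds",
    "compute_qc_table",
    "qc_filter_variants",
    "hwe_exact_p",
    "compute_grm",
    "GRMEigen",
    "fit_null_reml",
    "run_mlma",
    "bonferroni_threshold",
    "top_k_variants",
]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8


# -------------------------------------------------------------------- QC

@dataclass
class QCThresholds:
    """Variant-QC thresholds.

    Retention rules: call rate >= ``call_rate``; MAF strictly >
    ``maf``; HWE exact-test P >= ``hwe_p`` (strong deviations removed);
    imputation R2 strictly > ``r2`` when an R2 column is present.
    """

    call_rate: float = 0.90
    maf: float = 0.01
    hwe_p: float = 1e-4
    r2: float = 0.30

    def __post_init__(self):
        for name in ("call_rate", "maf", "hwe_p", "r2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"threshold {name} outside [0, 1]: {v}")


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test P-value (two-sided, by probability mass).

    Enumerates all heterozygote counts compatible with the observed
    allele counts and sums the probabilities of configurations no more
    likely than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # mid-range starting point, then recurse outward
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(hets))
    # start at the mode-ish midpoint
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1
    idx = {h: i for i, h in enumerate(hets)}
    probs[idx[mid]] = 1.0
    h = mid
    while h >= 2:
        # P(h-2)/P(h) = h*(h-1) / ((rare-h+2)*(2n-rare-h+2))
        probs[idx[h - 2]] = probs[idx[h]] * h * (h - 1) / (
            (n_rare - h + 2.0) * (2 * n - n_rare - h + 2.0)
        )
        h -= 2
    h = mid
    while h <= n_rare - 2:
        probs[idx[h + 2]] = probs[idx[h]] * (n_rare - h) * (2 * n - n_rare - h) / (
            (h + 2.0) * (h + 2.0 - 1.0)
        )
        h += 2
    probs /= probs.sum()
    p_obs = probs[idx[n_het]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def compute_qc_table(g: GenotypeMatrix, r2: pd.Series = None) -> pd.DataFrame:
    """Per-variant call rate, MAF and HWE exact P from hard genotypes.

    ``r2`` optionally maps variant_id -> imputation R2 and is merged in.
    Fractional dosages are rounded for the HWE genotype counts.
    """
    dos = g.dosages
    hard = np.rint(dos)
    hwe = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = hard[:, j]
        col = col[~np.isnan(col)]
        hwe[j] = hwe_exact_p(
            int((col == 1).sum()), int((col == 0).sum()), int((col == 2).sum())
        )
    out = pd.DataFrame(
        {
            "variant_id": g.variants["variant_id"].to_numpy(),
            "call_rate": g.call_rate(),
            "maf": g.maf(),
            "hwe_p": hwe,
        }
    )
    if r2 is not None:
        out["imputation_r2"] = out["variant_id"].map(r2)
    return out


def qc_filter_variants(qc: pd.DataFrame, thresholds: QCThresholds = None):
    """Apply the retention rules; returns ``(retained_ids, report)``.

    ``report`` counts, per filter, how many variants fail it (filters
    are assessed independently, so a variant can be counted by several).
    """
    thr = thresholds or QCThresholds()
    fails = {
        "call_rate": qc["call_rate"] < thr.call_rate,
        "maf": ~(qc["maf"] > thr.maf),
        "hwe": qc["hwe_p"] < thr.hwe_p,
    }
    if "imputation_r2" in qc.columns and qc["imputation_r2"].notna().any():
        fails["imputation_r2"] = ~(qc["imputation_r2"] > thr.r2)
    keep = ~np.logical_or.reduce(list(fails.values()))
    retained = qc.loc[keep, "variant_id"].tolist()
    report = {f"removed_{k}": int(v.sum()) for k, v in fails.items()}
    report["n_input"] = len(qc)
    report["n_retained"] = len(retained)
    if not retained:
        logger.warning("variant QC removed every variant")
    return retained, report


# -------------------------------------------------------------------- GRM

def compute_grm(g: GenotypeMatrix, variant_ids=None) -> GRM:
    """VanRaden method-1 GRM: ``Z Z' / (2 sum p(1-p))`` with
    frequency-centered dosages; monomorphic variants are excluded and
    missing dosages mean-imputed."""
    if g.n_individuals < 2:
        raise ValidationError("GRM needs at least 2 individuals")
    gm = g if variant_ids is None else g.subset_variants(variant_ids)
    dos = gm.dosages.copy()
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise NumericalError("all variants are monomorphic; GRM undefined")
    dos = dos[:, poly]
    p = p[poly]
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        logger.info("mean-imputing %d missing genotypes for GRM", nan_mask.sum())
        dos[nan_mask] = np.broadcast_to(2 * p, dos.shape)[nan_mask]
    Z = dos - 2 * p
    denom = 2.0 * np.sum(p * (1 - p))
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    return GRM(matrix=G, n_snps_used=int(poly.sum()))


# ------------------------------------------------------------------- REML

class GRMEigen:
    """Cached eigendecomposition of a GRM (computed once per trait set)."""

    def __init__(self, grm: GRM):
        d, U = np.linalg.eigh(grm.matrix)
        self.d = np.clip(d, 0.0, None)  # clip tiny negative eigenvalues
        self.U = U
        self.grm = grm

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self.U.T @ v


def _profiled_reml_neg2ll(h2, d, y_rot, x0_rot):
    """-2 * profiled restricted log-likelihood at heritability h2
    (total variance profiled out analytically)."""
    n = len(y_rot)
    v = h2 * d + (1.0 - h2)
    a = np.sum(x0_rot**2 / v)
    b = np.sum(x0_rot * y_rot / v)
    c = np.sum(y_rot**2 / v)
    ypy = c - b * b / a
    if ypy <= 0:
        return np.inf
    sp2 = ypy / (n - 1)
    return (
        (n - 1) * math.log(sp2)
        + np.sum(np.log(v))
        + math.log(a)
        + (n - 1) * (1.0 + math.log(2 * math.pi))
    )


def fit_null_reml(y: np.ndarray, grm, max_iter: int = 100) -> VarianceComponents:
    """REML variance components for ``y = 1mu + u + e`` given a GRM.

    ``grm`` may be a :class:`~feednet.containers.GRM` or a pre-computed
    :class:`GRMEigen`. The restricted likelihood is profiled to the
    single parameter h2 and maximized by bounded Brent search; this is
    exact for a single random effect, so no iterative update can
    diverge. Non-negative variances are enforced by the [0, 1] bound.
    """
    eig = grm if isinstance(grm, GRMEigen) else GRMEigen(grm)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != eig.U.shape[0]:
        raise ValidationError("GRM dimension does not match phenotype length")
    if n < 3:
        raise ValidationError("REML needs at least 3 observations")
    y_rot = eig.rotate(y)
    x0_rot = eig.rotate(np.ones(n))
    d = eig.d

    obj = lambda h2: _profiled_reml_neg2ll(h2, d, y_rot, x0_rot)
    res = minimize_scalar(
        obj,
        bounds=(0.0, 1.0 - 1e-9),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": max_iter},
    )
    if not res.success:
        raise NumericalError(
            f"REML scalar search did not converge after {max_iter} iterations "
            f"(last h2={res.x:.6f}, -2lR={res.fun:.6f})"
        )
    # the bounded optimizer can stall a hair inside the boundary; snap if better
    h2 = float(res.x)
    for cand in (0.0, 1.0 - 1e-9):
        if obj(cand) < obj(h2):
            h2 = cand
    v = h2 * d + (1.0 - h2)
    a = np.sum(x0_rot**2 / v)
    b = np.sum(x0_rot * y_rot / v)
    c = np.sum(y_rot**2 / v)
    sp2 = (c - b * b / a) / (n - 1)
    su2 = max(h2 * sp2, _VAR_FLOOR if h2 > 0 else 0.0)
    se2 = max((1.0 - h2) * sp2, _VAR_FLOOR)
    loglik = -0.5 * obj(h2)

    se_h2 = _h2_se(su2, se2, d, x0_rot)
    return VarianceComponents(
        sigma_u2=float(su2),
        sigma_e2=float(se2),
        h2=float(su2 / (su2 + se2)),
        se_h2=float(se_h2),
        loglik=float(loglik),
        converged=True,
        n_iter=int(res.nit),
    )


def _h2_se(su2, se2, d, x0_rot):
    """Delta-method SE of h2 from the Fisher (average) information of
    (su2, se2), computed in the rotated basis where V is diagonal."""
    n = len(d)
    v = su2 * d + se2
    vinv = 1.0 / v
    x = x0_rot * vinv
    xtvx = np.sum(x0_rot * x)
    # P = Vinv - Vinv x0 (x0' Vinv x0)^-1 x0' Vinv  (n x n, rotated basis)
    P = np.diag(vinv) - np.outer(x, x) / xtvx
    P2 = P * P
    i11 = 0.5 * np.sum(P2 * np.outer(d, d))
    i12 = 0.5 * np.sum(P2 * d[None, :])
    i22 = 0.5 * np.sum(P2)
    info = np.array([[i11, i12], [i12, i22]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float("nan")
    sp2 = su2 + se2
    grad = np.array([se2, -su2]) / sp2**2
    var = float(grad @ cov @ grad)
    return math.sqrt(max(var, 0.0))


# ------------------------------------------------------------------- MLMA

def run_mlma(
    g: GenotypeMatrix,
    y: np.ndarray,
    grm,
    vc: VarianceComponents,
) -> pd.DataFrame:
    """Per-variant association under fixed null variance components.

    GLS of ``y`` on ``[1, x]`` with ``V = G su2 + I se2`` held fixed;
    ``z = b/se`` and the two-sided P comes from the standard normal.
    Monomorphic variants are kept in the output with ``z = 0, p = 1``
    and flagged.
    """
    eig = grm if isinstance(grm, GRMEigen) else GRMEigen(grm)
    y = np.asarray(y, dtype=float)
    n, m = g.n_individuals, g.n_variants
    if len(y) != n or eig.U.shape[0] != n:
        raise ValidationError("dimension mismatch between y, GRM and genotypes")

    dos = g.dosages.copy()
    p_freq = np.nanmean(dos, axis=0) / 2.0
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        logger.info("mean-imputing %d missing genotypes for MLMA", nan_mask.sum())
        dos[nan_mask] = np.broadcast_to(2 * p_freq, dos.shape)[nan_mask]
    mono = dos.std(axis=0) == 0
    if mono.any():
        logger.info("%d monomorphic variants flagged (z=0, p=1)", mono.sum())

    w = 1.0 / (vc.sigma_u2 * eig.d + vc.sigma_e2)  # rotated V^-1 diagonal
    y_rot = eig.rotate(y)
    x0 = eig.rotate(np.ones(n))
    X_rot = eig.U.T @ dos  # (n, m)

    s00 = np.sum(w * x0 * x0)
    s0y = np.sum(w * x0 * y_rot)
    s0x = X_rot.T @ (w * x0)  # (m,)
    sxy = X_rot.T @ (w * y_rot)
    sxx = np.einsum("ij,ij->j", X_rot, w[:, None] * X_rot)

    det = s00 * sxx - s0x**2
    safe = (~mono) & (det > 0)
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    beta[safe] = (s00 * sxy[safe] - s0x[safe] * s0y) / det[safe]
    se[safe] = np.sqrt(s00 / det[safe])
    z = np.zeros(m)
    z[safe] = beta[safe] / se[safe]
    pval = np.ones(m)
    pval[safe] = 2.0 * norm.sf(np.abs(z[safe]))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    out = g.variants[["variant_id", "chrom", "pos", "a1", "a2"]].copy()
    out["maf"] = np.minimum(p_freq, 1 - p_freq)
    out["beta"] = beta
    out["se"] = se
    out["z"] = z
    out["p"] = pval
    out["monomorphic"] = mono
    return out


# ------------------------------------------------------------- thresholds

def bonferroni_threshold(alpha: float, m: int) -> float:
    """-log10 of the Bonferroni-corrected per-test significance level."""
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must be in (0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return -math.log10(alpha / m)


def _chrom_sort_key(chroms: pd.Series) -> pd.Series:
    """Numeric where possible so '2' sorts before '10'."""
    num = pd.to_numeric(chroms, errors="coerce")
    return num.fillna(np.inf)


def top_k_variants(
    res: pd.DataFrame, k: int, annotation: pd.DataFrame = None
) -> pd.DataFrame:
    """The k variants with the smallest P, ties broken by (chrom, pos).

    With an annotation table, each variant is paired with its gene
    (strictly within gene bodies; empty string if intergenic).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    df = res.copy()
    df["_ck"] = _chrom_sort_key(df["chrom"])
    df = df.sort_values(["p", "_ck", "pos"], kind="mergesort").drop(columns="_ck")
    out = df.head(k).reset_index(drop=True)
    if annotation is not None:
        from .awm import assign_genes

        gene_map = assign_genes(out, annotation)
        out["gene_id"] = out["variant_id"].map(gene_map).fillna("")
    return out
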