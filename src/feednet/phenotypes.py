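"""Trait derivation and fixed-effect precorrection.

Feed-efficiency criteria for growing bulls:

* ``ADG`` — average daily gain, (final - initial weight) / test days.
* ``MMW`` — metabolic mid-test weight, ((initial + final)/2) ** 0.75,
  a proxy for maintenance requirements.
* ``RFI`` — residual feed intake: residual of
  ``FI = year + b1*MMW + b2*ADG + b3*final_age + RFI``. Negative =
  efficient (eats less than predicted).
* ``RG`` — residual gain: residual of
  ``ADG = year + b1*MMW + b2*FI + b3*final_age + RG``. Positive =
  efficient.
* ``FE`` — feed efficiency ratio, ADG / FI.

By construction (OLS orthogonality) RFI is uncorrelated with MMW and
ADG within the fitted sample, and RG with MMW and FI.

Before association testing, all six traits are precorrected for the
GWAS fixed-effect set (contemporary-group year, dam-age class,
twinning, final-age covariate); the corrected traits are the OLS
residuals and have mean zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NumericalError, ValidationError

__all__ = [
    "compute_adg_mmw",
    "compute_fe",
    "fit_residual_trait",
    "derive_traits",
    "precorrect_phenotypes",
    "ResidualModelFit",
    "GWAS_COVARIATES",
]

GWAS_COVARIATES = ["year", "dam_age_class", "twinning", "final_age"]


@dataclass
class ResidualModelFit:
    """OLS fit of a residual trait model (RFI or RG)."""

    kind: str
    beta_mmw: float
    beta_partner: float  # ADG for RFI, FI for RG
    beta_age: float
    year_effects: dict
    residuals: pd.Series


def compute_adg_mmw(initial_weight, final_weight, test_days):
    """Average daily gain and metabolic mid-test weight.

    ``ADG = (final - initial) / days``; ``MMW = mid_weight ** 0.75``
    with the mid-test weight taken as the mean of the endpoint weights.
    """
    iw = np.asarray(initial_weight, dtype=float)
    fw = np.asarray(final_weight, dtype=float)
    days = np.asarray(test_days, dtype=float)
    if np.any(iw <= 0) or np.any(fw <= 0):
        raise ValidationError("weights must be positive")
    if np.any(days <= 0):
        raise ValidationError("test_days must be positive")
    adg = (fw - iw) / days
    mmw = ((iw + fw) / 2.0) ** 0.75
    return adg, mmw


def compute_fe(adg, fi):
    """Feed efficiency ratio ADG/FI (kg gain per kg feed)."""
    adg = np.asarray(adg, dtype=float)
    fi = np.asarray(fi, dtype=float)
    if np.any(fi <= 0):
        raise ValidationError("FI must be positive")
    return adg / fi


def _design_matrix(df: pd.DataFrame, categorical, covariates):
    """Full-rank design: intercept-free dummy coding for the first
    categorical factor, drop-first for the rest, plus covariates."""
    cols, names = [], []
    for k, cat in enumerate(categorical):
        levels = sorted(df[cat].astype(str).unique())
        use = levels if k == 0 else levels[1:]
        codes = df[cat].astype(str)
        for lev in use:
            cols.append((codes == lev).to_numpy(dtype=float))
            names.append(f"{cat}[{lev}]")
    for cov in covariates:
        cols.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
    return np.column_stack(cols), names


def _ols_residuals(y: np.ndarray, X: np.ndarray, names, check_rank=True):
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if check_rank and rank < p:
        # identify (approximately) the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in piv[diag < tol]] or [names[j] for j in piv[rank:]]
        raise NumericalError(
            f"rank-deficient design (rank {rank} < {p}); collinear terms: {bad}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def fit_residual_trait(df: pd.DataFrame, kind: str) -> ResidualModelFit:
    """Fit the RFI or RG regression and return residuals as the trait.

    ``kind='RFI'``: FI on year + MMW + ADG + final_age.
    ``kind='RG'``: ADG on year + MMW + FI + final_age.
    """
    if kind not in ("RFI", "RG"):
        raise ValidationError(f"kind must be 'RFI' or 'RG', got {kind!r}")
    for col in ("MMW", "ADG", "FI", "final_age", "year"):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r}")
    response, partner = ("FI", "ADG") if kind == "RFI" else ("ADG", "FI")
    n_params = df["year"].nunique() + 3
    if len(df) < 2 * n_params:
        raise ValidationError(
            f"need >= 2 animals per fitted parameter ({n_params} params, {len(df)} animals)"
        )
    X, names = _design_matrix(df, ["year"], ["MMW", partner, "final_age"])
    y = df[response].to_numpy(dtype=float)
    beta, resid = _ols_residuals(y, X, names)
    n_year = df["year"].nunique()
    year_levels = sorted(df["year"].astype(str).unique())
    return ResidualModelFit(
        kind=kind,
        beta_mmw=float(beta[n_year]),
        beta_partner=float(beta[n_year + 1]),
        beta_age=float(beta[n_year + 2]),
        year_effects=dict(zip(year_levels, beta[:n_year].tolist())),
        residuals=pd.Series(resid, index=df.index, name=kind),
    )


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Add ADG, MMW, FW, FE, RFI and RG to a raw phenotype table.

    ADG is recomputed from the endpoint weights (overwriting any
    existing column) so that all derived traits are internally
    consistent.
    """
    df = records.copy()
    adg, mmw = compute_adg_mmw(df["initial_weight"], df["final_weight"], df["test_days"])
    df["ADG"] = adg
    df["MMW"] = mmw
    df["FW"] = df["final_weight"].astype(float)
    df["FE"] = compute_fe(df["ADG"], df["FI"])
    df["RFI"] = fit_residual_trait(df, "RFI").residuals
    df["RG"] = fit_residual_trait(df, "RG").residuals
    return df


def precorrect_phenotypes(
    traits: pd.DataFrame, trait_cols=("RFI", "RG", "FE", "FI", "FW", "ADG")
) -> pd.DataFrame:
    """Residuals of each trait on the GWAS fixed-effect set.

    Corrected traits have mean zero and are orthogonal to every
    regressor (year, dam-age class, twinning, final age).
    """
    for cov in GWAS_COVARIATES:
        if cov not in traits.columns:
            raise ValidationError(f"missing covariate {cov!r}")
        if traits[cov].isna().any():
            raise ValidationError(f"covariate {cov!r} has missing values")
    X, names = _design_matrix(
        traits.assign(twinning=traits["twinning"].astype(int)),
        ["year", "dam_age_class", "twinning"],
        ["final_age"],
    )
    out = traits.copy()
    for t in trait_cols:
        if t not in traits.columns:
            raise ValidationError(f"missing trait column {t!r}")
        # rank deficiency is benign here: residuals of the projection are
        # unique even when the dummy coding is redundant (e.g. a constant
        # covariate absorbed by the year intercept)
        _, resid = _ols_residuals(
            traits[t].to_numpy(dtype=float), X, names, check_rank=False
        )
        out[t] = resid
    return out
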