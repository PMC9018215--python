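"""Phenotype-side computations.

Threshold classification of Lp(a) concentrations, LDL-C correction for the
cholesterol carried on Lp(a) particles, the rank-based inverse-normal
transform, nested variance-explained OLS models, and Welch's two-group
comparison.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

from .core import MG_DL_TO_MMOL_L, NMOL_PER_MG_DL, ConfigurationError, ModelFit

__all__ = [
    "LpaClassification",
    "classify_lpa",
    "corrected_ldl",
    "inverse_normal",
    "variance_explained",
    "welch_t",
    "WelchResult",
]

# clinical and family thresholds, nmol/L
ELEVATED_CLINICAL_THRESHOLD = 125.0   # risk threshold ("above" = strictly >)
FAMILY_HIGH_THRESHOLD = 150.0         # family high phenotype: > 150
FAMILY_NORMAL_THRESHOLD = 90.0        # family normal phenotype: <= 90


@dataclass(frozen=True)
class LpaClassification:
    """Clinical (>125 nmol/L) and family (>150 / <=90 nmol/L) labels."""

    elevated_clinical: bool
    family: str   # {high, normal, indeterminate}

    @property
    def family_high(self) -> bool:
        return self.family == "high"

    @property
    def family_normal(self) -> bool:
        return self.family == "normal"


def classify_lpa(lpa_nmol_l: float) -> LpaClassification:
    """Classify an Lp(a) concentration on both threshold systems.

    Values in (90, 150] are indeterminate for the family phenotype.
    """
    if lpa_nmol_l < 0:
        raise ConfigurationError("Lp(a) concentration must be >= 0")
    if lpa_nmol_l > FAMILY_HIGH_THRESHOLD:
        family = "high"
    elif lpa_nmol_l <= FAMILY_NORMAL_THRESHOLD:
        family = "normal"
    else:
        family = "indeterminate"
    return LpaClassification(
        elevated_clinical=lpa_nmol_l > ELEVATED_CLINICAL_THRESHOLD,
        family=family,
    )


def corrected_ldl(ldl_c_mmol_l: float, lpa_nmol_l: float,
                  chol_fraction: float = 0.30,
                  nmol_per_mg_dl: float = NMOL_PER_MG_DL) -> float:
    """LDL-C corrected for the cholesterol contained in Lp(a) particles.

    Lp(a) mass is obtained from the particle concentration with the
    configurable ``nmol_per_mg_dl`` factor; ``chol_fraction`` of that mass
    is cholesterol, converted from mg/dL to mmol/L (x 0.02586) and
    subtracted from measured LDL-C.  The result is floored at 0.
    """
    if ldl_c_mmol_l < 0 or lpa_nmol_l < 0:
        raise ConfigurationError("concentrations must be >= 0")
    if nmol_per_mg_dl <= 0:
        raise ConfigurationError("nmol_per_mg_dl must be > 0")
    lpa_mass_mg_dl = lpa_nmol_l / nmol_per_mg_dl
    return max(0.0, ldl_c_mmol_l
               - chol_fraction * lpa_mass_mg_dl * MG_DL_TO_MMOL_L)


def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps value of rank r (mid-ranks for ties) among n observations to
    ``Phi^{-1}((r - 3/8) / (n + 1/4))``; preserves rank order and is
    invariant to strictly monotone transforms of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("expected a 1-D array of values")
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ConfigurationError("need at least 2 finite values")
    xf = x[finite]
    if np.ptp(xf) == 0:
        raise ConfigurationError("all values identical: transform undefined")
    n = xf.size
    ranks = rankdata(xf, method="average")
    out = np.full(x.shape, np.nan)
    out[finite] = norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def _collinear_columns(X: pd.DataFrame) -> List[str]:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return []
    bad = []
    for col in X.columns:
        reduced = X.drop(columns=[col])
        r2 = np.linalg.matrix_rank(
            np.column_stack([np.ones(len(X)), reduced.to_numpy(dtype=float)])
        )
        if r2 == rank:
            bad.append(col)
    return bad or list(X.columns)


def variance_explained(response, models: Sequence[Tuple[str, pd.DataFrame]],
                       check_nesting: bool = True) -> List[ModelFit]:
    """OLS fits of nested covariate sets on a common response.

    ``models`` is a sequence of (label, design DataFrame) pairs; an
    intercept is added to each design.  Returns R-squared, the coefficient
    table and the overall F-test p-value per model.  When two models share
    the same observations and one covariate set contains the other, the
    nested model's R-squared may not exceed the larger model's; a violation
    raises, since it indicates mismatched observations.
    """
    y = np.asarray(response, dtype=float)
    fits: List[ModelFit] = []
    for label, X in models:
        X = pd.DataFrame(X)
        if len(X) != y.size:
            raise ConfigurationError(
                f"model {label!r}: design has {len(X)} rows, response {y.size}"
            )
        if y.size < X.shape[1] + 2:
            raise ConfigurationError(
                f"model {label!r}: need >= {X.shape[1] + 2} observations"
            )
        const_cols = [c for c in X.columns if np.ptp(X[c].to_numpy(float)) == 0]
        if const_cols:
            raise ConfigurationError(
                f"model {label!r}: constant covariates {const_cols}"
            )
        bad = _collinear_columns(X)
        if bad:
            raise ConfigurationError(
                f"model {label!r}: rank-deficient design, collinear columns {bad}"
            )
        res = sm.OLS(y, sm.add_constant(X.astype(float))).fit()
        coef = pd.DataFrame({
            "coef": res.params, "se": res.bse,
            "t": res.tvalues, "p": res.pvalues,
        })
        fits.append(ModelFit(
            label=label, covariates=list(X.columns),
            r_squared=float(res.rsquared), coefficients=coef,
            p_value=float(res.f_pvalue), n_obs=int(res.nobs),
        ))
    if check_nesting:
        for a in fits:
            for b in fits:
                if a is not b and set(a.covariates) < set(b.covariates):
                    if a.r_squared > b.r_squared + 1e-10:
                        raise ConfigurationError(
                            f"nesting violated: {a.label} (R2={a.r_squared:.4f}) "
                            f"> {b.label} (R2={b.r_squared:.4f})"
                        )
    return fits


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance t test with Satterthwaite degrees of freedom.

    Two-sided p-value; the df is clamped at >= 1 so that degenerate
    zero-variance groups of size 2 still yield a usable p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs at least 2 values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / a.size, vb / b.size
    se = math.sqrt(sa + sb)
    if se == 0.0:
        return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0,
                           mean_a=float(ma), mean_b=float(mb))
    if sa == 0.0 and sb == 0.0:
        df = float(a.size + b.size - 2)
    elif sa == 0.0 or sb == 0.0:
        df = float((b.size if sa == 0.0 else a.size) - 1)
    else:
        df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    df = max(1.0, float(df))
    t = float((ma - mb) / se)
    p = float(2.0 * t_dist.sf(abs(t), df))
    return WelchResult(t=t, df=df, p=p, mean_a=float(ma), mean_b=float(mb))
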