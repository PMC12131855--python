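"""Differential glycan abundance: per-glycan linear models, empirical-Bayes
moderated t-statistics, BH FDR, and composition-level aggregation.

The univariate analysis compares log2 relative abundance between groups
with a moderated t-test: per-glycan residual variances s²_g (d residual
df each) are shrunk toward a pooled prior by modelling them as draws from
a scaled F distribution with hyperparameters (d0, s0²) estimated from the
first two moments of log s² (the standard empirical-Bayes variance-
shrinkage construction).  The posterior variance

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d)

replaces s²_g in the t-statistic, which is then referred to a t
distribution with d0 + d degrees of freedom.  The multivariate analysis
adds confounder covariates (age, sex, comorbidity indicators) to the
design matrix; its group coefficient is the confounder-adjusted log2 fold
change.  Benjamini–Hochberg step-up FDR is applied to both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .quantify import impute_zeros

__all__ = [
    "build_design",
    "GlycanFits",
    "fit_linear_models",
    "ModeratedResult",
    "empirical_bayes_moderation",
    "adjust_bh",
    "differential_table",
    "composition_differential",
]

#: Default comorbidity indicator columns (binary), matching the cohort
#: metadata schema.
DEFAULT_COMORBIDITIES = ("hypertension", "cardiovascular_disease",
                         "type2_diabetes", "copd")


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------

def build_design(
    metadata: pd.DataFrame, covariates: Sequence[str] = ()
) -> pd.DataFrame:
    """Samples × predictors design: intercept, group indicator
    (positive = 1), then requested covariates.

    ``sex`` is encoded as an indicator ``sex_M``; comorbidity columns must
    already be 0/1.  Raises on missing covariates or a rank-deficient
    result (listing the collinear columns).
    """
    cols = {"intercept": np.ones(len(metadata))}
    group = metadata["group"].map({"negative": 0.0, "positive": 1.0})
    if group.isna().any():
        raise ValueError("group labels must be 'negative'/'positive'")
    cols["group"] = group.to_numpy(float)
    for cov in covariates:
        if cov == "sex":
            if "sex" not in metadata.columns:
                raise ValueError("covariate 'sex' not in metadata")
            cols["sex_M"] = (metadata["sex"] == "M").to_numpy(float)
        else:
            if cov not in metadata.columns:
                raise ValueError(f"covariate {cov!r} not in metadata")
            cols[cov] = metadata[cov].to_numpy(float)
    X = pd.DataFrame(cols, index=metadata.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            c for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X


# --------------------------------------------------------------------------
# Per-glycan OLS
# --------------------------------------------------------------------------

@dataclass
class GlycanFits:
    """Vectorized OLS results: one row per glycan."""

    ids: list
    coef: np.ndarray        # group (contrast) coefficient = log2FC
    se: np.ndarray          # its standard error (sqrt(s² · unscaled))
    stdev_unscaled: float   # sqrt([ (X'X)^-1 ]_gg), shared across glycans
    sigma2: np.ndarray      # residual variance s²_g
    df_residual: int

    @property
    def t_ordinary(self) -> np.ndarray:
        return self.coef / self.se


def fit_linear_models(
    Y: pd.DataFrame, X: pd.DataFrame, coef: str = "group"
) -> GlycanFits:
    """Ordinary least squares of each glycan's log2 values on the design.

    ``Y`` is glycans × samples; rows of ``X`` must align with ``Y``'s
    columns.  In the two-group no-covariate case the group coefficient is
    exactly the difference of group means.
    """
    if list(Y.columns) != list(X.index):
        raise ValueError("sample order of Y columns and X rows must match")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than predictors ({p})")
    if coef not in X.columns:
        raise ValueError(f"coefficient {coef!r} not in design")
    Xm = X.to_numpy(float)
    Ym = Y.to_numpy(float)
    if not np.isfinite(Ym).all():
        raise ValueError("Y contains non-finite values; apply a zero policy first")
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    beta = xtx_inv @ Xm.T @ Ym.T            # p × glycans
    resid = Ym.T - Xm @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    j = list(X.columns).index(coef)
    unscaled = xtx_inv[j, j]
    return GlycanFits(
        ids=list(Y.index),
        coef=beta[j],
        se=np.sqrt(sigma2 * unscaled),
        stdev_unscaled=float(np.sqrt(unscaled)),
        sigma2=sigma2,
        df_residual=df,
    )


# --------------------------------------------------------------------------
# Empirical-Bayes moderation
# --------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on the nearly
    linear 1/trigamma scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0² by matching the first
    two moments of log s² to a scaled F distribution."""
    s2 = np.asarray(sigma2, float)
    if not np.isfinite(s2).all():
        raise ValueError("non-finite residual variances")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    else:
        # no excess dispersion in log s^2: variances are exchangeable and
        # the pooled (arithmetic-mean) variance is the natural prior
        d0 = np.inf
        s0_2 = float(s2.mean())
    return float(d0), float(s0_2)


@dataclass
class ModeratedResult:
    """Moderated test results aligned with the input fits."""

    ids: list
    coef: np.ndarray
    prior_df: float
    prior_var: float
    posterior_var: np.ndarray
    t: np.ndarray
    df_total: float
    p: np.ndarray
    q: np.ndarray


def empirical_bayes_moderation(
    fits: GlycanFits, prior_df: Optional[float] = None
) -> ModeratedResult:
    """Shrink per-glycan variances toward the empirical-Bayes prior and
    recompute t, p and BH q.

    ``prior_df`` overrides the estimated d0 (0 reproduces the ordinary t
    exactly; inf pools every variance to s0²).
    """
    m = len(fits.sigma2)
    if m < 2:
        raise ValueError("need at least 2 glycans for moderation")
    d = fits.df_residual
    d0, s0_2 = _fit_f_dist(fits.sigma2, d)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        post = np.full(m, s0_2)
    elif d0 == 0:
        post = fits.sigma2.copy()
    else:
        post = (d0 * s0_2 + d * fits.sigma2) / (d0 + d)
    t = fits.coef / (np.sqrt(post) * fits.stdev_unscaled)
    df_total = d0 + d
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedResult(
        ids=list(fits.ids), coef=fits.coef.copy(),
        prior_df=d0, prior_var=s0_2, posterior_var=post,
        t=t, df_total=float(df_total), p=p, q=adjust_bh(p),
    )


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_j ≥ p_i of m·p_j/rank_j, capped at 1;
    order-preserving in p.
    """
    arr = np.asarray(p, float)
    if arr.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(arr) == 0:
        return arr.copy()
    return multipletests(arr, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# Result tables
# --------------------------------------------------------------------------

def differential_table(
    moderated: ModeratedResult,
    classes: Optional[Mapping[str, str]] = None,
    p_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Volcano-ready results sorted by p: glycan, class, log2FC, t, p, q
    and significance flags at both conventions (raw p for the univariate
    reading, BH q for the adjusted one)."""
    classes = classes or {}
    df = pd.DataFrame({
        "glycan_id": moderated.ids,
        "fine_class": [classes.get(g, "") for g in moderated.ids],
        "log2FC": moderated.coef,
        "t": moderated.t,
        "p": moderated.p,
        "q": moderated.q,
    })
    df["significant_p"] = df["p"] < p_threshold
    df["significant_q"] = df["q"] < q_threshold
    return df.sort_values(["p", "glycan_id"], kind="mergesort").reset_index(drop=True)


def composition_differential(
    rel: pd.DataFrame,
    composition_of: Mapping[str, str],
    groups: pd.Series,
    zero_policy: str = "half-min",
    tol: float = 0.05,
) -> pd.DataFrame:
    """Composition-level differential: structure abundances summed within
    composition per sample, then group-mean log2 ratio (positive vs
    negative) with increase/decrease/unchanged direction labels.

    Isomers of one composition moving in opposite directions cancel here —
    by design, this mirrors composition-level differential displays and is
    why the structure-level test remains the primary analysis.
    """
    missing = [g for g in rel.index if g not in composition_of]
    if missing:
        raise KeyError(f"no composition mapping for structures: {missing}")
    comp_labels = pd.Series({g: composition_of[g] for g in rel.index})
    summed = rel.groupby(comp_labels).sum()
    summed = impute_zeros(summed, zero_policy)
    g = groups.reindex(summed.columns)
    if g.isna().any():
        raise ValueError("groups must cover every sample column")
    mean_neg = summed.loc[:, (g == "negative").values].mean(axis=1)
    mean_pos = summed.loc[:, (g == "positive").values].mean(axis=1)
    log2fc = np.log2(mean_pos / mean_neg)
    direction = np.where(
        np.abs(log2fc) < tol, "unchanged",
        np.where(log2fc > 0, "increased", "decreased"),
    )
    return pd.DataFrame({
        "composition": summed.index,
        "mean_negative": mean_neg.values,
        "mean_positive": mean_pos.values,
        "log2FC": log2fc.values,
        "direction": direction,
    }).sort_values("composition", kind="mergesort").reset_index(drop=True)
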