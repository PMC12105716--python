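"""Negative-binomial GLM fold changes, differential-expression calls, age
regression of total circRNA signal, and PCA with top contributors.

The two-group NB GLM is fit per feature by iteratively reweighted least
squares with a log link and log size factors as offsets:

    y_fj ~ NB(mean = s_j * exp(b0 + b1 * I[j in group B]), dispersion a_f)

``b1`` is the natural-log fold change of group B over group A; the Wald
test divides it by its asymptotic standard error.  Dispersions are
estimated per feature by method of moments on normalized counts (pooled
within groups) with a floor of 1e-8, unless supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, SampleSheet, join_samples

__all__ = [
    "nb_glm_foldchange",
    "estimate_dispersion_mom",
    "call_de",
    "call_de_temperature_chained",
    "age_regression_total",
    "AgeRegression",
    "pca_with_contributors",
    "PcaResult",
]

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
_BETA_CLIP = 30.0  # |log fc| cap to keep separated fits finite


def estimate_dispersion_mom(
    counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion.

    On normalized counts, Var(y_fj / s_j) = mu_f / s_j + a_f * mu_f^2 within
    a group with mean mu_f; solving for a_f and pooling the two groups
    (weighted by degrees of freedom) gives the estimate, floored at 1e-8.
    """
    norm = counts / size_factors
    alphas = np.zeros(counts.shape[0])
    weights = np.zeros(counts.shape[0])
    for g in (0, 1):
        cols = groups == g
        n_g = cols.sum()
        if n_g < 2:
            continue
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        inv_sf = (1.0 / size_factors[cols]).mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu * inv_sf) / mu**2
        ok = mu > 0
        df = n_g - 1
        alphas[ok] += np.where(np.isfinite(a[ok]), a[ok], 0.0) * df
        weights[ok] += df
    with np.errstate(invalid="ignore"):
        out = np.where(weights > 0, alphas / np.maximum(weights, 1), 0.0)
    return np.maximum(out, DISPERSION_FLOOR)


def _irls_two_group(
    y: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for the two-group NB GLM.

    Returns (b0, b1, se_b1) per feature, with coefficients in natural log.
    """
    F, n = y.shape
    x = groups.astype(float)  # second design column
    offset = np.log(size_factors)
    eps = 1e-8

    norm = y / size_factors
    m_a = norm[:, groups == 0].mean(axis=1)
    m_b = norm[:, groups == 1].mean(axis=1)
    b0 = np.log(np.maximum(m_a, eps))
    b1 = np.log(np.maximum(m_b, eps)) - b0

    a = alpha[:, None]
    for _ in range(max_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        eta = np.clip(eta, -700, 700)
        mu = np.maximum(np.exp(eta), 1e-300)
        w = mu / (1.0 + a * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)      # x is 0/1 so this is also sum(w x^2)
        swz = (w * z).sum(axis=1)
        swzx = (w * z * x).sum(axis=1)
        det = sw * swx - swx**2
        det = np.where(det <= 0, np.nan, det)
        new_b0 = (swx * swz - swx * swzx) / det
        new_b1 = (sw * swzx - swx * swz) / det
        new_b0 = np.clip(new_b0, -_BETA_CLIP, _BETA_CLIP)
        new_b1 = np.clip(new_b1, -_BETA_CLIP, _BETA_CLIP)
        delta = np.nanmax(
            np.abs(np.concatenate([new_b0 - b0, new_b1 - b1]))
        )
        b0, b1 = new_b0, new_b1
        if delta < tol:
            break

    # refresh weights at the solution for the covariance
    eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    eta = np.clip(eta, -700, 700)
    mu = np.maximum(np.exp(eta), 1e-300)
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(sw / det)
    return b0, b1, se_b1


def nb_glm_foldchange(
    counts: CountMatrix,
    size_factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
    dispersion: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-feature NB-GLM log2 fold change of group B versus group A.

    Returns a frame indexed by feature with columns log2fc, se, wald_p,
    padj (Benjamini-Hochberg across tested features), and base_mean (mean
    normalized count over both groups).  Features with zero counts in both
    groups yield an all-NA row.  When a group mean is zero the reported
    log2fc uses a pseudo-count of 0.5 on the normalized group means to stay
    finite; the Wald test remains NB-based.
    """
    samples = list(group_a) + list(group_b)
    missing = [s for s in samples if s not in counts.sample_ids]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    if len(group_a) < 2 or len(group_b) < 2:
        warnings.warn("fewer than 2 replicates in a group; SE is unreliable")
    y = counts.values[samples].to_numpy(dtype=float)
    sf = size_factors.reindex(samples).to_numpy(dtype=float)
    groups = np.array([0] * len(group_a) + [1] * len(group_b))

    if dispersion is None:
        alpha = estimate_dispersion_mom(y, sf, groups)
    else:
        alpha = np.broadcast_to(
            np.maximum(np.asarray(dispersion, dtype=float), DISPERSION_FLOOR),
            (y.shape[0],),
        ).copy()

    b0, b1, se = _irls_two_group(y, sf, groups, alpha)

    norm = y / sf
    m_a = norm[:, groups == 0].mean(axis=1)
    m_b = norm[:, groups == 1].mean(axis=1)
    log2fc = b1 / LN2
    zero_mean = (m_a == 0) | (m_b == 0)
    log2fc = np.where(
        zero_mean, np.log2(m_b + 0.5) - np.log2(m_a + 0.5), log2fc
    )
    se_log2 = se / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se
    # Wald statistic referred to a t distribution with residual df; the
    # normal reference is anti-conservative when the dispersion is itself
    # estimated from a handful of replicates.
    df_resid = max(len(samples) - 2, 1)
    wald_p = 2.0 * stats.t.sf(np.abs(z), df_resid)

    all_zero = (m_a == 0) & (m_b == 0)
    log2fc = np.where(all_zero, np.nan, log2fc)
    se_log2 = np.where(all_zero, np.nan, se_log2)
    wald_p = np.where(all_zero | ~np.isfinite(se_log2), np.nan, wald_p)

    padj = np.full_like(wald_p, np.nan)
    tested = np.isfinite(wald_p)
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        padj[tested] = multipletests(wald_p[tested], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se_log2,
            "wald_p": wald_p,
            "padj": padj,
            "base_mean": norm.mean(axis=1),
        },
        index=counts.feature_ids,
    )


def call_de(
    results: pd.DataFrame,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Differentially expressed features: ``log2fc > 0.5`` (up) or
    ``log2fc < -0.5`` (down), with ``padj < 0.05``; all strict."""
    sig = results["padj"] < alpha
    up = results.index[sig & (results["log2fc"] > lfc_threshold)]
    down = results.index[sig & (results["log2fc"] < -lfc_threshold)]
    return list(up), list(down)


def call_de_temperature_chained(
    de_29v18: pd.DataFrame,
    de_29vpre: pd.DataFrame,
    de_18vpre: pd.DataFrame,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Chained temperature DE rule.

    A circRNA DE between 29C and 18C is retained only if it is also DE
    (same thresholds) against the pre-treatment condition in at least one
    temperature arm.  The direction versus pre-treatment is recorded, which
    distinguishes "up at 29C" from "up at 18C" responses.
    """
    up_main, down_main = call_de(de_29v18, lfc_threshold, alpha)
    candidates = list(up_main) + list(down_main)
    rows = []
    for circ_id in candidates:
        if circ_id not in de_29vpre.index or circ_id not in de_18vpre.index:
            warnings.warn(f"{circ_id} missing from a pre-treatment contrast; excluded")
            continue
        arms = {}
        for arm, frame in (("29C", de_29vpre), ("18C", de_18vpre)):
            row = frame.loc[circ_id]
            if row["padj"] < alpha and abs(row["log2fc"]) > lfc_threshold:
                arms[arm] = "up" if row["log2fc"] > 0 else "down"
        if not arms:
            continue
        rows.append(
            {
                "circ_id": circ_id,
                "direction_29v18": "up" if circ_id in up_main else "down",
                "de_vs_pre_29C": arms.get("29C", "ns"),
                "de_vs_pre_18C": arms.get("18C", "ns"),
                "label": (
                    "up at 29C" if circ_id in up_main else "up at 18C"
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["circ_id", "direction_29v18", "de_vs_pre_29C", "de_vs_pre_18C", "label"]
    ).set_index("circ_id") if rows else pd.DataFrame(
        columns=["direction_29v18", "de_vs_pre_29C", "de_vs_pre_18C", "label"],
        index=pd.Index([], name="circ_id"),
    )


# ---------------------------------------------------------------------------
# age regression of total circRNA signal
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeRegression:
    """OLS of per-replicate total normalized reads on age (reads/day)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def age_regression_total(circ: CountMatrix, sheet: SampleSheet) -> AgeRegression:
    """Regress per-sample total normalized circRNA reads on age in days."""
    joined = join_samples(circ, sheet)
    ages = joined.sheet.data.set_index("sample_id")["age_days"]
    if ages.nunique() < 3:
        raise ValueError("age regression needs at least 3 distinct ages")
    totals = circ.values.sum(axis=0)
    x = ages.reindex(totals.index).to_numpy(dtype=float)
    y = totals.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return AgeRegression(0.0, float(y[0]), 0.0, 1.0, len(y))
    res = stats.linregress(x, y)
    return AgeRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(y),
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """PCA of log2(x+1) expression, features centered and scaled."""

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    variance_explained: pd.Series
    top_contributors: dict[int, list[str]]
    transform: str = "log2(x+1), centered, unit variance"


def pca_with_contributors(
    expr: CountMatrix,
    top_n: int = 25,
    n_components: int | None = None,
    log_transform: bool = True,
    scale: bool = True,
) -> PcaResult:
    """PCA on log2(x+1)-transformed, feature-standardized expression.

    The transform is configurable (and recorded in the result): disabling
    ``scale`` keeps each feature's variance, so high-variance features
    dominate the components.  Contributors to a component are ranked by
    squared loading.  Zero-variance features are dropped (with a warning)
    before scaling.
    """
    from sklearn.decomposition import PCA

    X = expr.values.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    var = X.var(axis=1)
    keep = var > 0
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} zero-variance features before PCA")
    if keep.sum() < 2:
        raise ValueError("need at least 2 variable features for PCA")
    features = [f for f, k in zip(expr.feature_ids, keep) if k]
    X = X[keep]
    X = X - X.mean(axis=1, keepdims=True)
    if scale:
        X = X / X.std(axis=1, keepdims=True)
    M = X.T  # samples x features
    k = n_components or min(M.shape)
    k = min(k, min(M.shape))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(M)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(pca.components_.T, index=features, columns=comp_names)
    contributors = {
        i + 1: list(
            loadings[comp_names[i]].pow(2).sort_values(ascending=False).index[:top_n]
        )
        for i in range(k)
    }
    transform = ("log2(x+1), " if log_transform else "") + (
        "centered, unit variance" if scale else "centered"
    )
    return PcaResult(
        scores=pd.DataFrame(scores, index=expr.sample_ids, columns=comp_names),
        loadings=loadings,
        variance_explained=pd.Series(pca.explained_variance_ratio_, index=comp_names),
        top_contributors=contributors,
        transform=transform,
    )
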