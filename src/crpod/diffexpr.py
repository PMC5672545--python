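"""Negative-binomial differential expression at the maximum tested dose.

Each chemical's top-dose samples are contrasted against the shared vehicle
controls with a gene-wise negative-binomial generalized linear model
(log link, size factors as offsets) and a Wald test on the group
coefficient.  Dispersion is estimated per gene by method of moments on
normalized counts, then shrunk in log space toward a mean–dispersion trend
alpha(mu) = a0 + a1/mu fitted across genes.  Log2 fold changes are raw MLE
values (no shrinkage); p-values are BH-adjusted within each chemical.

Single-replicate treatment groups are supported: dispersion then comes from
the pooled controls only (low-power mode).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .qc_normalize import size_factors as _size_factors

LN2 = np.log(2.0)

_MIN_DISP = 1e-8
_MAX_DISP = 10.0
_PRIOR_WEIGHT = 20.0  # pseudo-samples pulling gene dispersions toward the trend


def _pooled_group_variance(z: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Within-group variance of normalized counts, pooled over groups with n>=2."""
    num = np.zeros(z.shape[0])
    dof = 0
    for idx in groups:
        if idx.size >= 2:
            sub = z[:, idx]
            num += sub.var(axis=1, ddof=1) * (idx.size - 1)
            dof += idx.size - 1
    if dof == 0:
        raise ValueError("need at least one group with >=2 samples to estimate dispersion")
    return num / dof


def estimate_dispersions(
    counts: np.ndarray,
    sf: np.ndarray,
    groups: list[np.ndarray],
    prior_weight: float = _PRIOR_WEIGHT,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Gene-wise NB dispersions: method of moments shrunk toward a trend.

    Moments: for z = y/s, Var(z) ≈ mu * mean(1/s) + alpha * mu^2, so
    alpha_mom = (pooled within-group var − mu·mean(1/s)) / mu^2.  The trend
    alpha(mu) = a0 + a1/mu is fitted by least squares over genes with a
    positive moment estimate (one re-fit excluding 3-sigma residuals), and
    gene estimates are averaged with the trend in log space, the trend
    carrying ``prior_weight`` pseudo-samples.

    Returns (final dispersions, moment estimates, (a0, a1)).
    """
    z = counts / sf
    mu = z.mean(axis=1)
    xi = float(np.mean(1.0 / sf))
    pooled_var = _pooled_group_variance(z, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (pooled_var - mu * xi) / mu**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)

    usable = (alpha_mom > 0) & (mu > 0)
    if usable.sum() >= 10:
        x = 1.0 / mu[usable]
        y = alpha_mom[usable]
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        keep = np.abs(resid) <= 3 * resid.std() + 1e-12
        if keep.sum() >= 10:
            coef, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
        if a0 == 0.0 and a1 == 0.0:
            a0 = float(np.median(y))
    else:  # too few genes for a trend; use a flat default
        a0, a1 = float(np.median(alpha_mom[usable])) if usable.any() else 0.05, 0.0

    with np.errstate(divide="ignore"):
        alpha_trend = np.clip(a0 + a1 / np.where(mu > 0, mu, np.inf), _MIN_DISP, _MAX_DISP)
    n_samples = counts.shape[1]
    log_mom = np.log(np.clip(alpha_mom, alpha_trend / 100.0, _MAX_DISP))
    log_final = (n_samples * log_mom + prior_weight * np.log(alpha_trend)) / (
        n_samples + prior_weight
    )
    alpha = np.clip(np.exp(log_final), _MIN_DISP, _MAX_DISP)
    alpha[~usable] = alpha_trend[~usable]
    return alpha, alpha_mom, (a0, a1)


def _nb_irls(
    y: np.ndarray,
    x: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for gene-wise NB GLM with design [1, x] and offsets.

    y: (genes, samples); x: (samples,) 0/1 group indicator; alpha: (genes,).
    Returns (beta0, beta1, se_beta1) on the natural-log scale.
    """
    G, n = y.shape
    sf = np.exp(log_sf)
    z = y / sf
    eps = 1e-8
    m_c = z[:, x == 0].mean(axis=1)
    m_t = z[:, x == 1].mean(axis=1)
    b0 = np.log(np.maximum(m_c, eps))
    b1 = np.log(np.maximum(m_t, eps)) - b0
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x + log_sf
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu / (1.0 + a * mu)
        # working response for log link
        zz = (eta - log_sf) + (y - mu) / mu
        A = W.sum(axis=1)
        B = (W * x).sum(axis=1)
        C = (W * x * x).sum(axis=1)
        det = A * C - B * B
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        t0 = (W * zz).sum(axis=1)
        t1 = (W * x * zz).sum(axis=1)
        nb0 = (C * t0 - B * t1) / det
        nb1 = (A * t1 - B * t0) / det
        step0 = np.where(np.isfinite(nb0), nb0 - b0, 0.0)
        step1 = np.where(np.isfinite(nb1), nb1 - b1, 0.0)
        b0 = b0 + step0
        b1 = np.clip(b1 + step1, -30, 30)
        if max(np.abs(step0).max(initial=0), np.abs(step1).max(initial=0)) < tol:
            break
    eta = b0[:, None] + b1[:, None] * x + log_sf
    mu = np.exp(np.clip(eta, -30, 30))
    W = mu / (1.0 + a * mu)
    A = W.sum(axis=1)
    B = (W * x).sum(axis=1)
    C = (W * x * x).sum(axis=1)
    det = A * C - B * B
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = A / det
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    return b0, b1, se


def nb_wald(
    counts: pd.DataFrame,
    group: np.ndarray | pd.Series,
    size_factors: pd.Series | None = None,
    prior_weight: float = _PRIOR_WEIGHT,
) -> pd.DataFrame:
    """Two-group NB Wald test for every gene.

    ``group`` is a 0/1 vector over the columns of ``counts`` (1 = treatment).
    Genes with all-zero counts in the contrast get NA statistics and are
    excluded from the BH denominator.

    Returns a DataFrame with baseMean, l2fc, lfcSE, stat, pvalue, padj.
    """
    x = np.asarray(group, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("group must be a 0/1 indicator")
    if (x == 1).sum() < 1 or (x == 0).sum() < 2:
        raise ValueError("need >=2 control samples and >=1 treatment sample")
    if size_factors is None:
        size_factors = _size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    Y = counts.to_numpy(dtype=float)
    nonzero = Y.sum(axis=1) > 0
    groups = [np.flatnonzero(x == 0), np.flatnonzero(x == 1)]

    out = pd.DataFrame(
        index=counts.index,
        columns=["baseMean", "l2fc", "lfcSE", "stat", "pvalue", "padj"],
        dtype=float,
    )
    if nonzero.any():
        Yn = Y[nonzero]
        alpha, _, _ = estimate_dispersions(Yn, sf, groups, prior_weight)
        b0, b1, se = _nb_irls(Yn, x, np.log(sf), alpha)
        z = b1 / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        out.loc[nonzero, "baseMean"] = (Yn / sf).mean(axis=1)
        out.loc[nonzero, "l2fc"] = b1 / LN2
        out.loc[nonzero, "lfcSE"] = se / LN2
        out.loc[nonzero, "stat"] = z
        out.loc[nonzero, "pvalue"] = p
        valid = out["pvalue"].notna()
        if valid.any():
            out.loc[valid, "padj"] = multipletests(
                out.loc[valid, "pvalue"], method="fdr_bh"
            )[1]
    out.loc[~nonzero, "baseMean"] = 0.0
    return out


def nb_test(
    counts: pd.DataFrame,
    layout: pd.DataFrame,
    chemical: str,
    dose: float | None = None,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Differential expression for one chemical at one dose vs vehicle controls.

    ``dose=None`` selects the chemical's maximum tested concentration.
    """
    lay = layout.set_index("sample_id").reindex(counts.columns)
    treated = lay[(lay["chemical"] == chemical) & ~lay["is_vehicle"]]
    if treated.empty:
        raise ValueError(f"no treated samples for chemical {chemical!r}")
    if dose is None:
        dose = float(treated["conc_uM"].max())
    sel_t = treated.index[np.isclose(treated["conc_uM"].astype(float), dose)]
    sel_c = lay.index[lay["is_vehicle"].fillna(False).astype(bool)]
    if len(sel_t) == 0:
        raise ValueError(f"no samples of {chemical!r} at {dose} uM")
    cols = list(sel_c) + list(sel_t)
    sub = counts[cols]
    group = np.array([0] * len(sel_c) + [1] * len(sel_t))
    sf = size_factors.reindex(cols) if size_factors is not None else None
    return nb_wald(sub, group, sf)


def deg_count(result: pd.DataFrame, alpha: float = 0.05) -> int:
    """Number of genes with BH-adjusted p below ``alpha``."""
    return int((result["padj"] < alpha).sum())


def l2fc_pca(results: dict[str, pd.DataFrame], n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the chemicals-by-genes l2fc matrix (first 3 components)."""
    if len(results) < 2:
        raise ValueError("need at least 2 chemicals for l2fc PCA")
    mat = pd.DataFrame({chem: r["l2fc"] for chem, r in results.items()}).T
    mat = mat.dropna(axis=1)
    n_components = min(n_components, mat.shape[0], mat.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(mat.to_numpy())
    scores_df = pd.DataFrame(
        scores, index=mat.index, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    return scores_df, pca.explained_variance_ratio_


def l2fc_dispersion_summary(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-chemical distribution summaries of |l2fc| (quartiles, mean, SD)."""
    rows = []
    for chem, r in results.items():
        a = r["l2fc"].abs().dropna()
        rows.append(
            {
                "chemical": chem,
                "mean": a.mean() if len(a) else 0.0,
                "sd": a.std(ddof=1) if len(a) > 1 else 0.0,
                "q25": a.quantile(0.25) if len(a) else 0.0,
                "median": a.quantile(0.5) if len(a) else 0.0,
                "q75": a.quantile(0.75) if len(a) else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("chemical")
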