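"""Negative-binomial GLM differential expression for two-group count tables.

The pipeline follows the standard count-based DE recipe: exclude
annotations with mean raw count below 1, estimate per-sample size factors
by the median-of-ratios method, estimate per-annotation NB dispersions
with a mean-dispersion trend and shrinkage, fit a per-annotation NB GLM
with a log link regressing counts on the diet indicator with
log-size-factor offsets, test the diet coefficient with a Wald test
(H0: log2FC = 0), and adjust p-values with the Benjamini-Hochberg
step-up procedure.  Testing is carried out separately within each
annotation class, so the multiplicity burden of e.g. the miRNA family
never leaks into the protein-coding family.

The log2 fold change sign convention is HFD relative to CD throughout:
positive log2FC means higher expression under the high-fat diet.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


# ----------------------------------------------------------------------
# filtering and normalisation
# ----------------------------------------------------------------------

def filter_low_counts(cm: CountMatrix, threshold: float = 1.0) -> CountMatrix:
    """Drop annotations whose raw mean count across all samples is below
    ``threshold``; the boundary is inclusive (mean == threshold is kept)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = cm.counts.mean(axis=1)
    keep = means >= threshold
    if not keep.any():
        warnings.warn("low-count filter removed every annotation", stacklevel=2)
    return CountMatrix(
        cm.counts.loc[keep.to_numpy()], cm.groups, cm.classes[keep], dict(cm.meta)
    )


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each annotation with a positive geometric mean across samples, the
    per-sample ratio count / geometric-mean is formed; the size factor of a
    sample is the median of these ratios.  When no annotation is expressed
    in every sample the reference geometric means are computed over
    positive counts only, restricted to annotations detected in at least
    half the samples.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    if all_positive.any():
        ref = np.exp(logc[all_positive].mean(axis=1))  # geometric means
        ratios = counts[all_positive] / ref[:, None]
    else:
        logger.warning(
            "no annotation expressed in all samples; "
            "falling back to positive-count geometric means"
        )
        pos = counts > 0
        enough = pos.sum(axis=1) >= counts.shape[1] / 2
        if not enough.any():
            raise ValueError("too sparse to estimate size factors")
        sub = counts[enough]
        subpos = sub > 0
        logsub = np.where(subpos, np.log(np.where(subpos, sub, 1.0)), np.nan)
        ref = np.exp(np.nanmean(logsub, axis=1))
        ratios = np.where(subpos, sub / ref[:, None], np.nan)
    s = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("degenerate size factors")
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1
    return pd.Series(s, index=cm.sample_ids, name="size_factor")


# ----------------------------------------------------------------------
# dispersion estimation
# ----------------------------------------------------------------------

@dataclass
class DispersionEstimates:
    """Per-annotation NB dispersions: raw method-of-moments estimate,
    fitted trend value at the annotation's mean, and the shrunk value used
    in testing.  ``trend_coefficients`` holds (a0, a1) of alpha(mu) = a0 + a1/mu."""

    alpha_gene: pd.Series
    alpha_trend: pd.Series
    alpha_final: pd.Series
    trend_coefficients: tuple[float, float]
    base_mean: pd.Series


def _moments_dispersion(norm: np.ndarray, indicator: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments alpha from within-group pooled variance.

    Pooling residual variance within diet groups keeps genuine fold
    changes from masquerading as overdispersion.
    """
    mask0 = indicator == 0
    mask1 = ~mask0
    n0, n1 = mask0.sum(), mask1.sum()
    v0 = norm[:, mask0].var(axis=1, ddof=1)
    v1 = norm[:, mask1].var(axis=1, ddof=1)
    pooled_var = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR), mu


def _fit_trend(alpha_gene: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Robust fit of alpha = a0 + a1/mu over informative annotations."""
    import statsmodels.api as sm

    usable = (alpha_gene > 10 * DISPERSION_FLOOR) & (mu > 0)
    if usable.sum() < 10:
        raise RuntimeError("too few annotations for a trend fit")
    X = sm.add_constant(1.0 / mu[usable])
    rlm = sm.RLM(alpha_gene[usable], X, M=sm.robust.norms.HuberT())
    res = rlm.fit()
    a0, a1 = float(res.params[0]), float(res.params[1])
    # keep the trend a valid dispersion function
    a0 = max(a0, DISPERSION_FLOOR)
    a1 = max(a1, 0.0)
    return a0, a1


def estimate_dispersions(
    cm: CountMatrix, sf: pd.Series, shrinkage_weight: float = 0.5
) -> DispersionEstimates:
    """Estimate per-annotation dispersions on size-factor-normalised counts.

    Per-annotation method-of-moments estimates are shrunk toward a
    hyperbolic mean-dispersion trend alpha(mu) = a0 + a1/mu by a weighted
    geometric average (``shrinkage_weight`` on the trend).  All final
    values are floored at 1e-8.
    """
    if not 0.0 <= shrinkage_weight <= 1.0:
        raise ValueError("shrinkage_weight must be in [0, 1]")
    counts = cm.counts.to_numpy(dtype=float)
    norm = counts / sf.to_numpy()[None, :]
    indicator = cm.design_indicator()
    alpha_gene, mu = _moments_dispersion(norm, indicator)
    try:
        a0, a1 = _fit_trend(alpha_gene, mu)
        with np.errstate(divide="ignore"):
            alpha_trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
        alpha_trend = np.maximum(alpha_trend, DISPERSION_FLOOR)
        w = shrinkage_weight
        # floored (uninformative) per-gene estimates carry no signal: give
        # them the trend value outright instead of a geometric average with
        # the floor, which would collapse the dispersion toward zero
        informative = alpha_gene > 10 * DISPERSION_FLOOR
        alpha_final = np.where(
            informative,
            np.exp(w * np.log(alpha_trend) + (1.0 - w) * np.log(alpha_gene)),
            alpha_trend,
        )
        # with few residual degrees of freedom, below-trend gene-wise
        # estimates are dominated by sampling noise; testing with them makes
        # the Wald test anti-conservative.  Keep above-trend signal, floor
        # the rest at the trend.
        alpha_final = np.maximum(alpha_final, alpha_trend)
    except RuntimeError as exc:
        logger.warning("dispersion trend fit failed (%s); using per-annotation estimates", exc)
        a0, a1 = float("nan"), float("nan")
        alpha_trend = alpha_gene.copy()
        alpha_final = alpha_gene.copy()
    alpha_final = np.maximum(alpha_final, DISPERSION_FLOOR)
    idx = cm.annotation_ids
    return DispersionEstimates(
        alpha_gene=pd.Series(alpha_gene, index=idx),
        alpha_trend=pd.Series(alpha_trend, index=idx),
        alpha_final=pd.Series(alpha_final, index=idx),
        trend_coefficients=(a0, a1),
        base_mean=pd.Series(mu, index=idx),
    )


# ----------------------------------------------------------------------
# NB GLM Wald test
# ----------------------------------------------------------------------

def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised IRLS for per-gene NB GLMs with log link and known dispersion.

    Fits ``G`` independent models that share the design ``X`` (n × p):
    log mu_gj = offset_j + X_j . beta_g, Var(y) = mu + alpha_g mu^2.
    Returns (beta: G × p, se: G × p, converged: G).
    """
    G, n = y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # initialise the intercept from mean normalised counts
    mean0 = np.maximum((y / np.exp(offset)[None, :]).mean(axis=1), 1e-8)
    beta[:, 0] = np.log(mean0)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    eta_cap = 50.0

    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active]
        eta = offset[None, :] + b @ X.T
        eta = np.clip(eta, -eta_cap, eta_cap)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[active, None] * mu)  # IRLS weights for log link
        z = (eta - offset[None, :]) + (y[active] - mu) / mu  # working response
        # normal equations per gene: (X' W X) beta = X' W z
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
        XtWz = np.einsum("ni,gn,gn->gi", X, w, z)
        try:
            new_b = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            XtWX = XtWX + 1e-10 * np.eye(p)[None, :, :]
            new_b = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.abs(new_b - b).max(axis=1)
        beta[active] = new_b
        done = delta < tol
        idx_active = np.where(active)[0]
        converged[idx_active[done]] = True
        active[idx_active[done]] = False

    # observed/expected Fisher information at the final fit
    eta = np.clip(offset[None, :] + beta @ X.T, -eta_cap, eta_cap)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(XtWX + 1e-12 * np.eye(p)[None, :, :])
            se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
        except np.linalg.LinAlgError:
            se = np.full((G, p), np.nan)
    return beta, se, converged


def wald_test(
    cm: CountMatrix, sf: pd.Series, disp: DispersionEstimates
) -> pd.DataFrame:
    """Per-annotation NB GLM Wald test of the diet effect.

    Fits log mu = beta0 + beta1 * diet with offsets log(s_j); reports the
    effect on the log2 scale, its standard error, the Wald statistic
    beta1/SE(beta1) (natural-log scale, invariant to base), the two-sided
    normal p-value, and the CD-group normalised base mean.  Annotations
    whose fit fails are flagged and assigned p = 1.
    """
    from scipy import stats

    y = cm.counts.to_numpy(dtype=float)
    indicator = cm.design_indicator()
    X = np.column_stack([np.ones_like(indicator), indicator])
    offset = np.log(sf.to_numpy(dtype=float))
    alpha = disp.alpha_final.reindex(cm.annotation_ids).to_numpy()

    beta, se, converged = _irls_nb(y, X, offset, alpha)
    coef = beta[:, 1]
    coef_se = se[:, 1]
    bad = (~converged) | ~np.isfinite(coef) | ~np.isfinite(coef_se) | (coef_se <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = coef / coef_se
    pval = 2.0 * stats.norm.sf(np.abs(wald))
    pval = np.where(bad, 1.0, pval)
    wald = np.where(bad, 0.0, wald)

    ref, _ = cm.levels
    norm = y / sf.to_numpy()[None, :]
    base_mean = norm[:, cm.group_mask(ref)].mean(axis=1)

    return pd.DataFrame(
        {
            "class": cm.classes.values,
            "base_mean": base_mean,
            "log2fc": coef / LN2,
            "se": coef_se / LN2,
            "wald_stat": wald,
            "pvalue": np.clip(pval, 0.0, 1.0),
            "flag": np.where(bad, "fit_failed", "ok"),
        },
        index=cm.annotation_ids.copy(),
    )


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ----------------------------------------------------------------------
# per-class pipeline
# ----------------------------------------------------------------------

def run_de(
    cm: CountMatrix,
    alpha_sig: float = 0.05,
    filter_threshold: float = 1.0,
    shrinkage_weight: float = 0.5,
) -> pd.DataFrame:
    """Full DE pipeline, executed independently within each annotation class.

    filter -> size factors -> dispersions -> Wald test -> BH, with BH
    multiplicity counted within the class only.  Returns the concatenated
    result table with a boolean ``significant`` column (padj < alpha_sig).
    """
    results = []
    for cls in cm.class_names():
        sub = cm.subset_class(cls)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = filter_low_counts(sub, filter_threshold)
        if sub.n_annotations < 2:
            logger.warning("class %s has <2 annotations after filtering; skipped", cls)
            continue
        sf = estimate_size_factors(sub)
        disp = estimate_dispersions(sub, sf, shrinkage_weight=shrinkage_weight)
        tab = wald_test(sub, sf, disp)
        tab["padj"] = adjust_bh(tab["pvalue"].to_numpy())
        tab["significant"] = tab["padj"] < alpha_sig
        results.append(tab)
    if not results:
        raise ValueError("no annotation class survived filtering")
    out = pd.concat(results)
    out.index.name = "annotation_id"
    return out
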