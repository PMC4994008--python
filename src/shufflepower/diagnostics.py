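"""Transcriptome-homogeneity diagnostics.

Variance-stabilising transform of the counts, between-sample Pearson
correlation, average-linkage hierarchical clustering on the distance
1 - |r|, and PCA on per-annotation scaled and centred VST values.  These
are the checks used to ask whether samples segregate by diet at all
before any per-annotation testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .countmatrix import CountMatrix
from .de import DispersionEstimates

LN2 = np.log(2.0)


# ----------------------------------------------------------------------
def vst(
    cm: CountMatrix,
    disp: DispersionEstimates,
    sf: pd.Series,
    rescale: bool = True,
) -> pd.DataFrame:
    """Closed-form NB variance-stabilising transform.

    For size-factor-normalised counts x and the trend dispersion intercept
    a0, applies

        v(x) = (2 / sqrt(a0)) * asinh(sqrt(a0 * x)),

    the exact variance-stabilising map of the NB mean-variance relation
    var = mu + a0 * mu^2.  With ``rescale=True`` (default) the result is
    affinely mapped so that v(x) -> log2(x) for large x, which puts values
    on the familiar log2 expression scale; v is strictly monotone in x
    either way.  A non-positive a0 falls back to log2(x + 1).
    """
    a0 = disp.trend_coefficients[0]
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy(dtype=float)[None, :]
    if not np.isfinite(a0) or a0 <= 0:
        values = np.log2(norm + 1.0)
    else:
        raw = (2.0 / np.sqrt(a0)) * np.arcsinh(np.sqrt(a0 * norm))
        if rescale:
            values = raw * np.sqrt(a0) / LN2 - np.log2(4.0 * a0)
        else:
            values = raw
    return pd.DataFrame(values, index=cm.annotation_ids.copy(), columns=cm.sample_ids.copy())


# ----------------------------------------------------------------------
def sample_correlations(v: pd.DataFrame) -> pd.DataFrame:
    """Between-sample Pearson correlation matrix over annotations.

    Samples with zero variance get NaN correlations (flagged missing);
    clustering drops them.
    """
    vals = v.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("need >= 2 annotations")
    sd = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=v.columns, columns=v.columns)


# ----------------------------------------------------------------------
@dataclass
class Dendrogram:
    """Average-linkage merge history over d = 1 - |r|.

    ``linkage`` is the scipy (n-1) × 4 linkage matrix; ``labels`` the leaf
    sample ids in input order.
    """

    linkage: np.ndarray
    labels: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels for k clusters."""
        assign = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return pd.Series(assign, index=self.labels)


def cluster_samples(corr: pd.DataFrame) -> Dendrogram:
    """UPGMA (average-linkage) clustering of samples at distance 1 - |r|."""
    r = corr.to_numpy(dtype=float)
    # drop samples with undefined correlations, fewest casualties first:
    # remove the worst offender until no NaN remains, so one zero-variance
    # sample does not take its partners down with it
    keep = np.ones(r.shape[0], dtype=bool)
    while True:
        sub = r[np.ix_(keep, keep)]
        nan_counts = np.isnan(sub).sum(axis=1)
        if nan_counts.sum() == 0:
            break
        worst = np.argmax(nan_counts)
        keep[np.where(keep)[0][worst]] = False
    dropped = [str(s) for s in corr.index[~keep]]
    r = r[np.ix_(keep, keep)]
    labels = [str(s) for s in corr.index[keep]]
    if len(labels) < 2:
        raise ValueError("fewer than 2 samples with defined correlations")
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrise against float noise
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=labels, dropped=dropped)


# ----------------------------------------------------------------------
@dataclass
class PCAResult:
    scores: pd.DataFrame                 # samples × components
    loadings: pd.DataFrame               # annotations × components
    explained_variance_fraction: np.ndarray


def pca(v: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of samples on per-annotation centred, unit-variance VST values.

    Each annotation (feature) is z-scored across samples; zero-variance
    annotations are dropped.  Decomposition is by SVD of the sample ×
    feature matrix, with a deterministic sign convention: the
    largest-magnitude loading of each component is positive.
    """
    if v.shape[1] < 2:
        raise ValueError("need >= 2 samples for PCA")
    vals = v.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    vals = vals[keep]
    ids = v.index[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    Xs = z.T  # samples × features
    n_samples = Xs.shape[0]
    max_comp = min(n_samples - 1, Xs.shape[1])
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)

    Xc = Xs - Xs.mean(axis=0, keepdims=True)  # already ~centred; exact for safety
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # sign convention: largest-|loading| entry positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    total_var = (Xc**2).sum()
    evf = (S**2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=v.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=ids, columns=comp_names),
        explained_variance_fraction=evf,
    )


# ----------------------------------------------------------------------
def group_correlation_contrast(corr: pd.DataFrame, groups: pd.Series) -> float:
    """Mean within-group minus mean between-group correlation.

    Near zero when the diet factor imposes no structure on the samples,
    positive when samples cluster by diet.
    """
    g = groups.reindex(corr.index)
    r = corr.to_numpy(dtype=float)
    same = (g.to_numpy()[:, None] == g.to_numpy()[None, :])
    off = ~np.eye(len(g), dtype=bool)
    within = r[same & off]
    between = r[~same]
    return float(np.nanmean(within) - np.nanmean(between))


def pc1_separates_groups(res: PCAResult, groups: pd.Series) -> bool:
    """True when all samples of one group sit strictly on one side of the
    other group along PC1."""
    pc1 = res.scores.iloc[:, 0]
    g = groups.reindex(pc1.index)
    levels = list(pd.unique(g))
    a = pc1[g == levels[0]]
    b = pc1[g == levels[1]]
    return bool(a.max() < b.min() or b.max() < a.min())
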