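"""Multivariate structure of the DMR methylation matrix.

Covers the variance decomposition used to separate tissue identity from
donor identity: per-sample variance/CV of methylation across compiled
DMRs, PCA of samples over DMRs with held-out projection, one-way MANOVA
of PC scores on tissue (Wilks' lambda, Rao's F — the tissue-to-donor
variance ratio), per-DMR Z-scoring, and Euclidean/Ward hierarchical
clustering for signature heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.multivariate.manova import MANOVA as _SmMANOVA

from .dmr import TileMatrix
from .io import SampleSheet


# ---------------------------------------------------------------------------
# Donor variance / CV
# ---------------------------------------------------------------------------

def donor_variance(tm: TileMatrix, sheet: SampleSheet | None = None,
                   ddof: int = 0) -> pd.DataFrame:
    """Variance and CV of each sample's methylation across compiled DMRs.

    ``tm`` should already be restricted to a compiled DMR set.  Returns
    a DataFrame indexed by sample with columns mean/variance/sd/cv
    (cv = sd/mean); missing tile values are excluded.  ``ddof=0`` gives
    the population variance (default; switchable).  Both variance and
    sd are reported because either may be the quantity of interest.
    """
    rows = {}
    for sid in tm.sample_ids:
        v = tm.values[sid].dropna().values
        if len(v) < 2:
            raise ValueError(f"{sid}: fewer than 2 non-missing DMR values")
        mean = float(np.mean(v))
        var = float(np.var(v, ddof=ddof))
        sd = float(np.sqrt(var))
        rows[sid] = {"mean": mean, "variance": var, "sd": sd,
                     "cv": sd / mean if mean != 0 else np.inf,
                     "n_dmrs": len(v)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    if sheet is not None:
        meta = sheet.samples.set_index("sample_id")[["tissue", "lineage", "cd69"]]
        out = out.join(meta)
    return out


# ---------------------------------------------------------------------------
# PCA with held-out projection
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """PCA of samples (observations) over DMRs (variables).

    ``scores``: samples x k; ``loadings``: DMRs x k orthonormal columns;
    ``mean``: per-DMR centering means from the training samples (also
    used to impute missing entries at projection time).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series


def _impute_row_means(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing entries with the per-DMR mean across samples.

    Rows missing in every sample are dropped (nothing to impute from).
    """
    means = values.mean(axis=1)
    keep = means.notna()
    values = values.loc[keep]
    filled = values.T.fillna(means[keep]).T
    return filled, means[keep]


def pca_fit(values: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Fit PCA on a DMRs x samples matrix.

    Samples are the observations; each DMR is centred by its mean, no
    variance scaling.  Missing entries are mean-imputed per DMR first.
    Sign convention: in each component the largest-|loading| element is
    made positive, so output is deterministic.
    """
    n_samples = values.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components is None:
        n_components = min(n_samples, values.shape[0])
    if n_components > n_samples:
        raise ValueError(f"{n_components} components requested from {n_samples} samples")
    filled, row_means = _impute_row_means(values)
    X = filled.T.values                       # samples x DMRs
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):    # 0/0 variance ratio when X is constant
        scores = pca.fit_transform(X)
    loadings = pca.components_.T              # DMRs x k
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    evr = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    cols = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.columns, columns=cols),
        loadings=pd.DataFrame(loadings, index=filled.index, columns=cols),
        explained_variance_ratio=evr,
        mean=pd.Series(pca.mean_, index=filled.index),
    )


def pca_project(res: PCAResult, values: pd.DataFrame) -> pd.DataFrame:
    """Project new samples (DMRs x samples) into a fitted PC space.

    Uses the training means for centering and imputation, so held-out
    samples (e.g. blood populations projected onto a tissue-trained
    space) are placed without refitting.
    """
    missing = res.loadings.index.difference(values.index)
    if len(missing):
        raise ValueError(f"{len(missing)} training DMRs absent from projection input")
    sub = values.loc[res.loadings.index]
    filled = sub.T.fillna(res.mean).T
    X = filled.T.values - res.mean.values
    scores = X @ res.loadings.values
    return pd.DataFrame(scores, index=values.columns, columns=res.loadings.columns)


# ---------------------------------------------------------------------------
# MANOVA: tissue-to-donor variance ratio
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    statistic_name: str
    statistic_value: float      # Wilks' lambda
    F: float
    p: float
    df_between: float
    df_within: float


def manova_tissue(scores: pd.DataFrame, labels: pd.Series | list,
                  k: int = 2) -> ManovaResult:
    """One-way MANOVA of the first ``k`` PC scores on tissue labels.

    Wilks' lambda with Rao's approximate F (exact for k <= 2 response
    variables).  The residual (within-tissue) variation is the
    donor-level variation, so F is the tissue-to-donor variance ratio.
    A singular within-group covariance is reported as an error, never
    silently regularised.
    """
    labels = pd.Series(list(labels), index=scores.index)
    if labels.nunique() < 2:
        raise ValueError("MANOVA needs at least 2 tissue groups")
    if k > scores.shape[1]:
        raise ValueError(f"k={k} exceeds {scores.shape[1]} available components")
    Y = scores.iloc[:, :k].values
    if k == 1:
        # Wilks reduces to one-way ANOVA for a single response
        y = Y[:, 0]
        groups = [y[labels.values == g] for g in labels.unique()]
        grand = y.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b = len(groups) - 1
        df_w = len(y) - len(groups)
        if ssw == 0:
            raise ValueError("singular within-group covariance in MANOVA")
        F = (ssb / df_b) / (ssw / df_w)
        from scipy.stats import f as f_dist
        return ManovaResult("Wilks", float(ssw / (ssb + ssw)), float(F),
                            float(f_dist.sf(F, df_b, df_w)), float(df_b), float(df_w))
    dummies = pd.get_dummies(labels, drop_first=True).astype(float)
    X = np.column_stack([np.ones(len(labels)), dummies.values])
    try:
        mv = _SmMANOVA(endog=Y, exog=X)
        # hypothesis: all group-contrast coefficients zero
        L = np.zeros((dummies.shape[1], X.shape[1]))
        L[:, 1:] = np.eye(dummies.shape[1])
        table = mv.mv_test(hypotheses=[("tissue", L, None)])
        stat = table.results["tissue"]["stat"]
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular within-group covariance in MANOVA") from exc
    row = stat.loc["Wilks' lambda"]
    return ManovaResult(
        statistic_name="Wilks",
        statistic_value=float(row["Value"]),
        F=float(row["F Value"]),
        p=float(row["Pr > F"]),
        df_between=float(row["Num DF"]),
        df_within=float(row["Den DF"]),
    )


# ---------------------------------------------------------------------------
# Z-scoring and hierarchical clustering
# ---------------------------------------------------------------------------

def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardisation (x - mean)/sd across samples.

    Population sd (ddof=0); rows with zero sd map to all zeros.
    """
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    z = matrix.sub(mean, axis=0).div(sd, axis=0)
    zero = sd == 0
    if zero.any():
        z.loc[zero] = 0.0
    return z


@dataclass
class ClusterResult:
    axis: str                   # "rows" or "columns"
    linkage: np.ndarray         # scipy linkage matrix
    labels: pd.Series           # flat cluster labels at the requested cut
    leaf_order: list[str]       # dendrogram leaf order


def hcluster(matrix: pd.DataFrame, axis: str = "rows",
             metric: str = "euclidean", method: str = "ward",
             n_clusters: int = 2) -> ClusterResult:
    """Hierarchical clustering of matrix rows or columns.

    Row clustering conventionally takes a Z-scored matrix.  Missing
    values are rejected; flat labels come from cutting the tree at
    ``n_clusters``.
    """
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    data = matrix if axis == "rows" else matrix.T
    if data.isna().any().any():
        raise ValueError("hcluster input contains missing values; impute first")
    if n_clusters > len(data):
        raise ValueError(f"n_clusters={n_clusters} exceeds {len(data)} leaves")
    Z = hierarchy.linkage(data.values, method=method, metric=metric)
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    order = [data.index[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(axis=axis, linkage=Z,
                         labels=pd.Series(flat, index=data.index), leaf_order=order)
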