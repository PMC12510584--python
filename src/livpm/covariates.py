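"""Covariate screening against principal components, and PC outliers.

The quality-control loop for these data is human-in-the-loop: an analyst
inspects covariate-PC relationships and picks one covariate per iteration.
This module produces the quantitative inputs for that review — canonical
correlations between each covariate and PCs 1-5 of a residual expression
matrix, a suggested ranking — and the PC-centroid sample-outlier rule. It
never auto-selects covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["ScreenReport", "pc_screen", "pc_outliers"]


@dataclass
class ScreenReport:
    correlations: pd.DataFrame  # covariate x PC canonical correlations
    ranking: pd.Series  # covariates ordered by their top correlation
    explained_variance_ratio: np.ndarray
    flags: dict


def _canonical_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """First canonical correlation between column blocks x and y."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    qx, rx = np.linalg.qr(x)
    qy, ry = np.linalg.qr(y)
    # drop rank-deficient directions
    qx = qx[:, np.abs(np.diag(rx)) > 1e-10 * max(1, np.abs(np.diag(rx)).max())]
    qy = qy[:, np.abs(np.diag(ry)) > 1e-10 * max(1, np.abs(np.diag(ry)).max())]
    if qx.shape[1] == 0 or qy.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def pc_screen(
    residuals: pd.DataFrame, covariate_table: pd.DataFrame, n_pcs: int = 5
) -> ScreenReport:
    """Canonical correlation of each covariate with PCs 1-n_pcs.

    ``residuals`` is features x samples; PCA runs in sample space. Numeric
    covariates enter as-is, categorical ones dummy-encoded; a constant
    covariate is recorded with correlation 0 and flagged. Canonical
    correlation is invariant to affine rescaling of numeric covariates.
    """
    X = residuals.to_numpy().T  # samples x features
    if X.shape[0] < n_pcs + 1:
        raise ValueError(f"need at least {n_pcs + 1} samples for {n_pcs} PCs")
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(X - X.mean(axis=0))
    covariate_table = covariate_table.loc[residuals.columns]
    flags = {}
    rows = {}
    for name in covariate_table.columns:
        col = covariate_table[name]
        if pd.api.types.is_numeric_dtype(col):
            block = col.to_numpy(float)[:, None]
        else:
            block = pd.get_dummies(col.astype(str), drop_first=True).to_numpy(float)
        if block.shape[1] == 0 or np.allclose(block.std(axis=0), 0):
            flags[name] = "constant"
            rows[name] = np.zeros(n_pcs)
            continue
        per_pc = [
            _canonical_correlation(block, scores[:, [j]]) for j in range(n_pcs)
        ]
        rows[name] = np.array(per_pc)
    corr = pd.DataFrame(rows, index=[f"PC{j + 1}" for j in range(n_pcs)]).T
    ranking = corr.max(axis=1).sort_values(ascending=False)
    return ScreenReport(
        correlations=corr,
        ranking=ranking,
        explained_variance_ratio=pca.explained_variance_ratio_,
        flags=flags,
    )


def pc_outliers(
    residuals: pd.DataFrame, sd_threshold: float = 3.0, per_axis: bool = False
) -> pd.DataFrame:
    """Samples far from the (PC1, PC2) centroid of a residual matrix.

    PC scores are standardized before distances are taken. In the default
    radial mode a sample is flagged when its Euclidean distance from the
    centroid exceeds mean + ``sd_threshold`` SDs of all distances;
    ``per_axis`` instead flags samples beyond the threshold on either axis
    separately.
    """
    X = residuals.to_numpy().T
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X - X.mean(axis=0))
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    z = (scores - scores.mean(axis=0)) / sd
    if per_axis:
        flag = (np.abs(z) > sd_threshold).any(axis=1)
        dist = np.abs(z).max(axis=1)
    else:
        dist = np.sqrt((z**2).sum(axis=1))
        flag = dist > dist.mean() + sd_threshold * dist.std()
    return pd.DataFrame(
        {"distance": dist, "outlier": flag}, index=residuals.columns
    ).sort_values("distance", ascending=False)
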