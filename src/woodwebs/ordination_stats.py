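"""Correlation-matrix PCA of species indices and traits, and
Kruskal-Wallis comparisons of species-level indices across treatments.

The ordination follows the classical correlation-PCA reading: variables
are standardized, the correlation matrix is eigendecomposed, and
loadings are reported as variable-component correlations
(eigenvector element x sqrt(eigenvalue)); a variable is flagged as
related to a component when |r| >= 0.6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "KWResult", "pca_correlation", "kruskal_wallis"]

LOADING_THRESHOLD = 0.6


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    proportion: np.ndarray
    loadings: pd.DataFrame  # variables x components, as correlations
    flagged: pd.DataFrame  # boolean, |loading| >= threshold
    scores: pd.DataFrame  # observations x components


@dataclass(frozen=True)
class KWResult:
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]


def pca_correlation(
    table: pd.DataFrame, threshold: float = LOADING_THRESHOLD
) -> PCAResult:
    """PCA on the correlation matrix of a species x variables table.

    Rows with missing values are dropped (logged).  Components carry a
    deterministic sign: the largest-magnitude loading of each component
    is made positive.
    """
    numeric = table.apply(pd.to_numeric)
    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d rows with missing values", n_missing)
        numeric = numeric.dropna()
    if numeric.shape[0] < 3:
        raise ValueError("PCA needs at least 3 complete observations")
    if numeric.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    sd = numeric.std(ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        raise ValueError(f"zero-variance variables: {degenerate}")
    Z = (numeric - numeric.mean()) / sd
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic orientation: largest |loading| positive per component
    for k in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[pivot, k] < 0:
            eigvec[:, k] *= -1
    loadings = eigvec * np.sqrt(eigval)[None, :]
    comp_names = [f"PC{k + 1}" for k in range(len(eigval))]
    loadings_df = pd.DataFrame(loadings, index=numeric.columns, columns=comp_names)
    scores = pd.DataFrame(
        Z.to_numpy() @ eigvec, index=numeric.index, columns=comp_names
    )
    return PCAResult(
        eigenvalues=eigval,
        proportion=eigval / eigval.sum(),
        loadings=loadings_df,
        flagged=loadings_df.abs() >= threshold,
        scores=scores,
    )


def kruskal_wallis(*groups) -> KWResult:
    """Rank-based Kruskal-Wallis H with tie correction; p from the
    chi-squared approximation with k-1 degrees of freedom.  If every
    value in every group is identical, H = 0 and p = 1."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, 1.0, tuple(a.size for a in arrays))
    h, p = stats.kruskal(*arrays)
    return KWResult(float(h), float(p), tuple(a.size for a in arrays))
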