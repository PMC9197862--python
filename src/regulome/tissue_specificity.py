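"""Jensen-Shannon tissue-specificity scoring and element/sample clustering.

Each element's accessibility profile across K tissues is normalized to a
probability vector p and scored by its Jensen-Shannon divergence from the
uniform distribution u = (1/K, ..., 1/K):

    JSD(p) = H2((p + u) / 2) - (H2(p) + H2(u)) / 2

with base-2 entropy H2 and the convention 0 * log2(0) = 0.  The score is
0 for a flat profile and maximal (JSmax(K) < 1 bit) for an element active
in a single tissue.  Elements above a configurable cutoff (default 0.26,
strict inequality) are called highly specific; those are clustered into
tissue groups by seeded k-means on row-normalized profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

DEFAULT_JSD_CUTOFF = 0.26


def _entropy2(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Base-2 Shannon entropy with 0*log0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=axis)


def js_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Jensen-Shannon divergence in bits between probability vectors."""
    m = (p + q) / 2.0
    return _entropy2(m) - (_entropy2(p) + _entropy2(q)) / 2.0


def jsd_max(k: int) -> float:
    """Score of a unit vector against uniform at K tissues (the maximum)."""
    delta = np.zeros(k)
    delta[0] = 1.0
    return float(js_divergence(delta, np.full(k, 1.0 / k)))


def jsd_specificity(row: Sequence[float], normalized: bool = False) -> float:
    """Tissue-specificity score of one accessibility profile.

    The row is normalized to sum 1 and scored against the uniform
    distribution.  With ``normalized=True`` the score is divided by
    JSmax(K) so that a single-tissue element scores exactly 1.
    """
    arr = np.asarray(row, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("profile must be a vector over K >= 2 tissues")
    if (arr < 0).any():
        raise ValueError("negative accessibility value in profile")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero profile has no defined specificity")
    p = arr / total
    k = arr.size
    score = float(js_divergence(p, np.full(k, 1.0 / k)))
    if normalized:
        score /= jsd_max(k)
    return score


def jsd_specificity_matrix(matrix: pd.DataFrame, normalized: bool = False) -> pd.Series:
    """Vectorized JSD-from-uniform for every row of an elements x tissues matrix."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values in accessibility matrix")
    totals = values.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero rows must be removed before scoring")
    p = values / totals[:, None]
    k = values.shape[1]
    u = np.full(k, 1.0 / k)
    m = (p + u) / 2.0
    scores = _entropy2(m, axis=1) - (_entropy2(p, axis=1) + np.log2(k)) / 2.0
    if normalized:
        scores = scores / jsd_max(k)
    return pd.Series(scores, index=matrix.index, name="jsd_score")


def specificity_to_tissue(matrix: pd.DataFrame) -> pd.DataFrame:
    """Alternative per-tissue specificity: 1 - sqrt(JSD(p, e_t)) for each tissue t.

    Offered as a mode because several published pipelines score elements
    against the ideal single-tissue profile rather than against uniform.
    Values use the JSD normalized to [0, 1] (divide by 1 bit).
    """
    values = matrix.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero rows must be removed before scoring")
    p = values / totals[:, None]
    n, k = p.shape
    out = np.empty((n, k))
    for t in range(k):
        e = np.zeros(k)
        e[t] = 1.0
        out[:, t] = 1.0 - np.sqrt(js_divergence(p, e))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class SpecificityResult:
    scores: pd.Series
    argmax_tissue: pd.Series
    is_highly_specific: pd.Series
    cutoff: float


def call_highly_specific(
    matrix: pd.DataFrame,
    cutoff: float = DEFAULT_JSD_CUTOFF,
    normalized: bool = False,
) -> SpecificityResult:
    """Score every element and call those with JSD strictly above the cutoff.

    ``argmax_tissue`` is the tissue of maximal normalized weight, with
    ties resolved to the lexicographically smallest tissue label.
    """
    scores = jsd_specificity_matrix(matrix, normalized=normalized)
    cols = np.array(sorted(matrix.columns))
    ordered = matrix[cols].to_numpy(dtype=float)
    argmax = cols[np.argmax(ordered, axis=1)]
    return SpecificityResult(
        scores=scores,
        argmax_tissue=pd.Series(argmax, index=matrix.index, name="argmax_tissue"),
        is_highly_specific=(scores > cutoff).rename("is_highly_specific"),
        cutoff=cutoff,
    )


def cluster_specific_elements(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 25,
    max_iter: int = 300,
) -> pd.Series:
    """Partition (highly specific) elements into k activity clusters.

    Rows are normalized to sum 1, then clustered by k-means with
    ``n_init`` seeded restarts, keeping the lowest within-cluster sum of
    squares.  Deterministic under a fixed seed.
    """
    if len(matrix) < k:
        raise ValueError(f"only {len(matrix)} rows but k={k}; choose a smaller k")
    values = matrix.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero rows cannot be clustered")
    p = values / totals[:, None]
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(p)
    return pd.Series(labels, index=matrix.index, name="cluster")


def sample_similarity(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman similarity of tissues/samples plus a dendrogram order.

    Input is the elements x tissues matrix; similarity is computed between
    the tissue columns.  Constant columns yield undefined correlations,
    recorded as 0 with a warning.  Ordering is average-linkage
    hierarchical clustering on 1 - correlation.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples for a similarity matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr, _ = spearmanr(matrix.to_numpy(dtype=float))
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    if np.isnan(corr).any():
        warnings.warn("constant sample vector: undefined correlations recorded as 0")
        corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    sim = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    order_idx = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    order = [matrix.columns[i] for i in order_idx]
    return sim, order
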