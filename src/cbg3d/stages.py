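"""Structure-stage typing: embed scA/B profiles, cluster, order by age.

Cells are embedded by centered PCA of their (imputed) scA/B profiles,
clustered by Ward-linkage agglomerative clustering on the top principal
components, and the clusters are relabeled S1..Sk in order of ascending
median donor age.  Age enters all correlations on a log scale, since
stages spread multiplicatively across the lifespan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

__all__ = [
    "Embedding",
    "StageAssignment",
    "qc_filter",
    "embed_scab",
    "cluster_stages",
    "order_stages_by_age",
    "age_correlation",
    "tsne_embed",
]


@dataclass
class Embedding:
    """PCA scores (cells x components) with explained-variance ratios."""

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    cell_ids: list[str]


@dataclass
class StageAssignment:
    """Per-cell stage labels S1..Sk ordered by median cluster age."""

    table: pd.DataFrame  # index cell; columns: cluster, stage, age_years
    stage_summary: pd.DataFrame  # per stage: n cells, median/min/max age
    unaged_clusters: list[int]  # clusters ordered last for lack of aged cells

    @property
    def stages(self) -> pd.Series:
        return self.table["stage"]


def qc_filter(matrix, min_bins: int = 200):
    """Indices of cells with at least ``min_bins`` scA/B-covered bins."""
    return np.flatnonzero(matrix.bins_covered_per_cell >= min_bins)


def embed_scab(
    values: np.ndarray,
    n_components: int = 10,
    cell_ids: list[str] | None = None,
    ages: np.ndarray | None = None,
) -> Embedding:
    """Centered PCA of a complete cells x bins matrix.

    Components are ordered by explained variance and are deterministic up
    to sign; when ages are supplied the sign of PC1 is fixed so that it
    correlates positively with log age.  If there are fewer cells than
    requested components the count is reduced.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 cells")
    if np.isnan(X).any():
        raise ValueError("matrix must be imputed (no NaN) before embedding")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    if ages is not None and len(ages) == X.shape[0]:
        la = np.log10(np.asarray(ages, dtype=float))
        if np.std(scores[:, 0]) > 0 and np.std(la) > 0:
            r = np.corrcoef(scores[:, 0], la)[0, 1]
            if r < 0:
                scores[:, 0] *= -1
    ids = cell_ids if cell_ids is not None else [f"cell_{i}" for i in range(X.shape[0])]
    return Embedding(scores, pca.explained_variance_ratio_, list(ids))


def cluster_stages(embedding: Embedding | np.ndarray, k: int, n_pcs: int = 10) -> np.ndarray:
    """Ward-linkage agglomerative clustering on the top PCs; deterministic."""
    X = embedding.scores if isinstance(embedding, Embedding) else np.asarray(embedding)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of cells ({X.shape[0]})")
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    X = X[:, : min(n_pcs, X.shape[1])]
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(X)


def order_stages_by_age(
    cluster_ids: np.ndarray,
    ages: np.ndarray,
    cell_ids: list[str] | None = None,
) -> StageAssignment:
    """Relabel clusters S1..Sk by ascending median age.

    Clusters containing no cell with a known age are ordered last and
    flagged; ties in median age break by cluster id.
    """
    cluster_ids = np.asarray(cluster_ids)
    ages = np.asarray(ages, dtype=float)
    uniq = np.unique(cluster_ids)
    med = {}
    unaged = []
    for c in uniq:
        a = ages[cluster_ids == c]
        a = a[~np.isnan(a)]
        if a.size == 0:
            unaged.append(int(c))
            med[int(c)] = np.inf
        else:
            med[int(c)] = float(np.median(a))
    order = sorted(med, key=lambda c: (med[c], c))
    relabel = {c: f"S{i + 1}" for i, c in enumerate(order)}
    ids = cell_ids if cell_ids is not None else [f"cell_{i}" for i in range(len(cluster_ids))]
    table = pd.DataFrame(
        {
            "cluster": cluster_ids,
            "stage": [relabel[int(c)] for c in cluster_ids],
            "age_years": ages,
        },
        index=pd.Index(ids, name="cell"),
    )
    summary = (
        table.groupby("stage")["age_years"]
        .agg(n="size", median_age="median", min_age="min", max_age="max")
        .reset_index()
    )
    return StageAssignment(table=table, stage_summary=summary, unaged_clusters=unaged)


def age_correlation(values: np.ndarray, ages: np.ndarray) -> tuple[float, float]:
    """Pearson r (and two-sided p) between a per-cell value and log10 age.

    Ages must be positive (years); requires >= 3 cells and nonzero
    variance on both sides, else (NaN, NaN) is returned as 'undefined'.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.any(ages <= 0):
        raise ValueError("ages must be > 0 for the log transform")
    la = np.log10(ages)
    if np.std(values) == 0 or np.std(la) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(values, la)
    return float(r), float(p)


def tsne_embed(embedding: Embedding, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Seeded 2-D t-SNE of the PC scores, for visualization only —
    never used for stage assignment."""
    from sklearn.manifold import TSNE

    X = embedding.scores
    perplexity = min(perplexity, max(2.0, (X.shape[0] - 1) / 3.0))
    return TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(X)
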