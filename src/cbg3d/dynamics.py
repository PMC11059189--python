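"""Stage-wise scA/B trajectory analysis.

Per-bin mean scA/B at each stage, selection of the most dynamic regions
(top fraction by range of the stage means), hierarchical clustering of
their trajectories into increasing/decreasing groups, and gene-set
trajectories with consecutive-stage U tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_stats import GroupComparison, compare_groups
from .core_io import BinIndex
from .scab import ScABMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StageMeans",
    "DynamicRegionSet",
    "stage_mean_scab",
    "dynamic_regions",
    "cluster_trajectories",
    "geneset_trajectory",
    "map_genes_to_bins",
    "read_gene_table",
]


@dataclass
class StageMeans:
    """Bins x stages matrix of mean scA/B with per-entry cell support."""

    stage_names: list[str]
    means: np.ndarray  # (n_bins, n_stages), NaN where unsupported
    support: np.ndarray  # (n_bins, n_stages) cells contributing
    eligible: np.ndarray  # bool per bin: supported in every stage

    @property
    def n_bins(self) -> int:
        return self.means.shape[0]


def stage_mean_scab(
    matrix: ScABMatrix, stage_labels, min_support: int = 10
) -> StageMeans:
    """Mean scA/B of every bin at every stage.

    ``stage_labels`` gives one stage per cell (same order as the matrix
    rows).  Masked entries are excluded from the means; a bin is eligible
    for dynamic-region analysis only if it is supported by at least
    ``min_support`` cells in every stage.
    """
    labels = np.asarray(stage_labels)
    if labels.shape[0] != matrix.n_cells:
        raise ValueError("one stage label per cell required")
    stage_names = sorted(pd.unique(labels))
    means = np.full((matrix.n_bins, len(stage_names)), np.nan)
    support = np.zeros((matrix.n_bins, len(stage_names)), dtype=np.int64)
    for s, name in enumerate(stage_names):
        rows = matrix.values[labels == name]
        if rows.shape[0] == 0:
            raise ValueError(f"stage {name!r} has zero cells")
        n_obs = (~np.isnan(rows)).sum(axis=0)
        col = np.nansum(rows, axis=0) / np.maximum(n_obs, 1)
        means[:, s] = np.where(n_obs > 0, col, np.nan)
        support[:, s] = n_obs
    eligible = (support >= min_support).all(axis=1)
    return StageMeans(stage_names=stage_names, means=means, support=support, eligible=eligible)


@dataclass
class DynamicRegionSet:
    """Bins selected as most dynamic across stages, with trend labels."""

    selected_bins: np.ndarray  # global bin ids, ranked by descending score
    scores: np.ndarray  # dynamic score of the selected bins
    all_scores: np.ndarray  # per eligible bin (same order as eligible_bins)
    eligible_bins: np.ndarray
    cluster_labels: pd.Series | None = None  # bin -> "increasing"/"decreasing"


def dynamic_regions(
    stage_means: StageMeans, top_frac: float = 0.20, score: str = "range"
) -> DynamicRegionSet:
    """Select the top fraction of eligible bins by cross-stage variability.

    The dynamic score is the range (max - min) of the stage means
    (``score="variance"`` is also available).  Exactly
    ``round(top_frac * n_eligible)`` bins are selected; ties break by bin
    id so selection is deterministic.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    elig = np.flatnonzero(stage_means.eligible)
    if elig.size < 5:
        raise ValueError("need >= 5 eligible bins")
    m = stage_means.means[elig]
    if score == "range":
        s = np.nanmax(m, axis=1) - np.nanmin(m, axis=1)
    elif score == "variance":
        s = np.nanvar(m, axis=1)
    else:
        raise ValueError(f"unknown score {score!r}")
    n_sel = int(np.floor(top_frac * elig.size + 0.5))
    order = np.lexsort((elig, -s))  # descending score, ascending bin id on ties
    pick = order[:n_sel]
    return DynamicRegionSet(
        selected_bins=elig[pick],
        scores=s[pick],
        all_scores=s,
        eligible_bins=elig,
    )


def cluster_trajectories(
    stage_means: StageMeans, selected_bins: np.ndarray, k: int = 2
) -> pd.Series:
    """Ward-cluster the stage profiles of the selected bins.

    Each profile is centered before clustering; clusters are named
    "increasing" / "decreasing" by the sign of the within-cluster mean of
    (last stage - first stage).  With k > 2 the extra clusters are named
    by trend with a numeric suffix.
    """
    from sklearn.cluster import AgglomerativeClustering

    sel = np.asarray(selected_bins)
    if k > sel.size:
        raise ValueError(f"k={k} exceeds number of selected bins ({sel.size})")
    prof = stage_means.means[sel]
    X = prof - prof.mean(axis=1, keepdims=True)
    if k == 1:
        ids = np.zeros(sel.size, dtype=int)
    else:
        ids = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    trend = prof[:, -1] - prof[:, 0]
    by_cluster = {c: float(trend[ids == c].mean()) for c in np.unique(ids)}
    names = {}
    used: dict[str, int] = {}
    for c in sorted(by_cluster, key=lambda c: -by_cluster[c]):
        base = "increasing" if by_cluster[c] >= 0 else "decreasing"
        n = used.get(base, 0)
        names[c] = base if n == 0 else f"{base}_{n + 1}"
        used[base] = n + 1
    return pd.Series([names[c] for c in ids], index=pd.Index(sel, name="bin"), name="trajectory")


def geneset_trajectory(
    matrix: ScABMatrix, stage_labels, bin_set
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-stage distribution of each cell's mean scA/B over a bin set.

    Returns a per-cell table (cell, stage, value) and the two-sided U
    tests between every pair of consecutive stages (sorted stage order).
    """
    bins = np.asarray(sorted(bin_set))
    if bins.size == 0:
        raise ValueError("empty bin set")
    sub = matrix.values[:, bins]
    if np.isnan(sub).all():
        raise ValueError("bin set is fully masked in every cell")
    n_obs = (~np.isnan(sub)).sum(axis=1)
    per_cell = np.where(n_obs > 0, np.nansum(sub, axis=1) / np.maximum(n_obs, 1), np.nan)
    labels = np.asarray(stage_labels)
    table = pd.DataFrame(
        {"cell": matrix.cell_ids, "stage": labels, "value": per_cell}
    ).set_index("cell")
    stage_names = sorted(pd.unique(labels))
    tests = []
    for a, b in zip(stage_names[:-1], stage_names[1:]):
        va = per_cell[(labels == a) & ~np.isnan(per_cell)]
        vb = per_cell[(labels == b) & ~np.isnan(per_cell)]
        tests.append(compare_groups(va, vb))
    return table, tests


def map_genes_to_bins(genes: pd.DataFrame, bin_index: BinIndex) -> set[int]:
    """Global bins overlapping any gene interval.

    ``genes`` is BED-like: columns chrom, start, end (0-based half-open).
    Genes spanning a bin boundary contribute every overlapped bin; genes
    on chromosomes absent from the genome are skipped with a warning.
    """
    req = {"chrom", "start", "end"}
    if not req.issubset(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(req)}")
    idx = bin_index.genome.index
    bs = bin_index.bin_size
    out: set[int] = set()
    skipped = 0
    for chrom, start, end in zip(genes["chrom"], genes["start"], genes["end"]):
        if chrom not in idx:
            skipped += 1
            continue
        ci = idx[chrom]
        start, end = int(start), int(end)
        if end <= start:
            continue
        first = start // bs
        last = (end - 1) // bs
        last = min(last, bin_index.n_bins_per_chrom[ci] - 1)
        for o in range(first, last + 1):
            out.add(bin_index.offsets[ci] + o)
    if skipped:
        logger.warning("map_genes_to_bins: skipped %d gene(s) on unknown chromosomes", skipped)
    return out


def read_gene_table(path) -> pd.DataFrame:
    """Read a BED-like gene table (chrom, start, end[, name]; no header
    required; 0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    cols = ["chrom", "start", "end", "name"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df
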