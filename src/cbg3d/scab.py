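"""Single-cell chromatin A/B compartment (scA/B) scoring.

The scA/B value of a genomic bin in one cell is the mean reference
compartment value of the bin's contact partners.  Contacts whose two
endpoints fall within the same region (same bin, optionally extended by
an exclusion radius in bins) are excluded, so the score primarily
reflects long-range interactions.  Each contact contributes to both of
its endpoint bins; bins supported by fewer than ``min_contacts``
contributing contacts are masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import BinIndex, CompartmentTrack, ContactSet

__all__ = ["ScABMatrix", "compute_scab", "scab_matrix", "impute_missing"]


@dataclass
class ScABMatrix:
    """Cells x bins matrix of scA/B values with missing mask and support."""

    cell_ids: list[str]
    bin_index: BinIndex
    values: np.ndarray  # (n_cells, n_bins), NaN where masked
    support: np.ndarray  # (n_cells, n_bins) int contact support

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_bins(self) -> int:
        return self.bin_index.n_bins

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def bins_covered_per_cell(self) -> np.ndarray:
        return (~self.missing_mask).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.cell_ids, name="cell"),
            columns=np.arange(self.n_bins),
        )


def compute_scab(
    cell: ContactSet,
    bin_index: BinIndex,
    track: CompartmentTrack,
    exclusion_radius: int = 0,
    min_contacts: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin scA/B for one cell.

    Returns (values, support): ``values[b]`` is the mean track value over
    the partner bins of all contacts touching bin b, NaN where support
    (contacts with an informative partner) is below ``min_contacts``.
    Intra-chromosomal contacts whose endpoint bins are within
    ``exclusion_radius`` bins of each other (default 0: same bin only)
    are excluded.
    """
    if track.bin_index.bin_size != bin_index.bin_size:
        raise ValueError("track bin size does not match bin index")
    n = bin_index.n_bins
    b1 = bin_index.bins_of_positions(cell.chrom1, cell.pos1)
    b2 = bin_index.bins_of_positions(cell.chrom2, cell.pos2)
    same_region = (cell.chrom1 == cell.chrom2) & (np.abs(b1 - b2) <= exclusion_radius)
    keep = ~same_region
    b1, b2 = b1[keep], b2[keep]
    tv = track.values
    sums = np.zeros(n)
    support = np.zeros(n, dtype=np.int64)
    # contact contributes the partner's track value to each endpoint bin
    for mine, partner in ((b1, b2), (b2, b1)):
        pv = tv[partner]
        ok = ~np.isnan(pv)
        np.add.at(sums, mine[ok], pv[ok])
        np.add.at(support, mine[ok], 1)
    values = np.full(n, np.nan)
    enough = support >= min_contacts
    values[enough] = sums[enough] / support[enough]
    return values, support


def scab_matrix(
    cells: list[ContactSet],
    bin_index: BinIndex,
    track: CompartmentTrack,
    exclusion_radius: int = 0,
    min_contacts: int = 5,
) -> ScABMatrix:
    """Stack per-cell scA/B rows into a cells x bins matrix."""
    if not cells:
        raise ValueError("need >= 1 cell")
    values = np.empty((len(cells), bin_index.n_bins))
    support = np.empty((len(cells), bin_index.n_bins), dtype=np.int64)
    for i, cell in enumerate(cells):
        values[i], support[i] = compute_scab(
            cell, bin_index, track, exclusion_radius, min_contacts
        )
    return ScABMatrix(
        cell_ids=[c.cell_id for c in cells],
        bin_index=bin_index,
        values=values,
        support=support,
    )


def impute_missing(
    matrix: ScABMatrix, strategy: str = "bin_mean"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete the matrix for downstream PCA.

    Missing entries are filled with the bin mean (default) or the cell
    mean; bins never observed in any cell are dropped.  Returns
    (completed matrix, kept bin ids, dropped bin ids).
    """
    if matrix.n_cells == 0 or matrix.n_bins == 0:
        raise ValueError("empty matrix")
    vals = matrix.values
    observed = ~np.isnan(vals)
    kept = np.flatnonzero(observed.any(axis=0))
    dropped = np.flatnonzero(~observed.any(axis=0))
    out = vals[:, kept].copy()
    if strategy == "bin_mean":
        fill = np.nanmean(out, axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = fill[idx[1]]
    elif strategy == "cell_mean":
        fill = np.nanmean(out, axis=1)
        idx = np.where(np.isnan(out))
        out[idx] = fill[idx[0]]
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    return out, kept, dropped
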