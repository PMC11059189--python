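"""Contact-distance and inter-chromosomal statistics.

Covers the per-cell ultra-long-range contact fraction (intra-chromosomal
contacts spanning at least a threshold distance, 10 Mb by default),
two-group Mann-Whitney U comparisons, aggregated contact maps over cell
groups, and chromosome-pair observed/expected enrichment with hub
scores.  The long-range fraction uses intra-chromosomal contacts only as
its denominator — inter-chromosomal contacts have no genomic distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import ContactSet, Genome

__all__ = [
    "DistanceProfile",
    "AggregateMap",
    "InterchromEnrichment",
    "GroupComparison",
    "distance_profile",
    "compare_groups",
    "aggregate_map",
    "interchrom_enrichment",
    "enrichment_delta",
]

ULTRA_THRESHOLD = 10_000_000


@dataclass
class DistanceProfile:
    """Per-cell intra-chromosomal distance summary."""

    cell_id: str
    distances: np.ndarray  # bp, one per intra contact
    threshold: int
    fraction_ge_threshold: float  # NaN if the cell has no intra contacts
    n_intra: int
    n_inter: int

    @property
    def n_contacts(self) -> int:
        return self.n_intra + self.n_inter


def distance_profile(cell: ContactSet, threshold: int = ULTRA_THRESHOLD) -> DistanceProfile:
    """Distances of intra-chromosomal contacts and the fraction >= threshold.

    The threshold is inclusive: a contact spanning exactly ``threshold``
    bp counts toward the numerator.  Cells without intra contacts get a
    NaN fraction (flagged as undefined).
    """
    intra = cell.is_intra
    d = np.abs(cell.pos2[intra] - cell.pos1[intra])
    n_intra = int(intra.sum())
    frac = float(np.mean(d >= threshold)) if n_intra else float("nan")
    return DistanceProfile(
        cell_id=cell.cell_id,
        distances=d,
        threshold=threshold,
        fraction_ge_threshold=frac,
        n_intra=n_intra,
        n_inter=len(cell) - n_intra,
    )


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    method: str  # "exact" | "asymptotic"


def compare_groups(values_a, values_b, exact_max_n: int = 20) -> GroupComparison:
    """Two-sided Mann-Whitney U test with descriptive mean +/- s.d.

    Small, tie-free groups (both n <= ``exact_max_n``) use exact
    enumeration; otherwise the normal approximation with continuity and
    tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        method=method,
    )


@dataclass
class AggregateMap:
    """Binned contact counts summed over a cell group.

    Scope is a single chromosome (square, symmetrized: each off-diagonal
    contact is counted once per triangle and mirrored), an ordered
    chromosome pair (rectangular), or "inter" (square over all
    genome-wide bins, inter-chromosomal contacts only, symmetrized).
    """

    scope: str | tuple[str, str]
    bin_size: int
    counts: np.ndarray
    group_label: str
    n_contacts: int  # in-scope contacts aggregated


def aggregate_map(
    cells: list[ContactSet],
    scope: str | tuple[str, str],
    bin_size: int,
    genome: Genome | None = None,
    group_label: str = "",
) -> AggregateMap:
    """Aggregate contacts of a cell group into a dense binned count matrix."""
    if not cells:
        raise ValueError("need >= 1 cell")
    genome = genome or cells[0].genome
    nb = {c: -(-genome.length_of(c) // bin_size) for c in genome.names}

    if isinstance(scope, tuple):
        ca, cb = scope
        if ca not in genome.index or cb not in genome.index:
            raise ValueError(f"unknown chromosome in scope {scope}")
        ia, ib = genome.index[ca], genome.index[cb]
        mat = np.zeros((nb[ca], nb[cb]), dtype=np.int64)
        total = 0
        for cell in cells:
            m = (cell.chrom1 == min(ia, ib)) & (cell.chrom2 == max(ia, ib))
            if ia <= ib:
                r, c = (cell.pos1[m] - 1) // bin_size, (cell.pos2[m] - 1) // bin_size
            else:
                r, c = (cell.pos2[m] - 1) // bin_size, (cell.pos1[m] - 1) // bin_size
            np.add.at(mat, (r, c), 1)
            total += int(m.sum())
        return AggregateMap(scope, bin_size, mat, group_label, total)

    if scope == "inter":
        offsets = np.concatenate([[0], np.cumsum([nb[c] for c in genome.names])[:-1]])
        n = int(offsets[-1] + nb[genome.names[-1]])
        mat = np.zeros((n, n), dtype=np.int64)
        total = 0
        for cell in cells:
            m = ~cell.is_intra
            r = offsets[cell.chrom1[m]] + (cell.pos1[m] - 1) // bin_size
            c = offsets[cell.chrom2[m]] + (cell.pos2[m] - 1) // bin_size
            np.add.at(mat, (r, c), 1)
            np.add.at(mat, (c, r), 1)
            total += int(m.sum())
        return AggregateMap(scope, bin_size, mat, group_label, total)

    # single-chromosome intra map
    if scope not in genome.index:
        raise ValueError(f"unknown chromosome {scope!r}")
    if bin_size > genome.length_of(scope):
        raise ValueError("bin size exceeds chromosome length")
    ci = genome.index[scope]
    nbin = nb[scope]
    mat = np.zeros((nbin, nbin), dtype=np.int64)
    total = 0
    for cell in cells:
        m = (cell.chrom1 == ci) & (cell.chrom2 == ci)
        r = (cell.pos1[m] - 1) // bin_size
        c = (cell.pos2[m] - 1) // bin_size
        np.add.at(mat, (r, c), 1)
        off = r != c
        np.add.at(mat, (c[off], r[off]), 1)
        total += int(m.sum())
    return AggregateMap(scope, bin_size, mat, group_label, total)


@dataclass
class InterchromEnrichment:
    """Chromosome-pair observed/expected inter-contact enrichment.

    The expected model is a marginal product: with m_i the number of
    inter-contact endpoints on chromosome i and T the total number of
    inter contacts, expected(i,j) = T * m_i * m_j / sum_{k<l} m_k * m_l.
    Using contact marginals (rather than chromosome lengths) keeps
    coverage differences between chromosomes from masquerading as
    enrichment.  hub_score(i) is the mean enrichment of i with all other
    chromosomes.
    """

    chrom_names: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    enrichment: np.ndarray  # NaN on diagonal and masked pairs
    hub_score: np.ndarray  # per chromosome, NaN if fully masked
    n_inter: int


def interchrom_enrichment(
    cells: list[ContactSet], genome: Genome | None = None, expected: str = "marginal"
) -> InterchromEnrichment:
    """Observed/expected contact enrichment for every chromosome pair.

    ``expected="marginal"`` (default) uses contact-endpoint marginals;
    ``expected="length"`` uses chromosome lengths as the marginals, which
    does not shrink concentrated hub signal into the null but conflates
    coverage differences with enrichment.
    """
    if not cells:
        raise ValueError("need >= 1 cell")
    genome = genome or cells[0].genome
    n = genome.n_chroms
    obs = np.zeros((n, n), dtype=np.int64)
    for cell in cells:
        m = ~cell.is_intra
        np.add.at(obs, (cell.chrom1[m], cell.chrom2[m]), 1)
    obs = obs + obs.T
    T = int(obs.sum() // 2)
    if T == 0:
        raise ValueError("no inter-chromosomal contacts in the group")
    if expected == "marginal":
        marg = obs.sum(axis=1).astype(float)  # endpoints per chromosome
    elif expected == "length":
        marg = genome.lengths_array.astype(float)
    else:
        raise ValueError(f"unknown expected model {expected!r}")
    denom = (marg.sum() ** 2 - (marg**2).sum()) / 2.0  # sum over unordered pairs
    expected = T * np.outer(marg, marg) / denom
    np.fill_diagonal(expected, 0.0)
    enrich = np.full((n, n), np.nan)
    ok = (expected > 0) & ~np.eye(n, dtype=bool)
    enrich[ok] = obs[ok] / expected[ok]
    with np.errstate(invalid="ignore"):
        hub = np.nanmean(np.where(np.eye(n, dtype=bool), np.nan, enrich), axis=1)
    return InterchromEnrichment(
        chrom_names=genome.names,
        observed=obs,
        expected=expected,
        enrichment=enrich,
        hub_score=hub,
        n_inter=T,
    )


def enrichment_delta(
    group_a: list[ContactSet], group_b: list[ContactSet], genome: Genome | None = None
) -> np.ndarray:
    """log2(enrichment_B / enrichment_A) per chromosome pair.

    NaN wherever either group's enrichment is undefined or zero;
    antisymmetric under swapping the groups.
    """
    ea = interchrom_enrichment(group_a, genome).enrichment
    eb = interchrom_enrichment(group_b, genome).enrichment
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.log2(eb / ea)
    delta[~np.isfinite(delta)] = np.nan
    return delta
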