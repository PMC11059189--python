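"""Pooled-sample (Pop-C) demultiplexing.

Two assigners:

* genotype-likelihood demultiplexing of cells against a known SNP panel —
  a read-level binomial error model with per-dosage alt-allele
  probabilities P(alt | g=0) = eps, P(alt | g=1) = 1/2,
  P(alt | g=2) = 1 - eps (missing genotypes contribute 1/2);
* sex demultiplexing from the length-normalized ratio of X-chromosome to
  autosomal contact endpoints (expected ~1.0 in female cells, ~0.5 in
  male cells; the default decision cut 0.75 is their midpoint).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core_io import ContactSet, Genome

__all__ = [
    "GenotypePanel",
    "AlleleObservations",
    "DemuxResult",
    "genotype_loglik",
    "assign_donors",
    "sex_ratio",
    "sex_demux",
    "read_panel",
    "write_panel",
]


@dataclass
class GenotypePanel:
    """SNPs x donors alt-allele dosage matrix (0/1/2, NaN = missing)."""

    snps: pd.DataFrame  # columns: chrom, pos, ref, alt
    donors: list[str]
    genotypes: np.ndarray  # shape (n_donors, n_snps), float with NaN

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.donors), len(self.snps)):
            raise ValueError("genotype matrix shape does not match donors x SNPs")
        g = self.genotypes[~np.isnan(self.genotypes)]
        if g.size and not np.isin(g, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.snps.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate SNP position")

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class AlleleObservations:
    """Sparse per-cell allele observations against a panel.

    ``table`` is long-form with columns cell, snp (panel row index),
    alt (bool: alt allele observed) and count (reads, >= 1).
    """

    table: pd.DataFrame
    n_snps: int

    def __post_init__(self) -> None:
        req = {"cell", "snp", "alt", "count"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"observation table needs columns {sorted(req)}")
        if len(self.table) and (self.table["count"] < 1).any():
            raise ValueError("observation counts must be >= 1")
        if len(self.table) and self.table["snp"].max() >= self.n_snps:
            raise ValueError("observation references SNP outside panel")

    @property
    def cells(self) -> list[str]:
        return list(pd.unique(self.table["cell"]))


@dataclass
class DemuxResult:
    """Per-cell donor assignment with posterior probabilities."""

    assignments: pd.Series  # cell -> donor
    loglik: pd.DataFrame  # cells x donors
    posterior: pd.DataFrame  # cells x donors, rows sum to 1
    ambiguous: pd.Series  # cell -> bool (top posterior < threshold)
    threshold: float


def genotype_loglik(
    obs: AlleleObservations,
    panel: GenotypePanel,
    epsilon: float = 0.01,
    cells: list[str] | None = None,
) -> pd.DataFrame:
    """Log-likelihood of each cell's observations under each donor.

    For an observation of SNP s with donor dosage g, the per-read alt
    probability is eps (g=0), 1/2 (g=1) or 1-eps (g=2); missing dosages
    contribute probability 1/2 per read.  Counts multiply the per-read
    log term.  Cells with zero observations get a uniform (all-zero)
    row — they are flagged downstream.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    G = panel.genotypes  # (D, S)
    p_alt = np.where(np.isnan(G), 0.5, epsilon + (G / 2.0) * (1 - 2 * epsilon))
    t = obs.table
    if cells is None:
        cells = obs.cells
    else:  # explicit roster: zero-observation cells get a uniform row
        cells = list(cells)
    out = np.zeros((len(cells), len(panel.donors)))
    cell_codes = pd.Categorical(t["cell"], categories=cells).codes
    known = cell_codes >= 0  # observations for cells outside the roster are ignored
    cell_codes = cell_codes[known]
    snp_idx = t["snp"].to_numpy()[known]
    alt = t["alt"].to_numpy(dtype=bool)[known]
    cnt = t["count"].to_numpy(dtype=float)[known]
    # (D, n_obs) per-read probability of what was actually observed
    p_obs = np.where(alt[None, :], p_alt[:, snp_idx], 1.0 - p_alt[:, snp_idx])
    contrib = cnt[None, :] * np.log(p_obs)
    for d in range(len(panel.donors)):
        out[:, d] = np.bincount(cell_codes, weights=contrib[d], minlength=len(cells))
    return pd.DataFrame(out, index=pd.Index(cells, name="cell"), columns=panel.donors)


def assign_donors(
    loglik: pd.DataFrame,
    prior: np.ndarray | None = None,
    ambiguity_threshold: float = 0.95,
) -> DemuxResult:
    """Softmax posterior over donors (uniform prior by default) and argmax
    assignment; ties break deterministically by donor order and are
    flagged ambiguous along with any cell whose top posterior falls below
    the threshold."""
    ll = loglik.to_numpy(dtype=float)
    if not np.isfinite(ll).all():
        raise ValueError("log-likelihoods must be finite")
    logp = ll + (np.log(prior)[None, :] if prior is not None else 0.0)
    post = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    best = np.argmax(post, axis=1)  # first max wins on ties
    top = post[np.arange(len(post)), best]
    donors = list(loglik.columns)
    assignments = pd.Series([donors[b] for b in best], index=loglik.index, name="donor")
    ambiguous = pd.Series(top < ambiguity_threshold, index=loglik.index, name="ambiguous")
    posterior = pd.DataFrame(post, index=loglik.index, columns=loglik.columns)
    return DemuxResult(assignments, loglik, posterior, ambiguous, ambiguity_threshold)


def sex_ratio(cell: ContactSet, genome: Genome | None = None) -> float:
    """Length-normalized X/autosome contact-endpoint density ratio.

    ratio = (X endpoints / X length) / (autosomal endpoints / total
    autosomal length); each contact contributes two endpoints.  Returns
    NaN (undefined) when the cell has no autosomal endpoints, 0.0 when it
    simply has no X endpoints.
    """
    genome = genome or cell.genome
    xi = genome.x_index
    if xi is None:
        raise ValueError("genome has no X chromosome")
    counts = np.bincount(cell.chrom1, minlength=genome.n_chroms) + np.bincount(
        cell.chrom2, minlength=genome.n_chroms
    )
    auto = np.array([genome.index[a] for a in genome.autosomes])
    n_auto = counts[auto].sum()
    if n_auto == 0:
        return float("nan")
    auto_len = genome.lengths_array[auto].sum()
    x_density = counts[xi] / genome.lengths[xi]
    auto_density = n_auto / auto_len
    return float(x_density / auto_density)


def sex_demux(
    cells: list[ContactSet], genome: Genome | None = None, cut: float = 0.75
) -> pd.DataFrame:
    """Classify cells as female (ratio > cut) or male.

    Returns a table with the per-cell ratio, label, and a flag for cells
    whose ratio is undefined (no autosomal endpoints).
    """
    rows = []
    for cell in cells:
        r = sex_ratio(cell, genome)
        label = None if np.isnan(r) else ("F" if r > cut else "M")
        rows.append({"cell": cell.cell_id, "ratio": r, "sex": label, "undefined": np.isnan(r)})
    return pd.DataFrame(rows).set_index("cell")


# ---------------------------------------------------------------------------
# panel I/O: VCF-like tab-separated table (CHROM POS REF ALT <donor>...)


def write_panel(panel: GenotypePanel, path) -> Path:
    df = panel.snps.copy()
    df.columns = [c.upper() for c in df.columns]
    G = panel.genotypes
    for d, donor in enumerate(panel.donors):
        col = np.where(np.isnan(G[d]), ".", np.char.mod("%d", np.nan_to_num(G[d]).astype(int)))
        df[donor] = col
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_observations(obs: AlleleObservations, path) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# n_snps: {obs.n_snps}\n")
        obs.table.to_csv(fh, sep="\t", index=False)
    return Path(path)


def read_observations(path) -> AlleleObservations:
    n_snps = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            n_snps = int(first.split(":")[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    df["alt"] = df["alt"].astype(bool)
    if n_snps is None:
        n_snps = int(df["snp"].max()) + 1
    return AlleleObservations(df, n_snps=n_snps)


def read_panel(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["CHROM", "POS", "REF", "ALT"]
    if df.columns[:4].tolist() != fixed:
        raise ValueError(f"panel must start with columns {fixed}")
    donors = df.columns[4:].tolist()
    if not donors:
        raise ValueError("panel has no donor columns")
    G = df[donors].replace(".", np.nan).to_numpy(dtype=float).T
    snps = pd.DataFrame(
        {
            "chrom": df["CHROM"],
            "pos": df["POS"].astype(int),
            "ref": df["REF"],
            "alt": df["ALT"],
        }
    )
    return GenotypePanel(snps=snps, donors=donors, genotypes=G)
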