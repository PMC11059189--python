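"""Synthetic single-cell contact generator with full ground truth.

Emulates the statistical structure that the downstream analyses assume:

* stage-dependent intra-chromosomal distance distributions — a truncated
  power law p(s) ~ s^-alpha on [10 kb, 10 Mb) mixed with a log-uniform
  ultra-long-range component on [10 Mb, chromosome length], mixed at the
  preset's target fraction ``f_ultra``;
* compartment-biased partner choice with preference ``rho`` for
  same-compartment (A/A or B/B) bin pairs;
* per-stage compartment drift of designated dynamic bins (each drifting
  bin interpolates from its baseline track value toward a target in the
  opposite compartment as the preset's ``drift_level`` goes 0 -> 1);
* inter-chromosomal contacts with chromosome-pair hub weights;
* X-chromosome dosage (male cells carry one X: X anchor weight halved);
* pooled-donor SNP panels with sparse, noisy per-cell allele observations.

Everything is deterministic under (design, seed); per-cell RNG streams are
spawned from a single root ``SeedSequence`` keyed by cell index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import BinIndex, CompartmentTrack, ContactSet, Genome, make_bins
from .demux import AlleleObservations, GenotypePanel

__all__ = [
    "StagePreset",
    "CohortDesign",
    "PoolDesign",
    "DriftPlan",
    "load_presets",
    "get_preset",
    "make_compartment_track",
    "designate_dynamic_bins",
    "sample_intra_distances",
    "expected_ultra_fraction",
    "simulate_cell",
    "simulate_cohort",
    "simulate_pool",
    "default_cohort_design",
]

ULTRA_MIN = 10_000_000  # bp; ultra-long-range threshold
SHORT_MIN = 10_000  # bp; lower bound of the short-range component


# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class StagePreset:
    """Generator parameters for one structure type / stage.

    ``f_ultra`` is the target fraction of intra-chromosomal contacts
    spanning >= 10 Mb; ``drift_level`` positions the preset along the
    compartment-drift trajectory shared by a cohort (0 at the first
    stage, 1 at the last).
    """

    name: str
    f_ultra: float
    alpha: float = 1.0
    f_inter: float = 0.03
    rho: float = 0.7
    drift_level: float = 0.0
    genome_tag: str = "human"
    hub_chroms: tuple[str, ...] = ()
    hub_pairs: tuple[tuple[str, str], ...] = ()
    hub_weight: float = 1.0

    def __post_init__(self) -> None:
        for nm, v in (("f_ultra", self.f_ultra), ("f_inter", self.f_inter), ("rho", self.rho)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1], got {v}")
        if self.hub_weight < 0:
            raise ValueError("hub weight must be nonnegative")

    def hub_matrix(self, genome: Genome) -> np.ndarray:
        """Symmetric nonnegative chromosome-pair weight matrix, normalized so
        that the off-diagonal entries average 1."""
        n = genome.n_chroms
        w = np.ones((n, n))
        idx = genome.index
        hub = [idx[c] for c in self.hub_chroms if c in idx]
        for a in hub:
            for b in hub:
                if a != b:
                    w[a, b] = self.hub_weight
        for ca, cb in self.hub_pairs:
            if ca in idx and cb in idx:
                w[idx[ca], idx[cb]] = w[idx[cb], idx[ca]] = self.hub_weight
        np.fill_diagonal(w, 0.0)
        off = w[~np.eye(n, dtype=bool)]
        if off.size and off.mean() > 0:
            w = w / off.mean()
        return w

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "StagePreset":
        hub = d.get("hub") or {}
        return cls(
            name=name,
            f_ultra=float(d["f_ultra"]),
            alpha=float(d.get("alpha", 1.0)),
            f_inter=float(d.get("f_inter", 0.03)),
            rho=float(d.get("rho", 0.7)),
            drift_level=float(d.get("drift_level", 0.0)),
            genome_tag=str(d.get("genome", "human")),
            hub_chroms=tuple(hub.get("chroms", ())),
            hub_pairs=tuple((a, b) for a, b in hub.get("pairs", ())),
            hub_weight=float(hub.get("weight", 1.0)),
        )


def load_presets() -> dict[str, StagePreset]:
    """Load the packaged preset library (data/presets.yaml)."""
    ref = resources.files("cbg3d.data") / "presets.yaml"
    raw = yaml.safe_load(ref.read_text())
    return {name: StagePreset.from_dict(name, d) for name, d in raw.items()}


def get_preset(name: str) -> StagePreset:
    presets = load_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]


# ---------------------------------------------------------------------------
# compartment track + drift ground truth


def make_compartment_track(
    genome: Genome,
    bin_size: int,
    mean_block_bins: float = 5.0,
    seed: int | np.random.Generator = 0,
    a_fraction: float = 0.5,
) -> CompartmentTrack:
    """Alternating A/B block track with ground-truth labels.

    Block lengths are geometric with the given mean (in bins), scaled so
    the expected A-bin proportion equals ``a_fraction``; A bins draw
    values from U[0.6, 1.0], B bins from U[0.0, 0.4].
    """
    if mean_block_bins < 1:
        raise ValueError("block length must be >= 1 bin")
    if not 0 < a_fraction < 1:
        raise ValueError("a_fraction must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bi = make_bins(genome, bin_size)
    n = bi.n_bins
    labels = np.empty(n, dtype="U1")
    values = np.empty(n, dtype=float)
    mean_a = 2 * mean_block_bins * a_fraction
    mean_b = 2 * mean_block_bins * (1 - a_fraction)
    # blocks restart at each chromosome boundary
    for ci in range(genome.n_chroms):
        start, stop = bi.offsets[ci], bi.offsets[ci] + bi.n_bins_per_chrom[ci]
        pos = start
        state = "A" if rng.random() < a_fraction else "B"
        while pos < stop:
            mean = mean_a if state == "A" else mean_b
            blk = int(rng.geometric(min(1.0, 1.0 / mean)))
            end = min(pos + blk, stop)
            labels[pos:end] = state
            if state == "A":
                values[pos:end] = rng.uniform(0.6, 1.0, end - pos)
            else:
                values[pos:end] = rng.uniform(0.0, 0.4, end - pos)
            pos = end
            state = "B" if state == "A" else "A"
    return CompartmentTrack(bi, values, truth_labels=labels)


@dataclass(frozen=True)
class DriftPlan:
    """Designated dynamic bins and their compartment targets.

    ``targets`` has one entry per global bin: NaN for static bins, the
    fully-drifted compartment value for dynamic bins.  At drift level
    ``t`` a dynamic bin's effective value is ``base + t * (target - base)``.
    """

    up_bins: np.ndarray  # B-baseline bins drifting toward A
    down_bins: np.ndarray  # A-baseline bins drifting toward B
    targets: np.ndarray

    @property
    def dynamic_bins(self) -> np.ndarray:
        return np.sort(np.concatenate([self.up_bins, self.down_bins]))

    def effective_values(self, base: np.ndarray, level: float) -> np.ndarray:
        eff = np.asarray(base, dtype=float).copy()
        m = ~np.isnan(self.targets)
        eff[m] = base[m] + level * (self.targets[m] - base[m])
        return eff


def designate_dynamic_bins(
    track: CompartmentTrack, n_dynamic: int = 120, seed: int | np.random.Generator = 0
) -> DriftPlan:
    """Pick ``n_dynamic`` bins (half up, half down) to drift across stages.

    Up-drifting bins start in compartment B and target a value in
    [0.6, 1.0]; down-drifting bins start in A and target [0.0, 0.4].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = track.values
    b_bins = np.flatnonzero(vals < 0.5)
    a_bins = np.flatnonzero(vals >= 0.5)
    n_up = n_dynamic // 2
    n_down = n_dynamic - n_up
    if len(b_bins) < n_up or len(a_bins) < n_down:
        raise ValueError("track has too few bins of each compartment for the drift plan")
    up = np.sort(rng.choice(b_bins, n_up, replace=False))
    down = np.sort(rng.choice(a_bins, n_down, replace=False))
    targets = np.full(track.bin_index.n_bins, np.nan)
    targets[up] = rng.uniform(0.6, 1.0, n_up)
    targets[down] = rng.uniform(0.0, 0.4, n_down)
    return DriftPlan(up_bins=up, down_bins=down, targets=targets)


# ---------------------------------------------------------------------------
# distance sampling


def _sample_short(rng: np.random.Generator, n: int, alpha: float, smin: float, smax: float) -> np.ndarray:
    """Inverse-CDF sampling of the truncated power law p(s) ~ s^-alpha."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return smin * (smax / smin) ** u
    a = 1.0 - alpha
    return (smin**a + u * (smax**a - smin**a)) ** (1.0 / a)


def sample_intra_distances(
    preset: StagePreset,
    chrom_length: int,
    n: int,
    rng: np.random.Generator,
    f_ultra: float | None = None,
) -> np.ndarray:
    """Draw ``n`` intra-chromosomal contact distances (bp) for one chromosome.

    With probability ``f_ultra`` the distance is log-uniform on
    [10 Mb, chromosome length]; otherwise truncated power law on
    [10 kb, 10 Mb).  Chromosomes too short for the ultra component draw
    only the short component.
    """
    if f_ultra is None:
        f_ultra = preset.f_ultra
    L = int(chrom_length)
    dmax = L - 1  # a pair must fit on the chromosome
    smax = min(float(ULTRA_MIN), float(dmax))
    smin = min(float(SHORT_MIN), smax / 2.0)
    d = np.empty(n, dtype=float)
    if dmax <= ULTRA_MIN or f_ultra <= 0:
        d[:] = _sample_short(rng, n, preset.alpha, smin, smax)
    else:
        ultra = rng.random(n) < f_ultra
        k = int(ultra.sum())
        if k:
            lo, hi = np.log(float(ULTRA_MIN)), np.log(float(dmax))
            d[ultra] = np.exp(lo + rng.random(k) * (hi - lo))
        if k < n:
            d[~ultra] = _sample_short(rng, n - k, preset.alpha, smin, smax)
    return np.clip(np.rint(d), 1, dmax).astype(np.int64)


def sample_intra_distance(preset: StagePreset, chrom_length: int, seed: int) -> int:
    """Scalar convenience wrapper around :func:`sample_intra_distances`."""
    return int(sample_intra_distances(preset, chrom_length, 1, np.random.default_rng(seed))[0])


def _anchor_weights(genome: Genome, sex: str | None) -> np.ndarray:
    w = genome.lengths_array.astype(float).copy()
    if sex == "M" and genome.x_index is not None:
        w[genome.x_index] *= 0.5
    return w


def expected_ultra_fraction(preset: StagePreset, genome: Genome, sex: str | None = "F") -> float:
    """Analytic expectation of the intra-contact fraction >= 10 Mb.

    The nominal mixture weight is boosted on chromosomes long enough to
    host the ultra component so that the genome-wide expectation matches
    ``f_ultra`` whenever the boost stays a valid probability; short
    chromosomes contribute only the short component.
    """
    w = _anchor_weights(genome, sex)
    long_mask = genome.lengths_array - 1 > ULTRA_MIN
    p_long = float(w[long_mask].sum() / w.sum()) if w.sum() > 0 else 0.0
    if p_long == 0.0:
        return 0.0
    f_eff = min(1.0, preset.f_ultra / p_long)
    return f_eff * p_long


def _ultra_boost(preset: StagePreset, genome: Genome, sex: str | None) -> float:
    """Per-long-chromosome ultra weight implied by the genome's length mix."""
    w = _anchor_weights(genome, sex)
    long_mask = genome.lengths_array - 1 > ULTRA_MIN
    p_long = float(w[long_mask].sum() / w.sum()) if w.sum() > 0 else 0.0
    if p_long == 0.0:
        return 0.0
    return min(1.0, preset.f_ultra / p_long)


# ---------------------------------------------------------------------------
# single-cell simulation

_MATCH_ROUNDS = 64


def _effective_classes(
    track: CompartmentTrack | None, drift_plan: DriftPlan | None, level: float
) -> np.ndarray | None:
    if track is None:
        return None
    base = np.nan_to_num(track.values, nan=0.5)
    eff = drift_plan.effective_values(base, level) if drift_plan is not None else base
    return eff >= 0.5  # True = A-like


def simulate_cell(
    preset: StagePreset,
    genome: Genome,
    track: CompartmentTrack | None,
    n_contacts: int,
    seed: int | np.random.Generator = 0,
    sex: str = "F",
    drift_plan: DriftPlan | None = None,
    cell_id: str = "cell",
    donor: str | None = None,
    age: float | None = None,
    age_unit: str = "years",
) -> ContactSet:
    """Simulate one cell's contact list under a stage preset.

    Each contact is inter-chromosomal with probability ``f_inter``
    (chromosome pair drawn proportional to length_i * length_j * hub
    weight); otherwise intra-chromosomal with an anchor chromosome drawn
    proportional to length (male X halved), a distance from the
    stage-dependent mixture, and the anchor placed uniformly among
    positions where the pair fits — so sampled distances are realized
    exactly.  With probability ``rho`` a contact is re-anchored until its
    two endpoint bins share an (effective, drift-adjusted) compartment.
    """
    if n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = _effective_classes(track, drift_plan, preset.drift_level)
    bi = track.bin_index if track is not None else None
    lens = genome.lengths_array

    f_inter = preset.f_inter if genome.n_chroms > 1 else 0.0
    n_inter = int(rng.binomial(n_contacts, f_inter))
    n_intra = n_contacts - n_inter

    parts: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []

    if n_intra:
        w = _anchor_weights(genome, sex)
        chroms = rng.choice(genome.n_chroms, n_intra, p=w / w.sum()).astype(np.int32)
        f_eff = _ultra_boost(preset, genome, sex)
        d = np.empty(n_intra, dtype=np.int64)
        for ci in np.unique(chroms):
            m = chroms == ci
            d[m] = sample_intra_distances(preset, int(lens[ci]), int(m.sum()), rng, f_ultra=f_eff)
        span = lens[chroms] - d  # number of valid anchor starts
        anchor = 1 + (rng.random(n_intra) * span).astype(np.int64)
        partner = anchor + d
        if classes is not None and preset.rho > 0:
            want = rng.random(n_intra) < preset.rho
            off = bi.offsets_array
            bs = bi.bin_size
            for rnd in range(2 * _MATCH_ROUNDS):
                b1 = off[chroms] + (anchor - 1) // bs
                b2 = off[chroms] + (partner - 1) // bs
                bad = want & (classes[b1] != classes[b2])
                if not bad.any():
                    break
                if rnd >= _MATCH_ROUNDS:
                    # some (chromosome, distance) pairs admit no same-class
                    # placement at all; redraw the distance for the stragglers
                    for ci in np.unique(chroms[bad]):
                        m = bad & (chroms == ci)
                        d[m] = sample_intra_distances(
                            preset, int(lens[ci]), int(m.sum()), rng, f_ultra=f_eff
                        )
                    span[bad] = lens[chroms[bad]] - d[bad]
                k = int(bad.sum())
                anchor[bad] = 1 + (rng.random(k) * span[bad]).astype(np.int64)
                partner[bad] = anchor[bad] + d[bad]
        parts.append((chroms, anchor, chroms.copy(), partner))

    if n_inter:
        w = _anchor_weights(genome, sex)
        pair_w = np.outer(w, w) * preset.hub_matrix(genome)
        iu, ju = np.triu_indices(genome.n_chroms, k=1)
        p = pair_w[iu, ju]
        p = p / p.sum()
        pick = rng.choice(len(p), n_inter, p=p)
        ci, cj = iu[pick].astype(np.int32), ju[pick].astype(np.int32)
        pi = 1 + (rng.random(n_inter) * lens[ci]).astype(np.int64)
        pj = 1 + (rng.random(n_inter) * lens[cj]).astype(np.int64)
        if classes is not None and preset.rho > 0:
            want = rng.random(n_inter) < preset.rho
            off = bi.offsets_array
            bs = bi.bin_size
            for rnd in range(2 * _MATCH_ROUNDS):
                b1 = off[ci] + (pi - 1) // bs
                b2 = off[cj] + (pj - 1) // bs
                bad = want & (classes[b1] != classes[b2])
                if not bad.any():
                    break
                k = int(bad.sum())
                if rnd >= _MATCH_ROUNDS:  # stuck pair (e.g. single-class chrom): redraw it
                    repick = rng.choice(len(p), k, p=p)
                    ci[bad], cj[bad] = iu[repick].astype(np.int32), ju[repick].astype(np.int32)
                pi[bad] = 1 + (rng.random(k) * lens[ci[bad]]).astype(np.int64)
                pj[bad] = 1 + (rng.random(k) * lens[cj[bad]]).astype(np.int64)
        parts.append((ci, pi, cj, pj))

    chrom1 = np.concatenate([p[0] for p in parts])
    pos1 = np.concatenate([p[1] for p in parts])
    chrom2 = np.concatenate([p[2] for p in parts])
    pos2 = np.concatenate([p[3] for p in parts])
    return ContactSet(
        cell_id=cell_id,
        genome=genome,
        chrom1=chrom1,
        pos1=pos1,
        chrom2=chrom2,
        pos2=pos2,
        donor=donor,
        age=age,
        age_unit=age_unit,
        sex=sex,
        species=genome.species,
        truth={"stage": preset.name, "donor": donor or "", "sex": sex},
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortDesign:
    """Design of a synthetic cohort: stage composition, depth, and seed."""

    genome: Genome
    stages: Sequence[tuple[StagePreset, int, tuple[float, float]]]  # (preset, n cells, age range in yr)
    n_contacts_mean: int = 20_000
    n_contacts_sigma: float = 0.15  # lognormal dispersion; 0 = constant depth
    bin_size: int = 1_000_000
    seed: int = 0
    female_fraction: float = 0.5
    donors: Sequence[str] = ("D1", "D2", "D3", "D4")
    n_dynamic_bins: int = 500  # ~top-20% of 1-Mb bins move across stages
    mean_block_bins: float = 5.0
    track: CompartmentTrack | None = None
    drift_plan: DriftPlan | None = None

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("empty cohort design")
        if any(n <= 0 for _, n, _ in self.stages):
            raise ValueError("n cells must be > 0 for every stage")


@dataclass
class Cohort:
    """A simulated cohort: cells, their metadata, and the generator truth."""

    cells: list[ContactSet]
    metadata: pd.DataFrame  # cell, stage_truth, donor, sex, age_years, n_contacts
    track: CompartmentTrack
    drift_plan: DriftPlan
    design: CohortDesign


def simulate_cohort(design: CohortDesign) -> Cohort:
    """Simulate every cell of a cohort design, reproducibly under its seed.

    Ages are log-uniform within each stage's range; per-cell contact
    counts are lognormal around the design mean; sexes and donors are
    drawn from the design composition.  Cell RNG streams are spawned from
    the design seed, so the cohort is reproducible cell-by-cell.
    """
    root = np.random.SeedSequence(design.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    track = design.track
    if track is None:
        track = make_compartment_track(
            design.genome, design.bin_size, design.mean_block_bins, rng
        )
    plan = design.drift_plan
    if plan is None:
        # cap at a fifth of the track so coarse-binned designs stay valid
        n_dyn = min(design.n_dynamic_bins, track.bin_index.n_bins // 5)
        plan = designate_dynamic_bins(track, max(2, n_dyn), rng)

    total = sum(n for _, n, _ in design.stages)
    cell_seeds = root.spawn(1 + total)[1:]
    cells: list[ContactSet] = []
    rows = []
    k = 0
    for preset, n, (age_lo, age_hi) in design.stages:
        ages = np.exp(rng.uniform(np.log(age_lo), np.log(age_hi), n))
        sexes = np.where(rng.random(n) < design.female_fraction, "F", "M")
        if design.n_contacts_sigma > 0:
            sig = design.n_contacts_sigma
            counts = np.maximum(
                1, np.rint(design.n_contacts_mean * np.exp(rng.normal(-sig**2 / 2, sig, n)))
            ).astype(int)
        else:
            counts = np.full(n, design.n_contacts_mean, dtype=int)
        for j in range(n):
            cid = f"cell_{k:05d}"
            donor = design.donors[k % len(design.donors)]
            cell = simulate_cell(
                preset,
                design.genome,
                track,
                int(counts[j]),
                seed=np.random.default_rng(cell_seeds[k]),
                sex=str(sexes[j]),
                drift_plan=plan,
                cell_id=cid,
                donor=donor,
                age=float(ages[j]),
            )
            cells.append(cell)
            rows.append(
                {
                    "cell": cid,
                    "stage_truth": preset.name,
                    "donor": donor,
                    "sex": str(sexes[j]),
                    "age_years": float(ages[j]),
                    "n_contacts": int(counts[j]),
                }
            )
            k += 1
    meta = pd.DataFrame(rows).set_index("cell")
    return Cohort(cells=cells, metadata=meta, track=track, drift_plan=plan, design=design)


def default_cohort_design(
    genome: Genome | None = None,
    n_per_stage: int = 100,
    n_contacts: int = 20_000,
    seed: int = 0,
    species: str = "human",
) -> CohortDesign:
    """The default five-stage granule-cell cohort.

    Stage age ranges bracket the ages at which the five structure stages
    peak in abundance in human (~0.2, 1, 10, 30 and 80 years).
    """
    from .core_io import load_packaged_genome

    if genome is None:
        genome = load_packaged_genome(species)
    presets = load_presets()
    tag = "human" if species == "human" else "mouse"
    if tag == "human":
        ranges = [(0.1, 0.5), (0.5, 3.0), (3.0, 20.0), (20.0, 50.0), (50.0, 86.0)]
    else:  # postnatal-day peaks P3..P365, expressed in years
        ranges = [(0.005, 0.02), (0.02, 0.05), (0.05, 0.12), (0.12, 0.5), (0.5, 1.8)]
    stages = [
        (presets[f"{tag}_S{i}"], n_per_stage, ranges[i - 1]) for i in range(1, 6)
    ]
    return CohortDesign(
        genome=genome, stages=stages, n_contacts_mean=n_contacts, seed=seed
    )


# ---------------------------------------------------------------------------
# pooled-donor SNP panels


@dataclass(frozen=True)
class PoolDesign:
    """Design of a synthetic pooled-donor experiment."""

    n_donors: int = 8
    n_cells: int = 672
    n_snps: int = 1000
    coverage: float = 0.15  # per-SNP observation probability per cell
    epsilon: float = 0.01  # allele read error
    allele_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("need >= 2 donors")
        if self.n_snps < 1:
            raise ValueError("need >= 1 SNP")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")


def simulate_pool(
    design: PoolDesign, seed: int = 0
) -> tuple[GenotypePanel, AlleleObservations, pd.Series]:
    """Simulate a genotype panel plus sparse per-cell allele observations.

    Donor genotypes are Hardy-Weinberg draws at the design allele
    frequency.  Each cell (donors assigned round-robin) observes each SNP
    with probability ``coverage``; the read allele is drawn from the
    donor's dosage and flipped with probability ``epsilon``.  Returns
    (panel, observations, truth donor per cell).
    """
    rng = np.random.default_rng(seed)
    donors = [f"D{i + 1}" for i in range(design.n_donors)]
    genotypes = rng.binomial(2, design.allele_freq, size=(design.n_donors, design.n_snps)).astype(float)
    snps = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": 10_000 * (np.arange(design.n_snps) + 1),
            "ref": "A",
            "alt": "G",
        }
    )
    panel = GenotypePanel(snps=snps, donors=donors, genotypes=genotypes)

    truth = pd.Series(
        [donors[i % design.n_donors] for i in range(design.n_cells)],
        index=[f"cell_{i:05d}" for i in range(design.n_cells)],
        name="donor",
    )
    rows = []
    for i, (cid, donor) in enumerate(truth.items()):
        g = genotypes[donors.index(donor)]
        seen = np.flatnonzero(rng.random(design.n_snps) < design.coverage)
        p_alt = g[seen] / 2.0
        alt = rng.random(len(seen)) < p_alt
        flip = rng.random(len(seen)) < design.epsilon
        alt = alt ^ flip
        rows.append(
            pd.DataFrame(
                {"cell": cid, "snp": seen, "alt": alt.astype(bool), "count": 1}
            )
        )
    obs = AlleleObservations(pd.concat(rows, ignore_index=True), n_snps=design.n_snps)
    return panel, obs, truth
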