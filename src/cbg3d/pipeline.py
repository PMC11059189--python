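"""End-to-end orchestration: config validation, staged runs, reproducibility.

A run executes simulate (optional) -> scab -> stages -> stats -> dynamics
into one flat run directory.  Every emitted table carries the config hash
and seed in its header; partial re-runs check the recorded hash of
upstream tables before reusing them.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contact_stats, demux, dynamics, scab, stages, synthetic_data
from .core_io import (
    CompartmentTrack,
    Genome,
    load_packaged_genome,
    make_bins,
    read_chrom_sizes,
    read_pairs,
    read_track,
    write_pairs,
    write_track,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

STAGES = ("simulate", "scab", "stages", "stats", "dynamics")


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults applied."""

    out_dir: str
    input_dir: str | None = None  # pairs files; omit to simulate
    chrom_sizes: str | None = None  # packaged genome used if omitted
    species: str = "human"
    track: str | None = None
    genes: str | None = None
    bin_size: int = 1_000_000
    ultra_threshold: int = 10_000_000
    min_contacts: int = 5
    qc_min_bins: int = 200
    top_frac: float = 0.20
    k_stages: int = 5
    epsilon: float = 0.01
    sex_cut: float = 0.75
    dynamics_min_support: int = 10
    seed: int = 0
    stage: str = "all"
    simulate: dict = field(default_factory=dict)  # n_per_stage, n_contacts

    def config_hash(self) -> str:
        d = asdict(self)
        # neither the requested stage nor where outputs land changes the products
        d.pop("stage", None)
        d.pop("out_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(source) -> RunConfig:
    """Normalize a config mapping or YAML file into a :class:`RunConfig`.

    Fills defaults, then hard-fails on out-of-range parameters or missing
    referenced paths.  Idempotent: re-validating an emitted config is a
    no-op.
    """
    if isinstance(source, RunConfig):
        raw = asdict(source)
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raw = yaml.safe_load(Path(source).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ValueError("config requires out_dir")
    cfg = RunConfig(**raw)
    if not 0 < cfg.top_frac <= 1:
        raise ValueError(f"top_frac must be in (0, 1], got {cfg.top_frac}")
    if not 0 < cfg.epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {cfg.epsilon}")
    if cfg.bin_size <= 0 or cfg.ultra_threshold <= 0:
        raise ValueError("bin_size and ultra_threshold must be > 0")
    if cfg.k_stages < 1:
        raise ValueError("k_stages must be >= 1")
    if cfg.stage not in ("all",) + STAGES:
        raise ValueError(f"unknown pipeline stage {cfg.stage!r}")
    for key in ("input_dir", "chrom_sizes", "track", "genes"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            raise ValueError(f"{key} path does not exist: {p}")
    if cfg.input_dir is None and cfg.stage in ("all", "simulate") and not cfg.simulate:
        cfg.simulate = {"n_per_stage": 20, "n_contacts": 10_000}
    return cfg


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg.config_hash()}\n")
        fh.write(f"# seed: {cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_table(path: Path, cfg: RunConfig, **kw) -> pd.DataFrame:
    with open(path) as fh:
        line = fh.readline()
        if not line.startswith("# config_hash:"):
            raise ValueError(f"{path}: missing config hash header")
        recorded = line.split(":", 1)[1].strip()
        if recorded != cfg.config_hash():
            raise ValueError(
                f"{path}: recorded config hash {recorded} does not match current "
                f"config {cfg.config_hash()}; re-run upstream stages"
            )
        fh.readline()  # seed line
        return pd.read_csv(fh, sep="\t", **kw)


def _load_genome(cfg: RunConfig) -> Genome:
    if cfg.chrom_sizes is not None:
        return read_chrom_sizes(cfg.chrom_sizes, species=cfg.species)
    return load_packaged_genome(cfg.species)


def _stage_simulate(cfg: RunConfig, out: Path, genome: Genome):
    sim = cfg.simulate
    design = synthetic_data.default_cohort_design(
        genome=genome,
        n_per_stage=int(sim.get("n_per_stage", 20)),
        n_contacts=int(sim.get("n_contacts", 10_000)),
        seed=cfg.seed,
        species=cfg.species,
    )
    design.bin_size = cfg.bin_size
    cohort = synthetic_data.simulate_cohort(design)
    pairs_dir = out / "pairs"
    write_pairs(cohort.cells, pairs_dir)
    write_track(cohort.track, out / "track.tsv")
    _write_table(cohort.metadata, out / "metadata.tsv", cfg)
    return cohort.cells, cohort.track, cohort.metadata


def _load_cells(cfg: RunConfig, out: Path, genome: Genome):
    src = Path(cfg.input_dir) if cfg.input_dir else out / "pairs"
    files = sorted(list(src.glob("*.pairs")) + list(src.glob("*.pairs.gz")))
    if not files:
        raise FileNotFoundError(f"no pairs files found in {src}")
    cells = [read_pairs(f, genome) for f in files]
    bi = make_bins(genome, cfg.bin_size)
    track_path = Path(cfg.track) if cfg.track else out / "track.tsv"
    if not track_path.exists():
        raise FileNotFoundError(f"compartment track not found: {track_path}")
    track = read_track(track_path, bi)
    rows = [
        {
            "cell": c.cell_id,
            "stage_truth": c.truth.get("stage", ""),
            "donor": c.donor or "",
            "sex": c.sex or "",
            "age_years": c.age_years if c.age_years is not None else np.nan,
            "n_contacts": len(c),
        }
        for c in cells
    ]
    meta = pd.DataFrame(rows).set_index("cell")
    return cells, track, meta


def _stage_scab(cfg: RunConfig, out: Path, cells, track):
    bi = track.bin_index
    mat = scab.scab_matrix(cells, bi, track, min_contacts=cfg.min_contacts)
    _write_table(mat.to_frame(), out / "scab_matrix.tsv", cfg)
    logger.info("scab: median bins covered per cell = %d", int(np.median(mat.bins_covered_per_cell)))
    return mat


def _stage_stages(cfg: RunConfig, out: Path, mat, meta):
    keep = stages.qc_filter(mat, cfg.qc_min_bins)
    if keep.size < max(2, cfg.k_stages):
        raise RuntimeError("too few cells pass the scA/B coverage QC gate")
    sub = scab.ScABMatrix(
        [mat.cell_ids[i] for i in keep], mat.bin_index, mat.values[keep], mat.support[keep]
    )
    X, _, _ = scab.impute_missing(sub)
    ages = meta.loc[sub.cell_ids, "age_years"].to_numpy(dtype=float)
    emb = stages.embed_scab(X, n_components=10, cell_ids=sub.cell_ids, ages=ages)
    ids = stages.cluster_stages(emb, cfg.k_stages)
    assign = stages.order_stages_by_age(ids, ages, cell_ids=sub.cell_ids)
    table = assign.table.copy()
    for j in range(min(3, emb.scores.shape[1])):
        table[f"PC{j + 1}"] = emb.scores[:, j]
    r, p = stages.age_correlation(emb.scores[:, 0], ages)
    table.attrs["pc1_logage_r"] = r
    _write_table(table, out / "stage_table.tsv", cfg)
    _write_table(assign.stage_summary, out / "stage_summary.tsv", cfg, index=False)
    logger.info("stages: PC1 vs log-age r = %.3f (p = %.2e)", r, p)
    return table


def _stage_stats(cfg: RunConfig, out: Path, cells, stage_table, genome):
    labels = stage_table["stage"]
    rows = []
    for c in cells:
        prof = contact_stats.distance_profile(c, cfg.ultra_threshold)
        rows.append(
            {
                "cell": c.cell_id,
                "fraction_ultra": prof.fraction_ge_threshold,
                "n_intra": prof.n_intra,
                "n_inter": prof.n_inter,
                "stage": labels.get(c.cell_id, ""),
            }
        )
    frac = pd.DataFrame(rows).set_index("cell")
    _write_table(frac, out / "distance_fractions.tsv", cfg)

    sex = demux.sex_demux(cells, genome, cut=cfg.sex_cut)
    _write_table(sex, out / "sex_demux.tsv", cfg)

    stage_names = sorted(x for x in pd.unique(labels) if x)
    comp_rows = []
    for a, b in zip(stage_names[:-1], stage_names[1:]):
        va = frac.loc[frac["stage"] == a, "fraction_ultra"].dropna()
        vb = frac.loc[frac["stage"] == b, "fraction_ultra"].dropna()
        if len(va) and len(vb):
            t = contact_stats.compare_groups(va, vb)
            comp_rows.append(
                {"stage_a": a, "stage_b": b, "U": t.u_statistic, "p": t.p_value,
                 "mean_a": t.mean_a, "sd_a": t.sd_a, "mean_b": t.mean_b, "sd_b": t.sd_b}
            )
    if comp_rows:
        _write_table(pd.DataFrame(comp_rows), out / "stage_comparisons.tsv", cfg, index=False)

    enr = contact_stats.interchrom_enrichment(cells, genome)
    enr_df = pd.DataFrame(enr.enrichment, index=enr.chrom_names, columns=enr.chrom_names)
    _write_table(enr_df, out / "interchrom_enrichment.tsv", cfg)
    hub = pd.DataFrame({"chrom": enr.chrom_names, "hub_score": enr.hub_score})
    _write_table(hub, out / "hub_scores.tsv", cfg, index=False)
    return frac


def _stage_dynamics(cfg: RunConfig, out: Path, mat, stage_table, track):
    labels = pd.Series("", index=pd.Index(mat.cell_ids, name="cell"))
    common = labels.index.intersection(stage_table.index)
    labels.loc[common] = stage_table.loc[common, "stage"]
    keep = labels != ""
    sub = scab.ScABMatrix(
        [cid for cid, k in zip(mat.cell_ids, keep) if k],
        mat.bin_index,
        mat.values[keep.to_numpy()],
        mat.support[keep.to_numpy()],
    )
    sm = dynamics.stage_mean_scab(sub, labels[keep].to_numpy(), min_support=cfg.dynamics_min_support)
    regions = dynamics.dynamic_regions(sm, top_frac=cfg.top_frac)
    traj = dynamics.cluster_trajectories(sm, regions.selected_bins, k=2)
    rows = []
    for b, score in zip(regions.selected_bins, regions.scores):
        chrom, start = mat.bin_index.bin_start(int(b))
        row = {"bin": int(b), "chrom": chrom, "start": start, "score": score,
               "trajectory": traj.loc[int(b)]}
        for s, name in enumerate(sm.stage_names):
            row[f"mean_{name}"] = sm.means[int(b), s]
        rows.append(row)
    _write_table(pd.DataFrame(rows), out / "dynamic_regions.tsv", cfg, index=False)

    if cfg.genes:
        genes = dynamics.read_gene_table(cfg.genes)
        bin_set = dynamics.map_genes_to_bins(genes, mat.bin_index)
        table, tests = dynamics.geneset_trajectory(sub, labels[keep].to_numpy(), bin_set)
        _write_table(table, out / "geneset_trajectory.tsv", cfg)
        test_df = pd.DataFrame(
            [
                {"stage_a": sm.stage_names[i], "stage_b": sm.stage_names[i + 1],
                 "U": t.u_statistic, "p": t.p_value}
                for i, t in enumerate(tests)
            ]
        )
        _write_table(test_df, out / "geneset_tests.tsv", cfg, index=False)
    return regions


def run_pipeline(config) -> Path:
    """Run the configured pipeline stages; returns the run directory.

    ``stage="all"`` runs everything end to end; a single stage name runs
    just that stage, reusing upstream outputs in the run directory after
    verifying their recorded config hash.
    """
    cfg = validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = _load_genome(cfg)
    todo = STAGES if cfg.stage == "all" else (cfg.stage,)

    cells = track = mat = stage_table = meta = None
    for name in todo:
        t0 = time.perf_counter()
        if name == "simulate":
            if cfg.input_dir is not None:
                continue  # real input supplied; nothing to simulate
            _stage_simulate(cfg, out, genome)
            # downstream stages reload from the written pairs files so that
            # full and partial runs see byte-identical, identically-ordered input
        elif name == "scab":
            if cells is None:
                cells, track, meta = _load_cells(cfg, out, genome)
            mat = _stage_scab(cfg, out, cells, track)
        elif name == "stages":
            if mat is None:
                cells, track, meta = _load_cells(cfg, out, genome)
                mat = _stage_scab(cfg, out, cells, track)
            stage_table = _stage_stages(cfg, out, mat, meta)
        elif name == "stats":
            if cells is None:
                cells, track, meta = _load_cells(cfg, out, genome)
            if stage_table is None:
                stage_table = _read_table(out / "stage_table.tsv", cfg, index_col=0)
            _stage_stats(cfg, out, cells, stage_table, genome)
        elif name == "dynamics":
            if mat is None:
                cells, track, meta = _load_cells(cfg, out, genome)
                mat = _stage_scab(cfg, out, cells, track)
            if stage_table is None:
                stage_table = _read_table(out / "stage_table.tsv", cfg, index_col=0)
            _stage_dynamics(cfg, out, mat, stage_table, track)
        logger.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages_run": list(todo),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out
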