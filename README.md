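# cbg3d

Single-cell 3D genome contact analysis across the lifespan.

`cbg3d` is a Python toolkit for analyzing per-cell chromatin contact lists
(Dip-C-style single-cell Hi-C) from tissues sampled across development and
aging, built around the analyses that reveal lifelong genome remodeling in
cerebellar granule neurons. It is aimed at computational biologists who have
per-cell contact files (pairs-dialect text), a chromosome-sizes table, and a
per-megabase reference A/B compartment track, and who want reproducible,
tested implementations of:

- **scA/B scoring** — the single-cell chromatin A/B compartment value of a
  1-Mb bin *b* in one cell is the mean reference compartment value of the
  bin's contact partners, excluding contacts that stay within the region
  (so the score reports on long-range structure):
  `scA/B(b) = mean{ track(partner(c)) : c touches b, c not within-region }`.
- **Structure-stage typing** — centered PCA of cells × bins scA/B profiles,
  Ward clustering on the top PCs, relabeling of clusters S1…Sk by ascending
  median donor age, and Pearson correlation of PC1 with log10(age).
- **Ultra-long-range contact statistics** — the per-cell fraction of
  intra-chromosomal contacts spanning ≥ 10 Mb, with two-sided Mann–Whitney
  U comparisons between cell groups.
- **Inter-chromosomal hubs** — chromosome-pair observed/expected enrichment
  under a marginal-product null, `E[i,j] = T·m_i·m_j / Σ_{k<l} m_k·m_l`,
  per-chromosome hub scores, and between-group log2 enrichment deltas.
- **Compartment trajectories** — per-bin mean scA/B at each stage, selection
  of the top-20% most dynamic 1-Mb regions, clustering of their trajectories
  into increasing/decreasing groups, and gene-set trajectories with
  consecutive-stage U tests.
- **Pooled-sample demultiplexing (Pop-C)** — assignment of pooled cells to
  donors by SNP genotype likelihood (per-read alt-allele probabilities ε,
  1/2, 1−ε for dosages 0/1/2), and to sex by the length-normalized
  X/autosome contact-endpoint ratio (≈1 in female, ≈0.5 in male cells).

Because real atlases of this kind are large external downloads, the package
ships a fully ground-truthed **synthetic cohort generator**
(`cbg3d.synthetic_data`) whose presets encode published per-cell-type
ultra-long-range contact fractions (e.g. human granule stages S1 → S5:
19% → 33%), compartment-biased partner choice, stage-wise compartment
drift, hub-weighted inter-chromosomal contacts, X dosage by sex, and sparse
noisy SNP observations. Every analysis stage is validated against this
generator's ground truth.

## Worked example

Simulate a five-stage cohort (30 cells per stage, 20,000 contacts per
cell), score scA/B, type stages, and compare ultra-long-range fractions:

```python
import numpy as np
from cbg3d.synthetic_data import default_cohort_design, simulate_cohort
from cbg3d.scab import scab_matrix, impute_missing
from cbg3d.stages import embed_scab, cluster_stages, order_stages_by_age, age_correlation
from cbg3d.contact_stats import distance_profile, compare_groups

design = default_cohort_design(n_per_stage=30, n_contacts=20_000, seed=0)
cohort = simulate_cohort(design)

mat = scab_matrix(cohort.cells, cohort.track.bin_index, cohort.track)
X, kept, dropped = impute_missing(mat)
ages = cohort.metadata["age_years"].to_numpy()
emb = embed_scab(X, n_components=10, cell_ids=mat.cell_ids, ages=ages)
assign = order_stages_by_age(cluster_stages(emb, k=5), ages, mat.cell_ids)
r, p = age_correlation(emb.scores[:, 0], ages)
print(f"PC1 vs log10(age): r = {r:.3f} (p = {p:.1e})")

frac = {s: [] for s in ("S1", "S5")}
for cell, stage in zip(cohort.cells, assign.table["stage"]):
    if stage in frac:
        frac[stage].append(distance_profile(cell).fraction_ge_threshold)
test = compare_groups(frac["S1"], frac["S5"])
print(f"ultra-long-range fraction: S1 = {100*test.mean_a:.1f} +/- {100*test.sd_a:.1f} %, "
      f"S5 = {100*test.mean_b:.1f} +/- {100*test.sd_b:.1f} % (U test p = {test.p_value:.1e})")
```

Output:

```
PC1 vs log10(age): r = 0.930 (p = 2.3e-66)
ultra-long-range fraction: S1 = 19.0 +/- 0.2 %, S5 = 33.0 +/- 0.4 % (U test p = 1.6e-10)
```

PC1 of the scA/B profiles tracks log age tightly (the stage transformation
is the dominant source of compartment variation), and the earliest/latest
stages recover their designed ultra-long-range contact fractions.

The same pipeline is available from the shell:

```sh
cbg3d simulate --n-per-stage 30 --n-contacts 20000 --seed 0 --out run/
cbg3d run --config config.yaml          # simulate -> scab -> stages -> stats -> dynamics
cbg3d demux --mode genotype --panel panel.tsv --obs obs.tsv --out donors.tsv
```

## Layout

- `src/cbg3d/core_io.py` — genome model, binning, pairs/track I/O
- `src/cbg3d/synthetic_data.py` — cohort/pool generator and preset library
- `src/cbg3d/demux.py` — genotype and sex demultiplexing
- `src/cbg3d/scab.py` — scA/B scoring
- `src/cbg3d/stages.py` — embedding, clustering, age ordering
- `src/cbg3d/contact_stats.py` — distance and inter-chromosomal statistics
- `src/cbg3d/dynamics.py` — dynamic regions and trajectories
- `src/cbg3d/pipeline.py`, `src/cbg3d/cli.py` — orchestration and CLI

See `docs/methods.md` for the models, parameter choices, and limitations.
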