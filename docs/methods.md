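# Methods

This note documents the models implemented in `cbg3d`, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Coordinate and data model

Input contacts are pairs-dialect text, one file per cell, with 1-based
positions (the dominant contact-file convention). Bins are 0-based
half-open internally; a 1-based position `p` maps to bin ordinal
`(p − 1) // bin_size`, so position 1,000,000 falls in bin 0 and 1,000,001
in bin 1 at 1-Mb resolution. Contacts are canonicalized (chromosome order
by the genome's stated order; ascending position within a chromosome) on
construction, and canonicalization is idempotent. Contacts with both
endpoints at the same position are kept; they drop out of distance
statistics naturally. Records on unknown chromosomes or with out-of-range
positions are skipped with a logged count rather than aborting the run, so
unplaced scaffolds in real data do not kill a batch. Donor age is stored
with an explicit unit (years or postnatal days) and converted at
1 day = 1/365 yr wherever species are compared.

## scA/B scoring

The scA/B value of bin *b* in one cell is the mean reference-track value of
the partner bins over all contacts touching *b*. Each contact contributes
to both of its endpoint bins (symmetric attribution). Contacts whose two
endpoints fall within the same region — same bin, optionally widened by an
exclusion radius in bins (default 0, i.e. the 1-Mb bin itself) — are
excluded, so the score primarily reflects long-range structure. Bins with
fewer than `min_contacts` (default 5) contributing contacts are masked.
Because the score is a count-normalized mean, it is invariant under
duplication of a cell's contact list.

The reference track is any per-bin compartment value scaled to [0, 1]
(A-like high); a CpG-density rank track is the natural choice for real
data, and the generator's own track serves for synthetic data. Raw track
means are reported without per-cell z-scoring by default; both paths exist
because the literature is split on whether to standardize before PCA, and
the default keeps scA/B interpretable on the track's own scale.

## Stage typing

Imputation (bin-mean by default; never-observed bins are dropped) completes
the matrix for PCA. Embedding is centered PCA with deterministic full SVD;
the sign of PC1 is fixed to correlate positively with log age when ages are
known, since PCA is otherwise sign-ambiguous. Cells covering fewer than
200 scA/B bins are excluded by a configurable QC gate before embedding.
Clustering is Ward-linkage agglomerative clustering on the top 10 PCs —
hierarchical clustering is the method used for the analogous published
heat-map orderings, and is deterministic, which matters for reproducible
runs. The number of stages `k` is a user parameter, not an algorithmic
constant: five stages in granule cells is a finding about the data, not
about the method. Clusters are relabeled S1…Sk by ascending median donor
age (ties break by cluster id; clusters with no aged cells sort last and
are flagged). Age correlations are Pearson r against log10(age in years),
because stages spread multiplicatively across a lifespan. A seeded t-SNE
is provided for visualization parity only and is never used for
assignment.

## Contact-distance statistics

The ultra-long-range fraction of a cell is the fraction of its
**intra-chromosomal** contacts spanning at least 10 Mb (inclusive
threshold). Inter-chromosomal contacts have no genomic distance and are
excluded from the denominator — the one place where the statistic's
definition is genuinely ambiguous in the literature; generator and
statistic share this convention so calibration is self-consistent.
Two-group comparisons use the two-sided Mann–Whitney U test: exact
enumeration for tie-free groups of ≤ 20, otherwise the normal
approximation with continuity and tie correction.

## Inter-chromosomal enrichment

For a cell group, observed counts per chromosome pair are compared with a
marginal-product expectation `E[i,j] = T · m_i · m_j / Σ_{k<l} m_k m_l`,
where `m_i` is the number of inter-contact endpoints on chromosome i and
`T` the total inter contacts; the expected matrix sums to `T`. Contact
marginals (not chromosome lengths) are the default because coverage
differences between chromosomes would otherwise masquerade as enrichment.
The trade-off is deliberate and documented: when contacts genuinely
concentrate in a hub, part of that signal inflates the hub chromosomes'
marginals, so marginal-normalized enrichment under-states the raw hub
weight (a simulated pair weight of 2.0 reads as ≈ 1.5–1.6). A
`expected="length"` option uses length-product marginals instead, which
recovers a simulated hub weight essentially exactly and is what the
ground-truth recovery test uses. Hub scores are reported as continuous
per-chromosome means of pairwise enrichment; no threshold defines "hub
membership". Group contrasts are `log2(enrichment_B / enrichment_A)` per
pair, masked where either side is undefined.

## Dynamic regions and trajectories

Per-bin stage means are computed over unmasked entries only; a bin is
eligible when every stage supports it with ≥ 10 cells (sparse stage means
are unstable). The dynamic score is the range (max − min) of the stage
means — chosen over variance for interpretability, with variance available
as an option. Exactly `round(top_frac × n_eligible)` bins are selected
(default top_frac 0.20), ties breaking by bin id so selection is
deterministic. Trajectory clustering Ward-clusters the row-centered stage
profiles into k = 2 groups named "increasing"/"decreasing" by the sign of
the mean last-minus-first change. Gene sets are mapped to bins by interval
overlap of a BED-like table (0-based half-open); a gene spanning a bin
boundary contributes every overlapped bin.

## Synthetic data generator

The generator produces cohorts with the statistical structure the
analyses assume, with full ground truth. Per preset:

- **Distances.** Intra-chromosomal distances are a two-component mixture:
  a truncated power law `p(s) ∝ s^−α` on [10 kb, 10 Mb) (α default 1.0 —
  the short-range shape is this package's choice, configurable) and a
  log-uniform ultra tail on [10 Mb, chromosome length], mixed at the
  preset's `f_ultra`. Chromosomes too short for the tail draw only the
  short component, and the mixture weight on long chromosomes is boosted
  so the genome-wide expectation still equals `f_ultra`. The anchor is
  placed uniformly among positions where the pair fits on the chromosome,
  so sampled distances are realized exactly — this is why calibration
  round-trips recover preset fractions to well within a percentage point.
  (Reflecting out-of-range partners at chromosome ends was considered and
  rejected: reflection shortens realized distances and would bias the
  calibrated fractions downward.)
- **Preset fractions.** `f_ultra` defaults encode published per-cell-type
  values: human granule S1 0.19 and S5 0.33, mouse S1 0.19 and S5 0.34
  (intermediate stages interpolate linearly), mature human forebrain
  neuron 0.16, adult Purkinje 0.10, microglia 0.34, oligodendrocyte 0.29
  (human) / 0.27 (mouse).
- **Compartments.** The reference track alternates A/B blocks (geometric
  block lengths, mean 5 bins; A values U[0.6, 1.0], B values U[0.0, 0.4]).
  With probability ρ (default 0.7) a contact is re-anchored until both
  endpoint bins share a compartment class (value ≥ 0.5 = A), keeping the
  sampled distance fixed; stragglers whose (chromosome, distance) admits
  no same-class placement redraw the distance. At ρ = 1 every contact
  joins same-compartment bins.
- **Drift.** A designated set of dynamic bins (default 500 — matching the
  scale of the published top-20% dynamic-region count — half up, half
  down) interpolates linearly from its baseline track value toward a
  target in the opposite compartment as the preset's `drift_level` goes
  0 → 1 across stages (granule presets: 0, 0.25, 0.5, 0.75, 1). Drift
  affects partner *choice* (the effective class used for matching), while
  scA/B is always measured against the baseline track, so drifting bins
  change their measured scA/B through their changing contact partners —
  the same causal path the statistic is designed to detect. Individual
  bins flip class at different drift levels depending on their baseline,
  so cohort-level trajectories rise or fall progressively across stages.
- **Inter-chromosomal contacts.** Each contact is inter-chromosomal with
  probability `f_inter` (granule presets ramp 0.02 → 0.06 across stages; a
  modest, unpublished parameter chosen in the range typical of clean
  single-cell Hi-C). Pairs are drawn ∝ length_i·length_j·hub_weight_ij;
  hub weights (human granule: the 9-chromosome hub of chr1, 9, 11, 14, 15,
  16, 17, 21, 22; mouse: chr7 paired with 4, 5, 11, 17, 19) ramp from 1.0
  at S1 to 2.0 at S5 and the weight matrix is renormalized to mean 1.
- **Sex dosage.** Male cells halve the X-chromosome anchor weight, giving
  X/autosome endpoint-density ratios near 0.5 (male) and 1.0 (female);
  the sex-demux cut of 0.75 is the midpoint of these analytic
  expectations.
- **Depth and ages.** Cells carry 5,000–50,000 contacts (default mean
  20,000 with lognormal dispersion 0.15) rather than the ~500,000 of a
  deeply sequenced real cell — distances and compartment statistics stay
  biologically meaningful at desk scale. Ages are log-uniform within
  stage ranges bracketing the published stage-abundance peaks (~0.2, 1,
  10, 30, 80 years in human).
- **Pools.** Donor genotypes are Hardy–Weinberg draws at allele frequency
  0.5; each cell observes each SNP with the coverage probability (default
  0.15, within the assay's 10–20% genomic coverage), and the read allele
  flips with error ε (default 0.01).

Reproducibility: one root seed per design; per-cell streams are spawned
from a `SeedSequence`, so cohorts are reproducible cell-by-cell and
parallelizable.

What the generator does **not** emulate: TADs, loops and polymer physics;
haplotype phase; read-level alignment artifacts; donor-level batch
structure; doublets; allelic imbalance at heterozygous sites. Passing
tests therefore demonstrate that the statistics recover the structures
they are defined on — not that those structures exhaust real data.

## Demultiplexing model

Per-read alt-allele probabilities are ε, 1/2, 1 − ε for donor dosages
0/1/2; missing dosages contribute 1/2; counts multiply the per-read log
term. The posterior is a softmax over donors with a uniform prior by
default; ties break deterministically by donor order and any cell whose
top posterior falls below 0.95 is flagged ambiguous. There is no doublet
model (doublet-aware genotype-free demultiplexing is an existing external
tool), and heterozygous sites ignore allelic imbalance — adequate at the
panel scales used here, where ~150 observed SNPs of which roughly half
are informative between any two unrelated donors separate posteriors by
hundreds of log units. ε and the ambiguity threshold are this package's
defaults; they are not published constants.

## Numerical choices and degenerate inputs

- Selection counts use round-half-up so `0.2 × 2,500 = 500` exactly.
- All stochastic components accept either an integer seed or a
  `numpy.random.Generator`; nothing reads global RNG state.
- Cells with no intra-chromosomal contacts have an undefined (NaN)
  ultra fraction and are flagged rather than zeroed; likewise cells with
  no autosomal endpoints for the sex ratio, and zero-variance inputs for
  the age correlation.
- Pipeline tables embed a config hash (excluding output location); partial
  re-runs verify the hash of upstream tables before reuse, and the
  pipeline reloads simulated cells from their written pairs files so full
  and partial runs accumulate floating-point sums in the same order and
  produce byte-identical outputs.

## Problem sizes

Defaults throughout target a laptop-scale desk run: cohorts of 100 cells
per stage at 20,000 contacts per cell for recovery experiments, 200 cells
per preset for calibration, and a 672-cell pool for demultiplexing
validation. All of these complete in seconds to a couple of minutes on a
single CPU.

## Known limitations

- De novo compartment calling (eigenvector on pooled correlation maps) is
  out of scope; a reference track must be supplied.
- The marginal-product enrichment null is conservative in the presence of
  strong hubs (see above); interpret hub scores comparatively, not as
  absolute weights.
- Stage typing assumes stages are separable in scA/B space; continuous
  maturation without discrete structure will still be partitioned into k
  clusters.
- The generator's drift mechanism moves whole 1-Mb bins; sub-bin
  compartment rearrangements are not modeled.
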