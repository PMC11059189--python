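import numpy as np
import pytest

from cbg3d.contact_stats import distance_profile
from cbg3d.core_io import Genome
from cbg3d.synthetic_data import (
    CohortDesign,
    PoolDesign,
    StagePreset,
    ULTRA_MIN,
    designate_dynamic_bins,
    expected_ultra_fraction,
    get_preset,
    load_presets,
    make_compartment_track,
    sample_intra_distances,
    simulate_cell,
    simulate_cohort,
    simulate_pool,
)


class TestPresets:
    def test_library_loads_granule_stages(self):
        presets = load_presets()
        for tag in ("human", "mouse"):
            for i in range(1, 6):
                assert f"{tag}_S{i}" in presets
        assert presets["human_S1"].f_ultra == pytest.approx(0.19)
        assert presets["human_S5"].f_ultra == pytest.approx(0.33)
        assert presets["mouse_S5"].f_ultra == pytest.approx(0.34)
        assert presets["forebrain_mature"].f_ultra == pytest.approx(0.16)
        assert presets["purkinje_adult"].f_ultra == pytest.approx(0.10)

    def test_hub_matrix_symmetric_normalized(self, human_genome):
        w = get_preset("human_S5").hub_matrix(human_genome)
        assert np.allclose(w, w.T)
        assert (w >= 0).all()
        off = w[~np.eye(len(w), dtype=bool)]
        assert off.mean() == pytest.approx(1.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            StagePreset("bad", f_ultra=1.5)


class TestCompartmentTrack:
    def test_deterministic_under_seed(self, toy_genome):
        t1 = make_compartment_track(toy_genome, 1_000_000, seed=4)
        t2 = make_compartment_track(toy_genome, 1_000_000, seed=4)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(t1.truth_labels, t2.truth_labels)

    def test_single_block_genome_constant_compartment(self):
        g = Genome("toy", ("chrA",), (3_000_000,))
        t = make_compartment_track(g, 1_000_000, mean_block_bins=1000, seed=0)
        assert len(set(t.truth_labels)) == 1

    def test_a_fraction_matches_design(self, human_genome):
        # ~3,000 bins at 1 Mb; designed A proportion 0.3
        t = make_compartment_track(human_genome, 1_000_000, seed=9, a_fraction=0.3)
        frac_a = (t.truth_labels == "A").mean()
        assert frac_a == pytest.approx(0.3, abs=0.05)
        a_vals = t.values[t.truth_labels == "A"]
        b_vals = t.values[t.truth_labels == "B"]
        assert a_vals.min() >= 0.6 and b_vals.max() <= 0.4


class TestDistanceSampling:
    def test_no_ultra_component(self, rng):
        p = StagePreset("p", f_ultra=0.0)
        d = sample_intra_distances(p, 50_000_000, 1000, rng)
        assert (d < ULTRA_MIN).all()

    def test_all_ultra(self, rng):
        p = StagePreset("p", f_ultra=1.0)
        d = sample_intra_distances(p, 50_000_000, 1000, rng)
        assert (d >= ULTRA_MIN).all() and (d < 50_000_000).all()

    def test_short_chromosome_draws_short_component_only(self, rng):
        p = StagePreset("p", f_ultra=0.5)
        d = sample_intra_distances(p, 8_000_000, 500, rng)
        assert (d < ULTRA_MIN).all()

    def test_empirical_fraction_matches_analytic_expectation(self, rng):
        # genome mixing chromosomes above and below the 10 Mb cutoff
        g = Genome("toy", ("c1", "c2", "c3"), (50_000_000, 8_000_000, 30_000_000))
        p = StagePreset("p", f_ultra=0.3, f_inter=0.0, rho=0.0)
        expect = expected_ultra_fraction(p, g)
        n = 100_000
        cell = simulate_cell(p, g, None, n, seed=rng)
        frac = distance_profile(cell).fraction_ge_threshold
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 3 * se

    def test_fraction_boosted_on_long_chromosomes(self):
        # the analytic expectation honors the length mix: the genome-wide
        # target is met by up-weighting chromosomes that can host the tail
        g = Genome("toy", ("c1", "c2"), (50_000_000, 8_000_000))
        p = StagePreset("p", f_ultra=0.2)
        assert expected_ultra_fraction(p, g) == pytest.approx(0.2)


class TestSimulateCell:
    def test_contact_count_conserved(self, human_genome, human_track):
        cell = simulate_cell(get_preset("human_S3"), human_genome, human_track, 777, seed=0)
        assert len(cell) == 777

    def test_rho_one_all_same_compartment(self, human_genome, human_track):
        p = StagePreset("p", f_ultra=0.3, f_inter=0.1, rho=1.0)
        cell = simulate_cell(p, human_genome, human_track, 5000, seed=1)
        bi = human_track.bin_index
        b1 = bi.bins_of_positions(cell.chrom1, cell.pos1)
        b2 = bi.bins_of_positions(cell.chrom2, cell.pos2)
        cls = human_track.values >= 0.5
        assert (cls[b1] == cls[b2]).all()

    def test_male_x_dosage_half_of_female(self, human_genome, human_track):
        p = get_preset("human_S1")
        xi = human_genome.x_index
        shares = {}
        for sex in ("M", "F"):
            tot_x = tot = 0
            for i in range(60):
                cell = simulate_cell(
                    p, human_genome, human_track, 5000,
                    seed=i + (7000 if sex == "F" else 0), sex=sex,
                )
                tot_x += int((cell.chrom1 == xi).sum() + (cell.chrom2 == xi).sum())
                tot += 2 * len(cell)
            shares[sex] = tot_x / tot
        assert shares["M"] / shares["F"] == pytest.approx(0.5, abs=0.08)

    def test_requires_at_least_one_contact(self, human_genome, human_track):
        with pytest.raises(ValueError):
            simulate_cell(get_preset("human_S1"), human_genome, human_track, 0)

    def test_hub_free_pair_frequencies_track_length_products(self, human_genome, rng):
        p = StagePreset("p", f_ultra=0.2, f_inter=1.0, rho=0.0)
        cell = simulate_cell(p, human_genome, None, 200_000, seed=rng)
        n = human_genome.n_chroms
        obs = np.zeros((n, n))
        np.add.at(obs, (cell.chrom1, cell.chrom2), 1)
        lens = human_genome.lengths_array.astype(float)
        iu, ju = np.triu_indices(n, k=1)
        expect = lens[iu] * lens[ju]
        expect = expect / expect.sum() * len(cell)
        got = obs[iu, ju]
        z = (got - expect) / np.sqrt(expect)
        assert np.abs(z).max() < 5.0


class TestSimulateCohort:
    def test_stage_bookkeeping_and_age_ranges(self, human_genome):
        presets = load_presets()
        design = CohortDesign(
            genome=human_genome,
            stages=[(presets[f"human_S{i}"], 20, (float(i), float(i + 1))) for i in (1, 5)],
            n_contacts_mean=500,
            seed=11,
        )
        cohort = simulate_cohort(design)
        counts = cohort.metadata["stage_truth"].value_counts()
        assert counts["human_S1"] == 20 and counts["human_S5"] == 20
        s5 = cohort.metadata.query("stage_truth == 'human_S5'")["age_years"]
        assert (s5 >= 5.0).all() and (s5 <= 6.0).all()

    def test_same_seed_identical_metadata(self, human_genome):
        presets = load_presets()

        def run():
            design = CohortDesign(
                genome=human_genome,
                stages=[(presets["human_S1"], 5, (0.1, 0.5))],
                n_contacts_mean=300,
                seed=3,
            )
            return simulate_cohort(design)

        a, b = run(), run()
        assert a.metadata.to_csv() == b.metadata.to_csv()
        assert a.cells[0].equals(b.cells[0])

    def test_empty_design_rejected(self, human_genome):
        with pytest.raises(ValueError):
            CohortDesign(genome=human_genome, stages=[])


class TestSimulatePool:
    def test_noise_free_full_coverage_matches_genotypes(self):
        d = PoolDesign(n_donors=2, n_cells=6, n_snps=40, coverage=1.0, epsilon=1e-12)
        panel, obs, truth = simulate_pool(d, seed=0)
        donors = panel.donors
        for cell, donor in truth.items():
            g = panel.genotypes[donors.index(donor)]
            t = obs.table[obs.table["cell"] == cell]
            assert len(t) == 40  # full coverage observes every SNP
            hom = np.isin(g[t["snp"].to_numpy()], (0.0, 2.0))
            expected_alt = g[t["snp"].to_numpy()][hom] == 2.0
            assert (t["alt"].to_numpy()[hom] == expected_alt).all()

    def test_observation_count_is_binomial(self):
        d = PoolDesign(n_donors=4, n_cells=200, n_snps=500, coverage=0.2)
        _, obs, _ = simulate_pool(d, seed=1)
        per_cell = obs.table.groupby("cell").size()
        mean, var = per_cell.mean(), per_cell.var()
        n, p = 500, 0.2
        assert mean == pytest.approx(n * p, abs=3 * np.sqrt(n * p * (1 - p) / 200))
        assert var == pytest.approx(n * p * (1 - p), rel=0.3)

    def test_deterministic_under_seed(self):
        d = PoolDesign(n_donors=3, n_cells=10, n_snps=50)
        a = simulate_pool(d, seed=9)
        b = simulate_pool(d, seed=9)
        assert a[0].genotypes.tolist() == b[0].genotypes.tolist()
        assert a[1].table.equals(b[1].table)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            PoolDesign(coverage=0.0)


class TestCalibration:
    @pytest.mark.parametrize("name", ["human_S1", "human_S5", "mouse_S5"])
    def test_mean_ultra_fraction_recovers_preset(self, name, human_genome, mouse_genome):
        preset = get_preset(name)
        genome = human_genome if preset.genome_tag == "human" else mouse_genome
        track = make_compartment_track(genome, 1_000_000, seed=2)
        seeds = np.random.SeedSequence(77).spawn(100)
        fracs = [
            distance_profile(
                simulate_cell(preset, genome, track, 5000, seed=np.random.default_rng(s))
            ).fraction_ge_threshold
            for s in seeds
        ]
        assert np.mean(fracs) == pytest.approx(preset.f_ultra, abs=0.02)

    def test_drift_plan_targets_opposite_compartment(self, human_track):
        plan = designate_dynamic_bins(human_track, 100, seed=0)
        assert len(plan.up_bins) + len(plan.down_bins) == 100
        assert (human_track.values[plan.up_bins] < 0.5).all()
        assert (plan.targets[plan.up_bins] >= 0.6).all()
        assert (human_track.values[plan.down_bins] >= 0.5).all()
        assert (plan.targets[plan.down_bins] <= 0.4).all()
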