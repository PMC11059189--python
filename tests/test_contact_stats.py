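import itertools

import numpy as np
import pytest

from cbg3d.contact_stats import (
    aggregate_map,
    compare_groups,
    distance_profile,
    enrichment_delta,
    interchrom_enrichment,
)
from cbg3d.core_io import ContactSet, Genome
from cbg3d.synthetic_data import StagePreset, simulate_cell


@pytest.fixture
def wide_genome():
    return Genome("toy", ("chrA", "chrB"), (100_000_000, 60_000_000))


def _cell(genome, contacts, cid="c"):
    return ContactSet.from_contacts(cid, genome, contacts)


class TestDistanceProfile:
    def test_direct_enumeration(self, wide_genome):
        contacts = [("chrA", 1, "chrA", 1 + d)
                    for d in (1_000_000, 5_000_000, 12_000_000, 50_000_000)]
        prof = distance_profile(_cell(wide_genome, contacts))
        assert prof.fraction_ge_threshold == pytest.approx(0.5)
        assert prof.n_intra == 4

    def test_all_short(self, wide_genome):
        contacts = [("chrA", 1, "chrA", 500_000)]
        assert distance_profile(_cell(wide_genome, contacts)).fraction_ge_threshold == 0.0

    def test_threshold_inclusive(self, wide_genome):
        contacts = [("chrA", 1, "chrA", 10_000_001)]  # spans exactly 10 Mb
        assert distance_profile(_cell(wide_genome, contacts)).fraction_ge_threshold == 1.0

    def test_no_intra_contacts_flagged(self, wide_genome):
        prof = distance_profile(_cell(wide_genome, [("chrA", 1, "chrB", 1)]))
        assert np.isnan(prof.fraction_ge_threshold)
        assert prof.n_inter == 1

    def test_counts_partition_total(self, wide_genome, rng):
        p = StagePreset("p", f_ultra=0.2, f_inter=0.3, rho=0.0)
        cell = simulate_cell(p, wide_genome, None, 2000, seed=rng)
        prof = distance_profile(cell)
        assert prof.n_intra + prof.n_inter == 2000


class TestCompareGroups:
    def test_identical_groups_null(self):
        res = compare_groups(np.arange(30) + 0.5, np.arange(30) + 0.5)
        assert res.p_value > 0.9

    def test_exact_enumeration_small_groups(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_u_symmetry_identity(self, rng):
        a, b = rng.random(8), rng.random(13)
        ra = compare_groups(a, b)
        rb = compare_groups(b, a)
        assert ra.u_statistic + rb.u_statistic == pytest.approx(8 * 13)

    def test_exact_agrees_with_full_enumeration(self):
        # brute-force two-sided p by enumerating all labelings of the pooled data
        a, b = [1.0, 4.0, 6.0], [2.0, 7.0, 9.0, 11.0]
        pooled = a + b
        n_a = len(a)

        def u_stat(xs, ys):
            return sum(1 for x in xs for y in ys if x > y) + 0.5 * sum(
                1 for x in xs for y in ys if x == y
            )

        observed = u_stat(a, b)
        us = []
        for idx in itertools.combinations(range(len(pooled)), n_a):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
            us.append(u_stat(xs, ys))
        mu = n_a * (len(pooled) - n_a) / 2
        p_exact = sum(1 for u in us if abs(u - mu) >= abs(observed - mu) - 1e-12) / len(us)
        res = compare_groups(a, b)
        assert res.p_value == pytest.approx(p_exact)

    def test_descriptives(self):
        res = compare_groups([1.0, 3.0], [10.0, 30.0, 50.0])
        assert res.mean_a == pytest.approx(2.0)
        assert res.mean_b == pytest.approx(30.0)
        assert res.sd_b == pytest.approx(20.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])

    def test_distinct_presets_separate(self, human_genome, human_track):
        # two stages with different ultra fractions must separate decisively
        from cbg3d.synthetic_data import get_preset

        fr = {}
        for name in ("human_S1", "human_S5"):
            preset = get_preset(name)
            fr[name] = [
                distance_profile(
                    simulate_cell(preset, human_genome, human_track, 3000,
                                  seed=i + hash(name) % 1000)
                ).fraction_ge_threshold
                for i in range(30)
            ]
        res = compare_groups(fr["human_S1"], fr["human_S5"])
        assert res.p_value < 0.01
        assert res.mean_a < res.mean_b


class TestAggregateMap:
    def test_single_contact_unit_count(self, wide_genome):
        m = aggregate_map([_cell(wide_genome, [("chrA", 100, "chrA", 30_000_100)])],
                          "chrA", 10_000_000)
        assert m.counts.sum() == 2  # mirrored off-diagonal
        assert m.counts[0, 3] == 1 and m.counts[3, 0] == 1

    def test_symmetry_and_conservation(self, wide_genome, rng):
        p = StagePreset("p", f_ultra=0.3, f_inter=0.0, rho=0.0)
        cells = [simulate_cell(p, wide_genome, None, 500, seed=rng, cell_id=f"c{i}")
                 for i in range(3)]
        m = aggregate_map(cells, "chrA", 5_000_000)
        assert np.array_equal(m.counts, m.counts.T)
        diag = np.trace(m.counts)
        assert diag + (m.counts.sum() - diag) // 2 == m.n_contacts

    def test_pair_scope_matches_brute_force(self, wide_genome, rng):
        p = StagePreset("p", f_ultra=0.2, f_inter=0.5, rho=0.0)
        cell = simulate_cell(p, wide_genome, None, 1000, seed=rng)
        bs = 10_000_000
        m = aggregate_map([cell], ("chrA", "chrB"), bs)
        brute = np.zeros_like(m.counts)
        for c in cell.iter_contacts():
            if c.chrom_a == "chrA" and c.chrom_b == "chrB":
                brute[(c.pos_a - 1) // bs, (c.pos_b - 1) // bs] += 1
        assert np.array_equal(m.counts, brute)

    def test_genomewide_inter_scope(self, wide_genome):
        cells = [_cell(wide_genome, [("chrA", 1, "chrB", 1), ("chrA", 1, "chrA", 2)])]
        m = aggregate_map(cells, "inter", 10_000_000)
        assert m.n_contacts == 1  # intra contact out of scope
        assert m.counts.sum() == 2

    def test_oversized_bin_rejected(self, wide_genome):
        with pytest.raises(ValueError):
            aggregate_map([_cell(wide_genome, [("chrA", 1, "chrA", 2)])],
                          "chrB", 200_000_000)


class TestInterchromEnrichment:
    def test_uniform_simulation_enrichment_near_one(self, human_genome, rng):
        p = StagePreset("p", f_ultra=0.2, f_inter=1.0, rho=0.0)
        cells = [simulate_cell(p, human_genome, None, 20_000, seed=rng, cell_id=f"c{i}")
                 for i in range(20)]
        iu, ju = np.triu_indices(human_genome.n_chroms, k=1)
        # length-product expected matches the generating null exactly:
        # every pair within 3.5 s.e. of enrichment 1
        e_len = interchrom_enrichment(cells, expected="length")
        dev = np.abs(e_len.enrichment[iu, ju] - 1.0)
        se = 1.0 / np.sqrt(e_len.expected[iu, ju])
        assert (dev <= np.maximum(3.5 * se, 0.02)).all()
        # marginal-product expected carries a small systematic offset for the
        # largest chromosomes but stays near 1 overall
        e = interchrom_enrichment(cells)
        dev_m = np.abs(e.enrichment[iu, ju] - 1.0)
        assert np.nanmean(dev_m) < 0.05
        assert np.nanmax(dev_m) < 0.25

    def test_expected_sums_to_observed_total(self, human_genome, rng):
        p = StagePreset("p", f_ultra=0.2, f_inter=0.5, rho=0.0)
        cells = [simulate_cell(p, human_genome, None, 2000, seed=rng)]
        e = interchrom_enrichment(cells)
        iu, ju = np.triu_indices(human_genome.n_chroms, k=1)
        assert e.expected[iu, ju].sum() == pytest.approx(e.n_inter)

    def test_matrix_symmetric(self, human_genome, rng):
        p = StagePreset("p", f_ultra=0.2, f_inter=0.5, rho=0.0)
        cells = [simulate_cell(p, human_genome, None, 5000, seed=rng)]
        e = interchrom_enrichment(cells)
        assert np.allclose(e.enrichment, e.enrichment.T, equal_nan=True)

    def test_designed_hub_recovered(self, human_genome):
        hub_chroms = ("chr1", "chr9", "chr11", "chr14", "chr15")
        p = StagePreset("p", f_ultra=0.2, f_inter=0.5, rho=0.0,
                        hub_chroms=hub_chroms, hub_weight=2.0)
        cells = [simulate_cell(p, human_genome, None, 20_000, seed=300 + i,
                               cell_id=f"c{i}") for i in range(20)]
        e = interchrom_enrichment(cells, expected="length")
        idx = [human_genome.index[c] for c in hub_chroms]
        hub_pairs = {(a, b) for a in idx for b in idx if a < b}
        iu, ju = np.triu_indices(human_genome.n_chroms, k=1)
        is_hub = np.array([(i, j) in hub_pairs for i, j in zip(iu, ju)])
        vals = e.enrichment[iu, ju]
        ratio = vals[is_hub].mean() / vals[~is_hub].mean()
        assert ratio == pytest.approx(2.0, rel=0.1)
        # hub chromosomes top the hub score ranking
        top = np.argsort(-e.hub_score)[: len(idx)]
        assert set(top.tolist()) == set(idx)

    def test_delta_identity_and_antisymmetry(self, human_genome, rng):
        p = StagePreset("p", f_ultra=0.2, f_inter=0.5, rho=0.0)
        a = [simulate_cell(p, human_genome, None, 10_000, seed=1, cell_id="a")]
        b = [simulate_cell(p, human_genome, None, 10_000, seed=2, cell_id="b")]
        zero = enrichment_delta(a, a)
        assert np.nanmax(np.abs(zero)) == pytest.approx(0.0, abs=1e-12)
        d_ab = enrichment_delta(a, b)
        d_ba = enrichment_delta(b, a)
        assert np.allclose(d_ab, -d_ba, equal_nan=True)
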