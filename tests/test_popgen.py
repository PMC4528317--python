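"""Genotype simulator and preprocessing: maps, meiosis, thinning, centering."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import poolwgr as pw
from conftest import two_marker_map


class TestGeneticMap:
    def test_degenerate_single_marker(self):
        gmap = pw.make_genetic_map(1, 100.0, 1, seed=0)
        assert gmap.n_markers == 1
        assert gmap.chromosome[0] == 1
        assert 0 <= gmap.position[0] <= 100

    def test_markers_spread_and_sorted(self):
        gmap = pw.make_genetic_map(10, 140.0, 285, seed=4)
        assert gmap.n_markers == 285
        counts = np.bincount(gmap.chromosome)[1:]
        assert counts.max() - counts.min() <= 1
        for c in range(1, 11):
            pos = gmap.position[gmap.chromosome == c]
            assert np.all(np.diff(pos) > 0)

    def test_deterministic(self):
        a = pw.make_genetic_map(2, 100.0, 200, seed=7)
        b = pw.make_genetic_map(2, 100.0, 200, seed=7)
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.chromosome, b.chromosome)

    @pytest.mark.parametrize(
        "args", [(0, 100.0, 10), (2, -1.0, 10), (2, 100.0, 0), (5, 100.0, 3)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            pw.make_genetic_map(*args, seed=0)

    def test_haldane_adjacent_recombination(self):
        gmap = pw.GeneticMap(
            np.array(["a", "b", "c"], dtype=object),
            np.array([1, 1, 2]),
            np.array([0.0, 10.0, 5.0]),
        )
        r = gmap.adjacent_recombination()
        assert r[0] == pytest.approx(0.5 * (1 - np.exp(-0.2)))
        assert r[1] == 0.5  # chromosome boundary


class TestFounderPanel:
    def test_haplotypes_binary_and_polymorphic(self):
        gmap = pw.make_genetic_map(2, 100.0, 300, seed=1)
        panel = pw.simulate_founder_panel(gmap, 8, 0.05, 0.5, seed=2)
        assert set(np.unique(panel.haplotypes)) <= {0, 1}
        assert np.all(panel.haplotypes.min(axis=0) < panel.haplotypes.max(axis=0))

    def test_two_founders_differ_at_half_of_markers(self):
        # frequency forced to 0.5: expected differing fraction 2 * 0.5 * 0.5,
        # conditional on polymorphism across the two founders it is 1.0; use
        # 3 founders so polymorphism does not force a difference of the pair
        gmap = pw.make_genetic_map(1, 100.0, 20000, seed=3)
        panel = pw.simulate_founder_panel(gmap, 3, 0.5, 0.5, seed=4)
        diff = np.mean(panel.haplotypes[0] != panel.haplotypes[1])
        # P(pair differs | marker polymorphic among 3 founders at f=0.5) = 2/3
        se = np.sqrt(2 / 3 * 1 / 3 / 20000)
        assert abs(diff - 2 / 3) < 4 * se

    def test_deterministic(self):
        gmap = pw.make_genetic_map(1, 50.0, 100, seed=5)
        a = pw.simulate_founder_panel(gmap, 4, 0.1, 0.4, seed=6)
        b = pw.simulate_founder_panel(gmap, 4, 0.1, 0.4, seed=6)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_invalid_maf_range(self):
        gmap = pw.make_genetic_map(1, 50.0, 10, seed=0)
        with pytest.raises(ValueError):
            pw.simulate_founder_panel(gmap, 4, 0.4, 0.6, seed=0)
        with pytest.raises(ValueError):
            pw.simulate_founder_panel(gmap, 1, 0.1, 0.4, seed=0)


class TestDerivePopulation:
    def test_identical_parents_give_identical_lines(self):
        gmap = pw.make_genetic_map(1, 80.0, 30, seed=1)
        hap = (np.random.default_rng(2).random((3, 30)) < 0.5).astype(np.int8)
        hap[1] = hap[0]  # donor 1 identical to the common parent haplotype
        panel = pw.FounderPanel(np.array(["CP", "F1", "F2"], dtype=object), hap, 0)
        pop = pw.derive_population(panel, 1, 10, "RIL", map=gmap, seed=3)
        assert np.array_equal(pop.genotypes, np.tile(2.0 * hap[0], (10, 1)))

    def test_dh_lines_fully_homozygous(self):
        gmap = pw.make_genetic_map(2, 100.0, 50, seed=4)
        panel = pw.simulate_founder_panel(gmap, 3, 0.2, 0.5, seed=5)
        pop = pw.derive_population(panel, 2, 200, "DH", map=gmap, seed=6)
        assert set(np.unique(pop.genotypes)) <= {0.0, 2.0}

    def test_donor_equal_common_parent_rejected(self):
        gmap = pw.make_genetic_map(1, 50.0, 10, seed=0)
        panel = pw.simulate_founder_panel(gmap, 3, 0.2, 0.5, seed=0)
        with pytest.raises(ValueError):
            pw.derive_population(panel, panel.common_parent_index, 5, map=gmap, seed=0)

    @pytest.mark.parametrize("dist", [1.0, 10.0, 50.0])
    def test_haldane_recombinant_fraction(self, dist):
        # DH gametes over a 2-marker map: empirical recombinant fraction must
        # match r = (1 - exp(-2d/100)) / 2 within 3 Monte-Carlo SE
        gmap = two_marker_map(dist)
        hap = np.array([[0, 0], [1, 1]], dtype=np.int8)  # coupling phase
        panel = pw.FounderPanel(np.array(["CP", "D"], dtype=object), hap, 0)
        n = 40_000
        pop = pw.derive_population(panel, 1, n, "DH", map=gmap, seed=int(dist))
        rec = np.mean(pop.genotypes[:, 0] != pop.genotypes[:, 1])
        r = 0.5 * (1 - np.exp(-2 * dist / 100))
        assert abs(rec - r) < 3 * np.sqrt(r * (1 - r) / n)

    def test_ril_residual_heterozygosity_matches_selfing_depth(self):
        # single locus: heterozygote frequency after g selfing generations
        # from the F1 is (1/2)^g
        gmap = pw.GeneticMap(np.array(["m"], dtype=object), np.array([1]), np.array([0.0]))
        panel = pw.FounderPanel(
            np.array(["CP", "D"], dtype=object), np.array([[0], [1]], dtype=np.int8), 0
        )
        g = 3
        n = 40_000
        pop = pw.derive_population(panel, 1, n, "RIL", selfing_generations=g, map=gmap, seed=9)
        het = np.mean(pop.genotypes == 1.0)
        expect = 0.5**g
        assert abs(het - expect) < 3 * np.sqrt(expect * (1 - expect) / n)

    def test_segregating_frequency_near_half(self, small_nam):
        for p in small_nam.populations[:3]:
            sub = small_nam.subset_lines(small_nam.lines_of(int(p)))
            freq = pw.allele_frequencies(sub)
            seg = (freq > 0.05) & (freq < 0.95)
            assert abs(freq[seg].mean() - 0.5) < 0.05


class TestAssemble:
    def test_labels_and_scale(self):
        gmap = pw.make_genetic_map(2, 100.0, 40, seed=1)
        panel = pw.simulate_founder_panel(gmap, 4, 0.2, 0.5, seed=2)
        data = pw.assemble_multi_population(panel, [1, 2, 3], [5, 6, 7], "DH", gmap, seed=3)
        assert data.n_lines == 18
        assert np.array_equal(np.unique(data.population_labels), [1, 2, 3])
        assert np.sum(data.population_labels == 2) == 6

    def test_single_cross_single_label(self):
        gmap = pw.make_genetic_map(1, 60.0, 20, seed=1)
        panel = pw.simulate_founder_panel(gmap, 3, 0.2, 0.5, seed=2)
        data = pw.assemble_multi_population(panel, [1], [7], "RIL", gmap, seed=3)
        assert np.all(data.population_labels == 1)

    def test_deterministic_and_empty_rejected(self):
        gmap = pw.make_genetic_map(1, 60.0, 20, seed=1)
        panel = pw.simulate_founder_panel(gmap, 3, 0.2, 0.5, seed=2)
        a = pw.assemble_multi_population(panel, [1, 2], [4, 4], "DH", gmap, seed=5)
        b = pw.assemble_multi_population(panel, [1, 2], [4, 4], "DH", gmap, seed=5)
        assert np.array_equal(a.genotypes, b.genotypes)
        with pytest.raises(ValueError):
            pw.assemble_multi_population(panel, [], [], "DH", gmap, seed=5)

    def test_nam_scale_construction(self):
        # 25 crosses x 188 lines reproduces the NAM design scale (4700 lines)
        data = pw.simulate_nam_like(
            n_populations=25, lines_per_population=188, n_markers=30, n_chromosomes=3, seed=1
        )
        assert data.n_lines == 4700
        assert data.populations.size == 25


class TestThinning:
    def test_sparse_markers_all_retained(self):
        gmap = pw.GeneticMap(
            np.array(["a", "b", "c"], dtype=object),
            np.array([1, 1, 1]),
            np.array([0.0, 5.0, 10.0]),
        )
        kept = pw.thin_markers_by_spacing(gmap, 5.0, seed=0)
        assert list(kept) == ["a", "b", "c"]

    def test_dense_grid_one_per_bin(self):
        pos = np.arange(100, dtype=float)
        gmap = pw.GeneticMap(
            np.array([f"m{i}" for i in range(100)], dtype=object),
            np.ones(100, dtype=int),
            pos,
        )
        kept = pw.thin_markers_by_spacing(gmap, 5.0, seed=1)
        assert kept.size == 20

    def test_spacing_larger_than_chromosome(self):
        gmap = pw.make_genetic_map(3, 50.0, 30, seed=2)
        kept = pw.thin_markers_by_spacing(gmap, 1000.0, seed=3)
        assert kept.size == 3

    def test_random_thinning(self):
        ids = [f"m{i}" for i in range(100)]
        assert list(pw.thin_markers_random(ids, 100, seed=0)) == ids
        a = pw.thin_markers_random(ids, 30, seed=5)
        b = pw.thin_markers_random(ids, 30, seed=5)
        assert np.array_equal(a, b)
        assert len(set(a)) == 30
        with pytest.raises(ValueError):
            pw.thin_markers_random(ids, 101, seed=0)


class TestImputeAndCenter:
    def _with_missing(self, small_nam):
        g = small_nam.genotypes.copy()
        g[1, 0] = np.nan
        g[4, 2] = np.nan
        return pw.MarkerData(
            small_nam.line_ids, small_nam.population_labels, g, small_nam.map
        )

    def test_fill_is_twice_frequency(self):
        gmap = pw.GeneticMap(np.array(["m"], dtype=object), np.array([1]), np.array([0.0]))
        g = np.array([[0.0], [0.0], [1.0], [1.0], [1.0], [np.nan]])
        # observed frequency 3/10 = 0.3 -> fill 0.6
        data = pw.MarkerData(
            np.array([f"l{i}" for i in range(6)], dtype=object),
            np.ones(6, dtype=int),
            g,
            gmap,
        )
        out = pw.impute_missing(data)
        assert out.genotypes[5, 0] == pytest.approx(0.6)

    def test_no_missing_is_identity(self, small_nam):
        assert pw.impute_missing(small_nam) is small_nam

    def test_boundary_frequency_one(self):
        gmap = pw.GeneticMap(np.array(["m"], dtype=object), np.array([1]), np.array([0.0]))
        data = pw.MarkerData(
            np.array(["a", "b", "c"], dtype=object),
            np.ones(3, dtype=int),
            np.array([[2.0], [2.0], [np.nan]]),
            gmap,
        )
        assert pw.impute_missing(data).genotypes[2, 0] == pytest.approx(2.0)

    def test_fully_missing_marker_names_it(self):
        gmap = pw.GeneticMap(
            np.array(["ok", "bad"], dtype=object), np.array([1, 1]), np.array([0.0, 1.0])
        )
        data = pw.MarkerData(
            np.array(["a", "b"], dtype=object),
            np.ones(2, dtype=int),
            np.array([[0.0, np.nan], [2.0, np.nan]]),
            gmap,
        )
        with pytest.raises(ValueError, match="bad"):
            pw.impute_missing(data)

    def test_centering_values_and_identity(self, small_nam):
        Z = pw.center_genotypes(small_nam)
        assert np.allclose(Z.values.mean(axis=0), 0.0, atol=1e-10)
        # frequency-0.5 marker gives centered values in {-1, 0, 1}
        half = np.isclose(Z.reference_frequencies, 0.5)
        if half.any():
            k = int(np.flatnonzero(half)[0])
            assert set(np.round(np.unique(Z.values[:, k]), 9)) <= {-1.0, 0.0, 1.0}

    def test_monomorphic_reference_centers_to_zero(self):
        gmap = pw.GeneticMap(np.array(["m"], dtype=object), np.array([1]), np.array([0.0]))
        data = pw.MarkerData(
            np.array(["a", "b"], dtype=object),
            np.ones(2, dtype=int),
            np.array([[2.0], [2.0]]),
            gmap,
        )
        assert np.allclose(pw.center_genotypes(data).values, 0.0)

    def test_center_requires_complete_data(self, small_nam):
        with pytest.raises(ValueError, match="impute"):
            pw.center_genotypes(self._with_missing(small_nam))

    def test_impute_then_center_preserves_observed(self, small_nam):
        data = self._with_missing(small_nam)
        out = pw.impute_missing(data)
        obs = ~data.missing_mask
        assert np.array_equal(out.genotypes[obs], data.genotypes[obs])
        Z = pw.center_genotypes(out)
        expect = data.genotypes[obs] - 2.0 * np.broadcast_to(
            Z.reference_frequencies, data.genotypes.shape
        )[obs]
        assert np.allclose(Z.values[obs], expect)

    def test_external_frequencies_applied(self, small_nam):
        freqs = np.full(small_nam.n_markers, 0.25)
        Z = pw.center_genotypes(small_nam, frequencies=freqs)
        assert np.allclose(Z.values, small_nam.genotypes - 0.5)


@given(st.integers(0, 2**31 - 1))
def test_map_generation_always_valid(seed):
    gmap = pw.make_genetic_map(3, 75.0, 30, seed=seed)
    assert gmap.n_markers == 30
    for c in (1, 2, 3):
        assert np.all(np.diff(gmap.position[gmap.chromosome == c]) > 0)
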