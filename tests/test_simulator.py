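"""Coalescent expectations and internal consistency of the simulator."""

import numpy as np
import pytest

import epismc as e
from epismc.markers import MarkerSpec, RegionMethylationModel
from epismc.simulate import (SimulationConfig, generate_fixture,
                             overlay_marker_mutations, selfing_rescaling,
                             simulate_arg, simulate_dataset,
                             true_tmrca_track)

DEM = e.Demography((0.0,), (10_000.0,))


def two_marker_config(L=200_000, mu1=1e-8, mu2=1e-4, r=1e-8, n=10):
    return SimulationConfig(
        n_haplotypes=n, sequence_length=L, r=r,
        markers=[MarkerSpec("m1", 4, mu=mu1, genome_fraction=0.98),
                 MarkerSpec("m2", 2, mu=mu2, genome_fraction=0.02)])


class TestSimulateArg:
    def test_no_recombination_single_tree(self):
        ts = simulate_arg(two_marker_config(r=0.0), DEM, seed=1)
        assert ts.num_trees == 1
        assert ts.sequence_length == 200_000

    def test_trees_cover_sequence(self):
        ts = simulate_arg(two_marker_config(r=1e-7), DEM, seed=2)
        left = 0.0
        for tree in ts.trees():
            assert tree.interval.left == left
            left = tree.interval.right
        assert left == ts.sequence_length

    def test_mean_pair_tmrca_matches_coalescent(self):
        # E[TMRCA] = 2N for a pair under constant N
        tm = []
        cfg = SimulationConfig(n_haplotypes=2, sequence_length=1000, r=0.0,
                               markers=[])
        for s in range(400):
            ts = simulate_arg(cfg, DEM, seed=1000 + s)
            tm.append(ts.first().tmrca(0, 1))
        tm = np.asarray(tm)
        se = tm.std(ddof=1) / np.sqrt(len(tm))
        assert abs(tm.mean() - 20_000) < 3 * se

    def test_tree_count_increases_with_r(self):
        counts = []
        for r in (1e-8, 1e-7, 1e-6):
            n = np.mean([simulate_arg(two_marker_config(r=r), DEM,
                                      seed=5 + s).num_trees for s in range(3)])
            counts.append(n)
        assert counts[0] < counts[1] < counts[2]

    def test_selfing_reduces_effective_recombination(self):
        assert selfing_rescaling(0.0) == 1.0
        assert selfing_rescaling(0.9) == pytest.approx(1 - 0.9 / 1.1)
        with pytest.raises(ValueError):
            selfing_rescaling(1.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_haplotypes=2, sequence_length=0, r=0, markers=[])


class TestMarkerOverlay:
    def test_zero_rates_give_monomorphic_sequences(self):
        cfg = two_marker_config(mu1=0.0, mu2=0.0)
        data = simulate_dataset(cfg, DEM, seed=3)
        assert data.records["m1"].n_polymorphic() == 0
        assert data.records["m2"].n_polymorphic() == 0

    def test_pair_segregating_sites_match_theta(self):
        # n=2: E[S] = 4 N mu L (infinite-site regime)
        L, mu = 1_000_000, 1e-8
        cfg = SimulationConfig(
            n_haplotypes=2, sequence_length=L, r=1e-8,
            markers=[MarkerSpec("m1", 4, mu=mu, genome_fraction=1.0)])
        counts = [simulate_dataset(cfg, DEM, seed=100 + s)
                  .records["m1"].n_polymorphic() for s in range(60)]
        counts = np.asarray(counts, dtype=float)
        expect = 4 * 10_000 * mu * L
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expect) < 3 * se

    def test_hypermutable_discordance_saturates_below_half(self, constant_data):
        rec = constant_data.records["m2"]
        frac = np.mean(rec.states[:, 0] != rec.states[:, 1])
        assert 0.2 < frac < 0.5

    def test_symbol_frequencies_match_emissions_given_tmrca(self, constant_data):
        """Pair symbol frequencies binned by true TMRCA track Eq-1."""
        rec = constant_data.records["m2"]
        pos_all = rec.designated_positions
        seg_pos = rec.positions[rec.states[:, 0] != rec.states[:, 1]]
        is_seg = np.zeros(len(pos_all), bool)
        is_seg[np.searchsorted(pos_all, seg_pos)] = True
        breaks, times = true_tmrca_track(constant_data.tree_sequence, 0, 1)
        site_t = times[np.searchsorted(breaks, pos_all, side="right") - 1]
        mu2 = constant_data.markers["m2"].mu
        chunks = 0
        for lo, hi in [(0, 5000), (5000, 20000), (20000, np.inf)]:
            m = (site_t >= lo) & (site_t < hi)
            if m.sum() < 300:
                continue
            theo = float(np.mean(0.5 * (1 - np.exp(-4 * mu2 * site_t[m]))))
            emp = is_seg[m].mean()
            # sites share genealogies, so allow a generous binomial slack
            assert abs(emp - theo) < 6 * np.sqrt(theo * (1 - theo) / m.sum()) + 0.02
            chunks += 1
        assert chunks >= 2

    def test_determinism_under_seed(self):
        cfg = two_marker_config(L=50_000)
        a = simulate_dataset(cfg, DEM, seed=9)
        b = simulate_dataset(cfg, DEM, seed=9)
        np.testing.assert_array_equal(a.records["m1"].positions,
                                      b.records["m1"].positions)
        np.testing.assert_array_equal(a.records["m2"].states,
                                      b.records["m2"].states)


class TestMethylome:
    def test_no_epimutation_keeps_ancestral_pattern(self):
        cfg = SimulationConfig(
            n_haplotypes=4, sequence_length=100_000, r=1e-8,
            markers=[MarkerSpec("snp", 4, mu=1e-8, genome_fraction=0.98),
                     MarkerSpec("meth", 2, rate_pair=(0.0, 0.0),
                                genome_fraction=0.02)],
            methylable_fraction=0.02)
        data = simulate_dataset(cfg, DEM, seed=4)
        st = data.records["meth"].states
        assert np.all(st == st[:, :1])

    def test_site_only_stationary_fraction(self, methylome_data):
        g, l = methylome_data.markers["meth"].rate_pair
        st = methylome_data.records["meth"].states
        frac = (st == 1).mean()
        pi_m = g / (g + l)
        # sites are stationary; allow for genealogy-induced correlation
        assert abs(frac - pi_m) < 0.02

    def test_region_discordance_matches_region_pair_law(self, rng):
        """Region-only process: leaf region-status discordance vs closed form."""
        from epismc.markers import asymmetric_site_emission
        cfg = SimulationConfig(
            n_haplotypes=10, sequence_length=400_000, r=1e-8,
            markers=[MarkerSpec("snp", 4, mu=1e-8, genome_fraction=0.98),
                     MarkerSpec("meth", 2, rate_pair=(0.0, 0.0),
                                genome_fraction=0.02)],
            region_model=RegionMethylationModel(2e-4, 1e-3, 1000),
            methylable_fraction=0.02)
        disc, theo_list = [], []
        for s in range(5):
            data = simulate_dataset(cfg, DEM, seed=40 + s)
            truth = data.region_truth
            ts = data.tree_sequence
            mids = data.genic_regions.mean(axis=1)
            for (i, j) in [(0, 1), (2, 3)]:
                breaks, times = true_tmrca_track(ts, i, j)
                t_mid = times[np.searchsorted(breaks, mids, side="right") - 1]
                theo = asymmetric_site_emission(2e-4, 1e-3, t_mid)[:, 2]
                disc.append((truth[:, i] != truth[:, j]).mean())
                theo_list.append(theo.mean())
        assert abs(np.mean(disc) - np.mean(theo_list)) < 0.05

    def test_region_length_larger_than_sequence_rejected(self):
        cfg = SimulationConfig(
            n_haplotypes=2, sequence_length=500, r=0.0,
            markers=[MarkerSpec("snp", 4, mu=1e-8, genome_fraction=0.98),
                     MarkerSpec("meth", 2, rate_pair=(1e-4, 1e-3),
                                genome_fraction=0.02)],
            region_model=RegionMethylationModel(1e-4, 1e-3, 1000),
            methylable_fraction=0.02)
        with pytest.raises(ValueError):
            simulate_dataset(cfg, DEM, seed=1)


class TestFixtures:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture("nope", seed=1)

    def test_determinism(self):
        a = generate_fixture("constant", seed=1, sequence_length=50_000)
        b = generate_fixture("constant", seed=1, sequence_length=50_000)
        np.testing.assert_array_equal(a.records["m1"].states,
                                      b.records["m1"].states)

    def test_bottleneck_truth_encodes_tenfold_drop(self):
        d = generate_fixture("bottleneck_fig2A", seed=1, sequence_length=50_000)
        sizes = np.asarray(d.demography.sizes)
        assert sizes.max() / sizes.min() == pytest.approx(10.0)

    def test_methylable_fraction_configurable(self):
        for f in (0.02, 0.2):
            d = generate_fixture("methylome_fig5", seed=1,
                                 sequence_length=100_000,
                                 methylable_fraction=f)
            got = d.records["meth"].total_designated / d.sequence_length
            assert got == pytest.approx(f, rel=0.2)

    def test_watterson_theta_recovery(self, constant_data):
        from epismc.rates import DiversitySummary
        s = DiversitySummary.from_annotated(constant_data)
        theta = s.theta_w("m1")
        assert abs(theta - 4e-4) < 2e-4  # single realisation, wide band
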