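"""Observation coding, region-effect test, DMR segmentation and SMCm fits."""

import numpy as np
import pytest

import epismc as e
from epismc.markers import RegionMethylationModel
from epismc.methylome import (MethylomeMatrix, encode_pair_observations,
                              fit_smcm, fit_snp_only, from_global_codes,
                              region_effect_test, segment_methylation_regions,
                              to_global_codes, _snp_only_obs)
from epismc.observations import MISSING


class TestObservationCoding:
    def test_site_symbols(self, methylome_data):
        obs = encode_pair_observations(methylome_data, 0, 1)
        rec = methylome_data.records["meth"]
        si, sj = rec.states[:, 0], rec.states[:, 1]
        want = np.where(si != sj, 2, np.where(si == 1, 1, 0))
        np.testing.assert_array_equal(obs.blocks[1].event_symbols, want)
        # equal nucleotides at a non-methylable site are the implicit 0 symbol
        assert obs.blocks[0].default_symbol == 0

    def test_snp_symbols(self, methylome_data):
        obs = encode_pair_observations(methylome_data, 0, 1)
        rec = methylome_data.records["snp"]
        seg = rec.states[:, 0] != rec.states[:, 1]
        np.testing.assert_array_equal(np.sort(obs.blocks[0].event_positions),
                                      np.sort(rec.positions[seg]))

    def test_nine_symbol_alphabet_with_segmentation(self, methylome_region_data):
        d = methylome_region_data
        meth = MethylomeMatrix.from_annotated(d)
        seg = segment_methylation_regions(meth, 0, 1, (3.5e-4, 1.5e-3),
                                          d.region_model)
        obs = encode_pair_observations(d, 0, 1, segmentation=seg)
        assert obs.blocks[1].n_symbols == 9
        syms = obs.blocks[1].event_symbols
        assert syms[syms != MISSING].max() <= 8

    def test_global_code_round_trip(self):
        """decode(encode(x)) = x over the full defined symbol set 0..4."""
        block_syms = np.array([0, 1, 2, 0, 1, MISSING])
        methylable = np.array([False, False, True, True, True, True])
        codes = np.where(methylable,
                         to_global_codes(block_syms, True),
                         to_global_codes(block_syms, False))
        m2, back = from_global_codes(codes)
        np.testing.assert_array_equal(m2[codes != MISSING],
                                      methylable[codes != MISSING])
        np.testing.assert_array_equal(back, block_syms)

    def test_segregating_only_drops_monomorphic_sites(self, methylome_data):
        d = methylome_data
        obs_all = encode_pair_observations(d, 0, 1)
        obs_seg = encode_pair_observations(d, 0, 1, segregating_only=True)
        n_poly = d.records["meth"].n_polymorphic()
        assert len(obs_seg.blocks[1].event_positions) == n_poly
        assert len(obs_all.blocks[1].event_positions) > n_poly
        # excluded sites vanish from every count
        c = obs_seg.window_counts(100)
        assert c.sum() < obs_all.window_counts(100).sum()


class TestRegionEffectTest:
    def test_single_site_rejected(self):
        m = MethylomeMatrix(np.array([5]), np.array([[1]], dtype=np.int8), 100)
        with pytest.raises(ValueError):
            region_effect_test(m, (3.5e-4, 1.5e-3))

    def test_null_acceptance_and_alternative_rejection(self, methylome_data):
        """No rejection under site-only epimutation; rejection when the
        region process dominates the site process."""
        from epismc.markers import MarkerSpec
        from epismc.simulate import SimulationConfig, simulate_dataset
        site = MethylomeMatrix.from_annotated(methylome_data)
        assert not region_effect_test(site, (3.5e-4, 1.5e-3)).region_effect
        site_rates = (1e-4, 5e-4)
        cfg = SimulationConfig(
            n_haplotypes=10, sequence_length=400_000, r=3.5e-8,
            selfing_rate=0.9,
            markers=[MarkerSpec("snp", 4, mu=7e-9, genome_fraction=0.98),
                     MarkerSpec("meth", 2, rate_pair=site_rates,
                                genome_fraction=0.02)],
            region_model=RegionMethylationModel(2e-4, 1e-3, 1000),
            methylable_fraction=0.02)
        d = simulate_dataset(cfg, e.Demography((0.0,), (10_000.0,)), 77)
        reg = MethylomeMatrix.from_annotated(d)
        assert region_effect_test(reg, site_rates).region_effect

    def test_distance_stratified_variant(self, methylome_region_data):
        m = MethylomeMatrix.from_annotated(methylome_region_data)
        near = region_effect_test(m, (3.5e-4, 1.5e-3))
        far = region_effect_test(m, (3.5e-4, 1.5e-3), min_distance=5000)
        # pairs straddling regions are less correlated than adjacent ones
        assert far.n_pairs < near.n_pairs


class TestSegmentation:
    def test_uniform_methylome_gives_single_segment(self):
        pos = np.arange(0, 5000, 10)
        st = np.ones((len(pos), 2), dtype=np.int8)
        m = MethylomeMatrix(pos, st, 5000)
        seg = segment_methylation_regions(m, 0, 1, (3.5e-4, 1.5e-3),
                                          RegionMethylationModel(2e-4, 1e-3, 1000))
        assert len(seg.intervals) == 1
        assert seg.intervals[0][2] == 2  # MM

    def test_empty_methylome_rejected(self):
        m = MethylomeMatrix(np.empty(0, dtype=int),
                            np.empty((0, 2), dtype=np.int8), 100)
        with pytest.raises(ValueError):
            segment_methylation_regions(m, 0, 1)

    def test_recovers_region_scale(self):
        """Low site noise, 1 kb regions: methylated segments ~ 1 kb."""
        from epismc.markers import MarkerSpec
        from epismc.simulate import SimulationConfig, simulate_dataset
        cfg = SimulationConfig(
            n_haplotypes=4, sequence_length=400_000, r=1e-8,
            markers=[MarkerSpec("snp", 4, mu=1e-8, genome_fraction=0.9),
                     MarkerSpec("meth", 2, rate_pair=(2e-5, 1e-4),
                                genome_fraction=0.1)],
            region_model=RegionMethylationModel(2e-4, 1e-3, 1000),
            methylable_fraction=0.1)
        lens = []
        for s in range(4):
            d = simulate_dataset(cfg, e.Demography((0.0,), (10_000.0,)), 70 + s)
            meth = MethylomeMatrix.from_annotated(d)
            seg = segment_methylation_regions(meth, 0, 1, (2e-5, 1e-4),
                                              d.region_model)
            ln = [e_ - s_ for s_, e_, st in seg.intervals if st != 0]
            lens.extend(ln)
        assert abs(np.mean(lens) - 1000) < 300

    def test_site_only_low_confidence_segments(self, methylome_data):
        """Negative control: no region process, segmentation finds no long
        methylated blocks."""
        meth = MethylomeMatrix.from_annotated(methylome_data)
        seg = segment_methylation_regions(meth, 0, 1, (3.5e-4, 1.5e-3),
                                          RegionMethylationModel(2e-4, 1e-3, 1000))
        ln = [e_ - s_ for s_, e_, st in seg.intervals if st == 2]
        if ln:  # any called MM segments stay short
            assert np.median(ln) < 1000


class TestSmcmFits:
    def test_zero_methylable_sites_equals_snp_only(self, methylome_data):
        """With the methylation track empty both fits share the likelihood."""
        import copy
        from epismc.smc import FreeParameters, baum_welch_fit
        d = copy.copy(methylome_data)
        d.records = dict(methylome_data.records)
        rec = d.records["meth"]
        from epismc.simulate import SiteRecords
        d.records["meth"] = SiteRecords(
            np.empty(0, dtype=np.int64),
            np.empty((0, d.n_haplotypes), dtype=np.int8), 0, complete=True,
            designated_positions=np.empty(0, dtype=np.int64))
        f_m = fit_smcm(d, rates_known=True, region_mode=False, n_states=8,
                       max_iter=1, max_haplotypes=3)
        f_s = fit_snp_only(d, n_states=8, max_iter=1, max_haplotypes=3)
        assert f_m.loglik_trajectory[0] == pytest.approx(
            f_s.loglik_trajectory[0], abs=1e-6)

    def test_region_off_symmetric_rates_reduce_to_two_marker_fit(
            self, methylome_data):
        """With equal gain/loss rates the SMCm likelihood equals the generic
        two-state-marker likelihood up to the constant n_id*log 2
        that re-splits 'identical' into both-U/both-M."""
        from epismc.methylome import encode_pair_observations
        from epismc.smc import (EmissionBlock, FreeParameters, SMCModel,
                                baum_welch_fit)
        d = methylome_data
        mu = 2e-4
        f_m = fit_smcm(d, rates_known=True, region_mode=False,
                       site_rates=(mu, mu), n_states=8, max_iter=1,
                       max_haplotypes=2)
        obs_m = encode_pair_observations(d, 0, 1)
        ll_meth = baum_welch_fit([obs_m], f_m.model,
                                 FreeParameters(demography=False)).loglik
        # same data, methylation coded as identical/segregating only
        rec = d.records["meth"]
        si, sj = rec.states[:, 0], rec.states[:, 1]
        n_id = int((si == sj).sum())
        from epismc.observations import ObsBlock, PairObservationSequence
        snp_obs = encode_pair_observations(d, 0, 1).blocks[0]
        m2_block = ObsBlock("meth", 2, rec.positions[si != sj],
                            np.ones(int((si != sj).sum()), dtype=np.int64),
                            site_positions=rec.positions, default_symbol=0)
        obs2 = PairObservationSequence(d.sequence_length, [snp_obs, m2_block])
        model2 = SMCModel(f_m.model.disc, f_m.model.demography, f_m.model.r,
                          [f_m.model.blocks[0],
                           EmissionBlock("meth", "symmetric", (mu,), nbs=2)],
                          selfing_rate=f_m.model.selfing_rate,
                          window_size=f_m.model.window_size)
        fit2 = baum_welch_fit([obs2], model2, FreeParameters(demography=False))
        assert fit2.loglik - n_id * np.log(2) == pytest.approx(ll_meth, abs=1e-5)

    def test_region_model_requested_without_rates_rejected(self, methylome_data):
        d = methylome_data
        assert d.region_model is None
        with pytest.raises(ValueError):
            fit_smcm(d, rates_known=True, region_mode=True, region_model=None,
                     n_states=8, max_iter=1, max_haplotypes=3)

    def test_snp_only_obs_exclude_methylable_sites(self, methylome_data):
        obs = _snp_only_obs(methylome_data, 0, 1)
        c = obs.window_counts(1000).sum()
        n_dropped = int((obs.blocks[0].event_symbols == MISSING).sum())
        assert n_dropped >= methylome_data.records["meth"].total_designated
        # dropped sites vanish from the total count
        assert c == pytest.approx(methylome_data.sequence_length - n_dropped)
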