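"""Coalescent simulation of genomes carrying several heritable marker types.

The ancestral recombination graph is generated with msprime; finite-site
mutations for each marker class are then overlaid on the marginal
genealogies.  Symmetric markers (nucleotides, generic hyper-mutable markers)
and site-level-only methylation use msprime's matrix mutation models
restricted to the designated marker positions; the coupled region+site
methylation process (region-level events rewrite whole blocks) is simulated
by a dedicated engine walking the marginal trees.

Partial self-fertilisation is handled by the standard effective-recombination
rescaling r_eff = r * (1 - F) with F = sigma / (2 - sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import msprime
import numpy as np
import tskit

from .demography import Demography
from .markers import MarkerSpec, RegionMethylationModel, region_site_stationary

__all__ = [
    "SimulationConfig",
    "SiteRecords",
    "AnnotatedHaplotypes",
    "selfing_rescaling",
    "simulate_arg",
    "overlay_marker_mutations",
    "simulate_methylome",
    "simulate_dataset",
    "generate_fixture",
    "true_tmrca_track",
    "SCENARIOS",
]


def selfing_rescaling(selfing_rate: float) -> float:
    """Effective recombination factor (1 - F), F = sigma/(2 - sigma)."""
    if not (0.0 <= selfing_rate < 1.0):
        raise ValueError("selfing rate must lie in [0, 1)")
    F = selfing_rate / (2.0 - selfing_rate)
    return 1.0 - F


@dataclass
class SimulationConfig:
    """Parameters of one simulation run."""

    n_haplotypes: int = 10
    sequence_length: int = 1_000_000
    r: float = 1e-8
    selfing_rate: float = 0.0
    markers: List[MarkerSpec] = field(default_factory=list)
    region_model: Optional[RegionMethylationModel] = None
    methylable_fraction: float = 0.0   # fraction of all sites that are annotated CG
    cg_spacing: int = 10               # bp between methylable CGs inside genic regions
    seed: int = 1

    def __post_init__(self):
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.sequence_length <= 0:
            raise ValueError("zero-length sequence")
        if self.r < 0:
            raise ValueError("negative recombination rate")
        if self.markers:
            tot = sum(m.genome_fraction for m in self.markers)
            if tot > 1.0 + 1e-9:
                raise ValueError("marker genome fractions exceed 1")


@dataclass
class SiteRecords:
    """States of one marker class at its recorded sites.

    ``positions`` are 0-based; ``states`` has shape (n_sites, n_haplotypes).
    ``total_designated`` counts every site of the class in the genome
    (including unrecorded monomorphic ones); ``complete`` says whether
    ``positions`` lists them all.
    """

    positions: np.ndarray
    states: np.ndarray
    total_designated: int
    complete: bool = False
    designated_positions: Optional[np.ndarray] = None

    def polymorphic_mask(self) -> np.ndarray:
        if len(self.positions) == 0:
            return np.zeros(0, dtype=bool)
        valid = self.states >= 0
        first_idx = np.argmax(valid, axis=1)
        first = self.states[np.arange(len(self.states)), first_idx]
        return np.any(valid & (self.states != first[:, None]), axis=1)

    def n_polymorphic(self) -> int:
        return int(self.polymorphic_mask().sum())


class AnnotatedHaplotypes:
    """Simulated haplotypes annotated per site with marker type and state.

    Ground truth (marginal genealogies, demography, per-region methylation
    status) rides along for evaluation.
    """

    def __init__(self, sequence_length, n_haplotypes, markers,
                 records: Dict[str, SiteRecords], dominant: str,
                 tree_sequence=None, demography=None, config=None, seed=None,
                 genic_regions=None, region_truth=None, region_model=None):
        self.sequence_length = int(sequence_length)
        self.n_haplotypes = int(n_haplotypes)
        self.markers = {m.name: m for m in markers}
        self.records = records
        self.dominant = dominant
        self.tree_sequence = tree_sequence
        self.demography = demography
        self.config = config
        self.seed = seed
        self.genic_regions = genic_regions
        self.region_truth = region_truth
        self.region_model = region_model
        for name, rec in records.items():
            if name not in self.markers:
                raise ValueError(f"records for unknown marker {name!r}")
            if rec.states.shape[1] != self.n_haplotypes:
                raise ValueError("state matrix does not match haplotype count")

    # -- encoding -----------------------------------------------------------

    def encode_pair(self, i: int, j: int, include=None):
        """Code the (i, j) pair of haplotypes as a PairObservationSequence.

        Handles the dominant nucleotide class, minority symmetric markers and
        site-level methylation (symbols both-U/both-M/discordant).  The
        region-conditioned 9-symbol coding lives in the methylation module.
        ``include`` restricts to a subset of marker names; excluded markers'
        designated sites are removed from all counts.
        """
        from .observations import MISSING, ObsBlock, PairObservationSequence
        blocks = []
        names = [self.dominant] + [n for n in self.records if n != self.dominant]
        for name in names:
            rec = self.records[name]
            m = self.markers[name]
            dominant = name == self.dominant
            excluded = include is not None and name not in include
            si, sj = rec.states[:, i], rec.states[:, j]
            missing = (si < 0) | (sj < 0)
            if excluded:
                if dominant:
                    raise ValueError("cannot exclude the dominant marker")
                # drop the class: its designated sites vanish from the counts
                pos = (rec.designated_positions if rec.designated_positions
                       is not None else rec.positions)
                blocks[0].event_positions = np.concatenate(
                    [blocks[0].event_positions, pos])
                blocks[0].event_symbols = np.concatenate(
                    [blocks[0].event_symbols, np.full(len(pos), MISSING)])
                blocks[0] = ObsBlock(blocks[0].name, 2,
                                     blocks[0].event_positions,
                                     blocks[0].event_symbols, dominant=True)
                continue
            if m.symmetric:
                seg = (si != sj) & ~missing
                ev_pos = np.concatenate([rec.positions[seg],
                                         rec.positions[missing]])
                ev_sym = np.concatenate([np.ones(seg.sum(), dtype=np.int64),
                                         np.full(missing.sum(), MISSING)])
                blocks.append(ObsBlock(
                    name, 2, ev_pos, ev_sym,
                    site_positions=None if dominant else rec.designated_positions,
                    default_symbol=0, dominant=dominant))
            else:
                sym = np.where(missing, MISSING,
                               np.where(si != sj, 2, np.where(si == 1, 1, 0)))
                blocks.append(ObsBlock(name, 3, rec.positions, sym,
                                       default_symbol=None))
        return PairObservationSequence(self.sequence_length, blocks, pair=(i, j))

    # -- summaries ----------------------------------------------------------

    def polymorphism_fraction(self, marker: str) -> float:
        if marker not in self.records:
            raise KeyError(f"marker {marker!r} absent from data")
        rec = self.records[marker]
        if rec.total_designated == 0:
            return 0.0
        return rec.n_polymorphic() / rec.total_designated

    def pair_states(self, marker: str, i: int, j: int):
        rec = self.records[marker]
        return rec.positions, rec.states[:, i], rec.states[:, j]

    def site_table(self, max_length: int = 2_000_000):
        """Dense per-site table (POS, MARKER, STATE_1..n); small genomes only."""
        import pandas as pd
        if self.sequence_length > max_length:
            raise ValueError("site_table is for small sequences; use records directly")
        marker_col = np.full(self.sequence_length, self.dominant, dtype=object)
        states = np.zeros((self.sequence_length, self.n_haplotypes), dtype=np.int8)
        for name, rec in self.records.items():
            if rec.designated_positions is not None:
                marker_col[rec.designated_positions] = name
            if rec.complete:
                marker_col[rec.positions] = name
            states[rec.positions] = rec.states
        df = pd.DataFrame({"POS": np.arange(self.sequence_length),
                           "MARKER": marker_col})
        for k in range(self.n_haplotypes):
            df[f"STATE_{k + 1}"] = states[:, k]
        return df

    def to_tsv(self, path, chrom="1"):
        df = self.site_table()
        df.insert(0, "CHROM", chrom)
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ancestry
# ---------------------------------------------------------------------------


def _msprime_demography(demography: Demography) -> msprime.Demography:
    # sizes are haploid-pair coalescent sizes (pair rate 1/(2N), theta=4*N*mu);
    # with ploidy=1 msprime's pair rate is 1/size, hence the factor 2
    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=2.0 * demography.sizes[0])
    for t, n in zip(demography.boundaries[1:], demography.sizes[1:]):
        dem.add_population_parameters_change(time=t, initial_size=2.0 * n)
    return dem


def simulate_arg(config: SimulationConfig, demography: Demography,
                 seed: Optional[int] = None) -> tskit.TreeSequence:
    """Simulate the ancestral recombination graph as a tree sequence.

    Selfing reduces the effective recombination rate; trees cover the whole
    sequence contiguously.
    """
    seed = config.seed if seed is None else seed
    r_eff = config.r * selfing_rescaling(config.selfing_rate)
    return msprime.sim_ancestry(
        samples=config.n_haplotypes,
        ploidy=1,
        sequence_length=config.sequence_length,
        recombination_rate=r_eff,
        demography=_msprime_demography(demography),
        random_seed=(seed % (2**31 - 2)) + 1,
        discrete_genome=True,
        record_provenance=False,
    )


# ---------------------------------------------------------------------------
# mutation overlays
# ---------------------------------------------------------------------------


def _symmetric_model(nbs: int) -> msprime.MatrixMutationModel:
    """nbs-state chain, every event changes state uniformly (total rate = mu)."""
    alleles = [str(i) for i in range(nbs)]
    P = np.full((nbs, nbs), 1.0 / (nbs - 1))
    np.fill_diagonal(P, 0.0)
    return msprime.MatrixMutationModel(
        alleles, root_distribution=np.full(nbs, 1.0 / nbs), transition_matrix=P)


def _asymmetric_model(mu_gain: float, mu_loss: float):
    """Two-state U/M chain with gain/loss rates; returns (model, total_rate)."""
    R = mu_gain + mu_loss
    if R == 0:
        raise ValueError("degenerate asymmetric model")
    row = np.array([mu_loss / R, mu_gain / R])
    model = msprime.MatrixMutationModel(
        ["0", "1"], root_distribution=row, transition_matrix=np.vstack([row, row]))
    return model, R


def _positions_rate_map(L: int, positions: np.ndarray, rate: float) -> msprime.RateMap:
    """RateMap that applies ``rate`` exactly at the given integer positions."""
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) == 0:
        return msprime.RateMap(position=[0, L], rate=[0.0])
    # merge adjacent positions into runs, interleave zero-rate gaps, then
    # drop zero-length intervals
    breaks = np.flatnonzero(np.diff(positions) > 1)
    starts = positions[np.concatenate([[0], breaks + 1])].astype(float)
    ends = (positions[np.concatenate([breaks, [len(positions) - 1]])] + 1).astype(float)
    raw_pos = np.empty(2 * len(starts) + 2)
    raw_pos[0] = 0.0
    raw_pos[1:-1:2] = starts
    raw_pos[2:-1:2] = ends
    raw_pos[-1] = float(L)
    raw_rates = np.zeros(2 * len(starts) + 1)
    raw_rates[1::2] = rate
    keep = np.diff(raw_pos) > 0
    pos = np.concatenate([[raw_pos[0]], raw_pos[1:][keep]])
    return msprime.RateMap(position=pos, rate=raw_rates[keep])


def _extract_states(mts: tskit.TreeSequence, keep_mask=None,
                    keep_monomorphic=False) -> Tuple[np.ndarray, np.ndarray]:
    """Positions and integer state matrix of mutated sites.

    Sites whose mutations cancel out (monomorphic after back-mutation) are
    skipped unless ``keep_monomorphic``: their shared state is *not* a fresh
    stationary draw, which matters for hyper-mutable markers.
    """
    positions, rows = [], []
    for var in mts.variants():
        p = int(var.site.position)
        if keep_mask is not None and not keep_mask(p):
            continue
        g = var.genotypes
        if not keep_monomorphic and np.all(g == g[0]):
            continue  # back-mutated to monomorphic
        alleles = np.array([int(a) for a in var.alleles if a is not None])
        positions.append(p)
        rows.append(alleles[g].astype(np.int8))
    if not positions:
        n = mts.num_samples
        return np.empty(0, dtype=np.int64), np.empty((0, n), dtype=np.int8)
    return np.asarray(positions, dtype=np.int64), np.vstack(rows)


def overlay_marker_mutations(ts: tskit.TreeSequence, markers: List[MarkerSpec],
                             seed: int) -> AnnotatedHaplotypes:
    """Overlay finite-site mutations for a set of symmetric marker classes.

    The marker with the largest genome fraction is the dominant class and
    owns every position not claimed by another marker; minority classes are
    placed deterministically round-robin (every k-th position with
    k = round(1/fraction)), so designated-site counts are reproducible.
    """
    if not markers:
        raise ValueError("no markers given")
    if any(not m.symmetric for m in markers):
        raise ValueError("overlay_marker_mutations handles symmetric markers; "
                         "use simulate_methylome for methylation")
    L = int(ts.sequence_length)
    dominant = max(markers, key=lambda m: m.genome_fraction)
    rng = np.random.default_rng(seed)

    minority_positions: Dict[str, np.ndarray] = {}
    claimed = np.empty(0, dtype=np.int64)
    for m in markers:
        if m is dominant or m.genome_fraction == 0:
            continue
        k = max(2, int(round(1.0 / m.genome_fraction)))
        pos = np.arange(k - 1, L, k, dtype=np.int64)
        pos = np.setdiff1d(pos, claimed, assume_unique=True)
        minority_positions[m.name] = pos
        claimed = np.union1d(claimed, pos)
    claimed_set_sorted = claimed

    records: Dict[str, SiteRecords] = {}
    for m in markers:
        sub_seed = int(rng.integers(1, 2**31 - 1))
        if m.genome_fraction == 0:
            records[m.name] = SiteRecords(
                np.empty(0, dtype=np.int64),
                np.empty((0, ts.num_samples), dtype=np.int8), 0)
            continue
        model = _symmetric_model(m.nbs)
        if m is dominant:
            mts = msprime.sim_mutations(ts, rate=m.mu, model=model,
                                        random_seed=sub_seed,
                                        record_provenance=False)
            def keep(p, _c=claimed_set_sorted):
                i = np.searchsorted(_c, p)
                return not (i < len(_c) and _c[i] == p)
            pos, states = _extract_states(mts, keep)
            total = L - len(claimed_set_sorted)
            records[m.name] = SiteRecords(pos, states, total)
        else:
            sites = minority_positions[m.name]
            rmap = _positions_rate_map(L, sites, m.mu)
            mts = msprime.sim_mutations(ts, rate=rmap, model=model,
                                        random_seed=sub_seed,
                                        record_provenance=False)
            pos, states = _extract_states(mts)
            records[m.name] = SiteRecords(pos, states, len(sites),
                                          designated_positions=sites)
    return AnnotatedHaplotypes(L, ts.num_samples, markers, records,
                               dominant.name, tree_sequence=ts, seed=seed)


# ---------------------------------------------------------------------------
# methylome overlay
# ---------------------------------------------------------------------------


def _place_genic_regions(L: int, methylable_fraction: float, region_length: int,
                         cg_spacing: int, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded placement of genic regions and their methylable CG positions."""
    # keep the CG density per genic region compatible with the requested
    # genome-wide methylable fraction (dense annotation for large fractions)
    if methylable_fraction > 0:
        cg_spacing = min(cg_spacing, max(1, int(1.0 / methylable_fraction)))
    sites_per_region = max(1, region_length // cg_spacing)
    n_target_sites = int(round(methylable_fraction * L))
    n_regions = max(1, n_target_sites // sites_per_region)
    n_slots = L // region_length
    if n_regions > n_slots:
        raise ValueError("region length too large for requested coverage")
    slots = np.sort(rng.choice(n_slots, size=n_regions, replace=False))
    starts = slots * region_length
    regions = np.stack([starts, starts + region_length], axis=1)
    positions = (starts[:, None] + np.arange(0, region_length, cg_spacing)[None, :])
    return regions, positions.ravel()


def _simulate_region_site_process(ts, regions, region_sites, site_rates,
                                  region_model, rng):
    """Walk one marginal tree per region, simulating the coupled process.

    Region status flips at the region rates and resets all sites in the
    region; site-level events continue on top.  Within a region all sites
    share the marginal tree at the region midpoint (regions are of the order
    of the genealogy span, so this is a documented approximation).
    Returns (site state matrix, leaf region-status matrix).
    """
    g_s, l_s = site_rates
    g_r, l_r = region_model.mu_region_meth, region_model.mu_region_unmeth
    pi4 = region_site_stationary(site_rates, region_model)
    pi_region_m = pi4[2] + pi4[3]
    n = ts.num_samples
    all_states = []
    leaf_region = np.zeros((len(regions), n), dtype=np.int8)

    def site_step(states, dt):
        if dt <= 0 or g_s + l_s == 0:
            return states
        rtot = g_s + l_s
        e = np.exp(-rtot * dt)
        pm = g_s / rtot
        p_to_m = np.where(states == 1, pm + (1 - pm) * e, pm * (1 - e))
        return (rng.random(states.shape) < p_to_m).astype(np.int8)

    for ri, ((start, end), sites) in enumerate(zip(regions, region_sites)):
        mid = (start + end) // 2
        tree = ts.at(mid)
        nsites = len(sites)
        root = tree.root
        if pi_region_m in (0.0, 1.0):
            R0 = int(pi_region_m)
        else:
            R0 = int(rng.random() < pi_region_m)
        block = pi4[2 * R0:2 * R0 + 2]
        p_m0 = block[1] / block.sum() if block.sum() > 0 else 0.5
        root_states = (rng.random(nsites) < p_m0).astype(np.int8)

        node_state = {root: (R0, root_states)}
        states_out = np.zeros((nsites, n), dtype=np.int8)
        for u in tree.preorder():
            if u == root:
                pass
            else:
                R, s = node_state[tree.parent(u)]
                s = s.copy()
                tau = tree.branch_length(u)
                while tau > 0:
                    rate = g_r if R == 0 else l_r
                    dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                    if dt >= tau:
                        s = site_step(s, tau)
                        break
                    s = site_step(s, dt)
                    R = 1 - R
                    s[:] = R
                    tau -= dt
                node_state[u] = (R, s)
            if tree.is_leaf(u):
                R, s = node_state[u]
                states_out[:, u] = s
                leaf_region[ri, u] = R
        all_states.append(states_out)
    return np.vstack(all_states) if all_states else np.empty((0, n), np.int8), leaf_region


def simulate_methylome(ts: tskit.TreeSequence, config: SimulationConfig,
                       seed: int) -> AnnotatedHaplotypes:
    """Overlay SNPs and a methylome (site and/or region epimutation) on an ARG.

    Methylable CG sites live only inside seeded genic regions; site states are
    in {U=0, M=1}.  With no region process (rates 0 or region model absent)
    each site evolves independently on its own local genealogy via msprime;
    otherwise the coupled engine is used.
    """
    L = int(ts.sequence_length)
    rng = np.random.default_rng(seed)
    meth_spec = next((m for m in config.markers if not m.symmetric), None)
    snp_spec = next((m for m in config.markers if m.symmetric), None)
    if meth_spec is None or snp_spec is None:
        raise ValueError("config needs one symmetric (SNP) and one asymmetric "
                         "(methylation) marker")
    region_model = config.region_model or RegionMethylationModel(0.0, 0.0, 1000)
    if region_model.region_length > L:
        raise ValueError("region length larger than sequence")
    regions, meth_positions = _place_genic_regions(
        L, config.methylable_fraction, region_model.region_length,
        config.cg_spacing, rng)

    # SNPs everywhere except methylable positions
    snp_seed = int(rng.integers(1, 2**31 - 1))
    mts = msprime.sim_mutations(ts, rate=snp_spec.mu,
                                model=_symmetric_model(snp_spec.nbs),
                                random_seed=snp_seed,
                                record_provenance=False)
    meth_sorted = np.sort(meth_positions)

    def keep(p, _c=meth_sorted):
        i = np.searchsorted(_c, p)
        return not (i < len(_c) and _c[i] == p)

    snp_pos, snp_states = _extract_states(mts, keep)
    records = {snp_spec.name: SiteRecords(snp_pos, snp_states,
                                          L - len(meth_sorted))}

    region_truth = None
    has_region = (region_model.mu_region_meth + region_model.mu_region_unmeth) > 0
    g_s, l_s = meth_spec.rate_pair
    if not has_region:
        if g_s + l_s == 0:
            # no epimutation at all: everyone carries the ancestral pattern
            pi_m = 0.5
            anc = (rng.random(len(meth_sorted)) < pi_m).astype(np.int8)
            meth_states = np.repeat(anc[:, None], ts.num_samples, axis=1)
        else:
            model, R = _asymmetric_model(g_s, l_s)
            rmap = _positions_rate_map(L, meth_sorted, R)
            meth_seed = int(rng.integers(1, 2**31 - 1))
            ets = msprime.sim_mutations(ts, rate=rmap, model=model,
                                        random_seed=meth_seed,
                                        record_provenance=False)
            pos, states = _extract_states(ets, keep_monomorphic=True)
            # sites never hit by an epimutation carry the ancestral
            # (stationary) state
            meth_states = np.zeros((len(meth_sorted), ts.num_samples), np.int8)
            pi_m = g_s / (g_s + l_s)
            anc = (rng.random(len(meth_sorted)) < pi_m).astype(np.int8)
            meth_states[:] = anc[:, None]
            idx = np.searchsorted(meth_sorted, pos)
            meth_states[idx] = states
    else:
        region_sites = [meth_positions[(meth_positions >= s) & (meth_positions < e)]
                        for s, e in regions]
        meth_states, region_truth = _simulate_region_site_process(
            ts, regions, region_sites, (g_s, l_s), region_model, rng)
        order = np.argsort(np.concatenate(region_sites))
        meth_states = meth_states[order]

    records[meth_spec.name] = SiteRecords(
        meth_sorted, meth_states, len(meth_sorted), complete=True,
        designated_positions=meth_sorted)
    return AnnotatedHaplotypes(
        L, ts.num_samples, [snp_spec, meth_spec], records, snp_spec.name,
        tree_sequence=ts, config=config, seed=seed, genic_regions=regions,
        region_truth=region_truth,
        region_model=config.region_model)


# ---------------------------------------------------------------------------
# scenarios / fixtures
# ---------------------------------------------------------------------------


def _two_marker_config(r, mu1, mu2, f2=0.02, L=100_000_000, n=10, selfing=0.0):
    return SimulationConfig(
        n_haplotypes=n, sequence_length=L, r=r, selfing_rate=selfing,
        markers=[MarkerSpec("m1", 4, mu=mu1, genome_fraction=1.0 - f2),
                 MarkerSpec("m2", 2, mu=mu2, genome_fraction=f2)])


def _methylome_config(r=3.5e-8, mu1=7e-9, mu_sm=3.5e-4, mu_su=1.5e-3,
                      region_model=None, frac=0.02, L=100_000_000, n=10,
                      selfing=0.9):
    return SimulationConfig(
        n_haplotypes=n, sequence_length=L, r=r, selfing_rate=selfing,
        markers=[MarkerSpec("snp", 4, mu=mu1, genome_fraction=1.0 - frac),
                 MarkerSpec("meth", 2, rate_pair=(mu_sm, mu_su),
                            genome_fraction=frac)],
        region_model=region_model, methylable_fraction=frac)


# Bottleneck epochs: the study scenarios fix the fold changes and ancestral
# sizes; the exact event times are free choices, documented in docs/methods.md.
SCENARIOS = {
    "constant": dict(
        demography=Demography((0.0,), (10_000.0,)),
        config=_two_marker_config(1e-8, 1e-8, 1e-4)),
    "bottleneck_fig2A": dict(
        demography=Demography((0.0, 1_000.0, 5_000.0),
                              (10_000.0, 1_000.0, 10_000.0)),
        config=_two_marker_config(1e-8, 1e-8, 1e-4)),
    "bottleneck_fig2B": dict(
        demography=Demography((0.0, 1_000.0, 5_000.0),
                              (1_000.0, 100.0, 1_000.0)),
        config=_two_marker_config(1e-8, 1e-8, 1e-4)),
    "bottleneck_fig2C": dict(
        demography=Demography((0.0, 2_000.0, 10_000.0),
                              (10_000.0, 1_000.0, 10_000.0)),
        config=_two_marker_config(1e-7, 1e-8, 1e-4)),
    "severe_fig2D": dict(
        demography=Demography((0.0, 200.0, 1_000.0),
                              (5_000.0, 10.0, 10_000.0)),
        config=_two_marker_config(1e-8, 1e-8, 1e-4)),
    "methylome_fig5": dict(
        demography=Demography((0.0, 1_000.0, 5_000.0),
                              (10_000.0, 500.0, 10_000.0)),
        config=_methylome_config()),
    "methylome_dmr": dict(
        demography=Demography((0.0, 1_000.0, 5_000.0),
                              (10_000.0, 500.0, 10_000.0)),
        config=_methylome_config(mu_sm=0.0, mu_su=0.0,
                                 region_model=RegionMethylationModel(2e-4, 1e-3, 1000))),
    "methylome_both": dict(
        demography=Demography((0.0, 1_000.0, 5_000.0),
                              (10_000.0, 500.0, 10_000.0)),
        config=_methylome_config(region_model=RegionMethylationModel(2e-4, 1e-3, 1000))),
}


def simulate_dataset(config: SimulationConfig, demography: Demography,
                     seed: int) -> AnnotatedHaplotypes:
    """ARG + mutation overlay in one call; dispatches on marker kinds."""
    ts = simulate_arg(config, demography, seed=seed)
    if any(not m.symmetric for m in config.markers):
        out = simulate_methylome(ts, config, seed=seed + 1)
    else:
        out = overlay_marker_mutations(ts, config.markers, seed=seed + 1)
    out.demography = demography
    out.config = config
    out.seed = seed
    return out


def generate_fixture(scenario_name: str, seed: int, sequence_length=None,
                     n_haplotypes=None, methylable_fraction=None) -> AnnotatedHaplotypes:
    """Simulate one named study scenario (optionally at reduced scale)."""
    if scenario_name not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_name!r}; "
                         f"choose from {sorted(SCENARIOS)}")
    sc = SCENARIOS[scenario_name]
    cfg = sc["config"]
    kw = {}
    if sequence_length is not None:
        kw["sequence_length"] = int(sequence_length)
    if n_haplotypes is not None:
        kw["n_haplotypes"] = int(n_haplotypes)
    if methylable_fraction is not None:
        kw["methylable_fraction"] = methylable_fraction
        f = methylable_fraction
        kw["markers"] = [replace(cfg.markers[0], genome_fraction=1 - f),
                         replace(cfg.markers[1], genome_fraction=f)]
    cfg = replace(cfg, **kw) if kw else cfg
    return simulate_dataset(cfg, sc["demography"], seed)


def true_tmrca_track(ts: tskit.TreeSequence, i: int, j: int):
    """(breakpoints, tmrca) of the pair (i, j) along the genome."""
    breaks, times = [], []
    for tree in ts.trees():
        breaks.append(tree.interval.left)
        times.append(tree.tmrca(i, j))
    breaks.append(ts.sequence_length)
    return np.asarray(breaks), np.asarray(times)
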