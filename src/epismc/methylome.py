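"""Methylation-specific layer: region-effect testing, DMR segmentation,
observation coding and the joint SNP+SMP(+DMR) demographic fit.

The observation coding follows the field's convention: at a non-methylable
position, 0 = identical nucleotides, 1 = segregating; at an annotated CG
site, 2 = both unmethylated, 3 = both methylated, 4 = discordant.  When a
region-level methylation process is modelled, symbols 2-4 are lifted to a
9-symbol alphabet conditioned on the inferred region-pair status
{UU, UM/MU, MM}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binomtest

from . import _hmm
from .markers import (RegionMethylationModel, asymmetric_site_emission,
                      region_conditioned_emission, region_pair_probabilities)
from .observations import MISSING, ObsBlock, PairObservationSequence
from .simulate import AnnotatedHaplotypes

__all__ = [
    "MethylomeMatrix",
    "MethylRegionSegmentation",
    "RegionEffectResult",
    "region_effect_test",
    "segment_methylation_regions",
    "encode_pair_observations",
    "fit_smcm",
    "fit_snp_only",
    "SITE_CODE_UU",
    "SITE_CODE_MM",
    "SITE_CODE_DISCORDANT",
]

# global observation codes (2/3/4 in the 5-symbol alphabet)
SITE_CODE_UU = 2
SITE_CODE_MM = 3
SITE_CODE_DISCORDANT = 4


@dataclass
class MethylomeMatrix:
    """Methylation status of annotated CG sites across haplotypes.

    ``states``: (n_sites, n_haplotypes) with U=0, M=1, missing=-1;
    ``genic_regions``: (m, 2) 0-based half-open intervals (optional).
    """

    positions: np.ndarray
    states: np.ndarray
    sequence_length: int
    genic_regions: Optional[np.ndarray] = None
    samples: Optional[List[str]] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int8)
        if np.any(np.diff(self.positions) < 0):
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.states = self.states[order]
        if not np.isin(self.states, [-1, 0, 1]).all():
            raise ValueError("methylation status outside {M, U, missing}")

    @property
    def n_haplotypes(self):
        return self.states.shape[1]

    @classmethod
    def from_annotated(cls, data: AnnotatedHaplotypes,
                       marker: str = "meth") -> "MethylomeMatrix":
        rec = data.records[marker]
        return cls(rec.positions, rec.states, data.sequence_length,
                   genic_regions=data.genic_regions)


@dataclass
class MethylRegionSegmentation:
    """Posterior-decoded region-pair methylation status along one pair."""

    pair: Tuple[int, int]
    positions: np.ndarray            # annotated site positions
    site_status: np.ndarray          # per-site region-pair status 0=UU,1=UM,2=MM
    intervals: List[Tuple[int, int, int]]  # (start, end, status)
    confidence: np.ndarray           # per-interval mean posterior of its status
    posterior: Optional[np.ndarray] = None

    def __post_init__(self):
        for s, e, _ in self.intervals:
            if e <= s:
                raise ValueError("non-positive segment length")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for s, e, _ in self.intervals], dtype=float)

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean())

    @property
    def median_length(self) -> float:
        return float(np.median(self.lengths))


# ---------------------------------------------------------------------------
# region-effect test
# ---------------------------------------------------------------------------


@dataclass
class RegionEffectResult:
    p_value: float
    region_effect: bool
    expected_identity: float
    n_pairs: int
    n_identical: int
    per_haplotype: Optional[List[float]] = None


def region_effect_test(methylome: MethylomeMatrix,
                       site_rates: Tuple[float, float],
                       haplotype: int = 0, threshold: float = 0.05,
                       min_distance: Optional[int] = None,
                       all_haplotypes: bool = False) -> RegionEffectResult:
    """Binomial test for spatial correlation of methylation states.

    Under site-level epimutation only, the states of distinct CG sites in one
    genome are independent draws from the stationary distribution of the
    gain/loss chain, so the probability that two annotated sites share their
    status is p = pi_M^2 + pi_U^2.  The observed number of identical pairs
    among disjoint successive site pairs (non-overlapping, so the count is
    binomial) is compared two-sidedly against that expectation; rejection
    indicates a region-level process.  ``min_distance`` keeps only pairs at
    least that many bp apart (the distance-stratified variant).
    """
    g, l = site_rates
    if g < 0 or l < 0 or g + l == 0:
        raise ValueError("invalid site rates")
    pi_m = g / (g + l)
    p_same = pi_m**2 + (1 - pi_m)**2

    def one(h):
        keep = methylome.states[:, h] >= 0
        pos = methylome.positions[keep]
        st = methylome.states[keep, h]
        if len(pos) < 2:
            raise ValueError("fewer than 2 annotated methylable sites")
        pairs = _disjoint_pairs(pos, min_distance)
        if len(pairs) == 0:
            raise ValueError("no site pairs satisfy the distance constraint")
        ident = int(np.sum(st[pairs[:, 0]] == st[pairs[:, 1]]))
        pv = binomtest(ident, len(pairs), p_same).pvalue
        return pv, ident, len(pairs)

    pv, ident, m = one(haplotype)
    per = None
    if all_haplotypes:
        per = [one(h)[0] for h in range(methylome.n_haplotypes)]
    return RegionEffectResult(pv, pv < threshold, p_same, m, ident, per)


def _disjoint_pairs(pos: np.ndarray, min_distance: Optional[int]) -> np.ndarray:
    if min_distance is None:
        k = (len(pos) // 2) * 2
        return np.arange(k).reshape(-1, 2)
    pairs = []
    i = 0
    while i < len(pos):
        j = int(np.searchsorted(pos, pos[i] + min_distance))
        if j >= len(pos):
            break
        pairs.append((i, j))
        i = j + 1
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# DMR segmentation HMM
# ---------------------------------------------------------------------------


def _pair_site_symbols(methylome, i, j):
    si, sj = methylome.states[:, i], methylome.states[:, j]
    missing = (si < 0) | (sj < 0)
    return np.where(missing, MISSING,
                    np.where(si != sj, 2, np.where(si == 1, 1, 0)))


def _match_discordance_time(site_rates, frac_disc: float) -> float:
    """Moment-matched pair TMRCA from the observed discordant fraction."""
    g, l = site_rates
    lo = 1e-6
    f_lo = float(asymmetric_site_emission(g, l, lo)[2])
    f_inf = float(asymmetric_site_emission(g, l, 1e12)[2])
    target = min(max(frac_disc, 2.0 * f_lo), 0.999 * f_inf)
    fun = lambda t: float(asymmetric_site_emission(g, l, t)[2]) - target
    return brentq(fun, lo, 1e12)


def segment_methylation_regions(methylome: MethylomeMatrix, i: int = 0,
                                j: int = 1,
                                site_rates: Tuple[float, float] = (3.5e-4, 1.5e-3),
                                region_model: Optional[RegionMethylationModel] = None,
                                t_ref: Optional[float] = None
                                ) -> MethylRegionSegmentation:
    """Posterior-decode the region-pair methylation status along one pair.

    A 3-state HMM over annotated CG sites: hidden states are the region-pair
    status {UU, UM/MU, MM}; emissions are the site-pair symbols {2, 3, 4}
    with region-conditioned probabilities; transitions implement a geometric
    region-length prior with mean the configured region length.  ``t_ref``
    is the pair coalescence time used in the emissions (moment-matched from
    the discordant-site fraction when not given).
    """
    if len(methylome.positions) == 0:
        raise ValueError("empty methylome")
    region_model = region_model or RegionMethylationModel(2e-4, 1e-3, 1000)
    sym = _pair_site_symbols(methylome, i, j)
    keep = sym != MISSING
    pos = methylome.positions
    if t_ref is None:
        fr = float(np.mean(sym[keep] == 2)) if keep.any() else 0.01
        t_ref = _match_discordance_time(site_rates, fr)

    E = np.vstack([region_conditioned_emission(site_rates, region_model, rp, t_ref)
                   for rp in ("UU", "UM", "MM")])          # (3 states, 3 syms)
    piR = region_pair_probabilities(region_model, t_ref)
    B = np.ones((len(pos), 3))
    B[keep] = E[:, sym[keep]].T
    d = np.diff(pos).astype(float)
    stay = np.exp(-2.0 * d / region_model.region_length)
    As = (stay[:, None, None] * np.eye(3)[None]
          + (1.0 - stay)[:, None, None] * piR[None, None, :])
    ll, gamma = _hmm.forward_backward_varying(piR.copy(), As, B)
    status = np.argmax(gamma, axis=1)

    intervals, confs = [], []
    start = 0
    for k in range(1, len(pos) + 1):
        if k == len(pos) or status[k] != status[start]:
            s = int(pos[start])
            e = int(pos[k - 1]) + 1
            intervals.append((s, e, int(status[start])))
            confs.append(float(gamma[start:k, status[start]].mean()))
            start = k
    return MethylRegionSegmentation((i, j), pos, status, intervals,
                                    np.asarray(confs), posterior=gamma)


# ---------------------------------------------------------------------------
# observation coding
# ---------------------------------------------------------------------------


def encode_pair_observations(data: AnnotatedHaplotypes, i: int, j: int,
                             segmentation: Optional[MethylRegionSegmentation] = None,
                             segregating_only: bool = False,
                             snp_marker: Optional[str] = None,
                             meth_marker: str = "meth") -> PairObservationSequence:
    """Code one pair's SNPs and methylation into an observation sequence.

    Without a segmentation, annotated CG sites carry the 3-symbol site-pair
    coding (global codes 2/3/4); with one, the 9-symbol region-conditioned
    coding (3 x region-pair status x site symbol).  ``segregating_only``
    keeps only SMPs segregating in the full sample (the default real-data
    mode); monomorphic annotated sites are then excluded from all counts.
    """
    snp_marker = snp_marker or data.dominant
    rec_snp = data.records[snp_marker]
    rec_m = data.records[meth_marker]
    if data.markers[meth_marker].symmetric:
        raise ValueError(f"{meth_marker!r} is not a methylation marker")

    si, sj = rec_snp.states[:, i], rec_snp.states[:, j]
    snp_missing = (si < 0) | (sj < 0)
    seg = (si != sj) & ~snp_missing
    ev_pos = np.concatenate([rec_snp.positions[seg],
                             rec_snp.positions[snp_missing]])
    ev_sym = np.concatenate([np.ones(int(seg.sum()), dtype=np.int64),
                             np.full(int(snp_missing.sum()), MISSING)])
    snp_block = ObsBlock(snp_marker, 2, ev_pos, ev_sym, dominant=True)

    sym = _pair_site_symbols_from(rec_m.states[:, i], rec_m.states[:, j])
    pos = rec_m.positions
    keep_sites = np.ones(len(pos), dtype=bool)
    if segregating_only:
        keep_sites = rec_m.polymorphic_mask()
    if segmentation is not None:
        idx = np.searchsorted(segmentation.positions, pos)
        idx = np.clip(idx, 0, len(segmentation.positions) - 1)
        reg = segmentation.site_status[idx]
        sym9 = np.where(sym == MISSING, MISSING, 3 * reg + sym)
        meth_block = ObsBlock(
            meth_marker, 9, pos[keep_sites], sym9[keep_sites],
            site_positions=pos, default_symbol=None)
    else:
        meth_block = ObsBlock(
            meth_marker, 3, pos[keep_sites], sym[keep_sites],
            site_positions=pos, default_symbol=None)
    return PairObservationSequence(data.sequence_length,
                                   [snp_block, meth_block], pair=(i, j))


def _pair_site_symbols_from(si, sj):
    missing = (si < 0) | (sj < 0)
    return np.where(missing, MISSING,
                    np.where(si != sj, 2, np.where(si == 1, 1, 0)))


def to_global_codes(site_symbols: np.ndarray, methylable: bool) -> np.ndarray:
    """Map within-block symbols to the global 0-4 observation codes."""
    if methylable:
        return np.where(site_symbols == MISSING, MISSING, site_symbols + 2)
    return site_symbols.copy()


def from_global_codes(codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_global_codes`: (methylable mask, block symbols)."""
    codes = np.asarray(codes)
    methylable = codes >= 2
    sym = np.where(codes == MISSING, MISSING,
                   np.where(methylable, codes - 2, codes))
    return methylable, sym


# ---------------------------------------------------------------------------
# SMCm fits
# ---------------------------------------------------------------------------


def _pairs(n, max_haplotypes=None):
    m = n if max_haplotypes is None else min(n, max_haplotypes)
    return [(i, j) for i in range(m) for j in range(i + 1, m)]


def _snp_only_obs(data, i, j, snp_marker=None, exclude_meth="meth"):
    """SNP-only coding: methylable sites are dropped from every count."""
    snp_marker = snp_marker or data.dominant
    rec = data.records[snp_marker]
    si, sj = rec.states[:, i], rec.states[:, j]
    missing = (si < 0) | (sj < 0)
    seg = (si != sj) & ~missing
    ev_pos = [rec.positions[seg], rec.positions[missing]]
    ev_sym = [np.ones(int(seg.sum()), dtype=np.int64),
              np.full(int(missing.sum()), MISSING)]
    if exclude_meth in data.records:
        mpos = data.records[exclude_meth].positions
        ev_pos.append(mpos)
        ev_sym.append(np.full(len(mpos), MISSING))
    block = ObsBlock(snp_marker, 2, np.concatenate(ev_pos),
                     np.concatenate(ev_sym), dominant=True)
    return PairObservationSequence(data.sequence_length, [block], pair=(i, j))


def fit_snp_only(data: AnnotatedHaplotypes, n_states: int = 20,
                 window_size: int = 100, method: str = "bw",
                 max_haplotypes: Optional[int] = None, max_iter: int = 15,
                 r: Optional[float] = None, free_r: bool = False):
    """Demographic fit from the nucleotide marker alone (SNP-only baseline)."""
    from .rates import DiversitySummary
    from .smc import (EmissionBlock, FreeParameters, baum_welch_fit,
                      constant_model, likelihood_fit)
    snp = data.dominant
    mu1 = data.markers[snp].mu
    summary = DiversitySummary.from_annotated(data)
    N0 = max(summary.theta_w(snp) / (4.0 * mu1), 10.0)
    if r is None:
        r = data.config.r if data.config is not None else mu1
    selfing = data.config.selfing_rate if data.config is not None else 0.0
    blocks = [EmissionBlock(snp, "symmetric", (mu1,),
                            nbs=data.markers[snp].nbs)]
    model = constant_model(N0, r, blocks, n_states=n_states,
                           window_size=window_size, selfing_rate=selfing)
    obs = [_snp_only_obs(data, i, j) for i, j in
           _pairs(data.n_haplotypes, max_haplotypes)]
    free = FreeParameters(demography=True, r=free_r)
    if method == "bw":
        return baum_welch_fit(obs, model, free, max_iter=max_iter)
    return likelihood_fit(obs, model, free)


def fit_smcm(data: AnnotatedHaplotypes, rates_known: bool = True,
             region_mode="auto", segregating_only: bool = False,
             method: str = "bw", n_states: int = 20, window_size: int = 100,
             max_haplotypes: Optional[int] = None, max_iter: int = 15,
             r: Optional[float] = None, free_r: bool = False,
             site_rates: Optional[Tuple[float, float]] = None,
             region_model: Optional[RegionMethylationModel] = None):
    """Joint SNP + SMP (+DMR) demographic fit.

    ``region_mode``: True / False force the region-conditioned 9-symbol model
    on or off; "auto" turns it on when the region-effect test rejects and a
    region model is available.  With ``rates_known=False`` the site (and, with
    regions, region) epimutation rates are freed in the fit.  Returns the
    FitResult with a ``diagnostics`` dict attached.
    """
    from .rates import DiversitySummary
    from .smc import (EmissionBlock, FreeParameters, baum_welch_fit,
                      constant_model, likelihood_fit)
    snp = data.dominant
    meth = next(n for n, m in data.markers.items() if not m.symmetric)
    mu1 = data.markers[snp].mu
    if site_rates is None:
        if rates_known:
            site_rates = data.markers[meth].rate_pair
        else:
            site_rates = (1e-4, 1e-4)
    region_model = region_model or data.region_model
    methylome = MethylomeMatrix.from_annotated(data, meth)

    diagnostics: Dict[str, object] = {}
    use_region = bool(region_mode) and region_mode is not None
    if region_mode == "auto":
        try:
            test = region_effect_test(methylome, site_rates)
            diagnostics["region_effect_test"] = test
            use_region = test.region_effect and region_model is not None
        except ValueError:
            use_region = False
    if use_region and region_model is None:
        raise ValueError("region model requested but no region rates/length given")

    pairs = _pairs(data.n_haplotypes, max_haplotypes)
    obs = []
    for i, j in pairs:
        seg = None
        if use_region:
            seg = segment_methylation_regions(methylome, i, j, site_rates,
                                              region_model)
        obs.append(encode_pair_observations(
            data, i, j, segmentation=seg, segregating_only=segregating_only))
    diagnostics["region_model_used"] = use_region

    summary = DiversitySummary.from_annotated(data)
    N0 = max(summary.theta_w(snp) / (4.0 * mu1), 10.0)
    if r is None:
        r = data.config.r if data.config is not None else mu1
    selfing = data.config.selfing_rate if data.config is not None else 0.0
    blocks = [EmissionBlock(snp, "symmetric", (mu1,), nbs=data.markers[snp].nbs)]
    if use_region:
        blocks.append(EmissionBlock(
            meth, "region9",
            tuple(site_rates) + ((region_model.mu_region_meth,
                                  region_model.mu_region_unmeth)
                                 if not rates_known else ()),
            region_model=region_model))
    else:
        blocks.append(EmissionBlock(meth, "asymmetric", tuple(site_rates)))
    model = constant_model(N0, r, blocks, n_states=n_states,
                           window_size=window_size, selfing_rate=selfing)
    free = FreeParameters(demography=True, r=free_r,
                          rates=(meth,) if not rates_known else ())
    if method == "bw":
        fit = baum_welch_fit(obs, model, free, max_iter=max_iter)
    else:
        fit = likelihood_fit(obs, model, free)
    fit.diagnostics = diagnostics
    return fit
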