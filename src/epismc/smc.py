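"""The pairwise SMC hidden Markov model and its fitting strategies.

The hidden state at a genomic position is the discretized coalescence time
(TMRCA) of one pair of haploid genomes.  Transitions along the genome follow
the SMC' recombination kernel under a piecewise-constant demography; each
marker class contributes its own closed-form emission distribution evaluated
at the interval's representative time.  The composite likelihood over all
haplotype pairs is maximised either by Baum-Welch (a generalized EM whose
M-step optimises the expected complete-data log-likelihood numerically) or
by direct numerical optimisation of the observed likelihood.

For long sequences the observations are binned into fixed windows: the
window emission is the product of the per-site emissions and transitions act
between windows (window_size=1 recovers the exact per-site HMM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize

from . import _hmm
from .demography import Demography
from .markers import (MarkerSpec, RegionMethylationModel,
                      asymmetric_site_emission, nine_symbol_emission,
                      symmetric_pair_emission)
from .observations import PairObservationSequence

__all__ = [
    "TimeDiscretization",
    "EmissionBlock",
    "SMCModel",
    "FreeParameters",
    "FitResult",
    "discretize_time",
    "transition_matrix",
    "emission_matrix",
    "forward_backward",
    "baum_welch_fit",
    "likelihood_fit",
    "constant_model",
]

_EPS = 1e-300


# ---------------------------------------------------------------------------
# time discretization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeDiscretization:
    """Hidden-state time intervals [boundaries[k], boundaries[k+1])."""

    boundaries: tuple   # length K+1; first 0, last +inf
    rep_times: tuple    # length K; representative time inside each interval

    def __post_init__(self):
        b = np.asarray(self.boundaries)
        r = np.asarray(self.rep_times)
        if len(b) != len(r) + 1 or len(r) < 2:
            raise ValueError("need at least 2 hidden states")
        if np.any(np.diff(b) <= 0) or b[0] != 0 or not np.isinf(b[-1]):
            raise ValueError("boundaries must increase from 0 to +inf")
        for k in range(len(r)):
            hi = b[k + 1]
            if not (b[k] < r[k] and (np.isinf(hi) or r[k] < hi)):
                raise ValueError("representative time outside its interval")

    @property
    def n_states(self):
        return len(self.rep_times)


def discretize_time(n_states: int, demography_guess: Demography,
                    tail_quantile: float = 1e-6) -> TimeDiscretization:
    """Equal-prior-mass time intervals under the guess demography.

    Boundaries are the k/K quantiles of the pair-coalescence distribution;
    the representative time is the conditional mean within the interval
    (approximated by averaging the inverse CDF over sub-quantiles).
    """
    if n_states < 2:
        raise ValueError("n_states must be at least 2")
    K = n_states
    q = np.arange(1, K) / K
    bounds = np.concatenate([[0.0],
                             demography_guess.inverse_pair_hazard(-np.log1p(-q)),
                             [np.inf]])
    reps = np.empty(K)
    m = 64
    for k in range(K):
        lo, hi = k / K, (k + 1) / K
        if k == K - 1:
            hi = 1.0 - tail_quantile
        u = lo + (hi - lo) * (np.arange(m) + 0.5) / m
        reps[k] = demography_guess.inverse_pair_hazard(-np.log1p(-u)).mean()
    return TimeDiscretization(tuple(bounds), tuple(reps))


# ---------------------------------------------------------------------------
# transition kernel (SMC')
# ---------------------------------------------------------------------------


def transition_matrix(disc: TimeDiscretization, demography: Demography,
                      r: float, gauss_points: int = 32) -> np.ndarray:
    """Per-site transition matrix of the SMC' kernel.

    From TMRCA ``s`` a recombination strikes one of the two branches with
    per-site probability ``1 - exp(-2 r s)``; the recombination height is
    uniform on [0, s], the detached lineage re-coalesces at rate 2/(2N(t))
    below ``s`` (half of which is the invisible back-coalescence that keeps
    the TMRCA) and at rate 1/(2N(t)) above.  ``r = 0`` gives the identity.
    """
    if r < 0:
        raise ValueError("negative recombination rate")
    K = disc.n_states
    edges = np.asarray(disc.boundaries)
    reps = np.asarray(disc.rep_times)
    x, w = leggauss(gauss_points)
    A = np.zeros((K, K))
    fin_edges = edges[:-1]
    for i in range(K):
        s = reps[i]
        u = s * (x + 1.0) / 2.0
        wu = w / 2.0
        Hu = demography.pair_hazard(u)                      # (m,)
        Hs = float(demography.pair_hazard(s))
        # below s: coalescence with the other branch inside (u, s)
        a_lo = np.clip(fin_edges[None, :], u[:, None], s)    # (m, K)
        b_hi = np.where(np.isinf(edges[1:]), s, np.minimum(edges[1:], s))
        b_lo = np.clip(b_hi[None, :], u[:, None], s)
        Ha = demography.pair_hazard(a_lo)
        Hb = demography.pair_hazard(b_lo)
        G = 0.5 * (np.exp(-2.0 * (Ha - Hu[:, None]))
                   - np.exp(-2.0 * (Hb - Hu[:, None])))
        # above s: survive to s then single-lineage coalescence
        S_u = np.exp(-2.0 * (Hs - Hu))                       # (m,)
        a_up = np.maximum(fin_edges, s)
        Fa = np.exp(-(demography.pair_hazard(a_up) - Hs))
        Fb = np.where(np.isinf(edges[1:]), 0.0,
                      np.exp(-(demography.pair_hazard(
                          np.maximum(np.where(np.isinf(edges[1:]), s, edges[1:]), s))
                          - Hs)))
        UP = S_u[:, None] * (Fa[None, :] - Fb[None, :])
        q = (wu[:, None] * (G + UP)).sum(axis=0)
        q_same = float((wu * 0.5 * (1.0 - S_u)).sum())
        p_rec = -np.expm1(-2.0 * r * s)
        A[i] = p_rec * q
        A[i, i] += 1.0 - p_rec + p_rec * q_same
    return A


# ---------------------------------------------------------------------------
# emission model
# ---------------------------------------------------------------------------


@dataclass
class EmissionBlock:
    """Emission model of one marker class.

    ``kind`` is one of ``"symmetric"`` (rates = (mu,), needs ``nbs``),
    ``"asymmetric"`` (rates = (mu_gain, mu_loss)) or ``"region9"``
    (rates = (mu_SM, mu_SU) site rates plus a region model; 9 symbols).
    ``free`` marks the rates as parameters to estimate.
    """

    name: str
    kind: str
    rates: Tuple[float, ...]
    nbs: int = 2
    region_model: Optional[RegionMethylationModel] = None
    free: bool = False

    @property
    def n_symbols(self) -> int:
        return {"symmetric": 2, "asymmetric": 3, "region9": 9}[self.kind]

    def emissions(self, t: np.ndarray) -> np.ndarray:
        """(len(t), n_symbols) emission probabilities; rows sum to 1."""
        if self.kind == "symmetric":
            if not self.rates:
                raise ValueError(f"marker {self.name!r} has no rates")
            spec = MarkerSpec(self.name, self.nbs, mu=self.rates[0])
            return symmetric_pair_emission(spec, t)
        if self.kind == "asymmetric":
            return asymmetric_site_emission(self.rates[0], self.rates[1], t)
        if self.kind == "region9":
            g_s, l_s = self.rates[:2]
            rm = self.region_model
            if len(self.rates) == 4:
                rm = replace(rm, mu_region_meth=self.rates[2],
                             mu_region_unmeth=self.rates[3])
            return np.vstack([nine_symbol_emission((g_s, l_s), rm, ti)
                              for ti in np.atleast_1d(t)])
        raise ValueError(f"unknown emission kind {self.kind!r}")


def emission_matrix(disc: TimeDiscretization,
                    blocks: Sequence[EmissionBlock]) -> np.ndarray:
    """(K, total_symbols) emissions; each block's rows sum to 1 per state."""
    t = np.asarray(disc.rep_times)
    return np.hstack([b.emissions(t) for b in blocks])


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class SMCModel:
    """Full specification of the pairwise multi-marker SMC HMM."""

    disc: TimeDiscretization
    demography: Demography
    r: float
    blocks: List[EmissionBlock]
    selfing_rate: float = 0.0
    window_size: int = 100

    @property
    def r_eff(self) -> float:
        F = self.selfing_rate / (2.0 - self.selfing_rate)
        return self.r * (1.0 - F)

    def prior(self) -> np.ndarray:
        pi = self.demography.interval_masses(np.asarray(self.disc.boundaries))
        return pi / pi.sum()

    def site_transition(self) -> np.ndarray:
        return transition_matrix(self.disc, self.demography, self.r_eff)

    def window_transition(self) -> np.ndarray:
        A = self.site_transition()
        if self.window_size == 1:
            return A
        return np.linalg.matrix_power(A, self.window_size)

    def emissions(self) -> np.ndarray:
        return emission_matrix(self.disc, self.blocks)

    def rates_dict(self) -> Dict[str, Tuple[float, ...]]:
        return {b.name: tuple(b.rates) for b in self.blocks}


def constant_model(N0: float, r: float, blocks: Sequence[EmissionBlock],
                   n_states: int = 40, window_size: int = 100,
                   selfing_rate: float = 0.0) -> SMCModel:
    """Model initialised at a constant population size N0."""
    dem = Demography((0.0,), (float(N0),))
    disc = discretize_time(n_states, dem)
    return SMCModel(disc, dem, r, list(blocks), selfing_rate, window_size)


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------


@dataclass
class FBResult:
    loglik: float
    posteriors: np.ndarray      # (n_windows, K), rows sum to 1
    xi_sum: np.ndarray          # (K, K) expected transition counts
    gamma0: np.ndarray
    window_size: int
    emission_counts: np.ndarray  # (K, S) expected symbol counts per state


def _window_loglik_matrix(counts: np.ndarray, E: np.ndarray):
    logE = np.log(np.clip(E, _EPS, None))
    logB = counts @ logE.T
    shift = logB.max(axis=1)
    return np.exp(logB - shift[:, None]), shift.sum()


def forward_backward(obs: PairObservationSequence, model: SMCModel) -> FBResult:
    """Posterior decoding of one pair; scaled arithmetic, no underflow.

    Posterior rows are rescaled to sum to one; the log-likelihood is exact
    for window_size=1 and the standard binned composite otherwise.
    """
    _check_alphabet(obs, model)
    counts = obs.window_counts(model.window_size)
    E = model.emissions()
    B, logshift = _window_loglik_matrix(counts, E)
    A = model.window_transition()
    pi = model.prior()
    ll, gamma, xi, g0 = _hmm.forward_backward_core(pi, A, B)
    ecounts = gamma.T @ counts
    return FBResult(ll + logshift, gamma, xi, g0, model.window_size, ecounts)


def _check_alphabet(obs, model):
    names_obs = obs.block_names
    names_mod = [b.name for b in model.blocks]
    if names_obs != names_mod:
        raise ValueError(f"observation blocks {names_obs} do not match model "
                         f"blocks {names_mod}")
    for ob, mb in zip(obs.blocks, model.blocks):
        if ob.n_symbols != mb.n_symbols:
            raise ValueError(f"block {ob.name!r}: symbol alphabet mismatch")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FreeParameters:
    """Which parameters a fit may move.

    ``demography_groups`` ties hidden-time intervals into groups sharing one
    population size (None = a default of ~8 contiguous groups; pass
    ``[[0], [1], ...]`` for one size per interval). ``rates`` lists emission
    blocks whose (epi)mutation rates are free.
    """

    demography: bool = True
    demography_groups: Optional[List[List[int]]] = None
    r: bool = False
    rates: Tuple[str, ...] = ()

    def any_free(self):
        return self.demography or self.r or bool(self.rates)


@dataclass
class FitResult:
    model: SMCModel
    demography: Demography
    r: float
    rates: Dict[str, Tuple[float, ...]]
    loglik_trajectory: List[float]
    converged: bool
    per_pair_loglik: Optional[np.ndarray] = None
    method: str = ""
    n_iterations: int = 0

    @property
    def loglik(self):
        return self.loglik_trajectory[-1] if self.loglik_trajectory else np.nan


def _default_groups(K: int, n_groups: int = 8) -> List[List[int]]:
    n_groups = min(n_groups, K)
    edges = np.linspace(0, K, n_groups + 1).astype(int)
    return [list(range(edges[i], edges[i + 1])) for i in range(n_groups)]


_SIZE_BOUND_FACTOR = 500.0  # fitted sizes stay within this factor of the start


def _pack(model: SMCModel, free: FreeParameters):
    """Parameter vector (log scale) and unpacking metadata."""
    meta = {"groups": None, "r": free.r, "rate_blocks": [], "bounds": None}
    x = []
    if free.demography:
        groups = free.demography_groups or _default_groups(model.disc.n_states)
        meta["groups"] = groups
        reps = np.asarray(model.disc.rep_times)
        logN = [np.log(float(np.mean(model.demography.size_at(reps[g]))))
                for g in groups]
        x.extend(logN)
        span = np.log(_SIZE_BOUND_FACTOR)
        meta["bounds"] = (min(logN) - span, max(logN) + span)
    if free.r:
        x.append(np.log(max(model.r, 1e-12)))
    for bi, b in enumerate(model.blocks):
        if b.name in free.rates or b.free:
            nr = len(b.rates)
            meta["rate_blocks"].append((bi, nr))
            x.extend(np.log(np.clip(b.rates, 1e-12, None)))
    return np.asarray(x), meta


def _unpack(x: np.ndarray, model: SMCModel, meta) -> SMCModel:
    pos = 0
    dem = model.demography
    if meta["groups"] is not None:
        groups = meta["groups"]
        K = model.disc.n_states
        sizes = np.empty(K)
        for g, xi in zip(groups, x[pos:pos + len(groups)]):
            sizes[g] = np.exp(xi)
        pos += len(groups)
        dem = Demography(tuple(model.disc.boundaries[:-1]), tuple(sizes))
    r = model.r
    if meta["r"]:
        r = float(np.exp(x[pos]))
        pos += 1
    blocks = [replace(b) for b in model.blocks]
    for bi, nr in meta["rate_blocks"]:
        blocks[bi].rates = tuple(np.exp(x[pos:pos + nr]))
        pos += nr
    return replace(model, demography=dem, r=r, blocks=blocks)


def _out_of_bounds(x, meta) -> bool:
    if meta.get("bounds") is None or meta["groups"] is None:
        return False
    lo, hi = meta["bounds"]
    head = x[:len(meta["groups"])]
    return bool(np.any(head < lo) or np.any(head > hi))


def _total_loglik(model: SMCModel, counts_list, forward_only=True):
    E = model.emissions()
    A = model.window_transition()
    pi = model.prior()
    lls = np.empty(len(counts_list))
    for k, counts in enumerate(counts_list):
        B, shift = _window_loglik_matrix(counts, E)
        if forward_only:
            lls[k] = _hmm.forward_core(pi, A, B) + shift
        else:
            lls[k] = _hmm.forward_backward_core(pi, A, B)[0] + shift
    return lls


def baum_welch_fit(obs_list: Sequence[PairObservationSequence],
                   model: SMCModel, free: FreeParameters,
                   max_iter: int = 30, rel_tol: float = 1e-5,
                   mstep_maxiter: Optional[int] = None) -> FitResult:
    """Composite-likelihood Baum-Welch over all haplotype pairs.

    E-step: expected transition counts and per-state symbol counts summed
    over pairs.  M-step: numerical maximisation of the expected complete-data
    log-likelihood Q over the free parameters, accepted only when Q improves,
    so the composite likelihood trajectory is non-decreasing.
    """
    if not obs_list:
        raise ValueError("no observation sequences")
    for obs in obs_list:
        _check_alphabet(obs, model)
    counts_list = [obs.window_counts(model.window_size) for obs in obs_list]

    if not free.any_free():
        lls = _total_loglik(model, counts_list)
        return FitResult(model, model.demography, model.r, model.rates_dict(),
                         [float(lls.sum())], True, lls, "baum-welch", 1)

    traj: List[float] = []
    cur = model
    prev_ll = -np.inf
    converged = False
    per_pair = None
    it = 0
    for it in range(1, max_iter + 1):
        E = cur.emissions()
        A = cur.window_transition()
        pi = cur.prior()
        ll_tot = 0.0
        xi_sum = np.zeros((cur.disc.n_states, cur.disc.n_states))
        g0_sum = np.zeros(cur.disc.n_states)
        ec_sum = np.zeros_like(E)
        per_pair = np.empty(len(counts_list))
        for k, counts in enumerate(counts_list):
            B, shift = _window_loglik_matrix(counts, E)
            ll, gamma, xi, g0 = _hmm.forward_backward_core(pi, A, B)
            per_pair[k] = ll + shift
            ll_tot += ll + shift
            xi_sum += xi
            g0_sum += g0
            ec_sum += gamma.T @ counts
        if traj and ll_tot < prev_ll - 1e-6 * abs(prev_ll):
            # numerical non-monotonicity guard: keep the previous model
            cur = prev_model
            converged = True
            break
        traj.append(ll_tot)
        if it > 1 and (ll_tot - prev_ll) <= rel_tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll_tot
        prev_model = cur

        x0, meta = _pack(cur, free)
        if it == 1:
            bounds0 = meta["bounds"]
        meta["bounds"] = bounds0
        xi_mask = xi_sum > 0
        ec_mask = ec_sum > 0

        def neg_q(x):
            if _out_of_bounds(x, meta):
                return np.inf
            m = _unpack(x, cur, meta)
            try:
                Aw = m.window_transition()
                Em = m.emissions()
                pim = m.prior()
            except (ValueError, FloatingPointError):
                return np.inf
            q = float(g0_sum @ np.log(np.clip(pim, _EPS, None)))
            q += float((xi_sum[xi_mask]
                        * np.log(np.clip(Aw[xi_mask], _EPS, None))).sum())
            q += float((ec_sum[ec_mask]
                        * np.log(np.clip(Em[ec_mask], _EPS, None))).sum())
            return -q

        q0 = neg_q(x0)
        res = minimize(neg_q, x0, method="Nelder-Mead",
                       options={"maxiter": mstep_maxiter or 120 * len(x0),
                                "xatol": 1e-3, "fatol": 1e-3})
        if res.fun < q0:
            cur = _unpack(res.x, cur, meta)
    return FitResult(cur, cur.demography, cur.r, cur.rates_dict(), traj,
                     converged, per_pair, "baum-welch", it)


def likelihood_fit(obs_list: Sequence[PairObservationSequence],
                   model: SMCModel, free: FreeParameters,
                   maxiter: Optional[int] = None, restarts: int = 1) -> FitResult:
    """Direct derivative-free optimisation of the composite log-likelihood.

    Positive parameters are optimised on the log scale with Nelder-Mead,
    restarted ``restarts`` times from the best point found (a fresh simplex
    escapes premature collapse); the returned likelihood is never below that
    of the initial model (best-so-far is kept if the optimiser fails to
    improve).
    """
    if not obs_list:
        raise ValueError("no observation sequences")
    for obs in obs_list:
        _check_alphabet(obs, model)
    if not free.any_free():
        raise ValueError("no free parameters and no evaluation requested")
    counts_list = [obs.window_counts(model.window_size) for obs in obs_list]
    x0, meta = _pack(model, free)
    best = {"x": x0, "ll": -np.inf}

    def neg_ll(x):
        if _out_of_bounds(x, meta):
            return np.inf
        m = _unpack(x, model, meta)
        try:
            ll = float(_total_loglik(m, counts_list).sum())
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return np.inf
        if ll > best["ll"]:
            best["x"], best["ll"] = x.copy(), ll
        return -ll

    ll0 = -neg_ll(x0)
    for attempt in range(restarts + 1):
        res = minimize(neg_ll, best["x"], method="Nelder-Mead",
                       options={"maxiter": maxiter or 250 * len(x0),
                                "xatol": 1e-3, "fatol": 1e-2})
    fitted = _unpack(best["x"], model, meta)
    lls = _total_loglik(fitted, counts_list)
    converged = bool(res.success) or best["ll"] >= ll0
    return FitResult(fitted, fitted.demography, fitted.r, fitted.rates_dict(),
                     [ll0, float(lls.sum())], converged, lls, "likelihood", 1)
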