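"""Closed-form per-site pair-observation probabilities for heritable markers.

A marker class is defined by its number of possible states ``nbs`` and its
mutation model: a symmetric Jukes-Cantor-type chain (every state mutates to
each of the other ``nbs - 1`` states at equal rate) or, for two-state
methylation-like markers, an asymmetric chain with distinct gain (methylation)
and loss (demethylation) rates.

All functions give the distribution of what a *pair* of haploid genomes shows
at one site, as a function of their coalescence time ``t`` (the pairwise
TMRCA, in generations): the ancestral state at the common ancestor is drawn
from the stationary distribution of the chain and the two descendant lineages
then evolve independently for time ``t`` each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import expm

__all__ = [
    "MarkerSpec",
    "RegionMethylationModel",
    "symmetric_pair_emission",
    "asymmetric_site_emission",
    "region_site_generator",
    "region_site_stationary",
    "region_conditioned_emission",
    "nine_symbol_emission",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerSpec:
    """One heritable marker class.

    Exactly one of ``mu`` (symmetric model) or ``rate_pair``
    ``(mu_gain, mu_loss)`` (asymmetric two-state model) must be given.
    ``genome_fraction`` is the proportion of sites carrying this marker.
    """

    name: str
    nbs: int
    mu: Optional[float] = None
    rate_pair: Optional[Tuple[float, float]] = None
    genome_fraction: float = 1.0

    def __post_init__(self):
        if self.nbs < 2:
            raise ValueError("a marker needs at least 2 states")
        if (self.mu is None) == (self.rate_pair is None):
            raise ValueError("give exactly one of mu or rate_pair")
        if self.mu is not None and self.mu < 0:
            raise ValueError("negative mutation rate")
        if self.rate_pair is not None:
            g, l = self.rate_pair
            if g < 0 or l < 0:
                raise ValueError("negative epimutation rate")
            if self.nbs != 2:
                raise ValueError("the asymmetric model is a two-state model")
        if not (0.0 <= self.genome_fraction <= 1.0):
            raise ValueError("genome_fraction outside [0, 1]")

    @property
    def symmetric(self) -> bool:
        return self.mu is not None

    def stationary(self) -> np.ndarray:
        if self.symmetric:
            return np.full(self.nbs, 1.0 / self.nbs)
        g, l = self.rate_pair
        if g + l == 0:
            raise ValueError("degenerate asymmetric model: both rates zero")
        return np.array([l, g]) / (g + l)  # [P(U), P(M)]


@dataclass(frozen=True)
class RegionMethylationModel:
    """Region-level epimutation process.

    A whole region of ``region_length`` bp gains methylation at rate
    ``mu_region_meth`` and loses it at rate ``mu_region_unmeth`` (per region
    per generation); a region-level event resets every site in the region to
    the region's new status.
    """

    mu_region_meth: float
    mu_region_unmeth: float
    region_length: int = 1000

    def __post_init__(self):
        if self.mu_region_meth < 0 or self.mu_region_unmeth < 0:
            raise ValueError("negative region epimutation rate")
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")

    def stationary(self) -> np.ndarray:
        g, l = self.mu_region_meth, self.mu_region_unmeth
        if g + l == 0:
            return np.array([0.5, 0.5])  # degenerate: frozen region status
        return np.array([l, g]) / (g + l)


# ---------------------------------------------------------------------------
# symmetric (Jukes-Cantor type) markers
# ---------------------------------------------------------------------------


def symmetric_pair_emission(marker: MarkerSpec, t):
    """P(identical), P(segregating) for a pair coalescing at time ``t``.

    For an ``nbs``-state symmetric chain with total per-site rate ``mu``::

        P(id) = 1/nbs + (nbs-1)/nbs * exp(-2 mu t nbs / (nbs-1))

    the factor 2 counting the two branches of length ``t``.
    Accepts scalar or array ``t``; returns shape ``t.shape + (2,)``.
    """
    if not marker.symmetric:
        raise ValueError("marker does not use the symmetric model")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative coalescence time")
    nbs, mu = marker.nbs, marker.mu
    p_id = 1.0 / nbs + (nbs - 1.0) / nbs * np.exp(-2.0 * mu * t * nbs / (nbs - 1.0))
    return np.stack([p_id, 1.0 - p_id], axis=-1)


def _two_state_transition(g: float, l: float, t):
    """Transition matrix of the U<->M chain over time ``t`` (vectorised).

    Returns array of shape ``t.shape + (2, 2)`` with states [U, M].
    """
    t = np.asarray(t, dtype=float)
    r = g + l
    e = np.exp(-r * t)
    pi_u, pi_m = (l / r, g / r) if r > 0 else (0.5, 0.5)
    out = np.empty(t.shape + (2, 2))
    out[..., 0, 0] = pi_u + pi_m * e
    out[..., 0, 1] = pi_m * (1.0 - e)
    out[..., 1, 0] = pi_u * (1.0 - e)
    out[..., 1, 1] = pi_m + pi_u * e
    return out


def asymmetric_site_emission(mu_gain: float, mu_loss: float, t):
    """Pair-site distribution over {both-U, both-M, discordant} at TMRCA ``t``.

    Symbols follow the observation coding: 2 = both unmethylated,
    3 = both methylated, 4 = discordant.  The ancestral state is stationary,
    the two lineages evolve independently for time ``t``.
    Returns shape ``t.shape + (3,)``.
    """
    if mu_gain < 0 or mu_loss < 0:
        raise ValueError("negative epimutation rate")
    if mu_gain + mu_loss == 0:
        raise ValueError("degenerate model: both rates zero")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative coalescence time")
    P = _two_state_transition(mu_gain, mu_loss, t)
    pi = np.array([mu_loss, mu_gain]) / (mu_gain + mu_loss)
    # joint over leaf pair: J[x, y] = sum_a pi_a P[a, x] P[a, y]
    J = np.einsum("a,...ax,...ay->...xy", pi, P, P)
    p_uu = J[..., 0, 0]
    p_mm = J[..., 1, 1]
    p_disc = J[..., 0, 1] + J[..., 1, 0]
    return np.stack([p_uu, p_mm, p_disc], axis=-1)


# ---------------------------------------------------------------------------
# coupled region + site methylation process
# ---------------------------------------------------------------------------

# joint (region, site) states, each U/M: index = 2*region + site
_RS_STATES = [(0, 0), (0, 1), (1, 0), (1, 1)]


def region_site_generator(site_rates: Tuple[float, float],
                          region_model: RegionMethylationModel) -> np.ndarray:
    """Generator of the joint (region status, site status) chain per lineage.

    Site-level gains/losses (``site_rates = (mu_SM, mu_SU)``) flip the site
    only; a region-level event flips the region status *and resets the site*
    to the new region status (a region event rewrites the whole block).
    States are indexed ``2*region + site`` with U=0, M=1.
    """
    g_s, l_s = site_rates
    g_r, l_r = region_model.mu_region_meth, region_model.mu_region_unmeth
    if g_s < 0 or l_s < 0:
        raise ValueError("negative site epimutation rate")
    Q = np.zeros((4, 4))
    # site-level events (region unchanged)
    Q[0, 1] = g_s  # (U,U) -> (U,M)
    Q[1, 0] = l_s
    Q[2, 3] = g_s
    Q[3, 2] = l_s
    # region-level events reset the site to the new region status
    Q[0, 3] = g_r  # (U,*) -> (M,M)
    Q[1, 3] = g_r
    Q[2, 0] = l_r  # (M,*) -> (U,U)
    Q[3, 0] = l_r
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def region_site_stationary(site_rates, region_model) -> np.ndarray:
    """Stationary distribution of the joint (region, site) chain."""
    Q = region_site_generator(site_rates, region_model)
    g_r = region_model.mu_region_meth + region_model.mu_region_unmeth
    if g_r == 0:
        # frozen region status: site chain stationary within each region block,
        # region status itself split evenly (degenerate, documented)
        g_s, l_s = site_rates
        if g_s + l_s == 0:
            raise ValueError("degenerate model: all rates zero")
        pi_site = np.array([l_s, g_s]) / (g_s + l_s)
        return 0.5 * np.concatenate([pi_site, pi_site])
    A = np.vstack([Q.T, np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


_REGION_PAIR_CODES = {"UU": 0, "UM": 1, "MU": 1, "MM": 2}


def _joint_pair_distribution(site_rates, region_model, t: float) -> np.ndarray:
    """4x4 joint distribution of the two leaves' (region, site) states."""
    Q = region_site_generator(site_rates, region_model)
    pi = region_site_stationary(site_rates, region_model)
    P = expm(Q * float(t))
    return P.T @ np.diag(pi) @ P  # J[x, y] = sum_a pi_a P[a,x] P[a,y]


def _aggregate_region_site(J: np.ndarray) -> np.ndarray:
    """Collapse the 4x4 leaf-pair joint to a 3x3 table.

    Rows: region-pair status {UU, UM/MU, MM}; columns: site-pair symbol
    {2: both-U, 3: both-M, 4: discordant}.
    """
    out = np.zeros((3, 3))
    for x in range(4):
        rx, sx = divmod(x, 2)
        for y in range(4):
            ry, sy = divmod(y, 2)
            row = rx + ry  # 0=UU, 1=UM/MU, 2=MM
            col = 2 if sx != sy else (0 if sx == 0 else 1)
            out[row, col] += J[x, y]
    return out


def region_conditioned_emission(site_rates, region_model: RegionMethylationModel,
                                region_status_pair: str, t) -> np.ndarray:
    """Site-pair distribution over {2, 3, 4} given the region-pair status.

    ``region_status_pair`` is one of ``"UU"``, ``"UM"``/``"MU"``, ``"MM"``.
    The conditioning is exact under the coupled region+site chain: region
    status evolves at the region rates and every region event resets the
    sites it covers.
    """
    if region_status_pair not in _REGION_PAIR_CODES:
        raise ValueError(f"unknown region status pair {region_status_pair!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("negative coalescence time")
    row = _REGION_PAIR_CODES[region_status_pair]
    out = np.empty(t_arr.shape + (3,))
    for i, ti in enumerate(t_arr.ravel()):
        table = _aggregate_region_site(
            _joint_pair_distribution(site_rates, region_model, ti))
        marg = table[row].sum()
        if marg <= 0:
            # unreachable region-pair configuration at this t; fall back to
            # the site-only law so emissions stay proper
            out.reshape(-1, 3)[i] = asymmetric_site_emission(*site_rates, ti)
        else:
            out.reshape(-1, 3)[i] = table[row] / marg
    return out.reshape(np.shape(t) + (3,)) if np.ndim(t) else out[0]


def nine_symbol_emission(site_rates, region_model: RegionMethylationModel,
                         t: float) -> np.ndarray:
    """Joint 9-symbol distribution: region-pair {UU, UM/MU, MM} x site {2,3,4}.

    Flattened row-major (region-pair major); sums to 1.
    """
    table = _aggregate_region_site(
        _joint_pair_distribution(site_rates, region_model, float(t)))
    return table.ravel()


def region_pair_probabilities(region_model: RegionMethylationModel, t) -> np.ndarray:
    """Distribution of the region-pair status {UU, UM/MU, MM} at TMRCA ``t``.

    The region status itself is a two-state chain with the region rates, so
    this is the asymmetric pair emission applied at region scale.
    """
    return asymmetric_site_emission(
        region_model.mu_region_meth, region_model.mu_region_unmeth, t)


def emission_distribution(marker: MarkerSpec, t):
    """Dispatch: pair-observation distribution for any marker class."""
    if marker.symmetric:
        return symmetric_pair_emission(marker, t)
    return asymmetric_site_emission(*marker.rate_pair, t)
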