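"""Evaluation statistics: demography RMSE, posterior TMRCA, genealogy spans
and linkage-disequilibrium decay."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .demography import Demography
from .simulate import AnnotatedHaplotypes

__all__ = [
    "rmse_demography",
    "TmrcaTrack",
    "expected_tmrca",
    "posterior_tmrca",
    "genealogy_spans",
    "ld_decay",
]

# The RMSE grid: evaluation points spread uniformly in log10 time across the
# window.  The summation deliberately runs over 102 points (i = 1..102).
_N_RMSE_POINTS = 102


def rmse_demography(true_dem: Demography, est_dem: Demography,
                    window: Tuple[float, float] = (100.0, 1e6),
                    log_sizes: bool = False) -> float:
    """Root mean square error between two size histories.

    102 evaluation points uniformly spaced in log10 time across ``window``;
    RMSE = sqrt(sum_i (y_i - y*_i)^2 / 102) on natural population sizes
    (``log_sizes=True`` compares log10 sizes instead).
    """
    lo, hi = window
    if lo <= 0 or hi <= lo:
        raise ValueError("invalid evaluation window")
    t = np.logspace(np.log10(lo), np.log10(hi), _N_RMSE_POINTS)
    y_true = true_dem.size_at(t)
    y_est = est_dem.size_at(t)
    if log_sizes:
        y_true, y_est = np.log10(y_true), np.log10(y_est)
    return float(np.sqrt(np.mean((y_true - y_est) ** 2)))


@dataclass
class TmrcaTrack:
    """Per-window expected pairwise coalescence times along the genome."""

    window_size: int
    length: int
    expected: np.ndarray     # (n_windows,) posterior mean TMRCA
    map_state: np.ndarray    # (n_windows,) maximum-a-posteriori hidden state
    rep_times: np.ndarray    # hidden-state time vector Tc

    def positions(self) -> np.ndarray:
        return np.arange(len(self.expected)) * self.window_size


def expected_tmrca(posteriors: np.ndarray, rep_times: np.ndarray) -> np.ndarray:
    """TMRCA_i = sum_j post_{i,j} Tc_j after per-row renormalisation."""
    post = np.asarray(posteriors, dtype=float)
    post = post / post.sum(axis=1, keepdims=True)
    return post @ np.asarray(rep_times, dtype=float)


def posterior_tmrca(obs, model) -> TmrcaTrack:
    """Posterior-decoded expected coalescence time at each window."""
    from .smc import forward_backward
    rep = np.asarray(model.disc.rep_times)
    fb = forward_backward(obs, model)
    return TmrcaTrack(model.window_size, obs.length,
                      expected_tmrca(fb.posteriors, rep),
                      np.argmax(fb.posteriors, axis=1), rep)


def genealogy_spans(track: TmrcaTrack, use_expected: bool = False,
                    rel_threshold: float = 0.0):
    """Lengths (bp) of runs of constant inferred genealogy.

    A span ends where the MAP hidden state changes (default), or where the
    expected TMRCA changes by more than ``rel_threshold`` relative when
    ``use_expected`` is set.  The spans partition the sequence.
    """
    if len(track.expected) == 0:
        raise ValueError("empty track")
    if use_expected:
        x = track.expected
        change = np.abs(np.diff(x)) > rel_threshold * np.maximum(x[:-1], 1e-12)
    else:
        change = np.diff(track.map_state) != 0
    idx = np.flatnonzero(change) + 1
    edges = np.concatenate([[0], idx * track.window_size, [track.length]])
    spans = np.diff(edges).astype(float)
    spans = spans[spans > 0]
    return spans


def _biallelic_binary(states: np.ndarray) -> Optional[np.ndarray]:
    """0/1 recode of one site; None if not biallelic among valid calls."""
    valid = states >= 0
    vals = np.unique(states[valid])
    if len(vals) != 2:
        return None
    return np.where(valid, (states == vals[1]).astype(float), np.nan)


def ld_decay(data, marker: str, bins: Sequence[float] = (0, 100, 1000, 10_000),
             max_sites: int = 3000, min_count: int = 2,
             seed: int = 0) -> pd.DataFrame:
    """Mean r^2 between polymorphic sites of a marker class, by distance bin.

    Only biallelic sites whose minor allele is carried by at least
    ``min_count`` haplotypes enter (LD is undefined for monomorphic sites).
    Returns a DataFrame with bin edges, mean r2 and pair counts.
    """
    if isinstance(data, AnnotatedHaplotypes):
        rec = data.records[marker]
        positions, states = rec.positions, rec.states
    else:
        positions, states = data
    n = states.shape[1]
    mask = []
    binarised = []
    for k in range(len(positions)):
        b = _biallelic_binary(states[k])
        ok = b is not None
        if ok:
            cnt = np.nansum(b)
            ok = min_count <= cnt <= n - min_count
        mask.append(ok)
        binarised.append(b if ok else None)
    keep = np.flatnonzero(mask)
    if len(keep) < 2:
        raise ValueError("fewer than 2 polymorphic sites")
    rng = np.random.default_rng(seed)
    if len(keep) > max_sites:
        keep = np.sort(rng.choice(keep, size=max_sites, replace=False))
    pos = positions[keep]
    G = np.vstack([binarised[k] for k in keep])
    bins = np.asarray(bins, dtype=float)
    max_d = bins[-1]
    sums = np.zeros(len(bins) - 1)
    cnts = np.zeros(len(bins) - 1, dtype=int)
    for a in range(len(pos) - 1):
        hi = np.searchsorted(pos, pos[a] + max_d, side="right")
        if hi <= a + 1:
            continue
        d = pos[a + 1:hi] - pos[a]
        x = G[a]
        Y = G[a + 1:hi]
        both = ~np.isnan(x)[None, :] & ~np.isnan(Y)
        nb = both.sum(axis=1).astype(float)
        xm = np.where(both, x[None, :], 0.0)
        ym = np.where(both, Y, 0.0)
        sx = xm.sum(axis=1)
        sy = ym.sum(axis=1)
        sxy = (xm * ym).sum(axis=1)
        sxx = (xm * xm).sum(axis=1)
        syy = (ym * ym).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy / nb - (sx / nb) * (sy / nb)
            vx = sxx / nb - (sx / nb) ** 2
            vy = syy / nb - (sy / nb) ** 2
            r2 = cov**2 / (vx * vy)
        ok = np.isfinite(r2)
        which = np.digitize(d, bins) - 1
        for b in range(len(bins) - 1):
            sel = ok & (which == b)
            sums[b] += r2[sel].sum()
            cnts[b] += int(sel.sum())
    with np.errstate(invalid="ignore"):
        mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return pd.DataFrame({"bin_lo": bins[:-1], "bin_hi": bins[1:],
                         "mean_r2": mean, "n_pairs": cnts})
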