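"""Estimating an unknown marker (epi)mutation rate from a reference marker.

Under the infinite-site regime (at most 1% of a marker's sites polymorphic)
the unknown rate follows from the ratio of Watterson's theta between the
target marker and a reference marker of known rate.  Hyper-mutable markers
violate the infinite-site assumption (homoplasy); their rates are then
estimated by Baum-Welch with the rate as a free emission parameter of the
SMC hidden Markov model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .simulate import AnnotatedHaplotypes

__all__ = [
    "DiversitySummary",
    "harmonic_number",
    "polymorphism_fraction",
    "state_count_correction",
    "watterson_rate_estimate",
    "estimate_rates_auto",
]


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson denominator for n haplotypes."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass
class DiversitySummary:
    """Per-marker segregating-site counts and Watterson's theta per site."""

    n_haplotypes: int
    total_sites: Dict[str, int]
    polymorphic_sites: Dict[str, int]

    def __post_init__(self):
        for name in self.total_sites:
            if self.polymorphic_sites.get(name, 0) > self.total_sites[name]:
                raise ValueError("polymorphic sites exceed total sites")

    @classmethod
    def from_annotated(cls, data: AnnotatedHaplotypes) -> "DiversitySummary":
        total = {n: r.total_designated for n, r in data.records.items()}
        poly = {n: r.n_polymorphic() for n, r in data.records.items()}
        return cls(data.n_haplotypes, total, poly)

    def theta_w(self, marker: str) -> float:
        """Watterson's theta per site: S / (a_n * sites)."""
        if marker not in self.total_sites:
            raise KeyError(f"marker {marker!r} absent from data")
        sites = self.total_sites[marker]
        if sites == 0:
            return 0.0
        return self.polymorphic_sites[marker] / (
            harmonic_number(self.n_haplotypes) * sites)


def polymorphism_fraction(data, marker: str) -> float:
    """Fraction of the marker's designated sites segregating in the sample."""
    if isinstance(data, DiversitySummary):
        if marker not in data.total_sites:
            raise KeyError(f"marker {marker!r} absent from data")
        tot = data.total_sites[marker]
        return data.polymorphic_sites[marker] / tot if tot else 0.0
    return data.polymorphism_fraction(marker)


def state_count_correction(nbs_ref: int, nbs_target: int) -> float:
    """Correction relating theta ratios to rate ratios across state counts.

    Derived by equating the small-t expansion of the pair segregating
    probability for the two markers: with the total-rate (Jukes-Cantor)
    parameterisation, P(seg) = (nbs-1)/nbs * (1 - exp(-2 mu t nbs/(nbs-1)))
    ~ 2 mu t + O(t^2) for *every* nbs, so equal diversity at low rates
    implies equal total rates and the correction is exactly 1.  (A
    parameterisation counting the rate per target state would instead need a
    (nbs-1) ratio; it is isolated here so it can be swapped.)
    """
    if nbs_ref < 2 or nbs_target < 2:
        raise ValueError("markers need at least 2 states")
    return 1.0


def watterson_rate_estimate(summary: DiversitySummary, reference_marker: str,
                            target_marker: str, reference_rate: float) -> float:
    """mu_target = mu_ref * (thetaW_target / thetaW_ref) * c(nbs).

    Valid in the infinite-site regime of both markers.
    """
    th_ref = summary.theta_w(reference_marker)
    th_tgt = summary.theta_w(target_marker)
    if th_ref <= 0:
        raise ValueError("reference marker shows no diversity")
    return reference_rate * (th_tgt / th_ref)


def estimate_rates_auto(data: AnnotatedHaplotypes, known_rates: Dict[str, float],
                        unknown_markers: Sequence[str], threshold: float = 0.01,
                        n_states: int = 20, window_size: int = 100,
                        r: Optional[float] = None,
                        max_haplotypes: Optional[int] = None,
                        max_iter: int = 10) -> Dict[str, dict]:
    """Estimate unknown marker rates, dispatching on the 1% polymorphism rule.

    A marker with at most ``threshold`` of its sites polymorphic is in the
    infinite-site regime and uses the Watterson-theta ratio estimator;
    beyond the threshold the finite-site Baum-Welch path frees the marker's
    emission rate(s) in the SMC HMM.
    """
    if not unknown_markers:
        raise ValueError("no unknown markers")
    (ref_name, ref_rate), = list(known_rates.items())[:1] or [(None, None)]
    if ref_name is None:
        raise ValueError("need a reference marker with known rate")
    summary = DiversitySummary.from_annotated(data)
    out: Dict[str, dict] = {}
    bw_targets = []
    for name in unknown_markers:
        frac = polymorphism_fraction(summary, name)
        if frac <= threshold:
            est = watterson_rate_estimate(summary, ref_name, name, ref_rate)
            est *= state_count_correction(data.markers[ref_name].nbs,
                                          data.markers[name].nbs)
            out[name] = {"estimate": (max(est, 1e-300),), "method": "watterson",
                         "polymorphism_fraction": frac}
        else:
            bw_targets.append(name)
            out[name] = {"method": "baum-welch", "polymorphism_fraction": frac}
    if bw_targets:
        fit = _baum_welch_rates(data, ref_name, ref_rate, bw_targets, summary,
                                n_states, window_size, r, max_haplotypes,
                                max_iter)
        for name in bw_targets:
            out[name]["estimate"] = tuple(max(v, 1e-300)
                                          for v in fit.rates[name])
            out[name]["loglik"] = fit.loglik
    return out


def moment_matched_symmetric_rate(seg_frac: float, nbs: int, N0: float) -> float:
    """Finite-site method-of-moments rate from the mean pair seg fraction.

    Under a constant size N0 the pair TMRCA is Exp(mean 2 N0), so the
    marginal segregating probability has the closed form
    p = (nbs-1)/nbs * 2 N0 c / (1 + 2 N0 c) with c = 2 mu nbs/(nbs-1);
    inverting gives the starting value for the finite-site fit.
    """
    ceiling = (nbs - 1) / nbs
    p = min(max(seg_frac, 1e-12), 0.999 * ceiling)
    q = (p / ceiling) / (1.0 - p / ceiling)
    c = q / (2.0 * N0)
    return c * (nbs - 1) / (2.0 * nbs)


def mean_pair_segregating_fraction(data, marker: str,
                                   max_haplotypes: Optional[int] = None) -> float:
    """Average over haplotype pairs of the fraction of differing sites."""
    rec = data.records[marker]
    n = data.n_haplotypes if max_haplotypes is None else min(
        data.n_haplotypes, max_haplotypes)
    if rec.total_designated == 0:
        return 0.0
    tot = 0.0
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = rec.states[:, i], rec.states[:, j]
            ok = (si >= 0) & (sj >= 0)
            tot += float(((si != sj) & ok).sum())
            cnt += rec.total_designated - int((~ok).sum())
    return tot / cnt if cnt else 0.0


def _baum_welch_rates(data, ref_name, ref_rate, targets, summary, n_states,
                      window_size, r, max_haplotypes, max_iter):
    from .smc import (EmissionBlock, FreeParameters, baum_welch_fit,
                      constant_model)
    theta_ref = summary.theta_w(ref_name)
    N0 = max(theta_ref / (4.0 * ref_rate), 10.0)
    if r is None:
        r = data.config.r if data.config is not None else ref_rate
    blocks = []
    order = [data.dominant] + [n for n in data.records if n != data.dominant]
    for name in order:
        m = data.markers[name]
        if m.symmetric:
            if name == ref_name:
                rate = ref_rate
            else:
                # finite-site moment-matched start (theta is saturated here)
                seg = mean_pair_segregating_fraction(data, name, max_haplotypes)
                rate = max(moment_matched_symmetric_rate(seg, m.nbs, N0), 1e-10)
            blocks.append(EmissionBlock(name, "symmetric", (rate,), nbs=m.nbs,
                                        free=name in targets))
        else:
            if name in targets or not m.rate_pair or sum(m.rate_pair) == 0:
                seg = mean_pair_segregating_fraction(data, name, max_haplotypes)
                mm = max(moment_matched_symmetric_rate(seg, 2, N0), 1e-8)
                g0 = (mm, mm)  # symmetric start; the fit moves it
            else:
                g0 = m.rate_pair
            blocks.append(EmissionBlock(name, "asymmetric", tuple(g0),
                                        free=name in targets))
    selfing = data.config.selfing_rate if data.config is not None else 0.0
    model = constant_model(N0, r, blocks, n_states=n_states,
                           window_size=window_size, selfing_rate=selfing)
    n = data.n_haplotypes if max_haplotypes is None else min(
        data.n_haplotypes, max_haplotypes)
    obs = [data.encode_pair(i, j) for i in range(n) for j in range(i + 1, n)]
    free = FreeParameters(demography=True, r=False,
                          rates=tuple(targets))
    return baum_welch_fit(obs, model, free, max_iter=max_iter,
                          mstep_maxiter=500)
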