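"""Piecewise-constant population-size histories.

Time is measured in generations before present, sizes are haploid-pair
coalescent sizes N (a pair of lineages coalesces at rate 1/(2N(t))).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Demography"]


@dataclass(frozen=True)
class Demography:
    """A step-function population size trajectory.

    Parameters
    ----------
    boundaries:
        Strictly increasing epoch start times in generations; the first
        entry must be 0.  Epoch ``i`` covers ``[boundaries[i], boundaries[i+1])``
        and the last epoch extends to infinity.
    sizes:
        Population size per epoch, all > 0.
    """

    boundaries: tuple = field(default=(0.0,))
    sizes: tuple = field(default=(10_000.0,))

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        s = np.asarray(self.sizes, dtype=float)
        if b.ndim != 1 or s.ndim != 1 or len(b) != len(s) or len(b) == 0:
            raise ValueError("boundaries and sizes must be equal-length 1-d sequences")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError("population sizes must be positive and finite")
        object.__setattr__(self, "boundaries", tuple(b))
        object.__setattr__(self, "sizes", tuple(s))

    # -- evaluation ---------------------------------------------------------

    def size_at(self, t):
        """N(t) for scalar or array times ``t >= 0``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time")
        idx = np.searchsorted(self.boundaries, t, side="right") - 1
        return np.asarray(self.sizes)[idx]

    def pair_hazard(self, t):
        """Cumulative pair-coalescence hazard H(t) = int_0^t dt'/(2 N(t'))."""
        t_in = np.asarray(t, dtype=float)
        t = np.atleast_1d(t_in)
        if np.any(t < 0):
            raise ValueError("negative time")
        b = np.asarray(self.boundaries)
        s = np.asarray(self.sizes)
        # cumulative hazard at epoch boundaries
        seg = np.diff(b) / (2.0 * s[:-1])
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        idx = np.searchsorted(b, t, side="right") - 1
        out = cum[idx] + (t - b[idx]) / (2.0 * s[idx])
        return out.reshape(t_in.shape)

    def inverse_pair_hazard(self, h):
        """Time t such that H(t) = h (h >= 0); vectorised."""
        h_in = np.asarray(h, dtype=float)
        h = np.atleast_1d(h_in)
        b = np.asarray(self.boundaries)
        s = np.asarray(self.sizes)
        seg = np.diff(b) / (2.0 * s[:-1])
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        idx = np.clip(np.searchsorted(cum, h, side="right") - 1, 0, len(b) - 1)
        return (b[idx] + (h - cum[idx]) * 2.0 * s[idx]).reshape(h_in.shape)

    def interval_masses(self, edges):
        """Prior pair-coalescence probability mass of intervals.

        ``edges`` are increasing times (last may be np.inf); returns the
        probability that a pair, coalescing under this history, does so within
        each ``[edges[i], edges[i+1])``.
        """
        edges = np.asarray(edges, dtype=float)
        fin = np.where(np.isfinite(edges), edges, 0.0)
        surv = np.exp(-self.pair_hazard(fin))
        surv = np.where(np.isfinite(edges), surv, 0.0)
        return surv[:-1] - surv[1:]

    def mean_pair_tmrca(self):
        """E[pairwise TMRCA] = int_0^inf exp(-H(t)) dt (closed form)."""
        b = np.asarray(self.boundaries)
        s = np.asarray(self.sizes)
        seg = np.diff(b) / (2.0 * s[:-1])
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = 0.0
        for i in range(len(b)):
            lo = b[i]
            hi = b[i + 1] if i + 1 < len(b) else np.inf
            rate = 1.0 / (2.0 * s[i])
            # int_lo^hi exp(-(cum[i] + (t-lo)*rate)) dt
            if np.isinf(hi):
                total += np.exp(-cum[i]) / rate
            else:
                total += np.exp(-cum[i]) * (1.0 - np.exp(-(hi - lo) * rate)) / rate
        return total

    # -- serialisation ------------------------------------------------------

    def to_dict(self):
        return {"boundaries": list(self.boundaries), "sizes": list(self.sizes)}

    @classmethod
    def from_dict(cls, d):
        return cls(tuple(d["boundaries"]), tuple(d["sizes"]))

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_step_tsv(self, path):
        """Write (time_generations, N) step function as TSV."""
        with open(path, "w") as fh:
            fh.write("time_generations\tN\n")
            for t, n in zip(self.boundaries, self.sizes):
                fh.write(f"{t:.6g}\t{n:.6g}\n")
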