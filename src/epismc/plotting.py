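"""Small matplotlib helpers for the standard result panels."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_demographies", "plot_ld_decay", "plot_span_histogram"]


def plot_demographies(demographies, labels=None, window=(100.0, 1e6), ax=None):
    """Step plot of one or more size histories on log-log axes."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    t = np.logspace(np.log10(window[0]), np.log10(window[1]), 400)
    labels = labels or [f"history {k + 1}" for k in range(len(demographies))]
    for dem, lab in zip(demographies, labels):
        ax.step(t, dem.size_at(t), where="post", label=lab)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("time (generations ago)")
    ax.set_ylabel("population size N")
    ax.legend()
    return ax


def plot_ld_decay(ld_frames, labels=None, ax=None):
    """Mean r^2 per distance bin for one or more marker classes."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    labels = labels or [f"marker {k + 1}" for k in range(len(ld_frames))]
    for df, lab in zip(ld_frames, labels):
        mid = 0.5 * (df["bin_lo"] + df["bin_hi"])
        ax.plot(mid, df["mean_r2"], marker="o", label=lab)
    ax.set_xscale("log")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel("mean $r^2$")
    ax.legend()
    return ax


def plot_span_histogram(spans, ax=None, bins=50):
    """Histogram of genealogy span lengths (right-skewed in practice)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.asarray(spans), bins=bins)
    ax.set_xlabel("genomic span of a genealogy (bp)")
    ax.set_ylabel("count")
    return ax
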