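"""Per-pair coded observation sequences.

A :class:`PairObservationSequence` stores, for one pair of haploid genomes,
the observation symbol at every position of the sequence in a sparse form:
each marker class (block) records only its informative sites, and the
dominant block (nucleotide sites) fills the remainder of the genome with its
default "identical" symbol.  The dense per-window symbol-count matrix used by
the HMM is materialised on demand.

Symbol coding (within-block indices follow the field's convention):

* nucleotide block ("snp"): 0 = identical, 1 = segregating
* generic symmetric marker block: 0 = identical, 1 = segregating
* methylation site block ("meth"): 0 -> code 2 (both U), 1 -> code 3
  (both M), 2 -> code 4 (discordant)
* region-conditioned methylation block ("meth9"): 3 x region-pair status
  {UU, UM/MU, MM} times the site symbol, 9 symbols
* missing data is recorded with symbol -1: the site is dropped from every
  count, which is equivalent to an emission of 1 in all hidden states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = ["ObsBlock", "PairObservationSequence", "MISSING"]

MISSING = -1


@dataclass
class ObsBlock:
    """Observations of one marker class along the sequence.

    ``event_positions``/``event_symbols`` list the sites whose symbol differs
    from ``default_symbol`` (or every annotated site if ``default_symbol`` is
    None, as for methylation where all annotated sites are informative).
    ``site_positions`` lists *all* designated sites of the class; required for
    non-dominant classes with a default symbol so that monomorphic sites are
    counted.  The dominant block owns every position not claimed by another
    block.
    """

    name: str
    n_symbols: int
    event_positions: np.ndarray
    event_symbols: np.ndarray
    site_positions: Optional[np.ndarray] = None
    default_symbol: Optional[int] = 0
    dominant: bool = False

    def __post_init__(self):
        self.event_positions = np.asarray(self.event_positions, dtype=np.int64)
        self.event_symbols = np.asarray(self.event_symbols, dtype=np.int64)
        if self.event_positions.shape != self.event_symbols.shape:
            raise ValueError("event positions and symbols have inconsistent lengths")
        if np.any((self.event_symbols >= self.n_symbols) |
                  ((self.event_symbols < 0) & (self.event_symbols != MISSING))):
            raise ValueError(f"symbol outside alphabet of block {self.name!r}")
        order = np.argsort(self.event_positions, kind="stable")
        self.event_positions = self.event_positions[order]
        self.event_symbols = self.event_symbols[order]
        if self.site_positions is not None:
            self.site_positions = np.sort(np.asarray(self.site_positions, dtype=np.int64))


@dataclass
class PairObservationSequence:
    """Coded observations for one pair of haploid genomes."""

    length: int
    blocks: List[ObsBlock]
    pair: Tuple[int, int] = (0, 1)

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("empty sequence")
        if sum(b.dominant for b in self.blocks) != 1:
            raise ValueError("exactly one block must be dominant")
        for b in self.blocks:
            if len(b.event_positions) and (b.event_positions[-1] >= self.length
                                           or b.event_positions[0] < 0):
                raise ValueError("event position outside sequence")

    @property
    def block_names(self):
        return [b.name for b in self.blocks]

    def symbol_offsets(self):
        """Column offset of each block in the concatenated symbol space."""
        offs, total = [], 0
        for b in self.blocks:
            offs.append(total)
            total += b.n_symbols
        return offs, total

    def window_counts(self, window_size: int) -> np.ndarray:
        """Per-window symbol counts, shape (n_windows, total_symbols).

        Window ``w`` covers ``[w*window_size, (w+1)*window_size)``; the last
        window may be shorter.  Missing sites are excluded from all counts.
        """
        if window_size < 1:
            raise ValueError("window_size must be >= 1")
        n_w = -(-self.length // window_size)
        offs, total = self.symbol_offsets()
        counts = np.zeros((n_w, total), dtype=np.float64)

        # window sizes (last one possibly short)
        wsizes = np.full(n_w, window_size, dtype=np.float64)
        wsizes[-1] = self.length - (n_w - 1) * window_size

        dom_idx = next(i for i, b in enumerate(self.blocks) if b.dominant)
        dom_col = offs[dom_idx] + (self.blocks[dom_idx].default_symbol or 0)
        counts[:, dom_col] = wsizes

        for bi, b in enumerate(self.blocks):
            off = offs[bi]
            if not b.dominant:
                if b.site_positions is not None:
                    w = b.site_positions // window_size
                    nsites = np.bincount(w, minlength=n_w).astype(float)
                    # these positions are not nucleotide sites
                    counts[:, dom_col] -= nsites
                    if b.default_symbol is not None:
                        counts[:, off + b.default_symbol] += nsites
                elif len(b.event_positions):
                    w = b.event_positions // window_size
                    counts[:, dom_col] -= np.bincount(w, minlength=n_w)
            if len(b.event_positions):
                w = b.event_positions // window_size
                miss = b.event_symbols == MISSING
                base = off + b.default_symbol if b.default_symbol is not None else None
                for sym in range(b.n_symbols):
                    sel = b.event_symbols == sym
                    if sel.any():
                        add = np.bincount(w[sel], minlength=n_w)
                        counts[:, off + sym] += add
                        if base is not None and sym != b.default_symbol:
                            counts[:, base] -= add
                        elif base is None:
                            pass
                if miss.any():
                    sub = np.bincount(w[miss], minlength=n_w)
                    if base is not None:
                        counts[:, base] -= sub
        if np.any(counts < -1e-9):
            raise ValueError("inconsistent site bookkeeping (negative counts)")
        return np.clip(counts, 0.0, None)

    def per_site_symbols(self) -> np.ndarray:
        """Dense per-position (block, symbol) codes; for small sequences only.

        Returns an integer array of shape (length, 2): column 0 the block
        index, column 1 the within-block symbol (MISSING for missing sites).
        """
        dom_idx = next(i for i, b in enumerate(self.blocks) if b.dominant)
        out = np.zeros((self.length, 2), dtype=np.int64)
        out[:, 0] = dom_idx
        out[:, 1] = self.blocks[dom_idx].default_symbol or 0
        for bi, b in enumerate(self.blocks):
            if b.site_positions is not None:
                out[b.site_positions, 0] = bi
                if b.default_symbol is not None:
                    out[b.site_positions, 1] = b.default_symbol
            out[b.event_positions, 0] = bi
            out[b.event_positions, 1] = b.event_symbols
        return out
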