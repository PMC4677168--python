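"""Sequence clustering statistics of interface residues.

Interface residues are not scattered uniformly along a chain: an interface
residue tends to have further interface residues among its sequence
neighbours, and this enrichment decays with sequence distance.  Two summaries
quantify the effect and motivate the windowed feature encoding:

* a neighbour profile — for every interface residue, how many interface
  residues sit at each signed offset d (negative = N-terminal side), summed
  over the dataset;
* a per-window composition table — for windows of size w centred on each
  interface residue, the percentage of centres whose window contains exactly
  k interface residues (k >= 1 always, since the centre itself counts).

Windows and offsets never cross chain boundaries; windows overhanging a
terminus are truncated to the in-chain positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .feature_io import Chain


@dataclass(frozen=True)
class NeighborProfile:
    """Interface-neighbour counts per signed offset, 0 excluded."""

    max_offset: int
    counts: Mapping[int, int]  # offset -> count, offsets in [-m,-1] u [1,m]

    def __post_init__(self) -> None:
        expected = set(range(-self.max_offset, 0)) | set(
            range(1, self.max_offset + 1)
        )
        if set(self.counts) != expected:
            raise ValueError("counts must cover offsets -m..-1 and 1..m")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class WindowRatioTable:
    """Percentage of interface-centred windows holding exactly k interfaces.

    ``percentages[w]`` is a length-``w`` array indexed by ``k-1``; rows sum
    to 100 up to rounding (or are all zero when the data has no interface
    residues at all).
    """

    percentages: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        for w, row in self.percentages.items():
            if len(row) != w:
                raise ValueError(f"window {w}: expected {w} bins, got {len(row)}")


def _labels_of(chain: Chain) -> np.ndarray:
    labels = chain.labels
    if labels is None:
        raise ValueError(f"chain {chain.chain_id} has unlabeled residues")
    return labels


def neighbor_profile(chains: Sequence[Chain], max_offset: int) -> NeighborProfile:
    """Count interface residues at each offset from every interface residue."""
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    offsets = [d for d in range(-max_offset, max_offset + 1) if d != 0]
    counts = {d: 0 for d in offsets}
    for chain in chains:
        y = _labels_of(chain)
        L = len(y)
        centers = np.flatnonzero(y == 1)
        for d in offsets:
            neighbors = centers + d
            valid = (neighbors >= 0) & (neighbors < L)
            counts[d] += int(np.sum(y[neighbors[valid]] == 1))
    return NeighborProfile(max_offset=max_offset, counts=counts)


def window_ratio_table(
    chains: Sequence[Chain], windows: Sequence[int]
) -> WindowRatioTable:
    """Tabulate per-window interface counts around interface centres."""
    for w in windows:
        if w < 1 or w % 2 == 0:
            raise ValueError(f"window sizes must be odd and >= 1, got {w}")
    tallies = {w: np.zeros(w, dtype=int) for w in windows}
    for chain in chains:
        y = _labels_of(chain)
        L = len(y)
        centers = np.flatnonzero(y == 1)
        for w in windows:
            half = (w - 1) // 2
            for i in centers:
                lo, hi = max(0, i - half), min(L, i + half + 1)
                k = int(np.sum(y[lo:hi] == 1))  # >= 1: the centre counts
                tallies[w][k - 1] += 1
    percentages = {}
    for w, tally in tallies.items():
        total = tally.sum()
        percentages[w] = (
            100.0 * tally / total if total > 0 else np.zeros(w, dtype=float)
        )
    return WindowRatioTable(percentages=percentages)


def cumulative_cluster_fraction(
    table: WindowRatioTable, w: int, k_min: int
) -> float:
    """Percentage of interface-centred windows with more than k_min interfaces."""
    if w not in table.percentages:
        raise KeyError(f"window size {w} not present in the table")
    row = table.percentages[w]
    return float(np.sum(row[k_min:]))  # bins k_min+1 .. w


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------


def neighbor_profile_tsv(profile: NeighborProfile) -> str:
    out = io.StringIO()
    out.write("offset\tcount\n")
    for d in sorted(profile.counts):
        out.write(f"{d}\t{profile.counts[d]}\n")
    return out.getvalue()


def window_ratio_tsv(table: WindowRatioTable) -> str:
    """Rows = window sizes, columns = interface count k."""
    windows = sorted(table.percentages)
    k_max = max(windows) if windows else 0
    out = io.StringIO()
    out.write("window\t" + "\t".join(str(k) for k in range(1, k_max + 1)) + "\n")
    for w in windows:
        row = table.percentages[w]
        cells = [f"{row[k - 1]:.2f}" if k <= w else "" for k in range(1, k_max + 1)]
        out.write(f"{w}\t" + "\t".join(cells) + "\n")
    return out.getvalue()
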