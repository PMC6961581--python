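"""Cell calling from the barcode-rank curve.

Not every barcode observed in a library marks a droplet that contained a
cell: most are ambient background.  Cell-containing BAGs concentrate the
vast majority of reads into a small number of barcodes, so the cumulative
fraction of counts, plotted against barcode rank, rises steeply and then
bends sharply at the boundary between cells and background.  Cells are the
barcodes left of that inflection.

The knee is located by the chord criterion: on the curve of (rank fraction,
cumulative count fraction), the knee is the point of maximum perpendicular
distance from the chord joining the curve's endpoints.  When the curve is
close to that chord (all barcodes similar in depth) there is no knee and no
cells are called — the method reports a diagnostic instead of guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["BarcodeRankCurve", "CellCallResult", "call_cells"]


@dataclass
class BarcodeRankCurve:
    """Barcodes sorted by descending count with the cumulative fraction."""

    barcodes: list[str]
    counts: np.ndarray
    cumulative_fraction: np.ndarray

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "BarcodeRankCurve":
        items = [(b, c) for b, c in counts.items() if c > 0]
        # sort by count desc, barcode asc: deterministic under relabeling ties
        items.sort(key=lambda bc: (-bc[1], bc[0]))
        barcodes = [b for b, _ in items]
        arr = np.asarray([c for _, c in items], dtype=float)
        cum = np.cumsum(arr) / arr.sum()
        return cls(barcodes, arr, cum)


@dataclass
class CellCallResult:
    selected: set[str]
    knee_index: Optional[int]  # number of barcodes left of the knee
    diagnostic: Optional[str] = None
    curve: Optional[BarcodeRankCurve] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        assert self.curve is not None
        return pd.DataFrame(
            {
                "barcode": self.curve.barcodes,
                "count": self.curve.counts.astype(int),
                "selected": [b in self.selected for b in self.curve.barcodes],
            }
        )


def call_cells(
    counts: Mapping[str, int],
    min_knee_distance: float = 0.02,
    manual_threshold: Optional[int] = None,
) -> CellCallResult:
    """Select cell-containing barcodes left of the rank-curve inflection.

    Parameters
    ----------
    counts
        Barcode -> read (or template) count.
    min_knee_distance
        Minimum perpendicular distance (in normalized curve units, where the
        chord has length sqrt(2)) for an inflection to count as a knee.
        Below it the curve is declared knee-free and nothing is selected.
    manual_threshold
        Optional count cutoff overriding knee detection: every barcode with
        at least this many counts is selected.

    The selection is invariant to barcode relabeling and to scaling all
    counts by a constant, and is always a prefix of the descending-sorted
    barcode list (ties at the knee included).
    """
    curve = BarcodeRankCurve.from_counts(counts)
    n = len(curve.barcodes)
    if n < 2:
        return CellCallResult(set(), None, "fewer than 2 nonzero barcodes", curve)

    if manual_threshold is not None:
        k = int(np.sum(curve.counts >= manual_threshold))
        return CellCallResult(set(curve.barcodes[:k]), k or None, None, curve)

    # points (k/n, C_k), k=0..n; chord is the line from (0,0) to (1,1)
    ranks = np.arange(n + 1) / n
    cum = np.concatenate([[0.0], curve.cumulative_fraction])
    distance = (cum - ranks) / np.sqrt(2.0)
    k = int(np.argmax(distance))
    if distance[k] < min_knee_distance or k == 0:
        return CellCallResult(set(), None, "no knee detected", curve)
    # inclusive prefix: extend through barcodes tied with the knee count
    knee_count = curve.counts[k - 1]
    while k < n and curve.counts[k] == knee_count:
        k += 1
    return CellCallResult(set(curve.barcodes[:k]), k, None, curve)
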