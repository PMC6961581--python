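"""Single-cell copy-number profiles: binning, normalization, segmentation.

The genome is divided into variable-width bins whose boundaries are chosen
empirically so that pooled capture positions distribute uniformly across
bins — under constant copy number every bin then expects the same template
count, and deviations are copy-number signal.  Per-cell bin counts are
ratio-normalized to mean one, GC-corrected by lowess, segmented by circular
binary segmentation (CBS) with permutation significance, and scaled to
integer copy number by a grid search over ploidy multipliers.

Segmentation is a from-scratch CBS: the maximal-|t| arc of each segment
(treating the segment as circular) proposes up to two change points, a
within-segment permutation test accepts or rejects the split, and weak
splits are undone when the adjacent means differ by less than a multiple of
the residual standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "BinScheme",
    "SegmentationParams",
    "CopyNumberProfile",
    "build_empirical_bins",
    "count_bins",
    "normalize_profile",
    "segment_profile",
    "estimate_ploidy",
    "cluster_profiles",
]

#: y-axis guide lines for log(y+1) display of high-amplitude profiles
DISPLAY_GUIDES = (1, 2, 3, 4, 20, 50, 80)


@dataclass
class BinScheme:
    """Ordered genomic intervals (0-based half-open) tiling the usable genome."""

    bins: pd.DataFrame  # columns: chrom, start, end, gc

    def __len__(self) -> int:
        return len(self.bins)

    def to_bed(self, path: str) -> None:
        self.bins.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str) -> "BinScheme":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gc"])
        return cls(df)


@dataclass(frozen=True)
class SegmentationParams:
    """CBS parameters; defaults match the DNAcopy settings used for BAG data."""

    alpha: float = 0.02
    nperm: int = 1000
    undo_sd: float = 0.5
    min_width: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclass
class CopyNumberProfile:
    """Per-BAG copy-number state at every stage of the transform."""

    bag: str
    bincounts: np.ndarray
    normalized: np.ndarray
    segments: np.ndarray = field(default=None)  # per-bin segment means
    breakpoints: list[int] = field(default_factory=list)
    ploidy: float = float("nan")
    scaled: np.ndarray = field(default=None)  # ploidy * segments

    @property
    def integer_states(self) -> np.ndarray:
        return _round_half_away(self.scaled).astype(int)


def build_empirical_bins(
    positions: Mapping[str, np.ndarray],
    n_bins: int,
    genome: Optional[Mapping[str, str]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> BinScheme:
    """Empirical equal-count bins from pooled capture positions.

    ``positions`` maps chromosome -> sorted array of distinct 0-based capture
    positions pooled over the reference libraries.  Bins are allocated to
    chromosomes proportionally to their position counts and boundaries are
    placed at empirical quantiles.  Within each chromosome every bin holds
    the same number of pooled positions plus or minus one (exactly so when
    positions are distinct); across chromosomes counts agree up to the
    rounding of the per-chromosome bin allocation, since whole bins cannot
    cross a chromosome end.  Per-bin GC fraction is computed from ``genome``
    (chromosome -> sequence) when given, else set to NaN.
    """
    chroms = [c for c in positions if len(positions[c]) > 0]
    counts = np.array([len(positions[c]) for c in chroms])
    total = int(counts.sum())
    if n_bins > total:
        raise ValueError(f"n_bins={n_bins} exceeds {total} pooled positions")
    # largest-remainder apportionment of bins to chromosomes
    quota = counts * n_bins / total
    alloc = np.maximum(np.floor(quota).astype(int), 1)
    while alloc.sum() < n_bins:
        alloc[np.argmax(quota - alloc)] += 1
    while alloc.sum() > n_bins:
        candidates = np.where(alloc > 1)[0]
        alloc[candidates[np.argmin((quota - alloc)[candidates])]] -= 1

    rows = []
    for chrom, k in zip(chroms, alloc):
        pos = np.asarray(positions[chrom])
        if not np.all(np.diff(pos) >= 0):
            raise ValueError(f"positions for {chrom} are not sorted")
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else (len(genome[chrom]) if genome is not None else int(pos[-1]) + 1)
        )
        # boundary after every ceil/floor-sized chunk of positions; the
        # boundary coordinate splits between distinct position values
        idx = np.linspace(0, len(pos), k + 1).round().astype(int)
        edges = [0]
        for i in idx[1:-1]:
            edges.append(int(pos[i - 1]) + 1)
        edges.append(length)
        for s, e in zip(edges, edges[1:]):
            rows.append({"chrom": chrom, "start": s, "end": max(e, s + 1)})
    bins = pd.DataFrame(rows)
    bins["gc"] = _bin_gc(bins, genome) if genome is not None else np.nan
    return BinScheme(bins)


def _bin_gc(bins: pd.DataFrame, genome: Mapping[str, str]) -> np.ndarray:
    gc = np.empty(len(bins))
    for i, row in enumerate(bins.itertuples(index=False)):
        seq = genome[row.chrom][row.start : row.end].upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        gc[i] = (seq.count("G") + seq.count("C")) / acgt if acgt else np.nan
    return gc


def count_bins(positions: Mapping[str, np.ndarray], scheme: BinScheme) -> np.ndarray:
    """Count positions falling in each bin of the scheme (multiplicity kept)."""
    out = np.zeros(len(scheme), dtype=int)
    for chrom, grp in scheme.bins.groupby("chrom", observed=True, sort=False):
        pos = np.sort(np.asarray(positions.get(chrom, np.array([], dtype=int))))
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        out[grp.index] = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
    return out


def normalize_profile(
    bincounts: np.ndarray,
    bin_gc: Optional[np.ndarray] = None,
    lowess_frac: float = 0.05,
    min_gc_span: float = 0.02,
    min_window: int = 30,
) -> np.ndarray:
    """Ratio-normalize bin counts to mean one and correct GC bias by lowess.

    The ratio r_i = (c_i + 1) / mean(c + 1) is corrected in log space: a
    locally weighted regression of log r on per-bin GC fraction (span
    ``lowess_frac``) is subtracted, residuals are exponentiated, and the
    vector is rescaled to mean exactly one.

    Two numerical guards keep the local regression well-conditioned.  GC
    correction is skipped when GC is missing or spans less than
    ``min_gc_span`` (no bias to fit; a robustified fit over a spread-free
    predictor chases copy-number structure instead).  The span is floored
    so every local fit uses at least ``min_window`` bins: at the intended
    bin counts (thousands) a 0.05 span covers hundreds of bins, but on
    small schemes the literal fraction would smooth over a handful of
    points and absorb segment-level signal.
    """
    c = np.asarray(bincounts, dtype=float)
    if c.sum() == 0:
        raise ValueError("empty profile: all bin counts are zero")
    r = (c + 1.0) / np.mean(c + 1.0)
    if bin_gc is not None:
        gc = np.asarray(bin_gc, dtype=float)
        ok = np.isfinite(gc)
        if ok.all() and np.ptp(gc) > min_gc_span:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            frac = max(lowess_frac, min(1.0, min_window / len(r)))
            fit = lowess(np.log(r), gc, frac=frac, return_sorted=False)
            r = np.exp(np.log(r) - fit)
    return r / r.mean()


# ---------------------------------------------------------------------------
# circular binary segmentation


def _valid_start_mask(n: int, k: int, min_width: int) -> np.ndarray:
    """Arc starts whose induced linear segments all have >= min_width bins.

    An arc x[i:i+k] cuts the segment at i and i+k; the flanking pieces
    [0, i) and [i+k, n) must each be empty or at least min_width wide.
    """
    i = np.arange(n - k + 1)
    left_ok = (i == 0) | (i >= min_width)
    right_ok = (i + k == n) | (i + k <= n - min_width)
    return left_ok & right_ok


def _arc_stats(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Max mean-shift statistic over circular arcs of one segment.

    Only linear arcs are enumerated: the statistic of an arc equals that of
    its (wrap-around) complement, so linear arcs cover the circular search.
    Returns (max_stat, i, j) with the arc being x[i:j].
    """
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    best, bi, bj = -1.0, 0, n
    for k in range(min_width, n - min_width + 1):
        sums = S[k:] - S[: n - k + 1]  # arc sums for all starts i
        stat = np.abs(sums / k - (total - sums) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        stat[~_valid_start_mask(n, k, min_width)] = -np.inf
        i = int(np.argmax(stat))
        if stat[i] > best:
            best, bi, bj = float(stat[i]), i, i + k
    return best, bi, bj


def _perm_exceed_count(
    x: np.ndarray,
    observed: float,
    nperm: int,
    min_width: int,
    rng: np.random.Generator,
    stop_after: int,
) -> int:
    """Number of within-segment permutations whose max arc stat >= observed.

    Permutations run in vectorized batches; stops early once ``stop_after``
    exceedances are seen (the split can no longer be accepted).
    """
    n = len(x)
    exceed = 0
    done = 0
    batch = max(1, min(nperm, 200_000 // max(n, 1)))
    while done < nperm:
        m = min(batch, nperm - done)
        perms = np.array([rng.permutation(x) for _ in range(m)])
        S = np.concatenate([np.zeros((m, 1)), np.cumsum(perms, axis=1)], axis=1)
        total = S[:, -1:]
        best = np.zeros(m)
        for k in range(min_width, n - min_width + 1):
            sums = S[:, k:] - S[:, : n - k + 1]
            stat = np.abs(sums / k - (total - sums) / (n - k)) / np.sqrt(
                1.0 / k + 1.0 / (n - k)
            )
            stat[:, ~_valid_start_mask(n, k, min_width)] = -np.inf
            np.maximum(best, stat.max(axis=1), out=best)
        exceed += int(np.sum(best >= observed))
        done += m
        if exceed >= stop_after:
            break
    return exceed


def segment_profile(
    values: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> tuple[np.ndarray, list[int]]:
    """Segment a normalized profile by circular binary segmentation.

    Returns (per-bin segment means, sorted interior breakpoints).  A
    breakpoint b means bins [.., b) and [b, ..) belong to different
    segments.  Deterministic for a fixed ``params.seed``.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("profile contains NaN")
    if len(x) < 2 * params.min_width:
        return np.full_like(x, x.mean()), []
    rng = np.random.default_rng(params.seed)
    threshold = int(np.ceil(params.alpha * params.nperm))

    breakpoints: set[int] = set()
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * params.min_width or np.ptp(seg) == 0:
            continue
        stat, i, j = _arc_stats(seg, params.min_width)
        exceed = _perm_exceed_count(seg, stat, params.nperm, params.min_width, rng, threshold)
        if exceed >= threshold:  # p-value >= alpha: not significant
            continue
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            continue
        for b in cuts:
            breakpoints.add(b)
        bounds = [lo] + cuts + [hi]
        for a, b in zip(bounds, bounds[1:]):
            stack.append((a, b))

    bps = _undo_weak_splits(x, sorted(breakpoints), params.undo_sd)
    return _segment_means(x, bps), bps


def _segment_means(x: np.ndarray, breakpoints: Sequence[int]) -> np.ndarray:
    out = np.empty_like(x)
    bounds = [0] + list(breakpoints) + [len(x)]
    for a, b in zip(bounds, bounds[1:]):
        out[a:b] = x[a:b].mean()
    return out


def _undo_weak_splits(x: np.ndarray, breakpoints: list[int], undo_sd: float) -> list[int]:
    """Iteratively remove the weakest breakpoint below undo_sd * residual SD."""
    bps = list(breakpoints)
    while bps:
        seg = _segment_means(x, bps)
        sd = float(np.std(x - seg))
        if sd == 0:
            break
        bounds = [0] + bps + [len(x)]
        diffs = [
            abs(x[bounds[i] : bounds[i + 1]].mean() - x[bounds[i + 1] : bounds[i + 2]].mean())
            for i in range(len(bps))
        ]
        weakest = int(np.argmin(diffs))
        if diffs[weakest] < undo_sd * sd:
            bps.pop(weakest)
        else:
            break
    return bps


# ---------------------------------------------------------------------------
# ploidy and clustering


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def estimate_ploidy(
    segments: np.ndarray,
    weights: Optional[np.ndarray] = None,
    grid: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Grid-search the multiplier mapping mean-one segments onto integers.

    Multiplies the segment vector by each candidate in 1.5, 1.55, ..., 4.5
    and keeps the multiplier minimizing the (optionally weighted) sum of
    squared distances to the nearest integers.  Rounding is half away from
    zero; SSE ties break toward the smallest multiplier.  Returns
    (ploidy, scaled segment vector).
    """
    s = np.asarray(segments, dtype=float)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    if grid is None:
        grid = np.round(np.arange(1.5, 4.5 + 1e-9, 0.05), 10)
    sse = np.array(
        [float(np.sum(w * (m * s - _round_half_away(m * s)) ** 2)) for m in grid]
    )
    best = int(np.argmin(sse))  # argmin returns the first (= smallest) minimizer
    ploidy = float(grid[best])
    return ploidy, ploidy * s


def cluster_profiles(
    segment_matrix: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Hierarchically cluster per-BAG segment vectors.

    ``segment_matrix`` is BAGs x bins.  Distances are Manhattan and the
    agglomeration is Ward's D2 criterion applied to those distances (the
    squared-update form).  Returns (scipy linkage matrix, leaf order as BAG
    labels).
    """
    if segment_matrix.ndim != 2 or len(segment_matrix) < 2:
        raise ValueError("need >= 2 profiles of equal length")
    dist = pdist(segment_matrix.to_numpy(), metric="cityblock")
    Z = linkage(dist, method="ward")
    order = [segment_matrix.index[i] for i in leaves_list(Z)]
    return Z, order


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
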