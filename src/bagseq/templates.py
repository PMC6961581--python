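"""Template collapse and per-BAG coverage statistics.

Reads sharing an identical (BAG barcode, varietal tag, map position, strand)
derive from one original template molecule; collapsing on that key converts
read counts into template counts, the unit every quantitative stage of the
pipeline works in.  This module also computes the per-BAG summary table
(reads, templates, reads-per-template, genome coverage), the strand-capture
partition (each template is captured as a single strand, its 3' end marked
by the restriction site), and read-downsampling saturation curves.

Reads enter as a DataFrame with columns ``bag``, ``tag``, ``chrom``,
``pos`` (0-based leftmost aligned base), ``strand``.  Tags are matched as
exact strings: no mismatch merging.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TEMPLATE_KEY",
    "collapse_templates",
    "bag_stats",
    "strand_capture_fractions",
    "downsample_saturation",
]

TEMPLATE_KEY = ["bag", "tag", "chrom", "pos", "strand"]


def _validate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TEMPLATE_KEY if c not in reads.columns]
    if missing:
        raise ValueError(f"reads table lacks columns {missing}")
    return reads


def collapse_templates(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse reads into uniquely tagged templates.

    Returns one row per distinct template key with a ``size`` column (number
    of member reads).  Rows with a null chromosome (unmapped) are skipped;
    their number is available as ``result.attrs["skipped_unmapped"]``.
    """
    reads = _validate_reads(reads)
    mapped = reads[reads["chrom"].notna()]
    out = (
        mapped.groupby(TEMPLATE_KEY, observed=True, sort=True)
        .size()
        .rename("size")
        .reset_index()
    )
    out.attrs["skipped_unmapped"] = int(len(reads) - len(mapped))
    return out


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    keep_s, keep_e = [], []
    cur_s, cur_e = None, None
    for s, e in zip(starts, ends):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                keep_s.append(cur_s)
                keep_e.append(cur_e)
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        keep_s.append(cur_s)
        keep_e.append(cur_e)
    return np.asarray(keep_s), np.asarray(keep_e)


def _footprints(templates: pd.DataFrame, read_length: int) -> pd.DataFrame:
    """Aligned footprint per template: [pos, pos+L) on '+', (pos-L, pos] on '-'."""
    pos = templates["pos"].to_numpy()
    plus = templates["strand"].to_numpy() == "+"
    start = np.where(plus, pos, np.maximum(pos - read_length + 1, 0))
    end = start + read_length
    return pd.DataFrame({"chrom": templates["chrom"].to_numpy(), "start": start, "end": end})


def _covered_bases(foot: pd.DataFrame) -> int:
    total = 0
    for _, grp in foot.groupby("chrom", observed=True):
        s, e = _merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
        total += int((e - s).sum())
    return total


def bag_stats(
    reads: pd.DataFrame,
    genome_size: int,
    read_length: int = 100,
) -> pd.DataFrame:
    """Per-BAG summary: reads, templates, reads per template, genome fraction.

    Genome coverage is computed over aligned read footprints (merged per
    chromosome), not inferred fragments.
    """
    reads = _validate_reads(reads)
    templates = collapse_templates(reads)
    rows = []
    for bag, grp in templates.groupby("bag", observed=True):
        n_reads = int(grp["size"].sum())
        n_templates = len(grp)
        covered = _covered_bases(_footprints(grp, read_length))
        rows.append(
            {
                "bag": bag,
                "reads": n_reads,
                "templates": n_templates,
                "reads_per_template": n_reads / n_templates,
                "genome_fraction": covered / genome_size,
            }
        )
    return pd.DataFrame(rows).set_index("bag")


def strand_capture_fractions(
    templates: pd.DataFrame,
    genome_size: int,
    read_length: int = 100,
) -> tuple[float, float, float]:
    """Partition covered genome fraction by strand of capture.

    Returns (plus_only, minus_only, both) fractions of the genome covered by
    template footprints captured on the plus strand only, the minus strand
    only, or both.
    """
    fracs = {}
    per_strand: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for strand in "+-":
        sub = templates[templates["strand"] == strand]
        foot = _footprints(sub, read_length)
        per_chrom = {}
        for chrom, grp in foot.groupby("chrom", observed=True):
            per_chrom[chrom] = _merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
        per_strand[strand] = per_chrom
    covered = {"+": 0, "-": 0, "both": 0}
    chroms = set(per_strand["+"]) | set(per_strand["-"])
    for chrom in chroms:
        ps, pe = per_strand["+"].get(chrom, (np.array([]), np.array([])))
        ms, me = per_strand["-"].get(chrom, (np.array([]), np.array([])))
        plus_len = int((pe - ps).sum())
        minus_len = int((me - ms).sum())
        both_len = _intersection_length(ps, pe, ms, me)
        covered["+"] += plus_len - both_len
        covered["-"] += minus_len - both_len
        covered["both"] += both_len
    return (
        covered["+"] / genome_size,
        covered["-"] / genome_size,
        covered["both"] / genome_size,
    )


def _intersection_length(
    s1: np.ndarray, e1: np.ndarray, s2: np.ndarray, e2: np.ndarray
) -> int:
    # both interval lists are merged and sorted; two-pointer sweep
    i = j = 0
    total = 0
    while i < len(s1) and j < len(s2):
        lo = max(s1[i], s2[j])
        hi = min(e1[i], e2[j])
        if hi > lo:
            total += int(hi - lo)
        if e1[i] < e2[j]:
            i += 1
        else:
            j += 1
    return total


def downsample_saturation(
    reads: pd.DataFrame,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    seed: int = 1,
    gene_column: str | None = None,
) -> pd.DataFrame:
    """Unique templates (and optionally genes) observed vs. reads sampled.

    Reads are sampled without replacement at each fraction; at fraction 1.0
    the full-data statistics are returned exactly.  The curve is monotone
    nondecreasing in expectation.
    """
    reads = _validate_reads(reads)
    fractions = sorted(fractions)
    if fractions[0] <= 0 or fractions[-1] > 1:
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(reads)
    # one shuffled order reused across fractions: nested subsamples give
    # a monotone realized curve, not just monotone in expectation
    order = rng.permutation(n)
    rows = []
    for f in fractions:
        take = n if f == 1.0 else int(round(f * n))
        sub = reads.iloc[order[:take]]
        tmpl = collapse_templates(sub)
        row = {"fraction": f, "reads": take, "templates": len(tmpl)}
        if gene_column is not None and gene_column in reads.columns:
            row["genes"] = int(sub[gene_column].dropna().nunique())
        rows.append(row)
    return pd.DataFrame(rows)
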