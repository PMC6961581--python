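"""Genotype-based cell identity, contamination, and barcode collisions.

When two cell sources with known genomes are mixed, SNVs specific to one
source identify which cell a BAG contained.  Each BAG's source-informative
template observations are counted per source; the majority source labels
the BAG and the minority SNV ratio min(a, b) / (a + b) measures
cross-contamination.  A BAG whose source ratio falls between 15% and 85% is
flagged MIXED — the signature of a barcode collision (two cells sharing a
composite barcode by chance) or a doublet.

The expected number of collisions among n cells drawing uniformly from N
composite barcodes follows occupancy statistics and is computed in closed
form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SnvPanel",
    "IdentityCall",
    "call_source_snvs",
    "assign_identity",
    "expected_collisions",
    "observed_collision_rate",
]

#: hg19 positions excluded from real-data runs (anomalous mapping artifacts)
DEFAULT_EXCLUDED_SITES = (
    ("chr1", 569874),
    ("chr6", 58777419),
    ("chr6", 58778584),
    ("chr6", 58779097),
    ("chr7", 61969087),
    ("chr10", 42385520),
)


@dataclass
class SnvPanel:
    """Source-specific SNV sites.

    ``sites`` columns: chrom, pos (0-based), ref, alt, source.  No site may
    be specific to both sources; excluded positions are never scored.
    """

    sites: pd.DataFrame
    excluded: set = None

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = set()
        dup = self.sites.duplicated(["chrom", "pos"], keep=False)
        if dup.any() and self.sites.loc[dup].groupby(["chrom", "pos"])["source"].nunique().gt(1).any():
            raise ValueError("a site cannot be specific to both sources")
        if self.excluded:
            keep = ~self.sites.apply(lambda r: (r["chrom"], r["pos"]) in self.excluded, axis=1)
            self.sites = self.sites.loc[keep].reset_index(drop=True)

    @property
    def sources(self) -> list[str]:
        return sorted(self.sites["source"].unique())


@dataclass
class IdentityCall:
    bag: str
    counts: dict[str, int]
    minority_ratio: float
    label: str  # source label, "MIXED", or "UNASSIGNED"


def call_source_snvs(
    pileup_a: pd.DataFrame,
    pileup_b: pd.DataFrame,
    source_a: str = "A",
    source_b: str = "B",
    min_alt_reads: int = 3,
    min_alt_fraction: float = 0.05,
    min_other_depth: int = 12,
    excluded: Optional[set] = None,
) -> SnvPanel:
    """Call SNVs specific to one of two bulk genomes.

    Each pileup has columns chrom, pos, ref, alt, alt_count, depth (quality
    filters already applied upstream).  A variant requires the alt in at
    least ``min_alt_reads`` reads and at least ``min_alt_fraction`` of
    covering reads.  It is source-specific only when the other genome shows
    no alt read at a position covered by at least ``min_other_depth``
    qualifying reads; under-covered sites are not assignable to either.
    """

    def variants(p: pd.DataFrame) -> pd.DataFrame:
        ok = (p["alt_count"] >= min_alt_reads) & (
            p["alt_count"] >= min_alt_fraction * p["depth"]
        )
        return p.loc[ok]

    def clean_in_other(var: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
        m = var.merge(
            other[["chrom", "pos", "alt_count", "depth"]],
            on=["chrom", "pos"],
            how="left",
            suffixes=("", "_other"),
        )
        ok = (m["depth_other"] >= min_other_depth) & (m["alt_count_other"] == 0)
        return m.loc[ok.fillna(False), ["chrom", "pos", "ref", "alt"]]

    va, vb = variants(pileup_a), variants(pileup_b)
    a_spec = clean_in_other(va, pileup_b).assign(source=source_a)
    b_spec = clean_in_other(vb, pileup_a).assign(source=source_b)
    sites = pd.concat([a_spec, b_spec], ignore_index=True)
    return SnvPanel(sites, excluded=set(excluded) if excluded else set())


def assign_identity(
    observations: pd.DataFrame,
    panel: SnvPanel,
    mixed_band: tuple[float, float] = (0.15, 0.85),
    min_templates: int = 0,
) -> list[IdentityCall]:
    """Assign each BAG a majority source and a minority SNV ratio.

    ``observations`` holds per-template consensus calls at panel sites:
    columns bag, chrom, pos, call (plus anything else, ignored).  A template
    observation is informative when its call equals a panel site's alt
    allele; it then counts for that site's source.  The minority ratio is
    min over sources of its share; a BAG is MIXED when its source ratio lies
    strictly inside ``mixed_band``, UNASSIGNED with zero informative
    observations or fewer than ``min_templates`` total observations.
    """
    if panel.sites.empty:
        raise ValueError("empty SNV panel")
    lo, hi = mixed_band
    merged = observations.merge(
        panel.sites[["chrom", "pos", "alt", "source"]], on=["chrom", "pos"], how="inner"
    )
    informative = merged[merged["call"] == merged["alt"]]
    sources = panel.sources
    calls = []
    totals = observations.groupby("bag", observed=True).size()
    for bag in sorted(observations["bag"].unique()):
        grp = informative[informative["bag"] == bag]
        counts = {s: int((grp["source"] == s).sum()) for s in sources}
        total = sum(counts.values())
        if total == 0 or totals.get(bag, 0) < min_templates:
            calls.append(IdentityCall(bag, counts, float("nan"), "UNASSIGNED"))
            continue
        minority = min(counts.values()) / total
        major_share = max(counts.values()) / total
        if lo < major_share < hi or lo < minority < hi:
            label = "MIXED"
        else:
            label = max(counts, key=lambda s: (counts[s], s))
        calls.append(IdentityCall(bag, counts, minority, label))
    return calls


def identity_table(calls: list[IdentityCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"bag": c.bag, "minority_ratio": c.minority_ratio, "label": c.label}
        row.update({f"n_{s}": v for s, v in c.counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def expected_collisions(n: int, n_barcodes: int) -> float:
    """Expected number of barcodes chosen by more than one of n cells.

    Cells draw composite barcodes independently and uniformly from a space
    of N possibilities; the expected count of barcodes hit at least twice is
    the occupancy (birthday-problem) expression

        N - N (1 - 1/N)^n - n (1 - 1/N)^(n-1).
    """
    if n < 0 or n_barcodes < 1:
        raise ValueError("need n >= 0 and n_barcodes >= 1")
    N = float(n_barcodes)
    q = 1.0 - 1.0 / N
    return N - N * q**n - n * q ** (n - 1)


def observed_collision_rate(n_mixed: int, n_total: int) -> float:
    """Observed collision (mixed-identity) rate as a percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_mixed / n_total
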