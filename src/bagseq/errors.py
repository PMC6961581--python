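"""Consensus error correction and trinucleotide-context error rates.

Every read of a template read set is an independent copy of one original
molecule, so requiring multiple reads to agree suppresses errors introduced
during amplification and sequencing.  Errors present in the template itself
(pre-amplification damage such as depurination or deamination) are copied
into every read and survive consensus — comparing the consensus error rate
with a one-read-per-template baseline separates the two error classes.

Rates are tabulated per trinucleotide context (64 contexts, read from the
reference strand) and per alternative central base, each with an explicit
opportunity denominator.  The truth set is a donor mask: positions where an
independent genome sequence of the donor is confidently homozygous
reference, so any mismatch there is an error (or a somatic variant, which
the candidate-variant analysis addresses via multi-BAG and strand
concordance).

Input tables carry one row per template per masked position with the column
``bases`` holding the read-level base calls (one character per member read,
in reference-strand frame).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "DonorTruthMask",
    "consensus_call",
    "consensus_table",
    "error_matrix",
    "candidate_variants",
]

BASES = "ACGT"
CONTEXTS = ["".join(t) for t in product(BASES, repeat=3)]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class DonorTruthMask:
    """Positions where the donor genome is confidently homozygous reference.

    ``sites`` columns: chrom, pos (0-based), ref, context (reference-strand
    trinucleotide centered on pos).  Built upstream from donor WGS with the
    standard filters (MQ >= 30, BQ >= 30, depth >= 20, no nearby variant);
    the synthetic generator emits it directly.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if self.sites.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate positions in donor mask")

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def from_genome(cls, genome: dict[str, str], exclude: Optional[set] = None) -> "DonorTruthMask":
        """Mask every internal position of a genome (synthetic/known-truth use)."""
        rows = []
        exclude = exclude or set()
        for chrom, seq in genome.items():
            seq = seq.upper()
            for pos in range(1, len(seq) - 1):
                if (chrom, pos) in exclude:
                    continue
                ctx = seq[pos - 1 : pos + 2]
                if set(ctx) - set(BASES):
                    continue
                rows.append((chrom, pos, seq[pos], ctx))
        return cls(pd.DataFrame(rows, columns=["chrom", "pos", "ref", "context"]))


def consensus_call(bases: str) -> Optional[str]:
    """Consensus base of one template read set at one position.

    A call requires at least two member reads with at least 80% agreeing
    (exactly 80% is a call); otherwise no-call (None).  The call is always a
    base present in the read set.
    """
    if len(bases) < 2:
        return None
    base, count = Counter(bases).most_common(1)[0]
    return base if count >= 0.8 * len(bases) else None


def consensus_table(pileups: pd.DataFrame) -> pd.DataFrame:
    """Apply consensus calling to a template pileup table.

    Expects columns bag, tag, chrom, pos, strand, bases; returns the rows
    with a successful consensus plus a ``call`` column.
    """
    calls = pileups["bases"].map(consensus_call)
    out = pileups.loc[calls.notna()].copy()
    out["call"] = calls[calls.notna()]
    return out


def _sample_one_read(pileups: pd.DataFrame, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    bases = pileups["bases"].to_numpy()
    picks = [b[rng.integers(len(b))] for b in bases]
    out = pileups.copy()
    out["call"] = picks
    return out


def error_matrix(
    pileups: pd.DataFrame,
    mask: DonorTruthMask,
    mode: str = "consensus",
    seed: int = 1,
) -> pd.DataFrame:
    """Trinucleotide-context error rates against the donor truth mask.

    ``mode='consensus'`` uses consensus calls (templates with >= 2 reads and
    >= 80% agreement); ``mode='raw'`` samples one read per template
    uniformly (seeded) as the no-correction baseline.  Returns the 64 x 3
    long table (context, alt, errors, opportunities, rate); cells with zero
    opportunities carry rate NaN, not zero.
    """
    if mode == "consensus":
        called = consensus_table(pileups)
    elif mode == "raw":
        called = _sample_one_read(pileups, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    called = called.merge(mask.sites, on=["chrom", "pos"], how="inner")

    opportunities = called.groupby("context", observed=True).size()
    err = called[called["call"] != called["ref"]]
    error_counts = err.groupby(["context", "call"], observed=True).size()

    rows = []
    for ctx in CONTEXTS:
        opp = int(opportunities.get(ctx, 0))
        for alt in BASES:
            if alt == ctx[1]:
                continue
            cnt = int(error_counts.get((ctx, alt), 0))
            rows.append(
                {
                    "context": ctx,
                    "alt": alt,
                    "errors": cnt,
                    "opportunities": opp,
                    "rate": cnt / opp if opp else np.nan,
                }
            )
    return pd.DataFrame(rows)


def candidate_variants(pileups: pd.DataFrame, mask: DonorTruthMask) -> pd.DataFrame:
    """Variants supported by concordant consensus in at least two BAGs.

    A candidate is a (position, alt) seen as a template consensus in >= 2
    distinct BAGs (same alt allele; capture strand free).  For each
    candidate the table also reports whether the position is captured on the
    opposite strand anywhere and whether the alt is also seen there — on a
    double-strand somatic variant the complement is expected, on
    single-strand template damage it is not.  Aggregate fractions are in
    ``result.attrs``.
    """
    called = consensus_table(pileups).merge(mask.sites, on=["chrom", "pos"], how="inner")
    alt_calls = called[called["call"] != called["ref"]]

    # strands on which each position is captured at all (consensus level)
    strands_at = called.groupby(["chrom", "pos"], observed=True)["strand"].agg(set)

    rows = []
    grouped = alt_calls.groupby(["chrom", "pos", "call"], observed=True)
    for (chrom, pos, alt), grp in grouped:
        bags = set(grp["bag"])
        if len(bags) < 2:
            continue
        var_strands = set(grp["strand"])
        other = {"+": "-", "-": "+"}
        opposite_captured = any(
            other[s] in strands_at.loc[(chrom, pos)] for s in var_strands
        )
        complement_seen = opposite_captured and len(var_strands) > 1
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": grp["ref"].iloc[0],
                "alt": alt,
                "n_bags": len(bags),
                "opposite_strand_captured": opposite_captured,
                "complement_seen": complement_seen,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "n_bags",
            "opposite_strand_captured",
            "complement_seen",
        ],
    )
    n = len(out)
    n_opp = int(out["opposite_strand_captured"].sum()) if n else 0
    out.attrs["opposite_capture_fraction"] = n_opp / n if n else np.nan
    out.attrs["complement_fraction"] = (
        int(out["complement_seen"].sum()) / n_opp if n_opp else np.nan
    )
    return out
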