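"""Read-structure validation, barcode/tag extraction, and pair filtering.

BAG libraries encode the cell of origin as a composite barcode assembled
across split-and-pool rounds, together with a varietal tag (a unique
molecular identifier marking the original template molecule).  Both live at
fixed positions on one of the two reads, interleaved with anchor sequences
(the NlaIII CATG cut site for DNA, a template-switch GGG or a fixed primer
for RNA).  This module knows those positional layouts, validates raw reads
against them, and extracts the annotations that every downstream stage keys
on.

Layout coordinates follow the bench convention: 1-based, inclusive.
Genomic intervals everywhere else in the package are 0-based half-open;
conversion happens only at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "Protocol",
    "AnchorSpec",
    "ReadLayout",
    "BarcodeWhitelist",
    "AnnotatedRead",
    "MappedMate",
    "Extraction",
    "LAYOUTS",
    "validate_read",
    "validate_dna_read2",
    "validate_rna_read1",
    "trim_adapter",
    "trim_and_retain_pair",
    "classify_proper_pair",
    "demux_fastq",
]


class Protocol(str, Enum):
    """Library protocol; determines which positional layout applies."""

    DNA = "dna"
    RNA_2SPLIT_A = "rna2a"  # primer-anchored two-round split-pool
    RNA_2SPLIT_B = "rna2b"  # whitelist-anchored two-round split-pool
    RNA_3SPLIT = "rna3"     # three-round split-pool


@dataclass(frozen=True)
class AnchorSpec:
    """A fixed subsequence expected at a 1-based inclusive position range."""

    sequence: str
    start: int
    end: int
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("anchor range length does not match its sequence")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class ReadLayout:
    """Positional layout of one protocol's identifying read.

    ``barcode_ranges`` are the split-round slices whose concatenation forms
    the composite BAG barcode; ``tag_ranges`` concatenate to the varietal
    tag.  ``whitelist_checked`` marks whether barcode slices must match the
    per-round whitelists (the primer-anchored 2-split layout is validated by
    its primer instead).
    """

    protocol: Protocol
    anchors: tuple[AnchorSpec, ...]
    barcode_ranges: tuple[tuple[int, int], ...]
    tag_ranges: tuple[tuple[int, int], ...]
    source_read: str = "read1"
    whitelist_checked: bool = False

    def __post_init__(self) -> None:
        spans = sorted(
            [(a.start, a.end) for a in self.anchors]
            + list(self.barcode_ranges)
            + list(self.tag_ranges)
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping layout ranges {(s1, e1)} and {(s2, e2)}")
        if any(s < 1 or e < s for s, e in spans):
            raise ValueError("layout ranges must be 1-based with end >= start")

    @property
    def min_length(self) -> int:
        return max(
            [a.end for a in self.anchors]
            + [e for _, e in self.barcode_ranges]
            + [e for _, e in self.tag_ranges]
        )

    @property
    def barcode_length(self) -> int:
        return sum(e - s + 1 for s, e in self.barcode_ranges)

    @property
    def tag_length(self) -> int:
        return sum(e - s + 1 for s, e in self.tag_ranges)


#: Canonical layouts.  DNA: CATG cut site at 31-34 (<=1 mismatch), barcode
#: 1-6 + 22-26 (positions 7-21 are a constant linker, not validated), tag
#: 27-30, all on read 2.  RNA layouts are on read 1.
LAYOUTS: dict[Protocol, ReadLayout] = {
    Protocol.DNA: ReadLayout(
        protocol=Protocol.DNA,
        anchors=(AnchorSpec("CATG", 31, 34, max_mismatches=1),),
        barcode_ranges=((1, 6), (22, 26)),
        tag_ranges=((27, 30),),
        source_read="read2",
        whitelist_checked=False,
    ),
    Protocol.RNA_2SPLIT_A: ReadLayout(
        protocol=Protocol.RNA_2SPLIT_A,
        anchors=(
            AnchorSpec("AGTGGAAAAGGAAGGTGGT", 7, 25, max_mismatches=2),
            AnchorSpec("GGG", 38, 40, max_mismatches=0),
        ),
        barcode_ranges=((1, 6), (26, 31)),
        tag_ranges=((32, 37), (43, 48)),
        whitelist_checked=False,
    ),
    Protocol.RNA_2SPLIT_B: ReadLayout(
        protocol=Protocol.RNA_2SPLIT_B,
        anchors=(AnchorSpec("GGG", 38, 40, max_mismatches=1),),
        barcode_ranges=((1, 6), (26, 31)),
        tag_ranges=((32, 37), (43, 48)),
        whitelist_checked=True,
    ),
    Protocol.RNA_3SPLIT: ReadLayout(
        protocol=Protocol.RNA_3SPLIT,
        anchors=(AnchorSpec("GGG", 67, 69, max_mismatches=1),),
        barcode_ranges=((1, 6), (30, 35), (55, 60)),
        tag_ranges=((61, 66), (72, 77)),
        whitelist_checked=True,
    ),
}


class BarcodeWhitelist:
    """Valid 6-base barcodes per split round.

    ``rounds[k]`` is the set accepted for the k-th barcode slice of the
    layout.  Matching is exact by default; an optional 1-mismatch rescue can
    be enabled where a corrupted slice is replaced by a whitelist entry iff
    exactly one entry lies within Hamming distance 1.
    """

    def __init__(self, rounds: Sequence[Iterable[str]]):
        self.rounds: list[frozenset[str]] = []
        for entries in rounds:
            fs = frozenset(str(b).upper() for b in entries)
            for b in fs:
                if len(b) != 6 or set(b) - set("ACGT"):
                    raise ValueError(f"whitelist barcode {b!r} is not a 6-mer over ACGT")
            self.rounds.append(fs)

    def __len__(self) -> int:
        return len(self.rounds)

    def match(self, barcode: str, round_index: int, rescue: bool = False) -> Optional[str]:
        """Return the whitelist entry matching ``barcode`` or None."""
        entries = self.rounds[round_index]
        if barcode in entries:
            return barcode
        if rescue:
            hits = [e for e in entries if _mismatches(barcode, e) == 1]
            if len(hits) == 1:
                return hits[0]
        return None


@dataclass
class AnnotatedRead:
    """A read (or pair) carrying its extracted barcode, tag, and mapping."""

    read_id: str
    bag_barcode: str = ""
    varietal_tag: str = ""
    pass_structure: bool = False
    read1_seq: str = ""
    read2_seq: str = ""
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 1-based leftmost when mapped
    strand: Optional[str] = None
    mapq: int = 0


@dataclass
class MappedMate:
    """Minimal mapped-record view used for proper-pair classification."""

    chrom: str
    start: int  # 0-based
    end: int    # 0-based half-open
    strand: str  # "+" or "-"
    mapped: bool = True
    structure_ok: bool = True  # read-2 restriction-site flag


@dataclass
class Extraction:
    ok: bool
    reason: Optional[str] = None
    bag_barcode: Optional[str] = None
    varietal_tag: Optional[str] = None


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _slice1(seq: str, start: int, end: int) -> str:
    # 1-based inclusive -> python slice
    return seq[start - 1 : end]


def validate_read(
    seq: str,
    layout: ReadLayout,
    whitelist: Optional[BarcodeWhitelist] = None,
    rescue: bool = False,
) -> Extraction:
    """Validate one read against a layout and extract barcode and tag.

    Checks every anchor within its mismatch allowance and, for
    whitelist-checked layouts, every barcode slice against the corresponding
    round's whitelist.  Returns a failed :class:`Extraction` with a reason
    (``too_short``, ``anchor``, ``invalid_barcode``) rather than raising.
    """
    seq = seq.upper()
    if len(seq) < layout.min_length:
        return Extraction(False, "too_short")
    for anchor in layout.anchors:
        observed = _slice1(seq, anchor.start, anchor.end)
        if _mismatches(observed, anchor.sequence) > anchor.max_mismatches:
            return Extraction(False, "anchor")
    parts: list[str] = []
    for k, (s, e) in enumerate(layout.barcode_ranges):
        part = _slice1(seq, s, e)
        if layout.whitelist_checked:
            if whitelist is None:
                raise ValueError("layout requires a whitelist")
            matched = whitelist.match(part, k, rescue=rescue)
            if matched is None:
                return Extraction(False, "invalid_barcode")
            part = matched
        parts.append(part)
    tag = "".join(_slice1(seq, s, e) for s, e in layout.tag_ranges)
    return Extraction(True, None, "".join(parts), tag)


def validate_dna_read2(seq: str, layout: Optional[ReadLayout] = None) -> Extraction:
    """DNA protocol: validate read 2 (CATG at 31-34, <=1 mismatch)."""
    return validate_read(seq, layout or LAYOUTS[Protocol.DNA])


def validate_rna_read1(
    seq: str,
    layout: ReadLayout,
    whitelist: Optional[BarcodeWhitelist] = None,
    rescue: bool = False,
) -> Extraction:
    """RNA protocols: validate read 1 for any of the three RNA layouts."""
    return validate_read(seq, layout, whitelist=whitelist, rescue=rescue)


def trim_adapter(
    seq: str,
    adapters: Sequence[str],
    min_overlap: int = 5,
    max_mismatch_frac: float = 0.10,
) -> str:
    """Remove a 3' suffix of ``seq`` matching the start of any adapter.

    Suffix-overlap matching: the longest suffix (leftmost cut point) whose
    overlap with an adapter prefix is at least ``min_overlap`` bases and has
    at most ``max_mismatch_frac`` mismatches is removed.
    """
    seq = seq.upper()
    n = len(seq)
    best_cut = n
    for adapter in adapters:
        adapter = adapter.upper()
        for i in range(max(0, n - len(adapter)), n - min_overlap + 1):
            overlap = n - i
            if _mismatches(seq[i:], adapter[:overlap]) <= max_mismatch_frac * overlap:
                best_cut = min(best_cut, i)
                break
    return seq[:best_cut]


def trim_and_retain_pair(
    read1: str,
    read2: str,
    adapters: Sequence[str],
    min_length: int = 100,
) -> Optional[tuple[str, str]]:
    """Adapter-trim both mates; keep the pair only if both stay >= min_length.

    Returns the trimmed pair, or None when the pair is dropped.
    """
    t1 = trim_adapter(read1, adapters)
    t2 = trim_adapter(read2, adapters)
    if len(t1) >= min_length and len(t2) >= min_length:
        return t1, t2
    return None


def classify_proper_pair(
    aln1: MappedMate,
    aln2: MappedMate,
    max_distance: int = 2000,
) -> tuple[bool, Optional[str]]:
    """Classify a mapped pair as proper or improper.

    Proper means: both mates mapped to the same chromosome, inner distance
    at most ``max_distance``, convergent (forward/reverse facing inward)
    orientation, and the read-2 structure flag (restriction site present)
    set.  Returns (is_proper, reason-if-not).
    """
    if not (aln1.mapped and aln2.mapped):
        return False, "unmapped_mate"
    if aln1.chrom != aln2.chrom:
        return False, "different_chrom"
    if aln1.strand == aln2.strand:
        return False, "orientation"
    fwd, rev = (aln1, aln2) if aln1.strand == "+" else (aln2, aln1)
    if fwd.start > rev.start:
        return False, "orientation"
    inner = rev.start - fwd.end
    if inner > max_distance:
        return False, "too_far"
    if not aln2.structure_ok:
        return False, "structure"
    return True, None


def demux_fastq(
    read1_path: str,
    read2_path: str,
    layout: ReadLayout,
    out1_path: str,
    out2_path: str,
    whitelist: Optional[BarcodeWhitelist] = None,
    rescue: bool = False,
) -> dict[str, int]:
    """Demultiplex a FASTQ pair, appending ``|barcode|tag`` to read IDs.

    Only structure-valid pairs are written.  Returns stage counters
    (pairs in, passed, and failure reasons) for the run manifest.
    """
    import pysam

    counters: dict[str, int] = {"pairs_in": 0, "passed": 0}
    source_is_r2 = layout.source_read == "read2"
    with pysam.FastxFile(read1_path) as f1, pysam.FastxFile(read2_path) as f2, open(
        out1_path, "w"
    ) as o1, open(out2_path, "w") as o2:
        for r1, r2 in zip(f1, f2):
            counters["pairs_in"] += 1
            source = r2.sequence if source_is_r2 else r1.sequence
            ext = validate_read(source, layout, whitelist=whitelist, rescue=rescue)
            if not ext.ok:
                key = f"fail_{ext.reason}"
                counters[key] = counters.get(key, 0) + 1
                continue
            counters["passed"] += 1
            new_id = f"{r1.name}|{ext.bag_barcode}|{ext.varietal_tag}"
            q1 = r1.quality or "I" * len(r1.sequence)
            q2 = r2.quality or "I" * len(r2.sequence)
            o1.write(f"@{new_id}\n{r1.sequence}\n+\n{q1}\n")
            o2.write(f"@{new_id}\n{r2.sequence}\n+\n{q2}\n")
    return counters
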