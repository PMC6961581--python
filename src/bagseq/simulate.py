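"""Synthetic BAG libraries with complete ground truth.

Everything the pipeline consumes can be generated here at desk scale: a toy
genome, clone-specific copy-number states, two-source SNV genotypes,
split-pool barcode/tag read structure (byte-exact against the positional
layouts), empty-droplet background barcodes, and the two error processes
the consensus method distinguishes — template damage (shared by all reads
of a template, introduced before amplification) and per-read sequencing
error (independent across reads).

Every generator takes a mandatory seed and is byte-reproducible.  The
ground-truth tables make extraction a checkable left inverse: whatever the
pipeline recovers can be compared field-by-field with what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .layouts import LAYOUTS, BarcodeWhitelist, Protocol, ReadLayout

__all__ = [
    "CloneSpec",
    "SimConfig",
    "SimulatedLibrary",
    "random_genome",
    "capture_sites",
    "simulate_library",
    "simulate_barcode_rank",
    "simulate_error_pileups",
    "simulate_identity_observations",
    "synthesize_structured_read",
    "default_dna_config",
    "default_rna_config",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_kmers(rng: np.random.Generator, n: int, k: int, distinct: bool = False) -> list[str]:
    out: list[str] = []
    seen = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n, k))
        for row in draw:
            s = b"".join(_BASES[row]).decode()
            if distinct:
                if s in seen:
                    continue
                seen.add(s)
            out.append(s)
            if len(out) == n:
                break
    return out


def random_genome(chrom_lengths: Mapping[str, int], seed: int) -> dict[str, str]:
    """Uniform-random ACGT genome with the given chromosome lengths."""
    rng = np.random.default_rng(seed)
    genome = {}
    for chrom, length in chrom_lengths.items():
        arr = _BASES[rng.integers(0, 4, size=length)]
        genome[chrom] = arr.tobytes().decode()
    return genome


def capture_sites(genome: Mapping[str, str], motif: str = "CATG") -> dict[str, np.ndarray]:
    """Positions of the restriction motif (template capture sites) per chromosome."""
    sites = {}
    for chrom, seq in genome.items():
        pos, found = [], seq.find(motif)
        while found != -1:
            pos.append(found)
            found = seq.find(motif, found + 1)
        sites[chrom] = np.asarray(pos, dtype=int)
    return sites


@dataclass(frozen=True)
class CloneSpec:
    """One clone: mixture fraction and integer copy-number state by interval.

    ``cn`` lists (chrom, start, end, state) in 0-based half-open
    coordinates; everything not covered defaults to ``baseline``.
    """

    name: str
    fraction: float
    cn: tuple = ()
    baseline: int = 2

    def states_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        out = np.full(len(positions), self.baseline, dtype=float)
        for c, s, e, st in self.cn:
            if c == chrom:
                out[(positions >= s) & (positions < e)] = st
        return out


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    seed: int
    protocol: Protocol = Protocol.DNA
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 800_000}
    )
    clones: tuple = (CloneSpec("cloneA", 1.0),)
    n_cells: int = 24
    templates_per_cell: int = 20_000
    reads_per_template_p: float = 2.0 / 7.0  # geometric; mean 3.5 reads/template
    barcodes_per_round: int = 96
    unique_cell_barcodes: bool = True
    n_background_barcodes: int = 0
    background_templates_mean: float = 50.0
    # RNA-specific
    n_genes: int = 40
    n_marker_genes: int = 8
    marker_fold: float = 8.0
    n_panel_sites: int = 60
    sources: tuple = ("SKN1", "SKBR3")
    contamination: float = 0.0
    n_doublets: int = 0
    read_length: int = 76
    # error processes (0 = noiseless)
    read_error_rate: float = 0.0
    damage_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.read_error_rate <= 1 or not 0 <= self.damage_rate <= 1:
            raise ValueError("error rates must lie in [0, 1]")
        if self.protocol == Protocol.DNA and len(self.clones) > self.n_cells:
            raise ValueError("more clones than cells")


def default_dna_config(seed: int) -> SimConfig:
    """Desk-scale DNA preset: 2-Mb genome, two clones with distinct CNVs."""
    clones = (
        CloneSpec(
            "cloneA",
            0.6,
            cn=(("chr1", 100_000, 500_000, 3), ("chr2", 200_000, 600_000, 1)),
        ),
        CloneSpec(
            "cloneB",
            0.4,
            cn=(("chr1", 700_000, 1_100_000, 4), ("chr2", 0, 300_000, 1)),
        ),
    )
    return SimConfig(
        seed=seed,
        protocol=Protocol.DNA,
        clones=clones,
        n_cells=24,
        n_background_barcodes=300,
    )


def default_rna_config(seed: int) -> SimConfig:
    """Desk-scale RNA preset: two sources, marker genes, SNV panel."""
    return SimConfig(
        seed=seed,
        protocol=Protocol.RNA_2SPLIT_B,
        n_cells=60,
        templates_per_cell=1500,
        contamination=0.0,
        n_doublets=0,
        n_background_barcodes=200,
        background_templates_mean=30.0,
    )


@dataclass
class SimulatedLibrary:
    """A generated library plus every ground-truth table."""

    config: SimConfig
    genome: dict[str, str]
    layout: ReadLayout
    whitelist: Optional[BarcodeWhitelist]
    cells: pd.DataFrame       # cell, bag, clone/source, is_doublet
    templates: pd.DataFrame   # bag, tag, chrom, pos, strand, depth (+gene for RNA)
    reads: pd.DataFrame       # one row per read pair: read_id + template key
    exon_model: Optional[object] = None
    panel: Optional[object] = None
    site_observations: Optional[pd.DataFrame] = None  # template pileups at panel sites
    clone_states: Optional[pd.DataFrame] = None       # per capture site true state per clone

    def mapped_reads(self) -> pd.DataFrame:
        """Pre-mapped annotated reads (bypasses the external aligner)."""
        return self.reads

    def barcode_read_counts(self) -> dict[str, int]:
        return self.reads.groupby("bag", observed=True).size().to_dict()

    def expression_truth(self) -> pd.DataFrame:
        """Planted genes x cells template counts (RNA libraries).

        The counting unit is a distinct (tag, gene) pair per cell, matching
        the pipeline's rule that reads of one tag within a gene collapse to
        one template.
        """
        if "gene" not in self.templates.columns:
            raise ValueError("not an RNA library")
        t = self.templates.dropna(subset=["gene"])
        return (
            t.drop_duplicates(["bag", "tag", "gene"])
            .groupby(["gene", "bag"], observed=True)
            .size()
            .unstack(fill_value=0)
        )

    def to_fastq(self, path1: str, path2: str) -> None:
        """Write the library as a FASTQ pair with exact positional layouts."""
        rng = np.random.default_rng(self.config.seed + 7)
        structural_on_r2 = self.layout.source_read == "read2"
        with open(path1, "w") as o1, open(path2, "w") as o2:
            for row in self.reads.itertuples(index=False):
                insert = _genomic_insert(
                    self.genome, row.chrom, row.pos, row.strand, 100, structural_on_r2
                )
                parts = _split_barcode(row.bag, self.layout)
                structured = synthesize_structured_read(
                    self.layout, parts, row.tag, insert, rng
                )
                mate = _genomic_insert(
                    self.genome, row.chrom, row.pos, row.strand, 120, not structural_on_r2
                )
                r1, r2 = (mate, structured) if structural_on_r2 else (structured, mate)
                o1.write(f"@{row.read_id}\n{r1}\n+\n{'I' * len(r1)}\n")
                o2.write(f"@{row.read_id}\n{r2}\n+\n{'I' * len(r2)}\n")


_RC = str.maketrans("ACGT", "TGCA")


def _genomic_insert(
    genome: Mapping[str, str], chrom: str, pos: int, strand: str, length: int, downstream: bool
) -> str:
    seq = genome[chrom]
    if strand == "+":
        s = seq[pos : pos + length] if downstream else seq[max(pos - length, 0) : pos]
    else:
        frag = (
            seq[max(pos - length, 0) : pos] if downstream else seq[pos : pos + length]
        )
        s = frag.translate(_RC)[::-1]
    return (s + "A" * length)[:length]


def _split_barcode(bag: str, layout: ReadLayout) -> list[str]:
    parts, at = [], 0
    for s, e in layout.barcode_ranges:
        n = e - s + 1
        parts.append(bag[at : at + n])
        at += n
    return parts


def synthesize_structured_read(
    layout: ReadLayout,
    barcode_parts: Sequence[str],
    tag: str,
    insert: str,
    rng: np.random.Generator,
    anchor_mismatches: int = 0,
) -> str:
    """Build a read obeying a positional layout, byte-exact.

    Unspecified positions (linkers) are random bases; ``anchor_mismatches``
    plants that many mismatches into the first anchor (for testing mismatch
    allowances).
    """
    n = layout.min_length
    arr = list(b"".join(_BASES[rng.integers(0, 4, size=n)]).decode())
    for (s, e), part in zip(layout.barcode_ranges, barcode_parts):
        arr[s - 1 : e] = list(part)
    at = 0
    for s, e in layout.tag_ranges:
        k = e - s + 1
        arr[s - 1 : e] = list(tag[at : at + k])
        at += k
    for a_i, anchor in enumerate(layout.anchors):
        seq = list(anchor.sequence)
        if a_i == 0 and anchor_mismatches:
            idx = rng.choice(len(seq), size=anchor_mismatches, replace=False)
            for i in idx:
                seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        arr[anchor.start - 1 : anchor.end] = seq
    return "".join(arr) + insert


# ---------------------------------------------------------------------------
# library generation


def _make_whitelist(layout: ReadLayout, per_round: int, rng: np.random.Generator) -> BarcodeWhitelist:
    rounds = []
    for s, e in layout.barcode_ranges:
        k = e - s + 1
        rounds.append(_random_kmers(rng, per_round, k, distinct=True))
    # BarcodeWhitelist validates 6-mers; DNA layouts carry a 5-base slice, so
    # whitelists are only built for whitelist-checked layouts (always 6-mers)
    return BarcodeWhitelist(rounds)


def _assign_cell_barcodes(
    layout: ReadLayout,
    n_cells: int,
    per_round: int,
    unique: bool,
    rng: np.random.Generator,
) -> tuple[list[str], list[list[str]]]:
    rounds = [
        _random_kmers(rng, per_round, e - s + 1, distinct=True)
        for s, e in layout.barcode_ranges
    ]
    space = per_round ** len(rounds)
    if unique and n_cells > space:
        raise ValueError("barcode space too small for unique assignment")
    bags, seen = [], set()
    while len(bags) < n_cells:
        bag = "".join(r[rng.integers(len(r))] for r in rounds)
        if unique and bag in seen:
            continue
        seen.add(bag)
        bags.append(bag)
    return bags, rounds


def simulate_library(config: SimConfig) -> SimulatedLibrary:
    """Generate a full library for the configured protocol."""
    if config.protocol == Protocol.DNA:
        return _simulate_dna(config)
    return _simulate_rna(config)


def _simulate_dna(config: SimConfig) -> SimulatedLibrary:
    rng = np.random.default_rng(config.seed)
    genome = random_genome(config.chrom_lengths, config.seed + 1)
    layout = LAYOUTS[Protocol.DNA]
    sites = capture_sites(genome)
    chroms = list(sites)
    flat_chrom = np.concatenate(
        [np.full(len(sites[c]), i) for i, c in enumerate(chroms)]
    )
    flat_pos = np.concatenate([sites[c] for c in chroms])
    n_sites = len(flat_pos)

    fractions = np.array([c.fraction for c in config.clones], dtype=float)
    fractions /= fractions.sum()
    clone_of_cell = rng.choice(len(config.clones), size=config.n_cells, p=fractions)
    # every clone gets at least one cell
    for k in range(len(config.clones)):
        if not np.any(clone_of_cell == k):
            clone_of_cell[k % config.n_cells] = k

    bags, _ = _assign_cell_barcodes(
        layout, config.n_cells, config.barcodes_per_round, config.unique_cell_barcodes, rng
    )
    tag_len = layout.tag_length

    state_rows = []
    weights_by_clone = []
    for clone in config.clones:
        w = np.concatenate(
            [clone.states_at(c, sites[c]) for c in chroms]
        )
        weights_by_clone.append(w / w.sum())
        state_rows.append(w)
    clone_states = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in flat_chrom],
            "pos": flat_pos,
            **{c.name: s for c, s in zip(config.clones, state_rows)},
        }
    )

    cell_rows, template_frames = [], []
    for cell_idx in range(config.n_cells):
        clone = config.clones[clone_of_cell[cell_idx]]
        bag = bags[cell_idx]
        cell_rows.append(
            {"cell": f"cell{cell_idx:03d}", "bag": bag, "clone": clone.name, "is_doublet": False}
        )
        idx = rng.choice(n_sites, size=config.templates_per_cell, p=weights_by_clone[clone_of_cell[cell_idx]])
        strands = np.where(rng.random(config.templates_per_cell) < 0.5, "+", "-")
        tags = _random_kmers(rng, config.templates_per_cell, tag_len)
        df = pd.DataFrame(
            {
                "bag": bag,
                "tag": tags,
                "chrom": [chroms[i] for i in flat_chrom[idx]],
                "pos": flat_pos[idx],
                "strand": strands,
            }
        ).drop_duplicates(["tag", "chrom", "pos", "strand"])
        df["depth"] = rng.geometric(config.reads_per_template_p, size=len(df))
        df["cell"] = f"cell{cell_idx:03d}"
        template_frames.append(df)

    # empty-droplet background barcodes: few templates, depth 1
    for b in range(config.n_background_barcodes):
        bag = "".join(_random_kmers(rng, 1, layout.barcode_length))
        n_t = max(1, int(rng.poisson(config.background_templates_mean)))
        idx = rng.integers(0, n_sites, size=n_t)
        template_frames.append(
            pd.DataFrame(
                {
                    "bag": bag,
                    "tag": _random_kmers(rng, n_t, tag_len),
                    "chrom": [chroms[i] for i in flat_chrom[idx]],
                    "pos": flat_pos[idx],
                    "strand": "+",
                    "depth": 1,
                    "cell": f"background{b:04d}",
                }
            )
        )

    templates = pd.concat(template_frames, ignore_index=True)
    reads = templates.loc[templates.index.repeat(templates["depth"])].reset_index(drop=True)
    reads["read_id"] = [f"read{i:08d}" for i in range(len(reads))]
    reads = reads.drop(columns=["depth"])

    return SimulatedLibrary(
        config=config,
        genome=genome,
        layout=layout,
        whitelist=None,
        cells=pd.DataFrame(cell_rows),
        templates=templates,
        reads=reads,
        clone_states=clone_states,
    )


def _build_exon_model(config: SimConfig, genome: Mapping[str, str]):
    """Tile genes along the genome: two exons separated by an intron."""
    from .expression import ExonModel

    exon, intron, gap = 400, 300, 400
    span = 2 * exon + intron + gap
    rows = []
    g = 0
    for chrom, length in config.chrom_lengths.items():
        start = 1000
        while start + span < length and g < config.n_genes:
            rows.append(
                {
                    "gene": f"gene{g:03d}",
                    "transcript": f"gene{g:03d}.t1",
                    "chrom": chrom,
                    "strand": "+",
                    "exons": [(start, start + exon), (start + exon + intron, start + 2 * exon + intron)],
                }
            )
            start += span
            g += 1
    if g < config.n_genes:
        raise ValueError("genome too small for requested gene count")
    return ExonModel(pd.DataFrame(rows))


def _simulate_rna(config: SimConfig) -> SimulatedLibrary:
    from .identity import SnvPanel

    rng = np.random.default_rng(config.seed)
    genome = random_genome(config.chrom_lengths, config.seed + 1)
    layout = LAYOUTS[config.protocol]
    whitelist = _make_whitelist(layout, config.barcodes_per_round, rng) if layout.whitelist_checked else None
    model = _build_exon_model(config, genome)
    genes = model.genes
    G = len(genes)
    src_a, src_b = config.sources

    # expression profiles: first n_marker_genes favor source A, next favor B
    base = np.ones(G)
    expr = {src_a: base.copy(), src_b: base.copy()}
    expr[src_a][: config.n_marker_genes] *= config.marker_fold
    expr[src_b][config.n_marker_genes : 2 * config.n_marker_genes] *= config.marker_fold
    for v in expr.values():
        v /= v.sum()

    # source-specific SNV panel: sites inside exons, alternating source
    exon_spans = []
    for t in model.transcripts.itertuples(index=False):
        for s, e in t.exons:
            exon_spans.append((t.chrom, s, e))
    panel_rows = []
    chosen = set()
    while len(panel_rows) < config.n_panel_sites:
        chrom, s, e = exon_spans[rng.integers(len(exon_spans))]
        pos = int(rng.integers(s + 5, e - 5))
        if (chrom, pos) in chosen:
            continue
        chosen.add((chrom, pos))
        ref = genome[chrom][pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        source = config.sources[len(panel_rows) % 2]
        panel_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "source": source})
    panel = SnvPanel(pd.DataFrame(panel_rows))

    # cells: even split between sources; barcodes drawn with replacement so
    # collisions occur at the natural occupancy rate unless disabled
    bags, _ = _assign_cell_barcodes(
        layout, config.n_cells, config.barcodes_per_round, config.unique_cell_barcodes, rng
    )
    source_of_cell = [config.sources[i % 2] for i in range(config.n_cells)]
    doublet_idx = set(rng.choice(config.n_cells, size=config.n_doublets, replace=False)) if config.n_doublets else set()

    gene_info = model.transcripts.set_index("gene")
    exons_of_gene = [gene_info.loc[g, "exons"] for g in genes]
    chrom_of_gene = [gene_info.loc[g, "chrom"] for g in genes]
    cell_rows, template_frames, obs_frames = [], [], []
    panel_df = panel.sites
    for cell_idx in range(config.n_cells):
        bag = bags[cell_idx]
        source = source_of_cell[cell_idx]
        is_doublet = cell_idx in doublet_idx
        cell_rows.append(
            {"cell": f"cell{cell_idx:03d}", "bag": bag, "source": source, "is_doublet": is_doublet}
        )
        T = config.templates_per_cell
        # template origin: own source, other source (contamination), or a
        # 50/50 mixture for doublets
        other = src_b if source == src_a else src_a
        if is_doublet:
            origins = np.where(rng.random(T) < 0.5, source, other)
        else:
            origins = np.where(rng.random(T) < config.contamination, other, source)
        gene_idx = np.empty(T, dtype=int)
        for s in (src_a, src_b):
            m = origins == s
            gene_idx[m] = rng.choice(G, size=int(m.sum()), p=expr[s])
        # position uniform within a random exon (read fits inside the exon)
        pos = np.empty(T, dtype=int)
        chrom_arr = np.empty(T, dtype=object)
        exon_pick = rng.integers(2, size=T)
        for i, gi in enumerate(gene_idx):
            es, ee = exons_of_gene[gi][exon_pick[i]]
            pos[i] = rng.integers(es, ee - config.read_length)
            chrom_arr[i] = chrom_of_gene[gi]
        tags = _random_kmers(rng, T, layout.tag_length)
        df = pd.DataFrame(
            {
                "bag": bag,
                "tag": tags,
                "chrom": chrom_arr,
                "pos": pos,
                "strand": "+",
                "gene": [genes[i] for i in gene_idx],
                "origin": origins,
            }
        ).drop_duplicates(["tag", "chrom", "pos", "strand"])
        df["depth"] = 1 + rng.geometric(0.5, size=len(df))  # >= 2 reads: consensus-callable
        df["cell"] = f"cell{cell_idx:03d}"
        template_frames.append(df)

        # template pileups at covered panel sites (reference-frame bases)
        cov = df.merge(panel_df, on="chrom", suffixes=("", "_site"))
        cov = cov[(cov["pos_site"] >= cov["pos"]) & (cov["pos_site"] < cov["pos"] + config.read_length)]
        if len(cov):
            call = np.where(cov["origin"] == cov["source"], cov["alt"], cov["ref"])
            obs_frames.append(
                pd.DataFrame(
                    {
                        "bag": bag,
                        "tag": cov["tag"].to_numpy(),
                        "chrom": cov["chrom"].to_numpy(),
                        "pos": cov["pos_site"].to_numpy(),
                        "strand": "+",
                        "bases": [c * d for c, d in zip(call, cov["depth"])],
                    }
                )
            )

    # ambient background barcodes (empty droplets): sparse, depth 1
    all_chroms = list(config.chrom_lengths)
    for b in range(config.n_background_barcodes):
        bag = "".join(_random_kmers(rng, 1, layout.barcode_length))
        n_t = max(1, int(rng.poisson(config.background_templates_mean)))
        bchrom = [all_chroms[i] for i in rng.integers(0, len(all_chroms), size=n_t)]
        bpos = [int(rng.integers(0, config.chrom_lengths[c] - config.read_length)) for c in bchrom]
        template_frames.append(
            pd.DataFrame(
                {
                    "bag": bag,
                    "tag": _random_kmers(rng, n_t, layout.tag_length),
                    "chrom": bchrom,
                    "pos": bpos,
                    "strand": "+",
                    "gene": None,
                    "origin": None,
                    "depth": 1,
                    "cell": f"background{b:04d}",
                }
            )
        )

    templates = pd.concat(template_frames, ignore_index=True)
    reads = templates.loc[templates.index.repeat(templates["depth"])].reset_index(drop=True)
    reads["read_id"] = [f"read{i:08d}" for i in range(len(reads))]
    reads = reads.drop(columns=["depth"])
    observations = (
        pd.concat(obs_frames, ignore_index=True) if obs_frames else pd.DataFrame()
    )

    return SimulatedLibrary(
        config=config,
        genome=genome,
        layout=layout,
        whitelist=whitelist,
        cells=pd.DataFrame(cell_rows),
        templates=templates,
        reads=reads,
        exon_model=model,
        panel=panel,
        site_observations=observations,
    )


# ---------------------------------------------------------------------------
# focused generators


def simulate_barcode_rank(
    seed: int,
    n_cells: int = 88,
    n_background: int = 9000,
    cell_mean: float = 1e6,
    background_mean: float = 1e3,
) -> pd.DataFrame:
    """Barcode count table with planted cells and empty-droplet background.

    Counts are Poisson around the respective means; the defaults emulate the
    scale at which 88 cell barcodes dominate ~9000 ambient barcodes.
    Returns columns barcode, count, is_cell.
    """
    rng = np.random.default_rng(seed)
    counts = np.concatenate(
        [
            rng.poisson(cell_mean, size=n_cells),
            rng.poisson(background_mean, size=n_background),
        ]
    )
    return pd.DataFrame(
        {
            "barcode": [f"BC{i:06d}" for i in range(n_cells + n_background)],
            "count": counts,
            "is_cell": [True] * n_cells + [False] * n_background,
        }
    )


def simulate_error_pileups(
    seed: int,
    n_templates: int = 100_000,
    genome_length: int = 30_000,
    read_error_rate: float | Mapping[str, float] = 0.0,
    damage_rate: float | Mapping[str, float] = 0.0,
    depth_geometric_p: float = 0.5,
    n_bags: int = 8,
):
    """Template pileups over a donor truth mask with planted error processes.

    ``read_error_rate`` / ``damage_rate`` may be scalars or per-context
    (trinucleotide -> rate) mappings.  Damage mutates the template before
    amplification (shared by all member reads); read errors are independent
    per read.  Returns (pileups DataFrame, DonorTruthMask).
    """
    from .errors import DonorTruthMask

    rng = np.random.default_rng(seed)
    genome = random_genome({"chrS": genome_length}, seed + 1)
    mask = DonorTruthMask.from_genome(genome)
    sites = mask.sites

    def rate_for(contexts: np.ndarray, spec) -> np.ndarray:
        if isinstance(spec, Mapping):
            return np.array([spec.get(c, 0.0) for c in contexts])
        return np.full(len(contexts), float(spec))

    idx = rng.integers(0, len(sites), size=n_templates)
    chrom = sites["chrom"].to_numpy()[idx]
    pos = sites["pos"].to_numpy()[idx]
    ref = sites["ref"].to_numpy()[idx]
    ctx = sites["context"].to_numpy()[idx]
    depth = 1 + rng.geometric(depth_geometric_p, size=n_templates)
    bag = np.array([f"bag{i:02d}" for i in rng.integers(0, n_bags, size=n_templates)])
    tags = _random_kmers(rng, n_templates, 6)
    strand = np.where(rng.random(n_templates) < 0.5, "+", "-")

    alts = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    template_base = ref.copy()
    damaged = rng.random(n_templates) < rate_for(ctx, damage_rate)
    for i in np.nonzero(damaged)[0]:
        template_base[i] = alts[ref[i]][rng.integers(3)]

    err_rate = rate_for(ctx, read_error_rate)
    bases = []
    for i in range(n_templates):
        d = depth[i]
        calls = [template_base[i]] * d
        if err_rate[i] > 0:
            flip = rng.random(d) < err_rate[i]
            for j in np.nonzero(flip)[0]:
                calls[j] = alts[calls[j]][rng.integers(3)]
        bases.append("".join(calls))

    pileups = pd.DataFrame(
        {
            "bag": bag,
            "tag": tags,
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "bases": bases,
            "true_damaged": damaged,
        }
    )
    return pileups, mask


def simulate_identity_observations(
    seed: int,
    n_cells: int = 200,
    obs_per_cell: int = 1000,
    contamination: float = 0.005,
    n_doublets: int = 0,
    sources: tuple[str, str] = ("SKN1", "SKBR3"),
):
    """Per-BAG informative SNV observations with planted contamination.

    Each cell yields ``obs_per_cell`` informative template observations;
    each is drawn from the cell's own genome with probability
    1 - contamination, otherwise from the other source.  Doublet cells draw
    50/50.  Returns (observations DataFrame compatible with
    :func:`bagseq.identity.assign_identity`, panel, truth DataFrame).
    """
    from .identity import SnvPanel

    rng = np.random.default_rng(seed)
    n_sites = 400
    rows = []
    for i in range(n_sites):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        rows.append(
            {"chrom": "chrS", "pos": 100 * (i + 1), "ref": ref, "alt": alt,
             "source": sources[i % 2]}
        )
    panel = SnvPanel(pd.DataFrame(rows))
    by_source = {s: panel.sites[panel.sites["source"] == s] for s in sources}

    doublets = set(rng.choice(n_cells, size=n_doublets, replace=False)) if n_doublets else set()
    obs_frames, truth_rows = [], []
    for c in range(n_cells):
        own = sources[c % 2]
        other = sources[(c + 1) % 2]
        p_other = 0.5 if c in doublets else contamination
        n_other = int(rng.binomial(obs_per_cell, p_other))
        truth_rows.append(
            {"bag": f"bag{c:04d}", "source": own, "is_doublet": c in doublets,
             "true_minority": n_other / obs_per_cell}
        )
        for src, n in ((own, obs_per_cell - n_other), (other, n_other)):
            if n == 0:
                continue
            sites = by_source[src].sample(n=n, replace=True, random_state=int(rng.integers(2**31)))
            obs_frames.append(
                pd.DataFrame(
                    {
                        "bag": f"bag{c:04d}",
                        "chrom": sites["chrom"].to_numpy(),
                        "pos": sites["pos"].to_numpy(),
                        "call": sites["alt"].to_numpy(),
                    }
                )
            )
    observations = pd.concat(obs_frames, ignore_index=True)
    return observations, panel, pd.DataFrame(truth_rows)
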