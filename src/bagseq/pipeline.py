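"""End-to-end orchestration with provenance logging.

``run_dna`` takes annotated mapped reads (from demultiplexing + an external
aligner, or pre-mapped synthetic data) through cell calling, template
collapse, empirical binning, normalization, segmentation, ploidy scaling,
and clustering.  ``run_rna`` runs the expression/identity arm: template
collapse, gene counting, source assignment, and PCA.

Each run emits a :class:`RunManifest` carrying the configuration hash, the
seeds, and per-stage counters, sufficient to reproduce the run and to
assert read conservation across stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import cellcalling, cnv, expression, identity, templates
from .cnv import BinScheme, CopyNumberProfile, SegmentationParams

__all__ = ["PipelineConfig", "RunManifest", "DnaRunResult", "RnaRunResult", "run_dna", "run_rna"]

#: HISAT2 parameters recorded for real-data runs (the aligner is external;
#: synthetic data arrives pre-mapped)
DNA_ALIGNER_ARGS = ("-3", "25", "-X", "2000", "--no-spliced-alignment")


@dataclass
class PipelineConfig:
    seed: int = 1
    n_bins: int = 120
    min_unique_tags: int = 100_000  # DNA profile admission (desk presets lower it)
    min_rna_tags: int = 5000        # RNA identity admission
    lowess_frac: float = 0.05
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    mixed_band: tuple = (0.15, 0.85)
    read_length: int = 100

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    counters: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def log(self, stage: str, **counts: int) -> None:
        self.stages.append(stage)
        for k, v in counts.items():
            self.counters[f"{stage}.{k}"] = int(v)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stages": self.stages,
                "counters": self.counters,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class DnaRunResult:
    bins: BinScheme
    profiles: list[CopyNumberProfile]
    segment_matrix: pd.DataFrame  # BAGs x bins (ploidy-scaled)
    linkage: Optional[np.ndarray]
    leaf_order: Optional[list]
    stats: pd.DataFrame
    manifest: RunManifest


@dataclass
class RnaRunResult:
    matrix: pd.DataFrame  # genes x cells
    identity_calls: Optional[pd.DataFrame]
    pca: Optional[expression.PcaResult]
    manifest: RunManifest


def _select_cells(reads: pd.DataFrame, manifest: RunManifest) -> pd.DataFrame:
    counts = reads.groupby("bag", observed=True).size().to_dict()
    called = cellcalling.call_cells(counts)
    if not called.selected:
        raise RuntimeError(f"cell calling failed: {called.diagnostic}")
    kept = reads[reads["bag"].isin(called.selected)]
    manifest.log(
        "cell_calling",
        barcodes_in=len(counts),
        cells_selected=len(called.selected),
        reads_in=len(reads),
        reads_kept=len(kept),
        reads_dropped=len(reads) - len(kept),
    )
    return kept


def run_dna(
    reads: pd.DataFrame,
    genome: Mapping[str, str],
    config: PipelineConfig,
) -> DnaRunResult:
    """DNA arm: mapped annotated reads -> clustered copy-number profiles.

    ``reads`` columns: bag, tag, chrom, pos, strand (0-based positions).
    """
    if len(reads) == 0:
        raise ValueError("empty input: no mapped reads")
    manifest = RunManifest(config.content_hash(), config.seed)
    manifest.log("input", reads=len(reads))

    kept = _select_cells(reads, manifest)
    tmpl = templates.collapse_templates(kept)
    manifest.log("collapse", templates=len(tmpl), reads=int(tmpl["size"].sum()))

    # empirical bins from the pooled distinct capture positions of all cells
    pooled = {
        chrom: np.unique(grp["pos"].to_numpy())
        for chrom, grp in tmpl.groupby("chrom", observed=True)
    }
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    scheme = cnv.build_empirical_bins(
        pooled, config.n_bins, genome=genome, chrom_lengths=chrom_lengths
    )
    manifest.log("binning", bins=len(scheme))

    genome_size = sum(chrom_lengths.values())
    stats = templates.bag_stats(kept, genome_size, config.read_length)

    profiles: list[CopyNumberProfile] = []
    rows = {}
    n_skipped = 0
    for bag, grp in tmpl.groupby("bag", observed=True):
        if len(grp) < config.min_unique_tags:
            n_skipped += 1
            continue
        positions = {c: g["pos"].to_numpy() for c, g in grp.groupby("chrom", observed=True)}
        counts = cnv.count_bins(positions, scheme)
        norm = cnv.normalize_profile(counts, scheme.bins["gc"].to_numpy(), config.lowess_frac)
        seg, bps = cnv.segment_profile(norm, config.segmentation)
        lengths = (scheme.bins["end"] - scheme.bins["start"]).to_numpy(dtype=float)
        ploidy, scaled = cnv.estimate_ploidy(seg, weights=lengths)
        profiles.append(
            CopyNumberProfile(
                bag=bag, bincounts=counts, normalized=norm, segments=seg,
                breakpoints=bps, ploidy=ploidy, scaled=scaled,
            )
        )
        rows[bag] = scaled
    manifest.log("profiles", profiles=len(profiles), skipped_low_tags=n_skipped)
    if not profiles:
        raise RuntimeError("no BAG passed the unique-tag threshold")

    segment_matrix = pd.DataFrame.from_dict(rows, orient="index")
    linkage = leaf_order = None
    if len(profiles) >= 2:
        linkage, leaf_order = cnv.cluster_profiles(segment_matrix)
    manifest.log("cluster", profiles=len(segment_matrix))

    return DnaRunResult(scheme, profiles, segment_matrix, linkage, leaf_order, stats, manifest)


def run_rna(
    reads: pd.DataFrame,
    exon_model: expression.ExonModel,
    config: PipelineConfig,
    panel: Optional[identity.SnvPanel] = None,
    site_observations: Optional[pd.DataFrame] = None,
    read_length: int = 76,
) -> RnaRunResult:
    """RNA arm: mapped annotated reads -> expression matrix, identity, PCA.

    ``site_observations`` are template pileups at panel sites (columns bag,
    tag, chrom, pos, strand, bases); identity is called from their consensus
    when both a panel and observations are provided.
    """
    if len(reads) == 0:
        raise ValueError("empty input: no mapped reads")
    manifest = RunManifest(config.content_hash(), config.seed)
    manifest.log("input", reads=len(reads))

    kept = _select_cells(reads, manifest)
    tmpl = templates.collapse_templates(kept)
    manifest.log("collapse", templates=len(tmpl))

    matrix = expression.count_expression(
        tmpl.rename(columns={"size": "reads"}), exon_model, mode="singlecell", read_length=read_length
    )
    manifest.log("expression", genes=matrix.shape[0], cells=matrix.shape[1])

    identity_calls = None
    if panel is not None and site_observations is not None and len(site_observations):
        from .errors import consensus_table

        obs = consensus_table(site_observations)
        obs = obs[obs["bag"].isin(set(kept["bag"]))]
        tag_counts = tmpl.groupby("bag", observed=True).size()
        calls = identity.assign_identity(
            obs, panel, mixed_band=config.mixed_band, min_templates=0
        )
        # RNA admission: drop BAGs under the unique-tag threshold
        calls = [c for c in calls if tag_counts.get(c.bag, 0) >= config.min_rna_tags]
        identity_calls = identity.identity_table(calls)
        manifest.log(
            "identity",
            bags=len(identity_calls),
            mixed=int((identity_calls["label"] == "MIXED").sum()) if len(identity_calls) else 0,
        )

    pca = None
    if matrix.shape[1] >= 3:
        pca = expression.pca_and_markers(matrix)
        manifest.log("pca", components=pca.coordinates.shape[1])

    return RnaRunResult(matrix, identity_calls, pca, manifest)
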