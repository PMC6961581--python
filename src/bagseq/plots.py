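"""Diagnostic plots: barcode-rank curve, genome profiles, CNV heatmap."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnv import DISPLAY_GUIDES


def barcode_rank_plot(curve, knee_index=None, path=None):
    """Cumulative barcode-count fraction vs. rank, with the knee marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    n = len(curve.barcodes)
    ax.plot(np.arange(1, n + 1), curve.cumulative_fraction, lw=1.5)
    if knee_index:
        ax.axvline(knee_index, color="crimson", ls="--", lw=1, label=f"knee = {knee_index}")
        ax.legend()
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("cumulative count fraction")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def genome_profile_plot(profile, path=None, log_display=False):
    """Per-bin scaled copy number along the genome for one BAG.

    With ``log_display`` the y axis is log(y + 1) with guide lines at the
    standard copy-number levels, for high-amplitude profiles.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    y = profile.ploidy * profile.normalized
    seg = profile.scaled
    if log_display:
        y, seg = np.log1p(y), np.log1p(seg)
        for g in DISPLAY_GUIDES:
            ax.axhline(np.log1p(g), color="grey", lw=0.5, alpha=0.5)
    ax.plot(y, ".", ms=2, alpha=0.5)
    ax.plot(seg, lw=1.5, color="crimson")
    ax.set_xlabel("bin")
    ax.set_ylabel("copy number" if not log_display else "log(copy number + 1)")
    ax.set_title(profile.bag)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def cnv_heatmap(segment_matrix: pd.DataFrame, leaf_order, path=None):
    """Profiles-by-bins heatmap in dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = segment_matrix.loc[leaf_order]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.2 * len(ordered))))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=0, vmax=4)
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels(ordered.index, fontsize=5)
    ax.set_xlabel("bin")
    fig.colorbar(im, ax=ax, label="copy number")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
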