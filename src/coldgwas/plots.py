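"""Manhattan plots for the SNP, haplotype and selection scans."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan(
    track: pd.DataFrame,
    p_col: str = "p",
    q_col: str | None = "q",
    suggestive_q: float = 0.10,
    significant_q: float = 0.05,
    ax=None,
    title: str = "",
):
    """-log10(p) against cumulative genome position, chromosomes alternating
    shades, with dotted FDR threshold lines (suggestive blue, significant
    red) placed at the largest p whose q passes each threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for k, (c, sub) in enumerate(track.groupby("chrom", sort=False)):
        x = sub["pos"].to_numpy() + offset
        y = -np.log10(sub[p_col].to_numpy(float))
        ax.scatter(x, y, s=4, color=("0.3", "0.6")[k % 2], rasterized=True)
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(c))
        offset += sub["pos"].max() + 1
    if q_col is not None and q_col in track:
        p = track[p_col].to_numpy(float)
        q = track[q_col].to_numpy(float)
        for thr, color in ((suggestive_q, "tab:blue"), (significant_q, "tab:red")):
            passing = p[np.isfinite(q) & (q <= thr)]
            if len(passing):
                ax.axhline(-np.log10(passing.max()), ls=":", color=color, lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    return ax


def manhattan_panels(tracks: dict[str, pd.DataFrame], path: str | None = None, **kwargs):
    """Stacked Manhattan panels (one per analysis), optionally saved."""
    fig, axes = plt.subplots(len(tracks), 1, figsize=(10, 3 * len(tracks)), squeeze=False)
    for ax, (name, tr) in zip(axes.ravel(), tracks.items()):
        manhattan(tr, ax=ax, title=name, **kwargs)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
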