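"""Optional SVG figures: NMDS scatter and similarity-ordered heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

_MARKERS = {"exercise": "o", "sedentary": "s"}
_COLORS = {"AC5KO": "#d62728", "WT": "#1f77b4"}


def plot_nmds(coordinates: pd.DataFrame, metadata: pd.DataFrame, stress: float,
              path: str) -> None:
    """Ordination scatter coded by genotype (color) and activity (marker)."""
    meta = metadata.set_index("sample_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    for sample, row in coordinates.iterrows():
        g = meta.loc[sample, "genotype"]
        a = meta.loc[sample, "activity"]
        ax.scatter(row.iloc[0], row.iloc[1], c=_COLORS.get(g, "gray"),
                   marker=_MARKERS.get(a, "x"), s=60,
                   label=f"{g} {a}")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), fontsize=7)
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"NMDS (stress-1 = {stress:.3f})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_heatmap(ordered: pd.DataFrame, path: str, n_bands: int = 4) -> None:
    """Similarity heatmap of an ordered distance matrix, banded into a
    small number of discrete similarity levels for visual block reading."""
    sim = 1.0 - ordered.values
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(sim, cmap=plt.get_cmap("viridis", n_bands),
                   vmin=sim.min(), vmax=1.0)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="percent similarity", fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
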