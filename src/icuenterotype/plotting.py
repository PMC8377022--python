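"""Minimal plotting: PCoA scatter coloured by enterotype."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .enterotype import EnterotypePartition, PcoaEmbedding


def plot_pcoa(embedding: PcoaEmbedding, partition: EnterotypePartition,
              path=None, ax=None):
    """Scatter the first two PCoA axes, one colour per enterotype."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    coords = embedding.coordinates
    names = partition.named_labels()
    for name in sorted(set(names)):
        sel = [i for i, n in enumerate(names) if n == name]
        ax.scatter(coords[sel, 0], coords[sel, 1], s=18, label=name, alpha=0.8)
    ax.set_xlabel(f"PCo1 ({embedding.explained_fraction[0]:.1%})")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"PCo2 ({embedding.explained_fraction[1]:.1%})")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
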