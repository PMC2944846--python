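"""Cosmetic plotting helpers: model-building flow bands and cluster
scatter plots on canonical axes.  Requires matplotlib (optional)."""

from __future__ import annotations

import numpy as np

from .model_selection import ClusterFlow


def flow_diagram(flows: list[ClusterFlow], ax=None):
    """Band diagram of individuals redistributing across nested models.

    One column of boxes per model (widths proportional to cluster
    sizes); the band connecting a cluster of Model i to one of Model
    i+1 has thickness proportional to the number of individuals the two
    clusters share.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.8 * (len(flows) + 1), 4))
    n = flows[0].total

    def box_positions(sizes):
        gaps = 0.02 * n
        total = sizes.sum() + gaps * (len(sizes) - 1)
        starts, y = [], (n - total) / 2
        for s in sizes:
            starts.append(y)
            y += s + gaps
        return np.array(starts)

    levels = [flows[0].sizes_i] + [f.sizes_i1 for f in flows]
    positions = [box_positions(s) for s in levels]
    for x, (sizes, pos) in enumerate(zip(levels, positions)):
        for c, (s, y) in enumerate(zip(sizes, pos)):
            ax.add_patch(
                plt.Rectangle((x - 0.08, y), 0.16, s, color="0.3", zorder=3)
            )
            ax.text(x, y + s / 2, str(c + 1), color="w", ha="center",
                    va="center", fontsize=8, zorder=4)
    for x, flow in enumerate(flows):
        top_a = positions[x].astype(float).copy()
        top_b = positions[x + 1].astype(float).copy()
        for a in range(flow.counts.shape[0]):
            for b in range(flow.counts.shape[1]):
                c = flow.counts[a, b]
                if c == 0:
                    continue
                ya, yb = top_a[a], top_b[b]
                ax.fill(
                    [x + 0.08, x + 0.92, x + 0.92, x + 0.08],
                    [ya, yb, yb + c, ya + c],
                    color="0.85", lw=0, zorder=1,
                )
                top_a[a] += c
                top_b[b] += c
    ax.set_xlim(-0.5, len(levels) - 0.5)
    ax.set_ylim(-0.02 * n, 1.12 * n)
    ax.set_xticks(range(len(levels)))
    ax.set_xticklabels([f"Model {i + 1}" for i in range(len(levels))])
    ax.set_yticks([])
    for side in ("left", "right", "top"):
        ax.spines[side].set_visible(False)
    return ax


def score_scatter(scores: np.ndarray, labels, ax=None, title: str = ""):
    """Scatter of the first two canonical variables, one color per cluster."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for c in np.unique(labels):
        pts = scores[labels == c]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.6, label=f"cluster {c}")
    ax.set_xlabel("canonical variable 1")
    ax.set_ylabel("canonical variable 2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    return ax
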