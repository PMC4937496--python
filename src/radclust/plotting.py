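"""Basic plots: consensus-matrix heatmap with features ordered by cluster."""

from __future__ import annotations

import numpy as np

from .consensus import ClusterAssignment


def plot_consensus_heatmap(
    consensus: np.ndarray,
    assignment: ClusterAssignment,
    out_path,
    title: str | None = None,
) -> None:
    """Save a consensus-matrix heatmap (PNG/PDF by extension).

    Features are reordered so clusters form contiguous blocks; cluster
    boundaries are drawn as thin lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = assignment.labels.to_numpy()
    order = np.argsort(labels, kind="stable")
    mat = consensus[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="Blues", vmin=0.0, vmax=1.0, interpolation="nearest")
    bounds = np.flatnonzero(np.diff(labels[order])) + 0.5
    for b in bounds:
        ax.axhline(b, color="0.4", lw=0.5)
        ax.axvline(b, color="0.4", lw=0.5)
    ax.set_xlabel("features (cluster order)")
    ax.set_ylabel("features (cluster order)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="consensus")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
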