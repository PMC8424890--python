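"""Heat-map rendering of matrices, profiles and differential profiles.

Layout mirrors the tabular form of the descriptor: rows are the seven
ligand feature types in canonical order, columns are residues × nine
interaction types with separators between per-residue blocks.  Cell
intensity is proportional to the count (grayscale); differential mode
renders positive cells red and negative cells blue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .constants import FEATURE_ROWS, INTERACTION_COLS, N_COLS, N_ROWS  # noqa: E402
from .matrix import InteractionMatrix  # noqa: E402
from .profiles import DifferentialProfile, InteractionProfile  # noqa: E402

logger = logging.getLogger(__name__)


@dataclass
class RenderSpec:
    color_mode: str = "grayscale_counts"  # or "diff_red_blue"
    display_threshold: float = 0.0        # hide |cells| at/below this value
    output_format: str = "png"            # png | svg

    def __post_init__(self):
        if not 0.0 <= self.display_threshold <= 1.0 + 1e-12:
            raise ValueError("display_threshold must lie in [0, 1]")
        if self.color_mode not in ("grayscale_counts", "diff_red_blue"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")


def _dense(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, InteractionMatrix):
        return data.stacked().astype(float), data.labels()
    if isinstance(data, InteractionProfile):
        values = data.values if data.values else []
        arr = np.hstack(values) if values else np.zeros((N_ROWS, 0))
        return arr.astype(float), list(data.positions)
    if isinstance(data, DifferentialProfile):
        diffs = data.differences
        arr = np.hstack(diffs) if diffs else np.zeros((N_ROWS, 0))
        return arr.astype(float), list(data.positions)
    raise TypeError(f"cannot render a {type(data).__name__}")


def render_heatmap(data, path, spec: RenderSpec | None = None) -> str:
    """Render a matrix / profile / differential profile to an image
    file.  An empty input still produces a valid (uniform) image, with
    a warning.  Returns the path written."""
    spec = spec or RenderSpec()
    arr, labels = _dense(data)
    if arr.size == 0:
        logger.warning("rendering an empty matrix: uniform background only")
        arr = np.zeros((N_ROWS, N_COLS))
        labels = [""]
    if spec.display_threshold > 0:
        arr = arr.copy()
        arr[np.abs(arr) <= spec.display_threshold] = 0.0

    n_res = len(labels)
    fig_w = max(4.0, 0.28 * arr.shape[1] + 1.5)
    fig, ax = plt.subplots(figsize=(fig_w, 3.2))
    if spec.color_mode == "diff_red_blue":
        vmax = max(float(np.abs(arr).max()), 1e-9)
        # diverging map: negative cells blue, positive red
        ax.imshow(arr, cmap="bwr", vmin=-vmax, vmax=vmax,
                  aspect="auto", interpolation="nearest")
    else:
        vmax = max(float(arr.max()), 1e-9)
        ax.imshow(arr, cmap="Greys", vmin=0.0, vmax=vmax,
                  aspect="auto", interpolation="nearest")

    ax.set_yticks(range(N_ROWS), FEATURE_ROWS)
    ax.set_xticks([N_COLS * i + (N_COLS - 1) / 2 for i in range(n_res)],
                  labels, rotation=90, fontsize=7)
    for i in range(1, n_res):
        ax.axvline(N_COLS * i - 0.5, color="black", linewidth=0.8)
    ax.set_xticks(np.arange(-0.5, arr.shape[1], 1.0), minor=True)
    ax.set_yticks(np.arange(-0.5, N_ROWS, 1.0), minor=True)
    ax.grid(which="minor", color="0.85", linewidth=0.3)
    ax.tick_params(which="minor", length=0)
    sub = ax.secondary_xaxis("top")
    sub.set_xticks(range(arr.shape[1]),
                   list(INTERACTION_COLS) * n_res, fontsize=4, rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
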