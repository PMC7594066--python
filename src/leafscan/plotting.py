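"""Optional diagnostic plots (never required by the pipeline or tests)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import LeafPosition, LeafTrack

__all__ = ["plot_tracks", "plot_positions_3d"]


def plot_tracks(tracks: list[LeafTrack], path: str | Path,
                image_w: int = 640, image_h: int = 480) -> None:
    """Overlay of detection centres coloured by leaf id (scan-view plot)."""
    fig, ax = plt.subplots(figsize=(6.4, 4.8))
    for t in tracks:
        xs = [d.centre_x for d in t.detections]
        ys = [d.centre_y for d in t.detections]
        ax.plot(xs, ys, "o-", ms=4, label=f"leaf {t.leaf_id}")
    ax.set_xlim(0, image_w)
    ax.set_ylim(image_h, 0)  # image convention: y down
    ax.set_xlabel("pixel x")
    ax.set_ylabel("pixel y")
    ax.set_title("Grouped detection centres")
    if len(tracks) <= 12:
        ax.legend(fontsize=7)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_positions_3d(positions: list[LeafPosition], path: str | Path) -> None:
    """3D scatter of reconstructed leaf positions (depth plotted as -z)."""
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    if positions:
        ax.scatter(
            [p.x_mm for p in positions],
            [p.y_mm for p in positions],
            [-p.depth_mm for p in positions],
            c=[p.depth_mm for p in positions], cmap="viridis", s=40,
        )
    ax.set_xlabel("x (mm, scan axis)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm, below camera)")
    ax.set_title("Reconstructed leaf positions")
    fig.savefig(path, dpi=120)
    plt.close(fig)
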