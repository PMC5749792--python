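"""Match overlay rendering (side-by-side images with correspondence lines)."""

from __future__ import annotations

import numpy as np

from .types import as_gray


def draw_matches(image_a, image_b, result, stage: str = "prosac", out_path=None):
    """Render both images side by side with lines joining stage matches.

    Returns the matplotlib figure; saves to ``out_path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = as_gray(image_a), as_gray(image_b)
    h = max(a.shape[0], b.shape[0])
    canvas = np.zeros((h, a.shape[1] + b.shape[1]))
    canvas[: a.shape[0], : a.shape[1]] = a
    canvas[: b.shape[0], a.shape[1] :] = b
    xoff = a.shape[1]

    fig, ax = plt.subplots(figsize=(10, 5))
    ax.imshow(canvas, cmap="gray", vmin=0, vmax=max(255.0, canvas.max()))
    src, dst = result.stage_points(stage)
    for (xs, ys), (xd, yd) in zip(src, dst):
        ax.plot([xs, xd + xoff], [ys, yd], "-", lw=0.7, alpha=0.8, color="lime")
        ax.plot([xs], [ys], ".", ms=3, color="red")
        ax.plot([xd + xoff], [yd], ".", ms=3, color="red")
    ax.set_axis_off()
    ax.set_title(f"{stage}: {len(src)} matches")
    if out_path:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
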