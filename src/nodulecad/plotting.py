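"""FROC plots and 2D slice overlays of detections."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import Candidate, CTVolume
from .evaluation import CPM_FPS_POINTS, FROCCurve

__all__ = ["plot_froc", "save_overlays"]


def plot_froc(curve: FROCCurve, path: str | Path, label: str = "detector") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(curve.fps_per_scan, curve.sensitivity, where="post", label=label)
    pts = [curve.seven_points[f] for f in CPM_FPS_POINTS]
    ax.plot(CPM_FPS_POINTS, pts, "o", ms=4,
            label=f"CPM = {100 * curve.cpm:.2f}%")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("FPs / scan")
    ax.set_ylabel("sensitivity")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_overlays(pre_image: CTVolume, candidates: list[Candidate],
                  out_dir: str | Path, max_slices: int = 20) -> list[Path]:
    """One PNG per detected candidate: the axial slice through its
    centre with a circle at the predicted diameter."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, c in enumerate(candidates[:max_slices]):
        z = int(round(c.center[0]))
        z = min(max(z, 0), pre_image.shape[0] - 1)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(np.asarray(pre_image.grid)[z], cmap="gray", vmin=0, vmax=255)
        circ = plt.Circle((c.center[2], c.center[1]), c.diameter / 2.0,
                          fill=False, color="red", lw=1.2)
        ax.add_patch(circ)
        ax.set_title(f"z={z}  p={c.probability:.2f}"
                     + (f"  s={c.score:.2f}" if c.score is not None else ""))
        ax.axis("off")
        path = out_dir / f"candidate_{i:03d}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
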