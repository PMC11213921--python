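"""Behavioral trajectory analysis: smoothing, visit density, quarter occupancy.

Raw arena trajectories are temporally smoothed with a Gaussian kernel
(half-width 2 s, sigma 2/3 s), binned into a 1000 x 1000 grid, spatially
smoothed with a wide 2-D Gaussian (s.d. 78 grid pixels, filter size = grid
size minus one) and normalized by frame count.  The resulting density map is
split into four quarters by the arena diagonals, one quarter per patch, and
re-ordered to the canonical patch order (Lvs, Lct, LvsLct, Ctr) so trials with
different physical patch placements can be pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .choice_model import PATCHES

__all__ = [
    "Trajectory",
    "DensityMap",
    "GRID_SIZE",
    "smooth_trajectory",
    "visit_density",
    "quarter_occupancy",
    "patch_quadrants_from_centers",
    "read_trajectories_csv",
    "write_trajectories_csv",
]

log = logging.getLogger(__name__)

GRID_SIZE = 1000


@dataclass
class Trajectory:
    """Per-frame (x, y) positions of one animal at constant frame rate."""

    animal_id: str
    positions: np.ndarray  # (n_frames, 2)
    fps: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_frames, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class DensityMap:
    grid: np.ndarray                      # (GRID_SIZE, GRID_SIZE), >= 0
    patch_quadrants: dict[str, int]       # patch label -> quadrant index 0..3
    per_animal: bool = False
    n_clipped: int = 0

    def __post_init__(self):
        if np.any(self.grid < 0):
            raise ValueError("density values must be non-negative")


def _gauss_kernel(fps: float, half_width_s: float, sigma_s: float) -> np.ndarray:
    half = int(round(half_width_s * fps))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / (sigma_s * fps)) ** 2)
    return k / k.sum()


def smooth_trajectory(
    traj: Trajectory, half_width_s: float = 2.0, sigma_s: float = 2.0 / 3.0
) -> Trajectory:
    """Temporal Gaussian smoothing of a trajectory.

    The kernel spans +-half_width_s*fps frames with sigma = sigma_s*fps frames
    and is renormalized at the edges (partial kernels keep unit mass), so a
    constant trajectory passes through unchanged everywhere.
    """
    kernel = _gauss_kernel(traj.fps, half_width_s, sigma_s)
    if len(traj) <= kernel.size // 2:
        raise ValueError("trajectory shorter than the smoothing kernel support")
    norm = np.convolve(np.ones(len(traj)), kernel, mode="same")
    smoothed = np.column_stack(
        [np.convolve(traj.positions[:, i], kernel, mode="same") / norm for i in (0, 1)]
    )
    return Trajectory(traj.animal_id, smoothed, traj.fps)


def visit_density(
    trajs,
    patch_quadrants: dict[str, int],
    sd_px: float = 78.0,
    arena_bounds=None,
) -> DensityMap:
    """Frame-count-normalized visit density on the 1000 x 1000 grid.

    Each frame deposits unit mass at its binned position; the accumulated
    histogram is smoothed with a 2-D Gaussian (s.d. ``sd_px`` grid pixels)
    whose support is clipped at the grid edge (mass may be lost there), and
    divided by the total frame count.  ``arena_bounds`` is
    (xmin, ymin, xmax, ymax) in trajectory units; by default the joint
    bounding box of all trajectories.  Multiple animals are pooled, which by
    linearity equals the mean of the per-animal maps.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no trajectories")
    allpos = np.vstack([t.positions for t in trajs])
    if arena_bounds is None:
        xmin, ymin = allpos.min(axis=0)
        xmax, ymax = allpos.max(axis=0)
    else:
        xmin, ymin, xmax, ymax = arena_bounds
    span_x = max(xmax - xmin, np.finfo(float).eps)
    span_y = max(ymax - ymin, np.finfo(float).eps)

    cols = np.floor((allpos[:, 0] - xmin) / span_x * GRID_SIZE).astype(int)
    rows = np.floor((allpos[:, 1] - ymin) / span_y * GRID_SIZE).astype(int)
    n_clipped = int(
        np.count_nonzero((cols < 0) | (cols >= GRID_SIZE) | (rows < 0) | (rows >= GRID_SIZE))
    )
    if n_clipped:
        log.warning("visit_density: %d positions outside grid were clipped", n_clipped)
    cols = np.clip(cols, 0, GRID_SIZE - 1)
    rows = np.clip(rows, 0, GRID_SIZE - 1)

    hist = np.zeros((GRID_SIZE, GRID_SIZE))
    np.add.at(hist, (rows, cols), 1.0)
    # smoothing the summed histogram == summing per-frame smoothed deposits
    # (truncate at ~half the 999-wide filter support)
    grid = gaussian_filter(hist, sigma=sd_px, mode="constant", cval=0.0,
                           truncate=(GRID_SIZE - 1) / 2 / sd_px)
    grid /= allpos.shape[0]
    return DensityMap(grid, dict(patch_quadrants),
                      per_animal=len(trajs) == 1, n_clipped=n_clipped)


def _quadrant_masks(shape):
    """Four quadrant masks cut by the two diagonals through the grid center.

    Quadrant indices: 0 = top (small row side), 1 = right, 2 = bottom,
    3 = left.  Pixels exactly on a diagonal join the lower-index quadrant.
    """
    h, w = shape
    r = np.arange(h)[:, None] - (h - 1) / 2
    c = np.arange(w)[None, :] - (w - 1) / 2
    top = (r <= c) & (r <= -c)
    right = (r < c) & (r > -c)
    bottom = (r > c) & (r >= -c)
    left = (r >= c) & (r < -c)
    return [top, right, bottom, left]


def quarter_occupancy(dmap: DensityMap) -> np.ndarray:
    """Per-quarter density mass in canonical patch order, normalized to 1.

    The four quarters are cut by the arena diagonals and realigned via the
    map's ``patch_quadrants`` so the output order is always
    (Lvs, Lct, LvsLct, Ctr) regardless of physical patch placement.
    """
    masks = _quadrant_masks(dmap.grid.shape)
    mass = np.array([dmap.grid[m].sum() for m in masks])
    total = mass.sum()
    if total <= 0:
        raise ValueError("density map carries no mass")
    missing = set(PATCHES) - set(dmap.patch_quadrants)
    if missing:
        raise ValueError(f"patch_quadrants missing patches: {sorted(missing)}")
    occ = np.array([mass[dmap.patch_quadrants[p]] for p in PATCHES])
    return occ / total


def patch_quadrants_from_centers(patch_centers: dict, arena_center) -> dict[str, int]:
    """Map patch labels to diagonal-cut quadrant indices (0 top, 1 right,
    2 bottom, 3 left) from patch center coordinates."""
    cx, cy = arena_center
    out = {}
    for label, (x, y) in patch_centers.items():
        dx, dy = x - cx, y - cy
        if dy <= -abs(dx):
            out[label] = 0
        elif dx >= abs(dy):
            out[label] = 1
        elif dy >= abs(dx):
            out[label] = 2
        else:
            out[label] = 3
    if len(set(out.values())) != len(out):
        raise ValueError("two patches fall in the same quadrant")
    return out


def read_trajectories_csv(path, fps: float) -> list[Trajectory]:
    """Read trajectories from CSV columns (animal_id, frame, x_px, y_px)."""
    df = pd.read_csv(path)
    out = []
    for aid, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"non-monotone frame index for animal {aid!r}")
        out.append(Trajectory(str(aid), sub[["x_px", "y_px"]].to_numpy(float), fps))
    return out


def write_trajectories_csv(trajs, path) -> None:
    rows = []
    for t in trajs:
        for f, (x, y) in enumerate(t.positions):
            rows.append((t.animal_id, f, x, y))
    pd.DataFrame(rows, columns=["animal_id", "frame", "x_px", "y_px"]).to_csv(
        path, index=False
    )
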