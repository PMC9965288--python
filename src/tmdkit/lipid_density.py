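"""Time-averaged lipid density in cylindrical coordinates around the
helix axis.

Lipid atoms are binned, frame by frame, into annular sector cells
(radial shell x azimuth x axial shift) of a cylinder aligned with the
per-frame helix axis.  Number density is counts / (cell volume x
frames), with the annular sector volume computed exactly, so the total
count is conserved.  Immobilized ("frozen") lipid patches on the helix
surface show up as high-density cells; ``contrast_score`` (max cell
density over shell-mean density) quantifies them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .helix_geometry import HelixAxis, HelixSegment, fit_axis
from .mhp_surface import SurfaceMap2D, _axis_frame
from .structure_io import Trajectory

__all__ = [
    "CylindricalGridSpec",
    "DensityMapStack",
    "frame_axis",
    "frame_axes",
    "accumulate_density",
    "contrast_score",
]

#: default radial shells, A — lipid-tail packing distances from the
#: helix surface outward; qualitative placeholders, fully configurable
DEFAULT_SHELLS: tuple[tuple[float, float], ...] = ((5.0, 8.0), (8.0, 11.0), (11.0, 14.0))


@dataclass(frozen=True)
class CylindricalGridSpec:
    """Cylindrical binning: radial shells x azimuth bins x axial bins."""

    radial_shells: tuple[tuple[float, float], ...] = DEFAULT_SHELLS
    angle_bin_width: float = 15.0
    z_range: tuple[float, float] = (-20.0, 20.0)
    z_bin_width: float = 1.5

    def __post_init__(self) -> None:
        if self.angle_bin_width <= 0 or self.z_bin_width <= 0:
            raise ValueError("bin widths must be > 0")
        if 360.0 % self.angle_bin_width > 1e-9:
            raise ValueError("angle_bin_width must divide 360")
        prev_hi = -np.inf
        for lo, hi in self.radial_shells:
            if hi <= lo or lo < 0:
                raise ValueError(f"invalid radial shell ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError("radial shells must be ordered and non-overlapping")
            prev_hi = hi
        if self.z_range[1] <= self.z_range[0]:
            raise ValueError("empty z range")

    @property
    def angle_edges(self) -> np.ndarray:
        return np.arange(0.0, 360.0 + 1e-9, self.angle_bin_width)

    @property
    def z_edges(self) -> np.ndarray:
        lo, hi = self.z_range
        n = int(round((hi - lo) / self.z_bin_width))
        return lo + self.z_bin_width * np.arange(n + 1)

    def cell_volume(self, shell_index: int) -> float:
        """Exact annular sector volume, A^3 (same for every cell of a shell)."""
        lo, hi = self.radial_shells[shell_index]
        dtheta = np.deg2rad(self.angle_bin_width)
        return 0.5 * (hi * hi - lo * lo) * dtheta * self.z_bin_width


@dataclass
class DensityMapStack:
    """Per-shell density maps (atoms/A^3) plus bookkeeping.

    ``maps[s].values`` is density; ``maps[s].weight`` is raw counts, so
    sum(weight) over all shells equals the number of in-range
    atom-frames exactly.
    """

    maps: list[SurfaceMap2D]
    grid: CylindricalGridSpec
    frame_count: int
    axis_info: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def total_counts(self) -> float:
        return float(sum(m.weight.sum() for m in self.maps))


def frame_axis(traj: Trajectory, frame_index: int, segment: HelixSegment) -> HelixAxis:
    """Helix axis of one trajectory frame (principal-axis fit on Calpha)."""
    return fit_axis(traj.frame_model(frame_index), segment)


def frame_axes(traj: Trajectory, segment: HelixSegment) -> list[HelixAxis]:
    return [frame_axis(traj, k, segment) for k in range(traj.n_frames)]


def accumulate_density(
    traj: Trajectory,
    axis_per_frame: Sequence[HelixAxis],
    selection: np.ndarray | str = "lipid_tails",
    grid: CylindricalGridSpec = CylindricalGridSpec(),
    reference_segment: HelixSegment | None = None,
    reference_direction: np.ndarray | None = None,
    z_origin: np.ndarray | None = None,
) -> DensityMapStack:
    """Bin selected atoms of every frame into the cylindrical grid.

    The azimuth reference is, per frame: ``reference_direction`` if
    given, else the projection of the reference segment's first-residue
    Calpha, else a fixed laboratory direction.  ``z_origin`` (a lab
    point, e.g. the bilayer midplane) sets where the axial coordinate
    is zero; default is the fitted axis centroid.  density = counts /
    (cell volume x frame count).
    """
    if isinstance(selection, str):
        sel = traj.groups.get(selection)
        if sel is None:
            raise ValueError(f"trajectory has no group {selection!r}")
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    if len(axis_per_frame) != traj.n_frames:
        raise ValueError("need one axis per frame")

    n_shell = len(grid.radial_shells)
    angle_edges = grid.angle_edges
    z_edges = grid.z_edges
    shape = (len(angle_edges) - 1, len(z_edges) - 1)
    counts = np.zeros((n_shell,) + shape)

    shell_lo = np.array([s[0] for s in grid.radial_shells])
    shell_hi = np.array([s[1] for s in grid.radial_shells])

    for k in range(traj.n_frames):
        axis = axis_per_frame[k]
        if reference_direction is not None:
            ref = reference_direction
        elif reference_segment is not None:
            fm = traj.frame_model(k)
            ref = fm.atom_position(reference_segment.first_residue, "CA") - axis.point
        else:
            ref = None
        ex, ey, ez = _axis_frame(axis, ref)
        rel = traj.frames[k][sel] - axis.point
        x, y = rel @ ex, rel @ ey
        origin = axis.point if z_origin is None else np.asarray(z_origin, float)
        z = (traj.frames[k][sel] - origin) @ ez
        r = np.hypot(x, y)
        azimuth = np.degrees(np.arctan2(y, x)) % 360.0
        iz_ok = (z >= z_edges[0]) & (z < z_edges[-1])
        ia = np.clip(np.digitize(azimuth, angle_edges) - 1, 0, shape[0] - 1)
        iz = np.clip(np.digitize(z, z_edges) - 1, 0, shape[1] - 1)
        for s in range(n_shell):
            in_shell = (r >= shell_lo[s]) & (r < shell_hi[s]) & iz_ok
            np.add.at(counts[s], (ia[in_shell], iz[in_shell]), 1.0)

    warnings: list[str] = []
    if counts.sum() == 0:
        warnings.append("no selected atom ever fell inside the grid")
    maps = []
    for s in range(n_shell):
        vol = grid.cell_volume(s)
        density = counts[s] / (vol * traj.n_frames)
        maps.append(SurfaceMap2D(angle_edges, z_edges, density, counts[s]))
    return DensityMapStack(
        maps, grid, traj.n_frames, axis_info="per-frame principal-axis fit", warnings=warnings
    )


def contrast_score(stack: DensityMapStack, shell_index: int = 0) -> float:
    """Max cell density / shell-mean density; >= 1 by construction.

    Uniform lipid motion gives a score near 1; lipids pinned at one
    azimuth concentrate counts in few cells and push the score up.
    Returns NaN for an all-zero shell.
    """
    m = stack.maps[shell_index]
    mean = float(m.values.mean())
    if mean == 0:
        return float("nan")
    return float(m.values.max() / mean)
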