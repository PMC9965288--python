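"""Molecular hydrophobicity potential (MHP) on a peptide surface, and
its projection onto a 2D cylindrical map.

MHP assigns each atom an empirical hydrophobicity constant f (octanol/
water log p units) and evaluates, at each point j of the solvent-
accessible surface, the distance-weighted sum

    MHP(j) = sum_i f_i * exp(-d_ij / alpha)

with decay length alpha (default 2.0 A).  The surface values are then
binned on a cylinder around the helix axis: x = rotation angle about
the axis, y = axial shift, giving the familiar "unrolled helix" map in
which hydrophilic stripes (candidate dimerization motifs) appear as
low-MHP sectors.  Maps from many trajectory frames can be averaged
weight-aware.

The atomic constants shipped here are a united-atom table in the
spirit of the Ghose-Crippen atomic log p typology: aliphatic and
aromatic carbons are hydrophobic (f > 0), polar nitrogens/oxygens are
hydrophilic (f < 0), hydrogens are folded into their heavy atom.  The
absolute values are approximate and fully configurable; analyses in
this package rely on orderings (e.g. a Leu side chain scores higher
than a Ser side chain), not on absolute log p calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .helix_geometry import HelixAxis
from .structure_io import MolecularModel

__all__ = [
    "SurfaceMap2D",
    "SurfacePointSet",
    "MapSpec",
    "UNITED_ATOM_LOGP",
    "VDW_RADII",
    "PROBE_RADIUS",
    "MissingConstantError",
    "assign_constants",
    "build_surface",
    "mhp_at_points",
    "cylindrical_project",
    "average_maps",
    "mhp_map_for_model",
    "mhp_map_for_trajectory",
]

PROBE_RADIUS = 1.4  # water rolling probe, A

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}

# united-atom hydrophobicity classes, log p units
_F = {
    "CH3": 0.63,
    "CH2": 0.46,
    "CH": 0.37,
    "CH_ar": 0.34,  # aromatic CH
    "C_ar": 0.29,  # substituted aromatic C
    "C_carbonyl": -0.28,
    "C_carboxyl": -0.12,
    "C_guanidinium": -0.40,
    "C_amide": -0.28,
    "N_amide": -0.60,
    "N_amine": -0.95,
    "N_guanidinium": -0.70,
    "N_ar": -0.50,  # His ring N
    "O_carbonyl": -0.25,
    "O_hydroxyl": -0.47,
    "O_carboxylate": -0.73,
    "S": 0.25,
    "SH": 0.10,
    "H_polar": 0.0,
}

# side-chain atom -> class, per residue (backbone handled generically)
_SIDECHAIN_CLASS: dict[str, dict[str, str]] = {
    "ALA": {"CB": "CH3"},
    "GLY": {},
    "VAL": {"CB": "CH", "CG1": "CH3", "CG2": "CH3"},
    "LEU": {"CB": "CH2", "CG": "CH", "CD1": "CH3", "CD2": "CH3"},
    "ILE": {"CB": "CH", "CG1": "CH2", "CG2": "CH3", "CD1": "CH3", "CD": "CH3"},
    "PRO": {"CB": "CH2", "CG": "CH2", "CD": "CH2"},
    "PHE": {
        "CB": "CH2", "CG": "C_ar", "CD1": "CH_ar", "CD2": "CH_ar",
        "CE1": "CH_ar", "CE2": "CH_ar", "CZ": "CH_ar",
    },
    "TRP": {
        "CB": "CH2", "CG": "C_ar", "CD1": "CH_ar", "CD2": "C_ar", "NE1": "N_ar",
        "CE2": "C_ar", "CE3": "CH_ar", "CZ2": "CH_ar", "CZ3": "CH_ar", "CH2": "CH_ar",
    },
    "TYR": {
        "CB": "CH2", "CG": "C_ar", "CD1": "CH_ar", "CD2": "CH_ar",
        "CE1": "CH_ar", "CE2": "CH_ar", "CZ": "C_ar", "OH": "O_hydroxyl",
    },
    "SER": {"CB": "CH2", "OG": "O_hydroxyl"},
    "THR": {"CB": "CH", "OG1": "O_hydroxyl", "CG2": "CH3"},
    "CYS": {"CB": "CH2", "SG": "SH"},
    "MET": {"CB": "CH2", "CG": "CH2", "SD": "S", "CE": "CH3"},
    "ASN": {"CB": "CH2", "CG": "C_amide", "OD1": "O_carbonyl", "ND2": "N_amide"},
    "GLN": {"CB": "CH2", "CG": "CH2", "CD": "C_amide", "OE1": "O_carbonyl", "NE2": "N_amide"},
    "ASP": {"CB": "CH2", "CG": "C_carboxyl", "OD1": "O_carboxylate", "OD2": "O_carboxylate"},
    "GLU": {"CB": "CH2", "CG": "CH2", "CD": "C_carboxyl", "OE1": "O_carboxylate", "OE2": "O_carboxylate"},
    "LYS": {"CB": "CH2", "CG": "CH2", "CD": "CH2", "CE": "CH2", "NZ": "N_amine"},
    "ARG": {
        "CB": "CH2", "CG": "CH2", "CD": "CH2", "NE": "N_guanidinium",
        "CZ": "C_guanidinium", "NH1": "N_guanidinium", "NH2": "N_guanidinium",
    },
    "HIS": {
        "CB": "CH2", "CG": "C_ar", "ND1": "N_ar", "CD2": "CH_ar",
        "CE1": "CH_ar", "NE2": "N_ar",
    },
}

_BACKBONE_CLASS = {
    "N": "N_amide",
    "CA": "CH",
    "C": "C_carbonyl",
    "O": "O_carbonyl",
    "OXT": "O_carboxylate",
    "H": "H_polar",
    "HN": "H_polar",
}


def _build_table() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for res, side in _SIDECHAIN_CLASS.items():
        for an, cls in {**_BACKBONE_CLASS, **side}.items():
            table[(res, an)] = _F[cls]
        # glycine CA carries two hydrogens: slightly more exposed CH2-like
        if res == "GLY":
            table[(res, "CA")] = _F["CH2"]
    return table


#: (residue_name, atom_name) -> united-atom hydrophobicity constant, log p units
UNITED_ATOM_LOGP: dict[tuple[str, str], float] = _build_table()


class MissingConstantError(KeyError):
    """Raised when atoms have no hydrophobicity constant; lists them."""

    def __init__(self, pairs: Sequence[tuple[str, str]]):
        self.pairs = list(pairs)
        super().__init__(
            "no hydrophobicity constant for: "
            + ", ".join(f"{r}/{a}" for r, a in self.pairs)
        )


def assign_constants(
    model: MolecularModel,
    table: Mapping[tuple[str, str], float] | None = None,
) -> np.ndarray:
    """Per-atom hydrophobicity constants aligned with model atom order.

    Unknown (residue, atom) pairs raise :class:`MissingConstantError`
    listing every offender — never a silent zero.
    """
    table = UNITED_ATOM_LOGP if table is None else table
    missing = []
    f = np.empty(len(model), dtype=float)
    for i, a in enumerate(model.atoms):
        key = (a.residue_name, a.name)
        if key in table:
            f[i] = table[key]
        elif a.element == "H":  # explicit protons not in the united-atom table
            f[i] = _F["H_polar"]
        else:
            missing.append(key)
    if missing:
        raise MissingConstantError(sorted(set(missing)))
    return f


@dataclass
class SurfacePointSet:
    """Dot-sampled solvent-accessible surface with per-point area weights."""

    points: np.ndarray  # (M, 3) A
    normals: np.ndarray  # (M, 3) unit
    areas: np.ndarray  # (M,) A^2
    owner_atom: np.ndarray  # (M,) int index into the generating model

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


def _golden_spiral(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def build_surface(model: MolecularModel, point_density: float = 2.0) -> SurfacePointSet:
    """Solvent-accessible surface by rolling-probe dot sampling.

    Shrake-Rupley style: each atom's expanded sphere (r_vdw + 1.4 A) is
    dotted on a golden spiral at ``point_density`` points per A^2; dots
    inside any neighbour's expanded sphere are discarded.  Every
    surviving dot is owned by its generating atom and carries an equal
    share of that sphere's area.
    """
    if point_density <= 0:
        raise ValueError("point_density must be > 0")
    coords = model.coordinates
    radii = np.array(
        [VDW_RADII.get(a.element, 1.7) + PROBE_RADIUS for a in model.atoms]
    )
    tree = cKDTree(coords)
    max_r = radii.max()
    pts, nrm, areas, owner = [], [], [], []
    for i, (c, r) in enumerate(zip(coords, radii)):
        n_dots = max(8, int(np.ceil(point_density * 4.0 * np.pi * r * r)))
        dots = _golden_spiral(n_dots)
        p = c + r * dots
        neighbours = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        keep = np.ones(n_dots, dtype=bool)
        for j in neighbours:
            keep &= np.linalg.norm(p - coords[j], axis=1) >= radii[j]
        if not keep.any():
            continue
        pts.append(p[keep])
        nrm.append(dots[keep])
        areas.append(np.full(keep.sum(), 4.0 * np.pi * r * r / n_dots))
        owner.append(np.full(keep.sum(), i, dtype=int))
    if not pts:
        raise ValueError("model has no exposed surface")
    return SurfacePointSet(
        np.concatenate(pts), np.concatenate(nrm), np.concatenate(areas), np.concatenate(owner)
    )


def mhp_at_points(
    points: SurfacePointSet | np.ndarray,
    atom_coords: np.ndarray,
    f: np.ndarray,
    decay_length: float = 2.0,
    chunk: int = 2048,
) -> np.ndarray:
    """MHP(j) = sum_i f_i exp(-d_ij / alpha) at each surface point."""
    if decay_length <= 0:
        raise ValueError("decay_length must be > 0")
    p = points.points if isinstance(points, SurfacePointSet) else np.asarray(points, float)
    atom_coords = np.asarray(atom_coords, float)
    f = np.asarray(f, float)
    out = np.empty(len(p))
    for s in range(0, len(p), chunk):
        block = p[s : s + chunk]
        d = np.linalg.norm(block[:, None, :] - atom_coords[None, :, :], axis=2)
        out[s : s + chunk] = np.exp(-d / decay_length) @ f
    return out


@dataclass(frozen=True)
class MapSpec:
    """Binning of the cylindrical map: angle (deg) x axial shift (A)."""

    angle_bin_width: float = 10.0
    z_bin_width: float = 1.0
    z_range: tuple[float, float] | None = None  # default: data range

    def __post_init__(self) -> None:
        if self.angle_bin_width <= 0 or self.z_bin_width <= 0:
            raise ValueError("bin widths must be > 0")
        if 360.0 % self.angle_bin_width > 1e-9:
            raise ValueError("angle_bin_width must divide 360")


@dataclass
class SurfaceMap2D:
    """2D grid over (rotation angle about the helix axis, axial shift).

    ``values`` holds MHP (log p) or density; ``weight`` the accumulated
    area/counts per cell.  Empty cells have weight 0 and value NaN.
    """

    angle_edges: np.ndarray  # degrees, [0, 360]
    z_edges: np.ndarray  # A
    values: np.ndarray  # (n_angle, n_z)
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.angle_edges = np.asarray(self.angle_edges, float)
        self.z_edges = np.asarray(self.z_edges, float)
        self.values = np.asarray(self.values, float)
        self.weight = np.asarray(self.weight, float)
        expected = (len(self.angle_edges) - 1, len(self.z_edges) - 1)
        if self.values.shape != expected or self.weight.shape != expected:
            raise ValueError(
                f"grid shape {self.values.shape} does not match bin edges {expected}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def empty_mask(self) -> np.ndarray:
        return self.weight == 0

    def angle_centers(self) -> np.ndarray:
        return 0.5 * (self.angle_edges[:-1] + self.angle_edges[1:])

    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def allclose(self, other: "SurfaceMap2D", atol: float = 0.0) -> bool:
        return (
            np.array_equal(self.angle_edges, other.angle_edges)
            and np.array_equal(self.z_edges, other.z_edges)
            and np.allclose(self.values, other.values, atol=atol, equal_nan=True)
            and np.allclose(self.weight, other.weight, atol=atol)
        )


def _axis_frame(axis: HelixAxis, reference: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ez = axis.direction
    if reference is None:
        # arbitrary but deterministic reference
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, ez)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
    else:
        ref = np.asarray(reference, float)
    ex = ref - np.dot(ref, ez) * ez
    nrm = np.linalg.norm(ex)
    if nrm < 1e-9:
        raise ValueError("azimuth reference direction is parallel to the axis")
    ex = ex / nrm
    ey = np.cross(ez, ex)
    return ex, ey, ez


def cylindrical_project(
    points: SurfacePointSet | np.ndarray,
    values: np.ndarray,
    axis: HelixAxis,
    map_spec: MapSpec = MapSpec(),
    reference_direction: np.ndarray | None = None,
    areas: np.ndarray | None = None,
) -> SurfaceMap2D:
    """Project surface-point values onto the (azimuth, axial) cylinder grid.

    The azimuth of a point is measured in the plane normal to the axis,
    from ``reference_direction`` (projected onto that plane).  Cell
    values are area-weighted means; cells with no points are flagged
    empty (NaN value, zero weight).
    """
    if isinstance(points, SurfacePointSet):
        p = points.points
        if areas is None:
            areas = points.areas
    else:
        p = np.asarray(points, float)
        if areas is None:
            areas = np.ones(len(p))
    values = np.asarray(values, float)
    ex, ey, ez = _axis_frame(axis, reference_direction)
    rel = p - axis.point
    x = rel @ ex
    y = rel @ ey
    z = rel @ ez
    r = np.hypot(x, y)
    if np.all(r < 1e-9):
        raise ValueError("all points lie on the axis: azimuth undefined")
    azimuth = np.degrees(np.arctan2(y, x)) % 360.0

    angle_edges = np.arange(0.0, 360.0 + 1e-9, map_spec.angle_bin_width)
    if map_spec.z_range is None:
        z_lo = np.floor(z.min() / map_spec.z_bin_width) * map_spec.z_bin_width
        z_hi = np.ceil(z.max() / map_spec.z_bin_width) * map_spec.z_bin_width
        if z_hi <= z_lo:
            z_hi = z_lo + map_spec.z_bin_width
    else:
        z_lo, z_hi = map_spec.z_range
    z_edges = np.arange(z_lo, z_hi + 1e-9, map_spec.z_bin_width)

    ia = np.clip(np.digitize(azimuth, angle_edges) - 1, 0, len(angle_edges) - 2)
    inside = (z >= z_edges[0]) & (z <= z_edges[-1])
    iz = np.clip(np.digitize(z, z_edges) - 1, 0, len(z_edges) - 2)

    shape = (len(angle_edges) - 1, len(z_edges) - 1)
    wsum = np.zeros(shape)
    vsum = np.zeros(shape)
    np.add.at(wsum, (ia[inside], iz[inside]), areas[inside])
    np.add.at(vsum, (ia[inside], iz[inside]), (areas * values)[inside])
    with np.errstate(invalid="ignore"):
        grid = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    return SurfaceMap2D(angle_edges, z_edges, grid, wsum)


def average_maps(maps: Sequence[SurfaceMap2D]) -> SurfaceMap2D:
    """Weight-aware mean of maps on identical grids.

    A cell is empty in the average only if it is empty in every input.
    """
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if not (
            np.array_equal(m.angle_edges, first.angle_edges)
            and np.array_equal(m.z_edges, first.z_edges)
        ):
            raise ValueError("maps have mismatched grids")
    wsum = np.zeros(first.shape)
    vsum = np.zeros(first.shape)
    for m in maps:
        filled = m.weight > 0
        wsum[filled] += m.weight[filled]
        vsum[filled] += (m.weight * m.values)[filled]
    grid = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    return SurfaceMap2D(first.angle_edges, first.z_edges, grid, wsum)


def mhp_map_for_model(
    model: MolecularModel,
    axis: HelixAxis,
    map_spec: MapSpec = MapSpec(),
    decay_length: float = 2.0,
    point_density: float = 2.0,
    table: Mapping[tuple[str, str], float] | None = None,
    reference_direction: np.ndarray | None = None,
) -> SurfaceMap2D:
    """Surface MHP map of one model around the given axis."""
    f = assign_constants(model, table)
    surf = build_surface(model, point_density)
    mhp = mhp_at_points(surf, model.coordinates, f, decay_length)
    return cylindrical_project(surf, mhp, axis, map_spec, reference_direction)


def mhp_map_for_trajectory(
    traj,
    segment,
    map_spec: MapSpec = MapSpec(),
    decay_length: float = 2.0,
    point_density: float = 2.0,
    table: Mapping[tuple[str, str], float] | None = None,
    frame_stride: int = 1,
) -> SurfaceMap2D:
    """Trajectory-averaged MHP map with a per-frame helix axis.

    The azimuth reference is anchored to the segment's first-residue
    Calpha in every frame, so the map phase tracks the helix.
    """
    from dataclasses import replace

    from .helix_geometry import fit_axis

    protein = traj.groups.get("protein")
    if map_spec.z_range is None:
        # common grid across frames: span of the first frame's segment,
        # padded so later frames stay in range
        fm0 = traj.frame_model(0)
        axis0 = fit_axis(fm0, segment)
        z0 = (fm0.coordinates - axis0.point) @ axis0.direction
        pad = 4.0
        map_spec = replace(map_spec, z_range=(float(z0.min()) - pad, float(z0.max()) + pad))
    maps = []
    for k in range(0, traj.n_frames, frame_stride):
        fm = traj.frame_model(k)
        if protein is not None and len(protein) < len(fm):
            fm = _submodel(fm, protein)
        axis = fit_axis(fm, segment)
        ref = fm.atom_position(segment.first_residue, "CA") - axis.point
        maps.append(
            mhp_map_for_model(
                fm, axis, map_spec, decay_length, point_density, table, ref
            )
        )
    return average_maps(maps)


def _submodel(model: MolecularModel, indices: np.ndarray) -> MolecularModel:
    return MolecularModel([model.atoms[i] for i in indices], model.model_id)
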