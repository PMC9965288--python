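"""Helix geometry: axis fitting, tilt/kink angles, end-to-end distances,
local bend profiles, RMSD to an ideal helix, RMSF, and two-state
conformer classification of NMR ensembles.

The geometric model of a transmembrane helix used here: the helix axis
of a residue span is the principal axis of its Calpha point cloud
through the centroid, sign-fixed N->C.  A proline hinge splits the
helix into an N-terminal and a C-terminal segment; the kink angle is
the angle between the two segment axes.  Ensembles of a proline-kinked
helix partition into a "straight" (I) and a "bent" (Gamma) conformer
family, recovered here by deterministic 2-means clustering on the
(kink angle, end-to-end distance) plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import Ensemble, MolecularModel, Trajectory

__all__ = [
    "HelixSegment",
    "HelixAxis",
    "GeometryReport",
    "RmsfProfile",
    "BUILTIN_SEGMENTS",
    "IDEAL_RISE",
    "IDEAL_TWIST",
    "CA_RADIUS",
    "BACKBONE_WHEEL",
    "ideal_helix_coordinates",
    "fit_axis",
    "tilt_angle",
    "angle_between_axes",
    "kink_angle",
    "end_to_end_distance",
    "local_bend_profile",
    "rmsd_to_ideal_helix",
    "rmsf_profile",
    "classify_conformers",
    "superpose",
]

#: canonical alpha-helix parameters: rise per residue (A), twist per
#: residue (deg), Calpha radius from the axis (A)
IDEAL_RISE = 1.5
IDEAL_TWIST = 100.0
CA_RADIUS = 2.3

#: cylindrical placement (radius A, phase offset deg, axial offset A) of
#: backbone atoms on the ideal helical wheel, relative to the residue's
#: Calpha position
BACKBONE_WHEEL: dict[str, tuple[float, float, float]] = {
    "N": (1.56, -27.0, -0.90),
    "CA": (CA_RADIUS, 0.0, 0.0),
    "C": (1.64, 27.0, 1.05),
    "O": (1.90, 23.0, 2.25),
}


@dataclass(frozen=True)
class HelixSegment:
    """Residue span defining a helical sub-segment (receptor numbering)."""

    first_residue: int
    last_residue: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.last_residue < self.first_residue + 3:
            raise ValueError(
                f"segment {self.label or ''} {self.first_residue}-{self.last_residue}: "
                "axis fitting needs at least 4 residues"
            )

    @property
    def residues(self) -> range:
        return range(self.first_residue, self.last_residue + 1)

    def __len__(self) -> int:
        return self.last_residue - self.first_residue + 1

    def overlaps(self, other: "HelixSegment") -> bool:
        return not (
            self.last_residue < other.first_residue
            or other.last_residue < self.first_residue
        )


#: helical-segment definitions for the three insulin-subfamily TMDs
#: (receptor numbering).  "pair" is the end-to-end residue pair the
#: report measures; IGF1R carries an extra C-terminal helix used for
#: the glycine-hinge kink after V948.
BUILTIN_SEGMENTS: dict[str, dict] = {
    "InsR": {
        "n_term": HelixSegment(955, 960, "InsR n-term"),
        "c_term": HelixSegment(961, 979, "InsR c-term"),
        "pair": (955, 980),
        "proline": 961,
    },
    "IGF1R": {
        "n_term": HelixSegment(933, 940, "IGF1R n-term"),
        "c_term": HelixSegment(941, 948, "IGF1R central"),
        "c_term2": HelixSegment(951, 960, "IGF1R c-term"),
        "pair": (933, 960),
        "proline": 941,
    },
    "IRR": {
        "n_term": HelixSegment(919, 925, "IRR n-term"),
        "c_term": HelixSegment(929, 946, "IRR c-term"),
        "pair": (919, 946),
        "proline": 928,
    },
}


@dataclass(frozen=True)
class HelixAxis:
    """Least-squares helix axis: unit direction (N->C) plus a point on it."""

    direction: np.ndarray
    point: np.ndarray
    segment: HelixSegment | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))


def ideal_helix_coordinates(
    n_residues: int,
    rise: float = IDEAL_RISE,
    twist: float = IDEAL_TWIST,
    atoms: Sequence[str] = ("N", "CA", "C", "O"),
) -> dict[str, np.ndarray]:
    """Backbone coordinates of an ideal helix built along +z.

    Returns atom-name -> (n_residues, 3) arrays.  Residue i has wheel
    phase ``i * twist`` and axial position ``i * rise``.
    """
    out: dict[str, np.ndarray] = {}
    idx = np.arange(n_residues)
    for name in atoms:
        r, dphi, dz = BACKBONE_WHEEL[name]
        phi = np.deg2rad(idx * twist + dphi)
        out[name] = np.column_stack(
            [r * np.cos(phi), r * np.sin(phi), idx * rise + dz]
        )
    return out


def _ca_coords(model: MolecularModel, segment: HelixSegment) -> np.ndarray:
    coords = []
    for rn in segment.residues:
        try:
            coords.append(model.atom_position(rn, "CA"))
        except KeyError as exc:
            raise ValueError(
                f"segment {segment.label or segment.first_residue}: missing CA of "
                f"residue {rn}"
            ) from exc
    return np.array(coords)


def _local_helix_centers(ca: np.ndarray, radius: float = CA_RADIUS) -> np.ndarray:
    """Displace interior Calpha toward the helix axis.

    For an ideal helix the second difference p[i-1] + p[i+1] - 2 p[i]
    points exactly at the axis, so p[i] + radius * unit(diff) lies on
    it; this cancels the 100-deg helical wobble that biases a plain
    principal-axis fit on short (sub-two-turn) segments.
    """
    v = ca[:-2] + ca[2:] - 2.0 * ca[1:-1]
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    safe = norms > 1e-8
    u = np.where(safe, v / np.where(safe, norms, 1.0), 0.0)
    return ca[1:-1] + radius * u


def fit_axis(model: MolecularModel, segment: HelixSegment) -> HelixAxis:
    """Fit the helix axis of a segment.

    Principal axis (first right singular vector) of the Calpha points
    displaced onto their local helix centers, through the centroid;
    this minimizes the squared point-to-line distances of the
    wobble-corrected cloud and is unbiased on segments much shorter
    than two helical turns.  The sign is fixed so the direction points
    from the N- to the C-terminus of the segment.
    """
    ca = _ca_coords(model, segment)
    if len(ca) < 4:
        raise ValueError("axis fitting needs at least 4 CA positions")
    pts = _local_helix_centers(ca)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    return HelixAxis(direction / np.linalg.norm(direction), centroid, segment)


def tilt_angle(axis: HelixAxis, normal: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """Tilt of the helix axis vs the membrane normal, degrees in [0, 90].

    Sign-free by convention: uses |cos|, so an axis and its negation
    tilt identically.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    c = abs(float(np.dot(axis.direction, n)))
    return math.degrees(math.acos(min(1.0, c)))


def angle_between_axes(a: HelixAxis, b: HelixAxis) -> float:
    """Full [0, 180] angle between two N->C oriented axes, degrees."""
    c = float(np.dot(a.direction, b.direction))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def kink_angle(
    model: MolecularModel, segment_n: HelixSegment, segment_c: HelixSegment
) -> float:
    """Inter-segment (hinge) angle between two fitted helix axes, degrees."""
    if segment_n.overlaps(segment_c):
        raise ValueError(
            f"segments {segment_n.first_residue}-{segment_n.last_residue} and "
            f"{segment_c.first_residue}-{segment_c.last_residue} overlap"
        )
    return angle_between_axes(fit_axis(model, segment_n), fit_axis(model, segment_c))


def end_to_end_distance(
    model: MolecularModel, residue_a: int, residue_b: int, atom_name: str = "CA"
) -> float:
    """Euclidean distance between the named atoms of two residues, A."""
    try:
        pa = model.atom_position(residue_a, atom_name)
    except KeyError:
        raise ValueError(f"residue {residue_a} has no {atom_name} atom") from None
    try:
        pb = model.atom_position(residue_b, atom_name)
    except KeyError:
        raise ValueError(f"residue {residue_b} has no {atom_name} atom") from None
    return float(np.linalg.norm(pa - pb))


def local_bend_profile(
    model: MolecularModel, full_segment: HelixSegment, window: int = 4
) -> dict[int, float]:
    """Per-residue local bend angle, degrees.

    For residue r the bend is the angle between axes fitted to
    [r-window, r] and [r, r+window].  Residues whose windows fall
    outside the segment get NaN.
    """
    if window < 4:
        raise ValueError("window must be >= 4 residues")
    if len(full_segment) < 2 * window:
        raise ValueError(
            f"segment of {len(full_segment)} residues too short for window {window}"
        )
    out: dict[int, float] = {}
    for r in full_segment.residues:
        lo, hi = r - window, r + window
        if lo < full_segment.first_residue or hi > full_segment.last_residue:
            out[r] = float("nan")
            continue
        left = HelixSegment(lo, r, f"bend-left@{r}")
        right = HelixSegment(r, hi, f"bend-right@{r}")
        out[r] = angle_between_axes(fit_axis(model, left), fit_axis(model, right))
    return out


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns the transformed mobile coordinates and the RMSD, A.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mobile - mc) @ rot.T + tc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return moved, rmsd


def rmsd_to_ideal_helix(
    model: MolecularModel,
    segment: HelixSegment,
    window: int = 7,
    atoms: Sequence[str] = ("N", "CA", "C", "O"),
) -> dict[int, float]:
    """Per-residue RMSD from an ideal alpha-helix, A.

    Each ``window``-residue stretch of backbone is optimally superposed
    onto an ideal helix template (rise 1.5 A, twist 100 deg); a residue
    gets the RMSD of the best-fitting window covering it.  Residues
    with missing backbone atoms are NaN and excluded from windows.
    """
    template = ideal_helix_coordinates(window, atoms=atoms)
    template_xyz = np.concatenate([template[a] for a in atoms], axis=0)
    # template atom order: all N, then all CA, ... matched below
    best: dict[int, float] = {r: float("inf") for r in segment.residues}
    ok_residue: dict[int, bool] = {}
    for r in segment.residues:
        ok_residue[r] = all(
            _has_atom(model, r, a) for a in atoms
        )
    for start in range(segment.first_residue, segment.last_residue - window + 2):
        span = list(range(start, start + window))
        if not all(ok_residue[r] for r in span):
            continue
        obs = np.concatenate(
            [np.array([model.atom_position(r, a) for r in span]) for a in atoms],
            axis=0,
        )
        _, rmsd = superpose(obs, template_xyz)
        for r in span:
            best[r] = min(best[r], rmsd)
    return {
        r: (best[r] if ok_residue[r] and np.isfinite(best[r]) else float("nan"))
        for r in segment.residues
    }


def _has_atom(model: MolecularModel, residue: int, name: str) -> bool:
    try:
        model.atom_index(residue, name)
        return True
    except KeyError:
        return False


@dataclass
class RmsfProfile:
    """Per-residue RMSF (A) of a named atom over a trajectory."""

    values: dict[int, float]
    atom_name: str = "CA"

    def __getitem__(self, residue: int) -> float:
        return self.values[residue]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=f"rmsf_{self.atom_name}_A").sort_index()


def rmsf_profile(
    traj: Trajectory,
    atom_name: str = "CA",
    superpose_frames: bool = True,
    residue_numbers: Sequence[int] | None = None,
) -> RmsfProfile:
    """RMSF per residue: sqrt(mean_t |x(t) - <x>|^2) of the named atom.

    With ``superpose_frames`` each frame's selection is first rigidly
    superposed onto the frame-mean structure (two-pass: mean of raw
    frames as initial reference, then mean of superposed frames).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    topo = traj.topology
    if residue_numbers is None:
        residue_numbers = [
            rn for rn in topo.residue_numbers() if _has_atom(topo, rn, atom_name)
        ]
    idx = np.array([topo.atom_index(rn, atom_name) for rn in residue_numbers])
    if idx.size == 0:
        raise ValueError("empty atom selection for RMSF")
    x = traj.frames[:, idx, :]  # (F, M, 3)
    if superpose_frames:
        ref = x.mean(axis=0)
        for _ in range(2):
            x = np.stack([superpose(f, ref)[0] for f in x])
            ref = x.mean(axis=0)
    mean = x.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    return RmsfProfile(dict(zip(residue_numbers, rmsf.tolist())), atom_name)


# ---------------------------------------------------------------------------
# Two-state conformer classification


@dataclass
class GeometryReport:
    """Per-model geometry and two-state classification of an ensemble."""

    per_model: pd.DataFrame  # model_id, kink_deg, end_to_end_A, state
    clusters: dict[str, dict[str, float]]
    warnings: list[str] = field(default_factory=list)
    schema_version: str = "1"

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "per_model": self.per_model.to_dict(orient="records"),
            "clusters": self.clusters,
            "warnings": self.warnings,
        }

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")
        return None


def _two_means(points: np.ndarray, init: tuple[int, int], max_iter: int = 100):
    """Deterministic 2-means; returns labels (0/1) per row."""
    centers = points[list(init)].copy()
    labels = np.zeros(len(points), dtype=int)
    for _ in range(max_iter):
        d0 = np.linalg.norm(points - centers[0], axis=1)
        d1 = np.linalg.norm(points - centers[1], axis=1)
        # exact ties go to cluster 0 (the lower-index init model)
        new = (d1 < d0).astype(int)
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for k in (0, 1):
            if np.any(labels == k):
                centers[k] = points[labels == k].mean(axis=0)
    return labels


def classify_conformers(
    ensemble: Ensemble,
    segment_n: HelixSegment,
    segment_c: HelixSegment,
    residue_a: int,
    residue_b: int,
) -> GeometryReport:
    """Partition an ensemble into straight (I) and bent (Gamma) conformers.

    Computes (kink angle, end-to-end distance) per model, standardizes
    both, and runs deterministic 2-means initialized at the models with
    the minimum and maximum kink angle.  The lower-angle cluster is
    labelled "straight", the other "bent".  An ensemble of identical
    models yields a single cluster with a warning flag.
    """
    if len(ensemble) < 2:
        raise ValueError("classification needs at least 2 models")
    rows = []
    for m in ensemble:
        rows.append(
            {
                "model_id": m.model_id,
                "kink_deg": kink_angle(m, segment_n, segment_c),
                "end_to_end_A": end_to_end_distance(m, residue_a, residue_b),
            }
        )
    df = pd.DataFrame(rows)
    warnings: list[str] = []
    feats = df[["kink_deg", "end_to_end_A"]].to_numpy()
    sd = feats.std(axis=0)
    if np.all(sd < 1e-9):
        df["state"] = "straight"
        warnings.append("all models identical: single-cluster result")
        clusters = {
            "straight": _cluster_stats(df),
        }
        return GeometryReport(df, clusters, warnings)
    scale = np.where(sd < 1e-12, 1.0, sd)
    z = (feats - feats.mean(axis=0)) / scale
    i_min = int(df["kink_deg"].idxmin())
    i_max = int(df["kink_deg"].idxmax())
    labels = _two_means(z, (i_min, i_max))
    mean_angles = [df.loc[labels == k, "kink_deg"].mean() for k in (0, 1)]
    straight_k = int(np.argmin(mean_angles))
    df["state"] = ["straight" if l == straight_k else "bent" for l in labels]
    if df["state"].nunique() == 1:
        warnings.append("clustering collapsed to a single cluster")
    clusters = {
        state: _cluster_stats(sub)
        for state, sub in df.groupby("state")
    }
    return GeometryReport(df, clusters, warnings)


def _cluster_stats(sub: pd.DataFrame) -> dict[str, float]:
    return {
        "n": int(len(sub)),
        "kink_deg_mean": float(sub["kink_deg"].mean()),
        "kink_deg_sd": float(sub["kink_deg"].std(ddof=0)),
        "end_to_end_A_mean": float(sub["end_to_end_A"].mean()),
        "end_to_end_A_sd": float(sub["end_to_end_A"].std(ddof=0)),
    }
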