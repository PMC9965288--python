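"""Synthetic fixtures with known ground truth.

Generates: ideal or proline-kinked alpha-helical peptides, two-state
NMR-style ensembles (straight/bent mixtures), coarse pseudo-bilayer
lipid-bead trajectories with a controllable immobilized-lipid fraction,
and relaxation intensity pairs produced from known rotational
correlation times.  Every generator is deterministic given its seed and
returns its ground truth alongside the fixture.

Also provided are synthetic stand-in ensembles for the three deposited
insulin-subfamily TMD NMR ensembles, built from the published construct
sequences and printed hinge geometry.  They are stand-ins, not the
deposited coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .helix_geometry import (
    BACKBONE_WHEEL,
    BUILTIN_SEGMENTS,
    IDEAL_RISE,
    IDEAL_TWIST,
    ideal_helix_coordinates,
)
from .nmr_metrics import RelaxationParams, forward_eta
from .structure_io import Atom, Ensemble, IntensityRecord, MolecularModel, Trajectory

__all__ = [
    "HelixSpec",
    "BilayerSpec",
    "make_helix",
    "make_random_coil",
    "make_two_state_ensemble",
    "make_bilayer_trajectory",
    "make_relaxation_table",
    "standin_ensemble",
    "STANDIN_SEQUENCES",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: coarse side-chain tip atom per residue (the functionally dominant
#: heavy atom), used when a spec requests side chains; CB is added for
#: every non-glycine residue
_SIDECHAIN_TIP = {
    "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "LEU": "CG",
    "ILE": "CG1", "MET": "SD", "PHE": "CZ", "TYR": "OH", "TRP": "NE1",
    "ASN": "ND2", "GLN": "NE2", "ASP": "OD1", "GLU": "OE1", "LYS": "NZ",
    "ARG": "NH1", "HIS": "NE2", "PRO": "CG",
}
# wheel placement (radius A, phase offset deg, axial offset A) of the
# coarse side-chain beads, pointing away from the helix axis
_CB_WHEEL = (3.3, -18.0, -0.5)
_TIP_WHEEL = (4.6, -22.0, -0.8)


@dataclass(frozen=True)
class HelixSpec:
    """Recipe for a backbone helix with an optional hinge.

    ``kink_position``/``kink_angle`` may be single values or parallel
    sequences for multiple coplanar hinges; the hinge rotates all
    residues after the kink residue rigidly about an axis through that
    residue's Calpha, perpendicular to the helix axis.
    ``kink_direction_deg`` sets the azimuth of that rotation axis in
    the plane normal to the helix — the direction the helix bends
    toward, which also controls how much a bend shortens the
    end-to-end distance.
    """

    sequence: str
    first_residue: int = 1
    rise: float = IDEAL_RISE
    twist: float = IDEAL_TWIST
    kink_position: int | Sequence[int] | None = None
    kink_angle: float | Sequence[float] = 0.0
    kink_direction_deg: float = 90.0
    coordinate_noise_sd: float = 0.0
    seed: int = 0
    chain: str = "A"
    side_chains: bool = False  # add coarse CB + tip beads per residue

    def __post_init__(self) -> None:
        if self.coordinate_noise_sd < 0:
            raise ValueError("noise must be >= 0")
        for p in self.kinks():
            if not (self.first_residue < p[0] < self.first_residue + len(self.sequence) - 1):
                raise ValueError(f"kink position {p[0]} outside the sequence")

    def kinks(self) -> list[tuple[int, float]]:
        if self.kink_position is None:
            return []
        if np.isscalar(self.kink_position):
            return [(int(self.kink_position), float(self.kink_angle))]
        return [
            (int(p), float(a))
            for p, a in zip(self.kink_position, np.atleast_1d(self.kink_angle))
        ]


def _rotation_matrix(axis_azimuth_deg: float, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation by ``angle`` about the in-plane unit vector at
    azimuth ``axis_azimuth_deg`` (measured in the xy-plane from +x)."""
    psi = np.deg2rad(axis_azimuth_deg)
    u = np.array([np.cos(psi), np.sin(psi), 0.0])
    th = np.deg2rad(angle_deg)
    k = np.array([[0.0, -u[2], u[1]], [u[2], 0.0, -u[0]], [-u[1], u[0], 0.0]])
    return np.eye(3) + np.sin(th) * k + (1.0 - np.cos(th)) * (k @ k)


def make_helix(spec: HelixSpec) -> MolecularModel:
    """Build a backbone (N, CA, C, O) helix from a :class:`HelixSpec`.

    The helix is built along +z on the ideal helical wheel; hinges are
    applied as rigid rotations in residue order; Gaussian coordinate
    noise (if any) is added last, seeded.
    """
    seq = spec.sequence.upper()
    for letter in seq:
        if letter not in _ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")
    n = len(seq)

    def wheel_pos(i: int, r: float, dphi: float, dz: float) -> np.ndarray:
        phi = np.deg2rad(i * spec.twist + dphi)
        return np.array([r * np.cos(phi), r * np.sin(phi), i * spec.rise + dz])

    names: list[tuple[int, str, str]] = []  # (residue index, atom name, resname)
    positions: list[np.ndarray] = []
    ca_index: dict[int, int] = {}
    for i, letter in enumerate(seq):
        resname = _ONE_TO_THREE[letter]
        for aname in _BACKBONE_ATOMS:
            r, dphi, dz = BACKBONE_WHEEL[aname]
            if aname == "CA":
                ca_index[i] = len(positions)
            names.append((i, aname, resname))
            positions.append(wheel_pos(i, r, dphi, dz))
        if spec.side_chains and resname != "GLY":
            names.append((i, "CB", resname))
            positions.append(wheel_pos(i, *_CB_WHEEL))
            tip = _SIDECHAIN_TIP.get(resname)
            if tip is not None:
                names.append((i, tip, resname))
                positions.append(wheel_pos(i, *_TIP_WHEEL))
    coords = np.array(positions)

    res_of_atom = np.array([i for i, _, _ in names])
    for kink_res, angle in spec.kinks():
        k = kink_res - spec.first_residue
        pivot = coords[ca_index[k]].copy()
        rot = _rotation_matrix(spec.kink_direction_deg, angle)
        sel = res_of_atom > k
        coords[sel] = (coords[sel] - pivot) @ rot.T + pivot

    if spec.coordinate_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.coordinate_noise_sd, coords.shape)

    atoms: list[Atom] = []
    for serial, ((i, aname, resname), pos) in enumerate(zip(names, coords), start=1):
        atoms.append(
            Atom(
                serial=serial,
                name=aname,
                element=aname[0],
                residue_number=spec.first_residue + i,
                residue_name=resname,
                chain=spec.chain,
                position=pos,
            )
        )
    return MolecularModel(atoms, model_id=1)


def make_random_coil(spec: HelixSpec) -> MolecularModel:
    """Random-coil control: helix backbone scrambled by large noise.

    Uses per-atom Gaussian displacement of 3 A (overriding the spec's
    noise), destroying helical regularity while keeping chain
    connectivity roughly intact for window fitting.
    """
    noisy = replace(spec, coordinate_noise_sd=3.0)
    return make_helix(noisy)


def make_two_state_ensemble(
    spec_straight: HelixSpec,
    spec_bent: HelixSpec,
    n_straight: int,
    n_bent: int,
    seed: int = 0,
    angle_sd: float = 0.0,
) -> tuple[Ensemble, list[str]]:
    """Mixture ensemble of straight and bent conformers.

    Per-model hinge angles are drawn N(spec angle, angle_sd); per-model
    coordinate noise uses child seeds of ``seed``.  Returns the
    ensemble and the ground-truth label list ("straight"/"bent") in
    model order.
    """
    if n_straight + n_bent < 2:
        raise ValueError("ensemble needs at least 2 models")
    rng = np.random.default_rng(seed)
    models = []
    labels = []
    for i in range(n_straight + n_bent):
        base = spec_straight if i < n_straight else spec_bent
        labels.append("straight" if i < n_straight else "bent")
        angles = np.atleast_1d(np.asarray(base.kink_angle, dtype=float)).copy()
        if angle_sd > 0 and angles.size:
            angles = angles + rng.normal(0.0, angle_sd, angles.shape)
        model_seed = int(rng.integers(0, 2**31 - 1))
        spec_i = replace(
            base,
            kink_angle=angles if angles.size > 1 else float(angles[0]) if angles.size else 0.0,
            seed=model_seed,
        )
        m = make_helix(spec_i)
        models.append(m.with_coordinates(m.coordinates, model_id=i + 1))
    return Ensemble(models), labels


@dataclass(frozen=True)
class BilayerSpec:
    """Recipe for a coarse pseudo-bilayer lipid-bead trajectory.

    Lipids are bead chains (one head, ``tail_bead_count`` tail beads)
    performing a lateral random walk around a rigid helix; a fraction
    of them is immobilized near the helix surface at a fixed azimuth
    (staying within 1 A of its anchor), emulating the "frozen" lipid
    patches seen on straight TM helices.
    """

    lipid_count: int = 64  # per leaflet
    leaflet_z: tuple[float, float] = (12.6, -12.6)
    tail_bead_count: int = 4
    bead_spacing: float = 2.8  # A between beads along z
    immobilized_fraction: float = 0.0
    immobilized_azimuth: float = 90.0  # degrees
    frame_count: int = 100
    diffusion_step: float = 3.0  # A per frame
    min_radius: float = 5.0  # helix exclusion, A
    max_radius: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.immobilized_fraction <= 1.0:
            raise ValueError("immobilized_fraction must lie in [0, 1]")
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")


def make_bilayer_trajectory(
    helix: MolecularModel, spec: BilayerSpec
) -> tuple[Trajectory, np.ndarray]:
    """Rigid helix plus random-walking lipid beads.

    The helix is recentred so its geometric centre sits at the origin
    (axis along z as built by :func:`make_helix`).  Returns the
    trajectory and the ground-truth boolean mask of immobilized lipids
    (length = total lipid count).
    """
    rng = np.random.default_rng(spec.seed)
    helix_xyz = helix.coordinates
    centre = helix_xyz.mean(axis=0)
    helix_xyz = helix_xyz - centre

    n_leaflets = len(spec.leaflet_z)
    total = spec.lipid_count * n_leaflets
    n_imm = int(round(spec.immobilized_fraction * total))
    imm_mask = np.zeros(total, dtype=bool)
    imm_mask[rng.permutation(total)[:n_imm]] = True

    # lateral anchor positions
    anchors = np.empty((total, 2))
    for li in range(total):
        if imm_mask[li]:
            az = np.deg2rad(spec.immobilized_azimuth + rng.uniform(-5.0, 5.0))
            r = spec.min_radius + rng.uniform(0.0, 1.0)
            anchors[li] = [r * np.cos(az), r * np.sin(az)]
        else:
            for attempt in range(100):
                xy = rng.uniform(-spec.max_radius, spec.max_radius, 2)
                r = np.hypot(*xy)
                if spec.min_radius <= r <= spec.max_radius:
                    anchors[li] = xy
                    break
            else:
                raise RuntimeError(
                    "failed to place a lipid outside the helix core after 100 tries"
                )

    # bead z-offsets per lipid: head at the leaflet plane, tails toward z=0.
    # Per-frame z jitter of half the bead spacing makes adjacent bead bands
    # tile the leaflet, so the time-averaged z distribution is uniform.
    n_beads = spec.tail_bead_count + 1
    bead_z = np.empty((total, n_beads))
    for li in range(total):
        zplane = spec.leaflet_z[li // spec.lipid_count]
        sign = -np.sign(zplane) if zplane != 0 else -1.0
        bead_z[li] = zplane + sign * spec.bead_spacing * np.arange(n_beads)
    half = spec.bead_spacing / 2.0

    def lipid_coords(xy: np.ndarray) -> np.ndarray:
        """(total, beads, 3) coordinates from lateral positions."""
        out = np.empty((total, n_beads, 3))
        out[:, :, 0] = xy[:, None, 0]
        out[:, :, 1] = xy[:, None, 1]
        jitter = rng.uniform(-half, half, (total, n_beads))
        # immobilized lipids bob less, staying near their anchor geometry
        jitter[imm_mask] *= 0.35
        out[:, :, 2] = bead_z + jitter
        return out

    frames = np.empty(
        (spec.frame_count, len(helix_xyz) + total * (spec.tail_bead_count + 1), 3)
    )
    xy = anchors.copy()
    for k in range(spec.frame_count):
        if k > 0:
            step = rng.normal(0.0, spec.diffusion_step, (total, 2))
            cand = xy + step
            # immobilized lipids stay within 1 A of their anchor
            off = cand[imm_mask] - anchors[imm_mask]
            d = np.linalg.norm(off, axis=1, keepdims=True)
            too_far = (d > 1.0).ravel()
            cand[np.where(imm_mask)[0][too_far]] = (
                anchors[imm_mask][too_far]
                + off[too_far] / d[too_far] * 1.0
            )
            # mobile lipids reflect at the radial bounds
            r = np.linalg.norm(cand, axis=1)
            low = (~imm_mask) & (r < spec.min_radius)
            high = (~imm_mask) & (r > spec.max_radius)
            cand[low] *= (spec.min_radius / r[low])[:, None]
            cand[high] *= (spec.max_radius / r[high])[:, None]
            xy = cand
        frames[k, : len(helix_xyz)] = helix_xyz
        frames[k, len(helix_xyz) :] = lipid_coords(xy).reshape(-1, 3)

    # topology from frame 0
    atoms = [
        Atom(a.serial, a.name, a.element, a.residue_number, a.residue_name, a.chain, p)
        for a, p in zip(helix.atoms, frames[0, : len(helix_xyz)])
    ]
    serial = len(atoms) + 1
    resnum = max(a.residue_number for a in helix.atoms) + 1
    lip0 = frames[0, len(helix_xyz) :].reshape(total, spec.tail_bead_count + 1, 3)
    for li in range(total):
        names = ["PH"] + [f"C{t + 1}" for t in range(spec.tail_bead_count)]
        for b, name in enumerate(names):
            atoms.append(
                Atom(serial, name, name[0], resnum + li, "LIP", "L", lip0[li, b])
            )
            serial += 1
    topology = MolecularModel(atoms, model_id=0)

    n_helix = len(helix_xyz)
    lipid_idx = np.arange(n_helix, len(atoms))
    heads = lipid_idx[[(i - n_helix) % (spec.tail_bead_count + 1) == 0 for i in lipid_idx]]
    tails = np.array(sorted(set(lipid_idx) - set(heads)), dtype=int)
    groups = {
        "protein": np.arange(n_helix),
        "lipid": lipid_idx,
        "lipid_heads": heads,
        "lipid_tails": tails,
    }
    return Trajectory(topology, frames, groups=groups), imm_mask


def make_relaxation_table(
    tau_per_residue: Mapping[int, float],
    params: RelaxationParams = RelaxationParams(),
    noise_fraction: float = 0.0,
    seed: int = 0,
    i_ref_base: float = 1e5,
) -> list[IntensityRecord]:
    """Intensity pairs from known tau_R via the forward relaxation model.

    I_att / I_ref = exp(-2 Delta eta(tau)); multiplicative Gaussian
    noise of relative size ``noise_fraction`` is applied independently
    to both intensities, and ``sigma_noise`` records the absolute noise
    level used.
    """
    rng = np.random.default_rng(seed)
    out = []
    for residue, tau in sorted(tau_per_residue.items()):
        if tau <= 0:
            raise ValueError(f"residue {residue}: tau must be positive")
        eta = forward_eta(tau, params)
        i_ref = i_ref_base
        i_att = i_ref_base * np.exp(-2.0 * params.delta_s * eta)
        if noise_fraction > 0:
            i_ref *= 1.0 + rng.normal(0.0, noise_fraction)
            i_att *= 1.0 + rng.normal(0.0, noise_fraction)
        out.append(
            IntensityRecord(
                residue_number=residue,
                i_ref=float(i_ref),
                i_att=float(i_att),
                sigma_noise=float(noise_fraction * i_ref_base),
            )
        )
    return out


#: published construct sequences (receptor numbering of the first residue)
STANDIN_SEQUENCES: dict[str, tuple[str, int]] = {
    "InsR": ("SNIAKIIIGPLIFVFLFSVVIGSIYLFLRKR", 952),
    "IGF1R": ("NFIHLIIALPVAVLLIVGGLVIMLYVFHRKR", 932),
    "IRR": ("AGGLHVLLTATPVGLTLLIVLAALGFFYGKKR", 917),
}

#: hinge geometry of the stand-ins: (kink positions, kink angles) per state
_STANDIN_GEOMETRY: dict[str, dict] = {
    # IRR: two-state mixture, hinge at P928 (26 deg straight / 70 deg bent);
    # bend azimuth chosen so the hinge geometry matches the printed
    # end-to-end characterization (~40 A straight, ~33 A bent)
    "IRR": {"two_state": True, "kink": 928, "straight_deg": 26.0, "bent_deg": 70.0,
            "straight_sd": 3.0, "bent_sd": 5.0, "direction_deg": 210.0},
    # InsR: single family, ~26 deg bend at P961, A955-R980 ~40 A
    "InsR": {"two_state": False, "kink": 961, "angle_deg": 26.0, "sd": 2.0,
             "direction_deg": 240.0},
    # IGF1R: ~30 deg bend at P941 plus ~10 deg kink at the G949-G950 hinge,
    # F933-R960 ~40 A
    "IGF1R": {"two_state": False, "kink": (941, 949), "angle_deg": (30.0, 10.0),
              "sd": 2.0, "direction_deg": 300.0},
}


def standin_ensemble(
    name: str,
    n_models: int = 20,
    coordinate_noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[Ensemble, list[str]]:
    """SYNTHETIC stand-in for a deposited TMD NMR ensemble.

    Built from the published construct sequence and printed hinge
    geometry of the named receptor ("InsR", "IGF1R" or "IRR"); NOT the
    deposited coordinates.  IRR is generated as a 50/50 straight/bent
    two-state mixture; InsR and IGF1R as single-family ensembles with
    small hinge-angle jitter.  Returns (ensemble, ground-truth labels).
    """
    if name not in STANDIN_SEQUENCES:
        raise KeyError(f"unknown receptor {name!r}")
    seq, first = STANDIN_SEQUENCES[name]
    geo = _STANDIN_GEOMETRY[name]
    if geo["two_state"]:
        straight = HelixSpec(
            seq, first, kink_position=geo["kink"], kink_angle=geo["straight_deg"],
            kink_direction_deg=geo["direction_deg"],
            coordinate_noise_sd=coordinate_noise_sd,
        )
        bent = replace(straight, kink_angle=geo["bent_deg"])
        n_str = n_models // 2
        ens, labels = make_two_state_ensemble(
            straight, bent, n_str, n_models - n_str, seed=seed,
            angle_sd=0.5 * (geo["straight_sd"] + geo["bent_sd"]),
        )
        return ens, labels
    base = HelixSpec(
        seq, first, kink_position=geo["kink"], kink_angle=geo["angle_deg"],
        kink_direction_deg=geo["direction_deg"],
        coordinate_noise_sd=coordinate_noise_sd,
    )
    ens, labels = make_two_state_ensemble(
        base, base, n_models, 0, seed=seed, angle_sd=geo["sd"]
    )
    return ens, labels
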