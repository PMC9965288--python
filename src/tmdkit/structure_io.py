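"""Reading and writing of external formats.

Multi-model PDB ensembles (NMR depositions), multi-frame coordinate
trajectories, chemical-shift / relaxation-intensity tables, and 2D map
exports.  All coordinates are in Angstrom and author (receptor) residue
numbering is preserved exactly as found in the source file: residue 919
in the file is residue 919 in memory.

PDB parsing and writing are delegated to :mod:`gemmi`; this module adds
the validation contracts (consistent atom ordering across models,
line-numbered errors for broken ATOM records) and the in-memory types
the analysis modules consume.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "MolecularModel",
    "Ensemble",
    "Trajectory",
    "ShiftRecord",
    "IntensityRecord",
    "StructureIOError",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_trajectory",
    "write_xyz_frames",
    "read_shift_table",
    "read_intensity_table",
    "write_map_tsv",
    "read_map_tsv",
]

#: residue names treated as solvent and skipped on read
SOLVENT_RESNAMES = {"HOH", "WAT", "DOD", "SOL"}


class StructureIOError(ValueError):
    """Structured error raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class Atom:
    """One atom with author numbering preserved.

    ``residue_number`` keeps the receptor numbering used throughout the
    analysis (e.g. P961 of InsR, P928 of IRR).
    """

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    position: np.ndarray  # (3,) float, Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureIOError(
                f"atom {self.serial} {self.name}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise StructureIOError(f"atom {self.serial} {self.name}: empty element")


class MolecularModel:
    """Ordered collection of atoms forming one structural model."""

    def __init__(self, atoms: Sequence[Atom], model_id: int = 1):
        if len(atoms) == 0:
            raise StructureIOError("model must contain at least one atom")
        self.atoms: list[Atom] = list(atoms)
        self.model_id = int(model_id)
        keys = [(a.chain, a.residue_number, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise StructureIOError(
                f"model {model_id}: duplicate (chain, residue, atom-name) triples"
            )
        self._index: dict[tuple[str, int, str], int] = {
            k: i for i, k in enumerate(keys)
        }

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray, model_id: int | None = None) -> "MolecularModel":
        """Copy of this model with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureIOError(
                f"coordinate array shape {coords.shape} does not match atom count {len(self.atoms)}"
            )
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_number, a.residue_name, a.chain, c)
            for a, c in zip(self.atoms, coords)
        ]
        return MolecularModel(atoms, self.model_id if model_id is None else model_id)

    def residue_numbers(self) -> list[int]:
        """Sorted unique residue numbers present."""
        return sorted({a.residue_number for a in self.atoms})

    def residue_names(self) -> dict[int, str]:
        return {a.residue_number: a.residue_name for a in self.atoms}

    def atom_index(self, residue_number: int, atom_name: str, chain: str | None = None) -> int:
        """Index of a named atom; raises with the residue named if absent."""
        if chain is not None:
            key = (chain, residue_number, atom_name)
            if key in self._index:
                return self._index[key]
        else:
            for (ch, rn, an), i in self._index.items():
                if rn == residue_number and an == atom_name:
                    return i
        raise KeyError(
            f"atom {atom_name} of residue {residue_number} not present in model {self.model_id}"
        )

    def atom_position(self, residue_number: int, atom_name: str = "CA") -> np.ndarray:
        return self.atoms[self.atom_index(residue_number, atom_name)].position

    def select_indices(
        self,
        atom_names: Iterable[str] | None = None,
        residue_numbers: Iterable[int] | None = None,
        residue_names: Iterable[str] | None = None,
    ) -> np.ndarray:
        names = set(atom_names) if atom_names is not None else None
        resnums = set(residue_numbers) if residue_numbers is not None else None
        resnames = set(residue_names) if residue_names is not None else None
        out = [
            i
            for i, a in enumerate(self.atoms)
            if (names is None or a.name in names)
            and (resnums is None or a.residue_number in resnums)
            and (resnames is None or a.residue_name in resnames)
        ]
        return np.array(out, dtype=int)


class Ensemble:
    """Ordered list of models sharing one topology (an NMR ensemble)."""

    def __init__(self, models: Sequence[MolecularModel]):
        if len(models) == 0:
            raise StructureIOError("ensemble must contain at least one model")
        first = models[0]
        sig = [(a.chain, a.residue_number, a.name) for a in first.atoms]
        for m in models[1:]:
            if len(m) != len(first):
                raise StructureIOError(
                    f"model {m.model_id}: atom count {len(m)} differs from "
                    f"model {first.model_id} ({len(first)})"
                )
            if [(a.chain, a.residue_number, a.name) for a in m.atoms] != sig:
                raise StructureIOError(
                    f"model {m.model_id}: atom ordering differs from model {first.model_id}"
                )
        self.models: list[MolecularModel] = list(models)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i: int) -> MolecularModel:
        return self.models[i]

    @property
    def sequence(self) -> dict[int, str]:
        """Shared residue_number -> residue_name mapping."""
        return self.models[0].residue_names()


@dataclass
class Trajectory:
    """Topology plus time-ordered coordinate frames.

    ``groups`` maps a name ("protein", "lipid", "lipid_heads",
    "lipid_tails") to atom indices into the topology.
    """

    topology: MolecularModel
    frames: np.ndarray  # (F, N, 3) Angstrom
    frame_spacing: float = 1.0  # metadata only
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        n = len(self.topology)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n, 3):
            raise StructureIOError(
                f"frames shape {self.frames.shape} incompatible with {n} topology atoms"
            )
        for name, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise StructureIOError(f"group '{name}' has out-of-range atom indices")
            self.groups[name] = idx

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_model(self, k: int) -> MolecularModel:
        """Topology with the coordinates of frame ``k``."""
        return self.topology.with_coordinates(self.frames[k], model_id=k)


@dataclass(frozen=True)
class ShiftRecord:
    residue_number: int
    atom: str
    shift: float  # ppm
    residue_name: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.shift):
            raise StructureIOError(
                f"residue {self.residue_number} {self.atom}: shift not finite"
            )


@dataclass(frozen=True)
class IntensityRecord:
    residue_number: int
    i_ref: float
    i_att: float
    sigma_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.i_ref <= 0:
            raise StructureIOError(
                f"residue {self.residue_number}: reference intensity must be > 0"
            )
        if self.sigma_noise < 0:
            raise StructureIOError(
                f"residue {self.residue_number}: sigma_noise must be >= 0"
            )


# ---------------------------------------------------------------------------
# PDB ensembles


def _prescan_pdb(path: Path) -> None:
    """Line-numbered validation of ATOM/HETATM coordinate fields."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise StructureIOError(
                        f"{path}, line {lineno}: truncated ATOM record"
                    )
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise StructureIOError(
                        f"{path}, line {lineno}: unparsable ATOM record ({exc})"
                    ) from exc


def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy altloc per atom name, ties to the first."""
    best: dict[str, gemmi.Atom] = {}
    for at in residue:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ:
            best[at.name] = at
    # preserve file order of the winners
    chosen = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in chosen]


def read_pdb_ensemble(path: str | Path, skip_solvent: bool = True) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    Models are ordered by MODEL number; single-model files yield a
    1-model ensemble.  HETATM solvent is skipped.  Altloc handling keeps
    the highest-occupancy conformer (ties to the first seen).
    """
    path = Path(path)
    _prescan_pdb(path)
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    models: list[MolecularModel] = []
    for gm in st:
        atoms: list[Atom] = []
        for chain in gm:
            for res in chain:
                if skip_solvent and res.name in SOLVENT_RESNAMES:
                    continue
                for at in _pick_altloc(res):
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name,
                            element=at.element.name or "X",
                            residue_number=res.seqid.num,
                            residue_name=res.name,
                            chain=chain.name,
                            position=np.array(
                                [at.pos.x, at.pos.y, at.pos.z], dtype=float
                            ),
                        )
                    )
        try:
            num = int(gm.num) if hasattr(gm, "num") else int(gm.name)
        except (TypeError, ValueError):
            num = len(models) + 1
        models.append(MolecularModel(atoms, model_id=num))
    if not models:
        raise StructureIOError(f"{path}: no models found")
    return Ensemble(models)


def write_pdb_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (MODEL/ENDMDL)."""
    lines: list[str] = []
    multi = len(ensemble) > 1
    for m in ensemble:
        if multi:
            lines.append(f"MODEL     {m.model_id:4d}")
        for a in m.atoms:
            x, y, z = a.position
            lines.append(
                f"ATOM  {a.serial:5d} {a.name:^4s}{a.residue_name:>4s} "
                f"{a.chain[:1]:1s}{a.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectories


def _assign_groups(
    topology: MolecularModel, lipid_resnames: Iterable[str]
) -> dict[str, np.ndarray]:
    lipid_resnames = set(lipid_resnames)
    lipid = topology.select_indices(residue_names=lipid_resnames)
    protein = np.array(
        [i for i in range(len(topology)) if i not in set(lipid.tolist())], dtype=int
    )
    heads = np.array(
        [i for i in lipid if topology.atoms[i].name.startswith(("P", "N"))], dtype=int
    )
    tails = np.array([i for i in lipid if i not in set(heads.tolist())], dtype=int)
    return {"protein": protein, "lipid": lipid, "lipid_heads": heads, "lipid_tails": tails}


def write_xyz_frames(frames: np.ndarray, path: str | Path) -> None:
    """Write frames in the plain per-frame xyz-table dialect.

    Format: a header line ``natoms N``, then for each frame a line
    ``frame K`` followed by N rows of three floats (Angstrom).
    """
    frames = np.asarray(frames, dtype=float)
    f, n, _ = frames.shape
    with open(path, "w") as fh:
        fh.write(f"natoms {n}\n")
        for k in range(f):
            fh.write(f"frame {k}\n")
            np.savetxt(fh, frames[k], fmt="%.6f")


def _read_xyz_frames(path: Path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2 or header[0] != "natoms":
            raise StructureIOError(f"{path}: malformed xyz-frames header")
        n = int(header[1])
        frames: list[np.ndarray] = []
        rows: list[list[float]] = []
        in_frame = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("frame"):
                if in_frame and len(rows) != n:
                    raise StructureIOError(
                        f"{path}: truncated frame; last complete frame is "
                        f"{len(frames) - 1}"
                    )
                if in_frame:
                    frames.append(np.array(rows, dtype=float))
                rows = []
                in_frame = True
            else:
                rows.append([float(v) for v in line.split()])
        if in_frame:
            if len(rows) != n:
                raise StructureIOError(
                    f"{path}: truncated frame; last complete frame is {len(frames) - 1}"
                )
            frames.append(np.array(rows, dtype=float))
    if not frames:
        raise StructureIOError(f"{path}: no frames found")
    return np.stack(frames)


def read_trajectory(
    topology_path: str | Path,
    frames_path: str | Path,
    dialect: str = "multi-model-pdb",
    lipid_resnames: Iterable[str] = ("LIP", "POPC", "DMPC", "DPC"),
    frame_spacing: float = 1.0,
) -> Trajectory:
    """Read a trajectory from topology + frames files.

    ``dialect`` is ``multi-model-pdb`` (concatenated MODEL blocks) or
    ``xyz-frames`` (plain per-frame coordinate table).  The "lipid"
    group is populated from ``lipid_resnames``.
    """
    topo_ens = read_pdb_ensemble(topology_path)
    topology = topo_ens.models[0]
    if dialect == "multi-model-pdb":
        ens = read_pdb_ensemble(frames_path)
        for k, m in enumerate(ens):
            if len(m) != len(topology):
                raise StructureIOError(
                    f"frame {k}: atom count {len(m)} does not match topology "
                    f"({len(topology)})"
                )
        frames = np.stack([m.coordinates for m in ens])
    elif dialect == "xyz-frames":
        frames = _read_xyz_frames(Path(frames_path))
        if frames.shape[1] != len(topology):
            raise StructureIOError(
                f"frame 0: atom count {frames.shape[1]} does not match topology "
                f"({len(topology)})"
            )
    else:
        raise ValueError(f"unknown trajectory dialect: {dialect!r}")
    groups = _assign_groups(topology, lipid_resnames)
    return Trajectory(topology, frames, frame_spacing=frame_spacing, groups=groups)


# ---------------------------------------------------------------------------
# Tables


def read_shift_table(path: str | Path) -> list[ShiftRecord]:
    """Read a TSV of chemical shifts.

    Columns: ``residue_number``, ``atom``, ``value`` and optionally
    ``residue_name``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"residue_number", "atom", "value"}
    if not required.issubset(df.columns):
        raise StructureIOError(
            f"{path}: shift table must have columns {sorted(required)}"
        )
    has_name = "residue_name" in df.columns
    out = []
    for _, row in df.iterrows():
        out.append(
            ShiftRecord(
                residue_number=int(row["residue_number"]),
                atom=str(row["atom"]),
                shift=float(row["value"]),
                residue_name=str(row["residue_name"]) if has_name else None,
            )
        )
    keys = [(r.residue_number, r.atom) for r in out]
    if len(set(keys)) != len(keys):
        raise StructureIOError(f"{path}: duplicate (residue, atom) shift entries")
    return out


def read_intensity_table(path: str | Path) -> list[IntensityRecord]:
    """Read a TSV of reference/attenuated peak intensities.

    Columns: ``residue_number``, ``i_ref``, ``i_att`` and optionally ``sigma``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"residue_number", "i_ref", "i_att"}
    if not required.issubset(df.columns):
        raise StructureIOError(
            f"{path}: intensity table must have columns {sorted(required)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            IntensityRecord(
                residue_number=int(row["residue_number"]),
                i_ref=float(row["i_ref"]),
                i_att=float(row["i_att"]),
                sigma_noise=float(row.get("sigma", 0.0)) if "sigma" in df.columns else 0.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# 2D map TSV round-trip


def write_map_tsv(surface_map, path: str | Path, comment: str | None = None) -> None:
    """Write a :class:`~tmdkit.mhp_surface.SurfaceMap2D` as TSV.

    Header lines record the angle (degrees) and z (Angstrom) bin edges;
    each data row is one angle bin, columns are z bins.  Empty cells are
    stored as ``nan`` together with a parallel weight block, so
    ``read_map_tsv(write_map_tsv(m)) == m`` to full stored precision.
    """
    from .mhp_surface import SurfaceMap2D  # local import avoids cycle

    if not isinstance(surface_map, SurfaceMap2D):
        raise TypeError("write_map_tsv expects a SurfaceMap2D")
    if surface_map.values.size == 0:
        raise StructureIOError("map grid is empty")
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "# angle_edges_deg\t" + "\t".join(repr(float(v)) for v in surface_map.angle_edges) + "\n"
        )
        fh.write(
            "# z_edges_A\t" + "\t".join(repr(float(v)) for v in surface_map.z_edges) + "\n"
        )
        fh.write("# block\tvalues\n")
        for row in surface_map.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
        fh.write("# block\tweight\n")
        for row in surface_map.weight:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_map_tsv(path: str | Path):
    """Read a map written by :func:`write_map_tsv`."""
    from .mhp_surface import SurfaceMap2D

    angle_edges = z_edges = None
    blocks: dict[str, list[list[float]]] = {}
    current: list[list[float]] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# angle_edges_deg"):
                angle_edges = np.array([float(v) for v in line.split("\t")[1:]])
            elif line.startswith("# z_edges_A"):
                z_edges = np.array([float(v) for v in line.split("\t")[1:]])
            elif line.startswith("# block"):
                name = line.split("\t")[1]
                current = blocks.setdefault(name, [])
            elif line.startswith("#") or not line.strip():
                continue
            else:
                if current is None:
                    raise StructureIOError(f"{path}: data before block header")
                current.append([float(v) for v in line.split("\t")])
    if angle_edges is None or z_edges is None or "values" not in blocks:
        raise StructureIOError(f"{path}: malformed map header")
    values = np.array(blocks["values"], dtype=float)
    expected = (len(angle_edges) - 1, len(z_edges) - 1)
    if values.shape != expected:
        raise StructureIOError(
            f"{path}: data shape {values.shape} does not match bin edges {expected}"
        )
    weight = (
        np.array(blocks["weight"], dtype=float)
        if "weight" in blocks
        else np.where(np.isnan(values), 0.0, 1.0)
    )
    if weight.shape != values.shape:
        raise StructureIOError(f"{path}: weight block shape mismatch")
    return SurfaceMap2D(angle_edges=angle_edges, z_edges=z_edges, values=values, weight=weight)
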