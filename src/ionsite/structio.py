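"""Structure and trajectory I/O, atom selections and basic geometry.

Coordinates are ångström throughout. Structures are single-model, ordered
atom lists; trajectories are a fixed topology plus a stack of coordinate
frames. PDB and mmCIF parsing/writing is delegated to gemmi; the plain XYZ
trajectory format is handled directly.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "SelectionError",
    "FormatError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "select_one",
    "distance",
    "parse_selection",
]


class FormatError(ValueError):
    """File does not conform to the named format."""


class SelectionError(ValueError):
    """A selection resolved to an unexpected number of atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model.

    ``name`` is the PDB atom name (e.g. ``"OE1"``, ``"NZ"``); ``element``
    is the chemical symbol, inferred from the name when the file omits it.
    """

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    x: float
    y: float
    z: float
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def label(self) -> str:
        """Human-readable ligand label, e.g. ``"A/GLU343/OE1"``."""
        return f"{self.chain}/{self.resname}{self.resid}/{self.name}"


@dataclass
class Structure:
    """An ordered list of atoms belonging to a single model."""

    atoms: list[AtomRecord]
    model_id: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise FormatError("a Structure must contain at least one atom")
        for a in self.atoms:
            if not all(map(math.isfinite, (a.x, a.y, a.z))):
                raise FormatError(f"non-finite coordinates for atom {a.serial}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected shape {(len(self.atoms), 3)}, got {coords.shape}")
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, coords)
        ]
        return Structure(atoms, model_id=self.model_id, source=self.source)


@dataclass
class Trajectory:
    """A frame sequence over one fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3); every frame is aligned
    index-for-index with ``topology.atoms``. ``box`` holds orthorhombic box
    lengths in Å when periodic analyses apply.
    """

    topology: Structure
    frames: np.ndarray
    box: tuple[float, float, float] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise FormatError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if self.frames.shape[0] < 1:
            raise FormatError("a trajectory needs at least one frame")

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """Conjunctive atom predicate over chain / resid / resname / name / element.

    ``None`` fields match everything. ``resid`` may be one residue number or
    an iterable of them.
    """

    chain: str | None = None
    resid: int | Iterable[int] | None = None
    resname: str | None = None
    name: str | None = None
    element: str | None = None

    def _resid_set(self) -> set[int] | None:
        if self.resid is None:
            return None
        if isinstance(self.resid, int):
            return {self.resid}
        return set(int(r) for r in self.resid)

    def matches(self, atom: AtomRecord) -> bool:
        rs = self._resid_set()
        return (
            (self.chain is None or atom.chain == self.chain)
            and (rs is None or atom.resid in rs)
            and (self.resname is None or atom.resname.upper() == self.resname.upper())
            and (self.name is None or atom.name.upper() == self.name.upper())
            and (self.element is None or atom.element.upper() == self.element.upper())
        )


_SELECTION_KEYS = {"chain", "resid", "resname", "name", "element"}


def parse_selection(text: str) -> Selection:
    """Parse the mini-language ``"chain A resid 791 name NZ"``.

    Grammar: selection = (key value)+ with keys chain|resid|resname|name|
    element; resid accepts comma-separated residue numbers.
    """
    tokens = text.split()
    if len(tokens) % 2 != 0 or not tokens:
        raise SelectionError(f"malformed selection {text!r}: expected key/value pairs")
    kwargs: dict = {}
    for key, value in zip(tokens[::2], tokens[1::2]):
        key = key.lower()
        if key not in _SELECTION_KEYS:
            raise SelectionError(f"unknown selection key {key!r} in {text!r}")
        if key == "resid":
            ids = [int(v) for v in value.split(",")]
            kwargs[key] = ids[0] if len(ids) == 1 else tuple(ids)
        else:
            kwargs[key] = value
    return Selection(**kwargs)


def select(structure: Structure, selection: Selection | str) -> list[int]:
    """Indices (topology order) of atoms matching ``selection``.

    An empty result is legal. String selections go through
    :func:`parse_selection`.
    """
    if isinstance(selection, str):
        selection = parse_selection(selection)
    return [i for i, a in enumerate(structure.atoms) if selection.matches(a)]


def select_one(structure: Structure, selection: Selection | str) -> int:
    """Index of the single atom matching ``selection``; error otherwise."""
    idx = select(structure, selection)
    if len(idx) != 1:
        raise SelectionError(
            f"selection {selection!r} resolved to {len(idx)} atoms; expected exactly 1"
        )
    return idx[0]


def distance(structure: Structure, sel_a: Selection | str, sel_b: Selection | str) -> float:
    """Euclidean distance in Å between two single-atom selections.

    No periodic imaging: binding-site analyses are intramolecular.
    """
    ia = select_one(structure, sel_a)
    ib = select_one(structure, sel_b)
    return float(np.linalg.norm(structure.atoms[ia].position - structure.atoms[ib].position))


# ---------------------------------------------------------------------------
# element inference

def _infer_element(name: str, resname: str) -> str:
    """PDB v3.3 atom-name element inference for files lacking element columns."""
    stripped = name.strip()
    if not stripped:
        return ""
    # Two-character elements used as monoatomic ions keep the residue name
    # (e.g. resname K / RB / NA with matching atom name).
    two = stripped[:2].upper()
    if resname.strip().upper() in {"K", "RB", "NA", "CL", "MG", "CA", "ZN"} and two in {
        "K", "RB", "NA", "CL", "MG", "CA", "ZN", "K+", "RB"
    }:
        el = resname.strip().upper()
        return el[0] + el[1:].lower() if len(el) > 1 else el
    head = stripped.lstrip("0123456789")
    return head[0].upper() if head else ""


# ---------------------------------------------------------------------------
# gemmi bridge

def _structure_from_gemmi_model(model: gemmi.Model, source: str, model_id: int) -> Structure:
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for residue in chain:
            for atom in residue:
                altloc = atom.altloc if atom.altloc not in ("\0", " ") else ""
                if altloc not in ("", "A"):
                    continue  # keep blank or "A"; drop other alternates
                serial += 1
                element = atom.element.name
                if not element or element == "X":
                    element = _infer_element(atom.name, residue.name)
                atoms.append(
                    AtomRecord(
                        serial=atom.serial if atom.serial else serial,
                        name=atom.name,
                        element=element,
                        resname=residue.name,
                        resid=residue.seqid.num,
                        chain=chain.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        altloc=altloc,
                        occupancy=atom.occ,
                        bfactor=atom.b_iso,
                    )
                )
    if not atoms:
        raise FormatError(f"{source}: no atoms parsed")
    return Structure(atoms, model_id=model_id, source=source)


def _gemmi_structure_from(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "ionsite"
    model = gemmi.Model(1)
    chain_map: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        chain_name = a.chain or "A"
        if chain_name not in chain_map:
            chain_map[chain_name] = gemmi.Chain(chain_name)
        chain = chain_map[chain_name]
        if len(chain) == 0 or chain[len(chain) - 1].seqid.num != a.resid or chain[
            len(chain) - 1
        ].name != a.resname:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resid, " ")
            chain.add_residue(res)
        res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element if a.element else "X")
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        atom.occ = a.occupancy
        atom.b_iso = a.bfactor
        atom.altloc = a.altloc if a.altloc else "\0"
        res.add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _detect_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    if suffix == ".xyz":
        return "xyz"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


def read_structure(path: str | Path, format: str = "auto", model_index: int = 0) -> Structure:
    """Read one model from a PDB or mmCIF file.

    Returns the first model unless ``model_index`` names another. Alternate
    locations other than blank/"A" are dropped.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format not in {"pdb", "mmcif"}:
        raise FormatError(f"unsupported structure format {format!r}")
    try:
        st = gemmi.read_structure(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    if model_index >= len(st):
        raise FormatError(f"{path}: model index {model_index} out of range ({len(st)} models)")
    return _structure_from_gemmi_model(st[model_index], str(path), model_index + 1)


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a structure as PDB or mmCIF, re-readable by :func:`read_structure`."""
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    st = _gemmi_structure_from(structure)
    if format == "pdb":
        st.write_pdb(os.fspath(path))
    elif format == "mmcif":
        st.make_mmcif_document().write_file(os.fspath(path))
    else:
        raise FormatError(f"unsupported structure format {format!r}")


# ---------------------------------------------------------------------------
# trajectories

def _read_xyz_frames(path: Path) -> tuple[list[str], np.ndarray]:
    frames: list[np.ndarray] = []
    names: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated frame at line {i + 1}")
        coords = np.empty((n, 3))
        frame_names = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed atom line {i + 3 + j}")
            frame_names.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        if not names:
            names = frame_names
        elif frame_names != names or n != len(names):
            raise FormatError(f"{path}: inconsistent atoms across frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames")
    return names, np.stack(frames)


def read_trajectory(path: str | Path, format: str = "auto") -> Trajectory:
    """Read a multi-model PDB or XYZ file as a trajectory.

    All models must share atom count and ordering; frames keep file order.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format in {"pdb", "multimodel_pdb"}:
        try:
            st = gemmi.read_structure(os.fspath(path))
        except (RuntimeError, ValueError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
        if len(st) == 0:
            raise FormatError(f"{path}: no models")
        topo = _structure_from_gemmi_model(st[0], str(path), 1)
        frames = np.empty((len(st), len(topo), 3))
        for m, model in enumerate(st):
            frame_struct = _structure_from_gemmi_model(model, str(path), m + 1)
            if len(frame_struct) != len(topo):
                raise FormatError(
                    f"{path}: model {m + 1} has {len(frame_struct)} atoms, "
                    f"expected {len(topo)}"
                )
            frames[m] = frame_struct.coords
        return Trajectory(topo, frames, source=str(path))
    if format == "xyz":
        names, frames = _read_xyz_frames(path)
        atoms = [
            AtomRecord(
                serial=i + 1,
                name=nm,
                element=nm,
                resname="UNK",
                resid=1,
                chain="A",
                x=float(frames[0, i, 0]),
                y=float(frames[0, i, 1]),
                z=float(frames[0, i, 2]),
            )
            for i, nm in enumerate(names)
        ]
        return Trajectory(Structure(atoms, source=str(path)), frames, source=str(path))
    raise FormatError(f"unsupported trajectory format {format!r}")


def write_trajectory(trajectory: Trajectory, path: str | Path, format: str = "auto") -> None:
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL) or XYZ."""
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format in {"pdb", "multimodel_pdb"}:
        st = _gemmi_structure_from(trajectory.topology)
        base_model = st[0]
        # replicate the model per frame with updated coordinates
        st2 = gemmi.Structure()
        st2.name = "ionsite"
        for f in range(trajectory.frame_count):
            model = gemmi.Model(f + 1)
            for chain in base_model:
                model.add_chain(chain.clone())
            k = 0
            for chain in model:
                for res in chain:
                    for atom in res:
                        p = trajectory.frames[f, k]
                        atom.pos = gemmi.Position(p[0], p[1], p[2])
                        k += 1
            st2.add_model(model)
        st2.setup_entities()
        st2.write_pdb(os.fspath(path))
    elif format == "xyz":
        with open(path, "w") as fh:
            names = [a.element or a.name for a in trajectory.topology.atoms]
            for f in range(trajectory.frame_count):
                fh.write(f"{len(names)}\nframe {f}\n")
                for nm, p in zip(names, trajectory.frames[f]):
                    fh.write(f"{nm} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    else:
        raise FormatError(f"unsupported trajectory format {format!r}")
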