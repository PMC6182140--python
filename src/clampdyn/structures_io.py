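"""Coordinate I/O and atom selections.

The canonical on-disk trajectory format here is multi-model PDB
(``MODEL``/``ENDMDL`` blocks with fixed-width ``ATOM``/``HETATM`` records),
which keeps fixtures plain-text and diffable.  Binary trajectory formats are
supported through a thin optional adapter (:func:`read_binary_trajectory`)
that yields the same in-memory :class:`Trajectory`.

Conventions: residue numbers are 1-based (as in PDB), frame indices are
0-based throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AtomLabel",
    "AtomSelection",
    "Trajectory",
    "FormatError",
    "SelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_binary_trajectory",
    "select_atoms",
]


class FormatError(ValueError):
    """Raised for structurally invalid coordinate files."""


class SelectionError(ValueError):
    """Raised for malformed atom-selection expressions."""


@dataclass(frozen=True)
class AtomLabel:
    """Identity of one atom: chain, residue and atom naming as in PDB."""

    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str = ""

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Trajectory:
    """Frames x atoms coordinate set with per-atom labels.

    Attributes
    ----------
    atoms : list of AtomLabel
        Atom identities, identical (and identically ordered) in every frame.
    coords : ndarray, shape (n_frames, n_atoms, 3), Å
    times : ndarray or None
        Optional per-frame time in ns, strictly increasing.
    """

    atoms: list[AtomLabel]
    coords: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords second axis ({self.coords.shape[1]}) does not match "
                f"number of atom labels ({len(self.atoms)})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.coords.shape[0],):
                raise ValueError("times must have one entry per frame")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass
class AtomSelection:
    """Ordered subset of trajectory atoms plus the expression that made it."""

    indices: np.ndarray
    spec: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


# --- multi-model PDB -------------------------------------------------------

_PDB_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<4s}"
    "{chain:1s}{resnum:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
    "{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB column rule: atom names start in column 14 unless the element
    # symbol is two characters (or the name is 4 chars), then column 13.
    if len(name) >= 4 or len(element.strip()) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file.

    One ``MODEL``/``ENDMDL`` block per frame, fixed-width columns, ``END``
    terminator.  Coordinates that do not fit the 8.3 field raise.
    """
    if traj.n_frames == 0:
        raise ValueError("no frames: refusing to write an empty trajectory")
    if np.any(np.abs(traj.coords) >= 10000.0):
        raise ValueError(
            "coordinate magnitude exceeds the PDB 8.3 field width (|x| >= 10000 Å)"
        )
    with open(path, "w") as fh:
        fh.write("REMARK   generated by clampdyn (frames 0-based, residues 1-based)\n")
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:>8d}\n")
            for i, (label, xyz) in enumerate(zip(traj.atoms, traj.coords[f])):
                fh.write(
                    "ATOM  "
                    + f"{(i % 99999) + 1:>5d} "
                    + _format_atom_name(label.atom_name, label.element)
                    + " "  # altLoc
                    + f"{label.residue_name:<4s}"
                    + f"{label.chain_id:1s}"
                    + f"{label.residue_number:>4d}"
                    + " "  # iCode
                    + "   "
                    + f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    + f"{1.00:6.2f}{0.00:6.2f}"
                    + " " * 10
                    + f"{label.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_multimodel_pdb(path) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    ``MODEL``/``ENDMDL`` records delimit frames; a file without them is a
    single implicit frame.  Only ``ATOM``/``HETATM`` records are read.
    Alternate locations: blank or 'A' kept, others dropped with a warning.
    """
    frames: list[list[tuple[AtomLabel, float, float, float]]] = []
    current: list[tuple[AtomLabel, float, float, float]] = []
    in_model = False
    seen_model = False
    dropped_altloc = 0
    model_no = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                seen_model = True
                in_model = True
                model_no += 1
                current = []
            elif rec.startswith("ENDMDL"):
                in_model = False
                frames.append(current)
            elif rec.startswith(("ATOM  ", "HETATM")):
                altloc = line[16] if len(line) > 16 else " "
                if altloc not in (" ", "A"):
                    dropped_altloc += 1
                    continue
                try:
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    chain = line[21]
                    resnum = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise FormatError(
                        f"unparseable ATOM record at line {lineno}: {exc}"
                    ) from None
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = name[:1]
                label = AtomLabel(chain, resname, resnum, name, element)
                current.append((label, x, y, z))

    if not seen_model:
        frames = [current]
    elif in_model:
        raise FormatError(f"MODEL {model_no} not terminated by ENDMDL")

    if dropped_altloc:
        warnings.warn(
            f"dropped {dropped_altloc} alternate-location atoms (kept altLoc ' '/'A')",
            stacklevel=2,
        )

    frames = [f for f in frames if f] or [[]]
    if not frames[0]:
        raise FormatError("file contains no ATOM/HETATM records")

    n_atoms = len(frames[0])
    labels = [a[0] for a in frames[0]]
    if len({lab.key() for lab in labels}) != n_atoms:
        raise FormatError("duplicate (chain, residue_number, atom_name) within a model")

    coords = np.empty((len(frames), n_atoms, 3))
    for m, frame in enumerate(frames):
        if len(frame) != n_atoms:
            raise FormatError(
                f"model {m + 1} has {len(frame)} atoms, expected {n_atoms}"
            )
        for i, (label, x, y, z) in enumerate(frame):
            if label.key() != labels[i].key():
                raise FormatError(
                    f"model {m + 1}: atom ordering differs from model 1 at position {i}"
                )
            coords[m, i] = (x, y, z)
    return Trajectory(atoms=labels, coords=coords)


def read_binary_trajectory(topology_path, trajectory_path) -> Trajectory:
    """Adapter: load a binary trajectory + topology pair via mdtraj.

    Returns the same :class:`Trajectory` contract as the PDB reader.
    Coordinates are converted from nm to Å and times from ps to ns.
    """
    import mdtraj  # deliberate lazy import: optional dependency

    t = mdtraj.load(str(trajectory_path), top=str(topology_path))
    labels = [
        AtomLabel(
            chain_id=(a.residue.chain.chain_id or chr(ord("A") + a.residue.chain.index)),
            residue_name=a.residue.name,
            residue_number=a.residue.resSeq,
            atom_name=a.name,
            element=a.element.symbol if a.element is not None else "",
        )
        for a in t.topology.atoms
    ]
    times = None
    if t.time is not None and len(np.unique(t.time)) == t.n_frames and t.n_frames > 1:
        times = np.asarray(t.time, dtype=float) / 1000.0
    return Trajectory(atoms=labels, coords=np.asarray(t.xyz, dtype=float) * 10.0, times=times)


# --- selection grammar -----------------------------------------------------
#
#   chain=<id>
#   resnum in <a>-<b>
#   resname in {NAME, NAME, ...}
#   atomname in {NAME, ...}
#   element=<X>
#
# clauses combined with AND; clause order is irrelevant.


def _parse_clause(clause: str):
    clause = clause.strip()
    low = clause.lower()
    if low.startswith("chain"):
        _, _, val = clause.partition("=")
        if not val.strip():
            raise SelectionError(f"malformed chain clause: {clause!r}")
        cid = val.strip()
        return lambda a: a.chain_id == cid
    if low.startswith("resnum"):
        rest = clause[len("resnum"):].strip()
        if not rest.lower().startswith("in"):
            raise SelectionError(f"malformed resnum clause: {clause!r}")
        rng = rest[2:].strip()
        lo_s, sep, hi_s = rng.partition("-")
        try:
            lo = int(lo_s)
            hi = int(hi_s) if sep else lo
        except ValueError:
            raise SelectionError(f"malformed resnum range: {clause!r}") from None
        if hi < lo:
            raise SelectionError(f"empty resnum range {lo}-{hi}")
        return lambda a: lo <= a.residue_number <= hi
    if low.startswith("resname") or low.startswith("atomname"):
        key = "resname" if low.startswith("resname") else "atomname"
        rest = clause[len(key):].strip()
        if not rest.lower().startswith("in"):
            raise SelectionError(f"malformed {key} clause: {clause!r}")
        setpart = rest[2:].strip()
        if not (setpart.startswith("{") and setpart.endswith("}")):
            raise SelectionError(f"{key} set must be brace-delimited: {clause!r}")
        names = {n.strip() for n in setpart[1:-1].split(",") if n.strip()}
        if not names:
            raise SelectionError(f"empty {key} set: {clause!r}")
        if key == "resname":
            return lambda a: a.residue_name in names
        return lambda a: a.atom_name in names
    if low.startswith("element"):
        _, _, val = clause.partition("=")
        if not val.strip():
            raise SelectionError(f"malformed element clause: {clause!r}")
        el = val.strip().upper()
        return lambda a: a.element.upper() == el
    raise SelectionError(f"unrecognised selection clause: {clause!r}")


def select_atoms(traj: Trajectory, spec: str) -> AtomSelection:
    """Evaluate a selection expression against the trajectory's atom labels.

    Deterministic and order-preserving; an empty result is legal and
    produces a warning, never an error.
    """
    if not spec or not spec.strip():
        raise SelectionError("empty selection expression")
    predicates = [_parse_clause(c) for c in spec.split(" AND ")]
    idx = [i for i, a in enumerate(traj.atoms) if all(p(a) for p in predicates)]
    if not idx:
        warnings.warn(f"selection {spec!r} matched no atoms", stacklevel=2)
    return AtomSelection(indices=np.array(idx, dtype=int), spec=spec)
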