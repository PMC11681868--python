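"""Structures, trajectories and atom selections.

A deliberately small in-memory model: a :class:`Structure` is an ordered list
of :class:`Residue` objects, each holding :class:`Atom` records with PDB-style
names and coordinates in Å.  A :class:`TrajectoryEnsemble` ties replicate
coordinate arrays to one topology, a frame interval and a phosphate
protonation-state label.

Parsing of PDB and mmCIF goes through :mod:`gemmi`; altloc resolution,
role assignment and the conjunction-only selection grammar live here.
XTC/DCD trajectory reading is available when MDAnalysis is importable
(``HAS_MDANALYSIS``); multi-model PDB is always supported.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

try:  # optional trajectory backend
    import MDAnalysis as _mda  # type: ignore

    HAS_MDANALYSIS = True
except Exception:  # pragma: no cover - depends on install
    _mda = None
    HAS_MDANALYSIS = False

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "TrajectoryEnsemble",
    "Role",
    "ProtonationState",
    "StructureFormatError",
    "EmptyStructureError",
    "SelectionError",
    "HAS_MDANALYSIS",
    "WATER_RESNAMES",
    "PHOSPHOSERINE_RESNAMES",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "select",
    "assign_roles",
]

#: Residue names treated as solvent water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "TIP", "SPC"})

#: Accepted phosphoserine residue codes (SEP is the standard PDB code;
#: aliases cover common force-field topologies).
PHOSPHOSERINE_RESNAMES = frozenset({"SEP", "SEP1", "SEP2", "S1P", "PSER"})


class StructureFormatError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no atoms (or no frames)."""


class SelectionError(ValueError):
    """Raised for malformed selection specs; carries the offending position."""


class Role(enum.Enum):
    """Coarse molecular role of a residue within the complex."""

    ANTIBODY_HEAVY = "antibody_heavy"
    ANTIBODY_LIGHT = "antibody_light"
    ANTIGEN = "antigen"
    OTHER = "other"


class ProtonationState(enum.Enum):
    """Protonation state of the phosphoserine phosphate group.

    Near physiological pH the phosphate (pKa ~6) is an equilibrium mixture of
    the singly protonated PO3H- and the unprotonated PO3^2- forms; the latter
    has three chemically equivalent terminal oxygens (3-fold symmetry).
    """

    PO3H_MINUS = "po3h"
    PO3_2MINUS = "po3"

    @property
    def symmetry_fold(self) -> int:
        return 3 if self is ProtonationState.PO3_2MINUS else 1


@dataclass
class Atom:
    """A single atom: PDB atom name, element symbol, serial, coords in Å."""

    name: str
    element: str
    serial: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    """One residue: author numbering (resseq + insertion code) is preserved."""

    chain_id: str
    resseq: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    role: Role = Role.OTHER

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"duplicate atom names {dup} in {self.chain_id}/{self.resname}{self.resseq}{self.icode}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        """(chain, resname, resseq+icode) identity used in report tables."""
        return (self.chain_id, self.resname, f"{self.resseq}{self.icode}")

    @property
    def sort_key(self) -> tuple[str, int, str]:
        # insertion codes sort after their base number: 95 < 95A < 95B
        return (self.chain_id, self.resseq, self.icode)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"atom {name!r} not found in {self.chain_id}/{self.resname}{self.resseq}{self.icode}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """An ordered residue list plus provenance; every atom belongs to one residue."""

    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    source_format: str = "memory"

    # -- flat atom view -------------------------------------------------

    def iter_atoms(self) -> Iterator[tuple[int, Residue, Atom]]:
        """Yield (global_index, residue, atom) in file order."""
        i = 0
        for res in self.residues:
            for atom in res.atoms:
                yield i, res, atom
                i += 1

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in the global atom order."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.vstack([a.coords for _, _, a in self.iter_atoms()])

    def atom_residue_index(self) -> np.ndarray:
        """Per-atom index into ``self.residues``."""
        out = np.empty(self.n_atoms, dtype=int)
        i = 0
        for ri, res in enumerate(self.residues):
            out[i : i + len(res.atoms)] = ri
            i += len(res.atoms)
        return out

    def find_residue(self, chain_id: str, resseq: int, icode: str = "") -> Residue:
        for res in self.residues:
            if res.chain_id == chain_id and res.resseq == resseq and res.icode == icode:
                return res
        raise KeyError(f"no residue {chain_id}/{resseq}{icode}")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)


def assign_roles(structure: Structure, chain_roles: dict[str, Role | str]) -> Structure:
    """Assign residue roles from a chain → role map (in place; returns structure).

    Chothia-style display labels like "H-R95" assume the heavy/light chains are
    known; automatic renumbering is out of scope, so the caller supplies the map.
    """
    resolved = {c: (Role(v) if isinstance(v, str) else v) for c, v in chain_roles.items()}
    for res in structure.residues:
        if res.chain_id in resolved:
            res.role = resolved[res.chain_id]
    return structure


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _gemmi_read(path: str | Path, fmt: str | None):
    import gemmi

    path = str(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(path)
        elif fmt.lower() == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt.lower() in ("cif", "mmcif"):
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureFormatError(f"unknown format {fmt!r} (use 'pdb' or 'mmcif')")
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending record
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    return st


def _resolve_altlocs(gemmi_residue) -> list:
    """Keep one atom per name: highest occupancy, ties broken by altloc label."""
    by_name: dict[str, list] = {}
    for at in gemmi_residue:
        by_name.setdefault(at.name, []).append(at)
    kept = []
    for at_list in by_name.values():
        best = min(at_list, key=lambda a: (-a.occ, a.altloc or ""))
        kept.append(best)
    # preserve file order of the winners
    order = {id(a): i for i, a in enumerate(gemmi_residue)}
    kept.sort(key=lambda a: order[id(a)])
    return kept


def _model_to_structure(model, title: str, source_format: str) -> Structure:
    residues: list[Residue] = []
    serial = 0
    for chain in model:
        for gres in chain:
            atoms = []
            for at in _resolve_altlocs(gres):
                serial += 1
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name if at.element else "",
                        serial=serial,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        resseq=gres.seqid.num,
                        icode=(gres.seqid.icode or "").strip(),
                        resname=gres.name.strip(),
                        atoms=atoms,
                    )
                )
    return Structure(residues=residues, title=title, source_format=source_format)


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    The first model is used; altlocs are resolved to the highest-occupancy
    conformer (ties: first altloc label); author residue numbering and
    insertion codes are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = _gemmi_read(path, format)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    structure = _model_to_structure(
        st[0], title=st.name or path.stem, source_format="mmcif" if "cif" in path.suffix.lower() else "pdb"
    )
    if structure.n_atoms == 0:
        raise EmptyStructureError(f"{path}: model contains no atoms")
    return structure


@dataclass
class TrajectoryEnsemble:
    """Replicate MD trajectories over one topology.

    ``replicates`` holds one (n_frames, n_atoms, 3) float array per replicate;
    ``dt_ps`` is the snapshot interval; ``equilibration_fraction`` is the
    leading fraction of each replicate discarded before any statistic is
    computed (default 0.2, matching a 200 ns discard from 1 μs runs).
    """

    topology: Structure
    replicates: list[np.ndarray] = field(default_factory=list)
    dt_ps: float = 100.0
    protonation_state: ProtonationState = ProtonationState.PO3_2MINUS
    equilibration_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")
        if not (0 <= self.equilibration_fraction < 1):
            raise ValueError("equilibration_fraction must be in [0, 1)")
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        n = self.topology.n_atoms
        for i, rep in enumerate(self.replicates):
            if rep.ndim != 3 or rep.shape[1:] != (n, 3):
                raise ValueError(
                    f"replicate {i}: frame shape {rep.shape} incompatible with "
                    f"topology atom count {n}"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def add_replicate(self, frames: np.ndarray) -> None:
        frames = np.asarray(frames, dtype=float)
        n = self.topology.n_atoms
        if frames.ndim != 3 or frames.shape[1:] != (n, 3):
            raise ValueError(
                f"frame atom count {frames.shape[1] if frames.ndim == 3 else '?'} "
                f"does not match topology atom count {n}"
            )
        self.replicates.append(frames)

    def n_discard(self, replicate: int) -> int:
        return int(math.floor(len(self.replicates[replicate]) * self.equilibration_fraction))

    def retained(self, replicate: int) -> np.ndarray:
        """Frames of one replicate after the equilibration discard."""
        rep = self.replicates[replicate]
        start = self.n_discard(replicate)
        if start >= len(rep):
            raise ValueError(f"replicate {replicate}: all frames discarded")
        return rep[start:]

    def retained_time_ns(self, replicate: int) -> float:
        return len(self.retained(replicate)) * self.dt_ps / 1000.0


def _read_frames_pdb(path: Path, n_atoms_expected: int | None) -> np.ndarray:
    st = _gemmi_read(path, None)
    frames = []
    for model in st:
        s = _model_to_structure(model, "", "pdb")
        if s.n_atoms:
            frames.append(s.coords())
    if not frames:
        raise EmptyStructureError(f"{path}: trajectory file contains no frames")
    counts = {f.shape[0] for f in frames}
    if len(counts) > 1:
        raise StructureFormatError(f"{path}: models differ in atom count: {sorted(counts)}")
    arr = np.stack(frames)
    if n_atoms_expected is not None and arr.shape[1] != n_atoms_expected:
        raise ValueError(
            f"{path}: frame atom count {arr.shape[1]} does not match "
            f"topology atom count {n_atoms_expected}"
        )
    return arr


def _read_frames_mdanalysis(topology_path: Path, path: Path, n_atoms_expected: int) -> np.ndarray:
    if not HAS_MDANALYSIS:
        raise StructureFormatError(
            f"{path.suffix} trajectories require MDAnalysis, which is not available"
        )
    u = _mda.Universe(str(topology_path), str(path))
    if len(u.atoms) != n_atoms_expected:
        raise ValueError(
            f"{path}: frame atom count {len(u.atoms)} does not match "
            f"topology atom count {n_atoms_expected}"
        )
    return np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])


def read_trajectory(
    topology_path: str | Path,
    traj_paths: str | Path | Sequence[str | Path],
    dt_ps: float,
    protonation_state: ProtonationState | str = ProtonationState.PO3_2MINUS,
    equilibration_fraction: float = 0.2,
    ensemble: TrajectoryEnsemble | None = None,
) -> TrajectoryEnsemble:
    """Read one or more trajectory files, each becoming one replicate.

    Multi-model PDB is always supported; XTC/DCD work when MDAnalysis is
    installed.  Passing an existing ``ensemble`` appends replicates to it.
    """
    if isinstance(protonation_state, str):
        protonation_state = ProtonationState(protonation_state)
    if isinstance(traj_paths, (str, Path)):
        traj_paths = [traj_paths]
    topology_path = Path(topology_path)
    if ensemble is None:
        topology = read_structure(topology_path)
        ensemble = TrajectoryEnsemble(
            topology=topology,
            replicates=[],
            dt_ps=dt_ps,
            protonation_state=protonation_state,
            equilibration_fraction=equilibration_fraction,
        )
    n = ensemble.topology.n_atoms
    for tp in traj_paths:
        tp = Path(tp)
        if tp.suffix.lower() in (".xtc", ".dcd", ".trr"):
            frames = _read_frames_mdanalysis(topology_path, tp, n)
        else:
            frames = _read_frames_pdb(tp, n)
        ensemble.add_replicate(frames)
    return ensemble


# ---------------------------------------------------------------------------
# Writing (PDB fixtures; multi-model for trajectories)
# ---------------------------------------------------------------------------


def _pdb_atom_line(serial: int, atom: Atom, res: Residue, x: float, y: float, z: float) -> str:
    name = atom.name
    # PDB atom-name column convention: element right-aligned in cols 13-14
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name}"
    return (
        f"ATOM  {serial:>5d} {name:<4s} {res.resname:<3s} {res.chain_id[:1]:1s}"
        f"{res.resseq:>4d}{res.icode[:1] or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element:>2s}\n"
    )


def write_pdb(
    structure: Structure,
    path: str | Path,
    frames: np.ndarray | None = None,
) -> None:
    """Write a structure, or a multi-model trajectory when ``frames`` is given.

    Coordinates are written with 3 decimals (standard PDB precision), which
    bounds the write→read round-trip error at 5e-4 Å per coordinate.
    """
    path = Path(path)
    flat = list(structure.iter_atoms())
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title[:70]}\n")
        if frames is None:
            frame_list = [None]
        else:
            frames = np.asarray(frames, dtype=float)
            if frames.ndim == 2:
                frames = frames[None]
            if frames.shape[1] != len(flat):
                raise ValueError(
                    f"frames have {frames.shape[1]} atoms, structure has {len(flat)}"
                )
            frame_list = list(frames)
        multi = frames is not None and len(frame_list) > 1
        for mi, frame in enumerate(frame_list, start=1):
            if multi:
                fh.write(f"MODEL     {mi:>4d}\n")
            for serial, (gi, res, atom) in enumerate(flat, start=1):
                xyz = atom.coords if frame is None else frame[gi]
                fh.write(_pdb_atom_line(serial, atom, res, *xyz))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection grammar: conjunctions of chain / resseq / resname / name / role
# ---------------------------------------------------------------------------

_RESSEQ_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")

_FIELDS = ("chain", "resseq", "resname", "name", "role")


def _parse_selection(spec: str) -> list[tuple[str, str]]:
    clauses: list[tuple[str, str]] = []
    tokens = spec.split()
    if not tokens:
        raise SelectionError("empty selection spec")
    pos = 0
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok == "and":
            if not clauses or i + 1 >= len(tokens):
                raise SelectionError(f"dangling 'and' at token {i} in {spec!r}")
            i += 1
            continue
        if tok not in _FIELDS:
            raise SelectionError(
                f"unknown field {tok!r} at token {i} in {spec!r} (expected one of {_FIELDS})"
            )
        if i + 1 >= len(tokens):
            raise SelectionError(f"field {tok!r} at token {i} has no value in {spec!r}")
        clauses.append((tok, tokens[i + 1]))
        i += 2
    return clauses


def select(structure: Structure, spec: str) -> list[int]:
    """Resolve a selection spec to an order-preserving global atom index list.

    Grammar: ``field value`` clauses joined by ``and``; fields are ``chain``,
    ``resseq`` (insertion code appended, e.g. ``95A``), ``resname``, ``name``
    and ``role``.  E.g. ``"chain H and resseq 53 and name OG"``.
    """
    clauses = _parse_selection(spec)
    preds = []
    for fieldname, value in clauses:
        if fieldname == "chain":
            preds.append(lambda r, a, v=value: r.chain_id == v)
        elif fieldname == "resname":
            preds.append(lambda r, a, v=value.upper(): r.resname == v)
        elif fieldname == "name":
            preds.append(lambda r, a, v=value.upper(): a.name == v)
        elif fieldname == "role":
            try:
                role = Role(value.lower())
            except ValueError as exc:
                raise SelectionError(f"unknown role {value!r}") from exc
            preds.append(lambda r, a, v=role: r.role is v)
        elif fieldname == "resseq":
            m = _RESSEQ_RE.match(value)
            if not m:
                raise SelectionError(f"bad resseq value {value!r}")
            num, icode = int(m.group(1)), m.group(2).upper()
            preds.append(lambda r, a, n=num, c=icode: r.resseq == n and r.icode == c)
    return [
        i
        for i, res, atom in structure.iter_atoms()
        if all(p(res, atom) for p in preds)
    ]
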