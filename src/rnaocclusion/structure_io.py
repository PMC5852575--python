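"""Structures, ensembles, atom selections and van der Waals radii.

PDB reading and writing is delegated to :mod:`biotite`; this module wraps it
in a small, stable domain model:

* :class:`Atom` / :class:`Structure` — one conformer, ordered atom records
  with coordinates in Å.
* :class:`Ensemble` — F frames sharing a single topology, the unit over
  which every time statistic (overlap series, RMSF, hydrogen bonds) runs.
* :class:`Selection` — AND-combined atom filters (chain, residue range,
  atom name, element, residue name), resolved to a sorted index list.
* :class:`RadiusTable` — element → vdW radius mapping; the shipped default
  is Bondi's compilation with a 1.50 Å fallback for unknown elements.

Altloc duplicates are collapsed to the highest-occupancy conformer (ties go
to 'A', i.e. first in file order). HETATM records are retained and flagged,
so ions such as Zn²⁺ and waters remain selectable by residue name.
Insertion codes are kept as a suffix on the residue key, never dropped.
Units are Å throughout.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    AnnotationError,
    CoordinateRangeError,
    PDBParseError,
    TopologyError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "Selection",
    "RadiusTable",
    "BONDI_RADII",
    "BACKBONE",
    "read_pdb",
    "write_pdb",
    "resolve_selection",
    "assign_radii",
    "build_structure",
]

#: Bondi (1964) van der Waals radii in Å for elements common in
#: protein/nucleic-acid structures. Elements not listed fall back to
#: ``RadiusTable.default_radius``.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "HE": 1.40, "LI": 1.82, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "NE": 1.54, "NA": 2.27, "MG": 1.73, "SI": 2.10, "P": 1.80,
    "S": 1.80, "CL": 1.75, "AR": 1.88, "K": 2.75, "NI": 1.63, "CU": 1.40,
    "ZN": 1.39, "GA": 1.87, "AS": 1.85, "SE": 1.90, "BR": 1.85, "KR": 2.02,
    "CD": 1.58, "I": 1.98, "XE": 2.16,
}


@dataclass
class Atom:
    """One atom record.

    ``radius`` stays ``None`` until :func:`assign_radii` annotates it.
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    coords: np.ndarray
    altloc: str = ""
    icode: str = ""
    occupancy: float = 1.0
    hetero: bool = False
    radius: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.name}: radius must be positive")

    @property
    def residue_key(self) -> tuple[str, str]:
        """(chain, res_id with insertion-code suffix) — the residue identity."""
        return (self.chain, f"{self.res_id}{self.icode}")

    @property
    def atom_key(self) -> tuple[str, str, str]:
        """(chain, residue key, atom name) — the atom identity used for
        cross-structure correspondence."""
        return (self.chain, f"{self.res_id}{self.icode}", self.name)


class Structure:
    """An ordered, non-empty list of atoms for one conformer."""

    def __init__(self, atoms: Sequence[Atom], label: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure must contain at least one atom")
        keys = [(a.chain, a.res_id, a.icode, a.name, a.altloc) for a in atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, res_id, name, altloc) in Structure")
        self.atoms = atoms
        self.label = label

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i):
        return self.atoms[i]

    @property
    def coords(self) -> np.ndarray:
        """N×3 coordinate array in Å (a copy; assign back to update atoms)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @coords.setter
    def coords(self, value: np.ndarray):
        value = np.asarray(value, dtype=float)
        if value.shape != (len(self.atoms), 3):
            raise ValueError(f"expected shape ({len(self.atoms)}, 3), got {value.shape}")
        for atom, xyz in zip(self.atoms, value):
            atom.coords = xyz

    @property
    def radii(self) -> np.ndarray:
        """Per-atom vdW radii; raises if any atom lacks one."""
        missing = [a.name for a in self.atoms if a.radius is None]
        if missing:
            raise AnnotationError(
                f"{len(missing)} atoms lack a vdW radius (e.g. {missing[:5]}); "
                "run assign_radii first"
            )
        return np.array([a.radius for a in self.atoms], dtype=float)

    def copy(self) -> "Structure":
        return Structure([replace(a, coords=a.coords.copy()) for a in self.atoms],
                         label=self.label)

    def subset(self, indices: Sequence[int], label: str | None = None) -> "Structure":
        return Structure([self.atoms[i] for i in indices],
                         label=self.label if label is None else label)

    def __repr__(self):
        return f"<Structure '{self.label}' with {len(self)} atoms>"


class Ensemble:
    """F frames over one topology; every time statistic runs over frames."""

    def __init__(self, topology: Structure, frames: np.ndarray,
                 frame_ids: Sequence[str] | None = None, label: str = "",
                 fitted: bool = False):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (len(topology), 3):
            raise TopologyError(
                f"frames must have shape (F, {len(topology)}, 3), got {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise TopologyError("an Ensemble needs at least one frame")
        if frame_ids is None:
            frame_ids = [f"frame_{i + 1:05d}" for i in range(frames.shape[0])]
        if len(frame_ids) != frames.shape[0]:
            raise TopologyError("frame_ids length must equal the frame count")
        self.topology = topology
        self.frames = frames
        self.frame_ids = list(frame_ids)
        self.label = label or topology.label
        #: set by superpose.fit_ensemble; overlap analysis checks this flag
        self.fitted = fitted

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def copy(self) -> "Ensemble":
        return Ensemble(self.topology.copy(), self.frames.copy(),
                        list(self.frame_ids), self.label, self.fitted)

    def __repr__(self):
        return (f"<Ensemble '{self.label}': {self.n_frames} frames × "
                f"{self.n_atoms} atoms, fitted={self.fitted}>")


@dataclass(frozen=True)
class Selection:
    """AND-combined atom filters; every field is optional.

    ``res_range`` is inclusive; ``None`` on either end leaves it open, so
    ``(305, None)`` selects everything from residue 305 onward (the usual
    deaminase-domain restriction).
    """

    chains: frozenset[str] | None = None
    res_range: tuple[int | None, int | None] | None = None
    atom_names: frozenset[str] | None = None
    elements: frozenset[str] | None = None
    res_names: frozenset[str] | None = None

    def __post_init__(self):
        for fld in ("chains", "atom_names", "elements", "res_names"):
            val = getattr(self, fld)
            if val is not None and not isinstance(val, frozenset):
                object.__setattr__(self, fld, frozenset(val))

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.res_range is not None:
            lo, hi = self.res_range
            if lo is not None and atom.res_id < lo:
                return False
            if hi is not None and atom.res_id > hi:
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.elements is not None and atom.element.upper() not in {
            e.upper() for e in self.elements
        }:
            return False
        if self.res_names is not None and atom.res_name not in self.res_names:
            return False
        return True

    @staticmethod
    def all() -> "Selection":
        return Selection()


#: Protein backbone heavy atoms — the conventional fitting selection.
BACKBONE = Selection(atom_names=frozenset({"N", "CA", "C"}))


def resolve_selection(structure: Structure, sel: Selection) -> list[int]:
    """Indices of atoms matching all active filters, sorted ascending.

    Deterministic, idempotent, and independent of the order in which the
    filters were specified; an empty result is valid.
    """
    return [i for i, atom in enumerate(structure.atoms) if sel.matches(atom)]


@dataclass
class RadiusTable:
    """Element → vdW radius (Å); unknown elements get ``default_radius``."""

    radii: dict[str, float]
    default_radius: float = 1.50
    name: str = "custom"

    def __post_init__(self):
        self.radii = {el.upper(): float(r) for el, r in self.radii.items()}
        bad = {el: r for el, r in self.radii.items() if not 0.5 < r < 3.0}
        if bad:
            raise ValueError(f"radii outside (0.5, 3.0) Å: {bad}")
        if not 0.5 < self.default_radius < 3.0:
            raise ValueError("default_radius must lie in (0.5, 3.0) Å")

    @classmethod
    def bondi(cls) -> "RadiusTable":
        return cls(dict(BONDI_RADII), default_radius=1.50, name="bondi")

    @classmethod
    def from_csv(cls, path, default_radius: float = 1.50) -> "RadiusTable":
        """Load a two-column CSV ``element,radius_A`` (header optional)."""
        radii = {}
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0].lower() in ("element", "elem"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}, line {line_no}: expected element,radius")
            radii[parts[0]] = float(parts[1])
        return cls(radii, default_radius=default_radius, name=str(path))

    def to_csv(self, path) -> None:
        lines = ["element,radius_A"]
        lines += [f"{el},{r}" for el, r in sorted(self.radii.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    def lookup(self, element: str) -> tuple[float, bool]:
        """Return (radius, known); unknown elements map to the default."""
        el = element.upper()
        if el in self.radii:
            return self.radii[el], True
        return self.default_radius, False


def assign_radii(structure: Structure, table: RadiusTable | None = None) -> Structure:
    """Return a copy of ``structure`` with every atom carrying a vdW radius.

    Unknown elements receive ``table.default_radius`` and trigger a single
    logged warning listing them.
    """
    table = table or RadiusTable.bondi()
    out = structure.copy()
    unknown: set[str] = set()
    for atom in out.atoms:
        radius, known = table.lookup(atom.element)
        if not known:
            unknown.add(atom.element)
        atom.radius = radius
    if unknown:
        msg = (f"elements {sorted(unknown)} not in radius table '{table.name}'; "
               f"using default {table.default_radius} Å")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(lines: list[str]) -> None:
    """Cheap pre-scan so malformed ATOM lines fail with a line number."""
    for no, line in enumerate(lines, 1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"line {no}: ATOM/HETATM record too short")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise PDBParseError(
                    f"line {no}: cannot parse coordinates from {line[30:54]!r}"
                ) from None


def _atoms_from_array(arr: struc.AtomArray) -> list[Atom]:
    occ = (arr.get_annotation("occupancy")
           if "occupancy" in arr.get_annotation_categories()
           else np.ones(arr.array_length()))
    serial = (arr.get_annotation("atom_id")
              if "atom_id" in arr.get_annotation_categories()
              else np.arange(1, arr.array_length() + 1))
    icode = (arr.get_annotation("ins_code")
             if "ins_code" in arr.get_annotation_categories()
             else [""] * arr.array_length())
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(Atom(
            serial=int(serial[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]).upper(),
            res_name=str(arr.res_name[i]),
            res_id=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]),
            coords=np.asarray(arr.coord[i], dtype=float),
            icode=str(icode[i]).strip(),
            occupancy=float(occ[i]),
            hetero=bool(arr.hetero[i]),
        ))
    return atoms


def read_pdb(source, label: str | None = None) -> Structure | Ensemble:
    """Read a PDB file or stream.

    Returns a :class:`Structure` when the file has no MODEL records and an
    :class:`Ensemble` otherwise (even for a single MODEL block). Altloc
    duplicates are collapsed to the highest-occupancy conformer; HETATM
    atoms are retained with ``hetero=True``.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = label or "<stream>"
    else:
        text = Path(source).read_text()
        name = label or Path(source).name
    lines = text.splitlines()
    _validate_pdb_lines(lines)
    has_models = any(l.startswith("MODEL") for l in lines)
    try:
        pdb = PDBFile.read(io.StringIO(text))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # element guessing
            stack = pdb.get_structure(
                altloc="occupancy", extra_fields=["atom_id", "occupancy"]
            )
    except PDBParseError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError/ValueError
        msg = str(exc)
        if "number of atoms" in msg or "model" in msg.lower():
            raise TopologyError(f"{name}: {msg}") from exc
        raise PDBParseError(f"{name}: {msg}") from exc

    blank = stack.element == ""
    if np.any(blank):
        inferred = struc.infer_elements(stack.atom_name)
        stack.element[blank] = inferred[blank]

    first = stack[0]
    atoms = _atoms_from_array(first)
    topology = Structure(atoms, label=name)
    if not has_models:
        return topology
    frame_ids = [f"model_{i + 1}" for i in range(stack.stack_depth())]
    return Ensemble(topology, np.asarray(stack.coord, dtype=float),
                    frame_ids=frame_ids, label=name)


def _array_from_structure(structure: Structure) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords
    arr.chain_id = np.array([a.chain or "A" for a in structure.atoms])
    arr.res_id = np.array([a.res_id for a in structure.atoms])
    arr.res_name = np.array([a.res_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.array([a.hetero for a in structure.atoms])
    arr.set_annotation("ins_code", np.array([a.icode for a in structure.atoms]))
    arr.set_annotation("occupancy",
                       np.array([a.occupancy for a in structure.atoms]))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_pdb(obj: Structure | Ensemble, dest) -> None:
    """Write a Structure (plain records) or Ensemble (MODEL/ENDMDL blocks).

    Raises :class:`CoordinateRangeError` when a coordinate does not fit the
    fixed 8.3 PDB columns (|x| ≥ 10000 Å).
    """
    if isinstance(obj, Ensemble):
        coords_all = obj.frames
        template = _array_from_structure(obj.topology)
    else:
        coords_all = obj.coords[None]
        template = _array_from_structure(obj)
    if np.any(np.abs(coords_all) >= 10000):
        raise CoordinateRangeError(
            "coordinates with |x| >= 10000 Å cannot be written in PDB columns"
        )
    if isinstance(obj, Ensemble):
        out = struc.from_template(template, coords_all)
    else:
        out = template
    pdb = PDBFile()
    pdb.set_structure(out)
    pdb.lines.append("END")
    if hasattr(dest, "write"):
        pdb.write(dest)
    else:
        with open(dest, "w") as fh:
            pdb.write(fh)


def build_structure(
    coords: np.ndarray,
    *,
    names: Iterable[str] | str = "CA",
    elements: Iterable[str] | str = "C",
    res_ids: Iterable[int] | None = None,
    res_names: Iterable[str] | str = "GLY",
    chain: Iterable[str] | str = "A",
    hetero: Iterable[bool] | bool = False,
    label: str = "",
) -> Structure:
    """Convenience constructor from arrays; scalar arguments broadcast.

    ``res_ids`` defaults to 1..N (one residue per atom).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]

    def expand(value, default=None):
        if isinstance(value, (str, bool, int)):
            return [value] * n
        return list(value)

    names = expand(names)
    elements = expand(elements)
    res_names = expand(res_names)
    chains = expand(chain)
    het = expand(hetero)
    res_ids = list(res_ids) if res_ids is not None else list(range(1, n + 1))
    atoms = [
        Atom(serial=i + 1, name=names[i], element=elements[i],
             res_name=res_names[i], res_id=res_ids[i], chain=chains[i],
             coords=coords[i], hetero=het[i])
        for i in range(n)
    ]
    return Structure(atoms, label=label)
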