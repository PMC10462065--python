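"""Structures, trajectories, selections and residue-number maps.

Coordinates are in Angstrom throughout; times in picoseconds.  Residue
numbering follows the author (PDB) numbering of the input file; generic
receptor position codes (e.g. ``"3.49"``) are an auxiliary map, never a
replacement for author numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

WATER_RESNAMES = {"HOH", "WAT", "TIP3"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Base class for structure/trajectory contract violations."""


class PDBParseError(StructureError):
    pass


class SelectionError(StructureError):
    pass


class RosterMismatchError(StructureError):
    pass


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure (PDB v3 naming conventions)."""

    serial: int
    atom_name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    element: str = ""
    is_water: bool = False

    def __post_init__(self):
        if not all(np.isfinite(self.coords)):
            raise StructureError(
                f"non-finite coordinates for atom {self.serial} {self.atom_name}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.atom_name)


class Structure:
    """An ordered list of atoms for a single conformation."""

    def __init__(self, atoms: Sequence[AtomRecord], title: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        self.title = title
        if not self.atoms:
            raise StructureError("a Structure must contain at least one atom")
        seen: set[tuple] = set()
        for a in self.atoms:
            if a.key in seen:
                raise StructureError(f"duplicate atom {a.key} in structure")
            seen.add(a.key)
        self._index = {a.key: i for i, a in enumerate(self.atoms)}

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<Structure {self.title!r} with {len(self)} atoms>"

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of coordinates, Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self)} atoms"
            )
        atoms = [
            replace(a, coords=tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.title if title is None else title)

    def index_of(self, residue_seq: int, atom_name: str, chain_id: str | None = None) -> int:
        """Index of a named atom; raises SelectionError listing what is missing."""
        if chain_id is not None:
            key = (chain_id, residue_seq, atom_name)
            if key in self._index:
                return self._index[key]
        else:
            for i, a in enumerate(self.atoms):
                if a.residue_seq == residue_seq and a.atom_name == atom_name:
                    return i
        raise SelectionError(
            f"atom {atom_name!r} of residue {residue_seq}"
            + (f" chain {chain_id!r}" if chain_id else "")
            + " not found in roster"
        )

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out


class FrameSource:
    """Ordered coordinate frames sharing one atom roster.

    ``roster`` is a :class:`Structure` whose coordinates are those of the
    first frame; ``frame(i)`` returns an (N, 3) array.  Reading the same
    index twice returns identical values.
    """

    def __init__(
        self,
        roster: Structure,
        coords: np.ndarray,
        frame_interval_ps: float = 200.0,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (len(roster), 3):
            raise StructureError(
                f"frame array shape {coords.shape} incompatible with roster of "
                f"{len(roster)} atoms"
            )
        if coords.shape[0] < 1:
            raise StructureError("a FrameSource needs at least one frame")
        self.roster = roster
        self._coords = coords
        self.frame_interval_ps = float(frame_interval_ps)

    @property
    def n_frames(self) -> int:
        return int(self._coords.shape[0])

    def frame(self, i: int) -> np.ndarray:
        return self._coords[i].copy()

    def coords_array(self) -> np.ndarray:
        """(F, N, 3) array of all frames (copy)."""
        return self._coords.copy()

    def frame_structure(self, i: int) -> Structure:
        return self.roster.with_coords(self._coords[i])

    def with_coords(self, coords: np.ndarray) -> "FrameSource":
        return FrameSource(self.roster, coords, self.frame_interval_ps)

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> AtomRecord | tuple:
    # fixed-column PDB v3; returns (record, altloc, occupancy)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed coordinate record at line {lineno}: {line.rstrip()!r}") from exc
    rec = AtomRecord(
        serial=serial,
        atom_name=name,
        residue_name=resname,
        residue_seq=resseq,
        chain_id=chain,
        coords=(x, y, z),
        element=element or _guess_element(name),
        is_water=resname in WATER_RESNAMES,
    )
    return rec, altloc, occupancy


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    return stripped[:1].upper()


def _resolve_altlocs(records: list[tuple[AtomRecord, str, float]]) -> list[AtomRecord]:
    """Keep highest-occupancy altloc per (chain, resseq, name); ties -> first listed."""
    best: dict[tuple, tuple[float, int]] = {}
    for i, (rec, altloc, occ) in enumerate(records):
        key = rec.key
        if key not in best or occ > best[key][0]:
            best[key] = (occ, i)
    keep = sorted(i for _, i in best.values())
    return [records[i][0] for i in keep]


def read_pdb(path: str | Path, model: int = 1) -> Structure:
    """Read one model of a PDB file into a Structure.

    Altlocs are resolved to the highest occupancy (ties go to the first
    listed).  Waters (HOH/WAT/TIP3) are flagged.
    """
    frames = read_frames(path)
    if model < 1 or model > frames.n_frames:
        raise PDBParseError(f"model {model} not present ({frames.n_frames} models)")
    return frames.frame_structure(model - 1)


def read_frames(path: str | Path, frame_interval_ps: float = 200.0) -> FrameSource:
    """Read a (possibly multi-model) PDB file as a FrameSource.

    The atom roster is taken from the first model; any model whose atoms do
    not match the roster raises :class:`RosterMismatchError` naming the model.
    """
    path = Path(path)
    text = path.read_text()
    models: list[list[tuple[AtomRecord, str, float]]] = []
    current: list[tuple[AtomRecord, str, float]] = []
    in_model = False
    title = path.stem
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec_name = line[:6]
        if rec_name.startswith("TITLE"):
            title = line[10:].strip() or title
        elif rec_name == "MODEL ":
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec_name == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec_name in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")

    resolved = [_resolve_altlocs(m) for m in models]
    roster_atoms = resolved[0]
    roster = Structure(roster_atoms, title=title)
    n = len(roster_atoms)
    coords = np.empty((len(resolved), n, 3), dtype=float)
    ref_keys = [a.key for a in roster_atoms]
    for mi, atoms in enumerate(resolved):
        if len(atoms) != n:
            raise RosterMismatchError(
                f"model {mi + 1} has {len(atoms)} atoms, expected {n} (from model 1)"
            )
        keys = [a.key for a in atoms]
        if keys != ref_keys:
            diff = set(ref_keys).symmetric_difference(keys)
            raise RosterMismatchError(
                f"model {mi + 1} atom roster differs from model 1: {sorted(diff)[:5]}"
            )
        coords[mi] = [a.coords for a in atoms]
    return FrameSource(roster, coords, frame_interval_ps=frame_interval_ps)


def _format_atom_line(a: AtomRecord, serial: int | None = None) -> str:
    if serial is None:
        serial = a.serial
    name = a.atom_name
    # PDB convention: 1-3 char names start in column 14
    if len(name) < 4 and not name[:1].isdigit():
        name = " " + name
    record = "HETATM" if a.is_water else "ATOM  "
    x, y, z = a.coords
    return (
        f"{record}{serial:>5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
        f"{a.chain_id:1s}{a.residue_seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2s}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    lines = [f"TITLE     {structure.title}"]
    for a in structure.atoms:
        lines.append(_format_atom_line(a))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_frames(frames: FrameSource, path: str | Path) -> None:
    """Write a FrameSource as a multi-model PDB (coordinates to 0.001 A)."""
    lines = [f"TITLE     {frames.roster.title}"]
    for fi in range(frames.n_frames):
        lines.append(f"MODEL     {fi + 1:>4d}")
        struct = frames.roster.with_coords(frames.frame(fi))
        for a in struct.atoms:
            lines.append(_format_atom_line(a))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Selection:
    """A resolved, ordered atom-index selection."""

    spec: str
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)

    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


_RESID_RE = re.compile(r"^\d+(-\d+)?(,\d+(-\d+)?)*$")


def _parse_resid_ranges(arg: str) -> list[tuple[int, int]]:
    if not _RESID_RE.match(arg):
        raise SelectionError(f"bad resid argument {arg!r}")
    out = []
    for part in arg.split(","):
        if "-" in part:
            lo, hi = part.split("-")
            out.append((int(lo), int(hi)))
        else:
            out.append((int(part), int(part)))
    return out


def resolve_selection(spec: str, roster: Structure) -> Selection:
    """Resolve a selection spec against a roster.

    Grammar: clauses joined by ``and``; each clause is one of
    ``chain <id>``, ``resid <n|a-b>[,c-d...]``, ``name <N1> [N2 ...]``,
    ``element <E> [..]``, ``backbone``, ``backbone-heavy``, ``water``,
    ``protein``; a clause may be prefixed with ``not``.

    Resolution is deterministic (roster order) and total: residue numbers or
    atom names that do not exist anywhere in the roster, or an empty final
    selection, raise :class:`SelectionError`.
    """
    atoms = roster.atoms
    mask = np.ones(len(atoms), dtype=bool)
    clauses = [c.strip() for c in spec.split(" and ")]
    all_resseq = {a.residue_seq for a in atoms}
    all_names = {a.atom_name for a in atoms}
    all_chains = {a.chain_id for a in atoms}

    for clause in clauses:
        if not clause:
            raise SelectionError(f"empty clause in spec {spec!r}")
        negate = False
        tokens = clause.split()
        if tokens[0] == "not":
            negate = True
            tokens = tokens[1:]
            if not tokens:
                raise SelectionError(f"dangling 'not' in spec {spec!r}")
        kw, args = tokens[0], tokens[1:]
        if kw == "chain":
            if len(args) != 1:
                raise SelectionError("chain takes exactly one argument")
            if args[0] not in all_chains:
                raise SelectionError(f"chain {args[0]!r} not found in roster")
            m = np.array([a.chain_id == args[0] for a in atoms])
        elif kw == "resid":
            if len(args) != 1:
                raise SelectionError("resid takes one range argument")
            ranges = _parse_resid_ranges(args[0])
            wanted = set()
            for lo, hi in ranges:
                wanted.update(range(lo, hi + 1))
            missing = sorted(wanted - all_resseq)
            if missing and not negate:
                raise SelectionError(
                    f"residues not found in roster: {missing[:10]}"
                    + (" ..." if len(missing) > 10 else "")
                )
            m = np.array([a.residue_seq in wanted for a in atoms])
        elif kw == "name":
            if not args:
                raise SelectionError("name requires at least one atom name")
            unknown = sorted(set(args) - all_names)
            if unknown and not negate:
                raise SelectionError(f"atom names not found in roster: {unknown}")
            wanted_names = set(args)
            m = np.array([a.atom_name in wanted_names for a in atoms])
        elif kw == "element":
            if not args:
                raise SelectionError("element requires at least one symbol")
            wanted_el = {e.upper() for e in args}
            m = np.array([a.element.upper() in wanted_el for a in atoms])
        elif kw in ("backbone", "backbone-heavy"):
            m = np.array([a.atom_name in BACKBONE_ATOMS for a in atoms])
        elif kw == "water":
            m = np.array([a.is_water for a in atoms])
        elif kw == "protein":
            m = np.array([not a.is_water for a in atoms])
        else:
            raise SelectionError(f"unknown selection keyword {kw!r} in {spec!r}")
        if negate:
            m = ~m
        mask &= m

    indices = tuple(int(i) for i in np.nonzero(mask)[0])
    if not indices:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return Selection(spec=spec, indices=indices)


# ---------------------------------------------------------------------------
# generic residue-position codes
# ---------------------------------------------------------------------------


@dataclass
class BWMap:
    """Author residue number <-> generic receptor position code map.

    The map must be injective (one code per residue and vice versa).
    """

    entries: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        codes = list(self.entries.values())
        if len(set(codes)) != len(codes):
            raise StructureError("position-code map is not injective")
        self._reverse = {c: r for r, c in self.entries.items()}

    def code(self, residue_seq: int) -> str:
        try:
            return self.entries[residue_seq]
        except KeyError:
            raise StructureError(f"residue {residue_seq} has no position code") from None

    def residue(self, code: str) -> int:
        try:
            return self._reverse[code]
        except KeyError:
            raise StructureError(f"position code {code!r} has no residue") from None

    def residue_range(self, code_lo: str, code_hi: str) -> range:
        """Inclusive author-number range between two codes."""
        lo = self.residue(code_lo)
        hi = self.residue(code_hi)
        if lo > hi:
            lo, hi = hi, lo
        return range(lo, hi + 1)
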