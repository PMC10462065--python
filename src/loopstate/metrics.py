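"""Per-frame scalar metrics of helix and loop arrangement.

All distances/RMSDs are Angstrom, angles degrees in (-180, 180].
Frames passed to :func:`icl2_rotation_angle` must already be aligned on
the transmembrane fit set to the reference orientation (membrane normal
along z, loop helical axis approximately along x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Selection, SelectionError, Structure, resolve_selection
from .superpose import SuperpositionError, kabsch, rmsd

AtomSpec = tuple[int, str]  # (author residue number, atom name)

#: minimum projected length (A) of the loop-orientation vector in the (y, z)
#: plane below which the rotation angle is flagged unreliable
MIN_PROJECTED_LENGTH = 0.1


class MissingAtomError(SelectionError):
    pass


def _atom_coords(struct: Structure, spec: AtomSpec, chain: str | None = None) -> np.ndarray:
    resseq, name = spec
    try:
        i = struct.index_of(resseq, name, chain)
    except SelectionError as exc:
        raise MissingAtomError(str(exc)) from exc
    return np.asarray(struct.atoms[i].coords, dtype=float)


def parse_atom_spec(text: str) -> AtomSpec:
    """Parse ``"114:OH"`` into ``(114, "OH")``."""
    resseq, _, name = text.partition(":")
    if not resseq.isdigit() or not name:
        raise SelectionError(f"bad atom spec {text!r}; expected 'RESSEQ:NAME'")
    return int(resseq), name


# ---------------------------------------------------------------------------
# distances and shifts
# ---------------------------------------------------------------------------


def pair_distance(frame: Structure, atom_a: AtomSpec | str, atom_b: AtomSpec | str) -> float:
    """Euclidean distance between two named atoms."""
    if isinstance(atom_a, str):
        atom_a = parse_atom_spec(atom_a)
    if isinstance(atom_b, str):
        atom_b = parse_atom_spec(atom_b)
    pa = _atom_coords(frame, atom_a)
    pb = _atom_coords(frame, atom_b)
    return float(np.linalg.norm(pa - pb))


def _axis_projection(struct: Structure, probe: int, axis_lo: int, axis_hi: int) -> float:
    p = _atom_coords(struct, (probe, "CA"))
    a = _atom_coords(struct, (axis_lo, "CA"))
    b = _atom_coords(struct, (axis_hi, "CA"))
    axis = b - a
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise SelectionError(
            f"zero-length axis between residues {axis_lo} and {axis_hi} CA atoms"
        )
    return float(np.dot(p - a, axis / norm))


def tm5_vertical_shift(
    frame: Structure,
    ref_zero: Structure,
    probe_residue: int = 190,
    axis_residues: tuple[int, int] = (130, 141),
) -> float:
    """Vertical shift of a TM5 probe CA along the TM4 axis, relative to a reference.

    The probe CA is projected onto the line through the two axis-residue CA
    atoms; the scalar position is reported relative to the same quantity in
    ``ref_zero`` (reference reads 0; positive = toward the extracellular
    side, i.e. along the low-to-high axis-residue direction).
    """
    lo, hi = axis_residues
    return _axis_projection(frame, probe_residue, lo, hi) - _axis_projection(
        ref_zero, probe_residue, lo, hi
    )


def loop_end_to_end(
    frame: Structure, res_a: int = 504, res_b: int = 508, chain: str | None = None
) -> float:
    """End-to-end CA distance of a loop segment (default Galpha beta6-alpha5)."""
    pa = _atom_coords(frame, (res_a, "CA"), chain)
    pb = _atom_coords(frame, (res_b, "CA"), chain)
    return float(np.linalg.norm(pa - pb))


# ---------------------------------------------------------------------------
# loop rotation angle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AngleResult:
    """Loop rotation angle about its (approximately x-aligned) helical axis."""

    raw_deg: float  # atan2(v_z, v_y) of the tip-to-base vector
    offset_deg: float | None  # raw minus the reference structure's raw angle
    reliable: bool  # projected vector length >= MIN_PROJECTED_LENGTH


def wrap_angle(deg: float) -> float:
    """Wrap to (-180, 180]."""
    w = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def icl2_rotation_angle(
    aligned_frame: Structure,
    tip_atom: AtomSpec = (114, "OH"),
    base_atom: AtomSpec = (112, "CG"),
    reference: Structure | None = None,
) -> AngleResult:
    """Rotation angle of the loop helix read off a two-atom vector.

    The vector from ``base_atom`` to ``tip_atom`` is projected onto the
    (y, z) plane of the aligned reference orientation and measured as on a
    unit circle: ``atan2(v_z, v_y)`` in degrees.  If ``reference`` is given,
    the angle with the reference structure defined as 0 is also reported.
    """
    v = _atom_coords(aligned_frame, tip_atom) - _atom_coords(aligned_frame, base_atom)
    raw = float(np.degrees(np.arctan2(v[2], v[1])))
    raw = wrap_angle(raw)
    reliable = bool(np.hypot(v[1], v[2]) >= MIN_PROJECTED_LENGTH)
    offset = None
    if reference is not None:
        ref = icl2_rotation_angle(reference, tip_atom, base_atom, reference=None)
        offset = wrap_angle(raw - ref.raw_deg)
    return AngleResult(raw_deg=raw, offset_deg=offset, reliable=reliable)


# ---------------------------------------------------------------------------
# local backbone RMSDs
# ---------------------------------------------------------------------------


def _backbone_selection(struct: Structure, residue_range: tuple[int, int]) -> Selection:
    lo, hi = residue_range
    return resolve_selection(f"resid {lo}-{hi} and backbone", struct)


def icl2_backbone_rmsd(
    frame: Structure,
    ref: Structure,
    residue_range: tuple[int, int] = (110, 118),
) -> float:
    """Superposed backbone (N, CA, C, O) RMSD of the loop segment.

    The selection is aligned locally onto the reference selection before
    the deviation is measured.
    """
    sel_f = _backbone_selection(frame, residue_range)
    sel_r = _backbone_selection(ref, residue_range)
    if len(sel_f) != len(sel_r):
        raise SelectionError(
            f"backbone atom count differs between frame ({len(sel_f)}) and "
            f"reference ({len(sel_r)}) for residues {residue_range}"
        )
    return rmsd(frame.coords[sel_f.array()], ref.coords[sel_r.array()], superpose=True)


def multi_rmsd_cv(
    frame: Structure,
    ref: Structure,
    residue_range: tuple[int, int] = (111, 118),
) -> float:
    """Backbone heavy-atom multi-RMSD collective variable (default residues 111-118)."""
    return icl2_backbone_rmsd(frame, ref, residue_range=residue_range)


# ---------------------------------------------------------------------------
# G-protein metrics
# ---------------------------------------------------------------------------


def helix5_displacement(
    complex_frame: Structure,
    ref: Structure,
    fit_selection_spec: str,
    g_alpha_range: tuple[int, int] = (519, 530),
    g_alpha_chain: str | None = None,
) -> float:
    """Displacement of the Galpha helix-5 segment relative to the receptor.

    The frame is aligned on the receptor fit selection (not on Galpha), then
    the unsuperposed CA RMSD of the Galpha residue range vs the reference is
    reported.
    """
    fit_f = resolve_selection(fit_selection_spec, complex_frame)
    fit_r = resolve_selection(fit_selection_spec, ref)
    result = kabsch(complex_frame.coords[fit_f.array()], ref.coords[fit_r.array()])

    lo, hi = g_alpha_range
    spec = f"resid {lo}-{hi} and name CA"
    if g_alpha_chain is not None:
        spec = f"chain {g_alpha_chain} and " + spec
    try:
        ga_f = resolve_selection(spec, complex_frame)
        ga_r = resolve_selection(spec, ref)
    except SelectionError as exc:
        raise SelectionError(f"G-alpha selection unresolved: {exc}") from exc
    moved = result.apply(complex_frame.coords[ga_f.array()])
    return rmsd(moved, ref.coords[ga_r.array()], superpose=False)


# ---------------------------------------------------------------------------
# vectorized helpers used by the per-frame pipeline
# ---------------------------------------------------------------------------


def pair_distance_batch(coords: np.ndarray, idx_a: int, idx_b: int) -> np.ndarray:
    """Distances for all frames of an (F, N, 3) coordinate array."""
    return np.linalg.norm(coords[:, idx_a, :] - coords[:, idx_b, :], axis=1)


def rotation_angle_batch(coords: np.ndarray, idx_tip: int, idx_base: int) -> np.ndarray:
    """Raw rotation angles (deg) for all frames of an aligned (F, N, 3) array."""
    v = coords[:, idx_tip, :] - coords[:, idx_base, :]
    return np.degrees(np.arctan2(v[:, 2], v[:, 1]))


def superposed_rmsd_batch(coords: np.ndarray, ref_coords: np.ndarray) -> np.ndarray:
    """Superposed RMSD of (F, M, 3) frames onto one (M, 3) reference."""
    from .superpose import kabsch_batch

    rot, trans = kabsch_batch(coords, ref_coords)
    moved = np.einsum("fij,fnj->fni", rot, coords) + trans[:, None, :]
    return np.sqrt(np.mean(np.sum((moved - ref_coords) ** 2, axis=2), axis=1))
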