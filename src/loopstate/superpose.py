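"""Least-squares rigid-body superposition (Kabsch) and RMSD.

The fit is unweighted and always returns a proper rotation
(det(R) = +1), correcting reflections via the sign of the smallest
singular value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import FrameSource, Selection, Structure, StructureError


class SuperpositionError(StructureError):
    pass


@dataclass(frozen=True)
class AlignmentResult:
    """Rigid transform mapping mobile onto reference: x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float  # A, after applying the transform

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def _check_points(coords: np.ndarray, label: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise SuperpositionError(f"{label} must be an (N, 3) array, got {coords.shape}")
    if coords.shape[0] < 3:
        raise SuperpositionError(f"{label} needs at least 3 points, got {coords.shape[0]}")
    return coords


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> AlignmentResult:
    """Optimal proper-rotation superposition of mobile onto reference.

    Raises :class:`SuperpositionError` for fewer than 3 points, mismatched
    counts, or a degenerate (collinear) configuration.
    """
    mobile = _check_points(mobile, "mobile")
    reference = _check_points(reference, "reference")
    if mobile.shape != reference.shape:
        raise SuperpositionError(
            f"point count mismatch: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear or coincident) point set")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cr - rotation @ cm
    moved = mobile @ rotation.T + translation
    value = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return AlignmentResult(rotation=rotation, translation=translation, rmsd=value)


def kabsch_batch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched Kabsch: mobile (F, N, 3) onto one reference (N, 3).

    Returns rotations (F, 3, 3) and translations (F, 3).  No degeneracy
    checks beyond the SVD itself; intended for the vectorized pipeline.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=1, keepdims=True)  # (F, 1, 3)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    h = np.einsum("fni,nj->fij", p, q)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(u) * np.linalg.det(vt)  # det(V @ U^T) per frame
    diag = np.zeros_like(h)
    diag[:, 0, 0] = 1.0
    diag[:, 1, 1] = 1.0
    diag[:, 2, 2] = np.sign(det)
    rot = vt.transpose(0, 2, 1) @ diag @ u.transpose(0, 2, 1)
    trans = cr - np.einsum("fij,fj->fi", rot, cm[:, 0, :])
    return rot, trans


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation in Angstrom.

    With ``superpose=True`` the optimal rigid transform is applied first.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise SuperpositionError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if superpose:
        return kabsch(a, b).rmsd
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def align_frames(
    frames: FrameSource,
    fit_selection: Selection,
    reference: Structure,
) -> FrameSource:
    """Align every frame onto the reference using the fit selection.

    The transform is fit on the selected atoms only and applied to all
    atoms; the roster is unchanged.
    """
    idx = fit_selection.array()
    ref_sel = reference.coords[idx]
    out = np.empty((frames.n_frames, len(frames.roster), 3), dtype=float)
    for fi in range(frames.n_frames):
        crd = frames.frame(fi)
        try:
            result = kabsch(crd[idx], ref_sel)
        except SuperpositionError as exc:
            raise SuperpositionError(f"frame {fi}: {exc}") from exc
        out[fi] = result.apply(crd)
    return frames.with_coords(out)


def align_coords_batch(
    coords: np.ndarray, fit_indices: np.ndarray, reference_coords: np.ndarray
) -> np.ndarray:
    """Vectorized variant of :func:`align_frames` on a raw (F, N, 3) array."""
    rot, trans = kabsch_batch(coords[:, fit_indices, :], reference_coords[fit_indices])
    return np.einsum("fij,fnj->fni", rot, coords) + trans[:, None, :]
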