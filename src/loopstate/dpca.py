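"""Backbone phi/psi extraction and principal component analysis.

Dihedrals enter PCA as raw degrees by default, matching the analysis
procedure; a sin/cos embedding is available as an opt-in to avoid
wraparound artifacts near +-180.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .structure import FrameSource, SelectionError, StructureError


class DihedralError(StructureError):
    pass


def dihedral_batch(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Torsion angle (deg, IUPAC sign) for stacked point quadruples (..., 3)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map the closed -180 endpoint onto +180 so values lie in (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


@dataclass
class DihedralMatrix:
    """Frames x (phi_i, psi_i) matrix in degrees, with column provenance."""

    values: np.ndarray  # (F, K)
    columns: list[str]  # e.g. "phi_110"
    dropped: list[str] = field(default_factory=list)  # undefined terminal dihedrals

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])


def compute_dihedrals(
    frames: FrameSource,
    residue_window: tuple[int, int] | range,
    chain: str | None = None,
) -> DihedralMatrix:
    """phi (C-, N, CA, C) and psi (N, CA, C, N+) for every window residue.

    Dihedrals whose flanking atom is missing (window termini without a
    neighbor) are dropped and recorded in ``dropped``.
    """
    if isinstance(residue_window, tuple):
        residues = list(range(residue_window[0], residue_window[1] + 1))
    else:
        residues = list(residue_window)
    if not residues:
        raise DihedralError("empty residue window")
    roster = frames.roster

    def idx(res: int, name: str) -> int | None:
        try:
            return roster.index_of(res, name, chain)
        except SelectionError:
            return None

    coords = frames.coords_array()
    cols: list[str] = []
    dropped: list[str] = []
    series: list[np.ndarray] = []
    for r in residues:
        n_i, ca_i, c_i = idx(r, "N"), idx(r, "CA"), idx(r, "C")
        if None in (n_i, ca_i, c_i):
            raise DihedralError(f"residue {r} lacks backbone atoms N/CA/C")
        c_prev = idx(r - 1, "C")
        n_next = idx(r + 1, "N")
        if c_prev is None:
            dropped.append(f"phi_{r}")
        else:
            cols.append(f"phi_{r}")
            series.append(
                dihedral_batch(
                    coords[:, c_prev], coords[:, n_i], coords[:, ca_i], coords[:, c_i]
                )
            )
        if n_next is None:
            dropped.append(f"psi_{r}")
        else:
            cols.append(f"psi_{r}")
            series.append(
                dihedral_batch(
                    coords[:, n_i], coords[:, ca_i], coords[:, c_i], coords[:, n_next]
                )
            )
    if not series:
        raise DihedralError("no defined dihedrals in window")
    return DihedralMatrix(values=np.stack(series, axis=1), columns=cols, dropped=dropped)


def embed_sincos(matrix: np.ndarray) -> np.ndarray:
    """Map degree columns to interleaved (sin, cos) columns."""
    rad = np.radians(np.asarray(matrix, dtype=float))
    out = np.empty((rad.shape[0], 2 * rad.shape[1]))
    out[:, 0::2] = np.sin(rad)
    out[:, 1::2] = np.cos(rad)
    return out


@dataclass
class PCAModel:
    mean: np.ndarray  # (K,)
    components: np.ndarray  # (C, K), orthonormal rows
    explained_variance: np.ndarray  # (C,), descending
    explained_variance_ratio: np.ndarray  # (C,)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean": self.mean.tolist(),
                    "components": self.components.tolist(),
                    "explained_variance": self.explained_variance.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        data = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(data["mean"]),
            components=np.array(data["components"]),
            explained_variance=np.array(data["explained_variance"]),
            explained_variance_ratio=np.array(data["explained_variance_ratio"]),
        )


def fit_pca(
    matrix: DihedralMatrix | np.ndarray,
    helical_mask: np.ndarray | None = None,
    n_components: int | None = None,
) -> PCAModel:
    """Mean-centered PCA of the masked rows (covariance, no column scaling)."""
    values = matrix.values if isinstance(matrix, DihedralMatrix) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise DihedralError(f"expected a 2D matrix with >= 1 column, got {values.shape}")
    if helical_mask is not None:
        mask = np.asarray(helical_mask, dtype=bool)
        if mask.shape != (values.shape[0],):
            raise DihedralError("helical_mask length must match the number of rows")
        values = values[mask]
    if values.shape[0] < 2:
        raise DihedralError(f"need >= 2 (masked) rows for PCA, got {values.shape[0]}")
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    pca.fit(values)
    return PCAModel(
        mean=pca.mean_.copy(),
        components=pca.components_.copy(),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project(model: PCAModel, matrix: DihedralMatrix | np.ndarray) -> np.ndarray:
    """Scores of rows in the model's principal-component basis."""
    values = matrix.values if isinstance(matrix, DihedralMatrix) else np.asarray(matrix, dtype=float)
    if values.size == 0:
        raise DihedralError("cannot project an empty matrix")
    if values.ndim != 2 or values.shape[1] != model.mean.shape[0]:
        raise DihedralError(
            f"column count {values.shape} does not match model dimension {model.mean.shape[0]}"
        )
    return (values - model.mean) @ model.components.T


def reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    return np.asarray(scores) @ model.components + model.mean
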