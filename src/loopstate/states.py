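"""Loop helicity rule, rotational-state classification, occupancy statistics.

A frame's loop is *helical* if it has >= 3 backbone i,i+4 hydrogen bonds
within the loop segment, or a locally superposed backbone RMSD to the
reference below 2.0 A.  Helical frames are assigned the PR (positively
rotated) state when the rotation angle ``a`` and tyrosine-to-TM2 distance
``d`` fall inside the printed windows (45 < a < 120 and
195 - 20*a < d < 13, strict inequalities); helical frames outside the PR
window are NR; everything else is NONHELICAL.  The threshold ``a`` is the
raw (un-offset) angle; a config switch allows thresholding the
crystal-offset angle instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbonds import HBondCriteria, sem_ci68
from .metrics import (
    icl2_backbone_rmsd,
    pair_distance_batch,
    rotation_angle_batch,
    superposed_rmsd_batch,
    wrap_angle,
)
from .structure import FrameSource, SelectionError, Structure, StructureError, resolve_selection
from .superpose import align_coords_batch

PR = "PR"
NR = "NR"
NONHELICAL = "NONHELICAL"

#: TM1-4 CA fit set; matches the synthetic scaffold's anchor helices.
#: Real systems must supply their own ranges in config.
DEFAULT_FIT_SELECTION = "resid 5-25,30-55,80-107,125-145 and name CA"


class ClassifierError(StructureError):
    pass


@dataclass(frozen=True)
class StateThresholds:
    """Printed classifier thresholds; every number is a config default."""

    a_lo: float = 45.0  # degrees
    a_hi: float = 120.0  # degrees
    d_hi: float = 13.0  # A
    d_lo_intercept: float = 195.0  # lower bound on d is intercept - slope * a
    d_lo_slope: float = 20.0
    rmsd_cutoff: float = 2.0  # A, helicity branch
    min_i4_hbonds: int = 3  # helicity branch


@dataclass(frozen=True)
class HelicityCriteria:
    residue_range: tuple[int, int] = (110, 118)
    rmsd_cutoff: float = 2.0
    min_i4_hbonds: int = 3
    hbond: HBondCriteria = field(default_factory=lambda: HBondCriteria(heavy_only=True))


def is_helical(n_i4_hbonds: int, backbone_rmsd: float, criteria: HelicityCriteria = HelicityCriteria()) -> bool:
    """The helicity rule itself: >= min bonds OR RMSD strictly below cutoff."""
    return n_i4_hbonds >= criteria.min_i4_hbonds or backbone_rmsd < criteria.rmsd_cutoff


def count_i4_hbonds(
    frame: Structure,
    residue_range: tuple[int, int],
    criteria: HBondCriteria,
) -> int:
    """Count backbone i,i+4 H-bonds (donor N(i+4), acceptor O(i)) in the range."""
    lo, hi = residue_range
    coords = frame.coords
    n = 0
    for i in range(lo, hi - 3):
        try:
            o_i = frame.index_of(i, "O")
            n_i4 = frame.index_of(i + 4, "N")
        except SelectionError as exc:
            raise ClassifierError(f"backbone atom missing for i,i+4 bond count: {exc}") from exc
        d = float(np.linalg.norm(coords[n_i4] - coords[o_i]))
        if d > criteria.da_cutoff:
            continue
        if criteria.heavy_only:
            n += 1
            continue
        # explicit-hydrogen path: require an amide H with good D-H...A angle
        from .hbonds import _angle_deg, _attached_hydrogens

        ok = False
        for hi_idx in _attached_hydrogens(frame, coords, n_i4):
            ang = _angle_deg(coords[n_i4], coords[hi_idx], coords[o_i])
            if ang >= criteria.dha_min_angle:
                ok = True
                break
        if ok:
            n += 1
    return n


def classify_helicity(
    frame: Structure,
    ref: Structure,
    criteria: HelicityCriteria = HelicityCriteria(),
) -> bool:
    """Apply the helicity rule to one frame against the reference."""
    bonds = count_i4_hbonds(frame, criteria.residue_range, criteria.hbond)
    if bonds >= criteria.min_i4_hbonds:
        return True
    value = icl2_backbone_rmsd(frame, ref, residue_range=criteria.residue_range)
    return value < criteria.rmsd_cutoff


def classify_state(a: float, d: float, helical: bool, thresholds: StateThresholds = StateThresholds()) -> str:
    """Assign PR / NR / NONHELICAL from angle a (deg), distance d (A), helicity.

    Inequalities are strict, exactly as printed; the lower d bound
    ``intercept - slope * a`` is applied verbatim even though it is vacuous
    over the printed angle window.
    """
    if not helical:
        return NONHELICAL
    if not (np.isfinite(a) and np.isfinite(d)):
        raise ClassifierError("a and d must be finite for helical frames")
    in_pr = (
        thresholds.a_lo < a < thresholds.a_hi
        and (thresholds.d_lo_intercept - thresholds.d_lo_slope * a) < d < thresholds.d_hi
    )
    return PR if in_pr else NR


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


@dataclass
class OccupancySummary:
    per_replica_fraction_pr: list[float]
    per_replica_fraction_nr: list[float]
    n_frames_per_replica: list[int]
    mean_pr: float
    ci68_pr: float
    mean_nr: float
    ci68_nr: float

    def to_dict(self) -> dict:
        return {
            "per_replica_fraction_pr": self.per_replica_fraction_pr,
            "per_replica_fraction_nr": self.per_replica_fraction_nr,
            "n_frames_per_replica": self.n_frames_per_replica,
            "mean_pr": self.mean_pr,
            "ci68_pr": self.ci68_pr,
            "mean_nr": self.mean_nr,
            "ci68_nr": self.ci68_nr,
        }


def occupancy(replica_labels: list) -> OccupancySummary:
    """Per-replica PR/NR fractions over all frames, with mean and 68% CI (SEM).

    Nonhelical frames stay in the denominator: fractions are of total time.
    """
    if not replica_labels:
        raise ClassifierError("at least one replica is required")
    fr_pr, fr_nr, counts = [], [], []
    for i, labels in enumerate(replica_labels):
        labels = list(labels)
        if not labels:
            raise ClassifierError(f"replica {i} has no frames")
        n = len(labels)
        fr_pr.append(sum(1 for s in labels if s == PR) / n)
        fr_nr.append(sum(1 for s in labels if s == NR) / n)
        counts.append(n)
    return OccupancySummary(
        per_replica_fraction_pr=fr_pr,
        per_replica_fraction_nr=fr_nr,
        n_frames_per_replica=counts,
        mean_pr=float(np.mean(fr_pr)),
        ci68_pr=sem_ci68(fr_pr),
        mean_nr=float(np.mean(fr_nr)),
        ci68_nr=sem_ci68(fr_nr),
    )


# ---------------------------------------------------------------------------
# per-frame state trace (vectorized pipeline)
# ---------------------------------------------------------------------------


@dataclass
class TraceConfig:
    """Everything the per-frame pipeline needs, with the printed defaults."""

    fit_selection: str = DEFAULT_FIT_SELECTION
    angle_tip: tuple[int, str] = (114, "OH")
    angle_base: tuple[int, str] = (112, "CG")
    distance_a: tuple[int, str] = (114, "OH")
    distance_b: tuple[int, str] = (39, "CB")
    icl2_range: tuple[int, int] = (110, 118)
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    hbond: HBondCriteria = field(default_factory=lambda: HBondCriteria(heavy_only=True))
    use_offset_angle: bool = False  # threshold on crystal-offset angle instead of raw


def state_trace(frames: FrameSource, ref: Structure, config: TraceConfig = TraceConfig()) -> pd.DataFrame:
    """Align, measure and classify every frame; one row per frame.

    Columns: frame_index, angle_raw_deg, angle_offset_deg, d_A, icl2_rmsd_A,
    n_i4_hbonds, helical, state.
    """
    if frames.n_frames == 0:
        raise ClassifierError("FrameSource has no frames")
    roster = frames.roster
    fit = resolve_selection(config.fit_selection, roster)
    resolve_selection(config.fit_selection, ref)  # fail fast on the reference too
    idx_tip = roster.index_of(*config.angle_tip)
    idx_base = roster.index_of(*config.angle_base)
    idx_da = roster.index_of(*config.distance_a)
    idx_db = roster.index_of(*config.distance_b)
    lo, hi = config.icl2_range
    bb = resolve_selection(f"resid {lo}-{hi} and backbone", roster)
    bb_ref = resolve_selection(f"resid {lo}-{hi} and backbone", ref)
    if len(bb) != len(bb_ref):
        raise ClassifierError("loop backbone atom count differs between roster and reference")
    # i,i+4 donor/acceptor index pairs (N(i+4), O(i))
    i4_pairs = [
        (roster.index_of(i + 4, "N"), roster.index_of(i, "O")) for i in range(lo, hi - 3)
    ]

    coords = frames.coords_array()
    ref_coords = ref.coords
    # the reference roster may differ from the trajectory roster; fit on the
    # trajectory roster's selection mapped by (chain, resseq, name)
    ref_fit = np.array(
        [ref.index_of(roster.atoms[i].residue_seq, roster.atoms[i].atom_name, roster.atoms[i].chain_id) for i in fit.indices]
    )
    rot_ref = ref_coords[ref_fit]
    from .superpose import kabsch_batch

    rot, trans = kabsch_batch(coords[:, fit.array(), :], rot_ref)
    aligned = np.einsum("fij,fnj->fni", rot, coords) + trans[:, None, :]

    angle_raw = rotation_angle_batch(aligned, idx_tip, idx_base)
    ref_tip = ref_coords[ref.index_of(*config.angle_tip)]
    ref_base = ref_coords[ref.index_of(*config.angle_base)]
    v_ref = ref_tip - ref_base
    ref_angle = float(np.degrees(np.arctan2(v_ref[2], v_ref[1])))
    angle_offset = np.array([wrap_angle(x - ref_angle) for x in angle_raw])

    d = pair_distance_batch(aligned, idx_da, idx_db)
    icl2_rmsd = superposed_rmsd_batch(coords[:, bb.array(), :], ref_coords[bb_ref.array()])

    # vectorized i,i+4 bond count (distance criterion; explicit-H path falls
    # back to the per-frame counter)
    if config.hbond.heavy_only:
        n_bonds = np.zeros(frames.n_frames, dtype=int)
        for dn, ac in i4_pairs:
            dist = np.linalg.norm(coords[:, dn, :] - coords[:, ac, :], axis=1)
            n_bonds += (dist <= config.hbond.da_cutoff).astype(int)
    else:
        n_bonds = np.array(
            [
                count_i4_hbonds(frames.frame_structure(fi), config.icl2_range, config.hbond)
                for fi in range(frames.n_frames)
            ]
        )

    helicity = HelicityCriteria(
        residue_range=config.icl2_range,
        rmsd_cutoff=config.thresholds.rmsd_cutoff,
        min_i4_hbonds=config.thresholds.min_i4_hbonds,
        hbond=config.hbond,
    )
    helical = (n_bonds >= helicity.min_i4_hbonds) | (icl2_rmsd < helicity.rmsd_cutoff)
    a_for_threshold = angle_offset if config.use_offset_angle else angle_raw
    labels = [
        classify_state(float(a), float(dd), bool(h), config.thresholds)
        for a, dd, h in zip(a_for_threshold, d, helical)
    ]

    return pd.DataFrame(
        {
            "frame_index": np.arange(frames.n_frames),
            "angle_raw_deg": angle_raw,
            "angle_offset_deg": angle_offset,
            "d_A": d,
            "icl2_rmsd_A": icl2_rmsd,
            "n_i4_hbonds": n_bonds,
            "helical": helical,
            "state": labels,
        }
    )
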