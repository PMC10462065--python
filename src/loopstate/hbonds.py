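"""Geometric hydrogen-bond detection, water bridges, and frequency tables.

Default criteria: donor-acceptor distance <= 3.5 A, and, when explicit
hydrogens are present and heavy-only mode is off, a D-H...A angle of at
least 110 degrees for some hydrogen attached to the donor.  Crystal
structures and other heavy-atom-only inputs should use heavy-only mode,
which applies the distance criterion alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import FrameSource, Selection, Structure, StructureError

#: maximum covalent D-H distance used to associate hydrogens with donors
H_COVALENT_CUTOFF = 1.25


class HBondError(StructureError):
    pass


@dataclass(frozen=True)
class HBondCriteria:
    da_cutoff: float = 3.5  # A
    dha_min_angle: float = 110.0  # degrees, used only when hydrogens present
    heavy_only: bool = False

    def __post_init__(self):
        if self.da_cutoff <= 0:
            raise HBondError("da_cutoff must be positive")
        if not 0.0 <= self.dha_min_angle <= 180.0:
            raise HBondError("dha_min_angle must be in [0, 180]")


@dataclass(frozen=True)
class HBondEvent:
    frame_index: int
    donor_index: int
    acceptor_index: int
    da_distance: float
    hydrogen_index: int | None = None
    dha_angle: float | None = None


@dataclass(frozen=True)
class WaterBridge:
    frame_index: int
    partner_a_index: int
    water_residue: tuple[str, int]  # (chain_id, residue_seq)
    partner_b_index: int


def _attached_hydrogens(struct: Structure, coords: np.ndarray, heavy_index: int) -> list[int]:
    heavy = struct.atoms[heavy_index]
    out = []
    for i, a in enumerate(struct.atoms):
        if a.element != "H":
            continue
        if a.chain_id != heavy.chain_id or a.residue_seq != heavy.residue_seq:
            continue
        if np.linalg.norm(coords[i] - coords[heavy_index]) <= H_COVALENT_CUTOFF:
            out.append(i)
    return out


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(
    frame: Structure,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    frame_index: int = 0,
) -> list[HBondEvent]:
    """All donor-acceptor pairs satisfying the geometric criteria.

    Each qualifying pair is reported once per frame.  If hydrogens are
    required (``heavy_only=False``) and a donor has none attached, an
    error instructs the caller to enable heavy-only mode.
    """
    if len(donors) == 0 or len(acceptors) == 0:
        raise HBondError("donor and acceptor selections must be non-empty")
    coords = frame.coords
    d_idx = donors.array()
    a_idx = acceptors.array()

    hydrogens: dict[int, list[int]] = {}
    if not criteria.heavy_only:
        for di in d_idx:
            hs = _attached_hydrogens(frame, coords, int(di))
            if not hs:
                atom = frame.atoms[int(di)]
                raise HBondError(
                    f"donor {atom.residue_name}{atom.residue_seq}:{atom.atom_name} "
                    "has no attached hydrogens; enable heavy-only mode "
                    "(criteria.heavy_only=True) for heavy-atom-only structures"
                )
            hydrogens[int(di)] = hs

    dist = np.linalg.norm(
        coords[d_idx][:, None, :] - coords[a_idx][None, :, :], axis=2
    )
    events: list[HBondEvent] = []
    for i, di in enumerate(d_idx):
        for j, aj in enumerate(a_idx):
            if int(di) == int(aj):
                continue
            d = float(dist[i, j])
            if d > criteria.da_cutoff:
                continue
            if criteria.heavy_only:
                events.append(HBondEvent(frame_index, int(di), int(aj), d))
                continue
            best = None
            for hi in hydrogens[int(di)]:
                ang = _angle_deg(coords[int(di)], coords[hi], coords[int(aj)])
                if ang >= criteria.dha_min_angle and (best is None or ang > best[1]):
                    best = (hi, ang)
            if best is not None:
                events.append(
                    HBondEvent(frame_index, int(di), int(aj), d, best[0], best[1])
                )
    return events


def _pair_hbonded(
    frame: Structure,
    coords: np.ndarray,
    i: int,
    j: int,
    criteria: HBondCriteria,
    h_cache: dict[int, list[int]],
) -> bool:
    """Whether atoms i and j are H-bonded in either donor/acceptor polarity."""
    d = float(np.linalg.norm(coords[i] - coords[j]))
    if d > criteria.da_cutoff:
        return False
    if criteria.heavy_only:
        return True
    for donor, acceptor in ((i, j), (j, i)):
        if donor not in h_cache:
            h_cache[donor] = _attached_hydrogens(frame, coords, donor)
        for hi in h_cache[donor]:
            ang = _angle_deg(coords[donor], coords[hi], coords[acceptor])
            if ang >= criteria.dha_min_angle:
                return True
    if not h_cache[i] and not h_cache[j]:
        raise HBondError(
            "neither atom of a candidate pair has attached hydrogens; enable "
            "heavy-only mode (criteria.heavy_only=True)"
        )
    return False


def detect_water_bridges(
    frame: Structure,
    partner_a: Selection,
    partner_b: Selection,
    criteria: HBondCriteria = HBondCriteria(),
    frame_index: int = 0,
) -> list[WaterBridge]:
    """Water residues H-bonded (either polarity) to both partner selections.

    One bridge is reported per (water residue, partner-a atom, partner-b
    atom) combination with the closest qualifying partner atoms; a frame
    with no waters yields an empty list.
    """
    coords = frame.coords
    waters: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(frame.atoms):
        if a.is_water and a.element == "O":
            waters.setdefault((a.chain_id, a.residue_seq), []).append(i)
    bridges: list[WaterBridge] = []
    h_cache: dict[int, list[int]] = {}
    set_a = set(int(i) for i in partner_a.indices)
    for wkey, w_oxygens in waters.items():
        for wo in w_oxygens:
            hit_a = [
                int(pa)
                for pa in partner_a.indices
                if _pair_hbonded(frame, coords, wo, int(pa), criteria, h_cache)
            ]
            if not hit_a:
                continue
            hit_b = [
                int(pb)
                for pb in partner_b.indices
                if int(pb) not in set_a
                and _pair_hbonded(frame, coords, wo, int(pb), criteria, h_cache)
            ]
            if not hit_b:
                continue
            best_a = min(hit_a, key=lambda i: np.linalg.norm(coords[i] - coords[wo]))
            best_b = min(hit_b, key=lambda i: np.linalg.norm(coords[i] - coords[wo]))
            bridges.append(WaterBridge(frame_index, best_a, wkey, best_b))
            break  # one bridge per water residue
    return bridges


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------


@dataclass
class FrequencyRow:
    pair_label: str
    per_replica_fractions: list[float]
    mean: float
    ci68_halfwidth: float


@dataclass
class FrequencyTable:
    rows: list[FrequencyRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_label": [r.pair_label for r in self.rows],
                "per_replica_fractions": [r.per_replica_fractions for r in self.rows],
                "mean": [r.mean for r in self.rows],
                "ci68_halfwidth": [r.ci68_halfwidth for r in self.rows],
            }
        )


def sem_ci68(values: list[float] | np.ndarray) -> float:
    """68% CI half-width across replicas = standard error of the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def _frame_positive(
    struct: Structure,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria,
    water_mediated: bool,
) -> bool:
    coords = struct.coords
    h_cache: dict[int, list[int]] = {}
    for di in donors.indices:
        for aj in acceptors.indices:
            if di == aj:
                continue
            if _pair_hbonded(struct, coords, int(di), int(aj), criteria, h_cache):
                return True
    if water_mediated:
        if detect_water_bridges(struct, donors, acceptors, criteria):
            return True
    return False


def interaction_frequency(
    replicas: list[FrameSource],
    pair_specs: list[tuple[str, str, str]],
    criteria: HBondCriteria = HBondCriteria(),
    frame_masks: list[np.ndarray] | None = None,
    water_mediated: bool = True,
) -> FrequencyTable:
    """Fraction of frames with a direct OR water-mediated bond, per pair.

    ``pair_specs`` is a list of (label, selection_a, selection_b).  A frame
    counts as positive if any atom of selection_a bonds any atom of
    selection_b directly or through a shared water.  Fractions are computed
    per replica over masked (counted) frames; the table reports replica
    fractions, their mean, and the 68% CI half-width (SEM).  Replicas with
    zero counted frames are excluded; if all are excluded an error is
    raised.
    """
    from .structure import resolve_selection

    if not replicas:
        raise HBondError("at least one replica is required")
    if frame_masks is not None and len(frame_masks) != len(replicas):
        raise HBondError("frame_masks length must match number of replicas")

    table = FrequencyTable()
    for label, spec_a, spec_b in pair_specs:
        fractions: list[float] = []
        for ri, rep in enumerate(replicas):
            sel_a = resolve_selection(spec_a, rep.roster)
            sel_b = resolve_selection(spec_b, rep.roster)
            mask = (
                np.ones(rep.n_frames, dtype=bool)
                if frame_masks is None
                else np.asarray(frame_masks[ri], dtype=bool)
            )
            if mask.shape != (rep.n_frames,):
                raise HBondError(
                    f"mask length {mask.shape} does not match replica {ri} "
                    f"({rep.n_frames} frames)"
                )
            counted = int(mask.sum())
            if counted == 0:
                continue
            positive = 0
            for fi in np.nonzero(mask)[0]:
                struct = rep.frame_structure(int(fi))
                if _frame_positive(struct, sel_a, sel_b, criteria, water_mediated):
                    positive += 1
            fractions.append(positive / counted)
        if not fractions:
            raise HBondError(f"all replicas excluded for pair {label!r}")
        table.rows.append(
            FrequencyRow(
                pair_label=label,
                per_replica_fractions=fractions,
                mean=float(np.mean(fractions)),
                ci68_halfwidth=sem_ci68(fractions),
            )
        )
    return table
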