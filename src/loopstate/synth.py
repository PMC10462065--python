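"""Synthetic scaffolds and two-state trajectories with known ground truth.

The scaffold is a receptor-like arrangement of CA anchor helices (numbered
so every metric in :mod:`loopstate.metrics` resolves), an ICL2 segment
built as an ideal helix whose helical axis lies along x, sidechain mount
atoms for the rotation-angle vector, an optional G-alpha fragment, and
optional waters.  Trajectories rigidly rotate the loop body between two
rotational states under a two-state Markov chain, with optional unfolding
episodes, planted water bridges, Gaussian coordinate noise, and per-frame
global rigid motion.  Every stochastic output is a pure function of
(spec, seed).
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import (
    AtomRecord,
    FrameSource,
    Structure,
    StructureError,
    write_frames,
    write_pdb,
)

# ---------------------------------------------------------------------------
# geometry constants of the scaffold (all Angstrom / degrees)
# ---------------------------------------------------------------------------

ICL2_RANGE = (110, 118)  # the rotating loop body
ICL2_BUILD_RANGE = (108, 120)  # built segment incl. static flanks
AXIS_POINT = np.array([0.0, 0.0, -16.0])  # design helical axis: along +x here
TIP_RADIUS = 6.0  # radial distance of the 114:OH mount from the axis
BASE_RADIUS = 1.0  # radial distance of the 112:CG mount
THETA_PR_DEFAULT = 80.0  # raw angle of the PR fixture (center of PR window)
THETA_NR_OFFSET = -40.0  # NR = PR - 40
D_PR = 10.5  # designed tyrosine-to-TM2 distance in the PR state

#: CA-only anchor helices: residue range, (x, y) center, start z, direction
_TM_HELICES = {
    "TM1": ((5, 25), (14.0, 0.0), -15.0, +1),
    "TM2": ((30, 55), (7.0, 12.0), -18.0, +1),
    "TM3": ((80, 107), (-7.0, 12.0), 18.0, -1),
    "TM4": ((125, 145), (-14.0, 0.0), -15.0, +1),
    "TM5": ((180, 210), (-7.0, -12.0), 20.0, -1),
    "TM6": ((215, 245), (7.0, -12.0), -20.0, +1),
}

#: CA selection of the TM1-4 fit set on the scaffold
from .states import DEFAULT_FIT_SELECTION as FIT_SELECTION  # noqa: E402

_RISE = 1.5
_CA_RADIUS = 2.3
_TWIST = 100.0  # degrees per residue

# ideal backbone internal coordinates
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7


class SynthError(StructureError):
    pass


# ---------------------------------------------------------------------------
# ideal helix construction (NeRF)
# ---------------------------------------------------------------------------


def _place(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, r: float, theta: float, chi: float) -> np.ndarray:
    """Place an atom bonded to p3 with bond length r, angle (p2,p3,new) = theta
    and dihedral (p1,p2,p3,new) = chi (degrees)."""
    theta = math.radians(theta)
    chi = math.radians(chi)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(chi),
            r * math.sin(theta) * math.sin(chi),
        ]
    )
    basis = np.column_stack([bc, m, n])
    return p3 + basis @ d


def make_ideal_helix(
    n_res: int,
    torsions: tuple[float, float] | list[tuple[float, float]] = (-57.0, -47.0),
    start_res: int = 1,
    chain: str = "A",
    residue_name: str = "ALA",
    with_hydrogens: bool = False,
) -> Structure:
    """Backbone segment built from ideal internal coordinates and set (phi, psi).

    Returns N, CA, C, O (and optionally amide H for residues after the
    first) for ``n_res`` residues.  With the default torsions the interior
    i,i+4 N...O distances are below 3.5 A.  Construction is deterministic.
    """
    if n_res < 4:
        raise SynthError(f"need at least 4 residues for a helix segment, got {n_res}")
    if isinstance(torsions, tuple):
        tor = [tuple(torsions)] * n_res
    else:
        tor = [tuple(t) for t in torsions]
        if len(tor) != n_res:
            raise SynthError("per-residue torsion list length must equal n_res")

    n_at = [np.array([0.0, 0.0, 0.0])]
    a_rad = math.radians(_A_N_CA_C)
    ca_at = [np.array([_B_N_CA, 0.0, 0.0])]
    c_at = [ca_at[0] + _B_CA_C * np.array([-math.cos(a_rad), math.sin(a_rad), 0.0])]
    for i in range(1, n_res):
        psi_prev = tor[i - 1][1]
        n_next = _place(n_at[-1], ca_at[-1], c_at[-1], _B_C_N, _A_CA_C_N, psi_prev)
        ca_next = _place(ca_at[-1], c_at[-1], n_next, _B_N_CA, _A_C_N_CA, 180.0)
        c_next = _place(c_at[-1], n_next, ca_next, _B_CA_C, _A_N_CA_C, tor[i][0])
        n_at.append(n_next)
        ca_at.append(ca_next)
        c_at.append(c_next)

    # carbonyl O: trigonal-planar completion of C's bonds (CA and next N)
    o_at = []
    for i in range(n_res):
        if i + 1 < n_res:
            n_next = n_at[i + 1]
        else:  # virtual next N from the final psi
            n_next = _place(n_at[i], ca_at[i], c_at[i], _B_C_N, _A_CA_C_N, tor[i][1])
        u = (ca_at[i] - c_at[i]) / np.linalg.norm(ca_at[i] - c_at[i])
        v = (n_next - c_at[i]) / np.linalg.norm(n_next - c_at[i])
        w = -(u + v)
        o_at.append(c_at[i] + _B_C_O * w / np.linalg.norm(w))

    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(n_res):
        res = start_res + i
        names = [("N", n_at[i], "N"), ("CA", ca_at[i], "C"), ("C", c_at[i], "C"), ("O", o_at[i], "O")]
        if with_hydrogens and i > 0:
            u = (ca_at[i] - n_at[i]) / np.linalg.norm(ca_at[i] - n_at[i])
            v = (c_at[i - 1] - n_at[i]) / np.linalg.norm(c_at[i - 1] - n_at[i])
            w = -(u + v)
            h = n_at[i] + _B_N_H * w / np.linalg.norm(w)
            names.append(("H", h, "H"))
        for name, xyz, element in names:
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    residue_name=residue_name,
                    residue_seq=res,
                    chain_id=chain,
                    coords=tuple(float(x) for x in xyz),
                    element=element,
                )
            )
            serial += 1
    return Structure(atoms, title=f"ideal segment {start_res}-{start_res + n_res - 1}")


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # orient along increasing point order
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    return axis


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation sending unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about any perpendicular
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        perp -= a * np.dot(a, perp)
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _x_rotation(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    return np.array(
        [[1.0, 0.0, 0.0], [0.0, math.cos(t), -math.sin(t)], [0.0, math.sin(t), math.cos(t)]]
    )


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScaffoldSpec:
    include_g_alpha: bool = True
    n_waters: int = 2
    with_hydrogens: bool = False


def _tm_ca_positions(res_range: tuple[int, int], center: tuple[float, float], z0: float, direction: int):
    lo, hi = res_range
    out = {}
    for k, res in enumerate(range(lo, hi + 1)):
        ang = math.radians(_TWIST * k)
        out[res] = np.array(
            [
                center[0] + _CA_RADIUS * math.cos(ang),
                center[1] + _CA_RADIUS * math.sin(ang),
                z0 + direction * _RISE * k,
            ]
        )
    return out


def _oriented_icl2(with_hydrogens: bool) -> Structure:
    """Ideal segment 108-120 with its CA principal axis along +x, CA centroid
    of the rotating body at AXIS_POINT."""
    lo, hi = ICL2_BUILD_RANGE
    seg = make_ideal_helix(
        hi - lo + 1, start_res=lo, chain="A", with_hydrogens=with_hydrogens
    )
    coords = seg.coords
    ca_idx = [i for i, a in enumerate(seg.atoms) if a.atom_name == "CA"]
    axis = _principal_axis(coords[ca_idx])
    rot = _rotation_between(axis, np.array([1.0, 0.0, 0.0]))
    coords = coords @ rot.T
    body_ca = [
        i
        for i, a in enumerate(seg.atoms)
        if a.atom_name == "CA" and ICL2_RANGE[0] <= a.residue_seq <= ICL2_RANGE[1]
    ]
    coords += AXIS_POINT - coords[body_ca].mean(axis=0)
    return seg.with_coords(coords)


def _tip_position(theta_deg: float, x_offset: float) -> np.ndarray:
    t = math.radians(theta_deg)
    return AXIS_POINT + np.array(
        [x_offset, TIP_RADIUS * math.cos(t), TIP_RADIUS * math.sin(t)]
    )


def make_scaffold(spec: ScaffoldSpec = ScaffoldSpec()) -> Structure:
    """Build the full scaffold structure.

    The T39:CB anchor is positioned so that the tyrosine-tip distance d
    reads ``D_PR`` in the default PR orientation and crosses the 13 A
    classifier threshold in the default NR orientation.
    """
    atoms: list[AtomRecord] = []
    serial = [0]

    def add(name, resname, resseq, chain, xyz, element, is_water=False):
        serial[0] += 1
        atoms.append(
            AtomRecord(
                serial=serial[0],
                atom_name=name,
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain,
                coords=tuple(float(x) for x in xyz),
                element=element,
                is_water=is_water,
            )
        )

    icl2 = _oriented_icl2(spec.with_hydrogens)
    icl2_by_res: dict[int, list[AtomRecord]] = {}
    for a in icl2.atoms:
        icl2_by_res.setdefault(a.residue_seq, []).append(a)
    x_ca = {
        a.residue_seq: a.coords[0] for a in icl2.atoms if a.atom_name == "CA"
    }

    tm_positions: dict[int, np.ndarray] = {}
    for rng_, center, z0, direction in _TM_HELICES.values():
        tm_positions.update(_tm_ca_positions(rng_, center, z0, direction))

    # tyrosine tip orbit: CB anchor placed on the PR->NR chord extension
    tip_pr = _tip_position(THETA_PR_DEFAULT, x_ca[114])
    tip_nr = _tip_position(THETA_PR_DEFAULT + THETA_NR_OFFSET, x_ca[114])
    u = (tip_pr - tip_nr) / np.linalg.norm(tip_pr - tip_nr)
    cb_39 = tip_pr + D_PR * u

    resnames = {39: "THR", 112: "LEU", 114: "TYR", 116: "ALA"}

    for res in sorted(set(tm_positions) | set(icl2_by_res)):
        resname = resnames.get(res, "ALA")
        if res in tm_positions:
            add("CA", resname, res, "A", tm_positions[res], "C")
            if res == 39:
                add("CB", resname, res, "A", cb_39, "C")
        else:
            for a in icl2_by_res[res]:
                add(a.atom_name, resname, res, "A", a.coords, a.element)
            if res == 112:
                base = AXIS_POINT + np.array([x_ca[112], BASE_RADIUS, 0.0])
                add("CG", resname, res, "A", base, "C")
            if res == 114:
                tip = AXIS_POINT + np.array([x_ca[114], TIP_RADIUS, 0.0])
                add("OH", resname, res, "A", tip, "O")

    if spec.include_g_alpha:
        for k, res in enumerate(range(500, 531)):
            ang = math.radians(_TWIST * k)
            xyz = np.array(
                [
                    -22.0 + _RISE * k,
                    _CA_RADIUS * math.cos(ang),
                    -30.0 + _CA_RADIUS * math.sin(ang),
                ]
            )
            add("CA", "ALA", res, "B", xyz, "C")

    for w in range(spec.n_waters):
        add("O", "HOH", 901 + w, "W", np.array([30.0 + 5.0 * w, 30.0, 30.0]), "O", is_water=True)

    return Structure(atoms, title="synthetic receptor scaffold")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySpec:
    n_frames: int
    seed: int
    n_replicas: int = 1
    theta_pr: float = THETA_PR_DEFAULT
    theta_nr: float | None = None  # default theta_pr - 40
    p_pr_to_nr: float = 0.0  # per-frame switch probabilities
    p_nr_to_pr: float = 0.0
    start_state: str = "PR"  # "PR", "NR" or "stationary"
    noise_sigma: float = 0.0  # A, isotropic per atom per frame
    unfold_fraction: float = 0.0
    unfold_schedule: list[int] | None = None
    bridge_fraction: float = 0.0
    bridge_schedule: list[int] | None = None
    bridge_partner: tuple[int, str] = (114, "OH")
    rigid_motion: bool = True
    galpha_shift: float = 0.0  # constant translation of the G-alpha chain, A
    frame_interval_ps: float = 200.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise SynthError("n_frames must be >= 1")
        if self.n_replicas < 1:
            raise SynthError("n_replicas must be >= 1")
        for p in (self.p_pr_to_nr, self.p_nr_to_pr, self.unfold_fraction, self.bridge_fraction):
            if not 0.0 <= p <= 1.0:
                raise SynthError("probabilities must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise SynthError("noise_sigma must be >= 0")
        if self.theta_nr is None:
            self.theta_nr = self.theta_pr + THETA_NR_OFFSET
        if self.start_state not in ("PR", "NR", "stationary"):
            raise SynthError("start_state must be PR, NR or stationary")
        if self.start_state == "stationary" and self.p_pr_to_nr + self.p_nr_to_pr == 0:
            raise SynthError("stationary start requires nonzero switch rates")


@dataclass
class ReplicaTruth:
    """Generator-side ground truth for one replica."""

    labels: list[str]  # PR / NR / NONHELICAL per frame
    angles: np.ndarray  # imposed raw angle (deg); NaN for unfolded frames
    unfolded: np.ndarray  # bool mask
    bridged: np.ndarray  # bool mask of planted-water-bridge frames
    bridge_partner_b: tuple[int, str] | None = None


def _random_unfolded_segment(rng: np.random.Generator, with_hydrogens: bool, reference_body: np.ndarray):
    """Randomized-torsion conformer for the loop body, guaranteed non-helical."""
    from .superpose import rmsd as _rmsd

    lo, hi = ICL2_RANGE
    n = hi - lo + 1
    for _ in range(100):
        tor = [(float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180))) for _ in range(n)]
        seg = make_ideal_helix(n, torsions=tor, start_res=lo, chain="A", with_hydrogens=with_hydrogens)
        coords = seg.coords
        # count i,i+4 N...O contacts
        n_idx = {a.residue_seq: i for i, a in enumerate(seg.atoms) if a.atom_name == "N"}
        o_idx = {a.residue_seq: i for i, a in enumerate(seg.atoms) if a.atom_name == "O"}
        bonds = sum(
            1
            for i in range(lo, hi - 3)
            if np.linalg.norm(coords[n_idx[i + 4]] - coords[o_idx[i]]) <= 3.5
        )
        bb = np.array(
            [i for i, a in enumerate(seg.atoms) if a.atom_name in ("N", "CA", "C", "O")]
        )
        value = _rmsd(coords[bb], reference_body, superpose=True)
        if bonds < 3 and value >= 2.5:
            ca = np.array([i for i, a in enumerate(seg.atoms) if a.atom_name == "CA"])
            axis = _principal_axis(coords[ca])
            rot = _rotation_between(axis, np.array([1.0, 0.0, 0.0]))
            coords = coords @ rot.T
            coords += AXIS_POINT - coords[ca].mean(axis=0)
            return seg.with_coords(coords)
    raise SynthError("failed to generate a non-helical conformer (seed exhausted)")


def _auto_bridge_partner(scaffold: Structure, tip: tuple[int, str]) -> tuple[int, str]:
    """Pick a loop backbone N/O atom 2.0-5.5 A from the tip atom."""
    tip_xyz = np.asarray(scaffold.atoms[scaffold.index_of(*tip)].coords)
    lo, hi = ICL2_RANGE
    best = None
    for a in scaffold.atoms:
        if a.chain_id != "A" or not (lo <= a.residue_seq <= hi):
            continue
        if a.atom_name not in ("N", "O"):
            continue
        d = float(np.linalg.norm(np.asarray(a.coords) - tip_xyz))
        if 2.0 <= d <= 5.5 and (best is None or d < best[0]):
            best = (d, (a.residue_seq, a.atom_name))
    if best is None:
        raise SynthError("no suitable bridge partner near the tip atom")
    return best[1]


def _bridge_water_position(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Point H-bond-distance from both p and q, off the p-q axis."""
    sep = float(np.linalg.norm(p - q))
    contact = max(2.6, sep / 2.0 + 0.15)
    if contact > 3.4:
        raise SynthError(f"bridge partners too far apart ({sep:.2f} A)")
    m = 0.5 * (p + q)
    u = (p - q) / sep
    n = np.cross(u, np.array([1.0, 0.0, 0.0]))
    if np.linalg.norm(n) < 1e-6:
        n = np.cross(u, np.array([0.0, 1.0, 0.0]))
    n /= np.linalg.norm(n)
    h = math.sqrt(max(contact**2 - (sep / 2.0) ** 2, 0.0))
    return m + h * n


def simulate_trajectory(
    spec: TrajectorySpec, scaffold: Structure | None = None
) -> tuple[list[FrameSource], list[ReplicaTruth]]:
    """Generate per-replica frame sources plus ground truth.

    Per frame the loop body (residues 110-118 with its mount atoms) is
    rigidly rotated about the design axis to the state angle; unfold frames
    substitute a randomized-torsion conformer; bridge frames place the first
    water so it H-bonds the tip atom and a nearby loop backbone atom;
    Gaussian noise and a global rigid motion are applied last.
    """
    if scaffold is None:
        scaffold = make_scaffold()
    base = scaffold.coords
    n_atoms = len(scaffold)
    body_idx = np.array(
        [
            i
            for i, a in enumerate(scaffold.atoms)
            if a.chain_id == "A" and ICL2_RANGE[0] <= a.residue_seq <= ICL2_RANGE[1]
        ]
    )
    tip_i = scaffold.index_of(*spec.bridge_partner)
    # current raw angle of the scaffold's tip-base vector
    tip0 = np.asarray(scaffold.atoms[scaffold.index_of(114, "OH")].coords)
    base0 = np.asarray(scaffold.atoms[scaffold.index_of(112, "CG")].coords)
    v0 = tip0 - base0
    theta0 = math.degrees(math.atan2(v0[2], v0[1]))

    partner_b = _auto_bridge_partner(scaffold, spec.bridge_partner)
    partner_b_i = scaffold.index_of(*partner_b)
    water_o = [i for i, a in enumerate(scaffold.atoms) if a.is_water and a.element == "O"]
    if (spec.bridge_fraction > 0 or spec.bridge_schedule) and not water_o:
        raise SynthError("bridge planting requires at least one water in the scaffold")

    ga_idx = np.array([i for i, a in enumerate(scaffold.atoms) if a.chain_id == "B"], dtype=int)
    if spec.galpha_shift != 0.0 and ga_idx.size == 0:
        raise SynthError("galpha_shift set but the scaffold has no G-alpha chain")

    states_theta = {"PR": float(spec.theta_pr), "NR": float(spec.theta_nr)}
    rot_by_state = {
        s: _x_rotation(t - theta0) for s, t in states_theta.items()
    }
    body_by_state = {
        s: (base[body_idx] - AXIS_POINT) @ r.T + AXIS_POINT for s, r in rot_by_state.items()
    }
    bridge_w_by_state = {}
    for s, r in rot_by_state.items():
        p = body_by_state[s][np.where(body_idx == tip_i)[0][0]]
        q = body_by_state[s][np.where(body_idx == partner_b_i)[0][0]]
        bridge_w_by_state[s] = _bridge_water_position(p, q)

    p_stat = (
        spec.p_nr_to_pr / (spec.p_pr_to_nr + spec.p_nr_to_pr)
        if (spec.p_pr_to_nr + spec.p_nr_to_pr) > 0
        else None
    )

    replicas: list[FrameSource] = []
    truths: list[ReplicaTruth] = []
    for rep in range(spec.n_replicas):
        rng = np.random.default_rng([spec.seed, rep])
        # state sequence
        if spec.start_state == "stationary":
            state = "PR" if rng.random() < p_stat else "NR"
        else:
            state = spec.start_state
        labels: list[str] = []
        for _ in range(spec.n_frames):
            labels.append(state)
            if state == "PR" and rng.random() < spec.p_pr_to_nr:
                state = "NR"
            elif state == "NR" and rng.random() < spec.p_nr_to_pr:
                state = "PR"
        labels_arr = np.array(labels)

        if spec.unfold_schedule is not None:
            unfolded = np.zeros(spec.n_frames, dtype=bool)
            unfolded[np.asarray(spec.unfold_schedule, dtype=int)] = True
        else:
            unfolded = rng.random(spec.n_frames) < spec.unfold_fraction
        if spec.bridge_schedule is not None:
            bridged = np.zeros(spec.n_frames, dtype=bool)
            bridged[np.asarray(spec.bridge_schedule, dtype=int)] = True
        else:
            bridged = rng.random(spec.n_frames) < spec.bridge_fraction

        coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
        for s in ("PR", "NR"):
            mask = (labels_arr == s) & ~unfolded
            if mask.any():
                coords[np.ix_(np.nonzero(mask)[0], body_idx)] = body_by_state[s]
        # also rotate the body of unfolded frames before substitution so the
        # mount atoms follow the nominal state
        for fi in np.nonzero(unfolded)[0]:
            s = labels_arr[fi]
            coords[fi, body_idx] = body_by_state[s]
            seg = _random_unfolded_segment(
                rng,
                any(a.atom_name == "H" for a in scaffold.atoms),
                _reference_body_backbone(scaffold),
            )
            for a in seg.atoms:
                if a.atom_name in ("N", "CA", "C", "O", "H"):
                    try:
                        j = scaffold.index_of(a.residue_seq, a.atom_name, "A")
                    except StructureError:
                        continue
                    coords[fi, j] = a.coords

        if bridged.any():
            for s in ("PR", "NR"):
                mask = bridged & (labels_arr == s) & ~unfolded
                if mask.any():
                    coords[np.nonzero(mask)[0], water_o[0]] = bridge_w_by_state[s]

        if spec.galpha_shift != 0.0:
            coords[:, ga_idx, 1] += spec.galpha_shift

        if spec.noise_sigma > 0:
            coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

        if spec.rigid_motion:
            rots = _random_rotations(rng, spec.n_frames)
            trans = rng.uniform(-10.0, 10.0, size=(spec.n_frames, 3))
            coords = np.einsum("fij,fnj->fni", rots, coords) + trans[:, None, :]

        truth_labels = [
            "NONHELICAL" if unfolded[i] else labels[i] for i in range(spec.n_frames)
        ]
        angles = np.array(
            [
                np.nan if unfolded[i] else states_theta[labels[i]]
                for i in range(spec.n_frames)
            ]
        )
        replicas.append(
            FrameSource(scaffold.with_coords(coords[0]), coords, spec.frame_interval_ps)
        )
        truths.append(
            ReplicaTruth(
                labels=truth_labels,
                angles=angles,
                unfolded=unfolded,
                bridged=bridged & ~unfolded,
                bridge_partner_b=partner_b,
            )
        )
    return replicas, truths


def _reference_body_backbone(scaffold: Structure) -> np.ndarray:
    lo, hi = ICL2_RANGE
    idx = [
        i
        for i, a in enumerate(scaffold.atoms)
        if a.chain_id == "A"
        and lo <= a.residue_seq <= hi
        and a.atom_name in ("N", "CA", "C", "O")
    ]
    return scaffold.coords[idx]


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    rot = np.empty((n, 3, 3))
    rot[:, 0, 0] = 1 - 2 * (y * y + z * z)
    rot[:, 0, 1] = 2 * (x * y - z * w)
    rot[:, 0, 2] = 2 * (x * z + y * w)
    rot[:, 1, 0] = 2 * (x * y + z * w)
    rot[:, 1, 1] = 1 - 2 * (x * x + z * z)
    rot[:, 1, 2] = 2 * (y * z - x * w)
    rot[:, 2, 0] = 2 * (x * z - y * w)
    rot[:, 2, 1] = 2 * (y * z + x * w)
    rot[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return rot


# ---------------------------------------------------------------------------
# dataset output and the optional crystal fetch
# ---------------------------------------------------------------------------


def write_dataset(
    replicas: list[FrameSource],
    truths: list[ReplicaTruth],
    outdir: str | Path,
    scaffold: Structure | None = None,
) -> dict:
    """Write multi-model PDB trajectories plus a ground-truth CSV."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scaffold is None:
        scaffold = make_scaffold()
    ref_path = outdir / "reference.pdb"
    write_pdb(scaffold, ref_path)
    paths = []
    rows = []
    for ri, (rep, truth) in enumerate(zip(replicas, truths)):
        path = outdir / f"replica_{ri:02d}.pdb"
        write_frames(rep, path)
        paths.append(str(path))
        for fi in range(rep.n_frames):
            rows.append(
                {
                    "replica": ri,
                    "frame": fi,
                    "true_state": truth.labels[fi],
                    "true_angle_deg": truth.angles[fi],
                    "unfolded": bool(truth.unfolded[fi]),
                    "bridged": bool(truth.bridged[fi]),
                }
            )
    truth_path = outdir / "ground_truth.csv"
    pd.DataFrame(rows).to_csv(truth_path, index=False)
    return {"reference": str(ref_path), "replicas": paths, "ground_truth": str(truth_path)}


def fetch_crystal_fixture(pdb_id: str, cache_dir: str | Path = "scratch/pdb", timeout: float = 20.0) -> Structure:
    """Download and cache a PDB entry (CLI convenience; needs network)."""
    from .structure import read_pdb

    pdb_id = pdb_id.strip().lower()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise SynthError(f"invalid PDB id {pdb_id!r}")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{pdb_id}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
        except Exception as exc:  # noqa: BLE001 - network failures surface clearly
            raise SynthError(f"could not fetch {pdb_id.upper()} from {url}: {exc}") from exc
        path.write_bytes(data)
    return read_pdb(path)
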