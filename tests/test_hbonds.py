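import numpy as np
import pytest

from conftest import random_rotation
from loopstate import synth
from loopstate.hbonds import (
    HBondCriteria,
    HBondError,
    detect_hbonds,
    detect_water_bridges,
    interaction_frequency,
    sem_ci68,
)
from loopstate.structure import AtomRecord, FrameSource, Structure, resolve_selection


def build(atoms_spec):
    """atoms_spec: list of (name, resname, resseq, chain, xyz, element, is_water)."""
    atoms = [
        AtomRecord(i + 1, n, rn, rs, ch, tuple(map(float, xyz)), el, w)
        for i, (n, rn, rs, ch, xyz, el, w) in enumerate(atoms_spec)
    ]
    return Structure(atoms)


def linear_nho(da=2.8):
    """Donor N with H on the N->O line, acceptor O at distance da."""
    return build(
        [
            ("N", "ALA", 1, "A", (0, 0, 0), "N", False),
            ("H", "ALA", 1, "A", (1.0, 0, 0), "H", False),
            ("O", "ALA", 2, "A", (da, 0, 0), "O", False),
        ]
    )


class TestDetectHbonds:
    def test_linear_geometry_detected(self):
        s = linear_nho(2.8)
        donors = resolve_selection("name N", s)
        acceptors = resolve_selection("name O", s)
        events = detect_hbonds(s, donors, acceptors)
        assert len(events) == 1
        assert events[0].da_distance == pytest.approx(2.8)
        assert events[0].dha_angle == pytest.approx(180.0)

    def test_beyond_cutoff_not_detected(self):
        s = linear_nho(3.6)
        donors = resolve_selection("name N", s)
        acceptors = resolve_selection("name O", s)
        assert detect_hbonds(s, donors, acceptors) == []

    def test_bad_angle_rejected(self):
        # H perpendicular to the N->O direction: D-H...A angle ~45 deg
        s = build(
            [
                ("N", "ALA", 1, "A", (0, 0, 0), "N", False),
                ("H", "ALA", 1, "A", (0, 1.0, 0), "H", False),
                ("O", "ALA", 2, "A", (2.8, 0, 0), "O", False),
            ]
        )
        donors = resolve_selection("name N", s)
        acceptors = resolve_selection("name O", s)
        assert detect_hbonds(s, donors, acceptors) == []
        assert len(detect_hbonds(s, donors, acceptors, HBondCriteria(heavy_only=True))) == 1

    def test_donor_without_hydrogen_instructs_heavy_only(self):
        s = build(
            [
                ("N", "ALA", 1, "A", (0, 0, 0), "N", False),
                ("O", "ALA", 2, "A", (2.8, 0, 0), "O", False),
            ]
        )
        donors = resolve_selection("name N", s)
        acceptors = resolve_selection("name O", s)
        with pytest.raises(HBondError, match="heavy-only"):
            detect_hbonds(s, donors, acceptors)

    def test_empty_selection_rejected(self):
        s = linear_nho()
        donors = resolve_selection("name N", s)
        with pytest.raises(Exception):
            detect_hbonds(s, donors, type(donors)(spec="x", indices=()))

    def test_brute_force_oracle_200_random_configs(self):
        rng = np.random.default_rng(99)
        criteria = HBondCriteria(heavy_only=True)
        for _ in range(200):
            n_d = int(rng.integers(1, 6))
            n_a = int(rng.integers(1, 6))
            spec = []
            for i in range(n_d):
                spec.append(("N", "ALA", i + 1, "A", rng.uniform(0, 8, 3), "N", False))
            for j in range(n_a):
                spec.append(("O", "GLY", 100 + j, "A", rng.uniform(0, 8, 3), "O", False))
            s = build(spec)
            donors = resolve_selection("name N", s)
            acceptors = resolve_selection("name O", s)
            got = {
                (e.donor_index, e.acceptor_index)
                for e in detect_hbonds(s, donors, acceptors, criteria)
            }
            coords = s.coords
            expected = {
                (di, aj)
                for di in donors.indices
                for aj in acceptors.indices
                if np.linalg.norm(coords[di] - coords[aj]) <= criteria.da_cutoff
            }
            assert got == expected

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        s = linear_nho(3.2)
        donors = resolve_selection("name N", s)
        acceptors = resolve_selection("name O", s)
        rot = random_rotation(rng)
        moved = s.with_coords(s.coords @ rot.T + rng.normal(size=3) * 7)
        a = detect_hbonds(s, donors, acceptors)
        b = detect_hbonds(moved, donors, acceptors)
        assert [(e.donor_index, e.acceptor_index) for e in a] == [
            (e.donor_index, e.acceptor_index) for e in b
        ]


class TestWaterBridges:
    def _system(self, water_xyz):
        return build(
            [
                ("OH", "TYR", 114, "A", (0, 0, 0), "O", False),
                ("O", "ALA", 111, "A", (5.0, 0, 0), "O", False),
                ("O", "HOH", 901, "W", water_xyz, "O", True),
            ]
        )

    def test_planted_bridge_detected(self):
        s = self._system((2.5, 1.2, 0))  # ~2.8 from both partners
        pa = resolve_selection("resid 114 and name OH", s)
        pb = resolve_selection("resid 111 and name O", s)
        bridges = detect_water_bridges(s, pa, pb, HBondCriteria(heavy_only=True))
        assert len(bridges) == 1
        assert bridges[0].water_residue == ("W", 901)

    def test_one_sided_contact_is_no_bridge(self):
        s = self._system((-2.8, 0, 0))  # near partner_a only
        pa = resolve_selection("resid 114 and name OH", s)
        pb = resolve_selection("resid 111 and name O", s)
        assert detect_water_bridges(s, pa, pb, HBondCriteria(heavy_only=True)) == []

    def test_no_waters_gives_empty(self, ideal_helix):
        pa = resolve_selection("resid 110 and name O", ideal_helix)
        pb = resolve_selection("resid 114 and name O", ideal_helix)
        assert detect_water_bridges(ideal_helix, pa, pb, HBondCriteria(heavy_only=True)) == []

    def test_planted_schedule_recovered_exactly(self, scaffold):
        schedule = [1, 4, 5, 11, 17]
        spec = synth.TrajectorySpec(n_frames=20, seed=21, bridge_schedule=schedule)
        reps, truths = synth.simulate_trajectory(spec, scaffold)
        rep, truth = reps[0], truths[0]
        pa = resolve_selection("resid 114 and name OH", rep.roster)
        rb, nb = truth.bridge_partner_b
        pb = resolve_selection(f"resid {rb} and name {nb}", rep.roster)
        criteria = HBondCriteria(heavy_only=True)
        detected = [
            fi
            for fi in range(rep.n_frames)
            if detect_water_bridges(rep.frame_structure(fi), pa, pb, criteria, fi)
        ]
        assert detected == schedule


class TestInteractionFrequency:
    def _replicas(self, scaffold, schedules, n_frames=10, seed=8):
        reps = []
        truths = []
        for i, sched in enumerate(schedules):
            spec = synth.TrajectorySpec(n_frames=n_frames, seed=seed + i, bridge_schedule=sched)
            r, t = synth.simulate_trajectory(spec, scaffold)
            reps.append(r[0])
            truths.append(t[0])
        return reps, truths

    def _pair(self, truth):
        rb, nb = truth.bridge_partner_b
        return [("tip-backbone", "resid 114 and name OH", f"resid {rb} and name {nb}")]

    def test_every_frame_positive(self, scaffold):
        reps, truths = self._replicas(scaffold, [list(range(10))] * 3)
        table = interaction_frequency(reps, self._pair(truths[0]), HBondCriteria(heavy_only=True))
        assert table.rows[0].mean == pytest.approx(1.0)
        assert table.rows[0].ci68_halfwidth == pytest.approx(0.0)

    def test_half_frames(self, scaffold):
        reps, truths = self._replicas(scaffold, [list(range(0, 10, 2))] * 2)
        table = interaction_frequency(reps, self._pair(truths[0]), HBondCriteria(heavy_only=True))
        assert table.rows[0].per_replica_fractions == [0.5, 0.5]
        assert table.rows[0].mean == pytest.approx(0.5)

    def test_mask_excluding_positives(self, scaffold):
        sched = [0, 1, 2]
        reps, truths = self._replicas(scaffold, [sched])
        mask = np.ones(10, dtype=bool)
        mask[sched] = False
        table = interaction_frequency(
            reps, self._pair(truths[0]), HBondCriteria(heavy_only=True), frame_masks=[mask]
        )
        assert table.rows[0].mean == pytest.approx(0.0)

    def test_all_replicas_excluded_errors(self, scaffold):
        reps, truths = self._replicas(scaffold, [[0]])
        mask = np.zeros(10, dtype=bool)
        with pytest.raises(HBondError, match="excluded"):
            interaction_frequency(
                reps, self._pair(truths[0]), HBondCriteria(heavy_only=True), frame_masks=[mask]
            )

    def test_direct_or_water_counting_bounds(self, scaffold):
        # combined frequency >= direct-only and <= direct + water-only
        reps, truths = self._replicas(scaffold, [[0, 3, 6, 9]], n_frames=10)
        pair = self._pair(truths[0])
        crit = HBondCriteria(heavy_only=True)
        combined = interaction_frequency(reps, pair, crit, water_mediated=True).rows[0].mean
        direct = interaction_frequency(reps, pair, crit, water_mediated=False).rows[0].mean
        assert 0.0 <= direct <= combined <= 1.0

    def test_bad_mask_length(self, scaffold):
        reps, truths = self._replicas(scaffold, [[0]])
        with pytest.raises(HBondError):
            interaction_frequency(
                reps,
                self._pair(truths[0]),
                HBondCriteria(heavy_only=True),
                frame_masks=[np.ones(7, dtype=bool)],
            )


class TestCriteriaAndStats:
    def test_criteria_validation(self):
        with pytest.raises(HBondError):
            HBondCriteria(da_cutoff=-1.0)
        with pytest.raises(HBondError):
            HBondCriteria(dha_min_angle=200.0)

    def test_sem_two_values(self):
        assert sem_ci68([0.4, 0.6]) == pytest.approx(0.1)

    def test_sem_single_value_is_zero(self):
        assert sem_ci68([0.4]) == 0.0
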