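import numpy as np
import pytest

from conftest import random_rotation
from loopstate import synth
from loopstate.metrics import (
    MissingAtomError,
    helix5_displacement,
    icl2_backbone_rmsd,
    icl2_rotation_angle,
    loop_end_to_end,
    multi_rmsd_cv,
    pair_distance,
    parse_atom_spec,
    tm5_vertical_shift,
    wrap_angle,
)
from loopstate.structure import SelectionError, Structure
from loopstate.superpose import rmsd
from loopstate.synth import FIT_SELECTION


def rigidly_move(struct: Structure, rng) -> Structure:
    rot = random_rotation(rng)
    t = rng.normal(size=3) * 10
    return struct.with_coords(struct.coords @ rot.T + t)


class TestTm5Shift:
    def test_self_is_zero(self, scaffold):
        assert tm5_vertical_shift(scaffold, scaffold) == pytest.approx(0.0)

    def test_translation_along_axis(self, scaffold):
        coords = scaffold.coords.copy()
        i130 = scaffold.index_of(130, "CA")
        i141 = scaffold.index_of(141, "CA")
        i190 = scaffold.index_of(190, "CA")
        axis = coords[i141] - coords[i130]
        axis /= np.linalg.norm(axis)
        coords[i190] += 2.0 * axis
        shifted = scaffold.with_coords(coords)
        assert tm5_vertical_shift(shifted, scaffold) == pytest.approx(2.0, abs=1e-9)

    def test_perpendicular_displacement_ignored(self, scaffold, rng):
        coords = scaffold.coords.copy()
        i130 = scaffold.index_of(130, "CA")
        i141 = scaffold.index_of(141, "CA")
        i190 = scaffold.index_of(190, "CA")
        axis = coords[i141] - coords[i130]
        axis /= np.linalg.norm(axis)
        perp = np.cross(axis, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        coords[i190] += 3.7 * perp
        shifted = scaffold.with_coords(coords)
        assert tm5_vertical_shift(shifted, scaffold) == pytest.approx(0.0, abs=1e-9)

    def test_linearity(self, scaffold):
        coords = scaffold.coords.copy()
        i130 = scaffold.index_of(130, "CA")
        i141 = scaffold.index_of(141, "CA")
        i190 = scaffold.index_of(190, "CA")
        axis = coords[i141] - coords[i130]
        axis /= np.linalg.norm(axis)
        for amount in (-3.0, -1.0, 0.5, 4.0):
            c = scaffold.coords.copy()
            c[i190] += amount * axis
            assert tm5_vertical_shift(scaffold.with_coords(c), scaffold) == pytest.approx(
                amount, abs=1e-9
            )

    def test_missing_atom_named(self, ideal_helix):
        with pytest.raises(SelectionError, match="190"):
            tm5_vertical_shift(ideal_helix, ideal_helix)


class TestPairDistance:
    def test_three_four_five(self, scaffold):
        coords = scaffold.coords.copy()
        ia = scaffold.index_of(114, "OH")
        ib = scaffold.index_of(112, "CG")
        coords[ia] = [0.0, 0.0, 0.0]
        coords[ib] = [3.0, 4.0, 0.0]
        s = scaffold.with_coords(coords)
        assert pair_distance(s, (114, "OH"), (112, "CG")) == pytest.approx(5.0)

    def test_coincident_is_zero(self, scaffold):
        coords = scaffold.coords.copy()
        coords[scaffold.index_of(114, "OH")] = coords[scaffold.index_of(112, "CG")]
        s = scaffold.with_coords(coords)
        assert pair_distance(s, "114:OH", "112:CG") == 0.0

    def test_rigid_motion_invariance(self, scaffold, rng):
        base = pair_distance(scaffold, "114:OH", "39:CB")
        for _ in range(10):
            moved = rigidly_move(scaffold, rng)
            assert pair_distance(moved, "114:OH", "39:CB") == pytest.approx(base, abs=1e-9)

    def test_missing_atom(self, scaffold):
        with pytest.raises(MissingAtomError):
            pair_distance(scaffold, "114:OH", "114:ZZ")

    def test_spec_parsing(self):
        assert parse_atom_spec("114:OH") == (114, "OH")
        with pytest.raises(SelectionError):
            parse_atom_spec("nope")


class TestRotationAngle:
    def test_scaffold_reads_zero(self, scaffold):
        res = icl2_rotation_angle(scaffold)
        assert res.raw_deg == pytest.approx(0.0, abs=1e-9)
        assert res.reliable

    @pytest.mark.parametrize("phi", [-170.0, -40.0, 0.0, 30.0, 90.0, 179.0])
    def test_equivariance_about_x(self, scaffold, phi):
        t = np.radians(phi)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
        )
        moved = scaffold.with_coords(scaffold.coords @ rot.T)
        res = icl2_rotation_angle(moved)
        assert res.raw_deg == pytest.approx(wrap_angle(phi), abs=1e-6)

    def test_offset_relative_to_reference(self, scaffold):
        t = np.radians(-40.0)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
        )
        moved = scaffold.with_coords(scaffold.coords @ rot.T)
        res = icl2_rotation_angle(moved, reference=scaffold)
        assert res.offset_deg == pytest.approx(-40.0, abs=1e-6)

    def test_unreliable_when_projection_short(self, scaffold):
        coords = scaffold.coords.copy()
        ia = scaffold.index_of(114, "OH")
        ib = scaffold.index_of(112, "CG")
        coords[ia] = coords[ib] + np.array([5.0, 0.05, 0.0])  # nearly along x
        res = icl2_rotation_angle(scaffold.with_coords(coords))
        assert not res.reliable


class TestBackboneRmsd:
    def test_self_zero(self, scaffold):
        assert icl2_backbone_rmsd(scaffold, scaffold) == pytest.approx(0.0, abs=1e-9)

    def test_extended_conformer_large(self, scaffold):
        extended = synth.make_ideal_helix(9, torsions=(-135.0, 135.0), start_res=110)
        value = icl2_backbone_rmsd(extended, scaffold)
        assert value > 2.0

    def test_definitional_equality_with_superposed_rmsd(self, scaffold, rng):
        noisy = scaffold.with_coords(scaffold.coords + rng.normal(size=(len(scaffold), 3)))
        from loopstate.structure import resolve_selection

        sel = resolve_selection("resid 110-118 and backbone", scaffold)
        expected = rmsd(
            noisy.coords[sel.array()], scaffold.coords[sel.array()], superpose=True
        )
        assert icl2_backbone_rmsd(noisy, scaffold) == pytest.approx(expected, abs=1e-12)

    def test_rotation_invariant_local_superposition(self, scaffold, rng):
        moved = rigidly_move(scaffold, rng)
        assert icl2_backbone_rmsd(moved, scaffold) == pytest.approx(0.0, abs=1e-8)


class TestMultiRmsdCv:
    def test_self_zero(self, scaffold):
        assert multi_rmsd_cv(scaffold, scaffold) == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force(self, scaffold, rng):
        from test_superpose import quaternion_rmsd

        noisy = scaffold.with_coords(scaffold.coords + rng.normal(size=(len(scaffold), 3)) * 0.5)
        idx = [
            i
            for i, a in enumerate(scaffold.atoms)
            if 111 <= a.residue_seq <= 118
            and a.chain_id == "A"
            and a.atom_name in ("N", "CA", "C", "O")
        ]
        expected = quaternion_rmsd(noisy.coords[idx], scaffold.coords[idx])
        assert multi_rmsd_cv(noisy, scaffold) == pytest.approx(expected, abs=1e-9)

    def test_within_sampled_cv_range_for_generator_output(self, scaffold):
        spec = synth.TrajectorySpec(
            n_frames=60, seed=5, noise_sigma=0.3, p_pr_to_nr=0.2, p_nr_to_pr=0.2, unfold_fraction=0.2
        )
        reps, _ = synth.simulate_trajectory(spec, scaffold)
        for fi in range(reps[0].n_frames):
            value = multi_rmsd_cv(reps[0].frame_structure(fi), scaffold)
            assert 0.0 <= value <= 5.5


class TestHelix5Displacement:
    def test_self_zero(self, scaffold):
        assert helix5_displacement(scaffold, scaffold, FIT_SELECTION) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_rigid_translation_of_g_alpha(self, scaffold):
        coords = scaffold.coords.copy()
        ga = [i for i, a in enumerate(scaffold.atoms) if a.chain_id == "B"]
        coords[ga] += np.array([0.0, 5.0, 0.0])
        moved = scaffold.with_coords(coords)
        assert helix5_displacement(moved, scaffold, FIT_SELECTION) == pytest.approx(
            5.0, abs=1e-9
        )

    def test_whole_complex_rotation_is_zero(self, scaffold, rng):
        moved = rigidly_move(scaffold, rng)
        assert helix5_displacement(moved, scaffold, FIT_SELECTION) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_missing_chain_errors(self):
        s = synth.make_scaffold(synth.ScaffoldSpec(include_g_alpha=False))
        with pytest.raises(SelectionError):
            helix5_displacement(s, s, FIT_SELECTION)


class TestLoopEndToEnd:
    def test_positive_and_matches_pair_distance(self, scaffold):
        value = loop_end_to_end(scaffold)
        assert value > 0
        assert value == pytest.approx(pair_distance(scaffold, "504:CA", "508:CA"))

    def test_rigid_invariance(self, scaffold, rng):
        base = loop_end_to_end(scaffold)
        moved = rigidly_move(scaffold, rng)
        assert loop_end_to_end(moved) == pytest.approx(base, abs=1e-9)

    def test_missing_atom(self, ideal_helix):
        with pytest.raises(SelectionError):
            loop_end_to_end(ideal_helix)


def test_wrap_angle_range():
    for x in (-721.0, -180.0, -179.9, 0.0, 179.9, 180.0, 360.0, 541.0):
        w = wrap_angle(x)
        assert -180.0 < w <= 180.0
        assert abs(((x - w) % 360.0)) < 1e-9 or abs(((x - w) % 360.0) - 360.0) < 1e-9
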