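import math

import numpy as np
import pytest

from tmdkit import helix_geometry as hg
from tmdkit import synthetic_data as syn
from tmdkit.structure_io import Ensemble, Trajectory

from conftest import random_rigid_transform, transform_model


def pca_axis_oracle(ca):
    """Independent axis estimate: plain SVD on raw Calpha positions."""
    c = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - c)
    d = vt[0]
    return d if d @ (ca[-1] - ca[0]) > 0 else -d


def seg_ca(model, seg):
    return np.array([model.atom_position(r, "CA") for r in seg.residues])


class TestFitAxis:
    def test_ideal_helix_axis_is_z(self, straight_helix):
        ax = hg.fit_axis(straight_helix, hg.HelixSegment(1, 28))
        angle = math.degrees(math.acos(abs(ax.direction @ np.array([0, 0, 1.0]))))
        assert angle < 1.0

    def test_rotation_equivariance(self, straight_helix):
        th = np.deg2rad(30.0)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        m = transform_model(straight_helix, rot, np.zeros(3))
        ax = hg.fit_axis(m, hg.HelixSegment(1, 28))
        assert hg.tilt_angle(ax) == pytest.approx(30.0, abs=0.5)

    def test_agrees_with_independent_svd_oracle(self, straight_helix):
        seg = hg.HelixSegment(1, 28)
        ax = hg.fit_axis(straight_helix, seg)
        oracle = pca_axis_oracle(seg_ca(straight_helix, seg))
        angle = math.degrees(math.acos(min(1.0, abs(ax.direction @ oracle))))
        assert angle < 1.0

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            hg.HelixSegment(1, 3)


class TestTiltAngle:
    @pytest.mark.parametrize(
        "direction,expected",
        [
            ((0.0, 0.0, 1.0), 0.0),
            ((1.0 / math.sqrt(2), 0.0, 1.0 / math.sqrt(2)), 45.0),
            ((0.0, 0.0, -1.0), 0.0),  # sign-free convention
        ],
    )
    def test_closed_forms(self, direction, expected):
        ax = hg.HelixAxis(np.array(direction), np.zeros(3))
        assert hg.tilt_angle(ax) == pytest.approx(expected, abs=1e-9)

    def test_range_is_0_to_90(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            t = hg.tilt_angle(hg.HelixAxis(d, np.zeros(3)))
            assert 0.0 <= t <= 90.0


class TestKinkAngle:
    def test_straight_helix_split_is_collinear(self, straight_helix):
        k = hg.kink_angle(
            straight_helix, hg.HelixSegment(1, 13), hg.HelixSegment(15, 28)
        )
        assert k <= 3.0

    @pytest.mark.parametrize("angle", [10.0, 26.0, 30.0, 70.0])
    def test_hinge_angle_recovery_noise_free(self, angle):
        m = syn.make_helix(
            syn.HelixSpec("A" * 28, 1, kink_position=14, kink_angle=angle)
        )
        k = hg.kink_angle(m, hg.HelixSegment(1, 13), hg.HelixSegment(15, 28))
        assert k == pytest.approx(angle, abs=2.0)

    @pytest.mark.parametrize("angle", [10.0, 26.0, 30.0, 70.0])
    def test_hinge_angle_recovery_with_noise(self, angle):
        m = syn.make_helix(
            syn.HelixSpec(
                "A" * 28, 1, kink_position=14, kink_angle=angle,
                coordinate_noise_sd=0.3, seed=42,
            )
        )
        k = hg.kink_angle(m, hg.HelixSegment(1, 13), hg.HelixSegment(15, 28))
        assert k == pytest.approx(angle, abs=5.0)

    def test_overlapping_segments_rejected(self, straight_helix):
        with pytest.raises(ValueError, match="overlap"):
            hg.kink_angle(
                straight_helix, hg.HelixSegment(1, 14), hg.HelixSegment(10, 28)
            )


class TestEndToEnd:
    def test_known_distance(self, straight_helix):
        m = straight_helix
        shifted = m.with_coordinates(m.coordinates)
        pa = m.atom_position(1, "CA")
        pb = m.atom_position(28, "CA")
        assert hg.end_to_end_distance(m, 1, 28) == pytest.approx(
            float(np.linalg.norm(pa - pb)), abs=1e-12
        )

    def test_ideal_helix_close_to_axial_rise(self, straight_helix):
        d = hg.end_to_end_distance(straight_helix, 1, 28)
        # 27 residues x 1.5 A rise, plus up to one wheel diameter laterally
        assert 27 * 1.5 - 0.1 <= d <= math.hypot(27 * 1.5, 2 * 2.3) + 0.1

    def test_missing_residue_named(self, straight_helix):
        with pytest.raises(ValueError, match="99"):
            hg.end_to_end_distance(straight_helix, 1, 99)


class TestLocalBend:
    def test_straight_helix_flat_profile(self, straight_helix):
        prof = hg.local_bend_profile(straight_helix, hg.HelixSegment(1, 28), 4)
        vals = [v for v in prof.values() if np.isfinite(v)]
        assert vals and max(vals) <= 3.0

    def test_kink_position_and_magnitude_recovered(self):
        m = syn.make_helix(
            syn.HelixSpec("A" * 28, 1, kink_position=14, kink_angle=30.0)
        )
        prof = hg.local_bend_profile(m, hg.HelixSegment(1, 28), 4)
        finite = {r: v for r, v in prof.items() if np.isfinite(v)}
        peak = max(finite, key=finite.get)
        assert abs(peak - 14) <= 1
        assert finite[peak] == pytest.approx(30.0, abs=3.0)

    def test_rigid_motion_invariance(self, kinked_helix):
        seg = hg.HelixSegment(1, 28)
        base = hg.local_bend_profile(kinked_helix, seg, 4)
        rng = np.random.default_rng(5)
        rot, trans = random_rigid_transform(rng)
        moved = transform_model(kinked_helix, rot, trans)
        other = hg.local_bend_profile(moved, seg, 4)
        diffs = [
            abs(base[r] - other[r])
            for r in base
            if np.isfinite(base[r]) and np.isfinite(other[r])
        ]
        assert max(diffs) < 1e-6

    def test_too_short_segment_rejected(self, straight_helix):
        with pytest.raises(ValueError, match="too short"):
            hg.local_bend_profile(straight_helix, hg.HelixSegment(1, 6), 4)


class TestRmsdToIdeal:
    def test_ideal_template_scores_zero(self, straight_helix):
        vals = hg.rmsd_to_ideal_helix(straight_helix, hg.HelixSegment(1, 28))
        assert max(v for v in vals.values() if np.isfinite(v)) <= 1e-6

    def test_local_displacement_is_localized(self, straight_helix):
        coords = straight_helix.coordinates
        i = straight_helix.atom_index(14, "CA")
        coords[i] += np.array([1.0, 0.0, 0.0])
        m = straight_helix.with_coordinates(coords)
        vals = hg.rmsd_to_ideal_helix(m, hg.HelixSegment(1, 28), window=7)
        assert vals[14] > 0.05
        assert vals[1] <= 1e-6 and vals[28] <= 1e-6

    def test_random_coil_scores_high(self):
        coil = syn.make_random_coil(syn.HelixSpec("A" * 28, 1, seed=11))
        vals = hg.rmsd_to_ideal_helix(coil, hg.HelixSegment(1, 28))
        frac = np.mean([v > 1.0 for v in vals.values()])
        assert frac >= 0.8


class TestRmsf:
    def _traj(self, frames):
        helix = syn.make_helix(syn.HelixSpec("A" * 10, 1))
        return Trajectory(helix, np.asarray(frames), groups={})

    def test_identical_frames_zero(self):
        helix = syn.make_helix(syn.HelixSpec("A" * 10, 1))
        traj = self._traj([helix.coordinates] * 5)
        prof = hg.rmsf_profile(traj, "CA")
        assert max(prof.values.values()) < 1e-12

    def test_single_oscillating_atom_closed_form(self):
        helix = syn.make_helix(syn.HelixSpec("A" * 10, 1))
        base = helix.coordinates
        i = helix.atom_index(5, "CA")
        up, down = base.copy(), base.copy()
        up[i, 0] += 0.8
        down[i, 0] -= 0.8
        traj = self._traj([up, down] * 10)
        prof = hg.rmsf_profile(traj, "CA", superpose_frames=False)
        assert prof[5] == pytest.approx(0.8, abs=1e-9)
        others = [v for r, v in prof.values.items() if r != 5]
        assert max(others) < 1e-12

    def test_gaussian_noise_rmsf_scaling(self):
        # per-coordinate noise sigma(r) -> 3D RMSF sigma * sqrt(3)
        helix = syn.make_helix(syn.HelixSpec("A" * 10, 1))
        base = helix.coordinates
        rng = np.random.default_rng(7)
        sigma = np.linspace(0.1, 0.6, len(base))[:, None]
        frames = base[None] + rng.normal(0, 1.0, (500, *base.shape)) * sigma
        traj = self._traj(frames)
        prof = hg.rmsf_profile(traj, "CA", superpose_frames=False)
        for rn, v in prof.values.items():
            i = helix.atom_index(rn, "CA")
            assert v == pytest.approx(float(sigma[i, 0]) * math.sqrt(3), rel=0.10)

    def test_frame_reversal_invariance(self):
        helix = syn.make_helix(syn.HelixSpec("A" * 10, 1))
        rng = np.random.default_rng(3)
        frames = helix.coordinates[None] + rng.normal(0, 0.4, (20, len(helix), 3))
        fwd = hg.rmsf_profile(self._traj(frames), "CA")
        rev = hg.rmsf_profile(self._traj(frames[::-1]), "CA")
        for r in fwd.values:
            assert fwd[r] == pytest.approx(rev[r], abs=1e-9)

    def test_needs_two_frames(self):
        helix = syn.make_helix(syn.HelixSpec("A" * 10, 1))
        with pytest.raises(ValueError):
            hg.rmsf_profile(self._traj(helix.coordinates[None]), "CA")


class TestClassifyConformers:
    SEG_N = hg.HelixSegment(1, 13)
    SEG_C = hg.HelixSegment(15, 28)

    def make_mixture(self, seed=1):
        straight = syn.HelixSpec(
            "A" * 28, 1, kink_position=14, kink_angle=26.0,
            kink_direction_deg=210.0, coordinate_noise_sd=0.25,
        )
        bent = syn.HelixSpec(
            "A" * 28, 1, kink_position=14, kink_angle=70.0,
            kink_direction_deg=210.0, coordinate_noise_sd=0.25,
        )
        return syn.make_two_state_ensemble(straight, bent, 10, 10, seed, angle_sd=3.0)

    def test_two_state_recovery(self):
        ens, labels = self.make_mixture()
        rep = hg.classify_conformers(ens, self.SEG_N, self.SEG_C, 1, 28)
        assert list(rep.per_model["state"]) == labels
        assert rep.clusters["straight"]["kink_deg_mean"] == pytest.approx(26.0, abs=2.0)
        assert rep.clusters["bent"]["kink_deg_mean"] == pytest.approx(70.0, abs=2.0)

    def test_identical_models_single_cluster_with_warning(self, straight_helix):
        models = [
            straight_helix.with_coordinates(straight_helix.coordinates, model_id=i)
            for i in range(1, 5)
        ]
        rep = hg.classify_conformers(Ensemble(models), self.SEG_N, self.SEG_C, 1, 28)
        assert rep.warnings
        assert set(rep.per_model["state"]) == {"straight"}

    def test_model_order_permutation_invariance(self):
        ens, _ = self.make_mixture()
        rep_a = hg.classify_conformers(ens, self.SEG_N, self.SEG_C, 1, 28)
        perm = np.random.default_rng(0).permutation(len(ens))
        shuffled = Ensemble([ens.models[i] for i in perm])
        rep_b = hg.classify_conformers(shuffled, self.SEG_N, self.SEG_C, 1, 28)
        by_id_a = dict(zip(rep_a.per_model["model_id"], rep_a.per_model["state"]))
        by_id_b = dict(zip(rep_b.per_model["model_id"], rep_b.per_model["state"]))
        assert by_id_a == by_id_b


class TestRigidMotionInvariance:
    """All geometric observables must be invariant under global rigid motion."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kink_and_distance_invariant(self, kinked_helix, seed):
        rng = np.random.default_rng(seed)
        rot, trans = random_rigid_transform(rng)
        moved = transform_model(kinked_helix, rot, trans)
        seg_n, seg_c = hg.HelixSegment(1, 13), hg.HelixSegment(15, 28)
        assert hg.kink_angle(moved, seg_n, seg_c) == pytest.approx(
            hg.kink_angle(kinked_helix, seg_n, seg_c), abs=1e-6
        )
        assert hg.end_to_end_distance(moved, 1, 28) == pytest.approx(
            hg.end_to_end_distance(kinked_helix, 1, 28), abs=1e-6
        )

    def test_rmsd_to_ideal_invariant(self, kinked_helix):
        rng = np.random.default_rng(9)
        rot, trans = random_rigid_transform(rng)
        moved = transform_model(kinked_helix, rot, trans)
        seg = hg.HelixSegment(1, 28)
        a = hg.rmsd_to_ideal_helix(kinked_helix, seg)
        b = hg.rmsd_to_ideal_helix(moved, seg)
        for r in a:
            if np.isfinite(a[r]):
                assert abs(a[r] - b[r]) < 1e-6
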