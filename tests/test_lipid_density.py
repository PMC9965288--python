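import numpy as np
import pytest

from tmdkit import helix_geometry as hg
from tmdkit import lipid_density as ld
from tmdkit import synthetic_data as syn
from tmdkit.structure_io import Atom, MolecularModel, Trajectory

SEG = hg.HelixSegment(929, 946)


def helix_model():
    return syn.make_helix(syn.HelixSpec(syn.STANDIN_SEQUENCES["IRR"][0], 917))


def static_atom_traj(r=10.0, azimuth_deg=45.0, z=0.0, frames=5):
    """Rigid helix plus one extra static atom at known cylinder coords."""
    helix = helix_model()
    xyz = helix.coordinates
    xyz -= xyz.mean(axis=0)
    az = np.deg2rad(azimuth_deg)
    extra = np.array([r * np.cos(az), r * np.sin(az), z])
    atoms = [
        Atom(a.serial, a.name, a.element, a.residue_number, a.residue_name, a.chain, p)
        for a, p in zip(helix.atoms, xyz)
    ]
    atoms.append(Atom(len(atoms) + 1, "C1", "C", 9000, "LIP", "L", extra))
    topo = MolecularModel(atoms, 0)
    coords = np.vstack([xyz, extra[None]])
    traj = Trajectory(
        topo,
        np.repeat(coords[None], frames, axis=0),
        groups={
            "protein": np.arange(len(xyz)),
            "lipid_tails": np.array([len(xyz)]),
        },
    )
    return traj


class TestFrameAxis:
    def test_static_trajectory_constant_axis(self):
        traj = static_atom_traj()
        axes = ld.frame_axes(traj, SEG)
        for ax in axes[1:]:
            assert np.allclose(ax.direction, axes[0].direction, atol=1e-12)

    def test_axis_follows_frame_rotation(self):
        traj = static_atom_traj(frames=2)
        th = np.deg2rad(20.0)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        frames = traj.frames.copy()
        frames[1] = frames[1] @ rot.T
        rotated = Trajectory(traj.topology, frames, groups=traj.groups)
        axes = ld.frame_axes(rotated, SEG)
        angle = np.degrees(
            np.arccos(np.clip(abs(axes[0].direction @ axes[1].direction), -1, 1))
        )
        assert angle == pytest.approx(20.0, abs=1.0)

    def test_axis_matches_independent_center_line_oracle(self):
        """Independent axis route: displace each interior Calpha onto the
        local helix centre (second-difference bisector, 2.3 A radius)
        and fit a straight line by least squares in z."""
        helix = helix_model()
        traj, _ = syn.make_bilayer_trajectory(
            helix, syn.BilayerSpec(lipid_count=4, frame_count=3, seed=5)
        )
        for k in range(traj.n_frames):
            ax = ld.frame_axis(traj, k, SEG)
            ca = np.array(
                [traj.frame_model(k).atom_position(r, "CA") for r in SEG.residues]
            )
            v = ca[:-2] + ca[2:] - 2.0 * ca[1:-1]
            centers = ca[1:-1] + 2.3 * v / np.linalg.norm(v, axis=1, keepdims=True)
            t = np.arange(len(centers))
            d = np.array([np.polyfit(t, centers[:, j], 1)[0] for j in range(3)])
            d /= np.linalg.norm(d)
            angle = np.degrees(np.arccos(np.clip(abs(ax.direction @ d), -1, 1)))
            assert angle <= 1.0


class TestAccumulateDensity:
    def test_single_static_atom_closed_form(self):
        traj = static_atom_traj(r=10.0, azimuth_deg=45.0, z=0.0, frames=7)
        grid = ld.CylindricalGridSpec(
            ((5.0, 8.0), (8.0, 11.0)), 15.0, (-6.0, 6.0), 1.5
        )
        axes = ld.frame_axes(traj, SEG)
        stack = ld.accumulate_density(
            traj, axes, "lipid_tails", grid,
            reference_direction=np.array([1.0, 0, 0]), z_origin=np.zeros(3),
        )
        inner, outer = stack.maps
        assert np.count_nonzero(inner.values) == 0
        assert np.count_nonzero(outer.values) == 1
        vol = grid.cell_volume(1)
        assert outer.values.max() == pytest.approx(1.0 / vol)
        # contrast equals the number of cells in the shell
        assert ld.contrast_score(stack, 1) == pytest.approx(outer.values.size)

    def test_total_count_conservation_is_exact(self):
        helix = helix_model()
        traj, _ = syn.make_bilayer_trajectory(
            helix, syn.BilayerSpec(frame_count=50, immobilized_fraction=0.2, seed=9)
        )
        grid = ld.CylindricalGridSpec()
        axes = ld.frame_axes(traj, SEG)
        stack = ld.accumulate_density(traj, axes, "lipid_tails", grid,
                                      reference_segment=SEG)
        # recount independently
        expected = 0
        shells = grid.radial_shells
        for k in range(traj.n_frames):
            ax = axes[k]
            rel = traj.frames[k][traj.groups["lipid_tails"]] - ax.point
            z = rel @ ax.direction
            r = np.linalg.norm(rel - np.outer(z, ax.direction), axis=1)
            in_z = (z >= grid.z_range[0]) & (z < grid.z_range[1])
            for lo, hi in shells:
                expected += int(np.sum((r >= lo) & (r < hi) & in_z))
        assert stack.total_counts == expected
        # density x volume x frames recovers integer counts
        for s, m in enumerate(stack.maps):
            np.testing.assert_allclose(
                m.values * grid.cell_volume(s) * traj.n_frames, m.weight, atol=1e-9
            )

    def test_doubling_z_bin_width_preserves_counts(self):
        helix = helix_model()
        traj, _ = syn.make_bilayer_trajectory(
            helix, syn.BilayerSpec(frame_count=20, seed=2)
        )
        axes = ld.frame_axes(traj, SEG)
        fine = ld.CylindricalGridSpec(z_bin_width=1.0, z_range=(-12.0, 12.0))
        coarse = ld.CylindricalGridSpec(z_bin_width=2.0, z_range=(-12.0, 12.0))
        st_f = ld.accumulate_density(traj, axes, "lipid_tails", fine,
                                     reference_segment=SEG)
        st_c = ld.accumulate_density(traj, axes, "lipid_tails", coarse,
                                     reference_segment=SEG)
        assert st_c.maps[0].shape[1] * 2 == st_f.maps[0].shape[1]
        assert st_c.total_counts == st_f.total_counts

    def test_uniform_points_match_poisson_expectation(self):
        """Uniform random points in one shell: cells within 3 Poisson sd."""
        rng = np.random.default_rng(0)
        helix = helix_model()
        xyz = helix.coordinates - helix.coordinates.mean(axis=0)
        # recentre laterally on the fitted axis so shell radii are exact
        ax0 = hg.fit_axis(helix.with_coordinates(xyz), SEG)
        xyz = xyz - np.array([ax0.point[0], ax0.point[1], 0.0])
        n_pts, n_frames = 200, 1000
        grid = ld.CylindricalGridSpec(((5.0, 8.0),), 30.0, (-6.0, 6.0), 3.0)
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_number, a.residue_name,
                 a.chain, p)
            for a, p in zip(helix.atoms, xyz)
        ]
        for i in range(n_pts):
            atoms.append(
                Atom(len(atoms) + 1, "C1", "C", 9000 + i, "LIP", "L", np.zeros(3))
            )
        topo = MolecularModel(atoms, 0)
        frames = np.empty((n_frames, len(atoms), 3))
        for k in range(n_frames):
            r = np.sqrt(rng.uniform(25.0, 64.0, n_pts))
            az = rng.uniform(0, 2 * np.pi, n_pts)
            z = rng.uniform(-6.0, 6.0, n_pts)
            frames[k, : len(xyz)] = xyz
            frames[k, len(xyz):] = np.column_stack(
                [r * np.cos(az), r * np.sin(az), z]
            )
        traj = Trajectory(
            topo, frames,
            groups={
                "protein": np.arange(len(xyz)),
                "lipid_tails": np.arange(len(xyz), len(atoms)),
            },
        )
        stack = ld.accumulate_density(
            traj, ld.frame_axes(traj, SEG), "lipid_tails", grid,
            reference_direction=np.array([1.0, 0, 0]), z_origin=np.zeros(3),
        )
        counts = stack.maps[0].weight
        mean = counts.mean()
        assert np.all(np.abs(counts - mean) <= 3.0 * np.sqrt(mean))
        assert ld.contrast_score(stack, 0) < 1.5

    def test_azimuthal_rotation_shifts_map(self):
        """Rotating the lipids about the axis circularly shifts the map."""
        helix = helix_model()
        traj, _ = syn.make_bilayer_trajectory(
            helix, syn.BilayerSpec(frame_count=10, immobilized_fraction=0.3,
                                   immobilized_azimuth=97.5, seed=4)
        )
        grid = ld.CylindricalGridSpec(((5.0, 8.0),), 15.0, (-11.2, 11.2), 2.8)
        axes = ld.frame_axes(traj, SEG)
        ref = np.array([1.0, 0, 0])
        base = ld.accumulate_density(traj, axes, "lipid_tails", grid,
                                     reference_direction=ref,
                                     z_origin=np.zeros(3))
        th = np.deg2rad(90.0)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        frames = traj.frames.copy()
        lip = traj.groups["lipid"]
        pivot = axes[0].point * np.array([1.0, 1.0, 0.0])  # on the helix axis
        frames[:, lip, :] = (frames[:, lip, :] - pivot) @ rot.T + pivot
        rotated = Trajectory(traj.topology, frames, groups=traj.groups)
        shifted = ld.accumulate_density(rotated, axes, "lipid_tails", grid,
                                        reference_direction=ref,
                                        z_origin=np.zeros(3))
        np.testing.assert_allclose(
            np.roll(base.maps[0].weight, 6, axis=0), shifted.maps[0].weight
        )

    def test_empty_overlap_warns_not_raises(self):
        traj = static_atom_traj(r=50.0)
        grid = ld.CylindricalGridSpec(((5.0, 8.0),))
        stack = ld.accumulate_density(
            traj, ld.frame_axes(traj, SEG), "lipid_tails", grid,
            reference_direction=np.array([1.0, 0, 0]),
        )
        assert stack.warnings
        assert np.isnan(ld.contrast_score(stack, 0))


class TestContrastMonotonicity:
    def test_contrast_increases_with_immobilized_fraction(self):
        helix = helix_model()
        grid = ld.CylindricalGridSpec(
            ((5.0, 8.0), (8.0, 11.0), (11.0, 14.0)), 15.0, (-11.2, 11.2), 2.8
        )
        scores = []
        for frac in (0.0, 0.1, 0.3, 0.5):
            traj, _ = syn.make_bilayer_trajectory(
                helix,
                syn.BilayerSpec(frame_count=1000, immobilized_fraction=frac,
                                immobilized_azimuth=97.5, seed=7),
            )
            axes = ld.frame_axes(traj, SEG)
            stack = ld.accumulate_density(
                traj, axes, "lipid_tails", grid, reference_segment=SEG,
                z_origin=np.zeros(3),
            )
            scores.append(ld.contrast_score(stack, 0))
        assert scores[0] < 1.5
        assert scores[3] > 3.0
        assert all(a < b for a, b in zip(scores, scores[1:]))
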