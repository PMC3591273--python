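import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_cloud
from pocketeer.fixtures import FixtureSpec, make_fixture
from pocketeer.oracle import GridTooLargeError, brute_force_labels
from pocketeer.pocketgrid import (
    Label,
    PocketParams,
    TargetBuriedError,
    build_grid,
    deep_pocket_volume,
    deep_volume_xyz,
    detect_pockets,
    mark_pockets,
    scan_sss,
)
from pocketeer.structio import Atom, ResidueSelector, Structure, assign_radii


def single_atom_structure():
    atoms = [
        Atom(serial=1, name="A001", element="C", residue_name="FXB",
             chain_id="A", residue_number=1, coords=np.zeros(3))
    ]
    return assign_radii(Structure(atoms=atoms))


def labeled(structure, target, params):
    return mark_pockets(scan_sss(build_grid(structure, target, params), params), params)


class TestBuildGrid:
    def test_single_atom_labels(self):
        s = single_atom_structure()
        params = PocketParams(capture_radius=6.0)
        grid = build_grid(s, ResidueSelector("A", 1), params)
        center = tuple(d // 2 for d in grid.spec.dims)
        # atom center: PROTEIN-occupied (relabeled SURFACE: one atom is all surface)
        assert grid.label[center] in (Label.PROTEIN, Label.SURFACE)
        # a point 5 A away along x is solvent
        off = (center[0] + 5, center[1], center[2])
        assert grid.label[off] == Label.SOLVENT

    def test_parallel_slabs_interslab_solvent(self, suite):
        structure, truth = suite["channel"]
        params = PocketParams()
        grid = build_grid(structure, truth.target, params)
        # point midway in the 6 A gap above the target is solvent-class
        centroid_idx = tuple(d // 2 for d in grid.spec.dims)
        mid = (centroid_idx[0], centroid_idx[1], centroid_idx[2] + 3)
        assert grid.label[mid] in (Label.SOLVENT,)
        # slab-facing protein points are SURFACE
        assert np.any(grid.label == Label.SURFACE)

    def test_buried_target_errors(self, flask_fixture):
        structure, _ = flask_fixture
        # residue 1 includes deeply buried wall atoms, but some surface
        # ones too; bury the target by selecting a custom interior atom
        interior = [
            a for a in structure.atoms
            if abs(a.coords[0]) < 0.1 and abs(a.coords[1]) < 0.1 and a.coords[2] < -4
        ]
        assert interior
        # relabel that atom into its own residue
        atoms = []
        for a in structure.atoms:
            if a is interior[0]:
                from dataclasses import replace

                atoms.append(replace(a, residue_number=99))
            else:
                atoms.append(a)
        s2 = Structure(atoms=atoms)
        with pytest.raises(TargetBuriedError):
            build_grid(s2, ResidueSelector("A", 99), PocketParams(contact_radius=1.0))


class TestScan:
    def test_channel_has_events(self, suite):
        structure, truth = suite["channel"]
        params = PocketParams()
        grid = scan_sss(build_grid(structure, truth.target, params), params)
        assert grid.event_count.max() >= 1
        # events only on solvent points
        assert np.all(grid.event_count[grid.label != Label.SOLVENT] == 0)

    def test_wide_gap_no_events(self):
        structure, truth = make_fixture(
            FixtureSpec("channel", geometry={"gap": 20.0, "half_width": 6.0})
        )
        params = PocketParams()
        grid = scan_sss(build_grid(structure, truth.target, params), params)
        # vertical span 20 A exceeds the 12 A cap; lateral runs exit the box
        mid_z = grid.spec.dims[2] // 2
        assert grid.event_count[:, :, mid_z].max() == 0

    def test_convex_sphere_no_events(self):
        # solid ball of atoms (dense enough that the vdW surface has no
        # inter-atom dimples): no concavity, no events anywhere
        pts = []
        for x in np.arange(-3.6, 3.7, 1.0):
            for y in np.arange(-3.6, 3.7, 1.0):
                for z in np.arange(-3.6, 3.7, 1.0):
                    if x * x + y * y + z * z <= 3.6**2:
                        pts.append((x, y, z))
        atoms = [
            Atom(serial=i + 1, name="A001", element="C", residue_name="FXB",
                 chain_id="A", residue_number=i + 1, coords=np.array(p))
            for i, p in enumerate(pts)
        ]
        s = assign_radii(Structure(atoms=atoms))
        params = PocketParams(capture_radius=10.0)
        grid = scan_sss(build_grid(s, ResidueSelector("A", 1), params), params)
        assert grid.event_count.max() == 0


class TestMarkAndCluster:
    def test_shallow_dish_zero_deep(self, slab_fixture):
        structure, truth = slab_fixture
        assert deep_pocket_volume(structure, truth.target) == 0.0

    def test_deep_split_distances(self, flask_fixture):
        structure, truth = flask_fixture
        params = PocketParams()
        grid = labeled(structure, truth.target, params)
        deep = np.argwhere(grid.label == Label.DEEP_POCKET)
        surfp = np.argwhere(grid.label == Label.SURFACE_POCKET)
        bulk = np.argwhere(grid.label == Label.SOLVENT)
        assert len(deep) and len(surfp) and len(bulk)
        # surface-pocket points lie within 2.5 A of bulk; deep beyond
        def min_dist(points):
            d2 = ((points[:, None, :] - bulk[None, :, :]) ** 2).sum(axis=2).min(axis=1)
            return np.sqrt(d2) * params.spacing

        assert np.all(min_dist(surfp) <= params.deep_cutoff + 1e-9)
        assert np.all(min_dist(deep) > params.deep_cutoff)

    def test_two_cavities_two_pockets(self, hinge_system):
        # the hinge deck has two isolated holes; at the open angle the
        # target hole is roofed (deep) while the parking hole stays
        # shallow: all pockets are pairwise disjoint components
        from pocketeer.benchmark import HINGE_POCKET_PARAMS

        pockets = detect_pockets(
            hinge_system.structure, hinge_system.target, HINGE_POCKET_PARAMS
        )
        assert len(pockets) >= 2
        seen = set()
        for p in pockets.pockets:
            pts = {tuple(i) for i in p.point_indices}
            assert not (pts & seen)
            seen |= pts

    def test_contacts_target_flags(self, flask_fixture):
        structure, truth = flask_fixture
        pockets = detect_pockets(structure, truth.target)
        best = pockets.largest_contacting()
        assert best is not None and best.contacts_target

    def test_no_candidates_empty_set(self, slab_fixture):
        structure, truth = slab_fixture
        pockets = detect_pockets(structure, truth.target)
        assert all(p.deep_volume == 0 for p in pockets.pockets)

    def test_lining_atoms_near_pocket(self, flask_fixture):
        structure, truth = flask_fixture
        pockets = detect_pockets(structure, truth.target)
        best = pockets.largest_contacting()
        assert len(best.lining_atoms) > 0


class TestDeepVolume:
    def test_flask_matches_oracle(self, flask_fixture, default_params):
        structure, truth = flask_fixture
        grid = labeled(structure, truth.target, default_params)
        oracle = brute_force_labels(structure, truth.target, default_params)
        assert np.array_equal(grid.label, oracle.label)
        v = deep_pocket_volume(structure, truth.target, default_params)
        n_deep_oracle = np.count_nonzero(oracle.label == Label.DEEP_POCKET)
        assert v <= n_deep_oracle * default_params.spacing**3

    def test_fast_path_agrees_with_full(self, suite):
        from pocketeer.benchmark import HINGE_POCKET_PARAMS

        for kind, params in [
            ("flask", PocketParams()),
            ("sphere_shell", PocketParams()),
            ("hinge_two_state", HINGE_POCKET_PARAMS),
        ]:
            structure, truth = suite[kind]
            heavy_idx = [i for i, a in enumerate(structure.atoms) if not a.is_hydrogen]
            coords = structure.coords()
            t_idx = [
                i for i, a in enumerate(structure.atoms)
                if a.residue_number == truth.target.residue_number
            ]
            fast = deep_volume_xyz(
                coords[heavy_idx], structure.heavy_radii(), coords[t_idx], params
            )
            full = deep_pocket_volume(structure, truth.target, params)
            assert fast == full, kind


class TestInvariants:
    def test_deep_volume_multiple_of_spacing_cubed(self, flask_fixture):
        structure, truth = flask_fixture
        for spacing in (1.0, 0.8):
            params = PocketParams(spacing=spacing)
            v = deep_pocket_volume(structure, truth.target, params)
            assert v >= 0
            assert abs(v / spacing**3 - round(v / spacing**3)) < 1e-9

    def test_deep_subset_total(self, suite):
        for kind in ("flask", "sphere_shell", "channel"):
            structure, truth = suite[kind]
            for p in detect_pockets(structure, truth.target).pockets:
                assert p.deep_volume <= p.total_volume
                assert len(p.deep_point_indices) <= len(p.point_indices)

    @pytest.mark.parametrize("kind", ["flask", "channel", "sphere_shell"])
    def test_monotone_in_deep_cutoff(self, suite, kind):
        structure, truth = suite[kind]
        vols = [
            deep_pocket_volume(structure, truth.target, PocketParams(deep_cutoff=c))
            for c in (1.5, 2.5, 3.5)
        ]
        assert vols[0] >= vols[1] >= vols[2]

    @pytest.mark.parametrize("kind", ["flask", "channel", "sphere_shell"])
    def test_monotone_in_max_span(self, suite, kind):
        structure, truth = suite[kind]
        totals = []
        for span in (8.0, 12.0, 16.0):
            pockets = detect_pockets(structure, truth.target, PocketParams(max_span=span))
            totals.append(sum(p.total_volume for p in pockets.pockets))
        assert totals[0] <= totals[1] <= totals[2]

    @pytest.mark.parametrize("shift", [(1, 0, 0), (0, -2, 3), (5, 5, 5)])
    def test_integer_translation_invariance(self, flask_fixture, shift):
        structure, truth = flask_fixture
        params = PocketParams()
        v0 = deep_pocket_volume(structure, truth.target, params)
        moved = structure.with_coords(
            structure.coords() + np.array(shift, dtype=float) * params.spacing
        )
        assert deep_pocket_volume(moved, truth.target, params) == v0

    def test_rotation_robustness(self, flask_fixture):
        structure, truth = flask_fixture
        params = PocketParams()
        v0 = deep_pocket_volume(structure, truth.target, params)
        assert v0 > 0
        vols = []
        for seed in range(20):
            rot = Rotation.random(rng=np.random.default_rng(seed))
            moved = structure.with_coords(rot.apply(structure.coords()))
            vols.append(deep_pocket_volume(moved, truth.target, params))
        vols = np.array(vols)
        assert np.all(np.abs(vols - v0) / v0 < 0.30)


class TestOracle:
    @pytest.mark.parametrize("kind,lattice", [
        ("slab", 1.2), ("channel", 1.2), ("flask", 1.4), ("sphere_shell", 1.2),
    ])
    def test_fixture_equivalence(self, suite, kind, lattice):
        structure, truth = suite[kind]
        params = PocketParams()
        grid = labeled(structure, truth.target, params)
        oracle = brute_force_labels(structure, truth.target, params)
        assert np.array_equal(grid.label, oracle.label)
        assert np.array_equal(grid.event_count, oracle.event_count)
        np.testing.assert_array_equal(grid.spec.origin, oracle.spec.origin)

    def test_single_atom_equivalence(self):
        s = single_atom_structure()
        params = PocketParams(capture_radius=6.0)
        grid = labeled(s, ResidueSelector("A", 1), params)
        oracle = brute_force_labels(s, ResidueSelector("A", 1), params)
        assert np.array_equal(grid.label, oracle.label)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_cloud_equivalence(self, seed):
        structure, target = random_cloud(seed)
        params = PocketParams(capture_radius=10.0)
        grid = labeled(structure, target, params)
        oracle = brute_force_labels(structure, target, params)
        assert np.array_equal(grid.label, oracle.label)
        assert np.array_equal(grid.event_count, oracle.event_count)

    def test_grid_too_large(self, suite):
        structure, truth = suite["hinge_two_state"]
        with pytest.raises(GridTooLargeError):
            brute_force_labels(structure, truth.target, PocketParams())


class TestParams:
    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PocketParams(spacing=0)
        with pytest.raises(ValueError):
            PocketParams(max_span=1.0, spacing=1.0)
        with pytest.raises(ValueError):
            PocketParams(connectivity=18)
        with pytest.raises(ValueError):
            PocketParams(directions=9)

    def test_direction_sets(self):
        assert len(PocketParams().direction_set) == 7
        assert len(PocketParams(directions=13).direction_set) == 13

    def test_thirteen_directions_run(self, flask_fixture):
        structure, truth = flask_fixture
        v = deep_pocket_volume(structure, truth.target, PocketParams(directions=13))
        assert v >= 0
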