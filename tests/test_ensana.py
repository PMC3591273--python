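import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketeer.ensana import (
    InterfaceDef,
    ReferenceSet,
    cumulative_volume_curve,
    derive_interface,
    irmsd,
    min_irmsd,
    pocket_hsasa,
    secondary_structure,
    select_random_sites,
    shrake_rupley_sasa,
)
from pocketeer.pocketgrid import detect_pockets
from pocketeer.structio import Atom, ResidueSelector, Structure, assign_radii


def with_ligand(structure, offsets, anchor_key=None, resname="LIG", resnum=500):
    """Copy of structure plus a HETATM ligand at anchor + offsets."""
    atoms = list(structure.atoms)
    if anchor_key is None:
        anchor = structure.coords().mean(axis=0)
    else:
        anchor = next(a.coords for a in atoms if a.residue_key == anchor_key)
    for i, off in enumerate(offsets):
        atoms.append(
            Atom(serial=10000 + i, name=f"L{i:03d}", element="C", residue_name=resname,
                 chain_id="A", residue_number=resnum, coords=anchor + np.asarray(off),
                 is_hetatm=True)
        )
    return assign_radii(Structure(atoms=atoms))


class TestDeriveInterface:
    def test_distant_ligand_errors(self, mini_protein):
        structure, _ = mini_protein
        far = with_ligand(structure, [(30.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="within"):
            derive_interface(far, contact_cutoff=5.0)

    def test_zero_cutoff_errors(self, mini_protein):
        structure, _ = mini_protein
        complex_ = with_ligand(structure, [(0.0, 0.0, 4.0)], anchor_key=("A", 10, ""))
        with pytest.raises(ValueError):
            derive_interface(complex_, contact_cutoff=0.0)

    def test_no_ligand_errors(self, mini_protein):
        structure, _ = mini_protein
        with pytest.raises(ValueError, match="no HETATM"):
            derive_interface(structure)

    def test_contacting_residues_exact(self, mini_protein):
        # ligand placed 3.5 A from residue 10's CA: compute the expected
        # residue set analytically from the fixture coordinates
        structure, _ = mini_protein
        anchor = next(a.coords for a in structure.atoms if a.residue_key == ("A", 10, "") and a.name == "CA")
        lig_pos = anchor + np.array([0.0, 0.0, 3.5])
        expected = set()
        for a in structure.atoms:
            if not a.is_hydrogen and np.linalg.norm(a.coords - lig_pos) <= 4.0:
                expected.add(a.residue_key)
        assert expected  # sanity: the ligand does contact something
        complex_ = with_ligand(structure, [lig_pos - structure.coords().mean(axis=0)])
        iface = derive_interface(complex_, contact_cutoff=4.0)
        got = {(r.chain_id, r.residue_number, r.insertion_code or "") for r in iface.residues}
        assert got == expected


@pytest.fixture(scope="module")
def irmsd_setup(mini_protein):
    structure, _ = mini_protein
    interface = InterfaceDef(
        residues=[ResidueSelector("A", i) for i in (8, 9, 10, 11)],
        atom_scope="heavy",
    )
    return structure, interface


class TestMinIrmsd:
    def test_identity_zero(self, irmsd_setup):
        structure, interface = irmsd_setup
        refs = ReferenceSet(bound_structures=[structure])
        assert min_irmsd(structure, refs, interface) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_zero(self, irmsd_setup):
        structure, interface = irmsd_setup
        rot = Rotation.random(rng=np.random.default_rng(11))
        moved = structure.with_coords(rot.apply(structure.coords()) + np.array([3.0, 4.0, 5.0]))
        refs = ReferenceSet(bound_structures=[structure])
        assert min_irmsd(moved, refs, interface) == pytest.approx(0.0, abs=1e-6)

    def test_min_over_references(self, irmsd_setup, mini_protein):
        structure, interface = irmsd_setup
        # ref1: perturbed copy; ref2: exact copy -> min must be 0 via ref2
        rng = np.random.default_rng(5)
        perturbed = structure.with_coords(structure.coords() + rng.normal(scale=0.8, size=(len(structure), 3)))
        refs = ReferenceSet(bound_structures=[perturbed, structure])
        v1 = irmsd(structure, perturbed, interface)
        assert v1 > 0.1
        assert min_irmsd(structure, refs, interface) == pytest.approx(0.0, abs=1e-9)
        assert min_irmsd(structure, refs, interface) <= v1

    def test_backbone_scope(self, irmsd_setup):
        structure, interface = irmsd_setup
        bb = InterfaceDef(residues=interface.residues, atom_scope="backbone")
        refs = ReferenceSet(bound_structures=[structure])
        assert min_irmsd(structure, refs, bb) == pytest.approx(0.0, abs=1e-9)

    def test_local_superposition_mode(self, irmsd_setup):
        structure, interface = irmsd_setup
        rot = Rotation.random(rng=np.random.default_rng(13))
        moved = structure.with_coords(rot.apply(structure.coords()))
        refs = ReferenceSet(bound_structures=[structure])
        assert min_irmsd(moved, refs, interface, superposition="local") == pytest.approx(0.0, abs=1e-6)

    def test_atom_mismatch_errors(self, irmsd_setup):
        structure, interface = irmsd_setup
        # drop one interface atom from the reference
        atoms = [a for a in structure.atoms if not (a.residue_key == ("A", 9, "") and a.name == "CB")]
        ref = Structure(atoms=atoms)
        refs = ReferenceSet(bound_structures=[ref])
        with pytest.raises(KeyError, match="A:9"):
            min_irmsd(structure, refs, interface)


class TestHsasa:
    def test_all_carbon_lining_is_100pct(self, flask_fixture):
        structure, truth = flask_fixture
        pocket = detect_pockets(structure, truth.target).largest_contacting()
        result = pocket_hsasa(structure, pocket)
        assert result.pct_hsasa == pytest.approx(100.0)

    def test_isolated_atom_exposure_ratio(self):
        # two isolated atoms, far apart: SASA_i = 4 pi (r_i + probe)^2
        atoms = [
            Atom(serial=1, name="C1", element="C", residue_name="UNK",
                 chain_id="A", residue_number=1, coords=np.zeros(3)),
            Atom(serial=2, name="N1", element="N", residue_name="UNK",
                 chain_id="A", residue_number=2, coords=np.array([50.0, 0.0, 0.0])),
        ]
        s = assign_radii(Structure(atoms=atoms))
        areas = shrake_rupley_sasa(s, n_points=2000)
        expected_c = 4 * math.pi * (1.70 + 1.4) ** 2
        expected_n = 4 * math.pi * (1.55 + 1.4) ** 2
        assert areas[0] == pytest.approx(expected_c, rel=0.02)
        assert areas[1] == pytest.approx(expected_n, rel=0.02)
        assert areas[0] / areas[1] == pytest.approx(expected_c / expected_n, rel=0.02)

    def test_pct_invariant_under_rigid_motion(self, flask_fixture):
        structure, truth = flask_fixture
        pocket = detect_pockets(structure, truth.target).largest_contacting()
        p0 = pocket_hsasa(structure, pocket).pct_hsasa
        rot = Rotation.random(rng=np.random.default_rng(2))
        moved = structure.with_coords(rot.apply(structure.coords()))
        pockets2 = detect_pockets(moved, truth.target)
        p1 = pocket_hsasa(moved, pockets2.largest_contacting()).pct_hsasa
        assert p1 == pytest.approx(p0, abs=1e-9)  # all-carbon: both exactly 100


class TestCumulativeCurve:
    def test_all_zero_volumes(self):
        curve = dict(cumulative_volume_curve([0.0, 0.0, 0.0]))
        assert curve[0.0] == 1.0
        assert len(curve) == 1

    def test_two_volumes(self):
        curve = cumulative_volume_curve([10.0, 20.0])
        frac = {v: f for v, f in curve}
        assert frac[0.0] == 1.0
        assert frac[10.0] == 1.0
        assert frac[20.0] == 0.5
        # fraction >= 15 interpolates between grid points: check directly
        v = np.array([10.0, 20.0])
        assert np.mean(v >= 15) == 0.5

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        curve = cumulative_volume_curve(rng.uniform(0, 100, size=50))
        fracs = [f for _v, f in curve]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cumulative_volume_curve([])


class TestRandomSites:
    def test_zero_sites_empty(self, mini_protein):
        structure, _ = mini_protein
        assert select_random_sites(structure, ResidueSelector("A", 5), 0) == []

    def test_helix_matching(self, mini_protein):
        structure, _ = mini_protein
        ss = secondary_structure(structure)
        assert ss[("A", 5, "")] == "H"
        sites = select_random_sites(
            structure, ResidueSelector("A", 5), 1,
            seed=1, min_separation=6.0, min_pocket_volume=0.0,
        )
        assert len(sites) == 1
        key = (sites[0].chain_id, sites[0].residue_number, sites[0].insertion_code or "")
        assert ss[key] == "H"

    def test_pairwise_separation(self, mini_protein):
        structure, _ = mini_protein
        sites = select_random_sites(
            structure, ResidueSelector("A", 5), 2,
            seed=3, min_separation=5.0, min_pocket_volume=0.0,
        )
        ca = {a.residue_key: a.coords for a in structure.atoms if a.name == "CA"}
        keys = [(s.chain_id, s.residue_number, s.insertion_code or "") for s in sites]
        d = np.linalg.norm(ca[keys[0]] - ca[keys[1]])
        assert d >= 5.0

    def test_too_many_requested_errors(self, mini_protein):
        structure, _ = mini_protein
        with pytest.raises(ValueError, match="eligible"):
            select_random_sites(
                structure, ResidueSelector("A", 5), 50,
                seed=0, min_separation=12.0, min_pocket_volume=0.0,
            )

    def test_pocket_volume_gate_postcondition(self, mini_protein):
        # any site passing the 100 A^3 gate must have a contacting pocket
        # with total volume above the gate; an absurd gate finds nothing
        structure, _ = mini_protein
        try:
            sites = select_random_sites(
                structure, ResidueSelector("A", 5), 1,
                seed=0, min_separation=6.0, min_pocket_volume=100.0,
            )
        except ValueError:
            sites = []
        for site in sites:
            pockets = detect_pockets(structure, site)
            total = max(p.total_volume for p in pockets.pockets if p.contacts_target)
            assert total > 100.0
        with pytest.raises(ValueError):
            select_random_sites(
                structure, ResidueSelector("A", 5), 1,
                seed=0, min_separation=6.0, min_pocket_volume=1e6,
            )

    def test_seeded_determinism(self, mini_protein):
        structure, _ = mini_protein
        kw = dict(seed=4, min_separation=5.0, min_pocket_volume=0.0)
        a = select_random_sites(structure, ResidueSelector("A", 5), 2, **kw)
        b = select_random_sites(structure, ResidueSelector("A", 5), 2, **kw)
        assert a == b


class TestSecondaryStructure:
    def test_helix_and_coil(self, mini_protein):
        structure, _ = mini_protein
        ss = secondary_structure(structure)
        # termini are coil (undefined phi or psi)
        assert ss[("A", 1, "")] == "C"
        assert ss[("A", 20, "")] == "C"
        helical = [k for k, v in ss.items() if v == "H"]
        assert len(helical) >= 14
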