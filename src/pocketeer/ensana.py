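"""Ensemble analytics: interface RMSD to bound references, pocket
hydrophobic surface fraction, cumulative volume curves, and matched
random-site selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .pocketgrid import Pocket, PocketParams, detect_pockets
from .structio import BACKBONE_NAMES, ResidueSelector, Structure

__all__ = [
    "InterfaceDef",
    "ReferenceSet",
    "SASAResult",
    "derive_interface",
    "kabsch",
    "irmsd",
    "min_irmsd",
    "shrake_rupley_sasa",
    "pocket_hsasa",
    "cumulative_volume_curve",
    "secondary_structure",
    "select_random_sites",
]


@dataclass
class InterfaceDef:
    residues: list  # of ResidueSelector
    atom_scope: str = "heavy"  # 'heavy' or 'backbone'
    derivation: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError("interface must contain at least one residue")
        if self.atom_scope not in ("heavy", "backbone"):
            raise ValueError("atom_scope must be 'heavy' or 'backbone'")


@dataclass
class ReferenceSet:
    bound_structures: list
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if not self.bound_structures:
            raise ValueError("reference set must contain at least one structure")
        if not self.labels:
            self.labels = [f"ref{i+1}" for i in range(len(self.bound_structures))]


@dataclass
class SASAResult:
    per_atom_area: np.ndarray
    hydrophobic_area: float
    total_area: float

    @property
    def pct_hsasa(self) -> float:
        return 100.0 * self.hydrophobic_area / self.total_area


def derive_interface(bound_structure: Structure, contact_cutoff: float = 5.0) -> InterfaceDef:
    """Interface residues: protein residues with any heavy atom within
    contact_cutoff of any heavy atom of the (single) HETATM ligand."""
    from .structio import STANDARD_AA

    ligand_atoms = [
        a
        for a in bound_structure.atoms
        if a.is_hetatm and a.residue_name not in STANDARD_AA and not a.is_hydrogen
    ]
    ligand_keys = {a.residue_key for a in ligand_atoms}
    if len(ligand_keys) == 0:
        raise ValueError("no HETATM ligand present")
    if len(ligand_keys) > 1:
        raise ValueError(f"expected exactly one ligand, found {sorted(ligand_keys)}")
    lig_xyz = np.array([a.coords for a in ligand_atoms])
    protein = [a for a in bound_structure.atoms if not a.is_hetatm and not a.is_hydrogen]
    residues: list = []
    seen = set()
    for a in protein:
        if a.residue_key in seen:
            continue
        d2 = ((lig_xyz - a.coords) ** 2).sum(axis=1).min()
        if d2 <= contact_cutoff**2:
            seen.add(a.residue_key)
            residues.append(
                ResidueSelector(a.chain_id, a.residue_number, a.insertion_code)
            )
    if not residues:
        raise ValueError(f"no residue within {contact_cutoff} A of the ligand")
    return InterfaceDef(
        residues=residues,
        atom_scope="heavy",
        derivation=f"heavy-atom contact within {contact_cutoff} A of ligand",
    )


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal least-squares superposition: returns (rotation, t_mobile,
    t_target) with mobile mapped by (x - t_mobile) @ R + t_target."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    return rot, cm, ct


def _interface_atom_pairs(conf: Structure, ref: Structure, interface: InterfaceDef):
    """Matched interface atom coordinate pairs (by residue + atom name)."""
    want_bb = interface.atom_scope == "backbone"
    a_list, b_list, missing = [], [], []
    conf_res = conf.residues()
    ref_res = ref.residues()
    for sel in interface.residues:
        key = (sel.chain_id, sel.residue_number, sel.insertion_code or "")
        ca = {a.name: a for a in conf_res.get(key, []) if not a.is_hydrogen}
        ra = {a.name: a for a in ref_res.get(key, []) if not a.is_hydrogen}
        if not ca or not ra:
            raise KeyError(f"interface residue {sel} missing from structure")
        names = sorted(set(ca) & set(ra))
        if want_bb:
            names = [n for n in names if n in BACKBONE_NAMES]
        for n in sorted(set(ca) | set(ra)):
            if want_bb and n not in BACKBONE_NAMES:
                continue
            if n not in ca or n not in ra:
                missing.append(f"{sel}/{n}")
        for n in names:
            a_list.append(ca[n].coords)
            b_list.append(ra[n].coords)
    if missing:
        raise KeyError(f"interface atom mismatch: {', '.join(missing)}")
    return np.array(a_list), np.array(b_list)


def _shared_ca(conf: Structure, ref: Structure):
    conf_ca = {a.residue_key: a.coords for a in conf.atoms if a.name == "CA"}
    ref_ca = {a.residue_key: a.coords for a in ref.atoms if a.name == "CA"}
    shared = sorted(set(conf_ca) & set(ref_ca))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared CA atoms for superposition")
    return (
        np.array([conf_ca[k] for k in shared]),
        np.array([ref_ca[k] for k in shared]),
    )


def irmsd(
    conformation: Structure,
    reference: Structure,
    interface: InterfaceDef,
    superposition: str = "global",
) -> float:
    """RMSD over interface atoms after least-squares superposition.

    superposition='global': Kabsch on all shared CA atoms (default);
    'local': Kabsch on the interface atoms themselves.
    """
    ia, ib = _interface_atom_pairs(conformation, reference, interface)
    if superposition == "global":
        ma, mb = _shared_ca(conformation, reference)
    elif superposition == "local":
        ma, mb = ia, ib
    else:
        raise ValueError("superposition must be 'global' or 'local'")
    rot, cm, ct = kabsch(ma, mb)
    moved = (ia - cm) @ rot + ct
    return float(np.sqrt(((moved - ib) ** 2).sum(axis=1).mean()))


def min_irmsd(
    conformation: Structure,
    reference_set: ReferenceSet,
    interface: InterfaceDef,
    superposition: str = "global",
) -> float:
    """Lowest interface RMSD across all bound references."""
    return min(
        irmsd(conformation, ref, interface, superposition)
        for ref in reference_set.bound_structures
    )


def shrake_rupley_sasa(
    structure: Structure, probe_radius: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-heavy-atom solvent-accessible surface area (A^2), Shrake-Rupley
    with >= 960 sphere points (via biotite)."""
    import biotite.structure as struc

    heavy = structure.heavy_atoms()
    arr = struc.AtomArray(len(heavy))
    arr.coord = np.array([a.coords for a in heavy], dtype=np.float32)
    for i, a in enumerate(heavy):
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.residue_number
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
    radii = np.array([a.vdw_radius for a in heavy], dtype=np.float32)
    if np.any(radii <= 0):
        raise ValueError("heavy atoms without radii; run assign_radii first")
    return np.asarray(
        struc.sasa(arr, probe_radius=probe_radius, point_number=n_points, vdw_radii=radii),
        dtype=float,
    )


def pocket_hsasa(
    structure: Structure, pocket: Pocket, probe_radius: float = 1.4, n_points: int = 960
) -> SASAResult:
    """Percent hydrophobic (C/S) SASA over a pocket's lining atoms.

    SASA is computed over the whole structure; the hydrophobic fraction
    is taken over the lining atoms only. Errors if the lining is fully
    buried (total lining SASA 0).
    """
    if not pocket.lining_atoms:
        raise ValueError("pocket has no lining atoms")
    areas = shrake_rupley_sasa(structure, probe_radius, n_points)
    heavy = structure.heavy_atoms()
    index = {id(a): i for i, a in enumerate(heavy)}
    lining_idx = [index[id(a)] for a in pocket.lining_atoms]
    lining_areas = areas[lining_idx]
    total = float(lining_areas.sum())
    if total <= 0:
        raise ValueError("lining atoms have zero accessible area (undefined %hSASA)")
    hydro = float(
        sum(area for a, area in zip(pocket.lining_atoms, lining_areas) if a.is_hydrophobic)
    )
    return SASAResult(per_atom_area=areas, hydrophobic_area=hydro, total_area=total)


def cumulative_volume_curve(volumes: Sequence[float]):
    """(volume, fraction of ensemble with volume >= that value) pairs.

    The curve starts at (0, 1) and is non-increasing.
    """
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one volume")
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    grid = np.unique(np.concatenate([[0.0], v]))
    frac = [(float(x), float(np.mean(v >= x)) if x > 0 else 1.0) for x in grid]
    return frac


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(structure: Structure) -> dict:
    """residue_key -> (phi, psi); None where undefined (termini)."""
    res = structure.residues()
    keys = [k for k in res if all(n in {a.name for a in res[k]} for n in ("N", "CA", "C"))]
    keys.sort()
    out = {}
    by_key = {
        k: {a.name: a.coords for a in res[k]} for k in keys
    }
    for i, k in enumerate(keys):
        phi = psi = None
        prev = keys[i - 1] if i > 0 else None
        nxt = keys[i + 1] if i + 1 < len(keys) else None
        if prev and prev[0] == k[0] and "C" in by_key[prev]:
            phi = _dihedral(by_key[prev]["C"], by_key[k]["N"], by_key[k]["CA"], by_key[k]["C"])
        if nxt and nxt[0] == k[0] and "N" in by_key[nxt]:
            psi = _dihedral(by_key[k]["N"], by_key[k]["CA"], by_key[k]["C"], by_key[nxt]["N"])
        out[k] = (phi, psi)
    return out


def secondary_structure(structure: Structure) -> dict:
    """residue_key -> 'H' / 'E' / 'C' by a backbone-dihedral rule.

    H: phi in [-100, -30] and psi in [-80, -5]
    E: phi in [-180, -45] and (psi >= 45 or psi <= -150)
    C: everything else (including termini with undefined angles)
    """
    out = {}
    for key, (phi, psi) in backbone_dihedrals(structure).items():
        ss = "C"
        if phi is not None and psi is not None:
            if -100 <= phi <= -30 and -80 <= psi <= -5:
                ss = "H"
            elif -180 <= phi <= -45 and (psi >= 45 or psi <= -150):
                ss = "E"
        out[key] = ss
    return out


# Theoretical maximum residue accessible areas (A^2), Tien et al. 2013,
# used to call a residue surface-exposed.
MAX_RESIDUE_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def select_random_sites(
    structure: Structure,
    interaction_site: ResidueSelector,
    n_sites: int,
    params: Optional[PocketParams] = None,
    seed: int = 0,
    min_separation: float = 12.0,
    min_pocket_volume: float = 100.0,
    min_rel_sasa: float = 0.25,
) -> list:
    """Seeded random surface residues matched to the interaction site.

    Eligible residues are surface-exposed (relative residue SASA >
    min_rel_sasa), share the interaction-site residue's secondary
    structure class, lie >= min_separation (CA-CA) from the interaction
    site and from each other, and have an adjacent total pocket volume
    (our detector's total, the stand-in for an external pocket finder)
    > min_pocket_volume.
    """
    if n_sites == 0:
        return []
    params = params or PocketParams()
    rng = np.random.default_rng(seed)
    ss = secondary_structure(structure)
    site_key = (
        interaction_site.chain_id,
        interaction_site.residue_number,
        interaction_site.insertion_code or "",
    )
    if site_key not in ss:
        raise KeyError(f"interaction site {interaction_site} not found")
    site_class = ss[site_key]
    areas = shrake_rupley_sasa(structure)
    heavy = structure.heavy_atoms()
    res_area: dict = {}
    ca_pos: dict = {}
    for a, area in zip(heavy, areas):
        res_area[a.residue_key] = res_area.get(a.residue_key, 0.0) + float(area)
        if a.name == "CA":
            ca_pos[a.residue_key] = a.coords
    site_ca = ca_pos.get(site_key)
    if site_ca is None:
        raise KeyError(f"interaction site {interaction_site} has no CA atom")

    candidates = []
    for key in sorted(res_area):
        if key == site_key or key not in ca_pos:
            continue
        resname = next(a.residue_name for a in heavy if a.residue_key == key)
        max_area = MAX_RESIDUE_SASA.get(resname)
        if max_area is None:
            continue
        if res_area[key] / max_area <= min_rel_sasa:
            continue
        if ss.get(key) != site_class:
            continue
        if np.linalg.norm(ca_pos[key] - site_ca) < min_separation:
            continue
        candidates.append(key)

    order = rng.permutation(len(candidates))
    chosen: list = []
    chosen_ca: list = []
    for idx in order:
        key = candidates[idx]
        if any(np.linalg.norm(ca_pos[key] - c) < min_separation for c in chosen_ca):
            continue
        sel = ResidueSelector(key[0], key[1], key[2])
        if min_pocket_volume > 0:
            pockets = detect_pockets(structure, sel, params)
            pocket = pockets.largest_contacting()
            total = 0.0
            if pocket is not None:
                total = max(
                    p.total_volume for p in pockets.pockets if p.contacts_target
                )
            if total <= min_pocket_volume:
                continue
        chosen.append(sel)
        chosen_ca.append(ca_pos[key])
        if len(chosen) == n_sites:
            return chosen
    raise ValueError(
        f"only {len(chosen)} eligible random sites found (requested {n_sites})"
    )
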