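"""Synthetic PDB-format toy structures with analytically known geometry.

All fixtures are carbon-atom lattices (except mini_protein, a polyalanine
fold built from ideal internal coordinates). Geometry is chosen so that
cavity volumes, target contacts and hinge states are known by
construction, letting every other module be tested without downloads.

Kinds
-----
slab            flat block; no cavity anywhere (deep volume 0)
channel         two parallel slabs separated by a gap
flask           cubic cavity of side `cavity` with a narrow mouth; the
                free interior seen by a 1 A grid is exactly cavity^3
sphere_shell    hollow shell enclosing a spherical cavity
hinge_two_state rigid deck + rigid lid on one vertical hinge torsion;
                exactly two clash-free rotamers, one roofing a deck hole
                (deep pocket present), one parked over an equivalent
                target-less hole (no pocket at the target); an optional
                variant adds a rim bump so roofing costs a soft clash
mini_protein    20-residue polyalanine helix-turn-helix with real
                backbone torsions
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .structio import Atom, ResidueSelector, Structure, assign_radii, write_pdb

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "make_fixture",
    "write_fixture_suite",
    "hinge_torsion",
    "DEFAULT_SUITE",
]

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _name36(i: int) -> str:
    """Unique <=4-char atom name: 'A' + base-36 index."""
    s = ""
    n = i
    while True:
        s = _B36[n % 36] + s
        n //= 36
        if n == 0:
            break
    return "A" + s.rjust(3, "0")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    geometry: dict = field(default_factory=dict)
    atom_element: str = "C"
    lattice: float = 1.2
    seed: int = 0

    KINDS = ("slab", "channel", "flask", "sphere_shell", "hinge_two_state", "mini_protein")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.lattice <= 0:
            raise ValueError("lattice spacing must be positive")


@dataclass
class FixtureTruth:
    analytic_cavity_volume: float = 0.0
    target: Optional[ResidueSelector] = None
    open_state_energy: Optional[float] = None
    closed_state_energy: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "analytic_cavity_volume": self.analytic_cavity_volume,
            "target": str(self.target) if self.target else None,
            "open_state_energy": self.open_state_energy,
            "closed_state_energy": self.closed_state_energy,
            "extras": {
                k: v for k, v in self.extras.items() if isinstance(v, (int, float, str, list))
            },
        }


def _build(atom_rows, element="C") -> Structure:
    """atom_rows: list of (coords, residue_number, residue_name).
    Names are unique per residue; radii assigned from the default table."""
    atoms = []
    counters: dict = {}
    for i, (xyz, resnum, resname) in enumerate(atom_rows):
        c = counters.get(resnum, 0)
        counters[resnum] = c + 1
        atoms.append(
            Atom(
                serial=i + 1,
                name=_name36(c),
                element=element,
                residue_name=resname,
                chain_id="A",
                residue_number=resnum,
                coords=np.asarray(xyz, dtype=float),
            )
        )
    return assign_radii(Structure(atoms=atoms))


def _lattice_coords(lo, hi, a):
    """Symmetric lattice multiples of a covering [lo, hi] (inclusive-ish)."""
    n_lo = int(math.floor(lo / a + 1e-9))
    n_hi = int(math.ceil(hi / a - 1e-9))
    return [a * n for n in range(n_lo, n_hi + 1)]


# --------------------------------------------------------------------------
# slab / channel
# --------------------------------------------------------------------------

def _make_slab(geom: dict, a: float):
    half = geom.get("half_width", 8.4)
    layers = geom.get("layers", 3)
    rows = []
    xs = _lattice_coords(-half, half, a)
    for x in xs:
        for y in xs:
            for li in range(layers):
                z = -li * a
                resnum = 1
                if li == 0 and abs(x) < a / 2 and abs(y) < a / 2:
                    resnum = 2  # target: top-center atom
                rows.append(((x, y, z), resnum, "FXT" if resnum == 2 else "FXB"))
    truth = FixtureTruth(
        analytic_cavity_volume=0.0,
        target=ResidueSelector("A", 2),
        extras={"kind": "slab"},
    )
    return rows, truth


def _make_channel(geom: dict, a: float):
    half = geom.get("half_width", 7.2)
    gap = geom.get("gap", 6.0)
    layers = geom.get("layers", 2)
    rows = []
    xs = _lattice_coords(-half, half, a)
    for x in xs:
        for y in xs:
            for li in range(layers):
                # lower slab top at z=0; upper slab bottom at z=gap
                rows.append(((x, y, -li * a), 1, "FXB"))
                rows.append(((x, y, gap + li * a), 1, "FXB"))
    # target: top-center atom of the lower slab
    rows.append(((0.0, 0.0, 0.0), 2, "FXT"))
    # remove the duplicate body atom at the same site
    rows = [r for r in rows if not (r[1] == 1 and r[0] == (0.0, 0.0, 0.0))]
    truth = FixtureTruth(
        analytic_cavity_volume=0.0,
        target=ResidueSelector("A", 2),
        extras={"kind": "channel", "gap": gap},
    )
    return rows, truth


# --------------------------------------------------------------------------
# flask
# --------------------------------------------------------------------------

def _make_flask(geom: dict, a: float):
    """Cubic cavity of side `cavity` (default 5 A of grid-free interior)
    with a mouth channel of width `mouth` through the top wall.

    With lattice 1.4 and C radius 1.70, removing atom sites strictly
    inside +/-(cavity/2 + 1.7) leaves wall planes whose vdW surfaces
    bound an open cube of exactly `cavity` per axis.
    """
    cavity = geom.get("cavity", 5.0)
    mouth = geom.get("mouth", 2.0)
    r_vdw = 1.70
    if mouth >= cavity:
        raise ValueError("flask mouth must be narrower than the cavity")
    # carve bounds in atom-center space
    cav_half = cavity / 2 + r_vdw
    mouth_half = mouth / 2 + r_vdw
    n_wall = geom.get("wall_sites", 1)  # extra wall planes beyond the first
    block_half = cav_half + n_wall * a
    xs = _lattice_coords(-block_half, block_half, a)
    top = max(xs)
    rows = []
    for x in xs:
        for y in xs:
            for z in xs:
                in_cavity = (
                    abs(x) < cav_half - 1e-9
                    and abs(y) < cav_half - 1e-9
                    and abs(z) < cav_half - 1e-9
                )
                in_mouth = (
                    abs(x) < mouth_half - 1e-9
                    and abs(y) < mouth_half - 1e-9
                    and z > 0
                )
                if in_cavity or in_mouth:
                    continue
                rows.append(((x, y, z), 1, "FXB"))
    # target: four atoms ringing the mouth on the top face -> centroid
    # at (0, 0, top), so the 1 A grid is integer-offset from the cavity
    ring = None
    for x in xs:
        if x >= mouth_half - 1e-9:
            ring = x
            break
    if ring is None:
        raise ValueError("flask walls too small for a mouth ring")
    new_rows = []
    ring_sites = {(ring, 0.0), (-ring, 0.0), (0.0, ring), (0.0, -ring)}
    for (x, y, z), resnum, resname in rows:
        if z == top and (x, y) in ring_sites:
            new_rows.append(((x, y, z), 2, "FXT"))
        else:
            new_rows.append(((x, y, z), resnum, resname))
    truth = FixtureTruth(
        analytic_cavity_volume=cavity**3,
        target=ResidueSelector("A", 2),
        extras={"kind": "flask", "cavity": cavity, "mouth": mouth},
    )
    return new_rows, truth


# --------------------------------------------------------------------------
# sphere shell
# --------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * i
    return radius * np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _make_sphere_shell(geom: dict, a: float):
    radius = geom.get("radius", 5.0)
    r_vdw = 1.70
    # enough points that neighbor spacing < vdW diameter (watertight)
    n = geom.get("n_atoms", max(64, int(4 * math.pi * radius**2 / (0.7 * a) ** 2)))
    pts = _fibonacci_sphere(n, radius)
    rows = [((float(p[0]), float(p[1]), float(p[2])), 1, "FXB") for p in pts[1:]]
    rows.insert(0, ((float(pts[0][0]), float(pts[0][1]), float(pts[0][2])), 2, "FXT"))
    free_r = radius - r_vdw
    truth = FixtureTruth(
        analytic_cavity_volume=4.0 / 3.0 * math.pi * free_r**3,
        target=ResidueSelector("A", 2),
        extras={"kind": "sphere_shell", "radius": radius, "free_radius": free_r},
    )
    return rows, truth


# --------------------------------------------------------------------------
# hinge
# --------------------------------------------------------------------------

HINGE_DEFAULTS = {
    # Geometry (A). The arm (residue 3, the lid) rotates about a vertical
    # axis at the origin over a two-layer slab topped by a full raised
    # deck (one extra lattice layer). Two identical rectangular holes are
    # cut in the deck at 0 and 180 degrees. Roofing a hole with the arm
    # turns it into a one-grid-plane deep pocket; unroofed holes are
    # shallow (every point within the deep cutoff of bulk). The hole at
    # 0 degrees carries the target residue (2); the hole at 180 degrees
    # is the parking spot (no target, invisible to the bias, but
    # contact-symmetric so the lid feels nearly the same energy at both
    # stations). Pillars block all other angles, leaving exactly two
    # clash-free rotamers: roofing the target hole ("open") and parked
    # ("closed"). With geometry {"bump_on_target": True} a single raised
    # atom on the target hole's far rim makes roofing it cost a soft
    # clash -- the "strained site" variant whose pocket only opens at an
    # energetic price.
    "slab_half": 16.8,
    "slab_layers": 2,
    "hole_x0": 6.0,  # removed deck sites: hole_x0 <= x' <= hole_x1,
    "hole_x1": 12.0,  # |y'| <= hole_half_w (station frame)
    "hole_half_w": 4.8,
    "arm_z": 4.4,  # lid height: seals on the 1.2-high deck, clears it,
    #               and leaves no vdW pores through the lid's grid planes
    "arm_r0": 3.6,
    "arm_r1": 14.4,
    "arm_half_w": 4.8,  # overhangs the hole (vdW)
    "open_angle": 0.0,
    "closed_angle": 180.0,
    "pillar_angles": (45.0, 90.0, 135.0, 225.0, 270.0, 315.0),
    "pillar_radius": 15.6,
    "pillar_top": 6.0,
    "bump_height": 3.0,  # z of the strained variant's single bump atom
    "bump_on_target": False,
}


def _rotz(xyz, deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    x, y, z = xyz
    return (c * x - s * y, s * x + c * y, z)


def _make_hinge(geom: dict, a: float):
    g = dict(HINGE_DEFAULTS)
    g.update(geom)
    rows = []
    occupied = set()

    def add(xyz, resnum=1, resname="FXB"):
        key = (round(xyz[0], 3), round(xyz[1], 3), round(xyz[2], 3))
        if key in occupied:
            return False
        occupied.add(key)
        rows.append(((key[0], key[1], key[2]), resnum, resname))
        return True

    xs = _lattice_coords(-g["slab_half"], g["slab_half"], a)
    mid_x = 0.5 * (g["hole_x0"] + g["hole_x1"])
    stations = (
        (g["open_angle"], 2, bool(g["bump_on_target"])),
        (g["closed_angle"], None, False),
    )

    # target atoms first (add() keeps the first occupant of a site): four
    # per station, flush in the deck on the hole's side rims. Flush
    # placement is load-bearing: atoms protruding above the deck would
    # act as extra scan-line flanks and bridge distant surface pockets.
    # The centroid lands at (mid_x, 0, a), putting grid planes at a + k
    # so the hole holds one solvent plane when roofed, none when the lid
    # is parked, and a bulk plane just above the deck keeps unroofed
    # holes shallow.
    hw = g["hole_half_w"]
    for angle_deg, resnum, _bump in stations:
        if resnum is None:
            continue
        for x in (mid_x - 0.5 * a, mid_x + 0.5 * a):
            for sgn in (+1, -1):
                add(_rotz((x, sgn * (hw + a), a), angle_deg), resnum, "FXT")

    def in_any_hole(x, y):
        for angle_deg, _r, _b in stations:
            xp, yp, _ = _rotz((x, y, 0.0), -angle_deg)
            if (
                g["hole_x0"] - 0.05 <= xp <= g["hole_x1"] + 0.05
                and abs(yp) <= g["hole_half_w"] + 0.05
            ):
                return True
        return False

    # slab + deck (deck = extra layer at z = a, minus the holes)
    for x in xs:
        for y in xs:
            for li in range(int(g["slab_layers"])):
                add((x, y, -li * a))
            if not in_any_hole(x, y):
                add((x, y, a))

    # strained variant: one atom raised over the target hole's far rim,
    # tuned so the roofing clash sits between the moderate and strong
    # bias rewards
    for angle_deg, _resnum, bump in stations:
        if bump:
            add(_rotz((g["hole_x1"] + a, 0.0, g["bump_height"]), angle_deg))

    # blocking pillars outside the arm-corner sweep: leave exactly the
    # open and closed angles clash-free
    for ang in g["pillar_angles"]:
        base = _rotz((g["pillar_radius"], 0.0, 0.0), ang)
        z = 2 * a
        while z <= g["pillar_top"] + 1e-9:
            add((base[0], base[1], z))
            z += a

    # hinge axis atom above the deck (the deck atom at the origin is the
    # lower axis atom)
    add((0.0, 0.0, 2 * a), 1, "FXB")
    axis_lo = (0.0, 0.0, a)
    axis_hi = (0.0, 0.0, 2 * a)

    # arm (lid) at the open angle
    rxs = [v for v in xs if g["arm_r0"] - 1e-9 <= v <= g["arm_r1"] + 1e-9]
    wys = [v for v in xs if abs(v) <= g["arm_half_w"] + 1e-9]
    for x in rxs:
        for y in wys:
            p = _rotz((x, y, g["arm_z"]), g["open_angle"])
            rows.append(((p[0], p[1], p[2]), 3, "ARM"))

    truth = FixtureTruth(
        analytic_cavity_volume=0.0,
        target=ResidueSelector("A", 2),
        extras={
            "kind": "hinge_two_state",
            "axis_lo": list(axis_lo),
            "axis_hi": list(axis_hi),
            "open_angle": g["open_angle"],
            "closed_angle": g["closed_angle"],
            "bump_on_target": bool(g["bump_on_target"]),
            "arm_residue": 3,
        },
    )
    return rows, truth


def hinge_torsion(structure: Structure):
    """The hinge fixture's single rotatable torsion (sampler.Torsion)."""
    from .sampler import Torsion

    axis_atoms = {}
    moving = []
    arm_key = None
    for i, atom in enumerate(structure.atoms):
        if atom.residue_number == 3:
            moving.append(i)
            arm_key = atom.residue_key
        elif atom.residue_number == 1 and abs(atom.coords[0]) < 1e-6 and abs(atom.coords[1]) < 1e-6:
            axis_atoms[round(float(atom.coords[2]), 3)] = i
    if len(axis_atoms) < 2 or not moving:
        raise ValueError("not a hinge fixture")
    zs = sorted(axis_atoms)
    return Torsion(
        name="hinge",
        kind="backbone",
        residue_key=arm_key,
        axis=(axis_atoms[zs[0]], axis_atoms[zs[1]]),
        moving=tuple(moving),
    )


# --------------------------------------------------------------------------
# mini protein (polyalanine helix-turn-helix)
# --------------------------------------------------------------------------

def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement: position D with |c-D|=bond, angle(b,c,D) and
    dihedral(a,b,c,D) as given."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


_HELIX = (-60.0, -45.0)


def _make_mini_protein(geom: dict, a_unused: float):
    n_res = int(geom.get("n_res", 20))
    turn_at = int(geom.get("turn_at", 10))
    phis = []
    psis = []
    for i in range(n_res):
        if i == turn_at - 1:
            phis.append(-90.0)
            psis.append(0.0)
        elif i == turn_at:
            phis.append(70.0)
            psis.append(40.0)
        else:
            phis.append(_HELIX[0])
            psis.append(_HELIX[1])
    # ideal backbone geometry
    b_n_ca, b_ca_c, b_c_n, b_c_o, b_ca_cb = 1.458, 1.525, 1.329, 1.231, 1.53
    ang_n_ca_c, ang_ca_c_n, ang_c_n_ca = 111.2, 116.2, 121.7
    ang_ca_c_o, ang_c_ca_cb = 120.5, 110.1
    coords: list = []  # (resnum, name, xyz)
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([b_n_ca, 0.0, 0.0])
    c = _place_atom(
        np.array([0.0, 1.0, 0.0]), n, ca, b_ca_c, ang_n_ca_c, phis[0]
    )
    for i in range(n_res):
        coords.append((i + 1, "N", n))
        coords.append((i + 1, "CA", ca))
        coords.append((i + 1, "C", c))
        cb = _place_atom(n, c, ca, b_ca_cb, ang_c_ca_cb, 122.6)
        coords.append((i + 1, "CB", cb))
        if i + 1 < n_res:
            n_next = _place_atom(n, ca, c, b_c_n, ang_ca_c_n, psis[i])
            o = _place_atom(ca, n_next, c, b_c_o, ang_ca_c_o, 180.0)
            coords.append((i + 1, "O", o))
            ca_next = _place_atom(ca, c, n_next, b_n_ca, ang_c_n_ca, 180.0)
            c_next = _place_atom(c, n_next, ca_next, b_ca_c, ang_n_ca_c, phis[i + 1])
            n, ca, c = n_next, ca_next, c_next
        else:
            o = _place_atom(n, ca, c, b_c_o, ang_ca_c_o, psis[i] + 180.0)
            coords.append((i + 1, "O", o))
    atoms = []
    order = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}
    coords.sort(key=lambda t: (t[0], order[t[1]]))
    for i, (resnum, name, xyz) in enumerate(coords):
        atoms.append(
            Atom(
                serial=i + 1,
                name=name,
                element=name[0],
                residue_name="ALA",
                chain_id="A",
                residue_number=resnum,
                coords=np.asarray(xyz, dtype=float),
            )
        )
    structure = assign_radii(Structure(atoms=atoms))
    truth = FixtureTruth(
        analytic_cavity_volume=0.0,
        target=ResidueSelector("A", int(geom.get("target_res", turn_at))),
        extras={"kind": "mini_protein", "n_res": n_res},
    )
    return structure, truth


# --------------------------------------------------------------------------
# dispatch + suite
# --------------------------------------------------------------------------

_MAKERS = {
    "slab": _make_slab,
    "channel": _make_channel,
    "flask": _make_flask,
    "sphere_shell": _make_sphere_shell,
    "hinge_two_state": _make_hinge,
}


def make_fixture(spec: FixtureSpec):
    """Build (Structure, FixtureTruth) for a fixture spec. Deterministic."""
    if spec.kind == "mini_protein":
        return _make_mini_protein(spec.geometry, spec.lattice)
    rows, truth = _MAKERS[spec.kind](spec.geometry, spec.lattice)
    structure = _build(rows, element=spec.atom_element)
    if spec.kind == "hinge_two_state":
        truth = _finish_hinge_truth(structure, truth)
    return structure, truth


def _finish_hinge_truth(structure: Structure, truth: FixtureTruth) -> FixtureTruth:
    from .biasenergy import base_energy
    from .sampler import rotate_about_axis

    t = hinge_torsion(structure)
    coords = structure.coords()
    open_e = base_energy(structure)
    delta = truth.extras["closed_angle"] - truth.extras["open_angle"]
    closed = rotate_about_axis(coords, t.moving, coords[t.axis[0]], coords[t.axis[1]], delta)
    closed_e = base_energy(structure.with_coords(closed))
    truth.open_state_energy = float(open_e)
    truth.closed_state_energy = float(closed_e)
    return truth


DEFAULT_SUITE = (
    FixtureSpec("slab"),
    FixtureSpec("channel"),
    FixtureSpec("flask", lattice=1.4),
    FixtureSpec("sphere_shell"),
    FixtureSpec("hinge_two_state"),
    FixtureSpec("mini_protein"),
)


def write_fixture_suite(directory) -> dict:
    """Write the canonical fixture suite (PDB + truth JSON). Returns the
    manifest; byte-stable across runs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for spec in DEFAULT_SUITE:
        structure, truth = make_fixture(spec)
        pdb_path = directory / f"{spec.kind}.pdb"
        write_pdb(structure, pdb_path)
        manifest[spec.kind] = {
            "pdb": pdb_path.name,
            "n_atoms": len(structure),
            "truth": truth.to_json(),
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
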