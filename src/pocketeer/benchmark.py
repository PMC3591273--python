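"""Reference two-state hinge benchmark.

A fixed protocol on the hinge fixture used by both the test suite and the
acceptance report: seeded biased / unbiased Monte Carlo ensembles, and an
independent 1-degree quadrature over the single hinge angle that yields
the exact stationary (Boltzmann) occupancies the sampler must reproduce.

The quadrature is a valid oracle because the hinge system has exactly one
degree of freedom: any Metropolis chain over that angle with symmetric
proposals has stationary density proportional to exp(-E_total(theta)/kT),
independent of the sampler's implementation details.

Two fixture variants are used:

* the plain hinge ("free"): roofing the target hole is clash-free, so a
  moderate bias opens the pocket at essentially no energetic cost;
* the strained variant ("bump_on_target"): a single raised rim atom makes
  roofing cost a soft clash, so only a strong bias opens the pocket and
  the resulting ensemble pays a visible base-energy price.

Protocol constants: pocket detection with a reduced capture radius (the
fixture is compact, and this keeps the brute-force oracle applicable);
weak contact reward and no torsion restraint so the two rotamer wells are
smooth on the kT = 1 scale and mixing is fast; uniform +/-180 degree
hinge proposals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biasenergy import BiasSpec, EnergyConfig, EnergyEvaluator
from .fixtures import FixtureSpec, hinge_torsion, make_fixture
from .pocketgrid import PocketParams, deep_volume_xyz
from .sampler import Ensemble, MCConfig, rotate_about_axis, run_mc
from .structio import ResidueSelector, Structure

__all__ = [
    "HINGE_POCKET_PARAMS",
    "HINGE_ENERGY_CONFIG",
    "OPEN_VOLUME_THRESHOLD",
    "LOCALITY_RADIUS",
    "HingeSystem",
    "hinge_system",
    "strained_hinge_system",
    "hinge_quadrature",
    "boltzmann_stats",
    "hinge_mc_config",
    "run_hinge_ensemble",
]

HINGE_POCKET_PARAMS = PocketParams(capture_radius=7.2)
HINGE_ENERGY_CONFIG = EnergyConfig(contact_reward=-0.01, torsion_k=0.0)
OPEN_VOLUME_THRESHOLD = 20.0  # A^3; a conformation above this is "open"
LOCALITY_RADIUS = 8.0  # A; validated against the quadrature scan
KT = 1.0


@dataclass
class HingeSystem:
    structure: Structure  # built at the open angle
    closed_structure: Structure  # rotated to the parked angle
    torsion: object
    target: ResidueSelector
    open_angle: float
    closed_angle: float
    strained: bool

    def rotated(self, angle_deg: float) -> np.ndarray:
        c = self.structure.coords()
        t = self.torsion
        return rotate_about_axis(c, t.moving, c[t.axis[0]], c[t.axis[1]], angle_deg)


def _build_system(strained: bool) -> HingeSystem:
    geometry = {"bump_on_target": True} if strained else {}
    structure, truth = make_fixture(FixtureSpec("hinge_two_state", geometry=geometry))
    torsion = hinge_torsion(structure)
    coords = structure.coords()
    closed = rotate_about_axis(
        coords,
        torsion.moving,
        coords[torsion.axis[0]],
        coords[torsion.axis[1]],
        truth.extras["closed_angle"] - truth.extras["open_angle"],
    )
    return HingeSystem(
        structure=structure,
        closed_structure=structure.with_coords(closed),
        torsion=torsion,
        target=truth.target,
        open_angle=truth.extras["open_angle"],
        closed_angle=truth.extras["closed_angle"],
        strained=strained,
    )


def hinge_system() -> HingeSystem:
    """The plain (clash-free pocket) hinge system."""
    return _build_system(strained=False)


def strained_hinge_system() -> HingeSystem:
    """The variant whose pocket only opens at a clash cost."""
    return _build_system(strained=True)


def hinge_quadrature(system: HingeSystem, step_deg: float = 1.0) -> dict:
    """Exact base energy and deep volume on an angle grid, plus the
    minimum moving-atom-to-target distance used to validate the sampler's
    bias locality shortcut."""
    ev = EnergyEvaluator(system.structure, HINGE_ENERGY_CONFIG)
    heavy_idx = [i for i, a in enumerate(system.structure.atoms) if not a.is_hydrogen]
    heavy_rad = system.structure.heavy_radii()
    t_idx = [
        i
        for i, a in enumerate(system.structure.atoms)
        if a.residue_key
        == (system.target.chain_id, system.target.residue_number, "")
    ]
    mov = list(system.torsion.moving)
    angles = np.arange(0.0, 360.0, step_deg)
    n = len(angles)
    out = {
        "angles": angles,
        "E": np.empty(n),
        "V": np.empty(n),
        "dmin": np.empty(n),
        "clash": np.empty(n),
    }
    for i, ang in enumerate(angles):
        c = system.rotated(ang)
        out["E"][i] = ev.energy(c)
        out["clash"][i] = ev.clash_only(c)
        out["V"][i] = deep_volume_xyz(c[heavy_idx], heavy_rad, c[t_idx], HINGE_POCKET_PARAMS)
        out["dmin"][i] = np.sqrt(
            ((c[mov][:, None, :] - c[t_idx][None, :, :]) ** 2).sum(axis=2).min()
        )
    return out


def boltzmann_stats(quad: dict, weight: float, kT: float = KT) -> dict:
    """Stationary occupancy / mean volume / mean base energy under
    E_total = E + weight * V, from the quadrature grid."""
    v = quad["V"]
    e_total = quad["E"] + weight * v
    w = np.exp(-(e_total - e_total.min()) / kT)
    p = w / w.sum()
    return {
        "p_open": float(p[v >= OPEN_VOLUME_THRESHOLD].sum()),
        "mean_volume": float(np.dot(p, v)),
        "mean_base_energy": float(np.dot(p, quad["E"])),
    }


def hinge_mc_config(seed: int, n_runs: int = 200, n_steps: int = 120) -> MCConfig:
    return MCConfig(
        n_steps=n_steps,
        n_runs=n_runs,
        kT=KT,
        p_sidechain=0.0,
        p_backbone=1.0,
        max_bb_step=180.0,  # uniform proposals over the full circle
        seed=seed,
        bias_locality_radius=LOCALITY_RADIUS,
    )


_BIAS_FACTORY = {
    "unbiased": BiasSpec.none,
    "moderate": BiasSpec.moderate,
    "strong": BiasSpec.strong,
}


def run_hinge_ensemble(
    system: HingeSystem,
    bias_mode: str,
    seed: int,
    n_runs: int = 200,
    n_steps: int = 120,
) -> Ensemble:
    """One benchmark ensemble, started from the parked (closed) state.

    bias_mode: 'unbiased', 'moderate' or 'strong' (applied at the
    system's target site).
    """
    bias = _BIAS_FACTORY[bias_mode](system.target, HINGE_POCKET_PARAMS)
    return run_mc(
        system.closed_structure,
        hinge_mc_config(seed, n_runs, n_steps),
        bias,
        torsions=[system.torsion],
        energy_config=HINGE_ENERGY_CONFIG,
    )
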