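"""Seeded Metropolis Monte Carlo over sidechain / backbone torsions.

Plain Metropolis sampling with uniform torsion perturbations, run with
or without the pocket-volume bias. One independent RNG substream per
run; the ensemble keeps the final conformation of each run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .biasenergy import BiasSpec, EnergyBreakdown, EnergyConfig, EnergyEvaluator, base_energy
from .pocketgrid import deep_pocket_volume, deep_volume_xyz
from .structio import BACKBONE_NAMES, Structure, resolve_selector

__all__ = [
    "Torsion",
    "MCConfig",
    "Conformation",
    "Ensemble",
    "derive_torsions",
    "rotate_about_axis",
    "propose_move",
    "run_mc",
    "rescore_ensemble",
]


@dataclass(frozen=True)
class Torsion:
    """A rotatable torsion: rotation of `moving` atom indices about the
    axis through atoms `axis[0]` -> `axis[1]` (pivot at axis[1])."""

    name: str  # e.g. 'phi', 'psi', 'chi1', 'hinge'
    kind: str  # 'chi' or 'backbone'
    residue_key: tuple
    axis: tuple  # (i, j) atom indices
    moving: tuple  # atom indices


@dataclass(frozen=True)
class MCConfig:
    n_steps: int = 500
    n_runs: int = 1000
    kT: float = 1.0
    p_sidechain: float = 0.7  # move mix: sidechain chi vs backbone phi/psi
    p_backbone: float = 0.3
    max_chi_step: float = 30.0  # degrees
    max_bb_step: float = 3.0  # degrees
    mobile_region: object = "all"  # 'all' or list of residue keys / selectors
    seed: int = 0
    pocket_eval_stride: int = 1
    # optional speedup: when every moving atom stays farther than this
    # from all target atoms (before and after the move), the deep volume
    # is taken from a cached "far" evaluation instead of being recomputed.
    # Only sound when the volume is constant over such states; callers
    # must verify that for their system (the hinge fixture tests do).
    bias_locality_radius: Optional[float] = None

    def __post_init__(self):
        if abs(self.p_sidechain + self.p_backbone - 1.0) > 1e-12:
            raise ValueError("move-mix probabilities must sum to 1")
        if self.n_steps < 0 or self.n_runs < 1:
            raise ValueError("n_steps must be >= 0 and n_runs >= 1")
        if self.pocket_eval_stride < 1:
            raise ValueError("pocket_eval_stride must be >= 1")


@dataclass
class Conformation:
    structure: Structure
    energy: EnergyBreakdown
    run_id: int
    step_id: int
    torsion_deltas: dict = field(default_factory=dict)


@dataclass
class Ensemble:
    conformations: list
    config: MCConfig
    bias_spec: BiasSpec
    acceptance_ratios: list = field(default_factory=list)

    def __post_init__(self):
        if not self.conformations:
            raise ValueError("ensemble must contain at least one conformation")

    def deep_volumes(self) -> np.ndarray:
        return np.array([c.energy.deep_volume for c in self.conformations])

    def base_energies(self) -> np.ndarray:
        return np.array([c.energy.base for c in self.conformations])


def derive_torsions(structure: Structure) -> list:
    """Standard amino-acid torsions from atom names.

    phi(i): axis N(i)-CA(i), moves {C,O,OXT}(i) + all later residues of
    the chain. psi(i): axis CA(i)-C(i), moves {O,OXT}(i) + later
    residues (defined only when residue i+1 exists). chi1: axis CA-CB,
    moves sidechain atoms beyond CB.
    """
    index = {}
    residue_order = []
    for i, a in enumerate(structure.atoms):
        key = a.residue_key
        if key not in index:
            index[key] = {}
            residue_order.append(key)
        index[key][a.name] = i
    torsions = []
    by_chain: dict = {}
    for key in residue_order:
        by_chain.setdefault(key[0], []).append(key)
    for chain, keys in by_chain.items():
        for pos, key in enumerate(keys):
            names = index[key]
            later = [
                i for k in keys[pos + 1 :] for i in index[k].values()
            ]
            prev_names = index[keys[pos - 1]] if pos > 0 else {}
            if pos > 0 and "C" in prev_names and "N" in names and "CA" in names:
                moving = [names[n] for n in ("C", "O", "OXT") if n in names] + later
                if moving:
                    torsions.append(
                        Torsion("phi", "backbone", key, (names["N"], names["CA"]), tuple(moving))
                    )
            if pos + 1 < len(keys) and "CA" in names and "C" in names:
                moving = [names[n] for n in ("O", "OXT") if n in names] + later
                if moving:
                    torsions.append(
                        Torsion("psi", "backbone", key, (names["CA"], names["C"]), tuple(moving))
                    )
            if "CA" in names and "CB" in names:
                side = [
                    i
                    for n, i in names.items()
                    if n not in BACKBONE_NAMES and n != "CB" and not n.startswith("H")
                ]
                if side:
                    torsions.append(
                        Torsion("chi1", "chi", key, (names["CA"], names["CB"]), tuple(side))
                    )
    return torsions


def rotate_about_axis(
    coords: np.ndarray, moving: Sequence[int], p0: np.ndarray, p1: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate `moving` rows of coords about the p0->p1 axis (pivot p1)."""
    if angle_deg == 0.0:
        return coords.copy()
    u = p1 - p0
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("degenerate torsion axis")
    u = u / norm
    rot = Rotation.from_rotvec(u * math.radians(angle_deg))
    out = coords.copy()
    idx = np.asarray(moving, dtype=int)
    out[idx] = rot.apply(coords[idx] - p1) + p1
    return out


def _wrap_angle(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


class _MoveEngine:
    """Shared proposal logic for propose_move and run_mc."""

    def __init__(self, structure: Structure, config: MCConfig, torsions=None):
        self.config = config
        self.torsions = list(torsions) if torsions is not None else derive_torsions(structure)
        if not self.torsions:
            raise ValueError("structure has no rotatable torsions")
        if config.mobile_region != "all":
            allowed = set()
            for item in config.mobile_region:
                allowed.add(item if isinstance(item, tuple) else
                            (item.chain_id, item.residue_number, item.insertion_code))
            self.torsions = [t for t in self.torsions if t.residue_key in allowed]
            if not self.torsions:
                raise ValueError("mobile_region leaves no rotatable torsions")
        self.by_residue: dict = {}
        for t in self.torsions:
            self.by_residue.setdefault(t.residue_key, {"chi": [], "backbone": []})[t.kind].append(t)
        self.residues = sorted(self.by_residue)

    def propose(self, coords: np.ndarray, rng: np.random.Generator):
        """One move: (new_coords, [(torsion, delta_deg), ...]).

        Draws a residue uniformly, then a move type from the move mix; a
        residue lacking the drawn torsion type triggers an internal
        redraw (never fails if any torsion exists).
        """
        cfg = self.config
        for _ in range(1000):
            key = self.residues[rng.integers(len(self.residues))]
            kind = "chi" if rng.random() < cfg.p_sidechain else "backbone"
            group = self.by_residue[key][kind]
            if not group:
                continue
            if kind == "chi":
                t = group[rng.integers(len(group))] if len(group) > 1 else group[0]
                chosen = [(t, float(rng.uniform(-cfg.max_chi_step, cfg.max_chi_step)))]
            else:
                chosen = [
                    (t, float(rng.uniform(-cfg.max_bb_step, cfg.max_bb_step)))
                    for t in group
                ]
            new = coords
            for t, delta in chosen:
                new = rotate_about_axis(new, t.moving, new[t.axis[0]], new[t.axis[1]], delta)
            return new, chosen
        # no residue has the drawn torsion type (e.g. sidechain-only mix
        # on an all-ALA chain): identity proposal
        return coords, []


def propose_move(
    structure: Structure,
    config: MCConfig,
    rng_state,
    torsions: Optional[list] = None,
) -> Structure:
    """Single proposal as a new Structure (all untouched atoms bit-identical)."""
    rng = rng_state if isinstance(rng_state, np.random.Generator) else np.random.default_rng(rng_state)
    engine = _MoveEngine(structure, config, torsions)
    new_coords, _ = engine.propose(structure.coords(), rng)
    return structure.with_coords(new_coords)


def _torsion_id(t: Torsion) -> tuple:
    return (t.residue_key, t.name)


def run_mc(
    structure: Structure,
    config: MCConfig,
    bias_spec: BiasSpec,
    torsions: Optional[list] = None,
    energy_config: Optional[EnergyConfig] = None,
) -> Ensemble:
    """Metropolis MC; returns the final conformation of each run.

    Acceptance uses the total energy (base + bias). The deep volume used
    by the bias is re-evaluated (on the proposed structure) whenever the
    count of accepted steps since the last evaluation would reach
    pocket_eval_stride; otherwise the stale value is reused. With the
    default stride of 1 every proposal is scored with a fresh volume.
    Each run draws from an independent substream seeded (seed, run_id);
    identical inputs give a bit-identical Ensemble.
    """
    ecfg = energy_config or EnergyConfig()
    engine = _MoveEngine(structure, config, torsions)
    evaluator = EnergyEvaluator(structure, ecfg)
    start_coords = structure.coords()
    bias_active = bias_spec.enabled and bias_spec.weight != 0.0
    heavy_idx = np.array(evaluator.heavy_index, dtype=int)
    heavy_rad = evaluator.rad
    target_atoms = resolve_selector(structure, bias_spec.target)
    id_by_pos = {id(a): i for i, a in enumerate(structure.atoms)}
    target_idx = np.array([id_by_pos[id(a)] for a in target_atoms], dtype=int)

    def volume_of(xyz: np.ndarray) -> float:
        return deep_volume_xyz(xyz[heavy_idx], heavy_rad, xyz[target_idx], bias_spec.params)

    # when every torsion moves the same rigid atom group (e.g. a single
    # hinge), energy differences reduce to the moving<->static cross term
    moving_sets = {t.moving for t in engine.torsions}
    if len(moving_sets) == 1:
        cross_fn, _ = evaluator.make_cross_evaluator(next(iter(moving_sets)), start_coords)

        def base_score(xyz, deltas):
            return cross_fn(xyz) + evaluator.torsion_energy(deltas)

    else:

        def base_score(xyz, deltas):
            return evaluator.energy(xyz, deltas)

    all_moving = sorted({i for t in engine.torsions for i in t.moving})
    loc_r = config.bias_locality_radius
    far_vol_cache: list = [None]

    def is_far(xyz: np.ndarray) -> bool:
        d2 = ((xyz[all_moving][:, None, :] - xyz[target_idx][None, :, :]) ** 2).sum(axis=2)
        return bool(d2.min() > loc_r * loc_r)

    conformations = []
    acceptance = []

    for run_id in range(config.n_runs):
        rng = np.random.default_rng([config.seed, run_id])
        coords = start_coords.copy()
        deltas: dict = {}
        cur_base = base_score(coords, deltas)
        cur_vol = volume_of(coords) if bias_active else 0.0
        accepted = 0
        accepted_since_eval = 0
        for _step in range(config.n_steps):
            new_coords, chosen = engine.propose(coords, rng)
            new_deltas = dict(deltas)
            for t, delta in chosen:
                tid = _torsion_id(t)
                new_deltas[tid] = _wrap_angle(new_deltas.get(tid, 0.0) + delta)
            new_base = base_score(new_coords, new_deltas)
            if bias_active:
                fresh = accepted_since_eval + 1 >= config.pocket_eval_stride
                if fresh and loc_r is not None and is_far(new_coords):
                    if far_vol_cache[0] is None:
                        far_vol_cache[0] = volume_of(new_coords)
                    new_vol = far_vol_cache[0]
                elif fresh:
                    new_vol = volume_of(new_coords)
                else:
                    new_vol = cur_vol
                d_e = (new_base + bias_spec.weight * new_vol) - (
                    cur_base + bias_spec.weight * cur_vol
                )
            else:
                fresh = False
                new_vol = cur_vol
                d_e = new_base - cur_base
            if d_e <= 0 or rng.random() < math.exp(-d_e / config.kT):
                coords = new_coords
                deltas = new_deltas
                cur_base = new_base
                accepted += 1
                if bias_active:
                    if fresh:
                        cur_vol = new_vol
                        accepted_since_eval = 0
                    else:
                        accepted_since_eval += 1
        final_struct = structure.with_coords(coords)
        final_vol = deep_pocket_volume(final_struct, bias_spec.target, bias_spec.params)
        final_base = evaluator.energy(coords, deltas)
        bias = bias_spec.weight * final_vol if bias_active else 0.0
        conformations.append(
            Conformation(
                structure=final_struct,
                energy=EnergyBreakdown(base=final_base, bias=bias, deep_volume=final_vol),
                run_id=run_id,
                step_id=config.n_steps,
                torsion_deltas=dict(deltas),
            )
        )
        acceptance.append(accepted / config.n_steps if config.n_steps else 1.0)
    return Ensemble(
        conformations=conformations,
        config=config,
        bias_spec=bias_spec,
        acceptance_ratios=acceptance,
    )


def rescore_ensemble(
    ensemble: Ensemble, bias_disabled: bool = True, energy_config: Optional[EnergyConfig] = None
) -> list:
    """Re-evaluate energies; with bias_disabled, base-only breakdowns for
    fair biased-vs-unbiased comparison."""
    ecfg = energy_config or EnergyConfig()
    out = []
    for c in ensemble.conformations:
        base = base_energy(c.structure, ecfg, c.torsion_deltas)
        if bias_disabled:
            out.append(EnergyBreakdown(base=base, bias=0.0, deep_volume=c.energy.deep_volume))
        else:
            vol = deep_pocket_volume(
                c.structure, ensemble.bias_spec.target, ensemble.bias_spec.params
            )
            bias = ensemble.bias_spec.weight * vol if ensemble.bias_spec.enabled else 0.0
            out.append(EnergyBreakdown(base=base, bias=bias, deep_volume=vol))
    return out
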