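"""Energy model: documented simplified base energy + pocket-volume bias.

The base energy is a contract, not a physical force field: a soft-sphere
clash penalty, a flat per-pair contact reward, and a harmonic restraint
on perturbed torsions. The bias term is linear in the deep pocket volume
at the target residue (moderate weight -0.25 units/A^3; strong is
tenfold, -2.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .pocketgrid import PocketParams, deep_pocket_volume
from .structio import ResidueSelector, Structure

__all__ = [
    "EnergyConfig",
    "BiasSpec",
    "EnergyBreakdown",
    "MODERATE_WEIGHT",
    "STRONG_WEIGHT",
    "base_energy",
    "pocket_bias",
    "total_energy",
]

MODERATE_WEIGHT = -0.25
STRONG_WEIGHT = 10 * MODERATE_WEIGHT  # -2.5


@dataclass(frozen=True)
class EnergyConfig:
    """Constants of the simplified base energy."""

    clash_factor: float = 0.8  # clash below clash_factor * (ri + rj)
    clash_k: float = 10.0  # units / A^2
    contact_reward: float = -0.1  # units per contacting pair
    contact_margin: float = 1.5  # contact up to (ri + rj) + margin
    torsion_k: float = 0.01  # units / deg^2 per perturbed torsion


@dataclass(frozen=True)
class BiasSpec:
    target: ResidueSelector
    params: PocketParams = field(default_factory=PocketParams)
    weight: float = MODERATE_WEIGHT  # energy units per A^3, <= 0 when enabled
    enabled: bool = True

    def __post_init__(self):
        if self.enabled and self.weight > 0:
            raise ValueError("bias weight must be <= 0 when enabled (rewards volume)")

    @classmethod
    def moderate(cls, target: ResidueSelector, params: Optional[PocketParams] = None) -> "BiasSpec":
        return cls(target=target, params=params or PocketParams(), weight=MODERATE_WEIGHT)

    @classmethod
    def strong(cls, target: ResidueSelector, params: Optional[PocketParams] = None) -> "BiasSpec":
        return cls(target=target, params=params or PocketParams(), weight=STRONG_WEIGHT)

    @classmethod
    def none(cls, target: ResidueSelector, params: Optional[PocketParams] = None) -> "BiasSpec":
        return cls(target=target, params=params or PocketParams(), weight=0.0, enabled=False)


@dataclass
class EnergyBreakdown:
    base: float
    bias: float
    deep_volume: float

    @property
    def total(self) -> float:
        return self.base + self.bias


class EnergyEvaluator:
    """Reusable nonbonded evaluator for one atom topology.

    Precomputes residue/backbone metadata once so repeated evaluations
    (the MC sampler's hot loop) only rebuild the neighbor list.
    """

    def __init__(self, structure: Structure, config: Optional[EnergyConfig] = None):
        self.config = config or EnergyConfig()
        heavy = structure.heavy_atoms()
        self.heavy_index = [i for i, a in enumerate(structure.atoms) if not a.is_hydrogen]
        self.rad = np.array([a.vdw_radius for a in heavy])
        if np.any(self.rad <= 0):
            raise ValueError("heavy atoms without assigned radii; run assign_radii first")
        res_keys = {}
        self.res_id = np.empty(len(heavy), dtype=np.int64)
        self.res_num = np.array([a.residue_number for a in heavy], dtype=np.int64)
        chains = {}
        self.chain_id = np.empty(len(heavy), dtype=np.int64)
        self.no_icode = np.array([a.insertion_code == "" for a in heavy])
        self.is_bb = np.array([a.is_backbone for a in heavy])
        for i, a in enumerate(heavy):
            self.res_id[i] = res_keys.setdefault(a.residue_key, len(res_keys))
            self.chain_id[i] = chains.setdefault(a.chain_id, len(chains))
        self.cutoff = 2 * self.rad.max() + self.config.contact_margin

    def nonbonded(self, heavy_xyz: np.ndarray) -> float:
        cfg = self.config
        tree = cKDTree(heavy_xyz)
        pairs = tree.query_pairs(r=self.cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return 0.0
        i, j = pairs[:, 0], pairs[:, 1]
        same_res = self.res_id[i] == self.res_id[j]
        adjacent_bb = (
            (self.chain_id[i] == self.chain_id[j])
            & (np.abs(self.res_num[i] - self.res_num[j]) == 1)
            & self.no_icode[i]
            & self.no_icode[j]
            & self.is_bb[i]
            & self.is_bb[j]
        )
        keep = ~(same_res | adjacent_bb)
        i, j = i[keep], j[keep]
        d = np.linalg.norm(heavy_xyz[i] - heavy_xyz[j], axis=1)
        rsum = self.rad[i] + self.rad[j]
        lo = cfg.clash_factor * rsum
        clash = d < lo
        e = cfg.clash_k * float(((lo[clash] - d[clash]) ** 2).sum())
        contact = (~clash) & (d <= rsum + cfg.contact_margin)
        e += cfg.contact_reward * float(np.count_nonzero(contact))
        return e

    def clash_only(self, heavy_xyz: np.ndarray) -> float:
        """Just the soft-sphere clash term (used to count clash-free wells)."""
        saved = self.config
        self.config = EnergyConfig(
            clash_factor=saved.clash_factor,
            clash_k=saved.clash_k,
            contact_reward=0.0,
            contact_margin=saved.contact_margin,
            torsion_k=saved.torsion_k,
        )
        try:
            return self.nonbonded(heavy_xyz)
        finally:
            self.config = saved

    def energy(self, all_xyz: np.ndarray, torsion_deltas: Optional[dict] = None) -> float:
        e = self.nonbonded(all_xyz[self.heavy_index])
        if torsion_deltas:
            for delta in torsion_deltas.values():
                e += self.config.torsion_k * float(delta) ** 2
        return e

    def torsion_energy(self, torsion_deltas: Optional[dict]) -> float:
        if not torsion_deltas:
            return 0.0
        return self.config.torsion_k * float(sum(d * d for d in torsion_deltas.values()))

    def make_cross_evaluator(self, moving_atom_idx, all_xyz: np.ndarray):
        """Closure computing the moving-group <-> static nonbonded energy.

        Valid when every proposal moves exactly this (rigid) atom group:
        within-group and static-static terms are then constant, so energy
        differences reduce to this cross term. The static KD-tree is
        built once.
        """
        cfg = self.config
        pos_of = {ai: hi for hi, ai in enumerate(self.heavy_index)}
        mov_h = np.array(sorted(pos_of[i] for i in moving_atom_idx if i in pos_of), dtype=int)
        stat_h = np.setdiff1d(np.arange(len(self.rad)), mov_h)
        heavy_xyz = all_xyz[self.heavy_index]
        tree = cKDTree(heavy_xyz[stat_h])
        mov_atoms_all = np.array(sorted(moving_atom_idx), dtype=int)

        def cross(all_xyz_new: np.ndarray) -> float:
            mxyz = all_xyz_new[self.heavy_index][mov_h]
            neigh = tree.query_ball_point(mxyz, r=self.cutoff)
            mi = np.repeat(mov_h, [len(n) for n in neigh])
            if len(mi) == 0:
                return 0.0
            sj = stat_h[np.concatenate([np.asarray(n, dtype=int) for n in neigh if len(n)])]
            same_res = self.res_id[mi] == self.res_id[sj]
            adjacent_bb = (
                (self.chain_id[mi] == self.chain_id[sj])
                & (np.abs(self.res_num[mi] - self.res_num[sj]) == 1)
                & self.no_icode[mi]
                & self.no_icode[sj]
                & self.is_bb[mi]
                & self.is_bb[sj]
            )
            keep = ~(same_res | adjacent_bb)
            mi, sj = mi[keep], sj[keep]
            hx = all_xyz_new[self.heavy_index]
            d = np.linalg.norm(hx[mi] - hx[sj], axis=1)
            rsum = self.rad[mi] + self.rad[sj]
            lo = cfg.clash_factor * rsum
            clash = d < lo
            e = cfg.clash_k * float(((lo[clash] - d[clash]) ** 2).sum())
            contact = (~clash) & (d <= rsum + cfg.contact_margin)
            e += cfg.contact_reward * float(np.count_nonzero(contact))
            return e

        return cross, mov_atoms_all


def base_energy(
    structure: Structure,
    config: Optional[EnergyConfig] = None,
    torsion_deltas: Optional[dict] = None,
) -> float:
    """Simplified base energy (proxy units).

    clash:   sum over heavy-atom pairs with d < 0.8 (ri+rj) of
             k_clash (0.8 (ri+rj) - d)^2,     k_clash = 10 / A^2
    contact: -0.1 per pair with 0.8 (ri+rj) <= d <= (ri+rj) + 1.5 A
    torsion: 0.01 delta^2 per perturbed torsion (delta in degrees from
             the input structure; supplied by the sampler)

    Bonded pairs (same residue or sequence-adjacent backbone) are
    excluded from the clash and contact terms.
    """
    return EnergyEvaluator(structure, config).energy(structure.coords(), torsion_deltas)


def pocket_bias(structure: Structure, bias_spec: BiasSpec, volume: Optional[float] = None):
    """Bias energy = weight x deep pocket volume at the target (0 when
    disabled). Returns (bias, deep_volume). If `volume` is given it is
    used instead of re-running the detector (stale-volume support)."""
    if volume is None:
        volume = deep_pocket_volume(structure, bias_spec.target, bias_spec.params)
    if not bias_spec.enabled:
        return 0.0, volume
    return bias_spec.weight * volume, volume


def total_energy(
    structure: Structure,
    bias_spec: BiasSpec,
    config: Optional[EnergyConfig] = None,
    torsion_deltas: Optional[dict] = None,
) -> EnergyBreakdown:
    """Full breakdown: base + bias; components always re-sum to total."""
    base = base_energy(structure, config, torsion_deltas)
    bias, volume = pocket_bias(structure, bias_spec)
    return EnergyBreakdown(base=base, bias=bias, deep_volume=volume)
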