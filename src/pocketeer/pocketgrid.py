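"""Target-restricted grid pocket detection.

A cubic grid is centered on a target residue, points are labeled
protein/surface/solvent, scan lines in a fixed direction set count
surface-solvent-surface events, event-rich solvent points become pocket
candidates, and candidates are split into surface-pocket vs deep-pocket
by Euclidean distance to bulk solvent. Connected components of pocket
points are reported with their deep volumes.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np
from scipy import ndimage

from .structio import ResidueSelector, Structure, resolve_selector

__all__ = [
    "Label",
    "GridSpec",
    "LabeledGrid",
    "PocketParams",
    "Pocket",
    "PocketSet",
    "TargetBuriedError",
    "build_grid",
    "scan_sss",
    "mark_pockets",
    "cluster_pockets",
    "detect_pockets",
    "deep_pocket_volume",
    "pocket_points_as_pdb",
]


class Label(IntEnum):
    SOLVENT = 0
    PROTEIN = 1
    SURFACE = 2
    SURFACE_POCKET = 3
    DEEP_POCKET = 4


class TargetBuriedError(RuntimeError):
    """Target residue has no surface point within contact_radius."""


# 3 axes + 4 body diagonals (default); the 13-set adds the 6 face diagonals.
DIRECTIONS_7 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)
DIRECTIONS_13 = DIRECTIONS_7 + (
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
)


@dataclass(frozen=True)
class PocketParams:
    """Detector parameters. Defaults: 1.0 A grid, 12 A span cap, 2.5 A
    deep cutoff, >=2 scan events per pocket point, 26-connectivity,
    7 scan directions, 4.0 A target-contact radius."""

    spacing: float = 1.0
    max_span: float = 12.0
    deep_cutoff: float = 2.5
    min_events: int = 2
    connectivity: int = 26
    directions: int = 7
    contact_radius: float = 4.0
    capture_radius: float = 18.0
    padding: float = 4.0

    def __post_init__(self):
        if self.spacing <= 0 or self.max_span <= 0 or self.deep_cutoff <= 0:
            raise ValueError("spacing, max_span and deep_cutoff must be positive")
        if self.max_span < 2 * self.spacing:
            raise ValueError("max_span must be at least 2 x spacing")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.directions not in (7, 13):
            raise ValueError("directions must be 7 or 13")
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")
        if self.contact_radius <= 0 or self.capture_radius <= 0 or self.padding < 0:
            raise ValueError("radii must be positive")

    @property
    def direction_set(self) -> tuple:
        return DIRECTIONS_7 if self.directions == 7 else DIRECTIONS_13

    def replace(self, **kw) -> "PocketParams":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass
class GridSpec:
    origin: np.ndarray  # coordinate of grid index (0,0,0), A
    spacing: float
    dims: tuple  # (nx, ny, nz)
    extent_rule: str = ""

    def point_coords(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def all_coords(self) -> np.ndarray:
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.point_coords(idx)

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz


@dataclass
class LabeledGrid:
    spec: GridSpec
    label: np.ndarray  # int8 array, shape dims
    event_count: np.ndarray  # int32 array, shape dims

    def volume_of(self, lab: Label) -> float:
        return float(np.count_nonzero(self.label == lab)) * self.spec.spacing**3


@dataclass
class Pocket:
    point_indices: np.ndarray  # (n, 3) int grid indices
    deep_point_indices: np.ndarray  # (m, 3) subset
    total_volume: float
    deep_volume: float
    contacts_target: bool
    lining_atoms: list

    @property
    def n_points(self) -> int:
        return len(self.point_indices)


@dataclass
class PocketSet:
    pockets: list
    params: PocketParams
    target: ResidueSelector

    def __len__(self) -> int:
        return len(self.pockets)

    def largest_contacting(self) -> Optional[Pocket]:
        for p in self.pockets:
            if p.contacts_target:
                return p
        return None


def _grid_geometry_xyz(coords: np.ndarray, radii: np.ndarray, target_xyz: np.ndarray,
                       params: PocketParams, label: str = "") -> GridSpec:
    """Cube centered on the target-residue heavy-atom centroid, covering
    every heavy atom (center + vdW extent) within capture_radius of the
    centroid, plus padding. Shared arithmetic: the brute-force oracle
    replicates this independently."""
    centroid = np.mean(target_xyz, axis=0)
    if np.any(radii <= 0):
        raise ValueError("heavy atoms without assigned vdW radii; run assign_radii first")
    dist = np.linalg.norm(coords - centroid, axis=1)
    captured = dist <= params.capture_radius
    if not np.any(captured):
        captured = dist == dist.min()
    extent = np.max(
        np.abs(coords[captured] - centroid).max(axis=1) + radii[captured]
    )
    half = float(extent) + params.padding
    n_half = int(np.ceil(half / params.spacing))
    n = 2 * n_half + 1
    origin = centroid - n_half * params.spacing
    return GridSpec(
        origin=origin,
        spacing=params.spacing,
        dims=(n, n, n),
        extent_rule=(
            f"cube centered on target {label} centroid, half-width "
            f"max(atom extent within {params.capture_radius} A) + {params.padding} A"
        ),
    )


def _build_grid_xyz(coords: np.ndarray, radii: np.ndarray, target_xyz: np.ndarray,
                    params: PocketParams, label: str = "") -> LabeledGrid:
    spec = _grid_geometry_xyz(coords, radii, target_xyz, params, label)
    nx, ny, nz = spec.dims
    occupied = np.zeros(spec.dims, dtype=bool)
    s = spec.spacing
    occ_flat = occupied.ravel()
    dims_arr = np.array(spec.dims)
    # only atoms whose vdW sphere can reach the box matter
    box_lo = spec.origin
    box_hi = spec.origin + (dims_arr - 1) * s
    reach = (coords + radii[:, None] >= box_lo) & (coords - radii[:, None] <= box_hi)
    in_reach = np.all(reach, axis=1)
    coords = coords[in_reach]
    radii = radii[in_reach]
    # process atoms in same-radius batches: one fixed index window per
    # batch, with separable per-axis distance terms
    for r in np.unique(radii):
        batch = coords[radii == r]
        w = int(np.ceil(r / s))
        off = np.arange(-w, w + 1)
        centers = np.rint((batch - spec.origin) / s).astype(np.int64)  # (n, 3)
        ax_i = centers[:, 0:1] + off  # (n, m)
        ax_j = centers[:, 1:2] + off
        ax_k = centers[:, 2:3] + off
        d2x = (spec.origin[0] + ax_i * s - batch[:, 0:1]) ** 2
        d2y = (spec.origin[1] + ax_j * s - batch[:, 1:2]) ** 2
        d2z = (spec.origin[2] + ax_k * s - batch[:, 2:3]) ** 2
        vx = (ax_i >= 0) & (ax_i < nx)
        vy = (ax_j >= 0) & (ax_j < ny)
        vz = (ax_k >= 0) & (ax_k < nz)
        d2 = (
            d2x[:, :, None, None] + d2y[:, None, :, None] + d2z[:, None, None, :]
        )
        hit = (
            (d2 <= r * r)
            & vx[:, :, None, None]
            & vy[:, None, :, None]
            & vz[:, None, None, :]
        )
        if np.any(hit):
            flat = (
                ax_i[:, :, None, None] * (ny * nz)
                + ax_j[:, None, :, None] * nz
                + ax_k[:, None, None, :]
            )
            occ_flat[flat[hit]] = True
    occupied = occ_flat.reshape(spec.dims)

    label = np.where(occupied, np.int8(Label.PROTEIN), np.int8(Label.SOLVENT))
    solvent = ~occupied
    near_solvent = ndimage.binary_dilation(solvent, structure=np.ones((3, 3, 3), dtype=bool))
    label[occupied & near_solvent] = Label.SURFACE

    grid = LabeledGrid(spec=spec, label=label, event_count=np.zeros(spec.dims, dtype=np.int32))
    _check_target_on_surface(grid, target_xyz, params)
    return grid


def build_grid(structure: Structure, target: ResidueSelector, params: PocketParams) -> LabeledGrid:
    """Label grid points PROTEIN / SURFACE / SOLVENT around the target.

    A point is PROTEIN if it lies within the vdW radius of any heavy atom;
    PROTEIN points with a SOLVENT 26-neighbor are relabeled SURFACE.
    Raises TargetBuriedError if no SURFACE point lies within
    contact_radius of a target heavy atom.
    """
    target_atoms = resolve_selector(structure, target)
    target_xyz = np.array([a.coords for a in target_atoms])
    return _build_grid_xyz(
        structure.heavy_coords(), structure.heavy_radii(), target_xyz, params, str(target)
    )


def _check_target_on_surface(grid: LabeledGrid, target_xyz: np.ndarray, params: PocketParams) -> None:
    surf_idx = np.argwhere(grid.label == Label.SURFACE)
    if len(surf_idx) == 0:
        raise TargetBuriedError("target not on surface (no surface points in box)")
    surf_xyz = grid.spec.point_coords(surf_idx)
    d2 = ((surf_xyz[:, None, :] - target_xyz[None, :, :]) ** 2).sum(axis=2)
    if not np.any(d2 <= params.contact_radius**2):
        raise TargetBuriedError("target not on surface")


@functools.lru_cache(maxsize=64)
def _scan_lines(dims: tuple, direction: tuple):
    """Concatenated flat indices of every scan line for one direction,
    separated by -1 sentinels. Cached per (dims, direction)."""
    nx, ny, nz = dims
    d = np.array(direction)
    starts = []
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    prev = pts - d
    outside = (
        (prev[:, 0] < 0) | (prev[:, 0] >= nx)
        | (prev[:, 1] < 0) | (prev[:, 1] >= ny)
        | (prev[:, 2] < 0) | (prev[:, 2] >= nz)
    )
    starts = pts[outside]
    chunks = []
    dims_arr = np.array(dims)
    for p0 in starts:
        # walk until leaving the box
        n_steps_axis = np.full(3, np.iinfo(np.int64).max, dtype=np.int64)
        for ax in range(3):
            if d[ax] > 0:
                n_steps_axis[ax] = dims_arr[ax] - p0[ax]
            elif d[ax] < 0:
                n_steps_axis[ax] = p0[ax] + 1
        length = int(n_steps_axis.min())
        steps = np.arange(length)
        line = p0[None, :] + steps[:, None] * d[None, :]
        flat = np.ravel_multi_index((line[:, 0], line[:, 1], line[:, 2]), dims)
        chunks.append(flat)
        chunks.append(np.array([-1], dtype=flat.dtype))
    return np.concatenate(chunks) if chunks else np.array([-1], dtype=np.int64)


def scan_sss(grid: LabeledGrid, params: PocketParams) -> LabeledGrid:
    """Count surface-solvent-surface events per solvent point.

    For every scan line, each maximal run of SOLVENT points flanked on
    both ends by SURFACE points with flank-to-flank Euclidean length
    <= max_span increments the run points' event_count by 1. Runs
    touching the box boundary never count (they lack a flank).
    """
    label_flat = grid.label.ravel()
    events_flat = np.zeros(label_flat.shape, dtype=np.int32)
    s = grid.spec.spacing
    for d in params.direction_set:
        cat = _scan_lines(grid.spec.dims, d)
        step_len = s * float(np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2))
        lab = np.where(cat >= 0, label_flat[np.maximum(cat, 0)], np.int8(-1))
        is_sol = lab == Label.SOLVENT
        padded = np.concatenate([[False], is_sol, [False]])
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.nonzero(diff == 1)[0]
        run_ends = np.nonzero(diff == -1)[0]  # exclusive
        if len(run_starts) == 0:
            continue
        left_ok = run_starts > 0
        right_ok = run_ends < len(lab)
        left_lab = np.where(left_ok, lab[np.maximum(run_starts - 1, 0)], np.int8(-1))
        right_lab = np.where(right_ok, lab[np.minimum(run_ends, len(lab) - 1)], np.int8(-1))
        run_len = run_ends - run_starts
        span = (run_len + 1) * step_len  # flank surface point to flank surface point
        good = (left_lab == Label.SURFACE) & (right_lab == Label.SURFACE) & (span <= params.max_span)
        if not np.any(good):
            continue
        inc = np.zeros(len(lab) + 1, dtype=np.int32)
        np.add.at(inc, run_starts[good], 1)
        np.add.at(inc, run_ends[good], -1)
        inc = np.cumsum(inc[:-1])
        sel = inc > 0
        np.add.at(events_flat, cat[sel], inc[sel])
    grid.event_count = events_flat.reshape(grid.spec.dims)
    return grid


def mark_pockets(grid: LabeledGrid, params: PocketParams) -> LabeledGrid:
    """Relabel event-rich solvent points as SURFACE_POCKET / DEEP_POCKET.

    Candidates are SOLVENT points with event_count >= min_events. A
    candidate within deep_cutoff (Euclidean, point-to-point) of any
    remaining bulk SOLVENT point is SURFACE_POCKET; the rest DEEP_POCKET.
    """
    cand = (grid.label == Label.SOLVENT) & (grid.event_count >= params.min_events)
    if not np.any(cand):
        return grid
    bulk = (grid.label == Label.SOLVENT) & ~cand
    if not np.any(bulk):
        grid.label[cand] = Label.DEEP_POCKET
        return grid
    # exact Euclidean distance (in index units) to nearest bulk voxel;
    # squared distances are integers, so compare in integer space
    edt = ndimage.distance_transform_edt(~bulk)
    d2_int = np.rint(edt**2).astype(np.int64)
    cutoff2 = params.deep_cutoff**2 / params.spacing**2
    near_bulk = d2_int.astype(float) <= cutoff2
    grid.label[cand & near_bulk] = Label.SURFACE_POCKET
    grid.label[cand & ~near_bulk] = Label.DEEP_POCKET
    return grid


def cluster_pockets(
    grid: LabeledGrid,
    structure: Structure,
    target: ResidueSelector,
    params: PocketParams,
) -> PocketSet:
    """Connected components of pocket points, sorted by deep volume.

    contacts_target: any pocket point within contact_radius of a target
    heavy atom. lining_atoms: atoms whose center lies within
    (vdw_radius + spacing) of a pocket point.
    """
    pocket_mask = (grid.label == Label.SURFACE_POCKET) | (grid.label == Label.DEEP_POCKET)
    if not np.any(pocket_mask):
        return PocketSet(pockets=[], params=params, target=target)
    if params.connectivity == 26:
        conn = np.ones((3, 3, 3), dtype=bool)
    else:
        conn = ndimage.generate_binary_structure(3, 1)
    comp, n_comp = ndimage.label(pocket_mask, structure=conn)
    target_atoms = resolve_selector(structure, target)
    t_xyz = np.array([a.coords for a in target_atoms])
    heavy = structure.heavy_atoms()
    h_xyz = structure.heavy_coords()
    h_rad = structure.heavy_radii()
    s3 = params.spacing**3

    pockets = []
    for c in range(1, n_comp + 1):
        idx = np.argwhere(comp == c)
        labs = grid.label[idx[:, 0], idx[:, 1], idx[:, 2]]
        deep_idx = idx[labs == Label.DEEP_POCKET]
        xyz = grid.spec.point_coords(idx)
        d2t = ((xyz[:, None, :] - t_xyz[None, :, :]) ** 2).sum(axis=2)
        contacts = bool(np.any(d2t <= params.contact_radius**2))
        d2a = ((h_xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        lining = [heavy[i] for i in np.nonzero(d2a <= (h_rad + params.spacing) ** 2)[0]]
        flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid.spec.dims)
        pockets.append(
            (
                Pocket(
                    point_indices=idx,
                    deep_point_indices=deep_idx,
                    total_volume=len(idx) * s3,
                    deep_volume=len(deep_idx) * s3,
                    contacts_target=contacts,
                    lining_atoms=lining,
                ),
                int(flat.min()),
            )
        )
    pockets.sort(key=lambda pf: (-pf[0].deep_volume, -pf[0].total_volume, pf[1]))
    return PocketSet(pockets=[p for p, _ in pockets], params=params, target=target)


def detect_pockets(
    structure: Structure, target: ResidueSelector, params: Optional[PocketParams] = None
) -> PocketSet:
    """Full pipeline: build grid, scan, mark, cluster."""
    params = params or PocketParams()
    grid = build_grid(structure, target, params)
    grid = scan_sss(grid, params)
    grid = mark_pockets(grid, params)
    return cluster_pockets(grid, structure, target, params)


def deep_pocket_volume(
    structure: Structure, target: ResidueSelector, params: Optional[PocketParams] = None
) -> float:
    """Deep volume (A^3) of the largest deep-volume pocket in contact with
    the target residue; 0 if no contacting pocket exists."""
    pocket = detect_pockets(structure, target, params).largest_contacting()
    return pocket.deep_volume if pocket is not None else 0.0


def deep_volume_xyz(
    heavy_xyz: np.ndarray,
    heavy_rad: np.ndarray,
    target_xyz: np.ndarray,
    params: Optional[PocketParams] = None,
) -> float:
    """Array-level deep_pocket_volume (no Structure objects, no lining
    atoms): the sampler's hot path. Produces the same value as
    deep_pocket_volume on the corresponding structure."""
    params = params or PocketParams()
    grid = _build_grid_xyz(heavy_xyz, heavy_rad, target_xyz, params)
    grid = scan_sss(grid, params)
    grid = mark_pockets(grid, params)
    pocket_mask = (grid.label == Label.SURFACE_POCKET) | (grid.label == Label.DEEP_POCKET)
    if not np.any(pocket_mask):
        return 0.0
    if params.connectivity == 26:
        conn = np.ones((3, 3, 3), dtype=bool)
    else:
        conn = ndimage.generate_binary_structure(3, 1)
    comp, n_comp = ndimage.label(pocket_mask, structure=conn)
    # components with a point within contact_radius of a target atom
    idx = np.argwhere(pocket_mask)
    xyz = grid.spec.point_coords(idx)
    d2 = ((xyz[:, None, :] - target_xyz[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    near = d2 <= params.contact_radius**2
    if not np.any(near):
        return 0.0
    comp_ids = np.unique(comp[idx[near, 0], idx[near, 1], idx[near, 2]])
    deep = grid.label == Label.DEEP_POCKET
    s3 = params.spacing**3
    best = 0.0
    for c in comp_ids:
        v = float(np.count_nonzero(deep & (comp == c))) * s3
        best = max(best, v)
    return best


def pocket_points_as_pdb(grid: LabeledGrid, deep_only: bool = False) -> str:
    """Pocket grid points as HETATM pseudo-atoms (resname PKT) for viewing."""
    labs = [Label.DEEP_POCKET] if deep_only else [Label.SURFACE_POCKET, Label.DEEP_POCKET]
    lines = []
    serial = 1
    for lab in labs:
        for idx in np.argwhere(grid.label == lab):
            x, y, z = grid.spec.point_coords(idx)
            deep = "D" if lab == Label.DEEP_POCKET else "S"
            lines.append(
                f"HETATM{serial:>5d}  PK{deep} PKT P   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{'C':>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
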