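"""Brute-force reference labeling.

Same contract as build_grid -> scan_sss -> mark_pockets, computed by
naive enumeration: full point x atom distance matrices for occupancy,
explicit neighbor loops for surface labeling, explicit line walking with
a run state machine for the scan, and all-pairs candidate/bulk distances
for the deep split. Written independently of the optimized path so the
two can be compared bit-for-bit; restricted to grids of <= 40^3 points.
"""

from __future__ import annotations

import numpy as np

from .pocketgrid import (
    DIRECTIONS_7,
    DIRECTIONS_13,
    GridSpec,
    Label,
    LabeledGrid,
    PocketParams,
    TargetBuriedError,
)
from .structio import ResidueSelector, Structure, resolve_selector

__all__ = ["brute_force_labels", "GridTooLargeError", "MAX_POINTS"]

MAX_POINTS = 40**3


class GridTooLargeError(ValueError):
    pass


def brute_force_labels(
    structure: Structure, target: ResidueSelector, params: PocketParams
) -> LabeledGrid:
    target_atoms = resolve_selector(structure, target)
    centroid = np.mean([a.coords for a in target_atoms], axis=0)
    coords = structure.heavy_coords()
    radii = structure.heavy_radii()
    if np.any(radii <= 0):
        raise ValueError("heavy atoms without assigned vdW radii; run assign_radii first")
    dist = np.linalg.norm(coords - centroid, axis=1)
    captured = dist <= params.capture_radius
    if not np.any(captured):
        captured = dist == dist.min()
    extent = np.max(np.abs(coords[captured] - centroid).max(axis=1) + radii[captured])
    half = float(extent) + params.padding
    n_half = int(np.ceil(half / params.spacing))
    n = 2 * n_half + 1
    if n**3 > MAX_POINTS:
        raise GridTooLargeError(f"grid {n}^3 exceeds {MAX_POINTS} points")
    origin = centroid - n_half * params.spacing
    s = params.spacing

    # --- occupancy: every point against every atom ------------------------
    ax_x = origin[0] + np.arange(n) * s
    ax_y = origin[1] + np.arange(n) * s
    ax_z = origin[2] + np.arange(n) * s
    label = np.full((n, n, n), int(Label.SOLVENT), dtype=np.int8)
    occupied = np.zeros((n, n, n), dtype=bool)
    for (atx, aty, atz), r in zip(coords, radii):
        d2 = (
            ((ax_x - atx) ** 2)[:, None, None]
            + ((ax_y - aty) ** 2)[None, :, None]
            + ((ax_z - atz) ** 2)[None, None, :]
        )
        occupied |= d2 <= r * r
    label[occupied] = Label.PROTEIN

    # --- surface: protein point with >=1 solvent 26-neighbor --------------
    surface = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if label[i, j, k] != Label.PROTEIN:
                    continue
                found = False
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            if di == dj == dk == 0:
                                continue
                            ii, jj, kk = i + di, j + dj, k + dk
                            if 0 <= ii < n and 0 <= jj < n and 0 <= kk < n:
                                if label[ii, jj, kk] == Label.SOLVENT:
                                    found = True
                if found:
                    surface.append((i, j, k))
    for pt in surface:
        label[pt] = Label.SURFACE

    # --- target-on-surface check ------------------------------------------
    on_surface = False
    t_xyz = [a.coords for a in target_atoms]
    for i, j, k in surface:
        px, py, pz = origin[0] + i * s, origin[1] + j * s, origin[2] + k * s
        for t in t_xyz:
            d2 = (px - t[0]) ** 2 + (py - t[1]) ** 2 + (pz - t[2]) ** 2
            if d2 <= params.contact_radius**2:
                on_surface = True
    if not on_surface:
        raise TargetBuriedError("target not on surface")

    # --- scan: walk every line in every direction --------------------------
    dirs = DIRECTIONS_7 if params.directions == 7 else DIRECTIONS_13
    events = np.zeros((n, n, n), dtype=np.int32)
    for d in dirs:
        step_len = s * float(np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2))
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    prev = (i - d[0], j - d[1], k - d[2])
                    if all(0 <= prev[ax] < n for ax in range(3)):
                        continue  # not a line start
                    line = []
                    p = (i, j, k)
                    while all(0 <= p[ax] < n for ax in range(3)):
                        line.append(p)
                        p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                    labs = [int(label[pt]) for pt in line]
                    m = len(line)
                    idx = 0
                    while idx < m:
                        if labs[idx] != Label.SOLVENT:
                            idx += 1
                            continue
                        start = idx
                        while idx < m and labs[idx] == Label.SOLVENT:
                            idx += 1
                        end = idx  # exclusive
                        left_ok = start > 0 and labs[start - 1] == Label.SURFACE
                        right_ok = end < m and labs[end] == Label.SURFACE
                        if left_ok and right_ok:
                            span = (end - start + 1) * step_len
                            if span <= params.max_span:
                                for t in range(start, end):
                                    events[line[t]] += 1

    # --- pocket marking: candidate vs bulk min distance --------------------
    candidates = []
    bulk = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if label[i, j, k] == Label.SOLVENT:
                    if events[i, j, k] >= params.min_events:
                        candidates.append((i, j, k))
                    else:
                        bulk.append((i, j, k))
    cutoff2 = params.deep_cutoff**2 / params.spacing**2
    bulk_arr = np.array(bulk, dtype=np.int64) if bulk else None
    for c in candidates:
        if bulk_arr is not None:
            diff = bulk_arr - np.array(c, dtype=np.int64)
            d2min = int((diff * diff).sum(axis=1).min())
            deep = float(d2min) > cutoff2
        else:
            deep = True
        label[c] = Label.DEEP_POCKET if deep else Label.SURFACE_POCKET

    spec = GridSpec(origin=origin, spacing=s, dims=(n, n, n), extent_rule="brute force")
    return LabeledGrid(spec=spec, label=label, event_count=events)
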