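"""Per-snapshot tunnel detection and minimal ("bottleneck") radius.

The gorge radius of a snapshot is defined by the widest path: over a 3-D
grid covering the structure plus a margin, find the path from an interior
start point to the bulk solvent that maximizes its minimum clearance
(distance to the nearest van der Waals surface). The bottleneck of that
path is the radius R of the largest spherical probe that can traverse the
gorge.

The maximal bottleneck is computed by bisection over the clearance
threshold with 26-connected component labelling (``scipy.ndimage.label``):
a probe of radius c can pass iff the start connects to an exposed grid
point through cells of clearance ≥ c, and the widest-path bottleneck is
the largest such c. An explicit path achieving the bottleneck is then
recovered by breadth-first search inside the supra-threshold region. The
test suite cross-checks this against an independent pure-Python widest-path
Dijkstra on small grids.

Probe semantics follow tunnel-detection conventions for channel enzymes:
an inner probe radius for the cavity search, an outer probe radius that
defines bulk-solvent exposure, a minimum tunnel radius below which the
gorge is reported "closed", and a shell radius that keeps surface pockets
from counting as bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InputError, SelectionError, TopologyError
from .radstats import RadiusSeries
from .structio import StructureModel, TrajectoryEnsemble, select

__all__ = [
    "ProbeParams",
    "TunnelProfile",
    "clearance",
    "find_start_point",
    "compute_tunnel",
    "radius_series",
    "bottleneck_distance",
]

# 26-neighbour offsets in lexicographic (dk, dj, di) order for determinism
_OFFSETS = np.array(
    [(dk, dj, di)
     for dk in (-1, 0, 1) for dj in (-1, 0, 1) for di in (-1, 0, 1)
     if (dk, dj, di) != (0, 0, 0)],
    dtype=int,
)
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ProbeParams:
    """Probe and grid parameters for the tunnel search (all lengths in Å)."""

    inner_probe: float = 1.4
    outer_probe: float = 3.0
    min_radius: float = 0.9       # below this the gorge counts as closed
    shell_radius: float = 5.0
    shell_depth: float = 10.0
    grid_spacing: float = 0.5
    start_hint: np.ndarray | None = None
    seed: int = 1
    clustering_threshold: float = 4.5   # accepted for config compatibility; unused
    hint_search_radius: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_probe < self.outer_probe:
            raise InputError("need 0 < inner probe < outer probe")
        if self.min_radius <= 0:
            raise InputError("minimum tunnel radius must be positive")
        if self.grid_spacing > self.min_radius:
            raise InputError("grid spacing must not exceed the minimum radius")


@dataclass
class TunnelProfile:
    """One snapshot's best tunnel: path, clearances, bottleneck radius."""

    path: np.ndarray              # (n_points, 3) Å, start → surface
    clearances: np.ndarray        # clearance at each path point
    min_radius: float             # R: bottleneck clearance of the path
    status: str                   # "open" | "closed"
    time_ns: float = 0.0
    chain: str = "A"


class _ClearanceField:
    """min over atoms of (distance − vdW radius), via one KD-tree per radius class."""

    def __init__(self, coords: np.ndarray, vdw: np.ndarray):
        if len(coords) == 0:
            raise InputError("empty structure")
        self._classes = []
        for r in np.unique(vdw):
            pts = coords[vdw == r]
            self._classes.append((float(r), cKDTree(pts)))

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(clearance, distance to nearest atom center) for each point."""
        points = np.atleast_2d(points)
        clear = np.full(len(points), np.inf)
        dist = np.full(len(points), np.inf)
        for r, tree in self._classes:
            d, _ = tree.query(points, k=1)
            clear = np.minimum(clear, d - r)
            dist = np.minimum(dist, d)
        return clear, dist


def clearance(point: np.ndarray, model: StructureModel) -> float:
    """Clearance of a point: min over atoms of (distance − vdW radius).

    Negative inside an atom's van der Waals sphere.
    """
    field = _ClearanceField(model.coords, model.vdw)
    return float(field.query(np.asarray(point, dtype=float))[0][0])


@dataclass
class _Grid:
    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]

    def points(self) -> np.ndarray:
        ax = [self.origin[d] + self.spacing * np.arange(self.shape[d])
              for d in range(3)]
        kk, jj, ii = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
        return np.stack([kk.ravel(), jj.ravel(), ii.ravel()], axis=1)

    def point(self, idx: tuple[int, int, int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx)


def _build_grid(model: StructureModel, params: ProbeParams) -> _Grid:
    margin = params.shell_radius + 2 * params.grid_spacing
    lo = model.coords.min(axis=0) - margin
    hi = model.coords.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / params.grid_spacing)) + 1
                  for d in range(3))
    return _Grid(origin=lo, spacing=params.grid_spacing, shape=shape)


def find_start_point(
    model: StructureModel, params: ProbeParams, hint: np.ndarray | None = None,
) -> np.ndarray:
    """Grid point near the hint with maximal clearance.

    Searches grid points within ``hint_search_radius`` of the hint and
    returns the one of largest clearance; ties break on lexicographic grid
    index. Raises if even the best point cannot host the minimum tunnel
    radius ("no cavity at hint").
    """
    hint = np.asarray(params.start_hint if hint is None else hint, dtype=float)
    if hint is None or hint.size != 3:
        raise InputError("a 3-D start-point hint is required")
    grid = _build_grid(model, params)
    pts = grid.points()
    near = np.flatnonzero(
        np.linalg.norm(pts - hint, axis=1) <= params.hint_search_radius
    )
    if near.size == 0:
        raise InputError("hint lies outside the analysis grid")
    clear, _ = _ClearanceField(model.coords, model.vdw).query(pts[near])
    best = near[np.argmax(clear)]   # argmax returns first max: lexicographic tie-break
    if clear.max() < params.min_radius:
        raise InputError(
            f"no cavity at hint: best clearance {clear.max():.2f} Å < "
            f"minimum tunnel radius {params.min_radius} Å"
        )
    return pts[best]


def _bulk_mask(dist: np.ndarray, shape, shell_radius: float) -> np.ndarray:
    """Bulk-solvent cells: beyond the shell radius AND connected to the box boundary.

    The molecular shell is the region within ``shell_radius`` of any atom
    center; interior cavities whose shell-free pockets do not reach the
    grid boundary are not bulk, which keeps a wide internal chamber from
    terminating the tunnel search.
    """
    free = (dist >= shell_radius).reshape(shape)
    labels, _ = ndimage.label(free, structure=_STRUCT26)
    boundary = np.unique(np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
    ]))
    boundary = boundary[boundary != 0]
    return np.isin(labels, boundary).ravel()


def _connects(region_flat: np.ndarray, shape, start_flat: int,
              outside_flat: np.ndarray) -> bool:
    labels, _ = ndimage.label(region_flat.reshape(shape), structure=_STRUCT26)
    lab = labels.ravel()
    s = lab[start_flat]
    if s == 0:
        return False
    return bool(np.any(lab[outside_flat] == s))


def _bfs_path(region: np.ndarray, shape, start_idx: np.ndarray,
              outside_flat: set[int]) -> list[int]:
    """Deterministic BFS inside ``region``; returns flat indices start → exit."""
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    start_flat = int(start_idx @ strides)
    pred = {start_flat: -1}
    frontier = np.array([start_flat])
    hit = start_flat if start_flat in outside_flat else None
    while frontier.size and hit is None:
        coords = np.stack(np.unravel_index(frontier, shape), axis=1)
        nb = coords[:, None, :] + _OFFSETS[None, :, :]
        src = np.repeat(frontier, len(_OFFSETS))
        nb = nb.reshape(-1, 3)
        ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        nb, src = nb[ok], src[ok]
        nb_flat = nb @ strides
        ok = region[nb_flat]
        nb_flat, src = nb_flat[ok], src[ok]
        order = np.argsort(nb_flat, kind="stable")
        nb_flat, src = nb_flat[order], src[order]
        keep = np.ones(len(nb_flat), dtype=bool)
        keep[1:] = nb_flat[1:] != nb_flat[:-1]     # first (lowest-src) discoverer
        nxt = []
        for f, s in zip(nb_flat[keep], src[keep]):
            f = int(f)
            if f in pred:
                continue
            pred[f] = int(s)
            nxt.append(f)
            if f in outside_flat:
                hit = f
        frontier = np.array(sorted(nxt), dtype=int)
    if hit is None:
        raise TopologyError("no surface-reachable path from the start point")
    path = []
    node = hit
    while node != -1:
        path.append(node)
        node = pred[node]
    return path[::-1]


def compute_tunnel(
    model: StructureModel, params: ProbeParams, hint: np.ndarray | None = None,
) -> TunnelProfile:
    """Widest path from the start point to bulk solvent; R is its bottleneck.

    A grid point counts as bulk-exposed when its clearance is at least the
    outer probe radius and it lies in the boundary-connected region beyond
    the molecular shell (no atom center within the shell radius).
    If the maximal bottleneck falls below the minimum tunnel radius the
    profile is flagged "closed", with R reporting the best achievable
    bottleneck.
    """
    start = find_start_point(model, params, hint)
    grid = _build_grid(model, params)
    shape = grid.shape
    pts = grid.points()
    clear, dist = _ClearanceField(model.coords, model.vdw).query(pts)
    outside = (clear >= params.outer_probe) & _bulk_mask(
        dist, shape, params.shell_radius
    )
    outside_flat = np.flatnonzero(outside)
    if outside_flat.size == 0:
        raise TopologyError("no bulk-exposed grid points: start is fully occluded")

    start_idx = np.rint((start - grid.origin) / grid.spacing).astype(int)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    start_flat = int(start_idx @ strides)

    # Maximal bottleneck: largest clearance threshold at which the start
    # still connects to an exposed point. Monotone in the threshold, so
    # bisect over the sorted unique clearance values.
    cap = min(clear[start_flat], clear[outside_flat].max())
    vals = np.unique(clear[clear <= cap + 1e-12])
    lo, hi = 0, len(vals) - 1
    if not _connects(clear >= vals[0], shape, start_flat, outside_flat):
        raise TopologyError("no surface-reachable path from the start point")
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _connects(clear >= vals[mid], shape, start_flat, outside_flat):
            lo = mid
        else:
            hi = mid - 1
    bottleneck = float(vals[lo])

    region = clear >= vals[lo]
    path_flat = _bfs_path(region, shape, start_idx, set(map(int, outside_flat)))
    path_pts = pts[path_flat]
    path_clear = clear[path_flat]
    status = "open" if bottleneck >= params.min_radius else "closed"
    return TunnelProfile(
        path=path_pts, clearances=path_clear,
        min_radius=float(path_clear.min()), status=status,
    )


def radius_series(
    traj: TrajectoryEnsemble,
    params: ProbeParams,
    hints: dict[str, np.ndarray] | np.ndarray | None = None,
) -> dict[str, RadiusSeries]:
    """One bottleneck radius per snapshot per chain.

    ``hints`` maps chain id → start-point hint (or a single hint applied to
    chain "A" alone). Per-snapshot failures are recorded as missing values
    with a status flag, never dropped.
    """
    if hints is None:
        if params.start_hint is None:
            raise InputError("a start-point hint is required")
        hints = {"A": np.asarray(params.start_hint, dtype=float)}
    if not isinstance(hints, dict):
        hints = {"A": np.asarray(hints, dtype=float)}
    out: dict[str, RadiusSeries] = {}
    for chain, hint in hints.items():
        values = np.full(traj.n_frames, np.nan)
        status: list[str] = []
        for t in range(traj.n_frames):
            snap = traj.frame(t)
            try:
                prof = compute_tunnel(snap, params, hint)
                status.append(prof.status)
                if prof.min_radius > 0:
                    values[t] = prof.min_radius
            except (InputError, TopologyError) as exc:
                status.append(f"error: {exc}")
        out[chain] = RadiusSeries(
            values=values, times_ns=traj.times_ns.copy(), chain=chain,
            status=tuple(status),
        )
    return out


def bottleneck_distance(
    snapshot: StructureModel,
    res_a: int = 330, atom_a: str = "CE2",
    res_b: int = 121, atom_b: str = "OH",
    chain: str | None = None,
) -> float:
    """Distance between two named bottleneck atoms (default Cε2 of F330 and OH of Y121)."""
    suffix = f" and chain {chain}" if chain is not None else ""
    ia = select(snapshot, f"resid {res_a} and name {atom_a}" + suffix)
    ib = select(snapshot, f"resid {res_b} and name {atom_b}" + suffix)
    if len(ia) != 1 or len(ib) != 1:
        raise SelectionError(
            f"bottleneck atoms not uniquely present: "
            f"{res_a}/{atom_a} matched {len(ia)}, {res_b}/{atom_b} matched {len(ib)}"
        )
    return float(np.linalg.norm(snapshot.coords[ia[0]] - snapshot.coords[ib[0]]))
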