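"""Tunnel search: clearance geometry, widest-path bottleneck, oracles.

The independent oracle is a pure-Python widest-path Dijkstra (max-heap on
the running minimum clearance) over the same grid; the implementation
itself finds the bottleneck by threshold bisection with connected-component
labelling, so the two routes share no path-search code.
"""

import heapq

import numpy as np
import pytest

from gorgedyn import synthio, tunnel
from gorgedyn.errors import InputError, SelectionError, TopologyError
from gorgedyn.tunnel import (
    ProbeParams, _ClearanceField, _OFFSETS, _build_grid, _bulk_mask,
    bottleneck_distance, clearance, compute_tunnel, find_start_point,
    radius_series,
)
from conftest import make_model, pdb_line, ring_model


def dijkstra_bottleneck(clear, shape, start_flat, outside_flat):
    """Independent widest-path oracle: max over paths of min clearance."""
    outside = set(int(i) for i in outside_flat)
    strides = (shape[1] * shape[2], shape[2], 1)
    best = {start_flat: clear[start_flat]}
    heap = [(-clear[start_flat], start_flat)]
    while heap:
        negb, u = heapq.heappop(heap)
        b = -negb
        if b < best.get(u, -np.inf) - 1e-15:
            continue
        if u in outside:
            return b
        uk, uj, ui = np.unravel_index(u, shape)
        for dk, dj, di in _OFFSETS:
            k, j, i = uk + dk, uj + dj, ui + di
            if not (0 <= k < shape[0] and 0 <= j < shape[1] and 0 <= i < shape[2]):
                continue
            v = k * strides[0] + j * strides[1] + i
            nb = min(b, clear[v])
            if nb > best.get(v, -np.inf):
                best[v] = nb
                heapq.heappush(heap, (-nb, v))
    return None


def grid_quantities(model, params, hint):
    """Grid, clearance, start index and outside set as the implementation sees them."""
    start = find_start_point(model, params, hint)
    grid = _build_grid(model, params)
    pts = grid.points()
    clear, dist = _ClearanceField(model.coords, model.vdw).query(pts)
    outside = np.flatnonzero(
        (clear >= params.outer_probe)
        & _bulk_mask(dist, grid.shape, params.shell_radius)
    )
    strides = np.array([grid.shape[1] * grid.shape[2], grid.shape[2], 1])
    start_idx = np.rint((start - grid.origin) / params.grid_spacing).astype(int)
    return grid, clear, int(start_idx @ strides), outside


class TestClearance:
    def test_point_near_single_atom(self):
        model = make_model([[0.0, 0.0, 0.0]], vdw=1.5)
        assert clearance([5.0, 0.0, 0.0], model) == pytest.approx(3.5)

    def test_point_at_atom_center_is_negative_vdw(self):
        model = make_model([[1.0, 2.0, 3.0]], vdw=1.7)
        assert clearance([1.0, 2.0, 3.0], model) == pytest.approx(-1.7)

    def test_ring_axis_matches_brute_force(self):
        model = ring_model(radius=4.0, vdw=1.5)
        got = clearance([0.0, 0.0, 0.0], model)
        brute = min(np.linalg.norm(model.coords - np.zeros(3), axis=1)
                    - model.vdw)
        assert got == pytest.approx(brute)
        assert got == pytest.approx(2.5)

    def test_mixed_radii_uses_per_atom_vdw(self):
        model = make_model([[0, 0, 0], [4.0, 0, 0]], vdw=[1.0, 1.9])
        # at x=2.5: atom1 gives 1.5, atom2 gives 1.5-0.4
        assert clearance([2.5, 0, 0], model) == pytest.approx(4.0 - 2.5 - 1.9)


class TestStartPoint:
    def test_on_axis_hint_stays_on_axis(self):
        spec = synthio.BreathingSpec(amplitude=0.0, n_frames=2, n_residues=0,
                                     seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        params = ProbeParams(grid_spacing=0.5)
        start = find_start_point(traj.frame(0), params, spec.chamber_hint)
        assert np.linalg.norm(start[:2] - spec.chamber_hint[:2]) < 0.5 + 1e-9

    def test_solid_cluster_raises_no_cavity(self):
        pts = np.stack(np.meshgrid(*[np.arange(0, 13.5, 1.5)] * 3),
                       axis=-1).reshape(-1, 3)
        model = make_model(pts, vdw=1.7)
        with pytest.raises(InputError, match="no cavity"):
            find_start_point(model, ProbeParams(grid_spacing=0.5),
                             hint=[6.0, 6.0, 6.0])

    def test_off_axis_hint_never_loses_clearance(self):
        spec = synthio.BreathingSpec(amplitude=0.0, n_frames=2, n_residues=0,
                                     seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        model = traj.frame(0)
        params = ProbeParams(grid_spacing=0.5)
        hint = spec.chamber_hint + np.array([1.7, 0.4, 0.0])
        start = find_start_point(model, params, hint)
        assert clearance(start, model) >= clearance(hint, model) - 1e-9


class TestComputeTunnel:
    def test_pocket_bottleneck_within_one_spacing(self):
        spec = synthio.BreathingSpec(base_radius=4.0, ring_vdw=1.5,
                                     amplitude=0.0, n_frames=2, n_residues=0,
                                     seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        params = ProbeParams(grid_spacing=0.5)
        prof = compute_tunnel(traj.frame(0), params, hint=spec.chamber_hint)
        assert prof.status == "open"
        assert prof.min_radius == pytest.approx(2.5, abs=params.grid_spacing)
        assert prof.min_radius == pytest.approx(prof.clearances.min())

    def test_constriction_sets_the_bottleneck(self):
        spec = synthio.BreathingSpec(base_radius=2.7, ring_vdw=1.5,
                                     amplitude=0.0, n_frames=2, n_residues=0,
                                     seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        params = ProbeParams(grid_spacing=0.5)
        prof = compute_tunnel(traj.frame(0), params, hint=spec.chamber_hint)
        assert prof.min_radius == pytest.approx(1.2, abs=params.grid_spacing)

    def test_blocked_mouth_reports_closed(self):
        spec = synthio.BreathingSpec(amplitude=0.0, n_frames=2, n_residues=0,
                                     seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        model = traj.frame(0)
        # solid disc sealing the mouth above the constriction ring
        top_z = model.coords[:, 2].max() + 1.0
        disc = []
        rho = 0.0
        while rho <= spec.chamber_radius + 1.5:
            n_k = max(1, int(np.ceil(2 * np.pi * rho / 1.0)))
            ang = 2 * np.pi * np.arange(n_k) / n_k
            disc.extend(np.stack([rho * np.cos(ang), rho * np.sin(ang),
                                  np.full(n_k, top_z)], axis=1))
            rho += 1.0
        disc = np.asarray(disc)
        blocked = make_model(np.vstack([model.coords, disc]), vdw=1.5)
        prof = compute_tunnel(blocked, ProbeParams(grid_spacing=0.5),
                              hint=spec.chamber_hint)
        assert prof.status == "closed"
        assert prof.min_radius < 0.9

    def test_removing_atoms_never_decreases_radius(self):
        spec = synthio.BreathingSpec(amplitude=0.0, n_frames=2, n_residues=0,
                                     n_rings=5, seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        model = traj.frame(0)
        params = ProbeParams(grid_spacing=0.5)
        r_full = compute_tunnel(model, params, hint=spec.chamber_hint).min_radius
        keep = np.arange(model.n_atoms - 3)  # drop three mouth atoms
        r_less = compute_tunnel(model.subset(keep), params,
                                hint=spec.chamber_hint).min_radius
        assert r_less >= r_full - 1e-9

    def test_grid_refinement_changes_radius_at_most_one_coarse_spacing(self):
        spec = synthio.BreathingSpec(amplitude=0.0, n_frames=2, n_residues=0,
                                     n_rings=4, seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        model = traj.frame(0)
        coarse = compute_tunnel(model, ProbeParams(grid_spacing=0.8),
                                hint=spec.chamber_hint).min_radius
        fine = compute_tunnel(model, ProbeParams(grid_spacing=0.4),
                              hint=spec.chamber_hint).min_radius
        assert abs(fine - coarse) <= 0.8 + 1e-9

    def test_bottleneck_equals_dijkstra_oracle(self):
        for seed, base in [(0, 3.2), (1, 4.0), (2, 2.8)]:
            spec = synthio.BreathingSpec(base_radius=base, ring_vdw=1.5,
                                         amplitude=0.0, n_frames=2,
                                         n_residues=0, n_rings=3,
                                         atoms_per_ring=8, seed=seed)
            traj, _, _ = synthio.make_breathing_ensemble(spec)
            model = traj.frame(0)
            params = ProbeParams(grid_spacing=0.9)
            prof = compute_tunnel(model, params, hint=spec.chamber_hint)
            grid, clear, start_flat, outside = grid_quantities(
                model, params, spec.chamber_hint)
            oracle = dijkstra_bottleneck(clear, grid.shape, start_flat, outside)
            assert prof.min_radius == pytest.approx(oracle, abs=1e-12)

    def test_path_runs_from_start_to_bulk(self):
        spec = synthio.BreathingSpec(amplitude=0.0, n_frames=2, n_residues=0,
                                     seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        model = traj.frame(0)
        params = ProbeParams(grid_spacing=0.5)
        prof = compute_tunnel(model, params, hint=spec.chamber_hint)
        # contiguous grid steps
        steps = np.linalg.norm(np.diff(prof.path, axis=0), axis=1)
        assert steps.max() <= np.sqrt(3) * params.grid_spacing + 1e-9
        # terminal point is bulk-exposed
        assert clearance(prof.path[-1], model) >= params.outer_probe - 1e-9


class TestRadiusSeries:
    def test_constant_pocket_gives_identical_radii(self):
        spec = synthio.BreathingSpec(amplitude=0.0, n_frames=4, n_residues=0,
                                     seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        out = radius_series(traj, ProbeParams(grid_spacing=0.5),
                            hints={"A": spec.chamber_hint})
        vals = out["A"].values
        assert len(vals) == 4
        np.testing.assert_allclose(vals, vals[0])

    def test_breathing_sd_tracks_amplitude(self):
        spec = synthio.BreathingSpec(amplitude=1.0, n_frames=25, n_residues=0,
                                     noise_sd=0.0, seed=8)
        traj, true_r, _ = synthio.make_breathing_ensemble(spec)
        out = radius_series(traj, ProbeParams(grid_spacing=0.5),
                            hints={"A": spec.chamber_hint})
        measured_sd = np.nanstd(out["A"].values)
        target = spec.amplitude * np.std(traj.latent)
        assert measured_sd == pytest.approx(target, rel=0.25)

    def test_two_chain_system_gives_two_equal_length_series(self):
        spec = synthio.BreathingSpec(amplitude=0.0, n_frames=3, n_residues=0,
                                     n_rings=4, seed=0)
        traj, _, _ = synthio.make_breathing_ensemble(spec)
        m = traj.model
        shift = np.array([60.0, 0.0, 0.0])
        both = make_model(
            np.vstack([m.coords, m.coords + shift]),
            vdw=np.concatenate([m.vdw, m.vdw]),
            resids=np.concatenate([m.resids, m.resids]),
            chains=["A"] * m.n_atoms + ["B"] * m.n_atoms,
        )
        coords = np.concatenate([traj.coords, traj.coords + shift], axis=1)
        from gorgedyn.structio import TrajectoryEnsemble
        traj2 = TrajectoryEnsemble(both, coords, traj.times_ns)
        out = radius_series(
            traj2, ProbeParams(grid_spacing=0.5),
            hints={"A": spec.chamber_hint, "B": spec.chamber_hint + shift},
        )
        assert set(out) == {"A", "B"}
        assert len(out["A"].values) == len(out["B"].values) == 3
        np.testing.assert_allclose(out["A"].values, out["B"].values, atol=1e-9)


class TestBottleneckDistance:
    def _model(self, d=4.7):
        return make_model(
            [[0.0, 0.0, 0.0], [d, 0.0, 0.0]],
            resids=[330, 121], names=["CE2", "OH"],
            resnames=["PHE", "TYR"],
        )

    def test_fixture_distance(self):
        assert bottleneck_distance(self._model(4.7)) == pytest.approx(4.7)

    def test_missing_atom_raises(self):
        model = self._model()
        with pytest.raises(SelectionError):
            bottleneck_distance(model.subset([1]))

    def test_invariant_under_rigid_rotation(self):
        model = self._model(3.3)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = model.with_coords(model.coords @ rot.T + [5, -2, 1])
        assert bottleneck_distance(rotated) == pytest.approx(
            bottleneck_distance(model))


class TestProbeParams:
    def test_spacing_cannot_exceed_min_radius(self):
        with pytest.raises(InputError):
            ProbeParams(grid_spacing=1.2, min_radius=0.9)

    def test_probe_ordering_enforced(self):
        with pytest.raises(InputError):
            ProbeParams(inner_probe=3.5, outer_probe=3.0)
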