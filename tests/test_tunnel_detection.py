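"""Geometric tunnel search: field, bulk labeling, Dijkstra, profiles."""

import numpy as np
import pytest

from tunnelgate.io_formats import Ensemble
from tunnelgate.synthetic_data import (
    Channel,
    ToyStructureSpec,
    build_toy_structure,
    realize_trajectory,
)
from tunnelgate.tunnel_detection import (
    DetectionParams,
    ScalarField,
    StartPointSpec,
    TunnelProfile,
    classify_bulk,
    compute_start_point,
    detect_ensemble,
    find_tunnels,
    free_radius_field,
    grid_shortest_paths,
    profile_geometry,
    profiles_from_table,
    profiles_to_table,
)

from .conftest import make_atom, make_snapshot


def brute_force_field(snapshot, field):
    """Independent double-loop minimum over atoms at every voxel."""
    pos = snapshot.positions
    radii = snapshot.vdw_radii
    shape = field.values.shape
    out = np.empty(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                v = field.center_of((i, j, k))
                out[i, j, k] = np.min(np.linalg.norm(pos - v, axis=1) - radii)
    return out


class TestStartPoint:
    def test_single_atom_identity(self):
        snap = make_snapshot([[1.0, 2.0, 3.0]])
        spec = StartPointSpec(residues=(("ALA", 1),))
        np.testing.assert_allclose(compute_start_point(snap, spec), [1, 2, 3])

    def test_equal_masses_midpoint(self):
        snap = make_snapshot([[0, 0, 0], [2, 0, 0]])
        spec = StartPointSpec(residues=(("ALA", 1),))
        np.testing.assert_allclose(compute_start_point(snap, spec), [1, 0, 0])

    def test_mass_weighting_closed_form(self):
        atoms = [
            make_atom(serial=1, name="C", position=(0, 0, 0), mass=12.0),
            make_atom(serial=2, name="H", position=(13, 0, 0), mass=1.0),
        ]
        from tunnelgate.io_formats import Snapshot

        snap = Snapshot(0, 0.0, atoms)
        spec = StartPointSpec(residues=(("ALA", 1),), heavy_atoms_only=False)
        assert compute_start_point(snap, spec)[0] == pytest.approx(1.0)
        # heavy-only drops the hydrogen
        spec_h = StartPointSpec(residues=(("ALA", 1),))
        assert compute_start_point(snap, spec_h)[0] == pytest.approx(0.0)

    def test_missing_residue_named(self):
        snap = make_snapshot([[0, 0, 0]])
        with pytest.raises(ValueError, match="TRP:109"):
            compute_start_point(snap, StartPointSpec(residues=(("TRP", 109),)))


class TestFreeRadiusField:
    def test_single_atom_one_term(self):
        snap = make_snapshot([[0.0, 0.0, 0.0]])
        field = free_radius_field(snap, spacing=1.0, margin=4.0)
        idx = field.index_of(np.array([3.0, 0.0, 0.0]))
        assert field.values[idx] == pytest.approx(1.3)

    def test_value_at_atom_center_is_minus_radius(self):
        snap = make_snapshot([[0.5, 0.5, 0.5]], radii=[1.7])
        field = free_radius_field(snap, spacing=0.5, margin=3.0)
        idx = field.index_of(np.array([0.5, 0.5, 0.5]))
        assert field.values[idx] == pytest.approx(-1.7)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        snap = make_snapshot(
            rng.uniform(-4, 4, size=(50, 3)),
            radii=rng.choice([1.2, 1.52, 1.7], size=50),
        )
        field = free_radius_field(snap, spacing=1.1, margin=3.0)
        np.testing.assert_allclose(
            field.values, brute_force_field(snap, field), atol=1e-9
        )

    def test_capped_field_exact_below_cap(self, one_channel_spec):
        snap = build_toy_structure(one_channel_spec)
        exact = free_radius_field(snap, spacing=0.9)
        capped = free_radius_field(snap, spacing=0.9, cap=3.0)
        below = exact.values < 3.0
        np.testing.assert_array_equal(exact.values[below], capped.values[below])
        assert (capped.values[~below] == 3.0).all()

    def test_empty_snapshot_rejected(self):
        from tunnelgate.io_formats import Snapshot

        with pytest.raises(ValueError):
            free_radius_field(Snapshot(0, 0.0, []), spacing=1.0)


class TestClassifyBulk:
    def test_far_voxel_is_bulk_cavity_is_interior(self, compact_spec):
        snap = build_toy_structure(compact_spec)
        field = free_radius_field(snap, spacing=0.8, cap=3.0)
        bulk = classify_bulk(field, DetectionParams(grid_spacing=0.8))
        assert bulk[0, 0, 0]  # box corner, far from all atoms
        # cavity free radius is 4 - 1.7 = 2.3 < shell radius: interior
        assert not bulk[field.index_of(np.zeros(3))]

    def test_wide_internal_void_stays_interior(self):
        # hollow cube shell with a 6 A-wide internal void (free radius > 3)
        # that has no connection to the boundary
        grid = np.arange(-6.0, 6.1, 1.0)
        pts = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), -1).reshape(-1, 3)
        inf_norm = np.abs(pts).max(axis=1)
        shell = pts[(inf_norm >= 5.0)]
        snap = make_snapshot(shell, radii=np.full(len(shell), 1.0))
        field = free_radius_field(snap, spacing=1.0)
        params = DetectionParams(grid_spacing=1.0)
        bulk = classify_bulk(field, params)
        center = field.index_of(np.zeros(3))
        assert field.values[center] >= params.shell_radius  # wide enough...
        assert not bulk[center]  # ...but unreachable from the boundary


class TestGridDijkstra:
    @staticmethod
    def random_instance(rng, shape):
        values = rng.uniform(0.2, 3.0, size=shape)
        traversable = values >= 0.7
        start = tuple(rng.integers(0, s) for s in shape)
        traversable[start] = True
        values[start] = max(values[start], 0.7)
        field = ScalarField(values, origin=np.zeros(3), spacing=0.5)
        return field, traversable, start

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_costs_match_networkx_oracle(self, seed):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(seed)
        field, trav, start = self.random_instance(rng, (12, 12, 12))
        dist, pred = grid_shortest_paths(field, trav, start)
        g = nx.DiGraph()
        nxs, nys, nzs = field.values.shape
        for i in range(nxs):
            for j in range(nys):
                for k in range(nzs):
                    if not trav[i, j, k]:
                        continue
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            for dk in (-1, 0, 1):
                                if di == dj == dk == 0:
                                    continue
                                ni, nj, nk = i + di, j + dj, k + dk
                                if not (0 <= ni < nxs and 0 <= nj < nys and 0 <= nk < nzs):
                                    continue
                                if not trav[ni, nj, nk]:
                                    continue
                                w = (
                                    field.spacing
                                    * np.sqrt(di * di + dj * dj + dk * dk)
                                    * field.values[ni, nj, nk] ** -2.0
                                )
                                g.add_edge((i, j, k), (ni, nj, nk), weight=w)
        ref = nx.single_source_dijkstra_path_length(g, start)
        dist3 = dist.reshape(field.values.shape)
        for node, d_ref in ref.items():
            assert dist3[node] == pytest.approx(d_ref, rel=1e-12, abs=1e-12)
        # unreached nodes agree too
        for node in zip(*np.nonzero(trav)):
            if tuple(node) not in ref:
                assert np.isinf(dist3[tuple(node)])

    def test_untraversable_start_rejected(self, rng):
        field, trav, start = self.random_instance(rng, (6, 6, 6))
        trav[start] = False
        with pytest.raises(ValueError):
            grid_shortest_paths(field, trav, start)


class TestFindTunnels:
    def test_one_channel_one_tunnel_with_br_tolerance(self, one_channel_spec):
        snap = build_toy_structure(one_channel_spec)
        params = DetectionParams(grid_spacing=0.5)
        tunnels = find_tunnels(snap, np.zeros(3), params)
        assert len(tunnels) == 1
        assert tunnels[0].bottleneck_radius == pytest.approx(1.5, abs=0.5)

    def test_probe_constraint_blocks_narrow_channel(self):
        spec = ToyStructureSpec(
            shell_outer_radius=10.0, shell_thickness=6.0, cavity_radius=4.0,
            channels=(Channel((0, 0, 1), 0.5),),
        )
        snap = build_toy_structure(spec)
        assert find_tunnels(snap, np.zeros(3), DetectionParams(grid_spacing=0.8)) == []

    def test_grid_refinement_tightens_bottleneck(self, one_channel_spec):
        snap = build_toy_structure(one_channel_spec)
        for spacing in (1.0, 0.5):
            tunnels = find_tunnels(
                snap, np.zeros(3), DetectionParams(grid_spacing=spacing)
            )
            assert len(tunnels) == 1
            assert abs(tunnels[0].bottleneck_radius - 1.5) <= spacing

    def test_invariants_probe_and_straightline(self, one_channel_spec):
        snap = build_toy_structure(one_channel_spec)
        params = DetectionParams(grid_spacing=0.5)
        start = np.zeros(3)
        for tp in find_tunnels(snap, start, params):
            assert tp.bottleneck_radius >= params.probe_radius
            straight = np.linalg.norm(tp.exit_point - tp.centers[0])
            assert tp.length >= straight - 1e-9

    def test_deterministic_under_atom_permutation(self, one_channel_spec, rng):
        from tunnelgate.io_formats import Snapshot

        snap = build_toy_structure(one_channel_spec)
        perm = rng.permutation(len(snap.atoms))
        shuffled = Snapshot(0, 0.0, [snap.atoms[i] for i in perm])
        params = DetectionParams(grid_spacing=0.8)
        a = find_tunnels(snap, np.zeros(3), params)
        b = find_tunnels(shuffled, np.zeros(3), params)
        assert len(a) == len(b) == 1
        np.testing.assert_array_equal(a[0].centers, b[0].centers)
        np.testing.assert_array_equal(a[0].radii, b[0].radii)

    def test_unburied_start_rejected(self, compact_spec):
        snap = build_toy_structure(compact_spec)
        with pytest.raises(ValueError, match="not buried"):
            find_tunnels(snap, np.array([0.0, 0.0, 14.0]),
                         DetectionParams(grid_spacing=0.8))

    def test_start_inside_atom_snaps_to_cavity(self, one_channel_spec, caplog):
        snap = build_toy_structure(one_channel_spec)
        params = DetectionParams(grid_spacing=0.8)
        # inside the inner shell wall: free radius < probe there
        with caplog.at_level("WARNING"):
            tunnels = find_tunnels(snap, np.array([0.0, 0.0, -3.8]), params)
        assert len(tunnels) == 1
        assert any("snapped" in r.message for r in caplog.records)


class TestProfileGeometry:
    def test_bottleneck_is_minimum(self):
        tp = TunnelProfile(
            centers=[[0, 0, 0], [0, 0, 1], [0, 0, 2]], radii=[1.2, 0.9, 1.5]
        )
        br, _ = profile_geometry(tp)
        assert br == 0.9

    def test_collinear_length(self):
        tp = TunnelProfile(
            centers=[[0, 0, 0], [0, 0, 2], [0, 0, 5]], radii=[1, 1, 1]
        )
        assert profile_geometry(tp)[1] == pytest.approx(5.0)

    def test_right_angle_exceeds_straight_line(self):
        tp = TunnelProfile(
            centers=[[0, 0, 0], [3, 0, 0], [3, 4, 0]], radii=[1, 1, 1]
        )
        assert profile_geometry(tp)[1] == pytest.approx(7.0)
        assert profile_geometry(tp)[1] >= 5.0

    def test_short_spine_rejected(self):
        with pytest.raises(ValueError):
            profile_geometry(TunnelProfile(centers=[[0, 0, 0]], radii=[1.0]))


class TestDetectEnsemble:
    def test_batching_is_result_invariant(self, one_channel_spec):
        series = np.array([1.5, 1.4, 0.3, 1.2, 1.5, 0.2, 1.0])
        ens = realize_trajectory(one_channel_spec, [series])
        params = DetectionParams(grid_spacing=0.8)
        unbatched = detect_ensemble(ens, np.zeros(3), params)
        batched = detect_ensemble(ens, np.zeros(3), params, batch_size=3)
        assert len(unbatched) == len(batched)
        for a, b in zip(unbatched, batched):
            assert a.frame_index == b.frame_index
            np.testing.assert_array_equal(a.centers, b.centers)
            np.testing.assert_array_equal(a.radii, b.radii)

    def test_profile_table_round_trip(self, one_channel_spec):
        ens = realize_trajectory(one_channel_spec, [np.array([1.5, 1.3])])
        profiles = detect_ensemble(ens, np.zeros(3), DetectionParams(grid_spacing=0.8))
        table = profiles_to_table(profiles, "r0")
        back = profiles_from_table(table)["r0"]
        assert len(back) == len(profiles)
        for a, b in zip(profiles, back):
            np.testing.assert_allclose(a.centers, b.centers)
            np.testing.assert_allclose(a.radii, b.radii)
            assert a.frame_index == b.frame_index
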