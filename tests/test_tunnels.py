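"""Tunnel search against generator truth and a dynamic-programming oracle."""

import numpy as np
import pytest

from mdtop import synthetic
from mdtop.errors import BlockedStartError, UsageError
from mdtop.topology import Atom, ToyTopology
from mdtop.tunnels import (
    Tunnel,
    TunnelSearchConfig,
    bottleneck_residues,
    cluster_tunnels,
    find_cheapest_tunnel,
    find_tunnels,
    free_radius_field,
    pathway_statistics,
)


@pytest.fixture(scope="module")
def cylinder():
    spec = synthetic.ChannelSpec(
        body_radius=15.0,
        channels=(
            synthetic.ChannelDef(axis=(0, 0, 1.0), profile=((0.0, 2.0), (15.0, 2.0))),
        ),
    )
    traj, truth = synthetic.generate_channel_system(spec, seed=3)
    return traj, truth[0]


class TestFreeRadiusField:
    def test_single_atom_examples(self):
        coords = np.zeros((1, 3))
        radii = np.array([1.5])
        cfg = TunnelSearchConfig(grid_spacing=0.5, margin=5.0)
        grid = free_radius_field(coords, radii, cfg)
        node = grid.nearest_node(np.array([4.0, 0.0, 0.0]))
        pt = grid.node_coords(np.array(node))
        expected = np.linalg.norm(pt) - 1.5
        assert grid.free[node] == pytest.approx(expected, abs=1e-9)
        center_node = grid.nearest_node(np.zeros(3))
        assert grid.free[center_node] == pytest.approx(
            max(np.linalg.norm(grid.node_coords(np.array(center_node))) - 1.5, 0.0)
        )

    def test_random_nodes_against_brute_force(self, rng):
        coords = rng.uniform(-5, 5, size=(30, 3))
        radii = rng.uniform(1.0, 2.0, size=30)
        cfg = TunnelSearchConfig(grid_spacing=0.7)
        grid = free_radius_field(coords, radii, cfg)
        for _ in range(100):
            ijk = tuple(rng.integers(0, s) for s in grid.shape)
            pt = grid.node_coords(np.array(ijk))
            d = np.linalg.norm(coords - pt, axis=1)
            nearest = int(np.argmin(d))
            oracle = max(d[nearest] - radii[nearest], 0.0)
            assert grid.free[ijk] == pytest.approx(oracle, abs=1e-9)

    def test_empty_structure_rejected(self):
        with pytest.raises(UsageError):
            free_radius_field(np.empty((0, 3)), np.empty(0), TunnelSearchConfig())


def _dp_oracle_cost(coords, radii, cfg, start_point):
    """Independent cheapest-exit cost by Bellman-Ford relaxation over the
    same grid definition (26-neighbour edges, exits absorbing)."""
    from mdtop.tunnels import _OFFSETS, _outside_hull_mask

    grid = free_radius_field(coords, radii, cfg)
    free = grid.free
    shape = grid.shape
    admissible = free >= cfg.probe_radius
    outside = _outside_hull_mask(grid, coords).reshape(shape)
    cost = np.full(shape, np.inf)
    start = grid.nearest_node(start_point)
    assert admissible[start]
    cost[start] = 0.0
    for _ in range(int(np.sum(admissible))):
        changed = False
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if not admissible[i, j, k] or not np.isfinite(cost[i, j, k]):
                        continue
                    if outside[i, j, k]:
                        continue  # exits absorb
                    for off in _OFFSETS:
                        ii, jj, kk = i + off[0], j + off[1], k + off[2]
                        if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                            continue
                        if not admissible[ii, jj, kk]:
                            continue
                        w = (
                            cfg.grid_spacing
                            * np.linalg.norm(off)
                            / min(free[i, j, k], free[ii, jj, kk]) ** cfg.cost_exponent
                        )
                        if cost[i, j, k] + w < cost[ii, jj, kk] - 1e-12:
                            cost[ii, jj, kk] = cost[i, j, k] + w
                            changed = True
        if not changed:
            break
    exit_costs = cost[admissible & outside]
    return exit_costs.min() if exit_costs.size else np.inf


class TestCheapestTunnel:
    def test_cylinder_matches_generator_truth(self, cylinder):
        traj, truth = cylinder
        cfg = TunnelSearchConfig(probe_radius=1.3, start=np.zeros(3))
        tunnel = find_cheapest_tunnel(traj.coords[0], traj.topology, cfg)
        assert tunnel is not None
        assert abs(tunnel.bottleneck - truth["bottleneck_radius"]) <= cfg.grid_spacing
        assert abs(tunnel.length - truth["length"]) <= 2.0 * cfg.grid_spacing

    def test_probe_larger_than_channel_absent(self, cylinder):
        traj, _ = cylinder
        cfg = TunnelSearchConfig(probe_radius=2.5, start=np.zeros(3))
        assert find_cheapest_tunnel(traj.coords[0], traj.topology, cfg) is None

    def test_blocked_start_distinct_from_absent(self, rng):
        # solid jittered lattice ball with no cavity: the centre is blocked
        grid1d = np.arange(-6.0, 6.1, 2.0)
        xx, yy, zz = np.meshgrid(grid1d, grid1d, grid1d, indexing="ij")
        pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
        pts += rng.uniform(-0.1, 0.1, size=pts.shape)
        pts = pts[np.linalg.norm(pts, axis=1) <= 6.0]
        top = ToyTopology(
            atoms=tuple(
                Atom("SPH", "BDY", i + 1, "C", 1.5) for i in range(len(pts))
            )
        )
        cfg = TunnelSearchConfig(probe_radius=1.3, start=np.array([1.0, 0.0, 0.0]))
        with pytest.raises(BlockedStartError):
            find_cheapest_tunnel(pts, top, cfg)

    def test_open_start_reaches_hull_directly(self, rng):
        # sparse distant atoms: the start sits in open admissible space
        coords = np.array(
            [[8.0, 0, 0], [-8.0, 0, 0], [0, 8.0, 0], [0, -8.0, 0], [0, 0, 8.0], [0, 0, -8.0]]
        )
        top = ToyTopology(
            atoms=tuple(Atom("SPH", "BDY", i + 1, "C", 1.5) for i in range(6))
        )
        cfg = TunnelSearchConfig(probe_radius=1.0, start=np.zeros(3))
        tunnel = find_cheapest_tunnel(coords, top, cfg)
        assert tunnel is not None
        # hull is the octahedron spanned by the atoms; the nearest facet lies
        # at 8/sqrt(3) ~ 4.6 A from the centre
        assert tunnel.length <= 8.0
        assert tunnel.throughput > 0.5

    def test_dp_oracle_agreement(self):
        spec = synthetic.ChannelSpec(
            body_radius=6.0,
            channels=(
                synthetic.ChannelDef(axis=(0, 0, 1.0), profile=((0.0, 2.0), (6.0, 2.0))),
            ),
            start_clearance=2.0,
        )
        traj, _ = synthetic.generate_channel_system(spec, seed=5)
        cfg = TunnelSearchConfig(
            probe_radius=1.0, grid_spacing=1.0, start=np.zeros(3), margin=2.0
        )
        tunnel = find_cheapest_tunnel(traj.coords[0], traj.topology, cfg)
        oracle = _dp_oracle_cost(
            traj.coords[0], traj.topology.vdw_radii, cfg, np.zeros(3)
        )
        assert tunnel is not None and np.isfinite(oracle)
        assert tunnel.cost == pytest.approx(oracle, rel=1e-9)

    def test_probe_monotonicity(self, cylinder):
        traj, _ = cylinder
        costs = []
        for probe in (0.7, 1.0, 1.3):
            cfg = TunnelSearchConfig(probe_radius=probe, start=np.zeros(3))
            t = find_cheapest_tunnel(traj.coords[0], traj.topology, cfg)
            costs.append(t.cost)
        assert costs[0] <= costs[1] <= costs[2] + 1e-12

    def test_throughput_bounds(self, cylinder):
        traj, _ = cylinder
        cfg = TunnelSearchConfig(probe_radius=1.3, start=np.zeros(3))
        for t in find_tunnels(traj.coords[0], traj.topology, cfg):
            assert 0.0 < t.throughput <= 1.0
            assert t.bottleneck >= cfg.probe_radius
            assert t.length >= np.linalg.norm(t.path[-1] - t.path[0]) - 1e-9


def _straight_tunnel(frame, direction, cost, n=10, length=10.0):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    s = np.linspace(0.0, length, n)
    path = s[:, None] * direction[None]
    return Tunnel(
        frame=frame,
        path=path,
        radii=np.full(n, 2.0),
        length=length,
        bottleneck=2.0,
        cost=cost,
        throughput=float(np.exp(-cost)),
    )


class TestPathways:
    def test_identical_tunnels_single_pathway(self):
        tunnels = [_straight_tunnel(f, (0, 0, 1), 1.0) for f in range(5)]
        pathways = cluster_tunnels(tunnels, linkage_cutoff=3.0)
        assert len(pathways) == 1
        assert len(pathways[0].frames) == 5

    def test_opposite_channels_two_pathways(self):
        tunnels = [_straight_tunnel(f, (0, 0, 1), 1.0) for f in range(4)]
        tunnels += [_straight_tunnel(f, (0, 0, -1), 2.0) for f in range(4)]
        pathways = cluster_tunnels(tunnels, linkage_cutoff=3.0)
        assert len(pathways) == 2
        assert pathways[0].mean_throughput > pathways[1].mean_throughput

    def test_toy_polylines_match_manual_average_linkage(self):
        """Six short polylines with hand-computed pairwise distances merge the
        same way as a naive average-linkage oracle."""
        dirs = [(0, 0, 1), (0.05, 0, 1), (0, 1, 0), (0, 1.02, 0.1), (1, 0, 0), (1, 0.07, 0)]
        tunnels = [_straight_tunnel(i, d, 1.0) for i, d in enumerate(dirs)]
        pathways = cluster_tunnels(tunnels, linkage_cutoff=3.0)
        got = sorted(sorted(t.frame for t in p.tunnels) for p in pathways)
        # manual distances group the three direction families
        assert got == [[0, 1], [2, 3], [4, 5]]

    def test_cheapest_tunnel_per_frame_used(self):
        cheap = _straight_tunnel(0, (0, 0, 1), 0.5)
        dear = _straight_tunnel(0, (0, 0.01, 1), 2.0)
        p = cluster_tunnels([cheap, dear], linkage_cutoff=5.0)[0]
        assert len(p.frames) == 1
        assert p.mean_throughput == pytest.approx(np.exp(-0.5))

    def test_statistics_table(self):
        tunnels = [_straight_tunnel(f, (0, 0, 1), 1.5) for f in range(3)]
        stats = pathway_statistics(
            cluster_tunnels(tunnels, linkage_cutoff=3.0), total_frames=4
        )
        assert stats.loc[0, "frames_present"] == 3
        assert stats.loc[0, "mean_throughput"] == pytest.approx(np.exp(-1.5))
        assert ((stats["mean_throughput"] > 0) & (stats["mean_throughput"] <= 1)).all()

    def test_wider_channel_ranks_first(self):
        spec = synthetic.ChannelSpec(
            body_radius=10.0,
            channels=(
                synthetic.ChannelDef(axis=(0, 0, 1.0), profile=((0.0, 2.2), (10.0, 2.2))),
                synthetic.ChannelDef(axis=(1.0, 0, 0), profile=((0.0, 1.7), (10.0, 1.7))),
            ),
        )
        cfg = TunnelSearchConfig(probe_radius=1.3, start=np.zeros(3))
        all_tunnels = []
        for f in range(2):
            traj, _ = synthetic.generate_channel_system(spec, seed=20 + f)
            all_tunnels += find_tunnels(traj.coords[0], traj.topology, cfg, frame=f)
        pathways = cluster_tunnels(all_tunnels, linkage_cutoff=4.0)
        assert len(pathways) == 2
        top = pathways[0]
        # the top-ranked pathway is the wide channel along +z
        mean_dir = np.mean([t.path[-1] - t.path[0] for t in top.tunnels], axis=0)
        assert abs(mean_dir[2]) > abs(mean_dir[0])
        assert top.mean_bottleneck > pathways[1].mean_bottleneck


class TestBottleneckResidues:
    def test_pinch_residues_found(self):
        atoms = (
            Atom("SPH", "BDY", 1, "C", 1.5),
            Atom("SPH", "BDY", 2, "C", 1.5),
            Atom("SPH", "BDY", 3, "C", 1.5),
        )
        top = ToyTopology(atoms=atoms)
        coords = np.array([[0.0, 3.0, 5.0], [0.0, -3.0, 5.0], [20.0, 0.0, 0.0]])
        tunnel = _straight_tunnel(0, (0, 0, 1), 1.0)
        tunnel.radii = np.array([5.0, 5.0, 5.0, 5.0, 1.5, 5.0, 5.0, 5.0, 5.0, 5.0])
        tunnel.bottleneck = 1.5
        # bottleneck point is path[4] = (0, 0, 4.44); both pinch atoms are
        # within shell of the bottleneck sphere surface, the far atom is not
        res = bottleneck_residues(tunnel, coords, top, shell=1.0)
        assert res == [1, 2]

    def test_zero_shell_no_touching_atoms_empty(self):
        atoms = (Atom("SPH", "BDY", 1, "C", 1.5),)
        top = ToyTopology(atoms=atoms)
        coords = np.array([[50.0, 0.0, 0.0]])
        tunnel = _straight_tunnel(0, (0, 0, 1), 1.0)
        assert bottleneck_residues(tunnel, coords, top, shell=0.0) == []
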