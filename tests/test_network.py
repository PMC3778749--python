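import numpy as np
import pytest

import connectoscan as cs
from connectoscan.network import (
    ConnectivityNetwork,
    assign_endpoints,
    build_network,
    group_average,
)
from connectoscan.tracking import Streamline, Tractogram

from conftest import uniform_tensor_field


def _toy_labels():
    """Three block regions on a 12×6×6 grid (2 mm voxels)."""
    lab = np.zeros((12, 6, 6), dtype=np.int32)
    lab[0:2] = 1
    lab[10:12] = 2
    lab[5:7, 0:2] = 3
    return cs.LabelVolume(lab, np.diag([2.0, 2.0, 2.0, 1.0]))


def _line(p0, p1, n=9):
    return np.linspace(np.asarray(p0, float), np.asarray(p1, float), n)


def _toy_tract(pair_counts):
    """Hand-built tractogram; pair_counts maps (i, j) voxel anchors to counts."""
    anchors = {1: (1, 3, 3), 2: (10, 3, 3), 3: (5, 1, 3), 0: (5, 4, 4)}
    streamlines = []
    for (a, b), n in pair_counts.items():
        p0 = np.asarray(anchors[a]) * 2.0
        p1 = np.asarray(anchors[b]) * 2.0
        for _ in range(n):
            streamlines.append(
                Streamline(_line(p0, p1), anchors[a], ("low_fa", "low_fa"))
            )
    return Tractogram(streamlines, np.diag([2.0, 2.0, 2.0, 1.0]), (12, 6, 6),
                      n_seeds=len(streamlines))


class TestAssignEndpoints:
    def test_straight_phantom_maps_to_endcap_pair(self, straight_tract, straight_phantom):
        pairs = assign_endpoints(straight_tract, straight_phantom["labels"])
        assert (1, 2) in pairs

    def test_background_endpoint_contributes_nothing(self):
        tract = _toy_tract({(1, 0): 3})
        pairs = assign_endpoints(tract, _toy_labels())
        assert pairs == [None, None, None]

    def test_same_region_loop_contributes_nothing(self):
        tract = _toy_tract({(1, 1): 2})
        assert assign_endpoints(tract, _toy_labels()) == [None, None]

    def test_grid_mismatch_rejected(self, straight_tract):
        with pytest.raises(ValueError, match="grid"):
            assign_endpoints(straight_tract, _toy_labels())


class TestBuildNetwork:
    def test_counts_match_brute_force_tally(self):
        pair_counts = {(1, 2): 7, (1, 3): 4, (2, 3): 2, (1, 0): 3}
        tract = _toy_tract(pair_counts)
        field = uniform_tensor_field(shape=(12, 6, 6))
        net = build_network(tract, _toy_labels(), field, m=1)
        assert net.counts[0, 1] == 7
        assert net.counts[0, 2] == 4
        assert net.counts[1, 2] == 2
        assert net.n_all == 16  # all launched fibres, labelled or not
        assert np.array_equal(net.counts, net.counts.T)

    def test_density_is_count_over_total(self):
        tract = _toy_tract({(1, 2): 6, (1, 3): 2})
        field = uniform_tensor_field(shape=(12, 6, 6))
        net = build_network(tract, _toy_labels(), field, m=1)
        assert net.density[0, 1] == pytest.approx(6 / 8)
        iu = np.triu_indices(3, k=1)
        assert net.density[iu].sum() <= 1.0

    def test_single_edge_takes_all_density(self, straight_tract, straight_phantom, straight_field):
        net = build_network(
            straight_tract, straight_phantom["labels"], straight_field, m=1
        )
        # ≥95% of straight-bundle fibres join the caps; a single edge exists
        assert net.counts[0, 1] >= 0.95 * net.n_all
        assert net.density[0, 1] == net.counts[0, 1] / net.n_all

    def test_connection_threshold_zeroes_weak_edges(self):
        tract = _toy_tract({(1, 2): 5, (1, 3): 2})
        field = uniform_tensor_field(shape=(12, 6, 6))
        m1 = build_network(tract, _toy_labels(), field, m=1)
        m3 = build_network(tract, _toy_labels(), field, m=3)
        assert m1.density[0, 2] > 0
        assert m3.density[0, 2] == 0 and m3.fa[0, 2] == 0 and m3.md[0, 2] == 0
        assert m3.density[0, 1] == m1.density[0, 1]

    def test_threshold_monotonicity(self):
        tract = _toy_tract({(1, 2): 6, (1, 3): 4, (2, 3): 2})
        field = uniform_tensor_field(shape=(12, 6, 6))
        nets = {m: build_network(tract, _toy_labels(), field, m=m) for m in (1, 3, 5)}
        prev_edges = None
        for m in (1, 3, 5):
            edges = set(map(tuple, np.argwhere(nets[m].density > 0)))
            if prev_edges is not None:
                assert edges <= prev_edges  # raising m never adds an edge
                for e in edges:  # surviving attributes unchanged
                    assert nets[m].density[e] == nets[1].density[e]
                    assert nets[m].fa[e] == nets[1].fa[e]
            prev_edges = edges

    def test_edge_fa_is_mean_over_unique_voxels(self):
        tract = _toy_tract({(1, 2): 2})
        field = uniform_tensor_field(shape=(12, 6, 6))
        # constant FA field: edge FA equals that constant
        net = build_network(tract, _toy_labels(), field, m=1)
        assert net.fa[0, 1] == pytest.approx(field.fa_map[0, 0, 0])

    def test_empty_tractogram_degenerate(self):
        tract = Tractogram([], np.diag([2.0, 2.0, 2.0, 1.0]), (12, 6, 6))
        field = uniform_tensor_field(shape=(12, 6, 6))
        net = build_network(tract, _toy_labels(), field, m=1)
        assert net.degenerate
        assert net.counts.sum() == 0

    def test_count_conservation(self):
        tract = _toy_tract({(1, 2): 5, (1, 0): 3, (3, 3): 1})
        field = uniform_tensor_field(shape=(12, 6, 6))
        net = build_network(tract, _toy_labels(), field, m=1)
        iu = np.triu_indices(3, k=1)
        assert net.counts[iu].sum() <= net.n_all


class TestGroupAverage:
    def _net(self, cd12):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 1] = counts[1, 0] = max(1, int(cd12 * 10))
        density = np.zeros((3, 3))
        density[0, 1] = density[1, 0] = cd12
        return ConnectivityNetwork(
            counts=counts, density=density, fa=np.zeros((3, 3)),
            md=np.zeros((3, 3)), n_all=10, m=1,
        )

    def test_single_network_is_its_own_average(self):
        n = self._net(0.2)
        means = group_average([n])
        assert np.array_equal(means["cd"], n.density)

    def test_mean_of_two(self):
        means = group_average([self._net(0.2), self._net(0.4)])
        assert means["cd"][0, 1] == pytest.approx(0.3)

    def test_never_connected_mask(self):
        means = group_average([self._net(0.2), self._net(0.4)])
        assert means["never_connected"][0, 2]
        assert not means["never_connected"][0, 1]

    def test_mixed_sizes_rejected(self):
        big = ConnectivityNetwork(
            counts=np.zeros((4, 4), dtype=int), density=np.zeros((4, 4)),
            fa=np.zeros((4, 4)), md=np.zeros((4, 4)), n_all=1, m=1,
        )
        with pytest.raises(ValueError, match="n_regions"):
            group_average([self._net(0.2), big])
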