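"""Layouts and figure manifests (content, not pixels)."""

import json

import numpy as np
import pytest

from cognet.ggm import PartialCorrelationNetwork
from cognet.graph import CoAssignmentMatrix, CommunityPartition, coassignment
from cognet.report import (
    layout_circular,
    layout_spring,
    render_ci_lines,
    render_coassignment_panel,
    render_network,
)


def _net(W, labels=None, group="g"):
    labels = labels or [f"v{i}" for i in range(W.shape[0])]
    return PartialCorrelationNetwork(
        labels=labels, W=W, lambda_selected=0.1, n=100, group_name=group
    )


def _dist(a, b):
    return np.hypot(a[0] - b[0], a[1] - b[1])


class TestCircularLayout:
    def test_four_nodes_at_cardinal_angles(self):
        coords = layout_circular(["a", "b", "c", "d"]).coordinates
        # first at top, then clockwise: 90, 0, 270, 180 degrees
        assert coords["a"] == pytest.approx((0.0, 1.0), abs=1e-12)
        assert coords["b"] == pytest.approx((1.0, 0.0), abs=1e-12)
        assert coords["c"] == pytest.approx((0.0, -1.0), abs=1e-12)
        assert coords["d"] == pytest.approx((-1.0, 0.0), abs=1e-12)

    def test_single_node_at_top(self):
        assert layout_circular(["x"]).coordinates["x"] == pytest.approx((0.0, 1.0))

    def test_all_nodes_on_unit_circle(self):
        coords = layout_circular([f"n{i}" for i in range(9)]).coordinates
        for x, y in coords.values():
            assert np.hypot(x, y) == pytest.approx(1.0)


class TestSpringLayout:
    def _pair_plus_isolate(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.8
        return _net(W, ["a", "b", "c"])

    def test_deterministic_under_seed(self):
        net = self._pair_plus_isolate()
        a = layout_spring(net, seed=4).coordinates
        b = layout_spring(net, seed=4).coordinates
        assert a == b

    def test_linked_pair_closer_than_isolate(self):
        c = layout_spring(self._pair_plus_isolate(), seed=0).coordinates
        assert _dist(c["a"], c["b"]) < _dist(c["a"], c["c"])
        assert _dist(c["a"], c["b"]) < _dist(c["b"], c["c"])

    def test_cliques_separate_across_seeds(self):
        W = np.zeros((6, 6))
        for blk in ([0, 1, 2], [3, 4, 5]):
            for i in blk:
                for j in blk:
                    if i != j:
                        W[i, j] = 0.5
        net = _net(W)
        for seed in range(20):
            c = layout_spring(net, seed=seed).coordinates
            intra, inter = [], []
            for i in range(6):
                for j in range(i + 1, 6):
                    d = _dist(c[f"v{i}"], c[f"v{j}"])
                    (intra if (i < 3) == (j < 3) else inter).append(d)
            assert np.mean(intra) < np.mean(inter)


class TestRenderNetwork:
    def test_edge_signs_color_the_manifest(self, tmp_path):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = -0.3
        net = _net(W, ["a", "b", "c"])
        man = render_network(net, layout_circular(net.labels),
                             path=tmp_path / "n.svg")
        colors = sorted(e["color"] for e in man["edges"])
        assert colors == ["green", "red"]

    def test_empty_network_draws_no_edges(self, tmp_path):
        man = render_network(_net(np.zeros((4, 4))), layout_circular(
            [f"v{i}" for i in range(4)]), path=tmp_path / "e.svg")
        assert man["edges"] == []
        assert len(man["nodes"]) == 4

    def test_widths_monotone_in_weight(self, tmp_path):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.2
        W[0, 2] = W[2, 0] = 0.5
        W[0, 3] = W[3, 0] = -0.9
        man = render_network(_net(W), layout_circular([f"v{i}" for i in range(4)]),
                             path=tmp_path / "w.svg")
        by_weight = sorted(man["edges"], key=lambda e: abs(e["weight"]))
        widths = [e["width"] for e in by_weight]
        assert widths == sorted(widths)

    def test_rerender_is_identical(self, tmp_path):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        net = _net(W, ["a", "b", "c"])
        render_network(net, layout_circular(net.labels), path=tmp_path / "1.svg")
        render_network(net, layout_circular(net.labels), path=tmp_path / "2.svg")
        m1 = (tmp_path / "1.svg.manifest.json").read_text()
        m2 = (tmp_path / "2.svg.manifest.json").read_text()
        assert json.loads(m1)["edges"] == json.loads(m2)["edges"]


class TestCoassignmentPanel:
    def _cam(self):
        labels = ["a", "b", "c"]
        parts = [
            CommunityPartition(labels=labels, assignment={"a": 0, "b": 0, "c": 1}, Q=0.0)
        ] * 4 + [
            CommunityPartition(labels=labels, assignment={"a": 0, "b": 1, "c": 1}, Q=0.0)
        ]
        return coassignment(parts)

    def test_colormap_endpoints(self, tmp_path):
        labels = ["a", "b", "c"]
        P = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        cam = CoAssignmentMatrix(labels=labels, P=P, B_effective=10)
        man = render_coassignment_panel(cam, "a", tmp_path / "p.svg")
        fills = {c["node"]: tuple(c["fill"]) for c in man["cells"]}
        assert fills["b"] == (1.0, 1.0, 1.0)  # proportion 1 -> white
        assert fills["c"] == (1.0, 0.0, 0.0)  # proportion 0 -> red

    def test_cell_text_two_decimals_and_own_column_excluded(self, tmp_path):
        man = render_coassignment_panel(self._cam(), "a", tmp_path / "p.svg")
        assert man["columns"] == ["b", "c"]
        vals = {c["node"]: c["value"] for c in man["cells"]}
        assert vals["b"] == pytest.approx(0.8)

    def test_unknown_node_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown"):
            render_coassignment_panel(self._cam(), "zzz", tmp_path / "p.svg")


class TestCiLines:
    def _table(self, lo_eq_hi=False):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": ["a", "b", "c"],
                "point": [1.0, 2.0, 3.0],
                "lo": [1.0, 1.5, 2.5] if not lo_eq_hi else [1.0, 2.0, 3.0],
                "hi": [1.0, 2.5, 3.5] if not lo_eq_hi else [1.0, 2.0, 3.0],
            }
        )

    def test_band_bounds_equal_interval_verbatim(self, tmp_path):
        man = render_ci_lines({"g1": self._table()}, tmp_path / "ci.svg")
        s = man["series"]["g1"]
        assert s["lo"] == [1.0, 1.5, 2.5] and s["hi"] == [1.0, 2.5, 3.5]

    def test_constant_bootstrap_band_collapses(self, tmp_path):
        man = render_ci_lines({"g1": self._table(lo_eq_hi=True)}, tmp_path / "c.svg")
        s = man["series"]["g1"]
        assert s["lo"] == s["point"] == s["hi"]

    def test_groups_plotted_in_declared_order(self, tmp_path):
        man = render_ci_lines(
            {"z_first": self._table(), "a_second": self._table()}, tmp_path / "o.svg"
        )
        assert man["groups"] == ["z_first", "a_second"]
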