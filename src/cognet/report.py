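"""Figures mirroring the study's visual outputs, with testable manifests.

Circular and spring-embedded network plots (green positive / red
negative edges, width proportional to |partial correlation|, node color
by community), per-node centrality and per-edge weight lines with shaded
95% bootstrap bands, and white-to-red co-assignment panels. Every
renderer writes a JSON "figure manifest" next to the image describing
exactly what was drawn (edges, colors, widths, cell values), so tests
assert content rather than pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .ggm import PartialCorrelationNetwork
from .graph import CoAssignmentMatrix, CommunityPartition

__all__ = [
    "LayoutSpec",
    "layout_circular",
    "layout_spring",
    "render_network",
    "render_coassignment_panel",
    "render_ci_lines",
]

_COMMUNITY_CMAP = plt.get_cmap("tab10")


@dataclass
class LayoutSpec:
    style: str  # "circular" | "spring"
    coordinates: dict[str, tuple[float, float]]
    seed: int | None = None


def layout_circular(labels: list[str]) -> LayoutSpec:
    """Nodes equally spaced on the unit circle, first at the top, clockwise."""
    if len(labels) < 1:
        raise ValueError("need at least one node")
    p = len(labels)
    coords = {}
    for k, lbl in enumerate(labels):
        theta = np.pi / 2 - 2 * np.pi * k / p
        coords[lbl] = (float(np.cos(theta)), float(np.sin(theta)))
    return LayoutSpec(style="circular", coordinates=coords)


def layout_spring(
    net: PartialCorrelationNetwork, seed: int = 0, iterations: int = 200
) -> LayoutSpec:
    """Fruchterman-Reingold layout with |weight| attraction, seeded."""
    G = nx.Graph()
    G.add_nodes_from(net.labels)
    for i in range(net.p):
        for j in range(i + 1, net.p):
            if net.W[i, j] != 0.0:
                G.add_edge(net.labels[i], net.labels[j], weight=abs(float(net.W[i, j])))
    pos = nx.spring_layout(G, seed=seed, iterations=iterations, weight="weight")
    coords = {lbl: (float(x), float(y)) for lbl, (x, y) in pos.items()}
    return LayoutSpec(style="spring", coordinates=coords, seed=seed)


def _write_manifest(path: Path, manifest: dict) -> Path:
    mpath = path.with_suffix(path.suffix + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def render_network(
    net: PartialCorrelationNetwork,
    layout: LayoutSpec,
    partition: CommunityPartition | None = None,
    path: str | Path = "network.svg",
    max_width: float = 6.0,
) -> dict:
    """Draw the network; returns the figure manifest (also written as JSON).

    Edge color encodes sign (green positive, red negative), edge width is
    proportional to |weight|, node fill encodes community membership.
    """
    path = Path(path)
    wmax = float(np.abs(net.W).max()) or 1.0
    edges = []
    fig, ax = plt.subplots(figsize=(6, 6))
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = float(net.W[i, j])
            if w == 0.0:
                continue
            a, b = net.labels[i], net.labels[j]
            color = "green" if w > 0 else "red"
            width = max_width * abs(w) / wmax
            xa, ya = layout.coordinates[a]
            xb, yb = layout.coordinates[b]
            ax.plot([xa, xb], [ya, yb], color=color, linewidth=width, zorder=1)
            edges.append(
                {"a": a, "b": b, "weight": w, "color": color, "width": width}
            )
    nodes = []
    for lbl in net.labels:
        x, y = layout.coordinates[lbl]
        comm = partition.assignment[lbl] if partition else 0
        ax.scatter([x], [y], s=900, color=_COMMUNITY_CMAP(comm % 10), zorder=2,
                   edgecolors="black")
        ax.annotate(lbl, (x, y), ha="center", va="center", fontsize=8, zorder=3)
        nodes.append({"label": lbl, "x": x, "y": y, "community": comm})
    ax.set_axis_off()
    ax.set_title(f"{net.group_name} (lambda={net.lambda_selected:.3f}, n={net.n})")
    fig.savefig(path)
    plt.close(fig)
    manifest = {
        "figure": "network",
        "style": layout.style,
        "group": net.group_name,
        "edges": sorted(edges, key=lambda e: (e["a"], e["b"])),
        "nodes": nodes,
    }
    _write_manifest(path, manifest)
    return manifest


def render_coassignment_panel(
    matrices: CoAssignmentMatrix | dict[str, CoAssignmentMatrix],
    node_of_interest: str,
    path: str | Path = "coassignment.svg",
) -> dict:
    """One row per group: co-assignment of the node of interest with every
    other node, cell text = proportion, fill from red (0) to white (1)."""
    if isinstance(matrices, CoAssignmentMatrix):
        matrices = {"": matrices}
    path = Path(path)
    first = next(iter(matrices.values()))
    if node_of_interest not in first.labels:
        raise ValueError(f"unknown node {node_of_interest!r}")
    others = [lbl for lbl in first.labels if lbl != node_of_interest]
    groups = list(matrices)
    cells = []
    fig, ax = plt.subplots(figsize=(1 + len(others), 1 + len(groups)))
    for r, g in enumerate(groups):
        cam = matrices[g]
        i = cam.labels.index(node_of_interest)
        for c, other in enumerate(others):
            v = float(cam.P[i, cam.labels.index(other)])
            fill = (1.0, v, v)  # red at 0 -> white at 1
            ax.add_patch(plt.Rectangle((c, len(groups) - 1 - r), 1, 1,
                                       facecolor=fill, edgecolor="black"))
            ax.text(c + 0.5, len(groups) - 1 - r + 0.5, f"{v:.2f}",
                    ha="center", va="center", fontsize=9)
            cells.append({"group": g, "node": other, "value": v, "fill": fill})
    ax.set_xlim(0, len(others))
    ax.set_ylim(0, len(groups))
    ax.set_xticks([c + 0.5 for c in range(len(others))])
    ax.set_xticklabels(others)
    ax.set_yticks([len(groups) - 1 - r + 0.5 for r in range(len(groups))])
    ax.set_yticklabels(groups)
    ax.set_title(f"Same-community proportions: {node_of_interest}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    manifest = {
        "figure": "coassignment_panel",
        "node_of_interest": node_of_interest,
        "columns": others,
        "groups": groups,
        "cells": cells,
    }
    _write_manifest(path, manifest)
    return manifest


def render_ci_lines(
    tables,  # dict[group, DataFrame] with columns (node | node_a+node_b), point, lo, hi
    path: str | Path = "ci.svg",
    title: str = "",
) -> dict:
    """Per-group point-estimate lines with shaded 95% bootstrap bands."""
    path = Path(path)
    groups = list(tables)
    if not groups:
        raise ValueError("need at least one group table")
    series = {}
    fig, ax = plt.subplots(figsize=(8, 4))
    for g in groups:
        df = tables[g]
        if "node" in df.columns:
            x_labels = df["node"].tolist()
        else:
            x_labels = (df["node_a"] + "-" + df["node_b"]).tolist()
        x = np.arange(len(x_labels))
        ax.plot(x, df["point"], marker="o", label=str(g))
        ax.fill_between(x, df["lo"], df["hi"], alpha=0.25)
        series[str(g)] = {
            "x": x_labels,
            "point": [float(v) for v in df["point"]],
            "lo": [float(v) for v in df["lo"]],
            "hi": [float(v) for v in df["hi"]],
        }
    ax.set_xticks(np.arange(len(x_labels)))
    ax.set_xticklabels(x_labels, rotation=90, fontsize=7)
    ax.set_title(title)
    ax.legend()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    manifest = {"figure": "ci_lines", "title": title, "groups": groups, "series": series}
    _write_manifest(path, manifest)
    return manifest
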