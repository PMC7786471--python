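"""Sociogram rendering.

Actors are drawn as squares colored by ring (ring 1 yellow, ring 2 green,
ring 3 blue), sized linearly in out-degree — actors with structurally
missing out-degree (ring 3) get the minimum size.  Edges are either plain
black, or colored by reciprocity: a mutual pair is drawn once as a blue
line, a one-sided nomination as a red arrow.  The layout is seeded
force-directed, so a fixed seed gives identical coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx

from .core_model import CollaborationNetwork
from .network_metrics import out_degree

RING_COLORS = {1: "gold", 2: "mediumseagreen", 3: "royalblue"}
RING_LABELS = {1: "ring 1 (program)", 2: "ring 2 (responders)", 3: "ring 3 (non-responders)"}


@dataclass(frozen=True)
class SociogramStyle:
    """Node/edge styling; defaults follow the field's ring conventions."""

    node_shape: str = "s"
    node_colors: dict = field(default_factory=lambda: dict(RING_COLORS))
    base_size: float = 80.0
    size_per_contact: float = 45.0  # linear in out-degree
    edge_mode: str = "plain"  # "plain" or "reciprocity"


def layout_positions(
    network: CollaborationNetwork, layout_seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Deterministic force-directed coordinates for a fixed seed."""
    pos = nx.spring_layout(network.graph, seed=layout_seed)
    return {str(k): (float(v[0]), float(v[1])) for k, v in pos.items()}


def positions_json(positions: dict[str, tuple[float, float]]) -> str:
    """Canonical serialization of layout coordinates (byte-stable)."""
    return json.dumps(
        {k: [f"{x:.12f}", f"{y:.12f}"] for k, (x, y) in sorted(positions.items())},
        sort_keys=True,
    )


def render_sociogram(
    network: CollaborationNetwork,
    path: str | Path,
    style: Optional[SociogramStyle] = None,
    layout_seed: int = 0,
    title: Optional[str] = None,
) -> dict[str, tuple[float, float]]:
    """Draw the network to ``path`` (PNG/SVG by extension); returns the node
    coordinates used."""
    if len(network) == 0:
        raise ValueError("cannot render an empty network")
    style = style or SociogramStyle()
    positions = layout_positions(network, layout_seed)

    sizes, colors = [], []
    for actor in network.actors.values():
        d = out_degree(network, actor.actor_id)
        sizes.append(style.base_size + style.size_per_contact * (d or 0))
        colors.append(style.node_colors.get(actor.ring, "grey"))

    fig, ax = plt.subplots(figsize=(7, 7))
    arcs = network.arcs()
    if style.edge_mode == "reciprocity":
        mutual = {(s, t) for (s, t) in arcs if (t, s) in arcs and s < t}
        one_sided = [(s, t) for (s, t) in arcs if (t, s) not in arcs]
        nx.draw_networkx_edges(
            network.graph, positions, edgelist=sorted(mutual), ax=ax,
            edge_color="blue", arrows=False, width=1.4,
        )
        nx.draw_networkx_edges(
            network.graph, positions, edgelist=sorted(one_sided), ax=ax,
            edge_color="red", arrows=True, arrowsize=8, width=0.9,
        )
    elif style.edge_mode == "plain":
        nx.draw_networkx_edges(
            network.graph, positions, ax=ax, edge_color="black",
            arrows=True, arrowsize=8, width=0.9,
        )
    else:
        raise ValueError(f"unknown edge mode {style.edge_mode!r}")

    ax.scatter(
        [positions[a][0] for a in network.actors],
        [positions[a][1] for a in network.actors],
        s=sizes, c=colors, marker=style.node_shape,
        edgecolors="black", linewidths=0.5, zorder=3,
    )
    rings_present = sorted({a.ring for a in network.actors.values()})
    handles = [
        plt.Line2D(
            [], [], marker="s", linestyle="", markersize=8,
            markerfacecolor=style.node_colors.get(r, "grey"),
            markeredgecolor="black", label=RING_LABELS.get(r, f"ring {r}"),
        )
        for r in rings_present
    ]
    ax.legend(handles=handles, loc="lower left", fontsize=8)
    ax.set_title(
        title
        or f"{network.district} — {network.timepoint.value} "
        f"({style.edge_mode} edges)"
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return positions
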