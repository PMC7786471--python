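"""Standard-format readers and writers: GraphML, Pajek NET, edge list.

GraphML is the canonical interchange format — it is attribute-rich, so a
single file round-trips actors, arcs, ratings and ring/discipline
attributes.  Pajek NET and delimited edge lists are provided for
interoperability with classic SNA tools; neither format holds arbitrary
node attributes, so both write a sidecar actor table
(``<path>.actors.tsv``) that the readers pick up when present.

Unvalued arcs are stored in Pajek with the sentinel weight 0.0 (real
ratings live in [1, 10]).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from .core_model import (
    Actor,
    CollaborationNetwork,
    Tie,
    Timepoint,
    read_actor_table,
    write_actor_table,
)

FORMATS = ("graphml", "pajek", "edgelist")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".actors.tsv")


def write_network(
    network: CollaborationNetwork, path: str | Path, format: str = "graphml"
) -> Path:
    """Write a network; returns the main file path written."""
    path = Path(path)
    if format == "graphml":
        g = network.graph.copy()
        # GraphML needs scalar attrs; absent value ↦ attribute omitted
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "pajek":
        g = nx.DiGraph()
        for actor_id in network.actors:
            g.add_node(actor_id)
        for tie in network.ties:
            g.add_edge(
                tie.source, tie.target, weight=0.0 if tie.value is None else tie.value
            )
        nx.write_pajek(g, path)
        write_actor_table(network.actors.values(), _sidecar(path))
    elif format == "edgelist":
        rows = [
            {
                "source": t.source,
                "target": t.target,
                "value": "" if t.value is None else f"{t.value:.1f}",
            }
            for t in network.ties
        ]
        pd.DataFrame(rows, columns=["source", "target", "value"]).to_csv(
            path, sep="\t", index=False
        )
        write_actor_table(network.actors.values(), _sidecar(path))
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    return path


def _actors_from_table(path: Path, rings: dict[str, int]) -> list[Actor]:
    df = read_actor_table(path)
    return [
        Actor(
            actor_id=str(row.actor_id),
            discipline=str(row.discipline),
            district=str(row.district),
            is_program_participant=bool(row.program),
            responded_t0=bool(row.responded_t0),
            responded_t1=bool(row.responded_t1),
            ring=rings.get(
                str(row.actor_id),
                1
                if row.program
                else 2
                if (row.responded_t0 or row.responded_t1)
                else 3,
            ),
        )
        for row in df.itertuples()
    ]


def read_network(
    path: str | Path,
    format: str = "graphml",
    district: str = "",
    timepoint: Timepoint | str = Timepoint.T0,
) -> CollaborationNetwork:
    """Read a network written by :func:`write_network`.

    For GraphML, district/timepoint are taken from the file when present.
    For Pajek/edge list the sidecar actor table supplies attributes; without
    it, actors are reconstructed with unknown discipline (warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:  # malformed XML/GraphML
            raise ValueError(f"malformed GraphML in {path}: {exc}") from exc
        actors = [
            Actor(
                actor_id=str(node),
                discipline=str(data.get("discipline", "unknown")),
                district=str(data.get("district", district)),
                is_program_participant=bool(data.get("is_program_participant", False)),
                responded_t0=bool(data.get("responded_t0", False)),
                responded_t1=bool(data.get("responded_t1", False)),
                ring=int(data.get("ring", 3)),
            )
            for node, data in g.nodes(data=True)
        ]
        tp = Timepoint.coerce(g.graph.get("timepoint", timepoint))
        ties = [
            Tie(str(s), str(t), data.get("value"), tp)
            for s, t, data in g.edges(data=True)
        ]
        return CollaborationNetwork(
            actors, ties, district=g.graph.get("district", district), timepoint=tp
        )

    tp = Timepoint.coerce(timepoint)
    if format == "pajek":
        try:
            g = nx.read_pajek(path)
        except Exception as exc:
            raise ValueError(f"malformed Pajek NET in {path}: {exc}") from exc
        arcs = [
            (str(s), str(t), d.get("weight"))
            for s, t, d in nx.DiGraph(g).edges(data=True)
        ]
        node_ids = [str(n) for n in g.nodes]
    elif format == "edgelist":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        except Exception as exc:
            raise ValueError(f"malformed edge list in {path}: {exc}") from exc
        if not {"source", "target"} <= set(df.columns):
            raise ValueError(f"edge list {path} lacks source/target columns")
        arcs = [
            (
                str(row.source),
                str(row.target),
                None if pd.isna(getattr(row, "value", None)) else float(row.value),
            )
            for row in df.itertuples()
        ]
        node_ids = []
        for s, t, _ in arcs:
            for n in (s, t):
                if n not in node_ids:
                    node_ids.append(n)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")

    ties = []
    for s, t, w in arcs:
        value = None if w is None else float(w)
        ties.append(Tie(s, t, None if value == 0.0 else value, tp))
    sidecar = _sidecar(path)
    if sidecar.exists():
        actors = _actors_from_table(sidecar, {})
        known = {a.actor_id for a in actors}
        extras = [n for n in node_ids if n not in known]
    else:
        warnings.warn(
            f"no sidecar actor table next to {path}; actors reconstructed "
            "without attributes",
            UserWarning,
            stacklevel=2,
        )
        actors, extras = [], list(node_ids)
    actors += [
        Actor(n, "unknown", district, responded_t0=True, responded_t1=True, ring=2)
        for n in extras
    ]
    if not district and actors:
        district = actors[0].district
    return CollaborationNetwork(actors, ties, district=district, timepoint=tp)
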