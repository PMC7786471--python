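"""Network-development metrics: contacts, reciprocity, diversity, value.

All metrics respect the unit-non-response structure of the data: ring-3
actors (nominated but never responded) have structurally *missing*
out-degree, so they are excluded from average-degree numerators and
denominators, while density denominators still count them whenever the
chosen ring subset includes them — a deliberate, documented downward bias
that matches how both "rings 1 and 2" and "rings 1, 2 and 3" columns are
conventionally reported.

Reciprocity is dyad-based by default (mutual dyads / non-null dyads),
matching the "pairs who shared a reciprocal connection" reading; the
arc-based variant (reciprocated arcs / arcs) is available via
``method="arc"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Iterable, Mapping, Optional

import numpy as np

from .core_model import CollaborationNetwork, DiversityComponents, EIDecomposition


@dataclass(frozen=True)
class NodeSubsetSpec:
    """Which rings a metric is computed over."""

    rings_included: frozenset[int]

    def __post_init__(self) -> None:
        if not self.rings_included:
            raise ValueError("ring subset must be non-empty")
        if not self.rings_included <= {1, 2, 3}:
            raise ValueError("rings must be within {1, 2, 3}")

    @property
    def label(self) -> str:
        return "rings_" + "".join(str(r) for r in sorted(self.rings_included))


RINGS_12 = NodeSubsetSpec(frozenset({1, 2}))
RINGS_123 = NodeSubsetSpec(frozenset({1, 2, 3}))


def _subset_ids(network: CollaborationNetwork, subset: NodeSubsetSpec) -> list[str]:
    ids = network.ids_in_rings(subset.rings_included)
    if not ids:
        raise ValueError(f"no actors in subset {subset.label}")
    return ids


def _subset_arcs(
    network: CollaborationNetwork, members: Collection[str]
) -> set[tuple[str, str]]:
    member_set = set(members)
    return {
        (s, t)
        for (s, t) in network.arcs()
        if s in member_set and t in member_set and s != t
    }


# ---------------------------------------------------------------------------
# number of contacts
# ---------------------------------------------------------------------------

def out_degree(network: CollaborationNetwork, actor_id: str) -> Optional[int]:
    """Number of professionals the actor nominated; ``None`` (missing) for
    actors who did not respond at this timepoint."""
    if actor_id not in network.actors:
        raise KeyError(f"unknown actor {actor_id!r}")
    if not network.actors[actor_id].responded_at(network.timepoint):
        return None
    return sum(1 for (s, _) in network.arcs() if s == actor_id)


def in_degree(network: CollaborationNetwork, actor_id: str) -> int:
    """Number of nominations received (always observed, even for ring 3)."""
    if actor_id not in network.actors:
        raise KeyError(f"unknown actor {actor_id!r}")
    return sum(1 for (_, t) in network.arcs() if t == actor_id)


def average_degree(
    network: CollaborationNetwork, subset: NodeSubsetSpec = RINGS_123
) -> float:
    """Mean out-degree over subset actors with an observed out-degree."""
    degrees = [
        d
        for actor_id in _subset_ids(network, subset)
        if (d := out_degree(network, actor_id)) is not None
    ]
    if not degrees:
        raise ValueError(
            f"no actor in subset {subset.label} has an observed out-degree"
        )
    return float(np.mean(degrees))


def density(
    network: CollaborationNetwork, subset: NodeSubsetSpec = RINGS_123
) -> float:
    """Arcs among subset actors over the n(n-1) possible directed arcs."""
    ids = _subset_ids(network, subset)
    n = len(ids)
    if n < 2:
        raise ValueError("density needs at least two actors")
    return len(_subset_arcs(network, ids)) / (n * (n - 1))


# ---------------------------------------------------------------------------
# reciprocity
# ---------------------------------------------------------------------------

def dyad_census(
    arcs: Collection[tuple[str, str]], n_nodes: int
) -> tuple[int, int, int]:
    """(mutual, asymmetric, null) dyad counts for a simple directed graph.

    ``arcs`` must be loop-free and duplicate-free; ``n_nodes`` fixes the
    number of unordered pairs, n(n-1)/2.
    """
    arc_set = set(arcs)
    mutual2 = sum(1 for (s, t) in arc_set if (t, s) in arc_set)
    if mutual2 % 2:
        raise ValueError("arc set is inconsistent (odd reciprocated count)")
    mutual = mutual2 // 2
    asymmetric = len(arc_set) - mutual2
    null = n_nodes * (n_nodes - 1) // 2 - mutual - asymmetric
    return mutual, asymmetric, null


def reciprocity(
    network: CollaborationNetwork,
    subset: NodeSubsetSpec = RINGS_12,
    method: str = "dyad",
) -> float:
    """Share of connected pairs whose nomination is returned.

    ``method="dyad"`` (default): mutual dyads / (mutual + asymmetric dyads).
    ``method="arc"``: reciprocated arcs / all arcs.
    """
    ids = _subset_ids(network, subset)
    arcs = _subset_arcs(network, ids)
    mutual, asymmetric, _ = dyad_census(arcs, len(ids))
    if mutual + asymmetric == 0:
        raise ValueError("reciprocity undefined: no connected dyads in subset")
    if method == "dyad":
        return mutual / (mutual + asymmetric)
    if method == "arc":
        return 2 * mutual / (2 * mutual + asymmetric)
    raise ValueError(f"unknown reciprocity method {method!r}")


# ---------------------------------------------------------------------------
# E-I index
# ---------------------------------------------------------------------------

def ei_decomposition(
    network: CollaborationNetwork,
    group: object,
    subset: NodeSubsetSpec = RINGS_123,
    partition: Optional[Mapping[str, object]] = None,
) -> EIDecomposition:
    """External-internal decomposition of one group's outgoing contacts.

    The partition defaults to ring membership.  Arcs are counted from group
    members to targets inside the chosen subset; the E-I index is
    (external - internal) / (external + internal), missing when the group
    has no contacts.
    """
    ids = _subset_ids(network, subset)
    if partition is None:
        partition = {a.actor_id: a.ring for a in network.actors.values()}
    labels = {partition.get(i) for i in ids}
    if group not in labels:
        raise ValueError(f"unknown group label {group!r} in subset {subset.label}")
    members = {i for i in ids if partition.get(i) == group}
    arcs = _subset_arcs(network, ids)
    internal = sum(1 for (s, t) in arcs if s in members and t in members)
    external = sum(1 for (s, t) in arcs if s in members and t not in members)
    size = len(members)
    total = internal + external
    return EIDecomposition(
        group=group,
        group_size=size,
        internal_contacts=internal,
        external_contacts=external,
        internal_avg_degree=internal / size,
        external_avg_degree=external / size,
        ei_index=None if total == 0 else (external - internal) / total,
    )


# ---------------------------------------------------------------------------
# diversity of contacts
# ---------------------------------------------------------------------------

def diversity(
    network: CollaborationNetwork, actor_id: str
) -> Optional[DiversityComponents]:
    """Discipline-diversity index of the actor's *received* nominations.

    In-degree is the basis because received nominations track actual
    collaboration more reliably than self-reports.  H_i is the product of
    the cross-discipline in-tie share P_iR and the share of other
    disciplines reached D_iD.  Returns ``None`` when the actor received no
    nominations (index undefined for that actor); raises when the network
    hosts a single discipline (index undefined for the whole network).
    """
    if actor_id not in network.actors:
        raise KeyError(f"unknown actor {actor_id!r}")
    disciplines = network.disciplines()
    if len(disciplines) < 2:
        raise ValueError("diversity undefined: network has a single discipline")
    own = network.actors[actor_id].discipline
    senders = [s for (s, t) in network.arcs() if t == actor_id]
    r_i = len(senders)
    if r_i == 0:
        return None
    sender_disciplines = [network.actors[s].discipline for s in senders]
    r_div = sum(1 for d in sender_disciplines if d != own)
    d_i = len(disciplines) - 1
    d_div = len({d for d in sender_disciplines if d != own})
    p_ir = r_div / r_i
    d_id = d_div / d_i
    return DiversityComponents(
        r_i=r_i,
        r_div_i=r_div,
        d_i=d_i,
        d_div_i=d_div,
        p_ir=p_ir,
        d_id=d_id,
        h_i=p_ir * d_id,
    )


def mean_diversity(
    network: CollaborationNetwork, subset: NodeSubsetSpec = RINGS_12
) -> tuple[float, float]:
    """Sample mean and SD (n-1 denominator) of H_i over the subset."""
    values = [
        comp.h_i
        for actor_id in _subset_ids(network, subset)
        if (comp := diversity(network, actor_id)) is not None
    ]
    if len(values) < 2:
        raise ValueError("mean diversity needs at least two defined H_i values")
    return float(np.mean(values)), float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# value of contacts
# ---------------------------------------------------------------------------

def mean_tie_value(network: CollaborationNetwork, actor_id: str) -> Optional[float]:
    """Mean 1-10 rating the actor placed on their contacts; ``None`` when the
    actor has no rated out-ties (including all non-responders)."""
    if actor_id not in network.actors:
        raise KeyError(f"unknown actor {actor_id!r}")
    values = [
        t.value for t in network.ties if t.source == actor_id and t.value is not None
    ]
    if not values:
        return None
    return float(np.mean(values))


def value_summary(
    network: CollaborationNetwork, subset: NodeSubsetSpec = RINGS_12
) -> tuple[float, float]:
    """Sample mean and SD of per-actor mean tie values over the subset."""
    values = [
        v
        for actor_id in _subset_ids(network, subset)
        if (v := mean_tie_value(network, actor_id)) is not None
    ]
    if len(values) < 2:
        raise ValueError("value summary needs at least two rated actors")
    return float(np.mean(values)), float(np.std(values, ddof=1))
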