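"""Domain types for two-wave interprofessional collaboration network studies.

The study design this package supports is an ego-nomination survey run twice
(baseline T0 and follow-up T1) over the primary healthcare professionals of a
community district.  A fixed list of program participants (the "first ring")
each name the colleagues they collaborate with regarding care for older
people and rate every contact on a 1-10 scale; the nominated professionals
("second ring") are then invited to do the same.  Professionals who never
return a survey still appear in the network because responders nominate them,
but all of their *outgoing* contacts are missing — classic unit non-response
in sociometric data.  Actors are therefore classified into three rings:

* ring 1 — program participants (always responders),
* ring 2 — consented non-participants who responded at least once,
* ring 3 — nominated professionals who never responded (out-ties missing,
  in-ties observed).

This module houses the shared dataclasses (actors, ties, networks, the
diversity and E-I decompositions, the paired-study container and the
report shape) plus network validation and the plain-text table formats
used for interchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Discipline categories observed in the study population.  The set is not
#: closed — callers may validate against their own roster of disciplines —
#: but these are the defaults used by the synthetic cohort generator.
DEFAULT_DISCIPLINES: tuple[str, ...] = (
    "general practitioner",
    "practice nurse",
    "physiotherapist",
    "social care worker",
    "social care prescriber",
    "district nurse",
    "pharmacist",
    "specialist geriatric medicine",
    "dietician",
)


class Timepoint(str, Enum):
    """Survey wave: baseline (T0) or follow-up (T1)."""

    T0 = "T0"
    T1 = "T1"

    @classmethod
    def coerce(cls, value: "Timepoint | str") -> "Timepoint":
        if isinstance(value, Timepoint):
            return value
        return cls(str(value).upper())


@dataclass(frozen=True)
class Actor:
    """One professional on a district roster.

    ``ring`` is fixed per study (classified once from the combined T0/T1
    consent record), not per timepoint.
    """

    actor_id: str
    discipline: str
    district: str
    is_program_participant: bool = False
    responded_t0: bool = False
    responded_t1: bool = False
    ring: int = 3

    def responded_at(self, timepoint: Timepoint | str) -> bool:
        tp = Timepoint.coerce(timepoint)
        return self.responded_t0 if tp is Timepoint.T0 else self.responded_t1

    @property
    def responded_ever(self) -> bool:
        return self.responded_t0 or self.responded_t1


@dataclass(frozen=True)
class Tie:
    """A directed nomination ego → alter with an optional 1-10 rating.

    ``value`` is optional because egos need not rate every contact; metrics
    that require ratings skip unrated ties.
    """

    source: str
    target: str
    value: Optional[float] = None
    timepoint: Timepoint = Timepoint.T0


class CollaborationNetwork:
    """Directed valued graph over a district roster at a single timepoint.

    Actors with ``responded == False`` at this timepoint contribute no
    out-ties (their out-degree is structurally missing) but may receive
    in-ties from responders.
    """

    def __init__(
        self,
        actors: Iterable[Actor],
        ties: Iterable[Tie],
        district: str,
        timepoint: Timepoint | str = Timepoint.T0,
    ) -> None:
        self.actors: dict[str, Actor] = {}
        for actor in actors:
            self.actors[actor.actor_id] = actor
        self.ties: tuple[Tie, ...] = tuple(ties)
        self.district = district
        self.timepoint = Timepoint.coerce(timepoint)
        self._graph: Optional[nx.DiGraph] = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.actors)

    def __contains__(self, actor_id: str) -> bool:
        return actor_id in self.actors

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CollaborationNetwork):
            return NotImplemented
        return (
            self.actors == other.actors
            and set(self.ties) == set(other.ties)
            and self.district == other.district
            and self.timepoint == other.timepoint
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CollaborationNetwork(district={self.district!r}, "
            f"timepoint={self.timepoint.value}, n={len(self.actors)}, "
            f"arcs={len(self.ties)})"
        )

    # -- views ---------------------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        """networkx view of the network (nodes carry actor attributes,
        edges carry ``value``). Built lazily and cached."""
        if self._graph is None:
            g = nx.DiGraph(district=self.district, timepoint=self.timepoint.value)
            for actor in self.actors.values():
                g.add_node(
                    actor.actor_id,
                    discipline=actor.discipline,
                    district=actor.district,
                    ring=actor.ring,
                    is_program_participant=actor.is_program_participant,
                    responded_t0=actor.responded_t0,
                    responded_t1=actor.responded_t1,
                )
            for tie in self.ties:
                attrs = {} if tie.value is None else {"value": float(tie.value)}
                g.add_edge(tie.source, tie.target, **attrs)
            self._graph = g
        return self._graph

    def responders(self) -> set[str]:
        """Actors who responded at this network's timepoint."""
        return {
            a.actor_id
            for a in self.actors.values()
            if a.responded_at(self.timepoint)
        }

    def ids_in_rings(self, rings: Iterable[int]) -> list[str]:
        wanted = set(rings)
        return [a.actor_id for a in self.actors.values() if a.ring in wanted]

    def disciplines(self) -> set[str]:
        return {a.discipline for a in self.actors.values()}

    def arcs(self) -> set[tuple[str, str]]:
        return {(t.source, t.target) for t in self.ties}


@dataclass(frozen=True)
class DiversityComponents:
    """Per-actor components of the discipline-diversity (heterogeneity) index.

    For actor *i* (in-degree basis, because received nominations track actual
    collaboration more reliably than self-reported out-ties):

    * ``r_i`` — total in-tie count,
    * ``r_div_i`` — in-ties received from *other* disciplines,
    * ``d_i`` — disciplines present in the network minus i's own,
    * ``d_div_i`` — distinct other disciplines among i's in-ties,
    * ``p_ir = r_div_i / r_i`` — share of in-ties crossing disciplines,
    * ``d_id = d_div_i / d_i`` — share of other disciplines reached,
    * ``h_i = p_ir * d_id`` — the diversity score, 0 (homogeneous) to 1
      (maximally heterogeneous).
    """

    r_i: int
    r_div_i: int
    d_i: int
    d_div_i: int
    p_ir: float
    d_id: float
    h_i: float


@dataclass(frozen=True)
class EIDecomposition:
    """External-internal contact decomposition for one group of a partition.

    ``ei_index = (E - I) / (E + I)`` over the group's outgoing arcs:
    -1 when every contact stays inside the group, +1 when every contact
    leaves it.  ``None`` when the group has no contacts at all (the ratio is
    undefined, not zero).
    """

    group: object
    group_size: int
    internal_contacts: int
    external_contacts: int
    internal_avg_degree: float
    external_avg_degree: float
    ei_index: Optional[float]


class PrePostStudy:
    """Paired baseline/follow-up networks over one shared district roster."""

    def __init__(self, t0: CollaborationNetwork, t1: CollaborationNetwork) -> None:
        if set(t0.actors) != set(t1.actors):
            raise ValueError(
                "T0 and T1 networks must share one roster; the comprehensive "
                "district list is reused at the second timepoint"
            )
        if t0.district != t1.district:
            raise ValueError("T0 and T1 networks belong to different districts")
        self.t0 = t0
        self.t1 = t1

    @property
    def roster(self) -> set[str]:
        return set(self.t0.actors)

    @property
    def district(self) -> str:
        return self.t0.district

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PrePostStudy):
            return NotImplemented
        return self.t0 == other.t0 and self.t1 == other.t1


#: display marker for cells the report intentionally leaves blank
NOT_APPLICABLE = "N.A."


@dataclass
class MetricsReport:
    """Descriptive-statistics report: one row per
    (district, ring subset, timepoint), metric values in columns, plus a
    table of paired pre/post tests per (district, subset).

    Reciprocity, diversity and value are only defined for the rings-1+2
    subset (ring-3 actors have structurally missing out-ties); the
    corresponding cells for ring-3-inclusive subsets are marked
    not-applicable.
    """

    table: pd.DataFrame
    tests: pd.DataFrame
    not_applicable: set = field(default_factory=set)

    def to_wide(self) -> pd.DataFrame:
        """Render rows=metrics, columns=(district, subset, timepoint), with
        not-applicable cells shown as ``N.A.`` — the classic report layout."""
        wide = self.table.set_index(["district", "subset", "timepoint"]).T
        wide = wide.astype(object)
        for district, subset, column in self.not_applicable:
            for tp in ("T0", "T1"):
                if (district, subset, tp) in wide.columns and column in wide.index:
                    wide.loc[column, (district, subset, tp)] = NOT_APPLICABLE
        return wide


# ---------------------------------------------------------------------------
# plain-text interchange tables
# ---------------------------------------------------------------------------

ACTOR_TABLE_COLUMNS = [
    "actor_id",
    "discipline",
    "district",
    "program",
    "responded_t0",
    "responded_t1",
]
TIE_LIST_COLUMNS = ["timepoint", "source", "target", "value"]


def write_actor_table(actors: Iterable[Actor], path: str | Path) -> None:
    """Write the actor attribute table (tab-delimited with header)."""
    rows = [
        {
            "actor_id": a.actor_id,
            "discipline": a.discipline,
            "district": a.district,
            "program": int(a.is_program_participant),
            "responded_t0": int(a.responded_t0),
            "responded_t1": int(a.responded_t1),
        }
        for a in actors
    ]
    pd.DataFrame(rows, columns=ACTOR_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_actor_table(path: str | Path) -> pd.DataFrame:
    """Read an actor attribute table; raises on missing columns."""
    df = pd.read_csv(path, sep="\t", dtype={"actor_id": str})
    missing = set(ACTOR_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"actor table {path} missing columns: {sorted(missing)}")
    return df


def write_tie_list(ties: Iterable[Tie], path: str | Path) -> None:
    """Write a tie list (tab-delimited; values with one decimal place)."""
    rows = [
        {
            "timepoint": t.timepoint.value,
            "source": t.source,
            "target": t.target,
            "value": "" if t.value is None else f"{t.value:.1f}",
        }
        for t in ties
    ]
    pd.DataFrame(rows, columns=TIE_LIST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tie_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    missing = set(TIE_LIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tie list {path} missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(
    network: CollaborationNetwork,
    allowed_disciplines: Optional[Sequence[str]] = None,
) -> list[str]:
    """Check every type invariant; return human-readable violations.

    Returns an empty list iff the network is well formed.  Reporting only —
    never raises.  Idempotent and independent of tie ordering.
    """
    violations: list[str] = []
    tp = network.timepoint

    for actor in network.actors.values():
        if actor.ring not in (1, 2, 3):
            violations.append(f"actor {actor.actor_id}: ring must be 1, 2 or 3")
            continue
        if (actor.ring == 1) != actor.is_program_participant:
            violations.append(
                f"actor {actor.actor_id}: ring 1 and program participation "
                f"must coincide (ring={actor.ring}, "
                f"program={actor.is_program_participant})"
            )
        if actor.ring == 2 and not actor.responded_ever:
            violations.append(
                f"actor {actor.actor_id}: ring 2 requires a response at "
                "at least one timepoint"
            )
        if actor.ring == 3 and actor.responded_ever:
            violations.append(
                f"actor {actor.actor_id}: ring 3 actors never responded"
            )
        if allowed_disciplines is not None and actor.discipline not in allowed_disciplines:
            violations.append(
                f"actor {actor.actor_id}: discipline {actor.discipline!r} "
                "not in the declared set"
            )

    seen_pairs: set[tuple[str, str]] = set()
    for tie in sorted(network.ties, key=lambda t: (t.source, t.target)):
        label = f"tie {tie.source}->{tie.target}"
        if tie.source == tie.target:
            violations.append(f"{label}: self-ties are not allowed")
        for endpoint in (tie.source, tie.target):
            if endpoint not in network.actors:
                violations.append(f"{label}: endpoint {endpoint} not on roster")
        if tie.value is not None and not (1.0 <= tie.value <= 10.0):
            violations.append(f"{label}: value {tie.value} outside [1, 10]")
        if tie.timepoint != tp:
            violations.append(
                f"{label}: timepoint {tie.timepoint.value} differs from "
                f"network timepoint {tp.value}"
            )
        pair = (tie.source, tie.target)
        if pair in seen_pairs:
            violations.append(f"{label}: duplicate arc for ordered pair")
        seen_pairs.add(pair)
        source = network.actors.get(tie.source)
        if source is not None and not source.responded_at(tp):
            violations.append(
                f"{label}: source did not respond at {tp.value} — "
                "out-ties of non-responders are structurally missing"
            )
    return violations
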