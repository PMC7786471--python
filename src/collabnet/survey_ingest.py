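"""Build district rosters and networks from two-round ego-nomination surveys.

Round 1 collects nominations (and 1-10 ratings) from the program
participants; the union of egos and alters forms the single comprehensive
district list.  Round 2 invites everyone on that list, and the same list is
reused at the follow-up wave.  Ring classification uses the response record
at *either* timepoint: responding once is enough to be a ring-2 actor,
because ring membership is held fixed across the pre/post comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core_model import (
    Actor,
    CollaborationNetwork,
    PrePostStudy,
    Tie,
    Timepoint,
    read_actor_table,
    read_tie_list,
)

logger = logging.getLogger(__name__)


class ConflictingNominationError(ValueError):
    """Same ego nominated the same alter twice with different ratings."""


@dataclass
class SurveyResponse:
    """One returned survey: an ego and their (alter, rating) nominations."""

    ego: str
    nominations: list[tuple[str, Optional[float]]]
    timepoint: Timepoint = Timepoint.T0
    district: str = ""

    def __post_init__(self) -> None:
        self.timepoint = Timepoint.coerce(self.timepoint)
        self.nominations = self._normalize(self.nominations)

    def _normalize(
        self, nominations: Iterable[tuple[str, Optional[float]]]
    ) -> list[tuple[str, Optional[float]]]:
        """Drop self-nominations and duplicate alters (warning for each)."""
        out: list[tuple[str, Optional[float]]] = []
        seen: dict[str, Optional[float]] = {}
        for alter, value in nominations:
            if alter == self.ego:
                warnings.warn(
                    f"ego {self.ego} nominated itself; nomination dropped",
                    UserWarning,
                    stacklevel=3,
                )
                continue
            if alter in seen:
                if seen[alter] != value:
                    raise ConflictingNominationError(
                        f"conflicting nomination: ego {self.ego} rated alter "
                        f"{alter} both {seen[alter]} and {value}"
                    )
                warnings.warn(
                    f"ego {self.ego} listed alter {alter} twice; deduplicated",
                    UserWarning,
                    stacklevel=3,
                )
                continue
            seen[alter] = value
            out.append((alter, value))
        return out


def build_roster(program_responses: Sequence[SurveyResponse]) -> list[str]:
    """Union of all egos and nominated alters, in first-seen order.

    This is the "comprehensive list" that bounds the district network: the
    snowball from the program participants plus the fixed list of their
    nominations.
    """
    if not program_responses:
        raise ValueError("no responses: cannot build a roster")
    districts = {r.district for r in program_responses if r.district}
    if len(districts) > 1:
        raise ValueError(f"responses span several districts: {sorted(districts)}")
    roster: list[str] = []
    seen: set[str] = set()
    for response in program_responses:
        for actor_id in [response.ego] + [a for a, _ in response.nominations]:
            if actor_id not in seen:
                seen.add(actor_id)
                roster.append(actor_id)
    return roster


def classify_rings(
    roster: Sequence[str],
    program_ids: Iterable[str],
    responder_ids: Iterable[str],
) -> dict[str, int]:
    """Partition the roster into rings 1 (program), 2 (responding
    non-participants) and 3 (never responded).

    ``responder_ids`` should be the union of responders over both survey
    waves — responding once makes an actor ring 2 for the whole study.
    """
    roster_set = set(roster)
    program = set(program_ids)
    responders = set(responder_ids)
    stray_program = program - roster_set
    if stray_program:
        raise ValueError(
            f"program participants outside network boundary: {sorted(stray_program)}"
        )
    stray = responders - roster_set
    if stray:
        raise ValueError(
            f"responder outside network boundary: {sorted(stray)}"
        )
    rings: dict[str, int] = {}
    for actor_id in roster:
        if actor_id in program:
            rings[actor_id] = 1
        elif actor_id in responders:
            rings[actor_id] = 2
        else:
            rings[actor_id] = 3
    return rings


def assemble_network(
    responses: Sequence[SurveyResponse],
    roster: Sequence[str],
    rings: Mapping[str, int],
    timepoint: Timepoint | str,
    district: str = "",
    attributes: Optional[Mapping[str, Mapping[str, object]]] = None,
    responded_other: Iterable[str] = (),
) -> CollaborationNetwork:
    """Assemble the directed valued network for one timepoint.

    One arc per (ego, alter) nomination with its rating.  Non-responders
    contribute no out-arcs but keep every in-arc.  Nominations of actors not
    on the roster are accepted as ring-3 additions with a warning (the
    follow-up wave may surface new names).

    ``attributes`` maps actor_id to a dict with optional keys ``discipline``
    and ``district``; ``responded_other`` lists responders at the *other*
    timepoint so that the fixed per-study response flags are complete.
    """
    tp = Timepoint.coerce(timepoint)
    attributes = attributes or {}
    roster = list(roster)
    rings = dict(rings)
    roster_set = set(roster)
    responders_here = {r.ego for r in responses}
    missing_egos = responders_here - roster_set
    if missing_egos:
        raise ValueError(f"response ego(s) not on roster: {sorted(missing_egos)}")

    ties: dict[tuple[str, str], Tie] = {}
    for response in responses:
        if response.timepoint != tp:
            raise ValueError(
                f"response from ego {response.ego} is for "
                f"{response.timepoint.value}, expected {tp.value}"
            )
        for alter, value in response.nominations:
            if alter not in roster_set:
                warnings.warn(
                    f"nominated actor {alter} not on roster; added as ring 3",
                    UserWarning,
                    stacklevel=2,
                )
                roster.append(alter)
                roster_set.add(alter)
                rings[alter] = 3
            pair = (response.ego, alter)
            if pair in ties and ties[pair].value != value:
                raise ConflictingNominationError(
                    f"conflicting nomination: arc {pair[0]}->{pair[1]} has "
                    f"values {ties[pair].value} and {value}"
                )
            ties[pair] = Tie(response.ego, alter, value, tp)

    responded_other = set(responded_other)
    actors = []
    for actor_id in roster:
        attrs = attributes.get(actor_id, {})
        here = actor_id in responders_here
        other = actor_id in responded_other
        actors.append(
            Actor(
                actor_id=actor_id,
                discipline=str(attrs.get("discipline", "unknown")),
                district=str(attrs.get("district", district)),
                is_program_participant=rings.get(actor_id) == 1,
                responded_t0=here if tp is Timepoint.T0 else other,
                responded_t1=here if tp is Timepoint.T1 else other,
                ring=rings.get(actor_id, 3),
            )
        )
    return CollaborationNetwork(actors, ties.values(), district=district, timepoint=tp)


def response_rate(roster: Sequence[str], responder_ids: Iterable[str]) -> float:
    """Share of the nominated roster that returned a survey, in [0, 1]."""
    roster_set = set(roster)
    if not roster_set:
        raise ValueError("empty roster: response rate undefined")
    responders = set(responder_ids)
    stray = responders - roster_set
    if stray:
        raise ValueError(f"responder outside network boundary: {sorted(stray)}")
    return len(responders) / len(roster_set)


# ---------------------------------------------------------------------------
# file-level ingestion
# ---------------------------------------------------------------------------

def responses_from_tie_table(
    ties: pd.DataFrame, timepoint: Timepoint | str, district: str = ""
) -> list[SurveyResponse]:
    """Group tie-list rows into per-ego survey responses for one wave."""
    tp = Timepoint.coerce(timepoint)
    wave = ties[ties["timepoint"].map(lambda v: Timepoint.coerce(v)) == tp]
    responses = []
    for ego, group in wave.groupby("source", sort=False):
        nominations = [
            (str(row.target), None if pd.isna(row.value) else float(row.value))
            for row in group.itertuples()
        ]
        responses.append(SurveyResponse(str(ego), nominations, tp, district))
    return responses


def load_study(
    actor_path: str | Path, tie_path: str | Path, district: str = ""
) -> PrePostStudy:
    """Read the attribute table + tie list and assemble a paired study.

    The roster and ring classification come from the attribute table
    (program/responded flags); arcs come from the tie list, one network per
    timepoint over the shared roster.
    """
    actor_df = read_actor_table(actor_path)
    if district:
        actor_df = actor_df[actor_df["district"] == district]
        if actor_df.empty:
            raise ValueError(f"no actors for district {district!r} in {actor_path}")
    else:
        districts = actor_df["district"].unique()
        if len(districts) > 1:
            raise ValueError(
                f"actor table spans districts {sorted(districts)}; pass district="
            )
        district = str(districts[0])
    tie_df = read_tie_list(tie_path)
    tie_df = tie_df[tie_df["source"].isin(actor_df["actor_id"])]

    roster = list(actor_df["actor_id"])
    program_ids = set(actor_df.loc[actor_df["program"].astype(bool), "actor_id"])
    responded_t0 = set(actor_df.loc[actor_df["responded_t0"].astype(bool), "actor_id"])
    responded_t1 = set(actor_df.loc[actor_df["responded_t1"].astype(bool), "actor_id"])
    rings = classify_rings(roster, program_ids, responded_t0 | responded_t1)
    attributes = {
        str(row.actor_id): {"discipline": row.discipline, "district": row.district}
        for row in actor_df.itertuples()
    }

    networks = {}
    for tp, here, other in (
        (Timepoint.T0, responded_t0, responded_t1),
        (Timepoint.T1, responded_t1, responded_t0),
    ):
        responses = responses_from_tie_table(tie_df, tp, district)
        egos = {r.ego for r in responses}
        silent = here - egos
        if silent:
            logger.info(
                "%d responder(s) at %s made no nominations", len(silent), tp.value
            )
        networks[tp] = assemble_network(
            responses, roster, rings, tp, district, attributes, responded_other=other
        )
        # responders are flagged from the attribute table, not only from the
        # presence of nominations, so restore flags for silent responders
        fixed = []
        for actor in networks[tp].actors.values():
            r0 = actor.actor_id in responded_t0
            r1 = actor.actor_id in responded_t1
            if (actor.responded_t0, actor.responded_t1) != (r0, r1):
                actor = Actor(
                    actor.actor_id,
                    actor.discipline,
                    actor.district,
                    actor.is_program_participant,
                    r0,
                    r1,
                    actor.ring,
                )
            fixed.append(actor)
        networks[tp] = CollaborationNetwork(
            fixed, networks[tp].ties, district, tp
        )
    return PrePostStudy(networks[Timepoint.T0], networks[Timepoint.T1])
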