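import hypothesis
import pytest

from collabnet import Actor, CollaborationNetwork, Tie, Timepoint

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


def make_network(
    n=None,
    arcs=(),
    disciplines=None,
    rings=None,
    values=None,
    district="d1",
    timepoint="T0",
):
    """Small-network factory: actors ``a0..a{n-1}``, ring-2 responders by
    default, arcs given as (source_index, target_index) pairs."""
    if n is None:
        n = 1 + max((max(s, t) for s, t in arcs), default=0)
    disciplines = disciplines or {}
    rings = rings or {}
    values = values or {}
    tp = Timepoint.coerce(timepoint)
    actors = []
    for i in range(n):
        ring = rings.get(i, 2)
        responded = ring != 3
        actors.append(
            Actor(
                actor_id=f"a{i}",
                discipline=disciplines.get(i, f"disc{i % 2}"),
                district=district,
                is_program_participant=ring == 1,
                responded_t0=responded,
                responded_t1=responded,
                ring=ring,
            )
        )
    ties = [
        Tie(f"a{s}", f"a{t}", values.get((s, t)), tp) for s, t in arcs
    ]
    return CollaborationNetwork(actors, ties, district=district, timepoint=tp)


@pytest.fixture
def triangle():
    """3 responders, arcs a0->a1, a1->a0, a1->a2 (one mutual, one one-way)."""
    return make_network(3, [(0, 1), (1, 0), (1, 2)])


@pytest.fixture
def diversity_worked_example():
    """The textbook heterogeneity scenario: actor a0 receives in-ties from
    all six colleagues — three of its own discipline, three spanning every
    other discipline present (two others) — so P_iR = 0.5, D_iD = 1."""
    return make_network(
        7,
        arcs=[(i, 0) for i in range(1, 7)],
        disciplines={0: "gp", 1: "gp", 2: "gp", 3: "gp",
                     4: "nurse", 5: "nurse", 6: "social"},
    )
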