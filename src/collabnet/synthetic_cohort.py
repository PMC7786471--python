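"""Synthetic two-wave district survey generator.

Emulates the study conditions the analysis assumes: a district roster of
7-10 program participants (ring 1), a handful of consented non-participants
(ring 2) and a larger pool of nominated never-responders (ring 3, out-ties
masked); disciplines drawn from the observed professional mix; baseline arc
probabilities that put density and dyadic reciprocity in their observed
ranges; an intervention effect that raises ring-1 out-tie probability at
follow-up plus a smaller spill-over effect on ring-2 actors; and 1-10 tie
ratings.

The arc model is independent Bernoulli with a reciprocal-closure step —
each generated arc induces its reverse with probability
``reciprocity_boost`` — the simplest mechanism that reproduces the observed
density and reciprocity ranges simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .core_model import (
    Actor,
    CollaborationNetwork,
    PrePostStudy,
    Tie,
    Timepoint,
    write_actor_table,
    write_tie_list,
)

#: Pooled discipline mix of the study population (program + non-program
#: head counts): social care workers and district nurses most frequent.
DEFAULT_DISCIPLINE_WEIGHTS: dict[str, float] = {
    "general practitioner": 8,
    "practice nurse": 6,
    "physiotherapist": 2,
    "social care worker": 15,
    "social care prescriber": 7,
    "district nurse": 10,
    "pharmacist": 4,
    "specialist geriatric medicine": 1,
    "dietician": 1,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters for one district.

    Defaults mirror a district-1-sized study arm: 7 program participants,
    9 consented non-participants and 33 never-responders (response rate
    16/49 ≈ 0.33, inside the observed 27-40% band).

    * ``base_density`` — baseline arc probability p0 for every ordered pair.
    * ``effect_ring1`` / ``spill_over`` — additive increase of the arc
      probability at T1 for ring-1 / ring-2 sources (the intervention and
      its spill-over).
    * ``reciprocity_boost`` — probability that a generated arc induces its
      reverse arc (reciprocal closure).
    * ``value_mean`` / ``value_sd`` — normal tie-rating parameters, ratings
      clamped to [1, 10] and rounded to one decimal.
    * ``nonresponse_rate`` — optional; when set, the non-program pool of
      size ``n_ring2 + n_ring3`` is re-split by independent
      Bernoulli(nonresponse_rate) draws into ring 3 instead of using the
      exact counts.
    """

    n_program: int = 7
    n_ring2: int = 9
    n_ring3: int = 33
    discipline_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISCIPLINE_WEIGHTS)
    )
    base_density: float = 0.20
    effect_ring1: float = 0.15
    spill_over: float = 0.08
    reciprocity_boost: float = 0.35
    value_mean: float = 7.5
    value_sd: float = 0.6
    nonresponse_rate: Optional[float] = None
    seed: int = 0
    district: str = "district-1"

    def validate(self) -> None:
        if self.n_program < 1:
            raise ValueError("need at least one program participant")
        if min(self.n_ring2, self.n_ring3) < 0:
            raise ValueError("ring sizes must be non-negative")
        for name in ("base_density", "reciprocity_boost"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("effect_ring1", "spill_over"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0 or self.base_density + p > 1.0:
                raise ValueError(f"{name}={p} pushes arc probability outside [0, 1]")
        if self.nonresponse_rate is not None and not 0.0 <= self.nonresponse_rate <= 1.0:
            raise ValueError("nonresponse_rate outside [0, 1]")
        if not 1.0 <= self.value_mean <= 10.0:
            raise ValueError("value_mean outside the 1-10 rating scale")
        if not self.discipline_weights or min(self.discipline_weights.values()) < 0:
            raise ValueError("discipline weights must be non-negative, non-empty")


def _sample_arcs(
    rng: np.random.Generator,
    ids: list[str],
    source_prob: Mapping[str, float],
    reciprocity_boost: float,
) -> set[tuple[str, str]]:
    """Independent Bernoulli arcs with reciprocal closure."""
    n = len(ids)
    probs = np.array([source_prob[i] for i in ids])[:, None] * np.ones((1, n))
    np.fill_diagonal(probs, 0.0)
    base = rng.random((n, n)) < probs
    closure = rng.random((n, n)) < reciprocity_boost
    adj = base | (base.T & closure)
    np.fill_diagonal(adj, False)
    srcs, tgts = np.nonzero(adj)
    return {(ids[s], ids[t]) for s, t in zip(srcs, tgts)}


def _rate_arcs(
    rng: np.random.Generator,
    arcs: set[tuple[str, str]],
    mean: float,
    sd: float,
    timepoint: Timepoint,
) -> list[Tie]:
    ordered = sorted(arcs)
    values = np.clip(rng.normal(mean, sd, size=len(ordered)), 1.0, 10.0)
    return [
        Tie(s, t, round(float(v), 1), timepoint)
        for (s, t), v in zip(ordered, values)
    ]


def generate_district(config: CohortConfig) -> tuple[PrePostStudy, dict]:
    """Generate one district's paired T0/T1 networks plus ground truth.

    Returns ``(study, truth)`` where ``study`` holds the *observed* networks
    (ring-3 out-arcs masked — unit non-response) and ``truth`` carries the
    latent, unmasked networks and the parameters used, for parameter-recovery
    checks.  Identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # roster and ring assignment
    n_pool = config.n_ring2 + config.n_ring3
    n_total = config.n_program + n_pool
    ids = [f"{config.district}-a{i:03d}" for i in range(n_total)]
    program_ids = ids[: config.n_program]
    pool = ids[config.n_program:]
    if config.nonresponse_rate is None:
        ring3 = set(pool[config.n_ring2:])
    else:
        mask = rng.random(n_pool) < config.nonresponse_rate
        ring3 = {a for a, m in zip(pool, mask) if m}
    rings = {
        a: (1 if a in program_ids else 3 if a in ring3 else 2) for a in ids
    }

    categories = list(config.discipline_weights)
    weights = np.array([config.discipline_weights[c] for c in categories], float)
    disciplines = rng.choice(categories, size=n_total, p=weights / weights.sum())

    actors = [
        Actor(
            actor_id=a,
            discipline=str(d),
            district=config.district,
            is_program_participant=rings[a] == 1,
            responded_t0=rings[a] != 3,
            responded_t1=rings[a] != 3,
            ring=rings[a],
        )
        for a, d in zip(ids, disciplines)
    ]

    # latent arcs per wave; T1 raises source probability by ring
    p0 = config.base_density
    prob_t0 = {a: p0 for a in ids}
    prob_t1 = {
        a: p0
        + (config.effect_ring1 if rings[a] == 1 else 0.0)
        + (config.spill_over if rings[a] == 2 else 0.0)
        for a in ids
    }
    latent = {}
    observed = {}
    for tp, probs in ((Timepoint.T0, prob_t0), (Timepoint.T1, prob_t1)):
        arcs = _sample_arcs(rng, ids, probs, config.reciprocity_boost)
        ties = _rate_arcs(rng, arcs, config.value_mean, config.value_sd, tp)
        latent[tp] = CollaborationNetwork(
            # latent view: everyone "responds", nothing masked
            [replace(a, responded_t0=True, responded_t1=True, ring=rings[a.actor_id])
             for a in actors],
            ties,
            config.district,
            tp,
        )
        observed[tp] = CollaborationNetwork(
            actors,
            [t for t in ties if t.source not in ring3],
            config.district,
            tp,
        )

    study = PrePostStudy(observed[Timepoint.T0], observed[Timepoint.T1])
    truth = {
        "config": config,
        "rings": rings,
        "latent_t0": latent[Timepoint.T0],
        "latent_t1": latent[Timepoint.T1],
        "arc_probability_t0": prob_t0,
        "arc_probability_t1": prob_t1,
    }
    return study, truth


def generate_study_arm(
    n_districts: int = 3, seed: int = 0, **overrides
) -> list[tuple[PrePostStudy, dict]]:
    """Generate several districts with per-district sub-seeds derived
    deterministically from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n_districts)
    out = []
    for k, child in enumerate(children):
        config = CohortConfig(
            seed=int(child.generate_state(1)[0] % (2**31)),
            district=f"district-{k + 1}",
            **overrides,
        )
        out.append(generate_district(config))
    return out


def export_survey_files(
    study: PrePostStudy, outdir: str | Path, stem: Optional[str] = None
) -> tuple[Path, Path]:
    """Write the study as an actor attribute table and a tie list.

    The files round-trip through :func:`collabnet.survey_ingest.load_study`
    to an identical study: non-responders appear as attribute rows with no
    tie rows, ratings carry one decimal place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or study.district or "district"
    actor_path = outdir / f"{stem}.actors.tsv"
    tie_path = outdir / f"{stem}.ties.tsv"
    write_actor_table(study.t0.actors.values(), actor_path)
    write_tie_list(list(study.t0.ties) + list(study.t1.ties), tie_path)
    return actor_path, tie_path
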