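# collabnet

Pre/post social network analysis of **interprofessional collaboration** among
primary healthcare professionals caring for community-living older people.

Community care is delivered by a heterogeneous workforce — general
practitioners, practice and district nurses, physiotherapists, pharmacists,
social care workers — whose ability to collaborate across disciplines is hard
to observe directly. A practical measurement design is a two-wave
ego-nomination survey around an educational intervention: program
participants list the colleagues they collaborate with about care for older
people and rate each contact 1–10; everyone nominated is then invited to do
the same, and the whole exercise is repeated after the program. `collabnet`
turns such data into directed valued district networks and quantifies how the
network developed.

## The model

Actors fall into three **rings**: ring 1 = program participants, ring 2 =
consented non-participants who responded at least once, ring 3 = nominated
professionals who never responded. Ring-3 actors exhibit *unit non-response*:
their outgoing contacts are entirely missing while their incoming contacts
are observed, and every metric respects that asymmetry.

For a district network with `n` actors and arc set `A`:

- **average degree** — mean out-degree over actors with an observed
  out-degree (non-responders excluded from numerator and denominator);
- **density** — `|A| / (n(n−1))`, in `[0, 1]`;
- **reciprocity** — mutual dyads over non-null dyads, `M / (M + Asym)`
  (the arc-based variant `2M / (2M + Asym)` is available as an option);
- **E-I index** — per group `g` of a partition (ring membership by default),
  `(E − I) / (E + I)` over the group's outgoing arcs, −1 when every contact
  is internal, +1 when every contact is external, undefined when `E + I = 0`;
- **diversity** — per actor `i`, on the in-degree basis:
  `P_iR = R_div,i / R_i` (share of in-ties from other disciplines) and
  `D_iD = D_div,i / D_i` (share of the network's other disciplines reached),
  combined as `H_i = P_iR · D_iD ∈ [0, 1]`;
- **value** — per actor, the mean 1–10 rating placed on their contacts.

Baseline/follow-up change is summarised per metric, and actor-level metrics
(diversity, value) are compared with a classical **paired t test**
(differences post − pre, two-sided p, 95% CI) over actors defined at both
waves.

## Worked example

The synthetic cohort generator reproduces the study conditions (a 49-person
district roster: 7 program participants, 9 consented non-participants, 33
never-responders; Bernoulli arcs with reciprocal closure; an intervention
effect on ring 1 and a spill-over effect on ring 2):

```python
import collabnet as cn

study, truth = cn.generate_district(cn.CohortConfig(seed=42))
summary = cn.compare_networks(study, cn.RINGS_12)
```

This prints, for the rings-1+2 subset (the 16 responders):

```
density     T0 0.23 -> T1 0.41  (+18 pp)
reciprocity T0 0.33 -> T1 0.50  (+17 pp)
diversity paired t: t=4.38, df=15, p=0.0005, CI [0.082, 0.238]
```

Read: at baseline 23% of the possible directed relations among responders
existed, rising to 41% after the program; a third of connected pairs were
mutual at baseline, half afterwards; and the per-actor discipline-diversity
index increased significantly (mean change 0.16, positive t because
differences are post − pre) — the intervention plus spill-over built a
denser, more reciprocal and more interdisciplinary network.

The same analysis is available from the shell:

```bash
collabnet --seed 42 simulate --outdir data/
collabnet ingest --actors data/district-1.actors.tsv \
                 --ties data/district-1.ties.tsv --timepoint T0 --out t0.graphml
collabnet metrics --network t0.graphml --subset rings12 --by-ring
collabnet report --config config.json --outdir out/   # full pipeline + figures
collabnet draw --network t0.graphml --out t0.png --mode reciprocity
```

`report` writes a descriptive-statistics table in the classic layout — one
column block per district × ring subset × timepoint, with reciprocity,
diversity and value marked `N.A.` for ring-3-inclusive subsets — plus
sociograms (squares colored by ring, sized by out-degree; blue reciprocal /
red one-sided edges in reciprocity mode).

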