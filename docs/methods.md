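# Methods

## Study design and data model

`collabnet` analyses a two-wave (baseline T0, follow-up T1) ego-nomination
survey over the primary healthcare professionals of a community district.
The network boundary is set by combining a snowball from the program
participants with a fixed list: participants name everyone they collaborate
with regarding care for older people, the union of egos and alters becomes
the single comprehensive district roster, everyone on it is invited to
respond, and the *same roster* is reused at follow-up. Consequently the
T0 and T1 networks of a study share one actor set, and this is enforced as
an invariant of `PrePostStudy`.

Actors are classified once per study into rings:

| ring | who | out-ties | in-ties |
|------|-----|----------|---------|
| 1 | program participants | observed | observed |
| 2 | consented non-participants, responded ≥ 1 wave | observed | observed |
| 3 | nominated, never responded | **missing** | observed |

Responding at either wave is sufficient for ring 2, because the pre/post
report holds ring membership fixed. Ring-3 actors are the network's unit
non-response: they appear because responders nominate them, so their
incoming arcs are real data while their outgoing arcs simply do not exist
in the dataset. Every downstream computation treats their out-degree as
*missing*, never as zero.

Ties are directed, at most one per ordered pair per wave, and carry an
optional rating in [1, 10] (alters need not be rated; metrics that need
ratings skip unrated ties). Self-nominations and duplicate alters within a
survey response are dropped with a warning; the same arc reported twice with
*different* ratings is an error rather than an average, to surface
data-entry faults. Nominations of actors outside the roster (possible at
follow-up) are accepted as ring-3 additions with a warning.

## Metrics

**Number of contacts.** Out-degree per responder; district-level average
degree is the mean over actors with an observed out-degree (ring-3 actors
are excluded from numerator *and* denominator). Density is arcs over
`n(n−1)`. When the chosen ring subset includes ring 3, the denominator
counts ring-3 actors although their out-arcs are structurally missing; this
matches how both "rings 1+2" and "rings 1+2+3" report columns are
conventionally produced and is a known, documented downward bias of the
ring-3-inclusive density.

**Reciprocity.** Dyad-based by default: mutual dyads over non-null dyads,
from a dyad census of the subset-restricted arc set. This matches the
"pairs who both chose each other" reading; the arc-based ratio
`2M/(2M+A)` is exposed via `method="arc"`. Undefined (error) when the
subset has no connected dyads.

**E-I index.** For a group of a partition (rings by default), internal and
external contacts are counted over the group members' outgoing arcs within
the chosen subset; the index is `(E−I)/(E+I)`, and internal/external
average degree divide the counts by group size. `E+I = 0` yields a missing
value, not 0 — the ratio is undefined.

**Diversity.** Per actor, on the in-degree basis (received nominations
track actual collaboration more reliably than self-reports): `P_iR` is the
share of in-ties arriving from other disciplines, `D_iD` the share of the
network's other disciplines represented among those senders, and
`H_i = P_iR · D_iD`. One common printed form of the first component,
`(R_i − R_div,i)/R_i`, is the *complement* of the verbal definition when
`R_div,i` counts other-discipline ties; the verbal definition
(`P_iR = R_div,i/R_i`) is implemented, because only it makes high scores
mean heterogeneity — the direction the index is used in. The textbook
scenario (in-ties from everyone, half own-discipline, spanning all other
disciplines) then gives `P_iR = 0.5`, `D_iD = 1`, `H_i = 0.5`. `H_i` is a
per-actor product (no summation), and an actor with in-degree 0 has no
index; a single-discipline network makes the index undefined outright.

**Value.** Per actor, the arithmetic mean of the ratings they placed on
their contacts; missing for actors without rated out-ties (hence for all
non-responders).

## Pre/post comparison

Network-level metrics are reported as (T0, T1, change), with
percentage-point change for density and reciprocity — a density move from
0.34 to 0.51 is reported as +17 pp. Actor-level metrics (diversity,
value) are compared with a classical paired t test over rings-1+2 actors
that have a defined value at both waves; incomplete pairs are dropped and
their count logged. Differences are post − pre, so improvement gives
positive t; software that feeds pairs as (pre, post) prints the same
magnitudes with opposite sign. Two-sided p at α = 0.05, 95% CI of the
mean difference, no multiple-testing correction (raw p values per
district). Zero-variance differences return t = 0 with a
`ZeroVarianceWarning` rather than failing, so degenerate fixtures and
identical-wave edge cases stay analysable.

Reciprocity, diversity and value are only reported for the rings-1+2
subset: with ring 3 included they would mix observed and structurally
missing out-ties, so those cells are marked `N.A.` in the report, and
`compare_networks` returns `None` for them on ring-3-inclusive subsets.

## Synthetic cohort generator

The generator exists so the full pipeline is runnable and testable with no
external data; its defaults are the study conditions, not tuning knobs.

- **Roster**: 7 program participants, 9 consented non-participants, 33
  never-responders (49 actors; response rate 16/49 ≈ 0.33, inside the
  observed 27–40% band). `nonresponse_rate`, when set, re-splits the
  non-program pool by independent Bernoulli draws instead of exact counts.
- **Disciplines**: sampled from the pooled professional mix of the study
  population (social care workers and district nurses most frequent, single
  specialists in geriatric medicine and dietetics).
- **Arcs**: independent Bernoulli with probability `base_density = 0.2`
  per ordered pair, plus a reciprocal-closure step — each generated arc
  induces its reverse with probability `reciprocity_boost = 0.35`. This is
  the simplest mechanism that lands latent density (≈ 0.26 marginal) and
  dyadic reciprocity (≈ 0.42) in their observed ranges simultaneously.
  At T1 the source-ring-specific probability rises by
  `effect_ring1 = 0.15` (the intervention) and `spill_over = 0.08`
  (ring-2 spill-over). T0 and T1 arcs are drawn independently.
- **Ratings**: normal(7.5, 0.6) clamped to [1, 10] and rounded to one
  decimal — a stand-in distribution matching the magnitude of observed
  value scores, not an estimate.
- **Masking**: ring-3 actors' out-arcs are removed from the observed
  networks (the latent, unmasked networks are returned as ground truth for
  parameter-recovery checks).
- **Seeding**: one `numpy` Generator per district config; multi-district
  arms derive per-district sub-seeds deterministically from a global seed.
  Identical config ⇒ identical output.

What the generator does **not** emulate: discipline homophily or
geographic structure in tie formation, wave-to-wave tie persistence
(arcs are redrawn, not evolved), rating–tie correlation, and actors
responding at exactly one wave. Passing tests therefore demonstrate the
pipeline's correctness and calibration under the stated mechanism, not
that real district networks follow it.

## Numerical and design choices

- Degenerate denominators are errors or missing values, never silent
  zeros: density needs ≥ 2 actors, reciprocity ≥ 1 connected dyad,
  mean diversity ≥ 2 defined actors, the paired t ≥ 2 complete pairs;
  E-I with no contacts and diversity with in-degree 0 are missing.
- Sample SD uses the n−1 denominator throughout.
- Actor identifiers are opaque strings; matching names across rounds is a
  pre-processing concern with an exact-match default.
- GraphML is the canonical interchange format (self-contained attributes);
  Pajek NET and delimited edge lists write a sidecar
  `<path>.actors.tsv` for actor attributes, and Pajek encodes an unrated
  arc as weight 0.0 (ratings live in [1, 10], so 0 is unambiguous).
- Sociograms use a seeded force-directed layout; node size is *linear* in
  out-degree (the scaling function is otherwise arbitrary), with minimum
  size for missing out-degree.
- Problem sizes in the test suite: exhaustive dyad-census verification on
  all digraphs with ≤ 4 nodes through the public API and all 2^20
  digraphs on 5 nodes through the shared census core, plus 500 random
  graphs up to 30 nodes; generator calibration uses 200 seeded replicates
  of a 60-actor roster. These sizes give exact coverage of the small-graph
  space and ≈ 1% Monte-Carlo precision on calibration means.

## Known limitations

- The ring-3-inclusive density is biased downward (missing out-ties in the
  denominator), so cross-subset density comparisons conflate structure
  with response behaviour; compare within a subset across waves instead.
- Diversity's `D_i` uses the whole network's discipline set, so adding an
  isolated actor of a new discipline lowers everyone's `D_iD`.
- The paired t test assumes approximately normal differences; with the
  small per-district n typical of this design (≈ 16 responders) it is a
  descriptive screen, not confirmatory inference, and no network-level
  dependence (QAP/ERGM-style) is modelled.
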