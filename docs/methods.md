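# Methods

## The audit model

A dyad (one mother–newborn pair) is the audit unit. Its first-hour record is
a timeline in integer seconds since birth (birth = 0): skin-to-skin contact
episodes (half-open intervals, right-censored with an explicit `OPEN`
sentinel when contact outlasts the observation window), care events
(removals, in-place interferences, policy holds) and coded Widström-stage
intervals. Integer seconds were chosen because field data mix `mm:ss` and
decimal-minute notations; seconds avoid decimal-minute ambiguity while being
finer than any hand-coded video timestamp.

The engine asks four ordered questions and stops at the first "no":

1. **Immediate** — is the earliest contact onset ≤ `immediate_threshold_s`
   (default 300 s, the 5-minute standard)? A sub-threshold onset preceded by
   a recorded separation/delay event stays on the path but is flagged yellow
   (a caution for review). A late or absent onset exits, attributed to
   *hospital policy* or *emergent care* from the recorded cause events; an
   uncaused late start defaults to policy attribution — institutional delay
   is the usual reading of uncaused late starts in elective-caesarean
   settings — unless `strict_attribution` makes it an error.
2. **Continuous** — does contact persist from onset to
   `continuity_horizon_s` (default 3600 s, measured from birth)? The first
   removal event or uncovered contact gap before the horizon exits the dyad
   (*emergent* or *routine* by the removal reason; a bare gap with no
   matching event counts as routine). Gaps up to `gap_tolerance_s` (default
   0: any separation restarts the newborn's stage progression) are forgiven.
   A **maternal-request removal does not exit here**: it is bookkept as an
   interruption and handled at the next step, so a cohort narrative of
   "seven removed for routine care, one interrupted at the mother's request"
   lands in the columns a reviewer expects.
3. **Uninterrupted** — did staff or family interfere with the newborn's
   instinctive behaviour (in-place interference, e.g. staff latching the
   baby, or a maternal-request removal)? The earliest qualifying event
   attributes the exit; at equal timestamps a removal outranks an in-place
   interference and staff outranks family — a documented, deterministic
   tie-break. An unknown actor on a qualifying event is an error rather than
   a guess.
4. **Nine stages** — `assess_stages` over the annotations with onset inside
   the horizon. The standard is met iff a stage-8 (self-attached suckling)
   onset falls inside the window. Stage 9 (sleep) is not required: it
   typically occurs 1.5–2 h after birth, beyond a 60-minute audit window.
   Rest (stage 5) can occur at any point, so it neither raises the
   progression ceiling nor participates in sequence-order checks. Missing
   intermediate stages are tolerated (coders miss brief stages); decreasing
   first-onset pairs among non-rest stages are reported as sequence
   violations for review but do not by themselves revoke a met standard.

Funnel identities hold by construction: every dyad has exactly one exit step
(or none with the standard met), and each row of the audit matrix satisfies
`prebirth = policy + emergent + immediate`, `immediate = removed_emergent +
removed_routine + continuous`, `continuous = staff + family + uninterrupted`,
`uninterrupted = not_achieved + met`. The delayed-under-5 column is a subset
annotation of the immediate column, not an exit — delayed dyads continue on
the path.

## Robson classification

`classify_robson` implements the Canadian-modified ten-group system as a
precedence ladder: multiple pregnancy (8) > transverse/oblique lie (9) >
breech (6 nullipara / 7 multipara) > preterm singleton cephalic, ≤ 36 weeks
(10) > previous caesarean (5) > term singleton cephalic by parity and onset
(1/2 nullipara, 3/4 multipara). Subgroups encode onset (groups 2/4: A
induced, B caesarean before labour; groups 5–10: A/B/C spontaneous / induced
/ before labour). The function is total and single-valued over the valid
profile grid, verified exhaustively in tests.

`paper_compat` mode exists because one published audit filed term singleton
cephalic elective repeat caesareans under 4B although the standard precedence
puts previous caesareans in group 5. The default is strict; the modes differ
on no other profile, and switching modes moves rows of the matrix without
changing any pathway column.

## Packaged cohorts

Two deterministic fixtures encode published desk-scale audits at the
per-dyad level. Only their aggregate funnel counts and a few narrated
details are externally fixed — a 194 s (3:14) onset after a hands-and-knees
mother repositioned, one routine removal at 50 minutes, a maternal-request
removal, caesarean-cohort onsets ranging up to 3903 s — so every other
timestamp is an arbitrary constant, synthetic by construction, and tests
assert only the published aggregates plus structural validity. The latest
caesarean onset is stored as 3903 s (the decimal-minutes reading of "65.05
min"; the mm.ss reading, 3905 s, also exceeds the 3600 s horizon, so the
choice cannot affect any classification).

## The simulator

`simulate_cohort` draws per-dyad timelines from one owned `numpy` Generator
(no global randomness; same config + seed ⇒ identical cohort):

- **Profile**: categorical draw over named templates (`robson_mix`),
  defaulting to a mixed maternity case-load (≈ 42% nullipara, 38% multipara
  term cephalic, 12% repeat caesarean, 8% preterm/breech).
- **Policy exclusion** with probability `p_policy_exclusion` (default 0.15):
  a policy hold at birth plus either a uniform late onset in (300 s, window)
  or, with `p_no_ssc_given_excluded` = 0.10, no contact at all. Policy
  exclusion is deliberately the *only* source of late starts; non-excluded
  onsets are exponential with mean 60 s capped at the 5-minute threshold.
  This keeps the degenerate corners exact (exclusion probability 1 ⇒ every
  dyad exits at the immediate step; all hazards zero plus instantaneous
  stage transitions ⇒ every dyad meets the standard) at the cost of not
  modelling uncaused borderline-late onsets.
- **Removal**: exponential time-to-removal with hazard
  `removal_hazard_per_min` (default 0.004/min ≈ 21% removed within the
  hour); removals end the contact episode and carry a routine reason.
- **Interference**: independent Bernoulli staff (default 0.30, the scale of
  staff "help" observed in the vaginal-birth cohort) and family (0.05)
  in-place interferences at uniform times.
- **Stage progression**: stage k onset = onset of contact plus cumulative
  exponential gaps with means `stage_gap_means_s` (defaults summing to
  3350 s, putting the chance of suckling by 60 minutes near one half; the
  probability of reaching stage 8 by any time is the hypoexponential tail,
  derivable in closed form). Progression is truncated at removal.

What the simulator does **not** emulate: labour-medication effects on stage
progression, emergent-care exclusions, maternal-request removals, multiple
re-placements after removal, or correlation between obstetric profile and
first-hour practice. Passing property tests therefore demonstrate the
engine's invariants (funnel monotonicity, conservation, reproducibility)
under a plausible load, not clinical realism of any one facility.

## Numerical and design choices

- **Removal↔episode matching tolerance 5 s**: hand-coded video timestamps
  jitter; exact equality would reject real data.
- **Continuity horizon from birth, not from onset**: "the first hour" of the
  standard is the newborn's first hour. Configurable for protocols that
  count from initial contact.
- **Ambiguous time tokens**: the dialect (seconds / decimal minutes / mm:ss)
  is declared per file, never inferred, because `65.05` parses to different
  instants under different notations.
- **Degenerate inputs**: empty cohorts and duplicate dyad ids are errors at
  tabulation; records with structural violations (overlapping episodes,
  unmatched removals, out-of-range stages, times beyond the window) are
  rejected by the engine but reported en masse — violations are data, not
  exceptions — so a loader can list every problem in one pass.
- **Problem sizes**: the property suites run the classifier over the
  exhaustive obstetric grid and the funnel invariants over 200 simulated
  cohorts of 1000 dyads, which completes in seconds; the packaged cohorts
  are desk-scale (14 and 21 dyads) by nature.

## Known limitations

- The met-standard flag requires an explicitly annotated stage 8; a
  staff-assisted latch is treated as interference upstream, so the engine
  never has to decide whether assisted suckling "counts".
- Colour is a three-way summary (green/yellow/red); facilities wanting
  step-specific colour maps should read the per-step statuses directly.
- The audit matrix renders subgroup rows only for groups that occur in the
  cohort; a facility comparing two runs should compare on row labels, which
  are stable, rather than row positions.
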