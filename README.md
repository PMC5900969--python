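# ssc-audit

An auditable classification engine for skin-to-skin contact (SSC) practice in
the first hour after birth, for maternity-care quality-improvement teams,
lactation researchers and clinical auditors.

The Baby-Friendly Hospital Initiative's Step 4 standard asks that every
newborn be placed skin-to-skin with the mother **immediately** (within 5
minutes of birth), and remain there **continuously** and **uninterrupted**
for the first hour or so, during which an uncompromised term newborn
progresses through Widström's nine instinctive stages — birth cry,
relaxation, awakening, activity, rest, crawling, familiarization, suckling,
sleep — culminating in self-attachment and suckling (stage 8). `ssc-audit`
takes per-dyad coded timelines (contact episodes, removals, interferences,
stage annotations) and routes each mother–baby dyad through that
best-practice funnel:

```
Robson group → immediate? → continuous? → uninterrupted? → suckled? → met standard
                  │              │              │              │
                  └ policy /     └ removed      └ staff /      └ stalled before
                    emergent       routine /      family         stage 8
                    exit           emergent       interfered
```

Each dyad receives exactly one exit point (or none, when the full standard is
met), a colour (green = standard met, yellow = met with a sub-5-minute delay
caution, red = left the path), and the cohort aggregates into a
**Robson-group × pathway-step audit matrix**. Stratifying by the
Canadian-modified Robson ten-group obstetric classification (parity, previous
caesarean, plurality, presentation, gestation, labour onset, with A/B/C
onset subgroups) lets facilities compare practice across comparable
obstetric populations.

## Worked example

```python
from ssc_audit import build_japan_cohort, run_pathway, tabulate, render

results = [run_pathway(r) for r in build_japan_cohort()]
print(render(tabulate(results), "csv"))
```

The packaged 14-dyad vaginal-birth cohort prints a totals row of

```
total,14,0,0,0,14,0,1,13,7,0,6,5,1
```

read left to right along the funnel: 14 dyads prebirth; none excluded by
policy or emergent care and none delayed, so all 14 in skin-to-skin within 5
minutes; one removed for routine care (at 50 minutes), 13 continuous; staff
interfered with 7 (typically by "helping" the baby latch, which forecloses
self-attachment), 6 uninterrupted; 5 stalled at the activity stage and **1
met the full standard** of self-attached suckling. The companion 21-dyad
elective-caesarean cohort (`build_australia_cohort()`) shows the opposite
failure mode: 13 dyads never reached immediate contact because of hospital
practice, and none met the standard. Short narrative scripts live in
`examples/`.

## Command line

```bash
ssc-audit fixtures japan --out fx/            # export a cohort as CSVs
ssc-audit audit --profiles fx/profiles.csv --events fx/events.csv \
          --stages fx/stages.csv --out run/   # audit it
ssc-audit simulate --seed 7 --n 500 --out sim/
ssc-audit validate --profiles ... --events ... --stages ...
```

Input schemas (UTF-8 CSV, header mandatory, `NA`/empty = missing):

| file | columns |
|---|---|
| profiles.csv | dyad_id, parity_prior_births, previous_caesarean, plurality, presentation, gestation_weeks, labour_onset, observation_end |
| events.csv | dyad_id, time, kind (`ssc_start`/`ssc_end`/`removal`/`in_place_interference`/`policy_hold`), actor, reason |
| stages.csv | dyad_id, stage (1–9), onset, offset (`open` for censored) |

Times may be written as seconds, decimal minutes, or `mm:ss`; the notation is
declared with `--dialect`, never guessed (a token like `65.05` means 3903 s
as decimal minutes but 3905 s as mm.ss). `--robson-mode
{strict,paper_compat}` switches how term singleton cephalic repeat
caesareans are filed (group 5C by the standard precedence, 4B by one
published audit's bookkeeping); the pathway columns are unaffected.

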