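# oartx

Extraction, analytics and visualization for **online-adaptive radiotherapy
(oART)** plan-check data.

CBCT-guided adaptive platforms re-plan patients on the treatment couch
every day, producing a scheduled/adaptive plan pair per fraction (and per
structure-set revision) — a flood of planning data that is painful to
export session by session. The secondary dose-verification system paired
with such platforms already holds a JSON *plan check* for every plan, plus
a delivery log-file check for the plan that was actually treated. `oartx`
mines those checks: it enumerates and fetches them per patient, resolves
plan lineage and delivered plans from the naming grammar and log-file
links, rebuilds DVHs and evaluates dose-volume objectives, trends
structure volumes against the reference set, and accumulates everything in
a de-identified, mergeable cohort store with longitudinal visualizations.

Because clinical plan-check databases cannot ship with a toolkit, a
synthetic fixture service generates whole courses in the same JSON dialect
(HTTP or file-backed) with ground truth emitted separately, so the entire
pipeline runs and is tested offline.

## The core machinery

* **Plan lineage.** Adaptive plans are named
  `[Reference Plan ID]/[SCH|ADP][2-digit fraction][2-digit suffix]`, e.g.
  `IM103/SCH1401` + `IM103/ADP1402` for fraction 14; the suffix advances
  by two per structure-set revision, so revision = ⌈suffix/2⌉
  (`ADP1403` is revision 2). A pre-treatment plan is *delivered* iff a
  delivery log-file check links to its check ID.
* **DVHs.** Truncated cumulative point lists (the flat 100 % head and 0 %
  tail are omitted at the source) become continuous dose→volume-%
  functions: piecewise-linear between nodes, padded to exactly 100 % below
  the listed range and exactly 0 % above it. On top sit V_D / D_V
  objectives (e.g. V42.5Gy to rectum), per-fraction adaptive-vs-scheduled
  paired differences, and pointwise min / 20th / median / 80th / max
  percentile bands across a course.
* **Cohorts.** Long-format rows keyed by `(patient_uid, plan_name,
  structure)`; UIDs are `<institution>-00019`-style sequential IDs, the
  source-ID lookback index stays in a private side file, exported dates
  are shifted per patient, and exports are deterministic compressed
  archives that merge across institutions without collisions.

See `docs/methods.md` for conventions and assumptions and
`docs/fixture_schema.md` for the JSON dialect.

## Worked example

```python
from oartx import (FixtureConfig, ObjectiveSpec, build_course, build_dvh,
                   dose_at_volume, generate_course, paired_differences,
                   resolve_delivered, volume_at_dose)

dvh = build_dvh([(10, 80), (20, 20)])
volume_at_dose(dvh, 5)    # 100.0  (below the list -> padded to exactly 100 %)
volume_at_dose(dvh, 15)   # 50.0   (linear midpoint of 80 and 20)
dose_at_volume(dvh, 50)   # 15.0   (inverse on the same segment, in Gy)

docs, truth = generate_course(FixtureConfig(n_patients=1, fractions_per_patient=6, seed=3))
course = build_course(docs, resolve_delivered([d.summary for d in docs]))
print(paired_differences(course, ObjectiveSpec("V_at_dose", 42.5, "Rectum")).round(3))
```

prints the per-fraction rectum V42.5 Gy of the adaptive and scheduled
plans and their paired difference:

```
 fraction  adaptive  scheduled  difference
        1     3.863      4.445      -0.583
        2     4.453      4.120       0.333
        3     4.079      4.644      -0.566
        4     5.164      4.221       0.943
        5     4.328      4.604      -0.276
        6     4.002      4.054      -0.051
```

Values are the % of rectum volume receiving ≥ 42.5 Gy; negative
differences mean the day's re-optimized plan spared the rectum relative to
the scheduled plan recalculated on the same anatomy.

The `examples/` directory holds one short script per capability
(fixture + HTTP client, full extraction into a store, DVH objectives,
volume-trend plotting, DVH spread plots and cohort merging). A thin CLI
wraps the same library paths:

```sh
oartx fixture generate --seed 3 --patients 2 --fractions 5 --out fx/
oartx extract --config cfg.yaml --ids ids.txt
oartx export --store store/ --out cohort.zip --filter "site == 'pelvis'"
oartx plot volume-trend --config cfg.yaml --patient PT0001 --structure Bladder --out trend.png
```

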