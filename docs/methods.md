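# Methods

`oartx` mines longitudinal data from CBCT-guided online-adaptive
radiotherapy (oART) courses via the plan-check records a secondary
dose-verification system keeps for every plan. This note documents the
models and conventions the package implements, the choices made where the
problem was genuinely open, and what the synthetic fixture does and does
not emulate.

## Data model and plan lineage

Every treatment fraction of an oART course spawns a *scheduled* plan (the
reference plan recalculated on the day's anatomy) and an *adaptive* plan
(re-optimized on the day's structures); editing the daily contours spawns a
further pair. Plans are named
`[Reference Plan ID]/[SCH|ADP][2-digit fraction][2-digit suffix]` and the
suffix advances by two per structure-set revision, so the revision number
is `ceil(suffix / 2)`. Because the scheduled/adaptive suffix parity within
a pair may be exchanged, pairing is done by revision, not parity. Parsing
is deliberately liberal (five or more trailing digits are accepted, the
last two always being the suffix) while formatting enforces the strict
two-digit grammar; names that carry a session token but violate the
grammar are quarantined with a log message rather than failing the course.

Which plan of a session was actually treated is resolved purely from
delivery log-file checks: a pre-treatment check is *delivered* iff a
log-file check links to it. Zero delivered plans per fraction is a valid
state (planned, not treated). When multiple log-file checks reference the
same fraction, the latest timestamp wins — re-deliveries supersede — with
a warning; links to absent checks are dropped with a warning.

## DVH reconstruction and objectives

The source stores each structure's cumulative DVH as a truncated point
list (the flat 100 % head and 0 % tail are omitted). The package rebuilds
a continuous dose → volume-% function by piecewise-linear interpolation
between nodes, padded to **exactly** 100 % below the first node and
**exactly** 0 % above the last. Degenerate inputs are repaired
deterministically: points are sorted by dose, duplicate doses collapse to
the maximum volume, volumes are clipped to [0, 100], and non-monotone
lists are repaired with a running minimum (logged).

* `volume_at_dose` (V_D) evaluates the padded interpolant.
* `dose_at_volume` (D_V) returns the smallest dose at which the evaluated
  volume is ≤ the target; on flat segments the left endpoint is returned
  (conservative and deterministic), and at the padded 100 % plateau the
  answer is 0 Gy.
* Percentile bands evaluate every curve on a common grid spanning 0 to the
  maximum listed dose plus one step (default step 0.1 Gy in the library,
  0.5 Gy in the spread plots) and take pointwise min / 20th / median /
  80th / max. Percentiles interpolate linearly between closest order
  statistics; the convention is stated because no standard exists for
  these plots.

Doses are Gy internally; documents declaring `doseUnit_str: "cgy"` are
converted on read. The two DVH sources (planning system vs. secondary
calculation) are kept as separate series everywhere — no silent mixing.

Plan complexity uses the only beam data the source exports (no MLC
apertures): total MU, control-point and beam counts, and a modulation
factor defined as total MU divided by the per-fraction prescription in
cGy. This definition is a documented package convention and is trivially
overridable by consumers who prefer another normalization.

## Structure roles and volume trends

ROI matching is case-insensitive and ignores whitespace/underscores.
Names prefixed `PTV`/`CTV` are targets, ranked by prescribed dose into
exactly three tiers (low / intermediate / high); more than three dose
levels pool the middle tiers as intermediate with a warning, a single
target is the high tier, and equal doses tie-break alphabetically. When
no dose table is supplied, `_High`/`_Int`/`_Low` name suffixes are used as
a rank surrogate. Organs at risk come from a per-site registry
(pelvis / thorax / head-and-neck defaults ship with the package; the
registry serializes to an editable YAML file).

Volume trends carry the per-session structure volumes straight from the
source documents (nothing is recomputed) and report absolute and relative
deltas versus the reference structure set, plus centroid shift as both a
Euclidean magnitude and per-axis components — contour geometry is not
exported by the source, so consistency checks are limited to volume and
center-of-mass. Relative deltas are undefined (NaN, never zero) when the
reference volume is zero or the structure is absent from the reference.

## Cohort store, de-identification and merge

Rows are long-format, keyed by `(patient_uid, plan_name, structure)`.
UIDs are `<institution id>-<5-digit sequential index>` (widening past
99999); the source-ID → UID lookback index is stored in a private side
file and is excluded from every export. Exported timestamps are shifted
per patient by a day offset seeded from the UID (0–3652 days), preserving
intra-patient fraction spacing while decoupling calendar dates.

Exports are single compressed archives (deterministic zip: fixed member
dates, canonical row/column order) containing the CSV table, a manifest
with schema version, institution list, extensible-column registry and
SHA-256 checksums. The snapshot format is a documented, versioned
container rather than a language-native object dump so it stays portable
across implementations; the persistence contract (lossless round-trip) is
what the `DataCollector` interface pins, and directory and in-memory
backends ship with the package.

Merging concatenates cohorts; institution-scoped UIDs make cross-site
collisions impossible, identical re-imported rows deduplicate, and
conflicting rows for the same key within one institution are an error.
Extensible columns declared by both sides with different units are
suffixed with institution tags (with a warning) instead of being silently
mixed.

## The synthetic fixture

No public plan-check dataset exists, so the fixture generates whole
courses in the documented JSON dialect with ground truth emitted
separately. Its defaults define the study conditions used throughout the
tests: a pelvis course of 25 daily fractions, per-fraction prescription
220 cGy for the highest target tier, an extra structure-set revision with
probability 0.1 per fraction, and the adaptive plan delivered with
probability 0.8 — a high adaptation rate typical of pelvic oART practice.

Cumulative DVHs are shifted sigmoids `v(d) = 100/(1 + exp((d − D50)/w))`,
sampled on a 0.5 Gy grid and truncated to the open interval (0, 100) %.
The sigmoid gives realistic monotone curves with an analytic closed form,
so oracle tests can compare interpolated values at list nodes exactly; the
0.5 Gy grid also places common objective doses (e.g. 42.5 Gy) on nodes.
The secondary-calculation series is generated 1 % off the planning series
in D50 to emulate an independent dose engine. Structure volumes follow
deterministic linear drifts — bladder at +2 % of reference per fraction,
other structures with small per-patient rates — emulating systematic
anatomical trends.

What the fixture does **not** emulate: daily stochastic volume noise,
realistic DVH shoulder/tail shapes beyond the sigmoid family, contour
geometry, machine log content, or dose recalculation. Passing tests
therefore demonstrate that the extraction, lineage, analytics and storage
machinery is correct on data of the documented shape — not that any
clinical conclusion holds on real cohorts.

## Problem sizes and numerics

The test suite and the acceptance script run cohorts of 1–4 patients with
4–8 fractions (and one 500-fraction run for the adaptation-rate
convergence check), sizes chosen so every property is exercised — multiple
patients, revisions, both delivered plan types, both DVH sources — while a
full run stays interactive on a laptop. Oracle comparisons use 1e-9
(volume) and 1e-6 Gy (dose) tolerances; padding and ground-truth volume
checks are exact by construction. Randomized tests derive all randomness
from fixed seeds or a caller-supplied seed.
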