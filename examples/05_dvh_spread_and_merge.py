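"""DVH spread plot (sliding box-and-whiskers) and two-institution merge.

The spread plot summarizes a whole course's daily DVHs per structure:
extrema band, 20th-80th percentile band, median curve and the dashed
reference curve, with adaptive and scheduled panels side by side. The
merge demonstrates collaboration: institution-scoped UIDs keep cohorts
disjoint by construction.
"""

import tempfile
from pathlib import Path

from oartx import (
    FixtureConfig,
    RunConfig,
    build_course,
    generate_course,
    merge_cohorts,
    plot_dvh_spread,
    render,
    resolve_delivered,
    run_extraction,
)
from oartx.fixture_mobius import DEFAULT_TOKEN, write_directory
from oartx.store import DirectoryCollector

docs, truth = generate_course(FixtureConfig(n_patients=1, fractions_per_patient=8, seed=11))
course = build_course(docs, resolve_delivered([d.summary for d in docs]))

fig = plot_dvh_spread(course, ["Bladder", "Rectum"])
band = fig.series["adaptive:Bladder"]
print("adaptive bladder band (every 20th grid point):")
print(band.iloc[::20].round(2).to_string(index=False))

tmp = Path(tempfile.mkdtemp())
render(fig, tmp / "dvh_spread.png")
print(f"figure: {tmp / 'dvh_spread.png'}")

# two institutions extract the same fixture under different IDs, then merge
src = write_directory(docs, truth, tmp / "src")
stores = []
for inst in ("1234", "5678"):
    cfg = RunConfig(source=str(src), token=DEFAULT_TOKEN, institution_id=inst,
                    store_path=str(tmp / f"store_{inst}"))
    run_extraction(cfg, sorted(truth.patients))
    stores.append(DirectoryCollector(cfg.store_path).load_store())
merged = merge_cohorts(stores[0], stores[1])
print(f"\nmerged rows: {len(merged.rows)} "
      f"(= {len(stores[0].rows)} + {len(stores[1].rows)}), "
      f"institutions: {merged.institution_ids}")
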