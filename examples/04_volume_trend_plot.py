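"""Longitudinal bladder-volume trend with adapted/scheduled color coding.

The fixture drifts bladder volume +2% of reference per fraction; the trend
series recovers that drift exactly because volumes are carried from the
source documents. The rendered figure is a pure function of the exported
series, so the CSV written next to the image fully describes the plot.
"""

import tempfile
from pathlib import Path

from oartx import (
    FixtureConfig,
    build_course,
    generate_course,
    plot_volume_trend,
    render,
    resolve_delivered,
)

docs, _ = generate_course(FixtureConfig(n_patients=1, fractions_per_patient=10, seed=5))
course = build_course(docs, resolve_delivered([d.summary for d in docs]))

spec = plot_volume_trend(course, "Bladder", mode="relative")
print(spec.series["trend"].round(4).to_string(index=False))

out = Path(tempfile.mkdtemp())
image = render(spec, out / "bladder_trend.png")
csvs = spec.export_series(out / "bladder_trend")
print(f"\nimage: {image}")
print(f"series: {[str(p) for p in csvs]}")
# value = (session volume - reference volume) / reference volume; the
# adapted column marks sessions treated with the re-optimized plan.
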