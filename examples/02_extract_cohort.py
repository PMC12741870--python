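"""Full extraction workflow: fixture directory -> de-identified cohort store.

Writes a file-backed fixture, runs the list -> fetch -> resolve -> analyze
-> store pipeline for all patients, and exports a compressed cohort
archive. The printed report counts patients, adaptive sessions and plans;
the store rows are keyed by institution-scoped UIDs, never source IDs.
"""

import tempfile
from pathlib import Path

from oartx import FixtureConfig, RunConfig, export_cohort, generate_course, run_extraction
from oartx.fixture_mobius import DEFAULT_TOKEN, write_directory
from oartx.store import DirectoryCollector

tmp = Path(tempfile.mkdtemp())
docs, truth = generate_course(FixtureConfig(n_patients=3, fractions_per_patient=5, seed=7))
source = write_directory(docs, truth, tmp / "source")

config = RunConfig(
    source=str(source),
    token=DEFAULT_TOKEN,
    institution_id="1234",
    store_path=str(tmp / "store"),
    objectives=["V42.5Gy@Bladder", "V42.5Gy@Rectum"],
)
report = run_extraction(config, sorted(truth.patients))
print("run report:", report.to_json())

store = DirectoryCollector(config.store_path).load_store()
print(f"cohort rows: {len(store.rows)}  patients: {store.patient_uids()}")
bladder = store.rows[(store.rows["structure"] == "Bladder") & store.rows["delivered"]]
print(bladder[["patient_uid", "plan_name", "fraction", "adapted", "V42.5Gy[Bladder]"]]
      .head(6).to_string(index=False))

archive = export_cohort(store, tmp / "cohort.zip")
print(f"exported de-identified archive: {archive} ({archive.stat().st_size} bytes)")
# V42.5Gy[Bladder] is the % of bladder volume receiving >= 42.5 Gy in the
# delivered plan of each session, evaluated from the reconstructed DVH.
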