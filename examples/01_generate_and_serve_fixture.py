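"""Generate a synthetic plan-check cohort and query it over HTTP.

Builds a 2-patient pelvis course, serves it from an in-process endpoint,
and lists one patient's checks through the authenticated client — the same
request path a clinical deployment would use against a real source.
"""

from oartx import FixtureConfig, generate_course, list_plan_checks, open_session, serve
from oartx.fixture_mobius import DEFAULT_TOKEN

config = FixtureConfig(n_patients=2, fractions_per_patient=3, seed=42)
documents, truth = generate_course(config)
print(f"generated {len(documents)} plan-check documents for {config.n_patients} patients")

with serve(documents) as server:
    session = open_session(server.base_url, DEFAULT_TOKEN)
    summaries = list_plan_checks(session, "PT0001")
    print(f"PT0001 has {len(summaries)} checks:")
    for s in summaries:
        link = f" -> {s.linked_check_id}" if s.linked_check_id else ""
        print(f"  {s.timestamp}  {s.check_kind:12s}  {s.plan_name}{link}")

# Each fraction shows a scheduled (SCH) / adaptive (ADP) pre-treatment pair;
# the log-file check's link marks which of the two was actually delivered.
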