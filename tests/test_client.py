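"""Client behaviour over both transports, plus delivered-plan resolution."""

import json

import pytest

from oartx import (
    FixtureConfig,
    fetch_check,
    generate_course,
    list_plan_checks,
    open_session,
    resolve_delivered,
    serve,
)
from oartx.client import DirectoryTransport
from oartx.documents import LOGFILE, PRETREATMENT, CheckSummary
from oartx.errors import AuthError, ConnectionFailedError, MissingCheckError, ParseError
from oartx.fixture_mobius import DEFAULT_TOKEN


@pytest.fixture(scope="module")
def served(tmp_path_factory):
    cfg = FixtureConfig(n_patients=1, fractions_per_patient=1, revision_probability=0.0, seed=1)
    docs, truth = generate_course(cfg)
    with serve(docs) as server:
        yield server, docs, truth


class TestHTTPTransport:
    def test_auth_and_round_trip(self, served):
        server, docs, _ = served
        session = open_session(server.base_url, DEFAULT_TOKEN)
        summaries = list_plan_checks(session, docs[0].summary.patient_id)
        assert len(summaries) == 4
        ts = [s.timestamp for s in summaries]
        assert ts == sorted(ts)
        for s in summaries:
            fetched = fetch_check(session, s.check_id)
            original = next(d for d in docs if d.summary.check_id == s.check_id)
            assert fetched.to_json() == original.to_json()

    def test_wrong_token_rejected(self, served):
        server, _, _ = served
        with pytest.raises(AuthError):
            open_session(server.base_url, "wrong-token")

    def test_unknown_patient_empty_list(self, served):
        server, _, _ = served
        session = open_session(server.base_url, DEFAULT_TOKEN)
        assert list_plan_checks(session, "NOBODY") == []

    def test_unknown_check_is_missing(self, served):
        server, _, _ = served
        session = open_session(server.base_url, DEFAULT_TOKEN)
        with pytest.raises(MissingCheckError):
            fetch_check(session, "CHK999999")

    def test_dead_port_fails_after_retries(self):
        with pytest.raises(ConnectionFailedError):
            open_session("http://127.0.0.1:9", "t", retries=3, backoff_s=0.01)


class TestDirectoryTransport:
    def test_equivalent_to_http(self, fixture_dir, small_cohort):
        docs, _ = small_cohort
        session = open_session(str(fixture_dir), DEFAULT_TOKEN)
        pid = docs[0].summary.patient_id
        summaries = list_plan_checks(session, pid)
        assert {s.check_id for s in summaries} == {
            d.summary.check_id for d in docs if d.summary.patient_id == pid
        }
        doc = fetch_check(session, summaries[0].check_id)
        original = next(d for d in docs if d.summary.check_id == summaries[0].check_id)
        assert doc.to_json() == original.to_json()

    def test_truncated_json_body_is_parse_error(self, fixture_dir, small_cohort):
        docs, _ = small_cohort
        cid = docs[0].summary.check_id
        path = fixture_dir / "checks" / f"{cid}.json"
        path.write_text(path.read_text()[:50])
        transport = DirectoryTransport(fixture_dir)
        with pytest.raises(ParseError):
            transport.get_check(cid)

    def test_extra_vendor_field_preserved_in_extras(self, fixture_dir, small_cohort):
        docs, _ = small_cohort
        cid = docs[0].summary.check_id
        path = fixture_dir / "checks" / f"{cid}.json"
        obj = json.loads(path.read_text())
        obj["vendorInternal_str"] = "opaque"
        path.write_text(json.dumps(obj))
        session = open_session(str(fixture_dir), DEFAULT_TOKEN)
        doc = fetch_check(session, cid)
        assert doc.extras["vendorInternal_str"] == "opaque"

    def test_cgy_dialect_converted_on_read(self, fixture_dir, small_cohort):
        docs, _ = small_cohort
        cid = next(d.summary.check_id for d in docs if d.dvh_sets)
        path = fixture_dir / "checks" / f"{cid}.json"
        obj = json.loads(path.read_text())
        gy_doses = [p[0] for p in obj["dvh"]["tpms"]["Bladder"]]
        obj["doseUnit_str"] = "cgy"
        path.write_text(json.dumps(obj))
        doc = fetch_check(open_session(str(fixture_dir), DEFAULT_TOKEN), cid)
        assert doc.dvh_sets["tpms"]["Bladder"][0][0] == pytest.approx(gy_doses[0] * 0.01)


def _summary(cid, plan, kind, ts, link=None):
    return CheckSummary(cid, "P", plan, kind, ts, link)


class TestResolveDelivered:
    def test_linked_adaptive_is_delivered(self):
        checks = [
            _summary("c1", "IM1/SCH0101", PRETREATMENT, "2024-01-01T08:00:00"),
            _summary("c2", "IM1/ADP0102", PRETREATMENT, "2024-01-01T08:10:00"),
            _summary("c3", "IM1/ADP0102", LOGFILE, "2024-01-01T09:00:00", "c2"),
        ]
        assert resolve_delivered(checks) == {"IM1/SCH0101": False, "IM1/ADP0102": True}

    def test_no_logfile_means_planned_not_treated(self):
        checks = [
            _summary("c1", "IM1/SCH0101", PRETREATMENT, "2024-01-01T08:00:00"),
            _summary("c2", "IM1/ADP0102", PRETREATMENT, "2024-01-01T08:10:00"),
        ]
        assert resolve_delivered(checks) == {"IM1/SCH0101": False, "IM1/ADP0102": False}

    def test_duplicate_logfiles_latest_wins(self, caplog):
        checks = [
            _summary("c1", "IM1/SCH0101", PRETREATMENT, "2024-01-01T08:00:00"),
            _summary("c2", "IM1/ADP0102", PRETREATMENT, "2024-01-01T08:10:00"),
            _summary("c3", "IM1/SCH0101", LOGFILE, "2024-01-01T09:00:00", "c1"),
            _summary("c4", "IM1/ADP0102", LOGFILE, "2024-01-01T10:00:00", "c2"),
        ]
        with caplog.at_level("WARNING"):
            result = resolve_delivered(checks)
        assert result == {"IM1/SCH0101": False, "IM1/ADP0102": True}
        assert any("multiple log-file checks" in r.message for r in caplog.records)

    def test_dangling_link_ignored_with_warning(self, caplog):
        checks = [
            _summary("c1", "IM1/SCH0101", PRETREATMENT, "2024-01-01T08:00:00"),
            _summary("c3", "IM1/SCH0101", LOGFILE, "2024-01-01T09:00:00", "missing"),
        ]
        with caplog.at_level("WARNING"):
            result = resolve_delivered(checks)
        assert result == {"IM1/SCH0101": False}
        assert any("dangling" in r.message or "absent" in r.message for r in caplog.records)

    def test_matches_ground_truth_across_seeds(self):
        """resolve_delivered reproduces the generator's delivered map exactly."""
        for seed in range(10):
            cfg = FixtureConfig(
                n_patients=1, fractions_per_patient=6, revision_probability=0.4, seed=seed
            )
            docs, truth = generate_course(cfg)
            delivered = resolve_delivered([d.summary for d in docs])
            pid = next(iter(truth.patients))
            for f, ftruth in truth.patients[pid]["fractions"].items():
                for plan in ftruth["plans"]:
                    assert delivered[plan] == (plan == ftruth["delivered"])
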