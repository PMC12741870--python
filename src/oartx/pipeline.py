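"""End-to-end extraction workflow: list -> fetch -> resolve -> analyze -> store.

One failing patient never aborts a run; failures are collected into the run
report.  A run is reproducible from (config, source data): the same fixture
and config produce byte-identical cohort exports.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import client as client_mod
from .client import Session, fetch_check, list_plan_checks, resolve_delivered
from .documents import PRETREATMENT, PlanCheckDocument
from .dvh import ObjectiveSpec, parse_objective, structure_dvh
from .errors import ConfigurationError, OartxError
from .plans import (
    REFERENCE,
    CourseRecord,
    build_course,
    complexity,
    parse_plan_name,
)
from .store import (
    CohortStore,
    DirectoryCollector,
    append_patient,
    assign_uid,
    shift_days_for_uid,
)
from .structures import OARRegistry, assign_roles, default_registry

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable description of one extraction run."""

    source: str  # http(s) URL or fixture directory
    token: str
    institution_id: str
    store_path: str
    site_registry_path: str | None = None
    objectives: list[str] = field(default_factory=list)
    dvh_source: str = "tpms"
    seed: int = 0
    log_level: str = "INFO"

    def registry(self) -> OARRegistry:
        if self.site_registry_path:
            return OARRegistry.from_yaml(self.site_registry_path)
        return default_registry()

    def objective_specs(self) -> list[ObjectiveSpec]:
        return [parse_objective(o) for o in self.objectives]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunReport:
    patients_requested: int = 0
    patients_ok: int = 0
    patients_failed: int = 0
    failures: dict[str, str] = field(default_factory=dict)
    n_sessions: int = 0
    n_plans: int = 0
    rows_appended: int = 0
    warnings: int = 0

    def to_json(self) -> dict:
        return asdict(self)


def build_patient_dataset(
    course: CourseRecord,
    uid: str,
    objectives: Sequence[ObjectiveSpec] = (),
    registry: OARRegistry | None = None,
    dvh_source: str = "tpms",
) -> pd.DataFrame:
    """Flatten one course into de-identified long-format cohort rows.

    One row per (plan, structure) across the reference plan and every
    pre-treatment session plan.  Objective values become extensible columns
    named by the objective label, populated on the matching structure's
    rows.  Timestamps are shifted by the UID-seeded per-patient day offset.
    """
    registry = registry or default_registry()
    shift = timedelta(days=shift_days_for_uid(uid))
    site = course.site
    ref_structs = {s.name: s for s in course.reference.structures} if course.reference else {}

    delivered_names = set()
    adapted_fractions: dict[int, bool] = {}
    for session in course.sessions:
        adapted_fractions[session.fraction] = session.adapted
        if session.delivered is not None:
            from .plans import format_plan_name

            delivered_names.add(format_plan_name(session.delivered))

    rows: list[dict] = []
    for plan_name, doc in sorted(course.documents.items()):
        ident = parse_plan_name(plan_name)
        structures = assign_roles(doc.structures, site or "", registry=registry)
        comp = None
        if doc.beams and doc.prescription_cGy:
            comp = complexity(doc.beams, doc.prescription_cGy)
        ts = datetime.fromisoformat(doc.summary.timestamp) + shift
        for entry in structures:
            ref = ref_structs.get(entry.name)
            delta_cm3 = delta_rel = cshift = np.nan
            if ref is not None and ident.plan_type != REFERENCE:
                delta_cm3 = entry.volume_cm3 - ref.volume_cm3
                if ref.volume_cm3 > 0:
                    delta_rel = (entry.volume_cm3 - ref.volume_cm3) / ref.volume_cm3
                if ref.centroid is not None and entry.centroid is not None:
                    cshift = float(np.linalg.norm(np.subtract(entry.centroid, ref.centroid)))
            row = {
                "patient_uid": uid,
                "plan_name": plan_name,
                "structure": entry.name,
                "site": site,
                "fraction": 0 if ident.fraction is None else ident.fraction,
                "plan_type": ident.plan_type,
                "revision": ident.revision,
                "delivered": plan_name in delivered_names,
                "adapted": adapted_fractions.get(ident.fraction, False)
                if ident.fraction is not None
                else False,
                "role": entry.role,
                "volume_cm3": entry.volume_cm3,
                "delta_cm3": delta_cm3,
                "delta_rel": delta_rel,
                "centroid_shift_cm": cshift,
                "total_mu": comp.total_mu if comp else np.nan,
                "modulation_factor": comp.modulation_factor if comp else np.nan,
                "n_control_points": comp.n_control_points if comp else np.nan,
                "n_beams": comp.n_beams if comp else np.nan,
                "timestamp_shifted": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            }
            for spec in objectives:
                if spec.structure == entry.name:
                    dvh = structure_dvh(doc, entry.name, dvh_source)
                    row[spec.label] = np.nan if dvh is None else spec.evaluate(dvh)
            rows.append(row)
    return pd.DataFrame(rows)


def process_patient(
    session: Session,
    source_patient_id: str,
    store: CohortStore,
    config: RunConfig,
    collector: DirectoryCollector | None = None,
) -> tuple[int, int, int]:
    """Full per-patient path; returns (n_sessions, n_plans, n_rows)."""
    summaries = list_plan_checks(session, source_patient_id)
    documents = [fetch_check(session, s.check_id) for s in summaries]
    delivered_map = resolve_delivered(summaries)
    course = build_course(documents, delivered_map)
    uid = assign_uid(store, source_patient_id)
    dataset = build_patient_dataset(
        course,
        uid.uid,
        objectives=config.objective_specs(),
        registry=config.registry(),
        dvh_source=config.dvh_source,
    )
    append_patient(store, dataset, collector=collector)
    store.last_seen[source_patient_id] = max((s.timestamp for s in summaries), default="")
    store.seen_checks[source_patient_id] = sorted(s.check_id for s in summaries)
    n_plans = sum(1 for d in documents if d.summary.check_kind == PRETREATMENT)
    return len(course.sessions), n_plans, len(dataset)


def _open_store(config: RunConfig) -> tuple[CohortStore, DirectoryCollector]:
    collector = DirectoryCollector(config.store_path)
    if (Path(config.store_path) / "manifest.json").exists():
        store = collector.load_store()
        if store.institution_id and store.institution_id != config.institution_id:
            raise ConfigurationError(
                f"store belongs to institution {store.institution_id!r}, "
                f"config says {config.institution_id!r}"
            )
        store.institution_id = config.institution_id
    else:
        store = CohortStore(institution_id=config.institution_id)
    return store, collector


def run_extraction(config: RunConfig, patient_ids: Iterable[str]) -> RunReport:
    """Extract, analyze and store every listed patient (fault-isolated)."""
    patient_ids = list(patient_ids)
    if not patient_ids:
        raise ConfigurationError("patient ID list is empty")
    report = RunReport(patients_requested=len(patient_ids))
    store, collector = _open_store(config)
    session = client_mod.open_session(config.source, config.token)
    for pid in patient_ids:
        try:
            n_sessions, n_plans, n_rows = process_patient(
                session, pid, store, config, collector
            )
        except OartxError as exc:
            logger.error("patient %r failed: %s", pid, exc)
            report.patients_failed += 1
            report.failures[pid] = str(exc)
            continue
        report.patients_ok += 1
        report.n_sessions += n_sessions
        report.n_plans += n_plans
        report.rows_appended += n_rows
    collector.save_store(store)
    if report.patients_ok == 0:
        raise OartxError(f"all {report.patients_failed} patients failed: {report.failures}")
    return report


def run_daily_update(config: RunConfig, patient_ids: Iterable[str] | None = None) -> RunReport:
    """Incremental pass: only patients with unseen checks are re-processed.

    A patient whose listing shows a check newer than the stored last-seen
    timestamp (or any unseen check ID) is re-fetched in full and their rows
    replaced atomically; unseen checks older than last-seen trigger the
    same full re-fetch with a clock-skew warning.
    """
    store, collector = _open_store(config)
    ids = list(patient_ids) if patient_ids is not None else sorted(store.lookback)
    report = RunReport(patients_requested=len(ids))
    session = client_mod.open_session(config.source, config.token)
    for pid in ids:
        try:
            summaries = list_plan_checks(session, pid)
            seen = set(store.seen_checks.get(pid, []))
            new = [s for s in summaries if s.check_id not in seen]
            if not new:
                report.patients_ok += 1
                continue
            last = store.last_seen.get(pid, "")
            if any(s.timestamp < last for s in new):
                logger.warning(
                    "patient %r has unseen checks older than last-seen (%s); full re-fetch",
                    pid,
                    last,
                )
                report.warnings += 1
            before = len(store.rows[store.rows["patient_uid"] == store.lookback.get(pid, "")]) if pid in store.lookback and len(store.rows) else 0
            n_sessions, n_plans, n_rows = process_patient(session, pid, store, config, collector)
            report.patients_ok += 1
            report.n_sessions += n_sessions
            report.n_plans += n_plans
            report.rows_appended += max(0, n_rows - before)
        except OartxError as exc:
            logger.error("patient %r failed during update: %s", pid, exc)
            report.patients_failed += 1
            report.failures[pid] = str(exc)
    collector.save_store(store)
    return report
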