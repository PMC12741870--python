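"""De-identified long-format cohort store with snapshots, export and merge.

Each row describes one structure in one plan of one patient, keyed by
``(patient_uid, plan_name, structure)``.  Patients carry institution-scoped
sequential UIDs (``<institution>-00019`` style) so cohorts from different
institutions can be merged without identifier collisions.  The private
source-ID -> UID lookback index and real timestamps live beside the store,
never inside an exported cohort; exported dates are shifted per patient by
a UID-seeded day offset that preserves intra-patient intervals.
"""

from __future__ import annotations

import abc
import hashlib
import io
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd

from .errors import ConfigurationError, IntegrityError, MergeConflictError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"
UID_WIDTH = 5

KEY_COLUMNS = ["patient_uid", "plan_name", "structure"]
CORE_COLUMNS = KEY_COLUMNS + [
    "site",
    "fraction",
    "plan_type",
    "revision",
    "delivered",
    "adapted",
    "role",
    "volume_cm3",
    "delta_cm3",
    "delta_rel",
    "centroid_shift_cm",
    "total_mu",
    "modulation_factor",
    "n_control_points",
    "n_beams",
    "timestamp_shifted",
]

# deterministic archive member dates (zip stores no useful provenance here)
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class PatientUID:
    """Institution-scoped sequential patient identifier."""

    institution_id: str
    index: int

    @property
    def uid(self) -> str:
        return f"{self.institution_id}-{self.index:0{UID_WIDTH}d}"

    def __str__(self) -> str:
        return self.uid


def shift_days_for_uid(uid: str) -> int:
    """Deterministic per-patient date shift (days) seeded from the UID."""
    digest = hashlib.sha256(uid.encode()).digest()
    return int.from_bytes(digest[:4], "big") % 3653


@dataclass
class CohortStore:
    """In-memory cohort plus the private indexes needed to extend it."""

    institution_id: str | None = None
    schema_version: str = SCHEMA_VERSION
    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CORE_COLUMNS))
    column_registry: dict[str, dict[str, str]] = field(default_factory=dict)
    lookback: dict[str, str] = field(default_factory=dict)  # source id -> uid (private)
    last_seen: dict[str, str] = field(default_factory=dict)  # source id -> timestamp (private)
    seen_checks: dict[str, list[str]] = field(default_factory=dict)  # source id -> check ids (private)

    @property
    def institution_ids(self) -> list[str]:
        ids = set() if self.institution_id is None else {self.institution_id}
        if len(self.rows):
            ids |= {u.rsplit("-", 1)[0] for u in self.rows["patient_uid"].unique()}
        return sorted(ids)

    def patient_uids(self) -> list[str]:
        return sorted(self.rows["patient_uid"].unique()) if len(self.rows) else []

    def register_column(self, name: str, units: str = "") -> None:
        """Declare an extensible analysis column; core names are protected."""
        if name in CORE_COLUMNS:
            raise ConfigurationError(f"column {name!r} collides with a core column")
        self.column_registry[name] = {"units": units}


def assign_uid(store: CohortStore, source_patient_id: str) -> PatientUID:
    """Stable sequential UID for a source patient ID.

    A previously seen source ID returns its existing UID via the private
    lookback index; a new ID gets the next index.  Re-runs over the same
    patient order reproduce identical assignments.
    """
    if not store.institution_id:
        raise ConfigurationError("institution_id is not configured on this store")
    existing = store.lookback.get(source_patient_id)
    if existing is not None:
        inst, idx = existing.rsplit("-", 1)
        return PatientUID(inst, int(idx))
    next_index = len(store.lookback) + 1
    uid = PatientUID(store.institution_id, next_index)
    store.lookback[source_patient_id] = uid.uid
    return uid


def append_patient(
    store: CohortStore,
    course_dataset: pd.DataFrame,
    collector: "DataCollector | None" = None,
) -> CohortStore:
    """Append (or atomically replace) one patient's rows.

    ``course_dataset`` must carry a single ``patient_uid`` and the key
    columns.  Re-appending the same patient replaces their rows; a key
    collision across different patients raises :class:`IntegrityError`.
    """
    for col in KEY_COLUMNS:
        if col not in course_dataset.columns:
            raise ConfigurationError(f"course dataset lacks key column {col!r}")
    uids = course_dataset["patient_uid"].unique()
    if len(uids) != 1:
        raise IntegrityError(f"course dataset must hold one patient, got {list(uids)}")
    uid = uids[0]
    dup = course_dataset.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        raise IntegrityError(
            f"duplicate (uid, plan, structure) keys in patient dataset: "
            f"{course_dataset.loc[dup, KEY_COLUMNS].values.tolist()[:3]}"
        )
    for col in course_dataset.columns:
        if col not in CORE_COLUMNS and col not in store.column_registry:
            store.register_column(col)
    kept = store.rows[store.rows["patient_uid"] != uid] if len(store.rows) else store.rows
    frames = [f for f in (kept, course_dataset) if len(f)]
    if not frames:
        store.rows = course_dataset
    elif len(frames) == 1:
        store.rows = frames[0].reset_index(drop=True)
    else:
        store.rows = pd.concat(frames, ignore_index=True, sort=False)
    if collector is not None:
        collector.save_patient(uid, course_dataset)
    return store


def _canonical_rows(df: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in CORE_COLUMNS if c in df.columns] + sorted(
        c for c in df.columns if c not in CORE_COLUMNS
    )
    return df[cols].sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)


def _apply_filter(df: pd.DataFrame, row_filter: str | Callable | None) -> pd.DataFrame:
    if row_filter is None:
        return df
    if callable(row_filter):
        return df[row_filter(df)]
    try:
        return df.query(row_filter)
    except Exception as exc:  # pandas raises several types for bad columns
        raise ConfigurationError(
            f"row filter {row_filter!r} failed ({exc}); available columns: "
            f"{', '.join(df.columns)}"
        ) from exc


def export_cohort(store: CohortStore, path, row_filter: str | Callable | None = None) -> Path:
    """Write a de-identified, compressed cohort archive.

    The archive holds ``cohort.csv`` (canonical column/row order),
    ``manifest.json`` (schema version, institution manifest, column
    registry, SHA-256 checksums).  The private lookback index, source IDs
    and real timestamps are never written.  Output is byte-stable for
    identical store contents.
    """
    df = _apply_filter(_canonical_rows(store.rows), row_filter)
    csv_bytes = df.to_csv(index=False).encode()
    manifest = {
        "schema_version": store.schema_version,
        "institutions": store.institution_ids,
        "column_registry": store.column_registry,
        "row_count": int(len(df)),
        "checksums": {"cohort.csv": hashlib.sha256(csv_bytes).hexdigest()},
    }
    manifest_bytes = json.dumps(manifest, sort_keys=True, indent=1).encode()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, data in (("cohort.csv", csv_bytes), ("manifest.json", manifest_bytes)):
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)
    return path


def import_cohort(path) -> CohortStore:
    """Read an exported cohort archive back into a store (no private indexes)."""
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        csv_bytes = zf.read("cohort.csv")
    digest = hashlib.sha256(csv_bytes).hexdigest()
    if digest != manifest["checksums"]["cohort.csv"]:
        raise IntegrityError("cohort.csv checksum mismatch in archive")
    rows = pd.read_csv(io.BytesIO(csv_bytes)) if csv_bytes.strip() else pd.DataFrame(columns=CORE_COLUMNS)
    insts = manifest.get("institutions", [])
    return CohortStore(
        institution_id=insts[0] if len(insts) == 1 else None,
        schema_version=manifest["schema_version"],
        rows=rows,
        column_registry=manifest.get("column_registry", {}),
    )


def merge_cohorts(a: CohortStore, b: CohortStore) -> CohortStore:
    """Merge two cohorts; UID scoping makes cross-institution collisions impossible.

    Identical rows re-imported for the same institution deduplicate;
    conflicting rows for the same key within one institution raise
    :class:`MergeConflictError`.  Extensible columns declared by both sides
    with different units are suffixed with an institution tag (warning).
    """
    if a.schema_version != b.schema_version:
        raise MergeConflictError(
            f"schema versions differ: {a.schema_version} vs {b.schema_version}"
        )
    a_rows, b_rows = a.rows.copy(), b.rows.copy()
    registry = dict(a.column_registry)
    for name, meta in b.column_registry.items():
        if name in registry and registry[name] != meta:
            a_tag = (a.institution_ids or ["a"])[0]
            b_tag = (b.institution_ids or ["b"])[0]
            logger.warning(
                "extensible column %r declared with different units (%r vs %r); "
                "suffixing with institution tags",
                name,
                registry[name],
                meta,
            )
            a_rows = a_rows.rename(columns={name: f"{name}__{a_tag}"})
            b_rows = b_rows.rename(columns={name: f"{name}__{b_tag}"})
            registry[f"{name}__{a_tag}"] = registry.pop(name)
            registry[f"{name}__{b_tag}"] = meta
        elif name not in registry:
            registry[name] = meta

    nonempty = [f for f in (a_rows, b_rows) if len(f)]
    if not nonempty:
        merged = a_rows
    elif len(nonempty) == 1:
        merged = nonempty[0].reset_index(drop=True)
    else:
        merged = pd.concat(nonempty, ignore_index=True, sort=False)
    if len(merged):
        merged = merged.drop_duplicates().reset_index(drop=True)
        dup_keys = merged.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup_keys.any():
            keys = merged.loc[dup_keys, KEY_COLUMNS].drop_duplicates().values.tolist()
            raise MergeConflictError(
                f"conflicting rows for keys (same institution, different values): {keys[:5]}"
            )
    out = CohortStore(
        institution_id=None,
        schema_version=a.schema_version,
        rows=_canonical_rows(merged) if len(merged) else merged,
        column_registry=registry,
    )
    return out


# ---------------------------------------------------------------------------
# persistence contract

class DataCollector(abc.ABC):
    """Abstract persistence backend for stores and per-patient snapshots.

    Implementations must make ``save`` -> ``load`` lossless, including
    extensible columns.
    """

    @abc.abstractmethod
    def save_patient(self, uid: str, df: pd.DataFrame) -> None: ...

    @abc.abstractmethod
    def load_patient(self, uid: str) -> pd.DataFrame: ...

    @abc.abstractmethod
    def save_store(self, store: CohortStore) -> None: ...

    @abc.abstractmethod
    def load_store(self) -> CohortStore: ...


class DirectoryCollector(DataCollector):
    """Plain-files backend: CSV tables plus JSON manifests in a directory.

    Layout: ``cohort.csv``, ``manifest.json`` (public), ``private.json``
    (lookback index + last-seen timestamps; excluded from any export) and
    ``patients/<uid>.csv`` snapshots.
    """

    def __init__(self, root) -> None:
        self.root = Path(root)
        (self.root / "patients").mkdir(parents=True, exist_ok=True)

    def save_patient(self, uid: str, df: pd.DataFrame) -> None:
        _canonical_rows(df).to_csv(self.root / "patients" / f"{uid}.csv", index=False)

    def load_patient(self, uid: str) -> pd.DataFrame:
        return pd.read_csv(self.root / "patients" / f"{uid}.csv")

    def save_store(self, store: CohortStore) -> None:
        _canonical_rows(store.rows).to_csv(self.root / "cohort.csv", index=False)
        manifest: dict[str, Any] = {
            "schema_version": store.schema_version,
            "institution_id": store.institution_id,
            "column_registry": store.column_registry,
        }
        with open(self.root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
        with open(self.root / "private.json", "w") as fh:
            json.dump(
                {
                    "lookback": store.lookback,
                    "last_seen": store.last_seen,
                    "seen_checks": store.seen_checks,
                },
                fh,
                sort_keys=True,
                indent=1,
            )

    def load_store(self) -> CohortStore:
        with open(self.root / "manifest.json") as fh:
            manifest = json.load(fh)
        csv_path = self.root / "cohort.csv"
        rows = pd.read_csv(csv_path) if csv_path.stat().st_size > 1 else pd.DataFrame(
            columns=CORE_COLUMNS
        )
        private = {"lookback": {}, "last_seen": {}}
        if (self.root / "private.json").exists():
            with open(self.root / "private.json") as fh:
                private = json.load(fh)
        return CohortStore(
            institution_id=manifest.get("institution_id"),
            schema_version=manifest["schema_version"],
            rows=rows,
            column_registry=manifest.get("column_registry", {}),
            lookback=private.get("lookback", {}),
            last_seen=private.get("last_seen", {}),
            seen_checks=private.get("seen_checks", {}),
        )


class InMemoryCollector(DataCollector):
    """Volatile backend for tests of the persistence contract."""

    def __init__(self) -> None:
        self.patients: dict[str, pd.DataFrame] = {}
        self.store: CohortStore | None = None

    def save_patient(self, uid: str, df: pd.DataFrame) -> None:
        self.patients[uid] = df.copy()

    def load_patient(self, uid: str) -> pd.DataFrame:
        return self.patients[uid].copy()

    def save_store(self, store: CohortStore) -> None:
        self.store = store

    def load_store(self) -> CohortStore:
        assert self.store is not None
        return self.store
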