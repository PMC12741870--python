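"""In-memory model of plan-check documents and their JSON dialect.

A *plan check* is one record in the secondary dose-verification database:
either a pre-treatment calculation for a scheduled/adaptive/reference plan,
or a log-file check built from machine delivery logs and linked back to the
pre-treatment check of the plan that was actually delivered.

The JSON dialect is defined by this repository (the vendor dialect is
proprietary); see ``docs/fixture_schema.md``.  ``planName_str`` is kept as
the plan-name field name.  Unknown fields survive a parse/serialize
round-trip in ``extras`` so newer source versions do not break the client.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .errors import ParseError

PRETREATMENT = "pretreatment"
LOGFILE = "logfile"

#: dialect keys the parser consumes; anything else lands in ``extras``
_SUMMARY_KEYS = {
    "checkId_str",
    "patientId_str",
    "planName_str",
    "checkType_str",
    "timestamp_str",
    "linkedCheckId_str",
}
_DOC_KEYS = _SUMMARY_KEYS | {
    "structures",
    "beams",
    "dvh",
    "doseUnit_str",
    "prescription_cGy",
    "site_str",
}


@dataclass(frozen=True)
class CheckSummary:
    """Listing-level view of one check (what a patient listing returns)."""

    check_id: str
    patient_id: str
    plan_name: str
    check_kind: str  # PRETREATMENT | LOGFILE
    timestamp: str  # ISO-8601
    linked_check_id: str | None = None

    def to_json(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "checkId_str": self.check_id,
            "patientId_str": self.patient_id,
            "planName_str": self.plan_name,
            "checkType_str": self.check_kind,
            "timestamp_str": self.timestamp,
        }
        if self.linked_check_id is not None:
            out["linkedCheckId_str"] = self.linked_check_id
        return out

    @classmethod
    def from_json(cls, obj: dict[str, Any]) -> "CheckSummary":
        try:
            kind = obj["checkType_str"]
            if kind not in (PRETREATMENT, LOGFILE):
                raise ParseError(f"checkType_str: unknown kind {kind!r}")
            return cls(
                check_id=obj["checkId_str"],
                patient_id=obj["patientId_str"],
                plan_name=obj["planName_str"],
                check_kind=kind,
                timestamp=obj["timestamp_str"],
                linked_check_id=obj.get("linkedCheckId_str"),
            )
        except KeyError as exc:  # noqa: PERF203
            raise ParseError(f"check summary missing field {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class StructureEntry:
    """One contoured structure as the source reports it.

    ``role`` is ``None`` until :func:`oartx.structures.assign_roles` runs.
    """

    name: str
    volume_cm3: float
    density_override: float | None = None  # g/cm^3
    centroid: tuple[float, float, float] | None = None  # patient-based cm
    role: str | None = None

    def to_json(self) -> dict[str, Any]:
        out: dict[str, Any] = {"name_str": self.name, "volume_cm3": self.volume_cm3}
        if self.density_override is not None:
            out["densityOverride_gcc"] = self.density_override
        if self.centroid is not None:
            out["centroid_cm"] = list(self.centroid)
        return out

    @classmethod
    def from_json(cls, obj: dict[str, Any]) -> "StructureEntry":
        try:
            cent = obj.get("centroid_cm")
            return cls(
                name=obj["name_str"],
                volume_cm3=float(obj["volume_cm3"]),
                density_override=obj.get("densityOverride_gcc"),
                centroid=tuple(cent) if cent is not None else None,
            )
        except KeyError as exc:
            raise ParseError(f"structure entry missing field {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class BeamEntry:
    """Per-beam delivery parameters stored with a check."""

    isocenter: tuple[float, float, float]  # cm
    n_control_points: int
    gantry_angles: tuple[float, ...]  # degrees
    collimator_angle: float  # degrees
    mu: float  # monitor units

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ParseError("mu_float: monitor units must be >= 0")
        if self.n_control_points < 2:
            raise ParseError("nControlPoints_int: need at least 2 control points")

    def to_json(self) -> dict[str, Any]:
        return {
            "isocenter_cm": list(self.isocenter),
            "nControlPoints_int": self.n_control_points,
            "gantryAngles_deg": list(self.gantry_angles),
            "collimatorAngle_deg": self.collimator_angle,
            "mu_float": self.mu,
        }

    @classmethod
    def from_json(cls, obj: dict[str, Any]) -> "BeamEntry":
        try:
            return cls(
                isocenter=tuple(obj["isocenter_cm"]),
                n_control_points=int(obj["nControlPoints_int"]),
                gantry_angles=tuple(obj["gantryAngles_deg"]),
                collimator_angle=float(obj["collimatorAngle_deg"]),
                mu=float(obj["mu_float"]),
            )
        except KeyError as exc:
            raise ParseError(f"beam entry missing field {exc.args[0]!r}") from exc


# DVH sources: planned dose from the treatment planning / on-couch session
# versus the independent secondary calculation.  Kept as distinct series
# end-to-end; nothing in the package ever mixes them.
DVH_SOURCES = ("tpms", "secondary")


@dataclass
class PlanCheckDocument:
    """Full JSON document for one check.

    ``dvh_sets`` maps source (``"tpms"`` | ``"secondary"``) to a mapping
    structure name -> truncated cumulative-DVH point list
    ``[(dose_gy, volume_pct), ...]``.  Doses are Gy internally; documents
    whose ``doseUnit_str`` is ``"cgy"`` are converted on read.
    """

    summary: CheckSummary
    structures: list[StructureEntry] = field(default_factory=list)
    beams: list[BeamEntry] = field(default_factory=list)
    dvh_sets: dict[str, dict[str, list[tuple[float, float]]]] = field(default_factory=dict)
    prescription_cGy: float | None = None
    site: str | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def structure(self, name: str) -> StructureEntry | None:
        for s in self.structures:
            if s.name == name:
                return s
        return None

    def to_json(self) -> dict[str, Any]:
        out = self.summary.to_json()
        out["structures"] = [s.to_json() for s in self.structures]
        out["beams"] = [b.to_json() for b in self.beams]
        out["dvh"] = {
            src: {name: [list(p) for p in pts] for name, pts in per.items()}
            for src, per in self.dvh_sets.items()
        }
        out["doseUnit_str"] = "gy"
        if self.prescription_cGy is not None:
            out["prescription_cGy"] = self.prescription_cGy
        if self.site is not None:
            out["site_str"] = self.site
        out.update(self.extras)
        return out

    @classmethod
    def from_json(cls, obj: dict[str, Any]) -> "PlanCheckDocument":
        summary = CheckSummary.from_json(obj)
        structures = [StructureEntry.from_json(s) for s in obj.get("structures", [])]
        beams = [BeamEntry.from_json(b) for b in obj.get("beams", [])]
        unit = obj.get("doseUnit_str", "gy").lower()
        if unit not in ("gy", "cgy"):
            raise ParseError(f"doseUnit_str: unknown unit {unit!r}")
        scale = 0.01 if unit == "cgy" else 1.0
        known = {s.name for s in structures}
        dvh_sets: dict[str, dict[str, list[tuple[float, float]]]] = {}
        for src, per in obj.get("dvh", {}).items():
            if src not in DVH_SOURCES:
                raise ParseError(f"dvh: unknown source {src!r}")
            dvh_sets[src] = {}
            for name, pts in per.items():
                if name not in known:
                    raise ParseError(f"dvh: structure {name!r} not in structures list")
                dvh_sets[src][name] = [(float(d) * scale, float(v)) for d, v in pts]
        extras = {k: v for k, v in obj.items() if k not in _DOC_KEYS}
        return cls(
            summary=summary,
            structures=structures,
            beams=beams,
            dvh_sets=dvh_sets,
            prescription_cGy=obj.get("prescription_cGy"),
            site=obj.get("site_str"),
            extras=extras,
        )
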