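"""Plan naming grammar, course assembly and simple plan-complexity measures.

CBCT-guided adaptive sessions generate a scheduled (SCH) and an adaptive
(ADP) plan per structure-set revision, named

    [Reference Plan ID]/[SCH|ADP][2-digit fraction][2-digit suffix]

e.g. ``IM103/SCH1401`` and ``IM103/ADP1402`` for the default pair on
fraction 14.  The two-digit suffix advances by two with each structure-set
revision (a revised pair is ``.../SCH1403`` + ``.../ADP1404``), and the
suffix parity of SCH vs ADP within a pair may be exchanged, so revision is
derived as ``ceil(suffix / 2)``.  Names without a ``/SCH`` or ``/ADP``
segment denote the reference plan.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .documents import PRETREATMENT, BeamEntry, PlanCheckDocument
from .errors import DomainError, MalformedPlanNameError, MissingReferenceError

logger = logging.getLogger(__name__)

REFERENCE = "reference"
SCHEDULED = "scheduled"
ADAPTIVE = "adaptive"

_TOKEN = {"SCH": SCHEDULED, "ADP": ADAPTIVE}
_TOKEN_INV = {SCHEDULED: "SCH", ADAPTIVE: "ADP"}

#: liberal on input: >= 4 trailing digits, the last two are always the suffix
_SESSION_RE = re.compile(r"^(?P<ref>.+)/(?P<tok>SCH|ADP)(?P<digits>\d{4,})$")
_SESSION_TOKEN_RE = re.compile(r"/(SCH|ADP)")


@dataclass(frozen=True)
class PlanIdentity:
    """Decomposition of a plan name."""

    reference_id: str
    plan_type: str  # REFERENCE | SCHEDULED | ADAPTIVE
    fraction: int | None = None
    suffix: int | None = None
    site: str | None = None

    @property
    def revision(self) -> int | None:
        """Structure-set revision: suffixes (1,2) are revision 1, (3,4) revision 2, ..."""
        if self.suffix is None:
            return None
        return (self.suffix + 1) // 2


def parse_plan_name(name: str) -> PlanIdentity:
    """Parse a plan name into its identity.

    Raises
    ------
    MalformedPlanNameError
        If the name carries a ``/SCH`` or ``/ADP`` token but fewer than four
        trailing digits.  Callers treating a whole course quarantine such
        names rather than aborting.
    """
    if not name:
        raise MalformedPlanNameError("empty plan name")
    m = _SESSION_RE.match(name)
    if m is None:
        if _SESSION_TOKEN_RE.search(name):
            raise MalformedPlanNameError(
                f"{name!r}: SCH/ADP token requires at least 4 trailing digits"
            )
        return PlanIdentity(reference_id=name, plan_type=REFERENCE)
    digits = m.group("digits")
    suffix = int(digits[-2:])
    fraction = int(digits[:-2])
    if suffix < 1 or fraction < 1:
        raise MalformedPlanNameError(f"{name!r}: fraction and suffix must be >= 1")
    return PlanIdentity(
        reference_id=m.group("ref"),
        plan_type=_TOKEN[m.group("tok")],
        fraction=fraction,
        suffix=suffix,
    )


def format_plan_name(identity: PlanIdentity) -> str:
    """Inverse of :func:`parse_plan_name` on grammar-conformant identities.

    Fraction and suffix are rendered as zero-padded two-digit fields; the
    grammar fixes two digits each, so values above 99 are refused.
    """
    if identity.plan_type == REFERENCE:
        return identity.reference_id
    if identity.fraction is None or identity.suffix is None:
        raise MalformedPlanNameError("session identity requires fraction and suffix")
    if not 1 <= identity.fraction <= 99:
        raise MalformedPlanNameError(
            f"fraction {identity.fraction} outside the 2-digit grammar range"
        )
    if not 1 <= identity.suffix <= 99:
        raise MalformedPlanNameError(
            f"suffix {identity.suffix} outside the 2-digit grammar range"
        )
    tok = _TOKEN_INV[identity.plan_type]
    return f"{identity.reference_id}/{tok}{identity.fraction:02d}{identity.suffix:02d}"


@dataclass
class RevisionPair:
    """SCH/ADP pair spawned by one structure-set revision."""

    revision: int
    scheduled: PlanIdentity | None = None
    adaptive: PlanIdentity | None = None

    def plans(self) -> list[PlanIdentity]:
        return [p for p in (self.scheduled, self.adaptive) if p is not None]


@dataclass
class FractionSession:
    """All plans generated for one treatment fraction."""

    fraction: int
    plan_pairs: list[RevisionPair] = field(default_factory=list)
    delivered: PlanIdentity | None = None

    @property
    def adapted(self) -> bool:
        return self.delivered is not None and self.delivered.plan_type == ADAPTIVE

    def latest_pair(self) -> RevisionPair | None:
        return self.plan_pairs[-1] if self.plan_pairs else None


@dataclass
class CourseRecord:
    """Per-patient timeline of fractions with their plan documents."""

    patient_id: str
    reference: PlanCheckDocument | None = None
    sessions: list[FractionSession] = field(default_factory=list)
    documents: dict[str, PlanCheckDocument] = field(default_factory=dict)
    site: str | None = None

    def session(self, fraction: int) -> FractionSession | None:
        for s in self.sessions:
            if s.fraction == fraction:
                return s
        return None

    def document_for(self, identity: PlanIdentity) -> PlanCheckDocument | None:
        return self.documents.get(format_plan_name(identity))


def build_course(
    documents: Iterable[PlanCheckDocument],
    delivered_map: Mapping[str, bool] | None = None,
) -> CourseRecord:
    """Group one patient's pre-treatment documents into a course timeline.

    Sessions are grouped by fraction and, within a fraction, pairs are
    ordered by structure-set revision.  Delivered/adapted flags come from
    ``delivered_map`` (plan name -> delivered flag, typically the output of
    :func:`oartx.client.resolve_delivered`).  Malformed plan names are
    quarantined with a log message rather than aborting the course.
    """
    delivered_map = delivered_map or {}
    course = CourseRecord(patient_id="")
    by_fraction: dict[int, dict[int, RevisionPair]] = {}

    for doc in documents:
        if doc.summary.check_kind != PRETREATMENT:
            continue
        course.patient_id = course.patient_id or doc.summary.patient_id
        name = doc.summary.plan_name
        try:
            ident = parse_plan_name(name)
        except MalformedPlanNameError as exc:
            logger.warning("quarantined plan name: %s", exc)
            continue
        if doc.site and course.site is None:
            course.site = doc.site
        if ident.plan_type == REFERENCE:
            course.reference = doc
            course.documents[name] = doc
            continue
        ident = replace(ident, site=doc.site)
        course.documents[name] = doc
        pairs = by_fraction.setdefault(ident.fraction, {})
        pair = pairs.setdefault(ident.revision, RevisionPair(revision=ident.revision))
        if ident.plan_type == SCHEDULED:
            pair.scheduled = ident
        else:
            pair.adaptive = ident

    for fraction in sorted(by_fraction):
        pairs = [by_fraction[fraction][r] for r in sorted(by_fraction[fraction])]
        session = FractionSession(fraction=fraction, plan_pairs=pairs)
        for pair in pairs:
            for ident in pair.plans():
                if delivered_map.get(format_plan_name(ident)):
                    session.delivered = ident
        course.sessions.append(session)

    if course.reference is None:
        logger.warning(
            "course for patient %r has no reference plan; baseline deltas unavailable",
            course.patient_id,
        )
    return course


def require_reference(course: CourseRecord) -> PlanCheckDocument:
    if course.reference is None:
        raise MissingReferenceError(
            f"course for patient {course.patient_id!r} has no reference plan"
        )
    return course.reference


@dataclass(frozen=True)
class ComplexitySummary:
    """Aggregate delivery-complexity surrogates for one plan.

    The modulation factor is total MU normalized by the fraction
    prescription in cGy — the coarse complexity surrogate available when
    MLC apertures are not exported by the source system.
    """

    total_mu: float
    modulation_factor: float
    n_control_points: int
    n_beams: int


def complexity(beams: Iterable[BeamEntry], prescription_cGy: float) -> ComplexitySummary:
    if prescription_cGy <= 0:
        raise DomainError(f"prescription must be positive, got {prescription_cGy}")
    beams = list(beams)
    total_mu = float(sum(b.mu for b in beams))
    return ComplexitySummary(
        total_mu=total_mu,
        modulation_factor=total_mu / prescription_cGy,
        n_control_points=int(sum(b.n_control_points for b in beams)),
        n_beams=len(beams),
    )
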