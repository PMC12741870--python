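"""Cumulative-DVH reconstruction, dose-volume objectives and percentile bands.

The source system stores each structure's cumulative DVH as a *truncated*
point list: the flat 100% head and the 0% tail are omitted.  A continuous
dose -> volume% function is rebuilt by piecewise-linear interpolation,
padded to exactly 100% below the listed range and exactly 0% above it, which
keeps V_D / D_V objectives and cross-course percentile statistics well
defined at every dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyDVHError

if TYPE_CHECKING:  # pragma: no cover
    from .plans import CourseRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DVHFunction:
    """Continuous cumulative DVH: dose (Gy) -> volume (% of structure).

    ``doses``/``volumes`` are the cleaned node arrays (sorted by dose,
    volumes in [0, 100], monotone non-increasing).  Evaluation below the
    first node returns exactly 100, above the last exactly 0.
    """

    doses: np.ndarray
    volumes: np.ndarray

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.doses.tolist(), self.volumes.tolist()))

    @property
    def max_dose(self) -> float:
        return float(self.doses[-1])

    def __call__(self, dose) -> np.ndarray | float:
        return volume_at_dose(self, dose)


def build_dvh(points: Iterable[Sequence[float]]) -> DVHFunction:
    """Rebuild a :class:`DVHFunction` from a truncated point list.

    Input points are sorted by dose; duplicate doses collapse keeping the
    maximum volume; volumes are clipped to [0, 100]; non-monotone inputs
    are repaired with a running minimum (logged).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        raise EmptyDVHError("cannot build a DVH from an empty point list")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError("points must be (dose, volume) pairs")
    if np.any(pts[:, 0] < 0):
        raise DomainError("doses must be non-negative")

    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    doses, volumes = pts[:, 0], np.clip(pts[:, 1], 0.0, 100.0)

    # collapse duplicate doses keeping the max volume
    uniq, inv = np.unique(doses, return_inverse=True)
    if uniq.size != doses.size:
        vmax = np.full(uniq.size, -np.inf)
        np.maximum.at(vmax, inv, volumes)
        doses, volumes = uniq, vmax

    repaired = np.minimum.accumulate(volumes)
    if np.any(repaired != volumes):
        logger.warning("non-monotone DVH input repaired with running minimum")
        volumes = repaired
    return DVHFunction(doses=doses, volumes=volumes)


def volume_at_dose(dvh: DVHFunction, dose) -> np.ndarray | float:
    """V_D: volume (%) receiving at least ``dose`` Gy (scalar or array)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be non-negative")
    out = np.interp(d, dvh.doses, dvh.volumes)
    out = np.where(d < dvh.doses[0], 100.0, out)
    out = np.where(d > dvh.doses[-1], 0.0, out)
    return float(out) if np.isscalar(dose) or out.ndim == 0 else out


def dose_at_volume(dvh: DVHFunction, volume: float) -> float:
    """D_V: smallest dose (Gy) at which the evaluated volume is <= ``volume``%.

    On flat segments the left endpoint (smallest dose) is returned; at the
    padded 100% plateau the answer is 0 Gy.
    """
    if not 0 <= volume <= 100:
        raise DomainError("volume must be in [0, 100]%")
    if volume >= 100:
        return 0.0
    ds, vs = dvh.doses, dvh.volumes
    idx = np.nonzero(vs <= volume)[0]
    if idx.size == 0:
        # function is > volume on the whole listed range; it drops to 0 just
        # past the last node, so the boundary dose is the infimum
        return float(ds[-1])
    i = int(idx[0])
    if i == 0 or vs[i] == volume:
        return float(ds[i])
    # strictly decreasing segment (ds[i-1], ds[i]) crosses the target
    frac = (vs[i - 1] - volume) / (vs[i - 1] - vs[i])
    return float(ds[i - 1] + frac * (ds[i] - ds[i - 1]))


@dataclass(frozen=True)
class ObjectiveSpec:
    """One dose-volume objective, e.g. V40Gy to Rectum or D2% to SpinalCord."""

    kind: str  # "V_at_dose" | "D_at_volume"
    threshold: float  # dose Gy for V, volume % for D
    structure: str
    relative_to_reference: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("V_at_dose", "D_at_volume"):
            raise DomainError(f"unknown objective kind {self.kind!r}")
        if self.threshold < 0:
            raise DomainError("threshold must be >= 0")
        if self.kind == "D_at_volume" and self.threshold > 100:
            raise DomainError("volume threshold must be <= 100%")

    @property
    def label(self) -> str:
        if self.kind == "V_at_dose":
            return f"V{self.threshold:g}Gy[{self.structure}]"
        return f"D{self.threshold:g}%[{self.structure}]"

    def evaluate(self, dvh: DVHFunction) -> float:
        if self.kind == "V_at_dose":
            return float(volume_at_dose(dvh, self.threshold))
        return dose_at_volume(dvh, self.threshold)


def parse_objective(text: str) -> ObjectiveSpec:
    """Parse a compact objective string like ``"V42.5Gy@Rectum"`` or ``"D2%@PTV_High"``."""
    try:
        metric, structure = text.split("@", 1)
        metric = metric.strip()
        if metric[0].upper() == "V" and metric.lower().endswith("gy"):
            return ObjectiveSpec("V_at_dose", float(metric[1:-2]), structure.strip())
        if metric[0].upper() == "D" and metric.endswith("%"):
            return ObjectiveSpec("D_at_volume", float(metric[1:-1]), structure.strip())
    except (ValueError, IndexError) as exc:
        raise DomainError(f"cannot parse objective {text!r}") from exc
    raise DomainError(f"cannot parse objective {text!r}")


@dataclass(frozen=True)
class DVHBand:
    """Pointwise spread of a family of DVH curves on a common dose grid."""

    grid: np.ndarray  # Gy
    lo: np.ndarray  # min, volume %
    p20: np.ndarray
    median: np.ndarray
    p80: np.ndarray
    hi: np.ndarray  # max
    reference: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "dose_gy": self.grid,
            "lo": self.lo,
            "p20": self.p20,
            "median": self.median,
            "p80": self.p80,
            "hi": self.hi,
        }
        if self.reference is not None:
            data["reference"] = self.reference
        return pd.DataFrame(data)


def band(
    curves: Sequence[DVHFunction],
    reference: DVHFunction | None = None,
    grid_step: float = 0.1,
) -> DVHBand:
    """Pointwise min / 20th / median / 80th / max volume across ``curves``.

    The dose grid spans 0 to the largest listed dose plus one step.
    Percentiles interpolate linearly between closest order statistics (the
    common statistical-library convention), stated here for reproducibility.
    """
    if not curves:
        raise DomainError("band requires at least one curve")
    if grid_step <= 0:
        raise DomainError("grid_step must be positive")
    dmax = max(c.max_dose for c in curves)
    if reference is not None:
        dmax = max(dmax, reference.max_dose)
    n = int(np.ceil(dmax / grid_step)) + 1
    grid = grid_step * np.arange(n + 1)
    values = np.vstack([volume_at_dose(c, grid) for c in curves])
    return DVHBand(
        grid=grid,
        lo=values.min(axis=0),
        p20=np.percentile(values, 20, axis=0),
        median=np.percentile(values, 50, axis=0),
        p80=np.percentile(values, 80, axis=0),
        hi=values.max(axis=0),
        reference=None if reference is None else np.asarray(volume_at_dose(reference, grid)),
    )


DELIVERED = "delivered"


def _session_plan(session, plan_filter: str):
    """Plan picked from a session: the delivered revision's plan of the
    requested type, else the highest revision's."""
    from .plans import ADAPTIVE, SCHEDULED  # local import to avoid cycle

    if plan_filter == DELIVERED:
        return session.delivered
    if plan_filter not in (ADAPTIVE, SCHEDULED):
        raise DomainError(f"unknown plan filter {plan_filter!r}")
    pair = None
    if session.delivered is not None:
        for p in session.plan_pairs:
            if session.delivered in p.plans():
                pair = p
    if pair is None:
        pair = session.latest_pair()
    if pair is None:
        return None
    return pair.scheduled if plan_filter == SCHEDULED else pair.adaptive


def structure_dvh(
    doc, structure: str, source: str = "tpms"
) -> DVHFunction | None:
    """DVH of ``structure`` in one document, or None if absent."""
    pts = doc.dvh_sets.get(source, {}).get(structure)
    return None if pts is None else build_dvh(pts)


def objective_series(
    course: "CourseRecord",
    spec: ObjectiveSpec,
    plan_filter: str = DELIVERED,
    source: str = "tpms",
) -> pd.DataFrame:
    """Evaluate one objective per fraction across a course.

    Returns a DataFrame with columns ``fraction, plan_name, value,
    relative, missing``.  ``relative`` is plan value minus the reference
    plan's value for the same objective (NaN when either is unavailable).
    Sessions where the structure is missing yield ``missing=True`` with NaN
    values, never silent zeros.
    """
    ref_value = np.nan
    if course.reference is not None:
        ref_dvh = structure_dvh(course.reference, spec.structure, source)
        if ref_dvh is not None:
            ref_value = spec.evaluate(ref_dvh)

    rows = []
    for session in course.sessions:
        ident = _session_plan(session, plan_filter)
        doc = course.document_for(ident) if ident is not None else None
        dvh = structure_dvh(doc, spec.structure, source) if doc is not None else None
        if dvh is None:
            rows.append(
                {
                    "fraction": session.fraction,
                    "plan_name": None if ident is None else doc and doc.summary.plan_name,
                    "value": np.nan,
                    "relative": np.nan,
                    "missing": True,
                }
            )
            continue
        value = spec.evaluate(dvh)
        rows.append(
            {
                "fraction": session.fraction,
                "plan_name": doc.summary.plan_name,
                "value": value,
                "relative": value - ref_value,
                "missing": False,
            }
        )
    return pd.DataFrame(rows, columns=["fraction", "plan_name", "value", "relative", "missing"])


def paired_differences(
    course: "CourseRecord", spec: ObjectiveSpec, source: str = "tpms"
) -> pd.DataFrame:
    """Adaptive-minus-scheduled objective difference per fraction."""
    from .plans import ADAPTIVE, SCHEDULED

    a = objective_series(course, spec, ADAPTIVE, source).set_index("fraction")
    s = objective_series(course, spec, SCHEDULED, source).set_index("fraction")
    out = pd.DataFrame(
        {
            "adaptive": a["value"],
            "scheduled": s["value"],
            "difference": a["value"] - s["value"],
        }
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# CSV interoperability (columns: structure, source, dose_gy, volume_pct)

def dvh_to_csv(per_structure: dict[str, dict[str, DVHFunction]], path) -> None:
    """Write DVHs as long-format CSV; ``per_structure[source][name]``."""
    rows = []
    for source in sorted(per_structure):
        for name in sorted(per_structure[source]):
            f = per_structure[source][name]
            for d, v in zip(f.doses, f.volumes):
                rows.append((name, source, d, v))
    pd.DataFrame(rows, columns=["structure", "source", "dose_gy", "volume_pct"]).to_csv(
        path, index=False
    )


def dvh_from_csv(path) -> dict[str, dict[str, DVHFunction]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, DVHFunction]] = {}
    for (source, name), grp in df.groupby(["source", "structure"]):
        out.setdefault(source, {})[name] = build_dvh(
            grp[["dose_gy", "volume_pct"]].to_numpy()
        )
    return out
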