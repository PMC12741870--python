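"""OAR registries, target-tier assignment, and per-session volume/centroid deltas.

Because the source system exports no contour geometry, consistency checks
against the reference structure set are limited to what travels with each
check: structure volume and (when present) center-of-mass position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .documents import StructureEntry
from .errors import ConfigurationError
from .plans import require_reference

if TYPE_CHECKING:  # pragma: no cover
    from .plans import CourseRecord

logger = logging.getLogger(__name__)

OAR = "oar"
TARGET_LOW = "target_low"
TARGET_INT = "target_int"
TARGET_HIGH = "target_high"
OTHER = "other"

_TARGET_PREFIXES = ("ptv", "ctv")


def _norm(name: str) -> str:
    """Case-insensitive matching key with whitespace/underscores removed."""
    return "".join(name.lower().split()).replace("_", "")


@dataclass
class OARRegistry:
    """Per-treatment-site lists of canonical OAR names with synonyms.

    ``sites[site]`` maps canonical name -> list of synonyms (the canonical
    name always matches itself).  Lookups are case-insensitive and ignore
    whitespace and underscores.
    """

    sites: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def lookup(self, site: str, roi_name: str) -> str | None:
        table = self.sites.get(site, {})
        key = _norm(roi_name)
        for canonical, synonyms in table.items():
            if key == _norm(canonical) or any(key == _norm(s) for s in synonyms):
                return canonical
        return None

    def oars(self, site: str) -> list[str]:
        return list(self.sites.get(site, {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"sites": self.sites}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "OARRegistry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        reg = cls()
        for site, table in (data or {}).get("sites", {}).items():
            set_oars(reg, site, table)
        return reg


def default_registry() -> OARRegistry:
    """Built-in registry for the three supported site groups."""
    reg = OARRegistry()
    set_oars(reg, "pelvis", {
        "Bladder": [],
        "Rectum": [],
        "BowelSpace": ["Bowel_Space", "Bowel Bag", "BowelBag"],
    })
    set_oars(reg, "thorax", {
        "Lungs": ["Lung_Total", "Lungs-GTV"],
        "Heart": [],
        "Esophagus": [],
        "SpinalCord": ["Spinal_Cord", "Cord"],
    })
    set_oars(reg, "head_and_neck", {
        "Parotid_L": ["Lt Parotid", "Parotid Left"],
        "Parotid_R": ["Rt Parotid", "Parotid Right"],
        "SpinalCord": ["Spinal_Cord", "Cord"],
        "Larynx": [],
    })
    return reg


def set_oars(
    registry: OARRegistry,
    site: str,
    names: Iterable[str] | Mapping[str, Iterable[str]],
) -> OARRegistry:
    """Replace a site's OAR list (list of names, or name -> synonyms map).

    Raises :class:`ConfigurationError` when one synonym would resolve to two
    canonical names within the site.
    """
    if not site:
        raise ConfigurationError("site label must be non-empty")
    if isinstance(names, Mapping):
        table = {str(k): [str(s) for s in v] for k, v in names.items()}
    else:
        table = {str(n): [] for n in names}
    seen: dict[str, str] = {}
    for canonical, synonyms in table.items():
        for key in [canonical, *synonyms]:
            nk = _norm(key)
            if nk in seen and seen[nk] != canonical:
                raise ConfigurationError(
                    f"synonym {key!r} maps to both {seen[nk]!r} and {canonical!r} in site {site!r}"
                )
            seen[nk] = canonical
    registry.sites[site] = table
    if not table:
        logger.warning("site %r has no OARs; OAR metrics will be skipped", site)
    return registry


def _is_target(name: str) -> bool:
    return _norm(name).startswith(_TARGET_PREFIXES)


def assign_roles(
    structures: Iterable[StructureEntry],
    site: str,
    target_dose_levels: Mapping[str, float] | None = None,
    registry: OARRegistry | None = None,
) -> list[StructureEntry]:
    """Assign each structure a role: tiered target, OAR, or other.

    ROI names with a PTV/CTV prefix are targets, ranked by prescribed dose
    from ``target_dose_levels``: lowest -> ``target_low``, highest ->
    ``target_high``, everything between pooled as ``target_int`` (a single
    target is ``target_high``).  Equal doses tie-break alphabetically with a
    logged warning.  Non-target names are matched against the site's OAR
    registry; the rest are ``other``.  Deterministic and invariant to input
    order.
    """
    registry = registry or default_registry()
    target_dose_levels = target_dose_levels or {}
    structures = list(structures)

    targets = [s for s in structures if _is_target(s.name)]
    dosed = []
    for s in targets:
        dose = None
        for key, d in target_dose_levels.items():
            if _norm(key) == _norm(s.name):
                dose = float(d)
                break
        if dose is None:
            dose = _dose_from_name(s.name)
            if dose is None:
                logger.warning(
                    "target %r has no prescribed dose level; treating as highest tier",
                    s.name,
                )
                dose = math.inf
        dosed.append((dose, s.name.lower(), s))
    doses_only = [d for d, _, _ in dosed]
    if len(set(doses_only)) < len(doses_only):
        logger.warning("targets with equal dose; tie broken alphabetically")
    dosed.sort(key=lambda t: (t[0], t[1]))

    tier_by_name: dict[str, str] = {}
    n = len(dosed)
    if n == 1:
        tier_by_name[dosed[0][2].name] = TARGET_HIGH
    elif n >= 2:
        if n > 3:
            logger.warning("%d target dose levels; middle tiers pooled as target_int", n)
        tier_by_name[dosed[0][2].name] = TARGET_LOW
        tier_by_name[dosed[-1][2].name] = TARGET_HIGH
        for _, _, s in dosed[1:-1]:
            tier_by_name[s.name] = TARGET_INT

    out = []
    for s in structures:
        if s.name in tier_by_name:
            role = tier_by_name[s.name]
        elif registry.lookup(site, s.name) is not None:
            role = OAR
        else:
            role = OTHER
        out.append(replace(s, role=role))
    return out


def _dose_from_name(name: str) -> float | None:
    """Fallback tier hint from names like PTV_High / CTV_Low (rank surrogate)."""
    key = _norm(name)
    for hint, rank in (("high", 3.0), ("int", 2.0), ("low", 1.0)):
        if key.endswith(hint):
            return rank
    return None


@dataclass(frozen=True)
class VolumeDelta:
    """Per-session change of one structure versus the reference set."""

    fraction: int
    volume_cm3: float
    absolute_cm3: float | None
    relative_fraction: float | None  # (session - reference) / reference
    centroid_shift_cm: float | None = None
    centroid_shift_xyz: tuple[float, float, float] | None = None
    adapted: bool = False


def volume_trend(course: "CourseRecord", structure: str) -> pd.DataFrame:
    """Per-delivered-session volume deltas for one structure.

    Emits one row per delivered session with absolute (cm^3) and relative
    (fraction of reference) deltas plus the adapted flag.  When the
    structure is absent from the reference set (or the reference volume is
    zero) the relative column is NaN while the absolute trajectory is still
    emitted.  Volumes are carried from the source documents, never
    recomputed.
    """
    ref_entry = None
    if course.reference is not None:
        ref_entry = course.reference.structure(structure)
    ref_vol = ref_entry.volume_cm3 if ref_entry else None
    ref_cent = ref_entry.centroid if ref_entry else None
    if ref_vol is not None and ref_vol <= 0:
        logger.warning("reference volume of %r is zero; relative deltas undefined", structure)
        ref_vol = None

    rows: list[VolumeDelta] = []
    for session in course.sessions:
        if session.delivered is None:
            continue
        doc = course.document_for(session.delivered)
        entry = doc.structure(structure) if doc is not None else None
        if entry is None:
            logger.warning(
                "structure %r missing in fraction %d; skipped", structure, session.fraction
            )
            continue
        shift = shift_xyz = None
        if ref_cent is not None and entry.centroid is not None:
            diff = np.subtract(entry.centroid, ref_cent)
            shift_xyz = tuple(float(x) for x in diff)
            shift = float(np.linalg.norm(diff))
        rows.append(
            VolumeDelta(
                fraction=session.fraction,
                volume_cm3=entry.volume_cm3,
                absolute_cm3=None if ref_vol is None and ref_entry is None
                else entry.volume_cm3 - (ref_entry.volume_cm3 if ref_entry else 0.0),
                relative_fraction=None if ref_vol is None
                else (entry.volume_cm3 - ref_vol) / ref_vol,
                centroid_shift_cm=shift,
                centroid_shift_xyz=shift_xyz,
                adapted=session.adapted,
            )
        )
    return pd.DataFrame(
        [
            {
                "fraction": r.fraction,
                "volume_cm3": r.volume_cm3,
                "delta_cm3": r.absolute_cm3,
                "delta_rel": r.relative_fraction,
                "centroid_shift_cm": r.centroid_shift_cm,
                "adapted": r.adapted,
            }
            for r in rows
        ],
        columns=["fraction", "volume_cm3", "delta_cm3", "delta_rel", "centroid_shift_cm", "adapted"],
    )


def reference_volume(course: "CourseRecord", structure: str) -> float:
    entry = require_reference(course).structure(structure)
    if entry is None:
        raise ConfigurationError(f"structure {structure!r} absent from reference set")
    return entry.volume_cm3
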