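"""Synthetic plan-check fixture: generator, file store and HTTP endpoint.

Real adaptive-therapy plan-check databases are clinical systems that cannot
ship with a toolkit, so this module synthesizes whole treatment courses in
the same JSON dialect the client consumes, together with the ground truth
used to make them (delivered plans, volume trajectories, DVH parameters).
Every downstream module is therefore testable offline against known truth.

Synthesis model
---------------
* Each fraction spawns one scheduled/adaptive plan pair per structure-set
  revision (suffixes 01/02, then 03/04, ...), and exactly one log-file
  check linking to the delivered plan's pre-treatment check.
* Cumulative DVHs are shifted sigmoids ``v(d) = 100 / (1 + exp((d - D50)/w))``
  — monotone, realistic in shape, and analytically evaluable, which gives
  oracle tests a closed form.  Point lists are sampled on a 0.5 Gy grid and
  truncated to the open interval (0, 100) volume-% the way the source
  system omits the flat head and tail.
* Structure volumes follow deterministic linear drifts (bladder defaults to
  +2% of reference per fraction); the generator emulates systematic
  anatomical trends, not daily stochastic variation.
"""

from __future__ import annotations

import json
import math
import threading
from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Any

import numpy as np

from .documents import LOGFILE, PRETREATMENT, BeamEntry, CheckSummary, PlanCheckDocument, StructureEntry
from .errors import ConfigurationError

DEFAULT_TOKEN = "fixture-token"

_BASE_DATE = datetime(2024, 1, 1)
_DOSE_STEP = 0.5  # Gy; objective doses like 42.5 Gy land on grid nodes
_TRUNC = 1e-3  # volume-% kept strictly inside (0, 100)


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic cohort."""

    institution_label: str = "fixture"
    n_patients: int = 3
    fractions_per_patient: int = 25
    revision_probability: float = 0.1
    adapt_probability: float = 0.8
    site: str = "pelvis"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.fractions_per_patient < 1:
            raise ConfigurationError("patient and fraction counts must be positive")
        for p in (self.revision_probability, self.adapt_probability):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if self.site not in SITE_PROFILES:
            raise ConfigurationError(
                f"unknown site {self.site!r}; known: {sorted(SITE_PROFILES)}"
            )


@dataclass(frozen=True)
class StructureProfile:
    name: str
    volume_cm3: float
    d50: float  # Gy, reference-plan sigmoid midpoint
    width: float  # Gy, sigmoid scale
    drift_per_fraction: float | None = None  # None: drawn per patient
    target_dose_gy: float | None = None  # prescribed dose for targets


@dataclass(frozen=True)
class SiteProfile:
    prescription_cGy: float  # per-fraction prescription of the highest tier
    structures: tuple[StructureProfile, ...]

    @property
    def target_dose_levels(self) -> dict[str, float]:
        return {
            s.name: s.target_dose_gy for s in self.structures if s.target_dose_gy is not None
        }


SITE_PROFILES: dict[str, SiteProfile] = {
    "pelvis": SiteProfile(
        prescription_cGy=220.0,
        structures=(
            StructureProfile("PTV_High", 320.0, 56.0, 0.9, target_dose_gy=55.0),
            StructureProfile("PTV_Low", 620.0, 46.5, 1.1, target_dose_gy=45.0),
            StructureProfile("CTV_High", 250.0, 56.3, 0.8, target_dose_gy=55.0),
            StructureProfile("Bladder", 150.0, 30.0, 7.0, drift_per_fraction=0.02),
            StructureProfile("Rectum", 65.0, 24.0, 6.0),
            StructureProfile("BowelSpace", 900.0, 14.0, 6.0),
        ),
    ),
    "thorax": SiteProfile(
        prescription_cGy=200.0,
        structures=(
            StructureProfile("PTV", 120.0, 61.0, 1.0, target_dose_gy=60.0),
            StructureProfile("Lungs", 3500.0, 9.0, 5.0),
            StructureProfile("Heart", 650.0, 12.0, 6.0),
            StructureProfile("Esophagus", 40.0, 20.0, 7.0),
            StructureProfile("SpinalCord", 45.0, 14.0, 5.0),
        ),
    ),
    "head_and_neck": SiteProfile(
        prescription_cGy=212.0,
        structures=(
            StructureProfile("PTV_High", 180.0, 71.0, 1.0, target_dose_gy=70.0),
            StructureProfile("PTV_Int", 320.0, 64.0, 1.2, target_dose_gy=63.0),
            StructureProfile("PTV_Low", 480.0, 57.0, 1.3, target_dose_gy=56.0),
            StructureProfile("Parotid_L", 28.0, 26.0, 8.0),
            StructureProfile("Parotid_R", 28.0, 26.0, 8.0),
            StructureProfile("SpinalCord", 45.0, 30.0, 6.0),
            StructureProfile("Larynx", 30.0, 35.0, 7.0),
        ),
    ),
}


def sigmoid_volume(dose, d50: float, width: float):
    """Closed form of the synthesized cumulative DVH (volume %)."""
    return 100.0 / (1.0 + np.exp((np.asarray(dose, dtype=float) - d50) / width))


def _truncated_points(d50: float, width: float) -> list[list[float]]:
    # sample past the midpoint until the tail falls below the truncation floor
    dmax = d50 + width * math.log(100.0 / _TRUNC - 1.0)
    doses = _DOSE_STEP * np.arange(0, int(math.ceil(dmax / _DOSE_STEP)) + 1)
    vols = sigmoid_volume(doses, d50, width)
    keep = (vols > _TRUNC) & (vols < 100.0 - _TRUNC)
    return [[float(d), float(v)] for d, v in zip(doses[keep], vols[keep])]


@dataclass
class GroundTruth:
    """Generator-side truth, emitted beside the documents.

    Never passed through the client path; tests compare client-side results
    against it.
    """

    config: FixtureConfig
    patients: dict[str, dict[str, Any]] = field(default_factory=dict)

    def delivered_plan(self, patient_id: str, fraction: int) -> str:
        return self.patients[patient_id]["fractions"][str(fraction)]["delivered"]

    def adapted(self, patient_id: str, fraction: int) -> bool:
        return self.patients[patient_id]["fractions"][str(fraction)]["adapted"]

    def volume(self, patient_id: str, structure: str, fraction: int) -> float:
        return self.patients[patient_id]["volumes"][structure]["trajectory"][str(fraction)]

    def dvh_params(self, patient_id: str, plan_name: str, structure: str, source: str) -> dict:
        return self.patients[patient_id]["dvh_params"][plan_name][structure][source]

    def to_json(self) -> dict[str, Any]:
        return {"config": asdict(self.config), "patients": self.patients}

    @classmethod
    def from_json(cls, obj: dict[str, Any]) -> "GroundTruth":
        return cls(config=FixtureConfig(**obj["config"]), patients=obj["patients"])


def _iso(dt: datetime) -> str:
    return dt.strftime("%Y-%m-%dT%H:%M:%S")


def generate_course(config: FixtureConfig) -> tuple[list[PlanCheckDocument], GroundTruth]:
    """Generate all plan-check documents for a synthetic cohort.

    Identical ``config`` (which includes the seed) yields byte-identical
    serialized documents.
    """
    rng = np.random.default_rng(config.seed)
    profile = SITE_PROFILES[config.site]
    documents: list[PlanCheckDocument] = []
    truth = GroundTruth(config=config)
    check_seq = 0

    def next_check_id() -> str:
        nonlocal check_seq
        check_seq += 1
        return f"CHK{check_seq:06d}"

    for p in range(config.n_patients):
        patient_id = f"PT{p + 1:04d}"
        ref_plan_id = f"IM{100 + int(rng.integers(0, 900)):d}"
        start = _BASE_DATE + timedelta(days=int(rng.integers(0, 200)))
        iso = tuple(float(x) for x in rng.uniform(-2, 2, size=3))
        drifts = {
            s.name: (
                s.drift_per_fraction
                if s.drift_per_fraction is not None
                else float(rng.uniform(-0.008, 0.008))
            )
            for s in profile.structures
        }
        centroids = {
            s.name: tuple(float(x) for x in rng.uniform(-8, 8, size=3))
            for s in profile.structures
        }

        ptruth: dict[str, Any] = {
            "reference_plan": ref_plan_id,
            "site": config.site,
            "prescription_cGy": profile.prescription_cGy,
            "target_dose_levels": profile.target_dose_levels,
            "fractions": {},
            "volumes": {
                s.name: {
                    "reference_cm3": s.volume_cm3,
                    "drift_per_fraction": drifts[s.name],
                    "trajectory": {},
                }
                for s in profile.structures
            },
            "dvh_params": {},
        }

        def volumes_at(fraction: int) -> dict[str, float]:
            return {
                s.name: s.volume_cm3 * (1.0 + drifts[s.name] * fraction)
                for s in profile.structures
            }

        def make_beams() -> list[BeamEntry]:
            n_beams = 2 + int(rng.integers(0, 2))
            beams = []
            for b in range(n_beams):
                mu = float(rng.uniform(0.9, 1.6)) * profile.prescription_cGy / n_beams
                beams.append(
                    BeamEntry(
                        isocenter=iso,
                        n_control_points=int(rng.integers(80, 120)),
                        gantry_angles=(179.0, 0.0, -179.0) if b % 2 == 0 else (-179.0, 0.0, 179.0),
                        collimator_angle=float(rng.uniform(0, 90)),
                        mu=mu,
                    )
                )
            return beams

        def dvh_for(truth_key: str, fraction: int, jitter_scale: float) -> dict:
            """Synthesize both DVH sources and record their parameters."""
            per_source: dict[str, dict[str, list[list[float]]]] = {"tpms": {}, "secondary": {}}
            ptruth["dvh_params"][truth_key] = {}
            for s in profile.structures:
                d50 = s.d50 * (1.0 + float(rng.normal(0.0, jitter_scale)))
                params = {
                    "tpms": {"d50": d50, "width": s.width},
                    # secondary calculation sits systematically ~1% off
                    "secondary": {"d50": d50 * 1.01, "width": s.width},
                }
                ptruth["dvh_params"][truth_key][s.name] = params
                for src in ("tpms", "secondary"):
                    per_source[src][s.name] = _truncated_points(
                        params[src]["d50"], params[src]["width"]
                    )
            return per_source

        def make_doc(
            plan_name: str,
            kind: str,
            when: datetime,
            fraction: int,
            linked: str | None = None,
            jitter_scale: float = 0.0,
        ) -> PlanCheckDocument:
            vols = volumes_at(fraction)
            structures = [
                StructureEntry(
                    name=s.name,
                    volume_cm3=vols[s.name],
                    density_override=1.0 if s.name == "BowelSpace" else None,
                    centroid=tuple(
                        c + 0.05 * fraction * (i + 1) / 3.0
                        for i, c in enumerate(centroids[s.name])
                    ),
                )
                for s in profile.structures
            ]
            return PlanCheckDocument(
                summary=CheckSummary(
                    check_id=next_check_id(),
                    patient_id=patient_id,
                    plan_name=plan_name,
                    check_kind=kind,
                    timestamp=_iso(when),
                    linked_check_id=linked,
                ),
                structures=structures,
                beams=make_beams(),
                dvh_sets=dvh_for(
                    plan_name if kind == PRETREATMENT else f"{plan_name}@logfile",
                    fraction,
                    jitter_scale,
                ),
                prescription_cGy=profile.prescription_cGy,
                site=config.site,
            )

        # reference plan check, fraction 0
        documents.append(make_doc(ref_plan_id, PRETREATMENT, start.replace(hour=8), 0))
        for s in profile.structures:
            ptruth["volumes"][s.name]["trajectory"]["0"] = s.volume_cm3

        for f in range(1, config.fractions_per_patient + 1):
            day = start + timedelta(days=f)
            n_revisions = 1 + int(rng.random() < config.revision_probability)
            plan_names: list[str] = []
            pretreat_ids: dict[str, str] = {}
            for r in range(1, n_revisions + 1):
                sch = f"{ref_plan_id}/SCH{f:02d}{2 * r - 1:02d}"
                adp = f"{ref_plan_id}/ADP{f:02d}{2 * r:02d}"
                for k, name in enumerate((sch, adp)):
                    when = day.replace(hour=8) + timedelta(minutes=10 * (2 * (r - 1) + k))
                    doc = make_doc(name, PRETREATMENT, when, f, jitter_scale=0.02)
                    documents.append(doc)
                    pretreat_ids[name] = doc.summary.check_id
                plan_names += [sch, adp]

            adapted = bool(rng.random() < config.adapt_probability)
            last_r = n_revisions
            delivered = (
                f"{ref_plan_id}/ADP{f:02d}{2 * last_r:02d}"
                if adapted
                else f"{ref_plan_id}/SCH{f:02d}{2 * last_r - 1:02d}"
            )
            documents.append(
                make_doc(
                    delivered,
                    LOGFILE,
                    day.replace(hour=9, minute=30),
                    f,
                    linked=pretreat_ids[delivered],
                )
            )
            ptruth["fractions"][str(f)] = {
                "delivered": delivered,
                "adapted": adapted,
                "revisions": n_revisions,
                "plans": plan_names,
            }
            vols = volumes_at(f)
            for s in profile.structures:
                ptruth["volumes"][s.name]["trajectory"][str(f)] = vols[s.name]

        truth.patients[patient_id] = ptruth

    return documents, truth


# ---------------------------------------------------------------------------
# file-backed mode

def write_directory(
    documents: list[PlanCheckDocument],
    truth: GroundTruth | None,
    path,
    token: str = DEFAULT_TOKEN,
) -> Path:
    """Write one JSON file per check plus an index; ground truth separately."""
    root = Path(path)
    (root / "checks").mkdir(parents=True, exist_ok=True)
    index: dict[str, Any] = {"token": token, "patients": {}}
    for doc in documents:
        cid = doc.summary.check_id
        index["patients"].setdefault(doc.summary.patient_id, []).append(cid)
        with open(root / "checks" / f"{cid}.json", "w") as fh:
            json.dump(doc.to_json(), fh, sort_keys=True, indent=1)
    with open(root / "index.json", "w") as fh:
        json.dump(index, fh, sort_keys=True, indent=1)
    if truth is not None:
        with open(root / "ground_truth.json", "w") as fh:
            json.dump(truth.to_json(), fh, sort_keys=True, indent=1)
    return root


def read_ground_truth(path) -> GroundTruth:
    with open(Path(path) / "ground_truth.json") as fh:
        return GroundTruth.from_json(json.load(fh))


# ---------------------------------------------------------------------------
# HTTP endpoint (stdlib server; threaded so tests can run it in-process)

class _Handler(BaseHTTPRequestHandler):
    server: "FixtureServer"

    def log_message(self, *args) -> None:  # quiet
        pass

    def _send(self, code: int, payload: dict) -> None:
        body = json.dumps(payload, sort_keys=True).encode()
        self.send_response(code)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _authorized(self) -> bool:
        auth = self.headers.get("Authorization", "")
        return auth == f"Bearer {self.server.token}"

    def do_POST(self) -> None:
        if self.path != "/auth":
            self._send(404, {"error_str": "unknown route"})
            return
        length = int(self.headers.get("Content-Length", 0))
        try:
            payload = json.loads(self.rfile.read(length) or b"{}")
        except json.JSONDecodeError:
            self._send(400, {"error_str": "malformed JSON body"})
            return
        if payload.get("token") != self.server.token:
            self._send(401, {"error_str": "bad credentials"})
            return
        self._send(200, {"ok": True})

    def do_GET(self) -> None:
        if not self._authorized():
            self._send(401, {"error_str": "missing or bad bearer token"})
            return
        parts = [p for p in self.path.split("/") if p]
        if len(parts) == 3 and parts[0] == "patients" and parts[2] == "checks":
            docs = self.server.by_patient.get(parts[1], [])
            self._send(200, {"checks": [d.summary.to_json() for d in docs]})
        elif len(parts) == 2 and parts[0] == "checks":
            doc = self.server.by_id.get(parts[1])
            if doc is None:
                self._send(404, {"error_str": f"check {parts[1]!r} not found"})
            else:
                self._send(200, doc.to_json())
        else:
            self._send(404, {"error_str": "unknown route"})


class FixtureServer:
    """In-process HTTP endpoint serving generated documents.

    Usable as a context manager; ``base_url`` is available after start.
    A port that is already bound raises ``OSError`` at construction.
    """

    def __init__(
        self,
        documents: list[PlanCheckDocument],
        host: str = "127.0.0.1",
        port: int = 0,
        token: str = DEFAULT_TOKEN,
    ) -> None:
        self.token = token
        self.by_id = {d.summary.check_id: d for d in documents}
        self.by_patient: dict[str, list[PlanCheckDocument]] = {}
        for d in documents:
            self.by_patient.setdefault(d.summary.patient_id, []).append(d)
        self._httpd = ThreadingHTTPServer((host, port), _Handler)
        self._httpd.token = token  # type: ignore[attr-defined]
        self._httpd.by_id = self.by_id  # type: ignore[attr-defined]
        self._httpd.by_patient = self.by_patient  # type: ignore[attr-defined]
        self._thread: threading.Thread | None = None

    @property
    def base_url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def start(self) -> "FixtureServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def __enter__(self) -> "FixtureServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


def serve(documents: list[PlanCheckDocument], host: str = "127.0.0.1", port: int = 0,
          token: str = DEFAULT_TOKEN) -> FixtureServer:
    """Start a fixture endpoint answering auth / list / fetch requests."""
    return FixtureServer(documents, host=host, port=port, token=token).start()
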