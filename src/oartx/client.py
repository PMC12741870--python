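"""Authenticated client for a plan-check source (HTTP endpoint or directory).

The network layer is an injectable transport so the file-backed fixture
mode can stand in for HTTP transparently; both speak the same JSON dialect
(see :mod:`oartx.documents`).  The client never mutates fetched documents
and repeated fetches are idempotent.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol

from .documents import LOGFILE, PRETREATMENT, CheckSummary, PlanCheckDocument
from .errors import AuthError, ConnectionFailedError, MissingCheckError, ParseError

logger = logging.getLogger(__name__)

RETRIES = 3


class Transport(Protocol):
    def auth(self, token: str) -> None: ...
    def list_checks(self, patient_id: str) -> list[dict]: ...
    def get_check(self, check_id: str) -> dict: ...


class HTTPTransport:
    """Bearer-token HTTP transport over the documented three-route API."""

    def __init__(self, base_url: str, timeout: float = 10.0) -> None:
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout
        self._token: str | None = None

    def _request(self, method: str, path: str, body: dict | None = None) -> tuple[int, dict]:
        req = urllib.request.Request(
            self.base_url + path,
            method=method,
            data=None if body is None else json.dumps(body).encode(),
            headers={"Content-Type": "application/json"},
        )
        if self._token is not None:
            req.add_header("Authorization", f"Bearer {self._token}")
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.status, json.loads(resp.read())
        except urllib.error.HTTPError as exc:
            try:
                payload = json.loads(exc.read())
            except (json.JSONDecodeError, ValueError):
                payload = {}
            return exc.code, payload
        except (urllib.error.URLError, OSError) as exc:
            raise ConnectionError(str(exc)) from exc
        except json.JSONDecodeError as exc:
            raise ParseError(f"response body is not valid JSON: {exc}") from exc

    def auth(self, token: str) -> None:
        status, _ = self._request("POST", "/auth", {"token": token})
        if status == 401:
            raise AuthError("endpoint rejected the credentials")
        if status != 200:
            raise ConnectionError(f"auth endpoint returned status {status}")
        self._token = token

    def list_checks(self, patient_id: str) -> list[dict]:
        status, payload = self._request("GET", f"/patients/{patient_id}/checks")
        if status != 200:
            raise ConnectionError(f"listing returned status {status}")
        return payload.get("checks", [])

    def get_check(self, check_id: str) -> dict:
        status, payload = self._request("GET", f"/checks/{check_id}")
        if status == 404:
            raise MissingCheckError(f"check {check_id!r} not found at source")
        if status != 200:
            raise ConnectionError(f"fetch returned status {status}")
        return payload


class DirectoryTransport:
    """File-backed source: one JSON document per check plus an index file."""

    def __init__(self, root) -> None:
        self.root = Path(root)
        if not (self.root / "index.json").exists():
            raise ConnectionError(f"no index.json under {self.root}")
        with open(self.root / "index.json") as fh:
            self._index = json.load(fh)

    def auth(self, token: str) -> None:
        if token != self._index.get("token"):
            raise AuthError("directory index rejected the credentials")

    def list_checks(self, patient_id: str) -> list[dict]:
        out = []
        for cid in self._index.get("patients", {}).get(patient_id, []):
            out.append(
                {
                    k: v
                    for k, v in self.get_check(cid).items()
                    if k.endswith("_str")
                }
            )
        return out

    def get_check(self, check_id: str) -> dict:
        path = self.root / "checks" / f"{check_id}.json"
        if not path.exists():
            raise MissingCheckError(f"check {check_id!r} not found under {self.root}")
        try:
            with open(path) as fh:
                return json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"check {check_id!r}: truncated or invalid JSON: {exc}") from exc


@dataclass
class Session:
    """Authenticated handle over a transport."""

    transport: Transport
    source: str


def open_session(
    source: str,
    token: str,
    retries: int = RETRIES,
    backoff_s: float = 0.2,
    transport: Transport | None = None,
) -> Session:
    """Authenticate against ``source`` (an http(s) URL or a directory path).

    Connection attempts retry with exponential backoff (``retries`` tries)
    before raising :class:`ConnectionFailedError`; bad credentials raise
    :class:`AuthError` immediately.
    """
    if transport is None:
        if source.startswith(("http://", "https://")):
            transport = HTTPTransport(source)
        else:
            transport = _retrying(lambda: DirectoryTransport(source), retries, backoff_s)
    _retrying(lambda: transport.auth(token), retries, backoff_s)
    return Session(transport=transport, source=source)


def _retrying(fn, retries: int, backoff_s: float):
    last: Exception | None = None
    for attempt in range(retries):
        try:
            return fn()
        except ConnectionError as exc:
            last = exc
            if attempt < retries - 1:
                time.sleep(backoff_s * 2**attempt)
    raise ConnectionFailedError(f"source unreachable after {retries} attempts: {last}")


def list_plan_checks(session: Session, patient_id: str) -> list[CheckSummary]:
    """All check summaries for one patient, sorted by timestamp ascending.

    An unknown patient yields an empty list (logged), matching how a
    clinical source answers for patients it has never checked.
    """
    raw = _retrying(lambda: session.transport.list_checks(patient_id), RETRIES, 0.2)
    summaries = [CheckSummary.from_json(obj) for obj in raw]
    if not summaries:
        logger.info("no checks listed for patient %r", patient_id)
    return sorted(summaries, key=lambda s: (s.timestamp, s.check_id))


def fetch_check(session: Session, check_id: str) -> PlanCheckDocument:
    """Fetch and parse one full check document.

    Unknown vendor fields are preserved in ``document.extras`` for forward
    compatibility.
    """
    raw = _retrying(lambda: session.transport.get_check(check_id), RETRIES, 0.2)
    return PlanCheckDocument.from_json(raw)


def fetch_course(session: Session, patient_id: str) -> list[PlanCheckDocument]:
    """List then fetch every check for one patient, in timestamp order."""
    return [fetch_check(session, s.check_id) for s in list_plan_checks(session, patient_id)]


def resolve_delivered(checks: Iterable[CheckSummary]) -> dict[str, bool]:
    """Mark each pre-treatment plan delivered iff a log-file check links to it.

    The delivered plan of a fraction is the one whose pre-treatment check a
    delivery log-file check references.  If several log-file checks exist
    for one fraction, the latest timestamp wins (re-deliveries supersede)
    with a logged warning; a log-file check linking to an absent
    pre-treatment check is ignored with a dangling-link warning.
    """
    checks = list(checks)
    pretreat_by_id = {c.check_id: c for c in checks if c.check_kind == PRETREATMENT}

    # fraction key -> (timestamp, linked pretreatment summary)
    winner: dict[str, tuple[str, CheckSummary]] = {}
    for c in checks:
        if c.check_kind != LOGFILE:
            continue
        target = pretreat_by_id.get(c.linked_check_id or "")
        if target is None:
            logger.warning(
                "log-file check %s links to absent pre-treatment check %r; ignored",
                c.check_id,
                c.linked_check_id,
            )
            continue
        frac_key = _fraction_key(target.plan_name)
        prev = winner.get(frac_key)
        if prev is not None:
            logger.warning(
                "multiple log-file checks for fraction %s; keeping the latest", frac_key
            )
            if c.timestamp <= prev[0]:
                continue
        winner[frac_key] = (c.timestamp, target)

    delivered_names = {t.plan_name for _, t in winner.values()}
    return {
        c.plan_name: c.plan_name in delivered_names
        for c in checks
        if c.check_kind == PRETREATMENT
    }


def _fraction_key(plan_name: str) -> str:
    from .plans import parse_plan_name  # local import to avoid cycle

    try:
        ident = parse_plan_name(plan_name)
        return f"f{ident.fraction}" if ident.fraction is not None else plan_name
    except Exception:
        return plan_name
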