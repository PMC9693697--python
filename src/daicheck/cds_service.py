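"""CDS Hooks 1.0 face of the drug-allergy interaction service.

Exposes the two CDS Hooks endpoints: service discovery
(``GET {base}/cds-services``) and the order-sign DAI check
(``POST {base}/cds-services/<service-id>``). The client supplies draft
medication orders in ``context.draftOrders`` and the patient's
AllergyIntolerance records in the ``prefetch`` field — the "serverless FHIR"
pattern: the service never calls back to a FHIR server, so a request without
the prefetch key is answered with 412 (prefetch required).

Authentication is a service-issued HMAC-SHA256 bearer token (JWT-compatible
compact serialization) checked against a whitelist of participating
providers. Results are returned as cards: one aggregate "warning" card per
implicated medication, with per-allergen detail; no findings means an empty
card array — the conformant way to say "nothing to report".

Every invocation, including rejected ones, writes exactly one audit record.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from . import audit as audit_mod
from .audit import AuditLog
from .fhir_model import (
    CodeSystems,
    parse_allergy_bundle,
    parse_draft_orders_bundle,
)
from .knowledge_base import KnowledgeBase
from .rule_engine import Finding, screen_request

__all__ = [
    "ServiceConfig",
    "ClientIdentity",
    "Rejection",
    "TokenError",
    "mint_token",
    "verify_token",
    "authenticate",
    "discovery",
    "Card",
    "CardResponse",
    "build_cards",
    "DAIService",
    "create_wsgi_app",
    "serve",
]

SUMMARY_LIMIT = 140
INDICATORS = ("info", "warning", "critical")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ServiceConfig:
    """Deployment configuration; loadable from a YAML or JSON file."""

    service_id: str = "drug-allergy-interaction-check"
    title: str = "Drug-allergy interaction check"
    description: str = (
        "Screens draft medication orders against the patient's recorded "
        "medication allergies: same product or ingredient, same drug or "
        "ingredient class, and cross-reactive allergens."
    )
    kd_code_system: str = "https://example.org/fhir/CodeSystem/kd-code"
    allergen_code_system: str = "https://example.org/fhir/CodeSystem/drug-allergen"
    source_label: str = "Drug-Allergy Interaction CDS Service"
    source_url: str | None = None
    card_link_label: str | None = None
    card_link_url: str | None = None
    token_secret: str = "dev-secret-change-me"
    token_lifetime_seconds: int = 86400  # 24 h
    whitelist: dict[str, str] = field(default_factory=dict)  # client_id -> display
    audit_log_path: str | None = None
    audit_hash_key: str | None = None  # defaults to token_secret when None
    reject_code_system_mismatch: bool = False  # strictness toggle

    @property
    def code_systems(self) -> CodeSystems:
        return CodeSystems(kd_code=self.kd_code_system, allergen=self.allergen_code_system)

    @property
    def hash_key(self) -> str:
        return self.audit_hash_key or self.token_secret

    @classmethod
    def from_file(cls, path: str | Path) -> "ServiceConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file must hold a mapping: {path}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "whitelist" in doc and isinstance(doc["whitelist"], list):
            doc["whitelist"] = {c: c for c in doc["whitelist"]}
        return cls(**doc)


# ---------------------------------------------------------------------------
# Tokens and authentication
# ---------------------------------------------------------------------------

class TokenError(Exception):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def _b64url(data: bytes) -> str:
    return base64.urlsafe_b64encode(data).rstrip(b"=").decode()


def _b64url_decode(text: str) -> bytes:
    pad = -len(text) % 4
    return base64.urlsafe_b64decode(text + "=" * pad)


def _sign(secret: str, signing_input: bytes) -> bytes:
    return hmac.new(secret.encode(), signing_input, hashlib.sha256).digest()


def mint_token(
    secret: str,
    client_id: str,
    lifetime_seconds: int = 86400,
    now: float | None = None,
) -> str:
    """Issue a signed bearer token (HS256, JWT compact form) for a client."""
    iat = int(now if now is not None else time.time())
    header = {"alg": "HS256", "typ": "JWT"}
    payload = {"sub": client_id, "iat": iat, "exp": iat + int(lifetime_seconds)}
    signing_input = (
        _b64url(json.dumps(header, separators=(",", ":")).encode())
        + "."
        + _b64url(json.dumps(payload, separators=(",", ":")).encode())
    ).encode()
    return signing_input.decode() + "." + _b64url(_sign(secret, signing_input))


def verify_token(token: str, secret: str, now: float | None = None) -> dict:
    """Verify signature and expiry; returns the claims or raises TokenError."""
    parts = token.split(".")
    if len(parts) != 3:
        raise TokenError("malformed")
    signing_input = (parts[0] + "." + parts[1]).encode()
    try:
        sig = _b64url_decode(parts[2])
        claims = json.loads(_b64url_decode(parts[1]))
    except (ValueError, TypeError):
        raise TokenError("malformed")
    if not hmac.compare_digest(sig, _sign(secret, signing_input)):
        raise TokenError("bad-signature")
    if not isinstance(claims, dict) or not isinstance(claims.get("sub"), str):
        raise TokenError("malformed")
    exp = claims.get("exp")
    ts = now if now is not None else time.time()
    if not isinstance(exp, (int, float)) or ts >= exp:
        raise TokenError("expired")
    return claims


@dataclass(frozen=True)
class ClientIdentity:
    client_id: str
    display: str = ""
    whitelisted: bool = True


@dataclass(frozen=True)
class Rejection:
    reason: str  # missing | malformed | bad-signature | expired | not-whitelisted
    status: int  # 401 or 403


def authenticate(
    authorization_header: str | None,
    whitelist: Mapping[str, str] | Iterable[str],
    secret: str,
    now: float | None = None,
) -> ClientIdentity | Rejection:
    """Resolve an Authorization header to a whitelisted client identity."""
    if not isinstance(whitelist, Mapping):
        whitelist = {c: c for c in whitelist}
    if not authorization_header:
        return Rejection("missing", 401)
    parts = authorization_header.split()
    if len(parts) != 2 or parts[0].lower() != "bearer":
        return Rejection("malformed", 401)
    try:
        claims = verify_token(parts[1], secret, now=now)
    except TokenError as exc:
        return Rejection(exc.reason, 401)
    client_id = claims["sub"]
    if client_id not in whitelist:
        return Rejection("not-whitelisted", 403)
    return ClientIdentity(client_id, whitelist[client_id], True)


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------

def discovery(config: ServiceConfig) -> dict:
    """The CDS Hooks discovery document: exactly one order-sign service."""
    return {
        "services": [
            {
                "id": config.service_id,
                "hook": "order-sign",
                "title": config.title,
                "description": config.description,
                "prefetch": {
                    "allergyIntolerance": (
                        "AllergyIntolerance?patient={{context.patientId}}"
                        "&category=medication"
                    )
                },
            }
        ]
    }


# ---------------------------------------------------------------------------
# Cards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Card:
    summary: str
    indicator: str
    source: Mapping[str, str]
    detail: str | None = None
    suggestions: tuple = ()
    links: tuple = ()

    def __post_init__(self):
        if not self.summary or len(self.summary) > SUMMARY_LIMIT:
            raise ValueError(f"summary must be 1..{SUMMARY_LIMIT} characters")
        if self.indicator not in INDICATORS:
            raise ValueError(f"indicator must be one of {INDICATORS}")

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "summary": self.summary,
            "indicator": self.indicator,
            "source": dict(self.source),
        }
        if self.detail is not None:
            d["detail"] = self.detail
        if self.suggestions:
            d["suggestions"] = [dict(s) for s in self.suggestions]
        if self.links:
            d["links"] = [dict(l) for l in self.links]
        return d


@dataclass(frozen=True)
class CardResponse:
    cards: tuple[Card, ...] = ()

    def to_dict(self) -> dict:
        return {"cards": [c.to_dict() for c in self.cards]}


def _truncate(text: str, limit: int = SUMMARY_LIMIT) -> str:
    if len(text) <= limit:
        return text
    return text[: limit - 1] + "…"


def _matched_label(matched: frozenset) -> str:
    parts = []
    for item in sorted(matched, key=lambda x: (isinstance(x, tuple), x)):
        if isinstance(item, tuple):
            parts.append(" ↔ ".join(item))
        else:
            parts.append(item)
    return ", ".join(parts)


def build_cards(
    findings: Iterable[Finding],
    unresolved: Iterable[str],
    kb: KnowledgeBase,
    config: ServiceConfig,
) -> list[Card]:
    """One aggregate warning card per medication with at least one finding.

    The summary names the drug and the allergens; the detail markdown lists
    every interaction with its cascade step, matched codes, and any codes the
    knowledge base could not resolve. No findings, no cards — unresolved codes
    alone never warrant a physician-facing interruption.
    """
    unresolved = list(unresolved)
    by_med: dict[str, list[Finding]] = {}
    for f in findings:
        by_med.setdefault(f.kd_code, []).append(f)

    source = {"label": config.source_label}
    if config.source_url:
        source["url"] = config.source_url
    links = ()
    if config.card_link_url:
        links = (
            {
                "label": config.card_link_label or "More information",
                "url": config.card_link_url,
                "type": "absolute",
            },
        )

    cards: list[Card] = []
    for kd_code, med_findings in by_med.items():
        drug = kb.drug_index.get(kd_code)
        drug_disp = drug.name if drug is not None else kd_code
        alg_disps = []
        detail_lines = [f"**{drug_disp}** (`{kd_code}`) may interact with:", ""]
        for f in med_findings:
            alg = kb.allergen_index.get(f.allergen_code)
            alg_disp = alg.display if alg is not None else f.allergen_code
            alg_disps.append(alg_disp)
            detail_lines.append(
                f"- {alg_disp} (`{f.allergen_code}`) — step {int(f.step)}: "
                f"{f.step.label}; matched: {_matched_label(f.matched_codes)}"
            )
        if unresolved:
            detail_lines += [
                "",
                "Codes not found in the knowledge base: "
                + ", ".join(f"`{c}`" for c in unresolved),
            ]
        summary = _truncate(
            f"Drug-allergy interaction: {drug_disp} — " + "; ".join(alg_disps)
        )
        cards.append(
            Card(
                summary=summary,
                indicator="warning",
                source=source,
                detail="\n".join(detail_lines),
                links=links,
            )
        )
    return cards


# ---------------------------------------------------------------------------
# Order-sign handler
# ---------------------------------------------------------------------------

def _operation_outcome(messages: Iterable[str], code: str = "invalid") -> dict:
    return {
        "resourceType": "OperationOutcome",
        "issue": [
            {"severity": "error", "code": code, "diagnostics": m} for m in messages
        ],
    }


class _Reject(Exception):
    def __init__(self, status: int, body: dict):
        self.status = status
        self.body = body


class DAIService:
    """The DAI check service bound to a knowledge base and configuration."""

    def __init__(
        self,
        kb: KnowledgeBase,
        config: ServiceConfig | None = None,
        audit_log: AuditLog | None = None,
        clock=time.time,
    ):
        self.kb = kb
        self.config = config or ServiceConfig()
        self.audit_log = (
            audit_log if audit_log is not None else AuditLog(self.config.audit_log_path)
        )
        self.clock = clock

    # -- discovery ---------------------------------------------------------
    def discovery_document(self) -> dict:
        return discovery(self.config)

    # -- order-sign --------------------------------------------------------
    def handle_order_sign(
        self, payload: Any, client: ClientIdentity
    ) -> tuple[int, dict]:
        """Run one order-sign invocation; returns (HTTP status, JSON body).

        Exactly one audit record is written per call, whatever the outcome.
        """
        hook_instance = None
        patient_id = None
        counts = {"n_orders": 0, "n_allergens": 0, "n_findings": 0, "n_cards": 0}
        unresolved: tuple[str, ...] = ()
        step_counts: dict[str, int] = {}
        try:
            if isinstance(payload, dict):
                hi = payload.get("hookInstance")
                hook_instance = hi if isinstance(hi, str) else None
                ctx = payload.get("context")
                if isinstance(ctx, dict) and isinstance(ctx.get("patientId"), str):
                    patient_id = ctx["patientId"]
            status, body, counts, unresolved, step_counts = self._process(payload)
        except _Reject as rej:
            status, body = rej.status, rej.body
        outcome = (
            "rejected" if status != 200 else ("warning" if counts["n_cards"] else "empty")
        )
        audit_mod.record_invocation(
            self.audit_log,
            client_id=client.client_id,
            hook_instance=hook_instance,
            patient_id=patient_id,
            outcome=outcome,
            unresolved_codes=unresolved,
            step_counts=step_counts,
            hash_key=self.config.hash_key,
            **counts,
        )
        return status, body

    def check(self, payload: Any) -> tuple[int, dict]:
        """Offline single-shot check (no auth, no audit): same request shape."""
        try:
            status, body, *_ = self._process(payload)
            return status, body
        except _Reject as rej:
            return rej.status, rej.body

    def _process(self, payload: Any):
        if not isinstance(payload, dict):
            raise _Reject(400, _operation_outcome(["request body must be a JSON object"]))
        if payload.get("hook") != "order-sign":
            raise _Reject(
                400,
                _operation_outcome([f"unsupported hook: {payload.get('hook')!r}"]),
            )
        if not isinstance(payload.get("hookInstance"), str) or not payload["hookInstance"]:
            raise _Reject(400, _operation_outcome(["hookInstance is required"], "required"))
        ctx = payload.get("context")
        if not isinstance(ctx, dict):
            raise _Reject(400, _operation_outcome(["context is required"], "required"))
        missing = [
            k
            for k in ("userId", "patientId", "draftOrders")
            if not ctx.get(k) or (k != "draftOrders" and not isinstance(ctx[k], str))
        ]
        if missing:
            raise _Reject(
                400,
                _operation_outcome(
                    [f"context.{k} is required" for k in missing], "required"
                ),
            )
        patient_id = ctx["patientId"]

        prefetch = payload.get("prefetch")
        if not isinstance(prefetch, dict) or not isinstance(
            prefetch.get("allergyIntolerance"), dict
        ):
            # Serverless-FHIR deployment: the service cannot fetch the data itself.
            raise _Reject(
                412,
                _operation_outcome(
                    ["prefetch.allergyIntolerance is required"], "required"
                ),
            )

        systems = self.config.code_systems
        orders, violations = parse_draft_orders_bundle(ctx["draftOrders"], systems)
        allergies, a_violations = parse_allergy_bundle(
            prefetch["allergyIntolerance"], systems
        )
        violations = violations + a_violations
        errors = [str(v) for v in violations if v.severity == "error"]
        if self.config.reject_code_system_mismatch:
            errors += [
                str(v)
                for v in violations
                if v.severity == "warning" and "code system mismatch" in v.rule
            ]
        if errors:
            raise _Reject(400, _operation_outcome(errors))

        # Cross-patient screening is a safety hazard: every parsed resource
        # must reference the patient in context.
        for ref in [o.patient_ref for o in orders] + [a.patient_ref for a in allergies]:
            if ref not in (patient_id, f"Patient/{patient_id}"):
                raise _Reject(
                    400,
                    _operation_outcome(
                        [
                            f"patient reference {ref!r} does not match "
                            f"context.patientId {patient_id!r}"
                        ]
                    ),
                )

        result = screen_request(self.kb, orders, allergies)
        cards = build_cards(result.findings, result.unresolved, self.kb, self.config)
        step_counts: dict[str, int] = {}
        for f in result.findings:
            key = str(int(f.step))
            step_counts[key] = step_counts.get(key, 0) + 1
        counts = {
            "n_orders": len(orders),
            "n_allergens": len(allergies),
            "n_findings": len(result.findings),
            "n_cards": len(cards),
        }
        body = CardResponse(tuple(cards)).to_dict()
        return 200, body, counts, result.unresolved, step_counts

    # -- tokens ------------------------------------------------------------
    def mint_token(self, client_id: str, now: float | None = None) -> str:
        return mint_token(
            self.config.token_secret,
            client_id,
            self.config.token_lifetime_seconds,
            now=now if now is not None else self.clock(),
        )

    def authenticate(self, authorization_header: str | None) -> ClientIdentity | Rejection:
        return authenticate(
            authorization_header,
            self.config.whitelist,
            self.config.token_secret,
            now=self.clock(),
        )


# ---------------------------------------------------------------------------
# WSGI transport
# ---------------------------------------------------------------------------

_STATUS_LINE = {
    200: "200 OK",
    400: "400 Bad Request",
    401: "401 Unauthorized",
    403: "403 Forbidden",
    412: "412 Precondition Failed",
}


def create_wsgi_app(service: DAIService):
    """Thin WSGI wrapper over the service; every response is JSON and every
    status is one of 200/400/401/403/412 — malformed input never raises."""

    base = "/cds-services"
    dai_path = f"{base}/{service.config.service_id}"

    def respond(start_response, status: int, body: dict):
        data = json.dumps(body, ensure_ascii=False).encode()
        start_response(
            _STATUS_LINE[status],
            [
                ("Content-Type", "application/json; charset=utf-8"),
                ("Content-Length", str(len(data))),
            ],
        )
        return [data]

    def app(environ, start_response):
        try:
            method = environ.get("REQUEST_METHOD", "GET").upper()
            path = environ.get("PATH_INFO", "").rstrip("/") or "/"
            if method == "GET" and path == base:
                return respond(start_response, 200, service.discovery_document())
            if method == "POST" and path == dai_path:
                auth = service.authenticate(environ.get("HTTP_AUTHORIZATION"))
                if isinstance(auth, Rejection):
                    audit_mod.record_invocation(
                        service.audit_log,
                        client_id=None,
                        hook_instance=None,
                        patient_id=None,
                        n_orders=0,
                        n_allergens=0,
                        n_findings=0,
                        n_cards=0,
                        outcome="rejected",
                        hash_key=service.config.hash_key,
                    )
                    code = "forbidden" if auth.status == 403 else "security"
                    return respond(
                        start_response,
                        auth.status,
                        _operation_outcome([f"authentication failed: {auth.reason}"], code),
                    )
                try:
                    length = int(environ.get("CONTENT_LENGTH") or 0)
                except ValueError:
                    length = 0
                raw = environ["wsgi.input"].read(length) if length else b""
                try:
                    payload = json.loads(raw.decode("utf-8"))
                except (ValueError, UnicodeDecodeError):
                    payload = None
                status, body = service.handle_order_sign(payload, auth)
                return respond(start_response, status, body)
            return respond(
                start_response,
                400,
                _operation_outcome([f"unsupported endpoint: {method} {path}"]),
            )
        except Exception:  # pragma: no cover - defensive: transport never 5xxs
            return respond(
                start_response, 400, _operation_outcome(["unprocessable request"])
            )

    return app


def serve(service: DAIService, host: str = "127.0.0.1", port: int = 8080):  # pragma: no cover
    """Run the service with the stdlib WSGI reference server."""
    from wsgiref.simple_server import make_server

    with make_server(host, port, create_wsgi_app(service)) as httpd:
        print(f"daicheck serving on http://{host}:{port}/cds-services")
        httpd.serve_forever()
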