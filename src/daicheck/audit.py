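"""Append-only invocation audit trail and usage summaries.

Every service invocation — including rejected ones — appends one JSON-lines
record. The summary reproduces the service's operational report: distinct
providers and patients, total DAI checks, and the warning / no-response split
with percentages rounded half-up to two decimals. Rejected invocations are
audited but excluded from the check counts.

Patient identifiers are pseudonymized with a keyed hash before they reach the
log, so the trail stores no direct identifiers.
"""

from __future__ import annotations

import hashlib
import hmac
import io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "OUTCOMES",
    "AuditRecord",
    "AuditLog",
    "AuditLogError",
    "UsageSummary",
    "pseudonymize_patient_id",
    "record_invocation",
    "summarize",
    "summary_from_counts",
    "format_summary",
    "summary_to_csv",
]

OUTCOMES = ("warning", "empty", "rejected")


class AuditLogError(Exception):
    pass


@dataclass(frozen=True)
class AuditRecord:
    timestamp: str  # ISO-8601 UTC
    client_id: str | None
    hook_instance: str | None
    patient_id: str | None
    n_orders: int
    n_allergens: int
    n_findings: int
    n_cards: int
    outcome: str
    unresolved_codes: tuple[str, ...] = ()
    step_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        if self.outcome == "warning" and self.n_cards <= 0:
            raise ValueError("warning outcome requires n_cards > 0")
        if self.outcome in ("empty", "rejected") and self.n_cards != 0:
            raise ValueError(f"{self.outcome} outcome requires n_cards == 0")

    def to_dict(self) -> dict:
        d = {
            "timestamp": self.timestamp,
            "client_id": self.client_id,
            "hook_instance": self.hook_instance,
            "patient_id": self.patient_id,
            "n_orders": self.n_orders,
            "n_allergens": self.n_allergens,
            "n_findings": self.n_findings,
            "n_cards": self.n_cards,
            "outcome": self.outcome,
            "unresolved_codes": list(self.unresolved_codes),
        }
        if self.step_counts:
            d["step_counts"] = dict(self.step_counts)
        return d

    def to_json_line(self) -> str:
        return json.dumps(self.to_dict(), separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: Mapping) -> "AuditRecord":
        return cls(
            timestamp=d["timestamp"],
            client_id=d.get("client_id"),
            hook_instance=d.get("hook_instance"),
            patient_id=d.get("patient_id"),
            n_orders=int(d.get("n_orders", 0)),
            n_allergens=int(d.get("n_allergens", 0)),
            n_findings=int(d.get("n_findings", 0)),
            n_cards=int(d.get("n_cards", 0)),
            outcome=d["outcome"],
            unresolved_codes=tuple(d.get("unresolved_codes", ())),
            step_counts=dict(d.get("step_counts", {})),
        )


class AuditLog:
    """Append-only JSON-lines log; ``path=None`` keeps records in memory only.

    The file is opened at construction so an unwritable path fails fast at
    service startup rather than dropping records silently later.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._memory: list[AuditRecord] = []
        self._fh: io.TextIOBase | None = None
        if self.path is not None:
            try:
                self.path.parent.mkdir(parents=True, exist_ok=True)
                self._fh = open(self.path, "a", encoding="utf-8")
            except OSError as exc:
                raise AuditLogError(f"audit log not writable: {self.path}: {exc}") from exc

    def append(self, record: AuditRecord) -> None:
        if self._fh is not None:
            self._fh.write(record.to_json_line() + "\n")
            self._fh.flush()
        else:
            self._memory.append(record)

    def records(self) -> list[AuditRecord]:
        if self.path is not None:
            out = []
            with open(self.path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if not line:
                        continue
                    try:
                        out.append(AuditRecord.from_dict(json.loads(line)))
                    except (ValueError, KeyError, TypeError):
                        continue
            return out
        return list(self._memory)

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None


def pseudonymize_patient_id(patient_id: str, key: str) -> str:
    """Keyed (HMAC-SHA256) pseudonym for a patient id; 64-bit hex prefix."""
    mac = hmac.new(key.encode(), patient_id.encode(), hashlib.sha256)
    return mac.hexdigest()[:16]


def record_invocation(
    log: AuditLog,
    *,
    client_id: str | None,
    hook_instance: str | None,
    patient_id: str | None,
    n_orders: int,
    n_allergens: int,
    n_findings: int,
    n_cards: int,
    outcome: str,
    unresolved_codes: Iterable[str] = (),
    step_counts: Mapping[str, int] | None = None,
    hash_key: str | None = None,
    now: datetime | None = None,
) -> AuditRecord:
    """Build, pseudonymize, append, and return one audit record."""
    ts = (now or datetime.now(timezone.utc)).astimezone(timezone.utc)
    pid = patient_id
    if pid is not None and hash_key is not None:
        pid = pseudonymize_patient_id(pid, hash_key)
    record = AuditRecord(
        timestamp=ts.strftime("%Y-%m-%dT%H:%M:%SZ"),
        client_id=client_id,
        hook_instance=hook_instance,
        patient_id=pid,
        n_orders=n_orders,
        n_allergens=n_allergens,
        n_findings=n_findings,
        n_cards=n_cards,
        outcome=outcome,
        unresolved_codes=tuple(unresolved_codes),
        step_counts=dict(step_counts or {}),
    )
    log.append(record)
    return record


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UsageSummary:
    n_providers: int
    n_patients: int
    n_checks: int
    n_warning: int
    n_empty: int
    pct_warning: float | None
    pct_empty: float | None
    n_rejected: int = 0
    n_corrupt_lines: int = 0
    step_breakdown: Mapping[str, int] = field(default_factory=dict)


def _pct(part: int, total: int) -> float | None:
    if total == 0:
        return None
    value = (Decimal(part) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(value)


def summary_from_counts(
    n_warning: int,
    n_empty: int,
    *,
    n_providers: int = 0,
    n_patients: int = 0,
    n_rejected: int = 0,
    n_corrupt_lines: int = 0,
    step_counts: Mapping[str, int] | None = None,
) -> UsageSummary:
    """O(1) summary from pre-aggregated counts; identical arithmetic to
    :func:`summarize` so the two routes agree exactly."""
    n_checks = n_warning + n_empty
    return UsageSummary(
        n_providers=n_providers,
        n_patients=n_patients,
        n_checks=n_checks,
        n_warning=n_warning,
        n_empty=n_empty,
        pct_warning=_pct(n_warning, n_checks),
        pct_empty=_pct(n_empty, n_checks),
        n_rejected=n_rejected,
        n_corrupt_lines=n_corrupt_lines,
        step_breakdown=dict(step_counts or {}),
    )


def _coerce_ts(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, datetime):
        return value.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    return str(value)


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def summarize(source, date_from=None, date_to=None) -> UsageSummary:
    """Stream a JSON-lines audit log into a usage summary.

    ``source`` is a file path or an iterable of lines. Corrupt lines are
    skipped and counted. The optional date range (ISO strings or datetimes,
    inclusive) filters on the record timestamp; ISO-8601 UTC timestamps
    compare correctly as strings.
    """
    lo = _coerce_ts(date_from)
    hi = _coerce_ts(date_to)
    providers: set[str] = set()
    patients: set[str] = set()
    n_warning = n_empty = n_rejected = n_corrupt = 0
    steps: dict[str, int] = {}
    for line in _iter_lines(source):
        line = line.strip()
        if not line:
            continue
        try:
            d = json.loads(line)
            ts = d["timestamp"]
            outcome = d["outcome"]
            if outcome not in OUTCOMES:
                raise ValueError(outcome)
        except (ValueError, KeyError, TypeError):
            n_corrupt += 1
            continue
        if lo is not None and ts < lo:
            continue
        if hi is not None and ts > hi:
            continue
        if outcome == "rejected":
            n_rejected += 1
            continue
        if outcome == "warning":
            n_warning += 1
        else:
            n_empty += 1
        cid = d.get("client_id")
        if cid:
            providers.add(cid)
        pid = d.get("patient_id")
        if pid:
            patients.add(pid)
        for step, count in (d.get("step_counts") or {}).items():
            steps[step] = steps.get(step, 0) + int(count)
    return summary_from_counts(
        n_warning,
        n_empty,
        n_providers=len(providers),
        n_patients=len(patients),
        n_rejected=n_rejected,
        n_corrupt_lines=n_corrupt,
        step_counts=steps,
    )


def format_summary(s: UsageSummary) -> str:
    """Aligned plain-text rendering in the style of an operations report."""

    def fmt_pct(p: float | None) -> str:
        return "n/a" if p is None else f"{p:.2f}"

    rows = [
        ("Health care providers", f"{s.n_providers:,}"),
        ("Patients", f"{s.n_patients:,}"),
        ("Drug-allergy interaction checks", f"{s.n_checks:,}"),
        ("Warning cards", f"{s.n_warning:,} ({fmt_pct(s.pct_warning)})"),
        ("No responses", f"{s.n_empty:,} ({fmt_pct(s.pct_empty)})"),
    ]
    if s.n_rejected:
        rows.append(("Rejected requests (excluded)", f"{s.n_rejected:,}"))
    if s.step_breakdown:
        for step in sorted(s.step_breakdown):
            rows.append((f"Findings at step {step}", f"{s.step_breakdown[step]:,}"))
    width = max(len(label) for label, _ in rows)
    lines = [f"{label:<{width}}  {value}" for label, value in rows]
    if s.n_corrupt_lines:
        lines.append(f"(skipped {s.n_corrupt_lines:,} corrupt log line(s))")
    return "\n".join(lines)


def summary_to_csv(s: UsageSummary) -> str:
    header = "metric,value"
    rows = [
        ("n_providers", s.n_providers),
        ("n_patients", s.n_patients),
        ("n_checks", s.n_checks),
        ("n_warning", s.n_warning),
        ("n_empty", s.n_empty),
        ("pct_warning", "" if s.pct_warning is None else s.pct_warning),
        ("pct_empty", "" if s.pct_empty is None else s.pct_empty),
        ("n_rejected", s.n_rejected),
        ("n_corrupt_lines", s.n_corrupt_lines),
    ]
    return "\n".join([header] + [f"{k},{v}" for k, v in rows])
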