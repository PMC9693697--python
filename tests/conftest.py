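import io
import json

import pytest

from daicheck.audit import AuditLog
from daicheck.cds_service import DAIService, ServiceConfig
from daicheck.synthetic_data import toy_kb as _toy_kb


@pytest.fixture(scope="session")
def toy_kb():
    return _toy_kb()


@pytest.fixture
def config():
    return ServiceConfig(
        whitelist={"hospital-A": "Hospital A", "clinic-B": "Clinic B"},
        token_secret="test-secret",
        source_url="https://cds.example.org/about",
    )


@pytest.fixture
def service(toy_kb, config):
    return DAIService(toy_kb, config, audit_log=AuditLog(None))


@pytest.fixture
def client(service):
    identity = service.authenticate("Bearer " + service.mint_token("hospital-A"))
    assert not isinstance(identity, tuple)
    return identity


def wsgi_call(app, method, path, body=None, headers=None):
    """Drive a WSGI app directly; returns (status code, parsed JSON body)."""
    captured = {}

    def start_response(status, _headers):
        captured["status"] = int(status.split()[0])

    if body is None:
        data = b""
    elif isinstance(body, bytes):
        data = body
    else:
        data = json.dumps(body).encode()
    environ = {
        "REQUEST_METHOD": method,
        "PATH_INFO": path,
        "CONTENT_LENGTH": str(len(data)),
        "wsgi.input": io.BytesIO(data),
    }
    for key, value in (headers or {}).items():
        environ["HTTP_" + key.upper().replace("-", "_")] = value
    chunks = app(environ, start_response)
    raw = b"".join(chunks)
    return captured["status"], json.loads(raw) if raw else {}


def order_sign_payload(
    med_codes,
    allergen_codes,
    patient_id="patient-00001",
    *,
    kb=None,
    hook="order-sign",
    prefetch_present=True,
):
    """Minimal conformant order-sign payload over the toy vocabulary."""
    from daicheck.fhir_model import DEFAULT_ALLERGEN_CODE_SYSTEM, DEFAULT_KD_CODE_SYSTEM

    def med(code):
        return {
            "resource": {
                "resourceType": "MedicationRequest",
                "status": "draft",
                "intent": "order",
                "medicationCodeableConcept": {
                    "coding": [{"system": DEFAULT_KD_CODE_SYSTEM, "code": code}]
                },
                "subject": {"reference": f"Patient/{patient_id}"},
            }
        }

    def allergy(code):
        return {
            "resource": {
                "resourceType": "AllergyIntolerance",
                "category": ["medication"],
                "code": {"coding": [{"system": DEFAULT_ALLERGEN_CODE_SYSTEM, "code": code}]},
                "patient": {"reference": f"Patient/{patient_id}"},
            }
        }

    payload = {
        "hook": hook,
        "hookInstance": "6f9e20bc-7b4b-4bd2-9c3e-0f81d0d0aaaa",
        "context": {
            "userId": "Practitioner/prac-0001",
            "patientId": patient_id,
            "draftOrders": {
                "resourceType": "Bundle",
                "type": "collection",
                "entry": [med(c) for c in med_codes],
            },
        },
    }
    if prefetch_present:
        payload["prefetch"] = {
            "allergyIntolerance": {
                "resourceType": "Bundle",
                "type": "collection",
                "entry": [allergy(c) for c in allergen_codes],
            }
        }
    return payload
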