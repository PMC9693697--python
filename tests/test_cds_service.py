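"""CDS Hooks endpoints: discovery, auth, order-sign handling, cards, transport."""

import dataclasses
import json

import pytest

from daicheck.audit import AuditLog
from daicheck.cds_service import (
    DAIService,
    Rejection,
    ServiceConfig,
    authenticate,
    build_cards,
    create_wsgi_app,
    discovery,
    mint_token,
)
from daicheck.knowledge_base import Drug, Ingredient, KnowledgeBase
from daicheck.rule_engine import Finding, MatchStep

from conftest import order_sign_payload, wsgi_call

ALLOWED_STATUSES = {200, 400, 401, 403, 412}


class TestDiscovery:
    def test_single_order_sign_service(self, config):
        doc = discovery(config)
        assert len(doc["services"]) == 1
        svc = doc["services"][0]
        assert svc["hook"] == "order-sign"
        assert set(svc["prefetch"]) == {"allergyIntolerance"}
        assert "{{context.patientId}}" in svc["prefetch"]["allergyIntolerance"]

    def test_stable_across_calls(self, config):
        a = json.dumps(discovery(config), sort_keys=True)
        b = json.dumps(discovery(config), sort_keys=True)
        assert a == b


class TestAuthentication:
    def test_minted_token_round_trip(self, config):
        token = mint_token(config.token_secret, "hospital-A")
        identity = authenticate(f"Bearer {token}", config.whitelist, config.token_secret)
        assert identity.client_id == "hospital-A"

    @pytest.mark.parametrize(
        "header,reason,status",
        [
            (None, "missing", 401),
            ("", "missing", 401),
            ("Basic dXNlcg==", "malformed", 401),
            ("Bearer not.a.token", "malformed", 401),
        ],
    )
    def test_rejections(self, config, header, reason, status):
        rej = authenticate(header, config.whitelist, config.token_secret)
        assert rej == Rejection(reason, status)

    def test_bad_signature(self, config):
        token = mint_token("other-secret", "hospital-A")
        rej = authenticate(f"Bearer {token}", config.whitelist, config.token_secret)
        assert rej.reason == "bad-signature"

    def test_expired_token(self, config):
        token = mint_token(config.token_secret, "hospital-A", lifetime_seconds=10, now=1000.0)
        rej = authenticate(
            f"Bearer {token}", config.whitelist, config.token_secret, now=2000.0
        )
        assert rej == Rejection("expired", 401)

    def test_valid_token_not_whitelisted(self, config):
        token = mint_token(config.token_secret, "rogue-clinic")
        rej = authenticate(f"Bearer {token}", config.whitelist, config.token_secret)
        assert rej == Rejection("not-whitelisted", 403)


class TestOrderSign:
    def test_interacting_order_yields_warning_card(self, service, client):
        status, body = service.handle_order_sign(
            order_sign_payload(["KD10001"], ["ALG001"]), client
        )
        assert status == 200
        assert len(body["cards"]) == 1
        card = body["cards"][0]
        assert card["indicator"] == "warning"
        assert len(card["summary"]) <= 140
        assert "same product or ingredient" in card["detail"]

    def test_unrelated_order_yields_empty_cards(self, service, client):
        status, body = service.handle_order_sign(
            order_sign_payload(["KD20001"], ["ALG001"]), client
        )
        assert (status, body) == (200, {"cards": []})

    def test_wrong_hook_rejected(self, service, client):
        status, body = service.handle_order_sign(
            order_sign_payload(["KD10001"], ["ALG001"], hook="patient-view"), client
        )
        assert status == 400
        assert body["resourceType"] == "OperationOutcome"

    def test_no_allergy_records_is_empty_cards(self, service, client):
        status, body = service.handle_order_sign(
            order_sign_payload(["KD10001"], []), client
        )
        assert (status, body) == (200, {"cards": []})

    def test_missing_prefetch_is_412(self, service, client):
        status, _ = service.handle_order_sign(
            order_sign_payload(["KD10001"], ["ALG001"], prefetch_present=False), client
        )
        assert status == 412

    @pytest.mark.parametrize("field", ["userId", "patientId", "draftOrders"])
    def test_missing_required_context_field_is_400(self, service, client, field):
        payload = order_sign_payload(["KD10001"], ["ALG001"])
        del payload["context"][field]
        status, _ = service.handle_order_sign(payload, client)
        assert status == 400

    def test_cross_patient_resource_rejected(self, service, client):
        payload = order_sign_payload(["KD10001"], ["ALG001"])
        payload["context"]["patientId"] = "someone-else"
        status, body = service.handle_order_sign(payload, client)
        assert status == 400
        assert "does not match" in body["issue"][0]["diagnostics"]

    def test_unresolved_codes_surface_in_detail(self, service, client):
        payload = order_sign_payload(["KD10001", "KD-MYSTERY"], ["ALG001"])
        status, body = service.handle_order_sign(payload, client)
        assert status == 200
        assert "KD-MYSTERY" in body["cards"][0]["detail"]

    def test_replay_is_idempotent_with_one_audit_record_each(self, service, client):
        payload = order_sign_payload(["KD10001"], ["ALG001"])
        first = service.handle_order_sign(payload, client)
        second = service.handle_order_sign(payload, client)
        assert first == second
        records = service.audit_log.records()
        assert len(records) == 2
        assert {r.outcome for r in records} == {"warning"}

    def test_rejected_requests_are_audited(self, service, client):
        service.handle_order_sign({"hook": "nope"}, client)
        records = service.audit_log.records()
        assert [r.outcome for r in records] == ["rejected"]
        assert records[0].n_cards == 0

    def test_cards_bounded_by_distinct_orders(self, service, client):
        status, body = service.handle_order_sign(
            order_sign_payload(
                ["KD10001", "KD10002", "KD10003", "KD20001"],
                ["ALG001", "ALG003", "ALG004"],
            ),
            client,
        )
        assert status == 200
        assert len(body["cards"]) <= 4


class TestCards:
    def test_one_card_per_medication_groups_allergens(self, toy_kb, config):
        findings = [
            Finding("KD10001", "ALG001", MatchStep.SAME_PRODUCT_OR_INGREDIENT,
                    frozenset({"ING001"})),
            Finding("KD10001", "ALG004", MatchStep.CROSS_REACTIVE,
                    frozenset({("ING001", "ING003")})),
        ]
        cards = build_cards(findings, [], toy_kb, config)
        assert len(cards) == 1
        assert cards[0].detail.count("- Allergy to") == 2

    def test_no_findings_no_cards(self, toy_kb, config):
        assert build_cards([], [], toy_kb, config) == []
        assert build_cards([], ["KD-UNKNOWN"], toy_kb, config) == []

    def test_long_summary_truncated_to_140_with_ellipsis(self, config):
        kb = KnowledgeBase(
            ingredients=(Ingredient("I1", "Verylongium"),),
            drugs=(Drug("KD1", "Verylongium " + "Extra " * 40 + "Tab", frozenset({"I1"})),),
        )
        findings = [
            Finding("KD1", "ALG-X", MatchStep.SAME_PRODUCT_OR_INGREDIENT, frozenset({"I1"}))
        ]
        (card,) = build_cards(findings, [], kb, config)
        assert len(card.summary) == 140
        assert card.summary.endswith("…")

    def test_configured_link_attached(self, toy_kb, config):
        cfg = dataclasses.replace(
            config, card_link_url="https://apps.example.org/dai", card_link_label="Open app"
        )
        findings = [
            Finding("KD10001", "ALG001", MatchStep.SAME_PRODUCT_OR_INGREDIENT,
                    frozenset({"ING001"}))
        ]
        (card,) = build_cards(findings, [], toy_kb, cfg)
        assert card.to_dict()["links"] == [
            {"label": "Open app", "url": "https://apps.example.org/dai", "type": "absolute"}
        ]


class TestTransport:
    @pytest.fixture
    def app(self, service):
        return create_wsgi_app(service)

    @pytest.fixture
    def auth_header(self, service):
        return {"Authorization": "Bearer " + service.mint_token("hospital-A")}

    def test_discovery_endpoint(self, app):
        status, body = wsgi_call(app, "GET", "/cds-services")
        assert status == 200
        assert body["services"][0]["id"] == "drug-allergy-interaction-check"

    def test_order_sign_endpoint_end_to_end(self, app, auth_header):
        status, body = wsgi_call(
            app,
            "POST",
            "/cds-services/drug-allergy-interaction-check",
            order_sign_payload(["KD10001"], ["ALG001"]),
            auth_header,
        )
        assert status == 200
        assert body["cards"][0]["indicator"] == "warning"
        assert set(body["cards"][0]) >= {"summary", "indicator", "source"}

    def test_missing_token_is_401_and_audited(self, service, app):
        status, _ = wsgi_call(
            app, "POST", "/cds-services/drug-allergy-interaction-check", {"hook": "order-sign"}
        )
        assert status == 401
        assert [r.outcome for r in service.audit_log.records()] == ["rejected"]

    def test_non_whitelisted_client_is_403(self, service, app):
        headers = {"Authorization": "Bearer " + service.mint_token("rogue")}
        status, _ = wsgi_call(
            app, "POST", "/cds-services/drug-allergy-interaction-check", {}, headers
        )
        assert status == 403

    @pytest.mark.parametrize(
        "method,path,body",
        [
            ("GET", "/unknown", None),
            ("POST", "/cds-services", None),
            ("PUT", "/cds-services/drug-allergy-interaction-check", None),
            ("POST", "/cds-services/drug-allergy-interaction-check", b"{truncated"),
            ("POST", "/cds-services/drug-allergy-interaction-check", b"[]"),
            ("POST", "/cds-services/drug-allergy-interaction-check", b'"hello"'),
            ("POST", "/cds-services/drug-allergy-interaction-check",
             b'{"hook": "order-sign"}'),
            ("POST", "/cds-services/drug-allergy-interaction-check",
             b'{"hook": "order-sign", "hookInstance": "x", "context": 5}'),
            ("POST", "/cds-services/drug-allergy-interaction-check", b"\xff\xfe garbage"),
        ],
    )
    def test_malformed_requests_never_5xx(self, app, auth_header, method, path, body):
        status, _ = wsgi_call(app, method, path, body, auth_header)
        assert status in ALLOWED_STATUSES
        assert status != 200

    def test_fuzzed_payload_shapes_never_crash(self, app, auth_header):
        import random

        rng = random.Random(0)
        atoms = [None, 0, 1.5, "", "x", [], {}, True]

        def rand_value(depth=0):
            if depth > 2 or rng.random() < 0.4:
                return rng.choice(atoms)
            if rng.random() < 0.5:
                return [rand_value(depth + 1) for _ in range(rng.randint(0, 3))]
            keys = ["hook", "hookInstance", "context", "prefetch", "userId",
                    "patientId", "draftOrders", "entry", "resource", "zz"]
            return {rng.choice(keys): rand_value(depth + 1) for _ in range(rng.randint(0, 4))}

        for _ in range(60):
            body = json.dumps(rand_value()).encode()
            status, _ = wsgi_call(
                app, "POST", "/cds-services/drug-allergy-interaction-check", body, auth_header
            )
            assert status in ALLOWED_STATUSES


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(
            "service_id: dai\n"
            "token_secret: s3cret\n"
            "whitelist:\n  hospital-A: Hospital A\n"
            "reject_code_system_mismatch: true\n",
            encoding="utf-8",
        )
        cfg = ServiceConfig.from_file(path)
        assert cfg.service_id == "dai"
        assert cfg.whitelist == {"hospital-A": "Hospital A"}
        assert cfg.reject_code_system_mismatch is True

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "config.json"
        path.write_text('{"no_such_option": 1}', encoding="utf-8")
        with pytest.raises(ValueError, match="no_such_option"):
            ServiceConfig.from_file(path)

    def test_strict_mode_rejects_foreign_code_system(self, toy_kb):
        cfg = ServiceConfig(
            whitelist={"hospital-A": "A"}, reject_code_system_mismatch=True
        )
        svc = DAIService(toy_kb, cfg, audit_log=AuditLog(None))
        payload = order_sign_payload(["KD10001"], ["ALG001"])
        coding = payload["context"]["draftOrders"]["entry"][0]["resource"][
            "medicationCodeableConcept"
        ]["coding"][0]
        coding["system"] = "urn:unexpected"
        status, _ = svc.check(payload)
        assert status == 400
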