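# daicheck

A shared, interoperable clinical-decision-support (CDS) service for
**drug-allergy interaction (DAI) checks**, built on the [CDS Hooks
1.0](https://cds-hooks.hl7.org/1.0/) specification and HL7 FHIR R4.

The service is aimed at health-care providers — tertiary hospitals down to
small clinics on heterogeneous EHR systems — that need medication-allergy
screening but lack the budget or expertise to build it in-house. When a
physician is ready to sign medication orders, the EHR fires the `order-sign`
hook: it POSTs the draft `MedicationRequest` resources (coded with the Korea
Drug, KD, product code) together with the patient's `AllergyIntolerance`
records (supplied in the `prefetch` field, so the service never needs to call
back to a FHIR server) and receives **cards** — short warnings with a
`summary`, an `indicator`, and markdown `detail` — or an empty card array
when there is nothing to say.

## The screening model

Each (prescribed medication *m*, recorded allergen *a*) pair is screened by a
three-step cascade over a drug-allergy knowledge base; the first matching
step wins, so attribution is mutually exclusive:

1. **Same product or ingredient** — *a* is the prescribed product itself, or
   ingredients(*a*) ∩ ingredients(*m*) ≠ ∅;
2. **Same drug or ingredient class** — a class containing *a* (or one of its
   ingredients) also contains an ingredient of *m*;
3. **Cross-reactive allergen** — some (*i*ₐ, *i*ₘ) with *i*ₐ ∈
   ingredients(*a*), *i*ₘ ∈ ingredients(*m*) is a known cross-reactive pair
   (e.g. a penicillin–cephalosporin link).

Allergens come in three kinds — a brand **product**, a **substance**
(ingredient), or a drug/ingredient **class** — and are expanded to
ingredient sets before screening. The knowledge base is a set of master and
relation tables (drugs keyed by KD code, ingredients with synonyms, drug and
ingredient classes, canonical cross-reactive pairs, and the allergen value
set) with full referential-integrity validation. Because the national drug
catalogue and the vendor's allergen value set are proprietary, the package
ships a synthetic-data generator that emulates their structure with known
ground truth.

Beyond the rule engine the package provides the whole service stack:
profile-constrained FHIR parsing, the discovery and order-sign HTTP
endpoints, HMAC bearer-token authentication against a provider whitelist, a
card generator, and an append-only audit trail with a usage-summary report
(providers, patients, checks, warning/no-response split).

## Worked example

Generate a scenario (knowledge-base CSVs plus conformant order-sign payloads
with certified ground truth), validate it, and run an offline check:

```sh
$ cat spec.yaml
seed: 5
n_patients: 4
planted_interactions: [[1, 1], [3, 1]]

$ daicheck simulate --spec spec.yaml --out scenario
$ daicheck kb validate --kb-dir scenario/kb
OK: 12 ingredients, 15 drugs, 2 drug classes, 2 ingredient classes, 3 cross-reactive pairs, 8 allergens

$ daicheck check --kb-dir scenario/kb --request scenario/requests/request-00001.json
{
  "cards": [
    {
      "summary": "Drug-allergy interaction: Mipromilo 200mg Tab — Allergy to Mipromilo",
      "indicator": "warning",
      "source": {
        "label": "Drug-Allergy Interaction CDS Service"
      },
      "detail": "**Mipromilo 200mg Tab** (`KD10005`) may interact with:\n\n- Allergy to Mipromilo (`ALG008`) — step 1: same product or ingredient; matched: ING006"
    }
  ]
}
```

The card says: the draft order `KD10005` resolves to ingredient `ING006`,
which is exactly what the patient's recorded allergen `ALG008` denotes, so
the cascade fired at step 1 and a single warning card was returned. All
names are pronounceable synthetic strings, not real drugs.

The audit trail is summarized with `daicheck report`:

```text
Health care providers            3
Patients                         120
Drug-allergy interaction checks  400
Warning cards                    12 (3.00)
No responses                     388 (97.00)
```

i.e. of 400 non-rejected invocations by 3 providers covering 120 distinct
patients, 3.00% returned a warning card and 97.00% returned an empty card
array ("no response").

Other entry points: `daicheck serve` (run the HTTP service),
`daicheck kb search-allergen` (the allergen/reaction/severity code inquiry),
`daicheck mint-token` (issue a client bearer token), `daicheck report --log`
(usage summary, optional CSV).

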