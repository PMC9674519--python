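# pgxledger

A desk-scale simulator of a permissioned blockchain for consent-governed
sharing of pharmacogenetic (PGx) data.

## The problem

Pharmacogenetic results stay clinically relevant for a patient's whole
life: roughly 10% of people are poor CYP2D6 metabolisers (codeine gives
them little analgesia) and about 2% are ultra-rapid metabolisers (at risk
of morphine toxicity), and similar gene–drug guidelines exist for
abacavir, the fluoropyrimidines and aminoglycosides. Acting on this
pre-emptively requires genomic data to move between laboratories,
pharmacists and physicians — which raises exactly the privacy, consent and
auditability concerns that have sunk centralised health-data programmes.

`pgxledger` implements, as a single deterministic in-process simulator, a
smart-contract architecture that addresses those concerns:

- **Pseudo-anonymous registration (RSC)** — invitation-based onboarding of
  patients, data creators and data requesters; accounts are hash-derived
  addresses, and one person may hold many unlinkable addresses.
- **Hybrid on-/off-chain storage (DSC)** — full PGx records stay in the
  creator's off-chain store; only a whitelisted, non-identifying metadata
  document (drug/gene/phenotype/recommendation codes, a SHA-256 content
  digest and an opaque pointer) goes on-chain.
- **Patient consent as a decision tree (ACMSC)** — a patient's policy is an
  allow-set of (drug, role, purpose) triples compiled to a decision tree;
  its Boolean form is `OR` over allowed triples of
  `AND(drug=d, role=r, purpose=p)`, with default deny and immediate
  revocation.
- **Ticket → token → eURL release pipeline** — each release needs an
  access ticket, then a one-time access token, then an encrypted pointer
  (eURL) sealed to the requester's public key by a trusted oracle, which
  re-checks the record digest against the on-chain hash before minting a
  capability URL that dereferences exactly once.
- **An immutable audit ledger** — every call is a signed transaction in a
  hash-chained block; mutations of any sealed field are detected and
  localised, and the whole chain replays to the live contract state.
- **Right to erasure** — deleting a patient's off-chain records leaves the
  chain intact but makes every future release fail closed
  (`POINTER_DANGLING`).

There is no network, mining or gas: consensus collapses to one honest
sealer and time is an integer tick clock, so every run is reproducible
from its seed.

## Worked example

```python
from pgxledger import Network
from pgxledger.synth import make_pgx_record, sample_patients

net = Network(seed=11)
patient = net.onboard_patient()
pharmacist = net.onboard_requester("pharmacist")
lab = net.onboard_creator()

profile = sample_patients(1, net.rng)[0]          # CYP2D6 class: poor
record, recs = make_pgx_record(profile, patient.address, "rec-1", net.rng)
net.publish_record(lab, record, recs)             # codeine -> AVOID

net.grant(patient, [("codeine", "pharmacist", "treatment")])
flow = net.request_flow(pharmacist, patient.address, "codeine", "treatment")
print(flow.ok, flow.document == record)           # True True
```

Running `python examples/end_to_end_release.py` prints the full
thirteen-step transcript:

```
patient CYP2D6 class: poor
codeine recommendation: AVOID
[step  1] ok  requester keypair registered on RSC
...
[step 13] ok  eURL decrypted; payload fetched once
delivered document equals stored record: True
```

The patient is a poor metaboliser, so the published recommendation is the
guideline's AVOID code; the pharmacist's request satisfies the consent
tree, each credential is consumed exactly once, and the delivered JSON
document is byte-identical to the record the laboratory stored. Asking
again with the same token (or a revoked triple, or a corrupted off-chain
record) fails with a machine-readable reason code.

Other narrative examples live in `examples/`: consent policies and
revocation, audit trail and erasure, cohort fixtures, and benchmark
workloads. A thin CLI wraps the same library:

```bash
pgxledger demo --seed 1 --out out/      # 13-step workflow + full artifact export
pgxledger verify-chain out/chain.jsonl --replay
pgxledger bench --seed 1 --out out/     # Write/Read workloads
pgxledger ramp --seed 1 --out out/      # latency-knee scalability probe
```

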