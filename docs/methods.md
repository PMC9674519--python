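# Methods

This note records the model the simulator implements, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open.

## System model and assumptions

The simulator models a permissioned ledger governing PGx data exchange
between four actor classes — a system owner (the authority that invites
and verifies users), data creators (laboratories holding full records
off-chain), patients (who own consent), and data requesters (pharmacists,
physicians, researchers) — plus a trusted oracle bridging chain and
off-chain store.

Assumptions, deliberately strong so that the properties under test are
the governance ones:

- **One honest sealer.** Proof-of-authority consensus is collapsed to a
  single validator that seals the pending pool FIFO. No forks, gossip or
  Byzantine behaviour: the claims exercised here are integrity,
  auditability and consent semantics, not fault tolerance.
- **Simulated time.** The clock is an integer tick counter advanced
  explicitly (by default one tick per sealed block). All expiry logic and
  every exported artifact are deterministic functions of (config, seed);
  nothing reads the wall clock.
- **Trusted oracle.** The oracle is a single genesis-provisioned identity.
  It re-checks record integrity at fulfilment time but does not re-check
  consent beyond token validity — the policy decision was made at ticket
  issuance, matching the release pipeline's sequence. Revocation between
  ticket issuance and delivery therefore does not retract an
  already-issued credential; it denies the *next* ticket. This boundary is
  part of the model, and the lifecycle tests pin it down.
- **Identity proofing is a stub.** Registration consults a configurable
  pass/fail hook where a production system would call external identity
  services.

## The ledger

A transaction is a signed contract call `(sender, contract, function,
args, nonce, optional public key)`; its id is the SHA-256 digest of the
canonical JSON of the full body *including the signature*. Blocks hash
their header, ordered transaction ids and full receipts, and link by
`prev_hash`. Consequences:

- any single-field mutation of a sealed block changes either a recomputed
  transaction id or the recomputed block hash, so `verify_chain` localises
  tampering to exactly the first affected block;
- `verify_chain` is hash-only and cheap; signature validity is enforced at
  submission and again during `replay`, which re-executes the chain from
  genesis and must reproduce both every block hash and the final contract
  state under canonical serialization.

Reverted calls consume their nonce, roll contract state back wholesale
(the executor snapshots state before each state-changing call) and record
a reason code from a closed enumeration (`PERMISSION_DENIED`,
`TICKET_EXPIRED`, `TOKEN_USED`, …). Events are emitted only by succeeded
calls — exactly one per state-changing call — so the event stream count
equals the succeeded state-changing receipt count; denied attempts are
audited through their reverted receipts, which the chain retains
permanently.

Canonical JSON (sorted keys, minimal separators, UTF-8, floats rejected)
underlies every digest and every equality check; this is what makes
"replay equality" and "state digest" well-defined.

## Cryptography

Each actor's keypair combines an Ed25519 signing key and an X25519
encryption key derived from one 32-byte seed; the address is
`0x` + first 20 bytes of SHA-256 of the 64-byte public key. Pointer
encryption is a sealed box: ephemeral X25519 agreement, SHA-256-based key
derivation, HMAC-SHA256 counter-mode keystream, encrypt-then-MAC tag.
Decryption with any key but the recipient's fails the tag check and
raises a typed error — the error contract the release pipeline depends
on. The curve code follows RFC 8032 / RFC 7748 and is pinned to their
test vectors; no constant-time or side-channel claims are made, and no
length padding is applied (ciphertext length reveals plaintext length
exactly — the plaintexts here are fixed-format capability URLs).

## Consent policies

A policy is a set of (drug, role, purpose) triples over closed
vocabularies (6 drugs × 3 roles × 3 purposes in the shipped tables),
compiled to a three-level decision tree stored canonically in contract
state. Evaluation is a tree walk; the requester's professional role is
read from the registry, never from the request. Matching is exact — no
wildcards, purpose hierarchies or delegation. Grants and revocations
recompile the tree in the transaction that records them, so a change is
effective for the next sealed block. The test suite checks tree
evaluation against brute-force set membership over the full cube, because
the tree and the set are maintained by different code paths.

## The release pipeline

Ticket and token are both single-use and time-bounded: a credential
issued at tick `t` with TTL `T` is valid strictly before `t + T`.
Defaults: ticket TTL 100 ticks, token TTL 20 ticks — the model requires
"a bounded window", not particular durations, and both are configuration.
A ticket mints at most one token (the strictest reading of
access-minimisation); the one-time payload URL is an unguessable 128-bit
capability that dereferences once and also dies at the token's expiry
tick. The oracle refuses to mint anything when the stored record's digest
no longer matches the on-chain hash (`INTEGRITY_MISMATCH`) or when the
pointer dangles after erasure (`POINTER_DANGLING`).

## Synthetic data

Cohorts sample per-gene phenotype classes independently per patient:
CYP2D6 poor/ultra-rapid/residual at 0.10/0.02/0.88 (the population
figures that motivate the system; normal and intermediate metabolisers
are collapsed into the residual class), HLA-B*57:01 carriage 6%, DPYD
intermediate 5% / poor 0.5%, MT-RNR1 variant 0.2% (rounded literature
frequencies; not calibration targets). Records carry guideline
recommendation codes (`STANDARD`, `REDUCE_DOSE`, `AVOID`) looked up from
the shipped drug–gene table, plus an opaque random blob standing in for
raw genomic data. There is no genotype-to-phenotype translation
(star-allele calling), no linkage between genes, no missingness and no
laboratory error model — so passing tests demonstrate the governance
machinery, not clinical realism of the fixtures.

`build_scenario(n_patients, n_requesters, policy_density, seed)` registers
everyone, publishes one record per patient, grants each triple of the
cube independently with probability `policy_density`, and scripts access
attempts whose expected outcome the generator retains; the suite's
central scenario property is that executed outcomes equal this ground
truth exactly.

## Benchmarking

Workloads inject `tx_total` operations at `send_rate` per tick; the
sealer spends a per-tick budget of `seal_capacity` cost units, with Write
operations costing `write_cost` (default 2) versus 1 for Reads — a
deliberately simple way to produce the write/read asymmetry a real chain
shows. Latency is ticks from submission to sealing; throughput is
succeeded transactions per elapsed tick; every aggregate is recomputable
from the exported raw receipt log, and the suite enforces that equality.
The ramp probe raises the send rate linearly and reports the first rate
whose average latency exceeds a threshold (default 2 ticks). Because the
clock is simulated, these numbers characterise the queueing model only;
wall-clock figures from deployed networks are out of scope by design.

Default problem sizes (scenarios of 2–5 patients and 2–3 requesters,
workloads of 40–120 transactions, 50-block tamper sweeps, 1,000-sequence
lifecycle sweeps, 10,000-patient cohorts) were chosen to exercise each
property at full coverage while keeping any single suite run in the
minutes range.

## Numerical and degenerate-input choices

- Floats are banned from canonical documents; all on-chain quantities are
  integers or strings, so serialization equality is exact.
- Empty blocks, empty policies (deny-all), empty payload hashes and
  genesis-only chains are all legal and tested.
- Cancelling a never-granted triple is an idempotent no-op; re-verifying
  a user likewise.
- Ticket/token expiry is checked with strict inequality (`now <
  expires_at`); boundary behaviour at `expiry − 1`, `expiry`, `expiry + 1`
  is pinned by tests.
- One active metadata record per (patient, creator) pair by default;
  benchmark scenarios enable the multi-record configuration because their
  Write mix publishes repeatedly.

## Known limitations

Single sealer and single oracle (no fault tolerance of either); no
wildcard or hierarchical consent; no guardian/proxy consent or
break-glass override; the capability URL is an in-process object, not an
HTTP endpoint; the off-chain store is in-memory with a directory export,
not a database; unlinkability of multiple addresses per person holds only
as far as the simulator never records the linkage — no traffic-analysis
model is included.
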