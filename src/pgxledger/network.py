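"""High-level orchestration of one simulated network.

:class:`Network` wires a ledger node, the three contracts, an off-chain
store and the oracle into a single object, and offers the operations a
study scenario needs: invite/register/verify users, publish records, grant
and revoke permissions, and run the full thirteen-step release workflow
(keypair → permission → publication → ticket → token → data request →
oracle fulfilment → eURL pickup → decryption → one-time payload fetch).

All randomness flows from one seed; two networks built with the same seed
and the same scripted calls export byte-identical chains.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .crypto import KeyPair, decrypt_with, generate_keypair, EncryptedPointer
from .errors import Revert, PgxLedgerError
from .ledger import (
    Node,
    Receipt,
    build_transaction,
    make_genesis,
)
from .oracle import Fulfilment, OffchainStore, OracleServer


class RevertedCall(PgxLedgerError):
    """A convenience wrapper raised by :meth:`Network.must_call` when a
    transaction reverts."""

    def __init__(self, receipt: Receipt):
        self.receipt = receipt
        self.reason = receipt.reason
        super().__init__(f"reverted: {receipt.reason}")


@dataclass
class Wallet:
    """A keypair plus its derived pseudo-anonymous address."""

    keypair: KeyPair
    label: str = ""

    @property
    def address(self) -> str:
        return self.keypair.address


@dataclass
class FlowStep:
    step: int
    description: str
    ok: bool
    detail: str = ""


@dataclass
class FlowResult:
    """Outcome of one end-to-end access flow."""

    steps: list[FlowStep] = field(default_factory=list)
    ticket_id: str | None = None
    token_id: str | None = None
    url: str | None = None
    document: dict | None = None
    failed_at: int | None = None
    failure_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.failed_at is None

    def log(self, step: int, description: str, detail: str = "") -> None:
        self.steps.append(FlowStep(step, description, True, detail))

    def fail(self, step: int, description: str, reason: str) -> None:
        self.steps.append(FlowStep(step, description, False, reason))
        self.failed_at = step
        self.failure_reason = reason


class Network:
    """One owner, one oracle, one sealer, and everything they govern."""

    def __init__(self, seed: int | bytes = 0, *, config: dict | None = None):
        self._seed_root = (seed if isinstance(seed, bytes)
                           else str(int(seed)).encode())
        self.rng = np.random.default_rng(
            int.from_bytes(self._derive(b"rng"), "big") % 2**63)
        self.owner = Wallet(generate_keypair(self._derive(b"owner")), "owner")
        oracle_keys = generate_keypair(self._derive(b"oracle"))
        self.node = Node(make_genesis(self.owner.keypair, oracle_keys, config=config))
        self.store = OffchainStore()
        self.oracle = OracleServer(
            oracle_keys, self.store, self.node,
            rng=np.random.default_rng(
                int.from_bytes(self._derive(b"oracle-rng"), "big") % 2**63))
        self._wallet_counter = 0

    def _derive(self, label: bytes) -> bytes:
        return hashlib.sha256(b"net:" + self._seed_root + b":" + label).digest()

    # -- wallets and calls --

    def new_wallet(self, label: str = "") -> Wallet:
        self._wallet_counter += 1
        return Wallet(generate_keypair(
            self._derive(f"wallet:{self._wallet_counter}:{label}".encode())), label)

    def call(self, wallet: Wallet, contract: str, function: str, args: dict,
             *, seal: bool = True) -> Receipt:
        """Sign, submit and (by default) immediately seal one call; returns
        its receipt."""
        registered = wallet.address in self.node.state.rsc["users"]
        tx = build_transaction(wallet.keypair, contract, function, args,
                               self.node.next_nonce(wallet.address),
                               include_public_key=not registered)
        self.node.submit_transaction(tx)
        if not seal:
            return Receipt(tx.tx_id, "pending", None, [], None, False)
        block = self.node.seal_block()
        for receipt in block.receipts:
            if receipt.tx_id == tx.tx_id:
                return receipt
        raise PgxLedgerError("sealed block lost the transaction")  # pragma: no cover

    def must_call(self, wallet: Wallet, contract: str, function: str, args: dict) -> Receipt:
        receipt = self.call(wallet, contract, function, args)
        if receipt.status != "succeeded":
            raise RevertedCall(receipt)
        return receipt

    # -- onboarding --

    def onboard(self, role: str, *, sub_role: str | None = None,
                label: str = "") -> Wallet:
        """Invite, register and owner-verify a fresh identity."""
        wallet = self.new_wallet(label or role)
        self.must_call(self.owner, "RSC", "inviteUser",
                       {"invitee": wallet.address, "role": role, "sub_role": sub_role})
        register_fn = {"patient": "patientRegister",
                       "data_requester": "dataRequesterRegister",
                       "data_creator": "dataCreatorRegister"}[role]
        args: dict = {"public_key": wallet.keypair.public_hex}
        if role == "data_requester":
            args["sub_role"] = sub_role
        self.must_call(wallet, "RSC", register_fn, args)
        self.must_call(self.owner, "RSC", "verifyUser", {"subject": wallet.address})
        return wallet

    def onboard_patient(self, label: str = "patient") -> Wallet:
        return self.onboard("patient", label=label)

    def onboard_requester(self, sub_role: str = "pharmacist", label: str = "") -> Wallet:
        return self.onboard("data_requester", sub_role=sub_role,
                            label=label or f"requester-{sub_role}")

    def onboard_creator(self, label: str = "creator") -> Wallet:
        return self.onboard("data_creator", label=label)

    # -- records and permissions --

    def publish_record(self, creator: Wallet, record: dict,
                       recommendations: list[dict]) -> tuple[str, str]:
        """Store the full record off-chain, then publish its metadata
        on-chain; returns ``(record_id, pointer)``."""
        pointer, digest = self.store.store_record(creator.address, record)
        metadata = {
            "record_id": record["record_id"],
            "patient": record["patient"],
            "creator": creator.address,
            "recommendations": recommendations,
            "data_hash": digest,
            "pointer": pointer,
        }
        self.must_call(creator, "DSC", "createData", {"metadata": metadata})
        return record["record_id"], pointer

    def grant(self, patient: Wallet, triples) -> Receipt:
        payload = [t if isinstance(t, dict)
                   else {"drug": t[0], "role": t[1], "purpose": t[2]} for t in triples]
        return self.must_call(patient, "ACMSC", "setAccessPermission",
                              {"triples": payload})

    def revoke(self, patient: Wallet, triples=None) -> Receipt:
        payload = None if triples is None else [
            t if isinstance(t, dict)
            else {"drug": t[0], "role": t[1], "purpose": t[2]} for t in triples]
        return self.must_call(patient, "ACMSC", "cancelAccessPermission",
                              {"triples": payload})

    def evaluate(self, patient_address: str, drug: str, role: str, purpose: str) -> bool:
        receipt = self.call(self.owner, "ACMSC", "evaluatePolicy",
                            {"patient": patient_address, "drug": drug,
                             "role": role, "purpose": purpose})
        return bool(receipt.result and receipt.result["allow"])

    # -- the end-to-end release flow --

    def request_flow(self, requester: Wallet, patient_address: str, drug: str,
                     purpose: str) -> FlowResult:
        """Run the release pipeline end to end for one request.

        Succeeds only when the patient's decision tree allows the triple and
        every credential is presented fresh and in time; the returned
        :class:`FlowResult` records each step and the first failure, if any.
        """
        flow = FlowResult()
        flow.log(1, "requester keypair registered on RSC")
        flow.log(2, "patient permission preferences held in ACMSC")
        flow.log(3, "record in off-chain store, metadata on DSC")

        receipt = self.call(requester, "ACMSC", "requestAccessTicket",
                            {"patient": patient_address, "drug": drug,
                             "purpose": purpose})
        if receipt.status != "succeeded":
            flow.fail(4, "access-ticket request", receipt.reason)
            return flow
        flow.ticket_id = receipt.result["ticket_id"]
        flow.log(4, "access-ticket request accepted")
        flow.log(5, f"ticket {flow.ticket_id[:8]}… stored in ACMSC")

        receipt = self.call(requester, "ACMSC", "requestAccessToken",
                            {"ticket_id": flow.ticket_id})
        if receipt.status != "succeeded":
            flow.fail(6, "access-token request", receipt.reason)
            return flow
        flow.token_id = receipt.result["token_id"]
        flow.log(6, "ticket validated")
        flow.log(7, f"one-time token {flow.token_id[:8]}… stored in ACMSC")

        receipt = self.call(requester, "ACMSC", "requestData",
                            {"token_id": flow.token_id})
        if receipt.status != "succeeded":
            flow.fail(8, "data request (token spend)", receipt.reason)
            return flow
        flow.log(8, "token validated and spent")
        flow.log(9, "request forwarded to oracle server")

        outcomes = [f for f in self.oracle.process_pending()
                    if f.token_id == flow.token_id]
        outcome: Fulfilment | None = outcomes[0] if outcomes else None
        if outcome is None or outcome.status != "fulfilled":
            flow.fail(11, "oracle fulfilment",
                      outcome.status if outcome else "NO_FULFILMENT")
            return flow
        flow.log(10, "oracle read requester public key from RSC")
        flow.log(11, "one-time JSON payload minted")
        flow.log(12, "eURL encrypted and stored in ACMSC")

        receipt = self.call(requester, "ACMSC", "fetchEncryptedUrl",
                            {"token_id": flow.token_id})
        if receipt.status != "succeeded":
            flow.fail(13, "eURL pickup", receipt.reason)
            return flow
        pointer = EncryptedPointer(bytes.fromhex(receipt.result["ciphertext"]),
                                   receipt.result["recipient"])
        try:
            url = decrypt_with(requester.keypair.private_key, pointer).decode()
            flow.document = self.oracle.fetch_payload(url)
            flow.url = url
        except PgxLedgerError as exc:
            flow.fail(13, "decrypt and dereference", type(exc).__name__)
            return flow
        flow.log(13, "eURL decrypted; payload fetched once")
        return flow
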