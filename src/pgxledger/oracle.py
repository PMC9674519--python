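"""Off-chain secure storage and the trusted oracle server.

The data creator's store keeps full PGx records off-chain as canonical JSON
bytes, addressed by opaque pointers; only the digest and pointer go
on-chain. The oracle bridges validated on-chain requests to delivery: when
a token has been spent via ``ACMSC.requestData``, the oracle fetches the
record, re-checks its digest against the on-chain hash (no release on
mismatch), mints a one-time capability URL for a temporary JSON payload,
encrypts that URL under the requester's registered public key and parks the
ciphertext on-chain for pickup. A capability URL dereferences exactly once
and dies at the token's expiry tick.

Erasing a patient's records here implements the right to erasure: the
immutable on-chain metadata stays, but its pointer dangles and every future
request fails closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path

import numpy as np

from .canonical import canonical_bytes
from .crypto import KeyPair, content_hash, encrypt_for
from .errors import (
    StoreConflict,
    UrlExhausted,
    UrlExpired,
    UrlUnknown,
)
from .ledger import Node, build_transaction


class OffchainStore:
    """A data creator's private record store, keyed by opaque pointer."""

    def __init__(self) -> None:
        self._blobs: dict[str, bytes] = {}
        self._owners: dict[str, tuple[str, str, str]] = {}  # ptr -> (creator, patient, record_id)

    def store_record(self, creator: str, record: dict) -> tuple[str, str]:
        """Persist *record*; returns ``(pointer, digest_hex)``.

        The creator then publishes both through ``DSC.createData``.
        """
        record_id = record["record_id"]
        pointer = "store://" + sha256(f"{creator}/{record_id}".encode()).hexdigest()[:32]
        if pointer in self._blobs:
            raise StoreConflict(f"record_id {record_id!r} already stored for {creator}")
        blob = canonical_bytes(record)
        self._blobs[pointer] = blob
        self._owners[pointer] = (creator, record["patient"], record_id)
        return pointer, content_hash(blob).value

    def fetch_bytes(self, pointer: str) -> bytes | None:
        return self._blobs.get(pointer)

    def replace_bytes(self, pointer: str, blob: bytes) -> None:
        """Overwrite a stored blob in place (corruption/testing hook)."""
        if pointer not in self._blobs:
            raise KeyError(pointer)
        self._blobs[pointer] = blob

    def erase_patient(self, creator: str, patient: str) -> int:
        """Delete every record this creator holds for *patient*; idempotent."""
        doomed = [ptr for ptr, (c, p, _r) in self._owners.items()
                  if c == creator and p == patient]
        for ptr in doomed:
            del self._blobs[ptr]
            del self._owners[ptr]
        return len(doomed)

    def pointers(self) -> list[str]:
        return list(self._blobs)

    def save_dir(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for ptr, blob in self._blobs.items():
            (directory / (ptr.removeprefix("store://") + ".json")).write_bytes(blob)
        return directory


@dataclass
class OneTimePayload:
    url: str
    document_bytes: bytes
    expires_at: int
    remaining_uses: int = 1


@dataclass
class Fulfilment:
    """Outcome of one oracle fulfilment attempt."""

    token_id: str
    status: str  # "fulfilled" | "INTEGRITY_MISMATCH" | "POINTER_DANGLING"
    requester: str | None = None
    url: str | None = None


class OracleServer:
    """The trusted data-feed service bridging chain and off-chain store."""

    def __init__(self, keypair: KeyPair, store: OffchainStore, node: Node,
                 rng: np.random.Generator | None = None):
        self.keypair = keypair
        self.address = keypair.address
        self.store = store
        self.node = node
        self.rng = rng if rng is not None else np.random.default_rng()
        self.payloads: dict[str, OneTimePayload] = {}
        self.audit_log: list[dict] = []

    def _pending_tokens(self) -> list[str]:
        eurls = self.node.state.acmsc["eurls"]
        return [tid for tid, slot in eurls.items() if slot["status"] == "awaiting"]

    def process_pending(self, *, seal: bool = True) -> list[Fulfilment]:
        """Handle every token spent via ``requestData`` that still awaits an
        eURL. Integrity failures and dangling pointers release nothing and
        are logged as incidents."""
        results = []
        for token_id in self._pending_tokens():
            results.append(self._handle(token_id, seal=seal))
        return results

    def _handle(self, token_id: str, *, seal: bool) -> Fulfilment:
        state = self.node.state
        token = state.acmsc["tokens"][token_id]
        metadata = state.dsc["records"][token["record_id"]]
        requester = token["requester"]
        blob = self.store.fetch_bytes(metadata["pointer"])
        if blob is None:
            self.audit_log.append({"event": "incident", "code": "POINTER_DANGLING",
                                   "token_id": token_id, "at": self.node.now})
            return Fulfilment(token_id, "POINTER_DANGLING", requester)
        if content_hash(blob).value != metadata["data_hash"]:
            self.audit_log.append({"event": "incident", "code": "INTEGRITY_MISMATCH",
                                   "token_id": token_id, "at": self.node.now})
            return Fulfilment(token_id, "INTEGRITY_MISMATCH", requester)
        # mint the one-time capability URL (unguessable 128-bit identifier)
        url = "otp://" + bytes(self.rng.bytes(16)).hex()
        self.payloads[url] = OneTimePayload(url=url, document_bytes=blob,
                                            expires_at=token["expires_at"])
        # requester's encryption key comes from the on-chain registry
        requester_pub = bytes.fromhex(state.rsc["users"][requester]["public_key"])
        pointer = encrypt_for(requester_pub, url.encode(),
                              ephemeral_seed=bytes(self.rng.bytes(32)))
        tx = build_transaction(self.keypair, "ACMSC", "storeEncryptedUrl",
                               {"token_id": token_id,
                                "ciphertext": pointer.ciphertext.hex(),
                                "recipient": pointer.recipient},
                               self.node.next_nonce(self.address))
        self.node.submit_transaction(tx)
        if seal:
            self.node.seal_block()
        self.audit_log.append({"event": "fulfilled", "token_id": token_id,
                               "requester": requester, "at": self.node.now})
        return Fulfilment(token_id, "fulfilled", requester, url)

    def fetch_payload(self, url: str, now: int | None = None) -> dict:
        """Dereference a capability URL exactly once; afterwards it is
        permanently dead."""
        payload = self.payloads.get(url)
        if payload is None:
            raise UrlUnknown(url)
        if payload.remaining_uses < 1:
            raise UrlExhausted(url)
        current = self.node.now if now is None else now
        if current >= payload.expires_at:
            payload.remaining_uses = 0
            raise UrlExpired(url)
        payload.remaining_uses = 0
        return json.loads(payload.document_bytes.decode("utf-8"))
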