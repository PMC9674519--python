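"""Off-chain store and oracle: integrity gate, one-time delivery,
confidentiality, right to erasure."""

from __future__ import annotations

import numpy as np
import pytest

from pgxledger import content_hash, decrypt_with, replay, verify_chain
from pgxledger.crypto import EncryptedPointer
from pgxledger.errors import (
    DecryptionError,
    StoreConflict,
    UrlExhausted,
    UrlExpired,
    UrlUnknown,
)
from pgxledger.oracle import OffchainStore


class TestStore:
    def test_stored_digest_equals_content_hash(self):
        store = OffchainStore()
        record = {"record_id": "r1", "patient": "0x" + "a" * 40, "payload": "x"}
        pointer, digest = store.store_record("creator", record)
        assert digest == content_hash(store.fetch_bytes(pointer)).value

    def test_two_records_get_distinct_pointers(self):
        store = OffchainStore()
        p1, _ = store.store_record("c", {"record_id": "r1", "patient": "p"})
        p2, _ = store.store_record("c", {"record_id": "r2", "patient": "p"})
        assert p1 != p2

    def test_duplicate_record_id_conflicts(self):
        store = OffchainStore()
        store.store_record("c", {"record_id": "r1", "patient": "p"})
        with pytest.raises(StoreConflict):
            store.store_record("c", {"record_id": "r1", "patient": "p"})

    def test_any_byte_change_shifts_the_digest(self):
        store = OffchainStore()
        pointer, digest = store.store_record(
            "c", {"record_id": "r1", "patient": "p", "raw": "ff" * 40})
        blob = store.fetch_bytes(pointer)
        rng = np.random.default_rng(3)
        for _ in range(100):
            mutated = bytearray(blob)
            mutated[int(rng.integers(len(blob)))] ^= 1 << int(rng.integers(8))
            assert content_hash(bytes(mutated)).value != digest


def _granted_clinic(clinic):
    net, patient = clinic["net"], clinic["patient"]
    net.grant(patient, [("codeine", "pharmacist", "treatment")])
    return net, patient, clinic["pharmacist"]


class TestIntegrityGate:
    def test_honest_flow_delivers_exact_record(self, clinic):
        net, patient, requester = _granted_clinic(clinic)
        flow = net.request_flow(requester, patient.address, "codeine", "treatment")
        assert flow.ok and flow.document == clinic["record"]

    def test_corruption_blocks_release(self, clinic):
        """Flipping any byte of the stored record trips the digest check:
        no payload is minted, no eURL stored."""
        net, patient, requester = _granted_clinic(clinic)
        pointer = net.store.pointers()[0]
        pristine = net.store.fetch_bytes(pointer)
        rng = np.random.default_rng(17)
        for _ in range(10):
            corrupted = bytearray(pristine)
            corrupted[int(rng.integers(len(pristine)))] ^= 1 << int(rng.integers(8))
            net.store.replace_bytes(pointer, bytes(corrupted))
            n_payloads = len(net.oracle.payloads)
            flow = net.request_flow(requester, patient.address, "codeine",
                                    "treatment")
            assert not flow.ok and flow.failure_reason == "INTEGRITY_MISMATCH"
            assert len(net.oracle.payloads) == n_payloads  # nothing minted
        net.store.replace_bytes(pointer, pristine)
        assert net.request_flow(requester, patient.address, "codeine",
                                "treatment").ok


class TestOneTimePayload:
    def test_second_fetch_is_exhausted(self, clinic):
        net, patient, requester = _granted_clinic(clinic)
        flow = net.request_flow(requester, patient.address, "codeine", "treatment")
        with pytest.raises(UrlExhausted):
            net.oracle.fetch_payload(flow.url)

    def test_guessed_url_is_unknown(self, clinic):
        with pytest.raises(UrlUnknown):
            clinic["net"].oracle.fetch_payload("otp://" + "00" * 16)

    def test_payload_dies_at_token_expiry(self, clinic):
        net, patient, requester = _granted_clinic(clinic)
        ticket = net.must_call(requester, "ACMSC", "requestAccessTicket",
                               {"patient": patient.address, "drug": "codeine",
                                "purpose": "treatment"}).result
        token = net.must_call(requester, "ACMSC", "requestAccessToken",
                              {"ticket_id": ticket["ticket_id"]}).result
        net.must_call(requester, "ACMSC", "requestData",
                      {"token_id": token["token_id"]})
        outcome = net.oracle.process_pending()[0]
        net.node.now = token["expires_at"]
        with pytest.raises(UrlExpired):
            net.oracle.fetch_payload(outcome.url)


class TestConfidentiality:
    def test_only_the_intended_requester_decrypts(self, clinic):
        net, patient, _ = _granted_clinic(clinic)
        net.grant(patient, [("codeine", "physician", "treatment")])
        flows = {}
        for who in ("pharmacist", "physician"):
            flows[who] = net.request_flow(clinic[who], patient.address,
                                          "codeine", "treatment")
            assert flows[who].ok
        for who, flow in flows.items():
            slot = net.node.state.acmsc["eurls"][flow.token_id]
            box = EncryptedPointer(bytes.fromhex(slot["ciphertext"]),
                                   slot["recipient"])
            for other in ("pharmacist", "physician"):
                if other == who:
                    url = decrypt_with(clinic[other].keypair.private_key, box)
                    assert url.decode() == flow.url
                else:
                    with pytest.raises(DecryptionError):
                        decrypt_with(clinic[other].keypair.private_key, box)


class TestErasure:
    def test_erasure_blocks_release_but_preserves_the_chain(self, clinic):
        net, patient, requester = _granted_clinic(clinic)
        assert net.request_flow(requester, patient.address, "codeine",
                                "treatment").ok
        removed = net.store.erase_patient(clinic["creator"].address,
                                          patient.address)
        assert removed == 1
        flow = net.request_flow(requester, patient.address, "codeine", "treatment")
        assert not flow.ok and flow.failure_reason == "POINTER_DANGLING"
        # on-chain metadata is untouched and history remains intact
        assert verify_chain(net.node.blocks) == (True, None)
        assert replay(net.node.blocks) == net.node.state

    def test_erase_is_idempotent(self, clinic):
        net = clinic["net"]
        net.store.erase_patient(clinic["creator"].address,
                                clinic["patient"].address)
        assert net.store.erase_patient(clinic["creator"].address,
                                       clinic["patient"].address) == 0
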