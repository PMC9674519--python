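"""Ledger: submission, sealing, integrity verification, replay, events."""

from __future__ import annotations

import dataclasses

import pytest

from pgxledger import (
    Network,
    SubmissionRejected,
    build_transaction,
    load_chain,
    replay,
    verify_chain,
)
from pgxledger.errors import ChainIntegrityError
from pgxledger.ledger import SignedTransaction, compute_block_hash, compute_tx_id


def _invite_tx(net, invitee, nonce=None):
    return build_transaction(
        net.owner.keypair, "RSC", "inviteUser",
        {"invitee": invitee.address, "role": "patient", "sub_role": None},
        net.node.next_nonce(net.owner.address) if nonce is None else nonce)


class TestSubmission:
    def test_valid_transaction_enters_pool(self, net):
        net.node.submit_transaction(_invite_tx(net, net.new_wallet()))
        assert len(net.node.pending) == 1

    def test_tampered_args_rejected_by_signature_check(self, net):
        tx = _invite_tx(net, net.new_wallet())
        tampered = dataclasses.replace(
            tx, args={**tx.args, "role": "data_creator"})
        tampered = dataclasses.replace(tampered, tx_id=compute_tx_id(tampered))
        with pytest.raises(SubmissionRejected) as err:
            net.node.submit_transaction(tampered)
        assert err.value.code == "BAD_SIGNATURE"

    def test_wrong_nonce_rejected(self, net):
        with pytest.raises(SubmissionRejected) as err:
            net.node.submit_transaction(_invite_tx(net, net.new_wallet(), nonce=5))
        assert err.value.code == "BAD_NONCE"

    def test_unknown_sender_without_key_rejected(self, net):
        stranger = net.new_wallet()
        tx = build_transaction(stranger.keypair, "ACMSC", "requestData",
                               {"token_id": "x"}, 0)
        with pytest.raises(SubmissionRejected) as err:
            net.node.submit_transaction(tx)
        assert err.value.code == "UNKNOWN_SENDER"

    def test_sealed_transactions_cannot_be_replayed(self, net):
        """Resubmitting any already-sealed tx_id is refused."""
        txs = []
        for _ in range(20):
            tx = _invite_tx(net, net.new_wallet())
            net.node.submit_transaction(tx)
            txs.append(tx)
        net.node.seal_block()
        for tx in txs:
            with pytest.raises(SubmissionRejected):
                net.node.submit_transaction(tx)


class TestSealing:
    def test_pool_drained_fifo_with_receipts(self, net):
        for _ in range(3):
            net.node.submit_transaction(_invite_tx(net, net.new_wallet()))
        block = net.node.seal_block()
        assert [r.status for r in block.receipts] == ["succeeded"] * 3
        assert net.node.pending == []

    def test_reverted_call_leaves_state_unchanged_and_consumes_nonce(self, net):
        patient = net.onboard_patient()
        digest_before = net.node.state_digest()
        nonce_before = net.node.next_nonce(patient.address)
        # patients may not invite: AUTH_ONLY_OWNER
        receipt = net.call(patient, "RSC", "inviteUser",
                           {"invitee": net.new_wallet().address,
                            "role": "patient", "sub_role": None})
        assert receipt.status == "reverted"
        assert receipt.reason == "AUTH_ONLY_OWNER"
        assert net.node.state_digest() == digest_before
        assert net.node.next_nonce(patient.address) == nonce_before + 1

    def test_non_validator_cannot_seal(self, net):
        with pytest.raises(SubmissionRejected) as err:
            net.node.seal_block(caller=net.new_wallet().address)
        assert err.value.code == "NOT_VALIDATOR"

    def test_every_sealed_block_hash_recomputes(self, net):
        net.onboard_patient()
        net.onboard_creator()
        for block in net.node.blocks:
            recomputed = compute_block_hash(
                block.index, block.timestamp, block.prev_hash,
                [t.tx_id for t in block.transactions], block.receipts,
                block.genesis)
            assert recomputed == block.block_hash


def _ten_block_chain():
    net = Network(seed=77)
    for i in range(5):
        net.onboard_patient(f"p{i}")  # 3 txs each, sealed one per block
    assert len(net.node.blocks) >= 10
    return net


class TestVerifyChain:
    def test_untampered_chain_verifies(self):
        net = _ten_block_chain()
        assert verify_chain(net.node.blocks) == (True, None)

    def test_genesis_only_chain_verifies(self):
        assert verify_chain(Network(seed=1).node.blocks) == (True, None)

    def test_mutation_at_each_position_is_localised(self):
        """Mutating one transaction argument in block i is reported as a
        first failure at exactly i, for every i."""
        net = _ten_block_chain()
        blocks = net.node.blocks
        for i in range(1, 10):
            mutated = list(blocks)
            block = mutated[i]
            tx = block.transactions[0]
            bad_tx = dataclasses.replace(tx, args={**tx.args, "evil": "yes"})
            mutated[i] = dataclasses.replace(
                block, transactions=(bad_tx,) + block.transactions[1:])
            assert verify_chain(mutated) == (False, i)

    def test_header_mutations_detected(self):
        net = _ten_block_chain()
        blocks = list(net.node.blocks)
        blocks[4] = dataclasses.replace(blocks[4], timestamp=999)
        assert verify_chain(blocks) == (False, 4)


class TestReplay:
    def test_replay_reproduces_live_state(self, clinic):
        net = clinic["net"]
        net.grant(clinic["patient"], [("codeine", "pharmacist", "treatment")])
        net.request_flow(clinic["pharmacist"], clinic["patient"].address,
                         "codeine", "treatment")
        assert replay(net.node.blocks) == net.node.state

    def test_replay_of_fresh_chain_gives_initial_state(self):
        net = Network(seed=3)
        assert replay(net.node.blocks) == net.node.state

    def test_replay_is_deterministic(self, clinic):
        blocks = clinic["net"].node.blocks
        assert replay(blocks) == replay(blocks)

    def test_invalid_chain_raises(self):
        net = _ten_block_chain()
        blocks = list(net.node.blocks)
        blocks[3] = dataclasses.replace(blocks[3], block_hash="0" * 64)
        with pytest.raises(ChainIntegrityError):
            replay(blocks)


class TestEvents:
    def test_patient_sees_all_events_concerning_them(self, clinic):
        net = clinic["net"]
        net.grant(clinic["patient"], [("codeine", "pharmacist", "treatment")])
        net.request_flow(clinic["pharmacist"], clinic["patient"].address,
                         "codeine", "treatment")
        names = [e.name for e in net.node.get_events(address=clinic["patient"].address)]
        assert names.index("PermissionSet") < names.index("TicketIssued")
        for expected in ("PermissionSet", "TicketIssued", "TokenIssued",
                         "DataRequested", "URLStored"):
            assert expected in names

    def test_empty_filter_returns_every_event(self, clinic):
        net = clinic["net"]
        assert net.node.get_events() == list(net.node.iter_events())

    def test_event_count_matches_succeeded_state_changing_receipts(self, clinic):
        """Each succeeded state-changing call emits exactly one event."""
        net = clinic["net"]
        net.grant(clinic["patient"], [("codeine", "pharmacist", "treatment")])
        net.request_flow(clinic["pharmacist"], clinic["patient"].address,
                         "codeine", "treatment")
        n_state_changing = sum(
            1 for b in net.node.blocks for r in b.receipts
            if r.status == "succeeded" and not r.view)
        assert len(net.node.get_events()) == n_state_changing


class TestPersistence:
    def test_chain_export_import_roundtrip(self, clinic, tmp_path):
        net = clinic["net"]
        path = net.node.export_chain(tmp_path / "chain.jsonl")
        loaded = load_chain(path)
        assert [b.block_hash for b in loaded] == [b.block_hash for b in net.node.blocks]
        assert verify_chain(loaded) == (True, None)
        assert replay(loaded) == net.node.state

    def test_event_csv_export(self, clinic, tmp_path):
        import pandas as pd

        net = clinic["net"]
        path = net.node.export_events_csv(tmp_path / "events.csv")
        df = pd.read_csv(path)
        assert len(df) == len(net.node.get_events())
        assert {"block_index", "name", "sender"} <= set(df.columns)
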