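"""The simulated permissioned ledger.

One honest sealer stands in for the proof-of-authority validator set: it
drains the pending pool in FIFO order, executes each signed transaction
against contract state (reverted calls roll back atomically and record a
reason code), and appends a hash-chained block. Time is an integer tick
clock advanced explicitly — never the wall clock — so expiry behaviour and
every exported artifact are deterministic.

Block hashes cover the header, the transaction ids (which themselves cover
every transaction field including the signature) and the full receipts, so
mutating any single field of any sealed block is detectable, and
``verify_chain`` reports exactly the first block at fault. ``replay``
re-executes an exported chain from genesis and returns the reconstructed
contract state for comparison with the live one.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .canonical import canonical_bytes, canonical_str
from .contracts import CallContext, ContractState, initial_state, is_view, resolve
from .crypto import KeyPair, content_hash, derive_address, sign, verify
from .errors import Revert, ChainIntegrityError, SubmissionRejected

GENESIS_PREV_HASH = "0" * 64


# --- transactions ---------------------------------------------------------


@dataclass(frozen=True)
class SignedTransaction:
    sender: str
    contract: str
    function: str
    args: dict
    nonce: int
    signature: str  # hex
    public_key: str | None = None  # hex; present when the sender is not yet registered
    tx_id: str = ""

    @staticmethod
    def signing_payload(sender: str, contract: str, function: str, args: dict,
                        nonce: int, public_key: str | None) -> bytes:
        return canonical_bytes({
            "sender": sender, "contract": contract, "function": function,
            "args": args, "nonce": nonce, "public_key": public_key,
        })

    def to_dict(self) -> dict:
        return {
            "sender": self.sender, "contract": self.contract,
            "function": self.function, "args": self.args, "nonce": self.nonce,
            "signature": self.signature, "public_key": self.public_key,
            "tx_id": self.tx_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignedTransaction":
        return cls(sender=d["sender"], contract=d["contract"], function=d["function"],
                   args=d["args"], nonce=d["nonce"], signature=d["signature"],
                   public_key=d.get("public_key"), tx_id=d["tx_id"])


def compute_tx_id(tx: SignedTransaction) -> str:
    body = tx.to_dict()
    body.pop("tx_id")
    return content_hash(canonical_bytes(body)).value


def build_transaction(keypair: KeyPair, contract: str, function: str, args: dict,
                      nonce: int, *, include_public_key: bool = False) -> SignedTransaction:
    """Sign a contract call with *keypair* and derive its transaction id."""
    sender = derive_address(keypair.public_key)
    public_key = keypair.public_hex if include_public_key else None
    payload = SignedTransaction.signing_payload(sender, contract, function, args,
                                                nonce, public_key)
    signature = sign(keypair.private_key, payload).hex()
    tx = SignedTransaction(sender=sender, contract=contract, function=function,
                           args=args, nonce=nonce, signature=signature,
                           public_key=public_key)
    return SignedTransaction(**{**tx.to_dict(), "tx_id": compute_tx_id(tx)})


# --- receipts, blocks, events ---------------------------------------------


@dataclass(frozen=True)
class Receipt:
    tx_id: str
    status: str  # "succeeded" | "reverted"
    reason: str | None
    events: list
    result: object
    view: bool

    def to_dict(self) -> dict:
        return {"tx_id": self.tx_id, "status": self.status, "reason": self.reason,
                "events": self.events, "result": self.result, "view": self.view}

    @classmethod
    def from_dict(cls, d: dict) -> "Receipt":
        return cls(tx_id=d["tx_id"], status=d["status"], reason=d["reason"],
                   events=d["events"], result=d["result"], view=d["view"])


@dataclass(frozen=True)
class Block:
    index: int
    timestamp: int
    prev_hash: str
    transactions: tuple
    receipts: tuple
    block_hash: str
    genesis: dict | None = None  # present on block 0 only

    def to_dict(self) -> dict:
        d = {
            "index": self.index, "timestamp": self.timestamp,
            "prev_hash": self.prev_hash,
            "transactions": [t.to_dict() for t in self.transactions],
            "receipts": [r.to_dict() for r in self.receipts],
            "block_hash": self.block_hash,
        }
        if self.genesis is not None:
            d["genesis"] = self.genesis
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Block":
        return cls(
            index=d["index"], timestamp=d["timestamp"], prev_hash=d["prev_hash"],
            transactions=tuple(SignedTransaction.from_dict(t) for t in d["transactions"]),
            receipts=tuple(Receipt.from_dict(r) for r in d["receipts"]),
            block_hash=d["block_hash"], genesis=d.get("genesis"),
        )


def compute_block_hash(index: int, timestamp: int, prev_hash: str,
                       tx_ids: list[str], receipts: Iterable[Receipt],
                       genesis: dict | None) -> str:
    header = {
        "index": index, "timestamp": timestamp, "prev_hash": prev_hash,
        "tx_ids": tx_ids, "receipts": [r.to_dict() for r in receipts],
        "genesis": genesis,
    }
    return content_hash(canonical_bytes(header)).value


@dataclass(frozen=True)
class Event:
    name: str
    contract: str
    block_index: int
    timestamp: int
    tx_id: str
    sender: str
    payload: dict

    def to_dict(self) -> dict:
        return {"name": self.name, "contract": self.contract,
                "block_index": self.block_index, "timestamp": self.timestamp,
                "tx_id": self.tx_id, "sender": self.sender, "payload": self.payload}


# --- the node -------------------------------------------------------------


DEFAULT_CHAIN_CONFIG = {
    "ticket_ttl": 100,
    "token_ttl": 20,
    "identity_check_passes": True,
    "allow_multiple_records_per_pair": False,
}


def make_genesis(owner: KeyPair, oracle: KeyPair, *, validator: str | None = None,
                 config: dict | None = None) -> dict:
    merged = dict(DEFAULT_CHAIN_CONFIG)
    if config:
        merged.update(config)
    return {
        "owner_address": owner.address,
        "owner_public_key": owner.public_hex,
        "oracle_address": oracle.address,
        "oracle_public_key": oracle.public_hex,
        "validator": validator or owner.address,
        "config": merged,
    }


class Node:
    """A single-sealer ledger node holding chain, pool, clock and contract
    state."""

    def __init__(self, genesis: dict):
        self.genesis = genesis
        self.config = genesis["config"]
        self.validator = genesis["validator"]
        self.now = 0
        self.state = initial_state(genesis)
        self.pending: list[SignedTransaction] = []
        self.blocks: list[Block] = []
        self._nonces: dict[str, int] = {}
        self._seen_tx_ids: set[str] = set()
        g_hash = compute_block_hash(0, 0, GENESIS_PREV_HASH, [], [], genesis)
        self.blocks.append(Block(index=0, timestamp=0, prev_hash=GENESIS_PREV_HASH,
                                 transactions=(), receipts=(), block_hash=g_hash,
                                 genesis=genesis))

    # -- clock --

    def advance_clock(self, ticks: int = 1) -> int:
        if ticks < 0:
            raise ValueError("clock only moves forward")
        self.now += ticks
        return self.now

    # -- nonces --

    def next_nonce(self, sender: str) -> int:
        return self._nonces.get(sender, 0)

    # -- submission --

    def _sender_public_key(self, tx: SignedTransaction) -> bytes:
        user = self.state.rsc["users"].get(tx.sender)
        if user is not None:
            return bytes.fromhex(user["public_key"])
        if tx.public_key is not None:
            pk = bytes.fromhex(tx.public_key)
            if derive_address(pk) == tx.sender:
                return pk
            raise SubmissionRejected("BAD_SIGNATURE",
                                     "attached public key does not match sender")
        raise SubmissionRejected("UNKNOWN_SENDER", tx.sender)

    def submit_transaction(self, tx: SignedTransaction) -> str:
        """Validate and queue a transaction; returns its id.

        Rejections (bad signature, wrong nonce, replayed id, unknown sender)
        never enter the pool or the chain.
        """
        if compute_tx_id(tx) != tx.tx_id:
            raise SubmissionRejected("BAD_SIGNATURE", "tx_id does not match body")
        if tx.tx_id in self._seen_tx_ids:
            raise SubmissionRejected("DUPLICATE_TX", tx.tx_id)
        public_key = self._sender_public_key(tx)
        payload = SignedTransaction.signing_payload(
            tx.sender, tx.contract, tx.function, tx.args, tx.nonce, tx.public_key)
        if not verify(public_key, payload, bytes.fromhex(tx.signature)):
            raise SubmissionRejected("BAD_SIGNATURE", tx.tx_id)
        expected = self.next_nonce(tx.sender)
        if tx.nonce != expected:
            raise SubmissionRejected("BAD_NONCE",
                                     f"got {tx.nonce}, expected {expected}")
        self._nonces[tx.sender] = expected + 1
        self._seen_tx_ids.add(tx.tx_id)
        self.pending.append(tx)
        return tx.tx_id

    # -- execution --

    def _execute(self, tx: SignedTransaction) -> Receipt:
        try:
            handler = resolve(tx.contract, tx.function)
        except Revert as rv:
            return Receipt(tx.tx_id, "reverted", rv.reason, [], None, False)
        view = is_view(handler)
        snapshot = None if view else self.state.snapshot()
        ctx = CallContext(sender=tx.sender, now=self.now, tx_id=tx.tx_id,
                          state=self.state, config=self.config)
        try:
            # deep-copied args/results so sealed blocks never alias live state
            result = handler(ctx, **copy.deepcopy(tx.args))
        except Revert as rv:
            if snapshot is not None:
                self.state = snapshot
            return Receipt(tx.tx_id, "reverted", rv.reason, [], None, view)
        except TypeError:
            if snapshot is not None:
                self.state = snapshot
            return Receipt(tx.tx_id, "reverted", "BAD_ARGUMENTS", [], None, view)
        return Receipt(tx.tx_id, "succeeded", None, copy.deepcopy(ctx.events),
                       copy.deepcopy(result), view)

    def seal_block(self, caller: str | None = None, *, max_txs: int | None = None,
                   advance: int = 1) -> Block:
        """Drain (up to ``max_txs`` of) the pool FIFO, execute, append a
        block, then advance the clock by ``advance`` ticks.

        ``caller`` defaults to the configured validator; any other identity
        is refused.
        """
        if caller is not None and caller != self.validator:
            raise SubmissionRejected("NOT_VALIDATOR", caller)
        count = len(self.pending) if max_txs is None else min(max_txs, len(self.pending))
        batch, self.pending = self.pending[:count], self.pending[count:]
        receipts = [self._execute(tx) for tx in batch]
        prev = self.blocks[-1]
        block = Block(
            index=prev.index + 1, timestamp=self.now, prev_hash=prev.block_hash,
            transactions=tuple(batch), receipts=tuple(receipts),
            block_hash=compute_block_hash(prev.index + 1, self.now, prev.block_hash,
                                          [t.tx_id for t in batch], receipts, None),
        )
        self.blocks.append(block)
        if advance:
            self.advance_clock(advance)
        return block

    # -- queries --

    def state_digest(self) -> str:
        return self.state.digest().value

    def iter_events(self) -> Iterator[Event]:
        yield from events_from_blocks(self.blocks)

    def get_events(self, *, contract: str | None = None, name: str | None = None,
                   address: str | None = None,
                   block_range: tuple[int, int] | None = None) -> list[Event]:
        """All matching events in chain order.

        ``address`` matches the transaction sender or any address appearing
        in the event payload — a patient filtering on their own address sees
        every grant, request, release and revocation concerning them.
        """
        out = []
        for ev in self.iter_events():
            if contract is not None and ev.contract != contract:
                continue
            if name is not None and ev.name != name:
                continue
            if block_range is not None and not (block_range[0] <= ev.block_index <= block_range[1]):
                continue
            if address is not None and ev.sender != address \
                    and address not in canonical_str(ev.payload):
                continue
            out.append(ev)
        return out

    # -- persistence --

    def export_chain(self, path: str | Path) -> Path:
        """Write the chain as JSON-lines, one block per line."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for block in self.blocks:
                fh.write(canonical_str(block.to_dict()) + "\n")
        return path

    def export_events_csv(self, path: str | Path) -> Path:
        rows = [dict(e.to_dict(), payload=canonical_str(e.payload))
                for e in self.iter_events()]
        df = pd.DataFrame(rows, columns=["block_index", "timestamp", "contract",
                                         "name", "tx_id", "sender", "payload"])
        df.to_csv(path, index=False)
        return Path(path)


def events_from_blocks(blocks: Iterable[Block]) -> Iterator[Event]:
    """All events on a chain in causal order; only succeeded transactions
    emit events."""
    for block in blocks:
        for tx, receipt in zip(block.transactions, block.receipts):
            if receipt.status != "succeeded":
                continue
            for ev in receipt.events:
                yield Event(name=ev["name"], contract=tx.contract,
                            block_index=block.index, timestamp=block.timestamp,
                            tx_id=tx.tx_id, sender=tx.sender,
                            payload=ev["payload"])


def load_chain(path: str | Path) -> list[Block]:
    blocks = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                blocks.append(Block.from_dict(json.loads(line)))
    return blocks


# --- verification and replay ----------------------------------------------


def verify_chain(blocks: list[Block]) -> tuple[bool, int | None]:
    """True iff every block's hash recomputes and every prev_hash links.

    Returns ``(ok, first_invalid_index)``; verification is a result, never
    an exception.
    """
    for i, block in enumerate(blocks):
        if block.index != i:
            return False, i
        expected_prev = GENESIS_PREV_HASH if i == 0 else blocks[i - 1].block_hash
        if block.prev_hash != expected_prev:
            return False, i
        if len(block.transactions) != len(block.receipts):
            return False, i
        tx_ids = []
        ok = True
        for tx, receipt in zip(block.transactions, block.receipts):
            if compute_tx_id(tx) != tx.tx_id or receipt.tx_id != tx.tx_id:
                ok = False
                break
            tx_ids.append(tx.tx_id)
        if not ok:
            return False, i
        recomputed = compute_block_hash(block.index, block.timestamp, block.prev_hash,
                                        tx_ids, block.receipts, block.genesis)
        if recomputed != block.block_hash:
            return False, i
    return True, None


def replay(blocks: list[Block]) -> ContractState:
    """Re-execute a verified chain from genesis; returns the reconstructed
    contract state.

    Raises :class:`ChainIntegrityError` if the chain does not verify or if
    re-execution diverges from the recorded blocks (different receipts or
    block hashes).
    """
    ok, bad = verify_chain(blocks)
    if not ok:
        raise ChainIntegrityError(f"chain invalid at block {bad}")
    if not blocks or blocks[0].genesis is None:
        raise ChainIntegrityError("missing genesis block")
    node = Node(blocks[0].genesis)
    for block in blocks[1:]:
        node.now = block.timestamp
        for tx in block.transactions:
            node.submit_transaction(tx)
        replayed = node.seal_block(max_txs=len(block.transactions), advance=0)
        if replayed.block_hash != block.block_hash:
            raise ChainIntegrityError(
                f"replay diverged at block {block.index}")
    return node.state
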