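"""Shared contract-execution plumbing: state container, call context and
the function dispatch registry.

Contract state is plain JSON-safe dicts so that replay equality can be
checked by canonical serialization, and so state snapshots are cheap to
deep-copy for revert semantics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Callable

from ..canonical import canonical_bytes
from ..crypto import Digest, content_hash
from ..errors import Revert

ROLE_PATIENT = "patient"
ROLE_CREATOR = "data_creator"
ROLE_REQUESTER = "data_requester"
ROLE_OWNER = "system_owner"
ROLE_ORACLE = "oracle"

USER_ROLES = (ROLE_PATIENT, ROLE_CREATOR, ROLE_REQUESTER)


class ContractState:
    """Mutable state of the three contracts (RSC, DSC, ACMSC)."""

    def __init__(self, rsc: dict, dsc: dict, acmsc: dict):
        self.rsc = rsc
        self.dsc = dsc
        self.acmsc = acmsc

    def to_canonical(self) -> dict:
        return {"RSC": self.rsc, "DSC": self.dsc, "ACMSC": self.acmsc}

    def digest(self) -> Digest:
        return content_hash(canonical_bytes(self.to_canonical()))

    def snapshot(self) -> "ContractState":
        return ContractState(
            copy.deepcopy(self.rsc), copy.deepcopy(self.dsc), copy.deepcopy(self.acmsc)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContractState):
            return NotImplemented
        return canonical_bytes(self.to_canonical()) == canonical_bytes(other.to_canonical())


def initial_state(genesis: dict) -> ContractState:
    """Bootstrap state from the genesis document.

    The system owner and the oracle identity are provisioned at genesis —
    they are the only accounts that exist without an invitation.
    """
    users = {
        genesis["owner_address"]: {
            "role": ROLE_OWNER,
            "sub_role": None,
            "public_key": genesis["owner_public_key"],
            "verified": True,
            "invited_by": None,
        },
        genesis["oracle_address"]: {
            "role": ROLE_ORACLE,
            "sub_role": None,
            "public_key": genesis["oracle_public_key"],
            "verified": True,
            "invited_by": None,
        },
    }
    rsc = {
        "owner": genesis["owner_address"],
        "oracle": genesis["oracle_address"],
        "invitations": {},
        "users": users,
    }
    dsc = {"records": {}, "by_patient": {}}
    acmsc = {"policies": {}, "tickets": {}, "tokens": {}, "eurls": {}}
    return ContractState(rsc, dsc, acmsc)


@dataclass
class CallContext:
    """Everything a contract function may see during one call."""

    sender: str
    now: int
    tx_id: str
    state: ContractState
    config: dict
    events: list = field(default_factory=list)

    def emit(self, name: str, payload: dict) -> None:
        self.events.append({"name": name, "payload": payload})


Handler = Callable[..., Any]

# registry: contract name -> function name -> handler
FUNCTIONS: dict[str, dict[str, Handler]] = {"RSC": {}, "DSC": {}, "ACMSC": {}}


def contract_function(contract: str, name: str, *, view: bool = False, aliases: tuple[str, ...] = ()):
    def deco(fn: Handler) -> Handler:
        fn._view = view  # type: ignore[attr-defined]
        FUNCTIONS[contract][name] = fn
        for alias in aliases:
            FUNCTIONS[contract][alias] = fn
        return fn

    return deco


def resolve(contract: str, function: str) -> Handler:
    try:
        table = FUNCTIONS[contract]
    except KeyError:
        raise Revert("UNKNOWN_CONTRACT", contract) from None
    try:
        return table[function]
    except KeyError:
        raise Revert("UNKNOWN_FUNCTION", f"{contract}.{function}") from None


def is_view(handler: Handler) -> bool:
    return bool(getattr(handler, "_view", False))


# --- cross-contract helpers ----------------------------------------------


def get_user(state: ContractState, address: str) -> dict:
    user = state.rsc["users"].get(address)
    if user is None:
        raise Revert("NOT_REGISTERED", address)
    return user


def require_verified(state: ContractState, address: str, role: str | None = None) -> dict:
    user = get_user(state, address)
    if not user["verified"]:
        raise Revert("NOT_VERIFIED", address)
    if role is not None and user["role"] != role:
        raise Revert("ROLE_MISMATCH", f"{address} is {user['role']}, need {role}")
    return user
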