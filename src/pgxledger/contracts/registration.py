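"""Registration contract (RSC): invitation-based onboarding with owner-side
verification.

The system owner (e.g. a national health service) invites an address for a
specific role; the invitee registers by presenting the public key their
address derives from; the owner then verifies the registration against
external identity services (stubbed here as a configurable pass). Only
verified users may call state-changing functions on the data and
access-control contracts. Roles are immutable and one record exists per
address; nothing links two addresses held by the same person.
"""

from __future__ import annotations

from ..crypto import derive_address
from ..errors import Revert, require
from .base import (
    ROLE_OWNER,
    ROLE_REQUESTER,
    USER_ROLES,
    CallContext,
    contract_function,
    get_user,
)


def _require_owner(ctx: CallContext) -> None:
    require(ctx.sender == ctx.state.rsc["owner"], "AUTH_ONLY_OWNER", ctx.sender)


@contract_function("RSC", "inviteUser")
def invite_user(ctx: CallContext, invitee: str, role: str, sub_role: str | None = None):
    _require_owner(ctx)
    require(role in USER_ROLES, "ROLE_MISMATCH", f"uninvitable role {role!r}")
    rsc = ctx.state.rsc
    require(invitee not in rsc["users"], "ALREADY_REGISTERED", invitee)
    require(invitee not in rsc["invitations"], "ALREADY_INVITED", invitee)
    rsc["invitations"][invitee] = {"role": role, "sub_role": sub_role}
    ctx.emit("Invited", {"invitee": invitee, "role": role})
    return {"invitee": invitee, "role": role}


def _register(ctx: CallContext, role: str, public_key: str, sub_role: str | None):
    rsc = ctx.state.rsc
    require(ctx.sender not in rsc["users"], "ALREADY_REGISTERED", ctx.sender)
    invitation = rsc["invitations"].get(ctx.sender)
    require(invitation is not None, "NOT_INVITED", ctx.sender)
    require(invitation["role"] == role, "ROLE_MISMATCH",
            f"invited as {invitation['role']}, registering as {role}")
    # identity-proofing stub: external services would be consulted here
    if not ctx.config.get("identity_check_passes", True):
        raise Revert("NOT_VERIFIED", "external identity check failed")
    try:
        derived = derive_address(bytes.fromhex(public_key))
    except Exception:
        raise Revert("KEY_MISMATCH", "malformed public key") from None
    require(derived == ctx.sender, "KEY_MISMATCH",
            "public key does not derive the caller address")
    rsc["users"][ctx.sender] = {
        "role": role,
        "sub_role": sub_role if sub_role is not None else invitation["sub_role"],
        "public_key": public_key,
        "verified": False,
        "invited_by": rsc["owner"],
    }
    del rsc["invitations"][ctx.sender]
    ctx.emit("Registered", {"address": ctx.sender, "role": role})
    return {"address": ctx.sender, "role": role, "verified": False}


@contract_function("RSC", "patientRegister")
def patient_register(ctx: CallContext, public_key: str):
    return _register(ctx, "patient", public_key, None)


@contract_function("RSC", "dataRequesterRegister")
def data_requester_register(ctx: CallContext, public_key: str, sub_role: str | None = None):
    return _register(ctx, ROLE_REQUESTER, public_key, sub_role)


@contract_function("RSC", "dataCreatorRegister")
def data_creator_register(ctx: CallContext, public_key: str):
    return _register(ctx, "data_creator", public_key, None)


@contract_function("RSC", "verifyUser")
def verify_user(ctx: CallContext, subject: str):
    _require_owner(ctx)
    user = get_user(ctx.state, subject)
    already = user["verified"]
    user["verified"] = True
    ctx.emit("Verified", {"address": subject, "idempotent": already})
    return {"address": subject, "verified": True}


@contract_function("RSC", "getPublicKey", view=True)
def get_public_key(ctx: CallContext, address: str):
    return get_user(ctx.state, address)["public_key"]


@contract_function("RSC", "getRole", view=True)
def get_role(ctx: CallContext, address: str):
    user = get_user(ctx.state, address)
    return {"role": user["role"], "sub_role": user["sub_role"]}
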