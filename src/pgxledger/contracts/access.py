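"""Access-control manager contract (ACMSC).

Two responsibilities: (1) hold each patient's permission policy as a
compiled decision tree over (drug, role, purpose) triples, evaluated
automatically on every access request; (2) drive the three-stage release
pipeline — access ticket, one-time access token, encrypted pointer (eURL)
— in which every credential is single-use, time-bounded on the simulated
clock, and bound to one requester.

Policy changes take effect at the very next sealed block: grants and
revocations recompile the tree in the same transaction that records them.
"""

from __future__ import annotations

import hashlib

from .. import policy as policy_mod
from ..errors import Revert, require
from .base import CallContext, contract_function, get_user, require_verified


def _policy_entry(acmsc: dict, patient: str) -> dict:
    return acmsc["policies"].setdefault(patient, {"triples": [], "tree": {}})


def _recompile(entry: dict) -> None:
    triples = [(t["drug"], t["role"], t["purpose"]) for t in entry["triples"]]
    entry["tree"] = policy_mod.compile_tree(triples)


def _derived_id(tx_id: str, label: str) -> str:
    return hashlib.sha256(f"{label}:{tx_id}".encode()).hexdigest()[:32]


@contract_function("ACMSC", "setAccessPermission", aliases=("setAcessPermission",))
def set_access_permission(ctx: CallContext, triples: list):
    user = require_verified(ctx.state, ctx.sender)
    require(user["role"] == "patient", "AUTH_ONLY_PATIENT", ctx.sender)
    validated = [policy_mod.validate_triple((t["drug"], t["role"], t["purpose"]))
                 if isinstance(t, dict) else policy_mod.validate_triple(t)
                 for t in triples]
    entry = _policy_entry(ctx.state.acmsc, ctx.sender)
    current = {(t["drug"], t["role"], t["purpose"]) for t in entry["triples"]}
    current |= {t.as_tuple() for t in validated}
    entry["triples"] = [
        {"drug": d, "role": r, "purpose": p} for d, r, p in sorted(current)
    ]
    _recompile(entry)
    ctx.emit("PermissionSet", {
        "patient": ctx.sender,
        "granted": [t.as_dict() for t in validated],
        "policy_size": len(entry["triples"]),
    })
    return {"policy_size": len(entry["triples"])}


@contract_function("ACMSC", "cancelAccessPermission", aliases=("cancelAcessPermission",))
def cancel_access_permission(ctx: CallContext, triples: list | None = None):
    """Remove specific triples, or the whole policy when ``triples`` is None.
    Cancelling a triple that was never granted is an idempotent no-op."""
    user = require_verified(ctx.state, ctx.sender)
    require(user["role"] == "patient", "AUTH_ONLY_PATIENT", ctx.sender)
    entry = _policy_entry(ctx.state.acmsc, ctx.sender)
    if triples is None:
        removed = list(entry["triples"])
        entry["triples"] = []
    else:
        validated = {policy_mod.validate_triple((t["drug"], t["role"], t["purpose"])
                     if isinstance(t, dict) else t).as_tuple() for t in triples}
        removed = [t for t in entry["triples"]
                   if (t["drug"], t["role"], t["purpose"]) in validated]
        entry["triples"] = [t for t in entry["triples"]
                            if (t["drug"], t["role"], t["purpose"]) not in validated]
    _recompile(entry)
    ctx.emit("PermissionCancelled", {
        "patient": ctx.sender,
        "removed": removed,
        "policy_size": len(entry["triples"]),
    })
    return {"policy_size": len(entry["triples"]), "removed": len(removed)}


@contract_function("ACMSC", "evaluatePolicy", view=True)
def evaluate_policy(ctx: CallContext, patient: str, drug: str, role: str, purpose: str):
    """Pure policy check; unknown patients deny (default deny)."""
    entry = ctx.state.acmsc["policies"].get(patient)
    if entry is None:
        return {"allow": False}
    return {"allow": policy_mod.evaluate_tree(entry["tree"], drug, role, purpose)}


def _find_record_for_drug(ctx: CallContext, patient: str, drug: str) -> dict | None:
    dsc = ctx.state.dsc
    for record_id in dsc["by_patient"].get(patient, []):
        record = dsc["records"][record_id]
        if any(rec["drug"] == drug for rec in record["recommendations"]):
            return record
    return None


@contract_function("ACMSC", "requestAccessTicket")
def request_access_ticket(ctx: CallContext, patient: str, drug: str, purpose: str):
    user = require_verified(ctx.state, ctx.sender)
    require(user["role"] == "data_requester", "NOT_VERIFIED",
            f"{ctx.sender} is not a verified data requester")
    get_user(ctx.state, patient)
    record = _find_record_for_drug(ctx, patient, drug)
    require(record is not None, "NO_METADATA_FOR_DRUG", f"{patient}/{drug}")
    # the requester's professional role comes from the registry, never
    # from the request itself
    role = user["sub_role"] or "physician"
    entry = ctx.state.acmsc["policies"].get(patient)
    allowed = entry is not None and policy_mod.evaluate_tree(
        entry["tree"], drug, role, purpose
    )
    require(allowed, "PERMISSION_DENIED", f"({drug}, {role}, {purpose})")
    ticket_id = _derived_id(ctx.tx_id, "ticket")
    ttl = ctx.config.get("ticket_ttl", 100)
    ticket = {
        "ticket_id": ticket_id,
        "requester": ctx.sender,
        "patient": patient,
        "drug": drug,
        "purpose": purpose,
        "role": role,
        "record_id": record["record_id"],
        "issued_at": ctx.now,
        "expires_at": ctx.now + ttl,
        "consumed": False,
    }
    ctx.state.acmsc["tickets"][ticket_id] = ticket
    ctx.emit("TicketIssued", {
        "ticket_id": ticket_id, "requester": ctx.sender, "patient": patient,
        "drug": drug, "purpose": purpose, "expires_at": ticket["expires_at"],
    })
    return {"ticket_id": ticket_id, "expires_at": ticket["expires_at"]}


@contract_function("ACMSC", "requestAccessToken")
def request_access_token(ctx: CallContext, ticket_id: str):
    ticket = ctx.state.acmsc["tickets"].get(ticket_id)
    require(ticket is not None, "TICKET_NOT_FOUND", ticket_id)
    require(ticket["requester"] == ctx.sender, "AUTH_NOT_TICKET_OWNER", ctx.sender)
    require(not ticket["consumed"], "TICKET_CONSUMED", ticket_id)
    require(ctx.now < ticket["expires_at"], "TICKET_EXPIRED",
            f"now={ctx.now} expires_at={ticket['expires_at']}")
    ticket["consumed"] = True
    token_id = _derived_id(ctx.tx_id, "token")
    ttl = ctx.config.get("token_ttl", 20)
    token = {
        "token_id": token_id,
        "ticket_id": ticket_id,
        "requester": ctx.sender,
        "patient": ticket["patient"],
        "drug": ticket["drug"],
        "purpose": ticket["purpose"],
        "record_id": ticket["record_id"],
        "issued_at": ctx.now,
        "expires_at": ctx.now + ttl,
        "used": False,
    }
    ctx.state.acmsc["tokens"][token_id] = token
    ctx.emit("TokenIssued", {
        "token_id": token_id, "ticket_id": ticket_id, "requester": ctx.sender,
        "patient": ticket["patient"], "expires_at": token["expires_at"],
    })
    return {"token_id": token_id, "expires_at": token["expires_at"]}


@contract_function("ACMSC", "requestData")
def request_data(ctx: CallContext, token_id: str):
    token = ctx.state.acmsc["tokens"].get(token_id)
    require(token is not None, "TOKEN_NOT_FOUND", token_id)
    require(token["requester"] == ctx.sender, "AUTH_NOT_TOKEN_OWNER", ctx.sender)
    require(not token["used"], "TOKEN_USED", token_id)
    require(ctx.now < token["expires_at"], "TOKEN_EXPIRED",
            f"now={ctx.now} expires_at={token['expires_at']}")
    token["used"] = True
    ctx.state.acmsc["eurls"][token_id] = {"status": "awaiting", "ciphertext": None,
                                          "recipient": None, "fetched": False}
    ctx.emit("DataRequested", {
        "token_id": token_id, "requester": ctx.sender, "patient": token["patient"],
        "record_id": token["record_id"], "drug": token["drug"],
    })
    return {"token_id": token_id, "forwarded_to_oracle": True}


@contract_function("ACMSC", "storeEncryptedUrl")
def store_encrypted_url(ctx: CallContext, token_id: str, ciphertext: str, recipient: str):
    require(ctx.sender == ctx.state.rsc["oracle"], "AUTH_ONLY_ORACLE", ctx.sender)
    token = ctx.state.acmsc["tokens"].get(token_id)
    require(token is not None, "TOKEN_NOT_FOUND", token_id)
    slot = ctx.state.acmsc["eurls"].get(token_id)
    require(slot is not None and token["used"], "EURL_NOT_READY",
            "token not awaiting fulfilment")
    require(slot["status"] == "awaiting", "EURL_ALREADY_STORED", token_id)
    slot.update(status="stored", ciphertext=ciphertext, recipient=recipient)
    ctx.emit("URLStored", {"token_id": token_id, "requester": token["requester"],
                           "patient": token["patient"]})
    return {"token_id": token_id}


@contract_function("ACMSC", "fetchEncryptedUrl")
def fetch_encrypted_url(ctx: CallContext, token_id: str):
    token = ctx.state.acmsc["tokens"].get(token_id)
    require(token is not None, "TOKEN_NOT_FOUND", token_id)
    require(token["requester"] == ctx.sender, "AUTH_NOT_TOKEN_OWNER", ctx.sender)
    slot = ctx.state.acmsc["eurls"].get(token_id)
    require(slot is not None and slot["status"] == "stored", "EURL_NOT_READY", token_id)
    require(not slot["fetched"], "EURL_ALREADY_FETCHED", token_id)
    slot["fetched"] = True
    ctx.emit("URLFetched", {"token_id": token_id, "requester": ctx.sender,
                            "patient": token["patient"]})
    return {"ciphertext": slot["ciphertext"], "recipient": slot["recipient"]}
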