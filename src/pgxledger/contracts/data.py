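"""Data contract (DSC): on-chain publication of non-identifying PGx
metadata.

What goes on-chain is a closed whitelist of fields — a list of drug/gene/
phenotype/recommendation codes, a content digest of the off-chain record
and an opaque storage pointer. Raw genotypes and direct identifiers are
rejected schema-level, so a scan of the whole chain can never surface
sensitive data. Updates bump a version counter; full history remains
reconstructable from the event log.
"""

from __future__ import annotations

from .. import vocab
from ..errors import Revert, require
from .base import CallContext, contract_function, get_user, require_verified

METADATA_FIELDS = frozenset(
    {"record_id", "patient", "creator", "recommendations", "data_hash", "pointer", "version"}
)
RECOMMENDATION_FIELDS = frozenset({"drug", "gene", "phenotype", "recommendation"})


def validate_recommendations(recommendations) -> None:
    if not isinstance(recommendations, list) or not recommendations:
        raise Revert("METADATA_INVALID", "recommendations must be a non-empty list")
    for rec in recommendations:
        if not isinstance(rec, dict):
            raise Revert("METADATA_INVALID", "recommendation entry must be a mapping")
        extra = set(rec) - RECOMMENDATION_FIELDS
        if extra:
            raise Revert("METADATA_INVALID", f"disallowed fields {sorted(extra)}")
        missing = RECOMMENDATION_FIELDS - set(rec)
        if missing:
            raise Revert("METADATA_INVALID", f"missing fields {sorted(missing)}")
        if rec["drug"] not in vocab.drugs():
            raise Revert("METADATA_INVALID", f"drug {rec['drug']!r} not in guideline table")
        if not all(isinstance(rec[k], str) for k in RECOMMENDATION_FIELDS):
            raise Revert("METADATA_INVALID", "recommendation fields must be strings")


def validate_metadata(metadata: dict) -> None:
    """Enforce the privacy whitelist: exactly the allowed fields, nothing
    free-form enough to carry genotypes or identifiers."""
    if not isinstance(metadata, dict):
        raise Revert("METADATA_INVALID", "metadata must be a mapping")
    extra = set(metadata) - METADATA_FIELDS
    if extra:
        raise Revert("METADATA_INVALID", f"disallowed fields {sorted(extra)}")
    missing = (METADATA_FIELDS - {"version"}) - set(metadata)
    if missing:
        raise Revert("METADATA_INVALID", f"missing fields {sorted(missing)}")
    validate_recommendations(metadata["recommendations"])
    data_hash = metadata["data_hash"]
    if not (isinstance(data_hash, str) and len(data_hash) == 64):
        raise Revert("METADATA_INVALID", "data_hash must be a 64-char hex digest")
    if not isinstance(metadata["pointer"], str) or not metadata["pointer"]:
        raise Revert("METADATA_INVALID", "pointer must be a non-empty string")
    if not isinstance(metadata["record_id"], str) or not metadata["record_id"]:
        raise Revert("METADATA_INVALID", "record_id must be a non-empty string")


@contract_function("DSC", "createData")
def create_data(ctx: CallContext, metadata: dict):
    require_verified(ctx.state, ctx.sender, None)
    user = get_user(ctx.state, ctx.sender)
    require(user["role"] == "data_creator", "AUTH_ONLY_CREATOR", ctx.sender)
    validate_metadata(metadata)
    patient = metadata["patient"]
    patient_user = get_user(ctx.state, patient)
    require(patient_user["role"] == "patient", "NOT_REGISTERED", f"{patient} is not a patient")
    require(metadata["creator"] == ctx.sender, "AUTH_ONLY_CREATOR",
            "creator field must equal the caller")
    dsc = ctx.state.dsc
    record_id = metadata["record_id"]
    require(record_id not in dsc["records"], "RECORD_EXISTS", record_id)
    if not ctx.config.get("allow_multiple_records_per_pair", False):
        for existing_id in dsc["by_patient"].get(patient, []):
            require(dsc["records"][existing_id]["creator"] != ctx.sender,
                    "RECORD_EXISTS", f"active record for ({patient}, {ctx.sender})")
    stored = dict(metadata, version=1)
    dsc["records"][record_id] = stored
    dsc["by_patient"].setdefault(patient, []).append(record_id)
    ctx.emit("DataCreated", {
        "record_id": record_id, "patient": patient, "creator": ctx.sender,
        "version": 1, "data_hash": stored["data_hash"], "pointer": stored["pointer"],
        "recommendations": stored["recommendations"],
    })
    return {"record_id": record_id, "version": 1}


@contract_function("DSC", "updateData")
def update_data(ctx: CallContext, record_id: str, recommendations: list,
                data_hash: str, pointer: str):
    require_verified(ctx.state, ctx.sender, None)
    dsc = ctx.state.dsc
    record = dsc["records"].get(record_id)
    require(record is not None, "RECORD_NOT_FOUND", record_id)
    require(record["creator"] == ctx.sender, "AUTH_NOT_RECORD_CREATOR", ctx.sender)
    validate_recommendations(recommendations)
    require(isinstance(data_hash, str) and len(data_hash) == 64,
            "METADATA_INVALID", "data_hash must be a 64-char hex digest")
    record["recommendations"] = recommendations
    record["data_hash"] = data_hash
    record["pointer"] = pointer
    record["version"] += 1
    ctx.emit("DataUpdated", {
        "record_id": record_id, "patient": record["patient"], "creator": ctx.sender,
        "version": record["version"], "data_hash": data_hash, "pointer": pointer,
        "recommendations": recommendations,
    })
    return {"record_id": record_id, "version": record["version"]}


@contract_function("DSC", "getMetadata", view=True)
def get_metadata(ctx: CallContext, record_id: str | None = None, patient: str | None = None):
    dsc = ctx.state.dsc
    if record_id is not None:
        record = dsc["records"].get(record_id)
        require(record is not None, "RECORD_NOT_FOUND", record_id)
        return record
    if patient is not None:
        ids = dsc["by_patient"].get(patient, [])
        require(bool(ids), "RECORD_NOT_FOUND", f"no records for {patient}")
        return [dsc["records"][i] for i in ids]
    raise Revert("BAD_ARGUMENTS", "need record_id or patient")
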