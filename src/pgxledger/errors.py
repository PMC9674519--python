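"""Error taxonomy: contract reverts, submission rejections, off-chain faults.

Revert reasons are a closed enumeration of short machine-checkable codes; a
reverted call leaves contract state untouched and records its reason in the
transaction receipt.
"""

from __future__ import annotations


class PgxLedgerError(Exception):
    """Base class for all simulator errors."""


# --- contract revert reasons (closed enumeration) -------------------------

REVERT_REASONS = frozenset(
    {
        # registration
        "AUTH_ONLY_OWNER",
        "ALREADY_REGISTERED",
        "ALREADY_INVITED",
        "NOT_INVITED",
        "ROLE_MISMATCH",
        "KEY_MISMATCH",
        "NOT_REGISTERED",
        "NOT_VERIFIED",
        # data contract
        "AUTH_ONLY_CREATOR",
        "AUTH_NOT_RECORD_CREATOR",
        "RECORD_NOT_FOUND",
        "RECORD_EXISTS",
        "METADATA_INVALID",
        # access-control manager
        "AUTH_ONLY_PATIENT",
        "BAD_TRIPLE",
        "PERMISSION_DENIED",
        "NO_METADATA_FOR_DRUG",
        "TICKET_NOT_FOUND",
        "AUTH_NOT_TICKET_OWNER",
        "TICKET_EXPIRED",
        "TICKET_CONSUMED",
        "TOKEN_NOT_FOUND",
        "AUTH_NOT_TOKEN_OWNER",
        "TOKEN_EXPIRED",
        "TOKEN_USED",
        "AUTH_ONLY_ORACLE",
        "EURL_NOT_READY",
        "EURL_ALREADY_STORED",
        "EURL_ALREADY_FETCHED",
        # dispatch
        "UNKNOWN_CONTRACT",
        "UNKNOWN_FUNCTION",
        "BAD_ARGUMENTS",
    }
)


class Revert(PgxLedgerError):
    """Raised inside a contract handler to abort the call.

    The executor catches it, rolls state back and records ``reason`` in the
    receipt; it never propagates to the caller of ``seal_block``.
    """

    def __init__(self, reason: str, detail: str = ""):
        if reason not in REVERT_REASONS:
            raise ValueError(f"unknown revert reason {reason!r}")
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


def require(condition: bool, reason: str, detail: str = "") -> None:
    if not condition:
        raise Revert(reason, detail)


# --- ledger-level submission rejections (never enter the pool) ------------


class SubmissionRejected(PgxLedgerError):
    def __init__(self, code: str, detail: str = ""):
        self.code = code
        super().__init__(f"{code}{': ' + detail if detail else ''}")


# codes: BAD_SIGNATURE, BAD_NONCE, DUPLICATE_TX, UNKNOWN_SENDER, NOT_VALIDATOR


class ChainIntegrityError(PgxLedgerError):
    """Chain fails verification (raised by replay on an invalid chain)."""


# --- crypto ---------------------------------------------------------------


class CryptoInputError(PgxLedgerError, ValueError):
    """Malformed key, signature or ciphertext structure."""


class DecryptionError(PgxLedgerError):
    """Authenticated decryption failed (wrong key or tampered ciphertext)."""


# --- off-chain store / oracle --------------------------------------------


class OffchainError(PgxLedgerError):
    code = "OFFCHAIN_ERROR"


class StoreConflict(OffchainError):
    code = "STORE_CONFLICT"


class IntegrityMismatch(OffchainError):
    code = "INTEGRITY_MISMATCH"


class PointerDangling(OffchainError):
    code = "POINTER_DANGLING"


class UrlUnknown(OffchainError):
    code = "URL_UNKNOWN"


class UrlExhausted(OffchainError):
    code = "URL_EXHAUSTED"


class UrlExpired(OffchainError):
    code = "URL_EXPIRED"


class GeneratorGap(PgxLedgerError):
    """A sampled phenotype has no row in the guideline table."""
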