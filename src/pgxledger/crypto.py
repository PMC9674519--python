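"""Keypairs, addresses, digests, signatures and sealed-box encryption.

Every actor in the simulated network holds one :class:`KeyPair` combining an
Ed25519 signing key and an X25519 encryption key, both derived from a single
32-byte seed. The 64-byte public key (signing half ‖ encryption half) is
what gets registered on-chain; its SHA-256 prefix is the actor's
pseudo-anonymous address. A real-world user may generate any number of
keypairs — the ledger never links two addresses to one person.

Pointer confidentiality uses a sealed-box construction: an ephemeral X25519
key agreement, HKDF-style key derivation, an HMAC-SHA256 counter-mode
keystream and an encrypt-then-MAC tag. Decryption with the wrong private
key fails the tag check and raises :class:`~pgxledger.errors.DecryptionError`
— never silent garbage.
"""

from __future__ import annotations

import hashlib
import hmac
import secrets
from dataclasses import dataclass
from typing import Any, Union

from ._curve25519 import (
    ed25519_public_key,
    ed25519_sign,
    ed25519_verify,
    x25519,
    x25519_public_key,
)
from .canonical import canonical_bytes
from .errors import CryptoInputError, DecryptionError

SeedLike = Union[int, bytes, None]

PUBLIC_KEY_LEN = 64  # 32-byte Ed25519 key ‖ 32-byte X25519 key
SIGNATURE_LEN = 64
ADDRESS_PREFIX = "0x"
ADDRESS_BYTES = 20
ADDRESS_LEN = len(ADDRESS_PREFIX) + 2 * ADDRESS_BYTES

_BOX_LABEL = b"pgxledger-box-v1"


def _seed_bytes(seed: SeedLike) -> bytes:
    if seed is None:
        return secrets.token_bytes(32)
    if isinstance(seed, int):
        if seed < 0:
            raise CryptoInputError("integer seed must be non-negative")
        return hashlib.sha256(b"pgxledger-seed:" + str(seed).encode()).digest()
    if isinstance(seed, (bytes, bytearray)):
        return hashlib.sha256(b"pgxledger-seed:" + bytes(seed)).digest()
    raise CryptoInputError(f"unsupported seed type {type(seed).__name__}")


@dataclass(frozen=True)
class KeyPair:
    """A signing (Ed25519) plus encryption (X25519) keypair.

    ``public_key`` and ``private_key`` are each 64 bytes: the signing half
    followed by the encryption half.
    """

    public_key: bytes
    private_key: bytes

    @property
    def public_hex(self) -> str:
        return self.public_key.hex()

    @property
    def address(self) -> str:
        return derive_address(self.public_key)


def generate_keypair(seed: SeedLike = None) -> KeyPair:
    """Generate a keypair; with a seed the result is reproducible."""
    root = _seed_bytes(seed)
    sign_secret = hashlib.sha256(b"sign" + root).digest()
    enc_secret = hashlib.sha256(b"enc" + root).digest()
    public = ed25519_public_key(sign_secret) + x25519_public_key(enc_secret)
    return KeyPair(public_key=public, private_key=sign_secret + enc_secret)


def _check_public(public_key: bytes) -> None:
    if not isinstance(public_key, (bytes, bytearray)) or len(public_key) != PUBLIC_KEY_LEN:
        raise CryptoInputError(
            f"public key must be {PUBLIC_KEY_LEN} bytes, got "
            f"{len(public_key) if isinstance(public_key, (bytes, bytearray)) else type(public_key).__name__}"
        )


def _check_private(private_key: bytes) -> None:
    if not isinstance(private_key, (bytes, bytearray)) or len(private_key) != 64:
        raise CryptoInputError("private key must be 64 bytes")


def derive_address(public_key: bytes) -> str:
    """Pseudo-anonymous account identifier: 0x + first 20 bytes of SHA-256."""
    _check_public(public_key)
    h = hashlib.sha256(bytes(public_key)).digest()
    return ADDRESS_PREFIX + h[:ADDRESS_BYTES].hex()


def is_address(value: Any) -> bool:
    return (
        isinstance(value, str)
        and len(value) == ADDRESS_LEN
        and value.startswith(ADDRESS_PREFIX)
        and all(c in "0123456789abcdef" for c in value[2:])
    )


@dataclass(frozen=True)
class Digest:
    """A content digest: hex value plus the algorithm that produced it."""

    value: str
    algorithm: str = "sha256"

    def __str__(self) -> str:
        return self.value


def content_hash(payload: bytes) -> Digest:
    """SHA-256 digest of a byte payload (empty payload allowed)."""
    if not isinstance(payload, (bytes, bytearray)):
        raise CryptoInputError("content_hash expects bytes")
    return Digest(hashlib.sha256(bytes(payload)).hexdigest())


def content_hash_document(document: Any) -> Digest:
    """Digest of a structured document via canonical JSON serialization."""
    return content_hash(canonical_bytes(document))


def sign(private_key: bytes, message: bytes) -> bytes:
    _check_private(private_key)
    if not isinstance(message, (bytes, bytearray)):
        raise CryptoInputError("message must be bytes")
    return ed25519_sign(bytes(private_key[:32]), bytes(message))


def verify(public_key: bytes, message: bytes, signature: bytes) -> bool:
    _check_public(public_key)
    if not isinstance(message, (bytes, bytearray)):
        raise CryptoInputError("message must be bytes")
    if not isinstance(signature, (bytes, bytearray)) or len(signature) != SIGNATURE_LEN:
        return False
    return ed25519_verify(bytes(public_key[:32]), bytes(message), bytes(signature))


# --- sealed boxes ---------------------------------------------------------


@dataclass(frozen=True)
class EncryptedPointer:
    """Ciphertext addressed to one recipient.

    Layout of ``ciphertext``: ephemeral X25519 public key (32) ‖ body ‖
    HMAC-SHA256 tag (32). Only the recipient's private key recovers the
    plaintext; any other key, or any bit flip, fails authentication.
    """

    ciphertext: bytes
    recipient: str  # Address

    @property
    def hex(self) -> str:
        return self.ciphertext.hex()


def _box_keys(shared: bytes, eph_pub: bytes, recipient_enc_pub: bytes) -> tuple[bytes, bytes]:
    master = hashlib.sha256(_BOX_LABEL + eph_pub + recipient_enc_pub + shared).digest()
    stream_key = hashlib.sha256(b"stream" + master).digest()
    mac_key = hashlib.sha256(b"mac" + master).digest()
    return stream_key, mac_key


def _keystream(key: bytes, length: int) -> bytes:
    out = bytearray()
    counter = 0
    while len(out) < length:
        out += hmac.new(key, counter.to_bytes(8, "big"), hashlib.sha256).digest()
        counter += 1
    return bytes(out[:length])


def encrypt_for(
    public_key: bytes, plaintext: bytes, *, ephemeral_seed: SeedLike = None
) -> EncryptedPointer:
    """Encrypt *plaintext* so only the holder of the matching private key
    can read it.

    ``ephemeral_seed`` fixes the ephemeral key for reproducible simulations;
    leave it ``None`` for a fresh random ephemeral key. No length padding is
    applied: ciphertext length equals plaintext length plus 64 bytes of
    framing, so ciphertexts reveal plaintext length exactly.
    """
    _check_public(public_key)
    if not isinstance(plaintext, (bytes, bytearray)) or len(plaintext) == 0:
        raise CryptoInputError("plaintext must be non-empty bytes")
    recipient_enc_pub = bytes(public_key[32:])
    eph_secret = _seed_bytes(ephemeral_seed)
    eph_pub = x25519_public_key(eph_secret)
    shared = x25519(eph_secret, recipient_enc_pub)
    stream_key, mac_key = _box_keys(shared, eph_pub, recipient_enc_pub)
    body = bytes(a ^ b for a, b in zip(plaintext, _keystream(stream_key, len(plaintext))))
    tag = hmac.new(mac_key, eph_pub + body, hashlib.sha256).digest()
    return EncryptedPointer(
        ciphertext=eph_pub + body + tag, recipient=derive_address(public_key)
    )


def decrypt_with(private_key: bytes, pointer: EncryptedPointer) -> bytes:
    """Open a sealed box; raises :class:`DecryptionError` on wrong key or
    tampering."""
    _check_private(private_key)
    ct = pointer.ciphertext if isinstance(pointer, EncryptedPointer) else bytes(pointer)
    if len(ct) < 65:
        raise CryptoInputError("ciphertext too short")
    eph_pub, body, tag = ct[:32], ct[32:-32], ct[-32:]
    enc_secret = bytes(private_key[32:])
    recipient_enc_pub = x25519_public_key(enc_secret)
    shared = x25519(enc_secret, eph_pub)
    stream_key, mac_key = _box_keys(shared, eph_pub, recipient_enc_pub)
    expected = hmac.new(mac_key, eph_pub + body, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expected):
        raise DecryptionError("authentication failed: wrong key or tampered ciphertext")
    return bytes(a ^ b for a, b in zip(body, _keystream(stream_key, len(body))))
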