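"""Curve25519 arithmetic: Ed25519 signatures and X25519 key agreement.

Self-contained implementations following RFC 8032 (EdDSA over edwards25519)
and RFC 7748 (X25519 Diffie-Hellman), validated against the RFC test
vectors in the test suite. Big-integer field arithmetic in CPython is
adequate for desk-scale simulation; this module makes no constant-time
claims and must not be used to protect real secrets.
"""

from __future__ import annotations

import hashlib

P = 2**255 - 19
L = 2**252 + 27742317777372353535851937790883648493  # group order
D = (-121665 * pow(121666, P - 2, P)) % P
I_SQRT = pow(2, (P - 1) // 4, P)  # sqrt(-1) mod p

# base point (extended homogeneous coordinates X, Y, Z, T)
_By = 4 * pow(5, P - 2, P) % P
_Bx_sq = (_By * _By - 1) * pow(D * _By * _By + 1, P - 2, P) % P


def _recover_x(y: int, sign: int) -> int | None:
    if y >= P:
        return None
    x2 = (y * y - 1) * pow(D * y * y + 1, P - 2, P) % P
    if x2 == 0:
        return None if sign else 0
    x = pow(x2, (P + 3) // 8, P)
    if (x * x - x2) % P != 0:
        x = x * I_SQRT % P
    if (x * x - x2) % P != 0:
        return None
    if x & 1 != sign:
        x = P - x
    return x


_Bx = _recover_x(_By, 0)
B = (_Bx, _By, 1, _Bx * _By % P)
IDENT = (0, 1, 1, 0)

Point = tuple[int, int, int, int]


def point_add(p: Point, q: Point) -> Point:
    x1, y1, z1, t1 = p
    x2, y2, z2, t2 = q
    a = (y1 - x1) * (y2 - x2) % P
    b = (y1 + x1) * (y2 + x2) % P
    c = 2 * t1 * t2 * D % P
    d = 2 * z1 * z2 % P
    e, f, g, h = b - a, d - c, d + c, b + a
    return (e * f % P, g * h % P, f * g % P, e * h % P)


def point_mul(s: int, p: Point) -> Point:
    q = IDENT
    while s > 0:
        if s & 1:
            q = point_add(q, p)
        p = point_add(p, p)
        s >>= 1
    return q


# fixed-window table for the base point: 64 windows of 4 bits
_BASE_WINDOWS: list[list[Point]] = []


def _build_base_table() -> None:
    p = B
    for _ in range(64):
        row = [IDENT]
        for i in range(15):
            row.append(point_add(row[i], p))
        _BASE_WINDOWS.append(row)
        for _ in range(4):
            p = point_add(p, p)


_build_base_table()


def base_mul(s: int) -> Point:
    q = IDENT
    for w in range(64):
        nib = (s >> (4 * w)) & 0xF
        if nib:
            q = point_add(q, _BASE_WINDOWS[w][nib])
    return q


def point_equal(p: Point, q: Point) -> bool:
    # cross-multiply to compare projective coordinates
    return (p[0] * q[2] - q[0] * p[2]) % P == 0 and (
        p[1] * q[2] - q[1] * p[2]
    ) % P == 0


def point_compress(p: Point) -> bytes:
    zinv = pow(p[2], P - 2, P)
    x = p[0] * zinv % P
    y = p[1] * zinv % P
    return ((y | ((x & 1) << 255))).to_bytes(32, "little")


def point_decompress(s: bytes) -> Point | None:
    if len(s) != 32:
        return None
    y = int.from_bytes(s, "little")
    sign = y >> 255
    y &= (1 << 255) - 1
    x = _recover_x(y, sign)
    if x is None:
        return None
    return (x, y, 1, x * y % P)


def _sha512(*parts: bytes) -> bytes:
    h = hashlib.sha512()
    for part in parts:
        h.update(part)
    return h.digest()


def _clamp_scalar(a: bytes) -> int:
    s = int.from_bytes(a, "little")
    s &= (1 << 254) - 8
    s |= 1 << 254
    return s


# --- Ed25519 (RFC 8032) ---------------------------------------------------


def ed25519_public_key(secret: bytes) -> bytes:
    if len(secret) != 32:
        raise ValueError("Ed25519 secret must be 32 bytes")
    h = _sha512(secret)
    a = _clamp_scalar(h[:32])
    return point_compress(base_mul(a))


def ed25519_sign(secret: bytes, message: bytes) -> bytes:
    h = _sha512(secret)
    a = _clamp_scalar(h[:32])
    prefix = h[32:]
    pub = point_compress(base_mul(a))
    r = int.from_bytes(_sha512(prefix, message), "little") % L
    r_enc = point_compress(base_mul(r))
    k = int.from_bytes(_sha512(r_enc, pub, message), "little") % L
    s = (r + k * a) % L
    return r_enc + s.to_bytes(32, "little")


def ed25519_verify(public: bytes, message: bytes, signature: bytes) -> bool:
    if len(public) != 32 or len(signature) != 64:
        return False
    a_point = point_decompress(public)
    r_point = point_decompress(signature[:32])
    if a_point is None or r_point is None:
        return False
    s = int.from_bytes(signature[32:], "little")
    if s >= L:
        return False
    k = int.from_bytes(_sha512(signature[:32], public, message), "little") % L
    return point_equal(base_mul(s), point_add(r_point, point_mul(k, a_point)))


# --- X25519 (RFC 7748) ----------------------------------------------------

_A24 = 121665


def _x25519_ladder(k: int, u: int) -> int:
    x1 = u
    x2, z2 = 1, 0
    x3, z3 = u, 1
    swap = 0
    for t in reversed(range(255)):
        k_t = (k >> t) & 1
        swap ^= k_t
        if swap:
            x2, x3 = x3, x2
            z2, z3 = z3, z2
        swap = k_t
        a = (x2 + z2) % P
        aa = a * a % P
        b = (x2 - z2) % P
        bb = b * b % P
        e = (aa - bb) % P
        c = (x3 + z3) % P
        d = (x3 - z3) % P
        da = d * a % P
        cb = c * b % P
        x3 = (da + cb) % P
        x3 = x3 * x3 % P
        z3 = (da - cb) % P
        z3 = x1 * z3 * z3 % P
        x2 = aa * bb % P
        z2 = e * (aa + _A24 * e) % P
    if swap:
        x2, x3 = x3, x2
        z2, z3 = z3, z2
    return x2 * pow(z2, P - 2, P) % P


def x25519(scalar: bytes, u_point: bytes) -> bytes:
    if len(scalar) != 32 or len(u_point) != 32:
        raise ValueError("X25519 inputs must be 32 bytes")
    k = _clamp_scalar(scalar)
    u = int.from_bytes(u_point, "little") & ((1 << 255) - 1)
    return _x25519_ladder(k, u).to_bytes(32, "little")


X25519_BASEPOINT = (9).to_bytes(32, "little")


def x25519_public_key(scalar: bytes) -> bytes:
    return x25519(scalar, X25519_BASEPOINT)
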