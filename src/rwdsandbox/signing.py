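"""Detached digital signatures (Ed25519, RFC 8032).

The dual-signature workflow needs deterministic asymmetric signatures with
small keys that both the sandbox and external users can exchange as PEM
files.  Ed25519 fits: 32-byte keys, 64-byte signatures, no signing-time
randomness.  This is a self-contained implementation over the twisted
Edwards curve edwards25519 using extended homogeneous coordinates; it is
validated against the published RFC 8032 test vectors in the test suite.

Keys serialise to standard PEM: PKCS#8 for private keys and
SubjectPublicKeyInfo for public keys (the DER framing for Ed25519 is a fixed
prefix around the raw 32 bytes).
"""

from __future__ import annotations

import base64
import hashlib
import secrets

# -- field and curve parameters (edwards25519) ---------------------------

_P = 2**255 - 19
_L = 2**252 + 27742317777372353535851937790883648493
_D = (-121665 * pow(121666, _P - 2, _P)) % _P
_I = pow(2, (_P - 1) // 4, _P)  # sqrt(-1)

_Bx = 15112221349535400772501151409588531511454012693041857206046113283949847762202
_By = 46316835694926478169428394003475163141307993866256225615783033603165251855960
_B = (_Bx % _P, _By % _P, 1, (_Bx * _By) % _P)
_IDENT = (0, 1, 1, 0)


def _point_add(p, q):
    x1, y1, z1, t1 = p
    x2, y2, z2, t2 = q
    a = ((y1 - x1) * (y2 - x2)) % _P
    b = ((y1 + x1) * (y2 + x2)) % _P
    c = (2 * t1 * t2 * _D) % _P
    d = (2 * z1 * z2) % _P
    e, f, g, h = b - a, d - c, d + c, b + a
    return (e * f % _P, g * h % _P, f * g % _P, e * h % _P)


def _scalar_mult(s, p):
    q = _IDENT
    while s > 0:
        if s & 1:
            q = _point_add(q, p)
        p = _point_add(p, p)
        s >>= 1
    return q


def _point_compress(p) -> bytes:
    x, y, z, _ = p
    zinv = pow(z, _P - 2, _P)
    x, y = x * zinv % _P, y * zinv % _P
    return int.to_bytes(y | ((x & 1) << 255), 32, "little")


def _recover_x(y, sign):
    if y >= _P:
        return None
    x2 = (y * y - 1) * pow(_D * y * y + 1, _P - 2, _P) % _P
    if x2 == 0:
        return None if sign else 0
    x = pow(x2, (_P + 3) // 8, _P)
    if (x * x - x2) % _P != 0:
        x = x * _I % _P
    if (x * x - x2) % _P != 0:
        return None
    if (x & 1) != sign:
        x = _P - x
    return x


def _point_decompress(s: bytes):
    if len(s) != 32:
        return None
    y = int.from_bytes(s, "little")
    sign = y >> 255
    y &= (1 << 255) - 1
    x = _recover_x(y, sign)
    if x is None:
        return None
    return (x, y, 1, x * y % _P)


def _point_equal(p, q) -> bool:
    x1, y1, z1, _ = p
    x2, y2, z2, _ = q
    return (x1 * z2 - x2 * z1) % _P == 0 and (y1 * z2 - y2 * z1) % _P == 0


def _sha512_int(*parts: bytes) -> int:
    return int.from_bytes(hashlib.sha512(b"".join(parts)).digest(), "little")


def _secret_expand(seed: bytes):
    h = hashlib.sha512(seed).digest()
    a = int.from_bytes(h[:32], "little")
    a &= (1 << 254) - 8
    a |= 1 << 254
    return a, h[32:]


# -- public API -----------------------------------------------------------

def generate_keypair(seed: bytes | None = None) -> tuple[bytes, bytes]:
    """Return (private_seed, public_key), each 32 bytes.

    ``seed`` allows deterministic key derivation in tests and fixtures;
    omit it for a cryptographically random key.
    """
    if seed is None:
        seed = secrets.token_bytes(32)
    if len(seed) != 32:
        raise ValueError("seed must be exactly 32 bytes")
    a, _ = _secret_expand(seed)
    return seed, _point_compress(_scalar_mult(a, _B))


def public_key(private_seed: bytes) -> bytes:
    a, _ = _secret_expand(private_seed)
    return _point_compress(_scalar_mult(a, _B))


def sign(private_seed: bytes, message: bytes) -> bytes:
    """Detached 64-byte signature over the exact message bytes."""
    a, prefix = _secret_expand(private_seed)
    pub = _point_compress(_scalar_mult(a, _B))
    r = _sha512_int(prefix, message) % _L
    big_r = _point_compress(_scalar_mult(r, _B))
    h = _sha512_int(big_r, pub, message) % _L
    s = (r + h * a) % _L
    return big_r + int.to_bytes(s, 32, "little")


def verify(pub: bytes, message: bytes, signature: bytes) -> bool:
    """True iff ``signature`` is a valid signature of ``message`` under ``pub``."""
    if len(pub) != 32 or len(signature) != 64:
        return False
    a = _point_decompress(pub)
    if a is None:
        return False
    big_r = _point_decompress(signature[:32])
    if big_r is None:
        return False
    s = int.from_bytes(signature[32:], "little")
    if s >= _L:
        return False
    h = _sha512_int(signature[:32], pub, message) % _L
    lhs = _scalar_mult(s, _B)
    rhs = _point_add(big_r, _scalar_mult(h, a))
    return _point_equal(lhs, rhs)


# -- PEM encoding ---------------------------------------------------------
# Fixed DER framing for Ed25519 (RFC 8410): the raw 32-byte key wrapped in a
# constant prefix.

_PKCS8_PREFIX = bytes.fromhex("302e020100300506032b657004220420")
_SPKI_PREFIX = bytes.fromhex("302a300506032b6570032100")


def _pem(tag: str, der: bytes) -> str:
    b64 = base64.b64encode(der).decode()
    lines = [b64[i : i + 64] for i in range(0, len(b64), 64)]
    return f"-----BEGIN {tag}-----\n" + "\n".join(lines) + f"\n-----END {tag}-----\n"


def _unpem(tag: str, pem: str) -> bytes:
    begin, end = f"-----BEGIN {tag}-----", f"-----END {tag}-----"
    if begin not in pem or end not in pem:
        raise ValueError(f"not a {tag} PEM")
    body = pem.split(begin, 1)[1].split(end, 1)[0]
    return base64.b64decode("".join(body.split()))


def private_key_to_pem(private_seed: bytes) -> str:
    return _pem("PRIVATE KEY", _PKCS8_PREFIX + private_seed)


def private_key_from_pem(pem: str) -> bytes:
    der = _unpem("PRIVATE KEY", pem)
    if not der.startswith(_PKCS8_PREFIX) or len(der) != len(_PKCS8_PREFIX) + 32:
        raise ValueError("not an Ed25519 PKCS#8 key")
    return der[len(_PKCS8_PREFIX):]


def public_key_to_pem(pub: bytes) -> str:
    return _pem("PUBLIC KEY", _SPKI_PREFIX + pub)


def public_key_from_pem(pem: str) -> bytes:
    der = _unpem("PUBLIC KEY", pem)
    if not der.startswith(_SPKI_PREFIX) or len(der) != len(_SPKI_PREFIX) + 32:
        raise ValueError("not an Ed25519 SubjectPublicKeyInfo key")
    return der[len(_SPKI_PREFIX):]
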