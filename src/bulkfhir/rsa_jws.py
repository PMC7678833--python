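"""RSA signatures and JSON Web Signature compact serialization.

Implements exactly the primitives SMART Backend Services authorization
needs: RSA key generation (Miller–Rabin primes, ≥2048-bit modulus),
RSASSA-PKCS1-v1_5 signing/verification with SHA-384 (JWS ``RS384``), a
PEM/DER codec for PKCS#8 private keys and SubjectPublicKeyInfo public keys,
and JWT compact serialization.  Scope is deliberately narrow — one
algorithm, deterministic padding, no encryption.
"""
from __future__ import annotations

import base64
import binascii
import hashlib
import json
import secrets
from dataclasses import dataclass
from random import Random
from typing import Callable, Mapping, Optional

__all__ = [
    "RsaPublicKey",
    "RsaPrivateKey",
    "generate_keypair",
    "sign_jwt",
    "verify_jwt",
    "decode_jwt_unverified",
    "JwsError",
]

# ---------------------------------------------------------------------------
# primes

_SMALL_PRIMES = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53,
                 59, 61, 67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113]


def _is_probable_prime(n: int, rounds: int = 40, randbelow: Callable[[int], int] = secrets.randbelow) -> bool:
    if n < 2:
        return False
    for p in _SMALL_PRIMES:
        if n % p == 0:
            return n == p
    d, r = n - 1, 0
    while d % 2 == 0:
        d //= 2
        r += 1
    for _ in range(rounds):
        a = 2 + randbelow(n - 3)
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(r - 1):
            x = pow(x, 2, n)
            if x == n - 1:
                break
        else:
            return False
    return True


def _random_prime(bits: int, getrandbits: Callable[[int], int]) -> int:
    while True:
        candidate = getrandbits(bits) | (1 << (bits - 1)) | (1 << (bits - 2)) | 1
        if _is_probable_prime(candidate):
            return candidate


# ---------------------------------------------------------------------------
# keys

_E = 65537


@dataclass(frozen=True)
class RsaPublicKey:
    n: int
    e: int = _E

    @property
    def byte_length(self) -> int:
        return (self.n.bit_length() + 7) // 8

    def to_pem(self) -> str:
        return _pem_encode("PUBLIC KEY", _spki_der(self))

    @classmethod
    def from_pem(cls, pem: str) -> "RsaPublicKey":
        label, der = _pem_decode(pem)
        if label != "PUBLIC KEY":
            raise ValueError(f"expected PUBLIC KEY PEM, got {label}")
        return _spki_parse(der)


@dataclass(frozen=True)
class RsaPrivateKey:
    n: int
    e: int
    d: int
    p: int
    q: int

    @property
    def public_key(self) -> RsaPublicKey:
        return RsaPublicKey(self.n, self.e)

    @property
    def byte_length(self) -> int:
        return (self.n.bit_length() + 7) // 8

    def to_pem(self) -> str:
        return _pem_encode("PRIVATE KEY", _pkcs8_der(self))

    @classmethod
    def from_pem(cls, pem: str) -> "RsaPrivateKey":
        label, der = _pem_decode(pem)
        if label == "PRIVATE KEY":
            return _pkcs8_parse(der)
        if label == "RSA PRIVATE KEY":
            return _rsa_private_parse(der)
        raise ValueError(f"expected PRIVATE KEY PEM, got {label}")


def generate_keypair(bits: int = 2048, rng: Optional[Random] = None) -> RsaPrivateKey:
    """Generate an RSA keypair with modulus of ``bits`` bits (min 2048).

    Pass a seeded ``rng`` only to obtain reproducible keys for fixtures;
    default entropy comes from the OS.
    """
    if bits < 2048:
        raise ValueError("modulus must be at least 2048 bits")
    getrandbits = rng.getrandbits if rng is not None else secrets.randbits
    while True:
        p = _random_prime(bits // 2, getrandbits)
        q = _random_prime(bits - bits // 2, getrandbits)
        if p == q:
            continue
        n = p * q
        phi = (p - 1) * (q - 1)
        if n.bit_length() != bits or phi % _E == 0:
            continue
        d = pow(_E, -1, phi)
        return RsaPrivateKey(n=n, e=_E, d=d, p=p, q=q)


# ---------------------------------------------------------------------------
# RSASSA-PKCS1-v1_5 with SHA-384

# DigestInfo prefix for SHA-384 (DER-encoded AlgorithmIdentifier + OCTET STRING tag)
_SHA384_PREFIX = bytes.fromhex("3041300d060960864801650304020205000430")


def _emsa_encode(message: bytes, em_len: int) -> bytes:
    t = _SHA384_PREFIX + hashlib.sha384(message).digest()
    if em_len < len(t) + 11:
        raise ValueError("RSA modulus too small for SHA-384 signature")
    return b"\x00\x01" + b"\xff" * (em_len - len(t) - 3) + b"\x00" + t


def rsa_sign(key: RsaPrivateKey, message: bytes) -> bytes:
    em = int.from_bytes(_emsa_encode(message, key.byte_length), "big")
    # CRT speeds the private-key exponentiation ~4x
    dp = key.d % (key.p - 1)
    dq = key.d % (key.q - 1)
    qinv = pow(key.q, -1, key.p)
    m1 = pow(em, dp, key.p)
    m2 = pow(em, dq, key.q)
    h = (qinv * (m1 - m2)) % key.p
    s = m2 + h * key.q
    return s.to_bytes(key.byte_length, "big")


def rsa_verify(key: RsaPublicKey, message: bytes, signature: bytes) -> bool:
    if len(signature) != key.byte_length:
        return False
    s = int.from_bytes(signature, "big")
    if s >= key.n:
        return False
    em = pow(s, key.e, key.n).to_bytes(key.byte_length, "big")
    return secrets.compare_digest(em, _emsa_encode(message, key.byte_length))


# ---------------------------------------------------------------------------
# JWS compact serialization (RS384)

class JwsError(ValueError):
    """Malformed or unverifiable JWT."""


def _b64url(data: bytes) -> str:
    return base64.urlsafe_b64encode(data).rstrip(b"=").decode("ascii")


def _b64url_decode(text: str) -> bytes:
    pad = "=" * (-len(text) % 4)
    try:
        return base64.urlsafe_b64decode(text + pad)
    except (binascii.Error, ValueError) as exc:
        raise JwsError(f"invalid base64url segment: {exc}") from exc


def sign_jwt(claims: Mapping[str, object], key: RsaPrivateKey,
             headers: Optional[Mapping[str, object]] = None) -> str:
    """Serialize and sign claims as a compact RS384 JWT."""
    header = {"alg": "RS384", "typ": "JWT"}
    if headers:
        header.update(headers)
    signing_input = (
        _b64url(json.dumps(header, separators=(",", ":")).encode())
        + "."
        + _b64url(json.dumps(dict(claims), separators=(",", ":")).encode())
    )
    signature = rsa_sign(key, signing_input.encode("ascii"))
    return signing_input + "." + _b64url(signature)


def _split(token: str) -> tuple[str, str, str]:
    parts = token.split(".")
    if len(parts) != 3:
        raise JwsError("compact JWT must have three dot-separated segments")
    return parts[0], parts[1], parts[2]


def decode_jwt_unverified(token: str) -> tuple[dict, dict]:
    """Return (header, claims) without checking the signature."""
    h, c, _ = _split(token)
    try:
        header = json.loads(_b64url_decode(h))
        claims = json.loads(_b64url_decode(c))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise JwsError(f"JWT segment is not valid JSON: {exc}") from exc
    if not isinstance(header, dict) or not isinstance(claims, dict):
        raise JwsError("JWT header and claims must be JSON objects")
    return header, claims


def verify_jwt(token: str, key: RsaPublicKey) -> dict:
    """Verify an RS384 signature and return the claims.

    Raises :class:`JwsError` on any structural or signature failure.
    """
    h, c, s = _split(token)
    header, claims = decode_jwt_unverified(token)
    if header.get("alg") != "RS384":
        raise JwsError(f"unsupported JWS algorithm {header.get('alg')!r}")
    if not rsa_verify(key, (h + "." + c).encode("ascii"), _b64url_decode(s)):
        raise JwsError("signature verification failed")
    return claims


# ---------------------------------------------------------------------------
# minimal DER / PEM codec

_RSA_OID = bytes.fromhex("2a864886f70d010101")  # 1.2.840.113549.1.1.1


def _der_len(length: int) -> bytes:
    if length < 0x80:
        return bytes([length])
    body = length.to_bytes((length.bit_length() + 7) // 8, "big")
    return bytes([0x80 | len(body)]) + body


def _der_tlv(tag: int, body: bytes) -> bytes:
    return bytes([tag]) + _der_len(len(body)) + body


def _der_int(value: int) -> bytes:
    body = value.to_bytes((value.bit_length() + 8) // 8 or 1, "big")
    return _der_tlv(0x02, body)


def _der_seq(*parts: bytes) -> bytes:
    return _der_tlv(0x30, b"".join(parts))


class _DerReader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def read_tlv(self, expected_tag: Optional[int] = None) -> tuple[int, bytes]:
        if self.pos >= len(self.data):
            raise ValueError("truncated DER")
        tag = self.data[self.pos]
        self.pos += 1
        first = self.data[self.pos]
        self.pos += 1
        if first < 0x80:
            length = first
        else:
            nbytes = first & 0x7F
            length = int.from_bytes(self.data[self.pos:self.pos + nbytes], "big")
            self.pos += nbytes
        body = self.data[self.pos:self.pos + length]
        if len(body) != length:
            raise ValueError("truncated DER body")
        self.pos += length
        if expected_tag is not None and tag != expected_tag:
            raise ValueError(f"expected DER tag 0x{expected_tag:02x}, got 0x{tag:02x}")
        return tag, body

    def read_int(self) -> int:
        _, body = self.read_tlv(0x02)
        return int.from_bytes(body, "big")


def _rsa_alg_identifier() -> bytes:
    return _der_seq(_der_tlv(0x06, _RSA_OID), _der_tlv(0x05, b""))


def _rsa_private_der(key: RsaPrivateKey) -> bytes:
    dp = key.d % (key.p - 1)
    dq = key.d % (key.q - 1)
    qinv = pow(key.q, -1, key.p)
    return _der_seq(
        _der_int(0), _der_int(key.n), _der_int(key.e), _der_int(key.d),
        _der_int(key.p), _der_int(key.q), _der_int(dp), _der_int(dq), _der_int(qinv),
    )


def _pkcs8_der(key: RsaPrivateKey) -> bytes:
    return _der_seq(
        _der_int(0),
        _rsa_alg_identifier(),
        _der_tlv(0x04, _rsa_private_der(key)),
    )


def _rsa_private_parse(der: bytes) -> RsaPrivateKey:
    outer = _DerReader(der)
    _, body = outer.read_tlv(0x30)
    r = _DerReader(body)
    version = r.read_int()
    if version != 0:
        raise ValueError("unsupported RSAPrivateKey version")
    n, e, d, p, q = (r.read_int() for _ in range(5))
    return RsaPrivateKey(n=n, e=e, d=d, p=p, q=q)


def _pkcs8_parse(der: bytes) -> RsaPrivateKey:
    outer = _DerReader(der)
    _, body = outer.read_tlv(0x30)
    r = _DerReader(body)
    r.read_int()  # version
    _, alg = r.read_tlv(0x30)
    alg_r = _DerReader(alg)
    _, oid = alg_r.read_tlv(0x06)
    if oid != _RSA_OID:
        raise ValueError("not an RSA private key")
    _, inner = r.read_tlv(0x04)
    return _rsa_private_parse(inner)


def _spki_der(key: RsaPublicKey) -> bytes:
    pub = _der_seq(_der_int(key.n), _der_int(key.e))
    return _der_seq(_rsa_alg_identifier(), _der_tlv(0x03, b"\x00" + pub))


def _spki_parse(der: bytes) -> RsaPublicKey:
    outer = _DerReader(der)
    _, body = outer.read_tlv(0x30)
    r = _DerReader(body)
    _, alg = r.read_tlv(0x30)
    alg_r = _DerReader(alg)
    _, oid = alg_r.read_tlv(0x06)
    if oid != _RSA_OID:
        raise ValueError("not an RSA public key")
    _, bitstring = r.read_tlv(0x03)
    if not bitstring or bitstring[0] != 0:
        raise ValueError("unsupported BIT STRING padding")
    inner = _DerReader(bitstring[1:])
    _, pub = inner.read_tlv(0x30)
    pr = _DerReader(pub)
    n = pr.read_int()
    e = pr.read_int()
    return RsaPublicKey(n=n, e=e)


def _pem_encode(label: str, der: bytes) -> str:
    b64 = base64.b64encode(der).decode("ascii")
    lines = [b64[i:i + 64] for i in range(0, len(b64), 64)]
    return f"-----BEGIN {label}-----\n" + "\n".join(lines) + f"\n-----END {label}-----\n"


def _pem_decode(pem: str) -> tuple[str, bytes]:
    lines = [ln.strip() for ln in pem.strip().splitlines() if ln.strip()]
    if len(lines) < 2 or not lines[0].startswith("-----BEGIN ") or not lines[-1].startswith("-----END "):
        raise ValueError("not a PEM document")
    label = lines[0][len("-----BEGIN "):].rstrip("-").strip()
    try:
        der = base64.b64decode("".join(lines[1:-1]), validate=True)
    except (binascii.Error, ValueError) as exc:
        raise ValueError(f"invalid PEM base64: {exc}") from exc
    return label, der
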