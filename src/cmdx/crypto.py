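"""Field-level encryption for sensitive personal data.

Patient-identifying form fields are protected with authenticated symmetric
encryption: AES-256 (Rijndael with a 128-bit block) in CTR mode, a key
derived from a passphrase by PBKDF2-HMAC-SHA256, and an HMAC-SHA256 tag over
the ciphertext (encrypt-then-MAC) so tampering and wrong passphrases are
detected rather than yielding garbage.  The AES core is implemented here
from the standard Rijndael construction and is checked against the published
known-answer vector in the test suite.

The envelope is a small versioned container (scheme tag, KDF iteration
count, salt, nonce, ciphertext+tag) with a stable text form that embeds in
XML attributes.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import os
from dataclasses import dataclass

SCHEME_TAG = "cmdx-aes256ctr-hmac-v1"
DEFAULT_KDF_ITERATIONS = 200_000
_SALT_LEN = 16
_NONCE_LEN = 16
_TAG_LEN = 32


class AuthenticationError(ValueError):
    """Wrong passphrase or tampered ciphertext."""


# ---------------------------------------------------------------------------
# Rijndael (AES) primitives.  S-box built from the standard GF(2^8)
# multiplicative-inverse + affine-map construction.

def _build_sbox() -> list[int]:
    p, q = 1, 1
    sbox = [0] * 256
    # iterate the generator 3 over GF(2^8) to enumerate inverses
    while True:
        # p := p * 3 in GF(2^8)
        p = p ^ ((p << 1) & 0xFF) ^ (0x1B if p & 0x80 else 0)
        # q := q / 3
        q ^= (q << 1) & 0xFF
        q ^= (q << 2) & 0xFF
        q ^= (q << 4) & 0xFF
        if q & 0x80:
            q ^= 0x09
        # affine transformation of the inverse
        x = q ^ ((q << 1) | (q >> 7)) ^ ((q << 2) | (q >> 6)) ^ ((q << 3) | (q >> 5)) ^ ((q << 4) | (q >> 4))
        sbox[p] = (x ^ 0x63) & 0xFF
        if p == 1:
            break
    sbox[0] = 0x63
    return sbox


_SBOX = _build_sbox()
_RCON = [0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36, 0x6C]


def _xtime(a: int) -> int:
    a <<= 1
    return (a ^ 0x1B) & 0xFF if a & 0x100 else a


def _expand_key_256(key: bytes) -> list[list[int]]:
    """AES-256 key schedule: 15 round keys of 16 bytes each."""
    assert len(key) == 32
    words = [list(key[i : i + 4]) for i in range(0, 32, 4)]
    for i in range(8, 60):
        temp = list(words[i - 1])
        if i % 8 == 0:
            temp = temp[1:] + temp[:1]
            temp = [_SBOX[b] for b in temp]
            temp[0] ^= _RCON[i // 8 - 1]
        elif i % 8 == 4:
            temp = [_SBOX[b] for b in temp]
        words.append([a ^ b for a, b in zip(words[i - 8], temp)])
    return [sum(words[4 * r : 4 * r + 4], []) for r in range(15)]


def _encrypt_block(block: bytes, round_keys: list[list[int]]) -> bytes:
    # state kept column-major as a flat 16-list, matching key-schedule layout
    s = [b ^ k for b, k in zip(block, round_keys[0])]
    for rnd in range(1, 15):
        s = [_SBOX[b] for b in s]
        # ShiftRows on column-major flat layout: row r rotates left by r
        s = [s[(i + 4 * (i % 4)) % 16] for i in range(16)]
        if rnd < 14:
            t = []
            for c in range(0, 16, 4):
                a0, a1, a2, a3 = s[c : c + 4]
                t += [
                    _xtime(a0) ^ _xtime(a1) ^ a1 ^ a2 ^ a3,
                    a0 ^ _xtime(a1) ^ _xtime(a2) ^ a2 ^ a3,
                    a0 ^ a1 ^ _xtime(a2) ^ _xtime(a3) ^ a3,
                    _xtime(a0) ^ a0 ^ a1 ^ a2 ^ _xtime(a3),
                ]
            s = t
        s = [b ^ k for b, k in zip(s, round_keys[rnd])]
    return bytes(s)


def _ctr_keystream(key: bytes, nonce: bytes, length: int) -> bytes:
    round_keys = _expand_key_256(key)
    counter = int.from_bytes(nonce, "big")
    out = bytearray()
    for _ in range((length + 15) // 16):
        out += _encrypt_block(counter.to_bytes(16, "big"), round_keys)
        counter = (counter + 1) % (1 << 128)
    return bytes(out[:length])


# ---------------------------------------------------------------------------
# Envelope layer.


@dataclass(frozen=True)
class KeyMaterial:
    """Derived keys bound to one salt; reusable across fields of one save."""

    salt: bytes
    kdf_iterations: int
    enc_key: bytes
    mac_key: bytes


def derive_keys(
    passphrase: str, salt: bytes | None = None, kdf_iterations: int = DEFAULT_KDF_ITERATIONS
) -> KeyMaterial:
    if not passphrase:
        raise ValueError("passphrase must be non-empty")
    if salt is None:
        salt = os.urandom(_SALT_LEN)
    okm = hashlib.pbkdf2_hmac("sha256", passphrase.encode("utf-8"), salt, kdf_iterations, dklen=64)
    return KeyMaterial(salt, kdf_iterations, okm[:32], okm[32:])


@dataclass(frozen=True)
class CipherEnvelope:
    """One encrypted field: scheme tag, KDF parameters and ciphertext+tag."""

    ciphertext: bytes  # AES-CTR ciphertext followed by the 32-byte HMAC tag
    salt: bytes
    iv: bytes
    kdf_iterations: int = DEFAULT_KDF_ITERATIONS
    scheme_tag: str = SCHEME_TAG

    def to_text(self) -> str:
        b64 = lambda b: base64.b64encode(b).decode("ascii")
        return "$".join(
            [self.scheme_tag, str(self.kdf_iterations), b64(self.salt), b64(self.iv), b64(self.ciphertext)]
        )

    @classmethod
    def from_text(cls, text: str) -> "CipherEnvelope":
        parts = text.split("$")
        if len(parts) != 5 or parts[0] != SCHEME_TAG:
            raise ValueError(f"not a recognised cipher envelope: {text[:40]!r}")
        b64 = base64.b64decode
        return cls(
            scheme_tag=parts[0],
            kdf_iterations=int(parts[1]),
            salt=b64(parts[2]),
            iv=b64(parts[3]),
            ciphertext=b64(parts[4]),
        )

    @classmethod
    def is_envelope_text(cls, text: str) -> bool:
        return text.startswith(SCHEME_TAG + "$")


def _mac(mac_key: bytes, salt: bytes, iv: bytes, ct: bytes) -> bytes:
    msg = SCHEME_TAG.encode("ascii") + b"\x00" + salt + iv + ct
    return hmac.new(mac_key, msg, hashlib.sha256).digest()


def encrypt_field(
    plaintext: str,
    passphrase: str | None = None,
    *,
    keys: KeyMaterial | None = None,
    kdf_iterations: int = DEFAULT_KDF_ITERATIONS,
) -> CipherEnvelope:
    """Encrypt one UTF-8 field with a fresh salt and nonce.

    Pass precomputed ``keys`` to amortise the KDF over several fields of one
    document; the envelope then reuses that salt but always a fresh nonce.
    """
    if keys is None:
        if passphrase is None:
            raise ValueError("either a passphrase or precomputed keys are required")
        keys = derive_keys(passphrase, kdf_iterations=kdf_iterations)
    iv = os.urandom(_NONCE_LEN)
    pt = plaintext.encode("utf-8")
    ct = bytes(a ^ b for a, b in zip(pt, _ctr_keystream(keys.enc_key, iv, len(pt))))
    tag = _mac(keys.mac_key, keys.salt, iv, ct)
    return CipherEnvelope(ct + tag, keys.salt, iv, keys.kdf_iterations)


def decrypt_field(envelope: CipherEnvelope, passphrase: str) -> str:
    """Decrypt one field; raises :class:`AuthenticationError` on any mismatch."""
    if envelope.scheme_tag != SCHEME_TAG:
        raise AuthenticationError(f"unknown scheme {envelope.scheme_tag!r}")
    if len(envelope.ciphertext) < _TAG_LEN:
        raise AuthenticationError("envelope truncated")
    ct, tag = envelope.ciphertext[:-_TAG_LEN], envelope.ciphertext[-_TAG_LEN:]
    keys = derive_keys(passphrase, envelope.salt, envelope.kdf_iterations)
    expected = _mac(keys.mac_key, envelope.salt, envelope.iv, ct)
    if not hmac.compare_digest(tag, expected):
        raise AuthenticationError("wrong passphrase or tampered ciphertext")
    pt = bytes(a ^ b for a, b in zip(ct, _ctr_keystream(keys.enc_key, envelope.iv, len(ct))))
    return pt.decode("utf-8")
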