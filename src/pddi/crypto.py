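"""Additively homomorphic threshold encryption for encrypted set intersection.

The linkage protocol needs three things from its cipher: ciphertexts of the
same plaintext must be unlinkable (probabilistic encryption, so an observer
cannot mount a dictionary attack on encrypted Bloom-filter bits), the server
must be able to sum ciphertexts without decrypting them, and decryption must
require the cooperation of *every* data-holding institution (n-of-n joint
decryption, so no single party — and certainly not the server — can open a
filter on its own).

Lifted (exponential) ElGamal over a Schnorr group provides all three:

    Enc(m) = (g^r, g^m * h^r)      with h = g^(x_1 + ... + x_n)

Component-wise multiplication of ciphertexts adds the exponents, so the
server can form the encrypted sum of the institutions' Bloom filters.
Each institution i contributes a partial decryption c1^(x_i); only the
product of all n partials cancels h^r.  Messages are tiny non-negative
counts (at most the number of institutions), so the final discrete
logarithm is decoded by table lookup and is exact.

Two parameter modes exist: ``production`` uses a 2048-bit safe-prime group
(RFC 3526 group 14) with randomness from the system CSPRNG; ``test`` uses
deliberately small, insecure groups with seedable randomness so protocol
runs are fast and reproducible in simulation.
"""

from __future__ import annotations

import hashlib
import secrets
from dataclasses import dataclass, field
from random import Random
from typing import Iterable, Sequence

__all__ = [
    "GroupParams",
    "KeyShare",
    "JointPublicKey",
    "Ciphertext",
    "PartialDecryption",
    "CryptoError",
    "ConfigurationError",
    "DecodeError",
    "production_params",
    "test_params",
    "tiny_params",
    "keygen",
    "encrypt",
    "add",
    "encrypt_vector",
    "add_vectors",
    "partial_decrypt",
    "partial_decrypt_vector",
    "combine_and_decode",
    "decode_vector",
]


class CryptoError(Exception):
    """Base class for encryption-layer failures."""


class ConfigurationError(CryptoError):
    """Invalid parameters or institution setup."""


class DecodeError(CryptoError):
    """No plaintext within the decode bound reproduces the transcript."""


# RFC 3526 group 14: p is a 2048-bit safe prime, q = (p-1)/2 is prime,
# g = 4 = 2^2 is a quadratic residue and therefore generates the order-q
# subgroup.
_RFC3526_2048_P = int(
    "FFFFFFFFFFFFFFFFC90FDAA22168C234C4C6628B80DC1CD129024E088A67CC74"
    "020BBEA63B139B22514A08798E3404DDEF9519B3CD3A431B302B0A6DF25F1437"
    "4FE1356D6D51C245E485B576625E7EC6F44C42E9A637ED6B0BFF5CB6F406B7ED"
    "EE386BFB5A899FA5AE9F24117C4B1FE649286651ECE45B3DC2007CB8A163BF05"
    "98DA48361C55D39A69163FA8FD24CF5F83655D23DCA3AD961C62F356208552BB"
    "9ED529077096966D670C354E4ABC9804F1746C08CA18217C32905E462E36CE3B"
    "E39E772C180E86039B2783A2EC07A28FB5C55DF06F4C52C9DE2BCBF695581718"
    "3995497CEA956AE515D2261898FA051015728E5A8AACAA68FFFFFFFFFFFFFFFF",
    16,
)

# 61-bit safe prime for test mode: fast modular exponentiation, insecure.
_TEST_P = 1346898466362022187


@dataclass(frozen=True)
class GroupParams:
    """A Schnorr group: prime modulus p, prime subgroup order q | p-1, generator g.

    ``security_mode`` is carried in every transcript so a test-mode run can
    never be mistaken for a production one.
    """

    p: int
    q: int
    g: int
    security_mode: str = "production"

    def __post_init__(self) -> None:
        if self.security_mode not in ("production", "test"):
            raise ConfigurationError(
                f"security_mode must be 'production' or 'test', got {self.security_mode!r}"
            )
        if (self.p - 1) % self.q != 0:
            raise ConfigurationError("q must divide p - 1")
        if self.g in (0, 1) or pow(self.g, self.q, self.p) != 1:
            raise ConfigurationError("g must generate the order-q subgroup")
        if self.security_mode == "production" and self.q.bit_length() < 224:
            raise ConfigurationError(
                "production mode requires a subgroup order of at least 224 bits"
            )


def production_params() -> GroupParams:
    """2048-bit safe-prime group (RFC 3526 group 14), generator 4."""
    p = _RFC3526_2048_P
    return GroupParams(p=p, q=(p - 1) // 2, g=4, security_mode="production")


def test_params() -> GroupParams:
    """Small (61-bit) safe-prime group for fast, reproducible simulations."""
    return GroupParams(p=_TEST_P, q=(_TEST_P - 1) // 2, g=4, security_mode="test")


def tiny_params() -> GroupParams:
    """Toy group with q = 101 (p = 607, g = 64) for worked examples."""
    return GroupParams(p=607, q=101, g=64, security_mode="test")


@dataclass(frozen=True)
class KeyShare:
    """One institution's additive share x_i of the joint secret key.

    Shares are never serialized into protocol messages; they exist only in
    the holding institution's process memory.
    """

    x: int
    institution_id: str


@dataclass(frozen=True)
class JointPublicKey:
    h: int  # g^(sum of shares) mod p
    n_institutions: int


@dataclass(frozen=True)
class Ciphertext:
    c1: int  # g^r
    c2: int  # g^m * h^r


@dataclass(frozen=True)
class PartialDecryption:
    d: int  # c1^(x_i)
    institution_id: str


def _rand_exponent(q: int, rng: Random | None) -> int:
    """Uniform in [1, q-1]; CSPRNG unless a seeded test-mode RNG is given."""
    if rng is None:
        return 1 + secrets.randbelow(q - 1)
    return rng.randrange(1, q)


def keygen(
    params: GroupParams,
    institution_ids: Sequence[str],
    rng: Random | None = None,
) -> tuple[list[KeyShare], JointPublicKey]:
    """Generate one additive key share per institution and the joint public key.

    The joint secret is x = sum(x_i) mod q and is never materialized; the
    public key h = g^x is the product of the per-institution components
    g^(x_i), so decryption requires every institution's cooperation.

    A seeded ``rng`` is accepted only in test mode.
    """
    ids = list(institution_ids)
    if len(ids) < 2:
        raise ConfigurationError("joint decryption requires at least 2 institutions")
    if len(set(ids)) != len(ids):
        raise ConfigurationError("institution ids must be distinct")
    if rng is not None and params.security_mode != "test":
        raise ConfigurationError("seeded randomness is only permitted in test mode")
    shares = [KeyShare(x=_rand_exponent(params.q, rng), institution_id=i) for i in ids]
    h = 1
    for s in shares:
        h = (h * pow(params.g, s.x, params.p)) % params.p
    return shares, JointPublicKey(h=h, n_institutions=len(ids))


def encrypt(
    pk: JointPublicKey,
    m: int,
    params: GroupParams,
    rng: Random | None = None,
    message_bound: int | None = None,
) -> Ciphertext:
    """Encrypt a small non-negative count m as (g^r, g^m * h^r).

    Fresh randomness r is drawn per call, so repeated encryptions of the
    same plaintext are distinct with overwhelming probability.
    """
    bound = pk.n_institutions if message_bound is None else message_bound
    if not 0 <= m <= bound:
        raise ValueError(f"plaintext {m} outside [0, {bound}]")
    if rng is not None and params.security_mode != "test":
        raise ConfigurationError("seeded randomness is only permitted in test mode")
    r = _rand_exponent(params.q, rng)
    c1 = pow(params.g, r, params.p)
    c2 = (pow(params.g, m, params.p) * pow(pk.h, r, params.p)) % params.p
    return Ciphertext(c1=c1, c2=c2)


def add(a: Ciphertext, b: Ciphertext, params: GroupParams) -> Ciphertext:
    """Homomorphic addition: component-wise product of ciphertexts."""
    return Ciphertext(c1=(a.c1 * b.c1) % params.p, c2=(a.c2 * b.c2) % params.p)


def encrypt_vector(
    pk: JointPublicKey,
    values: Iterable[int],
    params: GroupParams,
    rng: Random | None = None,
    chunk_size: int | None = None,
) -> list[Ciphertext]:
    """Element-wise encryption of a vector of counts.

    Each element is encrypted independently, so the work can be split into
    chunks (or across processes) in any order without changing what the
    transcript decrypts to.  ``chunk_size`` exercises that contract by
    encrypting in blocks; the result is element-aligned either way.
    """
    vals = list(values)
    if chunk_size is None:
        return [encrypt(pk, v, params, rng) for v in vals]
    out: list[Ciphertext] = []
    for start in range(0, len(vals), chunk_size):
        out.extend(encrypt(pk, v, params, rng) for v in vals[start : start + chunk_size])
    return out


def add_vectors(
    vectors: Sequence[Sequence[Ciphertext]], params: GroupParams
) -> list[Ciphertext]:
    """Element-wise homomorphic sum of equal-length ciphertext vectors."""
    if not vectors:
        raise ValueError("nothing to sum")
    length = len(vectors[0])
    if any(len(v) != length for v in vectors):
        raise CryptoError("ciphertext vectors have mismatched lengths")
    out = list(vectors[0])
    for vec in vectors[1:]:
        out = [add(a, b, params) for a, b in zip(out, vec)]
    return out


def partial_decrypt(c: Ciphertext, share: KeyShare, params: GroupParams) -> PartialDecryption:
    """One institution's decryption contribution d_i = c1^(x_i)."""
    return PartialDecryption(d=pow(c.c1, share.x, params.p), institution_id=share.institution_id)


def partial_decrypt_vector(
    cts: Sequence[Ciphertext], share: KeyShare, params: GroupParams
) -> list[PartialDecryption]:
    return [partial_decrypt(c, share, params) for c in cts]


def _decode_table(params: GroupParams, bound: int) -> dict[int, int]:
    return {pow(params.g, m, params.p): m for m in range(bound + 1)}


def combine_and_decode(
    c: Ciphertext,
    partials: Sequence[PartialDecryption],
    params: GroupParams,
    bound: int,
    _table: dict[int, int] | None = None,
) -> int:
    """Combine all partial decryptions and decode the count by table lookup.

    Computes g^m = c2 / prod(d_i) and searches m in [0, bound].  Raises
    :class:`DecodeError` when no m in range matches — the signature of a
    missing institution, a corrupted transcript, or a bound set too small.
    """
    if len({p.institution_id for p in partials}) != len(partials):
        raise CryptoError("duplicate partial decryption from one institution")
    denom = 1
    for part in partials:
        denom = (denom * part.d) % params.p
    gm = (c.c2 * pow(denom, params.p - 2, params.p)) % params.p
    table = _table if _table is not None else _decode_table(params, bound)
    if gm not in table:
        raise DecodeError(f"no plaintext in [0, {bound}] reproduces the quotient")
    return table[gm]


def decode_vector(
    cts: Sequence[Ciphertext],
    partials_per_institution: Sequence[Sequence[PartialDecryption]],
    params: GroupParams,
    bound: int,
) -> list[int]:
    """Decode a ciphertext vector given each institution's vector of partials."""
    for partials in partials_per_institution:
        if len(partials) != len(cts):
            raise CryptoError("partial-decryption vector length mismatch")
    table = _decode_table(params, bound)
    out = []
    for i, c in enumerate(cts):
        parts = [inst[i] for inst in partials_per_institution]
        out.append(combine_and_decode(c, parts, params, bound, _table=table))
    return out


# --- hybrid encryption of payload rows to the client -----------------------
#
# Payload rows leaving an institution in Step 3 must be readable by the
# client only, not by the server relaying them.  An ElGamal KEM in the same
# group establishes a shared secret g^(x_c * r); a SHA-256 counter stream
# keyed on it encrypts the row bytes.  This is a transport envelope, not the
# homomorphic layer.


@dataclass(frozen=True)
class SealedBox:
    epk: int  # ephemeral g^r
    ct: bytes


def _keystream(key: bytes, n: int) -> bytes:
    out = bytearray()
    counter = 0
    while len(out) < n:
        out.extend(hashlib.sha256(key + counter.to_bytes(8, "big")).digest())
        counter += 1
    return bytes(out[:n])


def _kdf(shared: int, params: GroupParams) -> bytes:
    width = (params.p.bit_length() + 7) // 8
    return hashlib.sha256(b"pddi-kem" + shared.to_bytes(width, "big")).digest()


def seal(plaintext: bytes, recipient_pub: int, params: GroupParams, rng: Random | None = None) -> SealedBox:
    r = _rand_exponent(params.q, rng)
    shared = pow(recipient_pub, r, params.p)
    key = _kdf(shared, params)
    stream = _keystream(key, len(plaintext))
    return SealedBox(epk=pow(params.g, r, params.p), ct=bytes(a ^ b for a, b in zip(plaintext, stream)))


def unseal(box: SealedBox, secret: int, params: GroupParams) -> bytes:
    shared = pow(box.epk, secret, params.p)
    key = _kdf(shared, params)
    stream = _keystream(key, len(box.ct))
    return bytes(a ^ b for a, b in zip(box.ct, stream))
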