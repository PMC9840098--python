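"""Bloom-filter encoding of compressed matching keys.

Each institution writes its set of key digests into a fixed-length bit
array.  Because every institution uses identical parameters (length, hash
count, and a shared session salt withheld from the server), the element-wise
integer sum of the filters — computed homomorphically by the server —
reveals exactly which positions are set by *all* institutions: a key held
by everyone has every one of its k positions summing to n.

Bloom encoding admits no false negatives; false positives arise only from
filter saturation, and the default sizing keeps the per-key false-positive
probability below 1e-9 at the declared capacity, so in practice the
protocol output equals the plaintext set intersection.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BloomParams",
    "PlainBloomFilter",
    "SummedFilter",
    "CorruptedTranscriptError",
    "params_for_capacity",
    "positions",
    "build_filter",
    "intersect_mask",
]

DEFAULT_FP_PROB = 1e-9


class CorruptedTranscriptError(Exception):
    """A summed filter position exceeds the number of institutions."""


@dataclass(frozen=True)
class BloomParams:
    """Shared filter geometry: m bits, k hash positions per key, session salt."""

    m_bits: int
    k_hashes: int
    salt: bytes

    def __post_init__(self) -> None:
        if self.k_hashes < 1:
            raise ValueError("k_hashes must be >= 1")
        if self.m_bits < self.k_hashes:
            raise ValueError("m_bits must be >= k_hashes")


def params_for_capacity(
    capacity: int, salt: bytes, fp_prob: float = DEFAULT_FP_PROB
) -> BloomParams:
    """Size a filter for ``capacity`` keys at a target per-key FP probability.

    Standard optimum: m = -n ln(p) / (ln 2)^2, k = round(m/n * ln 2).  All
    institutions in a session must declare the same capacity (the largest
    set), so the filter shapes agree for homomorphic summation.
    """
    if capacity < 1:
        raise ValueError("capacity must be positive")
    if not 0 < fp_prob < 1:
        raise ValueError("fp_prob must be in (0, 1)")
    m = math.ceil(-capacity * math.log(fp_prob) / (math.log(2) ** 2))
    k = max(1, round(m / capacity * math.log(2)))
    return BloomParams(m_bits=m, k_hashes=k, salt=salt)


@dataclass
class PlainBloomFilter:
    bits: np.ndarray  # uint8 array of {0,1}, length m_bits
    params: BloomParams

    def popcount(self) -> int:
        return int(self.bits.sum())

    def contains(self, key: bytes) -> bool:
        return all(self.bits[i] for i in positions(key, self.params))


@dataclass
class SummedFilter:
    counts: np.ndarray  # int array, each entry in [0, n_institutions]
    n_institutions: int

    def __post_init__(self) -> None:
        if len(self.counts) and int(self.counts.max(initial=0)) > self.n_institutions:
            raise CorruptedTranscriptError(
                "summed filter count exceeds the number of institutions"
            )


def positions(key: bytes, params: BloomParams) -> list[int]:
    """The k filter positions of a key digest: k independent salted hashes.

    index_j = SHA-256(salt || j || key) mod m.  Independent per-index
    hashes keep the false-positive rate at the textbook (1-e^{-kn/m})^k
    (arithmetic-progression schemes correlate probe and insert positions
    at small m and run above it).  The salt keeps positions unpredictable
    to the server, blocking dictionary attacks on the filter.
    """
    m = params.m_bits
    out = []
    for j in range(params.k_hashes):
        h = hashlib.sha256(params.salt + j.to_bytes(4, "big") + key).digest()
        out.append(int.from_bytes(h, "big") % m)
    return out


def build_filter(keys: Iterable[bytes], params: BloomParams) -> PlainBloomFilter:
    """Bloom filter of a deduplicated key set; every inserted key is a member."""
    bits = np.zeros(params.m_bits, dtype=np.uint8)
    for key in set(keys):
        bits[positions(key, params)] = 1
    return PlainBloomFilter(bits=bits, params=params)


def intersect_mask(
    summed: SummedFilter, own_keys: Sequence[bytes], params: BloomParams
) -> set[bytes]:
    """Keys of ours whose every filter position was set by all institutions.

    Exactly the Bloom-approximate n-way set intersection from this
    institution's point of view; superset of the true intersection (no
    false negatives), equal to it except for saturation false positives.
    """
    counts = summed.counts
    if len(counts) != params.m_bits:
        raise ValueError("summed filter length does not match Bloom parameters")
    if len(counts) and int(counts.max(initial=0)) > summed.n_institutions:
        raise CorruptedTranscriptError(
            "summed filter count exceeds the number of institutions"
        )
    n = summed.n_institutions
    return {
        key
        for key in own_keys
        if all(counts[i] == n for i in positions(key, params))
    }
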