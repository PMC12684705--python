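"""Exact big-integer arithmetic in Z[x]/(x^n + 1) via CRT over NTT primes.

Ciphertext polynomials have coefficients up to the ciphertext modulus q
(hundreds of bits), so products are computed residue-wise modulo enough
31-bit NTT-friendly primes that the signed product is recovered exactly by
Chinese remaindering, then reduced wherever the caller needs.

Coefficient vectors with big-integer entries are numpy object arrays of
Python ints; small operands (secret keys, errors, digits) may be int64.
"""

from __future__ import annotations

from functools import lru_cache
from math import prod

import numpy as np

from .ntt import aux_primes, get_transform

_MARGIN_BITS = 8  # slack on top of the worst-case product bound


class RingArith:
    """CRT/NTT multiplication helper for a fixed degree n."""

    def __init__(self, n: int):
        self.n = n
        self.order = 2 * n

    def primes_for(self, bound: int) -> tuple[int, ...]:
        """A prefix of auxiliary primes whose product exceeds 2*bound."""
        target_bits = bound.bit_length() + 1 + _MARGIN_BITS
        count = max(1, -(-target_bits // 30))
        primes = aux_primes(self.order, count)
        while prod(primes).bit_length() <= target_bits:
            count += 1
            primes = aux_primes(self.order, count)
        return primes

    def product_primes(self, max_a: int, max_b: int) -> tuple[int, ...]:
        """Primes sufficient for a negacyclic product of bounded operands."""
        return self.primes_for(self.n * max_a * max_b)

    def to_ntt(self, poly: np.ndarray, primes) -> dict[int, np.ndarray]:
        """Residue transforms of a coefficient vector (object or int64)."""
        out = {}
        for p in primes:
            res = poly % p
            if res.dtype == object:
                res = res.astype(np.int64)
            out[p] = get_transform(self.n, p).forward(res.astype(np.int64))
        return out

    def from_ntt(self, values: dict[int, np.ndarray], primes) -> np.ndarray:
        """Inverse transforms followed by centered CRT reconstruction."""
        residues = {
            p: get_transform(self.n, p).inverse(values[p]) for p in primes
        }
        return crt_center(residues, primes)

    def multiply(self, a: np.ndarray, b: np.ndarray, max_a: int, max_b: int) -> np.ndarray:
        """Exact centered product a*b mod (x^n + 1) over the integers."""
        primes = self.product_primes(max_a, max_b)
        ta = self.to_ntt(a, primes)
        tb = self.to_ntt(b, primes)
        return self.from_ntt(
            {p: ta[p] * tb[p] % p for p in primes}, primes
        )


@lru_cache(maxsize=None)
def _crt_constants(primes: tuple[int, ...]) -> tuple[int, tuple[int, ...]]:
    M = prod(primes)
    coeffs = []
    for p in primes:
        Mp = M // p
        coeffs.append(Mp * pow(Mp, -1, p) % M)
    return M, tuple(coeffs)


def crt_center(residues: dict[int, np.ndarray], primes) -> np.ndarray:
    """Combine residues into the unique representative in (-M/2, M/2]."""
    primes = tuple(primes)
    M, coeffs = _crt_constants(primes)
    acc = np.zeros(len(next(iter(residues.values()))), dtype=object)
    for p, c in zip(primes, coeffs):
        acc = acc + residues[p].astype(object) * c
    acc = acc % M
    return np.where(acc > M // 2, acc - M, acc)


def center_mod(poly: np.ndarray, q: int) -> np.ndarray:
    """Map coefficients from [0, q) to the centered range (-q/2, q/2]."""
    poly = poly % q
    return np.where(poly > q // 2, poly - q, poly)


@lru_cache(maxsize=None)
def ring(n: int) -> RingArith:
    return RingArith(n)
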