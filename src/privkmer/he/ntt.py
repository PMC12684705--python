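"""Negacyclic number-theoretic transforms over word-sized primes.

The BFV backend needs two kinds of transforms over Z[x]/(x^n + 1):

* slot batching mod the plaintext prime t (t ≡ 1 mod 2n), which turns
  slot-wise vector arithmetic into ring arithmetic, and
* exact integer polynomial products for ciphertext tensoring, computed by
  CRT over several auxiliary primes p ≡ 1 (mod 2n) below 2^31 so that all
  butterfly arithmetic fits in int64.

Transforms are iterative radix-2 Cooley–Tukey, vectorised with numpy; a
negacyclic product is a plain cyclic NTT after twisting by powers of a
2n-th root of unity psi.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy
from sympy.ntheory.residue_ntheory import primitive_root

_WORD_LIMIT = 1 << 31  # keeps butterfly products within int64


@lru_cache(maxsize=None)
def aux_primes(order: int, count: int) -> tuple[int, ...]:
    """First `count` primes p ≡ 1 (mod order) with 2^30 ≤ p < 2^31."""
    primes = []
    p = ((1 << 30) // order + 1) * order + 1
    while len(primes) < count:
        if p >= _WORD_LIMIT:
            raise ValueError(
                f"exhausted 31-bit primes ≡ 1 mod {order} (needed {count})"
            )
        if sympy.isprime(p):
            primes.append(p)
        p += order
    return tuple(primes)


def _bit_reverse_perm(n: int) -> np.ndarray:
    bits = n.bit_length() - 1
    rev = np.zeros(n, dtype=np.intp)
    for i in range(n):
        rev[i] = int(format(i, f"0{bits}b")[::-1], 2) if bits else 0
    return rev


@lru_cache(maxsize=None)
def get_transform(n: int, p: int) -> "NegacyclicNTT":
    return NegacyclicNTT(n, p)


class NegacyclicNTT:
    """Forward/inverse negacyclic NTT of length n modulo prime p.

    Requires p ≡ 1 (mod 2n) so a primitive 2n-th root of unity exists.
    """

    def __init__(self, n: int, p: int):
        if n & (n - 1):
            raise ValueError("transform length must be a power of two")
        if (p - 1) % (2 * n):
            raise ValueError(f"{p} is not ≡ 1 mod {2 * n}")
        self.n, self.p = n, p
        g = primitive_root(p)
        psi = pow(g, (p - 1) // (2 * n), p)
        assert pow(psi, n, p) == p - 1
        w = pow(psi, 2, p)
        self._fw = self._stage_tables(w)
        self._iw = self._stage_tables(pow(w, p - 2, p))
        self._rev = _bit_reverse_perm(n)
        self._psi = self._power_row(psi)
        self._ipsi = self._power_row(pow(psi, p - 2, p))
        self._n_inv = pow(n, p - 2, p)

    def _power_row(self, base: int) -> np.ndarray:
        row = np.empty(self.n, dtype=np.int64)
        acc = 1
        for i in range(self.n):
            row[i] = acc
            acc = acc * base % self.p
        return row

    def _stage_tables(self, w: int) -> dict[int, np.ndarray]:
        tables = {}
        half = 1
        while half < self.n:
            base = pow(w, self.n // (2 * half), self.p)
            tables[half] = self._power_row_of(base, half)
            half *= 2
        return tables

    def _power_row_of(self, base: int, length: int) -> np.ndarray:
        row = np.empty(length, dtype=np.int64)
        acc = 1
        for i in range(length):
            row[i] = acc
            acc = acc * base % self.p
        return row

    def _ntt(self, a: np.ndarray, tables: dict[int, np.ndarray]) -> np.ndarray:
        p = self.p
        a = a[self._rev]
        half = 1
        while half < self.n:
            a = a.reshape(-1, 2 * half)
            u = a[:, :half]
            v = a[:, half:] * tables[half] % p
            a = np.concatenate(((u + v) % p, (u - v) % p), axis=1).ravel()
            half <<= 1
        return a

    def forward(self, coeffs: np.ndarray) -> np.ndarray:
        """Negacyclic NTT of an int64 coefficient vector reduced mod p."""
        return self._ntt(coeffs * self._psi % self.p, self._fw)

    def inverse(self, values: np.ndarray) -> np.ndarray:
        a = self._ntt(values, self._iw) * self._n_inv % self.p
        return a * self._ipsi % self.p
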