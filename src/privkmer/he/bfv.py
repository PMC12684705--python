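"""BFV-style lattice backend with SIMD batching.

Scheme outline (standard scale-by-Δ BFV over R_q = Z_q[x]/(x^n + 1)):

* secret key s — uniform ternary; errors — centered discrete Gaussian
  (σ = 3.2, tails truncated at 6σ);
* public key (pk0, pk1) = (-(a·s + e), a) with a uniform in R_q;
* Encrypt(m): (pk0·u + e1 + Δ·m, pk1·u + e2) with Δ = ⌊q/t⌋ and ternary u;
* Decrypt(c): m = ⌈t·(c0 + c1·s)/q⌋ mod t — correct while the invariant
  noise is below 1/2, i.e. while the reported noise budget is positive;
* multiplication: tensor the ciphertexts exactly over the integers, scale
  each component by t/q with rounding; relinearisation decomposes the
  quadratic component into base-2^digit_bits digits and folds them with the
  evaluation key, returning the ciphertext to size 2.

Batching maps a slot vector to the plaintext polynomial through an inverse
negacyclic NTT mod t, so ciphertext addition/multiplication act slot-wise.
Only the depth-1 circuit {sub, square+relin, add} needed by the search
protocol is exposed; there are no rotations and no modulus switching.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..errors import KeyMismatchError, UsageError
from .base import CipherVec, Context, KeyMaterial
from .ntt import get_transform
from .params import CryptoParams
from .poly import center_mod, crt_center, ring

_FORMAT_VERSION = 1
_SIGMA = 3.2


@dataclass
class CachedPoly:
    """A key polynomial plus memoised NTT residue transforms per prime."""

    coeffs: np.ndarray
    transforms: dict = field(default_factory=dict)

    def ntt(self, ring_arith, primes):
        missing = [p for p in primes if p not in self.transforms]
        if missing:
            self.transforms.update(ring_arith.to_ntt(self.coeffs, missing))
        return self.transforms


@dataclass
class RelinKeys:
    """Evaluation key: one (k0, k1) pair per base-2^digit_bits digit."""

    digit_bits: int
    pairs: list  # [(CachedPoly, CachedPoly), ...]


class BfvContext(Context):
    backend_name = "bfv"

    def __init__(self, params: CryptoParams, seed: Optional[int] = None):
        super().__init__(params)
        self.n = params.poly_degree
        self.t = params.plain_modulus
        self.q = params.coeff_modulus
        self.delta = self.q // self.t
        self.ring = ring(self.n)
        self.encoder = get_transform(self.n, self.t)
        qbits = self.q.bit_length()
        self.digit_bits = min(60, max(10, qbits // 4))
        self.n_digits = -(-qbits // self.digit_bits)
        # Prime prefixes sized to each product's worst-case magnitude.
        half_q = self.q // 2
        self.primes_small = self.ring.product_primes(half_q, 1)
        self.primes_relin = self.ring.product_primes(half_q, 1 << self.digit_bits)
        self.primes_tensor = self.ring.primes_for(2 * self.n * half_q * half_q)
        self._enc_rng = np.random.default_rng(seed)

    # -- samplers --------------------------------------------------------
    def _ternary(self, rng) -> np.ndarray:
        return rng.integers(-1, 2, self.n).astype(np.int64)

    def _gauss(self, rng) -> np.ndarray:
        e = np.rint(rng.normal(0.0, _SIGMA, self.n)).astype(np.int64)
        bound = int(6 * _SIGMA)
        return np.clip(e, -bound, bound)

    def _uniform_poly(self, pr: random.Random) -> np.ndarray:
        return np.array([pr.randrange(self.q) for _ in range(self.n)], dtype=object)

    # -- ring helpers ----------------------------------------------------
    def _mul_with_cached(self, cached: CachedPoly, other: np.ndarray, primes):
        """cached_poly * other (other small, int64), centered exact product."""
        ta = cached.ntt(self.ring, primes)
        tb = self.ring.to_ntt(other, primes)
        return self.ring.from_ntt({p: ta[p] * tb[p] % p for p in primes}, primes)

    # -- key generation --------------------------------------------------
    def keygen(self, seed: Optional[int] = None) -> KeyMaterial:
        rng = np.random.default_rng(seed)
        pr = random.Random(int(rng.integers(1 << 62)))
        s = self._ternary(rng)
        s_cached = CachedPoly(s)
        a = self._uniform_poly(pr)
        a_cached = CachedPoly(a)
        e = self._gauss(rng)
        a_s = self._mul_with_cached(a_cached, s, self.primes_small)
        pk0 = (-(a_s + e)) % self.q
        pk1 = a
        # s^2 exactly (coefficients bounded by n).
        s2 = self.ring.multiply(s, s, 1, 1)
        pairs = []
        w = 1 << self.digit_bits
        for i in range(self.n_digits):
            ai = self._uniform_poly(pr)
            ai_cached = CachedPoly(ai)
            ei = self._gauss(rng)
            ai_s = self._mul_with_cached(ai_cached, s, self.primes_small)
            k0 = (-(ai_s + ei) + pow(w, i, self.q) * s2.astype(object)) % self.q
            pairs.append((CachedPoly(k0), CachedPoly(ai)))
        key_id = 0 if seed is None else int(seed) % (1 << 31)
        return KeyMaterial(
            secret_key=s_cached,
            public_key=(CachedPoly(pk0), CachedPoly(pk1)),
            relin_keys=RelinKeys(self.digit_bits, pairs),
            backend="bfv",
            key_id=key_id,
        )

    # -- encode / decode -------------------------------------------------
    def _encode(self, slots: np.ndarray) -> np.ndarray:
        return self.encoder.inverse(slots % self.t)

    def _decode(self, poly: np.ndarray) -> np.ndarray:
        return self.encoder.forward(poly % self.t)

    # -- encryption ------------------------------------------------------
    def encrypt_vec(self, v, keys: KeyMaterial) -> CipherVec:
        slots = self._prepare_vec(v)
        m = self._encode(slots)
        pk0, pk1 = keys.public_key
        u = self._ternary(self._enc_rng)
        e1 = self._gauss(self._enc_rng)
        e2 = self._gauss(self._enc_rng)
        primes = self.primes_small
        tu = self.ring.to_ntt(u, primes)
        t0 = pk0.ntt(self.ring, primes)
        t1 = pk1.ntt(self.ring, primes)
        pk0_u = self.ring.from_ntt({p: t0[p] * tu[p] % p for p in primes}, primes)
        pk1_u = self.ring.from_ntt({p: t1[p] * tu[p] % p for p in primes}, primes)
        c0 = (pk0_u + e1 + self.delta * m.astype(object)) % self.q
        c1 = (pk1_u + e2) % self.q
        return CipherVec(
            handle=[c0, c1], slot_count=self.slot_count, size=2,
            depth=0, backend="bfv",
        )

    # -- decryption ------------------------------------------------------
    def _phase(self, c: CipherVec, keys: KeyMaterial) -> np.ndarray:
        """Centered c0 + c1·s (+ c2·s²) mod q."""
        s = keys.secret_key
        polys = c.handle
        acc = polys[0].astype(object)
        c1s = self._mul_with_cached(CachedPoly(polys[1]), s.coeffs, self.primes_small)
        acc = acc + c1s
        if len(polys) == 3:
            s2 = self.ring.multiply(s.coeffs, s.coeffs, 1, 1)
            c2s2 = self.ring.multiply(
                center_mod(polys[2], self.q), s2, self.q // 2, self.n
            )
            acc = acc + c2s2
        return center_mod(acc, self.q)

    def decrypt_vec(self, c: CipherVec, keys: KeyMaterial) -> np.ndarray:
        if keys.backend != "bfv":
            raise KeyMismatchError("lattice ciphertext requires lattice keys")
        v = self._phase(c, keys)
        m = (v * (2 * self.t) + self.q) // (2 * self.q)
        return self._decode(np.asarray(m % self.t, dtype=object).astype(np.int64))

    def noise_budget(self, c: CipherVec, keys: KeyMaterial) -> int:
        """Invariant noise budget in bits; decryption is safe while > 0."""
        v = self._phase(c, keys)
        m = (v * (2 * self.t) + self.q) // (2 * self.q)
        r = self.t * v - self.q * m
        max_r = max(1, int(max(abs(int(x)) for x in r)))
        budget = (self.q // (2 * max_r)).bit_length() - 1
        return max(0, budget)

    # -- arithmetic ------------------------------------------------------
    def he_add(self, a: CipherVec, b: CipherVec) -> CipherVec:
        return self._binop(a, b, 1)

    def he_sub(self, a: CipherVec, b: CipherVec) -> CipherVec:
        return self._binop(a, b, -1)

    def _binop(self, a: CipherVec, b: CipherVec, sign: int) -> CipherVec:
        self._check_pair(a, b)
        if a.size != b.size:
            raise UsageError("ciphertext sizes differ")
        polys = [
            (pa.astype(object) + sign * pb.astype(object)) % self.q
            for pa, pb in zip(a.handle, b.handle)
        ]
        self.op_counts["add" if sign == 1 else "sub"] += 1
        return CipherVec(
            handle=polys, slot_count=self.slot_count, size=a.size,
            depth=max(a.depth, b.depth), backend="bfv",
        )

    def he_square_relin(self, a: CipherVec, relin_keys: RelinKeys) -> CipherVec:
        if a.size != 2:
            raise UsageError("squaring requires a size-2 ciphertext")
        primes = self.primes_tensor
        c0 = center_mod(a.handle[0], self.q)
        c1 = center_mod(a.handle[1], self.q)
        t0 = self.ring.to_ntt(c0, primes)
        t1 = self.ring.to_ntt(c1, primes)
        d0 = self.ring.from_ntt({p: t0[p] * t0[p] % p for p in primes}, primes)
        d1 = self.ring.from_ntt(
            {p: 2 * (t0[p] * t1[p] % p) % p for p in primes}, primes
        )
        d2 = self.ring.from_ntt({p: t1[p] * t1[p] % p for p in primes}, primes)
        d0, d1, d2 = (self._scale_round(d) for d in (d0, d1, d2))
        c0n, c1n = self._relinearize(d0, d1, d2, relin_keys)
        self.op_counts["square"] += 1
        return CipherVec(
            handle=[c0n, c1n], slot_count=self.slot_count, size=2,
            depth=a.depth + 1, backend="bfv",
        )

    def _scale_round(self, d: np.ndarray) -> np.ndarray:
        """round(t·d/q) mod q, elementwise on big integers."""
        return ((d * (2 * self.t) + self.q) // (2 * self.q)) % self.q

    def _relinearize(self, d0, d1, d2, rlk: RelinKeys):
        primes = self.primes_relin
        w = 1 << rlk.digit_bits
        acc0 = {p: np.zeros(self.n, dtype=np.int64) for p in primes}
        acc1 = {p: np.zeros(self.n, dtype=np.int64) for p in primes}
        rem = d2.copy()
        for k0, k1 in rlk.pairs:
            digit = np.asarray(rem % w, dtype=object).astype(np.int64)
            rem = rem // w
            td = self.ring.to_ntt(digit, primes)
            tk0 = k0.ntt(self.ring, primes)
            tk1 = k1.ntt(self.ring, primes)
            for p in primes:
                acc0[p] = (acc0[p] + td[p] * tk0[p] % p) % p
                acc1[p] = (acc1[p] + td[p] * tk1[p] % p) % p
        r0 = crt_center(
            {p: get_transform(self.n, p).inverse(acc0[p]) for p in primes}, primes
        )
        r1 = crt_center(
            {p: get_transform(self.n, p).inverse(acc1[p]) for p in primes}, primes
        )
        return (d0 + r0) % self.q, (d1 + r1) % self.q

    # -- serialization ---------------------------------------------------
    @property
    def _coeff_width(self) -> int:
        return (self.q.bit_length() + 7) // 8

    def _poly_bytes(self, poly: np.ndarray) -> bytes:
        w = self._coeff_width
        return b"".join(int(x).to_bytes(w, "big") for x in poly)

    def _poly_from_bytes(self, blob: bytes) -> np.ndarray:
        w = self._coeff_width
        return np.array(
            [int.from_bytes(blob[i * w:(i + 1) * w], "big") for i in range(self.n)],
            dtype=object,
        )

    def save_cipher(self, c: CipherVec, path) -> None:
        header = {
            "format_version": _FORMAT_VERSION, "backend": "bfv",
            "slot_count": c.slot_count, "size": c.size, "depth": c.depth,
            "coeff_width": self._coeff_width,
        }
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            for poly in c.handle:
                fh.write(self._poly_bytes(poly))

    def load_cipher(self, path) -> CipherVec:
        with open(path, "rb") as fh:
            header = json.loads(fh.readline())
            if header["backend"] != "bfv":
                raise UsageError(f"{path} is not a lattice ciphertext")
            polys = [
                self._poly_from_bytes(fh.read(self._coeff_width * self.n))
                for _ in range(header["size"])
            ]
        return CipherVec(
            handle=polys, slot_count=header["slot_count"],
            size=header["size"], depth=header["depth"], backend="bfv",
        )

    def save_relin_keys(self, keys: KeyMaterial, path) -> None:
        rlk: RelinKeys = keys.relin_keys
        header = {
            "format_version": _FORMAT_VERSION, "backend": "bfv",
            "digit_bits": rlk.digit_bits, "n_pairs": len(rlk.pairs),
            "coeff_width": self._coeff_width,
        }
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            for k0, k1 in rlk.pairs:
                fh.write(self._poly_bytes(k0.coeffs))
                fh.write(self._poly_bytes(k1.coeffs))

    def load_relin_keys(self, path) -> RelinKeys:
        with open(path, "rb") as fh:
            header = json.loads(fh.readline())
            pairs = []
            for _ in range(header["n_pairs"]):
                k0 = self._poly_from_bytes(fh.read(self._coeff_width * self.n))
                k1 = self._poly_from_bytes(fh.read(self._coeff_width * self.n))
                pairs.append((CachedPoly(k0), CachedPoly(k1)))
        return RelinKeys(header["digit_bits"], pairs)

    def save_secret_keys(self, keys: KeyMaterial, directory) -> None:
        s = keys.secret_key.coeffs
        pk0, pk1 = keys.public_key
        header = {
            "format_version": _FORMAT_VERSION, "backend": "bfv",
            "key_id": keys.key_id, "coeff_width": self._coeff_width,
        }
        with open(f"{directory}/secret.key", "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            fh.write((s.astype(np.int64) + 1).astype("<i1").tobytes())
            fh.write(self._poly_bytes(pk0.coeffs))
            fh.write(self._poly_bytes(pk1.coeffs))
        self.save_relin_keys(keys, f"{directory}/relin.key")

    def load_secret_keys(self, directory) -> KeyMaterial:
        with open(f"{directory}/secret.key", "rb") as fh:
            header = json.loads(fh.readline())
            s = np.frombuffer(fh.read(self.n), dtype="<i1").astype(np.int64) - 1
            pk0 = self._poly_from_bytes(fh.read(self._coeff_width * self.n))
            pk1 = self._poly_from_bytes(fh.read(self._coeff_width * self.n))
        rlk = self.load_relin_keys(f"{directory}/relin.key")
        return KeyMaterial(
            secret_key=CachedPoly(s),
            public_key=(CachedPoly(pk0), CachedPoly(pk1)),
            relin_keys=rlk, backend="bfv", key_id=header["key_id"],
        )
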