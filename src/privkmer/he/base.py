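"""Uniform integer-vector homomorphic arithmetic contract.

Two interchangeable implementations exist behind one interface:

* ``bfv``   — a lattice (RLWE) scheme with SIMD batching; ciphertexts are
  opaque polynomial pairs and arithmetic is slot-wise mod the plaintext
  prime t, up to noise.
* ``clear`` — a reference backend performing the identical slot-wise
  arithmetic mod t on plain integer vectors. It is the deterministic
  oracle every protocol test runs against first.

All protocol code is written against :class:`Context` and never touches a
backend's internals, so the two are freely interchangeable.
"""

from __future__ import annotations

import abc
from collections import Counter
from dataclasses import dataclass
from typing import Any, Optional

import numpy as np

from ..errors import ConfigurationError, UsageError
from .params import CryptoParams

#: Sentinel noise budget reported by the clear backend ("infinite").
INFINITE_BUDGET = 2**62


@dataclass
class CipherVec:
    """Opaque handle to one batched ciphertext of `slot_count` integer slots.

    ``size`` is the ciphertext polynomial count (2 after relinearisation);
    ``depth`` counts sequential ciphertext–ciphertext multiplications on the
    deepest path that produced this value, used to audit circuit depth.
    """

    handle: Any
    slot_count: int
    size: int = 2
    depth: int = 0
    backend: str = "clear"


@dataclass
class KeyMaterial:
    """Secret/public/relinearisation key triple from one context.

    The secret key must never be written into server-visible directories;
    only the relinearisation (evaluation) key is shipped with a deployment.
    """

    secret_key: Any
    public_key: Any
    relin_keys: Any
    backend: str = "clear"
    key_id: int = 0


class Context(abc.ABC):
    """One backend instance bound to a :class:`CryptoParams` set."""

    backend_name: str = "?"

    def __init__(self, params: CryptoParams):
        self.params = params
        self.op_counts: Counter = Counter()

    @property
    def slot_count(self) -> int:
        return self.params.slot_count

    # -- key management -------------------------------------------------
    @abc.abstractmethod
    def keygen(self, seed: Optional[int] = None) -> KeyMaterial: ...

    # -- encryption -----------------------------------------------------
    @abc.abstractmethod
    def encrypt_vec(self, v, keys: KeyMaterial) -> CipherVec: ...

    @abc.abstractmethod
    def decrypt_vec(self, c: CipherVec, keys: KeyMaterial) -> np.ndarray: ...

    # -- arithmetic -----------------------------------------------------
    @abc.abstractmethod
    def he_add(self, a: CipherVec, b: CipherVec) -> CipherVec: ...

    @abc.abstractmethod
    def he_sub(self, a: CipherVec, b: CipherVec) -> CipherVec: ...

    @abc.abstractmethod
    def he_square_relin(self, a: CipherVec, relin_keys) -> CipherVec: ...

    @abc.abstractmethod
    def noise_budget(self, c: CipherVec, keys: KeyMaterial) -> int: ...

    # -- serialization --------------------------------------------------
    @abc.abstractmethod
    def save_cipher(self, c: CipherVec, path) -> None: ...

    @abc.abstractmethod
    def load_cipher(self, path) -> CipherVec: ...

    @abc.abstractmethod
    def save_relin_keys(self, keys: KeyMaterial, path) -> None: ...

    @abc.abstractmethod
    def load_relin_keys(self, path): ...

    @abc.abstractmethod
    def save_secret_keys(self, keys: KeyMaterial, directory) -> None: ...

    @abc.abstractmethod
    def load_secret_keys(self, directory) -> KeyMaterial: ...

    # -- shared validation ----------------------------------------------
    def _prepare_vec(self, v) -> np.ndarray:
        t = self.params.plain_modulus
        v = np.asarray(v, dtype=np.int64)
        if v.ndim != 1 or len(v) > self.slot_count:
            raise UsageError(
                f"vector length {v.shape} exceeds slot count {self.slot_count}"
            )
        if len(v) and (v.min() < 0 or v.max() >= t):
            raise UsageError(f"vector entries must lie in [0, {t})")
        if len(v) < self.slot_count:
            v = np.concatenate(
                [v, np.zeros(self.slot_count - len(v), dtype=np.int64)]
            )
        return v

    def _check_pair(self, a: CipherVec, b: CipherVec) -> None:
        if a.backend != self.backend_name or b.backend != self.backend_name:
            raise UsageError("ciphertext from a different backend")
        if a.slot_count != self.slot_count or b.slot_count != self.slot_count:
            raise UsageError("ciphertext from a context with different geometry")


def create_context(params: CryptoParams, backend: str = "clear",
                   seed: Optional[int] = None) -> Context:
    """Instantiate a backend context for the given parameters.

    ``seed`` feeds the encryption randomness of the lattice backend; it has
    no effect on decrypted values, only on ciphertext bytes.
    """
    from .bfv import BfvContext
    from .clear import ClearContext

    if backend == "clear":
        return ClearContext(params)
    if backend == "bfv":
        return BfvContext(params, seed=seed)
    raise ConfigurationError(f"unknown backend {backend!r}")


# Thin functional facade mirroring the module contract.
def keygen(ctx: Context, seed: Optional[int] = None) -> KeyMaterial:
    return ctx.keygen(seed)


def encrypt_vec(v, ctx: Context, keys: KeyMaterial) -> CipherVec:
    return ctx.encrypt_vec(v, keys)


def decrypt_vec(c: CipherVec, ctx: Context, keys: KeyMaterial) -> np.ndarray:
    return ctx.decrypt_vec(c, keys)


def he_add(ctx: Context, a: CipherVec, b: CipherVec) -> CipherVec:
    return ctx.he_add(a, b)


def he_sub(ctx: Context, a: CipherVec, b: CipherVec) -> CipherVec:
    return ctx.he_sub(a, b)


def he_square_relin(ctx: Context, a: CipherVec, relin_keys) -> CipherVec:
    return ctx.he_square_relin(a, relin_keys)


def noise_budget(ctx: Context, c: CipherVec, keys: KeyMaterial) -> int:
    return ctx.noise_budget(c, keys)
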