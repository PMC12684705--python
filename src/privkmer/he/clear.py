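"""Clear reference backend: slot-wise arithmetic mod t on plain vectors.

Semantically identical to the lattice backend (same plaintext algebra,
same slot geometry) but with no encryption. Every protocol test runs here
first; the lattice backend is then cross-checked against it on smaller
instances. "Keys" are sentinels carrying only an identity token so that a
key-mismatch misuse is still detectable.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np

from ..errors import KeyMismatchError, UsageError
from .base import INFINITE_BUDGET, CipherVec, Context, KeyMaterial
from .params import CryptoParams

_FORMAT_VERSION = 1


class ClearContext(Context):
    backend_name = "clear"

    def __init__(self, params: CryptoParams):
        super().__init__(params)

    def keygen(self, seed: Optional[int] = None) -> KeyMaterial:
        key_id = 0 if seed is None else int(seed) % (1 << 31)
        token = f"clear-{key_id}"
        return KeyMaterial(
            secret_key=token, public_key=token, relin_keys=token,
            backend="clear", key_id=key_id,
        )

    def encrypt_vec(self, v, keys: KeyMaterial) -> CipherVec:
        values = self._prepare_vec(v)
        return CipherVec(
            handle=(keys.key_id, values.copy()),
            slot_count=self.slot_count, size=2, depth=0, backend="clear",
        )

    def decrypt_vec(self, c: CipherVec, keys: KeyMaterial) -> np.ndarray:
        key_id, values = c.handle
        if key_id != keys.key_id:
            raise KeyMismatchError(
                f"ciphertext was produced under key {key_id}, not {keys.key_id}"
            )
        return values.copy()

    def _binop(self, a: CipherVec, b: CipherVec, op: str) -> CipherVec:
        self._check_pair(a, b)
        t = self.params.plain_modulus
        ka, va = a.handle
        kb, vb = b.handle
        if ka != kb:
            raise UsageError("operands encrypted under different keys")
        res = (va + vb) % t if op == "add" else (va - vb) % t
        self.op_counts[op] += 1
        return CipherVec(
            handle=(ka, res), slot_count=self.slot_count, size=2,
            depth=max(a.depth, b.depth), backend="clear",
        )

    def he_add(self, a: CipherVec, b: CipherVec) -> CipherVec:
        return self._binop(a, b, "add")

    def he_sub(self, a: CipherVec, b: CipherVec) -> CipherVec:
        return self._binop(a, b, "sub")

    def he_square_relin(self, a: CipherVec, relin_keys) -> CipherVec:
        if a.size != 2:
            raise UsageError("squaring requires a size-2 ciphertext")
        t = self.params.plain_modulus
        key_id, va = a.handle
        self.op_counts["square"] += 1
        return CipherVec(
            handle=(key_id, va * va % t), slot_count=self.slot_count,
            size=2, depth=a.depth + 1, backend="clear",
        )

    def noise_budget(self, c: CipherVec, keys: KeyMaterial) -> int:
        return INFINITE_BUDGET

    # -- serialization --------------------------------------------------
    def save_cipher(self, c: CipherVec, path) -> None:
        key_id, values = c.handle
        header = {
            "format_version": _FORMAT_VERSION, "backend": "clear",
            "slot_count": c.slot_count, "size": c.size, "depth": c.depth,
            "key_id": key_id,
        }
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            fh.write(values.astype("<i8").tobytes())

    def load_cipher(self, path) -> CipherVec:
        with open(path, "rb") as fh:
            header = json.loads(fh.readline())
            if header["backend"] != "clear":
                raise UsageError(f"{path} is not a clear-backend ciphertext")
            values = np.frombuffer(fh.read(), dtype="<i8").astype(np.int64)
        return CipherVec(
            handle=(header["key_id"], values),
            slot_count=header["slot_count"], size=header["size"],
            depth=header["depth"], backend="clear",
        )

    def save_relin_keys(self, keys: KeyMaterial, path) -> None:
        with open(path, "w") as fh:
            json.dump({"backend": "clear", "key_id": keys.key_id}, fh)

    def load_relin_keys(self, path):
        with open(path) as fh:
            return json.load(fh)["key_id"]

    def save_secret_keys(self, keys: KeyMaterial, directory) -> None:
        with open(f"{directory}/secret.json", "w") as fh:
            json.dump({"backend": "clear", "key_id": keys.key_id}, fh)

    def load_secret_keys(self, directory) -> KeyMaterial:
        with open(f"{directory}/secret.json") as fh:
            key_id = json.load(fh)["key_id"]
        token = f"clear-{key_id}"
        return KeyMaterial(
            secret_key=token, public_key=token, relin_keys=token,
            backend="clear", key_id=key_id,
        )
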