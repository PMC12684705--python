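"""Cryptographic parameter sets for the integer (BFV-style) scheme.

The default profile mirrors the standard SEAL-style configuration for
128-bit security: ring degree 8192, a coefficient-modulus chain of
{43, 43, 44, 44, 44}-bit primes (≈218 bits total) and a batching-friendly
20-bit plaintext prime. Reduced profiles (degrees 1024–4096) exist for fast
tests; every protocol component is parameterised by `slot_count` and never
assumes a particular degree.

The plaintext prime must satisfy t ≡ 1 (mod 2n) for SIMD batching; the
default t = 786433 = 3·2^18 + 1 is batching-compatible for every supported
power-of-two degree. With symbols in {0..4} and queries over {0..3}, a
single squared difference is at most 16, so any k_max with 16·k_max < t is
free of slot wraparound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import sympy

from ..errors import ConfigurationError

#: 20-bit prime, ≡ 1 mod 2n for all power-of-two n ≤ 2^17.
DEFAULT_PLAIN_MODULUS = 786433

#: SEAL-style default coefficient-modulus bit chains per degree.
DEFAULT_COEFF_BITS = {
    1024: (40, 40, 40),    # test-only: far below 128-bit security
    2048: (42, 42, 42),    # test-only
    4096: (36, 36, 37),
    8192: (43, 43, 44, 44, 44),
    16384: (48, 48, 48, 49, 49, 49, 49, 49, 49),
}


@lru_cache(maxsize=None)
def _chain_primes(bits: tuple[int, ...]) -> tuple[int, ...]:
    """Deterministic distinct primes of the requested bit lengths."""
    primes: list[int] = []
    for b in bits:
        p = sympy.nextprime(1 << (b - 1))
        while p in primes:
            p = sympy.nextprime(p)
        primes.append(int(p))
    return tuple(primes)


@dataclass(frozen=True)
class CryptoParams:
    """Ring dimension, plaintext modulus and coefficient modulus chain.

    ``poly_degree`` equals the SIMD slot count under batching.
    ``coeff_modulus_bits`` names the chain profile; the actual ciphertext
    modulus q is the product of deterministic primes of those bit lengths.
    """

    poly_degree: int = 8192
    plain_modulus: int = DEFAULT_PLAIN_MODULUS
    coeff_modulus_bits: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    security_bits: int = 128

    def __post_init__(self):
        if self.coeff_modulus_bits is None:
            try:
                chain = DEFAULT_COEFF_BITS[self.poly_degree]
            except KeyError:
                raise ConfigurationError(
                    f"no default coefficient chain for degree {self.poly_degree}"
                )
            object.__setattr__(self, "coeff_modulus_bits", chain)
        else:
            object.__setattr__(
                self, "coeff_modulus_bits", tuple(self.coeff_modulus_bits)
            )
        self.validate()

    def validate(self) -> None:
        n = self.poly_degree
        if n < 1024 or n & (n - 1):
            raise ConfigurationError(
                f"poly_degree must be a power of two ≥ 1024, got {n}"
            )
        t = self.plain_modulus
        if not sympy.isprime(t):
            raise ConfigurationError(f"plain_modulus {t} is not prime")
        if t % (2 * n) != 1:
            raise ConfigurationError(
                f"plain_modulus {t} is not ≡ 1 mod {2 * n}; batching impossible"
            )

    @property
    def slot_count(self) -> int:
        return self.poly_degree

    @property
    def coeff_modulus(self) -> int:
        q = 1
        for p in _chain_primes(self.coeff_modulus_bits):
            q *= p
        return q

    @property
    def plain_bits(self) -> int:
        return self.plain_modulus.bit_length()

    def max_kmax(self) -> int:
        """Largest k_max free of SSD wraparound (16·k_max < t)."""
        return (self.plain_modulus - 1) // 16

    def to_dict(self) -> dict:
        return {
            "poly_degree": self.poly_degree,
            "plain_modulus": self.plain_modulus,
            "coeff_modulus_bits": list(self.coeff_modulus_bits),
            "security_bits": self.security_bits,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CryptoParams":
        return cls(
            poly_degree=d["poly_degree"],
            plain_modulus=d["plain_modulus"],
            coeff_modulus_bits=tuple(d["coeff_modulus_bits"]),
            security_bits=d.get("security_bits", 128),
        )

    @classmethod
    def default(cls) -> "CryptoParams":
        """Production profile: degree 8192, ≈218-bit chain, 20-bit t."""
        return cls()

    @classmethod
    def test_profile(cls) -> "CryptoParams":
        """Reduced profile for protocol tests (not a secure parameter set)."""
        return cls(poly_degree=2048, security_bits=0)

    @classmethod
    def tiny_profile(cls) -> "CryptoParams":
        """Smallest functional profile, for unit tests only."""
        return cls(poly_degree=1024, security_bits=0)
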