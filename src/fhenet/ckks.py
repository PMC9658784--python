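"""Interpreting cyphertext meta-object over a simulated levelled-CKKS backend.

A :class:`CyphertextMeta` packs a message vector into fixed-capacity SIMD
slots (capacity = polynomial modulus degree / 2) and carries the CKKS
bookkeeping the scheme imposes: the current scale, the remaining modulus
switching chain, the key identity and an accumulated noise estimate.  Every
arithmetic call enforces the levelled-FHE constraint list:

* only whole-vector element-wise addition and multiplication — never a
  sub-slot selection;
* interacting cyphertexts must be identical containers (same parameters,
  same key);
* each multiplication consumes one prime of the switching chain (automatic
  relinearisation and rescaling); an exhausted chain raises
  :class:`~fhenet.errors.DepthExhaustedError` — a key rotation or (out of
  scope) bootstrap is then required;
* mixed-level operands are matched by swapping the higher operand down the
  chain;
* noise grows with every operation, much faster for multiplication than for
  addition, and decryption of an over-noisy cyphertext degrades or garbles.

The simulated backend is noise-exact in values: slot arithmetic is ordinary
IEEE-754 element-wise numpy arithmetic, so a plaintext shadow computation and
its encrypted counterpart agree bit for bit.  An optional ``noisy`` mode
injects seeded Gaussian slot noise scaled by the noise estimate for
robustness testing.  ``key_id`` is an opaque token: there is no actual
cryptography here, and the seam for a real CKKS library is
:class:`BackendInterface`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .autofhe import FHEParams
from .errors import (CapacityError, DepthExhaustedError, InteroperabilityError,
                     KeyMismatchError, NoiseError)

__all__ = [
    "CyphertextMeta",
    "NoiseModel",
    "BackendInterface",
    "SimulatedBackend",
    "encrypt",
    "decrypt",
    "add",
    "multiply",
    "rotate",
    "is_encrypted",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseModel:
    """Noise bookkeeping constants, in bits.

    Additions grow noise slowly, multiplications faster; the rescale that
    follows every multiplication is what keeps the estimate additive rather
    than doubling.  Decryption warns when fewer than ``warn_margin`` bits of
    headroom remain below the scale and fails once the estimate reaches the
    scale itself (the message garbles).
    """

    base_bits: float = 4.0
    add_bits: float = 1.0
    mult_bits: float = 3.0
    warn_margin: float = 6.0


@dataclass
class CyphertextMeta:
    """Slot-packed value vector plus CKKS bookkeeping."""

    slots: np.ndarray
    message_len: int
    scale_log2: int
    chain_remaining: tuple[int, ...]
    key_id: str
    noise_bits: float
    params: FHEParams

    @property
    def level(self) -> int:
        """Multiplicative rescales still available."""
        return len(self.chain_remaining)

    # element-wise call surface shared with plain arrays, so layers run
    # identically on plaintexts and cyphertexts
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return multiply(self, other)

    __rmul__ = __mul__

    def __repr__(self) -> str:  # pragma: no cover
        return (f"CyphertextMeta(len={self.message_len}, "
                f"level={self.level}, key={self.key_id!r}, "
                f"noise={self.noise_bits:.1f}b)")


def is_encrypted(x) -> bool:
    return isinstance(x, CyphertextMeta)


class BackendInterface:
    """Operation contract a real CKKS backend must fulfil."""

    def encrypt(self, message, params, key_id):  # pragma: no cover
        raise NotImplementedError

    def decrypt(self, ct, key_id=None):  # pragma: no cover
        raise NotImplementedError

    def add(self, a, b):  # pragma: no cover
        raise NotImplementedError

    def multiply(self, a, b):  # pragma: no cover
        raise NotImplementedError

    def relinearise(self, ct):  # pragma: no cover
        raise NotImplementedError

    def rescale(self, ct):  # pragma: no cover
        raise NotImplementedError

    def refresh(self, ct, params=None, key_id=None):  # pragma: no cover
        raise NotImplementedError


class SimulatedBackend(BackendInterface):
    """Deterministic CKKS simulator tracking chain and noise exactly."""

    def __init__(self, noise_model: NoiseModel | None = None,
                 noisy: bool = False, seed: int | None = None):
        self.noise_model = noise_model or NoiseModel()
        self.noisy = noisy
        self._rng = np.random.default_rng(seed)

    # -- lifecycle -------------------------------------------------------
    def encrypt(self, message: Sequence[float], params: FHEParams,
                key_id: str = "default") -> CyphertextMeta:
        msg = np.asarray(message, dtype=np.float64).ravel()
        if msg.size > params.slot_capacity:
            raise CapacityError(
                f"message of {msg.size} values exceeds the "
                f"{params.slot_capacity} slots of a degree-"
                f"{params.poly_modulus_degree} cyphertext")
        slots = np.zeros(params.slot_capacity, dtype=np.float64)
        slots[:msg.size] = msg
        return CyphertextMeta(
            slots=slots,
            message_len=int(msg.size),
            scale_log2=params.scale_power,
            chain_remaining=tuple(params.coeff_mod_bit_sizes[1:-1]),
            key_id=key_id,
            noise_bits=self.noise_model.base_bits,
            params=params,
        )

    def decrypt(self, ct: CyphertextMeta, key_id: str | None = None
                ) -> np.ndarray:
        if key_id is not None and key_id != ct.key_id:
            raise KeyMismatchError(
                f"cyphertext was encrypted under {ct.key_id!r}, "
                f"not {key_id!r}")
        garble = float(ct.scale_log2)
        if ct.noise_bits >= garble:
            raise NoiseError(
                f"noise estimate {ct.noise_bits:.1f} bits reaches the "
                f"scale ({garble:.0f} bits); the message would garble")
        if ct.noise_bits >= garble - self.noise_model.warn_margin:
            logger.warning(
                "decrypting with %.1f noise bits against a %.0f-bit scale: "
                "precision loss likely", ct.noise_bits, garble)
        msg = ct.slots[:ct.message_len].copy()
        if self.noisy:
            sd = 2.0 ** (ct.noise_bits - ct.scale_log2)
            msg = msg + self._rng.normal(0.0, sd, size=msg.shape)
        return msg

    # -- arithmetic ------------------------------------------------------
    def _check_interop(self, a: CyphertextMeta, b: CyphertextMeta) -> None:
        if a.key_id != b.key_id:
            raise KeyMismatchError(
                f"cyphertexts from different private keys ({a.key_id!r} vs "
                f"{b.key_id!r}) cannot interoperate")
        if a.params != b.params:
            raise InteroperabilityError(
                "cyphertexts with different encryption parameters are not "
                "identical containers and cannot interoperate")

    @staticmethod
    def _swap_down(ct: CyphertextMeta, levels: int) -> CyphertextMeta:
        """Consume ``levels`` primes without multiplying (modulus switch)."""
        if levels <= 0:
            return ct
        if levels > ct.level:
            raise DepthExhaustedError(
                "cannot switch below the end of the modulus chain")
        return replace(ct, chain_remaining=ct.chain_remaining[levels:])

    def _align(self, a: CyphertextMeta, b: CyphertextMeta
               ) -> tuple[CyphertextMeta, CyphertextMeta]:
        if a.level > b.level:
            a = self._swap_down(a, a.level - b.level)
        elif b.level > a.level:
            b = self._swap_down(b, b.level - a.level)
        return a, b

    def _coerce_plain(self, b, ct: CyphertextMeta):
        arr = np.asarray(b, dtype=np.float64)
        if arr.ndim == 0:
            return arr  # scalar broadcast over every slot
        flat = arr.ravel()
        if flat.size > ct.params.slot_capacity:
            raise CapacityError(
                f"plaintext operand of {flat.size} values exceeds the "
                f"{ct.params.slot_capacity}-slot capacity")
        padded = np.zeros_like(ct.slots)
        padded[:flat.size] = flat
        return padded

    def add(self, a: CyphertextMeta, b) -> CyphertextMeta:
        nm = self.noise_model
        if isinstance(b, CyphertextMeta):
            self._check_interop(a, b)
            a2, b2 = self._align(a, b)
            return replace(
                a2,
                slots=a2.slots + b2.slots,
                message_len=max(a2.message_len, b2.message_len),
                noise_bits=max(a2.noise_bits, b2.noise_bits) + nm.add_bits,
            )
        vec = self._coerce_plain(b, a)
        return replace(a, slots=a.slots + vec,
                       noise_bits=a.noise_bits + nm.add_bits)

    def multiply(self, a: CyphertextMeta, b) -> CyphertextMeta:
        nm = self.noise_model
        if isinstance(b, CyphertextMeta):
            self._check_interop(a, b)
            a2, b2 = self._align(a, b)
            if a2.level == 0:
                raise DepthExhaustedError(
                    "modulus switching chain exhausted: a key rotation or "
                    "refresh is required before further multiplication")
            prod = replace(
                a2,
                slots=a2.slots * b2.slots,
                message_len=max(a2.message_len, b2.message_len),
                noise_bits=max(a2.noise_bits, b2.noise_bits) + nm.mult_bits,
            )
            return self.rescale(self.relinearise(prod))
        if a.level == 0:
            raise DepthExhaustedError(
                "modulus switching chain exhausted: a key rotation or "
                "refresh is required before further multiplication")
        vec = self._coerce_plain(b, a)
        prod = replace(a, slots=a.slots * vec,
                       noise_bits=a.noise_bits + nm.mult_bits)
        return self.rescale(prod)

    def relinearise(self, ct: CyphertextMeta) -> CyphertextMeta:
        # size bookkeeping only in the simulator; values are unchanged
        return ct

    def rescale(self, ct: CyphertextMeta) -> CyphertextMeta:
        if ct.level == 0:
            raise DepthExhaustedError("no prime left to rescale with")
        return replace(ct, chain_remaining=ct.chain_remaining[1:])

    def refresh(self, ct: CyphertextMeta, params: FHEParams | None = None,
                key_id: str | None = None) -> CyphertextMeta:
        msg = ct.slots[:ct.message_len]
        return self.encrypt(msg, params or ct.params, key_id or ct.key_id)


#: module-level default backend used by the convenience functions below
DEFAULT_BACKEND = SimulatedBackend()


def encrypt(message, params: FHEParams, key_id: str = "default",
            backend: BackendInterface | None = None) -> CyphertextMeta:
    return (backend or DEFAULT_BACKEND).encrypt(message, params, key_id)


def decrypt(ct: CyphertextMeta, key_id: str | None = None,
            backend: BackendInterface | None = None) -> np.ndarray:
    return (backend or DEFAULT_BACKEND).decrypt(ct, key_id)


def add(a: CyphertextMeta, b, backend: BackendInterface | None = None
        ) -> CyphertextMeta:
    return (backend or DEFAULT_BACKEND).add(a, b)


def multiply(a: CyphertextMeta, b, backend: BackendInterface | None = None
             ) -> CyphertextMeta:
    return (backend or DEFAULT_BACKEND).multiply(a, b)


def rotate(ct: CyphertextMeta, new_params: FHEParams | None = None,
           new_key_id: str | None = None, mode: str = "refresh",
           ranges: Sequence[tuple[int, int]] | None = None,
           backend: BackendInterface | None = None):
    """Key rotation: simulated decrypt + re-encrypt under new parameters.

    Modes: ``"refresh"`` re-packs the same message with a full chain;
    ``"fold"`` re-encrypts the slot-sum as a length-1 message (this is what
    realises the commuted sum of the convolution windows); ``"split"``
    returns one cyphertext per requested slot range (default: one per slot).
    """
    be = backend or DEFAULT_BACKEND
    params = new_params or ct.params
    key_id = new_key_id or ct.key_id
    msg = ct.slots[:ct.message_len]
    if mode == "refresh":
        return be.encrypt(msg, params, key_id)
    if mode == "fold":
        return be.encrypt(np.asarray([msg.sum()]), params, key_id)
    if mode == "split":
        if ranges is None:
            ranges = [(i, i + 1) for i in range(ct.message_len)]
        return [be.encrypt(msg[lo:hi], params, key_id) for lo, hi in ranges]
    raise ValueError(f"unknown rotation mode {mode!r}")
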