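"""SIMD leveled homomorphic-encryption abstraction.

The protocol needs a CKKS-style cipher: encryption of real vectors with
componentwise (SIMD) addition and multiplication, cyclic slot rotation, and a
finite multiplicative-depth budget per ciphertext.  The mandatory backend here
is an exact-arithmetic *simulator*: the slot vector is held privately inside
the ciphertext payload, level/scale bookkeeping is enforced exactly as a
leveled scheme would, and Gaussian encoding noise is (optionally) injected at
encryption time.  A real-crypto backend can be plugged in behind the same
interface; every protocol property is defined against decrypted values, so the
two backends are interchangeable.

Conventions fixed here and relied on by the packed linear algebra:

* slots are 0-based;
* ``he_rotate(ct, k)`` is a cyclic **left** shift: slot ``i`` of the result
  holds slot ``(i + k) mod n`` of the input;
* every multiplication — ciphertext x ciphertext *and* ciphertext x plaintext —
  consumes exactly one level.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HEParams",
    "KeyMaterial",
    "Ciphertext",
    "HEError",
    "HEParameterError",
    "HEShapeError",
    "DepthExhaustedError",
    "DecryptionError",
    "keygen",
    "encrypt",
    "decrypt",
    "he_add",
    "he_sub",
    "he_mul",
    "he_rotate",
    "save_ciphertext",
    "load_ciphertext",
    "save_keys",
    "load_keys",
]


class HEError(Exception):
    """Base class for homomorphic-encryption layer errors."""


class HEParameterError(HEError, ValueError):
    """Invalid scheme parameters."""


class HEShapeError(HEError, ValueError):
    """Slot-count / vector-length mismatch."""


class DepthExhaustedError(HEError, RuntimeError):
    """A multiplication was requested on a level-0 ciphertext.

    Signals that an interactive masked refresh is required before further
    multiplicative work.
    """


class DecryptionError(HEError, ValueError):
    """Decryption attempted with a non-matching secret key."""


@dataclass(frozen=True)
class HEParams:
    """Scheme parameters.

    slot_count
        Number of real slots *n* per ciphertext (power of two).
    max_level
        Multiplicative depth budget of a fresh ciphertext.
    scale
        Fixed-point encoding scale (bookkeeping only in the simulator; kept
        constant by rescaling after every multiplication).
    encode_noise_std
        Standard deviation of the per-slot Gaussian encoding noise the
        simulator injects at encryption.  ``eps_enc = 5 * encode_noise_std``
        is the advertised componentwise round-trip accuracy; the default is
        chosen so that even after the protocol's worst-case noise
        amplification (bit ciphertexts multiplied by clamped pre-activations)
        end-to-end deviations stay below 1e-6.
    message_bound
        Maximum |slot value| the backend guarantees to encode faithfully.
    """

    slot_count: int = 4096
    max_level: int = 8
    scale: float = 2.0**30
    encode_noise_std: float = 2e-9
    message_bound: float = 2.0**40

    def __post_init__(self) -> None:
        n = self.slot_count
        if n <= 0 or (n & (n - 1)) != 0:
            raise HEParameterError(f"slot_count must be a power of two, got {n}")
        if self.max_level < 1:
            raise HEParameterError("max_level must be >= 1")
        if self.scale <= 0:
            raise HEParameterError("scale must be positive")
        if self.encode_noise_std < 0:
            raise HEParameterError("encode_noise_std must be non-negative")
        if self.encode_noise_std > 1e-3:
            raise HEParameterError("encode_noise_std too large for the encoding precision")
        if self.message_bound <= 0:
            raise HEParameterError("message_bound must be positive")

    @property
    def eps_enc(self) -> float:
        """Componentwise round-trip bound (noise is truncated at this magnitude)."""
        return 5.0 * self.encode_noise_std

    def digest(self) -> bytes:
        """Stable 16-byte parameter hash used in file headers."""
        blob = struct.pack(
            "<qqddd",
            self.slot_count,
            self.max_level,
            self.scale,
            self.encode_noise_std,
            self.message_bound,
        )
        return hashlib.blake2s(blob, digest_size=16).digest()


@dataclass
class KeyMaterial:
    """Key bundle of the simulator backend.

    All fields are deterministic functions of ``(params, seed)`` so that
    regenerating with the same seed yields byte-identical keys.  The secret
    key never leaves this object; ciphertexts carry only a fingerprint of it
    so that decryption with a foreign key fails loudly instead of returning
    garbage.
    """

    params: HEParams
    seed: int
    secret_key: bytes
    public_key: bytes
    rotation_keys: bytes
    _noise_rng: np.random.Generator = field(repr=False, compare=False, default=None)

    @property
    def fingerprint(self) -> bytes:
        return self.public_key


def keygen(params: HEParams, seed: int) -> KeyMaterial:
    """Generate a deterministic key bundle for ``params`` from ``seed``."""
    if not isinstance(params, HEParams):
        raise HEParameterError("params must be an HEParams instance")
    base = hashlib.blake2s(
        b"ppgru-hekeys" + struct.pack("<q", int(seed)) + params.digest()
    ).digest()
    sk = hashlib.blake2s(base + b"sk").digest()
    pk = hashlib.blake2s(sk + b"pk").digest()
    rk = hashlib.blake2s(sk + b"rot").digest()
    noise_rng = np.random.default_rng(int.from_bytes(base[:8], "little"))
    return KeyMaterial(
        params=params,
        seed=int(seed),
        secret_key=sk,
        public_key=pk,
        rotation_keys=rk,
        _noise_rng=noise_rng,
    )


@dataclass
class Ciphertext:
    """Opaque handle on an encrypted slot vector.

    ``_slots`` is backend-private; protocol code must only ever look at a
    ciphertext through :func:`decrypt` with the matching secret key.  Level
    never increases under any operation here — only the interactive masked
    refresh of the secure GRU layer produces a fresh-level ciphertext from an
    exhausted one.
    """

    _slots: np.ndarray
    level: int
    scale: float
    n_slots: int
    key_fingerprint: bytes

    def serialized_size(self) -> int:
        """Bytes on the wire for transcript accounting (header + 8 B/slot)."""
        return 64 + 8 * self.n_slots


def _check_keys(keys: KeyMaterial) -> None:
    if not isinstance(keys, KeyMaterial):
        raise HEParameterError("keys must be KeyMaterial")


def encrypt(v: np.ndarray, keys: KeyMaterial) -> Ciphertext:
    """Encrypt a real vector of length <= slot_count (zero-padded to n).

    The fresh ciphertext sits at ``max_level``.  Slot values must respect
    ``params.message_bound``.
    """
    _check_keys(keys)
    p = keys.params
    v = np.asarray(v, dtype=np.float64).ravel()
    if v.size > p.slot_count:
        raise HEShapeError(f"vector of length {v.size} exceeds slot count {p.slot_count}")
    if v.size and np.max(np.abs(v)) > p.message_bound:
        raise HEParameterError("slot magnitude exceeds message_bound")
    slots = np.zeros(p.slot_count, dtype=np.float64)
    slots[: v.size] = v
    if p.encode_noise_std > 0:
        # truncated just inside +-5 sigma so the eps_enc bound survives the
        # floating-point rounding of the sum
        noise = keys._noise_rng.normal(0.0, p.encode_noise_std, p.slot_count)
        bound = 0.999 * p.eps_enc
        slots = slots + np.clip(noise, -bound, bound)
    return Ciphertext(
        _slots=slots,
        level=p.max_level,
        scale=p.scale,
        n_slots=p.slot_count,
        key_fingerprint=keys.fingerprint,
    )


def decrypt(ct: Ciphertext, keys: KeyMaterial) -> np.ndarray:
    """Decrypt to the full length-n slot vector; fails with a wrong key."""
    _check_keys(keys)
    if ct.key_fingerprint != keys.fingerprint:
        raise DecryptionError("ciphertext was not encrypted under this key")
    return ct._slots.copy()


def _coerce_plain(b, n: int) -> np.ndarray:
    arr = np.asarray(b, dtype=np.float64).ravel()
    if arr.size == 1:
        return np.full(n, float(arr[0]))
    if arr.size > n:
        raise HEShapeError(f"plain operand of length {arr.size} exceeds slot count {n}")
    if arr.size < n:
        arr = np.concatenate([arr, np.zeros(n - arr.size)])
    return arr


def _align(a: Ciphertext, b: Ciphertext) -> int:
    if a.n_slots != b.n_slots:
        raise HEShapeError(f"slot counts differ: {a.n_slots} vs {b.n_slots}")
    if a.key_fingerprint != b.key_fingerprint:
        raise DecryptionError("ciphertexts under different keys cannot be combined")
    # mod-switch the fresher operand down: levels combine at the minimum
    return min(a.level, b.level)


def he_add(a: Ciphertext, b) -> Ciphertext:
    """Componentwise addition with a ciphertext or a plain vector/scalar."""
    if isinstance(b, Ciphertext):
        lvl = _align(a, b)
        return Ciphertext(a._slots + b._slots, lvl, a.scale, a.n_slots, a.key_fingerprint)
    plain = _coerce_plain(b, a.n_slots)
    return Ciphertext(a._slots + plain, a.level, a.scale, a.n_slots, a.key_fingerprint)


def he_sub(a: Ciphertext, b) -> Ciphertext:
    """Componentwise subtraction (same alignment rules as :func:`he_add`)."""
    if isinstance(b, Ciphertext):
        lvl = _align(a, b)
        return Ciphertext(a._slots - b._slots, lvl, a.scale, a.n_slots, a.key_fingerprint)
    plain = _coerce_plain(b, a.n_slots)
    return Ciphertext(a._slots - plain, a.level, a.scale, a.n_slots, a.key_fingerprint)


def he_mul(a: Ciphertext, b) -> Ciphertext:
    """Componentwise product; consumes exactly one level (ct or plain operand).

    Raises :class:`DepthExhaustedError` at level 0 — the caller must run the
    interactive masked refresh first.
    """
    if isinstance(b, Ciphertext):
        lvl = _align(a, b)
        if lvl < 1:
            raise DepthExhaustedError("multiplication at level 0; masked refresh required")
        return Ciphertext(a._slots * b._slots, lvl - 1, a.scale, a.n_slots, a.key_fingerprint)
    if a.level < 1:
        raise DepthExhaustedError("multiplication at level 0; masked refresh required")
    plain = _coerce_plain(b, a.n_slots)
    return Ciphertext(a._slots * plain, a.level - 1, a.scale, a.n_slots, a.key_fingerprint)


def he_rotate(ct: Ciphertext, k: int) -> Ciphertext:
    """Cyclic left shift by ``k``: result slot i = input slot (i+k) mod n."""
    k = int(k) % ct.n_slots
    return Ciphertext(
        np.roll(ct._slots, -k), ct.level, ct.scale, ct.n_slots, ct.key_fingerprint
    )


# ---------------------------------------------------------------------------
# versioned binary files for keys and ciphertexts
# ---------------------------------------------------------------------------

_MAGIC_CT = b"PPGRUCT1"
_MAGIC_KEY = b"PPGRUKY1"
_BACKEND_ID = b"SIM0"


def save_ciphertext(ct: Ciphertext, path, params: HEParams) -> None:
    with open(path, "wb") as fh:
        fh.write(_MAGIC_CT)
        fh.write(_BACKEND_ID)
        fh.write(params.digest())
        fh.write(struct.pack("<qdq", ct.level, ct.scale, ct.n_slots))
        fh.write(ct.key_fingerprint)
        fh.write(ct._slots.astype("<f8").tobytes())


def load_ciphertext(path, params: HEParams) -> Ciphertext:
    with open(path, "rb") as fh:
        if fh.read(8) != _MAGIC_CT:
            raise HEParameterError("not a ciphertext file")
        if fh.read(4) != _BACKEND_ID:
            raise HEParameterError("unknown backend id")
        if fh.read(16) != params.digest():
            raise HEParameterError("parameter hash mismatch; refusing to load")
        level, scale, n = struct.unpack("<qdq", fh.read(24))
        fp = fh.read(32)
        slots = np.frombuffer(fh.read(8 * n), dtype="<f8").copy()
    return Ciphertext(slots, level, scale, n, fp)


def save_keys(keys: KeyMaterial, path) -> None:
    with open(path, "wb") as fh:
        fh.write(_MAGIC_KEY)
        fh.write(_BACKEND_ID)
        fh.write(keys.params.digest())
        fh.write(struct.pack("<q", keys.seed))


def load_keys(path, params: HEParams) -> KeyMaterial:
    """Rebuild keys from the stored seed; refuses on a params-hash mismatch."""
    with open(path, "rb") as fh:
        if fh.read(8) != _MAGIC_KEY:
            raise HEParameterError("not a key file")
        if fh.read(4) != _BACKEND_ID:
            raise HEParameterError("unknown backend id")
        if fh.read(16) != params.digest():
            raise HEParameterError("parameter hash mismatch; refusing to load")
        (seed,) = struct.unpack("<q", fh.read(8))
    return keygen(params, seed)
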