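"""Packed homomorphic linear algebra.

Feature vectors (length 70) are zero-padded to the next power of two (128) so
that with 4096 slots one ciphertext holds B = 4096/128 = 32 slot blocks.  In
single-query mode only block 0 carries data; in batch mode block j carries
sample j, which is how 32 inference queries ride on a single ciphertext and
the homomorphic cost of a linear stage stays independent of the batch size.

Matrix products use generalized-diagonal packing: with the weight matrix W
zero-padded to pad_len x pad_len,

    (W v)_i = sum_j W[i, (i+j) mod p] * v[(i+j) mod p]

so the product is a sum over j of rotate(ct, j) times a plain diagonal mask.
Rotations are cyclic over the whole slot vector, so each block-internal
rotation is realized as the pair rotate(j) / rotate(j - p) with complementary
masks — that keeps every block's arithmetic confined to itself.  One level is
consumed (all plain multiplications happen at the same level), and because
padded rows/columns are zero, no garbage ever appears outside the leading
output slots of each block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .he_core import Ciphertext, DepthExhaustedError, HEShapeError, he_add, he_mul, he_rotate

__all__ = [
    "PackedLayout",
    "WeightMatrix",
    "CapacityError",
    "pad_pow2",
    "he_matvec",
    "pack_batch",
    "unpack_batch",
    "he_matmat",
]


class CapacityError(HEShapeError):
    """More samples than the layout's block capacity B."""


def pad_pow2(v: np.ndarray) -> np.ndarray:
    """Zero-pad to the smallest power of two >= len(v); idempotent."""
    v = np.asarray(v, dtype=np.float64).ravel()
    if v.size == 0:
        raise HEShapeError("cannot pad an empty vector")
    target = 1 << (int(v.size) - 1).bit_length()
    out = np.zeros(target)
    out[: v.size] = v
    return out


@dataclass(frozen=True)
class PackedLayout:
    """Slot partition: B = slot_count / pad_len blocks of pad_len slots.

    ``vec_len``, when set, declares the unpadded vector length the layout was
    built for; matrix products then verify the weight dimensions against it.
    """

    pad_len: int
    slot_count: int = 4096
    mode: str = "single"
    vec_len: int | None = None

    def __post_init__(self) -> None:
        p, n = self.pad_len, self.slot_count
        if p <= 0 or (p & (p - 1)) != 0:
            raise HEShapeError(f"pad_len must be a power of two, got {p}")
        if n % p != 0:
            raise HEShapeError("slot_count must be a multiple of pad_len")
        if self.mode not in ("single", "batch"):
            raise HEShapeError(f"unknown layout mode {self.mode!r}")
        if self.vec_len is not None and not (0 < self.vec_len <= p):
            raise HEShapeError("vec_len must fit inside pad_len")

    @property
    def block_count(self) -> int:
        return self.slot_count // self.pad_len

    @classmethod
    def for_length(cls, length: int, slot_count: int = 4096, mode: str = "single") -> "PackedLayout":
        return cls(
            pad_len=1 << (int(length) - 1).bit_length(),
            slot_count=slot_count,
            mode=mode,
            vec_len=int(length),
        )


@dataclass(frozen=True)
class WeightMatrix:
    """Dense weight matrix with its role in the layer (input W, recurrent U, dense)."""

    entries: np.ndarray
    role: str = "W"

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=np.float64)
        if e.ndim != 2:
            raise HEShapeError("weight matrix must be 2-D")
        if not np.all(np.isfinite(e)):
            raise HEShapeError("weight matrix has non-finite entries")
        if self.role not in ("W", "U", "dense"):
            raise HEShapeError(f"unknown weight role {self.role!r}")
        object.__setattr__(self, "entries", e)

    @property
    def shape(self) -> tuple:
        return self.entries.shape


def _diag_masks(W: np.ndarray, layout: PackedLayout):
    """Per-rotation plain masks, replicated over blocks, split at the block edge."""
    p = layout.pad_len
    n_out, n_in = W.shape
    Wp = np.zeros((p, p))
    Wp[:n_out, :n_in] = W
    masks = []
    i = np.arange(p)
    for j in range(p):
        col = (i + j) % p
        diag = Wp[i, col]
        if not np.any(diag):
            continue
        inner = np.where(i + j < p, diag, 0.0)  # rotate(j) stays inside the block
        outer = np.where(i + j >= p, diag, 0.0)  # rotate(j - p) wraps within the block
        m_in = np.tile(inner, layout.block_count) if np.any(inner) else None
        m_out = np.tile(outer, layout.block_count) if np.any(outer) else None
        masks.append((j, m_in, m_out))
    return masks


def _he_linear(W: WeightMatrix, ct: Ciphertext, layout: PackedLayout) -> Ciphertext:
    Wm = W.entries
    n_out, n_in = Wm.shape
    p = layout.pad_len
    if n_in > p or n_out > p:
        raise HEShapeError(f"matrix {Wm.shape} does not fit pad_len {p}")
    if layout.vec_len is not None and n_in != layout.vec_len:
        raise HEShapeError(
            f"matrix expects input length {n_in} but layout declares {layout.vec_len}"
        )
    if ct.n_slots != layout.slot_count:
        raise HEShapeError("ciphertext slot count does not match layout")
    if ct.level < 1:
        raise DepthExhaustedError("matrix product needs one level; masked refresh required")
    acc = None
    for j, m_in, m_out in _diag_masks(Wm, layout):
        if m_in is not None:
            term = he_mul(he_rotate(ct, j), m_in)
            acc = term if acc is None else he_add(acc, term)
        if m_out is not None:
            term = he_mul(he_rotate(ct, j - p), m_out)
            acc = term if acc is None else he_add(acc, term)
    if acc is None:  # all-zero matrix: burn the level for uniform accounting
        acc = he_mul(ct, 0.0)
    return acc


def he_matvec(W: WeightMatrix, ct_v: Ciphertext, layout: PackedLayout) -> Ciphertext:
    """Single-query product: leading slots of block 0 become W v; one level."""
    if layout.mode != "single":
        raise HEShapeError("he_matvec requires a single-mode layout")
    return _he_linear(W, ct_v, layout)


def he_matmat(W: WeightMatrix, ct_X: Ciphertext, layout: PackedLayout) -> Ciphertext:
    """Batch product: block j of the result is W x_j, one ciphertext for all B samples."""
    if layout.mode != "batch":
        raise HEShapeError("he_matmat requires a batch-mode layout")
    return _he_linear(W, ct_X, layout)


def pack_batch(samples, layout: PackedLayout) -> np.ndarray:
    """Lay out up to B sample vectors block-contiguously (client side, pre-encryption)."""
    samples = [np.asarray(s, dtype=np.float64).ravel() for s in samples]
    B, p = layout.block_count, layout.pad_len
    if len(samples) > B:
        raise CapacityError(f"{len(samples)} samples exceed batch capacity {B}")
    out = np.zeros(layout.slot_count)
    for j, s in enumerate(samples):
        if s.size > p:
            raise HEShapeError(f"sample of length {s.size} exceeds pad_len {p}")
        out[j * p : j * p + s.size] = s
    return out


def unpack_batch(slots: np.ndarray, layout: PackedLayout, length: int | None = None) -> list:
    """Inverse of :func:`pack_batch`: per-block leading slots."""
    p = layout.pad_len
    length = p if length is None else int(length)
    return [slots[j * p : j * p + length].copy() for j in range(layout.block_count)]
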