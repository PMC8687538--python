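"""Secure input adjustment: clamp encrypted pre-activations into [-R, R].

A polynomial activation approximation is only trustworthy inside its
approximation range, but the server cannot see the encrypted pre-activations
to check them.  This protocol replaces each selected slot m by

    m' = R    if m > R        (upper branch)
    m' = m    if -R <= m <= R
    m' = -R   if m < -R       (lower branch)

without either party learning m or the comparison outcomes:

Step 1 — the server adds an integer mask r per slot and sends the ciphertext;
the client decrypts and rounds, leaving the parties with additive shares
m_s = -r and m_c = round(m + r).

Step 2 — one batched garbled-circuit execution compares the share sum against
±R; the client learns only the XOR-blinded bits h_g = c_g ^ b_g and
h_l = c_l ^ b_l, encrypts them, and returns the ciphertexts.

Step 3 — the server unblinds homomorphically (c = h when b = 0, c = 1 - h
when b = 1) and evaluates the recovery polynomial
m' = (1 - c_g - c_l) * m + R * (c_g - c_l), spending at most two levels.

Because the masks are integers, round(m + r) - r = round(m), so the decision
is exactly (round(m) > R): values with |m| <= R - 1 always pass through,
values with |m| >= R + 1 always clamp, and inside the rounding band
(R - 1, R + 1) the output is one of {m, sign(m) * R} — the band the
approximation range [-R - 1, R + 1] is widened to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gc_2pc import GCProtocolError, run_2pc_compare
from .he_core import (
    Ciphertext,
    DepthExhaustedError,
    HEShapeError,
    KeyMaterial,
    decrypt,
    encrypt,
    he_add,
    he_mul,
    he_sub,
)

__all__ = [
    "AdjustConfig",
    "ShareState",
    "clamp_plain",
    "ct_to_shares",
    "recover_clamped",
    "secure_clamp",
]


@dataclass(frozen=True)
class AdjustConfig:
    """Clamp-protocol parameters.

    R
        Clamp threshold (integer).  With the sigmoid interpolant built on
        [-10, 10] and the rounding band extending the effective range to
        [-R-1, R+1], R = 9 for sigmoid gates; the tanh identity doubles its
        argument, so the candidate gate uses R = 4.
    mask_bound
        Masks are drawn uniformly from the integers of [-mask_bound,
        mask_bound]; must exceed the message bound by the statistical hiding
        margin 2**stat_sec.
    k
        Comparator bit width (two's complement) for the garbled circuit.
    message_bound
        Asserted ceiling on |m| for adjusted slots (protocol contract).
    stat_sec
        Statistical hiding margin, in bits, of mask over message.
    """

    R: int = 9
    mask_bound: int = 1 << 27
    k: int = 32
    message_bound: float = 64.0
    stat_sec: int = 20

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("clamp threshold R must be a positive integer")
        if self.message_bound <= 0:
            raise ValueError("message_bound must be positive")
        if self.message_bound + self.mask_bound >= 2 ** (self.k - 1):
            raise ValueError(
                "message_bound + mask_bound must fit k-1 bits (overflow risk)"
            )
        if self.mask_bound < (1 << self.stat_sec) * self.message_bound:
            raise ValueError(
                "mask_bound too small for the statistical hiding margin "
                f"(need >= 2^{self.stat_sec} * message_bound)"
            )


@dataclass
class ShareState:
    """Post-Step-1 state: additive shares and the server's blind bits."""

    server_m_s: list
    client_m_c: list
    blinds_g: list = field(default_factory=list)
    blinds_l: list = field(default_factory=list)
    slots: list = field(default_factory=list)


def clamp_plain(m, R: float):
    """The plaintext clamp oracle the secure protocol must reproduce."""
    return np.clip(np.asarray(m, dtype=np.float64), -R, R)


def ct_to_shares(
    ct_m: Ciphertext,
    slots,
    cfg: AdjustConfig,
    keys: KeyMaterial,
    rng: np.random.Generator,
    transcript=None,
) -> ShareState:
    """Step 1: HE ciphertext -> additive shares of the selected slots.

    The server masks *every* slot (so the client's decrypt reveals nothing),
    sends the ciphertext, and the client rounds the selected slots.  The
    share sum satisfies |m_s + m_c - m| <= 1 (integer masks leave only the
    client-side rounding error of at most 1/2).
    """
    slots = [int(s) for s in slots]
    if any(s < 0 or s >= ct_m.n_slots for s in slots):
        raise HEShapeError("adjusted slot index out of range")
    r_all = rng.integers(-cfg.mask_bound, cfg.mask_bound + 1, size=ct_m.n_slots)
    ct_masked = he_add(ct_m, r_all.astype(np.float64))
    if transcript is not None:
        transcript.log("adjust/step1", "server->client", ct_masked.serialized_size(), "ciphertext")
    # client side: decrypt and take the integer part of the selected slots
    masked = decrypt(ct_masked, keys)
    m_c = [int(np.rint(masked[s])) for s in slots]
    m_s = [-int(r_all[s]) for s in slots]
    b_g = [int(b) for b in rng.integers(0, 2, size=len(slots))]
    b_l = [int(b) for b in rng.integers(0, 2, size=len(slots))]
    return ShareState(server_m_s=m_s, client_m_c=m_c, blinds_g=b_g, blinds_l=b_l, slots=slots)


def _unblind_plain_vectors(state: ShareState, n_slots: int):
    """Plain (sign, offset) vectors realizing c = h ^ b with a slot selector.

    c = h * (1 - 2b) + b at selected slots, 0 elsewhere — the XOR with the
    server's own plain bit, fused with the mask that keeps non-adjusted slots
    at zero so the recovery polynomial is the identity there.
    """
    sign_g = np.zeros(n_slots)
    off_g = np.zeros(n_slots)
    sign_l = np.zeros(n_slots)
    off_l = np.zeros(n_slots)
    for s, bg, bl in zip(state.slots, state.blinds_g, state.blinds_l):
        sign_g[s] = 1.0 - 2.0 * bg
        off_g[s] = float(bg)
        sign_l[s] = 1.0 - 2.0 * bl
        off_l[s] = float(bl)
    return sign_g, off_g, sign_l, off_l


def recover_clamped(
    ct_m: Ciphertext,
    ct_h_g: Ciphertext,
    ct_h_l: Ciphertext,
    state: ShareState,
    R: int,
    transcript=None,
) -> Ciphertext:
    """Step 3: unblind and evaluate m' = (1 - c_g - c_l) m + R (c_g - c_l).

    Consumes at most two levels: one on the h-bit ciphertexts for the
    unblinding products, one on ct_m for the selector product.  Non-adjusted
    slots pass through unchanged (their c bits are forced to zero).
    """
    if ct_m.level < 1:
        raise DepthExhaustedError("recovery needs one level on the message ciphertext")
    sign_g, off_g, sign_l, off_l = _unblind_plain_vectors(state, ct_m.n_slots)
    c_g = he_add(he_mul(ct_h_g, sign_g), off_g)
    c_l = he_add(he_mul(ct_h_l, sign_l), off_l)
    # expand: m' = m - (c_g + c_l) * m + R*c_g - R*c_l  (avoids negating a ciphertext)
    both = he_add(c_g, c_l)
    prod = he_mul(both, ct_m)
    r_term = he_sub(he_mul(c_g, float(R)), he_mul(c_l, float(R)))
    return he_add(he_sub(ct_m, prod), r_term)


def secure_clamp(
    ct_m: Ciphertext,
    slots,
    cfg: AdjustConfig,
    keys: KeyMaterial,
    rng: np.random.Generator,
    transcript=None,
) -> Ciphertext:
    """Full Steps 1-3: returns the ciphertext of the clamped message.

    Per selected slot, m' = m when |m| <= R - 1, m' = sign(m) * R when
    |m| >= R + 1, and one of {m, sign(m) * R} inside the rounding band;
    non-selected slots are untouched.  Neither party sees m or the comparison
    bits in the clear.
    """
    state = ct_to_shares(ct_m, slots, cfg, keys, rng, transcript)
    for m_s, m_c in zip(state.server_m_s, state.client_m_c):
        if abs(m_s) >= 2 ** (cfg.k - 1) or abs(m_c) >= 2 ** (cfg.k - 1):
            raise GCProtocolError("share outside the comparator's bit width")
    gc_seed = int(rng.integers(0, 2**31))
    h_g, h_l = run_2pc_compare(
        {"m_s": state.server_m_s, "b_g": state.blinds_g, "b_l": state.blinds_l},
        {"m_c": state.client_m_c},
        cfg.k,
        cfg.R,
        seed=gc_seed,
        transcript=transcript,
    )
    # client encrypts the blinded bits at the adjusted slot positions
    vec_g = np.zeros(ct_m.n_slots)
    vec_l = np.zeros(ct_m.n_slots)
    for s, hg, hl in zip(state.slots, h_g, h_l):
        vec_g[s] = hg
        vec_l[s] = hl
    ct_h_g = encrypt(vec_g, keys)
    ct_h_l = encrypt(vec_l, keys)
    if transcript is not None:
        transcript.log("adjust/step2-bits", "client->server", ct_h_g.serialized_size(), "ciphertext")
        transcript.log("adjust/step2-bits", "client->server", ct_h_l.serialized_size(), "ciphertext")
    return recover_clamped(ct_m, ct_h_g, ct_h_l, state, cfg.R, transcript)
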