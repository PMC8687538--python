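"""Secure GRU cell evaluation and full two-party model inference.

The server holds the model weights, the client holds the visit sequence and
the decryption key.  Each GRU cell runs the fixed seven-stage workflow:

1. Linear (HE):      z_in = W_z x + U_z h + b_z,  r_in = W_r x + U_r h + b_r
2. Adjustment (2PC): clamp z_in and r_in into [-R, R]           (R = 9)
3. Non-linear (HE):  z = σ(z_in), r = σ(r_in) via the Chebyshev interpolant
4. Linear (HE):      h⊙r, then g_in = W_g x + U_g (h⊙r) + b_g
5. Adjustment (2PC): clamp g_in into [-R_tanh, R_tanh]          (R_tanh = 4)
6. Non-linear (HE):  g = tanh(g_in) via the identity 2σ(2x) - 1
7. Linear (HE):      h_t = g + z ⊙ (h_prev - g)

A level accountant precedes every multiplicative stage: whenever the
ciphertext's remaining depth is below the stage's declared requirement it
inserts a masked refresh — the interactive stand-in for bootstrapping, where
the server sends the additively masked ciphertext, the client
decrypts-then-re-encrypts it fresh, and the server removes the mask.

A patient with N visits costs exactly 2N cell evaluations (N per layer);
layer 2 contributes only its final state, the server stops after the dense
matrix product, and the client finishes with the (plain) Weibull activation.
Batch mode packs up to 32 equal-length patients into each ciphertext, so the
homomorphic work per linear stage is independent of the batch size while the
garbled-circuit work grows linearly — the throughput asymmetry the hybrid
design exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation_approx import (
    ChebPoly,
    build_sigmoid_cheb,
    cheb_levels_required,
    eval_cheb_he,
    tanh_from_sigmoid,
)
from .he_core import (
    Ciphertext,
    HEShapeError,
    KeyMaterial,
    decrypt,
    encrypt,
    he_add,
    he_mul,
    he_sub,
)
from .input_adjust import AdjustConfig, secure_clamp
from .plain_model import (
    GRUCellWeights,
    GRUModelWeights,
    weibull_activate,
)
from .secure_linear import CapacityError, PackedLayout, he_matmat, he_matvec, pack_batch, pad_pow2
from .transcript import Transcript

__all__ = [
    "Transcript",
    "SecureSession",
    "BatchingError",
    "masked_refresh",
    "secure_gru_cell",
    "secure_infer",
    "secure_infer_batch",
]


class BatchingError(ValueError):
    """Batch constraint violated (mixed visit counts or over capacity)."""


REFRESH_MASK_BOUND = float(1 << 27)


def masked_refresh(
    ct: Ciphertext,
    keys: KeyMaterial,
    rng: np.random.Generator,
    transcript: Transcript | None = None,
) -> Ciphertext:
    """Restore full level interactively; the message is preserved.

    The server adds a uniform random mask (hiding the intermediate result),
    ships the ciphertext, the client decrypts and re-encrypts fresh, and the
    server subtracts the mask from the returned ciphertext.
    """
    mask = rng.uniform(-REFRESH_MASK_BOUND, REFRESH_MASK_BOUND, ct.n_slots)
    ct_masked = he_add(ct, mask)
    if transcript is not None:
        transcript.log("refresh/out", "server->client", ct_masked.serialized_size(), "ciphertext")
    # client side: decrypt-then-encrypt
    fresh = encrypt(decrypt(ct_masked, keys), keys)
    if transcript is not None:
        transcript.log("refresh/back", "client->server", fresh.serialized_size(), "ciphertext")
    return he_sub(fresh, mask)


@dataclass
class SecureSession:
    """Two-party inference context: keys, approximation, clamp configs, log.

    ``protocol_rng`` drives every server-side protocol random choice (masks,
    blind bits, garbling seeds); with the simulator backend a fixed seed makes
    the whole interaction deterministic.
    """

    keys: KeyMaterial
    sig_poly: ChebPoly = None
    cfg_sig: AdjustConfig = field(default_factory=lambda: AdjustConfig(R=9))
    cfg_tanh: AdjustConfig = field(default_factory=lambda: AdjustConfig(R=4))
    protocol_rng: np.random.Generator = None
    transcript: Transcript = field(default_factory=Transcript)
    cell_count: int = 0
    refresh_count: int = 0

    def __post_init__(self) -> None:
        if self.sig_poly is None:
            self.sig_poly = build_sigmoid_cheb(24, (-10.0, 10.0))
        if self.protocol_rng is None:
            self.protocol_rng = np.random.default_rng(0)
        a, b = self.sig_poly.range
        if not (-self.cfg_sig.R - 1 >= a and self.cfg_sig.R + 1 <= b):
            raise ValueError("sigmoid clamp band [-R-1, R+1] must lie inside the interpolant range")
        if not (2 * (self.cfg_tanh.R + 1) <= b):
            raise ValueError("tanh clamp band doubled must lie inside the interpolant range")
        self.layout_single = PackedLayout(pad_len=128, slot_count=self.keys.params.slot_count, mode="single")
        self.layout_batch = PackedLayout(pad_len=128, slot_count=self.keys.params.slot_count, mode="batch")

    # -- level accountant ---------------------------------------------------

    def ensure_level(self, ct: Ciphertext, need: int) -> Ciphertext:
        if ct.level < need:
            ct = masked_refresh(ct, self.keys, self.protocol_rng, self.transcript)
            self.refresh_count += 1
        return ct

    def _linear(self, W, ct, batch: bool):
        if batch:
            return he_matmat(W, ct, self.layout_batch)
        return he_matvec(W, ct, self.layout_single)

    def _bias_slots(self, bias: np.ndarray, n_blocks: int) -> np.ndarray:
        p = self.layout_single.pad_len
        out = np.zeros(self.keys.params.slot_count)
        block = np.zeros(p)
        block[: bias.size] = bias
        for j in range(n_blocks):
            out[j * p : (j + 1) * p] = block
        return out


def _clamp_slots(n_hidden: int, n_blocks: int, pad_len: int) -> list:
    return [j * pad_len + i for j in range(n_blocks) for i in range(n_hidden)]


def secure_gru_cell(
    ct_x: Ciphertext,
    ct_h_prev: Ciphertext,
    w: GRUCellWeights,
    session: SecureSession,
    *,
    n_blocks: int = 1,
    batch: bool = False,
) -> Ciphertext:
    """One encrypted GRU step (the seven-stage workflow); returns E(h_t)."""
    s = session
    keys, rng, tr = s.keys, s.protocol_rng, s.transcript
    sig_need = cheb_levels_required(s.sig_poly.degree)
    slots = _clamp_slots(w.n_hidden, n_blocks, s.layout_single.pad_len)
    bias_z = s._bias_slots(w.b_z, n_blocks)
    bias_r = s._bias_slots(w.b_r, n_blocks)
    bias_g = s._bias_slots(w.b_g_vec, n_blocks)

    # Linear 1
    ct_x = s.ensure_level(ct_x, 1)
    ct_h_prev = s.ensure_level(ct_h_prev, 1)
    z_in = he_add(he_add(s._linear(w.W_z, ct_x, batch), s._linear(w.U_z, ct_h_prev, batch)), bias_z)
    r_in = he_add(he_add(s._linear(w.W_r, ct_x, batch), s._linear(w.U_r, ct_h_prev, batch)), bias_r)

    # Input adjustment 1 + Non-linear 1
    z_cl = secure_clamp(s.ensure_level(z_in, 2), slots, s.cfg_sig, keys, rng, tr)
    r_cl = secure_clamp(s.ensure_level(r_in, 2), slots, s.cfg_sig, keys, rng, tr)
    z = eval_cheb_he(s.sig_poly, s.ensure_level(z_cl, sig_need))
    r = eval_cheb_he(s.sig_poly, s.ensure_level(r_cl, sig_need))

    # Linear 2
    r = s.ensure_level(r, 1)
    ct_h_prev = s.ensure_level(ct_h_prev, 1)
    hr = he_mul(ct_h_prev, r)
    hr = s.ensure_level(hr, 1)
    g_in = he_add(he_add(s._linear(w.W_g, ct_x, batch), s._linear(w.U_g, hr, batch)), bias_g)

    # Input adjustment 2 + Non-linear 2
    g_cl = secure_clamp(s.ensure_level(g_in, 2), slots, s.cfg_tanh, keys, rng, tr)
    g = tanh_from_sigmoid(s.sig_poly, s.ensure_level(g_cl, sig_need))

    # Linear 3: h_t = g + z * (h_prev - g)
    diff = he_sub(ct_h_prev, g)
    z = s.ensure_level(z, 1)
    diff = s.ensure_level(diff, 1)
    h_t = he_add(g, he_mul(z, diff))
    s.cell_count += 1
    return h_t


def _validate_records(records, model: GRUModelWeights):
    seq = [np.asarray(x, dtype=np.float64).ravel() for x in records]
    if len(seq) == 0:
        raise ValueError("at least one visit record is required")
    n_in = model.layer1.n_input
    for x in seq:
        if x.size != n_in:
            raise HEShapeError(f"feature vector length {x.size} != {n_in}")
    return seq


def _run_layers(ct_seq, model, session, n_blocks, batch):
    """Shared layer loop: returns the dense-output ciphertext."""
    s = session
    zero = encrypt(np.zeros(s.keys.params.slot_count), s.keys)  # h_0 = 0, server-encrypted
    h1 = zero
    outputs1 = []
    for ct_x in ct_seq:
        h1 = secure_gru_cell(ct_x, h1, model.layer1, s, n_blocks=n_blocks, batch=batch)
        outputs1.append(h1)
    h2 = encrypt(np.zeros(s.keys.params.slot_count), s.keys)
    for ct_y in outputs1:
        h2 = secure_gru_cell(ct_y, h2, model.layer2, s, n_blocks=n_blocks, batch=batch)
    h2 = s.ensure_level(h2, 1)
    dense_ct = s._linear(model.dense, h2, batch)
    bias = s._bias_slots(model.dense_bias, n_blocks)
    return he_add(dense_ct, bias)


def secure_infer(records, model: GRUModelWeights, session: SecureSession) -> dict:
    """Single-query inference: one patient, one ciphertext per visit.

    Returns the client-side result: dense outputs (a, b), Weibull parameters,
    and the protocol counters (2N cells for N visits).
    """
    seq = _validate_records(records, model)
    s = session
    cells_before = s.cell_count
    refresh_before = s.refresh_count
    # client encrypts each record vector into its own ciphertext
    ct_seq = []
    for x in seq:
        ct = encrypt(pad_pow2(x), s.keys)
        s.transcript.log("query/record", "client->server", ct.serialized_size(), "ciphertext")
        ct_seq.append(ct)
    out_ct = _run_layers(ct_seq, model, s, n_blocks=1, batch=False)
    s.transcript.log("result/dense", "server->client", out_ct.serialized_size(), "ciphertext")
    # client side: decrypt, read (a, b), finish with the plain Weibull map
    dec = decrypt(out_ct, s.keys)
    a, b = float(dec[0]), float(dec[1])
    wp = weibull_activate(a, b)
    return {
        "a": a,
        "b": b,
        "alpha": wp.alpha,
        "beta": wp.beta,
        "cell_count": s.cell_count - cells_before,
        "refresh_count": s.refresh_count - refresh_before,
    }


def secure_infer_batch(cohort_records, model: GRUModelWeights, session: SecureSession) -> list:
    """Batch inference: up to 32 patients with an equal number of visits.

    Per time step one ciphertext carries all patients (block-packed); the
    results are per-patient dicts matching the single-query output.
    """
    s = session
    B = s.layout_batch.block_count
    if len(cohort_records) == 0:
        raise ValueError("empty batch")
    if len(cohort_records) > B:
        raise CapacityError(f"batch of {len(cohort_records)} exceeds capacity {B}")
    seqs = [_validate_records(r, model) for r in cohort_records]
    n_visits = {len(q) for q in seqs}
    if len(n_visits) != 1:
        raise BatchingError("all batched patients must share the same number of visits")
    N = n_visits.pop()
    cells_before = s.cell_count
    refresh_before = s.refresh_count
    ct_seq = []
    for t in range(N):
        packed = pack_batch([pad_pow2(q[t]) for q in seqs], s.layout_batch)
        ct = encrypt(packed, s.keys)
        s.transcript.log("query/batch-record", "client->server", ct.serialized_size(), "ciphertext")
        ct_seq.append(ct)
    out_ct = _run_layers(ct_seq, model, s, n_blocks=len(seqs), batch=True)
    s.transcript.log("result/dense", "server->client", out_ct.serialized_size(), "ciphertext")
    dec = decrypt(out_ct, s.keys)
    p = s.layout_batch.pad_len
    results = []
    for j in range(len(seqs)):
        a, b = float(dec[j * p]), float(dec[j * p + 1])
        wp = weibull_activate(a, b)
        results.append(
            {
                "a": a,
                "b": b,
                "alpha": wp.alpha,
                "beta": wp.beta,
                "cell_count": s.cell_count - cells_before,
                "refresh_count": s.refresh_count - refresh_before,
            }
        )
    return results
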