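# Methods

## The problem

A server owns a trained GRU survival model for clinical time-to-event
prediction; a client owns a patient's longitudinal visit records.  The goal
is for the client to obtain the model's prediction while the server learns
nothing about the records and the client learns nothing about the weights
beyond what the prediction itself reveals.  Both parties are assumed
semi-honest: they follow the protocol but may try to infer extra information
from their view.

The model is fixed and public in architecture: visit records are 70-length
real vectors; GRU layer 1 maps the sequence of 70-vectors to a sequence of
32-vectors, GRU layer 2 consumes that sequence and keeps only its last
20-length state, and a dense layer emits two numbers (a, b) that the client
maps to a Weibull distribution over time to recurrence, alpha = exp(a)
(scale, in months) and beta = softplus(b) (shape).  Both maps are strictly
monotone, so handing the client (a, b) is informationally identical to
handing it the prediction; the server therefore stops after the dense matrix
product and the Weibull activation runs client-side in the clear.

## Protocol overview

Homomorphic encryption handles everything linear; a garbled-circuit
two-party computation handles the one thing polynomials cannot: deciding
whether a hidden value is out of range.

* **HE layer.** A CKKS-style leveled scheme over vectors of 4096 real slots
  with SIMD addition/multiplication and cyclic rotation.  Every
  multiplication (ciphertext or plaintext operand) consumes one level of a
  depth budget of 8; a level-0 ciphertext must be refreshed before further
  products.  The mandatory backend in this package is an exact-arithmetic
  simulator: the slot vector is held privately inside the ciphertext, level
  and scale bookkeeping are enforced exactly, and bounded Gaussian encoding
  noise (sigma = 2e-9, truncated at 5 sigma, so the per-slot round-trip
  bound eps_enc = 1e-8 is exact) is injected at encryption.  The default is
  chosen so that even after the protocol's worst noise amplification —
  bit-carrying ciphertexts multiplied by pre-activations up to the message
  bound — end-to-end deviations stay below 1e-6, which is the tolerance the
  protocol-level tests use.  A real-crypto backend can be plugged in behind
  the same interface; all contracts are stated on decrypted values.

* **Packing.** 70-length records are zero-padded to 128 slots, so one
  ciphertext holds 4096/128 = 32 blocks.  Single-query mode uses block 0;
  batch mode gives each of up to 32 equal-length patients a block.  Matrix
  products use generalized-diagonal packing: rotate-by-j times a plain
  diagonal mask, summed over j, with each rotation realized as the pair
  (j, j-128) with complementary masks so block contents never mix.  One
  level per product; because padded rows and columns are zero, no garbage
  slots are produced and no masking level is needed (the rotate-and-sum
  alternative with row-replicated weights computes the same contract but
  leaves garbage to clean).  The homomorphic cost of a linear stage is
  independent of the batch size — only the garbled-circuit work grows with
  the number of queries.

* **Activation approximation.** Sigmoid is evaluated through its degree-24
  Chebyshev interpolant on [-10, 10] (first-kind nodes).  Its dense-grid
  max error, measured on 10,001 points, is 5.39e-4 and is pinned in the
  test suite at 5.5e-4.  tanh reuses the same interpolant via
  tanh(x) = 2 sigma(2x) - 1; both the argument doubling and the output
  affine map fold into existing levels, so encrypted tanh costs the same
  depth as sigmoid.  Encrypted evaluation builds T_1..T_24 by the product
  recurrences T_2k = 2 T_k^2 - 1 and T_2k+1 = 2 T_k T_k+1 - T_1
  (doubling done by addition, which is free), for a total depth of
  1 (domain map) + 5 (basis tree) + 1 (coefficient products) = 7 levels.

* **Secure input adjustment (clamp).** Chebyshev interpolants diverge
  violently outside their range, and the server cannot see whether an
  encrypted pre-activation strayed.  The clamp protocol replaces each
  selected slot m by m' = m if |m| <= R, else sign(m) * R, without either
  party learning m: (1) the server adds a uniform *integer* mask
  r in [-2^27, 2^27] to every slot and ships the ciphertext; the client
  decrypts and rounds, leaving additive shares m_s = -r, m_c = round(m + r);
  (2) one garbled-circuit execution per gate vector (32 or 20 comparator
  instances with concatenated wires) computes the share sum in two's
  complement, widened internally by two bits so it cannot overflow, and
  hands the client only the XOR-blinded bits h_g = (m > R) xor b_g,
  h_l = (m < -R) xor b_l; the client encrypts them and sends them back;
  (3) the server unblinds homomorphically (c = h when its own bit b = 0,
  1 - h when b = 1, fused with a selector that zeroes non-adjusted slots)
  and evaluates m' = (1 - c_g - c_l) m + R (c_g - c_l), spending one level
  on the h-bits and one on m.  Because masks are integers,
  round(m + r) - r = round(m) exactly, so the decision is deterministic at
  threshold R + 1/2; within the rounding band (R-1, R+1) the output is one
  of {m, sign(m) R}, and the approximation range is widened to [-R-1, R+1]
  to absorb it.  With the sigmoid range [-10, 10] this gives R = 9 for the
  sigmoid gates; the tanh identity doubles its argument, so the candidate
  gate uses R_tanh = 4 (2 * (4+1) <= 10).

* **Garbled circuits.** Classic Yao with point-and-permute and free-XOR:
  128-bit wire labels whose low bit is the select bit, a global odd offset,
  XOR/NOT free, and one four-row table per AND gate encrypted under a
  blake2s-based PRF of the two input labels and the gate id.  Rows carry
  128 zero check bits and output wires carry per-label authentication
  hashes, so corrupted labels fail loudly instead of decoding to a wrong
  answer.  The comparator uses k = 32-bit shares by default: the integer
  masks must exceed the message bound (64, generous for pre-activations
  that rarely pass +-15) by the statistical hiding margin 2^20, and
  message + mask must fit k-1 bits.  Oblivious transfer is an in-process
  ideal functionality — the sender's label pairs and the receiver's choice
  bits never co-reside in either party object; a cryptographic OT can be
  substituted behind the same interface.

* **Masked refresh.** Instead of native bootstrapping, an exhausted
  ciphertext is additively masked by the server, decrypted-and-re-encrypted
  by the client, and unmasked by the server.  A level accountant precedes
  every multiplicative stage of the cell (linear products need 1 level, the
  clamp 2, the activation 7) and inserts refreshes whenever the remaining
  depth is short, so depth exhaustion can never surface for any sequence
  length; placement is recorded in the transcript.

* **Cell workflow.**  Linear-1 (z and r pre-activations) → clamp both at
  R = 9 → sigmoid → Linear-2 (h ⊙ r, then the candidate pre-activation,
  reset applied to the state *before* the recurrent product) → clamp at
  R_tanh = 4 → tanh → Linear-3, using the one-multiplication output form
  h_t = g + z ⊙ (h_prev - g).  A patient with N visits costs exactly 2N
  cell evaluations.  The number of visits is revealed to the server by the
  ciphertext count; this is accepted as public, like the architecture.

## The plaintext reference ("clamped mode")

The function the encrypted pipeline computes is *not* the exact GRU — it is
the GRU with every pre-activation clamped and every activation replaced by
the interpolant.  `plain_model` implements both: `exact` mode (true
sigmoid/tanh) and `clamped` mode, which is the oracle every secure test
compares against.  Clamping is nearly harmless by design — sigma changes by
at most ~2e-4 beyond |x| = 8 — which is precisely why the method loses no
accuracy; it also means the clamped and exact models differ by well under
1e-3 on typical cells, so "the secure path follows the clamp oracle" is
asserted through its several-fold smaller deviation, not a gross gap.

Measured deviations with the simulator backend (deterministic seeds): the
secure cell matches the clamped reference to ~2e-4 over 100 random-weight
trials (the residual comes from the rounding band, where the secure
threshold sits at R + 1/2 while the oracle clamps at exactly R), and full
two-layer inference matches to under 1e-4 on (a, b).  Both tolerances are
pinned in the tests at 1e-3.  Risk rankings of secure and plaintext
predictions agree patient-for-patient, hence the two concordance indices
are identical — the desk-scale analogue of "privacy preservation costs no
accuracy".

## Synthetic data

The clinical cohort the protocol was originally validated on (13k+ breast
cancer patients with recurrence follow-up) is not publicly available, so the
generator emulates its statistical shape rather than its clinical content:

* per patient, 1 + truncated-Poisson visits (mean 5.13, matching roughly
  twice-yearly follow-up) at sorted uniform month offsets in a 24-month
  window;
* 70 encoded columns: twelve patient-level one-hot blocks totalling 40
  columns (clinicopathologic/treatment categoricals), 29 continuous labs
  built from a patient-level latent mean plus visit noise, 10% of entries
  knocked out and refilled by last-observation-carried-forward (cohort
  average at the first visit), then z-scored cohort-wide; and one
  ki67-style proportion feature binned to decile midpoints
  {0.05, ..., 0.95};
* Weibull event times (shape 1.5, base scale 60 months) accelerated by a
  standardized linear risk score — by default a random projection of the
  mean feature vector, or, to emulate a *trained* model, the model's own
  plaintext risk predictions (used by the demo and the acceptance script so
  the reported C-index is meaningfully above chance); independent uniform
  censoring with the horizon bisected to hit the target censoring fraction
  (default 0.9, mirroring a ~9% event rate).

Model weights are Gaussian, globally rescaled by bisection until a target
fraction (default 5%) of gate pre-activations measured on a 500-patient
reference cohort exceeds the clamp-relevant range — guaranteeing the clamp
path is genuinely exercised rather than vacuously passed.  What the
generator does *not* emulate: real marginals and correlations of clinical
features, informative censoring, visit-time irregularity tied to disease
state, and a trained (rather than calibrated-random) weight matrix.  Green
tests therefore certify protocol fidelity — encrypted inference equals the
clamped plaintext model wherever the model came from — not clinical model
quality.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| slot_count | 4096 | real slots per ciphertext |
| max_level | 8 | depth budget between refreshes (covers one cell segment) |
| encode_noise_std | 2e-9 | simulator encoding noise (truncated, eps_enc = 1e-8) |
| R / R_tanh | 9 / 4 | clamp thresholds for sigmoid / candidate gates |
| cheb degree, range | 24, [-10, 10] | sigmoid interpolant |
| comparator k | 32 bits | share width in the garbled comparator |
| mask_bound | 2^27 | integer share masks (2^20 hiding margin over message bound 64) |
| refresh mask bound | 2^27 | additive mask for interactive refresh |

## Numerical and design choices

* Integer share masks make the clamp decision exact ((round(m) > R)); only
  the client-side rounding contributes error, inside the +-1 band budget.
* Chebyshev nodes of the first kind; encrypted evaluation by the
  depth-balanced basis-tree schedule above (Clenshaw would cost linear
  depth).
* Degenerate inputs: empty visit sequences, mixed batch lengths, batches
  over 32, share overflow, level exhaustion, wrong-key decryption, and
  parameter-hash mismatches on key/ciphertext files all raise typed errors.
* Determinism: all protocol randomness flows from one seeded generator
  (masks, blinds, garbling seeds), data generation from another; the
  simulator makes whole runs byte-reproducible.
* Problem sizes: the test suite verifies the comparator exhaustively at
  k = 6 and 8 bits for R in {1, 5, 9} (835,584 garbled evaluations), the
  clamp on a 0.1-grid over [-30, 30] under three mask seeds, and end-to-end
  equivalence on a 200-patient cohort; `scripts/acceptance.py` re-runs the
  same battery with a 60-patient end-to-end cohort, sizes chosen to keep a
  desk-scale run comfortable.

## Known limitations

* The HE simulator reproduces CKKS *semantics* (slots, levels, scale,
  bounded encoding noise), not its security; no RLWE parameters are chosen
  here and no security estimation is performed.
* The ideal OT and in-process transport give structural, not cryptographic,
  isolation; they are the correctness surface, with real backends pluggable.
* Latency and communication volumes are hardware- and library-specific and
  are reported only as transcript byte counts, never asserted against
  external figures.
* Harrell's C with the negated Weibull median as the risk functional is one
  conventional choice; both are swappable.
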