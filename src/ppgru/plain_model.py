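"""Plaintext reference GRU model with Weibull head and concordance index.

Two forward modes exist:

``exact``
    The textbook GRU cell with true sigmoid/tanh — what a trained model
    computes in the clear.

``clamped``
    The clamp-then-approximate reference: every pre-activation is clamped at
    the gate's threshold (±R for the sigmoid gates, ±R_tanh for the candidate
    gate) and the activations are evaluated through the shared Chebyshev
    interpolant.  This is, slot for slot, the function the encrypted pipeline
    computes, so it serves as the secure path's oracle; whenever no
    pre-activation exceeds R - 1 the two modes agree up to the interpolation
    error.

Cell equations (update gate z, reset gate r, candidate g):

    z_t = act(W_z x_t + U_z h_{t-1} + b_z)
    r_t = act(W_r x_t + U_r h_{t-1} + b_r)
    g_t = act_t(W_g x_t + U_g (h_{t-1} ⊙ r_t) + b_g)
    h_t = g_t + z_t ⊙ (h_{t-1} - g_t)        # = z⊙h + (1-z)⊙g

The model head emits two real numbers (a, b) which the client maps to Weibull
parameters alpha = exp(a) (scale) and beta = softplus(b) (shape); predicted
risk is the negated median event time alpha * (ln 2)^(1/beta).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .activation_approx import ChebPoly, build_sigmoid_cheb, eval_cheb_plain, sigmoid
from .he_core import HEShapeError
from .input_adjust import clamp_plain
from .secure_linear import WeightMatrix

__all__ = [
    "GRUCellWeights",
    "GRUModelWeights",
    "WeibullParams",
    "SurvivalRecord",
    "ClampedReference",
    "gru_cell_plain",
    "model_forward",
    "weibull_activate",
    "weibull_median",
    "risk_score",
    "concordance_index",
    "save_weights_json",
    "load_weights_json",
]


@dataclass(frozen=True)
class GRUCellWeights:
    """All matrices/vectors of one GRU layer (shared across its cells)."""

    W_z: WeightMatrix
    W_r: WeightMatrix
    W_g: WeightMatrix
    U_z: WeightMatrix
    U_r: WeightMatrix
    U_g: WeightMatrix
    b_z: np.ndarray
    b_r: np.ndarray
    b_g_vec: np.ndarray

    def __post_init__(self) -> None:
        n_h, n_i = self.W_z.shape
        for name in ("W_r", "W_g"):
            if getattr(self, name).shape != (n_h, n_i):
                raise HEShapeError(f"{name} shape {getattr(self, name).shape} != {(n_h, n_i)}")
        for name in ("U_z", "U_r", "U_g"):
            if getattr(self, name).shape != (n_h, n_h):
                raise HEShapeError(f"{name} shape {getattr(self, name).shape} != {(n_h, n_h)}")
        for name in ("b_z", "b_r", "b_g_vec"):
            vec = np.asarray(getattr(self, name), dtype=np.float64).ravel()
            if vec.size != n_h:
                raise HEShapeError(f"{name} length {vec.size} != {n_h}")
            object.__setattr__(self, name, vec)

    @property
    def n_hidden(self) -> int:
        return self.W_z.shape[0]

    @property
    def n_input(self) -> int:
        return self.W_z.shape[1]


@dataclass(frozen=True)
class GRUModelWeights:
    """Two stacked GRU layers plus the dense Weibull head.

    Layer 1 maps 70-length visit vectors to a 32-length sequence, layer 2
    consumes that sequence and emits only its last 20-length state, and the
    dense layer maps it to the two Weibull pre-activations.
    """

    layer1: GRUCellWeights
    layer2: GRUCellWeights
    dense: WeightMatrix
    dense_bias: np.ndarray
    layer2_returns_last_state_only: bool = True

    def __post_init__(self) -> None:
        if self.layer2.n_input != self.layer1.n_hidden:
            raise HEShapeError("layer2 input dim must equal layer1 hidden dim")
        if self.dense.shape != (2, self.layer2.n_hidden):
            raise HEShapeError(f"dense must be 2x{self.layer2.n_hidden}, got {self.dense.shape}")
        bias = np.asarray(self.dense_bias, dtype=np.float64).ravel()
        if bias.size != 2:
            raise HEShapeError("dense bias must have length 2")
        object.__setattr__(self, "dense_bias", bias)


@dataclass(frozen=True)
class WeibullParams:
    alpha: float  # scale, > 0
    beta: float  # shape, > 0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Weibull parameters must be strictly positive")


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject for the concordance index: follow-up time, event flag, risk."""

    time: float
    event: int
    risk: float

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError("time must be positive")


@dataclass(frozen=True)
class ClampedReference:
    """Shared approximation context of the clamped mode and the secure path."""

    sig_poly: ChebPoly
    R: int = 9
    R_tanh: int = 4

    @classmethod
    def default(cls) -> "ClampedReference":
        return cls(sig_poly=build_sigmoid_cheb(24, (-10.0, 10.0)))

    def act_sigmoid(self, pre: np.ndarray) -> np.ndarray:
        return eval_cheb_plain(self.sig_poly, clamp_plain(pre, self.R))

    def act_tanh(self, pre: np.ndarray) -> np.ndarray:
        clamped = clamp_plain(pre, self.R_tanh)
        return 2.0 * eval_cheb_plain(self.sig_poly, 2.0 * clamped) - 1.0


_DEFAULT_REF: list = []


def _default_ref() -> ClampedReference:
    if not _DEFAULT_REF:
        _DEFAULT_REF.append(ClampedReference.default())
    return _DEFAULT_REF[0]


def gru_cell_plain(
    x: np.ndarray,
    h: np.ndarray,
    w: GRUCellWeights,
    mode: str = "exact",
    ref: ClampedReference | None = None,
) -> np.ndarray:
    """One GRU step; ``mode='clamped'`` uses the clamp-then-interpolant oracle."""
    x = np.asarray(x, dtype=np.float64).ravel()
    h = np.asarray(h, dtype=np.float64).ravel()
    if x.size != w.n_input:
        raise HEShapeError(f"input length {x.size} != {w.n_input}")
    if h.size != w.n_hidden:
        raise HEShapeError(f"state length {h.size} != {w.n_hidden}")
    z_in = w.W_z.entries @ x + w.U_z.entries @ h + w.b_z
    r_in = w.W_r.entries @ x + w.U_r.entries @ h + w.b_r
    if mode == "exact":
        z = sigmoid(z_in)
        r = sigmoid(r_in)
    elif mode == "clamped":
        ref = ref or _default_ref()
        z = ref.act_sigmoid(z_in)
        r = ref.act_sigmoid(r_in)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    g_in = w.W_g.entries @ x + w.U_g.entries @ (h * r) + w.b_g_vec
    if mode == "exact":
        g = np.tanh(g_in)
    else:
        g = ref.act_tanh(g_in)
    # one-multiplication output form; identical to z*h + (1-z)*g
    return g + z * (h - g)


def model_forward(
    records,
    model: GRUModelWeights,
    mode: str = "exact",
    ref: ClampedReference | None = None,
):
    """Full forward pass over a visit sequence: (a, b) pre-activations.

    Layer 1 runs over all N steps and emits the full 32-length sequence;
    layer 2 runs over that sequence and keeps only its last state; the dense
    layer maps it to the two Weibull pre-activations.
    """
    seq = [np.asarray(x, dtype=np.float64).ravel() for x in records]
    if len(seq) == 0:
        raise ValueError("at least one visit record is required")
    if mode == "clamped" and ref is None:
        ref = _default_ref()
    h1 = np.zeros(model.layer1.n_hidden)
    outputs1 = []
    for x in seq:
        h1 = gru_cell_plain(x, h1, model.layer1, mode, ref)
        outputs1.append(h1)
    h2 = np.zeros(model.layer2.n_hidden)
    for y in outputs1:
        h2 = gru_cell_plain(y, h2, model.layer2, mode, ref)
    out = model.dense.entries @ h2 + model.dense_bias
    return float(out[0]), float(out[1])


def _softplus(b: float) -> float:
    return float(np.logaddexp(0.0, b))


def weibull_activate(a: float, b: float) -> WeibullParams:
    """Map the dense outputs to Weibull parameters: alpha=exp(a), beta=softplus(b).

    Both maps are strictly increasing (one-to-one), so handing the client
    (a, b) is informationally the same as handing it the final prediction.
    """
    a = float(np.clip(a, -700.0, 700.0))
    return WeibullParams(alpha=float(np.exp(a)), beta=max(_softplus(float(b)), 1e-12))


def weibull_median(p: WeibullParams) -> float:
    """Median event time alpha * (ln 2)^(1/beta)."""
    return p.alpha * np.log(2.0) ** (1.0 / p.beta)


def risk_score(a: float, b: float) -> float:
    """Risk functional for ranking: negated predicted median time (monotone)."""
    return -weibull_median(weibull_activate(a, b))


def concordance_index(records) -> float:
    """Harrell's C over admissible pairs; risk ties count 1/2.

    A pair is admissible when the observed ordering of event times is
    determinable under right-censoring: the earlier time must be an event.
    Raises ``ValueError`` when no pair is admissible.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two records")
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records], dtype=bool)
    s = np.array([r.risk for r in records])
    conc = 0.0
    n_adm = 0
    for i in np.nonzero(e)[0]:
        # subject i had an event; comparable with anyone surviving past t_i
        later = t > t[i]
        n = int(np.sum(later))
        if n == 0:
            continue
        n_adm += n
        conc += np.sum(s[i] > s[later]) + 0.5 * np.sum(s[i] == s[later])
        # tied event times with both events are indeterminate under Harrell's
    if n_adm == 0:
        raise ValueError("no admissible pairs (all times tied or censored)")
    return float(conc / n_adm)


# ---------------------------------------------------------------------------
# weights file I/O (shared JSON format with the server-side loader)
# ---------------------------------------------------------------------------


def _cell_to_dict(w: GRUCellWeights) -> dict:
    return {
        "W_z": w.W_z.entries.tolist(),
        "W_r": w.W_r.entries.tolist(),
        "W_g": w.W_g.entries.tolist(),
        "U_z": w.U_z.entries.tolist(),
        "U_r": w.U_r.entries.tolist(),
        "U_g": w.U_g.entries.tolist(),
        "b_z": w.b_z.tolist(),
        "b_r": w.b_r.tolist(),
        "b_g": w.b_g_vec.tolist(),
    }


def _cell_from_dict(d: dict) -> GRUCellWeights:
    return GRUCellWeights(
        W_z=WeightMatrix(np.array(d["W_z"]), "W"),
        W_r=WeightMatrix(np.array(d["W_r"]), "W"),
        W_g=WeightMatrix(np.array(d["W_g"]), "W"),
        U_z=WeightMatrix(np.array(d["U_z"]), "U"),
        U_r=WeightMatrix(np.array(d["U_r"]), "U"),
        U_g=WeightMatrix(np.array(d["U_g"]), "U"),
        b_z=np.array(d["b_z"]),
        b_r=np.array(d["b_r"]),
        b_g_vec=np.array(d["b_g"]),
    )


def save_weights_json(model: GRUModelWeights, path) -> None:
    doc = {
        "format": "ppgru-weights-v1",
        "layer1": _cell_to_dict(model.layer1),
        "layer2": _cell_to_dict(model.layer2),
        "dense": {"W": model.dense.entries.tolist(), "b": model.dense_bias.tolist()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_weights_json(path) -> GRUModelWeights:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "ppgru-weights-v1":
        raise ValueError("unrecognized weights file format")
    return GRUModelWeights(
        layer1=_cell_from_dict(doc["layer1"]),
        layer2=_cell_from_dict(doc["layer2"]),
        dense=WeightMatrix(np.array(doc["dense"]["W"]), "dense"),
        dense_bias=np.array(doc["dense"]["b"]),
    )
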