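"""Chebyshev approximation of the sigmoid, plain and on ciphertexts.

The sigmoid and tanh inside the GRU cell cannot be computed homomorphically,
so they are replaced by a polynomial: the degree-24 Chebyshev interpolant of
σ(x) = 1/(1+e^(-x)) on [-10, 10].  tanh is derived from the same interpolant
through the identity tanh(x) = 2σ(2x) - 1, which is why the candidate-gate
clamp radius is smaller (the argument is doubled).  Outside its range a
Chebyshev interpolant diverges rapidly — the whole reason the secure input
adjustment exists — so encrypted evaluation assumes its inputs were clamped
into range first.

Encrypted evaluation uses a depth-balanced schedule: the Chebyshev basis
polynomials T_1..T_d are built by the product recurrences
T_{2k} = 2 T_k^2 - 1 and T_{2k+1} = 2 T_k T_{k+1} - T_1, giving a
multiplicative depth of ceil(log2 d) ciphertext products, plus one level for
the affine domain map and one for the coefficient products — 7 levels in all
for d = 24.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev as _cheb

from .he_core import Ciphertext, DepthExhaustedError, he_add, he_mul, he_sub

__all__ = [
    "ChebPoly",
    "build_sigmoid_cheb",
    "sigmoid",
    "eval_cheb_plain",
    "eval_cheb_he",
    "cheb_levels_required",
    "tanh_from_sigmoid",
    "tanh_levels_required",
]


def sigmoid(x):
    """Numerically safe σ(x) = 1/(1+e^(-x))."""
    return 0.5 * (1.0 + np.tanh(np.asarray(x, dtype=np.float64) / 2.0))


@dataclass(frozen=True)
class ChebPoly:
    """Chebyshev-basis interpolant of a target function on [a, b].

    ``coefficients`` has length degree+1; ``max_grid_error`` is the dense-grid
    (10,001 points) max deviation from the target, recorded at build time.
    """

    coefficients: tuple
    range: tuple
    target: str = "sigmoid"
    max_grid_error: float = float("nan")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def nodes(self) -> np.ndarray:
        """First-kind Chebyshev points mapped to [a, b] (the interpolation nodes)."""
        d = self.degree
        a, b = self.range
        t = np.cos(np.pi * (2 * np.arange(d + 1) + 1) / (2 * (d + 1)))
        return 0.5 * (b - a) * t + 0.5 * (a + b)

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.target,
                "degree": self.degree,
                "range": list(self.range),
                "coefficients": list(self.coefficients),
                "max_grid_error": self.max_grid_error,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ChebPoly":
        d = json.loads(text)
        return cls(
            coefficients=tuple(d["coefficients"]),
            range=tuple(d["range"]),
            target=d["target"],
            max_grid_error=d["max_grid_error"],
        )


def build_sigmoid_cheb(degree: int = 24, rng: tuple = (-10.0, 10.0)) -> ChebPoly:
    """Interpolate σ at the first-kind Chebyshev nodes of ``rng``.

    The dense-grid max error is measured on 10,001 equispaced points and
    stored in the result's metadata.
    """
    a, b = float(rng[0]), float(rng[1])
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if not a < b:
        raise ValueError(f"degenerate range [{a}, {b}]")
    series = _cheb.Chebyshev.interpolate(sigmoid, degree, domain=[a, b])
    grid = np.linspace(a, b, 10001)
    err = float(np.max(np.abs(series(grid) - sigmoid(grid))))
    return ChebPoly(coefficients=tuple(series.coef), range=(a, b), max_grid_error=err)


def eval_cheb_plain(p: ChebPoly, x):
    """Clenshaw evaluation; diverges (by design) outside [a, b]."""
    a, b = p.range
    t = (2.0 * np.asarray(x, dtype=np.float64) - (a + b)) / (b - a)
    return _cheb.chebval(t, np.asarray(p.coefficients))


def cheb_levels_required(degree: int) -> int:
    """Multiplicative depth of :func:`eval_cheb_he`: domain map + T-tree + coeffs."""
    if degree <= 1:
        return 1 + (1 if degree == 1 else 0)
    return 2 + math.ceil(math.log2(degree))


def eval_cheb_he(p: ChebPoly, ct: Ciphertext, *, input_scale: float = 1.0) -> Ciphertext:
    """Evaluate the interpolant slot-wise on a ciphertext.

    ``input_scale`` folds a plain pre-multiplication of the argument into the
    domain-mapping level (used by the tanh identity, which evaluates at 2x).
    Slots are assumed pre-clamped so ``input_scale * x`` lies in [a, b].
    """
    d = p.degree
    need = cheb_levels_required(d)
    if ct.level < need:
        raise DepthExhaustedError(
            f"degree-{d} Chebyshev evaluation needs {need} levels, ciphertext has {ct.level}"
        )
    a, b = p.range
    c = np.asarray(p.coefficients)
    # affine map to [-1, 1], with the optional argument scaling folded in
    t1 = he_add(he_mul(ct, 2.0 * input_scale / (b - a)), -(a + b) / (b - a))
    if d == 0:
        # constant interpolant: level accounting still burns the map level
        return he_add(he_mul(t1, 0.0), float(c[0]))
    T = {1: t1}
    for k in range(2, d + 1):
        if k in T:
            continue
        half = k // 2
        if k % 2 == 0:
            prod = he_mul(T[half], T[half])
        else:
            prod = he_mul(T[half], T[half + 1])
        twice = he_add(prod, prod)  # doubling by addition: no level cost
        T[k] = he_sub(twice, 1.0 if k % 2 == 0 else T[1])
    # assemble sum(c_k T_k) + c_0; each coefficient product costs one level
    acc = he_add(he_mul(T[1], float(c[1])), float(c[0]))
    for k in range(2, d + 1):
        acc = he_add(acc, he_mul(T[k], float(c[k])))
    return acc


def tanh_levels_required(degree: int) -> int:
    """Same depth as the sigmoid evaluation: both affine steps fold into existing levels."""
    return cheb_levels_required(degree)


def tanh_from_sigmoid(p: ChebPoly, x):
    """tanh via the identity 2σ(2x) - 1, reusing the sigmoid interpolant.

    Accepts a plain array/scalar or a :class:`~ppgru.he_core.Ciphertext`.  For
    ciphertexts the doubling of the argument is folded into the domain map and
    the output affine step into the coefficients, so no extra level is spent.
    """
    if isinstance(x, Ciphertext):
        c = np.asarray(p.coefficients) * 2.0
        c[0] -= 1.0
        folded = ChebPoly(
            coefficients=tuple(c),
            range=p.range,
            target=p.target,
            max_grid_error=p.max_grid_error,
        )
        return eval_cheb_he(folded, x, input_scale=2.0)
    return 2.0 * eval_cheb_plain(p, 2.0 * np.asarray(x, dtype=np.float64)) - 1.0
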