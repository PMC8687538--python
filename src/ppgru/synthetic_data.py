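"""Seeded generators for synthetic patient cohorts, weights, and outcomes.

The clinical study data this package's protocol was designed around (breast
cancer follow-up records with recurrence labels) is not publicly available,
so this module generates cohorts with the same *statistical shape*: per
patient, a variable-length sequence of visits inside a 24-month window, each
visit encoded as a 70-length real vector composed of one-hot categorical
blocks, z-scored continuous labs, and one proportion feature binned in 10%
units; longitudinal missingness is filled by last-observation-carried-forward
(cohort average at the first visit); recurrence times are Weibull with a
linear risk score acting on the log-scale (accelerated failure time), under
independent uniform right-censoring.

Model weights are generated rather than trained: Gaussian weights are
globally rescaled until a target fraction of gate pre-activations, measured
on a reference cohort, exceeds the clamp-relevant range — which is what lets
tests drive the secure clamp path deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation_approx import sigmoid
from .plain_model import GRUCellWeights, GRUModelWeights
from .secure_linear import WeightMatrix

__all__ = [
    "FeatureSchema",
    "CohortConfig",
    "PatientRecordSequence",
    "gen_cohort",
    "gen_weights",
    "gen_outcomes",
    "true_risk_scores",
    "save_cohort_csv",
    "load_cohort_csv",
    "save_survival_csv",
]

FEATURE_LENGTH = 70


@dataclass(frozen=True)
class FeatureSchema:
    """Block layout of the 70 encoded columns.

    Twelve one-hot blocks (40 columns) stand in for the clinicopathologic and
    treatment categoricals, 29 z-scored columns for the continuous follow-up
    labs, and one 10%-binned proportion feature completes the vector.  Only
    the total length and the encoding conventions matter to the protocol; the
    block sizes are configurable.
    """

    onehot_blocks: tuple = (2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 5, 5)
    n_continuous: int = 29
    n_binned: int = 1

    def __post_init__(self) -> None:
        if self.total != FEATURE_LENGTH:
            raise ValueError(
                f"feature schema encodes {self.total} columns, expected {FEATURE_LENGTH}"
            )

    @property
    def n_onehot(self) -> int:
        return int(sum(self.onehot_blocks))

    @property
    def total(self) -> int:
        return self.n_onehot + self.n_continuous + self.n_binned

    @property
    def continuous_slice(self) -> slice:
        return slice(self.n_onehot, self.n_onehot + self.n_continuous)

    @property
    def binned_slice(self) -> slice:
        return slice(self.n_onehot + self.n_continuous, self.total)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generation parameters.

    ``visit_rate`` is the expected visits per patient inside the window
    (default 5.13, matching a follow-up cadence of roughly a visit every few
    months over two years); visit counts are 1 + truncated Poisson so every
    patient has at least one record.
    """

    n_patients: int = 200
    visit_window_months: int = 24
    visit_rate: float = 5.13
    feature_schema: FeatureSchema = field(default_factory=FeatureSchema)
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.visit_rate < 1.0:
            raise ValueError("visit_rate must be >= 1 (every patient has a visit)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class PatientRecordSequence:
    """One patient: chronologically ordered visits plus the survival label."""

    patient_id: str
    visits: list  # [(month_offset, feature_vector length 70), ...]
    survival: tuple | None = None  # (time, event bit)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def feature_matrix(self) -> np.ndarray:
        return np.vstack([v for _, v in self.visits])

    @property
    def months(self) -> np.ndarray:
        return np.array([m for m, _ in self.visits])


def _truncated_poisson(rng: np.random.Generator, lam: float, size: int, cap: int = 30) -> np.ndarray:
    draw = rng.poisson(max(lam, 0.0), size=size)
    return np.minimum(1 + draw, cap)


def gen_cohort(cfg: CohortConfig) -> list:
    """Generate a deterministic cohort of visit sequences (no outcomes yet).

    Missingness/LOCF and the cohort-wide z-scoring are applied across the
    pooled visit rows, so continuous columns come out with mean ~0 and sd ~1
    exactly as a preprocessing pipeline on real data would leave them.
    """
    schema = cfg.feature_schema
    rng = np.random.default_rng(cfg.seed)
    n_visits = _truncated_poisson(rng, cfg.visit_rate - 1.0, cfg.n_patients)
    months_per_patient = [
        np.sort(rng.uniform(0.0, cfg.visit_window_months, nv)) for nv in n_visits
    ]

    # raw continuous values with NaN holes, then LOCF / first-visit average
    total_rows = int(np.sum(n_visits))
    cont = np.empty((total_rows, schema.n_continuous))
    row = 0
    patient_rows = []
    for i, nv in enumerate(n_visits):
        mean_i = rng.normal(0.0, 1.0, schema.n_continuous)
        vals = mean_i[None, :] + rng.normal(0.0, 0.5, (nv, schema.n_continuous))
        miss = rng.uniform(size=(nv, schema.n_continuous)) < cfg.missing_rate
        vals[miss] = np.nan
        cont[row : row + nv] = vals
        patient_rows.append((row, row + nv))
        row += nv

    col_means = np.nanmean(cont, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    for start, stop in patient_rows:
        block = cont[start:stop]
        # first time point: cohort average; later: carry the last observation forward
        nan0 = np.isnan(block[0])
        block[0, nan0] = col_means[nan0]
        for t in range(1, block.shape[0]):
            nant = np.isnan(block[t])
            block[t, nant] = block[t - 1, nant]
    mu = cont.mean(axis=0)
    sd = cont.std(axis=0)
    sd[sd == 0] = 1.0
    cont = (cont - mu) / sd

    patients = []
    bins = np.arange(0.05, 1.0, 0.1)
    for i, nv in enumerate(n_visits):
        start, stop = patient_rows[i]
        onehot = []
        for size in schema.onehot_blocks:
            # categoricals are patient-level (diagnosis/treatment style)
            cat = int(rng.integers(0, size))
            block = np.zeros(size)
            block[cat] = 1.0
            onehot.append(block)
        onehot_vec = np.concatenate(onehot)
        binned_patient = rng.choice(bins)
        visits = []
        for t in range(nv):
            binned = binned_patient if rng.uniform() > 0.2 else rng.choice(bins)
            vec = np.concatenate([onehot_vec, cont[start + t], [binned]])
            visits.append((float(months_per_patient[i][t]), vec))
        patients.append(PatientRecordSequence(patient_id=f"P{i:05d}", visits=visits))
    return patients


# ---------------------------------------------------------------------------
# model weights with controlled pre-activation ranges
# ---------------------------------------------------------------------------


def _random_cell(rng, n_h, n_i, scale) -> GRUCellWeights:
    def mat(rows, cols, role):
        return WeightMatrix(rng.normal(0.0, scale / np.sqrt(cols), (rows, cols)), role)

    return GRUCellWeights(
        W_z=mat(n_h, n_i, "W"),
        W_r=mat(n_h, n_i, "W"),
        W_g=mat(n_h, n_i, "W"),
        U_z=mat(n_h, n_h, "U"),
        U_r=mat(n_h, n_h, "U"),
        U_g=mat(n_h, n_h, "U"),
        b_z=rng.normal(0.0, 0.1 * scale, n_h),
        b_r=rng.normal(0.0, 0.1 * scale, n_h),
        b_g_vec=rng.normal(0.0, 0.1 * scale, n_h),
    )


def _scale_cell(w: GRUCellWeights, m: float) -> GRUCellWeights:
    return GRUCellWeights(
        W_z=WeightMatrix(w.W_z.entries * m, "W"),
        W_r=WeightMatrix(w.W_r.entries * m, "W"),
        W_g=WeightMatrix(w.W_g.entries * m, "W"),
        U_z=WeightMatrix(w.U_z.entries * m, "U"),
        U_r=WeightMatrix(w.U_r.entries * m, "U"),
        U_g=WeightMatrix(w.U_g.entries * m, "U"),
        b_z=w.b_z * m,
        b_r=w.b_r * m,
        b_g_vec=w.b_g_vec * m,
    )


def _preact_outlier_fraction(model: GRUModelWeights, cohort, R: int = 9, R_tanh: int = 4) -> float:
    """Fraction of gate pre-activations beyond the clamp-relevant range.

    Sigmoid gates are measured against R - 1, the candidate gate against
    R_tanh - 1 (its argument is doubled by the tanh identity).
    """
    n_out = 0
    n_tot = 0
    for patient in cohort:
        seq = patient.feature_matrix
        for w in (model.layer1, model.layer2):
            h = np.zeros(w.n_hidden)
            nxt = []
            for x in seq:
                z_in = w.W_z.entries @ x + w.U_z.entries @ h + w.b_z
                r_in = w.W_r.entries @ x + w.U_r.entries @ h + w.b_r
                z = sigmoid(z_in)
                r = sigmoid(r_in)
                g_in = w.W_g.entries @ x + w.U_g.entries @ (h * r) + w.b_g_vec
                g = np.tanh(g_in)
                h = g + z * (h - g)
                nxt.append(h)
                n_out += int(np.sum(np.abs(z_in) > R - 1)) + int(np.sum(np.abs(r_in) > R - 1))
                n_out += int(np.sum(np.abs(g_in) > R_tanh - 1))
                n_tot += z_in.size + r_in.size + g_in.size
            seq = np.vstack(nxt)
    return n_out / max(n_tot, 1)


def gen_weights(
    dims: tuple = (70, 32, 20, 2),
    preact_scale: float = 1.0,
    outlier_frac: float = 0.0,
    seed: int = 0,
) -> GRUModelWeights:
    """Random model weights with a calibrated pre-activation profile.

    A global multiplier on all GRU weights is bisected until the fraction of
    gate pre-activations beyond the clamp-relevant range, measured on a
    500-patient reference cohort, is approximately ``outlier_frac`` (0 means
    essentially all pre-activations stay inside).  ``preact_scale = 0`` short-
    circuits to all-zero weights.  Deterministic per seed.
    """
    if not (0.0 <= outlier_frac <= 0.2):
        raise ValueError("outlier_frac must lie in [0, 0.2]")
    n_i, n_h1, n_h2, n_out = dims
    rng = np.random.default_rng(seed)
    base1 = _random_cell(rng, n_h1, n_i, 1.0)
    base2 = _random_cell(rng, n_h2, n_h1, 1.0)
    dense = WeightMatrix(rng.normal(0.0, 0.5 / np.sqrt(n_h2), (n_out, n_h2)), "dense")
    dense_bias = np.array([np.log(48.0), 0.5])[:n_out]

    def build(mult: float) -> GRUModelWeights:
        return GRUModelWeights(
            layer1=_scale_cell(base1, mult),
            layer2=_scale_cell(base2, mult),
            dense=dense,
            dense_bias=dense_bias,
        )

    if preact_scale == 0.0:
        return build(0.0)

    ref_cohort = gen_cohort(
        CohortConfig(n_patients=500, seed=int(rng.integers(0, 2**31)))
    )
    target = outlier_frac
    lo, hi = 1e-3 * preact_scale, 64.0 * preact_scale
    if _preact_outlier_fraction(build(hi), ref_cohort) < target:
        return build(hi)  # even saturated weights cannot exceed the target
    for _ in range(20):
        mid = np.sqrt(lo * hi)
        if _preact_outlier_fraction(build(mid), ref_cohort) > target:
            hi = mid
        else:
            lo = mid
    return build(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# Weibull outcomes under a linear risk score
# ---------------------------------------------------------------------------


def gen_outcomes(
    cohort,
    effect_size: float = 1.0,
    censor_frac: float = 0.9,
    seed: int = 0,
    shape: float = 1.5,
    base_scale: float = 60.0,
    scores=None,
) -> list:
    """Fill survival fields: accelerated-failure-time Weibull + uniform censoring.

    The risk score driving event times is either ``scores`` (one value per
    patient — pass a model's own predicted risks to emulate outcomes a
    *trained* model would be predictive for) or, by default, a fixed random
    projection of the mean feature vector.  Scores are standardized across
    the cohort; event times follow
    T = base_scale * exp(-effect_size * s) * (-ln U)^(1/shape).  The uniform
    censoring horizon is bisected so the realized censoring fraction is close
    to ``censor_frac``.  Returns the same patient objects with ``survival``
    set; the risk direction is higher score -> earlier recurrence.
    """
    if not (0.0 <= censor_frac <= 0.9):
        raise ValueError("censor_frac must lie in [0, 0.9]")
    rng = np.random.default_rng(seed)
    if scores is None:
        X = np.vstack([p.feature_matrix.mean(axis=0) for p in cohort])
        proj = rng.normal(0.0, 1.0, X.shape[1]) / np.sqrt(X.shape[1])
        s = X @ proj
    else:
        s = np.asarray(scores, dtype=np.float64)
        if s.size != len(cohort):
            raise ValueError("need exactly one score per patient")
    sd = s.std()
    s = (s - s.mean()) / (sd if sd > 0 else 1.0)
    u = rng.uniform(1e-12, 1.0, len(cohort))
    T = base_scale * np.exp(-effect_size * s) * (-np.log(u)) ** (1.0 / shape)

    if censor_frac <= 0.0:
        times, events = T, np.ones(len(cohort), dtype=int)
    else:
        draw = rng.uniform(0.0, 1.0, len(cohort))

        def realized(c_max: float) -> float:
            C = draw * c_max
            return float(np.mean(C < T))

        lo, hi = 1e-6, float(np.max(T)) * 4.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if realized(mid) > censor_frac:
                lo = mid
            else:
                hi = mid
        C = draw * 0.5 * (lo + hi)
        events = (T <= C).astype(int)
        times = np.where(events == 1, T, C)
    times = np.maximum(times, 1e-6)
    for p, t, e in zip(cohort, times, events):
        p.survival = (float(t), int(e))
    return cohort


def true_risk_scores(cohort, seed: int = 0) -> np.ndarray:
    """The standardized linear score used by :func:`gen_outcomes` (same seed)."""
    rng = np.random.default_rng(seed)
    X = np.vstack([p.feature_matrix.mean(axis=0) for p in cohort])
    proj = rng.normal(0.0, 1.0, X.shape[1]) / np.sqrt(X.shape[1])
    s = X @ proj
    sd = s.std()
    return (s - s.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# CSV interfaces (one row per visit; survival in its own file)
# ---------------------------------------------------------------------------


def save_cohort_csv(cohort, path) -> None:
    rows = []
    for p in cohort:
        for idx, (month, vec) in enumerate(p.visits):
            rows.append(
                {"patient_id": p.patient_id, "visit_index": idx, "month": month}
                | {f"f{j:02d}": vec[j] for j in range(FEATURE_LENGTH)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cohort_csv(path) -> list:
    df = pd.read_csv(path)
    cols = [f"f{j:02d}" for j in range(FEATURE_LENGTH)]
    patients = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("visit_index")
        visits = [
            (float(r["month"]), r[cols].to_numpy(dtype=np.float64)) for _, r in grp.iterrows()
        ]
        patients.append(PatientRecordSequence(patient_id=str(pid), visits=visits))
    return patients


def save_survival_csv(cohort, path) -> None:
    rows = [
        {"patient_id": p.patient_id, "time": p.survival[0], "event": p.survival[1]}
        for p in cohort
        if p.survival is not None
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
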