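"""Plaintext reference model: GRU cell/model, Weibull head, concordance index."""

import numpy as np
import pytest
from lifelines.utils import concordance_index as lifelines_cindex

from ppgru.activation_approx import sigmoid
from ppgru.he_core import HEShapeError
from ppgru.plain_model import (
    GRUCellWeights,
    GRUModelWeights,
    SurvivalRecord,
    concordance_index,
    gru_cell_plain,
    load_weights_json,
    model_forward,
    risk_score,
    save_weights_json,
    weibull_activate,
    weibull_median,
)
from ppgru.secure_linear import WeightMatrix
from ppgru.synthetic_data import gen_weights


def _zero_cell(n_h=4, n_i=3):
    z = lambda *s: WeightMatrix(np.zeros(s))
    return GRUCellWeights(
        W_z=z(n_h, n_i), W_r=z(n_h, n_i), W_g=z(n_h, n_i),
        U_z=z(n_h, n_h), U_r=z(n_h, n_h), U_g=z(n_h, n_h),
        b_z=np.zeros(n_h), b_r=np.zeros(n_h), b_g_vec=np.zeros(n_h),
    )


def _random_cell(rng, n_h, n_i, scale=1.0):
    m = lambda *s: WeightMatrix(rng.normal(0, scale / np.sqrt(s[-1]), s))
    return GRUCellWeights(
        W_z=m(n_h, n_i), W_r=m(n_h, n_i), W_g=m(n_h, n_i),
        U_z=m(n_h, n_h), U_r=m(n_h, n_h), U_g=m(n_h, n_h),
        b_z=rng.normal(0, 0.1, n_h), b_r=rng.normal(0, 0.1, n_h),
        b_g_vec=rng.normal(0, 0.1, n_h),
    )


class TestCell:
    def test_zero_weights_halve_the_state_in_both_modes(self, clamped_ref):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        for mode in ("exact", "clamped"):
            out = gru_cell_plain(np.zeros(3), v, _zero_cell(), mode, clamped_ref)
            assert np.max(np.abs(out - 0.5 * v)) <= 1e-3  # clamped mode: interpolant error only

    def test_modes_agree_when_nothing_clips(self, clamped_ref):
        rng = np.random.default_rng(0)
        w = _random_cell(rng, 8, 6, scale=0.5)
        x, h = rng.normal(size=6), rng.normal(0, 0.3, 8)
        exact = gru_cell_plain(x, h, w, "exact")
        clamped = gru_cell_plain(x, h, w, "clamped", clamped_ref)
        assert np.max(np.abs(exact - clamped)) <= 10 * 5.5e-4

    def test_output_form_identity(self):
        rng = np.random.default_rng(1)
        z, h, g = rng.uniform(0, 1, 16), rng.normal(size=16), rng.normal(size=16)
        assert np.max(np.abs((z * h + (1 - z) * g) - (g + z * (h - g)))) <= 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(HEShapeError):
            gru_cell_plain(np.zeros(5), np.zeros(4), _zero_cell())


class TestModelForward:
    def test_single_visit_zero_weights_gives_dense_bias(self):
        model = gen_weights(preact_scale=0.0, seed=0)
        a, b = model_forward([np.zeros(70)], model)
        assert abs(a - model.dense_bias[0]) <= 1e-12
        assert abs(b - model.dense_bias[1]) <= 1e-12

    def test_visit_order_matters(self, small_model):
        rng = np.random.default_rng(2)
        v1, v2 = rng.normal(size=70), rng.normal(size=70)
        assert model_forward([v1, v2], small_model) != model_forward([v2, v1], small_model)

    def test_two_step_toy_against_independent_recurrence(self):
        """Hand-rolled scalar recurrence on a 2x2 toy, written independently."""
        Wz = np.array([[0.5, -0.2], [0.1, 0.3]])
        Uz = np.array([[0.2, 0.0], [0.0, 0.2]])
        bz = np.array([0.1, -0.1])
        cell = GRUCellWeights(
            W_z=WeightMatrix(Wz), W_r=WeightMatrix(Wz * 0.5), W_g=WeightMatrix(Wz * -1.0),
            U_z=WeightMatrix(Uz), U_r=WeightMatrix(Uz * 2.0), U_g=WeightMatrix(Uz * 0.5),
            b_z=bz, b_r=bz * 0.0, b_g_vec=bz * 3.0,
        )
        xs = [np.array([1.0, -1.0]), np.array([0.5, 0.25])]
        # independent reimplementation: explicit elementwise loops
        h = [0.0, 0.0]
        for x in xs:
            z = [0.0, 0.0]
            r = [0.0, 0.0]
            g = [0.0, 0.0]
            for i in range(2):
                zi = sum(Wz[i][j] * x[j] for j in range(2)) + Uz[i][i] * h[i] + bz[i]
                ri = sum(0.5 * Wz[i][j] * x[j] for j in range(2)) + 2 * Uz[i][i] * h[i]
                z[i] = 1.0 / (1.0 + np.exp(-zi))
                r[i] = 1.0 / (1.0 + np.exp(-ri))
            for i in range(2):
                gi = sum(-Wz[i][j] * x[j] for j in range(2)) + 0.5 * Uz[i][i] * (h[i] * r[i]) + 3 * bz[i]
                g[i] = np.tanh(gi)
            h = [z[i] * h[i] + (1 - z[i]) * g[i] for i in range(2)]
        lib_h = np.zeros(2)
        for x in xs:
            lib_h = gru_cell_plain(x, lib_h, cell, "exact")
        assert np.max(np.abs(lib_h - np.array(h))) <= 1e-12


class TestWeibull:
    def test_unit_scale_at_zero(self):
        assert weibull_activate(0.0, 5.0).alpha == pytest.approx(1.0)

    def test_shape_softplus_at_zero(self):
        assert weibull_activate(3.0, 0.0).beta == pytest.approx(np.log(2.0))

    def test_strict_monotonicity(self):
        grid = np.linspace(-5, 5, 41)
        alphas = [weibull_activate(a, 0.0).alpha for a in grid]
        betas = [weibull_activate(0.0, b).beta for b in grid]
        assert all(x < y for x, y in zip(alphas, alphas[1:]))
        assert all(x < y for x, y in zip(betas, betas[1:]))

    def test_risk_is_negated_median(self):
        p = weibull_activate(1.0, 1.0)
        assert risk_score(1.0, 1.0) == pytest.approx(-weibull_median(p))

    def test_overflow_guarded(self):
        assert np.isfinite(weibull_activate(1e6, -1e6).alpha)


class TestConcordance:
    def test_perfectly_concordant_risks(self):
        recs = [SurvivalRecord(t, 1, -t) for t in (1.0, 2.0, 3.0, 4.0)]
        assert concordance_index(recs) == 1.0

    def test_perfectly_discordant_risks(self):
        recs = [SurvivalRecord(t, 1, t) for t in (1.0, 2.0, 3.0, 4.0)]
        assert concordance_index(recs) == 0.0

    def test_risk_ties_count_half(self):
        recs = [SurvivalRecord(1.0, 1, 0.0), SurvivalRecord(2.0, 1, 0.0)]
        assert concordance_index(recs) == 0.5

    def test_no_admissible_pairs_raises(self):
        with pytest.raises(ValueError):
            concordance_index([SurvivalRecord(1.0, 0, 0.1), SurvivalRecord(2.0, 0, 0.2)])

    def test_independent_risks_near_half(self):
        rng = np.random.default_rng(3)
        recs = [
            SurvivalRecord(float(t), int(e), float(s))
            for t, e, s in zip(
                rng.exponential(10, 5000), rng.integers(0, 2, 5000), rng.normal(size=5000)
            )
        ]
        assert 0.47 <= concordance_index(recs) <= 0.53

    def test_agreement_with_lifelines(self):
        """Harrell's C matches the survival library on 100 seeded datasets."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(20, 80))
            t = rng.exponential(5, n) + 1e-3
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            s = rng.normal(size=n)
            recs = [SurvivalRecord(float(ti), int(ei), float(si)) for ti, ei, si in zip(t, e, s)]
            ours = concordance_index(recs)
            theirs = lifelines_cindex(t, -s, e)  # lifelines expects higher = later
            assert abs(ours - theirs) <= 1e-9


class TestWeightsFile:
    def test_json_roundtrip(self, tmp_path, small_model):
        path = tmp_path / "w.json"
        save_weights_json(small_model, path)
        back = load_weights_json(path)
        assert np.array_equal(back.layer1.W_z.entries, small_model.layer1.W_z.entries)
        assert np.array_equal(back.dense_bias, small_model.dense_bias)

    def test_dimension_validation_on_build(self):
        with pytest.raises(HEShapeError):
            GRUModelWeights(
                layer1=_zero_cell(32, 70),
                layer2=_zero_cell(20, 31),  # must consume layer1's 32 outputs
                dense=WeightMatrix(np.zeros((2, 20)), "dense"),
                dense_bias=np.zeros(2),
            )
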