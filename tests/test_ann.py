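"""Normalization, forward pass, data splitting and Levenberg-Marquardt training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from desopt.ann import (
    MLPParams,
    NormalizationSpec,
    TrainConfig,
    denormalize,
    forward,
    init_params,
    neuron_sweep,
    normalize,
    split_data,
    train_lm,
    train_multistart,
    tansig,
)
from desopt.design import build_bbd, table1_factors
from desopt.synth import SurfaceTruth, gen_surface


def random_params(rng, H=5):
    return MLPParams(
        w1=rng.normal(size=(H, 3)),
        b1=rng.normal(size=H),
        w2=rng.normal(size=H),
        b2=float(rng.normal()),
        norm_x=NormalizationSpec(np.array([20.0, 450.0, 30.0]),
                                 np.array([40.0, 750.0, 50.0])),
        norm_y=NormalizationSpec(np.array([12.86]), np.array([14.95])),
    )


def forward_oracle(params, x_actual):
    """Scalar-loop forward pass, independent of the vectorized implementation."""
    xn = [
        -1 + 2 * (x_actual[j] - params.norm_x.n_min[j])
        / (params.norm_x.n_max[j] - params.norm_x.n_min[j])
        for j in range(3)
    ]
    out = params.b2
    for h in range(params.hidden):
        z = params.b1[h]
        for j in range(3):
            z += params.w1[h, j] * xn[j]
        a = 2.0 / (1.0 + np.exp(-2.0 * z)) - 1.0
        out += params.w2[h] * a
    lo, hi = params.norm_y.n_min[0], params.norm_y.n_max[0]
    return lo + (out + 1) * (hi - lo) / 2


class TestNormalization:
    def test_bounds_map_to_unit_interval(self):
        spec = NormalizationSpec(np.array([10.0]), np.array([20.0]))
        assert normalize(10.0, spec) == pytest.approx(-1.0)
        assert normalize(20.0, spec) == pytest.approx(1.0)
        assert normalize(15.0, spec) == pytest.approx(0.0)

    def test_published_yield_bounds(self):
        # response range of the packaged design: 12.86 to 14.95
        spec = NormalizationSpec(np.array([12.86]), np.array([14.95]))
        assert normalize(13.36, spec) == pytest.approx(
            (13.36 - 13.905) / 1.045, abs=1e-10
        )

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            NormalizationSpec(np.array([5.0]), np.array([5.0]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_denormalize_inverts_normalize(self, seed):
        rng = np.random.default_rng(seed)
        spec = NormalizationSpec(np.array([20.0, 450.0, 30.0]),
                                 np.array([40.0, 750.0, 50.0]))
        v = rng.uniform(0, 1000, (20, 3))
        assert denormalize(normalize(v, spec), spec) == pytest.approx(v)


class TestForward:
    def test_zero_network_outputs_response_midpoint(self, rng):
        p = random_params(rng)
        p = MLPParams(np.zeros_like(p.w1), np.zeros_like(p.b1),
                      np.zeros_like(p.w2), 0.0, p.norm_x, p.norm_y)
        assert forward(p, np.array([30.0, 600.0, 40.0])) == pytest.approx(
            (12.86 + 14.95) / 2
        )

    def test_tansig_saturates(self):
        assert tansig(50.0) == pytest.approx(1.0)
        assert tansig(-50.0) == pytest.approx(-1.0)
        assert tansig(0.0) == 0.0

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(20):
            p = random_params(rng, H=int(rng.integers(1, 9)))
            x = rng.uniform([20, 450, 30], [40, 750, 50])
            assert forward(p, x) == pytest.approx(forward_oracle(p, x), abs=1e-12)

    def test_inconsistent_dimensions_rejected(self, rng):
        with pytest.raises(ValueError, match="dimensions"):
            MLPParams(np.zeros((3, 3)), np.zeros(4), np.zeros(3), 0.0,
                      NormalizationSpec(np.zeros(3), np.ones(3)),
                      NormalizationSpec(np.zeros(1), np.ones(1)))


class TestSplitData:
    def test_seventeen_runs_split(self):
        tr, va, te = split_data(17, rng=0)
        assert (len(tr), len(va), len(te)) == (12, 3, 2)
        assert sorted(np.concatenate([tr, va, te])) == list(range(17))

    def test_round_sizes(self):
        tr, va, te = split_data(100, rng=0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_seed_determinism(self):
        a = split_data(17, rng=42)
        b = split_data(17, rng=42)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_data(2)


@pytest.fixture(scope="module")
def smooth_table(table1_model):
    """Noiseless quadratic responses on the 17-run BBD: an easy LM target."""
    truth = SurfaceTruth.from_model(table1_model, noise_sd=0.0)
    return gen_surface(truth, build_bbd(table1_factors(), 5), rng=0)


class TestTrainLM:
    def test_fits_noiseless_smooth_surface(self, smooth_table):
        runs = train_multistart(smooth_table, 7, 20, seed=11)
        best_train = min(r.mse_history[r.best_epoch][0] for _, r in runs)
        assert best_train <= 1e-4

    def test_training_mse_never_worse_than_initialization(self, smooth_table):
        for _, rec in train_multistart(smooth_table, 5, 10, seed=3):
            hist = np.array(rec.mse_history)
            assert hist[rec.best_epoch, 0] <= hist[0, 0] + 1e-15

    def test_validation_early_stopping_contract(self, table1):
        cfg = TrainConfig(max_fail=6)
        # over many short runs at least one must stop on validation failures
        stopped = [
            rec for _, rec in train_multistart(table1, 7, 30, seed=5, config=cfg)
            if rec.stop_reason == "validation"
        ]
        assert stopped
        for rec in stopped:
            vals = [h[1] for h in rec.mse_history]
            assert rec.best_epoch == int(np.argmin(vals))

    def test_seed_determinism(self, table1):
        (p1, r1), = train_multistart(table1, 4, 1, seed=9)
        (p2, r2), = train_multistart(table1, 4, 1, seed=9)
        assert np.array_equal(p1.to_vector(), p2.to_vector())
        assert r1.mse_history == r2.mse_history

    def test_overparameterized_regime_reaches_high_r2(self, table1):
        """Enough restarts of the 3-7-1 network fit all 17 runs tightly."""
        from desopt.metrics import PredictionPairs, compare

        runs = train_multistart(table1, 7, 1000, seed=2)
        best = max(
            compare(
                PredictionPairs(forward(p, table1.actual_levels()), table1.response)
            ).r2
            for p, _ in runs
        )
        assert best >= 0.98

    def test_lm_step_shrinks_with_damping(self, table1, rng):
        # on a fixed Jacobian the step norm is monotone decreasing in mu
        from desopt.ann import _forward_norm, _jacobian, normalize as nrm

        p = init_params(table1, 5, rng)
        xn = nrm(table1.actual_levels(), p.norm_x)
        yn = nrm(table1.response, p.norm_y)
        J = _jacobian(p, xn)
        e = _forward_norm(p, xn) - yn
        g = J.T @ e
        JtJ = J.T @ J
        norms = [
            np.linalg.norm(np.linalg.solve(JtJ + mu * np.eye(len(g)), g))
            for mu in 10.0 ** np.arange(-3, 8)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-5


class TestNeuronSweep:
    def test_shape_and_determinism(self, table1):
        sweep1 = neuron_sweep(table1, range(1, 5), restarts=3, seed=7)
        sweep2 = neuron_sweep(table1, range(1, 5), restarts=3, seed=7)
        assert sweep1 == sweep2
        assert [h for h, _ in sweep1] == [1, 2, 3, 4]
        assert all(m >= 0 for _, m in sweep1)

    def test_single_neuron_fits_linear_response(self, factors):
        # noiseless capability check: drop the MSE goal below the threshold
        # so the stopping rule does not mask the attainable fit
        design = build_bbd(factors, 5)
        truth = SurfaceTruth(14.0, [0.3, 0.2, 0.1], [0, 0, 0], [0, 0, 0])
        table = gen_surface(truth, design, rng=0)
        cfg = TrainConfig(goal=1e-9)
        sweep = neuron_sweep(table, [1], restarts=20, seed=1, config=cfg)
        assert sweep[0][1] <= 1e-6
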