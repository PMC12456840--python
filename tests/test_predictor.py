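"""Tests for the encoding, physics loss, splits and training loop of the
shim-weight regressor."""

from dataclasses import replace

import numpy as np
import pytest

import ptxshim.predictor as P
from ptxshim.fieldsim import GeneratorConfig, simulate_dataset
from ptxshim.shimcore import (
    ShimObjectiveConfig,
    ShimWeights,
    quadrature_weights,
    rmse_percent,
    shim_volume,
)


@pytest.fixture(scope="module")
def tiny_examples():
    """32 examples (2 volumes x 4 slices x 4 rotations) on a 32x32 grid with
    Adam references."""
    vols = simulate_dataset(
        GeneratorConfig(n_volumes=2, n_slices=4, n_rotations=4, grid_shape=(32, 32)),
        seed=5,
    )
    cfg = ShimObjectiveConfig(n_restarts=6, max_iters=250)
    refs = [shim_volume(v, "adam", replace(cfg, seed=i)) for i, v in enumerate(vols)]
    return P.build_examples(vols, refs)


# ---------------------------------------------------------------------------
# encoding / decoding
# ---------------------------------------------------------------------------

def test_encode_plane_counts_and_roundtrip(small_slice):
    fields, _, _ = small_slice
    enc16 = P.encode_input(fields, "realimag16")
    assert enc16.plane_count == 16
    enc32 = P.encode_input(fields, "rimp32")
    assert enc32.plane_count == 32
    # lossless: real/imag planes reassemble the complex field bit-exactly
    rebuilt = enc16.planes[0::2] + 1j * enc16.planes[1::2]
    np.testing.assert_array_equal(rebuilt, fields.values.astype(np.complex64))
    assert np.all(np.abs(enc32.planes[3::4]) <= np.pi + 1e-6)
    with pytest.raises(ValueError):
        P.encode_input(fields, "magnitudeonly")


def test_decode_weights():
    out = np.zeros(16)
    out[0::2] = 1.0
    np.testing.assert_array_equal(
        P.decode_weights(out, 8).coefficients, np.ones(8, dtype=complex)
    )
    assert np.all(P.decode_weights(np.zeros(16), 8).coefficients == 0)
    # surplus entries of a 32-wide head are ignored
    rng = np.random.default_rng(0)
    full = rng.standard_normal(32)
    np.testing.assert_array_equal(
        P.decode_weights(full, 8).coefficients,
        P.decode_weights(full[:16], 8).coefficients,
    )
    with pytest.raises(ValueError):
        P.decode_weights(np.zeros(7))
    # round trip through the (real, imag) pairing
    b = rng.standard_normal(8) + 1j * rng.standard_normal(8)
    vec = np.empty(16)
    vec[0::2], vec[1::2] = b.real, b.imag
    np.testing.assert_array_equal(P.decode_weights(vec, 8).coefficients, b)


# ---------------------------------------------------------------------------
# physics loss
# ---------------------------------------------------------------------------

def test_physics_loss_zero_at_reference(tiny_examples):
    batch = tiny_examples[:4]
    weights = [ex.weights_ref for ex in batch]
    assert P.physics_loss(weights, batch, "plain") == pytest.approx(0.0, abs=1e-9)
    assert P.physics_loss(weights, batch, "mse") == pytest.approx(0.0, abs=1e-12)


def test_physics_loss_offset_arithmetic(tiny_examples):
    """A prediction whose RMSE is exactly d above the reference gives plain
    loss d and squared loss d^2."""
    ex = tiny_examples[0]
    # scaling the reference weights rescales |Ab| linearly; pick the factor
    # numerically to land 2.0 RMSE points above the reference
    from scipy.optimize import brentq

    def gap(s):
        w = ShimWeights(ex.weights_ref.coefficients * s)
        return (
            rmse_percent(ex.fields_ref, w, ex.target_map, ex.mask)
            - ex.rmse_ref - 2.0
        )

    s = brentq(gap, 1.0, 2.0, xtol=1e-12)
    w = [ShimWeights(ex.weights_ref.coefficients * s)]
    assert P.physics_loss(w, [ex], "plain") == pytest.approx(2.0, abs=1e-6)
    assert P.physics_loss(w, [ex], "mse") == pytest.approx(4.0, abs=1e-5)


def test_loss_gradient_matches_finite_differences(tiny_examples):
    batch = tiny_examples[:3]
    rng = np.random.default_rng(1)
    outputs = rng.standard_normal((3, 16))
    for form in ("plain", "mse"):
        loss, dout, _ = P._loss_and_grad(outputs, batch, form)
        eps = 1e-6
        probe = np.random.default_rng(2)
        for _ in range(6):
            i = int(probe.integers(0, 3))
            j = int(probe.integers(0, 16))
            pert = outputs.copy()
            pert[i, j] += eps
            lp, _, _ = P._loss_and_grad(pert, batch, form)
            assert (lp - loss) / eps == pytest.approx(dout[i, j], rel=1e-3, abs=1e-7)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_split_sizes_disjoint_exhaustive_and_seeded(tiny_examples):
    tr, va, te = P.split_dataset(tiny_examples, (0.8, 0.1, 0.1), seed=0)
    all_idx = sorted(tr + va + te)
    assert all_idx == list(range(len(tiny_examples)))
    assert not (set(tr) & set(va)) and not (set(tr) & set(te)) and not (set(va) & set(te))
    assert P.split_dataset(tiny_examples, (0.8, 0.1, 0.1), seed=0) == (tr, va, te)
    assert P.split_dataset(tiny_examples, (0.8, 0.1, 0.1), seed=1) != (tr, va, te)


def test_split_keeps_rotated_copies_together(tiny_examples):
    tr, va, te = P.split_dataset(tiny_examples, (0.8, 0.1, 0.1), seed=3)
    assignment = {}
    for name, idx in (("train", tr), ("val", va), ("test", te)):
        for i in idx:
            g = tiny_examples[i].group
            assert assignment.setdefault(g, name) == name


def test_split_ratio_1000_source_slices():
    """100 unaugmented source slices at 8:1:1 split into 80/10/10."""

    class FakeExample:
        def __init__(self, g):
            self.group = (g,)

    examples = [FakeExample(i) for i in range(100)]
    tr, va, te = P.split_dataset(examples, (0.8, 0.1, 0.1), seed=0)
    assert (len(tr), len(va), len(te)) == (80, 10, 10)


def test_split_too_small_rejected(tiny_examples):
    with pytest.raises(P.SplitError):
        P.split_dataset(tiny_examples[:5], (0.8, 0.1, 0.1), seed=0)


# ---------------------------------------------------------------------------
# model / training
# ---------------------------------------------------------------------------

def test_model_shape_and_seeded_build(tiny_examples):
    cfg = P.PredictorConfig(stage_widths=(4, 8, 8, 16), seed=7, epochs=1)
    m1 = P.build_model(cfg)
    m2 = P.build_model(cfg)
    for p1, p2 in zip(m1.params(), m2.params()):
        np.testing.assert_array_equal(p1.v, p2.v)
    x = tiny_examples[0].input.planes[None]
    out = m1.forward(x, train=False)
    assert out.shape == (1, 16)
    assert m1.n_parameters() > 0


def test_training_reduces_loss_and_checkpoints(tiny_examples):
    """Over a short seeded run on 32 slices the physics loss decreases and
    the best-validation checkpoint is restored."""
    cfg = P.PredictorConfig(
        stage_widths=(8, 16, 32, 64), epochs=10, batch_size=8, seed=0
    )
    model, hist = P.train(tiny_examples, cfg)
    assert len(hist.train_loss) == cfg.epochs
    assert min(hist.train_loss[5:]) < hist.train_loss[0]
    assert hist.best_epoch >= 0
    # restored parameters reproduce the recorded best validation RMSE
    val = [tiny_examples[i] for i in hist.splits["val"]]
    rep = P.evaluate(model, val)
    assert rep["mean"]["predicted"] == pytest.approx(
        hist.val_rmse[hist.best_epoch], rel=1e-6
    )


def test_training_is_reproducible(tiny_examples):
    cfg = P.PredictorConfig(stage_widths=(4, 8, 8, 8), epochs=3, batch_size=8, seed=2)
    _, h1 = P.train(tiny_examples, cfg)
    _, h2 = P.train(tiny_examples, cfg)
    assert h1.train_loss == h2.train_loss
    assert h1.val_rmse == h2.val_rmse


def test_predict_and_checkpoint_roundtrip(tiny_examples, tmp_path):
    cfg = P.PredictorConfig(stage_widths=(4, 8, 8, 8), epochs=2, batch_size=8, seed=1)
    model, _ = P.train(tiny_examples, cfg)
    ex = tiny_examples[0]
    res = P.predict(model, ex.fields_ref, ex.mask, ex.target_map)
    assert res.weights.n_channels == 8
    assert res.rmse_percent == pytest.approx(
        rmse_percent(ex.fields_ref, res.weights, ex.target_map, ex.mask), rel=1e-9
    )
    P.save_model(model, tmp_path / "model.npz")
    clone = P.load_model(tmp_path / "model.npz")
    res2 = P.predict(clone, ex.fields_ref, ex.mask, ex.target_map)
    assert res2.rmse_percent == pytest.approx(res.rmse_percent, rel=1e-6)


def test_prediction_speed_batched(tiny_examples):
    """Batched prediction over 200 slices stays well under 10 s on one CPU."""
    import time

    cfg = P.PredictorConfig(stage_widths=(8, 16, 32, 64), epochs=1, batch_size=8, seed=0)
    model = P.build_model(cfg)
    x = np.repeat(tiny_examples[0].input.planes[None], 20, axis=0)
    t0 = time.perf_counter()
    for _ in range(10):
        model.forward(x, train=False)
    assert time.perf_counter() - t0 < 10.0
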