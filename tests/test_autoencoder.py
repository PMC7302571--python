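"""Stacked-autoencoder training, encoding and reconstruction checks."""

import numpy as np
import pytest

from nirparity.autoencoder import (
    AeConfig,
    AutoencoderStack,
    AutoencoderStep,
    encode,
    encode_matrix,
    reconstruct,
    train_autoencoder,
)
from nirparity.dataset import SpectralDataset
from nirparity.errors import (
    DimensionMismatchError,
    ScalingRangeError,
    StepDimensionError,
)

LINEAR = AeConfig(epochs=4000, encoder_activation="linear",
                  decoder_activation="linear")


def _subspace_data(n=120, d=20, k=5, seed=0):
    """Data lying exactly in a k-dimensional linear subspace of R^d."""
    rng = np.random.default_rng(seed)
    basis = np.linalg.qr(rng.normal(size=(d, k)))[0]
    return rng.normal(size=(n, k)) @ basis.T


def test_exact_subspace_reconstructs_to_machine_precision():
    X = _subspace_data()
    stack = train_autoencoder(X, [5], LINEAR, seed=0)
    assert stack.step_mse[-1] <= 1e-6


def test_identity_capable_step_reaches_near_zero_mse():
    X = _subspace_data(n=60, d=8, k=8)
    stack = train_autoencoder(X, [8], LINEAR, seed=0)
    assert stack.step_mse[-1] <= 1e-6


def test_zero_weight_stack_mse_equals_data_variance():
    # an untrained (all-zero, linear) stack predicts the constant 0, so the
    # reconstruction MSE of centred unit-variance data is the data variance
    rng = np.random.default_rng(2)
    X = rng.normal(size=(500, 6))
    X = (X - X.mean(0)) / X.std(0)
    step = AutoencoderStep(
        W_enc=np.zeros((3, 6)), b_enc=np.zeros(3),
        W_dec=np.zeros((6, 3)), b_dec=np.zeros(6),
        encoder_activation="linear", decoder_activation="linear",
    )
    _, mse = reconstruct(AutoencoderStack(steps=[step]), X)
    assert mse == pytest.approx(float(np.mean(X ** 2)), rel=1e-12)


def test_codes_have_final_dimension_and_preserve_rows(full_grid_dataset):
    from nirparity.preprocessing import apply_scaler, fit_scaler, preprocess

    pp = preprocess(full_grid_dataset)
    scaled = apply_scaler(pp, fit_scaler(pp))
    stack = train_autoencoder(scaled, (256, 64, 10), AeConfig(epochs=2), seed=0)
    enc = encode(stack, scaled)
    assert enc.n_features == 10
    assert enc.n_samples == scaled.n_samples
    assert np.array_equal(enc.labels, scaled.labels)
    assert enc.encoder_fingerprint == stack.fingerprint()


def test_encoding_is_deterministic_and_permutation_equivariant():
    rng = np.random.default_rng(4)
    X = rng.random((30, 12))
    stack = train_autoencoder(X, [6, 3], AeConfig(epochs=20), seed=1)
    c1 = encode_matrix(stack, X)
    c2 = encode_matrix(stack, X)
    assert np.array_equal(c1, c2)
    perm = rng.permutation(30)
    assert np.array_equal(encode_matrix(stack, X[perm]), c1[perm])


def test_training_is_deterministic_under_seed():
    rng = np.random.default_rng(5)
    X = rng.random((40, 15))
    s1 = train_autoencoder(X, [5], AeConfig(epochs=30), seed=9)
    s2 = train_autoencoder(X, [5], AeConfig(epochs=30), seed=9)
    assert np.array_equal(s1.steps[0].W_enc, s2.steps[0].W_enc)
    assert s1.step_mse == s2.step_mse
    s3 = train_autoencoder(X, [5], AeConfig(epochs=30), seed=10)
    assert not np.array_equal(s1.steps[0].W_enc, s3.steps[0].W_enc)


def test_loss_trace_is_monotone_non_increasing():
    rng = np.random.default_rng(6)
    X = rng.random((50, 20))
    stack = train_autoencoder(X, [8, 4], AeConfig(epochs=200), seed=0)
    for trace in stack.loss_traces:
        assert np.all(np.diff(trace) <= 1e-15)


def test_more_epochs_never_hurt_training_loss():
    rng = np.random.default_rng(8)
    X = rng.random((40, 10))
    losses = []
    for epochs in (10, 50, 200):
        stack = train_autoencoder(X, [4], AeConfig(epochs=epochs), seed=3)
        losses.append(stack.loss_traces[0][-1])
    assert losses[0] >= losses[1] >= losses[2]


def test_reconstruct_matches_stored_step_mse():
    rng = np.random.default_rng(7)
    X = rng.random((30, 16))
    stack = train_autoencoder(X, [8, 4], AeConfig(epochs=30), seed=0)
    for i in range(2):
        _, mse = reconstruct(stack, X, through_step=i + 1)
        assert mse == pytest.approx(stack.step_mse[i], rel=1e-12)


def test_reconstruct_step_index_out_of_range():
    X = np.random.default_rng(0).random((10, 6))
    stack = train_autoencoder(X, [3], AeConfig(epochs=1), seed=0)
    with pytest.raises(IndexError):
        reconstruct(stack, X, through_step=2)


def test_dimension_mismatch_on_encode():
    X = np.random.default_rng(0).random((10, 6))
    stack = train_autoencoder(X, [3], AeConfig(epochs=1), seed=0)
    with pytest.raises(DimensionMismatchError):
        encode_matrix(stack, np.zeros((4, 100)))


def test_increasing_step_dims_rejected():
    X = np.random.default_rng(0).random((10, 6))
    with pytest.raises(StepDimensionError):
        train_autoencoder(X, [3, 5], AeConfig(epochs=1), seed=0)


def test_logistic_encoder_requires_scaled_input():
    X = np.random.default_rng(0).normal(size=(10, 6)) * 5
    with pytest.raises(ScalingRangeError):
        train_autoencoder(X, [3], AeConfig(epochs=1), seed=0)


def test_class_signal_survives_compression():
    """A nearest-centroid rule on the 10-dim codes must beat chance —
    the mechanism behind the classifier's accuracy gain."""
    from nirparity.preprocessing import apply_scaler, fit_scaler, preprocess
    from nirparity.synthetic import SyntheticConfig, generate

    ds = generate(SyntheticConfig(n_parous=60, n_nulliparous=60,
                                  effect_size=2.0, seed=11))
    pp = preprocess(ds)
    scaled = apply_scaler(pp, fit_scaler(pp))
    stack = train_autoencoder(scaled, (64, 10), AeConfig(epochs=60), seed=1)
    codes = encode(stack, scaled)
    X, y = codes.codes, codes.labels
    mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
    pred = (((X - mu1) ** 2).sum(1) < ((X - mu0) ** 2).sum(1)).astype(int)
    assert (pred == y).mean() >= 0.8
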