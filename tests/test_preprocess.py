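"""Scatter corrections: definitions, affine invariance, ground-truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sportfuse import (
    PreprocSpec,
    PreprocessingBank,
    SpectrumSet,
    msc,
    second_derivative,
    snv,
    vsn,
)
from sportfuse.preprocess import vsn_weights


def _set(X, wn=None):
    X = np.atleast_2d(np.asarray(X, float))
    wn = np.arange(X.shape[1], dtype=float) if wn is None else wn
    return SpectrumSet(wavenumbers=wn, intensities=X,
                       sample_ids=[f"s{i}" for i in range(X.shape[0])])


# ---------------------------------------------------------------- SNV

def test_snv_hand_case():
    out = snv(_set([[1.0, 2.0, 3.0]]))
    assert np.allclose(out.intensities, [[-1.0, 0.0, 1.0]])


def test_snv_definition_on_generated_rows(small_dataset):
    out = snv(small_dataset)
    assert np.max(np.abs(out.intensities.mean(axis=1))) < 1e-10
    assert np.max(np.abs(out.intensities.std(axis=1, ddof=1) - 1)) < 1e-10


def test_snv_constant_row_error_names_sample():
    data = _set([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
    with pytest.raises(ValueError, match="s1"):
        snv(data)


def test_snv_affine_invariance(clean_dataset):
    """Per-sample gain and offset leave the SNV output unchanged."""
    rng = np.random.default_rng(0)
    g = np.exp(rng.normal(0, 0.2, clean_dataset.n_samples))
    o = rng.normal(0, 0.5, clean_dataset.n_samples)
    distorted = clean_dataset.with_intensities(
        clean_dataset.intensities * g[:, None] + o[:, None])
    assert np.allclose(snv(distorted).intensities, snv(clean_dataset).intensities,
                       atol=1e-8)


@settings(derandomize=True, max_examples=25)
@given(st.lists(st.floats(-50, 50), min_size=4, max_size=12, unique=True))
def test_snv_property_rows_standardized(row):
    out = snv(_set([row]))
    assert abs(out.intensities.mean()) < 1e-8
    assert abs(out.intensities.std(ddof=1) - 1) < 1e-8


# ---------------------------------------------------------------- MSC

def test_msc_reference_row_unchanged():
    ref = np.array([1.0, 3.0, 2.0, 5.0])
    out = msc(_set([ref]), reference=ref)
    assert np.allclose(out.intensities[0], ref)


def test_msc_affine_inversion_exact():
    ref = np.array([1.0, 3.0, 2.0, 5.0])
    out = msc(_set([2 * ref + 3]), reference=ref)
    assert np.allclose(out.intensities[0], ref)


def test_msc_recovers_shared_pure_spectrum(clean_dataset):
    """Noise-free rows differing only by affine artifacts collapse to one."""
    pure = clean_dataset.intensities[0]
    rng = np.random.default_rng(1)
    g = np.exp(rng.normal(0, 0.3, 12))
    o = rng.normal(0, 0.4, 12)
    distorted = _set(pure[None] * g[:, None] + o[:, None],
                     wn=clean_dataset.wavenumbers)
    out = msc(distorted, reference=pure)
    assert np.allclose(out.intensities, pure[None], atol=1e-8)


def test_msc_degenerate_slope_error():
    ref = np.array([1.0, 3.0, 2.0, 5.0])
    flat = np.full(4, 2.0)
    with pytest.raises(ValueError, match="s0"):
        msc(_set([flat]), reference=ref)


# ---------------------------------------------------------------- VSN

def test_vsn_with_uniform_weights_equals_msc(small_dataset):
    spec = PreprocSpec(method="VSN", vsn_iterations=0)  # weights stay 1
    out_v = vsn(small_dataset, spec)
    out_m = msc(small_dataset)
    assert np.allclose(out_v.intensities, out_m.intensities, atol=1e-10)


def test_vsn_recovers_artifacts_better_than_msc():
    """Half the variables carry pure affine artifact, half strong signal;
    VSN's weighted fit recovers the true gains/offsets more accurately."""
    rng = np.random.default_rng(3)
    p, n = 40, 30
    ref = 1.0 + np.sin(np.linspace(0, 3, p)) ** 2
    signal_shape = np.zeros(p)
    signal_shape[p // 2:] = rng.normal(0, 1.0, p // 2)
    a_true = np.exp(rng.normal(0, 0.3, n))
    b_true = rng.normal(0, 0.3, n)
    s = rng.normal(0, 2.0, n)
    X = a_true[:, None] * ref[None] + b_true[:, None] + s[:, None] * signal_shape[None]
    data = _set(X)
    from sportfuse.preprocess import _affine_fit

    w = vsn_weights(X, ref, iterations=8, bandwidth=1.0)
    a_v, b_v = _affine_fit(X, ref, w)
    a_m, b_m = _affine_fit(X, ref, None)
    mse = lambda a, b: np.mean((a - a_true) ** 2 + (b - b_true) ** 2)  # noqa: E731
    assert mse(a_v, b_v) < mse(a_m, b_m)


def test_vsn_single_sample_self_normalizes():
    row = np.array([1.0, 2.0, 4.0, 3.0])
    out = vsn(_set([row]), PreprocSpec(method="VSN", vsn_iterations=2))
    # against its own mean (itself), the affine fit is (a=1, b=0)
    assert np.allclose(out.intensities[0], row, atol=1e-10)


def test_vsn_collapsed_weights_suggest_bandwidth():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(20, 30))  # uniform residual structure
    with pytest.raises(ValueError, match="bandwidth"):
        vsn_weights(X, X.mean(axis=0), iterations=3, bandwidth=0.05)


# ---------------------------------------------------------------- SD

def test_sd_exact_on_quadratic():
    wn = np.linspace(0, 50, 60)
    data = _set([wn**2], wn=wn)
    out = second_derivative(data, PreprocSpec(method="SD"))
    assert np.allclose(out.intensities[0][5:-5], 2.0, atol=1e-8)


def test_sd_zero_on_linear():
    wn = np.linspace(0, 50, 60)
    out = second_derivative(_set([3 * wn + 1], wn=wn), PreprocSpec(method="SD"))
    assert np.allclose(out.intensities[0][5:-5], 0.0, atol=1e-10)


@pytest.mark.parametrize("window,tol", [(21, 2e-3), (11, 2e-4), (7, 5e-5)])
def test_sd_sine_analytic_oracle(window, tol):
    """-k^2 sin(kv) oracle; accuracy improves as the window shrinks."""
    wn = np.linspace(0, 400, 801)
    k = 0.05
    y = np.sin(k * wn)
    out = second_derivative(_set([y], wn=wn), PreprocSpec(method="SD", sd_window=window))
    interior = slice(window, -window)
    assert np.allclose(out.intensities[0][interior], -(k**2) * y[interior], atol=tol)


def test_sd_window_must_fit():
    with pytest.raises(ValueError):
        second_derivative(_set([[1.0, 2.0, 3.0, 4.0]]), PreprocSpec(method="SD", sd_window=11))


@pytest.mark.parametrize("bad", [
    dict(sd_window=10),
    dict(sd_polyorder=1),
    dict(sd_window=3, sd_polyorder=3),
    dict(vsn_bandwidth=0.0),
    dict(method="FOO"),
])
def test_invalid_preproc_specs_rejected(bad):
    with pytest.raises(ValueError):
        PreprocSpec(**{"method": "SD", **bad})


# ----------------------------------------------------- shared invariants

@pytest.mark.parametrize("method", ["MSC", "SNV", "VSN", "SD"])
def test_constant_offset_removed(small_dataset, method):
    """A constant added to every sample vanishes under the frozen corrections."""
    bank = PreprocessingBank().fit(small_dataset)
    base = bank.transform_one(small_dataset, method)
    shifted = small_dataset.with_intensities(small_dataset.intensities + 5.0)
    out = bank.transform_one(shifted, method)
    assert np.allclose(out.intensities, base.intensities, atol=1e-8)


@pytest.mark.parametrize("method", ["MSC", "SNV", "VSN"])
def test_per_sample_gain_removed_noise_free(clean_dataset, method):
    rng = np.random.default_rng(7)
    g = np.exp(rng.normal(0, 0.25, clean_dataset.n_samples))
    distorted = clean_dataset.with_intensities(clean_dataset.intensities * g[:, None])
    bank = PreprocessingBank().fit(clean_dataset)
    base = bank.transform_one(clean_dataset, method)
    out = bank.transform_one(distorted, method)
    assert np.allclose(out.intensities, base.intensities, atol=1e-7)


def test_snv_and_msc_idempotent(small_dataset):
    once = snv(small_dataset)
    assert np.allclose(snv(once).intensities, once.intensities, atol=1e-10)
    ref = small_dataset.intensities.mean(axis=0)
    m1 = msc(small_dataset, reference=ref)
    # second application with the SAME frozen reference
    assert np.allclose(msc(m1, reference=ref).intensities, m1.intensities, atol=1e-10)


def test_bank_freezes_training_state(small_dataset):
    """Test rows are corrected with the training reference, not their own."""
    train = small_dataset.subset(np.arange(0, 40))
    test = small_dataset.subset(np.arange(40, 60))
    bank = PreprocessingBank().fit(train)
    out = bank.transform_one(test, "MSC")
    expected = msc(test, reference=train.intensities.mean(axis=0))
    assert np.allclose(out.intensities, expected.intensities)
    own = msc(test)  # reference from the test rows themselves: must differ
    assert not np.allclose(out.intensities, own.intensities)
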