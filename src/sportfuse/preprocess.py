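"""Scatter-correction preprocessing for absorbance spectra.

Four corrections, each mapping a SpectrumSet to a corrected SpectrumSet:

* SNV  — standard normal variate: per-spectrum standardization.
* MSC  — multiplicative scatter correction: per-spectrum affine regression
         against a reference spectrum, then inversion.
* VSN  — variable sorting for normalization: a weighted MSC whose
         per-variable weights down-weight analyte-bearing variables so the
         affine fit is driven by scatter-dominated regions. Implemented as
         deterministic iterative reweighting (see ``vsn``); this captures
         the intent of the published method and is documented as an
         approximation.
* SD   — Savitzky-Golay second derivative, removing additive and linear
         baselines and sharpening overlapped bands.

Any data-dependent state (the MSC/VSN reference spectrum, the VSN weights)
is estimated from training rows only and applied frozen to test rows; the
``PreprocessingBank`` class packages this fit/apply split for the
multi-block fusion stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import savgol_filter

from .synthdata import SpectrumSet

__all__ = [
    "PreprocSpec",
    "snv",
    "msc",
    "vsn",
    "second_derivative",
    "PreprocessingBank",
    "METHODS",
]

Method = Literal["RAW", "MSC", "SNV", "VSN", "SD"]
METHODS: tuple[str, ...] = ("RAW", "MSC", "SNV", "VSN", "SD")


@dataclass
class PreprocSpec:
    """Configuration of one scatter-correction method.

    ``sd_window``/``sd_polyorder`` apply to SD only; ``vsn_iterations`` and
    ``vsn_bandwidth`` to VSN only. ``reference`` optionally fixes the
    MSC/VSN reference spectrum (default: mean of the fitted rows).
    """

    method: str = "RAW"
    sd_window: int = 11
    sd_polyorder: int = 3
    vsn_iterations: int = 5
    vsn_bandwidth: float = 1.0
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.sd_window % 2 != 1:
            raise ValueError("sd_window must be odd")
        if self.sd_polyorder < 2:
            raise ValueError("sd_polyorder must be >= 2 (second derivative)")
        if self.sd_window <= self.sd_polyorder:
            raise ValueError("sd_window must exceed sd_polyorder")
        if self.vsn_bandwidth <= 0:
            raise ValueError("vsn_bandwidth must be positive")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)


def snv(data: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: each row to mean 0, sample sd 1 (ddof=1)."""
    X = data.intensities
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        names = [data.sample_ids[i] for i in bad]
        raise ValueError(f"constant spectra cannot be SNV-corrected: {names}")
    return data.with_intensities((X - mu) / sd, note="snv")


def _affine_fit(X: np.ndarray, ref: np.ndarray, weights: np.ndarray | None = None):
    """Per-row weighted least-squares fit x ~ a*ref + b.

    Returns (a, b) vectors of length n_rows. Closed form of the 2-parameter
    weighted normal equations.
    """
    if weights is None:
        weights = np.ones_like(ref)
    w = weights / weights.sum()
    ref_mean = w @ ref
    x_mean = X @ w
    ref_c = ref - ref_mean
    denom = w @ (ref_c**2)
    if denom < 1e-300:
        raise ValueError("reference spectrum is constant under the given weights")
    a = ((X - x_mean[:, None]) * ref_c) @ w / denom
    b = x_mean - a * ref_mean
    return a, b


def msc(data: SpectrumSet, reference: np.ndarray | str = "mean") -> SpectrumSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is replaced by (x - b) / a, where (a, b) are the ordinary
    least-squares slope and intercept of x regressed on the reference.
    The default reference is the column mean of ``data`` itself; pass a
    frozen vector to correct test rows with training-set state.
    """
    X = data.intensities
    ref = X.mean(axis=0) if isinstance(reference, str) else np.asarray(reference, float)
    if ref.shape != (X.shape[1],):
        raise ValueError("reference length must equal wavenumber count")
    if ref.std() == 0:
        raise ValueError("reference spectrum must not be constant")
    a, b = _affine_fit(X, ref)
    if np.any(np.abs(a) < 1e-12):
        bad = [data.sample_ids[i] for i in np.flatnonzero(np.abs(a) < 1e-12)]
        raise ValueError(f"degenerate spectra (slope ~ 0) in MSC: {bad}")
    return data.with_intensities((X - b[:, None]) / a[:, None], note="msc")


def vsn_weights(
    X: np.ndarray, ref: np.ndarray, iterations: int, bandwidth: float
) -> np.ndarray:
    """Estimate per-variable VSN weights in [0, 1] by iterative reweighting.

    Starting from uniform weights, each pass fits every spectrum affinely to
    the reference under the current weights, pools the absolute residuals per
    variable (median over samples), rescales them by their own median, and
    maps them through a Gaussian kernel exp(-(r/bandwidth)^2). Variables
    whose residuals are dominated by chemical signal rather than scatter end
    up down-weighted. With ``iterations=0`` the weights stay uniform and the
    downstream fit reduces to plain MSC.
    """
    w = np.ones_like(ref)
    for _ in range(iterations):
        a, b = _affine_fit(X, ref, w)
        resid = X - (a[:, None] * ref[None, :] + b[:, None])
        per_var = np.median(np.abs(resid), axis=0)
        scale = np.median(per_var)
        if scale <= 0:
            break  # perfect affine fit everywhere; weights stay as-is
        z = per_var / scale
        w = np.exp(-((z / bandwidth) ** 2))
        if w.max() < 1e-8:
            raise ValueError(
                "VSN weights collapsed to zero; increase vsn_bandwidth"
            )
    return w


def vsn(
    data: SpectrumSet,
    spec: PreprocSpec | None = None,
    reference: np.ndarray | str = "mean",
    weights: np.ndarray | None = None,
) -> SpectrumSet:
    """Variable sorting for normalization: weighted MSC.

    Weights are estimated by ``vsn_weights`` unless supplied frozen (the
    test-set path). The estimated weights are recorded in provenance.
    """
    spec = spec or PreprocSpec(method="VSN")
    X = data.intensities
    if X.shape[1] < 2:
        raise ValueError("VSN requires at least 2 wavenumbers")
    ref = X.mean(axis=0) if isinstance(reference, str) else np.asarray(reference, float)
    if weights is None:
        weights = vsn_weights(X, ref, spec.vsn_iterations, spec.vsn_bandwidth)
    a, b = _affine_fit(X, ref, weights)
    if np.any(np.abs(a) < 1e-12):
        bad = [data.sample_ids[i] for i in np.flatnonzero(np.abs(a) < 1e-12)]
        raise ValueError(f"degenerate spectra (slope ~ 0) in VSN: {bad}")
    out = data.with_intensities(
        (X - b[:, None]) / a[:, None],
        note=f"vsn(weights_mean={weights.mean():.4f})",
    )
    return out


def second_derivative(data: SpectrumSet, spec: PreprocSpec | None = None) -> SpectrumSet:
    """Savitzky-Golay second derivative, units absorbance * cm^2.

    Output length equals input length; edge points come from the one-sided
    polynomial fits of the filter (``mode='interp'``), noted in provenance.
    """
    spec = spec or PreprocSpec(method="SD")
    X = data.intensities
    if spec.sd_window >= X.shape[1]:
        raise ValueError("sd_window must be smaller than the spectrum length")
    step = float(np.mean(np.diff(data.wavenumbers)))
    D2 = savgol_filter(
        X,
        window_length=spec.sd_window,
        polyorder=spec.sd_polyorder,
        deriv=2,
        delta=step,
        axis=1,
        mode="interp",
    )
    return data.with_intensities(
        D2, note=f"sd(window={spec.sd_window},polyorder={spec.sd_polyorder},edges=interp)"
    )


@dataclass
class PreprocessingBank:
    """Fit scatter corrections on training rows, apply frozen to any rows.

    ``fit`` estimates the MSC/VSN reference (training mean spectrum) and the
    VSN weights; ``transform`` applies each requested method with that
    frozen state, so no test information leaks into the correction.
    """

    specs: dict[str, PreprocSpec] = field(default_factory=dict)
    _reference: np.ndarray | None = None
    _vsn_weights: np.ndarray | None = None

    def __init__(self, methods: list[str] | None = None,
                 specs: dict[str, PreprocSpec] | None = None) -> None:
        methods = list(methods) if methods is not None else ["MSC", "SNV", "VSN", "SD"]
        self.specs = dict(specs) if specs else {}
        for m in methods:
            self.specs.setdefault(m, PreprocSpec(method=m))
        self.methods = methods
        self._reference = None
        self._vsn_weights = None

    def fit(self, train: SpectrumSet) -> "PreprocessingBank":
        self._reference = train.intensities.mean(axis=0)
        if "VSN" in self.methods:
            spec = self.specs["VSN"]
            self._vsn_weights = vsn_weights(
                train.intensities, self._reference, spec.vsn_iterations, spec.vsn_bandwidth
            )
        return self

    def transform_one(self, data: SpectrumSet, method: str) -> SpectrumSet:
        if self._reference is None:
            raise RuntimeError("PreprocessingBank must be fit before transform")
        if method == "RAW":
            return data.with_intensities(data.intensities.copy(), note="raw")
        if method == "SNV":
            return snv(data)
        if method == "MSC":
            return msc(data, reference=self._reference)
        if method == "VSN":
            return vsn(data, self.specs["VSN"], reference=self._reference,
                       weights=self._vsn_weights)
        if method == "SD":
            return second_derivative(data, self.specs["SD"])
        raise ValueError(f"unknown method {method!r}")

    def transform(self, data: SpectrumSet) -> dict[str, SpectrumSet]:
        return {m: self.transform_one(data, m) for m in self.methods}
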