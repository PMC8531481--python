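"""Synchronous generalized two-dimensional correlation spectroscopy.

Given m spectra treated as a perturbation series, the dynamic spectra are
the deviations from a reference spectrum (here the mean over the series,
the standard generalized-2DCOS convention). The synchronous correlation
intensity between two wavenumbers v1 and v2 is

    Phi(v1, v2) = S(v1)^T S(v2) / (m - 1),

i.e. the sample covariance of the dynamic intensities; the diagonal holds
the per-variable variances (auto-peaks). Comparing the maps of differently
preprocessed copies of one dataset quantifies how much complementary
structure each preprocessing exposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import SpectrumSet

__all__ = ["SyncMap", "sync_2dcos", "map_difference", "plot_sync_map"]


@dataclass
class SyncMap:
    """Synchronous 2D correlation map for one (preprocessed) dataset."""

    wavenumbers: np.ndarray
    phi: np.ndarray
    m: int
    dynamic_reference: np.ndarray

    def auto_peaks(self) -> np.ndarray:
        """Diagonal of the map: per-variable dynamic variance."""
        return np.diag(self.phi)


def sync_2dcos(data: SpectrumSet, order: np.ndarray | None = None) -> SyncMap:
    """Synchronous 2D correlation map of a spectra set.

    Samples play the role of the perturbation steps. ``order`` optionally
    reorders them (e.g. by analyte content); the synchronous map is
    invariant to the ordering, but the hook keeps the perturbation axis
    explicit and is used by the asynchronous extensions users may build.
    """
    X = data.intensities
    if order is not None:
        X = X[np.asarray(order, dtype=int)]
    m = X.shape[0]
    if m < 2:
        raise ValueError("synchronous 2DCOS needs at least 2 spectra")
    ref = X.mean(axis=0)
    S = X - ref
    phi = (S.T @ S) / (m - 1)
    return SyncMap(wavenumbers=data.wavenumbers.copy(), phi=phi, m=m, dynamic_reference=ref)


def map_difference(a: SyncMap, b: SyncMap) -> dict[str, float]:
    """Quantify how different two synchronous maps are.

    Each map is scaled by its own maximum absolute intensity (so the
    comparison is about structure, not raw magnitude), then summarized by
    the Frobenius norm of the difference and by the auto-peak (diagonal)
    discrepancies.
    """
    if a.wavenumbers.shape != b.wavenumbers.shape or not np.allclose(
        a.wavenumbers, b.wavenumbers
    ):
        raise ValueError("maps must share the same wavenumber grid")
    na = np.max(np.abs(a.phi))
    nb = np.max(np.abs(b.phi))
    pa = a.phi / na if na > 0 else a.phi
    pb = b.phi / nb if nb > 0 else b.phi
    diff = pa - pb
    auto = np.diag(pa) - np.diag(pb)
    return {
        "frobenius": float(np.linalg.norm(diff)),
        "auto_peak_rms": float(np.sqrt(np.mean(auto**2))),
        "auto_peak_max": float(np.max(np.abs(auto))),
    }


def plot_sync_map(sync_map: SyncMap, ax=None, n_levels: int = 16):
    """Optional contour rendering of a synchronous map (display helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    w = sync_map.wavenumbers
    ax.contour(w, w, sync_map.phi, levels=n_levels)
    ax.set_xlabel("wavenumber $v_1$ (cm$^{-1}$)")
    ax.set_ylabel("wavenumber $v_2$ (cm$^{-1}$)")
    ax.invert_xaxis()
    ax.invert_yaxis()
    return ax
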