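"""Synthetic FT-IR-like spectra with known class structure and analyte content.

Each spectrum is a sum of Gaussian absorption bands on a wavenumber grid,
modulated per sample by

* a class effect (deterministic per-class perturbation of band amplitudes),
* the analyte content (selected band amplitudes scale linearly with it),
* scatter artifacts: a per-sample multiplicative gain, an additive offset,
  a smooth quadratic baseline, and white noise.

The gain/offset pair is exactly the affine artifact model that MSC and SNV
assume, so in the noise-free case those corrections are exactly invertible —
which is what makes the generator usable as ground truth for the
preprocessing tests downstream.

Content is drawn from a lognormal distribution parameterized by its mean and
coefficient of variation, guaranteeing positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "SpectrumSet",
    "generate_dataset",
    "write_spectra",
    "read_spectra",
]

# The eight dominant mid-IR absorption bands of dried Gentiana root powder
# (O-H stretch, ester methylene, aromatic C-C, CH3 bends, C-O stretches).
DEFAULT_BAND_CENTERS = (3400.0, 2928.0, 2857.0, 1615.0, 1427.0, 1375.0, 1260.0, 1057.0)
DEFAULT_BAND_WIDTHS = (180.0, 45.0, 40.0, 70.0, 40.0, 30.0, 50.0, 90.0)
DEFAULT_BAND_AMPLITUDES = (0.9, 0.35, 0.30, 0.85, 0.40, 0.38, 0.42, 0.75)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic FT-IR generator.

    Defaults emulate the study conditions: 5 geographic origin classes,
    ~55 samples per class (273 total), absorbance over 4000-400 cm^-1 at
    4 cm^-1 resolution, eight dominant bands, and a total-secoiridoid
    content with mean 10 mg/g and coefficient of variation 25.2%.
    """

    n_classes: int = 5
    n_per_class: int = 55
    wavenumber_start: float = 4000.0
    wavenumber_stop: float = 400.0
    wavenumber_step: float = 4.0
    band_centers: Sequence[float] = DEFAULT_BAND_CENTERS
    band_widths: Sequence[float] = DEFAULT_BAND_WIDTHS
    band_amplitudes: Sequence[float] = DEFAULT_BAND_AMPLITUDES
    class_effect_size: float = 0.25
    content_mean: float = 10.0
    content_cv: float = 0.252
    content_bands: Sequence[int] = (3, 7)
    scatter_gain_sd: float = 0.15
    scatter_offset_sd: float = 0.05
    baseline_curvature_sd: float = 0.03
    noise_sd: float = 0.005
    seed: int = 0

    def wavenumbers(self) -> np.ndarray:
        """Ascending wavenumber grid, regardless of acquisition convention."""
        lo = min(self.wavenumber_start, self.wavenumber_stop)
        hi = max(self.wavenumber_start, self.wavenumber_stop)
        step = abs(self.wavenumber_step)
        n_steps = (hi - lo) / step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("wavenumber_step must divide the grid range")
        return lo + step * np.arange(int(round(n_steps)) + 1)

    def validate(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        widths = np.asarray(self.band_widths, dtype=float)
        if np.any(widths <= 0):
            raise ValueError("band widths must be positive")
        if not (0 <= self.content_cv < 1):
            raise ValueError(
                "content_cv must lie in [0, 1) for the lognormal parameterization"
            )
        if len(self.band_centers) != len(widths) or len(widths) != len(
            self.band_amplitudes
        ):
            raise ValueError("band_centers, band_widths, band_amplitudes must align")
        for mag in (
            self.scatter_gain_sd,
            self.scatter_offset_sd,
            self.baseline_curvature_sd,
            self.noise_sd,
        ):
            if mag < 0:
                raise ValueError("artifact magnitudes must be >= 0")
        if any(b < 0 or b >= len(self.band_centers) for b in self.content_bands):
            raise ValueError("content_bands indices out of range")


@dataclass
class SpectrumSet:
    """A spectra matrix with per-sample metadata.

    The universal currency between pipeline stages: ``intensities`` has one
    row per sample, one column per wavenumber (ascending cm^-1).
    ``provenance`` records the preprocessing history as free text lines.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    class_labels: np.ndarray | None = None
    content: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (samples x wavenumbers)")
        n, p = self.intensities.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal intensity row count")
        if self.wavenumbers.shape != (p,):
            raise ValueError("wavenumber count must equal intensity column count")
        if len(set(self.sample_ids)) != n:
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if self.class_labels is not None:
            self.class_labels = np.asarray(self.class_labels)
            if self.class_labels.shape != (n,):
                raise ValueError("class_labels length mismatch")
        if self.content is not None:
            self.content = np.asarray(self.content, dtype=float)
            if self.content.shape != (n,):
                raise ValueError("content length mismatch")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.intensities.shape[1]

    def subset(self, indices: np.ndarray) -> "SpectrumSet":
        """A new SpectrumSet restricted to ``indices`` (row order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            class_labels=None if self.class_labels is None else self.class_labels[idx],
            content=None if self.content is None else self.content[idx],
            provenance=list(self.provenance),
        )

    def with_intensities(
        self, intensities: np.ndarray, note: str | None = None
    ) -> "SpectrumSet":
        """Copy with replaced intensity matrix and an appended provenance note."""
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return SpectrumSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=np.asarray(intensities, dtype=float),
            sample_ids=list(self.sample_ids),
            class_labels=None if self.class_labels is None else self.class_labels.copy(),
            content=None if self.content is None else self.content.copy(),
            provenance=prov,
        )


def _pure_spectrum(
    config: GeneratorConfig,
    wavenumbers: np.ndarray,
    class_pattern: np.ndarray,
    content: float,
) -> np.ndarray:
    """Artifact-free spectrum for one (class, content) combination."""
    amps = np.asarray(config.band_amplitudes, dtype=float).copy()
    amps *= 1.0 + config.class_effect_size * class_pattern
    for b in config.content_bands:
        amps[b] *= content / config.content_mean
    centers = np.asarray(config.band_centers, dtype=float)
    widths = np.asarray(config.band_widths, dtype=float)
    # (n_bands, n_wn) Gaussian profiles summed with amplitudes
    profiles = np.exp(-0.5 * ((wavenumbers[None, :] - centers[:, None]) / widths[:, None]) ** 2)
    return amps @ profiles


def generate_dataset(config: GeneratorConfig) -> SpectrumSet:
    """Generate a synthetic spectra set with known class and content truth.

    Deterministic for a fixed config (including seed): same config, same
    bits. Class band patterns are drawn once from a seed-derived stream, so
    two samples of the same class and content are identical when all
    artifact magnitudes and the noise level are zero.
    """
    config.validate()
    wn = config.wavenumbers()
    rng = np.random.default_rng(config.seed)

    # fixed per-class band-amplitude perturbation patterns in [-1, 1]
    pattern_rng = np.random.default_rng([config.seed, 2371])
    patterns = pattern_rng.uniform(-1.0, 1.0, size=(config.n_classes, len(config.band_centers)))

    n = config.n_classes * config.n_per_class
    labels = np.repeat([f"O{c + 1}" for c in range(config.n_classes)], config.n_per_class)

    if config.content_cv > 0:
        sigma2 = np.log1p(config.content_cv**2)
        mu = np.log(config.content_mean) - sigma2 / 2.0
        content = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    else:
        content = np.full(n, config.content_mean)

    gains = np.exp(rng.normal(0.0, config.scatter_gain_sd, size=n))
    offsets = rng.normal(0.0, config.scatter_offset_sd, size=n)
    curvatures = rng.normal(0.0, config.baseline_curvature_sd, size=n)

    # normalized coordinate for the smooth baseline
    u = (wn - wn.mean()) / (wn[-1] - wn[0])
    X = np.empty((n, wn.size))
    for i in range(n):
        c = i // config.n_per_class
        pure = _pure_spectrum(config, wn, patterns[c], content[i])
        X[i] = pure * gains[i] + offsets[i] + curvatures[i] * (u**2)
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)

    ids = [f"S{i + 1:04d}" for i in range(n)]
    return SpectrumSet(
        wavenumbers=wn,
        intensities=X,
        sample_ids=ids,
        class_labels=labels,
        content=content,
        provenance=[f"synthetic(seed={config.seed})"],
    )


def noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with every artifact magnitude zeroed."""
    return replace(
        config,
        scatter_gain_sd=0.0,
        scatter_offset_sd=0.0,
        baseline_curvature_sd=0.0,
        noise_sd=0.0,
    )


# ---------------------------------------------------------------------------
# I/O: plain CSV, acquisition display order (high -> low wavenumber)
# ---------------------------------------------------------------------------

def write_spectra(dataset: SpectrumSet, spectra_path, meta_path=None) -> None:
    """Write spectra (and optionally metadata) as plain CSV.

    The spectra file has a header row ``sample_id`` followed by wavenumbers
    as numerals in acquisition display order (descending, 4000 -> 400); one
    row per sample. The metadata file has columns sample_id, class_label,
    content (columns omitted when the field is absent).
    """
    order = np.argsort(dataset.wavenumbers)[::-1]
    df = pd.DataFrame(
        dataset.intensities[:, order],
        columns=[_format_wn(w) for w in dataset.wavenumbers[order]],
    )
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(spectra_path, index=False)
    if meta_path is not None:
        meta = pd.DataFrame({"sample_id": dataset.sample_ids})
        if dataset.class_labels is not None:
            meta["class_label"] = dataset.class_labels
        if dataset.content is not None:
            meta["content"] = dataset.content
        meta.to_csv(meta_path, index=False)


def _format_wn(w: float) -> str:
    return f"{w:.6g}"


def read_spectra(spectra_path, meta_path=None) -> SpectrumSet:
    """Read a spectra CSV (plus optional metadata CSV) back into a SpectrumSet.

    Wavenumbers are re-sorted ascending; classification remains possible when
    the metadata lacks a content column.
    """
    df = pd.read_csv(spectra_path)
    if df.columns[0] != "sample_id":
        raise ValueError("first column of a spectra file must be 'sample_id'")
    ids = df["sample_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    try:
        wn = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber column: {exc}") from exc
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    order = np.argsort(wn)
    labels = None
    content = None
    if meta_path is not None and Path(meta_path).exists():
        meta = pd.read_csv(meta_path).set_index("sample_id")
        meta = meta.loc[ids]
        if "class_label" in meta.columns:
            labels = meta["class_label"].to_numpy()
        if "content" in meta.columns and meta["content"].notna().all():
            content = meta["content"].to_numpy(dtype=float)
    return SpectrumSet(
        wavenumbers=wn[order],
        intensities=X[:, order],
        sample_ids=ids,
        class_labels=labels,
        content=content,
        provenance=[f"loaded({spectra_path})"],
    )
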