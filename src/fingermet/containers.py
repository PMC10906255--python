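"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

#: the fingerprinting acquisition window in Da
MZ_WINDOW: tuple[float, float] = (100.0, 400.0)


@dataclass
class Spectrum:
    """One acquisition: an m/z grid with intensities plus sample metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError(f"{self.sample_id or 'spectrum'}: mz/intensity must be 1-D and equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"{self.sample_id or 'spectrum'}: mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError(f"{self.sample_id or 'spectrum'}: negative intensities")

    def windowed(self, lo: float = MZ_WINDOW[0], hi: float = MZ_WINDOW[1]) -> "Spectrum":
        keep = (self.mz >= lo) & (self.mz <= hi)
        return Spectrum(self.mz[keep], self.intensity[keep], self.sample_id, dict(self.metadata))


@dataclass
class PeakList:
    """Centroided peaks of one spectrum: (m/z, intensity, SNR) triples."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.mz.shape == self.intensity.shape == self.snr.shape):
            raise ValueError("peak arrays must share a shape")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"{self.sample_id or 'peaklist'}: peak m/z must be ascending")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class FeatureMatrix:
    """Samples × aligned m/z features with optional group labels."""

    feature_mz: np.ndarray
    values: np.ndarray
    sample_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be samples × features")
        if self.values.shape != (len(self.sample_ids), self.feature_mz.size):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.sample_ids)} samples × {self.feature_mz.size} features"
            )
        if self.feature_mz.size >= 2 and not np.all(np.diff(self.feature_mz) > 0):
            raise ValueError("feature m/z must be strictly increasing")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must match sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix carries no labels")
        return np.asarray(self.labels, dtype=object)

    def subset_features(self, index: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        index = np.asarray(index)
        return FeatureMatrix(
            self.feature_mz[index],
            self.values[:, index],
            list(self.sample_ids),
            None if self.labels is None else list(self.labels),
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        index = np.asarray(index)
        return FeatureMatrix(
            self.feature_mz.copy(),
            self.values[index],
            [self.sample_ids[i] for i in index],
            None if self.labels is None else [self.labels[i] for i in index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{m:.4f}" for m in self.feature_mz],
        )
        return df
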