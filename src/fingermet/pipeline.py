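"""Raw spectra → aligned, normalized feature matrix with QC.

The processing chain is: baseline removal and smoothing
(:func:`preprocess`), SNR-thresholded centroiding (:func:`detect_peaks`),
cross-sample m/z alignment (:func:`align_features`), total-ion-current
normalization (:func:`normalize_tic`), and two QC summaries — per-sample
cosine similarity against the leave-one-out group median profile
(:func:`similarity_scores`) and per-feature replicate coefficients of
variation (:func:`replicate_cv`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, minimum_filter1d, uniform_filter1d
from scipy.signal import argrelmax, savgol_filter

from .containers import FeatureMatrix, PeakList, Spectrum


def preprocess(spectrum: Spectrum, baseline_window: float = 5.0,
               smooth_window: int = 7) -> Spectrum:
    """Baseline-subtract and smooth one spectrum.

    Baseline is a rolling minimum over ``baseline_window`` Da followed by a
    rolling mean of the same width, subtracted with a floor at zero;
    smoothing is a degree-2 moving polynomial (Savitzky–Golay) over
    ``smooth_window`` points.
    """
    if baseline_window <= 0 or smooth_window <= 0:
        raise ValueError("windows must be positive")
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    mz, y = spectrum.mz, spectrum.intensity
    span = mz[-1] - mz[0]
    if baseline_window > span:
        raise ValueError(f"baseline_window {baseline_window} Da exceeds spectrum span {span:.3g} Da")
    step = float(np.median(np.diff(mz)))
    w = max(3, int(round(baseline_window / step)))
    baseline = uniform_filter1d(minimum_filter1d(y, size=w, mode="nearest"),
                                size=w, mode="nearest")
    cleaned = np.clip(y - baseline, 0.0, None)
    if smooth_window >= 5 and cleaned.size >= smooth_window:
        cleaned = np.clip(savgol_filter(cleaned, smooth_window, polyorder=2), 0.0, None)
    return Spectrum(mz, cleaned, spectrum.sample_id, dict(spectrum.metadata))


def detect_peaks(spectrum: Spectrum, snr_min: float = 3.0) -> PeakList:
    """Centroid local maxima above ``snr_min`` times a robust noise level.

    Noise is estimated as 1.4826 × the median absolute deviation of the
    detrended signal (residual about a rolling median), which tracks the
    post-smoothing noise scale.  Centroid m/z is the intensity-weighted
    mean over the apex ± its support (contiguous descending flanks above
    a small floor).
    """
    if snr_min <= 0:
        raise ValueError("snr_min must be positive")
    mz, y = spectrum.mz, spectrum.intensity
    if y.size == 0 or np.all(y == 0):
        return PeakList(np.array([]), np.array([]), np.array([]), spectrum.sample_id)
    trend = median_filter(y, size=min(51, y.size), mode="nearest")
    resid = np.clip(y - trend, 0.0, None)
    mad = np.median(np.abs((y - trend) - np.median(y - trend)))
    noise = 1.4826 * mad
    if noise <= 0:
        noise = max(1e-12, 1e-9 * float(y.max()))
    (apexes,) = argrelmax(y, order=2)
    keep = resid[apexes] >= snr_min * noise
    apexes = apexes[keep]
    if np.isinf(snr_min) or apexes.size == 0:
        return PeakList(np.array([]), np.array([]), np.array([]), spectrum.sample_id)
    cents, heights, snrs = [], [], []
    for a in apexes:
        # gate on the locally detrended residual, but centroid/quantify from
        # the baseline-corrected signal itself: near two close peaks the
        # rolling-median trend rides up the shared flank and would skew a
        # residual-weighted centroid
        floor = max(0.005 * y[a], noise)
        i0 = a
        while i0 > 0 and y[i0 - 1] >= floor and y[i0 - 1] <= y[i0]:
            i0 -= 1
        i1 = a
        while i1 < y.size - 1 and y[i1 + 1] >= floor and y[i1 + 1] <= y[i1]:
            i1 += 1
        seg = slice(i0, i1 + 1)
        w = y[seg]
        cents.append(float(np.sum(mz[seg] * w) / np.sum(w)))
        heights.append(float(y[a]))
        snrs.append(float(resid[a] / noise))
    order = np.argsort(cents)
    cents = np.asarray(cents)[order]
    heights = np.asarray(heights)[order]
    snrs = np.asarray(snrs)[order]
    # merge pathological duplicate centroids so the peak list stays strictly ascending
    uniq = np.concatenate(([True], np.diff(cents) > 0))
    return PeakList(cents[uniq], heights[uniq], snrs[uniq], spectrum.sample_id)


def align_features(peaklists: list[PeakList], tol: float = 0.2,
                   min_presence: float = 0.1) -> FeatureMatrix:
    """Cluster peak m/z across samples into aligned features.

    Greedy left-to-right single-linkage on the pooled sorted peak list,
    capping cluster width at ``tol`` (this greedy packing minimizes the
    number of clusters for sorted points under a width cap).  Feature m/z
    is the median member m/z; a sample contributing several peaks to one
    cluster keeps the most intense; features present in fewer than
    ``min_presence`` of samples are dropped; missing entries are 0.
    """
    if not peaklists:
        raise ValueError("no peak lists to align")
    if tol <= 0 or not 0 < min_presence <= 1:
        raise ValueError("need tol > 0 and 0 < min_presence <= 1")
    sample_ids = [p.sample_id or f"sample_{i}" for i, p in enumerate(peaklists)]
    pooled_mz, pooled_int, pooled_sample = [], [], []
    for si, p in enumerate(peaklists):
        pooled_mz.extend(p.mz)
        pooled_int.extend(p.intensity)
        pooled_sample.extend([si] * len(p))
    if not pooled_mz:
        raise ValueError("all peak lists are empty")
    order = np.argsort(pooled_mz)
    pooled_mz = np.asarray(pooled_mz)[order]
    pooled_int = np.asarray(pooled_int)[order]
    pooled_sample = np.asarray(pooled_sample)[order]

    assignment = assign_clusters_greedy(pooled_mz, tol)
    n_clusters = assignment[-1] + 1
    n_samples = len(peaklists)
    values = np.zeros((n_samples, n_clusters))
    feature_mz = np.empty(n_clusters)
    for c in range(n_clusters):
        members = assignment == c
        feature_mz[c] = float(np.median(pooled_mz[members]))
        for si, inten in zip(pooled_sample[members], pooled_int[members]):
            values[si, c] = max(values[si, c], inten)
    presence = (values > 0).mean(axis=0)
    keep = presence >= min_presence
    return FeatureMatrix(feature_mz[keep], values[:, keep], sample_ids)


def assign_clusters_greedy(sorted_mz: np.ndarray, tol: float) -> np.ndarray:
    """Greedy width-capped clustering of ascending m/z values."""
    assignment = np.empty(sorted_mz.size, dtype=int)
    cluster = 0
    start = sorted_mz[0]
    for i, m in enumerate(sorted_mz):
        if m - start > tol:
            cluster += 1
            start = m
        assignment[i] = cluster
    return assignment


def normalize_tic(matrix: FeatureMatrix) -> FeatureMatrix:
    """Scale each sample to the cohort-median raw total intensity."""
    totals = matrix.values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        bad = ", ".join(matrix.sample_ids[i] for i in zero[:5])
        raise ValueError(f"zero-total sample(s): {bad}")
    target = float(np.median(totals))
    values = matrix.values * (target / totals)[:, None]
    return FeatureMatrix(matrix.feature_mz.copy(), values,
                         list(matrix.sample_ids),
                         None if matrix.labels is None else list(matrix.labels))


@dataclass
class SimilarityReport:
    scores: pd.Series  # per sample_id
    fraction_above: float
    threshold: float


def similarity_scores(matrix: FeatureMatrix, threshold: float = 0.85) -> SimilarityReport:
    """Cosine similarity of each sample against its leave-one-out group median.

    Returns per-sample scores and the fraction exceeding ``threshold``
    (the spectral-quality summary used to certify fingerprint
    reproducibility).
    """
    labels = matrix.label_array()
    scores = np.empty(matrix.n_samples)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        block = matrix.values[idx]
        for k, i in enumerate(idx):
            others = np.delete(block, k, axis=0)
            ref = np.median(others, axis=0) if others.shape[0] else block[k]
            v = matrix.values[i]
            nv, nr = np.linalg.norm(v), np.linalg.norm(ref)
            if nv == 0:
                raise ValueError(f"zero-vector sample {matrix.sample_ids[i]}: similarity undefined")
            if nr == 0:
                raise ValueError(f"zero reference profile for group {g}")
            scores[i] = float(v @ ref / (nv * nr))
    series = pd.Series(scores, index=matrix.sample_ids, name="similarity")
    return SimilarityReport(series, float((series > threshold).mean()), threshold)


def replicate_cv(matrix: FeatureMatrix) -> pd.Series:
    """Per-feature CV% (sd/mean × 100) across replicate rows of one sample.

    Zero-mean features get NaN (CV undefined), with a warning.
    """
    if matrix.n_samples < 3:
        raise ValueError("replicate CV needs >= 3 replicates")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean * 100.0, np.nan)
    if np.any(mean == 0):
        warnings.warn(f"{int((mean == 0).sum())} zero-mean feature(s): CV reported as NaN")
    return pd.Series(cv, index=[f"{m:.4f}" for m in matrix.feature_mz], name="cv_percent")


def process_cohort(spectra: list[Spectrum], labels: dict[str, str] | None = None,
                   baseline_window: float = 5.0, smooth_window: int = 7,
                   snr_min: float = 3.0, tol: float = 0.2,
                   min_presence: float = 0.1) -> FeatureMatrix:
    """Convenience chain: preprocess → detect → align → TIC-normalize."""
    peaklists = [detect_peaks(preprocess(s, baseline_window, smooth_window), snr_min)
                 for s in spectra]
    matrix = align_features(peaklists, tol=tol, min_presence=min_presence)
    matrix = normalize_tic(matrix)
    if labels is not None:
        matrix.labels = [labels[sid] for sid in matrix.sample_ids]
    return matrix
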