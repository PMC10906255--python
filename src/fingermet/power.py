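"""Pilot-based power and sample-size estimation at a controlled FDR.

From a small pilot cohort the per-feature standardized effects (Cohen's
d on log intensities) and the null fraction π₀ are estimated; the
per-test significance level α* at which Benjamini–Hochberg control is
expected to hit a target FDR is then solved by fixed-point iteration on

    E[FDR](α) = π₀ · m · α / E[#rejections](α),

and the average two-sample t-test power of the non-null features at α*
gives the predicted study power for a candidate per-group sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix
from .diagnosis import _binary_labels


@dataclass
class PilotSummary:
    effects: np.ndarray  # per-feature Cohen's d on log intensities (signed)
    variances: np.ndarray  # per-feature pooled variance of log intensities
    n_pilot: tuple[int, int]
    pi0: float
    feature_mz: np.ndarray
    p_values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("pilot effects must be finite")
        if not 0 <= self.pi0 <= 1:
            raise ValueError("pi0 must be in [0, 1]")

    @property
    def nonnull_effects(self) -> np.ndarray:
        """Effects of features deemed non-null under the π₀ histogram split.

        The m·(1−π₀) features with the smallest pilot p values are treated
        as the non-null set.
        """
        m = self.effects.size
        k = int(round((1 - self.pi0) * m))
        if k == 0:
            return np.array([])
        order = np.argsort(self.p_values)
        return self.effects[order[:k]]


def summarize_pilot(matrix: FeatureMatrix, labels=None, log_transform: bool = True,
                    shrink: bool = True, positive_label: str | None = None,
                    ) -> PilotSummary:
    """Per-feature effect sizes and a π₀ estimate from a pilot cohort.

    d = (case mean − control mean) / pooled sd on (log1p-transformed)
    intensities; π₀ is twice the fraction of two-sample t-test p values
    above 0.5, clipped to [0, 1].  Zero-variance features are excluded
    with a warning.  With ``shrink`` on (default), each d is shrunk
    toward 0 by a positive-part factor 1 − v_d/d² (v_d the usual
    large-sample variance of a standardized mean difference), countering
    the winner's-curse inflation of small pilots.
    """
    lab = np.asarray(labels if labels is not None else matrix.label_array())
    y, _, _ = _binary_labels(lab, positive_label)
    n1, n0 = int(y.sum()), int((y == 0).sum())
    if min(n0, n1) < 3:
        raise ValueError("pilot needs >= 3 samples per group")
    x = np.log1p(matrix.values) if log_transform else matrix.values.copy()
    case, ctrl = x[y == 1], x[y == 0]
    var1 = case.var(axis=0, ddof=1)
    var0 = ctrl.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * var1 + (n0 - 1) * var0) / (n1 + n0 - 2)
    ok = pooled > 0
    if not np.all(ok):
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance feature(s) from the pilot summary")
    d = (case.mean(axis=0) - ctrl.mean(axis=0))[ok] / np.sqrt(pooled[ok])
    t = stats.ttest_ind(case[:, ok], ctrl[:, ok], axis=0)
    p = np.asarray(t.pvalue)
    pi0 = float(np.clip(2.0 * np.mean(p > 0.5), 0.0, 1.0))
    if shrink:
        v_d = (n1 + n0) / (n1 * n0) + d**2 / (2 * (n1 + n0))
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(d != 0, np.clip(1.0 - v_d / d**2, 0.0, 1.0), 0.0)
        d = d * factor
    return PilotSummary(effects=d, variances=pooled[ok], n_pilot=(n1, n0),
                        pi0=pi0, feature_mz=matrix.feature_mz[ok], p_values=p)


def _t_power(d: np.ndarray, n_per_group: int, alpha: float) -> np.ndarray:
    """Two-sided two-sample t-test power at effect |d|, noncentral-t exact.

    Power = P[T > t_crit] + P[T < −t_crit] with T ~ nct(2n−2, d·√(n/2)).
    The wrong-side tail underflows to NaN in scipy at large noncentrality;
    it is below 1e-10 there and is floored at 0 (statsmodels'
    TTestIndPower inherits the same NaN, hence the direct computation;
    the two agree at moderate effects — see the test suite).
    """
    d = np.atleast_1d(np.abs(np.asarray(d, float)))
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    crit = stats.t.ppf(1 - alpha / 2.0, df)
    right = stats.nct.sf(crit, df, nc)
    wrong = np.nan_to_num(stats.nct.cdf(-crit, df, nc), nan=0.0)
    return np.clip(right + wrong, 0.0, 1.0)


def solve_alpha_star(effects: np.ndarray, m: int, pi0: float, n_per_group: int,
                     fdr: float, tol: float = 1e-8, max_iter: int = 200) -> float:
    """Per-test α at which expected BH-controlled FDR equals the target.

    Fixed-point iteration on α ← fdr · R(α) / (π₀ m), with
    R(α) = π₀ m α + Σ power_i(α); the result is capped at α* ≤ fdr, which
    also covers the degenerate all-non-null pilot (π₀ = 0 ⇒ α* = fdr).
    """
    effects = np.asarray(effects, float)
    if effects.size == 0:
        raise ValueError("no non-null features: predicted power undefined")
    n_null = pi0 * m
    if n_null <= 0:
        return fdr
    alpha = fdr / m  # Bonferroni-like start, well below the target
    for _ in range(max_iter):
        rejections = n_null * alpha + _t_power(effects, n_per_group, alpha).sum()
        new = fdr * rejections / n_null
        new = float(np.clip(new, 1e-12, fdr))
        if abs(new - alpha) < tol:
            alpha = new
            break
        alpha = new
    return min(alpha, fdr)


def predicted_power(summary: PilotSummary, n_per_group: int, fdr: float = 0.1,
                    ) -> float:
    """Average detection power of the non-null features at the FDR target."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    effects = summary.nonnull_effects
    if effects.size == 0:
        raise ValueError("pilot is all-null: predicted power undefined")
    m = summary.effects.size
    alpha = solve_alpha_star(effects, m, summary.pi0, n_per_group, fdr)
    return float(_t_power(effects, n_per_group, alpha).mean())


def power_curve(summary: PilotSummary, n_grid, fdr: float = 0.1) -> pd.DataFrame:
    """(n per group, predicted power) over a grid of candidate sizes."""
    rows = [{"n_per_group": int(n), "power": predicted_power(summary, int(n), fdr)}
            for n in n_grid]
    return pd.DataFrame(rows)


def required_sample_size(summary: PilotSummary, target_power: float = 0.9,
                         fdr: float = 0.1, n_max: int = 1024) -> int:
    """Smallest per-group n (doubling then bisection) reaching the target power."""
    lo, hi = 2, 4
    while predicted_power(summary, hi, fdr) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(f"target power {target_power} not reached by n={n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if predicted_power(summary, mid, fdr) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
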