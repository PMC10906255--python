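"""Four-criterion biomarker screening and the panel-level summaries.

A feature survives the screen when it simultaneously satisfies
(i) selection frequency ≥ 90% across resampled sparse-model fits,
(ii) two-sided rank-sum p < 0.05, (iii) mean normalized abundance > 500,
and (iv) single-feature AUC > 0.7.  The surviving panel is then refit as
an unpenalized logistic model, and summarized as a row-standardized
heatmap and a panel-restricted PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix
from .diagnosis import (ModelResult, _binary_labels, _l1_fit, _standardize_fit,
                        auc_rank, fit_sparse_classifier, operating_point,
                        roc_with_ci)


@dataclass(frozen=True)
class ScreeningCriteria:
    min_frequency: float = 0.90
    max_p: float = 0.05
    min_abundance: float = 500.0
    min_auc: float = 0.7
    n_resamples: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.min_frequency <= 1:
            raise ValueError("min_frequency must be in [0, 1]")
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")
        if self.min_abundance < 0:
            raise ValueError("min_abundance must be nonnegative")
        if not 0 <= self.min_auc <= 1:
            raise ValueError("min_auc must be in [0, 1]")
        if self.n_resamples < 50:
            raise ValueError("n_resamples must be >= 50")


def feature_frequency(matrix: FeatureMatrix, labels=None,
                      criteria: ScreeningCriteria = ScreeningCriteria(),
                      seed: int = 0, lambda_: float | None = None,
                      subsample_fraction: float = 0.8,
                      scheme: str = "bootstrap", **fit_kwargs) -> pd.Series:
    """Selection frequency of each feature across resampled sparse fits.

    When ``lambda_`` is None the penalty is first tuned on the full
    cohort.  Each resample draws ``subsample_fraction`` of the cohort,
    stratified by class — with replacement under the default
    ``scheme='bootstrap'``, without replacement under ``scheme='subsample'``
    — refits the L1 model at the tuned penalty, and a feature counts as
    selected when its coefficient is nonzero.
    """
    lab = np.asarray(labels if labels is not None else matrix.label_array())
    y, _, _ = _binary_labels(lab, fit_kwargs.get("positive_label"))
    if lambda_ is None:
        lambda_ = fit_sparse_classifier(matrix, lab, seed=seed, n_boot=50,
                                        **fit_kwargs).lambda_
    rng = np.random.default_rng(seed)
    counts = np.zeros(matrix.n_features)
    idx_by_class = [np.flatnonzero(y == c) for c in (0, 1)]
    for _ in range(criteria.n_resamples):
        take = []
        for idx in idx_by_class:
            k = max(2, int(round(subsample_fraction * idx.size)))
            take.append(rng.choice(idx, size=min(k, idx.size) if scheme == "subsample" else k,
                                   replace=(scheme == "bootstrap")))
        bi = np.concatenate(take)
        xb, yb = matrix.values[bi], y[bi]
        mean, sd = _standardize_fit(xb)
        clf = _l1_fit((xb - mean) / sd, yb, lambda_, seed)
        counts += clf.coef_.ravel() != 0
    freq = counts / criteria.n_resamples
    return pd.Series(freq, index=[f"{m:.4f}" for m in matrix.feature_mz],
                     name="frequency")


def feature_stats(matrix: FeatureMatrix, labels=None,
                  positive_label: str | None = None) -> pd.DataFrame:
    """Per-feature screening statistics.

    Columns: ``mz, p, q, abundance, auc_single, fold_change, direction``.
    p is the two-sided Wilcoxon rank-sum p; q its Benjamini–Hochberg
    adjustment; abundance the mean normalized intensity over all samples;
    auc_single is oriented so it is ≥ 0.5 with the orientation recorded
    in ``direction`` (case/control mean ratio tie → "up").  Constant
    features get p = 1 and AUC = 0.5 by convention.
    """
    lab = np.asarray(labels if labels is not None else matrix.label_array())
    y, _, _ = _binary_labels(lab, positive_label)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need >= 3 samples per class for feature statistics")
    x = matrix.values
    case, ctrl = x[y == 1], x[y == 0]
    p = np.ones(matrix.n_features)
    aucs = np.full(matrix.n_features, 0.5)
    for j in range(matrix.n_features):
        col = x[:, j]
        if np.ptp(col) == 0:
            continue
        p[j] = float(stats.mannwhitneyu(case[:, j], ctrl[:, j],
                                        alternative="two-sided").pvalue)
        a = auc_rank(col, y)
        aucs[j] = max(a, 1 - a)
    q = stats.false_discovery_control(p, method="bh")
    case_mean = case.mean(axis=0)
    ctrl_mean = ctrl.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(ctrl_mean > 0, case_mean / np.where(ctrl_mean > 0, ctrl_mean, 1.0),
                        np.inf)
    fold = np.where((case_mean == 0) & (ctrl_mean == 0), 1.0, fold)
    direction = np.where(fold >= 1.0, "up", "down")
    return pd.DataFrame({
        "mz": matrix.feature_mz,
        "p": p,
        "q": q,
        "abundance": x.mean(axis=0),
        "auc_single": aucs,
        "fold_change": fold,
        "direction": direction,
    }, index=[f"{m:.4f}" for m in matrix.feature_mz])


@dataclass
class PanelReport:
    stats: pd.DataFrame  # full per-feature table including frequency
    criteria: ScreeningCriteria
    panel_index: np.ndarray  # positions into the feature matrix columns
    panel_mz: np.ndarray
    criterion_sets: dict[str, np.ndarray] = field(default_factory=dict)
    model: ModelResult | None = None
    heatmap: pd.DataFrame | None = None
    pca_scores: np.ndarray | None = None
    pca_explained: np.ndarray | None = None

    @property
    def panel_stats(self) -> pd.DataFrame:
        return self.stats.iloc[self.panel_index]


def screen_panel(stats: pd.DataFrame, criteria: ScreeningCriteria = ScreeningCriteria(),
                 ) -> PanelReport:
    """Intersect the four criterion sets (the screening Venn).

    ``stats`` must carry the :func:`feature_stats` columns plus a
    ``frequency`` column.  Deterministic given the table; an empty panel
    is returned with a warning, not an error.
    """
    required = {"mz", "frequency", "p", "abundance", "auc_single"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    sets = {
        "frequency": (stats["frequency"] >= criteria.min_frequency).to_numpy(),
        "p": (stats["p"] < criteria.max_p).to_numpy(),
        "abundance": (stats["abundance"] > criteria.min_abundance).to_numpy(),
        "auc": (stats["auc_single"] > criteria.min_auc).to_numpy(),
    }
    mask = sets["frequency"] & sets["p"] & sets["abundance"] & sets["auc"]
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn("screening produced an empty panel")
    return PanelReport(stats=stats, criteria=criteria, panel_index=idx,
                       panel_mz=stats["mz"].to_numpy()[idx], criterion_sets=sets)


def panel_model(matrix: FeatureMatrix, panel_index: np.ndarray, labels=None,
                seed: int = 0, n_boot: int = 500,
                positive_label: str | None = None,
                split: tuple[np.ndarray, np.ndarray] | None = None) -> ModelResult:
    """Unpenalized logistic model on the surviving panel features.

    A tiny ridge term (C = 1e6) keeps separable small panels finite; this
    perturbs non-separable fits negligibly.  With ``split`` = (discovery
    row indices, validation row indices) the model is fit and thresholded
    on discovery only and additionally evaluated on validation
    (``validation_auc`` / ``validation_ci``).
    """
    panel_index = np.asarray(panel_index)
    if panel_index.size == 0:
        raise ValueError("panel is empty")
    lab = np.asarray(labels if labels is not None else matrix.label_array())
    y, pos, neg = _binary_labels(lab, positive_label)
    sub = matrix.values[:, panel_index]
    disc = np.asarray(split[0]) if split is not None else np.arange(len(lab))
    mean, sd = _standardize_fit(sub[disc])
    z = (sub - mean) / sd
    from sklearn.linear_model import LogisticRegression
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
    clf.fit(z[disc], y[disc])
    probs = clf.predict_proba(z)[:, 1]
    auc, ci, _ = roc_with_ci(probs[disc], y[disc], n_boot=n_boot, seed=seed)
    sens, spec, acc, thr = operating_point(probs[disc], y[disc])
    val_auc = val_ci = val_probs = None
    if split is not None:
        val = np.asarray(split[1])
        val_probs = probs[val]
        val_auc, val_ci, _ = roc_with_ci(val_probs, y[val], n_boot=n_boot, seed=seed)
    return ModelResult(
        feature_mz=matrix.feature_mz[panel_index].copy(),
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        lambda_=0.0,
        scale_mean=mean, scale_sd=sd,
        positive_label=pos, negative_label=neg,
        cv_auc_mean=float("nan"),
        probabilities=probs,
        auc=auc, auc_ci=ci,
        sensitivity=sens, specificity=spec, accuracy=acc, threshold=thr,
        seed=seed,
        validation_auc=val_auc, validation_ci=val_ci,
        validation_probabilities=val_probs,
    )


def heatmap_matrix(matrix: FeatureMatrix, panel_index: np.ndarray, labels=None,
                   probabilities: np.ndarray | None = None) -> pd.DataFrame:
    """Row-standardized panel heatmap (features × samples).

    Each panel feature is standardized to mean 0, sd 1 across samples;
    samples are ordered by group and, within group, by panel-model
    probability when given (else by sample id).  Constant features are
    dropped with a warning.
    """
    panel_index = np.asarray(panel_index)
    if panel_index.size == 0:
        raise ValueError("panel is empty")
    lab = np.asarray([str(v) for v in (labels if labels is not None else matrix.label_array())])
    sub = matrix.values[:, panel_index]
    sd = sub.std(axis=0, ddof=0)
    if np.any(sd == 0):
        warnings.warn(f"dropping {int((sd == 0).sum())} constant panel feature(s)")
    keep = sd > 0
    panel_index = panel_index[keep]
    sub = sub[:, keep]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=0)
    sort_key = probabilities if probabilities is not None else np.asarray(matrix.sample_ids, object)
    order = np.lexsort((sort_key, lab))
    return pd.DataFrame(
        z[order].T,
        index=[f"{m:.4f}" for m in matrix.feature_mz[panel_index]],
        columns=[matrix.sample_ids[i] for i in order],
    )


def group_separation(scores: np.ndarray, labels) -> float:
    """Between-group centroid distance over mean within-group spread.

    Used to compare panel-restricted PCA against all-feature PCA on
    cohorts with planted markers.
    """
    lab = np.asarray([str(v) for v in labels])
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("separation ratio is defined for two groups")
    a = scores[lab == groups[0]]
    b = scores[lab == groups[1]]
    between = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    within = float(np.mean([np.linalg.norm(a - a.mean(axis=0), axis=1).mean(),
                            np.linalg.norm(b - b.mean(axis=0), axis=1).mean()]))
    return between / within if within > 0 else np.inf


def run_screen(matrix: FeatureMatrix, labels=None,
               criteria: ScreeningCriteria = ScreeningCriteria(),
               seed: int = 0, positive_label: str | None = None,
               **fit_kwargs) -> PanelReport:
    """Full screening flow: stats + frequency → Venn → panel model + summaries."""
    lab = np.asarray(labels if labels is not None else matrix.label_array())
    stats_table = feature_stats(matrix, lab, positive_label=positive_label)
    stats_table["frequency"] = feature_frequency(
        matrix, lab, criteria, seed=seed, positive_label=positive_label,
        **fit_kwargs).to_numpy()
    report = screen_panel(stats_table, criteria)
    if report.panel_index.size:
        report.model = panel_model(matrix, report.panel_index, lab, seed=seed,
                                   positive_label=positive_label)
        report.heatmap = heatmap_matrix(matrix, report.panel_index, lab,
                                        probabilities=report.model.probabilities)
        from .diagnosis import pca_scores as _pca
        sub = matrix.subset_features(report.panel_index)
        k = min(2, report.panel_index.size, matrix.n_samples)
        report.pca_scores, report.pca_explained = _pca(sub, n_components=k)
    return report
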