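"""Sparse-learning diagnosis: penalized classification with resampling QC.

The classifier is L1-penalized logistic regression on standardized
feature intensities.  The penalty weight is tuned by maximizing mean
cross-validated AUC over a log-spaced grid, the model is refit on the
full discovery cohort at the chosen penalty, and a frozen discovery
standardization is applied to validation samples.  Statistical guards
mirror common clinical-fingerprinting practice: stratified discovery/
validation splitting with a covariate-balance report, rank-statistic AUC
with stratified-bootstrap confidence intervals, a Youden operating
point, a label-permutation test of the whole tuning pipeline, and
unsupervised PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureMatrix


def _binary_labels(labels: np.ndarray, positive_label: str | None) -> tuple[np.ndarray, str, str]:
    classes = sorted(set(map(str, labels)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive_label is None:
        # convention: healthy controls are the negative class when present
        positive_label = classes[0] if classes[1] == "HC" else classes[1]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {classes}")
    negative = next(c for c in classes if c != positive_label)
    y = (np.asarray([str(v) for v in labels]) == positive_label).astype(int)
    return y, positive_label, negative


def auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann–Whitney rank statistic (ties counted one half)."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class SplitPlan:
    discovery_ids: list[str]
    validation_ids: list[str]
    stratify_by: str
    seed: int
    balance: dict[str, float] = field(default_factory=dict)  # covariate -> p value


def split_cohort(metadata: pd.DataFrame, validation_fraction: float,
                 seed: int = 0, stratify_by: str = "group") -> SplitPlan:
    """Stratified discovery/validation split with a covariate-balance report.

    The balance report tests age (two-sided rank-sum) and sex (chi-square)
    between the two groups *within the discovery cohort*, mirroring the
    demographic check a clinical study reports before modeling.
    """
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    groups = metadata[stratify_by].astype(str)
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members to stratify")
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for g, n in counts.items():
        idx = np.flatnonzero(groups.to_numpy() == g)
        k = int(round(validation_fraction * n))
        k = min(max(k, 1), n - 1)
        val_idx.extend(rng.choice(idx, size=k, replace=False))
    val_mask = np.zeros(len(metadata), dtype=bool)
    val_mask[val_idx] = True
    ids = metadata["sample_id"].astype(str).to_numpy()
    disc = metadata.loc[~val_mask]
    balance: dict[str, float] = {}
    glabels = sorted(disc[stratify_by].astype(str).unique())
    if len(glabels) == 2:
        a = disc.loc[disc[stratify_by].astype(str) == glabels[0]]
        b = disc.loc[disc[stratify_by].astype(str) == glabels[1]]
        if "age" in disc.columns:
            balance["age"] = float(stats.mannwhitneyu(a["age"], b["age"],
                                                      alternative="two-sided").pvalue)
        if "sex" in disc.columns:
            table = pd.crosstab(disc[stratify_by], disc["sex"])
            if table.shape == (2, 2):
                balance["sex"] = float(stats.chi2_contingency(table.to_numpy(),
                                                              correction=False).pvalue)
            else:
                balance["sex"] = 1.0
    return SplitPlan(list(ids[~val_mask]), list(ids[val_mask]),
                     stratify_by, seed, balance)


@dataclass
class ModelResult:
    """A fitted sparse classifier plus its discovery-cohort evaluation."""

    feature_mz: np.ndarray
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    positive_label: str
    negative_label: str
    cv_auc_mean: float
    probabilities: np.ndarray  # discovery samples
    auc: float
    auc_ci: tuple[float, float] = (0.0, 1.0)
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    accuracy: float = float("nan")
    threshold: float = 0.5
    seed: int = 0
    validation_auc: float | None = None
    validation_ci: tuple[float, float] | None = None
    validation_probabilities: np.ndarray | None = None

    @property
    def nonzero_features(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients != 0)

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        """Class-1 probabilities under the frozen discovery standardization."""
        if matrix.n_features != self.feature_mz.size:
            raise ValueError("feature count mismatch with the fitted model")
        z = (matrix.values - self.scale_mean) / self.scale_sd
        logit = z @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))

    def to_dict(self) -> dict:
        return {
            "coefficients": {f"{m:.4f}": float(c)
                             for m, c in zip(self.feature_mz, self.coefficients) if c != 0},
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "cv_auc_mean": float(self.cv_auc_mean),
            "auc": float(self.auc),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
            "threshold": float(self.threshold),
            "seed": int(self.seed),
        }


def default_lambda_grid(n_values: int = 50) -> np.ndarray:
    return np.logspace(-3.0, 1.5, n_values)


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _l1_fit(z: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / lam, solver="liblinear",
                             max_iter=2000, random_state=seed, tol=1e-6)
    clf.fit(z, y)
    return clf


def cv_auc_path(z: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray,
                cv_folds: int, seed: int) -> np.ndarray:
    """Mean cross-validated AUC for every penalty on the grid."""
    counts = np.bincount(y)
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than cv_folds="
            f"{cv_folds}; reduce cv_folds to avoid degenerate single-class folds"
        )
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_aucs = np.zeros((cv_folds, lambda_grid.size))
    for f, (tr, te) in enumerate(skf.split(z, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(
                "degenerate single-class fold; reduce cv_folds or rebalance the cohort"
            )
        for j, lam in enumerate(lambda_grid):
            clf = _l1_fit(z[tr], y[tr], lam, seed)
            p = clf.predict_proba(z[te])[:, 1]
            fold_aucs[f, j] = auc_rank(p, y[te])
    return fold_aucs.mean(axis=0)


def fit_sparse_classifier(
    matrix: FeatureMatrix,
    labels: list[str] | np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    positive_label: str | None = None,
    n_boot: int = 500,
) -> ModelResult:
    """Tune, fit and evaluate the L1 logistic model on a discovery cohort.

    Features are standardized with discovery statistics only; the penalty
    maximizing mean CV AUC is chosen (ties go to the stronger penalty,
    i.e. the sparser model) and the model is refit on the full cohort.
    The returned result carries both the tuned ``cv_auc_mean`` and the
    refit-model discovery ``auc`` — these are distinct quantities and are
    reported separately.
    """
    lab = np.asarray(labels if labels is not None else matrix.label_array())
    y, pos, neg = _binary_labels(lab, positive_label)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.sort(np.asarray(lambda_grid, float))
    mean, sd = _standardize_fit(matrix.values)
    z = (matrix.values - mean) / sd
    path = cv_auc_path(z, y, lambda_grid, cv_folds, seed)
    best = np.flatnonzero(path == path.max())[-1]  # sparser on ties
    lam = float(lambda_grid[best])
    clf = _l1_fit(z, y, lam, seed)
    probs = clf.predict_proba(z)[:, 1]
    auc, ci, _ = roc_with_ci(probs, y, n_boot=n_boot, seed=seed)
    sens, spec, acc, thr = operating_point(probs, y)
    return ModelResult(
        feature_mz=matrix.feature_mz.copy(),
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        lambda_=lam,
        scale_mean=mean,
        scale_sd=sd,
        positive_label=pos,
        negative_label=neg,
        cv_auc_mean=float(path[best]),
        probabilities=probs,
        auc=auc,
        auc_ci=ci,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        threshold=thr,
        seed=seed,
    )


def roc_with_ci(probabilities: np.ndarray, labels: np.ndarray, n_boot: int = 1000,
                seed: int = 0, positive_label: str | None = None,
                ) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Rank-statistic AUC with a stratified-bootstrap percentile 95% CI.

    Returns ``(auc, (lo, hi), roc_curve)`` where the curve is a DataFrame
    of (threshold, fpr, tpr) over all observed score cuts.
    """
    p = np.asarray(probabilities, float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "if" and set(np.unique(lab)) <= {0, 1, 0.0, 1.0}:
        y = lab.astype(int)
    else:
        y, _, _ = _binary_labels(lab, positive_label)
    auc = auc_rank(p, y)
    pos = np.flatnonzero(y == 1)
    negs = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bi = np.concatenate([rng.choice(pos, pos.size, replace=True),
                             rng.choice(negs, negs.size, replace=True)])
        boots[b] = auc_rank(p[bi], y[bi])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    thr = np.unique(p)[::-1]
    curve = pd.DataFrame({
        "threshold": thr,
        "fpr": [(p[y == 0] >= t).mean() for t in thr],
        "tpr": [(p[y == 1] >= t).mean() for t in thr],
    })
    return auc, ci, curve


def operating_point(probabilities: np.ndarray, labels: np.ndarray,
                    rule: str = "youden", fixed_threshold: float = 0.5,
                    ) -> tuple[float, float, float, float]:
    """Sensitivity/specificity/accuracy at a probability cut.

    ``rule='youden'`` maximizes J = sens + spec − 1 over observed cuts
    (ties resolved toward the smallest threshold, so a degenerate
    all-equal score vector yields the all-positive reading sens=1,
    spec=0); ``rule='fixed'`` applies ``fixed_threshold``.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, int)
    if rule == "fixed":
        thr = fixed_threshold
    elif rule == "youden":
        best_j, thr = -np.inf, float(p.min())
        for t in np.unique(p):
            pred = p >= t
            sens = pred[y == 1].mean()
            spec = (~pred[y == 0]).mean()
            j = sens + spec - 1
            if j > best_j:
                best_j, thr = j, float(t)
    else:
        raise ValueError("rule must be 'youden' or 'fixed'")
    pred = p >= thr
    sens = float(pred[y == 1].mean())
    spec = float((~pred)[y == 0].mean())
    acc = float((pred == y).mean())
    return sens, spec, acc, thr


def permutation_test(matrix: FeatureMatrix, labels: list[str] | np.ndarray | None = None,
                     n_perm: int = 1000, seed: int = 0, **fit_kwargs) -> tuple[float, np.ndarray, float]:
    """Label-permutation test of the tuned cross-validated AUC.

    The *entire* tuning procedure (standardization, penalty grid search,
    CV) is rerun on each permuted label vector so the null statistic is
    exchangeable with the observed one.  Returns ``(p, null_aucs,
    observed_auc)`` with the add-one estimate p = (1 + #{null ≥ obs}) /
    (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful p value")
    lab = np.asarray(labels if labels is not None else matrix.label_array())
    y, _, _ = _binary_labels(lab, fit_kwargs.get("positive_label"))
    lambda_grid = np.sort(np.asarray(fit_kwargs.get("lambda_grid",
                                                    default_lambda_grid()), float))
    cv_folds = fit_kwargs.get("cv_folds", 5)
    mean, sd = _standardize_fit(matrix.values)
    z = (matrix.values - mean) / sd

    def tuned_cv_auc(yv: np.ndarray, s: int) -> float:
        return float(cv_auc_path(z, yv, lambda_grid, cv_folds, s).max())

    observed = tuned_cv_auc(y, seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = tuned_cv_auc(rng.permutation(y), seed)
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_perm)
    return p, null, observed


def pca_scores(matrix: FeatureMatrix, n_components: int = 2,
               ) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of the mean-centered, unit-variance-scaled matrix.

    Constant features are dropped (with a warning) before scaling.
    Returns ``(scores, explained_variance_fractions)``.
    """
    x = matrix.values
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        warnings.warn(f"dropping {int((sd == 0).sum())} constant feature(s) before PCA")
        x = x[:, sd > 0]
        sd = sd[sd > 0]
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    return scores, pca.explained_variance_ratio_
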