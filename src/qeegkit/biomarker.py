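"""Stability-selected elastic-net biomarkers with cross-validated ROC.

The biomarker construction has two resampling stages:

1. *Stability selection.*  The sample is split into a stratified 70%
   training / 30% test partition; the training part is screened with the
   univariate IndFeat statistic |m1 - m2| / sqrt(s1^2/n1 + s2^2/n2) and
   the survivors enter an elastic-net-penalized logistic regression
   whose penalty strength is chosen by inner cross-validation.  Features
   with nonzero coefficients count as selected.  The split is redrawn
   independently (1000 iterations by default) and only features selected
   in strictly more than 50% of iterations are retained.

2. *ROC evaluation.*  On the retained features, a further independent
   set of resplits (1000 by default) each fits a classifier on the
   training part and scores the held-out part; the per-repetition ROC
   curves are reduced to a pointwise-median ROC over a common
   false-positive grid, and the distribution of the per-repetition AUCs
   is summarized by a Gaussian kernel density.

The median ROC is the operational characterization of the classifier;
the AUC density quantifies how classification performance varies with
the resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler


def indfeat_screen(
    features: np.ndarray,
    labels: np.ndarray,
    threshold: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Univariate signal-to-noise screen (IndFeat).

    Score per feature: |m1 - m2| / sqrt(s1^2/n1 + s2^2/n2); features
    scoring at or above ``threshold`` pass.  Zero variance in both
    groups gives score 0.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    groups = np.unique(y)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    a, b = x[y == groups[0]], x[y == groups[1]]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            a.var(axis=0, ddof=1) / a.shape[0]
            + b.var(axis=0, ddof=1) / b.shape[0]
        )
        scores = np.abs(a.mean(axis=0) - b.mean(axis=0)) / se
    scores = np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)
    return np.flatnonzero(scores >= threshold), scores


@dataclass
class StabilityProfile:
    """Per-feature selection frequencies over resampling iterations."""

    frequencies: np.ndarray
    n_iter: int
    seed: int | None
    retention_level: float = 0.5

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask: selected in strictly more than half the iterations."""
        return self.frequencies > self.retention_level

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)


class StabilitySelection:
    """Repeated split / screen / elastic-net selection of stable features."""

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        n_iter: int = 1000,
        train_fraction: float = 0.7,
        screen_threshold: float = 2.0,
        l1_ratio: float = 0.5,
        n_penalties: int = 5,
        inner_cv: int = 5,
        seed: int | None = None,
    ) -> None:
        self.x = np.atleast_2d(np.asarray(features, dtype=float))
        self.y = np.asarray(labels)
        if np.unique(self.y).size != 2:
            raise ValueError("exactly two groups required")
        self.n_iter = int(n_iter)
        self.train_fraction = float(train_fraction)
        self.screen_threshold = float(screen_threshold)
        self.l1_ratio = float(l1_ratio)
        self.n_penalties = int(n_penalties)
        self.inner_cv = int(inner_cv)
        self.seed = seed

    def _one_iteration(self, rs: int) -> np.ndarray:
        x, y = self.x, self.y
        idx_train, _ = train_test_split(
            np.arange(len(y)), train_size=self.train_fraction,
            stratify=y, random_state=rs,
        )
        xt, yt = x[idx_train], y[idx_train]
        keep, _ = indfeat_screen(xt, yt, self.screen_threshold)
        selected = np.zeros(x.shape[1], dtype=bool)
        if keep.size == 0:
            return selected
        xs = StandardScaler().fit_transform(xt[:, keep])
        y01 = (yt == np.unique(yt)[1]).astype(int)
        C = self._choose_penalty(xs, y01, rs)
        if C is None:
            return selected
        clf = self._elastic_net(C, rs).fit(xs, y01)
        selected[keep[np.abs(clf.coef_[0]) > 1e-8]] = True
        return selected

    def _elastic_net(self, C: float, rs: int) -> LogisticRegression:
        return LogisticRegression(
            C=C, l1_ratio=self.l1_ratio, solver="saga",
            max_iter=3000, tol=1e-3, random_state=rs,
        )

    def _choose_penalty(self, xs, y01, rs) -> float | None:
        """Inner-CV penalty choice with the one-standard-error rule.

        The strongest penalty whose mean validation AUC is within one
        standard error of the best is kept; when even the best penalty
        does no better than chance the iteration selects nothing.
        """
        Cs = np.logspace(-2, 2, self.n_penalties)
        folds = StratifiedKFold(self.inner_cv, shuffle=True, random_state=rs)
        scores = np.zeros((len(Cs), self.inner_cv))
        for f, (tr, va) in enumerate(folds.split(xs, y01)):
            if y01[tr].min() == y01[tr].max():
                continue
            for c, C in enumerate(Cs):
                clf = self._elastic_net(C, rs).fit(xs[tr], y01[tr])
                s = clf.decision_function(xs[va])
                scores[c, f] = roc_auc_score(y01[va], s) if (
                    y01[va].min() != y01[va].max()
                ) else 0.5
        mean = scores.mean(axis=1)
        best = int(np.argmax(mean))
        se = scores[best].std(ddof=1) / np.sqrt(self.inner_cv)
        if mean[best] <= 0.5 + se:
            return None  # no better than chance: keep nothing
        ok = np.flatnonzero(mean >= mean[best] - se)
        return float(Cs[ok[0]])  # smallest C = strongest penalty

    def fit(self) -> StabilityProfile:
        rng = np.random.default_rng(self.seed)
        counts = np.zeros(self.x.shape[1])
        for _ in range(self.n_iter):
            counts += self._one_iteration(int(rng.integers(2 ** 31)))
        return StabilityProfile(
            frequencies=counts / self.n_iter,
            n_iter=self.n_iter,
            seed=self.seed,
        )


def stability_select(
    features: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 1000,
    train_fraction: float = 0.7,
    seed: int | None = None,
    **kwargs,
) -> StabilityProfile:
    """Functional wrapper around :class:`StabilitySelection`."""
    return StabilitySelection(
        features, labels, n_iter=n_iter, train_fraction=train_fraction,
        seed=seed, **kwargs
    ).fit()


@dataclass
class BiomarkerReport:
    """Cross-validated ROC evaluation of a retained feature set."""

    aucs: np.ndarray
    fpr_grid: np.ndarray
    tpr_curves: np.ndarray          # n_cv x grid
    median_tpr: np.ndarray
    n_cv: int
    seed: int | None
    retained_indices: np.ndarray | None = None
    auc_density: object = field(default=None, repr=False)

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    @property
    def median_roc_auc(self) -> float:
        """Area under the pointwise-median ROC curve."""
        return float(auc(self.fpr_grid, self.median_tpr))

    def summary(self) -> dict:
        return {
            "n_cv": self.n_cv,
            "median_auc": self.median_auc,
            "auc_iqr": tuple(np.percentile(self.aucs, [25, 75])),
            "median_roc_auc": self.median_roc_auc,
        }


def cross_validated_roc(
    features: np.ndarray,
    labels: np.ndarray,
    n_cv: int = 1000,
    train_fraction: float = 0.7,
    seed: int | None = None,
    retained_indices: np.ndarray | None = None,
    n_fpr_grid: int = 101,
) -> BiomarkerReport:
    """Repeated-split ROC analysis of a (retained) feature set.

    Each repetition draws a stratified split, fits a standardized
    logistic model on the training part and scores the held-out part;
    AUC is the trapezoidal area of the per-repetition ROC.  The median
    ROC is the pointwise median of the repetition curves on a common
    false-positive grid (made monotone), and the AUC distribution is
    summarized by a Gaussian KDE (None when degenerate).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] == 0:
        raise ValueError("retained feature set is empty: no biomarker")
    y = np.asarray(labels)
    groups = np.unique(y)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    y01 = (y == groups[1]).astype(int)
    rng = np.random.default_rng(seed)
    fpr_grid = np.linspace(0.0, 1.0, n_fpr_grid)
    tpr_curves = np.empty((n_cv, n_fpr_grid))
    aucs = np.empty(n_cv)
    for i in range(n_cv):
        rs = int(rng.integers(2 ** 31))
        idx_train, idx_test = train_test_split(
            np.arange(len(y01)), train_size=train_fraction,
            stratify=y01, random_state=rs,
        )
        scaler = StandardScaler().fit(x[idx_train])
        clf = LogisticRegression(max_iter=1000)
        clf.fit(scaler.transform(x[idx_train]), y01[idx_train])
        scores = clf.decision_function(scaler.transform(x[idx_test]))
        fpr, tpr, _ = roc_curve(y01[idx_test], scores)
        aucs[i] = auc(fpr, tpr)
        tpr_curves[i] = np.interp(fpr_grid, fpr, tpr)
    median_tpr = np.maximum.accumulate(np.median(tpr_curves, axis=0))
    median_tpr[0], median_tpr[-1] = 0.0, 1.0
    density = None
    if np.std(aucs) > 1e-12:
        density = gaussian_kde(aucs)
    return BiomarkerReport(
        aucs=aucs,
        fpr_grid=fpr_grid,
        tpr_curves=tpr_curves,
        median_tpr=median_tpr,
        n_cv=n_cv,
        seed=seed,
        retained_indices=retained_indices,
        auc_density=density,
    )
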