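"""Age-dependent normative models of log spectral power and z-spectra.

Each of the channels x bins features gets its own age regression for the
mean and for the spread of log power; a subject's z-spectrum is the
cellwise standardization z = (x - mu(age)) / sigma(age).

mu(age) is fitted by least squares on a polynomial basis in log(age)
(degree 2 by default).  sigma(age) is fitted by regressing the log
squared residuals on the same basis, with the chi-square smearing
correction E[log chi2_1] = psi(1/2) + log 2 so that the back-transformed
sigma is unbiased under Gaussian residuals, and floored at a small
positive constant.  On data generated from this family, held-out
z-scores are standard normal up to Monte-Carlo error — the module's
core calibration property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma

# E[log chi^2_1] = psi(1/2) + log 2
_LOG_CHI2_1_MEAN = digamma(0.5) + np.log(2.0)


def _age_basis(ages: np.ndarray, degree: int) -> np.ndarray:
    la = np.log(np.asarray(ages, dtype=float))
    return np.vander(la, degree + 1, increasing=True)


class NormativeSpectrumModel:
    """Normative age-regression model for a table of log-power features.

    Parameters
    ----------
    features : ndarray (n_subjects, n_features)
        Log power per subject, flattened channels x bins (or sources x bins).
    ages : array of years, one per subject.
    degree : polynomial degree of the log(age) basis (default 2).
    sigma_floor : lower bound on the fitted spread.
    """

    def __init__(
        self,
        features: np.ndarray,
        ages: np.ndarray,
        degree: int = 2,
        sigma_floor: float = 1e-6,
        feature_shape: tuple[int, int] | None = None,
        labels: tuple[str, ...] | None = None,
    ) -> None:
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.ages = np.asarray(ages, dtype=float)
        if self.features.shape[0] != self.ages.size:
            raise ValueError("one age per subject required")
        self.degree = int(degree)
        self.sigma_floor = float(sigma_floor)
        self.feature_shape = feature_shape
        self.labels = labels

    def fit(self) -> "NormativeResults":
        n, p = self.features.shape
        d = self.degree + 1
        degenerate = np.ptp(self.ages) < 1e-12
        if degenerate:
            warnings.warn(
                "all ages equal; falling back to a constant normative model",
                stacklevel=2,
            )
            if n < 3:
                raise ValueError("constant model needs at least 3 subjects")
            mu_coefs = np.zeros((d, p))
            mu_coefs[0] = self.features.mean(axis=0)
            sd = self.features.std(axis=0, ddof=1)
            sigma_coefs = np.zeros((d, p))
            sigma_coefs[0] = 2.0 * np.log(np.maximum(sd, self.sigma_floor))
            # undo the smearing shift applied at prediction time
            sigma_coefs[0] += _LOG_CHI2_1_MEAN
            return NormativeResults(
                mu_coefs=mu_coefs, sigma_coefs=sigma_coefs,
                degree=self.degree, sigma_floor=self.sigma_floor,
                age_range=(float(self.ages[0]), float(self.ages[0])),
                n_subjects=n, degenerate=True,
                feature_shape=self.feature_shape, labels=self.labels,
            )
        if n <= d + 2:
            raise ValueError(
                f"cohort of {n} too small for a degree-{self.degree} basis"
            )
        B = _age_basis(self.ages, self.degree)
        mu_coefs, *_ = np.linalg.lstsq(B, self.features, rcond=None)
        resid = self.features - B @ mu_coefs
        # df inflation for the mean fit
        resid = resid * np.sqrt(n / (n - d))
        logr2 = np.log(np.maximum(resid ** 2, 1e-300))
        sigma_coefs, *_ = np.linalg.lstsq(B, logr2, rcond=None)
        return NormativeResults(
            mu_coefs=mu_coefs, sigma_coefs=sigma_coefs,
            degree=self.degree, sigma_floor=self.sigma_floor,
            age_range=(float(self.ages.min()), float(self.ages.max())),
            n_subjects=n, degenerate=False,
            feature_shape=self.feature_shape, labels=self.labels,
        )


@dataclass
class NormativeResults:
    """Fitted normative model: per-feature mu(age) and sigma(age)."""

    mu_coefs: np.ndarray       # basis-dim x n_features
    sigma_coefs: np.ndarray    # basis-dim x n_features (log residual scale)
    degree: int
    sigma_floor: float
    age_range: tuple[float, float]
    n_subjects: int
    degenerate: bool = False
    feature_shape: tuple[int, int] | None = None
    labels: tuple[str, ...] | None = None

    @property
    def n_features(self) -> int:
        return self.mu_coefs.shape[1]

    def _basis(self, age: float) -> np.ndarray:
        return _age_basis(np.atleast_1d(age), self.degree)

    def mu(self, age: float) -> np.ndarray:
        """Normative mean log power at ``age`` (n_features,)."""
        return (self._basis(age) @ self.mu_coefs)[0]

    def sigma(self, age: float) -> np.ndarray:
        """Normative spread of log power at ``age`` (n_features,), floored."""
        log_s2 = (self._basis(age) @ self.sigma_coefs)[0] - _LOG_CHI2_1_MEAN
        return np.maximum(np.exp(log_s2 / 2.0), self.sigma_floor)

    def z_transform(self, features: np.ndarray, age: float) -> np.ndarray:
        """z = (x - mu(age)) / sigma(age), cellwise; preserves input shape."""
        x = np.asarray(features, dtype=float)
        flat = x.reshape(-1)
        if flat.size != self.n_features:
            raise ValueError(
                f"feature grid mismatch: got {flat.size}, "
                f"model has {self.n_features}"
            )
        lo, hi = self.age_range
        if not self.degenerate and not (lo <= age <= hi):
            warnings.warn(
                f"age {age} outside fitted range [{lo:.2f}, {hi:.2f}]; "
                "extrapolating",
                stacklevel=2,
            )
        z = (flat - self.mu(age)) / self.sigma(age)
        return z.reshape(x.shape)

    def inverse_transform(self, z: np.ndarray, age: float) -> np.ndarray:
        """Round trip: x = mu(age) + z * sigma(age)."""
        zf = np.asarray(z, dtype=float).reshape(-1)
        return (self.mu(age) + zf * self.sigma(age)).reshape(np.shape(z))


def fit_normative_model(
    features: np.ndarray,
    ages: np.ndarray,
    degree: int = 2,
    **kwargs,
) -> NormativeResults:
    """Convenience wrapper: build and fit a :class:`NormativeSpectrumModel`."""
    return NormativeSpectrumModel(features, ages, degree=degree, **kwargs).fit()


def gaussianity_report(z_table: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature normality check of a subjects x features z table.

    Uses the D'Agostino-Pearson omnibus test; constant columns are
    flagged degenerate and not tested.  The returned frame carries one
    row per feature (statistic, p, reject flag, degenerate flag) and the
    overall rejection fraction in ``.attrs['rejection_fraction']``.
    """
    z = np.atleast_2d(np.asarray(z_table, dtype=float))
    if z.shape[0] < 20:
        raise ValueError("normality screening needs at least 20 subjects")
    degenerate = z.std(axis=0) < 1e-12
    stat = np.full(z.shape[1], np.nan)
    p = np.full(z.shape[1], np.nan)
    ok = ~degenerate
    if np.any(ok):
        stat[ok], p[ok] = stats.normaltest(z[:, ok], axis=0)
    report = pd.DataFrame({
        "statistic": stat,
        "p_value": p,
        "reject": p < alpha,
        "degenerate": degenerate,
    })
    tested = int(ok.sum())
    report.attrs["rejection_fraction"] = (
        float(report.loc[ok, "reject"].mean()) if tested else np.nan
    )
    report.attrs["alpha"] = alpha
    return report
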