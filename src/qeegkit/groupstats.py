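"""Mass-univariate group comparison with max-t permutation correction.

A two-sample t statistic is computed for every feature of the z-spectrum
grid (912 scalp features in the default configuration).  Familywise
error over the grid is controlled with the max-statistic permutation
test: subjects' whole feature vectors are relabeled jointly (preserving
the cross-feature correlation), the maximum |t| over all features is
recorded for each permutation, and the empirical 95th percentile of that
null is the significance threshold.  Corrected p-values use the
add-one convention (1 + #{null >= |t|}) / (n_perm + 1), so they are
never zero.  When the groups are so small that fewer distinct
relabelings exist than requested permutations, the test enumerates all
of them exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .spectra import FrequencyGrid

#: Broad-band partition of the analysis grid (Hz, half-open upper edges).
DEFAULT_BANDS = {
    "delta": (0.5, 3.7),
    "theta": (3.7, 7.6),
    "alpha1": (7.6, 10.4),
    "alpha2": (10.4, 13.3),
    "beta1": (13.3, 19.5),
}


@dataclass
class TTestGrid:
    """Per-feature two-sample t values."""

    t: np.ndarray
    n_a: int
    n_b: int
    mode: str
    zero_variance: np.ndarray | None = None

    @property
    def df(self) -> int:
        return self.n_a + self.n_b - 2


def _t_stats(sum_a, sumsq_a, n_a, total, total_sq, n, mode):
    """Vectorized two-sample t from group-A sums and overall totals."""
    n_b = n - n_a
    sum_b = total - sum_a
    sumsq_b = total_sq - sumsq_a
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sumsq_a - n_a * mean_a ** 2
    ss_b = sumsq_b - n_b * mean_b ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "pooled":
            sp2 = (ss_a + ss_b) / (n - 2)
            se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        elif mode == "unequal":
            se = np.sqrt(ss_a / (n_a * (n_a - 1)) + ss_b / (n_b * (n_b - 1)))
        else:
            raise ValueError(f"unknown variance mode: {mode!r}")
        t = (mean_a - mean_b) / se
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0), se


def t_grid(z_a: np.ndarray, z_b: np.ndarray, mode: str = "pooled") -> TTestGrid:
    """Two-sample t per feature between two subjects x features z tables."""
    a = np.atleast_2d(np.asarray(z_a, dtype=float))
    b = np.atleast_2d(np.asarray(z_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature grids of the two groups differ")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    x = np.vstack([a, b])
    t, se = _t_stats(
        a.sum(axis=0), (a ** 2).sum(axis=0), a.shape[0],
        x.sum(axis=0), (x ** 2).sum(axis=0), x.shape[0], mode,
    )
    return TTestGrid(
        t=t, n_a=a.shape[0], n_b=b.shape[0], mode=mode,
        zero_variance=~np.isfinite(se) | (se == 0),
    )


@dataclass
class SignificanceReport:
    """Max-t permutation outcome over the feature grid."""

    t: np.ndarray
    threshold: float
    mask: np.ndarray
    p_corrected: np.ndarray
    null_maxt: np.ndarray
    n_perm: int
    alpha: float
    seed: int | None
    method: str
    n_a: int
    n_b: int

    def to_frame(self, grid: FrequencyGrid | None = None,
                 labels: tuple[str, ...] | None = None) -> pd.DataFrame:
        """Tidy per-feature table; channel/frequency columns if grid given."""
        df = pd.DataFrame({
            "t": self.t.ravel(),
            "p_corrected": self.p_corrected.ravel(),
            "significant": self.mask.ravel(),
        })
        if grid is not None and labels is not None:
            n_bins = grid.n_bins
            df.insert(0, "channel", np.repeat(labels, n_bins))
            df.insert(1, "frequency_hz",
                      np.tile(np.round(grid.frequencies, 2), len(labels)))
        return df


class MaxTPermutation:
    """Max-|t| permutation model for a subjects x features table.

    ``fit()`` returns a :class:`SignificanceReport`.  ``method`` is
    ``'auto'`` (exact enumeration when there are no more distinct
    relabelings than ``n_perm``, Monte Carlo otherwise), ``'exact'`` or
    ``'montecarlo'``.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        n_perm: int = 10_000,
        alpha: float = 0.05,
        mode: str = "pooled",
        method: str = "auto",
        seed: int | None = None,
        chunk: int = 2000,
    ) -> None:
        self.x = np.atleast_2d(np.asarray(features, dtype=float))
        labels = np.asarray(labels)
        groups = np.unique(labels)
        if groups.size != 2:
            raise ValueError("exactly two groups required")
        self.is_a = labels == groups[0]
        self.group_names = (groups[0], groups[1])
        self.n_a = int(self.is_a.sum())
        self.n_b = int((~self.is_a).sum())
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("need at least 2 subjects per group")
        if n_perm < 100:
            raise ValueError("need at least 100 permutations")
        self.n_perm = int(n_perm)
        self.alpha = float(alpha)
        self.mode = mode
        self.method = method
        self.seed = seed
        self.chunk = int(chunk)

    def fit(self) -> SignificanceReport:
        x = self.x
        n, p = x.shape
        total = x.sum(axis=0)
        total_sq = (x ** 2).sum(axis=0)
        a_rows = np.flatnonzero(self.is_a)
        t_obs, _ = _t_stats(
            x[a_rows].sum(axis=0), (x[a_rows] ** 2).sum(axis=0),
            self.n_a, total, total_sq, n, self.mode,
        )
        n_distinct = comb(n, self.n_a)
        method = self.method
        if method == "auto":
            method = "exact" if n_distinct <= self.n_perm else "montecarlo"
        if n_distinct < 10 and method != "exact":
            warnings.warn(
                f"only {n_distinct} distinct relabelings; using exact "
                "enumeration",
                stacklevel=2,
            )
            method = "exact"

        if method == "exact":
            idx = np.array(list(combinations(range(n), self.n_a)))
            null_maxt = self._null_for_index_blocks(idx, x, total, total_sq)
            abs_t = np.abs(t_obs)
            # observed labeling is one of the enumerated splits
            p_corr = (null_maxt[None, :] >= abs_t[:, None]).mean(axis=1)
            p_corr = np.maximum(p_corr, 1.0 / n_distinct)
            n_used = n_distinct
        elif method == "montecarlo":
            rng = np.random.default_rng(self.seed)
            null_maxt = np.empty(self.n_perm)
            done = 0
            while done < self.n_perm:
                m = min(self.chunk, self.n_perm - done)
                order = np.argsort(rng.random((m, n)), axis=1)
                idx = order[:, : self.n_a]
                null_maxt[done:done + m] = self._null_for_index_blocks(
                    idx, x, total, total_sq
                )
                done += m
            abs_t = np.abs(t_obs)
            exceed = (null_maxt[None, :] >= abs_t[:, None]).sum(axis=1)
            p_corr = (1.0 + exceed) / (self.n_perm + 1.0)
            n_used = self.n_perm
        else:
            raise ValueError(f"unknown method: {self.method!r}")

        threshold = float(np.quantile(null_maxt, 1.0 - self.alpha))
        mask = np.abs(t_obs) > threshold  # ties resolved as non-significant
        return SignificanceReport(
            t=t_obs, threshold=threshold, mask=mask, p_corrected=p_corr,
            null_maxt=np.sort(null_maxt), n_perm=n_used, alpha=self.alpha,
            seed=self.seed, method=method, n_a=self.n_a, n_b=self.n_b,
        )

    def _null_for_index_blocks(self, idx, x, total, total_sq):
        """Max |t| for each relabeling given group-A row indices (m, n_a)."""
        out = np.empty(idx.shape[0])
        for start in range(0, idx.shape[0], self.chunk):
            block = idx[start:start + self.chunk]
            sum_a = x[block].sum(axis=1)          # m x p
            sumsq_a = (x[block] ** 2).sum(axis=1)
            t, _ = _t_stats(sum_a, sumsq_a, self.n_a, total, total_sq,
                            x.shape[0], self.mode)
            out[start:start + block.shape[0]] = np.abs(t).max(axis=1)
        return out


def maxt_test(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    **kwargs,
) -> SignificanceReport:
    """Functional wrapper around :class:`MaxTPermutation`."""
    return MaxTPermutation(
        features, labels, n_perm=n_perm, alpha=alpha, seed=seed, **kwargs
    ).fit()


@dataclass
class ClusterSummary:
    """Significant cells grouped by broad band and channel."""

    clusters: pd.DataFrame       # band, channel, f_lo, f_hi, n_cells, sign
    bands: pd.DataFrame          # band-level aggregate

    @property
    def detected_bands(self) -> dict[str, int]:
        """Mapping band name -> dominant sign (+1/-1) of its clusters."""
        return dict(zip(self.bands["band"], self.bands["sign"]))


def summarize_bands(
    report: SignificanceReport,
    grid: FrequencyGrid,
    labels: tuple[str, ...],
    band_definitions: dict[str, tuple[float, float]] | None = None,
) -> ClusterSummary:
    """Group the significant cells of a report into band/channel clusters.

    ``band_definitions`` must cover every grid bin exactly once.  Each
    cluster is annotated with the sign of its t values and its frequency
    extent; the band-level table aggregates channels and extent per band.
    """
    if band_definitions is None:
        band_definitions = DEFAULT_BANDS
    freqs = grid.frequencies
    bin_band = np.full(freqs.size, None, dtype=object)
    for name, (lo, hi) in band_definitions.items():
        sel = (freqs >= lo) & (freqs < hi)
        already = sel & (bin_band != None)  # noqa: E711
        if np.any(already):
            raise ValueError(f"band {name!r} overlaps another band")
        bin_band[sel] = name
    uncovered = np.flatnonzero(bin_band == None)  # noqa: E711
    if uncovered.size:
        raise ValueError(
            f"grid bins not covered by any band: "
            f"{np.round(freqs[uncovered], 2).tolist()}"
        )

    n_ch, n_bins = len(labels), grid.n_bins
    mask = report.mask.reshape(n_ch, n_bins)
    t = report.t.reshape(n_ch, n_bins)
    rows = []
    for c, b in zip(*np.nonzero(mask)):
        rows.append({
            "band": bin_band[b],
            "channel": labels[c],
            "frequency_hz": round(float(freqs[b]), 2),
            "t": float(t[c, b]),
        })
    cells = pd.DataFrame(rows, columns=["band", "channel", "frequency_hz", "t"])
    if cells.empty:
        empty_cl = pd.DataFrame(
            columns=["band", "channel", "f_lo", "f_hi", "n_cells", "sign"]
        )
        empty_bd = pd.DataFrame(
            columns=["band", "channels", "f_lo", "f_hi", "n_cells", "sign"]
        )
        return ClusterSummary(clusters=empty_cl, bands=empty_bd)

    clusters = (
        cells.groupby(["band", "channel"], sort=False)
        .agg(f_lo=("frequency_hz", "min"), f_hi=("frequency_hz", "max"),
             n_cells=("t", "size"), t_mean=("t", "mean"))
        .reset_index()
    )
    clusters["sign"] = np.sign(clusters["t_mean"]).astype(int)
    clusters = clusters.drop(columns="t_mean")
    bands = (
        cells.groupby("band", sort=False)
        .agg(f_lo=("frequency_hz", "min"), f_hi=("frequency_hz", "max"),
             n_cells=("t", "size"), t_mean=("t", "mean"))
        .reset_index()
    )
    bands["channels"] = [
        tuple(sorted(cells.loc[cells["band"] == b, "channel"].unique()))
        for b in bands["band"]
    ]
    bands["sign"] = np.sign(bands["t_mean"]).astype(int)
    bands = bands[["band", "channels", "f_lo", "f_hi", "n_cells", "sign"]]
    return ClusterSummary(clusters=clusters, bands=bands)
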