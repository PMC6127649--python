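"""Smoothness-regularized linear EEG inverse and source power spectra.

A deliberately simplified tomographic stage: given a lead field K
(electrodes x sources) the inverse operator is the Tikhonov solution
with a graph-Laplacian smoothness penalty on the source layout,

    T = (K^T K + lambda L^T L)^{-1} K^T,

and source power per frequency bin is the diagonal of T S(f) T^H with
S(f) the scalp cross-spectrum — real and nonnegative because S(f) is
Hermitian positive semidefinite.  Source spectra then flow through the
same log/normative-z machinery as scalp spectra; with an identity lead
field the two pipelines agree exactly.

No variable-resolution weighting, anatomical atlas or head model is
involved: sources are abstract grid points and lambda is a single
global weight (choosable by generalized cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import CrossSpectrum, FrequencyGrid


def chain_adjacency(n: int) -> np.ndarray:
    """Adjacency of a 1-D chain of ``n`` source points."""
    adj = np.zeros((n, n))
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = 1.0
    adj[idx + 1, idx] = 1.0
    return adj


def graph_laplacian(adjacency: np.ndarray) -> np.ndarray:
    adjacency = np.asarray(adjacency, dtype=float)
    return np.diag(adjacency.sum(axis=1)) - adjacency


@dataclass
class LeadField:
    """Forward gain matrix with the source adjacency used for smoothing."""

    matrix: np.ndarray           # electrodes x sources
    adjacency: np.ndarray | None = None
    condition_number: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("lead field must be a matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead field must be finite")
        if self.adjacency is None:
            self.adjacency = chain_adjacency(self.matrix.shape[1])
        if np.linalg.matrix_rank(self.matrix) < min(self.matrix.shape):
            raise ValueError("lead field must have full row rank")

    @property
    def n_electrodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


@dataclass
class InverseOperator:
    """Sources x electrodes mapping with its regularization context."""

    matrix: np.ndarray
    lam: float
    laplacian: np.ndarray


@dataclass
class SourceSpectrum:
    """Sources x bins real power on the analysis grid."""

    values: np.ndarray
    grid: FrequencyGrid | None = None


def build_inverse_operator(leadfield: LeadField, lam: float) -> InverseOperator:
    """Tikhonov inverse with Laplacian smoothness penalty.

    Solves (K^T K + lambda L^T L) T = K^T; requires lambda > 0 when the
    problem is under-determined (more sources than electrodes).
    """
    if lam < 0:
        raise ValueError("regularization weight must be nonnegative")
    K = leadfield.matrix
    L = graph_laplacian(leadfield.adjacency)
    A = K.T @ K + lam * (L.T @ L)
    if lam == 0 and leadfield.n_sources > leadfield.n_electrodes:
        raise np.linalg.LinAlgError(
            "under-determined problem is singular at lambda = 0"
        )
    T = np.linalg.solve(A, K.T)
    resid = np.linalg.norm(A @ T - K.T) / max(np.linalg.norm(K.T), 1e-300)
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"normal equations solved to {resid:.2e} relative residual only"
        )
    return InverseOperator(matrix=T, lam=float(lam), laplacian=L)


def source_spectra(
    operator: InverseOperator,
    cross: CrossSpectrum,
    grid: FrequencyGrid | None = None,
) -> SourceSpectrum:
    """Source power per bin: diagonal of T S(f) T^H, floored at zero."""
    T = operator.matrix
    S = cross.matrices
    if S.shape[1] != T.shape[1]:
        raise ValueError("electrode dimensions of operator and spectrum differ")
    herm_err = np.max(np.abs(S - np.conj(np.swapaxes(S, 1, 2))))
    scale = max(np.max(np.abs(S)), 1e-300)
    if herm_err > 1e-8 * scale:
        raise ValueError("cross-spectrum matrices are not Hermitian")
    # diag(T S T^H) per bin
    power = np.einsum("se,feg,sg->fs", T, S, np.conj(T)).real.T
    if grid is not None:
        power = power[:, grid.indices]
    power = np.where(power < 0, np.maximum(power, -1e-12) * 0.0, power)
    return SourceSpectrum(values=np.maximum(power, 0.0), grid=grid)


def choose_lambda_gcv(
    leadfield: LeadField,
    data: np.ndarray,
    lambdas: np.ndarray | None = None,
) -> float:
    """Generalized cross-validation choice of the smoothing weight.

    ``data`` is an electrodes x observations matrix (e.g. Fourier
    coefficients or per-bin scalp amplitudes).  Minimizes
    ||(I - K T) y||^2 / (1 - tr(K T)/n_e)^2 over a log-spaced ladder.
    """
    K = leadfield.matrix
    y = np.asarray(data)
    if lambdas is None:
        scale = np.trace(K.T @ K) / K.shape[1]
        lambdas = scale * np.logspace(-6, 2, 25)
    best_lam, best_score = None, np.inf
    n_e = K.shape[0]
    for lam in lambdas:
        try:
            T = build_inverse_operator(leadfield, float(lam)).matrix
        except np.linalg.LinAlgError:
            continue
        H = K @ T
        resid = y - H @ y
        denom = (1.0 - np.trace(H) / n_e) ** 2
        if denom <= 0:
            continue
        score = float(np.mean(np.abs(resid) ** 2) / denom)
        if score < best_score:
            best_lam, best_score = float(lam), score
    if best_lam is None:
        raise ValueError("GCV failed for every candidate lambda")
    return best_lam
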