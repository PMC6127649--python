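"""Epoching, Bartlett cross-spectra and the narrow-band analysis grid.

The resting EEG is cut into non-overlapping epochs of fixed length
(256 samples at 100 Hz by default) and the channel-by-channel
cross-spectrum is estimated by Bartlett's method: the average of the
per-epoch cross-periodograms, with no taper and the per-epoch mean
removed.  Power is then restricted to a narrow-band grid (0.78--19.14 Hz,
one DFT bin of resolution, 48 bins in the default configuration),
scale-corrected by the geometric mean over all in-band cells, and
log-transformed.  On the standard 19-channel 10/20 montage this yields
19 x 48 = 912 scalp features per subject.

Periodogram convention: for an epoch x of length N with DFT X_k,
the one-sided (non-doubled) power at bin k is |X_k|^2 / N^2, so that
epoch variance = p_0 + p_{N/2} + 2 * sum of the interior bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Standard 10/20 montage of the pipeline, linked-ear referenced.
MONTAGE_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

DEFAULT_EPOCH_SAMPLES = 256
DEFAULT_BAND = (0.78, 19.14)
MIN_EPOCHS = 20


class TooFewEpochs(ValueError):
    """Fewer clean epochs than the minimum needed for a stable spectrum."""


@dataclass
class Recording:
    """Multichannel EEG time series with subject metadata."""

    samples: np.ndarray          # channels x time
    fs: float
    labels: tuple[str, ...]
    age: float | None = None
    group: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = tuple(self.labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class FrequencyGrid:
    """Equally spaced in-band DFT bins (1-based index k, frequency k*fs/N)."""

    frequencies: np.ndarray      # bin centre frequencies, Hz
    spacing: float               # fs / epoch_samples
    indices: np.ndarray          # DFT bin indices into the one-sided spectrum
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size == 0:
            raise ValueError("empty frequency grid")
        if not np.all(np.diff(f) > 0):
            raise ValueError("grid frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=int))

    @property
    def n_bins(self) -> int:
        return self.frequencies.size


@dataclass
class CrossSpectrum:
    """Hermitian channel x channel matrix per one-sided DFT bin."""

    matrices: np.ndarray         # n_bins_onesided x channels x channels, complex
    frequencies: np.ndarray      # all one-sided bin frequencies
    fs: float
    n_epochs: int
    labels: tuple[str, ...]

    def diagonal_power(self) -> np.ndarray:
        """Real, nonnegative per-channel power: channels x bins."""
        diag = np.einsum("fcc->fc", self.matrices).real.T
        return np.maximum(diag, 0.0)


@dataclass
class ScalpSpectrum:
    """Channels x in-band-bins power table with transform state flags."""

    values: np.ndarray
    grid: FrequencyGrid
    labels: tuple[str, ...]
    n_epochs: int = 0
    log_transformed: bool = False
    geometric_corrected: bool = False
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), self.grid.n_bins):
            raise ValueError("values must be channels x grid bins")
        if not self.log_transformed and np.any(self.values < 0):
            raise ValueError("power must be nonnegative before log transform")


def segment_epochs(
    recording: Recording,
    epoch_samples: int = DEFAULT_EPOCH_SAMPLES,
    reject_threshold: float | None = None,
    min_epochs: int = MIN_EPOCHS,
) -> np.ndarray:
    """Cut a recording into clean, non-overlapping, contiguous epochs.

    Epochs containing any sample whose absolute amplitude exceeds
    ``reject_threshold`` are dropped.  Raises :class:`TooFewEpochs` when
    fewer than ``min_epochs`` clean epochs remain, which marks the
    recording as unusable.

    Returns
    -------
    ndarray of shape (n_epochs, channels, epoch_samples)
    """
    if recording.n_samples < epoch_samples:
        raise TooFewEpochs(
            f"recording has {recording.n_samples} samples, "
            f"shorter than one epoch of {epoch_samples}"
        )
    n_full = recording.n_samples // epoch_samples
    x = recording.samples[:, : n_full * epoch_samples]
    epochs = x.reshape(recording.n_channels, n_full, epoch_samples)
    epochs = np.moveaxis(epochs, 1, 0)  # epochs x channels x samples
    if reject_threshold is not None:
        keep = np.max(np.abs(epochs), axis=(1, 2)) <= reject_threshold
        epochs = epochs[keep]
    if epochs.shape[0] < min_epochs:
        raise TooFewEpochs(
            f"only {epochs.shape[0]} clean epochs, need at least {min_epochs}"
        )
    return epochs


def bartlett_cross_spectrum(epochs: np.ndarray, fs: float) -> CrossSpectrum:
    """Average of per-epoch cross-periodograms (no taper, mean removed).

    ``epochs`` has shape (n_epochs, channels, epoch_samples).  The per-bin
    matrix is mean over epochs of X(f) X(f)^H / N^2, with X the DFT of the
    demeaned epoch; it is Hermitian positive semidefinite by construction.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, channels, epoch_samples)")
    n_epochs, n_channels, n = epochs.shape
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    demeaned = epochs - epochs.mean(axis=2, keepdims=True)
    coefs = np.fft.rfft(demeaned, axis=2)          # epochs x channels x bins
    # S[f, i, j] = mean_e X_i conj(X_j) / N^2
    matrices = np.einsum("eif,ejf->fij", coefs, np.conj(coefs)) / (n_epochs * n * n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return CrossSpectrum(
        matrices=matrices,
        frequencies=freqs,
        fs=fs,
        n_epochs=n_epochs,
        labels=("",) * n_channels,
    )


def band_grid(
    fs: float,
    epoch_samples: int = DEFAULT_EPOCH_SAMPLES,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> FrequencyGrid:
    """Analysis grid: DFT bins of the epoch falling inside [f_lo, f_hi].

    With fs = 100 Hz and 256-sample epochs the spacing is 0.390625 Hz
    (0.39 to two decimals) and [0.78, 19.14] Hz holds 48 bins.
    Band endpoints are inclusive up to half a rounding unit, so printed
    two-decimal limits select the intended bins.
    """
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError("need 0 < f_lo < f_hi < Nyquist")
    spacing = fs / epoch_samples
    k = np.arange(epoch_samples // 2 + 1)
    freqs = k * spacing
    # tolerance so that limits printed to 2 decimals (0.78, 19.14) still
    # capture bins at 0.78125 and 19.140625
    tol = 5e-3
    inband = (freqs >= f_lo - tol) & (freqs <= f_hi + tol)
    inband &= k > 0
    if not np.any(inband):
        raise ValueError(f"no DFT bins inside [{f_lo}, {f_hi}] Hz")
    return FrequencyGrid(
        frequencies=freqs[inband],
        spacing=spacing,
        indices=k[inband],
        f_lo=f_lo,
        f_hi=f_hi,
    )


def scalp_spectrum(cross: CrossSpectrum, grid: FrequencyGrid,
                   labels: tuple[str, ...] | None = None) -> ScalpSpectrum:
    """Retain the cross-spectrum diagonal on the analysis grid."""
    power = cross.diagonal_power()[:, grid.indices]
    if labels is None:
        labels = cross.labels if any(cross.labels) else tuple(
            f"ch{i}" for i in range(power.shape[0])
        )
    return ScalpSpectrum(values=power, grid=grid, labels=tuple(labels),
                         n_epochs=cross.n_epochs)


def geometric_power_correct(spectrum: ScalpSpectrum) -> tuple[ScalpSpectrum, float]:
    """Divide every cell by the geometric mean of in-band power.

    Removes global amplitude differences between subjects (electrode
    impedance, gain); the geometric mean of the corrected table is one.
    Returns the corrected spectrum and the global scale factor.
    """
    if spectrum.log_transformed:
        raise ValueError("geometric correction applies to raw power, not log")
    if np.any(spectrum.values <= 0):
        raise ValueError("all power cells must be positive")
    factor = float(np.exp(np.mean(np.log(spectrum.values))))
    corrected = replace(
        spectrum,
        values=spectrum.values / factor,
        geometric_corrected=True,
        scale_factor=factor,
    )
    return corrected, factor


def log_spectrum(spectrum: ScalpSpectrum) -> ScalpSpectrum:
    """Natural-log transform toward Gaussianity, cellwise."""
    if spectrum.log_transformed:
        raise ValueError("spectrum already log transformed")
    if np.any(spectrum.values <= 0):
        raise ValueError("all power cells must be positive")
    return replace(spectrum, values=np.log(spectrum.values), log_transformed=True)


def subject_features(
    recording: Recording,
    epoch_samples: int = DEFAULT_EPOCH_SAMPLES,
    reject_threshold: float | None = None,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    geometric_correct: bool = True,
) -> ScalpSpectrum:
    """Full scalp feature extraction for one subject.

    Epoching -> Bartlett cross-spectrum -> in-band diagonal ->
    geometric power correction -> log transform.
    """
    epochs = segment_epochs(recording, epoch_samples, reject_threshold)
    cross = bartlett_cross_spectrum(epochs, recording.fs)
    grid = band_grid(recording.fs, epoch_samples, f_lo, f_hi)
    spec = scalp_spectrum(cross, grid, labels=recording.labels)
    if geometric_correct:
        spec, _ = geometric_power_correct(spec)
    return log_spectrum(spec)
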