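"""Synthetic EEG cohorts with known spectra and planted group effects.

Every input the pipeline needs is generated here with seeded
reproducibility: resting-EEG recordings whose expected spectrum is known
in closed form, normative and two-group study cohorts, ordinal
visual-rating tables drawn from a graded-response model, and toy lead
fields for the source-imaging stage.

Signals are synthesized by random-phase spectral shaping: the DFT
amplitudes of the full-length recording are fixed to the target spectral
density and only the phases are random.  The realized signal variance
therefore matches the model exactly (Parseval), and the expected
Bartlett periodogram at an analysis bin equals the closed-form density
times half the bin width (one-sided, non-doubled convention of
:mod:`qeegkit.spectra`).

The generator is the ground-truth source for the statistical test
suites: planted effect magnitudes are expressed in z-units of log power
and are recoverable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit, polygamma

from .spectra import (
    DEFAULT_BAND,
    DEFAULT_EPOCH_SAMPLES,
    MIN_EPOCHS,
    MONTAGE_1020,
    FrequencyGrid,
    Recording,
    band_grid,
)

DEFAULT_ITEMS = (
    "background_frequency",
    "focal_abnormality",
    "paroxysmal_activity",
    "diffuse_slow_activity",
    "sharp_waves",
)


@dataclass(frozen=True)
class Bump:
    """Gaussian spectral bump, optionally age dependent.

    ``center_log_slope`` moves the centre by that many Hz per natural-log
    unit of (age / age_ref); ``amplitude_age_exp`` scales the amplitude as
    (age / age_ref) ** exponent.
    """

    center: float
    width: float
    amplitude: float
    center_log_slope: float = 0.0
    amplitude_age_exp: float = 0.0

    def center_at(self, age: float, age_ref: float) -> float:
        return self.center + self.center_log_slope * np.log(age / age_ref)

    def amplitude_at(self, age: float, age_ref: float) -> float:
        return self.amplitude * (age / age_ref) ** self.amplitude_age_exp


def default_bumps() -> tuple[Bump, ...]:
    """Developmental defaults: alpha peak speeds up and grows with age,
    theta power declines, a small beta bump is age-stable."""
    return (
        Bump(center=8.5, width=1.0, amplitude=4.0,
             center_log_slope=2.0, amplitude_age_exp=0.5),
        Bump(center=5.0, width=1.5, amplitude=2.0, amplitude_age_exp=-1.0),
        Bump(center=16.0, width=2.0, amplitude=0.5),
    )


@dataclass
class SpectralModel:
    """Closed-form generative spectrum for resting EEG.

    ``density(f, age)`` is a one-sided spectral density (power per Hz):
    a 1/f^gamma background times an age factor, plus Gaussian bumps.
    Between-subject variability enters as log-normal multiplicative
    gains: one per channel (SD ``channel_gain_sd`` in natural-log power
    units) and one global amplitude factor (removed downstream by
    geometric power correction).
    """

    fs: float = 100.0
    background_amplitude: float = 10.0
    background_exponent: float = 1.0
    background_age_exp: float = -0.5
    bumps: tuple[Bump, ...] = field(default_factory=default_bumps)
    channel_labels: tuple[str, ...] = MONTAGE_1020
    channel_gain_sd: float = 0.25
    global_gain_sd: float = 0.4
    lowpass_hz: float | None = None
    age_ref: float = 8.0
    f_floor: float = 0.5

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        for b in self.bumps:
            if not (0.0 < b.center < self.fs / 2):
                raise ValueError(
                    f"bump center {b.center} Hz outside (0, Nyquist)"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def density(self, freqs: np.ndarray, age: float) -> np.ndarray:
        """One-sided spectral density (power per Hz) at frequencies ``freqs``."""
        f = np.asarray(freqs, dtype=float)
        rel = age / self.age_ref
        out = (
            self.background_amplitude
            * rel ** self.background_age_exp
            * np.maximum(f, self.f_floor) ** (-self.background_exponent)
        )
        for b in self.bumps:
            c = b.center_at(age, self.age_ref)
            if not (0.0 < c < self.fs / 2):
                raise ValueError(
                    f"bump center {c:.2f} Hz at age {age} outside (0, Nyquist)"
                )
            out = out + b.amplitude_at(age, self.age_ref) * np.exp(
                -0.5 * ((f - c) / b.width) ** 2
            )
        if self.lowpass_hz is not None:
            out = out / (1.0 + (f / self.lowpass_hz) ** 8)
        return out

    def expected_bin_power(
        self,
        age: float,
        epoch_samples: int = DEFAULT_EPOCH_SAMPLES,
        grid: FrequencyGrid | None = None,
    ) -> np.ndarray:
        """Expected (non-doubled) Bartlett periodogram at the analysis bins."""
        if grid is None:
            grid = band_grid(self.fs, epoch_samples)
        spacing = self.fs / epoch_samples
        return self.density(grid.frequencies, age) * spacing / 2.0

    def total_power(self, age: float, n_samples: int = 6000) -> float:
        """Signal variance implied by the density (integral over the band)."""
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / self.fs)
        df = self.fs / n_samples
        dens = self.density(freqs, age)
        # interior bins count twice (two-sided), DC excluded, Nyquist half
        var = df * dens[1:-1].sum() + df * dens[-1] / 2.0
        return float(var)

    def log_power_sd(self, n_epochs: int = MIN_EPOCHS + 3) -> float:
        """Approximate between-subject SD of in-band log bin power.

        Channel-gain variability plus the Bartlett sampling noise of an
        ``n_epochs``-epoch average (trigamma approximation).
        """
        return float(
            np.sqrt(self.channel_gain_sd ** 2 + polygamma(1, n_epochs))
        )


def synthesize_recording(
    model: SpectralModel,
    age: float,
    duration: float,
    seed: int,
    power_multiplier: np.ndarray | None = None,
    min_samples: int = MIN_EPOCHS * DEFAULT_EPOCH_SAMPLES,
    subject_id: str | None = None,
    group: str | None = None,
) -> Recording:
    """Random-phase surrogate recording with the model's exact spectrum.

    ``power_multiplier``, if given, multiplies the per-channel spectral
    density on the full-resolution rfft grid (channels x bins) — the
    hook used for planting group effects.  Deterministic given ``seed``.
    """
    n = int(round(duration * model.fs))
    if n < min_samples:
        raise ValueError(
            f"duration {duration} s gives {n} samples; "
            f"need at least {min_samples} for downstream epoching"
        )
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / model.fs)
    dens = model.density(freqs, age)[None, :].repeat(model.n_channels, axis=0)
    # multiplicative subject variability in power
    chan_gain = np.exp(rng.normal(0.0, model.channel_gain_sd, model.n_channels))
    global_gain = np.exp(rng.normal(0.0, model.global_gain_sd))
    dens = dens * chan_gain[:, None] * global_gain
    if power_multiplier is not None:
        dens = dens * np.asarray(power_multiplier, dtype=float)
    # exact-amplitude random-phase synthesis
    amp = np.sqrt(n * model.fs * dens / 2.0)
    amp[:, 0] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amp.shape)
    coefs = amp * np.exp(1j * phases)
    if n % 2 == 0:
        coefs[:, -1] = amp[:, -1] * np.sign(np.cos(phases[:, -1]))
    samples = np.fft.irfft(coefs, n=n, axis=1)
    return Recording(
        samples=samples,
        fs=model.fs,
        labels=model.channel_labels,
        age=age,
        group=group,
        subject_id=subject_id,
    )


@dataclass
class Cohort:
    """A bundle of recordings with a subject manifest."""

    recordings: list[Recording]
    table: pd.DataFrame  # subject_id, age, group

    def __iter__(self):
        return iter(self.recordings)

    def __len__(self) -> int:
        return len(self.recordings)


def make_normative_cohort(
    n: int,
    age_range: tuple[float, float],
    model: SpectralModel,
    seed: int,
    duration: float = 60.0,
) -> Cohort:
    """Normative cohort: ages uniform on ``age_range``, one recording each."""
    if n < 2:
        raise ValueError("normative cohort needs at least 2 subjects")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError("age_range must be an interval")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n)
    recs, rows = [], []
    for i, age in enumerate(ages):
        sid = f"N{i:04d}"
        rec = synthesize_recording(
            model, float(age), duration,
            seed=int(rng.integers(2 ** 31)),
            subject_id=sid, group="norm",
        )
        recs.append(rec)
        rows.append({"subject_id": sid, "age": float(age), "group": "norm"})
    return Cohort(recordings=recs, table=pd.DataFrame(rows))


@dataclass(frozen=True)
class EffectEntry:
    """Signed log-power shift, in z-units, at a set of electrodes and a
    frequency range (endpoints in printed two-decimal Hz are accepted)."""

    electrodes: tuple[str, ...]
    f_lo: float
    f_hi: float
    magnitude: float


@dataclass
class EffectSpec:
    """Collection of planted effects for the study cohort."""

    entries: list[EffectEntry] = field(default_factory=list)

    FREQ_TOL = 0.011  # printed two-decimal frequencies vs exact k*fs/N

    def validate(self, labels: tuple[str, ...],
                 band: tuple[float, float] = DEFAULT_BAND) -> None:
        for e in self.entries:
            missing = set(e.electrodes) - set(labels)
            if missing:
                raise ValueError(f"effect electrodes not in montage: {missing}")
            if not np.isfinite(e.magnitude):
                raise ValueError("effect magnitude must be finite")
            if e.f_lo > e.f_hi:
                raise ValueError("effect range reversed")
            if e.f_lo < band[0] - self.FREQ_TOL or e.f_hi > band[1] + self.FREQ_TOL:
                raise ValueError(
                    f"effect range {e.f_lo}-{e.f_hi} outside analysis band {band}"
                )

    def magnitude_grid(self, labels: tuple[str, ...],
                       grid: FrequencyGrid) -> np.ndarray:
        """Channels x bins matrix of summed z-magnitudes."""
        mag = np.zeros((len(labels), grid.n_bins))
        index = {lab: i for i, lab in enumerate(labels)}
        for e in self.entries:
            bins = np.flatnonzero(
                (grid.frequencies >= e.f_lo - self.FREQ_TOL)
                & (grid.frequencies <= e.f_hi + self.FREQ_TOL)
            )
            for lab in e.electrodes:
                mag[index[lab], bins] += e.magnitude
        return mag

    def cells(self, labels: tuple[str, ...], grid: FrequencyGrid) -> set:
        """Set of (electrode, bin frequency rounded to 2 dp) with nonzero effect."""
        mag = self.magnitude_grid(labels, grid)
        return {
            (labels[c], round(float(grid.frequencies[b]), 2))
            for c, b in zip(*np.nonzero(mag))
        }


def four_cluster_effects(magnitude: float = 1.25) -> EffectSpec:
    """Default planted effects: four band/electrode clusters.

    Increased theta (3.91--5.86 Hz, T4/Pz/O2), decreased alpha1
    (8.59--8.98 Hz, fronto-central), increased alpha2 (11.33--12.50 Hz,
    temporo-parieto-occipital) and increased beta1 (13.67--18.36 Hz,
    T4/T5/P4), cell for cell.
    """
    m = float(magnitude)
    return EffectSpec(entries=[
        # theta, increased
        EffectEntry(("T4", "Pz"), 3.91, 3.91, +m),
        EffectEntry(("T4",), 5.07, 5.07, +m),
        EffectEntry(("T4", "O2"), 5.86, 5.86, +m),
        # alpha1, decreased
        EffectEntry(("Fz", "C3"), 8.59, 8.59, -m),
        EffectEntry(("Cz", "Fp1", "Fp2", "F3", "F4"), 8.98, 8.98, -m),
        # alpha2, increased
        EffectEntry(("T4",), 11.33, 11.33, +m),
        EffectEntry(("T4", "T5"), 11.72, 11.72, +m),
        EffectEntry(("T4", "T5", "O1"), 12.11, 12.11, +m),
        EffectEntry(("P3", "P4"), 12.50, 12.50, +m),
        # beta1, increased
        EffectEntry(("P4", "T5"), 13.67, 13.67, +m),
        EffectEntry(("T4",), 14.45, 14.45, +m),
        EffectEntry(("T4",), 17.58, 17.58, +m),
        EffectEntry(("T4",), 18.36, 18.36, +m),
    ])


def make_study_cohort(
    n_a: int,
    n_b: int,
    model: SpectralModel,
    effects: EffectSpec,
    seed: int,
    reference=None,
    age_range: tuple[float, float] = (5.0, 11.0),
    duration: float = 60.0,
    epoch_samples: int = DEFAULT_EPOCH_SAMPLES,
    band: tuple[float, float] = DEFAULT_BAND,
) -> Cohort:
    """Two-group study cohort with planted log-power effects in group B.

    Group B's spectral density is multiplied, at each targeted
    (electrode, bin) cell, by exp(magnitude * sigma_log), so that the
    planted z-shift equals the requested magnitude.  ``sigma_log`` comes
    from a fitted normative model (``reference``, per cell and age) when
    given, else from the generator's closed-form log-power SD.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 subjects")
    effects.validate(model.channel_labels, band)
    rng = np.random.default_rng(seed)
    grid = band_grid(model.fs, epoch_samples, *band)
    mag = effects.magnitude_grid(model.channel_labels, grid)
    n = int(round(duration * model.fs))
    full_freqs = np.fft.rfftfreq(n, d=1.0 / model.fs)
    half = grid.spacing / 2.0
    # map each analysis bin to its full-resolution frequency window
    bin_masks = [
        np.abs(full_freqs - f) < half for f in grid.frequencies
    ]
    # epoch-window (Fejer) smoothing bleeds power across bin boundaries;
    # widening each planted region by half a bin keeps the realized shift
    # at the targeted bins close to the nominal magnitude
    dilate_steps = max(int(round(half / (model.fs / n))), 0)
    n_epochs = int(duration * model.fs) // epoch_samples
    recs, rows = [], []
    for g, count in (("A", n_a), ("B", n_b)):
        for i in range(count):
            sid = f"{g}{i:04d}"
            age = float(rng.uniform(*age_range))
            mult = None
            if g == "B" and np.any(mag):
                if reference is not None:
                    sd = reference.sigma(age).reshape(mag.shape)
                else:
                    sd = model.log_power_sd(n_epochs)
                delta = mag * sd
                profile = np.zeros((model.n_channels, full_freqs.size))
                for b, mask in enumerate(bin_masks):
                    if np.any(delta[:, b] != 0.0):
                        profile[:, mask] = delta[:, b][:, None]
                if dilate_steps:
                    profile = _dilate_profile(profile, dilate_steps)
                mult = np.exp(profile)
            rec = synthesize_recording(
                model, age, duration,
                seed=int(rng.integers(2 ** 31)),
                power_multiplier=mult,
                subject_id=sid, group=g,
            )
            recs.append(rec)
            rows.append({"subject_id": sid, "age": age, "group": g})
    return Cohort(recordings=recs, table=pd.DataFrame(rows))


def _dilate_profile(profile: np.ndarray, steps: int) -> np.ndarray:
    """Extend each nonzero run of a log-shift profile outward by ``steps``
    grid points, filling with the nearest nonzero value."""
    out = profile.copy()
    for c in range(profile.shape[0]):
        row = profile[c]
        nz = np.flatnonzero(row)
        if nz.size == 0:
            continue
        zeros = np.flatnonzero(row == 0.0)
        pos = np.searchsorted(nz, zeros)
        left = nz[np.clip(pos - 1, 0, nz.size - 1)]
        right = nz[np.clip(pos, 0, nz.size - 1)]
        dl = np.abs(zeros - left)
        dr = np.abs(right - zeros)
        nearest = np.where(dl <= dr, left, right)
        dist = np.minimum(dl, dr)
        fill = dist <= steps
        out[c, zeros[fill]] = row[nearest[fill]]
    return out


@dataclass
class ItemModelSpec:
    """Graded-response generative model for ordinal visual-rating items."""

    discriminations: np.ndarray
    thresholds: list[np.ndarray]
    group_shift: float = 0.0
    n_raters: int = 2
    rater_offsets: np.ndarray | None = None
    item_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.discriminations = np.asarray(self.discriminations, dtype=float)
        self.thresholds = [np.asarray(b, dtype=float) for b in self.thresholds]
        if len(self.thresholds) != self.discriminations.size:
            raise ValueError("one threshold vector per item required")
        for b in self.thresholds:
            if b.size < 1:
                raise ValueError("each item needs >= 2 categories")
            if np.any(np.diff(b) <= 0):
                raise ValueError("thresholds must be strictly increasing")
        if self.rater_offsets is None:
            self.rater_offsets = np.zeros(self.n_raters)
        self.rater_offsets = np.asarray(self.rater_offsets, dtype=float)
        if self.rater_offsets.size != self.n_raters:
            raise ValueError("one offset per rater required")
        if self.item_names is None:
            names = DEFAULT_ITEMS[: self.n_items] if self.n_items <= len(
                DEFAULT_ITEMS
            ) else tuple(f"item_{j}" for j in range(self.n_items))
            self.item_names = names

    @property
    def n_items(self) -> int:
        return self.discriminations.size


def default_item_spec(group_shift: float = 1.0, n_raters: int = 2) -> ItemModelSpec:
    """Five-item defaults mimicking the study's loading pattern: four
    well-discriminating abnormality items and one near-uninformative
    background-frequency item."""
    return ItemModelSpec(
        discriminations=np.array([0.05, 2.5, 2.2, 1.6, 1.4]),
        thresholds=[
            np.array([-1.0, 0.0, 1.0]),
            np.array([-0.5, 0.8, 2.0]),
            np.array([0.0, 1.2, 2.4]),
            np.array([-0.8, 0.5, 1.8]),
            np.array([-0.2, 1.0, 2.2]),
        ],
        group_shift=group_shift,
        n_raters=n_raters,
        item_names=DEFAULT_ITEMS,
    )


def make_item_responses(
    spec: ItemModelSpec,
    n_per_group: int,
    seed: int,
) -> pd.DataFrame:
    """Sample ordinal responses from the graded-response model.

    Latent trait theta ~ N(0, 1) in group A and N(group_shift, 1) in
    group B; each rater sees theta plus their offset.  One row per
    subject x rater, wide format (one column per item).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g, shift in (("A", 0.0), ("B", spec.group_shift)):
        thetas = rng.normal(shift, 1.0, size=n_per_group)
        for i, theta in enumerate(thetas):
            sid = f"{g}{i:04d}"
            for r in range(spec.n_raters):
                theta_eff = theta + spec.rater_offsets[r]
                row = {"subject_id": sid, "rater": f"R{r + 1}", "group": g}
                for j, name in enumerate(spec.item_names):
                    a = spec.discriminations[j]
                    b = spec.thresholds[j]
                    u = rng.uniform()
                    row[name] = int(np.sum(expit(a * theta_eff - b) > u))
                rows.append(row)
    return pd.DataFrame(rows)


def make_leadfield(
    n_electrodes: int,
    n_sources: int,
    smoothness: float = 1.0,
    seed: int | None = None,
    kind: str = "random",
):
    """Toy forward model: electrodes x sources gain matrix.

    Sources live on a 1-D chain; ``smoothness`` is the Gaussian-filter
    width (in source steps) applied along the source axis so that
    columns vary smoothly under the chain adjacency.  ``kind='identity'``
    returns the identity (square case only), making inversion exact.
    """
    from .inverse import LeadField, chain_adjacency

    if n_electrodes < 2 or n_sources < 2:
        raise ValueError("need at least 2 electrodes and 2 sources")
    if kind == "identity":
        if n_electrodes != n_sources:
            raise ValueError("identity lead field requires a square problem")
        K = np.eye(n_electrodes)
    elif kind == "random":
        rng = np.random.default_rng(seed)
        K = rng.standard_normal((n_electrodes, n_sources))
        if smoothness > 0:
            K = gaussian_filter1d(K, sigma=smoothness, axis=1, mode="nearest")
        # rescale rows so electrode magnitudes stay O(1)
        K /= np.linalg.norm(K, axis=1, keepdims=True) / np.sqrt(n_sources)
    else:
        raise ValueError(f"unknown lead field kind: {kind!r}")
    rank = np.linalg.matrix_rank(K)
    if rank < min(n_electrodes, n_sources):
        raise ValueError("generated lead field is rank deficient")
    return LeadField(
        matrix=K,
        adjacency=chain_adjacency(n_sources),
        condition_number=float(np.linalg.cond(K)),
    )
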