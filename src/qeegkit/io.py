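"""Readers, writers and configuration for the pipeline.

Recordings travel either as EDF (read through MNE; written by a minimal
16-bit EDF writer) or as a plain numeric TSV matrix (channels x time)
with a JSON sidecar holding labels, sampling rate and subject metadata —
the latter is the native fixture format.  Feature tables, z-spectra and
reports are TSV with JSON metadata, so every artifact is diffable text.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import MONTAGE_1020, Recording, ScalpSpectrum


class MissingChannelError(ValueError):
    """A recording lacks channels required by the configured montage."""


# ---------------------------------------------------------------------------
# recordings

def write_recording(recording: Recording, prefix: str | Path) -> tuple[Path, Path]:
    """Write samples as TSV (channels x time) plus a JSON sidecar."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".tsv")
    sidecar_path = prefix.with_suffix(".json")
    np.savetxt(data_path, recording.samples, delimiter="\t", fmt="%.8g")
    sidecar = {
        "labels": list(recording.labels),
        "fs": recording.fs,
        "age": recording.age,
        "group": recording.group,
        "subject_id": recording.subject_id,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return data_path, sidecar_path


def _check_montage(labels, montage):
    missing = [ch for ch in montage if ch not in labels]
    if missing:
        raise MissingChannelError(
            f"recording is missing channels: {', '.join(missing)}"
        )


def read_recording(
    path: str | Path,
    sidecar: str | Path | None = None,
    montage: tuple[str, ...] | None = None,
    fs_expected: float | None = None,
) -> Recording:
    """Read a recording from EDF or TSV+JSON.

    When ``montage`` is given, missing channels raise
    :class:`MissingChannelError` and the channels are reordered to the
    montage.  ``fs_expected`` guards against configuration mismatches.
    """
    path = Path(path)
    meta: dict = {}
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = tuple(raw.ch_names)
        samples = raw.get_data() * 1e6  # MNE loads volts; store microvolts
        fs = float(raw.info["sfreq"])
    else:
        if sidecar is None:
            sidecar = path.with_suffix(".json")
            meta = json.loads(Path(sidecar).read_text())
        samples = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        labels = tuple(meta["labels"])
        fs = float(meta["fs"])
    if fs_expected is not None and abs(fs - fs_expected) > 1e-6:
        raise ValueError(f"sampling rate {fs} Hz, expected {fs_expected}")
    if montage is not None:
        _check_montage(labels, montage)
        order = [labels.index(ch) for ch in montage]
        samples = samples[order]
        labels = tuple(montage)
    return Recording(
        samples=samples,
        fs=fs,
        labels=labels,
        age=meta.get("age"),
        group=meta.get("group"),
        subject_id=meta.get("subject_id"),
    )


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Minimal EDF export: one data record per second, 16-bit samples.

    Physical units are microvolts; each channel is scaled to its own
    physical min/max.  Requires an integer number of samples per second.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = recording.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record")
    x = recording.samples[:, : n_rec * spr]
    nch = recording.n_channels

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    phys_min = np.floor(x.min(axis=1)) - 1
    phys_max = np.ceil(x.max(axis=1)) + 1
    dig_min, dig_max = -32768, 32767

    header = b""
    header += pad("0", 8)
    header += pad(str(recording.subject_id or "X"), 80)
    header += pad("Startdate X", 80)
    header += pad("01.01.00", 8) + pad("00.00.00", 8)
    header += pad(str(256 * (1 + nch)), 8)
    header += pad("", 44)
    header += pad(str(n_rec), 8)
    header += pad("1", 8)          # record duration, seconds
    header += pad(str(nch), 4)
    for lab in recording.labels:
        header += pad(lab, 16)
    header += b"".join(pad("EEG", 80) for _ in range(nch))
    header += b"".join(pad("uV", 8) for _ in range(nch))
    header += b"".join(pad(f"{phys_min[c]:.0f}", 8) for c in range(nch))
    header += b"".join(pad(f"{phys_max[c]:.0f}", 8) for c in range(nch))
    header += b"".join(pad(str(dig_min), 8) for _ in range(nch))
    header += b"".join(pad(str(dig_max), 8) for _ in range(nch))
    header += b"".join(pad("", 80) for _ in range(nch))
    header += b"".join(pad(str(spr), 8) for _ in range(nch))
    header += b"".join(pad("", 32) for _ in range(nch))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(nch):
                seg = x[c, r * spr:(r + 1) * spr]
                dig = np.round(
                    (seg - phys_min[c]) * scale[c] + dig_min
                ).astype("<i2")
                fh.write(dig.tobytes())
    return path


# ---------------------------------------------------------------------------
# spectra and feature tables

def write_spectrum(spec: ScalpSpectrum, prefix: str | Path) -> tuple[Path, Path]:
    """Spectrum as TSV (rows = channels, columns = bin Hz) + JSON metadata."""
    prefix = Path(prefix)
    df = pd.DataFrame(
        spec.values,
        index=list(spec.labels),
        columns=[f"{f:.2f}" for f in spec.grid.frequencies],
    )
    tsv = prefix.with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", index_label="channel")
    meta = {
        "spacing_hz": spec.grid.spacing,
        "f_lo": spec.grid.f_lo,
        "f_hi": spec.grid.f_hi,
        "n_epochs": spec.n_epochs,
        "log_transformed": spec.log_transformed,
        "geometric_corrected": spec.geometric_corrected,
        "scale_factor": spec.scale_factor,
    }
    meta_path = prefix.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return tsv, meta_path


def feature_columns(labels, grid) -> list[str]:
    return [
        f"{ch}:{f:.2f}" for ch in labels for f in grid.frequencies
    ]


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def split_feature_table(df: pd.DataFrame):
    """Split a feature table into (metadata frame, feature matrix)."""
    meta_cols = [c for c in ("subject_id", "age", "group") if c in df.columns]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    return df[meta_cols], df[feat_cols].to_numpy(dtype=float), feat_cols


# ---------------------------------------------------------------------------
# normative model serialization

def write_normative_model(results, prefix: str | Path) -> Path:
    prefix = Path(prefix)
    payload = {
        "degree": results.degree,
        "sigma_floor": results.sigma_floor,
        "age_range": list(results.age_range),
        "n_subjects": results.n_subjects,
        "degenerate": results.degenerate,
        "feature_shape": list(results.feature_shape)
        if results.feature_shape else None,
        "labels": list(results.labels) if results.labels else None,
        "mu_coefs": results.mu_coefs.tolist(),
        "sigma_coefs": results.sigma_coefs.tolist(),
    }
    out = prefix.with_suffix(".json")
    out.write_text(json.dumps(payload))
    coefs = pd.DataFrame(
        np.vstack([results.mu_coefs, results.sigma_coefs]).T,
        columns=[f"mu_c{i}" for i in range(results.mu_coefs.shape[0])]
        + [f"logs2_c{i}" for i in range(results.sigma_coefs.shape[0])],
    )
    coefs.to_csv(prefix.with_suffix(".coefs.tsv"), sep="\t", index=False)
    return out


def read_normative_model(path: str | Path):
    from .norms import NormativeResults

    payload = json.loads(Path(path).read_text())
    return NormativeResults(
        mu_coefs=np.asarray(payload["mu_coefs"]),
        sigma_coefs=np.asarray(payload["sigma_coefs"]),
        degree=payload["degree"],
        sigma_floor=payload["sigma_floor"],
        age_range=tuple(payload["age_range"]),
        n_subjects=payload["n_subjects"],
        degenerate=payload["degenerate"],
        feature_shape=tuple(payload["feature_shape"])
        if payload["feature_shape"] else None,
        labels=tuple(payload["labels"]) if payload["labels"] else None,
    )


# ---------------------------------------------------------------------------
# reports

def write_significance_report(report, grid, labels,
                              prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    report.to_frame(grid, labels).to_csv(tsv, sep="\t", index=False)
    meta = {
        "threshold": report.threshold,
        "alpha": report.alpha,
        "n_perm": report.n_perm,
        "seed": report.seed,
        "method": report.method,
        "n_a": report.n_a,
        "n_b": report.n_b,
    }
    meta_path = prefix.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
    return [tsv, meta_path]


def write_biomarker_report(profile, report, feature_names,
                           prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    written = []
    prof = pd.DataFrame({
        "feature": feature_names,
        "selection_frequency": profile.frequencies,
        "retained": profile.retained,
    })
    p1 = Path(str(prefix) + ".stability.tsv")
    prof.to_csv(p1, sep="\t", index=False)
    written.append(p1)
    if report is not None:
        roc = pd.DataFrame({
            "fpr": report.fpr_grid,
            "median_tpr": report.median_tpr,
        })
        p2 = Path(str(prefix) + ".median_roc.tsv")
        roc.to_csv(p2, sep="\t", index=False)
        p3 = Path(str(prefix) + ".auc.tsv")
        pd.DataFrame({"auc": report.aucs}).to_csv(p3, sep="\t", index=False)
        written.extend([p2, p3])
    return written


def write_results(reports: dict, out_dir: str | Path,
                  config: dict | None = None) -> dict:
    """Write a dictionary of pipeline artifacts; return the manifest.

    Values are written by type-appropriate writers; the manifest lists
    every file with its producing stage and a hash of the configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[dict] = []

    def record(stage, paths):
        for p in np.atleast_1d(paths):
            files.append({"stage": stage, "path": str(Path(p).name)})

    for stage, obj in reports.items():
        base = out_dir / stage
        if isinstance(obj, pd.DataFrame):
            path = base.with_suffix(".tsv")
            obj.to_csv(path, sep="\t", index=False)
            record(stage, path)
        elif isinstance(obj, dict):
            path = base.with_suffix(".json")
            path.write_text(json.dumps(obj, indent=1, default=_jsonable))
            record(stage, path)
        else:
            raise TypeError(f"cannot serialize report {stage!r}: {type(obj)}")
    config_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=_jsonable).encode()
    ).hexdigest()[:16]
    manifest = {"config_hash": config_hash, "files": files}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (tuple, set)):
        return list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; every seed is explicit."""

    seed: int
    out_dir: str = "qeegkit_results"
    fs: float = 100.0
    epoch_samples: int = 256
    band: tuple[float, float] = (0.78, 19.14)
    reject_threshold: float | None = None
    montage: tuple[str, ...] = MONTAGE_1020
    duration: float = 60.0
    age_range: tuple[float, float] = (5.0, 11.0)
    n_normative: int = 80
    n_group_a: int = 30
    n_group_b: int = 30
    effect_magnitude: float = 1.25
    plant_effects: bool = True
    n_perm: int = 1000
    alpha: float = 0.05
    irt_enabled: bool = True
    irt_n_per_group: int = 50
    irt_group_shift: float = 1.0
    biomarker_n_iter: int = 100
    biomarker_n_cv: int = 200
    n_sources: int | None = None
    inverse_lambda: float | None = None

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an explicit integer")
        for name in ("fs", "epoch_samples", "duration", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.band[0] < self.band[1] < self.fs / 2):
            raise ValueError("band must satisfy 0 < lo < hi < Nyquist")
        if self.n_normative < 10:
            raise ValueError("normative cohort too small")
        if min(self.n_group_a, self.n_group_b) < 2:
            raise ValueError("study groups need at least 2 subjects")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in payload:
            raise ValueError("config must set an explicit seed")
        for key in ("band", "age_range", "montage"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
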