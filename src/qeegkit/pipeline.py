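"""End-to-end pipeline: simulate -> spectra -> norms -> stats -> IRT -> biomarker.

``run_full_pipeline`` executes every stage on synthetic cohorts under a
single explicit seed, writes TSV/JSON artifacts plus a manifest, and
fails fast with stage-named errors.  Deterministic given the config.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from . import biomarker as bm
from . import groupstats, inverse, irt, norms, spectra, synthgen
from .io import PipelineConfig, feature_columns, write_results


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name, fn, log):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc
    log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
    return out


def extract_features(cohort, config: PipelineConfig) -> pd.DataFrame:
    """Log, geometry-corrected scalp features for every cohort member."""
    rows = []
    for rec in cohort:
        spec = spectra.subject_features(
            rec,
            epoch_samples=config.epoch_samples,
            reject_threshold=config.reject_threshold,
            f_lo=config.band[0],
            f_hi=config.band[1],
        )
        rows.append({
            "subject_id": rec.subject_id,
            "age": rec.age,
            "group": rec.group,
            **dict(zip(feature_columns(spec.labels, spec.grid),
                       spec.values.ravel())),
        })
    return pd.DataFrame(rows)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; returns the output manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    log: list[dict] = []
    model = synthgen.SpectralModel(fs=config.fs, channel_labels=config.montage)
    grid = spectra.band_grid(config.fs, config.epoch_samples, *config.band)
    feat_names = feature_columns(config.montage, grid)

    # --- normative side -------------------------------------------------
    norm_cohort = _stage("simulate_normative", lambda: synthgen.make_normative_cohort(
        config.n_normative, config.age_range, model,
        seed=int(rng.integers(2 ** 31)), duration=config.duration,
    ), log)
    norm_feats = _stage("normative_features",
                        lambda: extract_features(norm_cohort, config), log)
    norm_fit = _stage("fit_norms", lambda: norms.fit_normative_model(
        norm_feats[feat_names].to_numpy(),
        norm_feats["age"].to_numpy(),
        feature_shape=(len(config.montage), grid.n_bins),
        labels=config.montage,
    ), log)

    # --- study side ------------------------------------------------------
    effects = (synthgen.four_cluster_effects(config.effect_magnitude)
               if config.plant_effects else synthgen.EffectSpec([]))
    study = _stage("simulate_study", lambda: synthgen.make_study_cohort(
        config.n_group_a, config.n_group_b, model, effects,
        seed=int(rng.integers(2 ** 31)), reference=norm_fit,
        age_range=config.age_range, duration=config.duration,
        epoch_samples=config.epoch_samples, band=config.band,
    ), log)
    study_feats = _stage("study_features",
                         lambda: extract_features(study, config), log)
    z = np.vstack([
        norm_fit.z_transform(row[feat_names].to_numpy(dtype=float), row["age"])
        for _, row in study_feats.iterrows()
    ])
    labels = study_feats["group"].to_numpy()

    # --- group statistics -------------------------------------------------
    report = _stage("maxt_test", lambda: groupstats.maxt_test(
        z, labels, n_perm=config.n_perm, alpha=config.alpha,
        seed=int(rng.integers(2 ** 31)),
    ), log)
    summary = groupstats.summarize_bands(report, grid, config.montage)

    # --- optional simplified source imaging ------------------------------
    source_note = None
    if config.n_sources:
        def _source_stage():
            lf = synthgen.make_leadfield(
                len(config.montage), config.n_sources,
                seed=int(rng.integers(2 ** 31)),
            )
            lam = config.inverse_lambda
            if lam is None:
                lam = np.trace(lf.matrix.T @ lf.matrix) / lf.n_sources * 1e-2
            op = inverse.build_inverse_operator(lf, lam)
            epochs = spectra.segment_epochs(
                study.recordings[0], config.epoch_samples,
                config.reject_threshold,
            )
            cross = spectra.bartlett_cross_spectrum(epochs, config.fs)
            src = inverse.source_spectra(op, cross, grid)
            return {"lambda": lam, "n_sources": lf.n_sources,
                    "source_power_shape": list(src.values.shape)}

        source_note = _stage("inverse", _source_stage, log)

    # --- IRT on visual-rating items --------------------------------------
    irt_results = {}
    if config.irt_enabled:
        def _irt_stage():
            table = synthgen.make_item_responses(
                synthgen.default_item_spec(config.irt_group_shift),
                config.irt_n_per_group, seed=int(rng.integers(2 ** 31)),
            )
            fit = irt.fit_graded_model(table)
            test = irt.latent_group_test(table)
            return {
                "loadings": fit.loadings[:, 0].round(3).tolist(),
                "items": fit.model.items,
                "aic": fit.aic,
                "group_estimate": test.estimate,
                "group_z": test.z,
                "group_p": test.p_value,
            }

        irt_results = _stage("irt", _irt_stage, log)

    # --- biomarker --------------------------------------------------------
    def _biomarker_stage():
        profile = bm.stability_select(
            z, labels, n_iter=config.biomarker_n_iter,
            seed=int(rng.integers(2 ** 31)),
        )
        roc = None
        if profile.retained.any():
            roc = bm.cross_validated_roc(
                z[:, profile.retained], labels,
                n_cv=config.biomarker_n_cv,
                seed=int(rng.integers(2 ** 31)),
                retained_indices=profile.retained_indices,
            )
        return profile, roc

    profile, roc = _stage("biomarker", _biomarker_stage, log)

    # --- write artifacts --------------------------------------------------
    reports = {
        "normative_features": norm_feats,
        "study_z": pd.concat(
            [study_feats[["subject_id", "age", "group"]],
             pd.DataFrame(z, columns=feat_names)], axis=1
        ),
        "significance": report.to_frame(grid, config.montage),
        "band_clusters": summary.clusters,
        "band_summary": summary.bands.assign(
            channels=summary.bands["channels"].map(list)
        ) if len(summary.bands) else summary.bands,
        "stability": pd.DataFrame({
            "feature": feat_names,
            "selection_frequency": profile.frequencies,
            "retained": profile.retained,
        }),
        "stage_log": pd.DataFrame(log),
    }
    stats_meta = {
        "threshold": report.threshold,
        "n_perm": report.n_perm,
        "alpha": report.alpha,
        "n_significant": int(report.mask.sum()),
        "detected_bands": {
            str(k): int(v) for k, v in summary.detected_bands.items()
        },
    }
    if roc is not None:
        reports["median_roc"] = pd.DataFrame({
            "fpr": roc.fpr_grid, "median_tpr": roc.median_tpr,
        })
        reports["auc_distribution"] = pd.DataFrame({"auc": roc.aucs})
        stats_meta["median_auc"] = roc.median_auc
    if irt_results:
        reports["irt"] = irt_results
    if source_note:
        reports["inverse"] = source_note
    reports["stats_meta"] = stats_meta
    return write_results(reports, config.out_dir, config=config.to_dict())
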