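"""End-to-end simulated experiments: cohort -> silhouettes -> features ->
models -> agreement reports.

Two experiments mirror a method-validation study design:

* a validation experiment — a derivation cohort trains per-gender models
  for total and abdominal fat mass, an independent validation cohort
  (default 84 female / 74 male) is predicted, and the full agreement
  battery is reported per gender and target;
* a reproducibility experiment — each subject is rendered twice with
  repositioning jitter and the replicate predictions are summarised with
  TEM, CV and concordance.

Derivation, validation and reproducibility cohorts draw from
non-overlapping seed streams, so the model is always evaluated on
subjects it has never seen. Every run directory carries a manifest with
content hashes; re-running with the same configuration and seed
reproduces the output files byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditioning import QCConfig, binarize, quality_check
from .errors import PipelineStageError, SampleSizeError
from .geometry import (
    FEATURE_ORDER,
    GeometryConfig,
    build_virtual_frame,
    detect_landmarks,
    extract_features,
)
from .model import predict_many, save_model, train
from .synthetic import (
    DEFAULT_COHORT_CONFIG,
    CohortConfig,
    RenderSpec,
    render_silhouette,
    sample_cohort,
    write_cohort_csv,
)
from .validation import full_report, plot_agreement, reproducibility

__all__ = ["PipelineConfig", "run_validation_experiment", "run_reproducibility_experiment"]

GENDERS = ("female", "male")
TARGETS = ("fm_total", "fm_abdominal")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serialisable description of one experiment run."""

    seed: int = 0
    # cohort sizes
    n_train_female: int = 100
    n_train_male: int = 100
    n_val_female: int = 84
    n_val_male: int = 74
    n_repro_female: int = 12
    n_repro_male: int = 15
    # rendering
    render_megapixels: float = 2.0
    pose_jitter: float = 1e-4
    # modelling
    use_stature: bool = False
    ridge: float = 0.0
    ape_mode: str = "group_mean"
    # sub-configs
    cohort: CohortConfig = field(default_factory=lambda: DEFAULT_COHORT_CONFIG)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    make_figures: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _streams(seed: int, n: int) -> list[int]:
    """Non-overlapping integer sub-seeds below 2**31."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def _measure_cohort(cohort, cfg: PipelineConfig, render_seed: int, log: list[str],
                    stage: str, replicate: int = 0):
    """Render, condition, QC and featurise a cohort.

    Returns (kept BodyParams list, FeatureVector list, excluded count).
    Subjects failing QC are excluded and counted, not fatal.
    """
    kept, feats, excluded = [], [], 0
    for i, params in enumerate(cohort):
        sid = params.subject_id
        try:
            spec = RenderSpec.for_megapixels(
                cfg.render_megapixels,
                pose_jitter=cfg.pose_jitter,
                seed=(render_seed + 1000003 * replicate + i) % (2**31),
            )
            img, _ = render_silhouette(params, spec, cfg.geometry.frame_fraction)
            sil = binarize(img, threshold=128)
            qc = quality_check(sil, cfg.qc)
            if not qc.passed:
                excluded += 1
                _log(log, f"{stage}: subject {sid} excluded by QC: "
                          f"{','.join(qc.failures)}")
                continue
            lm = detect_landmarks(sil, cfg.geometry)
            frame = build_virtual_frame(lm, sil, cfg.geometry.frame_fraction)
            fv = extract_features(
                sil, lm, frame, params.gender,
                params.stature,
                cfg.geometry.occupancy_mode,
            )
        except Exception as exc:  # noqa: BLE001 - stage context then abort
            raise PipelineStageError(stage, sid, exc) from exc
        kept.append(params)
        feats.append(fv)
    _log(log, f"{stage}: measured {len(kept)} subjects, excluded {excluded}")
    return kept, feats, excluded


def _features_frame(cohort, feats) -> pd.DataFrame:
    rows = []
    for p, fv in zip(cohort, feats):
        row = {"subject_id": p.subject_id}
        row.update({name: getattr(fv, name) for name in FEATURE_ORDER})
        row.update({"span_px": fv.span_px, "gender": fv.gender,
                    "stature_cm": fv.stature_cm})
        rows.append(row)
    return pd.DataFrame(rows)


def _train_models(cohort, feats, cfg: PipelineConfig, log: list[str]):
    models = {}
    for gender in GENDERS:
        idx = [i for i, p in enumerate(cohort) if p.gender == gender]
        g_feats = [feats[i] for i in idx]
        for target in TARGETS:
            ref = np.array([getattr(cohort[i], target) for i in idx])
            try:
                m = train(
                    g_feats, ref, target, gender,
                    use_stature=cfg.use_stature, ridge=cfg.ridge,
                )
            except SampleSizeError:
                _log(log, f"train: aborting, too few {gender} records "
                          f"({len(g_feats)}) for target {target}")
                raise
            models[(gender, target)] = m
            _log(log, f"train: {gender}/{target} n={m.training_n} "
                      f"see={m.training_see:.3f} kg")
    return models


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _finalize_run(outdir: Path, cfg: PipelineConfig, log: list[str]) -> None:
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "files": {
            str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in files
        },
    }
    _write_json(outdir / "manifest.json", manifest)


def run_validation_experiment(cfg: PipelineConfig, outdir) -> Path:
    """Derive models on one cohort, validate on an independent one.

    Writes cohort/feature/prediction tables, model files, per-gender
    agreement reports (both fat-mass targets), figures and a hashed
    manifest to ``outdir``. Returns the run directory path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"run_validation_experiment seed={cfg.seed}"]
    s_train, s_val, s_rtrain, s_rval = _streams(cfg.seed, 4)

    n_train = cfg.n_train_female + cfg.n_train_male
    train_cohort = sample_cohort(
        n_train, cfg.n_train_female / n_train, seed=s_train, config=cfg.cohort
    )
    n_val = cfg.n_val_female + cfg.n_val_male
    val_cohort = sample_cohort(
        n_val, cfg.n_val_female / n_val, seed=s_val, config=cfg.cohort
    )
    write_cohort_csv(train_cohort, outdir / "derivation_cohort.csv")
    write_cohort_csv(val_cohort, outdir / "validation_cohort.csv")

    train_kept, train_feats, _ = _measure_cohort(
        train_cohort, cfg, s_rtrain, log, "derivation"
    )
    val_kept, val_feats, _ = _measure_cohort(val_cohort, cfg, s_rval, log, "validation")
    _features_frame(train_kept, train_feats).to_csv(
        outdir / "derivation_features.csv", index=False, float_format="%.8f"
    )
    _features_frame(val_kept, val_feats).to_csv(
        outdir / "validation_features.csv", index=False, float_format="%.8f"
    )

    models = _train_models(train_kept, train_feats, cfg, log)
    for (gender, target), m in models.items():
        save_model(m, outdir / f"model_{target}_{gender}.json")

    reports = {}
    pred_rows = []
    for gender in GENDERS:
        idx = [i for i, p in enumerate(val_kept) if p.gender == gender]
        g_feats = [val_feats[i] for i in idx]
        for target in TARGETS:
            m = models[(gender, target)]
            pred, floored = predict_many(m, g_feats)
            ref = np.array([getattr(val_kept[i], target) for i in idx])
            rep = full_report(pred, ref, cfg.ape_mode)
            reports[f"{gender}/{target}"] = rep.to_dict()
            _log(log, f"validate: {gender}/{target} n={rep.n} ccc={rep.ccc:.4f} "
                      f"r2={rep.r2:.4f} bias={rep.bias:.3f}")
            for j, i in enumerate(idx):
                pred_rows.append({
                    "subject_id": val_kept[i].subject_id,
                    "gender": gender,
                    "target": target,
                    "predicted_kg": pred[j],
                    "reference_kg": ref[j],
                    "floored": bool(floored[j]),
                })
            if cfg.make_figures and target == "fm_total":
                plot_agreement(
                    pred, ref,
                    scatter_path=outdir / f"identity_{gender}.png",
                    bland_altman_path=outdir / f"bland_altman_{gender}.png",
                    label="FM",
                )
    pd.DataFrame(pred_rows).to_csv(
        outdir / "predictions.csv", index=False, float_format="%.8f"
    )
    _write_json(outdir / "agreement_reports.json", reports)
    _finalize_run(outdir, cfg, log)
    return outdir


def run_reproducibility_experiment(cfg: PipelineConfig, outdir) -> Path:
    """Render each subject twice with repositioning jitter and summarise
    the replicate agreement of the predicted fat-mass values."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"run_reproducibility_experiment seed={cfg.seed}"]
    s_train, s_repro, s_rtrain, s_r1, s_r2 = _streams(cfg.seed + 1, 5)

    n_train = cfg.n_train_female + cfg.n_train_male
    train_cohort = sample_cohort(
        n_train, cfg.n_train_female / n_train, seed=s_train, config=cfg.cohort
    )
    train_kept, train_feats, _ = _measure_cohort(
        train_cohort, cfg, s_rtrain, log, "derivation"
    )
    models = _train_models(train_kept, train_feats, cfg, log)

    n_rep = cfg.n_repro_female + cfg.n_repro_male
    repro_cohort = sample_cohort(
        n_rep, cfg.n_repro_female / n_rep, seed=s_repro, config=cfg.cohort
    )
    write_cohort_csv(repro_cohort, outdir / "reproducibility_cohort.csv")
    kept1, feats1, _ = _measure_cohort(repro_cohort, cfg, s_r1, log,
                                       "replicate1", replicate=0)
    kept2, feats2, _ = _measure_cohort(repro_cohort, cfg, s_r2, log,
                                       "replicate2", replicate=1)
    ids1 = {p.subject_id for p in kept1}
    ids2 = {p.subject_id for p in kept2}
    common = ids1 & ids2

    reports = {}
    for gender in GENDERS:
        pairs1 = [(p, f) for p, f in zip(kept1, feats1)
                  if p.gender == gender and p.subject_id in common]
        pairs2 = [(p, f) for p, f in zip(kept2, feats2)
                  if p.gender == gender and p.subject_id in common]
        for target in TARGETS:
            m = models[(gender, target)]
            pred1, _ = predict_many(m, [f for _, f in pairs1])
            pred2, _ = predict_many(m, [f for _, f in pairs2])
            rep = reproducibility(pred1, pred2)
            reports[f"{gender}/{target}"] = rep.to_dict()
            _log(log, f"reproducibility: {gender}/{target} n={rep.n} "
                      f"tem={rep.tem:.4f} ccc={rep.ccc:.5f} "
                      f"mean_diff={rep.mean_diff:.4f}")
    _write_json(outdir / "reproducibility_reports.json", reports)
    _finalize_run(outdir, cfg, log)
    return outdir
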