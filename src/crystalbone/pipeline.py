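"""End-to-end orchestration: simulate/ingest -> fracture qualification ->
windows -> split/oversample -> embeddings -> models -> evaluation and
human-level reports, with per-stage seeds, a canonical config hash stamped
into every artifact, and prediction-level caching so that changing only
the decision threshold never retrains models.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_model, synthetic
from .embeddings import (
    CodeEmbeddingConfig,
    WindowEmbeddingConfig,
    train_code_embedding,
    train_window_embedding,
    infer_window_vectors,
)
from .evaluation import evaluate_stratified
from .fractures import FractureCatalog, anchor_events, qualify_fracture_events
from .human_level import InterventionCatalog, cohort_analysis, overlap_analysis
from .lstm import LSTMConfig
from .models import (
    train_baseline,
    train_ensemble,
    train_gbdt,
    train_lstm,
)
from .windows import (
    apply_split,
    build_all_windows,
    build_vocabulary,
    oversample_balance,
    select_cohort,
    split_train_holdout,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric constant of the experiment in one serializable place."""

    # simulated inputs (ignored when ingesting real CSVs)
    n_patients_pan: int = 4000
    n_patients_bone: int = 1500
    mean_events_per_patient_year: float = 12.0
    vocabulary_size: int = 2000

    # cohort + windows
    min_age: float = 50.0
    min_history_days: int = 730
    horizon_days: int = 730
    max_windows: int = 5
    stride_days: int = 183
    washout_days: int = 90

    # vocabulary / embeddings
    min_count: int = 5
    code_dim: int = 100
    window_dim: int = 128
    skipgram_window: int = 10
    skipgram_epochs: int = 5
    dbow_epochs: int = 15
    max_len: int = 100

    # sampling / models
    split_ratio: float = 0.7
    lstm_hidden: int = 64
    lstm_epochs: int = 16
    lstm_batch_size: int = 64
    threshold: float = 0.5

    # per-stage seeds: stages are independently reproducible
    seed_data: int = 11
    seed_split: int = 12
    seed_oversample: int = 13
    seed_embed: int = 14
    seed_model: int = 15
    seed_infer: int = 16

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def canonical_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def model_hash(self) -> str:
        """Hash of everything that influences the fitted models — the
        decision threshold deliberately excluded."""
        d = asdict(self)
        d.pop("threshold")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    reports: dict
    cohort_report: object
    overlap_report: object
    predictions: pd.DataFrame
    log: dict
    retrained: bool


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _prepare_cohort(cohort, config, catalog, tag, log):
    """records -> fractures -> anchors -> eligibility -> windows."""
    records, asm = data_model.assemble_records(
        cohort.diagnoses, cohort.medications, cohort.demographics
    )
    fractures = {
        pid: qualify_fracture_events(rec, config.washout_days, catalog)
        for pid, rec in records.items()
    }
    anchors = {
        pid: anchor_events(rec, fractures[pid]) for pid, rec in records.items()
    }
    selection = select_cohort(
        records, anchors, min_age=config.min_age, min_history_days=config.min_history_days
    )
    wins = build_all_windows(
        selection,
        fractures,
        cohort_tag=tag,
        horizon_days=config.horizon_days,
        max_windows=config.max_windows,
        stride_days=config.stride_days,
        history_days=config.min_history_days,
    )
    log[f"{tag}_patients"] = len(records)
    log[f"{tag}_anchors"] = sum(len(a) for a in anchors.values())
    log[f"{tag}_excluded"] = selection.exclusions
    log[f"{tag}_windows"] = len(wins)
    return records, fractures, wins


def run_pipeline(
    config: PipelineConfig,
    outdir,
    simulate: bool = True,
    inputs: dict | None = None,
) -> PipelineResult:
    """Run every stage in dependency order and write all artifacts.

    ``inputs``, when given instead of ``simulate``, maps
    ``{"diagnoses": path, "medications": path, "demographics": path}`` for
    the pan-therapeutic cohort (no bone-health oversampling pool in that
    mode).  A stage failure raises :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": config.canonical_hash(), "model_hash": config.model_hash()}
    catalog = FractureCatalog.default()
    iv_catalog = InterventionCatalog.default()

    # ---- stage: data ---------------------------------------------------
    try:
        if simulate:
            pan = synthetic.generate_cohort(
                synthetic.GeneratorConfig(
                    n_patients=config.n_patients_pan,
                    cohort_kind="pan_therapeutic",
                    mean_events_per_patient_year=config.mean_events_per_patient_year,
                    vocabulary_size=config.vocabulary_size,
                    seed=config.seed_data,
                )
            )
            bone = synthetic.generate_cohort(
                synthetic.GeneratorConfig(
                    n_patients=config.n_patients_bone,
                    cohort_kind="bone_health",
                    mean_events_per_patient_year=config.mean_events_per_patient_year,
                    vocabulary_size=config.vocabulary_size,
                    seed=config.seed_data + 1,
                )
            )
        else:
            if not inputs:
                raise ValueError("inputs required when simulate=False")
            dx, _ = data_model.read_events(inputs["diagnoses"], "diagnosis")
            med, _ = data_model.read_events(inputs["medications"], "medication")
            demo, _ = data_model.read_demographics(inputs["demographics"])
            pan = synthetic.CohortData(
                dx, med, demo,
                synthetic.GroundTruth(pd.DataFrame(), pd.DataFrame()),
                synthetic.GeneratorConfig(n_patients=0),
            )
            bone = None
    except Exception as e:  # noqa: BLE001 - stage-named rethrow
        raise StageError("data", e) from e

    # ---- stage: windows ------------------------------------------------
    try:
        records, fractures, pan_windows = _prepare_cohort(
            pan, config, catalog, "pan_therapeutic", log
        )
        bone_pool = []
        if bone is not None and config.n_patients_bone > 0:
            _, _, bone_windows = _prepare_cohort(bone, config, catalog, "bone_health", log)
            bone_pool = [w for w in bone_windows if w.label]
        plan = split_train_holdout(pan_windows, config.split_ratio, config.seed_split)
        train_nat, holdout = apply_split(pan_windows, plan)
        train = oversample_balance(train_nat, bone_pool, config.seed_oversample) \
            if bone_pool else train_nat
        log["train_windows"] = len(train)
        log["holdout_windows"] = len(holdout)
        from .windows import windows_to_frame

        windows_to_frame(pan_windows).to_csv(outdir / "windows_pan.csv", index=False)
    except Exception as e:
        raise StageError("windows", e) from e

    if not holdout or not train:
        raise StageError("windows", ValueError("no windows survived cohort selection"))

    # ---- stage: models (cached at the prediction level) ----------------
    pred_path = outdir / "predictions.csv"
    meta_path = outdir / "predictions.meta.json"
    retrained = True
    preds = None
    lstm_model = None
    if pred_path.exists() and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("model_hash") == config.model_hash():
            preds = pd.read_csv(pred_path)
            retrained = False
    if preds is None:
        try:
            preds, lstm_model = _train_and_predict(config, train, train_nat, holdout, log)
            preds.to_csv(pred_path, index=False)
            meta_path.write_text(
                json.dumps({"model_hash": config.model_hash(), "stage": "models"})
            )
        except Exception as e:
            raise StageError("models", e) from e
    log["models_retrained"] = retrained

    # ---- stage: evaluation ---------------------------------------------
    try:
        reports = {}
        for kind in ("lstm_seq", "gbdt_vec", "baseline_age_sex",
                     "baseline_age_sex_count", "ensemble"):
            scores = preds[kind].to_numpy()
            if kind == "lstm_seq":
                reports[kind] = {
                    s: r.to_dict()
                    for s, r in evaluate_stratified(holdout, scores, config.threshold).items()
                }
            else:
                reports[kind] = {
                    "overall": evaluate_stratified(holdout, scores, config.threshold)[
                        "overall"
                    ].to_dict()
                }
        (outdir / "evaluation.json").write_text(
            json.dumps({"config_hash": config.canonical_hash(), "reports": reports}, indent=2)
        )
    except Exception as e:
        raise StageError("evaluation", e) from e

    # ---- stage: human-level --------------------------------------------
    try:
        f1_flags = preds["lstm_seq"].to_numpy() >= config.threshold
        cohort_rep = cohort_analysis(
            holdout, f1_flags, records, iv_catalog, config.min_history_days
        )
        holdout_records = {pid: records[pid] for pid in {w.patient_id for w in holdout}}
        scorer = _CachedScorer(preds, holdout, lstm_model)
        overlap_rep = overlap_analysis(
            holdout_records,
            fractures,
            scorer,
            iv_catalog,
            threshold=config.threshold,
            horizon_days=config.horizon_days,
            history_days=config.min_history_days,
        )
        (outdir / "hlp_cohort.json").write_text(json.dumps(cohort_rep.to_dict(), indent=2))
        (outdir / "hlp_overlap.json").write_text(json.dumps(overlap_rep.to_dict(), indent=2))
    except Exception as e:
        raise StageError("human_level", e) from e

    (outdir / "log.json").write_text(json.dumps(log, indent=2, default=str))
    config.to_yaml(outdir / "config.yaml")
    return PipelineResult(
        config=config,
        reports=reports,
        cohort_report=cohort_rep,
        overlap_report=overlap_rep,
        predictions=preds,
        log=log,
        retrained=retrained,
    )


class _CachedScorer:
    """Scores overlap-analysis windows with the cached framework-1 model;
    when only cached predictions exist (no retraining), falls back to the
    nearest holdout window of the same patient."""

    def __init__(self, preds: pd.DataFrame, holdout, model=None):
        self._model = model
        self._by_patient: dict[str, float] = {}
        probs = preds["lstm_seq"].to_numpy()
        for w, p in zip(holdout, probs):
            # keep the most recent window's probability per patient
            self._by_patient.setdefault(w.patient_id, float(p))

    def __call__(self, wins):
        if self._model is not None:
            return self._model.predict_proba(wins)
        return np.array([self._by_patient.get(w.patient_id, 0.0) for w in wins])


def _train_and_predict(config, train, train_nat, holdout, log) -> pd.DataFrame:
    """Fit embeddings, the two frameworks, baselines, and the ensemble;
    return holdout probabilities, one column per model kind."""
    corpus = [w for w in train_nat if w.source == "natural"]
    vocab = build_vocabulary(corpus, min_count=config.min_count)
    log["vocabulary_size"] = len(vocab)

    code_emb = train_code_embedding(
        corpus,
        vocab,
        CodeEmbeddingConfig(
            dim=config.code_dim,
            context_window=config.skipgram_window,
            epochs=config.skipgram_epochs,
            seed=config.seed_embed,
        ),
    )
    win_emb = train_window_embedding(
        corpus,
        vocab,
        WindowEmbeddingConfig(
            dim=config.window_dim, epochs=config.dbow_epochs, seed=config.seed_embed + 1
        ),
    )

    # out-of-fold calibration split for the ensemble metaclassifier;
    # calibration uses only natural windows so the meta-weights are fitted
    # on the evaluation distribution, not the oversampled mixture
    patients = sorted({w.patient_id for w in train})
    rng = np.random.default_rng(config.seed_model)
    perm = rng.permutation(len(patients))
    n_cal = max(1, int(round(0.1 * len(patients))))
    cal_patients = {patients[i] for i in perm[:n_cal]}
    fit = [w for w in train if w.patient_id not in cal_patients]
    cal = [
        w for w in train
        if w.patient_id in cal_patients and w.source == "natural"
    ]

    lstm_cfg = LSTMConfig(
        hidden=config.lstm_hidden,
        epochs=config.lstm_epochs,
        batch_size=config.lstm_batch_size,
        seed=config.seed_model,
    )
    lstm = train_lstm(fit, code_emb, lstm_cfg, max_len=config.max_len,
                      threshold=config.threshold, seed=config.seed_model)
    fit_vecs = infer_window_vectors(win_emb, fit, seed=config.seed_infer)
    gbdt = train_gbdt(fit, win_emb, vectors=fit_vecs, infer_seed=config.seed_infer,
                      threshold=config.threshold, seed=config.seed_model)

    cal_labels = [w.label for w in cal]
    if cal and len(set(cal_labels)) == 2:
        ens = train_ensemble(
            lstm.predict_proba(cal),
            gbdt.predict_proba(cal),
            cal_labels,
            base_lstm=lstm,
            base_gbdt=gbdt,
            threshold=config.threshold,
            seed=config.seed_model,
        )
    else:
        ens = None
        warnings.warn("calibration fold lacks both classes; ensemble skipped")

    b2 = train_baseline(train, ("age", "sex"), threshold=config.threshold,
                        seed=config.seed_model)
    b3 = train_baseline(train, ("age", "sex", "dx_count"), threshold=config.threshold,
                        seed=config.seed_model)

    hold_vecs = infer_window_vectors(win_emb, holdout, seed=config.seed_infer)
    p_lstm = lstm.predict_proba(holdout)
    p_gbdt = gbdt.predict_proba(holdout, vectors=hold_vecs)
    preds = pd.DataFrame(
        {
            "window_id": [w.window_id for w in holdout],
            "label": [int(w.label) for w in holdout],
            "lstm_seq": p_lstm,
            "gbdt_vec": p_gbdt,
            "baseline_age_sex": b2.predict_proba(holdout),
            "baseline_age_sex_count": b3.predict_proba(holdout),
            "ensemble": ens.predict_from_probs(p_lstm, p_gbdt)
            if ens is not None
            else 0.5 * (p_lstm + p_gbdt),
        }
    )
    return preds, lstm
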