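"""Risk classifiers: the two sequence-based frameworks, two baselines,
and the logistic-regression ensemble.

* ``lstm_seq`` — code-vector sequences through the LSTM network, statics
  joined at the merge layer (framework 1);
* ``gbdt_vec`` — the 128-d window vector plus statics through gradient
  boosted trees (framework 2, backed by xgboost);
* ``baseline_age_sex`` / ``baseline_age_sex_count`` — gradient boosted
  trees over the named static features only;
* ``ensemble`` — logistic regression over the two framework probabilities,
  fitted on a fold the bases were not trained on.

Sex is encoded as a single column (female 0, male 1, unknown 0.5) so the
framework-2 feature table is exactly embedding_dim + 3 columns wide.  All
models are seeded and single-threaded; prediction is deterministic and
batch-order independent after fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

from .embeddings import CodeEmbedding, WindowEmbeddingModel, embed_sequence, infer_window_vectors
from .evaluation import auroc
from .lstm import LSTMClassifier, LSTMConfig
from .windows import Window

SEX_CODE = {"female": 0.0, "male": 1.0, "unknown": 0.5}

STATIC_NAMES = ("age", "sex", "dx_count")


@dataclass(frozen=True)
class Prediction:
    window_id: str
    probability: float
    flag: bool


def static_features(windows: list[Window], features=STATIC_NAMES) -> np.ndarray:
    cols = []
    for name in features:
        if name == "age":
            cols.append([w.age for w in windows])
        elif name == "sex":
            cols.append([SEX_CODE[w.sex] for w in windows])
        elif name == "dx_count":
            cols.append([w.dx_count for w in windows])
        else:
            raise ValueError(f"unknown static feature {name!r}")
    return np.array(cols, dtype=float).T


def labels_of(windows: list[Window]) -> np.ndarray:
    return np.array([w.label for w in windows], dtype=int)


def _check_trainable(y: np.ndarray) -> None:
    if len(y) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")


def _patient_validation_split(
    windows: list[Window], val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level fit/validation carve-out of the training set.

    Validation keeps only natural (non-oversampled) windows of the
    held-out patients, so early stopping scores the distribution the
    model is evaluated on."""
    patients = sorted({w.patient_id for w in windows})
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(patients))
    n_val = max(1, int(round(val_fraction * len(patients))))
    val_patients = {patients[i] for i in perm[:n_val]}
    in_val = np.array([w.patient_id in val_patients for w in windows])
    natural = np.array([w.source == "natural" for w in windows])
    return ~in_val, in_val & natural


class RiskModel:
    """Fitted classifier + decision threshold; predict() is deterministic."""

    kind: str = "abstract"

    def __init__(self, threshold: float = 0.5, seed: int = 0):
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        self.threshold = threshold
        self.seed = seed

    def predict_proba(self, windows: list[Window]) -> np.ndarray:
        raise NotImplementedError

    def predict(self, windows: list[Window]) -> list[Prediction]:
        probs = self.predict_proba(windows)
        return [
            Prediction(w.window_id, float(p), bool(p >= self.threshold))
            for w, p in zip(windows, probs)
        ]


class LSTMRiskModel(RiskModel):
    kind = "lstm_seq"

    def __init__(self, net, code_embedding, max_len, static_mean, static_std,
                 input_scale=1.0, threshold=0.5, seed=0, history=None):
        super().__init__(threshold, seed)
        self.net = net
        self.code_embedding = code_embedding
        self.max_len = max_len
        self.static_mean = static_mean
        self.static_std = static_std
        # scale-only input normalization: division preserves the zero
        # padding rows that centering would destroy
        self.input_scale = input_scale
        self.history = history or {}

    def featurize(self, windows: list[Window]) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack(
            [embed_sequence(w.codes, self.code_embedding, self.max_len)[0] for w in windows]
        ).astype(float) / self.input_scale
        S = (static_features(windows) - self.static_mean) / self.static_std
        return X, S

    def predict_proba(self, windows: list[Window]) -> np.ndarray:
        X, S = self.featurize(windows)
        return self.net.predict_proba(X, S)


def train_lstm(
    train_windows: list[Window],
    code_embedding: CodeEmbedding,
    config: LSTMConfig | None = None,
    max_len: int = 200,
    val_fraction: float = 0.1,
    threshold: float = 0.5,
    seed: int = 0,
) -> LSTMRiskModel:
    """Fit framework 1 with an internal patient-level validation carve-out
    and early stopping on validation AUROC."""
    config = config or LSTMConfig(seed=seed)
    y = labels_of(train_windows)
    _check_trainable(y)

    S_raw = static_features(train_windows)
    mean = S_raw.mean(axis=0)
    std = S_raw.std(axis=0)
    std[std == 0] = 1.0

    scale = float(code_embedding.matrix[2:].std()) or 1.0
    model = LSTMRiskModel(
        net=LSTMClassifier(code_embedding.dim, S_raw.shape[1], config),
        code_embedding=code_embedding,
        max_len=max_len,
        static_mean=mean,
        static_std=std,
        input_scale=scale,
        threshold=threshold,
        seed=seed,
    )
    X, S = model.featurize(train_windows)

    fit_mask, val_mask = _patient_validation_split(train_windows, val_fraction, seed)
    use_early_stop = val_mask.sum() > 0 and len(np.unique(y[val_mask])) == 2
    if not use_early_stop:
        fit_mask = np.ones(len(y), dtype=bool)

    rng = np.random.default_rng(seed)
    best_auc, best_snap, bad_epochs = -np.inf, None, 0
    history = {"train_loss": [], "val_auroc": []}
    for _epoch in range(config.epochs):
        loss = model.net.fit_epoch(X[fit_mask], S[fit_mask], y[fit_mask].astype(float), rng)
        history["train_loss"].append(loss)
        if use_early_stop:
            val_auc = auroc(model.net.predict_proba(X[val_mask], S[val_mask]), y[val_mask])
            history["val_auroc"].append(val_auc)
            if val_auc > best_auc:
                best_auc, best_snap, bad_epochs = val_auc, model.net.snapshot(), 0
            else:
                bad_epochs += 1
                if bad_epochs > config.patience:
                    break
    if best_snap is not None:
        model.net.restore(best_snap)
    model.history = history
    return model


class GBDTRiskModel(RiskModel):
    kind = "gbdt_vec"

    def __init__(self, booster, window_embedding, infer_seed, threshold=0.5, seed=0):
        super().__init__(threshold, seed)
        self.booster = booster
        self.window_embedding = window_embedding
        self.infer_seed = infer_seed

    def featurize(self, windows: list[Window], vectors: np.ndarray | None = None) -> np.ndarray:
        if vectors is None:
            vectors = infer_window_vectors(self.window_embedding, windows, seed=self.infer_seed)
        return np.hstack([vectors, static_features(windows)])

    def predict_proba(self, windows: list[Window], vectors: np.ndarray | None = None) -> np.ndarray:
        return self.booster.predict_proba(self.featurize(windows, vectors))[:, 1]


DEFAULT_XGB_PARAMS = dict(
    n_estimators=400,
    max_depth=3,
    learning_rate=0.05,
    subsample=0.8,
    colsample_bytree=0.8,
)


def _patient_masks(groups, val_fraction, seed, natural=None):
    """Patient-level fit/validation masks.  When window provenance is
    given, the validation fold keeps only *natural* windows so that model
    selection scores the evaluation distribution, not the oversampled
    training mixture."""
    uniq = sorted(set(groups))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    n_val = max(1, int(round(val_fraction * len(uniq))))
    val_pat = {uniq[i] for i in perm[:n_val]}
    in_val = np.array([g in val_pat for g in groups])
    val = in_val if natural is None else in_val & np.asarray(natural)
    return ~in_val, val


def _fit_xgb(F, y, seed, params=None, tuning_grid=None, groups=None,
             natural=None, val_fraction=0.1):
    """Fit an xgboost classifier with AUROC early stopping on a
    patient-level validation carve-out (oversampled duplicate windows make
    unregularized boosting memorize exact feature values).  If a tuning
    grid is given, the AUROC-best combination on the same carve-out wins.
    """
    base = dict(DEFAULT_XGB_PARAMS)
    base.update(params or {})
    common = dict(n_jobs=1, random_state=seed, tree_method="hist", eval_metric="auc")
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=int)
    fit_mask, val_mask = _patient_masks(groups, val_fraction, seed, natural)
    can_validate = val_mask.any() and len(np.unique(y[val_mask])) == 2 \
        and len(np.unique(y[fit_mask])) == 2

    def fit_one(cand):
        if can_validate:
            m = XGBClassifier(**cand, **common, early_stopping_rounds=25)
            m.fit(F[fit_mask], y[fit_mask], eval_set=[(F[val_mask], y[val_mask])],
                  verbose=False)
        else:
            m = XGBClassifier(**cand, **common)
            m.fit(F, y)
        return m

    candidates = [base]
    if tuning_grid and can_validate:
        from itertools import product

        keys = sorted(tuning_grid)
        candidates = []
        for combo in product(*(tuning_grid[k] for k in keys)):
            cand = dict(base)
            cand.update(dict(zip(keys, combo)))
            candidates.append(cand)

    best, best_auc = None, -np.inf
    for cand in candidates:
        m = fit_one(cand)
        score = (
            auroc(m.predict_proba(F[val_mask])[:, 1], y[val_mask])
            if can_validate
            else 0.0
        )
        if score > best_auc or best is None:
            best, best_auc = m, score
    return best


def train_gbdt(
    train_windows: list[Window],
    window_embedding: WindowEmbeddingModel,
    vectors: np.ndarray | None = None,
    params: dict | None = None,
    tuning_grid: dict | None = None,
    infer_seed: int = 0,
    threshold: float = 0.5,
    seed: int = 0,
) -> GBDTRiskModel:
    """Fit framework 2: gradient boosted trees over window vectors + statics."""
    y = labels_of(train_windows)
    _check_trainable(y)
    model = GBDTRiskModel(None, window_embedding, infer_seed, threshold, seed)
    F = model.featurize(train_windows, vectors)
    groups = [w.patient_id for w in train_windows]
    natural = [w.source == "natural" for w in train_windows]
    model.booster = _fit_xgb(F, y, seed, params, tuning_grid, groups, natural)
    return model


class BaselineRiskModel(RiskModel):
    def __init__(self, booster, features, threshold=0.5, seed=0):
        super().__init__(threshold, seed)
        self.booster = booster
        self.features = tuple(features)
        self.kind = "baseline_" + "_".join(
            "count" if f == "dx_count" else f for f in self.features
        )

    def predict_proba(self, windows: list[Window]) -> np.ndarray:
        return self.booster.predict_proba(static_features(windows, self.features))[:, 1]


def train_baseline(
    train_windows: list[Window],
    features=("age", "sex"),
    params: dict | None = None,
    tuning_grid: dict | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> BaselineRiskModel:
    """Static-feature baseline over {age, sex} or {age, sex, dx_count},
    using the same boosted-tree classifier as framework 2."""
    for f in features:
        if f not in STATIC_NAMES:
            raise ValueError(f"unknown baseline feature {f!r}")
    y = labels_of(train_windows)
    _check_trainable(y)
    F = static_features(train_windows, features)
    groups = [w.patient_id for w in train_windows]
    natural = [w.source == "natural" for w in train_windows]
    booster = _fit_xgb(F, y, seed, params, tuning_grid, groups, natural)
    return BaselineRiskModel(booster, features, threshold, seed)


class EnsembleRiskModel(RiskModel):
    kind = "ensemble"

    def __init__(self, meta, base_lstm, base_gbdt, threshold=0.5, seed=0):
        super().__init__(threshold, seed)
        self.meta = meta
        self.base_lstm = base_lstm
        self.base_gbdt = base_gbdt

    @property
    def coef_(self) -> np.ndarray:
        return self.meta.coef_.ravel()

    def predict_from_probs(self, p1, p2) -> np.ndarray:
        F = np.column_stack([p1, p2])
        return self.meta.predict_proba(F)[:, 1]

    def predict_proba(self, windows: list[Window]) -> np.ndarray:
        if self.base_lstm is None or self.base_gbdt is None:
            raise ValueError("ensemble lacks base models; use predict_from_probs")
        return self.predict_from_probs(
            self.base_lstm.predict_proba(windows),
            self.base_gbdt.predict_proba(windows),
        )


def train_ensemble(
    framework1_probs,
    framework2_probs,
    labels,
    base_lstm: LSTMRiskModel | None = None,
    base_gbdt: GBDTRiskModel | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> EnsembleRiskModel:
    """Logistic-regression metaclassifier over the two framework
    probabilities.  The probabilities must come from a fold the base
    models were not fitted on."""
    p1 = np.asarray(framework1_probs, dtype=float)
    p2 = np.asarray(framework2_probs, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_trainable(y)
    if np.ptp(p1) == 0 or np.ptp(p2) == 0:
        raise ValueError("constant base-model probabilities cannot be ensembled")
    meta = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000, random_state=seed)
    meta.fit(np.column_stack([p1, p2]), y)
    return EnsembleRiskModel(meta, base_lstm, base_gbdt, threshold, seed)


def predict(model: RiskModel, windows: list[Window]) -> list[Prediction]:
    """One probability + flag per window; order-independent."""
    return model.predict(windows)
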