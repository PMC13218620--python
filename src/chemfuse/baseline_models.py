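"""pIC50 regression suite: CV, grid search, metrics, robustness, Taylor stats.

Six mandatory regressors (ridge, linear SVR, extra trees, LightGBM,
XGBoost, random forest) are trained on the concatenated
fingerprint+descriptor matrix with an 80/20 split, grid search inside
5-fold cross-validation on the training split only, and evaluated with
MAE/RMSE/R² plus classification metrics after discretising predictions
at pIC50 > 7.  Neural model families (cnn/gnn) are optional and reported
as explicit skips when their backend is unavailable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lightgbm import LGBMRegressor
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import LinearSVR
from xgboost import XGBRegressor

from .activity_rules import HIGH_THRESHOLD

MANDATORY_MODELS = ("ridge", "linear_svr", "extra_trees", "lightgbm", "xgboost", "random_forest")
OPTIONAL_MODELS = ("cnn", "gnn")

#: Final hyperparameter configurations for each model family.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "ridge": {"alpha": 1.0},
    "linear_svr": {"C": 0.1, "epsilon": 0.01},
    "extra_trees": {"n_estimators": 200, "max_depth": None},
    "lightgbm": {"learning_rate": 0.05, "n_estimators": 300, "max_depth": 7, "num_leaves": 31},
    "xgboost": {"learning_rate": 0.1, "n_estimators": 200, "max_depth": 6, "reg_alpha": 0.0, "subsample": 0.8},
    "random_forest": {"n_estimators": 150, "max_depth": None},
}

#: Small default grids centred on the final configurations.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ridge": {"alpha": [0.1, 1.0, 10.0]},
    "linear_svr": {"C": [0.1, 1.0]},
    "extra_trees": {},
    "lightgbm": {},
    "xgboost": {},
    "random_forest": {},
}


@dataclass
class ModelSpec:
    """One model family with its hyperparameters and (optional) search grid."""

    name: str
    hyperparams: dict = field(default_factory=dict)
    grid: dict[str, list] = field(default_factory=dict)

    @classmethod
    def default(cls, name: str, with_grid: bool = True) -> "ModelSpec":
        if name not in DEFAULT_HYPERPARAMS and name not in OPTIONAL_MODELS:
            raise ValueError(f"unknown model family {name!r}")
        return cls(
            name=name,
            hyperparams=dict(DEFAULT_HYPERPARAMS.get(name, {})),
            grid=dict(DEFAULT_GRIDS.get(name, {})) if with_grid else {},
        )


def default_specs(with_grid: bool = True, names: Sequence[str] = MANDATORY_MODELS) -> list[ModelSpec]:
    return [ModelSpec.default(n, with_grid=with_grid) for n in names]


def _make_estimator(spec: ModelSpec, seed: int):
    p = spec.hyperparams
    if spec.name == "ridge":
        return Ridge(**p)
    if spec.name == "linear_svr":
        return LinearSVR(max_iter=20000, random_state=seed, **p)
    if spec.name == "extra_trees":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **p)
    if spec.name == "lightgbm":
        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **p)
    if spec.name == "xgboost":
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **p)
    if spec.name == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **p)
    return None  # optional families without an available backend


def split_train_test(n: int, test_fraction: float = 0.2, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seed-reproducible train/test index partition."""
    if n < 5:
        raise ValueError(f"need at least 5 samples, got {n}")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    if n_test >= n:
        raise ValueError("test fraction leaves no training data")
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def classification_metrics(
    y_true_pic50: np.ndarray, y_pred_pic50: np.ndarray, threshold: float = HIGH_THRESHOLD
) -> dict:
    """Accuracy/precision/recall/F1 after discretising at pIC50 > threshold.

    Precision and recall are taken on the high class; degenerate cases
    (no predicted or no true positives) are flagged ``undefined`` rather
    than propagating NaN.
    """
    y_true = np.asarray(y_true_pic50, dtype=float)
    y_pred = np.asarray(y_pred_pic50, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    t = y_true > threshold
    p = y_pred > threshold
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    out: dict = {"accuracy": float(np.mean(t == p))}
    out["precision"] = tp / (tp + fp) if (tp + fp) > 0 else None
    out["recall"] = tp / (tp + fn) if (tp + fn) > 0 else None
    if out["precision"] is not None and out["recall"] is not None and (out["precision"] + out["recall"]) > 0:
        out["f1"] = 2 * out["precision"] * out["recall"] / (out["precision"] + out["recall"])
    else:
        out["f1"] = None
    out["undefined"] = sorted(k for k in ("precision", "recall", "f1") if out[k] is None)
    return out


class FitRecorder:
    """Instrumentation hook recording the row indices of every fit/score call.

    Used to assert that grid search and CV never touch the held-out test
    rows before final scoring.
    """

    def __init__(self) -> None:
        self.calls: list[tuple[str, str, np.ndarray]] = []

    def record(self, model: str, stage: str, indices: np.ndarray) -> None:
        self.calls.append((model, stage, np.asarray(indices).copy()))


@dataclass
class EvalReport:
    """Per-model metrics, predictions, fold assignments and metadata."""

    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    fold_assignments: np.ndarray  # fold id per training-row position
    models: dict[str, dict] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        payload = {
            "seed": self.seed,
            "train_idx": self.train_idx,
            "test_idx": self.test_idx,
            "fold_assignments": self.fold_assignments,
            "models": self.models,
            "skipped": self.skipped,
            "metadata": self.metadata,
        }
        return json.dumps(payload, default=conv, indent=2)

    def metrics_frame(self):
        import pandas as pd

        rows = []
        for name, m in self.models.items():
            rows.append(
                {
                    "model": name,
                    "train_mae": m["train_mae"],
                    "test_mae": m["test_mae"],
                    "train_r2": m["train_r2"],
                    "test_r2": m["test_r2"],
                    "cv_accuracy": m["cv_classification"]["accuracy"],
                    "cv_f1": m["cv_classification"]["f1"],
                    "test_accuracy": m["test_classification"]["accuracy"],
                    "test_f1": m["test_classification"]["f1"],
                }
            )
        return pd.DataFrame(rows)


def train_and_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    n_folds: int = 5,
    recorder: FitRecorder | None = None,
) -> EvalReport:
    """Fit every requested model with grid search in K-fold CV; score on test.

    The test split is untouched until final scoring.  CV classification
    metrics discretise the per-fold predictions (pooled over folds);
    this convention is recorded in the report metadata.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if specs is None:
        specs = default_specs()
    train_idx, test_idx = split_train_test(X.shape[0], test_fraction, seed)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(Xtr))
    fold_assignments = np.empty(len(train_idx), dtype=int)
    for f, (_, val) in enumerate(folds):
        fold_assignments[val] = f

    report = EvalReport(
        seed=seed,
        train_idx=train_idx,
        test_idx=test_idx,
        fold_assignments=fold_assignments,
        metadata={
            "n_folds": n_folds,
            "test_fraction": test_fraction,
            "cv_classification_convention": "per-fold predictions pooled over folds, then discretised",
        },
    )

    for spec in specs:
        est = _make_estimator(spec, seed)
        if est is None:
            report.skipped[spec.name] = "backend unavailable (optional neural family)"
            continue
        if spec.grid:
            search = GridSearchCV(est, spec.grid, cv=folds, scoring="neg_mean_absolute_error", n_jobs=1, refit=False)
            if recorder is not None:
                for tr_f, _ in folds:
                    recorder.record(spec.name, "grid_fit", train_idx[tr_f])
            search.fit(Xtr, ytr)
            best = dict(spec.hyperparams)
            best.update(search.best_params_)
            est = _make_estimator(ModelSpec(spec.name, best), seed)
            chosen = best
        else:
            chosen = dict(spec.hyperparams)

        # out-of-fold predictions with the chosen configuration
        oof = np.empty(len(ytr))
        for tr_f, val_f in folds:
            fold_est = _make_estimator(ModelSpec(spec.name, chosen), seed)
            if recorder is not None:
                recorder.record(spec.name, "cv_fit", train_idx[tr_f])
            fold_est.fit(Xtr[tr_f], ytr[tr_f])
            oof[val_f] = fold_est.predict(Xtr[val_f])

        if recorder is not None:
            recorder.record(spec.name, "final_fit", train_idx)
        est.fit(Xtr, ytr)
        pred_tr = est.predict(Xtr)
        pred_te = est.predict(Xte)
        report.models[spec.name] = {
            "hyperparams": chosen,
            "train_mae": float(mean_absolute_error(ytr, pred_tr)),
            "test_mae": float(mean_absolute_error(yte, pred_te)),
            "train_rmse": float(np.sqrt(np.mean((ytr - pred_tr) ** 2))),
            "test_rmse": float(np.sqrt(np.mean((yte - pred_te) ** 2))),
            "train_r2": float(r2_score(ytr, pred_tr)),
            "test_r2": float(r2_score(yte, pred_te)),
            "cv_mae": float(mean_absolute_error(ytr, oof)),
            "cv_r2": float(r2_score(ytr, oof)),
            "cv_classification": classification_metrics(ytr, oof),
            "test_classification": classification_metrics(yte, pred_te),
            "predictions": {"train": pred_tr, "test": pred_te, "oof": oof},
            "_estimator": est,
        }
    return report


def perturbation_analysis(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    intensities: Sequence[float],
    repeats: int = 20,
    seed: int = 0,
) -> dict:
    """MAE/R² versus additive-Gaussian input perturbation intensity.

    Noise is N(0, intensity) added to the (standardised) feature matrix;
    intensity 0 reproduces the baseline metrics exactly (no noise draw),
    and each positive intensity averages ``repeats`` draws.
    """
    intensities = list(intensities)
    if not intensities:
        raise ValueError("intensity list is empty")
    if intensities[0] != 0:
        raise ValueError("intensities must start at 0 (the baseline)")
    if sorted(intensities) != intensities:
        raise ValueError("intensities must be increasing")
    rng = np.random.default_rng(seed)
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    maes, r2s = [], []
    for s in intensities:
        if s == 0:
            pred = model.predict(X_test)
            maes.append(float(mean_absolute_error(y_test, pred)))
            r2s.append(float(r2_score(y_test, pred)))
            continue
        m_acc, r_acc = 0.0, 0.0
        for _ in range(repeats):
            pred = model.predict(X_test + rng.normal(0.0, s, size=X_test.shape))
            m_acc += mean_absolute_error(y_test, pred)
            r_acc += r2_score(y_test, pred)
        maes.append(m_acc / repeats)
        r2s.append(r_acc / repeats)
    return {"intensity": intensities, "mae": maes, "r2": r2s, "repeats": repeats, "seed": seed}


def taylor_stats(y_true: np.ndarray, predictions: dict[str, np.ndarray]) -> dict[str, dict]:
    """Taylor-diagram statistics per model: sd, correlation, centred RMSE.

    The identity crmse² = sd_pred² + sd_obs² − 2·sd_pred·sd_obs·corr holds
    by construction (population standard deviations).
    """
    y = np.asarray(y_true, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    sd_obs = float(y.std())
    if sd_obs == 0:
        raise ValueError("observations have zero variance")
    out: dict[str, dict] = {}
    for name, pred in predictions.items():
        p = np.asarray(pred, dtype=float)
        if p.shape != y.shape:
            raise ValueError(f"prediction shape mismatch for {name!r}")
        sd_pred = float(p.std())
        if sd_pred == 0:
            corr = 0.0  # flagged: constant predictions carry no pattern
        else:
            corr = float(np.corrcoef(y, p)[0, 1])
        crmse = float(np.sqrt(np.mean(((p - p.mean()) - (y - y.mean())) ** 2)))
        out[name] = {
            "sd_pred": sd_pred,
            "sd_obs": sd_obs,
            "corr": corr,
            "centered_rmse": crmse,
            "degenerate": sd_pred == 0,
        }
    return out
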