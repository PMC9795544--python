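"""Gradient-boosted QSAR/PCM models, the 16-flavor model grid and 5-fold CV.

The model grid crosses two engines (conformal prediction, gradient
boosting), two descriptor modes (ligand-only QSAR, ligand+protein PCM) and
four scopes (general plus one selective model per transporter), giving 16
model flavors.  Selective scopes label a compound active only when it is
active on the chosen transporter and inactive on the other two wherever
data exist.

Gradient boosting defaults follow the settings used for the original
screen: 100 trees, learning rate 0.3, max depth 7, full row sampling, 70%
column sampling, tree booster, seed 12345.  PCM gradient-boosted models
can be run either as classifiers or as pActivity regressors binarized at
6.5 log units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier, XGBRegressor

from .chem_data import ACTIVE, TARGETS

ENGINE_CP = "CP"
ENGINE_GB = "GB"
SCOPE_GENERAL = "general"

#: pActivity call threshold for regression models (~300 nM).
PACTIVITY_THRESHOLD = 6.5


@dataclass
class GBConfig:
    max_trees: int = 100
    learning_rate: float = 0.3
    max_depth: int = 7
    row_fraction: float = 1.0
    column_fraction: float = 0.7
    booster: str = "gbtree"
    seed: int = 12345


@dataclass(frozen=True)
class ModelSpec:
    engine: str          # CP | GB
    descriptor_mode: str  # QSAR | PCM
    scope: str           # general | one of TARGETS

    def __post_init__(self) -> None:
        if self.engine not in (ENGINE_CP, ENGINE_GB):
            raise ValueError(f"engine must be CP or GB, got {self.engine!r}")
        if self.descriptor_mode not in ("QSAR", "PCM"):
            raise ValueError(f"descriptor_mode must be QSAR or PCM")
        if self.scope != SCOPE_GENERAL and self.scope not in TARGETS:
            raise ValueError(f"scope must be 'general' or one of {TARGETS}")

    @property
    def name(self) -> str:
        return f"{self.engine}-{self.descriptor_mode}-{self.scope}"


def enumerate_model_grid() -> list[ModelSpec]:
    """All 16 model flavors: 2 engines x 2 descriptor modes x 4 scopes."""
    return [
        ModelSpec(engine=e, descriptor_mode=d, scope=s)
        for e, d, s in itertools.product(
            (ENGINE_CP, ENGINE_GB), ("QSAR", "PCM"), (SCOPE_GENERAL,) + TARGETS
        )
    ]


def load_model_grid(path) -> list[ModelSpec]:
    """Read a YAML list of {engine, descriptor_mode, scope} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [ModelSpec(**entry) for entry in raw]


# ---------------------------------------------------------------------------
# scope labels

def make_labels_for_scope(labels: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Binary labels for one model scope from consolidated per-target labels.

    ``labels`` has columns compound_id, target, label.  Returns a DataFrame
    with columns compound_id (and target for PCM general) and y in {0, 1}.

    General scope: PCM keeps every (compound, target) row with its own
    label; QSAR marks a compound active when it is active on any target.
    Selective scope: active iff active on the chosen target AND inactive on
    both others wherever data exist; compounds without data on the chosen
    target are excluded.
    """
    wide = labels.pivot_table(
        index="compound_id", columns="target", values="label", aggfunc="first"
    )
    if spec.scope == SCOPE_GENERAL:
        if spec.descriptor_mode == "PCM":
            out = labels[["compound_id", "target"]].copy()
            out["y"] = (labels["label"] == ACTIVE).astype(int)
            return out.reset_index(drop=True)
        y = (wide == ACTIVE).any(axis=1).astype(int)
        return pd.DataFrame({"compound_id": wide.index, "y": y.values})
    chosen = spec.scope
    if chosen not in wide.columns:
        raise ValueError(f"no data for target {chosen}")
    has_data = wide[chosen].notna()
    sub = wide[has_data]
    active_on_chosen = sub[chosen] == ACTIVE
    others = [t for t in TARGETS if t != chosen and t in wide.columns]
    inactive_elsewhere = pd.Series(True, index=sub.index)
    for t in others:
        inactive_elsewhere &= (sub[t] != ACTIVE) | sub[t].isna()
    y = (active_on_chosen & inactive_elsewhere).astype(int)
    return pd.DataFrame({"compound_id": sub.index, "y": y.values})


# ---------------------------------------------------------------------------
# gradient boosting

def _xgb_params(config: GBConfig) -> dict:
    return dict(
        n_estimators=config.max_trees,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        subsample=config.row_fraction,
        colsample_bytree=config.column_fraction,
        booster=config.booster,
        random_state=config.seed,
        tree_method="hist",
        n_jobs=1,
    )


def fit_gb(X, y, config: GBConfig | None = None, task: str = "classify"):
    """Fit a gradient-boosted tree model; deterministic under a fixed seed.

    ``task='classify'`` expects binary labels and exposes ``predict_proba``;
    ``task='regress'`` expects numeric responses (pActivity) and exposes
    ``predict``.
    """
    config = config or GBConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if task == "classify":
        if np.unique(y).size < 2:
            raise ValueError("labels are constant; cannot fit a classifier")
        model = XGBClassifier(**_xgb_params(config), eval_metric="logloss")
    elif task == "regress":
        model = XGBRegressor(**_xgb_params(config))
    else:
        raise ValueError(f"task must be 'classify' or 'regress', got {task!r}")
    model.fit(X, y.astype(float) if task == "regress" else y.astype(int))
    return model


def gb_scores(model, X) -> np.ndarray:
    """Ranking score: P(active) for classifiers, predicted pActivity for regressors."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(np.asarray(X, dtype=float))
        col = int(np.flatnonzero(model.classes_ == 1)[0])
        return proba[:, col]
    return model.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVReport:
    roc_auc: float
    sensitivity: float
    specificity: float
    fold_roc: list[float] = field(default_factory=list)
    oof_scores: np.ndarray | None = None


FitScoreFn = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def gb_fit_score(config: GBConfig | None = None) -> FitScoreFn:
    def fn(X_tr, y_tr, X_te):
        model = fit_gb(X_tr, y_tr, config=config, task="classify")
        return gb_scores(model, X_te)

    return fn


def cp_fit_score(cp_config) -> FitScoreFn:
    """Score held-out rows by the aggregated conformal p-value for 'active'."""
    from . import conformal

    def fn(X_tr, y_tr, X_te):
        ensemble = conformal.fit_acp(X_tr, y_tr, cp_config)
        return conformal.ensemble_pvalues(X_te, ensemble)[:, 1]

    return fn


def crossvalidate(
    X,
    y,
    fit_score: FitScoreFn | None = None,
    k: int = 5,
    threshold: float = 0.5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV with pooled out-of-fold scoring.

    Pooled scores give the ROC AUC; thresholding them gives the confusion
    matrix from which sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP)
    are computed.  Default threshold 0.5 suits probability-like scores; use
    6.5 for pActivity-scale regressors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the minority class count {counts.min()}")
    fit_score = fit_score or gb_fit_score()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(len(y), dtype=float)
    fold_roc = []
    for tr, te in skf.split(X, y):
        scores = fit_score(X[tr], y[tr], X[te])
        oof[te] = scores
        if np.unique(y[te]).size == 2:
            fold_roc.append(float(roc_auc_score(y[te], scores)))
    roc = float(roc_auc_score(y, oof))
    calls = oof > threshold
    tp = int(np.sum(calls & (y == 1)))
    fn_ = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    fp = int(np.sum(calls & (y == 0)))
    sens = tp / (tp + fn_) if (tp + fn_) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return CVReport(
        roc_auc=roc, sensitivity=sens, specificity=spec, fold_roc=fold_roc, oof_scores=oof
    )


def write_cv_table(path, reports: dict[str, CVReport]) -> None:
    """CV summary TSV: model, ROC, sensitivity, specificity."""
    rows = [
        (name, r.roc_auc, r.sensitivity, r.specificity) for name, r in reports.items()
    ]
    pd.DataFrame(rows, columns=["model", "roc", "sensitivity", "specificity"]).to_csv(
        path, sep="\t", index=False
    )
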