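"""Mondrian aggregated conformal prediction for binary activity.

A conformal predictor turns any point classifier into a set-valued
predictor with a finite-sample error guarantee: at significance level
epsilon, the prediction region misses the true class at most an
epsilon-fraction of the time, provided the data are exchangeable.
"Mondrian" means the calibration is class-conditional, so the guarantee
holds per class even under heavy imbalance — essential for bioactivity
data where actives are the minority.

The underlying model is a random forest; the conformity score of a
compound for a class is the fraction of trees voting for that class.
Each ensemble member draws an independent proper-training (70%) /
calibration (20%) split, and a compound's final p-value per class is the
median over the members' p-values (aggregated conformal prediction, 20
members by default).  The remaining 10% of each split is held out
entirely.

p-values use the conservative smoothed rank rule
``(#{calibration scores <= score} + 1) / (n_calib + 1)``; the strict,
unsmoothed variant (fraction of calibration scores strictly below) is
available via ``smoothing=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

ACTIVE_CLASS = 1
INACTIVE_CLASS = 0

REGION_ACTIVE = "active"
REGION_INACTIVE = "inactive"
REGION_BOTH = "both"
REGION_EMPTY = "empty"


@dataclass
class CPConfig:
    epsilon: float = 0.2
    n_members: int = 20
    proper_frac: float = 0.70
    calib_frac: float = 0.20
    n_trees: int = 100
    seed: int = 0
    smoothing: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must lie in (0, 1)")
        if self.proper_frac + self.calib_frac > 1.0 + 1e-9:
            raise ValueError("proper_frac + calib_frac must not exceed 1")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


@dataclass
class CPMember:
    forest: RandomForestClassifier
    calib_scores: dict[int, np.ndarray]  # class -> sorted conformity scores


@dataclass
class CPEnsemble:
    config: CPConfig
    members: list[CPMember] = field(default_factory=list)


@dataclass
class CPEvaluation:
    validity: dict[int, float]
    efficiency: dict[int, float]
    n_single: int
    n_both: int
    n_empty: int

    @property
    def n_total(self) -> int:
        return self.n_single + self.n_both + self.n_empty


def member_pvalue(new_score: float, calib_scores: np.ndarray, smoothing: bool = True) -> float:
    """Conformal p-value of ``new_score`` against one class's calibration scores.

    Smoothed (default): ``(#{<= new} + 1) / (n + 1)`` — ties count toward the
    p-value and the +1 keeps the finite-sample guarantee.  Unsmoothed:
    ``#{< new} / n`` (the literal "fraction with lower probabilities").
    """
    calib = np.asarray(calib_scores, dtype=float)
    if calib.size == 0:
        raise ValueError("empty calibration score list")
    calib = np.sort(calib)
    if smoothing:
        count_le = int(np.searchsorted(calib, new_score, side="right"))
        return (count_le + 1) / (calib.size + 1)
    count_lt = int(np.searchsorted(calib, new_score, side="left"))
    return count_lt / calib.size


def fit_acp(X, y, config: CPConfig, max_retries: int = 25) -> CPEnsemble:
    """Fit a Mondrian aggregated conformal predictor.

    Each member shuffles the data with its own seed (derived from the global
    seed and the member index), trains a forest on the proper fraction and
    keeps class-conditional calibration scores from the calibration fraction.
    A split whose calibration set misses a class is redrawn, up to
    ``max_retries`` times.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if set(classes) - {INACTIVE_CLASS, ACTIVE_CLASS} or classes.size < 2:
        raise ValueError("y must contain both classes coded as {0, 1}")
    n = len(y)
    n_proper = int(round(config.proper_frac * n))
    n_calib = int(round(config.calib_frac * n))
    if n_proper < 2 or n_calib < 2:
        raise ValueError("dataset too small for the requested split fractions")

    ensemble = CPEnsemble(config=config)
    for m in range(config.n_members):
        member_seed = (config.seed * 100_003 + m) % (2**31 - 1)
        rng = np.random.default_rng(member_seed)
        for attempt in range(max_retries):
            perm = rng.permutation(n)
            proper_idx = perm[:n_proper]
            calib_idx = perm[n_proper : n_proper + n_calib]
            y_cal = y[calib_idx]
            if (y_cal == ACTIVE_CLASS).any() and (y_cal == INACTIVE_CLASS).any():
                break
        else:
            raise RuntimeError(
                f"member {m}: calibration set missing a class after {max_retries} redraws"
            )
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, random_state=member_seed
        )
        forest.fit(X[proper_idx], y[proper_idx])
        proba = forest.predict_proba(X[calib_idx])
        col = {c: i for i, c in enumerate(forest.classes_)}
        calib_scores = {}
        for c in (INACTIVE_CLASS, ACTIVE_CLASS):
            scores = proba[y_cal == c, col[c]]
            calib_scores[c] = np.sort(scores)
        ensemble.members.append(CPMember(forest=forest, calib_scores=calib_scores))
    return ensemble


def ensemble_pvalues(X, ensemble: CPEnsemble) -> np.ndarray:
    """Median-over-members p-values, shape (n, 2): columns (p_inactive, p_active)."""
    X = np.asarray(X, dtype=float)
    smoothing = ensemble.config.smoothing
    all_p = np.empty((len(ensemble.members), X.shape[0], 2))
    for mi, member in enumerate(ensemble.members):
        proba = member.forest.predict_proba(X)
        col = {c: i for i, c in enumerate(member.forest.classes_)}
        for ci, c in enumerate((INACTIVE_CLASS, ACTIVE_CLASS)):
            calib = member.calib_scores[c]
            scores = proba[:, col[c]]
            if smoothing:
                counts = np.searchsorted(calib, scores, side="right")
                all_p[mi, :, ci] = (counts + 1) / (calib.size + 1)
            else:
                counts = np.searchsorted(calib, scores, side="left")
                all_p[mi, :, ci] = counts / calib.size
    return np.median(all_p, axis=0)


def region_from_pvalues(p_inactive: float, p_active: float, epsilon: float) -> str:
    """Prediction region at significance epsilon: classes with p > epsilon."""
    inc_a = p_active > epsilon
    inc_i = p_inactive > epsilon
    if inc_a and inc_i:
        return REGION_BOTH
    if inc_a:
        return REGION_ACTIVE
    if inc_i:
        return REGION_INACTIVE
    return REGION_EMPTY


def predict_region(X, ensemble: CPEnsemble, epsilon: float | None = None) -> pd.DataFrame:
    """Predict p-values and regions for a feature matrix.

    Returns a DataFrame with columns p_inactive, p_active, region.
    """
    eps = ensemble.config.epsilon if epsilon is None else epsilon
    p = ensemble_pvalues(X, ensemble)
    regions = [region_from_pvalues(pi, pa, eps) for pi, pa in p]
    return pd.DataFrame(
        {"p_inactive": p[:, 0], "p_active": p[:, 1], "region": regions}
    )


def evaluate_cp(regions, y_true, epsilon: float | None = None) -> CPEvaluation:
    """Per-class validity and efficiency of a set of region predictions.

    A prediction is correct when its region contains the true class: "both"
    regions are always correct, "empty" ones never.  Efficiency for class c
    is the fraction of class-c examples receiving a single-class region,
    correct or not.
    """
    regions = list(regions)
    y_true = np.asarray(y_true, dtype=int)
    if len(regions) != len(y_true):
        raise ValueError("regions and labels differ in length")
    class_region = {ACTIVE_CLASS: REGION_ACTIVE, INACTIVE_CLASS: REGION_INACTIVE}
    validity, efficiency = {}, {}
    for c in (INACTIVE_CLASS, ACTIVE_CLASS):
        mask = y_true == c
        if not mask.any():
            validity[c] = float("nan")
            efficiency[c] = float("nan")
            continue
        sub = [regions[i] for i in np.flatnonzero(mask)]
        contains = sum(1 for r in sub if r in (class_region[c], REGION_BOTH))
        single = sum(1 for r in sub if r in (REGION_ACTIVE, REGION_INACTIVE))
        validity[c] = contains / len(sub)
        efficiency[c] = single / len(sub)
    n_single = sum(1 for r in regions if r in (REGION_ACTIVE, REGION_INACTIVE))
    n_both = sum(1 for r in regions if r == REGION_BOTH)
    n_empty = sum(1 for r in regions if r == REGION_EMPTY)
    return CPEvaluation(
        validity=validity,
        efficiency=efficiency,
        n_single=n_single,
        n_both=n_both,
        n_empty=n_empty,
    )
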