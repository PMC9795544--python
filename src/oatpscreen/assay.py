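"""Transport-assay analytics: normalization, screen categories, IC50 fits.

The inhibition assay measures substrate uptake (fluorescence) in
transporter-overexpressing cells.  Transporter-specific transport is the
raw signal minus the mock-transfected background, expressed as a
percentage of the no-compound control.  A three-concentration screen
(~1/10/100 uM) assigns each compound a potency category from the lowest
concentration reaching 50% inhibition; full eight-point curves are fitted
with the one-site Hill model

    T(c) = bottom + (top - bottom) / (1 + (c / IC50)^n)

to extract IC50 values, from which per-target hit rates and selectivity
folds are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

CAT_BELOW_1 = "below_1uM"
CAT_1_TO_10 = "1_to_10uM"
CAT_ABOVE_10 = "above_10uM"
CAT_NO_EFFECT = "no_effect"
CAT_ACTIVATOR = "activator"

#: Normalized transport at or below this is "50% inhibition".
INHIBITION_TRANSPORT = 50.0
#: Transport at or above this (with no inhibition anywhere) marks an activator.
ACTIVATOR_TRANSPORT = 120.0
#: Transport at the top concentration must be at or below this for the
#: above_10uM call; otherwise the compound is a no-effect.
PARTIAL_INHIBITION_TRANSPORT = 75.0


@dataclass
class DoseResponseSeries:
    compound_id: str
    target: str
    concentrations_uM: np.ndarray
    transport_pct: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_uM, dtype=float)
        t = np.asarray(self.transport_pct, dtype=float)
        if c.size == 0:
            raise ValueError("empty dose-response series")
        if c.size != t.size:
            raise ValueError("concentration and transport arrays differ in length")
        if (c <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.diff(c) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.isfinite(t).all():
            raise ValueError("transport values must be finite")
        self.concentrations_uM = c
        self.transport_pct = t


@dataclass
class HillFit:
    bottom: float
    top: float
    ic50_uM: float
    hill_n: float
    rss: float
    converged: bool


def normalize_transport(raw: float, mock_raw: float, control_specific: float):
    """Transporter-specific transport as % of the no-compound control.

    ``control_specific`` is the control signal minus the mock background;
    it must be positive for the normalization to be meaningful.
    """
    control_specific = np.asarray(control_specific, dtype=float)
    if np.any(control_specific <= 0):
        raise ValueError("control-specific signal must be positive")
    out = 100.0 * (np.asarray(raw, dtype=float) - np.asarray(mock_raw, dtype=float)) / control_specific
    return float(out) if out.ndim == 0 else out


def categorize_three_point(series: DoseResponseSeries) -> str:
    """Potency category from a short (>=2 point) concentration screen.

    The category is the bin of the lowest tested concentration at which
    transport falls to 50% or below (<=1 uM, 1–10 uM, >10 uM).  Compounds
    never reaching 50% are activators when transport exceeds the activator
    threshold anywhere, otherwise above_10uM when the top concentration
    shows a partial-inhibition trend (transport <= 75%), else no_effect.
    """
    c = series.concentrations_uM
    t = series.transport_pct
    if c.size < 2:
        raise ValueError("three-point categorization needs >= 2 concentrations")
    inhibited = np.flatnonzero(t <= INHIBITION_TRANSPORT)
    if inhibited.size:
        c_first = c[inhibited[0]]
        if c_first <= 1.0:
            return CAT_BELOW_1
        if c_first <= 10.0:
            return CAT_1_TO_10
        return CAT_ABOVE_10
    if (t >= ACTIVATOR_TRANSPORT).any():
        return CAT_ACTIVATOR
    if t[-1] <= PARTIAL_INHIBITION_TRANSPORT:
        return CAT_ABOVE_10
    return CAT_NO_EFFECT


# ---------------------------------------------------------------------------
# Hill fitting

def hill_curve(c, bottom, top, ic50, n):
    """One-site Hill (sigmoid) inhibition curve on a linear transport scale."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** n)


def fit_hill1(series: DoseResponseSeries) -> HillFit:
    """Least-squares Hill fit of a dose-response series.

    Initialization: top = max(y), bottom = min(y), IC50 at the tested
    concentration nearest the half-maximal transport, n = 1.  Bounds keep
    IC50 within [c_min/100, c_max*100] and n within [0.1, 10].  A
    monotone-increasing series cannot be an inhibition curve and is
    rejected; non-convergence yields a flagged fit with NaN IC50.
    """
    c = series.concentrations_uM
    y = series.transport_pct
    if c.size < 4:
        raise ValueError("Hill fit needs at least 4 points")
    if np.all(np.diff(y) >= 0):
        raise ValueError(
            f"{series.compound_id}/{series.target}: transport increases with "
            "concentration; not an inhibition curve"
        )
    top0, bot0 = float(y.max()), float(y.min())
    half = (top0 + bot0) / 2.0
    ic50_0 = float(c[np.argmin(np.abs(y - half))])
    lower = [-50.0, 0.0, c.min() / 100.0, 0.1]
    upper = [100.0, 200.0, c.max() * 100.0, 10.0]
    p0 = [
        np.clip(bot0, lower[0], upper[0]),
        np.clip(top0, lower[1], upper[1]),
        np.clip(ic50_0, lower[2], upper[2]),
        1.0,
    ]
    try:
        popt, _ = curve_fit(
            hill_curve, c, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError:
        logger.warning("Hill fit did not converge for %s/%s", series.compound_id, series.target)
        return HillFit(float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), False)
    bottom, top, ic50, n = (float(v) for v in popt)
    if bottom > top:
        bottom, top = top, bottom
    rss = float(np.sum((hill_curve(c, *popt) - y) ** 2))
    return HillFit(bottom=bottom, top=top, ic50_uM=ic50, hill_n=n, rss=rss, converged=True)


# ---------------------------------------------------------------------------
# reporting

ACTIVE = "active"
INACTIVE = "inactive"
ACTIVATOR = "activator"


def hit_rate(outcomes: dict[str, str]) -> tuple[int, int, int, int]:
    """Percent of tested compounds confirmed active, plus the raw counts.

    ``outcomes`` maps compound_id to one of {active, inactive, activator};
    activators count as tested but never as active.  Returns
    (percent, n_active, n_inactive, n_activator) with the percent rounded
    to the nearest integer.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    vals = list(outcomes.values())
    bad = set(vals) - {ACTIVE, INACTIVE, ACTIVATOR}
    if bad:
        raise ValueError(f"unknown outcomes: {sorted(bad)}")
    n_act = vals.count(ACTIVE)
    n_inact = vals.count(INACTIVE)
    n_activ = vals.count(ACTIVATOR)
    pct = int(round(100.0 * n_act / len(vals)))
    return pct, n_act, n_inact, n_activ


def selectivity_fold(ic50_map: dict[str, float]) -> dict[str, float]:
    """Fold loss of potency of every target relative to the most potent one.

    ``ic50_map`` maps target -> IC50 (uM).  The best (lowest) IC50 defines
    the reference; each fold is ic50_target / ic50_best, so the reference
    itself reports 1.0.
    """
    finite = {t: v for t, v in ic50_map.items() if v is not None and math.isfinite(v)}
    if len(finite) < 2:
        raise ValueError("selectivity folds need >= 2 finite IC50 values")
    if any(v <= 0 for v in finite.values()):
        raise ValueError("IC50 values must be positive")
    best = min(finite.values())
    return {t: v / best for t, v in finite.items()}


# ---------------------------------------------------------------------------
# plate I/O

PLATE_COLUMNS = ["compound_id", "target", "concentration_uM", "raw", "mock_raw", "control_raw"]


def read_plate_csv(path) -> list[DoseResponseSeries]:
    """Read raw plate measurements and normalize to transport percentages.

    Expected columns: compound_id, target, concentration_uM, raw, mock_raw,
    control_raw (the no-compound control signal in transporter cells).
    """
    df = pd.read_csv(path)
    missing = [col for col in PLATE_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"plate CSV missing columns: {missing}")
    out = []
    for (cid, target), sub in df.groupby(["compound_id", "target"], sort=True):
        sub = sub.sort_values("concentration_uM")
        pct = normalize_transport(
            sub["raw"].to_numpy(),
            sub["mock_raw"].to_numpy(),
            sub["control_raw"].to_numpy() - sub["mock_raw"].to_numpy(),
        )
        out.append(
            DoseResponseSeries(
                compound_id=str(cid),
                target=str(target),
                concentrations_uM=sub["concentration_uM"].to_numpy(),
                transport_pct=np.asarray(pct),
            )
        )
    return out


def ic50_table(fits: dict[tuple[str, str], HillFit]) -> pd.DataFrame:
    """Wide IC50 table: one row per compound, one column per target."""
    rows: dict[str, dict[str, float]] = {}
    for (cid, target), fit in fits.items():
        rows.setdefault(cid, {})[target] = fit.ic50_uM if fit.converged else float("nan")
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
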