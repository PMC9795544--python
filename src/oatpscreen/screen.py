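"""Library screening bookkeeping: activity calls, top-k ranking, consensus.

Each of the 16 model flavors scores the screening library on its own scale
(pActivity for regressors, P(active) for classifiers, the conformal
p-value for the active class for CP models).  Per model, predicted actives
are ranked best-first and the top k (default 250) kept; the union of the
per-model lists, with duplicate removal and nominating-model provenance,
forms the consensus set carried forward to docking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Predicted pActivity above which a regression-scale prediction is called
#: active (~300 nM); strictly greater than.
PACTIVITY_CALL = 6.5
#: Probability threshold for classifier-scale calls.
PROBABILITY_CALL = 0.5
DEFAULT_TOP_K = 250


@dataclass
class ConsensusSet:
    """Deduplicated compound ids with nominating-model provenance."""

    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "nominated_by": [",".join(self.provenance[c]) for c in self.compound_ids],
            }
        )


def call_actives(scores, threshold: float = PACTIVITY_CALL) -> np.ndarray:
    """Boolean active calls: score strictly greater than the threshold.

    The default threshold is the 6.5 log-unit pActivity call; pass
    :data:`PROBABILITY_CALL` for probability-scale classifier scores.
    """
    return np.asarray(scores, dtype=float) > threshold


def top_k_per_model(
    predictions: pd.DataFrame, k: int = DEFAULT_TOP_K, threshold: float | None = None
) -> dict[str, list[str]]:
    """Top-k predicted actives per model, best score first.

    ``predictions`` has columns compound_id, model, score and optionally a
    boolean is_active_call column; when ``threshold`` is given the call is
    recomputed as score > threshold.  Ties are broken by compound_id so the
    selection is deterministic.  Models with fewer than k predicted actives
    contribute all of them.
    """
    df = predictions.copy()
    if threshold is not None:
        df["is_active_call"] = call_actives(df["score"], threshold)
    elif "is_active_call" not in df.columns:
        raise ValueError("predictions need an is_active_call column or a threshold")
    out: dict[str, list[str]] = {}
    for model, sub in df.groupby("model", sort=True):
        act = sub[sub["is_active_call"]]
        act = act.sort_values(["score", "compound_id"], ascending=[False, True])
        out[model] = act["compound_id"].head(k).tolist()
    return out


def consensus_union(per_model_lists: dict[str, list[str]]) -> ConsensusSet:
    """Union of the per-model selections with provenance, duplicates removed."""
    cs = ConsensusSet()
    for model in sorted(per_model_lists):
        for cid in per_model_lists[model]:
            cs.provenance.setdefault(cid, []).append(model)
    return cs


def library_fraction(count: int, library_size: int) -> float:
    """Percentage of the screened library, rounded to two decimals."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if not (0 <= count <= library_size):
        raise ValueError("count must lie in [0, library_size]")
    return round(100.0 * count / library_size, 2)


def summarize_screen(
    predictions: pd.DataFrame, library_size: int, threshold: float | None = None
) -> pd.DataFrame:
    """Per-model predicted-active counts and library percentages."""
    df = predictions.copy()
    if threshold is not None:
        df["is_active_call"] = call_actives(df["score"], threshold)
    rows = []
    for model, sub in df.groupby("model", sort=True):
        n_act = int(sub["is_active_call"].sum())
        rows.append((model, n_act, library_fraction(n_act, library_size)))
    return pd.DataFrame(rows, columns=["model", "n_active", "pct_of_library"])
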