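"""Compound standardization, activity labeling and dataset assembly.

Bioactivity records for the three hepatic uptake transporters OATP1B1,
OATP1B3 and OATP2B1 arrive as (compound, target, endpoint, value, units)
rows.  Compounds are standardized to a canonical parent structure and every
(compound, target) pair receives a single active/inactive label using the
10 uM potency cutoff that is conventional for transporter inhibition data:
a concentration endpoint strictly below 10 uM is "active", anything at or
above it "inactive".  Percentage-inhibition records are mapped onto the
same scale (>= 50% inhibition at a test concentration <= 10 uM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

#: The three hepatic organic anion transporting polypeptides modelled here.
TARGETS = ("OATP1B1", "OATP1B3", "OATP2B1")

#: Supported bioactivity endpoint types.
CONCENTRATION_ENDPOINTS = ("Ki", "IC50", "EC50", "Km")
ENDPOINTS = CONCENTRATION_ENDPOINTS + ("pct_inhibition",)

ACTIVE = "active"
INACTIVE = "inactive"

#: Potency cutoff (uM); strictly below => active.
DEFAULT_CUTOFF_UM = 10.0

_UNIT_TO_UM = {
    "pM": 1e-6,
    "nM": 1e-3,
    "uM": 1.0,
    "μM": 1.0,  # μM
    "mM": 1e3,
    "M": 1e6,
}


class StandardizationError(ValueError):
    """Raised when a SMILES string cannot be parsed or standardized."""


@dataclass(frozen=True)
class Compound:
    compound_id: str
    smiles_raw: str
    smiles_std: str


@dataclass
class ActivityRecord:
    compound_id: str
    target: str
    endpoint: str
    value: float
    units: str
    test_conc_uM: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}; expected one of {TARGETS}")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")


@dataclass
class LabeledDataset:
    """Per-(compound, target) consolidated labels plus the raw records."""

    records: list[ActivityRecord]
    labels: pd.DataFrame = field(default=None)  # columns: compound_id, target, label

    def counts(self, target: str) -> tuple[int, int]:
        sub = self.labels[self.labels["target"] == target]
        n_act = int((sub["label"] == ACTIVE).sum())
        n_inact = int((sub["label"] == INACTIVE).sum())
        return n_act, n_inact


# ---------------------------------------------------------------------------
# standardization

_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_compound(smiles_raw: str, compound_id: str | None = None) -> str:
    """Return the canonical parent structure of ``smiles_raw``.

    Salts and solvents are stripped (largest organic fragment kept) and
    charges neutralized where rule-based neutralization applies; the result
    is a canonical SMILES.  Standardization is idempotent.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        ident = f" (compound {compound_id})" if compound_id else ""
        raise StandardizationError(f"unparseable SMILES{ident}: {smiles_raw!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def murcko_scaffold(smiles_std: str) -> str:
    """Bemis–Murcko framework (ring systems plus linkers) of a molecule.

    Acyclic molecules have no framework and return the empty string.
    """
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles_std!r}")
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaf) if scaf.GetNumAtoms() else ""


# ---------------------------------------------------------------------------
# labeling

def to_uM(value: float, units: str) -> float:
    """Convert a concentration to micromolar."""
    try:
        factor = _UNIT_TO_UM[units]
    except KeyError:
        raise ValueError(f"unknown concentration unit {units!r}") from None
    return value * factor


def pactivity(value_uM: float) -> float:
    """-log10 of a molar concentration value given in uM."""
    if value_uM <= 0:
        raise ValueError("pActivity undefined for non-positive concentration")
    return -math.log10(value_uM * 1e-6)


def label_activity(
    record: ActivityRecord,
    cutoff_uM: float = DEFAULT_CUTOFF_UM,
    pct_threshold: float = 50.0,
) -> str | None:
    """Derive the active/inactive label for a single record.

    Concentration endpoints: active iff value (in uM) is strictly below the
    cutoff.  Percentage-inhibition endpoints: active iff inhibition >=
    ``pct_threshold`` at a test concentration <= cutoff; inhibition below the
    threshold at any concentration <= cutoff is inconclusive only when the
    test concentration is missing, in which case ``None`` is returned and the
    record should be dropped.
    """
    if record.endpoint in CONCENTRATION_ENDPOINTS:
        if record.value is None or not math.isfinite(record.value) or record.value <= 0:
            raise ValueError(
                f"invalid {record.endpoint} value {record.value!r} for {record.compound_id}"
            )
        value_uM = to_uM(record.value, record.units)
        return ACTIVE if value_uM < cutoff_uM else INACTIVE
    # pct_inhibition
    if record.test_conc_uM is None:
        logger.warning(
            "dropping pct_inhibition record for %s/%s: no test concentration",
            record.compound_id,
            record.target,
        )
        return None
    if record.test_conc_uM <= cutoff_uM and record.value >= pct_threshold:
        return ACTIVE
    return INACTIVE


def consolidate_labels(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    """One label per (compound, target), worst-case-active rule.

    When a pair carries both active and inactive records, any active record
    wins: inhibition screening favors sensitivity.  Conflicts are logged.
    """
    rows = [
        (r.compound_id, r.target, r.label)
        for r in records
        if r.label is not None
    ]
    df = pd.DataFrame(rows, columns=["compound_id", "target", "label"])
    if df.empty:
        return df

    def _resolve(group: pd.Series) -> str:
        labels = set(group)
        if len(labels) > 1:
            logger.info("conflicting labels resolved worst-case-active")
            return ACTIVE
        return labels.pop()

    out = (
        df.groupby(["compound_id", "target"], sort=True)["label"]
        .apply(_resolve)
        .reset_index()
    )
    return out


def build_dataset(
    records: Sequence[ActivityRecord],
    cutoff_uM: float = DEFAULT_CUTOFF_UM,
) -> LabeledDataset:
    """Label every record and consolidate to per-pair labels."""
    for r in records:
        r.label = label_activity(r, cutoff_uM=cutoff_uM)
    kept = [r for r in records if r.label is not None]
    return LabeledDataset(records=kept, labels=consolidate_labels(kept))


def class_balance(dataset: LabeledDataset, target: str) -> tuple[str, int, int]:
    """Return ("1:r", n_active, n_inactive) with r = inactives per active.

    r is rounded to one decimal, matching the conventional reporting of
    class imbalance for bioactivity datasets.
    """
    n_act, n_inact = dataset.counts(target)
    if n_act == 0:
        raise ZeroDivisionError(f"no actives for {target}: balance ratio undefined")
    ratio = n_inact / n_act
    return f"1:{ratio:.1f}", n_act, n_inact


# ---------------------------------------------------------------------------
# I/O

ACTIVITY_CSV_COLUMNS = ["compound_id", "smiles", "target", "endpoint", "value", "units"]


def read_activity_csv(path) -> tuple[list[Compound], list[ActivityRecord]]:
    """Read an activity table (CSV) and standardize its compounds.

    Expected columns: compound_id, smiles, target, endpoint, value, units and
    optionally test_conc_uM.  Returns standardized compounds (deduplicated by
    id) and unlabeled activity records.
    """
    df = pd.read_csv(path)
    missing = [c for c in ACTIVITY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity CSV missing columns: {missing}")
    compounds: dict[str, Compound] = {}
    records: list[ActivityRecord] = []
    for row in df.itertuples(index=False):
        cid = str(row.compound_id)
        if cid not in compounds:
            compounds[cid] = Compound(cid, row.smiles, standardize_compound(row.smiles, cid))
        records.append(
            ActivityRecord(
                compound_id=cid,
                target=row.target,
                endpoint=row.endpoint,
                value=float(row.value),
                units=str(row.units),
                test_conc_uM=(
                    float(row.test_conc_uM)
                    if "test_conc_uM" in df.columns and pd.notna(row.test_conc_uM)
                    else None
                ),
            )
        )
    return list(compounds.values()), records


def write_labeled_tsv(path, compounds: Sequence[Compound], dataset: LabeledDataset) -> None:
    """Write the standardized, labeled dataset as TSV."""
    smiles_std = {c.compound_id: c.smiles_std for c in compounds}
    out = dataset.labels.copy()
    out.insert(1, "smiles_std", out["compound_id"].map(smiles_std))
    out.to_csv(path, sep="\t", index=False)
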