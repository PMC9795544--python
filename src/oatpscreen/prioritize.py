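"""Docking-score-driven hit prioritization.

The funnel: per prioritization class (G1/G2/G3 — compounds nominated by
OATP1B1-, OATP1B3- and OATP2B1-scoped models), keep the 30 best docking
scores; drop compounds whose physicochemical properties (SlogP, TPSA, SMR,
rotatable bonds, AMW) fall outside the range spanned by known actives;
cluster the survivors by maximum-common-substructure (MCS) distance with
complete linkage cut at 0.5; keep one representative per cluster (best
class-target docking score, ties broken by the selectivity gap); truncate
to 15 per class.

MCS distance between two molecules is ``1 - |MCS atoms| / max(nA, nB)``,
where the MCS is the largest connected common substructure under
element-and-bond-order matching with ring atoms restricted to ring atoms.
Normalizing by the larger molecule keeps the distance in [0, 1] and
penalizes size mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, rdFMCS, rdMolDescriptors
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

CLASS_TARGET = {"G1": "OATP1B1", "G2": "OATP1B3", "G3": "OATP2B1"}
TARGET_CLASS = {v: k for k, v in CLASS_TARGET.items()}

FILTER_PROPERTIES = ("slogp", "tpsa", "smr", "rotatable_bonds", "amw")

DEFAULT_TOP_N_DOCK = 30
DEFAULT_CLUSTER_CUT = 0.5
DEFAULT_QUOTA = 15
MCS_TIMEOUT_S = 10


# ---------------------------------------------------------------------------
# docking scores

def read_dock_tsv(path) -> pd.DataFrame:
    """Read a docking-score table (TSV: compound_id, target, score kcal/mol)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"compound_id", "target", "score"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"docking TSV missing columns: {sorted(missing)}")
    return df


def dedup_best(dock: pd.DataFrame) -> pd.DataFrame:
    """Keep the best (most negative) score per (compound, target)."""
    return (
        dock.sort_values("score")
        .drop_duplicates(["compound_id", "target"], keep="first")
        .reset_index(drop=True)
    )


def top_n_by_dock(
    dock: pd.DataFrame,
    class_tag: str,
    members: list[str] | None = None,
    n: int = DEFAULT_TOP_N_DOCK,
) -> list[str]:
    """The n best-docking compounds of one class against its own target.

    ``members`` restricts candidates to the class's nominees (from consensus
    provenance); duplicate poses are collapsed to the best score first.
    Ties are broken by compound_id.
    """
    target = CLASS_TARGET[class_tag]
    sub = dedup_best(dock[dock["target"] == target])
    if members is not None:
        sub = sub[sub["compound_id"].isin(members)]
    sub = sub.sort_values(["score", "compound_id"], ascending=[True, True])
    return sub["compound_id"].head(n).tolist()


# ---------------------------------------------------------------------------
# property filtering

def compute_filter_properties(smiles: str) -> dict[str, float]:
    """SlogP, TPSA, SMR, rotatable bonds and average molecular weight."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return {
        "slogp": Crippen.MolLogP(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "smr": Crippen.MolMR(mol),
        "rotatable_bonds": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "amw": Descriptors.MolWt(mol),
    }


def property_ranges(
    reference_smiles: list[str], percentile: float = 0.0
) -> dict[str, tuple[float, float]]:
    """Per-property [low, high] ranges spanned by a reference active set.

    ``percentile`` = 0 gives min–max ranges; e.g. 2.5 gives the central 95%
    band for a more aggressive outlier definition.
    """
    if not reference_smiles:
        raise ValueError("reference set is empty")
    table = pd.DataFrame([compute_filter_properties(s) for s in reference_smiles])
    lo = table.quantile(percentile / 100.0)
    hi = table.quantile(1.0 - percentile / 100.0)
    return {p: (float(lo[p]), float(hi[p])) for p in FILTER_PROPERTIES}


def property_range_filter(
    compounds: dict[str, str], ranges: dict[str, tuple[float, float]]
) -> list[str]:
    """Retain compound ids whose every property lies inside its closed interval.

    ``compounds`` maps compound_id -> SMILES.  Compounds whose properties
    cannot be computed are excluded with a log entry.
    """
    kept = []
    for cid in sorted(compounds):
        try:
            props = compute_filter_properties(compounds[cid])
        except ValueError:
            logger.warning("property filter: excluding %s (descriptor failure)", cid)
            continue
        ok = all(ranges[p][0] <= props[p] <= ranges[p][1] for p in ranges)
        if ok:
            kept.append(cid)
    return kept


# ---------------------------------------------------------------------------
# MCS distance and clustering

def mcs_distance(mol_a: Chem.Mol, mol_b: Chem.Mol, timeout: int = MCS_TIMEOUT_S) -> float:
    """1 - |MCS atoms| / max(heavy atoms), symmetric, in [0, 1].

    Element and exact bond-order matching (an aromatic bond never matches a
    single bond), ring atoms and bonds restricted to ring atoms and bonds,
    atom count maximized.
    """
    res = rdFMCS.FindMCS(
        [mol_a, mol_b],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        ringMatchesRingOnly=True,
        maximizeBonds=False,
        timeout=timeout,
    )
    if res.canceled:
        logger.warning("MCS search timed out; using best structure found")
    n_mcs = res.numAtoms if res.numAtoms > 0 else 0
    denom = max(mol_a.GetNumHeavyAtoms(), mol_b.GetNumHeavyAtoms())
    if denom == 0:
        raise ValueError("cannot compute MCS distance for empty molecules")
    return 1.0 - n_mcs / denom


def mcs_distance_matrix(smiles_by_id: dict[str, str], timeout: int = MCS_TIMEOUT_S):
    """Symmetric MCS distance matrix over a compound panel (sorted by id)."""
    ids = sorted(smiles_by_id)
    mols = [Chem.MolFromSmiles(smiles_by_id[i]) for i in ids]
    if any(m is None for m in mols):
        bad = [i for i, m in zip(ids, mols) if m is None]
        raise ValueError(f"unparseable SMILES for: {bad}")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mcs_distance(mols[i], mols[j], timeout)
    return ids, D


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    cut: float

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, lab in self.labels.items():
            out.setdefault(lab, []).append(cid)
        return {k: sorted(v) for k, v in out.items()}


def cluster_compounds(
    ids: list[str], distance_matrix: np.ndarray, threshold: float = DEFAULT_CLUSTER_CUT
) -> ClusterAssignment:
    """Complete-linkage hierarchical clustering cut at ``threshold``.

    Cutting a complete-linkage dendrogram at h guarantees every
    within-cluster pairwise distance is at most h.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > 1e-12:
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(ids) != D.shape[0]:
        raise ValueError("ids and matrix size differ")
    if len(ids) == 1:
        return ClusterAssignment(labels={ids[0]: 1}, cut=threshold)
    Z = linkage(squareform(D, checks=False), method="complete")
    flat = fcluster(Z, t=threshold, criterion="distance")
    return ClusterAssignment(labels=dict(zip(ids, (int(x) for x in flat))), cut=threshold)


# ---------------------------------------------------------------------------
# representative selection

@dataclass
class PrioritizedList:
    class_tag: str
    compound_ids: list[str] = field(default_factory=list)


def pick_representatives(
    assignment: ClusterAssignment,
    dock: pd.DataFrame,
    class_tag: str,
    per_class_quota: int = DEFAULT_QUOTA,
) -> PrioritizedList:
    """One representative per cluster, truncated to the per-class quota.

    Within a cluster, pick the compound with the best (most negative)
    docking score against the class target; on a score tie, prefer the
    larger selectivity gap (second-best-target score minus best-target
    score, i.e. the margin by which the compound prefers one transporter).
    The representatives are then ranked by class-target score and cut to
    the quota.
    """
    target = CLASS_TARGET[class_tag]
    dock = dedup_best(dock)
    score_map = dock.pivot_table(index="compound_id", columns="target", values="score")

    def class_score(cid: str) -> float:
        try:
            s = score_map.loc[cid, target]
        except KeyError:
            return float("inf")
        return float(s) if pd.notna(s) else float("inf")

    def selectivity_gap(cid: str) -> float:
        if cid not in score_map.index:
            return 0.0
        row = score_map.loc[cid].dropna().sort_values()
        if len(row) < 2:
            return 0.0
        return float(row.iloc[1] - row.iloc[0])  # >= 0; larger = more selective

    reps = []
    for members in assignment.clusters.values():
        best = min(members, key=lambda c: (class_score(c), -selectivity_gap(c), c))
        reps.append(best)
    reps.sort(key=lambda c: (class_score(c), c))
    if per_class_quota > len(reps):
        logger.warning(
            "class %s: quota %d exceeds cluster count %d; returning all representatives",
            class_tag,
            per_class_quota,
            len(reps),
        )
    return PrioritizedList(class_tag=class_tag, compound_ids=reps[:per_class_quota])


# ---------------------------------------------------------------------------
# similarity reporting

def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    union = np.sum(a | b)
    if union == 0:
        return 0.0
    return float(np.sum(a & b) / union)


def mean_tanimoto_to_reference(
    reference_fps: list[np.ndarray],
    query_fps: list[np.ndarray],
    convention: str = "mean_of_means",
) -> float:
    """Average Tanimoto similarity of a reference set to a query set.

    ``mean_of_means``: for each reference compound take its mean similarity
    to the query set, then average over references.  ``pooled``: mean over
    all reference x query pairs.  The two agree when the query set size is
    constant (it is), but both are provided for transparency.
    """
    if not reference_fps or not query_fps:
        raise ValueError("reference and query sets must be non-empty")
    sims = np.array(
        [[tanimoto(r, q) for q in query_fps] for r in reference_fps], dtype=float
    )
    if convention == "mean_of_means":
        return float(sims.mean(axis=1).mean())
    if convention == "pooled":
        return float(sims.mean())
    raise ValueError(f"unknown convention {convention!r}")
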