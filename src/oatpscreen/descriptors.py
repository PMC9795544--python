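"""Ligand and protein descriptors for QSAR and proteochemometric modeling.

Ligand block: a fixed physicochemical vector plus a functional-class
circular fingerprint of radius 3 (FCFP-style: Morgan environments with
pharmacophoric atom invariants, folded to a configurable bit length).

Protein block: per aligned position the first three z-scales of the residue
(gaps encode as zeros), so a length-L alignment yields a 3L vector per
target.  Concatenating ligand and protein blocks gives proteochemometric
(PCM) rows — one per (compound, target) — while the ligand block alone
gives QSAR rows.

Two of the physicochemical descriptors reported by closed commercial
platforms have no exact open equivalent; this module uses documented
analogs (an ESOL-style logS solubility estimate, Labute approximate surface
areas) and records them in the feature manifest.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

QSAR = "QSAR"
PCM = "PCM"

DEFAULT_NBITS = 2048
FP_RADIUS = 3

#: Order and meaning of the physicochemical block.
PHYSCHEM_NAMES = (
    "clogp",            # Crippen logP (AlogP analog)
    "mw",               # molecular weight
    "hbd",              # H-bond donors
    "hba",              # H-bond acceptors
    "rotatable_bonds",
    "n_atoms",          # heavy atoms
    "n_rings",
    "n_aromatic_rings",
    "n_fragments",      # disconnected fragments (1 after standardization)
    "n_plus_o",         # nitrogen + oxygen count
    "logs_esol",        # ESOL-style aqueous solubility estimate (logS)
    "asa_labute",       # Labute approximate surface area
    "tpsa",             # topological polar surface area
    "polar_asa",        # Labute ASA summed over N/O/S/P atoms (polar-SASA analog)
)


class DescriptorError(ValueError):
    pass


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DescriptorError(f"unparseable SMILES: {smiles!r}")
    return mol


def compute_physchem(smiles_std: str) -> np.ndarray:
    """Physicochemical descriptor vector, ordered as :data:`PHYSCHEM_NAMES`."""
    mol = _mol(smiles_std)
    clogp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rotb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    n_arom = rdMolDescriptors.CalcNumAromaticRings(mol)
    # ESOL (Delaney 2004): logS from logP, MW, rotatable bonds, aromatic proportion
    n_heavy = mol.GetNumHeavyAtoms()
    arom_prop = (
        sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / n_heavy if n_heavy else 0.0
    )
    logs = 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rotb - 0.74 * arom_prop
    contribs = rdMolDescriptors._CalcLabuteASAContribs(mol)
    atom_asa = list(contribs[0])
    polar_asa = sum(
        asa
        for asa, atom in zip(atom_asa, mol.GetAtoms())
        if atom.GetSymbol() in ("N", "O", "S", "P")
    )
    return np.array(
        [
            clogp,
            mw,
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rotb,
            n_heavy,
            rdMolDescriptors.CalcNumRings(mol),
            n_arom,
            len(Chem.GetMolFrags(mol)),
            sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O")),
            logs,
            rdMolDescriptors.CalcLabuteASA(mol),
            rdMolDescriptors.CalcTPSA(mol),
            polar_asa,
        ],
        dtype=float,
    )


def compute_fingerprint(smiles_std: str, nbits: int = DEFAULT_NBITS) -> np.ndarray:
    """Functional-class circular fingerprint (radius 3) folded to ``nbits`` bits."""
    if nbits < 1 or (nbits & (nbits - 1)) != 0:
        raise ValueError(f"nbits must be a power of two, got {nbits}")
    mol = _mol(smiles_std)
    gen = _fp_generator(nbits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(nbits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


_GENERATORS: dict[int, object] = {}


def _fp_generator(nbits: int):
    if nbits not in _GENERATORS:
        _GENERATORS[nbits] = rdFingerprintGenerator.GetMorganGenerator(
            radius=FP_RADIUS,
            fpSize=nbits,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
    return _GENERATORS[nbits]


# ---------------------------------------------------------------------------
# protein z-scale encoding

GAP_CHARS = "-."


def load_zscales() -> dict[str, tuple[float, float, float]]:
    """The shipped three-component z-scale table, keyed by one-letter code."""
    ref = importlib.resources.files("oatpscreen").joinpath("data/zscales3.tsv")
    table: dict[str, tuple[float, float, float]] = {}
    with ref.open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("aa"):
                continue
            aa, z1, z2, z3 = line.split()
            table[aa] = (float(z1), float(z2), float(z3))
    return table


_ZSCALES = None


def zscale_table() -> dict[str, tuple[float, float, float]]:
    global _ZSCALES
    if _ZSCALES is None:
        _ZSCALES = load_zscales()
    return _ZSCALES


@dataclass(frozen=True)
class ProteinEncoding:
    target_id: str
    zvector: np.ndarray  # length 3L

    @property
    def alignment_length(self) -> int:
        return len(self.zvector) // 3


def read_alignment_fasta(path) -> dict[str, str]:
    """Aligned FASTA reader; all sequences must share one length."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    return seqs


def encode_protein(alignment: dict[str, str], target_id: str) -> ProteinEncoding:
    """Encode one aligned sequence as (z1, z2, z3) per position; gaps -> zeros."""
    if target_id not in alignment:
        raise KeyError(f"target {target_id!r} not in alignment ({sorted(alignment)})")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    table = zscale_table()
    seq = alignment[target_id]
    vec = np.zeros(3 * len(seq), dtype=float)
    for i, aa in enumerate(seq):
        if aa in GAP_CHARS:
            continue
        try:
            vec[3 * i : 3 * i + 3] = table[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue code {aa!r} at alignment position {i + 1} of {target_id}"
            ) from None
    return ProteinEncoding(target_id=target_id, zvector=vec)


# ---------------------------------------------------------------------------
# feature assembly

@dataclass
class FeatureMatrix:
    """Assembled feature rows plus identifying columns.

    ``ids`` carries compound_id (QSAR) or (compound_id, target) pairs (PCM);
    ``X`` is the dense feature matrix, one row per id.
    """

    mode: str
    ids: pd.DataFrame
    X: np.ndarray
    nbits: int

    @property
    def width(self) -> int:
        return self.X.shape[1]


def ligand_features(smiles_std: str, nbits: int = DEFAULT_NBITS) -> np.ndarray:
    return np.concatenate([compute_physchem(smiles_std), compute_fingerprint(smiles_std, nbits)])


def assemble_features(
    compounds,
    mode: str = QSAR,
    targets: tuple[str, ...] = (),
    encodings: dict[str, ProteinEncoding] | None = None,
    nbits: int = DEFAULT_NBITS,
    fingerprint_only: bool = False,
) -> FeatureMatrix:
    """Build the QSAR (per compound) or PCM (per compound-target) matrix.

    ``compounds`` is an iterable of objects with ``compound_id`` and
    ``smiles_std``.  For PCM mode, an encoding must be supplied for every
    requested target; the protein block is appended to the ligand block.
    ``fingerprint_only`` drops the physicochemical block (useful when the
    fingerprint is the only informative block, as for synthetic libraries).
    """
    compounds = list(compounds)
    lig_rows = []
    for c in compounds:
        fp = compute_fingerprint(c.smiles_std, nbits).astype(float)
        if fingerprint_only:
            lig_rows.append(fp)
        else:
            lig_rows.append(np.concatenate([compute_physchem(c.smiles_std), fp]))
    lig = np.asarray(lig_rows)

    if mode == QSAR:
        ids = pd.DataFrame({"compound_id": [c.compound_id for c in compounds]})
        return FeatureMatrix(mode=QSAR, ids=ids, X=lig, nbits=nbits)
    if mode != PCM:
        raise ValueError(f"mode must be {QSAR!r} or {PCM!r}, got {mode!r}")
    if not targets:
        raise ValueError("PCM mode requires targets")
    encodings = encodings or {}
    missing = [t for t in targets if t not in encodings]
    if missing:
        raise ValueError(f"missing protein encodings for targets: {missing}")
    widths = {len(encodings[t].zvector) for t in targets}
    if len(widths) != 1:
        raise ValueError("protein encodings have inconsistent lengths")
    rows, id_rows = [], []
    for t in targets:
        z = encodings[t].zvector
        for c, lrow in zip(compounds, lig):
            rows.append(np.concatenate([lrow, z]))
            id_rows.append((c.compound_id, t))
    ids = pd.DataFrame(id_rows, columns=["compound_id", "target"])
    return FeatureMatrix(mode=PCM, ids=ids, X=np.asarray(rows), nbits=nbits)


def write_feature_matrix(prefix, fm: FeatureMatrix) -> None:
    """Write features as TSV plus a JSON manifest (mode, nbits, descriptor set)."""
    df = pd.concat(
        [fm.ids.reset_index(drop=True), pd.DataFrame(fm.X)], axis=1
    )
    df.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    manifest = {
        "mode": fm.mode,
        "nbits": fm.nbits,
        "n_rows": int(fm.X.shape[0]),
        "width": int(fm.X.shape[1]),
        "physchem": list(PHYSCHEM_NAMES),
        "fingerprint": f"functional-class Morgan radius {FP_RADIUS}, folded",
        "substituted_descriptors": {
            "logs_esol": "ESOL-style estimate standing in for platform solubility",
            "asa_labute": "Labute approximate surface area",
            "polar_asa": "Labute ASA over N/O/S/P atoms (polar-SASA analog)",
        },
    }
    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
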