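"""Synthetic benchmark generator for the whole screening pipeline.

Real OATP bioactivity data, the commercial screening library and the
docking runs cannot be shipped; this module generates stand-ins with the
same statistical structure, so every stage of the pipeline is testable
end to end with known ground truth:

* a compound library from a scaffold x substituent grammar (valid,
  diverse SMILES, deterministic under a seed);
* three aligned pseudo-sequences whose pairwise identities match the
  transporter family (OATP1B1-OATP1B3 ~0.80, OATP2B1 vs both ~0.30);
* per-target activities from a planted linear model on fingerprint bits,
  with weights correlated across targets according to sequence identity,
  intercepts calibrated to the per-target class imbalances observed for
  the real datasets (1:2.8, 1:4.7, 1:2.2 inactives per active) and a
  configurable label-flip rate;
* docking scores as a noisy affine map of the latent activity, clipped to
  the score range seen in the original docking runs;
* Hill-shaped dose-response curves with multiplicative noise.

The pseudo-sequences are synthetic: only their identity structure matters
to proteochemometric tests.  The generator makes no attempt to mimic real
OATP chemotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_data import ActivityRecord, Compound, TARGETS
from .descriptors import compute_fingerprint

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: pActivity value of the 10 uM labeling cutoff.
CUTOFF_PACTIVITY = 5.0

# Scaffold templates: {r1}/{r2} mark substitution slots (ring digits 1-4 are
# reserved for scaffold rings, 5+ for ring-bearing substituents).
SCAFFOLDS = (
    "c1ccc({r1})c({r2})c1",                 # benzene, ortho pattern
    "c1cc({r1})ccc1{r2}",                   # benzene, para pattern
    "c1cc({r1})cc({r2})c1",                 # benzene, meta pattern
    "c1ccc2cc({r1})c({r2})cc2c1",           # naphthalene
    "c1cc({r1})nc({r2})c1",                 # pyridine
    "c1nc({r1})nc({r2})c1",                 # pyrimidine
    "c1cnc({r1})c(n1){r2}",                 # pyrazine
    "c1csc({r1})c1{r2}",                    # thiophene
    "c1oc({r1})cc1{r2}",                    # furan
    "c1c({r2})c({r1})[nH]n1",               # pyrazole
    "c1[nH]c({r1})nc1{r2}",                 # imidazole
    "c1ccc2c(c1)c({r2})c({r1})[nH]2",       # indole
    "c1cc({r2})c2c(c1)nc({r1})[nH]2",       # benzimidazole
    "c1cc({r2})c2c(c1)nc({r1})s2",          # benzothiazole
    "C1CC({r2})CCN1{r1}",                   # piperidine
    "C1CN({r1})CCN1{r2}",                   # piperazine
    "O1CCN({r2})CC1{r1}",                   # morpholine
    "C1CC({r1})CCC1{r2}",                   # cyclohexane
    "c1cc({r1})ccc1-c2ccc({r2})cc2",        # biphenyl
    "c1ccc2c(c1)CC({r1})C({r2})C2",         # tetralin
    "c1cc({r2})ccc1S({r1})(=O)=O",          # aryl sulfone
    "c1ccc2c(c1)oc({r1})c2{r2}",            # benzofuran
)

SUBSTITUENTS = (
    "", "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "[N+](=O)[O-]", "C(=O)O", "C(=O)OC",
    "C(=O)N", "C(=O)NC", "S(C)(=O)=O", "S(N)(=O)=O", "C(F)(F)F", "OC(F)(F)F",
    "CO", "CCO", "CN", "CCN", "CC(=O)O", "c5ccccc5", "c5ccncc5",
    "Cc5ccccc5", "OCc5ccccc5", "N5CCOCC5", "N5CCCC5",
)


@dataclass
class SynthConfig:
    n_compounds: int = 2000
    #: inactives per active, per target (order follows TARGETS)
    imbalance: tuple[float, float, float] = (2.8, 4.7, 2.2)
    #: pairwise sequence identities (symmetric, diagonal 1)
    identity: tuple[tuple[float, float, float], ...] = (
        (1.00, 0.80, 0.30),
        (0.80, 1.00, 0.30),
        (0.30, 0.30, 1.00),
    )
    alignment_length: int = 700
    #: planted linear model: support size and weight scale (log units per bit)
    n_planted_bits: int = 24
    effect_scale: float = 1.0
    #: fingerprint width the planted model acts on (coarse folding keeps the
    #: planted signal dense; models may featurize at any width)
    nbits: int = 256
    #: latent pActivity noise (log units), label-flip rate, docking noise
    #: (kcal/mol) and assay noise (% of signal)
    latent_noise: float = 0.25
    label_flip_rate: float = 0.05
    dock_noise: float = 1.0
    assay_noise_pct: float = 5.0
    dock_range: tuple[float, float] = (-10.7, -0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        I = np.asarray(self.identity, dtype=float)
        if I.shape != (3, 3) or not np.allclose(I, I.T) or not np.allclose(np.diag(I), 1.0):
            raise ValueError("identity matrix must be 3x3 symmetric with unit diagonal")
        if ((I < 0) | (I > 1)).any():
            raise ValueError("identities must lie in [0, 1]")
        if any(r <= 0 for r in self.imbalance):
            raise ValueError("imbalance ratios must be positive")


@dataclass
class PlantedModel:
    support: np.ndarray                 # planted bit indices
    weights: dict[str, np.ndarray]      # target -> length-nbits weight vector
    intercepts: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# compounds

def _build_smiles(scaffold: str, sub1: str, sub2: str) -> str | None:
    smi = scaffold.format(r1=sub1, r2=sub2).replace("()", "")
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def gen_compounds(n: int, seed: int = 0) -> list[Compound]:
    """Generate ``n`` valid compounds from the scaffold x substituent grammar.

    Combinations are sampled without replacement from the full grammar, so
    duplicate SMILES can only arise from molecular symmetry and stay rare.
    Deterministic under the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_combo = len(SCAFFOLDS) * len(SUBSTITUENTS) ** 2
    if n > n_combo:
        raise ValueError(f"grammar supports at most {n_combo} compounds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_combo)
    ns = len(SUBSTITUENTS)
    compounds: list[Compound] = []
    for idx in order:
        if len(compounds) == n:
            break
        si, rest = divmod(int(idx), ns * ns)
        r1, r2 = divmod(rest, ns)
        smi = _build_smiles(SCAFFOLDS[si], SUBSTITUENTS[r1], SUBSTITUENTS[r2])
        if smi is None:
            continue
        cid = f"SYN-{len(compounds) + 1:06d}"
        compounds.append(Compound(compound_id=cid, smiles_raw=smi, smiles_std=smi))
    if len(compounds) < n:
        raise RuntimeError("grammar yielded too few valid molecules")
    return compounds


# ---------------------------------------------------------------------------
# targets

def _column_pattern_counts(identity: np.ndarray, L: int) -> dict[str, int]:
    """Alignment-column pattern counts realizing the requested identities.

    Columns fall in five patterns: all three residues equal, exactly one of
    the three pairs equal, or all distinct.  Pairwise identity I_ij is the
    fraction of columns where i and j agree, giving a linear system with a
    one-parameter family of solutions; the smallest feasible "all equal"
    share is used.
    """
    i12, i13, i23 = identity[0, 1], identity[0, 2], identity[1, 2]
    s = i12 + i13 + i23
    a = max(0.0, (s - 1.0) / 2.0)  # all-equal share; smallest feasible
    b, c, d = i12 - a, i13 - a, i23 - a
    e = 1.0 - a - b - c - d
    if min(b, c, d, e) < -1e-9:
        raise ValueError(f"infeasible identity triple: {i12}, {i13}, {i23}")
    counts = {
        "abc": int(round(a * L)),
        "ab": int(round(b * L)),
        "ac": int(round(c * L)),
        "bc": int(round(d * L)),
    }
    counts["none"] = L - sum(counts.values())
    if counts["none"] < 0:
        raise ValueError("rounding produced an infeasible column allocation")
    return counts


def gen_targets(config: SynthConfig) -> dict[str, str]:
    """Three aligned pseudo-sequences matching the requested identity matrix.

    Realized identities are exact up to column-count rounding (within
    +-0.02 of the request for alignment length >= 600).
    """
    L = config.alignment_length
    identity = np.asarray(config.identity, dtype=float)
    counts = _column_pattern_counts(identity, L)
    rng = np.random.default_rng(config.seed + 1_000_001)
    cols = []
    aa = np.array(list(AMINO_ACIDS))

    def draw(k: int) -> list[str]:
        return list(rng.choice(aa, size=k, replace=False))

    for _ in range(counts["abc"]):
        (x,) = draw(1)
        cols.append((x, x, x))
    for _ in range(counts["ab"]):
        x, y = draw(2)
        cols.append((x, x, y))
    for _ in range(counts["ac"]):
        x, y = draw(2)
        cols.append((x, y, x))
    for _ in range(counts["bc"]):
        x, y = draw(2)
        cols.append((y, x, x))
    for _ in range(counts["none"]):
        x, y, z = draw(3)
        cols.append((x, y, z))
    order = rng.permutation(len(cols))
    cols = [cols[i] for i in order]
    seqs = ["".join(col[i] for col in cols) for i in range(3)]
    return dict(zip(TARGETS, seqs))


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    return sum(a == b for a, b in zip(seq_a, seq_b)) / len(seq_a)


# ---------------------------------------------------------------------------
# planted activities

def make_planted_model(config: SynthConfig) -> PlantedModel:
    """Sparse per-target weight vectors, correlated via sequence identity."""
    rng = np.random.default_rng(config.seed + 2_000_002)
    support = np.sort(rng.choice(config.nbits, size=config.n_planted_bits, replace=False))
    corr = np.asarray(config.identity, dtype=float)
    # identity matrix doubles as the weight correlation across targets
    chol = np.linalg.cholesky(corr + 1e-9 * np.eye(3))
    raw = rng.standard_normal((config.n_planted_bits, 3)) @ chol.T
    weights = {}
    for ti, t in enumerate(TARGETS):
        w = np.zeros(config.nbits)
        w[support] = config.effect_scale * raw[:, ti]
        weights[t] = w
    return PlantedModel(support=support, weights=weights)


def _fingerprints(compounds, nbits: int) -> np.ndarray:
    return np.asarray([compute_fingerprint(c.smiles_std, nbits) for c in compounds], float)


def plant_activities(
    compounds: list[Compound],
    planted: PlantedModel,
    config: SynthConfig,
    fingerprints: np.ndarray | None = None,
) -> tuple[list[ActivityRecord], pd.DataFrame]:
    """Latent activities, labels and activity records for every target.

    Latent pActivity = intercept + planted-bit term + Gaussian noise; the
    intercept is calibrated per target so that, after label flips, the
    expected imbalance matches the request.  Flips mirror the pActivity
    across the 10 uM cutoff so records stay consistent with their labels.
    Returns the records plus a tidy frame of the true (pre-flip) latents.
    """
    rng = np.random.default_rng(config.seed + 3_000_003)
    fps = _fingerprints(compounds, config.nbits) if fingerprints is None else fingerprints
    f = config.label_flip_rate
    if not (0.0 <= f < 0.5):
        raise ValueError("label_flip_rate must lie in [0, 0.5)")
    records: list[ActivityRecord] = []
    latent_rows = []
    for ti, t in enumerate(TARGETS):
        ratio = config.imbalance[ti]
        pi_target = 1.0 / (1.0 + ratio)
        pi_pre = (pi_target - f) / (1.0 - 2.0 * f)
        if not (0.0 < pi_pre < 1.0):
            raise ValueError(
                f"imbalance {ratio} unreachable at flip rate {f}"
            )
        signal = fps @ planted.weights[t]
        noise = rng.normal(0.0, config.latent_noise, size=len(compounds))
        raw = signal + noise
        n = len(compounds)
        # exact-count calibration: place the intercept so that exactly
        # n_act_pre compounds sit above the cutoff before flipping, with
        # n_act_pre solved so the post-flip expectation hits the target
        n_act_target = int(round(pi_target * n))
        n_act_pre = int(round((n_act_target - f * n) / (1.0 - 2.0 * f)))
        n_act_pre = min(max(n_act_pre, 1), n - 1)
        order = np.argsort(raw)
        boundary = (raw[order[n - n_act_pre - 1]] + raw[order[n - n_act_pre]]) / 2.0
        intercept = CUTOFF_PACTIVITY - float(boundary)
        planted.intercepts[t] = intercept
        pact = raw + intercept
        # flip exact per-class counts so the realized imbalance stays on target
        act_idx = np.flatnonzero(pact > CUTOFF_PACTIVITY)
        inact_idx = np.flatnonzero(pact <= CUTOFF_PACTIVITY)
        flips = np.zeros(n, dtype=bool)
        for idx in (act_idx, inact_idx):
            k = int(round(f * idx.size))
            if k:
                flips[rng.choice(idx, size=k, replace=False)] = True
        pact_obs = np.where(flips, 2.0 * CUTOFF_PACTIVITY - pact, pact)
        value_uM = 10.0 ** (6.0 - pact_obs)
        for c, lat, v in zip(compounds, pact, value_uM):
            latent_rows.append((c.compound_id, t, float(lat)))
            records.append(
                ActivityRecord(
                    compound_id=c.compound_id,
                    target=t,
                    endpoint="IC50",
                    value=float(v),
                    units="uM",
                )
            )
        realized_actives = int(np.sum(value_uM < 10.0))
        # integer rounding dominates at small n; 5% governs at realistic n
        if abs(realized_actives - n_act_target) > max(2, 0.05 * n_act_target):
            realized_ratio = (n - realized_actives) / realized_actives
            raise RuntimeError(
                f"{t}: imbalance calibration failed (requested 1:{ratio}, "
                f"realized 1:{realized_ratio:.2f})"
            )
    latent = pd.DataFrame(latent_rows, columns=["compound_id", "target", "pactivity"])
    return records, latent


# ---------------------------------------------------------------------------
# docking scores

def gen_dock_scores(
    latent: pd.DataFrame,
    sigma: float = 1.0,
    score_range: tuple[float, float] = (-10.7, -0.3),
    seed: int = 0,
) -> pd.DataFrame:
    """Docking scores as a noisy affine map of latent activity.

    More active compounds dock better (more negative) in expectation; the
    map places a pActivity of 3 near the weak end and 8 near the strong end
    of the configured score range before clipping.
    """
    rng = np.random.default_rng(seed)
    lo, hi = min(score_range), max(score_range)
    pact = latent["pactivity"].to_numpy()
    slope = (hi - lo) / 5.0  # kcal/mol per log unit over the pActivity span 3..8
    score = -2.8 - slope * (pact - 3.0) + rng.normal(0.0, sigma, size=len(pact))
    score = np.clip(score, lo, hi)
    return pd.DataFrame(
        {
            "compound_id": latent["compound_id"],
            "target": latent["target"],
            "score": np.round(score, 3),
        }
    )


# ---------------------------------------------------------------------------
# dose-response curves

DEFAULT_CONCENTRATIONS = tuple(float(c) for c in np.geomspace(0.01, 100.0, 8).round(4))


def gen_dose_response(
    ic50_uM: float,
    hill_n: float = 1.0,
    concentrations_uM: tuple[float, ...] = DEFAULT_CONCENTRATIONS,
    noise_pct: float = 0.0,
    seed: int = 0,
    compound_id: str = "SYN-DR",
    target: str = "OATP2B1",
    top: float = 100.0,
    bottom: float = 0.0,
):
    """Hill-shaped dose-response series with multiplicative Gaussian noise."""
    from .assay import DoseResponseSeries, hill_curve

    if ic50_uM <= 0:
        raise ValueError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations_uM, dtype=float)
    y = hill_curve(c, bottom, top, ic50_uM, hill_n)
    if noise_pct:
        y = y * (1.0 + rng.normal(0.0, noise_pct / 100.0, size=c.size))
    return DoseResponseSeries(
        compound_id=compound_id, target=target, concentrations_uM=c, transport_pct=y
    )


# ---------------------------------------------------------------------------
# fixture bundle

def write_fixture_bundle(outdir, config: SynthConfig) -> dict:
    """Emit the full fixture bundle for one seed.

    Writes the compound library (CSV), activity records (CSV), aligned
    FASTA, docking TSV, an eight-point plate CSV for a handful of actives,
    and a manifest JSON recording the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    compounds = gen_compounds(config.n_compounds, seed=config.seed)
    targets = gen_targets(config)
    planted = make_planted_model(config)
    records, latent = plant_activities(compounds, planted, config)

    pd.DataFrame(
        [(c.compound_id, c.smiles_std) for c in compounds],
        columns=["compound_id", "smiles"],
    ).to_csv(outdir / "library.csv", index=False)

    smiles = {c.compound_id: c.smiles_std for c in compounds}
    act = pd.DataFrame(
        [
            (r.compound_id, smiles[r.compound_id], r.target, r.endpoint, r.value, r.units)
            for r in records
        ],
        columns=["compound_id", "smiles", "target", "endpoint", "value", "units"],
    )
    act.to_csv(outdir / "activities.csv", index=False)

    with open(outdir / "alignment.fasta", "w") as fh:
        for t, seq in targets.items():
            fh.write(f">{t}\n{seq}\n")

    dock = gen_dock_scores(
        latent, sigma=config.dock_noise, score_range=config.dock_range,
        seed=config.seed + 4_000_004,
    )
    dock.to_csv(outdir / "docking.tsv", sep="\t", index=False)

    # eight-point plates for the six most potent synthetic compounds on OATP2B1
    sub = latent[latent["target"] == "OATP2B1"].nlargest(6, "pactivity")
    plate_rows = []
    for i, row in enumerate(sub.itertuples(index=False)):
        ic50 = 10.0 ** (6.0 - row.pactivity)
        series = gen_dose_response(
            ic50_uM=max(ic50, 1e-3),
            noise_pct=config.assay_noise_pct,
            seed=config.seed + 5_000_005 + i,
            compound_id=row.compound_id,
        )
        for c, pct in zip(series.concentrations_uM, series.transport_pct):
            raw = 200.0 + 8.0 * pct  # mock background 200, control-specific 800
            plate_rows.append((row.compound_id, "OATP2B1", c, raw, 200.0, 1000.0))
    pd.DataFrame(
        plate_rows, columns=["compound_id", "target", "concentration_uM", "raw", "mock_raw", "control_raw"],
    ).to_csv(outdir / "plates.csv", index=False)

    manifest = {
        "seed": config.seed,
        "n_compounds": config.n_compounds,
        "imbalance": list(config.imbalance),
        "identity": [list(r) for r in config.identity],
        "alignment_length": config.alignment_length,
        "n_planted_bits": config.n_planted_bits,
        "nbits": config.nbits,
        "label_flip_rate": config.label_flip_rate,
        "files": ["library.csv", "activities.csv", "alignment.fasta", "docking.tsv", "plates.csv"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
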