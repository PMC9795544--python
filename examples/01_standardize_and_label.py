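"""Standardize compounds and derive active/inactive labels.

Builds a tiny activity table, standardizes the SMILES (salt stripping,
charge neutralization, canonicalization), applies the 10 uM potency cutoff
per (compound, target) pair and prints the class balance per transporter.
"""

import pandas as pd

from oatpscreen import chem_data as cd

raw = pd.DataFrame(
    [
        ("drug1", "CC(=O)Nc1ccc(O)cc1", "OATP1B1", "IC50", 4.2, "uM"),
        ("drug1", "CC(=O)Nc1ccc(O)cc1", "OATP1B3", "IC50", 35.0, "uM"),
        ("drug2", "CCN(CC)CCOC(=O)c1ccc(N)cc1.Cl", "OATP1B1", "Ki", 600, "nM"),
        ("drug3", "OC(=O)c1ccccc1O", "OATP1B1", "IC50", 120.0, "uM"),
        ("drug4", "Cc1ccccc1S(N)(=O)=O", "OATP1B1", "pct_inhibition", 72.0, "%"),
    ],
    columns=["compound_id", "smiles", "target", "endpoint", "value", "units"],
)
raw["test_conc_uM"] = [None, None, None, None, 10.0]
raw.to_csv("/tmp/example_activities.csv", index=False)

compounds, records = cd.read_activity_csv("/tmp/example_activities.csv")
dataset = cd.build_dataset(records)

print("standardized parents:")
for c in compounds:
    print(f"  {c.compound_id}: {c.smiles_raw}  ->  {c.smiles_std}")

print("\nconsolidated labels (10 uM cutoff, strictly below = active):")
print(dataset.labels.to_string(index=False))

ratio, n_act, n_inact = cd.class_balance(dataset, "OATP1B1")
print(f"\nOATP1B1 balance {ratio} ({n_act} actives, {n_inact} inactives)")
# drug2's 600 nM Ki converts to 0.6 uM -> active; the hydrochloride salt is
# stripped before featurization.  drug4 inhibits 72% at 10 uM -> active.
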