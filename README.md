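# oatpscreen

Consensus virtual screening and assay analytics for discovering inhibitors
of the hepatic uptake transporters **OATP1B1, OATP1B3 and OATP2B1**
(organic anion transporting polypeptides). These transporters control the
liver uptake of statins and many other drugs; their inhibition is a major
source of drug–drug interactions, so both potent and *selective* inhibitors
are sought as pharmacological tools.

The package re-implements, as a tested and reusable library, a
ligand/structure-combined screening pipeline:

1. **Data curation** — SMILES standardization (salt stripping, charge
   neutralization, canonical parent), activity labeling with the 10 µM
   potency cutoff (strictly below ⇒ active), per-target class balances.
2. **Features** — a physicochemical block plus functional-class circular
   fingerprints of radius 3 (FCFP-style) for ligands; the first three
   z-scales per aligned position for proteins, giving proteochemometric
   (PCM) rows `[ligand ‖ protein]` or ligand-only QSAR rows.
3. **Mondrian aggregated conformal prediction (ACP)** — 20 members, each a
   100-tree random forest trained on a 70% proper split and calibrated
   class-conditionally on a 20% split. The conformity score of compound
   *x* for class *c* is the forest vote fraction *P̂(c|x)*; the member
   p-value is the smoothed rank
   `p_c(x) = (#{s ∈ calib_c : s ≤ P̂(c|x)} + 1) / (n_c + 1)`,
   the ensemble p-value is the member median, and the prediction region at
   significance ε is `{c : p_c(x) > ε}` — possibly *both* or *empty*.
   Validity (fraction of regions containing the truth) and efficiency
   (fraction of single-class regions) are reported per class.
4. **Gradient boosting** — xgboost with the screen's settings (100 trees,
   η = 0.3, depth 7, column fraction 0.7, seed 12345), as classifier or as
   pActivity regressor; a 16-cell model grid crosses {CP, GB} ×
   {QSAR, PCM} × {general, three selective scopes}, evaluated by
   stratified 5-fold CV (pooled ROC AUC, sensitivity, specificity).
5. **Library screening** — per-model active calls (pActivity > 6.5 log
   units ≈ 300 nM, or P(active) > 0.5), top-250 ranked actives per model,
   consensus union with nominating-model provenance.
6. **Prioritization funnel** — per hit class (G1/G2/G3 = nominated for
   OATP1B1/1B3/2B1): top 30 by docking score, physicochemical range filter
   (SlogP, TPSA, SMR, rotatable bonds, AMW vs known actives), maximum
   common substructure distance `d = 1 − |MCS|/max(n_A, n_B)` with
   complete-linkage clustering cut at 0.5, one best-docking representative
   per cluster, 15 per class.
7. **Assay analytics** — transport normalization
   `100·(raw − mock)/(control − mock)`, three-point screen categories,
   Hill IC50 fits `T(c) = bottom + (top − bottom)/(1 + (c/IC50)^n)`,
   hit rates and selectivity folds.
8. **Synthetic benchmark generator** — scaffold×substituent compound
   grammar, aligned pseudo-sequences with prescribed pairwise identities
   (0.80 / 0.30), planted linear activity models with calibrated class
   imbalances (1:2.8, 1:4.7, 1:2.2), docking scores and dose–response
   curves with known ground truth.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/02_conformal_and_boosted_models.py` trains both engines
on an 800-compound planted benchmark and prints:

```
800 compounds, 210 actives (imbalance 1:2.8)

conformal prediction at epsilon = 0.2 (held-out 200 compounds):
  active   validity 0.81 (error 0.19 <= 0.2 expected), efficiency 1.00
  inactive validity 0.84 (error 0.16 <= 0.2 expected), efficiency 0.98
  regions: 197 single, 0 both, 3 empty

gradient boosting, 5-fold CV (pooled out-of-fold):
  ROC 0.881, sensitivity 0.714, specificity 0.922
```

The per-class error staying at or below ε = 0.2 is the Mondrian conformal
guarantee under exchangeability; the ROC measures how much of the planted
structure–activity signal the booster recovers (0.5 = chance). The other
examples cover standardization/labeling, the consensus screen, the
docking-driven funnel, IC50 fitting, and the fixture bundle writer.

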