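"""Transport-assay analytics: screen categories, Hill fits, selectivity.

Simulates the two-stage assay readout: a three-point screen that bins
compounds by the concentration reaching 50% inhibition, then an
eight-point dose-response curve fitted with the one-site Hill model to
extract IC50, and the selectivity folds computed from per-target IC50s.
"""

import numpy as np

from oatpscreen import assay
from oatpscreen import synthgen as sg

# three-point screen: normalized transport at 1, 10, 100 uM
screens = {
    "potent": [25.0, 8.0, 2.0],
    "moderate": [85.0, 40.0, 12.0],
    "weak": [95.0, 82.0, 60.0],
    "silent": [101.0, 99.0, 97.0],
    "activator": [120.0, 140.0, 155.0],
}
print("three-point screen categories:")
for name, transports in screens.items():
    series = assay.DoseResponseSeries(name, "OATP2B1", np.array([1.0, 10.0, 100.0]), np.array(transports))
    print(f"  {name:10s} transport {transports} -> {assay.categorize_three_point(series)}")

# eight-point curves at the potency of a strong OATP2B1 inhibitor; single
# noisy curves scatter around the truth, so report the replicate median
fits = [
    assay.fit_hill1(sg.gen_dose_response(ic50_uM=0.39, hill_n=1.0, noise_pct=5.0, seed=s))
    for s in range(20)
]
ic50s = np.array([f.ic50_uM for f in fits if f.converged])
print("\nHill fits of 20 noisy 8-point curves (true IC50 0.39 uM, 5% noise):")
print(
    f"  median IC50 {np.median(ic50s):.3f} uM "
    f"(range {ic50s.min():.3f}..{ic50s.max():.3f}), all converged={all(f.converged for f in fits)}"
)

folds = assay.selectivity_fold({"OATP1B3": 5.4, "OATP2B1": 0.04})
print(f"\nselectivity folds for IC50s 5.4 uM (OATP1B3) vs 0.04 uM (OATP2B1):")
print(f"  {folds['OATP1B3']:.0f}-fold lower affinity on OATP1B3")
# the fold is the IC50 ratio to the most potently inhibited transporter;
# large folds mark selective inhibitors.
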