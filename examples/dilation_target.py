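"""Invert the FEV1 model to a surgical dilation target.

Given simulated outlet flows for a stenosis-to-normal transition series
(one CFD run per dilation ratio alpha), the fitted regression converts
each flow to a predicted FEV1.  The smallest alpha whose predicted FEV1
reaches the normality threshold FEV1 >= 0.70 x predicted FVC is the
quantitative dilation target for surgery.

The per-alpha flows here are illustrative placeholders for an external
CFD campaign; in practice they come from simulating each transition model.
"""

import airwaykit as ak

fit = ak.fit_ols(ak.TRAINING_RECORDS)

# patient: predicted normal FEV1 c and predicted FVC from the reference
# equation; target FEV1 = 0.70 * FVC
c, predicted_fvc = 2.25, 2.67
spec = ak.DilationTargetSpec(predicted_fvc=predicted_fvc, target_ratio=0.70)
print(f"target FEV1 = 0.70 x {predicted_fvc} = {spec.target_fev1:.3f} L/s")

# simulated outlet flow (L/s) of the transition model at each alpha
alpha_flows = [(0.0, 1.135), (0.2, 1.48), (0.4, 1.85),
               (0.6, 2.20), (0.8, 2.52), (1.0, 2.80)]
print("\nalpha   flow a   predicted FEV1 (L/s)")
for a, q in alpha_flows:
    print(f"{a:5.0%}  {q:7.3f}   {ak.predict(fit, q, c)[1]:.3f}")

alpha_star = ak.solve_dilation_target(alpha_flows, fit, c, spec)
print(f"\nsmallest sufficient dilation ratio: alpha* = {alpha_star:.2%}")
# dilating the stenotic segment alpha* of the way to the healthy radii is
# predicted to restore FEV1/FVC to the normal range
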