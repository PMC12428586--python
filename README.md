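# airwaykit

Patient-specific airway modelling and pulmonary-function prediction for
large-airway stenosis.

Spirometry needs active patient cooperation, which many patients with
severe airway stenosis cannot give, and it says nothing about what lung
function *would be* after a planned airway dilation. `airwaykit`
implements the computational side of a simulation-based alternative:

1. **Convolution-surface airway models.** From a skeleton — a tree of
   centreline polylines with per-point radii, extracted from CT — a smooth,
   watertight airway surface is built as an iso-level of the field obtained
   by integrating a compactly supported quartic kernel
   `f(r) = (1 − r²/R²)²` (r ≤ R) along the skeleton's line segments. The
   line integral has a closed form, so no numerical quadrature enters the
   geometry. The resulting STL meshes are clean enough for CFD volume
   meshing, unlike raw region-growing segmentations.
2. **Parametric stenosis dilation.** A stenotic interval carries its
   current radii R₂ and healthy reference radii R₁; the dilation ratio
   α = (R − R₂)/(R₁ − R₂) generates a family of transitional models
   between the patient's current state (α = 0) and healthy state (α = 1).
3. **Active-breathing boundary conditions.** Expiratory flow is split over
   the 18 bronchopulmonary segments by fixed ventilation fractions and
   written as velocity-inlet / zero-pressure-outlet tables for an external
   CFD solver; orifice pressures from the normal-geometry run are
   transferred back as pressure inlets for the stenotic run.
4. **FEV1 regression.** With a = simulated stenotic-model outlet flow,
   b = measured FEV1 and c = predicted normal FEV1 (all L/s), ordinary
   least squares on the normalized ratios x = a/c, y = b/c gives
   `y = 0.8199·x − 0.089` on the four training patients. Predicted FEV1 is
   ŷ·c. Inverting the model over a per-α flow table yields the smallest
   dilation ratio α* whose predicted FEV1 reaches the normality threshold
   FEV1 ≥ 0.70 × predicted FVC.

The CFD solve itself (meshing, turbulence modelling) stays in external
software; this package produces its geometric and boundary-condition
inputs and consumes its flow outputs.

## Worked example

```sh
python examples/fev1_prediction.py
```

prints

```
fitted model: y = 0.8199 x + (-0.089)
training RMSE = 0.0247, R2 = 0.9822  (n = 4)

held-out patients:
  E: predicted b/c = 0.325, predicted FEV1 = 0.730 L/s, measured 0.700 L/s -> error 4.3 %
  F: predicted b/c = 0.606, predicted FEV1 = 1.158 L/s, measured 1.270 L/s -> error 8.8 %
test RMSE = 0.0424, test R2 = 0.9425
```

The slope/intercept are the fitted normalized-ratio model; RMSE and R²
are √(SSres/n) and 1 − SSres/SStot on the respective set. The held-out
relative errors (4.3 %, 8.8 %) are the out-of-sample FEV1 prediction
errors for the two test patients.

Geometry end to end:

```sh
python examples/build_airway_surface.py
```

```
skeleton: 7 branches, 232 mm total centreline
surface: 35954 vertices, 71904 faces, watertight=True
wrote airway_model.stl
requested trachea radius 6.00 mm, measured 5.996 mm (0.07 % error)
```

The measured radius is recovered from the exported mesh by cutting a
cross-section and taking √(S/π); the 0.07 % gap is pure grid
discretization, confirming the iso-value calibration
`T(s) = (16/15)(s² − 1)^{5/2}/s⁵`.

The other scripts in `examples/` cover the dilation series, boundary
conditions, the dilation-target inversion and the one-call pipeline. A
thin CLI mirrors them: `airway synth tree`, `airway surface`,
`airway dilate-series`, `airway bc allocate`, `airway fev1 fit`,
`airway run --config case.yaml`.

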