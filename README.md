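# periwound

Quantitative wound-edge morphometry from clinical photographs.

Wound-edge classification (indistinct, attached, not attached,
rolled-under/fibrotic, hyperkeratotic) is one of the most subjective items in
structured wound scoring tools such as BWAT and PWAT: expert clinicians
scoring the same 2-D photographs agree only weakly with one another.
`periwound` implements an image-analysis pipeline that makes the edge
measurable, and the two evaluations that question what clinicians are
actually scoring:

1. **Standardization.** Given a wound photograph, its binary segmentation
   mask and a monocular depth map, the peri-wound *transition band* — the
   annulus `dilate(mask, d_out) \ erode(mask, d_in)` — is unwrapped into a
   rectangle indexed by contour arc length × signed normal offset δ
   (δ > 0 outside the wound, δ = 0 on the border, δ < 0 in the bed). The
   depth map is first detrended with a least-squares plane `z = ax + by + c`
   so skin orientation does not masquerade as edge shape.
2. **Edge profiles.** The per-column median of the rectified depth band is a
   1-D outside→inside *edge profile*, which is anchored, scaled, and
   classified by BIC among four trend templates: flat `c`, linear
   `α + βδ`, and the logistic step `A/(1 + e^{-(δ-δ₀)/w}) + c`, read as
   *abrupt* when the fitted width `w ≤ 3 px` and *smooth* otherwise.
3. **Descriptors.** A geometry group (area, perimeter, circularity
   `4πA/P²`, solidity, eccentricity, border irregularity, radial CV, and the
   profile descriptors) and a visual group (RGB/HSV statistics and redness
   `R/(R+G+B)` of bed / inner band / outer band; gray-level co-occurrence
   texture of the rectified band; gradient statistics).
4. **Experiments.** Unsupervised: cluster profile summaries (PCA or UMAP +
   k-means, k = 5) and compare post hoc with each rater via optimal label
   matching + Cohen's κ and the Adjusted Rand Index. Supervised: one
   classifier per rater under repeated stratified cross-validation,
   geometry-only vs full features, compared with a two-sample Student's
   t-test on the per-run κ values.

All agreement statistics are chance-corrected:
`κ = (p_o − p_e)/(1 − p_e)` with `p_e = Σ_c marginal_a(c)·marginal_b(c)`.

Because no annotated clinical wound dataset is public, the package ships a
first-class synthetic generator: wounds with radial-Fourier contours
`ρ(θ) = r₀(1 + Σ a_m cos(mθ + φ_m))`, archetype-specific depth craters (one
per merged clinical category), planar depth tilt, per-archetype colouring,
and simulated raters drawn from per-rater confusion matrices whose exact
pairwise κ is available in closed form.

## Worked example

```python
import periwound as pw
from periwound import agreement, experiments, synthetic

# a 200-wound synthetic cohort rated by four noisy simulated clinicians
truths = [synthetic.ARCHETYPES[i % 5] for i in range(200)]
table = synthetic.simulate_annotations(
    truths, synthetic.default_annotator_panel(), seed=7
)
rep = agreement.pairwise_kappa(table)
print(f"inter-rater kappa = {rep.mean:.3f} +/- {rep.sd:.3f}")

# analyze a single rolled-edge wound
scene = synthetic.generate_scene(
    "rolled_fibrotic", synthetic.scaled_scene_params(0.5), seed=7
)
a = pw.analyze_wound(
    scene.image, scene.mask, scene.depth, experiments.experiment_config()
)
print(f"selected template = {a.fit.selected}")
print(f"rim prominence = {a.features.values['rim_prominence']:.2f}")
print(f"circularity = {a.features.values['circularity']:.3f}")
print(f"plane tilt = ({a.plane.a:.4f}, {a.plane.b:.4f})")
```

prints

```
inter-rater kappa = 0.227 +/- 0.031
selected template = abrupt
rim prominence = 0.35
circularity = 0.990
plane tilt = (0.0203, 0.0098)
```

The simulated panel agrees only weakly (κ ≈ 0.2, the level reported for
expert clinicians), the rolled edge profile is read as an abrupt drop with a
raised rim 0.35 normalized units above the peri-wound baseline, and the
detrending plane recovers the injected depth tilt (0.02, 0.01).

A command-line interface mirrors the library
(`periwound simulate | band | rectify | profiles | features | agree |
cluster | classify | compare`); run `periwound --help`.

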