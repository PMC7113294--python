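# octbiofilm

Quantitative structural analysis of biofilm development from optical
coherence tomography (OCT) C-scans, for labs that monitor biofilms growing
in flow cells with an automated, robot-positioned scanning probe.

Biofilms — surface-attached microbial communities — are routinely imaged
non-invasively with OCT: each C-scan is a 3D intensity volume over a flow
channel, with the substratum (channel floor) at the bottom and the bulk
liquid above. This package turns such volumes, plus the calibration
photographs used to verify the robot's positioning, into the standard
quantitative descriptors, and ships a synthetic phantom generator so the
entire pipeline can be validated without any hardware.

## What it computes

For a binarized volume with N A-scan columns and effective axial voxel
height Δz = Δz_air / n (refractive-index corrected):

- **Substratum coverage** — SC = 100 · A_biofilm / (A_biofilm + A_background),
  counting every pixel ≥ 1 in the z maximum-intensity projection as biomass.
- **Mean biofilm thickness** — L̄_F = (1/N) Σᵢ L_F,i with the local thickness
  L_F,i = (Σ binary column values) · Δz / 255, i.e. biomass voxel count × Δz.
- **Intrinsic porosity** — Φ_intrinsic = 100 · A_voids / (A_biofilm + A_voids)
  from the three-class labeling {biomass 150, void 50, background 0};
  background is excluded.
- **Global porosity** — Φ_global: the non-biomass share of everything beneath
  the bulk–biofilm interface.
- **Textural entropy** — TE = −Σ_{a,b} p(a,b) ln p(a,b) over the pixel-pair
  intensity co-occurrence probabilities of the projection image (nats;
  0 for a homogeneous image).
- **Height maps** — per-column interface topography in µm.

For positioning accuracy: the centre of mass (CoM) of a printed 1 mm disc
is detected in each repeat photograph (mean filter r = 2 px → 8-bit
grayscale → threshold 120 → particle filtering → centroid), deviations
Δx_i = x_i − x̄, Δy_i = y_i − ȳ are summarised per axis, outliers flagged by
the 1.5·IQR rule, and the run judged against the 8 µm optical-resolution
criterion (≥ 75 % of movements within tolerance per axis).

For replicate experiments: per-day two-sided Grubbs tests (iterative
removal), mean/median/sample-SD summaries of the survivors, and annotated
heat-map tables (missing cells blank, outliers marked "o").

## Worked example

```python
from octbiofilm import GrowthParams, structure_report, synth_biofilm_series

params = GrowthParams(void_fraction=0.15, noise_sd=8.0, seed=0)
for vol, truth in synth_biofilm_series(params, days=5):
    rep = structure_report(vol, filter_radius=1, biomass_threshold=90)
    print(truth.day, round(rep.sc_percent, 2), round(rep.mean_thickness_um, 2),
          round(rep.phi_intrinsic_percent, 2), round(rep.textural_entropy, 3))
```

Output (pipeline estimates; `examples/structure_analysis.py` prints them
next to the phantom's ground truth):

```
0 1.48 0.34 26.32 3.741
1 4.76 2.19 16.67 3.895
2 10.12 6.64 16.45 4.137
3 16.8 15.02 14.13 4.414
4 26.28 28.22 14.79 4.719
```

Coverage and thickness climb as colonies spread and merge; porosity stays
near the constructed 15 % void share; TE rises as the projection becomes
more heterogeneous. The estimates track the noise-free ground truth to
within a fraction of a coverage point and about one voxel of thickness.

A thin CLI wraps the same functions for batch runs
(`octbiofilm simulate | analyze | target-accuracy | summarize`); see
`examples/batch_workflow.py`. The other examples cover positioning
accuracy and replicate statistics.

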