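# tagstrain

Detecting infarcted left-ventricular (LV) myocardium from grid-tagged
cardiac MRI — without gadolinium contrast — by tracking the tag texture
through the cardiac cycle, computing circumferential Green–Lagrange
strain, and classifying each AHA segment by the collapse of its strain
H-spread.

Late-gadolinium-enhancement (LGE) imaging is the clinical gold standard
for localising myocardial infarction, but it requires contrast
administration. Tagged MRI imprints a saturation grid (6 mm spacing) on
the tissue at end-diastole (ED); the grid deforms with the muscle, so
intramyocardial motion becomes trackable texture. `tagstrain` implements
the full analysis chain for users of such data (cardiac-MR researchers
and methodologists):

1. **Tracking** — hierarchical normalized-cross-correlation (NCC)
   template matching follows every masked myocardial point from ED to
   end-systole (ES): a coarse-to-fine cascade of templates
   (49/25/13/7 px, search radii 10/6/4/2 px) with quadratic subpixel
   refinement and Gaussian field smoothing.
2. **Strain** — from tracked displacements *u* the deformation gradient
   *F = I + ∇u* (gradients w.r.t. ED coordinates) gives the
   Green–Lagrange tensor *E = ½(FᵀF − I)*, projected onto the local
   circumferential direction: CS = e_cᵀ E e_c. Healthy systole shortens
   circumferentially, so CS < 0 at ES.
3. **AHA partition** — each slice (basal / midventricular / apical) is
   divided into equal-angle sectors (6/6/4, the 16-segment AHA model)
   anchored at the anterior RV insertion.
4. **Detection** — two stages per segment:
   - *benchmark flagging*: median ES strain, ES_calculated = Med(CS_ES),
     is compared with literature healthy benchmarks per slice and wall
     sector; a segment shortening less than the benchmark mean is
     "potentially infarcted";
   - *Infarction Condition*: the H-spread (interquartile range) of the
     per-frame segment-median CS values, H = IQR(S_f1…S_fES), collapses
     in fibrotic tissue. A flagged segment is infarcted when its
     H-spread is reduced by at least α% versus the mean H-spread of the
     unflagged segments of its slice (α = 30/30/20 for
     basal/mid/apical; whole-LV fallback when a slice has no unflagged
     segment).
5. **Evaluation** — confusion statistics, ROC/AUC over the
   H-spread-reduction score, and repeated k-fold cross-validation that
   selects the α maximising training-fold AUC.

Because no public tagged-MRI infarct dataset accompanies the method, the
package ships a first-class phantom: an incompressible annular LV whose
tag texture is advected by a closed-form contraction map
r′(t) = √(r² − c(θ)·Δ(t)), with per-sector contractility c(θ) for
synthetic infarcts, optional twist, tag fading and noise — and analytic
ground-truth strain E_cc = ½(λ_c² − 1) for every point and frame.

## Worked example

```python
import tagstrain as ts

# three-slice synthetic LV with an akinetic lateral-wall territory
lv = ts.simulate_lv(infarcted_segments={5, 6, 11, 12, 16},
                    contractility=0.2, seed=4)
report, series = ts.analyze_lv(lv.sequences)   # track -> strain -> detect
print("true infarcted segments:", sorted(lv.infarcted_segments))
print("detected infarcted     :", report.infarcted_ids)
print(report.to_frame()[["slice_level", "es_calculated", "h_spread",
                         "potentially_infarcted", "reduction_pct",
                         "infarcted"]].round(3).to_string())
```

prints

```
true infarcted segments: [5, 6, 11, 12, 16]
detected infarcted     : [5, 6, 11, 12, 16]
               slice_level  es_calculated  h_spread  potentially_infarcted  reduction_pct  infarcted
segment_id
1                    basal         -0.167     0.102                   True          4.780      False
6                    basal         -0.069     0.049                   True         53.762       True
5                    basal         -0.065     0.024                   True         77.315       True
4                    basal         -0.179     0.098                  False          0.000      False
...
16                  apical         -0.057     0.025                   True         77.859       True
```

Reading the rows: segment 5 shortens only to −0.065 (healthy basal
inferolateral benchmark: −0.21), so it is flagged; its H-spread 0.024 is
77% below the mean H-spread of the unflagged basal segments, far beyond
the 30% basal threshold, so it is classified infarcted. Segment 1 is
flagged (−0.167 vs the −0.20 anterior benchmark) but its H-spread is
healthy-sized (reduction < 5%), so it is correctly kept healthy — that
is exactly the false-positive suppression the second stage exists for.

The command line mirrors the library:

```bash
tagstrain simulate --config phantom.json --out sim/
tagstrain track    --images sim/sequence.tif --mask sim/mask.png --out traj.csv
tagstrain strain   --traj traj.csv --mask sim/mask.png --slice basal --out strain.csv
tagstrain detect   --strain strain.csv --out report.json
tagstrain evaluate --labels labels.csv --k 5 --repeats 10 --seed 17 --out eval/
tagstrain run      --config run.json
```

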