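# nmjquant

Quantitative analysis of *Drosophila* larval neuromuscular-junction (NMJ)
presynapses. The package re-implements, as a reusable and tested pipeline,
the measurement stack commonly assembled from ImageJ macros, spreadsheet
steps and acquisition-software routines in synapse-biology studies:

* **Confocal punctum quantification** — HRP-mask construction, per-slice
  muscle-signal "cleaning", prominence-based maxima detection, seeded
  watershed segmentation, and the standard per-NMJ metrics (mean active-zone
  area, density, mean/total intensity, NMJ length via skeletonization,
  control-normalized percentages).
* **Pearson colocalization** — Costes auto-thresholds on the orthogonal
  regression line, Pearson's r above threshold, and the horizontally flipped
  second channel as a negative control.
* **STED nanoscale analysis** — BRP ring centers of mass in 53 × 53-px ROIs,
  ranked Euclidean distances (k1…k5) from partner-channel maxima to the AZ
  center, AZ size binning, counts within 400 nm, and radial intensity
  profiles with the moments-preserving (Tsai) auto-threshold.
* **Electrophysiology** — Gaussian low-pass filtering, Clements–Bekkers
  template detection of miniature events, 10–90% rise time, exponential
  decay τ, charge, quantal content, paired-pulse ratios, and
  readily-releasable-pool (RRP) estimation by back-extrapolating cumulative
  quantal content of a 61-stimulation, 100-Hz train.
* **Behavior and statistics** — T-maze choice/performance indices, the
  D'Agostino–Pearson-gated test decision tree (t test / ANOVA + Tukey /
  Mann–Whitney), and iterated Grubbs outlier screening.
* **Synthetic data with ground truth** — every input the pipeline consumes
  (NMJ z-stacks with muscle distractors, STED frames, correlated channel
  pairs, mini/train recordings from a depressing release model, T-maze
  counts) can be generated deterministically, so every stage is testable
  without any microscope or rig data.

## The core quantities

For a punctum table of one NMJ with spot areas \(A_i\) and HRP-mask area
\(A_{NMJ}\):

    mean spot area = (1/n) Σ A_i          density = n / A_NMJ
    integrated density = Σ_{x ∈ mask} I(x)

Pearson colocalization above Costes thresholds \((T_1, T_2)\):

    Rcoloc = corr( I_1(x), I_2(x) | I_1(x) > T_1  or  I_2(x) > T_2 )

RRP back-extrapolation from per-stimulus amplitudes \(a_i\) (pre-artifact
baselines) and mean mini amplitude \(q\):

    C_i = Σ_{j ≤ i} |a_j| / |q| ,   OLS of C_i vs i on the last 20 stimuli
    intercept → RRP (quanta),  slope → refill rate (quanta / stimulus)

Behavioral performance index from one reciprocal pair of T-maze runs:

    CI = (n_avoid − n_approach) / n_total ,   PI = (CI_1 + CI_2) / 2

## Worked example

```python
import nmjquant as nq

params = nq.NMJSimParams(n_spots=50, min_separation_um=0.6, seed=1)
stack, truth = nq.make_nmj_stack(params)

cleaned = nq.clean_stack_per_slice(stack, "spots", "HRP", threshold=50.0)
proj = nq.max_project(cleaned, "spots")
maxima = nq.find_maxima(proj, prominence=50.0)
labels = nq.segment_spots(proj, threshold=60.0, maxima=maxima)
table = nq.measure_spots(labels, proj, params.pixel_pitch_um)

hrp_mask = nq.make_mask(nq.max_project(stack, "HRP"), 50.0,
                        pixel_pitch_um=params.pixel_pitch_um)
metrics = nq.nmj_metrics(table, hrp_mask, proj,
                         nmj_length_um=nq.skeleton_length(hrp_mask))
print(f"spots: {metrics.total_spot_count}  "
      f"mean area: {metrics.mean_spot_area_um2:.4f} um^2  "
      f"density: {metrics.spot_density_per_um2:.3f} /um^2  "
      f"NMJ length: {metrics.nmj_length_um:.1f} um")
```

prints

```
spots: 50  mean area: 0.0568 um^2  density: 0.766 /um^2  NMJ length: 29.1 um
```

All 50 simulated puncta are recovered (the generator placed exactly 50
inside the neuronal envelope; the muscle distractors outside it were removed
by the per-slice cleaning step), the mean measured area of the
diffraction-limited puncta is ~0.05 µm² at the chosen threshold, and the
density times the mask area reproduces the count exactly.

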