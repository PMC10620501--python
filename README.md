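# azlmquant

Quantification of endocytosed synaptophysin-pHluorin around individual
active-zone-like membranes in live-cell TIRF recordings — with a synthetic
acquisition simulator that provides full ground truth, so every stage of the
pipeline is verifiable without experimental data.

## The problem

Presynaptic terminals retrieve vesicle membrane through several endocytic
routes — clathrin-mediated endocytosis (CME), activity-dependent bulk
endocytosis (ADBE) and ultrafast endocytosis (UFE) — that differ in timing,
size and temperature sensitivity. One way to watch them in a living neuron:
induce an active-zone-like membrane (AZLM) flat on a neuroligin-coated
coverslip, mark it with CAST-RFP, express synaptophysin tagged with
superecliptic pHluorin (Syp-SEP), and image under TIRF. Rapidly switching
the bath to pH 6.0 quenches all surface SEP; the signal that remains comes
from just-endocytosed vesicles whose lumen is still neutral. Quantifying
those signals — where they sit relative to the AZLM edge, how bright they
are, how their locations change trial to trial — is an image-analysis
pipeline with many coupled conventions. `azlmquant` implements that
pipeline as a tested, reusable library for researchers doing pHluorin-based
endocytosis imaging, together with the forward model needed to validate it.

## What it computes

For a dual-channel recording (SEP green, CAST red) with an acquisition
timeline (frame times, stimulus, pH windows):

- drift compensation (sub-pixel cross-correlation on the CAST channel),
  double-exponential photobleach correction, per-image `mean + 3 SD`
  background thresholds;
- AZLM segmentation (CAST areas in the inclusive 0.098–0.38 um^2 gate) and
  Syp-SEP cluster detection (areas > 0.098 um^2), with watershed splitting
  of merged clusters;
- per-window analysis images (later 4 of 5 frames in each 700 ms pH 6.0
  window averaged, pre-stimulus pH 6.0 image subtracted), influx exclusion,
  intensity-weighted centroids and **signed distances to the AZLM edge**
  (negative inside), cluster metrics (max intensity, area, density),
  trial-to-trial nearest-centroid displacements, normalized time courses
  and decay constants;
- instrument calibrations: single-molecule SEP intensity by change-point
  step-bleach detection, evanescent-field depth constant by exponential
  fit, and 10–90% solution-exchange times;
- seeded synthetic acquisitions (multi-page TIFF + JSON ground-truth
  sidecar) emulating the full physics: evanescent attenuation
  `exp(-z/151 nm)`, PSF blur, quench kinetics, acidification,
  photobleaching, drift, EMCCD-like noise, and mode-specific endocytic
  event statistics (UFE only near physiological temperature).

Results are tidy CSV tables (`edge_distances.csv`, `cluster_metrics.csv`,
`timecourses.csv`) plus a manifest that makes runs reproducible by hash.

## Worked example

```python
from azlmquant import AnalysisConfig
from azlmquant.pipeline import run_simulation, run_analysis

sim = run_simulation("demo", seed=5, preset="rt50")   # 50 pulses, RT
tables = run_analysis(AnalysisConfig(), sim["sep"], sim["cast"])
print(tables["edge_distances"]
      [["timepoint_label", "signed_edge_nm", "excluded"]].round(1))
```

prints (seed 5):

```
   timepoint_label  signed_edge_nm  excluded
0              3.2            43.3     False
1              7.3            44.2     False
2             15.2            59.6     False
```

One clathrin-mediated event was generated at 16 nm outside the AZLM edge in
this trial; the pipeline re-detects it in each post-stimulus pH 6.0 window
(timepoint labels are seconds after the stimulus — 3.24, 7.32 and 15.24 s,
the first analysed frame of each window) at a positive signed distance, i.e. in
the AZLM periphery, and never flags it as influx. Across many seeds the
recovered distances average ~110 nm for events drawn around a 100 nm mean
offset — the geometry the pH 6.0 signal shows around real active zones.

The same flow is available from the shell:

```bash
azlmquant simulate --out sim --seed 5 --preset rt50
azlmquant analyze --sep sim/sep.tif --cast sim/cast.tif \
    --timeline tl.json --out results
azlmquant calibrate --seed 1 --out calibrations.csv
```

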