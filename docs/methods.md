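# Methods

`azlmquant` quantifies endocytosed synaptophysin-pHluorin (Syp-SEP) around
active-zone-like membranes (AZLM) in dual-channel TIRF recordings, and ships
a forward simulator that generates such recordings with complete ground
truth. This note describes the model behind each stage, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish about real recordings.

## The measurement problem

An AZLM is a presynaptic active-zone-like specialization induced flat
against a neuroligin-coated coverslip, so that TIRF illumination (evanescent
field, exponential axial decay) images the release face of the synapse
head-on. CAST-RFP marks the AZLM in the red channel. Syp-SEP reports vesicle
cycling in the green channel: superecliptic pHluorin is fluorescent at
neutral pH and quenched at acid pH. Briefly switching the extracellular bath
to pH 6.0 through a U-tube quenches every surface-exposed SEP; what remains
visible are recently endocytosed vesicles whose lumen is still neutral
(reacidification takes seconds). The pipeline measures, per pH 6.0 window,
where those endocytic signals sit relative to the AZLM edge, how bright and
large they are, and how their positions move between repeated trials.

## Analysis pipeline

Stage order is fixed: drift -> bleach -> threshold -> segment ->
window-average -> subtract -> exclude -> measure.

**Drift.** Stage drift is estimated per frame on the CAST channel (the AZLM
marker barely moves) by upsampled cross-correlation against frame 0, with
sub-pixel precision set by `drift_upsample` (default 1/20 px). The identical
shift is applied to both channels (linear interpolation; out-of-field pixels
filled with the channel's median and flagged). The pipeline replaces the raw
per-frame estimates with a least-squares linear drift model: mechanical
drift is slow and smooth, whereas the raw estimates carry quantization
jitter of order the upsampling step, which would otherwise contaminate
frame-to-frame intensity differences of bright clusters (and with it the
influx-exclusion rule). The raw estimator remains available
(`smooth="none"`) and is exact for integer shifts on noise-free images.

**Bleach.** Photobleaching is corrected by dividing by a normalized
double-exponential `a1*exp(-t/tau1) + a2*exp(-t/tau2)` (a1+a2 = 1, tau1 <=
tau2) fitted to a no-stimulation recording. Division, not subtraction:
bleaching is a multiplicative loss of fluorophores. There is no additive
offset in the model; offsets belong to background subtraction. A constant
trace returns the identity sentinel (tau = inf). The fit tries three
starting points and keeps the best residual; a pure mono-exponential input
yields a degenerate but valid fit (a2 ~ 0 or tau1 ~ tau2).

**Threshold.** The detection threshold is `background mean + k*SD`
(default k = 3), recomputed per analysed image. When no background region
is annotated, the default background is the set of pixels surviving
iterative 3-sigma clipping of the temporal-mean image. Sigma-clipping
removes sparse bright signal but keeps static cellular texture, which *is*
background for thresholding purposes. We initially selected the
lowest-intensity 20% of pixels instead; that samples the lower noise tail
and yields a threshold below the true background level on noise-dominated
fields, so it was replaced.

**Segmentation.** Supra-threshold pixels are grouped into 8-connected
components (4-connectivity would split diagonal blobs at the ~0.1 um^2
scale). CAST components with area inside the inclusive gate
[0.098, 0.38] um^2 are AZLM regions; Syp-SEP components strictly above
0.098 um^2 are signal clusters (the asymmetry mirrors the definitions the
gates come from). Area is the exact pixel count times pixel area — no
rounding before the comparison. AZLM is gated on the drift-corrected
temporal-mean CAST image, exploiting its stability. Merged clusters with
two or more intensity peaks are split by marker-based watershed on the
negative Gaussian-smoothed image (sigma 1 px), seeded at h-maxima with
prominence `1 x background SD`; children always partition the parent pixel
set exactly. skimage's watershed resolves plateau ties deterministically by
processing order.

**pH 6.0 window handling.** Frame timestamps are end-of-exposure, and a
frame belongs to a window only if its timestamp is strictly inside it — a
frame whose exposure ended at the switch was exposed at the previous pH.
With 120 ms frames a 700 ms window opened at a grid-aligned time then holds
exactly five frames; the first (during which the exchange completes) is
skipped and the later four are averaged. The timepoint label is the time of
the first averaged frame, so a window opened 3 s after the stimulus is
analysed "at 3.24 s". From each averaged image the corresponding
pre-stimulus pH 6.0 average is subtracted (post minus pre, preserving
negatives) to remove stimulation-insensitive intracellular signal such as
endoplasmic reticulum. A cluster whose summed intensity rises by more than
`3 x background SD x sqrt(n_pixels)` from the first to the last intra-window
frame is flagged excluded: signal appearing while surface SEP is already
quenched reflects vesicles drifting into the evanescent field, not local
endocytosis.

**Measurements.** Cluster position is the intensity-weighted centroid of
member pixels (nm, from the top-left pixel centre). The signed edge
distance is the minimum distance from the centroid to AZLM boundary-pixel
centres (boundary = member pixels with a 4-neighbour outside), negative
inside the mask. There is no sub-pixel contour interpolation; accuracy is
half a pixel near the edge and up to one pixel deep inside a jagged
discrete circle. With several AZLMs the nearest (smallest |distance|) is
reported. Other measurements: max intensity, area and their ratio (density)
per cluster; nearest-centroid displacement between centroid sets (trial
vs trial, or timepoint vs timepoint); whole-field time courses normalized
by the mean pre-stimulus pH 7.4 intensity, with `F - F_before` referenced
to the designated pre-stimulus pH 6.0 frame; mono-exponential post-peak
decay fits; Pearson correlation between exocytosed (pH 7.4 peak) and
endocytosed (pH 6.0) intensities; and the PT-to-RT brightness rescaling
`value * (I_RT / I_PT)` using the single-molecule calibration intensities
(SEP is ~32% brighter at room temperature).

## Calibrations

*Single-molecule intensity.* Bleach steps are found by binary-segmentation
change-point search minimizing the residual sum of squares, with a minimum
segment of 3 frames and an amplitude floor of 3x the robust noise SD
(median absolute successive difference / sqrt(2)); each break point is then
refined by an exact single-point search between its neighbours, which
removes the edge bias the minimum-segment constraint would otherwise cause
when a molecule bleaches in the first or last frames. Only downward
transitions count as steps. Traces with exactly one step are retained and
their amplitudes averaged.

*Evanescent depth.* `I0*exp(-z/lambda)` is fitted by least squares (no
offset — the instrument calibration reports a single length constant) to a
z-series of a dye-filled tip raised in 125 nm steps; a log-linear fit seeds
the optimizer. Exact on noiseless data; bias < 2% at 3% multiplicative
noise.

*Exchange time.* The 10–90% transition duration operationalizes the
"about X ms" exchange speed, measured by linear interpolation between
samples in the quench (down) or recovery (up) direction; exact on noiseless
traces up to one sample interval.

## Forward simulator

The simulator draws a ground-truth event list and renders both channels.

*Release model.* Expected exocytosis count after p pulses is
`N(p) = N_max*(1 - exp(-p/p0))`, monotone and concave: near-proportional at
5/20/50 pulses and saturating by 125 (depletion of the readily releasable
pool). Defaults `N_max = 180`, `p0 = 150` give N(5) ~ 6 vesicles, the
scale estimated for a 5-pulse train in this preparation. Exocytosed Syp
spreads laterally as a 2-D Gaussian of width
`diffusion_sigma_rate*sqrt(t - t_event)` (default 150 nm/sqrt(s); no
measured rate exists, so this is a free parameter of plausible magnitude).

*Endocytosis model.* Endocytic events land on an annulus around the disc
edge, radial offset ~ Normal(100, 80) nm outside the edge. CME and ADBE
event counts scale with the exocytosed amount (4 expected events per
50-pulse trial at the default mode mix) and occur 0.5–10 s after stimulus
onset; UFE keeps its own base rate (3 expected events per trial), occurs
within 100 ms of the end of the train, and is generated only at
temperatures >= 30 C — a hard gate standing in for the observed room- vs
near-physiological-temperature contrast. Amplitudes per event are free
defaults (CME 30 molecules ~ one 50 nm vesicle; UFE 120 ~ a 100 nm vesicle,
i.e. four vesicle areas; ADBE 240 ~ a bulk endosome). Endocytosed vesicles
sit 50–150 nm above the glass and fade with an acidification constant drawn
uniformly from 3–15 s.

*Rendering.* Each fluorophore contributes
`amplitude x brightness(T) x exp(-z/tirf_depth) x pH factor x bleach factor`,
integrated exactly over pixels through an error-function Gaussian (PSF sigma
default 130 nm; combined in quadrature with the exocytic spread). Surface
fluorophores are quenched to `quench_residual` while the bath is at pH 6.0;
endocytosed ones ignore the bath. The CAST channel renders only the static
AZLM disc. Drift displaces all emitters at `drift_nm_per_s`. Noise is
Poisson shot noise on `signal/photon_scale` scaled back (EM-gain excess
noise folded into `photon_scale`), Gaussian read noise, and a static smooth
background-texture field (Gaussian random field, SD 25 a.u., correlation
4 px in the standard scenario) emulating cellular structure that does not
average out over frames — it is exactly the component the pre-stimulus
subtraction removes. The pH exchange itself is a logistic in time
parameterized by its 10–90% duration (100 ms down, 200 ms up); frames are
treated as exposed entirely at the window's nominal pH, since the standard
protocol does not expose during the transition, while `simulate_ph_trace`
samples the logistic densely (1 ms) for exchange-time calibration.

*Default scenario calibration.* The default CAST disc amplitude (200 a.u.
over a 100 a.u. background with the standard noise) is set so that the
mean+3SD threshold contour of the blurred disc falls inside the AZLM area
gate; the brightest consistent choice would place the contour far down the
PSF tail and the detected component would overflow the gate. The
edge-distance recovery study sharpens this: its CAST amplitude is computed
so the expected threshold contour coincides with the true disc edge radius,
because the recovered distance is referenced to the *detected* edge, and
any contour offset would bias every distance identically. Its background
region is a signal-free corner rectangle (single noisy frames defeat the
clipping heuristic's assumptions less gracefully than temporal means).

*What the simulator omits.* Vector PSF structure, depletion of vesicle
pools across repeated trials, clathrin biochemistry and pharmacology
(inhibitor conditions are represented only as a shifted mode mix), axial
motion of vesicles, intensity fluctuations of single fluorophores
(blinking), and correlated camera artefacts. Passing tests therefore show
that the published measurement procedure recovers the generating parameters
of this model family at realistic SNR; they do not certify performance on
real recordings with un-modelled structure.

## Numerical choices and degenerate inputs

- All randomness flows from `numpy.random.default_rng` seeds; child seeds
  are spawned via `SeedSequence`, and identical seed + configuration gives
  bit-identical stacks, traces and CSVs (manifest hash equality).
- Timepoint labels and window starts must respect the 120 ms frame grid;
  the standard schedule places the stimulus at 8.04 s so the post-stimulus
  windows are phase-aligned (the 7 s window sits at 7.08 s).
- Constant bleach traces return the identity model; zero-variance
  correlation inputs, non-decaying decay fits, empty centroid sets and
  empty AZLM boundaries raise `ValueError` rather than returning NaN.
- Area-gate comparisons are inclusive for AZLM and strict for Syp clusters,
  on exact um^2 values.
- The problem sizes used by the recovery studies (200 z-series, 114
  photobleaching traces, 50 decay traces, 100 rendered frames, 64x64 px
  fields, 400-frame stacks) keep every stage well-sampled while the whole
  suite runs in well under a minute; they match the sample sizes of the
  corresponding bench calibrations where those exist.

## Known limitations

- The boundary-pixel edge-distance convention carries a systematic
  discretization of order half a pixel (~33 nm at the default pixel size);
  the recovery study shows a residual +5 to +10 nm mean bias at a 100 nm
  offset, inside the documented accuracy but visible.
- The influx-exclusion rule is a last-vs-first comparison against
  `k x SD`; slowly rising signals that stay below the threshold pass.
- Watershed children inherit no sub-pixel refinement; deeply merged puncta
  (separation << PSF) are not resolvable and are reported merged.
- `run_analysis` fits nothing per-cell: the bleach model must come from a
  no-stimulation recording supplied by the caller (or the correction is
  skipped).
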