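"""Measurements on segmented recordings.

Covers the full quantification repertoire: pH 6.0 window averaging and
pre-stimulus subtraction, the intra-window influx exclusion rule,
intensity-weighted centroids, signed distances to the AZLM edge, per-cluster
intensity/area/density metrics, the RT/PT brightness correction,
trial-to-trial nearest-centroid displacement, normalized time courses,
post-stimulus decay fitting, the vesicle membrane-area ratio and the
exo-endo intensity correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .io import AcquisitionTimeline, AnalysisConfig, FrameStack, PhWindow, PH_NEUTRAL
from .segment import AZLMRegion, SignalCluster


@dataclass(frozen=True)
class EdgeDistance:
    """Signed distance (nm) from a cluster centroid to the AZLM edge.

    Negative inside the AZLM mask, positive outside; the magnitude is the
    minimum Euclidean distance from the centroid to the centres of the AZLM
    boundary pixels (documented accuracy: half a pixel).
    """

    cluster_label: int
    azlm_label: int
    signed_nm: float


@dataclass(frozen=True)
class TimepointMeasurement:
    timepoint_label: float
    delta_f: float        # F - F_before (designated pre-stimulus pH 6.0 frame)
    normalized_f: float   # F / F_pre (mean pre-stimulus pH 7.4 intensity)


def average_ph6_window(
    stack_or_pixels,
    timeline: AcquisitionTimeline,
    window: PhWindow,
    config: AnalysisConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Average the later frames of one pH 6.0 window.

    Of the (>= 5) frames inside the window the first is skipped and the next
    four are averaged pixel-wise; the timepoint label is the time of the
    first averaged frame (the 3.24 s convention: frames at 3.24-3.60 s
    averaged, analysed at 3.24 s).
    """
    config = config or AnalysisConfig()
    pixels = stack_or_pixels.pixels if isinstance(stack_or_pixels, FrameStack) \
        else np.asarray(stack_or_pixels, dtype=float)
    idx = timeline.frames_in_window(window)
    need = config.ph6_skip_frames + config.ph6_avg_frames
    if idx.size < need:
        raise ValueError(
            f"pH 6.0 window at {window.start} s holds {idx.size} frames; "
            f"{need} required"
        )
    sel = idx[config.ph6_skip_frames:need]
    return pixels[sel].mean(axis=0), float(timeline.frame_times[sel[0]])


def subtract_prestim(img: np.ndarray, prestim_img: np.ndarray) -> np.ndarray:
    """Post-stimulus pH 6.0 image minus the pre-stimulus pH 6.0 image.

    Removes stimulation-insensitive intracellular signal (endoplasmic
    reticulum, neutral endosomes); negative values are retained.
    """
    img = np.asarray(img, dtype=float)
    prestim_img = np.asarray(prestim_img, dtype=float)
    if img.shape != prestim_img.shape:
        raise ValueError(f"grid mismatch: {img.shape} vs {prestim_img.shape}")
    return img - prestim_img


def flag_influx_exclusion(window_trace, background_sd: float,
                          k_excl: float = 3.0) -> bool:
    """Exclusion rule for signal appearing while the pH is already 6.0.

    A rise from the first to the last intra-window sample greater than
    ``k_excl`` background SDs indicates Syp moving into the observation
    field (not endocytosis at this site) and the cluster is excluded.
    """
    trace = np.asarray(window_trace, dtype=float)
    if trace.size < 4:
        raise ValueError(f"need >= 4 intra-window samples, got {trace.size}")
    return bool(trace[-1] - trace[0] > k_excl * background_sd)


def intensity_centroid(frame: np.ndarray, cluster, pixel_size_nm: float
                       ) -> tuple[float, float]:
    """Intensity-weighted centroid of a cluster's member pixels, in nm
    (row, col), measured from the top-left pixel centre."""
    frame = np.asarray(frame, dtype=float)
    mask = cluster.mask if hasattr(cluster, "mask") else np.asarray(cluster, bool)
    rows, cols = np.nonzero(mask)
    w = frame[rows, cols]
    total = w.sum()
    if total <= 0:
        raise ValueError("cluster has non-positive total intensity")
    return (float((w * rows).sum() / total * pixel_size_nm),
            float((w * cols).sum() / total * pixel_size_nm))


def signed_edge_distance(centroid_nm, azlm: AZLMRegion,
                         pixel_size_nm: float) -> EdgeDistance:
    """Signed distance from a centroid to the AZLM edge.

    Magnitude: minimum distance to AZLM boundary-pixel centres. Sign:
    negative iff the centroid falls in a member pixel. No sub-pixel contour
    interpolation: accuracy is half a pixel near the edge and up to one
    pixel for deep interior points (the discrete circle is jagged).
    """
    cy, cx = (float(centroid_nm[0]), float(centroid_nm[1]))
    if not (np.isfinite(cy) and np.isfinite(cx)):
        raise ValueError("centroid must be finite")
    rows, cols = np.nonzero(azlm.boundary)
    if rows.size == 0:
        raise ValueError("AZLM region has no boundary pixels")
    d = float(np.min(np.hypot(rows * pixel_size_nm - cy,
                              cols * pixel_size_nm - cx)))
    r = int(round(cy / pixel_size_nm))
    c = int(round(cx / pixel_size_nm))
    ny, nx = azlm.mask.shape
    inside = 0 <= r < ny and 0 <= c < nx and bool(azlm.mask[r, c])
    return EdgeDistance(cluster_label=0, azlm_label=azlm.label,
                        signed_nm=-d if inside else d)


def nearest_edge_distance(centroid_nm, azlms: list[AZLMRegion],
                          pixel_size_nm: float) -> EdgeDistance:
    """Signed edge distance to the nearest of several AZLM regions."""
    if not azlms:
        raise ValueError("no AZLM regions")
    results = [signed_edge_distance(centroid_nm, a, pixel_size_nm) for a in azlms]
    return min(results, key=lambda e: abs(e.signed_nm))


def cluster_metrics(frame: np.ndarray, cluster: SignalCluster
                    ) -> tuple[float, float, float]:
    """(max_intensity, area_um2, density = max_intensity / area_um2) over the
    cluster's member pixels of the analysis image."""
    frame = np.asarray(frame, dtype=float)
    vals = frame[cluster.mask]
    if vals.size == 0:
        raise ValueError("empty cluster")
    max_i = float(vals.max())
    return max_i, cluster.area_um2, max_i / cluster.area_um2


def temperature_correct(value: float, i_rt: float, i_pt: float) -> float:
    """Rescale a PT intensity-derived value to the RT brightness scale.

    SEP is brighter at room temperature; multiplying by the single-molecule
    brightness ratio ``i_rt / i_pt`` (~1.32) makes PT and RT measurements
    comparable.
    """
    if i_pt <= 0 or i_rt <= 0:
        raise ValueError("calibration intensities must be > 0")
    return value * (i_rt / i_pt)


def nearest_centroid_displacement(set_a, set_b) -> np.ndarray:
    """For each centroid in ``set_a``, the Euclidean distance (nm) to its
    nearest neighbour in ``set_b``."""
    a = np.atleast_2d(np.asarray(set_a, dtype=float))
    b = np.atleast_2d(np.asarray(set_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both centroid sets must be non-empty")
    return cdist(a, b).min(axis=1)


def normalized_timecourse(trace, timeline: AcquisitionTimeline,
                          config: AnalysisConfig | None = None
                          ) -> list[TimepointMeasurement]:
    """Per-frame normalized intensities of a cluster/field trace.

    ``normalized_f`` divides by the mean of all pre-stimulus pH 7.4 frames;
    ``delta_f`` subtracts the value at the designated pre-stimulus pH 6.0
    frame (the first analysed frame of the last pre-stimulus window, the
    "3.88 s before the stimulation" convention). ``delta_f`` is NaN when no
    pre-stimulus pH 6.0 window exists; it may be slightly negative under
    noise.
    """
    config = config or AnalysisConfig()
    trace = np.asarray(trace, dtype=float)
    if timeline.stim_onset is None:
        raise ValueError("timeline has no stimulation onset")
    t = timeline.frame_times
    ph = np.asarray(timeline.ph_at(t))
    pre74 = (t < timeline.stim_onset) & (ph == PH_NEUTRAL)
    if not pre74.any():
        raise ValueError("no pre-stimulus pH 7.4 frames")
    f_pre = trace[pre74].mean()
    if f_pre <= 0:
        raise ValueError("pre-stimulus baseline is not positive")
    pre_acid = [w for w in timeline.acid_windows() if w.end <= timeline.stim_onset]
    ref = np.nan
    if pre_acid:
        idx = timeline.frames_in_window(pre_acid[-1])
        if idx.size > config.ph6_skip_frames:
            ref = trace[idx[config.ph6_skip_frames]]
    return [
        TimepointMeasurement(timepoint_label=float(tt),
                             delta_f=float(v - ref),
                             normalized_f=float(v / f_pre))
        for tt, v in zip(t, trace)
    ]


def fit_decay_constant(times, values, t_start: float) -> float:
    """Mono-exponential decay constant of the post-peak trace segment.

    Fits ``A * exp(-(t - t_start)/tau) + c`` by least squares on frames at
    ``t >= t_start``; raises on a non-decaying segment.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    sel = t >= t_start
    t, y = t[sel], y[sel]
    if t.size < 4:
        raise ValueError("too few post-peak samples")
    if y[-1] >= y[0]:
        raise ValueError("trace does not decay after t_start")
    t0 = t[0]

    def model(tt, a, tau, c):
        return a * np.exp(-(tt - t0) / tau) + c

    span = t[-1] - t[0]
    p0 = (y[0] - y[-1], span / 3.0, y[-1])
    popt, _ = curve_fit(model, t, y, p0=p0,
                        bounds=([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                        maxfev=20000)
    return float(popt[1])


def membrane_area_ratio(d_large: float, d_small: float) -> float:
    """Sphere-surface-area ratio of two vesicles given their diameters.

    A 100 nm endocytic vesicle internalizes the membrane of
    ``(100/50)^2 = 4`` standard 50 nm synaptic vesicles.
    """
    if d_large <= 0 or d_small <= 0:
        raise ValueError("diameters must be > 0")
    return (d_large / d_small) ** 2


def exo_endo_correlation(peak_ph74, ph6_intensity) -> float:
    """Pearson correlation between per-cluster exocytosed (pH 7.4 peak) and
    endocytosed (pH 6.0) Syp-SEP intensities."""
    x = np.asarray(peak_ph74, dtype=float)
    y = np.asarray(ph6_intensity, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(pearsonr(x, y)[0])
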