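"""Instrument calibrations: single-molecule brightness via step-bleach
detection, evanescent-field depth constant, and U-tube solution-exchange
times.

These mirror the three calibrations every quantitative TIRF/pHluorin
recording depends on: the brightness of a single SEP molecule (detected by
its single-step photobleach), the axial length constant of the evanescent
excitation field, and the 10-90% pH exchange durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class StepFit:
    """Piecewise-constant change-point fit of one photobleaching trace."""

    n_steps: int
    step_frames: list[int]
    amplitudes: list[float]   # downward drops, positive values
    residual: float

    def __post_init__(self) -> None:
        if not (self.n_steps == len(self.step_frames) == len(self.amplitudes)):
            raise ValueError("inconsistent step fit")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("step amplitudes must be > 0")


@dataclass
class CalibrationResult:
    single_mol_mean: float
    single_mol_sem: float
    n_molecules: int
    depth_nm: float
    exchange_down_ms: float
    exchange_up_ms: float

    def __post_init__(self) -> None:
        if self.single_mol_sem < 0:
            raise ValueError("sem must be >= 0")
        if self.depth_nm <= 0:
            raise ValueError("depth_nm must be > 0")


def _robust_noise_sd(trace: np.ndarray) -> float:
    """Noise SD from the median absolute successive difference (insensitive
    to the bleach steps themselves)."""
    d = np.diff(trace)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def _best_split(y: np.ndarray, min_size: int) -> tuple[int, float, float]:
    """Best single change point by residual-sum-of-squares reduction.

    Returns (index, rss_gain, mean_difference); index such that the segments
    are y[:index] and y[index:]. Index -1 when no admissible split exists.
    """
    n = y.size
    if n < 2 * min_size:
        return -1, 0.0, 0.0
    cs = np.cumsum(y)
    total = cs[-1]
    ks = np.arange(min_size, n - min_size + 1)
    left = cs[ks - 1]
    mean_l = left / ks
    mean_r = (total - left) / (n - ks)
    gain = ks * (n - ks) / n * (mean_l - mean_r) ** 2
    best = int(np.argmax(gain))
    k = int(ks[best])
    return k, float(gain[best]), float(mean_l[best] - mean_r[best])


def detect_bleach_steps(trace, amplitude_floor: float | None = None,
                        min_size: int = 3) -> StepFit:
    """Detect photobleaching steps by binary-segmentation change-point search.

    Recursively places the change point that most reduces the residual sum
    of squares; a split is kept only when the segment-mean difference
    exceeds the amplitude floor (default: 3x the robust noise SD estimated
    from successive differences). Only downward transitions count as bleach
    steps. A flat trace yields 0 steps.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 10:
        raise ValueError(f"trace too short ({y.size} < 10 frames)")
    sigma = _robust_noise_sd(y)
    floor = amplitude_floor if amplitude_floor is not None else 3.0 * sigma

    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        k, gain, dmean = _best_split(y[lo:hi], min_size)
        if k < 0 or abs(dmean) <= max(floor, 0.0) or abs(dmean) == 0.0:
            return
        breakpoints.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, y.size)
    breakpoints.sort()
    # local refinement: the min-size constraint of the global search can
    # misplace a change point that falls within min_size of a segment end,
    # contaminating the neighbouring mean; re-locate each break point by an
    # exact single-point search between its neighbours
    for _ in range(2):
        moved = False
        for i, bp in enumerate(breakpoints):
            lo = (breakpoints[i - 1] + 1) if i > 0 else 1
            hi = (breakpoints[i + 1] - 1) if i + 1 < len(breakpoints) else y.size - 1
            lo = max(lo, bp - 2 * min_size)
            hi = min(hi, bp + 2 * min_size)
            best_k, best_rss = bp, np.inf
            for k in range(lo, hi + 1):
                seg_l = y[(breakpoints[i - 1] if i > 0 else 0):k]
                seg_r = y[k:(breakpoints[i + 1] if i + 1 < len(breakpoints)
                             else y.size)]
                rss = seg_l.var() * seg_l.size + seg_r.var() * seg_r.size
                if rss < best_rss:
                    best_k, best_rss = k, rss
            if best_k != bp:
                breakpoints[i] = best_k
                moved = True
        if not moved:
            break
    bounds = [0] + breakpoints + [y.size]
    means = [y[a:b].mean() for a, b in zip(bounds, bounds[1:])]
    residual = float(sum(((y[a:b] - m) ** 2).sum()
                         for (a, b), m in zip(zip(bounds, bounds[1:]), means)))
    frames, amps = [], []
    for i, bp in enumerate(breakpoints):
        drop = means[i] - means[i + 1]
        if drop > max(floor, 0.0):
            frames.append(int(bp))
            amps.append(float(drop))
    return StepFit(n_steps=len(frames), step_frames=frames,
                   amplitudes=amps, residual=residual)


def single_molecule_intensity(traces, amplitude_floor: float | None = None
                              ) -> tuple[float, float, int]:
    """Mean single-molecule intensity from step-bleach traces.

    Only traces with exactly one detected bleach step are retained (multi-
    step traces are multi-emitter spots); returns the mean, standard error
    and count of the retained step amplitudes.
    """
    amps = []
    for tr in traces:
        fit = detect_bleach_steps(tr, amplitude_floor=amplitude_floor)
        if fit.n_steps == 1:
            amps.append(fit.amplitudes[0])
    if not amps:
        raise ValueError("no single-step traces retained")
    arr = np.asarray(amps)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem, int(arr.size)


def fit_length_constant(z_values, intensities) -> float:
    """Evanescent-field length constant from a z-series.

    Least-squares fit of ``I(z) = I0 * exp(-z / lambda)`` (no offset; the
    emulated calibration reports a single length constant). Returns lambda
    in the units of ``z_values``.
    """
    z = np.asarray(z_values, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if np.unique(z).size < 3:
        raise ValueError("need >= 3 distinct z values")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")
    slope = np.polyfit(z, np.log(y), 1)[0]
    if slope >= 0:
        raise ValueError("intensity does not decay with z")
    lam0 = -1.0 / slope
    popt, _ = curve_fit(lambda zz, i0, lam: i0 * np.exp(-zz / lam),
                        z, y, p0=(float(y.max()), lam0), maxfev=10000)
    return float(popt[1])


def measure_exchange_time(times, values, direction: str = "down",
                          window: tuple[float, float] | None = None) -> float:
    """10-90% transition duration (ms) of a quench or recovery trace.

    ``direction='down'`` measures the fall into the pH 6.0 plateau,
    ``'up'`` the recovery; crossing times are linearly interpolated between
    samples, so the result is exact up to one sample interval.
    ``window=(t0, t1)`` optionally restricts the trace to one transition.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, v = t[sel], v[sel]
    if t.size < 3:
        raise ValueError("trace too short")
    v_hi, v_lo = float(v.max()), float(v.min())
    if v_hi - v_lo <= 0:
        raise ValueError("no transition in trace")
    imin = int(np.argmin(v))
    thr10 = v_hi - 0.10 * (v_hi - v_lo)
    thr90 = v_hi - 0.90 * (v_hi - v_lo)
    if direction == "down":
        seg_t, seg_v = t[: imin + 1], v[: imin + 1]
        if seg_t.size < 2 or seg_v[0] < thr10:
            raise ValueError("downward transition not bracketed by the trace")
        t10 = _cross_time(seg_t, seg_v, thr10, falling=True)
        t90 = _cross_time(seg_t, seg_v, thr90, falling=True)
    elif direction == "up":
        seg_t, seg_v = t[imin:], v[imin:]
        if seg_t.size < 2 or seg_v[-1] < thr10:
            raise ValueError("upward transition not bracketed by the trace")
        t10 = _cross_time(seg_t, seg_v, thr90, falling=False)  # 10% recovered
        t90 = _cross_time(seg_t, seg_v, thr10, falling=False)  # 90% recovered
    else:
        raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")
    return (t90 - t10) * 1000.0


def _cross_time(t: np.ndarray, v: np.ndarray, threshold: float,
                falling: bool) -> float:
    """First time the trace crosses ``threshold``, linearly interpolated."""
    if falling:
        idx = np.nonzero(v <= threshold)[0]
    else:
        idx = np.nonzero(v >= threshold)[0]
    if idx.size == 0:
        raise ValueError("transition not bracketed by the trace")
    i = int(idx[0])
    if i == 0:
        return float(t[0])
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t[i])
    frac = (threshold - v0) / (v1 - v0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))
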