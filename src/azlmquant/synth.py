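"""Synthetic TIRF acquisition simulator with full ground truth.

The forward model emulates the experiment end to end: an active-zone-like
membrane (AZLM) disc in the CAST channel; stimulus-evoked exocytosis inside
the disc with lateral spread of surface synaptophysin; endocytic puncta
appearing on an annulus around the disc edge with mode-specific timing
(CME/ADBE on a seconds scale, UFE sub-second and only near physiological
temperature); quenching of surface SEP during pH 6.0 windows with the
configured exchange kinetics; intravesicular acidification over seconds;
evanescent-field axial attenuation ``exp(-z/depth)``; Gaussian PSF blur;
shot + read noise; double-exponential photobleaching; and slow stage drift.

Every public generator takes a ``seed`` and is bit-reproducible for a fixed
seed and configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from scipy.special import erf

from .io import AcquisitionTimeline, FrameStack, PhWindow, PH_ACID, PH_NEUTRAL
from .preprocess import BleachModel

LOG9 = math.log(9.0)  # logistic scale <-> 10-90% duration conversion

# Mode-specific defaults for endocytic events. Amplitudes are free parameters
# (molecule counts per internalized structure are not measured here): one
# ~50 nm synaptic vesicle carries ~30 synaptophysin copies; a UFE vesicle
# (~100 nm) internalizes the membrane area of ~4 vesicles; an ADBE endosome
# is larger still.
MODE_AMPLITUDE = {"CME": 30.0, "ADBE": 240.0, "UFE": 120.0}
UFE_TEMPERATURE_C = 30.0  # hard gate: RT (21-23 C) vs PT (31-32 C)


@dataclass(frozen=True)
class OpticsConfig:
    """Optical parameters of the simulated TIRF system.

    ``pixel_size_nm`` defaults to 66.7 nm (150x objective with a 1.6x
    intermediate lens and a 16 um-pixel EMCCD). ``tirf_depth_nm`` is the
    evanescent-field length constant; 151 nm is the calibrated value of the
    emulated instrument. Brightness is per SEP molecule in camera units and
    is temperature dependent (SEP is brighter at room temperature).
    """

    pixel_size_nm: float = 66.7
    psf_sigma_nm: float = 130.0
    tirf_depth_nm: float = 151.0
    quench_residual: float = 0.0
    sep_brightness_rt: float = 2900.0
    sep_brightness_pt: float = 2200.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "psf_sigma_nm", "tirf_depth_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.quench_residual < 0.1):
            raise ValueError("quench_residual must be in [0, 0.1)")
        if self.sep_brightness_rt <= 0 or self.sep_brightness_pt <= 0:
            raise ValueError("brightness values must be > 0")

    def brightness(self, temperature_C: float) -> float:
        return (self.sep_brightness_pt if temperature_C >= UFE_TEMPERATURE_C
                else self.sep_brightness_rt)


@dataclass(frozen=True)
class NoiseConfig:
    """EMCCD-like noise: Poisson shot noise on ``signal/photon_scale`` scaled
    back up, plus Gaussian read noise. ``photon_scale <= 0`` disables shot
    noise; all-zero config leaves frames noiseless.

    ``background_texture_sd`` adds a *static* smooth random field (SD in
    camera units, correlation length ``texture_corr_px``) emulating cellular
    background structure — out-of-focus membrane, endoplasmic reticulum —
    that does not average away over frames. It is the component the
    pre-stimulus subtraction removes, and it keeps per-image background SDs
    realistic on temporal means.
    """

    photon_scale: float = 0.0
    read_noise_sd: float = 0.0
    background_level: float = 100.0
    background_texture_sd: float = 0.0
    texture_corr_px: float = 4.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.background_texture_sd < 0:
            raise ValueError("background_texture_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruthEvent:
    """One exocytic or endocytic ground-truth event.

    Positions are nm relative to the AZLM centre; ``z_nm`` is height above
    the coverslip. ``acidification_tau`` (endo only) is the seconds-scale
    reacidification constant of the internalized vesicle;
    ``diffusion_sigma_rate`` (exo only) is the lateral spread rate of
    surface synaptophysin in nm per sqrt(s).
    """

    kind: str  # {"exo", "endo"}
    mode: str  # {"CME", "ADBE", "UFE", "none"}
    t_event: float
    xy_nm: tuple[float, float]
    z_nm: float
    amplitude_molecules: float
    acidification_tau: float | None = None
    diffusion_sigma_rate: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("exo", "endo"):
            raise ValueError(f"kind must be exo/endo, got {self.kind!r}")
        if self.mode not in ("CME", "ADBE", "UFE", "none"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.t_event < 0:
            raise ValueError("t_event must be >= 0")
        if self.z_nm < 0:
            raise ValueError("z_nm must be >= 0")
        if self.amplitude_molecules <= 0:
            raise ValueError("amplitude_molecules must be > 0")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "mode": self.mode, "t_event": self.t_event,
            "xy_nm": list(self.xy_nm), "z_nm": self.z_nm,
            "amplitude_molecules": self.amplitude_molecules,
            "acidification_tau": self.acidification_tau,
            "diffusion_sigma_rate": self.diffusion_sigma_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthEvent":
        d = dict(d)
        d["xy_nm"] = tuple(d["xy_nm"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Complete simulator ground truth for one recording."""

    azlm_center_nm: tuple[float, float] = (0.0, 0.0)
    azlm_radius_nm: float = 252.3  # disc area 0.2 um^2, inside the AZLM gate
    events: list[GroundTruthEvent] = field(default_factory=list)
    drift_nm_per_s: tuple[float, float] = (0.0, 0.0)
    bleach: BleachModel = field(default_factory=BleachModel.identity)
    exchange_down_ms: float = 100.0
    exchange_up_ms: float = 200.0
    temperature_C: float = 22.0

    def __post_init__(self) -> None:
        area = math.pi * (self.azlm_radius_nm / 1000.0) ** 2
        if not (0.098 <= area <= 0.38):
            raise ValueError(
                f"AZLM disc area {area:.3f} um^2 outside the [0.098, 0.38] gate"
            )
        if self.exchange_down_ms <= 0 or self.exchange_up_ms <= 0:
            raise ValueError("exchange times must be > 0")

    @property
    def azlm_area_um2(self) -> float:
        return math.pi * (self.azlm_radius_nm / 1000.0) ** 2

    def to_dict(self) -> dict:
        return {
            "azlm_center_nm": list(self.azlm_center_nm),
            "azlm_radius_nm": self.azlm_radius_nm,
            "events": [e.to_dict() for e in self.events],
            "drift_nm_per_s": list(self.drift_nm_per_s),
            "bleach": self.bleach.to_dict(),
            "exchange_down_ms": self.exchange_down_ms,
            "exchange_up_ms": self.exchange_up_ms,
            "temperature_C": self.temperature_C,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["azlm_center_nm"] = tuple(d["azlm_center_nm"])
        d["drift_nm_per_s"] = tuple(d["drift_nm_per_s"])
        d["events"] = [GroundTruthEvent.from_dict(e) for e in d["events"]]
        d["bleach"] = BleachModel.from_dict(d["bleach"])
        return cls(**d)


def make_timeline(
    frame_interval: float,
    duration: float,
    stim_onset: float | None = None,
    n_pulses: int = 0,
    ph6_starts=(),
    ph6_duration: float = 0.7,
    pulse_rate: float = 50.0,
    temperature_C: float = 22.0,
) -> AcquisitionTimeline:
    """Build the acquisition schedule.

    Frame timestamps are end-of-exposure, ``t_i = (i+1)*frame_interval``; with
    the standard 120 ms interval a 700 ms pH 6.0 window opened at 3.0 s then
    contains exactly the five frames 3.12-3.60 s, of which the later four are
    averaged downstream.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(math.floor(duration / frame_interval + 1e-9))
    if n == 0:
        raise ValueError("duration shorter than one frame interval")
    frame_times = frame_interval * np.arange(1, n + 1)
    windows = tuple(PhWindow(float(s), float(ph6_duration), PH_ACID)
                    for s in ph6_starts)
    return AcquisitionTimeline(
        frame_times=frame_times,
        exposure=frame_interval,
        stim_onset=stim_onset,
        n_pulses=int(n_pulses),
        pulse_rate=pulse_rate,
        ph_windows=windows,
        temperature_C=temperature_C,
    )


def expected_exo_count(n_pulses: float, n_max: float = 180.0,
                       p0: float = 150.0) -> float:
    """Expected number of exocytosed vesicles after ``n_pulses`` pulses.

    ``N(p) = N_max * (1 - exp(-p/p0))``: near-proportional for 5/20/50 pulses
    and saturating by 125, reflecting depletion of the readily releasable
    pool. Defaults give N(5) ~ 6 vesicles.
    """
    if n_pulses < 0:
        raise ValueError("n_pulses must be >= 0")
    return n_max * (1.0 - math.exp(-n_pulses / p0))


def simulate_events(
    n_pulses: int,
    temperature_C: float = 22.0,
    mode_mix: dict[str, float] | None = None,
    seed: int | None = None,
    *,
    stim_onset: float = 8.0,
    pulse_rate: float = 50.0,
    azlm_area_um2: float = 0.2,
    n_max: float = 180.0,
    p0: float = 150.0,
    endo_events_at_50: float = 4.0,
    ufe_events_base: float = 3.0,
    endo_offset_mean_nm: float = 100.0,
    endo_offset_sd_nm: float = 80.0,
    exo_amplitude: float = 30.0,
    diffusion_sigma_rate: float = 150.0,
    drift_nm_per_s: tuple[float, float] = (1.5, -1.0),
    bleach: BleachModel | None = None,
) -> GroundTruth:
    """Draw a seeded ground-truth event list for one stimulation trial.

    Exocytosis events land uniformly inside the AZLM disc during the pulse
    train, with count Poisson(N(p)). Endocytic events are placed on an
    annulus around the disc edge (radial offset ~ Normal(mean, sd) outside
    the edge); their expected count scales with the exocytosed amount.
    Mode timing: UFE within 0.1 s of the end of the train and only at
    >= 30 C; CME/ADBE at 0.5-10 s after stimulus onset. CME/ADBE counts
    scale with the exocytosed amount; UFE retrieves membrane locally per
    stimulus and keeps its own base rate, which makes it the dominant mode
    for small pulse numbers at PT. Acidification constants are uniform on
    [3, 15] s.
    """
    if n_pulses < 0:
        raise ValueError("n_pulses must be >= 0")
    if mode_mix is None:
        mode_mix = ({"CME": 0.25, "ADBE": 0.25, "UFE": 0.5}
                    if temperature_C >= UFE_TEMPERATURE_C
                    else {"CME": 0.5, "ADBE": 0.5, "UFE": 0.0})
    total = sum(mode_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"mode_mix must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    radius = 1000.0 * math.sqrt(azlm_area_um2 / math.pi)
    gt = GroundTruth(
        azlm_radius_nm=radius,
        drift_nm_per_s=drift_nm_per_s,
        bleach=bleach if bleach is not None else BleachModel.identity(),
        temperature_C=temperature_C,
    )
    if n_pulses == 0:
        return gt

    n_exp = expected_exo_count(n_pulses, n_max=n_max, p0=p0)
    train = n_pulses / pulse_rate
    n_exo = rng.poisson(n_exp)
    for _ in range(n_exo):
        r = radius * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        gt.events.append(GroundTruthEvent(
            kind="exo", mode="none",
            t_event=float(stim_onset + rng.uniform(0, train)),
            xy_nm=(r * math.sin(th), r * math.cos(th)),
            z_nm=0.0,
            amplitude_molecules=exo_amplitude,
            diffusion_sigma_rate=diffusion_sigma_rate,
        ))

    ref = expected_exo_count(50, n_max=n_max, p0=p0)
    scale = n_exp / ref if ref > 0 else 0.0
    for mode, frac in mode_mix.items():
        if frac <= 0:
            continue
        if mode == "UFE" and temperature_C < UFE_TEMPERATURE_C:
            continue  # UFE does not occur at room temperature
        if mode == "UFE":
            n_mode = rng.poisson(frac * ufe_events_base)
        else:
            n_mode = rng.poisson(frac * endo_events_at_50 * scale)
        for _ in range(n_mode):
            offset = rng.normal(endo_offset_mean_nm, endo_offset_sd_nm)
            r = max(radius + offset, 0.25 * radius)
            th = rng.uniform(0, 2 * math.pi)
            if mode == "UFE":
                t = stim_onset + train + rng.uniform(0, 0.1)
            else:
                t = stim_onset + rng.uniform(0.5, 10.0)
            gt.events.append(GroundTruthEvent(
                kind="endo", mode=mode,
                t_event=float(t),
                xy_nm=(r * math.sin(th), r * math.cos(th)),
                z_nm=float(rng.uniform(50.0, 150.0)),
                amplitude_molecules=MODE_AMPLITUDE[mode],
                acidification_tau=float(rng.uniform(3.0, 15.0)),
            ))
    gt.events.sort(key=lambda e: e.t_event)
    return gt


def _add_gaussian_blob(img: np.ndarray, y_nm: float, x_nm: float,
                       total: float, sigma_nm: float, px_nm: float) -> None:
    """Add a 2-D Gaussian of integrated intensity ``total`` to ``img``.

    Pixel values are the exact integral of the Gaussian over each pixel
    (difference of error functions), so the blob's summed intensity equals
    ``total`` whenever it lies inside the frame.
    """
    ny, nx = img.shape
    s = sigma_nm * math.sqrt(2.0)
    halfw = 5.0 * sigma_nm / px_nm + 1
    r0 = max(int(y_nm / px_nm - halfw), 0)
    r1 = min(int(y_nm / px_nm + halfw) + 1, ny)
    c0 = max(int(x_nm / px_nm - halfw), 0)
    c1 = min(int(x_nm / px_nm + halfw) + 1, nx)
    if r0 >= r1 or c0 >= c1:
        return
    # pixel (r, c) spans [(r-0.5)px, (r+0.5)px] in nm (centres at r*px)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    ey = erf(((rows + 0.5) * px_nm - y_nm) / s) - erf(((rows - 0.5) * px_nm - y_nm) / s)
    ex = erf(((cols + 0.5) * px_nm - x_nm) / s) - erf(((cols - 0.5) * px_nm - x_nm) / s)
    img[r0:r1, c0:c1] += (total / 4.0) * np.outer(ey, ex)


def _quench_level(t: float, timeline: AcquisitionTimeline,
                  down_ms: float, up_ms: float) -> float:
    """Fraction of surface-SEP quench at time ``t`` (0 neutral, 1 fully acid).

    Logistic transitions parameterized by their 10-90% durations, centred on
    each pH window's start (downward) and end (upward)."""
    s_down = (down_ms / 1000.0) / (2.0 * LOG9)
    s_up = (up_ms / 1000.0) / (2.0 * LOG9)
    q = 0.0
    for w in timeline.acid_windows():
        down = 1.0 / (1.0 + math.exp(-(t - w.start) / s_down))
        up = 1.0 / (1.0 + math.exp(-(t - w.end) / s_up))
        q += down * (1.0 - up)
    return min(q, 1.0)


def render_stack(
    gt: GroundTruth,
    timeline: AcquisitionTimeline,
    optics: OpticsConfig,
    noise: NoiseConfig,
    channel: str = "SEP",
    seed: int | None = None,
    shape: tuple[int, int] = (64, 64),
    cast_amplitude: float = 200.0,
    sharp_ph: bool = True,
) -> FrameStack:
    """Render one channel of the acquisition as a :class:`FrameStack`.

    Per frame, each fluorophore contributes
    ``amplitude * brightness * exp(-z/tirf_depth) * pH factor * bleach``
    blurred by the Gaussian PSF; stage drift displaces all emitters; the CAST
    channel renders only the static AZLM disc. ``sharp_ph=True`` treats the
    pH exchange as complete at every frame time (frames are not exposed
    during the ~100-200 ms transitions in the emulated protocol); set False
    to apply the logistic exchange kinetics at each frame time.
    """
    if channel not in ("SEP", "CAST"):
        raise ValueError(f"channel must be SEP or CAST, got {channel!r}")
    px = optics.pixel_size_nm
    ny, nx = shape
    center = np.array([(ny - 1) / 2.0 * px + gt.azlm_center_nm[0],
                       (nx - 1) / 2.0 * px + gt.azlm_center_nm[1]])
    rng = np.random.default_rng(seed)
    brightness = optics.brightness(gt.temperature_C)
    frames = np.zeros((timeline.n_frames, ny, nx), dtype=float)

    yy, xx = np.meshgrid(np.arange(ny) * px, np.arange(nx) * px, indexing="ij")
    for i, t in enumerate(timeline.frame_times):
        img = frames[i]
        drift = np.array(gt.drift_nm_per_s) * t
        if channel == "CAST":
            cy, cx = center + drift
            d = np.hypot(yy - cy, xx - cx)
            disc = np.clip((gt.azlm_radius_nm - d) / px + 0.5, 0.0, 1.0)
            img += cast_amplitude * ndi.gaussian_filter(disc, optics.psf_sigma_nm / px)
            continue
        if sharp_ph:
            quench = 1.0 if timeline.ph_at(t) == PH_ACID else 0.0
        else:
            quench = _quench_level(float(t), timeline, gt.exchange_down_ms,
                                   gt.exchange_up_ms)
        surface_factor = 1.0 - (1.0 - optics.quench_residual) * quench
        bleach = float(gt.bleach.factor(t))
        for ev in gt.events:
            if t < ev.t_event:
                continue
            amp = ev.amplitude_molecules * brightness * bleach
            if ev.kind == "exo":
                amp *= surface_factor  # surface-exposed: quenched at pH 6.0
                rate = ev.diffusion_sigma_rate or 0.0
                spread = rate * math.sqrt(t - ev.t_event)
                sigma = math.hypot(optics.psf_sigma_nm, spread)
            else:
                # intravesicular lumen stays neutral until reacidified, so
                # extracellular pH does not touch it; brightness fades with
                # the acidification constant and the evanescent field
                amp *= math.exp(-ev.z_nm / optics.tirf_depth_nm)
                if ev.acidification_tau:
                    amp *= math.exp(-(t - ev.t_event) / ev.acidification_tau)
                sigma = optics.psf_sigma_nm
            if amp <= 0:
                continue
            y = center[0] + ev.xy_nm[0] + drift[0]
            x = center[1] + ev.xy_nm[1] + drift[1]
            _add_gaussian_blob(img, y, x, amp, sigma, px)

    frames += noise.background_level
    if noise.background_texture_sd > 0:
        field = ndi.gaussian_filter(rng.standard_normal((ny, nx)),
                                    noise.texture_corr_px)
        field *= noise.background_texture_sd / max(field.std(), 1e-12)
        frames += np.clip(field, -noise.background_level, None)
    if noise.photon_scale > 0:
        frames = rng.poisson(np.clip(frames, 0, None) / noise.photon_scale
                             ) * noise.photon_scale
        frames = frames.astype(float)
    if noise.read_noise_sd > 0:
        frames += rng.normal(0.0, noise.read_noise_sd, size=frames.shape)
    return FrameStack(channel=channel, pixels=frames,
                      pixel_size_nm=px, timeline=timeline)


def simulate_single_molecule_traces(
    n: int,
    amplitude: float,
    read_noise_sd: float,
    n_frames: int,
    seed: int | None = None,
    background: float = 0.0,
) -> np.ndarray:
    """Single-molecule photobleaching traces: constant at ``amplitude`` until a
    uniform-random bleach frame, then background, plus Gaussian read noise.

    Returns an ``(n, n_frames)`` array. ``amplitude = 0`` gives flat
    background traces."""
    if n <= 0 or n_frames <= 0:
        raise ValueError("n and n_frames must be > 0")
    rng = np.random.default_rng(seed)
    traces = np.full((n, n_frames), background, dtype=float)
    if amplitude != 0:
        bleach_at = rng.integers(1, n_frames, size=n)
        idx = np.arange(n_frames)[None, :]
        traces += np.where(idx < bleach_at[:, None], amplitude, 0.0)
    if read_noise_sd > 0:
        traces += rng.normal(0.0, read_noise_sd, size=traces.shape)
    return traces


def simulate_ztip_series(
    depth_nm: float,
    z_values,
    cv_noise: float = 0.0,
    seed: int | None = None,
    i0: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evanescent-depth calibration series: ``I(z) = i0*exp(-z/depth)*(1+eps)``
    with multiplicative Gaussian noise of coefficient of variation
    ``cv_noise``. The emulated protocol raises the dye-filled tip at 125 nm
    steps from the glass surface."""
    z = np.asarray(z_values, dtype=float)
    if np.any(z < 0):
        raise ValueError("z_values must be non-negative")
    if depth_nm <= 0:
        raise ValueError("depth_nm must be > 0")
    intensity = i0 * np.exp(-z / depth_nm)
    if cv_noise > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + rng.normal(0.0, cv_noise, size=z.shape))
    return z, intensity


def simulate_ph_trace(
    timeline: AcquisitionTimeline,
    exchange_down_ms: float = 100.0,
    exchange_up_ms: float = 200.0,
    noise_sd: float = 0.0,
    dt: float = 1e-3,
    seed: int | None = None,
    quench_residual: float = 0.0,
    i0: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface-SEP fluorescence through the U-tube pH exchanges.

    The quench follows a smooth logistic whose 10-90% duration equals the
    configured exchange time in each direction. Sampled densely (default
    1 ms) because the exchange is faster than the imaging frame interval.
    Returns ``(times, intensity)``.
    """
    if exchange_down_ms <= 0 or exchange_up_ms <= 0:
        raise ValueError("exchange times must be > 0")
    windows = timeline.acid_windows()
    t_end = timeline.duration
    if windows:
        t_end = max(t_end, max(w.end for w in windows) + 10 * exchange_up_ms / 1000.0)
    t = np.arange(0.0, t_end + dt, dt)
    s_down = (exchange_down_ms / 1000.0) / (2.0 * LOG9)
    s_up = (exchange_up_ms / 1000.0) / (2.0 * LOG9)
    q = np.zeros_like(t)
    for w in windows:
        down = 1.0 / (1.0 + np.exp(-(t - w.start) / s_down))
        up = 1.0 / (1.0 + np.exp(-(t - w.end) / s_up))
        q += down * (1.0 - up)
    q = np.clip(q, 0.0, 1.0)
    intensity = i0 * (1.0 - (1.0 - quench_residual) * q)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=t.shape)
    return t, intensity


def simulate_stimulus_traces(
    n: int,
    peak: float,
    tau_s: float,
    frame_interval: float = 0.5,
    duration: float = 40.0,
    t_stim: float = 5.0,
    noise_frac: float = 0.02,
    seed: int | None = None,
    baseline: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus-evoked whole-field traces: baseline, instantaneous rise of
    ``peak`` at ``t_stim``, then mono-exponential decay with constant
    ``tau_s``; Gaussian noise of SD ``noise_frac * peak``.

    Returns ``(times, traces)`` with traces of shape ``(n, len(times))``."""
    if n <= 0 or tau_s <= 0:
        raise ValueError("n and tau_s must be > 0")
    t = np.arange(frame_interval, duration + frame_interval / 2, frame_interval)
    clean = baseline + np.where(t >= t_stim, peak * np.exp(-(t - t_stim) / tau_s), 0.0)
    traces = np.tile(clean, (n, 1))
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        traces = traces + rng.normal(0.0, noise_frac * peak, size=traces.shape)
    return t, traces
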