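"""Shared data model, file I/O and configuration.

Conventions used throughout the package:

* pixel indices are 0-based ``(row, col)``;
* physical coordinates in nm are measured from the *centre* of the top-left
  pixel, so pixel ``(r, c)`` has its centre at ``(r * px, c * px)`` nm;
* areas are reported in um^2 (``pixel count * (px/1000)**2``);
* times are seconds from the start of the recording;
* extracellular pH is either 7.4 (neutral) or 6.0 (quenching).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml

PH_NEUTRAL = 7.4
PH_ACID = 6.0

CHANNELS = ("SEP", "CAST")


@dataclass(frozen=True)
class PhWindow:
    """One extracellular-pH window: ``[start, start + duration)`` seconds."""

    start: float
    duration: float
    ph: float = PH_ACID

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"pH window duration must be > 0, got {self.duration}")
        if self.ph not in (PH_NEUTRAL, PH_ACID):
            raise ValueError(f"pH must be 7.4 or 6.0, got {self.ph}")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def contains(self, t) -> np.ndarray:
        """Strict at the start: a frame whose exposure ended exactly at the
        window opening was exposed entirely at the previous pH."""
        t = np.asarray(t, dtype=float)
        return (t > self.start) & (t < self.end)


@dataclass(frozen=True)
class AcquisitionTimeline:
    """Frame times plus the stimulation and pH-exchange schedule.

    Every downstream stage indexes against this object: frame selection for
    pH 6.0 window averaging, pre/post-stimulus bookkeeping and the per-frame
    extracellular pH used by the simulator.
    """

    frame_times: np.ndarray
    exposure: float
    stim_onset: float | None = None
    n_pulses: int = 0
    pulse_rate: float = 50.0
    ph_windows: tuple[PhWindow, ...] = ()
    temperature_C: float = 22.0

    def __post_init__(self) -> None:
        ft = np.asarray(self.frame_times, dtype=float)
        if ft.ndim != 1 or ft.size == 0:
            raise ValueError("frame_times must be a non-empty 1-D array")
        if not np.all(np.diff(ft) > 0):
            raise ValueError("frame_times must be strictly increasing")
        object.__setattr__(self, "frame_times", ft)
        windows = tuple(
            w if isinstance(w, PhWindow) else PhWindow(*w) for w in self.ph_windows
        )
        object.__setattr__(self, "ph_windows", windows)
        ordered = sorted(windows, key=lambda w: w.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"pH windows overlap: [{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
        for w in windows:
            if w.start < 0 or w.end > self.duration + 1e-9:
                raise ValueError(
                    f"pH window [{w.start}, {w.end}) falls outside the recording "
                    f"(duration {self.duration} s)"
                )
        if self.stim_onset is not None and not (0 <= self.stim_onset <= self.duration):
            raise ValueError(
                f"stim_onset {self.stim_onset} s outside recording duration "
                f"{self.duration} s"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def duration(self) -> float:
        return float(self.frame_times[-1])

    @property
    def stim_end(self) -> float | None:
        """Time of the last stimulation pulse (train of n_pulses at pulse_rate)."""
        if self.stim_onset is None or self.n_pulses == 0:
            return self.stim_onset
        return self.stim_onset + self.n_pulses / self.pulse_rate

    def ph_at(self, t) -> np.ndarray:
        """Extracellular pH at time(s) ``t`` (7.4 outside every window)."""
        t = np.asarray(t, dtype=float)
        ph = np.full(t.shape, PH_NEUTRAL)
        for w in self.ph_windows:
            ph = np.where(w.contains(t), w.ph, ph)
        return ph if ph.shape else float(ph)

    def frames_in_window(self, window: PhWindow) -> np.ndarray:
        """Indices of frames whose timestamp lies inside ``window``."""
        return np.nonzero(window.contains(self.frame_times))[0]

    def acid_windows(self) -> list[PhWindow]:
        return [w for w in self.ph_windows if w.ph == PH_ACID]

    def to_dict(self) -> dict:
        return {
            "frame_times": self.frame_times.tolist(),
            "exposure": self.exposure,
            "stim_onset": self.stim_onset,
            "n_pulses": self.n_pulses,
            "pulse_rate": self.pulse_rate,
            "ph_windows": [[w.start, w.duration, w.ph] for w in self.ph_windows],
            "temperature_C": self.temperature_C,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionTimeline":
        d = dict(d)
        d["frame_times"] = np.asarray(d["frame_times"], dtype=float)
        d["ph_windows"] = tuple(PhWindow(*w) for w in d.get("ph_windows", ()))
        return cls(**d)


@dataclass
class FrameStack:
    """One channel's time-lapse pixel data tied to its timeline."""

    channel: str
    pixels: np.ndarray  # (t, y, x)
    pixel_size_nm: float
    timeline: AcquisitionTimeline

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[None]
        if px.ndim != 3:
            raise ValueError(f"pixels must be (t, y, x), got shape {px.shape}")
        if px.shape[0] != self.timeline.n_frames:
            raise ValueError(
                f"frame count {px.shape[0]} does not match timeline length "
                f"{self.timeline.n_frames}"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        self.pixels = px

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


def write_stack(path, stack: FrameStack) -> pathlib.Path:
    """Write a stack as a multi-page TIFF (dtype preserved)."""
    path = pathlib.Path(path)
    tifffile.imwrite(path, stack.pixels)
    return path


def read_stack(path, pixel_size_nm: float, timeline: AcquisitionTimeline,
               channel: str = "SEP") -> FrameStack:
    """Read a multi-page TIFF into a :class:`FrameStack`.

    Raises if the file is missing or its page count disagrees with the
    timeline (both counts reported).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.shape[0] != timeline.n_frames:
        raise ValueError(
            f"{path}: {pixels.shape[0]} TIFF pages but timeline has "
            f"{timeline.n_frames} frames"
        )
    return FrameStack(channel=channel, pixels=pixels,
                      pixel_size_nm=pixel_size_nm, timeline=timeline)


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, defaulting to the published procedure.

    The area gates and the ``mean + k*SD`` threshold are the values used for
    AZLM definition and Syp-SEP positive-area detection; the pH 6.0 window
    handling keeps 5 frames per 700 ms window and averages the later four.
    """

    azlm_area_min_um2: float = 0.098
    azlm_area_max_um2: float = 0.38
    syp_area_min_um2: float = 0.098
    threshold_k_sd: float = 3.0
    exclusion_k_sd: float = 3.0
    ph6_skip_frames: int = 1
    ph6_avg_frames: int = 4
    background_roi: tuple[int, int, int, int] | None = None  # (y0, x0, y1, x1)
    background_clip_k: float = 3.0
    watershed_smooth_sigma_px: float = 1.0
    watershed_prominence_sd: float = 1.0
    drift_upsample: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.azlm_area_min_um2 < self.azlm_area_max_um2):
            raise ValueError(
                f"need 0 < azlm_area_min ({self.azlm_area_min_um2}) < "
                f"azlm_area_max ({self.azlm_area_max_um2})"
            )
        if self.syp_area_min_um2 <= 0:
            raise ValueError("syp_area_min_um2 must be > 0")
        if self.threshold_k_sd <= 0 or self.exclusion_k_sd <= 0:
            raise ValueError("threshold multipliers must be > 0")
        if self.ph6_skip_frames < 0 or self.ph6_avg_frames < 1:
            raise ValueError("invalid pH 6.0 frame selection")
        if self.background_clip_k <= 0:
            raise ValueError("background_clip_k must be > 0")
        if self.background_roi is not None:
            self.background_roi = tuple(int(v) for v in self.background_roi)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["background_roi"] is not None:
            d["background_roi"] = list(d["background_roi"])
        return d


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML (JSON is valid YAML).

    Unknown keys are rejected; missing keys fall back to the defaults.
    An empty file yields the full default configuration.
    """
    path = pathlib.Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**data)


def save_config(path, config: AnalysisConfig) -> pathlib.Path:
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def write_timeline(path, timeline: AcquisitionTimeline) -> pathlib.Path:
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        json.dump(timeline.to_dict(), fh, indent=1)
    return path


def read_timeline(path) -> AcquisitionTimeline:
    with open(path) as fh:
        return AcquisitionTimeline.from_dict(json.load(fh))
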