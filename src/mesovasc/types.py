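"""Core domain containers for the widefield / two-photon quantification chain.

The pipeline revolves around a small set of plain dataclasses: a
:class:`ChannelStack` is one LED channel's movie, a :class:`StimulusParadigm`
describes when stimuli occurred, masks carry manual segmentations, and the
result records (:class:`EvokedResult`, :class:`ReactivityResult`,
:class:`VesselRecord`, :class:`PathologyResult`) are what the statistics
module consumes as long-format rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

Channel = Literal["gcamp470", "cbv570", "bold620"]
#: LED channels in acquisition cycle order: blue GCaMP6f excitation (470 nm),
#: green total-haemoglobin isosbestic reflectance (570 nm, "OIS CBV"), red
#: deoxyhaemoglobin-weighted reflectance (620 nm, "OIS BOLD").
CHANNELS: tuple[Channel, ...] = ("gcamp470", "cbv570", "bold620")

MaskLabel = Literal[
    "brain_roi", "skull_control", "vessel_large", "barrel_roi", "vessel_outline"
]


class PipelineError(Exception):
    """Base class for quantification-chain failures."""


class EmptyInputError(PipelineError):
    """Raised when an input holds no usable frames/pixels."""


class MeasurementFailed(PipelineError):
    """Raised when a single-vessel/ROI measurement cannot be made."""


class InvalidParadigm(PipelineError):
    """Raised when a trace does not cover the paradigm's epochs."""


@dataclass
class ChannelStack:
    """One wavelength channel's time x row x col intensity movie.

    Parameters
    ----------
    channel:
        Which LED this movie belongs to.
    frames:
        ``(T, H, W)`` array of non-negative intensities (arbitrary camera
        units).
    frame_times:
        Acquisition time of each frame in seconds, strictly increasing.
    pixel_size:
        In-plane sampling in micrometres per pixel (isotropic).
    """

    channel: Channel
    frames: np.ndarray
    frame_times: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if self.frame_times.shape != (self.frames.shape[0],):
            raise ValueError("frame_times length must equal number of frames")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(H, W)``."""
        return self.frames.shape[1:]

    @property
    def frame_rate(self) -> float:
        """Mean frame rate in Hz (frames are near-uniformly spaced)."""
        if self.n_frames < 2:
            return float("nan")
        return float((self.n_frames - 1) / (self.frame_times[-1] - self.frame_times[0]))

    def with_frames(self, frames: np.ndarray) -> "ChannelStack":
        """Copy of this stack with ``frames`` replaced (same times/geometry)."""
        return ChannelStack(self.channel, frames, self.frame_times.copy(), self.pixel_size)


@dataclass
class StimulusParadigm:
    """Stimulus timing: onsets, stimulus length and pre-stimulus baseline.

    ``kind`` is ``"whisker"`` (air-puff trains) or ``"hypercapnia"`` (CO2
    challenge epochs). ``baseline_duration`` is the window immediately
    preceding each onset used as F0/R0.
    """

    kind: Literal["whisker", "hypercapnia"]
    onsets: np.ndarray
    stim_duration: float
    baseline_duration: float
    n_repeats: Optional[int] = None

    def __post_init__(self) -> None:
        self.onsets = np.atleast_1d(np.asarray(self.onsets, dtype=float))
        if self.onsets.size == 0:
            raise ValueError("paradigm needs at least one onset")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if not self.stim_duration > 0 or not self.baseline_duration > 0:
            raise ValueError("stim_duration and baseline_duration must be positive")
        if self.onsets.size > 1 and np.min(np.diff(self.onsets)) < self.stim_duration:
            raise ValueError("inter-onset gaps must be >= stim_duration")
        if self.n_repeats is None:
            self.n_repeats = int(self.onsets.size)


def whisker_paradigm(
    n_trials: int = 8, isi: float = 16.0, first_onset: float = 4.0,
    stim_duration: float = 2.0, baseline_duration: float = 2.0,
) -> StimulusParadigm:
    """Whisker air-puff paradigm: 2-s stimulus trains at a fixed ISI."""
    onsets = first_onset + isi * np.arange(n_trials)
    return StimulusParadigm("whisker", onsets, stim_duration, baseline_duration, n_trials)


def hypercapnia_paradigm(
    n_repeats: int = 2, baseline: float = 30.0, stim: float = 90.0,
    recovery: float = 270.0,
) -> StimulusParadigm:
    """CO2 challenge: baseline, 90-s stimulation, recovery; repeated."""
    epoch = baseline + stim + recovery
    onsets = baseline + epoch * np.arange(n_repeats)
    return StimulusParadigm("hypercapnia", onsets, stim, baseline, n_repeats)


@dataclass
class MaskImage:
    """A binary 2-D mask aligned to a ChannelStack's spatial grid."""

    label: MaskLabel
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())


@dataclass
class SessionMeta:
    """Identity of one imaging session (mouse x longitudinal time point)."""

    mouse_id: str
    genotype: Literal["APP_PS1", "WT"]
    sex: Literal["M", "F"]
    age: float  # months
    session_index: int = 0

    def __post_init__(self) -> None:
        if not self.mouse_id:
            raise ValueError("mouse_id must be non-empty")
        if not self.age > 0:
            raise ValueError("age must be positive (months)")


@dataclass
class ActivationMap:
    """Per-pixel evoked fractional change, reduced over the stimulus epoch."""

    values: np.ndarray
    reduction: Literal["peak_over_stim", "mean_over_stim"] = "peak_over_stim"
    valid: Optional[np.ndarray] = None  # False where F0 <= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activation map must be 2-D")
        if self.valid is None:
            self.valid = np.isfinite(self.values)


@dataclass
class EvokedResult:
    """Whisker-evoked peaks (in %) and the OIS-BOLD:GCaMP coupling ratio."""

    peak_gcamp: float
    peak_bold: float
    bold_gcamp_ratio: float
    roi_size: int
    session: Optional[SessionMeta] = None


@dataclass
class ReactivityResult:
    """Tissue CO2-reactivity peaks (%).

    ``peak_cbv`` is sign-adjusted: the 570-nm reflectance drop accompanying a
    blood-volume rise is negated so that higher reactivity is positive in both
    channels.
    """

    peak_bold: float
    peak_cbv: float
    tissue_fraction: float
    session: Optional[SessionMeta] = None


@dataclass
class VesselProbe:
    """A cross-sectional measurement site on one vessel."""

    vessel_id: str
    center: tuple[float, float]  # (y, x) pixels
    normal: tuple[float, float]  # unit (dy, dx) perpendicular to the axis
    half_length: float  # um
    vessel_type: Literal["artery", "vein"] = "artery"

    def __post_init__(self) -> None:
        n = np.hypot(*self.normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            if n == 0:
                raise ValueError("probe normal must be nonzero")
            self.normal = (self.normal[0] / n, self.normal[1] / n)
        if not self.half_length > 0:
            raise ValueError("half_length must be positive")


@dataclass
class VesselRecord:
    """One vessel's baseline diameter and hypercapnic dilation."""

    vessel_id: str
    vessel_type: Literal["artery", "vein"]
    baseline_diameter: float  # um
    percent_change: float  # signed %
    size_class: Optional[Literal["small", "large"]] = None
    session: Optional[SessionMeta] = None


@dataclass
class TwoPhotonVolume:
    """Two-channel two-photon z-stack (methoxy-X04 amyloid + SR101 vessels)."""

    methoxy: np.ndarray  # (Z, Y, X)
    sr101: np.ndarray  # (Z, Y, X)
    voxel_size: tuple[float, float, float] = (3.0, 2.207, 2.207)  # (z, y, x) um

    def __post_init__(self) -> None:
        self.methoxy = np.asarray(self.methoxy, dtype=float)
        self.sr101 = np.asarray(self.sr101, dtype=float)
        if self.methoxy.shape != self.sr101.shape or self.methoxy.ndim != 3:
            raise ValueError("channels must be congruent 3-D (Z, Y, X) arrays")
        if not all(v > 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return float(np.prod(self.voxel_size))


@dataclass
class PathologyResult:
    """Per-image (or session-averaged) amyloid pathology metrics."""

    caa_coverage: float  # % of vessel-outline area
    plaque_volume: float  # um^3
    n_plaques: int
    session: Optional[SessionMeta] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.caa_coverage <= 100.0):
            raise ValueError("caa_coverage must be in [0, 100]")
        if self.plaque_volume < 0:
            raise ValueError("plaque_volume must be non-negative")
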