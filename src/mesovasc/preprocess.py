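"""Spatial binning, sub-pixel rigid motion correction, illumination regression.

Every widefield movie passes through the same chain before quantification:
2x2 spatial binning, Fourier-based rigid registration to the session's first
frame, and removal of shared illumination drift by regressing each pixel's
time series on the mean trace of a skull/head-bar control region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .types import ChannelStack, MaskImage

log = logging.getLogger(__name__)


@dataclass
class RigidShift:
    """Per-frame rigid translation estimates.

    ``dy``/``dx`` are the estimated displacement of each frame relative to the
    reference frame, in pixels (sub-pixel, signed): frame ``i`` appears
    translated by ``(dy[i], dx[i])`` with respect to the reference, and is
    corrected by translating it back by the negative of that displacement.
    """

    dy: np.ndarray
    dx: np.ndarray

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        if self.dy.shape != self.dx.shape or self.dy.ndim != 1:
            raise ValueError("dy and dx must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.dy)) and np.all(np.isfinite(self.dx))):
            raise ValueError("shifts must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)

    def frames_ok(self, max_shift: float = 5.0) -> np.ndarray:
        """Boolean mask of frames whose displacement is within ``max_shift``.

        Frames moving more than ~5 binned pixels are excluded from trial
        averages downstream (excessive-motion rule).
        """
        return self.magnitude <= max_shift


def spatial_bin(stack: ChannelStack, factor: int) -> ChannelStack:
    """Bin each frame by ``factor`` using block means.

    Output pixel = mean of the corresponding ``factor x factor`` input block;
    pixel size is multiplied by ``factor``. Trailing rows/columns that do not
    fill a block are discarded.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return stack
    T, H, W = stack.frames.shape
    if H < factor or W < factor:
        raise ValueError(f"bin factor {factor} exceeds image size {(H, W)}")
    Hb, Wb = H // factor, W // factor
    cropped = stack.frames[:, : Hb * factor, : Wb * factor]
    binned = cropped.reshape(T, Hb, factor, Wb, factor).mean(axis=(2, 4))
    return ChannelStack(
        stack.channel, binned, stack.frame_times.copy(), stack.pixel_size * factor
    )


def _fourier_translate(frame: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Translate a 2-D frame by ``(dy, dx)`` via a Fourier phase ramp (wraps)."""
    f = np.fft.fft2(frame)
    out = np.fft.ifft2(ndi.fourier_shift(f, shift)).real
    return out


def _mask_edges(frame: np.ndarray, width: int) -> np.ndarray:
    """Replace a ``width``-pixel border with the nearest interior values.

    Fourier translation wraps content around the frame edges; the wrapped
    strip is overwritten by edge replication so border pixels never carry
    opposite-edge intensities into ROI statistics.
    """
    if width <= 0:
        return frame
    out = frame.copy()
    out[:width, :] = out[width, :]
    out[-width:, :] = out[-width - 1, :]
    out[:, :width] = out[:, width][:, None]
    out[:, -width:] = out[:, -width - 1][:, None]
    return out


def estimate_shifts(
    stack: ChannelStack,
    reference: np.ndarray | None = None,
    upsample_factor: int = 20,
    max_shift: float = 10.0,
) -> RigidShift:
    """Estimate per-frame rigid displacements by Fourier cross-correlation.

    The reference defaults to frame 0, whose displacement is (0, 0) by
    construction. Sub-pixel refinement uses Fourier upsampling
    (``upsample_factor`` >= 10). A constant (zero-contrast) reference makes
    registration unreliable; a warning is logged and all shifts are 0.
    Estimates beyond ``max_shift`` are clipped (and logged) — displacements of
    that size mean the rigid model has failed for the frame.
    """
    frames = np.asarray(stack.frames, dtype=float)
    ref = frames[0] if reference is None else np.asarray(reference, dtype=float)
    if np.ptp(ref) == 0:
        log.warning("constant reference frame: registration unreliable, shifts set to 0")
        z = np.zeros(frames.shape[0])
        return RigidShift(z, z.copy())
    dy = np.zeros(frames.shape[0])
    dx = np.zeros(frames.shape[0])
    for i in range(frames.shape[0]):
        if reference is None and i == 0:
            continue
        # phase_cross_correlation returns the shift to apply to the moving
        # frame to align it with the reference, i.e. minus the displacement.
        shift, _, _ = phase_cross_correlation(
            ref, frames[i], upsample_factor=upsample_factor, normalization=None
        )
        dy[i], dx[i] = -shift[0], -shift[1]
    mag = np.hypot(dy, dx)
    if np.any(mag > max_shift):
        n = int(np.sum(mag > max_shift))
        log.warning("%d frame(s) exceed max_shift=%.1f px; clipping", n, max_shift)
        scale = np.minimum(1.0, max_shift / np.maximum(mag, 1e-12))
        dy *= scale
        dx *= scale
    return RigidShift(dy, dx)


def apply_shifts(
    stack: ChannelStack, shifts: RigidShift, edge_mask: int = 2
) -> ChannelStack:
    """Resample frames by the inverse of their estimated displacements.

    Uses Fourier phase shifting (exact for band-limited content, no
    interpolation blur that would bias FWHM diametry); the wrapped border is
    then overwritten by ``edge_mask``-pixel edge replication.
    """
    frames = np.asarray(stack.frames, dtype=float)
    out = np.empty_like(frames)
    for i in range(frames.shape[0]):
        if shifts.dy[i] == 0 and shifts.dx[i] == 0:
            out[i] = frames[i]
        else:
            out[i] = _mask_edges(
                _fourier_translate(frames[i], (-shifts.dy[i], -shifts.dx[i])), edge_mask
            )
    return stack.with_frames(out)


def register_rigid(
    stack: ChannelStack,
    reference: np.ndarray | None = None,
    upsample_factor: int = 20,
    max_shift: float = 10.0,
    edge_mask: int = 2,
) -> tuple[ChannelStack, RigidShift]:
    """Estimate and correct rigid motion against the first frame.

    Returns the motion-corrected stack and the per-frame displacement
    estimates. Registration is normally estimated once on the 570-nm channel
    (strongest vessel contrast) and the same shifts applied to all channels
    via :func:`apply_shifts`; the channels are near-simultaneous.
    """
    shifts = estimate_shifts(stack, reference, upsample_factor, max_shift)
    return apply_shifts(stack, shifts, edge_mask), shifts


def intensity_correct(
    stack: ChannelStack,
    control: MaskImage,
    smooth_window: int | None = None,
) -> ChannelStack:
    """Regress the control-region mean trace out of every pixel.

    The mean time series over the skull/head-bar control region captures LED
    intensity drift and fluctuation shared across the field. For each pixel
    the least-squares projection onto ``[1, control_trace]`` is removed and
    the pixel's temporal mean added back, so baseline levels stay physically
    meaningful for the downstream dF/F0 and dR/R0 ratios.

    ``smooth_window`` optionally box-smooths the control trace (frames)
    before regression; default regresses the raw trace.
    """
    if control.n_pixels == 0:
        raise ValueError("control mask is empty")
    frames = np.asarray(stack.frames, dtype=float)
    T = frames.shape[0]
    c = frames[:, control.grid].mean(axis=1)
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        c = np.convolve(c, kernel, mode="same")
    c_centred = c - c.mean()
    denom = float(c_centred @ c_centred)
    if denom < 1e-12 * T * max(1.0, float(np.abs(c).mean()) ** 2):
        log.warning("constant control trace: intensity correction skipped")
        return stack
    Y = frames.reshape(T, -1)
    # slope of each pixel on the centred control trace; intercept handled by
    # centring, and the temporal mean is restored afterwards.
    beta = (c_centred @ Y) / denom
    corrected = Y - np.outer(c_centred, beta)
    return stack.with_frames(corrected.reshape(frames.shape))


def preprocess_session(
    stacks: dict[str, ChannelStack],
    control: MaskImage | None = None,
    bin_factor: int = 2,
    register_on: str = "cbv570",
    max_shift: float = 10.0,
) -> tuple[dict[str, ChannelStack], RigidShift | None]:
    """Full preprocessing chain for one session's three channels.

    Bins each channel, estimates motion on the ``register_on`` channel (570 nm
    by default), applies the same shifts everywhere, then regresses out the
    control trace per channel. Returns the processed stacks and the shift
    series (None when fewer than 2 frames).
    """
    out = {ch: spatial_bin(s, bin_factor) for ch, s in stacks.items()}
    shifts = None
    if register_on in out and out[register_on].n_frames >= 2:
        shifts = estimate_shifts(out[register_on], max_shift=max_shift)
        out = {ch: apply_shifts(s, shifts) for ch, s in out.items()}
    if control is not None:
        ctrl = control
        if ctrl.grid.shape != next(iter(out.values())).shape:
            raise ValueError("control mask shape must match the binned frames")
        out = {ch: intensity_correct(s, ctrl) for ch, s in out.items()}
    return out, shifts
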