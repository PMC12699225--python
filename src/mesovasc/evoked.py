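"""Whisker-stimulation neurovascular coupling quantification.

The evoked chain: per-trial fractional change (dF/F0 against the 2-s
pre-stimulus baseline), trial averaging, an activation map reduced over the
stimulus epoch, a barrel-cortex ROI grown greedily from the activation peak
to the top-100 connected pixels, ROI peak responses for GCaMP (470 nm) and
OIS-BOLD (620 nm), and their ratio.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .types import (
    ActivationMap,
    ChannelStack,
    EvokedResult,
    MaskImage,
    MeasurementFailed,
    StimulusParadigm,
)

log = logging.getLogger(__name__)

#: Seconds after stimulus offset kept in the trial epoch, sized to capture the
#: slower haemodynamic peak within the shortest (16 s) inter-stimulus interval.
DEFAULT_RESPONSE_WINDOW = 8.0


@dataclass
class TrialAverage:
    """Trial-averaged fractional-change movie for one channel.

    ``dff`` is ``(T_epoch, H, W)`` fractional change (not %); ``times`` are
    seconds relative to stimulus onset; ``valid`` is False where any trial had
    a non-positive baseline F0 (those pixels are excluded from ROI search).
    """

    dff: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    n_trials: int


def trial_fractional_change(
    stack: ChannelStack,
    paradigm: StimulusParadigm,
    baseline_window: float | None = None,
    response_window: float = DEFAULT_RESPONSE_WINDOW,
    frame_ok: np.ndarray | None = None,
) -> TrialAverage:
    """Per-trial dF/F0 epochs, averaged across trials.

    For each stimulus onset, F0 is the per-pixel mean over the
    ``baseline_window`` seconds preceding the onset (the paradigm's 2-s
    baseline by default) and the trial epoch runs from onset to
    ``onset + stim_duration + response_window``. Trials are averaged
    time-point by time-point; frames flagged False in ``frame_ok`` (e.g.
    excessive motion) are dropped from both baselines and the average.
    """
    if baseline_window is None:
        baseline_window = paradigm.baseline_duration
    t = stack.frame_times
    fs = stack.frame_rate
    if not np.isfinite(fs):
        raise ValueError("need at least 2 frames to form trial epochs")
    n_epoch = int(round((paradigm.stim_duration + response_window) * fs)) + 1
    frames = np.asarray(stack.frames, dtype=np.float32)
    ok = np.ones(stack.n_frames, bool) if frame_ok is None else np.asarray(frame_ok, bool)

    epochs = []
    for onset in paradigm.onsets:
        if t[0] > onset - baseline_window + 0.5 / fs:
            raise ValueError(f"onset at {onset:g}s lacks {baseline_window:g}s of baseline data")
        base_sel = (t >= onset - baseline_window) & (t < onset) & ok
        if base_sel.sum() == 0:
            raise ValueError(f"no usable baseline frames before onset {onset:g}s")
        i0 = int(np.searchsorted(t, onset))
        if i0 + n_epoch > stack.n_frames:
            raise ValueError(f"onset at {onset:g}s lacks a complete response epoch")
        f0 = frames[base_sel].mean(axis=0)
        epoch = frames[i0 : i0 + n_epoch].astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            dff = (epoch - f0) / f0
        dff[:, f0 <= 0] = np.nan
        dff[~ok[i0 : i0 + n_epoch]] = np.nan
        epochs.append(dff)

    stacked = np.stack(epochs)  # (n_trials, T_epoch, H, W)
    with warnings.catch_warnings():
        # invalid pixels are all-NaN across trials; they are masked below
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dff = np.nanmean(stacked, axis=0)
    valid = np.all(np.isfinite(mean_dff), axis=0)
    mean_dff[:, ~valid] = 0.0
    times = np.arange(n_epoch) / fs
    return TrialAverage(mean_dff, times, valid, len(paradigm.onsets))


def activation_map(
    avg: TrialAverage,
    paradigm: StimulusParadigm,
    reduction: str = "peak_over_stim",
) -> ActivationMap:
    """Reduce the trial-averaged movie to a per-pixel activation value.

    ``peak_over_stim`` (default) takes each pixel's maximum dF/F0 over the
    stimulus epoch; ``mean_over_stim`` averages it instead.
    """
    sel = (avg.times >= 0) & (avg.times <= paradigm.stim_duration)
    seg = avg.dff[sel]
    if reduction == "peak_over_stim":
        vals = seg.max(axis=0)
    elif reduction == "mean_over_stim":
        vals = seg.mean(axis=0)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    vals = np.where(avg.valid, vals, -np.inf)
    return ActivationMap(vals, reduction, avg.valid.copy())


_NEIGHBOURS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def extract_barrel_roi(
    amap: ActivationMap, k: int = 100, method: str = "greedy"
) -> MaskImage:
    """Top-``k`` connected activation pixels as the barrel-cortex ROI.

    ``greedy`` (default): seed at the global activation maximum and repeatedly
    add the highest-valued pixel 8-connected to the current region until the
    region holds ``k`` pixels. ``threshold_component`` is an alternative for
    sensitivity checks: lower a threshold until the component containing the
    maximum reaches ``k`` pixels, then keep its ``k`` strongest pixels.
    """
    values = np.asarray(amap.values, dtype=float)
    valid = amap.valid & np.isfinite(values)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise MeasurementFailed("no valid pixels in activation map")
    if n_valid < k:
        log.warning("only %d valid pixels; ROI smaller than requested %d", n_valid, k)
        k = n_valid
    H, W = values.shape
    work = np.where(valid, values, -np.inf)
    if method == "greedy":
        seed = np.unravel_index(np.argmax(work), work.shape)
        roi = np.zeros((H, W), bool)
        in_heap = np.zeros((H, W), bool)
        heap: list[tuple[float, int, int]] = [(-work[seed], seed[0], seed[1])]
        in_heap[seed] = True
        while heap and roi.sum() < k:
            negv, y, x = heapq.heappop(heap)
            roi[y, x] = True
            for dy, dx in _NEIGHBOURS8:
                ny, nx = y + dy, x + dx
                if 0 <= ny < H and 0 <= nx < W and not in_heap[ny, nx] and valid[ny, nx]:
                    heapq.heappush(heap, (-work[ny, nx], ny, nx))
                    in_heap[ny, nx] = True
        return MaskImage("barrel_roi", roi)
    elif method == "threshold_component":
        from scipy import ndimage as ndi

        seed = np.unravel_index(np.argmax(work), work.shape)
        order = np.sort(work[valid])[::-1]
        lo, hi = 0, order.size - 1
        # lowest threshold whose seed component has >= k pixels
        best = None
        while lo <= hi:
            mid = (lo + hi) // 2
            lab, _ = ndi.label(work >= order[mid], structure=np.ones((3, 3)))
            comp = lab == lab[seed]
            if comp.sum() >= k:
                best = comp
                hi = mid - 1
            else:
                lo = mid + 1
        if best is None:
            lab, _ = ndi.label(work >= order[-1], structure=np.ones((3, 3)))
            best = lab == lab[seed]
        # keep the k strongest pixels of the component
        ys, xs = np.nonzero(best)
        idx = np.argsort(work[ys, xs])[::-1][:k]
        roi = np.zeros((H, W), bool)
        roi[ys[idx], xs[idx]] = True
        return MaskImage("barrel_roi", roi)
    raise ValueError(f"unknown ROI method {method!r}")


def peak_from_trace(trace: np.ndarray, times: np.ndarray, window: tuple[float, float]) -> float:
    """Signed extremum of largest magnitude within a time window, in %."""
    sel = (times >= window[0]) & (times <= window[1])
    if not np.any(sel):
        raise ValueError("peak window contains no samples")
    seg = trace[sel]
    return float(100.0 * seg[np.argmax(np.abs(seg))])


def peak_response(
    stack: ChannelStack,
    roi: MaskImage,
    paradigm: StimulusParadigm,
    baseline_window: float | None = None,
    response_window: float = DEFAULT_RESPONSE_WINDOW,
    frame_ok: np.ndarray | None = None,
) -> float:
    """ROI-mean trial-averaged peak fractional change, in %.

    The ROI-mean trace of the trial-averaged dF/F0 movie is searched from
    onset to ``onset + stim + response_window`` for the signed extremum of
    largest magnitude. The 620-nm dR/R0 is reported as-is (reflectance rise =
    BOLD-like positive); no sign flip here.
    """
    if roi.n_pixels == 0:
        raise ValueError("empty ROI")
    if roi.grid.shape != stack.shape:
        raise ValueError("ROI shape must match the stack frames")
    avg = trial_fractional_change(stack, paradigm, baseline_window, response_window, frame_ok)
    trace = avg.dff[:, roi.grid].mean(axis=1)
    return peak_from_trace(trace, avg.times, (0.0, paradigm.stim_duration + response_window))


def bold_gcamp_ratio(peak_bold: float, peak_gcamp: float) -> float:
    """OIS-BOLD : GCaMP coupling ratio (both peaks in the same % units)."""
    if peak_gcamp == 0:
        raise ZeroDivisionError("undefined ratio: peak GCaMP response is zero")
    return peak_bold / peak_gcamp


def run_evoked_session(
    stacks: dict[str, ChannelStack],
    paradigm: StimulusParadigm,
    baseline_window: float | None = None,
    response_window: float = DEFAULT_RESPONSE_WINDOW,
    roi_size: int = 100,
    frame_ok: np.ndarray | None = None,
    session=None,
) -> tuple[EvokedResult, MaskImage]:
    """Full evoked quantification for one preprocessed session.

    The barrel ROI is extracted from the GCaMP activation map (top
    ``roi_size`` connected pixels), then GCaMP and OIS-BOLD peaks are read
    from that same region.
    """
    gc = stacks["gcamp470"]
    avg = trial_fractional_change(gc, paradigm, baseline_window, response_window, frame_ok)
    amap = activation_map(avg, paradigm)
    roi = extract_barrel_roi(amap, k=roi_size)
    peak_gc = peak_from_trace(
        avg.dff[:, roi.grid].mean(axis=1), avg.times,
        (0.0, paradigm.stim_duration + response_window),
    )
    peak_bold = peak_response(
        stacks["bold620"], roi, paradigm, baseline_window, response_window, frame_ok
    )
    result = EvokedResult(
        peak_gcamp=peak_gc,
        peak_bold=peak_bold,
        bold_gcamp_ratio=bold_gcamp_ratio(peak_bold, peak_gc),
        roi_size=roi.n_pixels,
        session=session,
    )
    return result, roi
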