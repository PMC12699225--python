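"""Single-vessel FWHM diametry and hypercapnic percent-dilation.

Vessel diameter is the full width at half maximum of the cross-sectional
intensity profile sampled along a probe perpendicular to the local vessel
axis. At 570 nm vessels are dark (hemoglobin absorption), so the profile is
a trough; polarity is explicit per-channel configuration, never inferred.
Percent dilation over the CO2 challenge is the peak absolute diameter change
during the stimulus window relative to the 30-s baseline mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .types import (
    ChannelStack,
    MeasurementFailed,
    StimulusParadigm,
    VesselProbe,
    VesselRecord,
)

log = logging.getLogger(__name__)


def extract_profile(
    frame: np.ndarray,
    probe: VesselProbe,
    pixel_size: float,
    step: float | None = None,
    n_lines: int = 1,
    line_spacing_px: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Sample the cross-sectional intensity profile along a probe.

    Intensities are bilinearly interpolated at uniform ``step`` um spacing
    (default 0.25x the pixel size) along the segment
    ``center +/- half_length * normal``. With ``n_lines`` > 1 the profile is
    averaged over that many parallel lines offset along the local vessel
    axis (``line_spacing_px`` apart) — the vessel is locally straight, so
    this suppresses pixel noise without blurring the cross-section. Returns
    ``(profile, step_um)``. Raises if any sample falls outside the image.
    """
    frame = np.asarray(frame, dtype=float)
    if step is None:
        step = 0.25 * pixel_size
    half_px = probe.half_length / pixel_size
    n_half = int(np.floor(probe.half_length / step))
    s_um = step * np.arange(-n_half, n_half + 1)
    dy, dx = probe.normal
    ay, ax = -dx, dy  # unit vector along the vessel axis
    offsets = line_spacing_px * (np.arange(n_lines) - (n_lines - 1) / 2)
    H, W = frame.shape
    acc = np.zeros(s_um.size)
    for off in offsets:
        ys = probe.center[0] + (s_um / pixel_size) * dy + off * ay
        xs = probe.center[1] + (s_um / pixel_size) * dx + off * ax
        if ys.min() < 0 or ys.max() > H - 1 or xs.min() < 0 or xs.max() > W - 1:
            raise ValueError(
                f"probe {probe.vessel_id} ({half_px:.1f} px half-length) exits the image"
            )
        acc += ndi.map_coordinates(frame, np.vstack([ys, xs]), order=1, mode="nearest")
    return acc / len(offsets), float(step)


def fwhm_diameter(
    profile: np.ndarray,
    spacing: float,
    polarity: str = "dark_vessel",
    smooth: int = 3,
    tail_fraction: float = 0.2,
    min_contrast_snr: float = 3.0,
) -> float:
    """FWHM of a vessel cross-sectional profile, in um.

    The profile is lightly smoothed (moving average of ``smooth`` samples).
    Baseline = median of the outer ``tail_fraction`` of samples at each end
    (local, so neighbouring vessels do not bias the half level); the
    extremum depth is the mean over a small window at the trough bottom
    (a single noisy minimum is extreme-value biased); the half level sits
    midway between them. Each half-level crossing is first bracketed walking
    outward from the extremum, then refined by a least-squares line over a
    window scaled to the rough width — a first-crossing rule alone is
    noise-biased inward, a symmetric local fit is not.

    Raises :class:`MeasurementFailed` when the extremum sits at the profile
    edge, fewer than two crossings bracket it, or the contrast does not
    exceed ``min_contrast_snr`` times the tail noise.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 7:
        raise MeasurementFailed("profile too short for FWHM measurement")
    if smooth > 1:
        p = ndi.uniform_filter1d(p, smooth, mode="nearest")
    if polarity == "bright_vessel":
        p = -p  # analyse everything as a trough
    elif polarity != "dark_vessel":
        raise ValueError(f"unknown polarity {polarity!r}")

    n_tail = max(2, int(round(tail_fraction * p.size)))
    tails = np.concatenate([p[:n_tail], p[-n_tail:]])
    baseline = float(np.median(tails))
    noise = float(np.std(tails))
    i_min = int(np.argmin(p))
    edge = max(1, smooth // 2)
    if i_min < edge or i_min >= p.size - edge:
        raise MeasurementFailed("profile extremum at edge")

    def _cross(half: float, w: int) -> tuple[float, float]:
        out = []
        for direction in (-1, +1):
            i = i_min
            while 0 <= i + direction < p.size and p[i + direction] < half:
                i += direction
            j = i + direction
            if j < 0 or j >= p.size:
                raise MeasurementFailed("half-level crossing not found within profile")
            c0 = i + direction * (half - p[i]) / (p[j] - p[i])
            if w >= 1:
                lo = max(0, int(np.floor(c0)) - w)
                hi = min(p.size, int(np.ceil(c0)) + w + 1)
                xs = np.arange(lo, hi, dtype=float)
                if xs.size >= 3:
                    slope, icpt = np.polyfit(xs, p[lo:hi], 1)
                    if direction * slope > 0:
                        c_fit = (half - icpt) / slope
                        if lo - 1 <= c_fit <= hi:
                            c0 = c_fit
            out.append(c0)
        return out[0], out[1]

    # rough pass: single-sample extremum, bracketing crossings only
    depth0 = baseline - p[i_min]
    if depth0 <= 0 or depth0 <= min_contrast_snr * noise:
        raise MeasurementFailed("profile contrast below noise floor")
    l0, r0 = _cross(baseline - 0.5 * depth0, 0)
    width0 = max(r0 - l0, 3.0)
    # refined pass: the averaging windows trade bias for variance, so they
    # scale with the measured noise-to-contrast ratio (a noiseless profile
    # needs no averaging and keeps the rough estimate's locality)
    noise_ratio = noise / depth0
    wm = int(round(width0 * min(0.08, 2.0 * noise_ratio)))
    lo = max(0, i_min - wm)
    v_min = float(np.mean(p[lo : i_min + wm + 1]))
    depth = baseline - v_min
    if depth <= 0 or depth <= min_contrast_snr * noise:
        raise MeasurementFailed("profile contrast below noise floor")
    w_fit = int(np.clip(round(width0 * min(0.06, 3.0 * noise_ratio)), 1, 12))
    left, right = _cross(baseline - 0.5 * depth, w_fit)
    return float((right - left) * spacing)


def measure_vessel_series(
    stack: ChannelStack,
    probe: VesselProbe,
    polarity: str = "dark_vessel",
    step: float | None = None,
    time_smooth: int = 1,
    n_lines: int = 5,
) -> np.ndarray:
    """Per-frame FWHM diameters (um) for one probe; NaN on failed frames.

    Profiles are averaged over ``n_lines`` parallel lines along the vessel
    axis. ``time_smooth`` > 1 applies a NaN-aware moving average; the
    default leaves the series raw because :func:`percent_dilation` applies
    its own light smoothing before peak detection.
    """
    d = np.full(stack.n_frames, np.nan)
    for i in range(stack.n_frames):
        profile, spacing = extract_profile(
            stack.frames[i], probe, stack.pixel_size, step, n_lines=n_lines
        )
        try:
            d[i] = fwhm_diameter(profile, spacing, polarity)
        except MeasurementFailed:
            continue
    if time_smooth > 1:
        d = _smooth_series(d, time_smooth)
    return d


def _smooth_series(d: np.ndarray, width: int) -> np.ndarray:
    """NaN-aware, edge-normalised moving average of a diameter series."""
    kernel = np.ones(width)
    finite = np.isfinite(d).astype(float)
    num = np.convolve(np.nan_to_num(d), kernel, mode="same")
    den = np.convolve(finite, kernel, mode="same")
    with np.errstate(invalid="ignore"):
        sm = num / den
    sm[den == 0] = np.nan
    return sm


def measure_mean_diameter(
    stack: ChannelStack,
    probe: VesselProbe,
    window: tuple[float, float] | None = None,
    polarity: str = "dark_vessel",
    step: float | None = None,
    n_lines: int = 5,
) -> float:
    """FWHM measured on the temporal-mean frame of a time window.

    Averaging the frames first suppresses noise by ~sqrt(n) before the
    profile is measured, which is the preferred estimator for a vessel's
    baseline diameter from a 30-s baseline recording.
    """
    t = stack.frame_times
    sel = np.ones(stack.n_frames, bool) if window is None else (t >= window[0]) & (t < window[1])
    if sel.sum() == 0:
        raise MeasurementFailed("empty time window for mean-frame diametry")
    mean_frame = np.asarray(stack.frames[sel], dtype=float).mean(axis=0)
    profile, spacing = extract_profile(mean_frame, probe, stack.pixel_size, step, n_lines=n_lines)
    return fwhm_diameter(profile, spacing, polarity)


def percent_dilation(
    diameters: np.ndarray,
    times: np.ndarray,
    paradigm: StimulusParadigm,
    max_missing: float = 0.2,
    time_smooth: int = 3,
) -> float:
    """Signed peak percent diameter change during the CO2 stimulus.

    The series is first lightly smoothed in time (moving average of
    ``time_smooth`` frames) so the peak cannot be a single-frame noise
    excursion. Per repeat, baseline D0 = mean diameter over the 30-s
    pre-onset window and the epoch trace is ``(D(t) - D0) / D0`` over the
    stimulus window; repeats are averaged at the epoch level (the paradigm
    reports one peak per session over its two repeats) and the returned
    value is 100x the averaged trace's deviation of largest magnitude, sign
    attached. Raises :class:`MeasurementFailed` if more than ``max_missing``
    of the frames in either window failed.
    """
    d_raw = np.asarray(diameters, dtype=float)
    t = np.asarray(times, dtype=float)
    d = _smooth_series(d_raw, time_smooth) if time_smooth > 1 else d_raw
    per_epoch = []
    for onset in paradigm.onsets:
        bsel = (t >= onset - paradigm.baseline_duration) & (t < onset)
        ssel = (t >= onset) & (t <= onset + paradigm.stim_duration)
        if bsel.sum() == 0 or ssel.sum() == 0:
            raise MeasurementFailed("diameter series does not span the paradigm epochs")
        for name, sel in (("baseline", bsel), ("stimulus", ssel)):
            frac_bad = np.mean(~np.isfinite(d_raw[sel]))
            if frac_bad > max_missing:
                raise MeasurementFailed(
                    f"{frac_bad:.0%} failed frames in {name} window exceeds {max_missing:.0%}"
                )
        d0 = np.nanmean(d[bsel])
        if not d0 > 0:
            raise MeasurementFailed("non-positive baseline diameter")
        per_epoch.append((d[ssel] - d0) / d0)
    n = min(len(e) for e in per_epoch)
    with np.errstate(invalid="ignore"):
        mean_dev = np.nanmean([e[:n] for e in per_epoch], axis=0)
    mean_dev = mean_dev[np.isfinite(mean_dev)]
    if mean_dev.size == 0:
        raise MeasurementFailed("no finite stimulus-window diameters")
    return float(100.0 * mean_dev[np.argmax(np.abs(mean_dev))])


def measure_session_vessels(
    stack: ChannelStack,
    probes: list[VesselProbe],
    paradigm: StimulusParadigm,
    polarity: str = "dark_vessel",
    session=None,
) -> list[VesselRecord]:
    """Diameter + dilation for every probe in a session; failures skipped."""
    records = []
    for probe in probes:
        try:
            d = measure_vessel_series(stack, probe, polarity)
            bsel = (stack.frame_times >= paradigm.onsets[0] - paradigm.baseline_duration) & (
                stack.frame_times < paradigm.onsets[0]
            )
            baseline = float(np.nanmean(d[bsel]))
            pct = percent_dilation(d, stack.frame_times, paradigm)
        except (MeasurementFailed, ValueError) as exc:
            log.warning("vessel %s skipped: %s", probe.vessel_id, exc)
            continue
        records.append(
            VesselRecord(
                vessel_id=probe.vessel_id,
                vessel_type=probe.vessel_type,
                baseline_diameter=baseline,
                percent_change=pct,
                session=session,
            )
        )
    return records


@dataclass
class MedianSplit:
    """Cohort-level arterial median split result."""

    median: float
    records: pd.DataFrame


def median_split(records: pd.DataFrame, scope: str = "artery") -> MedianSplit:
    """Classify arterial vessels as small/large by the cohort median diameter.

    The median is computed over all ``scope``-type baseline diameters in the
    cohort (an output of the data, never an input); ``small`` is strictly
    below the median and ``large`` includes it. Non-scope rows keep
    ``size_class`` as missing.
    """
    df = records.copy()
    sel = df["vessel_type"] == scope
    if sel.sum() < 2:
        raise ValueError(f"need at least 2 {scope} records for a median split")
    med = float(df.loc[sel, "baseline_diameter"].median())
    if (df.loc[sel, "baseline_diameter"] == med).all():
        log.warning("all %s diameters equal the median; every vessel classified large", scope)
    df.loc[sel, "size_class"] = np.where(
        df.loc[sel, "baseline_diameter"] < med, "small", "large"
    )
    return MedianSplit(med, df)


def records_to_frame(records: list[VesselRecord]) -> pd.DataFrame:
    """Flatten VesselRecords (with SessionMeta) into a long-format table."""
    rows = []
    for r in records:
        row = {
            "vessel_id": r.vessel_id,
            "vessel_type": r.vessel_type,
            "baseline_diameter": r.baseline_diameter,
            "percent_change": r.percent_change,
            "size_class": r.size_class,
        }
        if r.session is not None:
            row.update(
                mouse_id=r.session.mouse_id,
                genotype=r.session.genotype,
                sex=r.session.sex,
                age=r.session.age,
                session_index=r.session.session_index,
            )
        rows.append(row)
    return pd.DataFrame(rows)
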