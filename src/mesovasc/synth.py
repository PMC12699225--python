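"""Synthetic widefield sessions, vessel fields, two-photon volumes, cohorts.

Every generator draws from a seeded ``numpy.random.default_rng`` and records
the ground truth of every observable it plants, so each pipeline stage can be
tested end to end without external data. The defaults mirror the study's
acquisition conditions at desk scale: a 130 x 174 px widefield canvas
(half-scale of the raw 260 x 348 camera matrix over the same 4.4 x 5.9 mm
field), 30 Hz acquisition interleaving three LEDs (10 Hz per channel), the
2-s whisker stimulus, the 30/90/270-s hypercapnia epoch repeated twice, the
two-photon 2.207 um in-plane / 3 um z sampling, and the 8/8/8/8
genotype-by-sex cohort imaged ~5.4 times at ~1.5-month intervals.

Important realized-vs-nominal distinction: planted response peaks are
recorded *as sampled* (the noiseless trace's maximum on the actual frame
grid), so recovery tests measure estimation error, not sampling phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield


import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats

from .preprocess import _fourier_translate
from .types import (
    ChannelStack,
    MaskImage,
    SessionMeta,
    StimulusParadigm,
    TwoPhotonVolume,
    VesselProbe,
    hypercapnia_paradigm,
    whisker_paradigm,
)

#: Half-scale widefield canvas: 4.4 x 5.9 mm over 130 x 174 px.
WIDEFIELD_SHAPE = (130, 174)
WIDEFIELD_PIXEL_SIZE = 4400.0 / 130  # ~33.8 um/px


@dataclass
class GroundTruth:
    """Recorded truth for one generated dataset (seed included for replay)."""

    seed: int
    values: dict = dfield(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def __setitem__(self, key, value):
        self.values[key] = value

    def __contains__(self, key):
        return key in self.values


def _gamma_kernel(t: np.ndarray, peak_time: float, shape: float) -> np.ndarray:
    """Gamma-variate response kernel, unit peak at ``peak_time``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_time
    out[pos] = x**shape * np.exp(shape * (1.0 - x))
    return out


def _plateau(t: np.ndarray, duration: float, rise: float, fall: float) -> np.ndarray:
    """Smooth 0->1 plateau: cosine rise, hold, cosine decay after offset."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    r = (t > 0) & (t < rise)
    out[r] = 0.5 * (1 - np.cos(np.pi * t[r] / rise))
    out[(t >= rise) & (t <= duration)] = 1.0
    f = (t > duration) & (t < duration + fall)
    out[f] = 0.5 * (1 + np.cos(np.pi * (t[f] - duration) / fall))
    return out


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float,
                  amplitude: float) -> np.ndarray:
    """Smooth zero-mean random field with RMS ``amplitude``."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f * (amplitude / sd) if sd > 0 else f


def _render_vessels(
    shape: tuple[int, int],
    within: np.ndarray,
    rng: np.random.Generator,
    coverage: float,
    width_px: tuple[float, float] = (2.0, 6.0),
    max_segments: int = 400,
) -> np.ndarray:
    """Random straight dark-vessel segments until ``coverage`` of ``within``.

    Returns the boolean vessel mask (exact realized coverage is
    ``(mask & within).sum() / within.sum()``).
    """
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    mask = np.zeros(shape, bool)
    n_roi = max(int(within.sum()), 1)
    for _ in range(max_segments):
        if (mask & within).sum() / n_roi >= coverage:
            break
        y0, x0 = rng.uniform(0, H), rng.uniform(0, W)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.3, 0.9) * max(H, W)
        dy, dx = np.sin(ang), np.cos(ang)
        y1, x1 = y0 + length * dy, x0 + length * dx
        # distance from segment
        py, px = yy - y0, xx - x0
        t = np.clip((py * dy + px * dx) / max(length, 1e-9), 0, 1) * length
        dist = np.hypot(py - t * dy, px - t * dx)
        mask |= dist <= rng.uniform(*width_px) / 2
    return mask


@dataclass
class WidefieldConfig:
    """Study conditions for one synthetic widefield session."""

    kind: str = "whisker"  # or "hypercapnia"
    shape: tuple[int, int] = WIDEFIELD_SHAPE
    pixel_size: float = WIDEFIELD_PIXEL_SIZE
    acquisition_rate: float = 30.0  # Hz across the LED cycle (10 Hz/channel)
    # whisker mode
    n_trials: int = 8
    isi: float = 16.0
    stim_duration: float = 2.0
    amp_gcamp: float = 0.03  # peak dF/F0 (fraction)
    amp_bold: float = 0.01  # peak dR/R0 at 620 nm
    amp_cbv: float = -0.01  # peak dR/R0 at 570 nm (reflectance drop)
    # hypercapnia mode (frame rate reduced, recovery shortened at desk scale;
    # peaks fall inside the 90-s stimulus window so neither affects them)
    hc_rate: float = 3.0  # Hz across the cycle (1 Hz/channel)
    hc_rendered_recovery: float = 60.0
    hc_amp_bold: float = 0.02
    hc_amp_cbv: float = -0.02
    vessel_coverage: float = 0.2  # fraction of brain ROI covered by vessels
    # nuisance processes; per-pixel noise SD = baseline * noise_ref_amp / snr
    # (referenced to the 3% GCaMP response scale so null sessions keep a
    # realistic noise floor)
    snr: float = 10.0
    noise_ref_amp: float = 0.03
    motion_px: float = 0.0  # RMS of the rigid motion random walk
    drift_amp: float = 0.0  # RMS fractional illumination drift
    baseline_level: float = 1000.0


@dataclass
class WidefieldSession:
    stacks: dict[str, ChannelStack]
    paradigm: StimulusParadigm
    masks: dict[str, MaskImage]
    truth: GroundTruth

    def interleaved(self) -> np.ndarray:
        """Re-interleave the channels into one acquisition-order movie."""
        order = ["gcamp470", "cbv570", "bold620"]
        n = min(self.stacks[c].n_frames for c in order)
        first = self.stacks[order[0]].frames
        out = np.empty((3 * n,) + first.shape[1:], dtype=first.dtype)
        for k, c in enumerate(order):
            out[k::3] = self.stacks[c].frames[:n]
        return out


def _session_masks(shape: tuple[int, int]) -> dict[str, MaskImage]:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = H / 2, W / 2
    brain = ((yy - cy) / (0.42 * H)) ** 2 + ((xx - cx) / (0.42 * W)) ** 2 <= 1.0
    rim = ((yy - cy) / (0.48 * H)) ** 2 + ((xx - cx) / (0.48 * W)) ** 2 > 1.0
    return {
        "brain_roi": MaskImage("brain_roi", brain),
        "skull_control": MaskImage("skull_control", rim),
    }


def gen_widefield_session(
    config: WidefieldConfig | None = None, seed: int = 0
) -> WidefieldSession:
    """Generate one interleaved-LED widefield session with known truth.

    Whisker mode plants a barrel-localised flat-topped GCaMP response (fast
    gamma kernel) plus slower haemodynamic OIS responses; hypercapnia mode
    plants tissue-wide dR/R0 plateaus on a vessel-textured field. Shared
    rigid motion, multiplicative illumination drift (visible in the skull
    control region too) and white noise are added on top. Truths record both
    nominal amplitudes and the realized sampled peaks.
    """
    cfg = config or WidefieldConfig()
    rng = np.random.default_rng(seed)
    H, W = cfg.shape
    masks = _session_masks(cfg.shape)
    brain = masks["brain_roi"].grid

    if cfg.kind == "whisker":
        if cfg.stim_duration + 8.0 > cfg.isi:
            raise ValueError("response window exceeds the inter-stimulus interval")
        paradigm = whisker_paradigm(cfg.n_trials, cfg.isi, first_onset=4.0,
                                    stim_duration=cfg.stim_duration)
        rate = cfg.acquisition_rate / 3.0
        total = paradigm.onsets[-1] + cfg.isi
        amps = {"gcamp470": cfg.amp_gcamp, "bold620": cfg.amp_bold, "cbv570": cfg.amp_cbv}
        kernels = {"gcamp470": (0.6, 2.0), "bold620": (1.5, 2.5), "cbv570": (1.8, 2.5)}
    elif cfg.kind == "hypercapnia":
        paradigm = hypercapnia_paradigm()
        rate = cfg.hc_rate / 3.0
        epoch = 30.0 + 90.0 + cfg.hc_rendered_recovery
        total = 2 * epoch
        # rendered onsets follow the shortened epoch; stim/baseline keep the
        # paradigm's true durations
        paradigm = StimulusParadigm(
            "hypercapnia", 30.0 + epoch * np.arange(2), 90.0, 30.0, 2
        )
        amps = {"gcamp470": 0.0, "bold620": cfg.hc_amp_bold, "cbv570": cfg.hc_amp_cbv}
        kernels = {}
    else:
        raise ValueError(f"unknown paradigm kind {cfg.kind!r}")

    n_frames = int(round(total * rate))
    dt = 1.0 / rate

    # static scene: smooth tissue texture, dark vessel tree, bright skull rim
    texture = 1.0 + _smooth_field(cfg.shape, rng, sigma=6.0, amplitude=0.05)
    vessel_mask = _render_vessels(cfg.shape, brain, rng, cfg.vessel_coverage)
    base = {}
    vessel_dark = {"gcamp470": 0.85, "cbv570": 0.55, "bold620": 0.75}
    for ch in ("gcamp470", "cbv570", "bold620"):
        img = cfg.baseline_level * texture
        img[vessel_mask] *= vessel_dark[ch]
        img[~brain] = cfg.baseline_level * 0.8  # skull/bone
        base[ch] = img

    # spatial response footprints
    yy, xx = np.mgrid[0:H, 0:W]
    if cfg.kind == "whisker":
        by, bx = 0.42 * H, 0.62 * W  # barrel cortex location
        r = np.hypot(yy - by, xx - bx)
        r0 = 11.0  # ~380 px of flat top; the top-100 ROI sits inside it
        footprint = np.exp(-((r / r0) ** 8))
        barrel_truth = footprint > 0.5
        masks["barrel_truth"] = MaskImage("barrel_roi", barrel_truth)
    else:
        footprint = brain.astype(float)  # tissue-wide response

    # shared nuisance time courses
    drift = np.zeros(n_frames)
    if cfg.drift_amp > 0:
        slow = ndi.gaussian_filter1d(rng.standard_normal(n_frames), 12.0 * rate * dt * 10)
        drift = slow / max(slow.std(), 1e-12) * cfg.drift_amp
    motion = np.zeros((n_frames, 2))
    if cfg.motion_px > 0:
        steps = rng.normal(0, 1, size=(n_frames, 2))
        walk = np.cumsum(steps, axis=0)
        walk -= walk.mean(axis=0)
        rms = np.sqrt((walk**2).mean())
        motion = walk / max(rms, 1e-12) * cfg.motion_px

    truth = GroundTruth(seed)
    truth["vessel_fraction"] = float((vessel_mask & brain).sum() / brain.sum())
    truth["motion_dy"] = motion[:, 0].copy()
    truth["motion_dx"] = motion[:, 1].copy()
    truth["nominal_amp_pct"] = {ch: 100 * a for ch, a in amps.items()}

    stacks = {}
    peak_truth = {}
    for k, ch in enumerate(("gcamp470", "cbv570", "bold620")):
        times = (k + 3 * np.arange(n_frames)) * (dt / 3.0)
        amp = amps[ch]
        resp = np.zeros(n_frames)
        if amp != 0:
            for onset in paradigm.onsets:
                if cfg.kind == "whisker":
                    tp, sh = kernels[ch]
                    resp += _gamma_kernel(times - onset, tp, sh)
                else:
                    resp += _plateau(times - onset, paradigm.stim_duration,
                                     rise=10.0, fall=30.0)
            resp = np.clip(resp, 0, 1.0 if cfg.kind == "hypercapnia" else np.inf)
        # realized noiseless peak of the response-core fractional change
        peak_truth[ch] = float(100 * amp * resp.max()) if amp != 0 else 0.0

        frames = np.empty((n_frames, H, W), dtype=np.float32)
        noise_sd = cfg.baseline_level * cfg.noise_ref_amp / cfg.snr if cfg.snr > 0 else 0.0
        for i in range(n_frames):
            frame = base[ch] * (1.0 + amp * resp[i] * footprint) * (1.0 + drift[i])
            if motion[i, 0] != 0 or motion[i, 1] != 0:
                frame = _fourier_translate(frame, (motion[i, 0], motion[i, 1]))
            if noise_sd > 0:
                frame = frame + rng.normal(0, noise_sd, size=(H, W))
            frames[i] = frame
        stacks[ch] = ChannelStack(ch, frames, times, cfg.pixel_size)

    truth["peak_pct"] = peak_truth
    return WidefieldSession(stacks, paradigm, masks, truth)


def gen_registration_frames(
    n_frames: int = 50,
    shape: tuple[int, int] = WIDEFIELD_SHAPE,
    max_shift: float = 5.0,
    snr: float = 10.0,
    seed: int = 0,
) -> tuple[ChannelStack, np.ndarray]:
    """Textured frames with planted sub-pixel rigid shifts.

    Frame 0 is the unshifted reference; later frames are Fourier-translated
    by displacements drawn uniformly within ``[-max_shift, max_shift]`` per
    axis. Returns the stack and the ``(n, 2)`` true displacements. SNR is
    texture SD / noise SD.
    """
    rng = np.random.default_rng(seed)
    base = 1000.0 * (1.0 + _smooth_field(shape, rng, sigma=3.0, amplitude=0.1))
    vessels = _render_vessels(shape, np.ones(shape, bool), rng, 0.1)
    base[vessels] *= 0.6
    contrast_sd = base.std()
    noise_sd = contrast_sd / snr
    shifts = rng.uniform(-max_shift, max_shift, size=(n_frames, 2))
    shifts[0] = 0.0
    frames = np.empty((n_frames,) + shape)
    for i in range(n_frames):
        f = base if i == 0 else _fourier_translate(base, tuple(shifts[i]))
        frames[i] = f + rng.normal(0, noise_sd, size=shape)
    stack = ChannelStack("cbv570", frames, np.arange(n_frames) / 10.0, WIDEFIELD_PIXEL_SIZE)
    return stack, shifts


# ---------------------------------------------------------------------------
# single-vessel fields for FWHM diametry


@dataclass
class VesselFieldConfig:
    """Conditions for synthetic vessel frames with known diameters."""

    diameters_um: tuple[float, ...] = ()  # empty -> draw from lognormal
    n_vessels: int = 12
    median_diameter_um: float = 54.0  # cohort arterial median
    log_sigma: float = 0.45
    pixel_size: float = 1.0  # high-zoom rendering so 10-um vessels resolve
    cross_section: str = "gaussian"  # or "tophat"
    contrast: float = 0.45  # fractional darkening at vessel centre
    dilation_pct: float = 8.0
    snr: float = 10.0  # contrast depth / per-pixel noise SD
    dt: float = 2.0  # s between rendered frames
    rendered_recovery: float = 30.0
    background: float = 1000.0


def _vessel_profile(dist_px: np.ndarray, diameter_px: float, kind: str) -> np.ndarray:
    """Unit-depth trough cross-section as a function of |distance| in px."""
    if kind == "gaussian":
        sigma = diameter_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * (dist_px / sigma) ** 2)
    if kind == "tophat":
        return (dist_px <= diameter_px / 2).astype(float)
    raise ValueError(f"unknown cross-section {kind!r}")


def gen_single_vessel_frame(
    diameter_um: float,
    angle_deg: float = 0.0,
    offset_px: float = 0.0,
    config: VesselFieldConfig | None = None,
    seed: int = 0,
    n_frames: int = 1,
) -> tuple[ChannelStack, VesselProbe, GroundTruth]:
    """One straight vessel at a given orientation and sub-pixel offset.

    The canvas is sized to the vessel; the probe crosses the centre
    perpendicular to the axis with tails of 1.5 diameters on each side.
    ``n_frames`` identical-statistics frames are rendered for time-averaged
    measurement.
    """
    cfg = config or VesselFieldConfig()
    rng = np.random.default_rng(seed)
    d_px = diameter_um / cfg.pixel_size
    half_len_um = 2.0 * diameter_um
    side = int(np.ceil(2 * half_len_um / cfg.pixel_size)) + 16
    H = W = side
    cy = H / 2 + offset_px
    cx = W / 2
    ang = np.deg2rad(angle_deg)
    axis = np.array([np.sin(ang), np.cos(ang)])  # (dy, dx) along the vessel
    normal = np.array([-axis[1], axis[0]])
    yy, xx = np.mgrid[0:H, 0:W]
    dist = np.abs((yy - cy) * normal[0] + (xx - cx) * normal[1])
    clean = cfg.background * (1.0 - cfg.contrast * _vessel_profile(dist, d_px, cfg.cross_section))
    noise_sd = cfg.background * cfg.contrast / cfg.snr if cfg.snr > 0 else 0.0
    frames = clean[None] + rng.normal(0, noise_sd, size=(n_frames, H, W))
    stack = ChannelStack(
        "cbv570", frames, cfg.dt * np.arange(n_frames), cfg.pixel_size
    )
    probe = VesselProbe(
        vessel_id=f"d{diameter_um:g}_a{angle_deg:g}_o{offset_px:g}",
        center=(cy, cx),
        normal=(float(normal[0]), float(normal[1])),
        half_length=half_len_um,
    )
    truth = GroundTruth(seed, {"diameter_um": float(diameter_um)})
    return stack, probe, truth


def gen_vessel_frame_series(
    config: VesselFieldConfig | None = None, seed: int = 0
) -> tuple[ChannelStack, list[VesselProbe], StimulusParadigm, GroundTruth]:
    """Frames of several dilating vessels locked to the CO2 epoch.

    Vessels are laid out on a grid of non-overlapping cells, horizontal axes
    with alternating artery/vein labels; each dilates by ``dilation_pct`` at
    the plateau of the CO2 stimulus. Truths: per-vessel baseline diameter and
    planted dilation.
    """
    cfg = config or VesselFieldConfig()
    rng = np.random.default_rng(seed)
    if cfg.diameters_um:
        diameters = np.asarray(cfg.diameters_um, dtype=float)
    else:
        diameters = np.clip(
            rng.lognormal(np.log(cfg.median_diameter_um), cfg.log_sigma, cfg.n_vessels),
            10.0, 150.0,
        )
    n = diameters.size
    # grid cells sized by the largest vessel's probe span
    cell_um = 4.0 * diameters.max() + 40.0
    cell_px = int(np.ceil(cell_um / cfg.pixel_size))
    n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    H, W = n_rows * cell_px, n_cols * cell_px

    epoch = 30.0 + 90.0 + cfg.rendered_recovery
    times = np.arange(0.0, 2 * epoch, cfg.dt)
    onsets = 30.0 + epoch * np.arange(2)
    paradigm = StimulusParadigm("hypercapnia", onsets, 90.0, 30.0, 2)
    s_t = np.zeros_like(times)
    for onset in onsets:
        s_t += _plateau(times - onset, 90.0, rise=10.0, fall=30.0)

    probes = []
    cells = []  # (row slice, col slice, local |dy| map) per vessel
    for i, d in enumerate(diameters):
        r, c = divmod(i, n_cols)
        cy = (r + 0.5) * cell_px + rng.uniform(-1, 1)
        cx = (c + 0.5) * cell_px + rng.uniform(-1, 1)
        rows = slice(r * cell_px, (r + 1) * cell_px)
        cols = slice(c * cell_px, (c + 1) * cell_px)
        local_dy = np.abs(np.arange(rows.start, rows.stop, dtype=float) - cy)
        cells.append((rows, cols, local_dy[:, None]))
        probes.append(
            VesselProbe(
                vessel_id=f"v{i:03d}",
                center=(cy, cx),
                normal=(1.0, 0.0),
                half_length=2.0 * d,
                vessel_type="artery" if i % 2 == 0 else "vein",
            )
        )
    noise_sd = cfg.background * cfg.contrast / cfg.snr if cfg.snr > 0 else 0.0
    frames = np.empty((times.size, H, W), dtype=np.float32)
    for ti, s in enumerate(s_t):
        img = np.full((H, W), cfg.background)
        for d0, (rows, cols, dist) in zip(diameters, cells):
            d_t = d0 * (1.0 + cfg.dilation_pct / 100.0 * s)
            img[rows, cols] -= cfg.background * cfg.contrast * _vessel_profile(
                dist, d_t / cfg.pixel_size, cfg.cross_section
            )
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, size=(H, W))
        frames[ti] = img
    stack = ChannelStack("cbv570", frames, times, cfg.pixel_size)
    truth = GroundTruth(
        seed,
        {
            "diameters_um": diameters.copy(),
            "dilation_pct": float(cfg.dilation_pct),
            "vessel_types": [p.vessel_type for p in probes],
        },
    )
    return stack, probes, paradigm, truth


def gen_diameter_series(
    baseline_um: float = 50.0,
    dilation_pct: float = 8.0,
    noise_sd_pct: float = 1.0,
    dt: float = 2.0,
    rendered_recovery: float = 30.0,
    n_repeats: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, StimulusParadigm, GroundTruth]:
    """Per-frame diameter series of one vessel dilating during CO2.

    Noise is placed on the measured diameter itself (``noise_sd_pct`` percent
    of baseline, white across frames), the level at which FWHM measurement
    jitter appears. The CO2 epoch repeats ``n_repeats`` times (twice in the
    study paradigm). Returns ``(diameters_um, times_s, paradigm, truth)``.
    """
    rng = np.random.default_rng(seed)
    epoch = 30.0 + 90.0 + rendered_recovery
    times = np.arange(0.0, n_repeats * epoch, dt)
    onsets = 30.0 + epoch * np.arange(n_repeats)
    paradigm = StimulusParadigm("hypercapnia", onsets, 90.0, 30.0, n_repeats)
    s_t = np.zeros_like(times)
    for onset in onsets:
        s_t += _plateau(times - onset, 90.0, rise=10.0, fall=30.0)
    clean = baseline_um * (1.0 + dilation_pct / 100.0 * s_t)
    noisy = clean + rng.normal(0, noise_sd_pct / 100.0 * baseline_um, times.size)
    truth = GroundTruth(seed, {"baseline_um": baseline_um, "dilation_pct": dilation_pct})
    return noisy, times, paradigm, truth


# ---------------------------------------------------------------------------
# two-photon volumes


@dataclass
class TwoPhotonConfig:
    """Conditions for one synthetic two-photon z-stack."""

    shape: tuple[int, int, int] = (24, 128, 128)  # (Z, Y, X)
    voxel_size: tuple[float, float, float] = (3.0, 2.207, 2.207)
    n_vessels: int = 4
    vessel_radius_px: float = 13.0
    caa_fraction: float = 0.25  # angular-band fraction of each vessel disk
    plaque_radii_vox: tuple[float, ...] = (2.5, 3.0, 3.5)
    background: float = 0.2
    wall_level: float = 1.0  # methoxy level of non-CAA vessel wall
    caa_level: float = 3.0
    # dense plaque cores label much brighter than vessel-wall amyloid, so the
    # 0.6 x max plaque threshold clears every CAA-compartment intensity
    plaque_level: float = 6.0
    depth_decay_um: float = 300.0  # exponential attenuation length, 0 = off
    snr: float = 15.0  # CAA contrast / noise SD


def gen_twophoton_volume(
    config: TwoPhotonConfig | None = None, seed: int = 0
) -> tuple[TwoPhotonVolume, np.ndarray, GroundTruth]:
    """Two-channel z-stack with known CAA coverage and plaque voxel counts.

    SR101 holds bright penetrating-vessel cylinders; methoxy holds CAA
    angular bands on the vessel walls plus spherical tissue plaques placed
    clear of the vessels. Exponential depth decay and white noise are
    applied. Truths record the exact rendered CAA pixel fraction and
    per-plaque voxel counts.
    """
    cfg = config or TwoPhotonConfig()
    rng = np.random.default_rng(seed)
    Z, Y, X = cfg.shape
    yy, xx = np.mgrid[0:Y, 0:X]

    outlines = np.zeros((Y, X), dtype=np.int32)
    caa2d = np.zeros((Y, X), bool)
    margin = cfg.vessel_radius_px + 4
    centres = []
    attempts = 0
    while len(centres) < cfg.n_vessels and attempts < 200:
        attempts += 1
        cy = rng.uniform(margin, Y - margin)
        cx = rng.uniform(margin, X - margin)
        if any(np.hypot(cy - a, cx - b) < 2.8 * cfg.vessel_radius_px for a, b in centres):
            continue
        centres.append((cy, cx))
    if len(centres) < cfg.n_vessels:
        raise ValueError("could not place vessels without overlap; reduce n_vessels")
    for i, (cy, cx) in enumerate(centres, start=1):
        disk = np.hypot(yy - cy, xx - cx) <= cfg.vessel_radius_px
        outlines[disk] = i
        theta = np.mod(np.arctan2(yy - cy, xx - cx) - rng.uniform(0, 2 * np.pi), 2 * np.pi)
        caa2d |= disk & (theta < 2 * np.pi * cfg.caa_fraction)

    methoxy = np.full(cfg.shape, cfg.background)
    sr101 = np.full(cfg.shape, cfg.background)
    vessel2d = outlines > 0
    sr101[:, vessel2d] = 1.0
    methoxy[:, vessel2d] = cfg.wall_level
    methoxy[:, caa2d] = cfg.caa_level

    # spherical plaques clear of the vessels
    zz = np.arange(Z)[:, None, None]
    plaque_sizes = []
    keepout = ndi.binary_dilation(vessel2d, iterations=6)
    for r in cfg.plaque_radii_vox:
        placed = False
        for _ in range(100):
            cz = rng.uniform(r + 1, Z - r - 1)
            cy = rng.uniform(r + 2, Y - r - 2)
            cx = rng.uniform(r + 2, X - r - 2)
            if keepout[int(cy), int(cx)]:
                continue
            sphere = (zz - cz) ** 2 + (yy[None] - cy) ** 2 + (xx[None] - cx) ** 2 <= r**2
            if np.any(sphere[:, keepout]):
                continue
            methoxy[sphere] = cfg.plaque_level
            plaque_sizes.append(int(sphere.sum()))
            placed = True
            break
        if not placed:
            raise ValueError("could not place a plaque clear of vessels and CAA")

    if cfg.depth_decay_um > 0:
        decay = np.exp(-(np.arange(Z) * cfg.voxel_size[0]) / cfg.depth_decay_um)
        methoxy *= decay[:, None, None]
        sr101 *= decay[:, None, None]
    noise_sd = (cfg.caa_level - cfg.wall_level) / cfg.snr if cfg.snr > 0 else 0.0
    if noise_sd > 0:
        methoxy = methoxy + rng.normal(0, noise_sd, size=cfg.shape)
        sr101 = sr101 + rng.normal(0, noise_sd, size=cfg.shape)
    methoxy = np.clip(methoxy, 0, None)
    sr101 = np.clip(sr101, 0, None)

    caa_frac = float(caa2d[vessel2d].sum() / vessel2d.sum())
    truth = GroundTruth(
        seed,
        {
            "caa_coverage_pct": 100.0 * caa_frac,
            "nominal_caa_fraction": cfg.caa_fraction,
            "plaque_voxels": plaque_sizes,
            "plaque_volume_um3": float(
                sum(plaque_sizes) * np.prod(cfg.voxel_size)
            ),
        },
    )
    vol = TwoPhotonVolume(methoxy, sr101, cfg.voxel_size)
    return vol, outlines, truth


# ---------------------------------------------------------------------------
# longitudinal cohorts


@dataclass
class CohortConfig:
    """Design and effect structure of a synthetic longitudinal cohort.

    Defaults mirror the study: 8 mice per genotype-by-sex group, ages 3-20
    months, visit counts ~ N(5.4, 3.1) clipped to [1, 12], inter-visit
    intervals ~ N(1.52, 0.5) months clipped at 0.5. ``betas`` names the fixed
    effects of the session-outcome model; unspecified terms are zero.
    """

    n_per_group: int = 8
    age_start: float = 3.0
    age_end: float = 20.0
    visits_mean: float = 5.4
    visits_sd: float = 3.1
    interval_mean: float = 1.52
    interval_sd: float = 0.5
    betas: dict = dfield(default_factory=dict)  # keys: intercept, age, sexF,
    # genotypeAD, age_genotypeAD, age_sexF
    intercept_sd: float = 0.3  # mouse random-intercept SD
    residual_sd: float = 0.4
    outcome: str = "peak_bold"


def _cohort_design(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for genotype in ("APP_PS1", "WT"):
        for sex in ("F", "M"):
            for i in range(cfg.n_per_group):
                mouse = f"{genotype[:2]}_{sex}{i:02d}"
                n_visits = int(np.clip(round(rng.normal(cfg.visits_mean, cfg.visits_sd)), 1, 12))
                age = cfg.age_start + rng.uniform(0, 1.0)
                for v in range(n_visits):
                    if age > cfg.age_end:
                        break
                    rows.append(
                        {
                            "mouse_id": mouse,
                            "genotype": genotype,
                            "sex": sex,
                            "age": age,
                            "session_index": v,
                        }
                    )
                    age += max(0.5, rng.normal(cfg.interval_mean, cfg.interval_sd))
    return pd.DataFrame(rows)


def gen_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format session outcomes drawn from a linear mixed model.

    The outcome is ``b0 + b_age*age + b_sexF*[sex=F] + b_AD*[APP_PS1] +
    b_age_AD*age*[APP_PS1] + b_age_sexF*age*[sex=F] + u_mouse + eps`` with
    ``u ~ N(0, intercept_sd^2)`` and ``eps ~ N(0, residual_sd^2)``.
    """
    cfg = config or CohortConfig()
    if cfg.intercept_sd < 0 or cfg.residual_sd <= 0:
        raise ValueError("variance components must be positive")
    rng = np.random.default_rng(seed)
    df = _cohort_design(cfg, rng)
    b = {
        "intercept": 0.0, "age": 0.0, "sexF": 0.0, "genotypeAD": 0.0,
        "age_genotypeAD": 0.0, "age_sexF": 0.0,
    }
    unknown = set(cfg.betas) - set(b)
    if unknown:
        raise ValueError(f"unknown beta terms: {sorted(unknown)}")
    b.update(cfg.betas)
    is_f = (df["sex"] == "F").astype(float)
    is_ad = (df["genotype"] == "APP_PS1").astype(float)
    mean = (
        b["intercept"]
        + b["age"] * df["age"]
        + b["sexF"] * is_f
        + b["genotypeAD"] * is_ad
        + b["age_genotypeAD"] * df["age"] * is_ad
        + b["age_sexF"] * df["age"] * is_f
    )
    mice = df["mouse_id"].unique()
    u = pd.Series(rng.normal(0, cfg.intercept_sd, mice.size), index=mice)
    df[cfg.outcome] = (
        mean.to_numpy()
        + u[df["mouse_id"]].to_numpy()
        + rng.normal(0, cfg.residual_sd, len(df))
    )
    truth = GroundTruth(seed, {"betas": dict(b), "intercept_sd": cfg.intercept_sd,
                               "residual_sd": cfg.residual_sd, "n_obs": len(df)})
    return df, truth


@dataclass
class VesselCohortConfig:
    """Vessel-level cohort for the dilation ~ diameter x age surface.

    ``jn_boundary_months`` plants the age at which the conditional
    diameter-dilation slope loses significance: the interaction coefficient
    is chosen so that, using the expected OLS coefficient covariance of the
    realised design, the deterministic Johnson-Neyman root sits exactly at
    the target. ``slope_per_month`` fixes how fast the slope shrinks with
    age.
    """

    n_mice: int = 8
    sex: str = "F"
    genotype: str = "APP_PS1"
    vessels_per_session: int = 10
    median_diameter_um: float = 54.0
    log_sigma: float = 0.45
    jn_boundary_months: float = 11.0
    slope_per_month: float = 0.008  # d(theta)/d(age), %/um per month
    age_effect: float = -0.29  # dilation decline with age, %/month
    mean_dilation: float = 8.0
    intercept_sd: float = 1.0
    residual_sd: float = 3.0
    visits_mean: float = 5.4
    visits_sd: float = 3.1
    interval_mean: float = 1.52
    interval_sd: float = 0.5
    age_start: float = 3.0
    age_end: float = 20.0
    alpha: float = 0.05


def gen_vessel_cohort(
    config: VesselCohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Vessel dilation records with a planted Johnson-Neyman boundary.

    The design (mice, visit ages, vessel baseline diameters) is generated
    first; the expected OLS covariance of the ``dilation ~ diameter * age``
    coefficients under the marginal error variance then calibrates the
    diameter coefficient so theta(age) = b_d + b_inter * age crosses the
    critical Wald value exactly at ``jn_boundary_months``, with the slope
    significant (negative) at younger ages.
    """
    cfg = config or VesselCohortConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(cfg.n_mice):
        mouse = f"{cfg.genotype[:2]}_{cfg.sex}{i:02d}"
        n_visits = int(np.clip(round(rng.normal(cfg.visits_mean, cfg.visits_sd)), 1, 12))
        age = cfg.age_start + rng.uniform(0, 1.0)
        for v in range(n_visits):
            if age > cfg.age_end:
                break
            d = np.clip(
                rng.lognormal(np.log(cfg.median_diameter_um), cfg.log_sigma,
                              cfg.vessels_per_session),
                10.0, 150.0,
            )
            for j, dj in enumerate(d):
                rows.append(
                    {
                        "mouse_id": mouse, "sex": cfg.sex, "genotype": cfg.genotype,
                        "age": age, "session_index": v, "vessel_type": "artery",
                        "baseline_diameter": dj,
                    }
                )
            age += max(0.5, rng.normal(cfg.interval_mean, cfg.interval_sd))
    df = pd.DataFrame(rows)

    d = df["baseline_diameter"].to_numpy()
    a = df["age"].to_numpy()
    X = np.column_stack([np.ones(len(df)), d, a, d * a])
    n, p = X.shape
    sigma2 = cfg.residual_sd**2 + cfg.intercept_sd**2  # marginal error variance
    cov = sigma2 * np.linalg.inv(X.T @ X)
    v11, v33, v13 = cov[1, 1], cov[3, 3], cov[1, 3]
    t_crit = scipy.stats.t.ppf(1 - cfg.alpha / 2, n - p)
    m = cfg.jn_boundary_months
    b3 = cfg.slope_per_month
    var_theta = v11 + m**2 * v33 + 2 * m * v13
    theta_m = -t_crit * np.sqrt(var_theta)  # slope exactly at the boundary
    b1 = theta_m - b3 * m

    mice = df["mouse_id"].unique()
    u = pd.Series(rng.normal(0, cfg.intercept_sd, mice.size), index=mice)
    df["percent_change"] = (
        cfg.mean_dilation
        + b1 * d
        + cfg.age_effect * a
        + b3 * d * a
        + u[df["mouse_id"]].to_numpy()
        + rng.normal(0, cfg.residual_sd, len(df))
    )
    truth = GroundTruth(
        seed,
        {
            "b_diameter": float(b1),
            "b_age": cfg.age_effect,
            "b_diameter_age": float(b3),
            "jn_boundary_months": float(m),
            "t_crit": float(t_crit),
            "expected_cov": cov,
        },
    )
    return df, truth


def gen_session_meta(rng_or_seed=0, genotype="APP_PS1", sex="F", age=6.0,
                     mouse_id="AP_F00", session_index=0) -> SessionMeta:
    """Convenience constructor for tests and examples."""
    return SessionMeta(mouse_id, genotype, sex, age, session_index)
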