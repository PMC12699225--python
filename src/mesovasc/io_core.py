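"""Reading/writing stacks, masks, paradigms and results tables.

Widefield movies are multi-page TIFFs whose pages cycle through the three LED
channels (blue 470 / green 570 / red 620) frame by frame; the cycle phase is
not recoverable from the pixel data, so the channel order is always supplied
explicitly (config or CLI flag), never inferred.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .types import CHANNELS, Channel, ChannelStack, EmptyInputError, MaskImage, MaskLabel

log = logging.getLogger(__name__)

DEFAULT_LAYOUT: tuple[Channel, ...] = CHANNELS
#: LED cycle order used throughout: blue (GCaMP), green (570), red (620).

#: Widefield acquisition geometry: 260 x 348 px over 4.4 x 5.9 mm.
WIDEFIELD_PIXEL_SIZE_UM = 4400.0 / 260  # ~16.9 um/px unbinned


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into a ``(T, H, W)`` array in page order.

    Raises ``IOError`` for unreadable files and :class:`EmptyInputError` for
    files with zero pages. Page count is logged for audit.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / truncated file
        raise IOError(f"could not read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.size == 0:
        raise EmptyInputError(f"{path} contains no image data")
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise IOError(f"{path}: expected a (T, H, W) page stack, got shape {frames.shape}")
    log.info("read %d pages of %s from %s", frames.shape[0], frames.shape[1:], path)
    return frames


def write_stack(path: str | Path, frames: np.ndarray) -> None:
    """Write a ``(T, H, W)`` array as a multi-page TIFF."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    tifffile.imwrite(Path(path), frames)


def demux_channels(
    raw: np.ndarray,
    layout: Sequence[Channel] = DEFAULT_LAYOUT,
    frame_rate: float = 30.0,
    pixel_size: float = WIDEFIELD_PIXEL_SIZE_UM,
    start_time: float = 0.0,
) -> dict[Channel, ChannelStack]:
    """Split an interleaved LED movie into per-channel stacks.

    ``raw`` holds frames in acquisition order cycling through ``layout``.
    Each channel keeps its own acquisition times (``start_time + i / rate``);
    the per-channel rate is ``frame_rate / len(layout)`` (30 Hz acquisition ->
    10 Hz per LED). Trailing frames not completing a full LED cycle are
    dropped, not imputed.
    """
    raw = np.asarray(raw)
    ncyc = len(layout)
    if len(set(layout)) != ncyc:
        raise ValueError("layout must not repeat channels")
    n = raw.shape[0]
    if n < ncyc:
        raise EmptyInputError(f"need at least one full LED cycle ({ncyc} frames), got {n}")
    n_keep = (n // ncyc) * ncyc
    if n_keep < n:
        log.warning("dropping %d trailing frame(s) of an incomplete LED cycle", n - n_keep)
    dt = 1.0 / frame_rate
    out: dict[Channel, ChannelStack] = {}
    for k, channel in enumerate(layout):
        frames = raw[k:n_keep:ncyc]
        times = start_time + dt * np.arange(k, n_keep, ncyc)
        out[channel] = ChannelStack(channel, frames, times, pixel_size)
    return out


def read_mask(path: str | Path, label: MaskLabel) -> MaskImage:
    """Read a binary mask from PNG or TIFF (any nonzero pixel is set)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # RGB(A) PNG: any channel set
        arr = arr[..., :3].max(axis=-1)
    return MaskImage(label, arr > 0)


def write_mask(path: str | Path, mask: MaskImage) -> None:
    path = Path(path)
    arr = (mask.grid.astype(np.uint8)) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a session-metrics table as CSV (header row; NaN -> empty cell).

    Non-finite values are written as empty cells and logged so that failed
    measurements remain visible in downstream tables.
    """
    if records.empty:
        raise ValueError("refusing to write an empty results table")
    num = records.select_dtypes(include=[np.number])
    n_bad = int((~np.isfinite(num.to_numpy(dtype=float))).sum()) if num.size else 0
    if n_bad:
        log.warning("results table contains %d non-finite value(s); written as empty cells", n_bad)
    records.to_csv(Path(path), index=False, na_rep="")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def read_config(path: str | Path) -> dict:
    """Read a YAML/JSON session config (channel order, rates, pixel size)."""
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def read_probes(path: str | Path) -> list:
    """Read vessel probe annotations from CSV.

    Expected columns: ``vessel_id, y, x, normal_dy, normal_dx,
    half_length_um, type``.
    """
    from .types import VesselProbe

    df = pd.read_csv(Path(path))
    probes = []
    for _, r in df.iterrows():
        probes.append(
            VesselProbe(
                vessel_id=str(r["vessel_id"]),
                center=(float(r["y"]), float(r["x"])),
                normal=(float(r["normal_dy"]), float(r["normal_dx"])),
                half_length=float(r["half_length_um"]),
                vessel_type=str(r["type"]),
            )
        )
    return probes


def write_probes(probes, path: str | Path) -> None:
    rows = [
        {
            "vessel_id": p.vessel_id,
            "y": p.center[0],
            "x": p.center[1],
            "normal_dy": p.normal[0],
            "normal_dx": p.normal[1],
            "half_length_um": p.half_length,
            "type": p.vessel_type,
        }
        for p in probes
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
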