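"""Readers and writers for frame stacks, traces and run configurations.

Real-data entry points: TIFF stacks and PNG sequences exported by the
camera software (including the merged-buffer convention where every 100
camera buffers are stored stacked vertically in one tall image), raw 8-bit
frames with a JSON header sidecar, and two-column oscilloscope CSV exports.
All timestamps are synthesized from a frame rate when the source carries no
timing metadata — an explicit rate is then required, never guessed.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .chain import ChainParams, MsTrace
from .synthetic import CurrentTrace, FrameStack

__all__ = [
    "RunConfig",
    "read_frame_stack",
    "write_frame_stack",
    "read_trace_csv",
    "write_trace_csv",
]


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------


def _timestamps(n: int, frame_rate: float | None, meta_rate: float | None):
    rate = frame_rate if frame_rate is not None else meta_rate
    if rate is None:
        raise ValueError(
            "no frame-rate metadata found; pass frame_rate= explicitly"
        )
    return np.arange(n) / float(rate)


def _split_merged(pages: np.ndarray, merged_frames: int) -> np.ndarray:
    """Split vertically merged buffer images into individual frames.

    Each stored image of height ``merged_frames * h`` holds that many
    consecutive frames stacked top to bottom (the camera software's
    merged-buffer export convention).
    """
    n, hh, w = pages.shape
    if hh % merged_frames:
        raise ValueError(
            f"merged image height {hh} is not divisible by {merged_frames}"
        )
    h = hh // merged_frames
    return pages.reshape(n * merged_frames, h, w)


def read_frame_stack(
    path: str | Path,
    *,
    frame_rate: float | None = None,
    merged_frames: int = 1,
) -> FrameStack:
    """Read a TIFF stack, PNG sequence directory, or raw file with sidecar.

    PNG sequences must be consecutively numbered (``name_000123.png``); a
    gap raises an error naming the first missing index.  Raw files require
    a ``<name>.json`` sidecar with ``height``, ``width``, ``n_frames`` and
    optionally ``frame_rate``.  ``merged_frames > 1`` expands vertically
    merged buffer images into individual frames.
    """
    path = Path(path)
    meta_rate: float | None = None
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        indices = []
        for f in files:
            m = re.search(r"(\d+)$", f.stem)
            if not m:
                raise ValueError(f"unnumbered frame file {f.name}")
            indices.append(int(m.group(1)))
        start = min(indices)
        expected = set(range(start, start + len(files)))
        missing = sorted(expected - set(indices))
        if missing:
            raise ValueError(f"PNG sequence is missing frame index {missing[0]}")
        pages = np.stack([iio.imread(f) for _, f in sorted(zip(indices, files))])
    elif path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            meta = tf.shaped_metadata or ()
            for m in meta:
                if "frame_rate" in m:
                    meta_rate = float(m["frame_rate"])
        if pages.ndim == 2:
            pages = pages[None]
    elif path.suffix.lower() == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw stack requires sidecar {sidecar.name}")
        hdr = json.loads(sidecar.read_text())
        data = np.fromfile(path, dtype=np.uint8)
        shape = (int(hdr["n_frames"]), int(hdr["height"]), int(hdr["width"]))
        if data.size != np.prod(shape):
            raise ValueError("raw file size does not match sidecar dimensions")
        pages = data.reshape(shape)
        meta_rate = hdr.get("frame_rate")
    else:
        raise ValueError(f"unsupported frame-stack source {path}")
    if pages.ndim != 3:
        raise ValueError("frames must be single-channel grayscale")
    if merged_frames > 1:
        pages = _split_merged(pages, merged_frames)
    ts = _timestamps(len(pages), frame_rate, meta_rate)
    return FrameStack(np.ascontiguousarray(pages, dtype=np.uint8), ts)


def write_frame_stack(
    stack: FrameStack,
    path: str | Path,
    *,
    frame_rate: float | None = None,
) -> None:
    """Write a stack as TIFF (``.tif``), PNG sequence (dir) or raw+sidecar."""
    path = Path(path)
    frames = np.stack([stack[i] for i in range(len(stack))]) if len(stack) \
        else np.zeros((0, 1, 1), np.uint8)
    if frame_rate is None and len(stack) > 1:
        frame_rate = 1.0 / float(np.median(np.diff(stack.timestamps)))
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, frames, metadata={"frame_rate": frame_rate})
    elif path.suffix.lower() == ".raw":
        frames.tofile(path)
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "n_frames": int(frames.shape[0]),
                    "height": int(frames.shape[1]),
                    "width": int(frames.shape[2]),
                    "frame_rate": frame_rate,
                }
            )
        )
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i in range(len(frames)):
            iio.imwrite(path / f"frame_{i:06d}.png", frames[i])


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


def read_trace_csv(
    path: str | Path,
    *,
    kind: str = "current",
    grid_tolerance: float = 0.01,
) -> CurrentTrace | MsTrace:
    """Read a two-column ``time,value`` CSV (optional header).

    The time column must be a uniform grid within ``grid_tolerance`` of the
    median step; jittered exports are rejected with a hint to resample.
    ``kind`` selects the container: ``current`` (oscilloscope) or ``ms``
    (SIM event trace).
    """
    df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    # Drop a header row if the first row is non-numeric.
    first = pd.to_numeric(df.iloc[0], errors="coerce") if len(df) else None
    if first is not None and first.isna().any():
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns time,value")
    arr = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if np.isnan(arr).any():
        raise ValueError(f"{path}: non-numeric rows in trace")
    times, values = arr[:, 0], arr[:, 1]
    steps = np.diff(times)
    if len(steps) == 0:
        raise ValueError(f"{path}: a single sample is not a trace")
    med = float(np.median(steps))
    if med <= 0 or np.any(np.abs(steps - med) > grid_tolerance * med):
        raise ValueError(
            f"{path}: timestamps are not uniform within {grid_tolerance:.0%} "
            "of the median step; resample before analysis"
        )
    if kind == "current":
        return CurrentTrace(values, med, t0=float(times[0]))
    if kind == "ms":
        return MsTrace(times, np.clip(values, 0, None))
    raise ValueError(f"unknown trace kind {kind!r}")


def write_trace_csv(trace, path: str | Path) -> None:
    """Write a trace (CurrentTrace or MsTrace) as two-column CSV."""
    if isinstance(trace, CurrentTrace):
        times, values = trace.times, trace.current
    else:
        times, values = trace.event_times, trace.intensity
    pd.DataFrame({"time_s": times, "value": values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ALLOWED_KEYS = {
    "esi_voltage",
    "duration",
    "seed",
    "frame_rate",
    "bin_size",
    "intensity_threshold",
    "count_threshold",
    "tip_x",
    "tip_y",
    "pixel_noise_sd",
    "transit_delay",
    "mixing_tau",
    "dwell",
    "event",
    "detector_noise_sd",
    "gain",
    "gate_schedule",
    "output_dir",
}


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run.

    Unknown keys are rejected on load so thresholds can never fall back to
    silent defaults by being misspelled.  Every CLI command writes the
    resolved configuration and seed next to its outputs.
    """

    esi_voltage: float = 4.0
    duration: float = 30.0
    seed: int = 1
    frame_rate: float = 5000.0
    bin_size: int = 20
    intensity_threshold: int = 128
    count_threshold: int = 10
    tip_x: int = 100
    tip_y: int = 128
    pixel_noise_sd: float = 5.0
    transit_delay: float = 1e-3
    mixing_tau: float = 5e-3
    dwell: float = 0.8e-3
    event: float = 4e-3
    detector_noise_sd: float = 500.0
    gain: float = 2500.0
    gate_schedule: list = field(default_factory=lambda: [[0.0, 30.0]])
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def chain_params(self) -> ChainParams:
        return ChainParams(
            transit_delay=self.transit_delay,
            mixing_tau=self.mixing_tau,
            dwell=self.dwell,
            event=self.event,
            detector_noise_sd=self.detector_noise_sd,
            gain=self.gain,
        )
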