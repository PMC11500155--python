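"""Reference-line black-pixel classifier for Taylor-cone presence.

A vertical reference line of ``line_length`` pixels (default 120) is placed
``horizontal_offset`` pixels (30-50, voltage-dependent) in front of the
user-selected emitter-tip anchor.  A frame is classified cone-present when
the number of pixels on that line darker than ``intensity_threshold``
reaches ``count_threshold``.  The same single-frame decision is used both
for offline stack analysis and by the simulated real-time control loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import FrameStack, GeometryError, SprayPreset

__all__ = [
    "DetectionGeometry",
    "ConeTrace",
    "extract_reference_column",
    "count_black_pixels",
    "classify_presence",
    "analyze_stack",
    "geometry_for_preset",
    "propose_tip",
]

#: Mid-gray binarization level; "black" is any intensity strictly below it.
DEFAULT_INTENSITY_THRESHOLD = 128
#: Minimum black pixels on the line for the cone to be considered present.
DEFAULT_COUNT_THRESHOLD = 10
DEFAULT_LINE_LENGTH = 120


@dataclass(frozen=True)
class DetectionGeometry:
    """Placement and thresholds of the reference-line classifier.

    ``tip_x``/``tip_y`` anchor the emitter tip midpoint (user-selected; see
    :func:`propose_tip` for a suggestion helper).  The reference column sits
    at ``tip_x + horizontal_offset`` and spans ``line_length`` rows centered
    on ``tip_y``.
    """

    tip_x: int
    tip_y: int
    horizontal_offset: int = 40
    line_length: int = DEFAULT_LINE_LENGTH
    intensity_threshold: int = DEFAULT_INTENSITY_THRESHOLD
    count_threshold: int = DEFAULT_COUNT_THRESHOLD

    def __post_init__(self) -> None:
        if not 0 <= self.intensity_threshold <= 255:
            raise ValueError("intensity_threshold must lie in [0, 255]")
        if not 0 <= self.count_threshold <= self.line_length:
            raise ValueError("count_threshold must lie in [0, line_length]")
        if self.line_length <= 0:
            raise ValueError("line_length must be positive")

    @property
    def line_x(self) -> int:
        return int(self.tip_x + self.horizontal_offset)

    @property
    def row_start(self) -> int:
        return int(self.tip_y - self.line_length // 2)

    @property
    def rows(self) -> slice:
        return slice(self.row_start, self.row_start + self.line_length)

    def validate_for_shape(self, height: int, width: int) -> None:
        """Raise :class:`GeometryError` unless the line fits in the frame."""
        if not 0 <= self.line_x < width:
            raise GeometryError(
                f"reference line at x={self.line_x} outside frame width {width}"
            )
        if self.row_start < 0 or self.row_start + self.line_length > height:
            raise GeometryError(
                f"{self.line_length}-px line centered on y={self.tip_y} "
                f"outside frame height {height}"
            )


def geometry_for_preset(
    preset: SprayPreset,
    *,
    tip_x: int = 100,
    tip_y: int = 128,
    **thresholds,
) -> DetectionGeometry:
    """Geometry with the voltage-dependent offset resolved from a preset."""
    return DetectionGeometry(
        tip_x=tip_x,
        tip_y=tip_y,
        horizontal_offset=int(round(preset.horizontal_offset)),
        **thresholds,
    )


def extract_reference_column(
    frame: np.ndarray, geometry: DetectionGeometry
) -> np.ndarray:
    """The ``line_length`` intensities on the reference line of one frame."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D intensity array")
    geometry.validate_for_shape(*frame.shape)
    return frame[geometry.rows, geometry.line_x]


def count_black_pixels(column: np.ndarray, intensity_threshold: int) -> int:
    """Number of entries strictly below the binarization level."""
    return int(np.count_nonzero(np.asarray(column) < intensity_threshold))


def classify_presence(black_count: int, count_threshold: int) -> bool:
    """Cone present iff the black-pixel count reaches the threshold."""
    return black_count >= count_threshold


@dataclass
class ConeTrace:
    """Per-frame black-pixel counts and Boolean cone presence."""

    timestamps: np.ndarray
    black_count: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.black_count = np.asarray(self.black_count, dtype=np.int64)
        self.present = np.asarray(self.present, dtype=bool)
        if not len(self.timestamps) == len(self.black_count) == len(self.present):
            raise ValueError("trace fields must have equal length")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def frame_rate(self) -> float:
        if len(self) < 2:
            raise ValueError("frame rate undefined for traces shorter than 2")
        return 1.0 / float(np.median(np.diff(self.timestamps)))


def analyze_stack(stack: FrameStack, geometry: DetectionGeometry) -> ConeTrace:
    """Classify every frame of a stack, preserving its timestamps.

    Uses the stack's vectorized reference-column accessor when available
    (lazily rendered synthetic stacks and array stacks both provide it);
    otherwise falls back to per-frame extraction.
    """
    n = len(stack)
    if n == 0:
        return ConeTrace(np.zeros(0), np.zeros(0, dtype=int), np.zeros(0, bool))
    geometry.validate_for_shape(*stack.frame_shape)
    if hasattr(stack, "get_columns"):
        cols = stack.get_columns(geometry.line_x, geometry.rows)
        counts = np.count_nonzero(cols < geometry.intensity_threshold, axis=1)
    else:  # pragma: no cover - all shipped stacks provide get_columns
        counts = np.empty(n, dtype=np.int64)
        for i in range(n):
            try:
                col = extract_reference_column(stack[i], geometry)
            except GeometryError as exc:
                raise GeometryError(f"frame {i}: {exc}") from exc
            counts[i] = count_black_pixels(col, geometry.intensity_threshold)
    present = counts >= geometry.count_threshold
    return ConeTrace(np.asarray(stack.timestamps), counts, present)


def propose_tip(frame: np.ndarray, *, dark_level: int = 128) -> tuple[int, int]:
    """Suggest an emitter-tip anchor: the rightmost dark silhouette column.

    Returns ``(tip_x, tip_y)`` where ``tip_x`` is the rightmost column whose
    dark run is at least as thick as half the silhouette's maximum, and
    ``tip_y`` the center of the dark run there.  This is a convenience for
    interactive use; analysis functions never apply it implicitly.
    """
    frame = np.asarray(frame)
    dark = frame < dark_level
    col_counts = dark.sum(axis=0)
    if not col_counts.any():
        raise ValueError("no dark silhouette found in frame")
    thick = col_counts >= max(1, col_counts.max() // 2)
    tip_x = int(np.max(np.nonzero(thick)))
    rows = np.nonzero(dark[:, tip_x])[0]
    return tip_x, int(rows.mean().round())
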