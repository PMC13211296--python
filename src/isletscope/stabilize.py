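"""Translation-only stabilization of a time-lapse stack.

The pipeline follows the standard sequential scheme for perfusion-induced
motion: the lateral shift of each frame relative to the immediately preceding
frame is estimated by phase correlation (normalized cross-power spectrum,
subpixel peak by local upsampling), the stepwise shifts are cumulatively
composed into the coordinate system of the first frame, every frame is
resampled into that reference geometry with out-of-view pixels set exactly to
zero, and the stack is cropped to the rectangle that carries valid content in
every frame.

Sign convention: a :class:`Translation2D` ``(dy, dx)`` is the displacement of
image content, dy positive downward, dx positive rightward, origin top-left,
row-major.  ``ShiftSeries.cumulative[t]`` is the content displacement of frame
t relative to frame 0; stabilization undoes it.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.signal.windows import hann
from skimage.registration import phase_cross_correlation

from .stack import TimeLapseStack

__all__ = [
    "Translation2D",
    "ShiftSeries",
    "CropWindow",
    "RegistrationError",
    "estimate_pairwise_shift",
    "accumulate_shifts",
    "resample_to_reference",
    "valid_crop_window",
    "stabilize_stack",
]

DEFAULT_UPSAMPLE = 10  # 0.1 px subpixel precision

_INT_TOL = 1e-9  # shifts this close to an integer are treated as exact


class RegistrationError(ValueError):
    """Raised for degenerate inputs or impossible geometry."""


@dataclasses.dataclass(frozen=True)
class Translation2D:
    """In-plane content displacement in pixels (possibly fractional)."""

    dy: float
    dx: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dy) and math.isfinite(self.dx)):
            raise RegistrationError(f"non-finite translation ({self.dy}, {self.dx})")

    def __neg__(self) -> "Translation2D":
        return Translation2D(-self.dy, -self.dx)

    def __add__(self, other: "Translation2D") -> "Translation2D":
        return Translation2D(self.dy + other.dy, self.dx + other.dx)

    def as_tuple(self) -> tuple[float, float]:
        return self.dy, self.dx


@dataclasses.dataclass(frozen=True)
class ShiftSeries:
    """Per-frame cumulative displacement relative to frame 0."""

    cumulative: tuple[Translation2D, ...]

    def __post_init__(self) -> None:
        if not self.cumulative:
            raise RegistrationError("shift series is empty")
        if self.cumulative[0].as_tuple() != (0.0, 0.0):
            raise RegistrationError("cumulative[0] must be exactly (0, 0)")

    def __len__(self) -> int:
        return len(self.cumulative)

    def __getitem__(self, t: int) -> Translation2D:
        return self.cumulative[t]

    def as_array(self) -> np.ndarray:
        return np.array([s.as_tuple() for s in self.cumulative])

    def to_frame(self) -> pd.DataFrame:
        arr = self.as_array()
        return pd.DataFrame(
            {"frame": np.arange(len(self)), "dy_px": arr[:, 0], "dx_px": arr[:, 1]}
        )


@dataclasses.dataclass(frozen=True)
class CropWindow:
    """Half-open pixel-index rectangle, 0-based, row-major."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise RegistrationError(f"degenerate crop window {self}")
        if min(self.row_start, self.col_start) < 0:
            raise RegistrationError(f"crop window {self} outside frame bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.row_end - self.row_start, self.col_end - self.col_start

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_end), slice(self.col_start, self.col_end)

    def apply(self, frames: np.ndarray) -> np.ndarray:
        rs, cs = self.slices()
        return frames[..., rs, cs]


# ------------------------------------------------------------------ operations


def estimate_pairwise_shift(
    moving: np.ndarray,
    reference: np.ndarray,
    upsample: int = DEFAULT_UPSAMPLE,
    use_hann: bool = False,
) -> Translation2D:
    """Displacement of ``moving``'s content relative to ``reference``.

    Phase correlation with subpixel refinement at precision ``1/upsample``.
    Shifting ``moving`` by the negated result aligns it to ``reference``.
    Antisymmetric within tolerance: estimate(a, b) ~ -estimate(b, a).
    """
    moving = np.asarray(moving, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if moving.shape != reference.shape:
        raise RegistrationError(
            f"frame shapes differ: {moving.shape} vs {reference.shape}"
        )
    if upsample < 1:
        raise RegistrationError("upsample must be >= 1")
    for name, frame in (("moving", moving), ("reference", reference)):
        if np.ptp(frame) == 0:
            raise RegistrationError(
                f"{name} frame is constant; correlation is undefined"
            )
    if use_hann:
        win = np.outer(hann(moving.shape[0]), hann(moving.shape[1]))
        moving = moving * win
        reference = reference * win
    # skimage returns the shift to apply to `moving` to register it onto
    # `reference`, i.e. the negated content displacement
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample, normalization="phase"
    )
    return Translation2D(-float(shift[0]), -float(shift[1]))


def accumulate_shifts(pairwise: list[Translation2D]) -> ShiftSeries:
    """Running sum of stepwise shifts; cumulative[0] is the zero transform."""
    cumulative = [Translation2D(0.0, 0.0)]
    for step in pairwise:
        cumulative.append(cumulative[-1] + step)  # Translation2D validates finiteness
    return ShiftSeries(cumulative=tuple(cumulative))


def _snap(v: float) -> float:
    r = round(v)
    return float(r) if abs(v - r) <= _INT_TOL else float(v)


def _translate_zero_fill(frame: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Undo a content displacement of (dy, dx): out[r, c] = in[r + dy, c + dx].

    Integer shifts use pure index moves (bit-exact); fractional shifts use
    bilinear interpolation.  Pixels pulling from outside the frame are 0.
    """
    rows, cols = frame.shape
    if abs(dy) >= rows or abs(dx) >= cols:
        raise RegistrationError(
            f"shift ({dy}, {dx}) >= frame size {frame.shape}: no overlap"
        )
    dy, dx = _snap(dy), _snap(dx)
    if dy == 0.0 and dx == 0.0:
        return frame.copy()
    if dy.is_integer() and dx.is_integer():
        idy, idx = int(dy), int(dx)
        out = np.zeros_like(frame)
        src_r = slice(max(0, idy), min(rows, rows + idy))
        src_c = slice(max(0, idx), min(cols, cols + idx))
        dst_r = slice(max(0, -idy), min(rows, rows - idy))
        dst_c = slice(max(0, -idx), min(cols, cols - idx))
        out[dst_r, dst_c] = frame[src_r, src_c]
        return out
    # ndi.shift(in, s) computes out[r] = in[r - s]; we want in[r + dy]
    return ndi.shift(frame, (-dy, -dx), order=1, mode="constant", cval=0.0)


def resample_to_reference(stack: TimeLapseStack, shifts: ShiftSeries) -> TimeLapseStack:
    """Undo each frame's cumulative displacement; zero-fill out-of-view pixels.

    Frame 0 is returned unchanged (identity transform); output shape equals
    input shape.
    """
    if len(shifts) != stack.n_frames:
        raise RegistrationError(
            f"shift series length {len(shifts)} != n_frames {stack.n_frames}"
        )
    out = np.empty_like(stack.frames)
    out[0] = stack.frames[0]
    for t in range(1, stack.n_frames):
        dy, dx = shifts[t].as_tuple()
        out[t] = _translate_zero_fill(stack.frames[t], dy, dx)
    return TimeLapseStack(
        frames=np.maximum(out, 0.0),
        frame_interval_s=stack.frame_interval_s,
        provenance=f"stabilized({stack.provenance})",
    )


def valid_crop_window(shifts: ShiftSeries, frame_shape: tuple[int, int]) -> CropWindow:
    """Maximal rectangle covered by every stabilized frame.

    A stabilized pixel (r, c) of frame t pulls from raw position
    (r + dy_t, c + dx_t); it is valid when that position lies fully inside
    the frame, including the bilinear support for fractional shifts.  Ceil
    and floor are chosen so no partially interpolated border pixel is ever
    admitted.
    """
    rows, cols = frame_shape
    arr = shifts.as_array()
    dys, dxs = arr[:, 0], arr[:, 1]
    row_start = int(max(0, math.ceil(_snap(float(np.max(-dys))))))
    col_start = int(max(0, math.ceil(_snap(float(np.max(-dxs))))))
    row_end = int(min(rows, math.floor(_snap(float(np.min(rows - 1 - dys)))) + 1))
    col_end = int(min(cols, math.floor(_snap(float(np.min(cols - 1 - dxs)))) + 1))
    if row_end <= row_start or col_end <= col_start:
        raise RegistrationError(
            "no region is valid in every frame; extreme shifts: "
            f"dy in [{dys.min():.2f}, {dys.max():.2f}], "
            f"dx in [{dxs.min():.2f}, {dxs.max():.2f}] on a {rows}x{cols} frame"
        )
    return CropWindow(row_start, row_end, col_start, col_end)


def stabilize_stack(
    stack: TimeLapseStack,
    upsample: int = DEFAULT_UPSAMPLE,
    use_hann: bool = False,
) -> tuple[TimeLapseStack, ShiftSeries, CropWindow]:
    """Full stabilization: estimate, accumulate, resample, crop.

    Returns the cropped stabilized stack plus the shift series and crop
    window for provenance.  Deterministic for fixed input.
    """
    if stack.n_frames < 2:
        raise RegistrationError("registration needs at least 2 frames")
    pairwise = [
        estimate_pairwise_shift(
            stack.frames[t], stack.frames[t - 1], upsample=upsample, use_hann=use_hann
        )
        for t in range(1, stack.n_frames)
    ]
    shifts = accumulate_shifts(pairwise)
    resampled = resample_to_reference(stack, shifts)
    window = valid_crop_window(shifts, stack.frame_shape)
    cropped = TimeLapseStack(
        frames=window.apply(resampled.frames),
        frame_interval_s=stack.frame_interval_s,
        provenance=resampled.provenance,
    )
    return cropped, shifts, window
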