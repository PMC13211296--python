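"""Background-normalized mean-intensity readout.

The sensor metric is the whole-frame mean intensity divided by the mean
intensity within a fixed, user-defined background region of interest (ROI)
drawn in an area free of islet signal.  Because the same multiplicative gain
acts on every pixel of a frame, the ratio is exactly invariant to per-frame
illumination and detector-gain fluctuations — the normalization is the whole
of the photometric correction, by design.

The ROI lives in the reference (first-frame, post-crop) coordinate system and
is applied unchanged to all frames.  Whole-frame means include the ROI
pixels; this choice is recorded in the trace provenance.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import ProtocolError, StimulusProtocol
from .stack import TimeLapseStack

__all__ = [
    "RegionMask",
    "NormalizedTrace",
    "ReadoutError",
    "load_background_mask",
    "normalized_intensity_trace",
    "annotate_protocol",
]


class ReadoutError(ValueError):
    """Raised for empty/ill-shaped masks or degenerate backgrounds."""


@dataclasses.dataclass(frozen=True)
class RegionMask:
    """Fixed boolean ROI in reference coordinates."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        self.mask.setflags(write=False)
        if self.mask.ndim != 2:
            raise ReadoutError(f"mask must be 2-D, got shape {self.mask.shape}")
        if self.n_pixels < 1:
            raise ReadoutError("region mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def crop(self, row_slice: slice, col_slice: slice) -> "RegionMask":
        return RegionMask(self.mask[row_slice, col_slice])


@dataclasses.dataclass(frozen=True)
class NormalizedTrace:
    """Per-frame dimensionless ratio plus timing and protocol annotations."""

    values: np.ndarray
    frame_times_min: np.ndarray
    annotations: tuple[tuple[str, int, int], ...] = ()  # (label, start, end) half-open
    provenance: str = "whole-frame mean / background-ROI mean (ROI included in numerator)"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        object.__setattr__(
            self, "frame_times_min", np.asarray(self.frame_times_min, dtype=np.float64)
        )
        if self.values.shape != self.frame_times_min.shape:
            raise ReadoutError("values and frame_times_min lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ReadoutError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def phase_label(self, frame: int) -> str:
        for label, lo, hi in self.annotations:
            if lo <= frame < hi:
                return label
        return ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "minutes": self.frame_times_min,
                "normalized_intensity": self.values,
                "phase_label": [self.phase_label(t) for t in range(len(self))],
            }
        )


def _rasterize_polygon(vertices, frame_shape: tuple[int, int]) -> np.ndarray:
    """Pixel centers-inside rasterization (boundary inclusive)."""
    import shapely

    verts = [(float(r), float(c)) for r, c in vertices]
    if len(verts) < 3:
        raise ReadoutError(f"polygon needs >= 3 vertices, got {len(verts)}")
    poly = shapely.Polygon(verts)
    if not poly.is_valid:
        from shapely.validation import explain_validity

        raise ReadoutError(
            f"polygon is invalid ({explain_validity(poly)}); vertices: {verts}"
        )
    if poly.area == 0:
        raise ReadoutError(f"degenerate (zero-area) polygon: {verts}")
    rows, cols = frame_shape
    minr, minc, maxr, maxc = poly.bounds
    r0, r1 = max(0, int(np.floor(minr))), min(rows - 1, int(np.ceil(maxr)))
    c0, c1 = max(0, int(np.floor(minc))), min(cols - 1, int(np.ceil(maxc)))
    mask = np.zeros(frame_shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    inside = shapely.intersects_xy(poly, rr.ravel(), cc.ravel())
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def load_background_mask(source, frame_shape: tuple[int, int]) -> RegionMask:
    """Build the background ROI from an image file, polygon, or array.

    Accepted sources: a single-page 8-bit TIFF/PNG path (nonzero = ROI), a
    dict ``{"vertices": [[r, c], ...]}`` or path to such a JSON document, a
    bare vertex list, or a boolean array.  Polygons are rasterized with a
    boundary-inclusive pixel centers-inside rule.
    """
    if isinstance(source, np.ndarray):
        mask = source.astype(bool)
    elif isinstance(source, dict):
        mask = _rasterize_polygon(source["vertices"], frame_shape)
    elif isinstance(source, (list, tuple)):
        mask = _rasterize_polygon(source, frame_shape)
    elif isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() == ".json":
            doc = json.loads(path.read_text())
            mask = _rasterize_polygon(doc["vertices"], frame_shape)
        else:
            import imageio.v3 as iio

            img = np.asarray(iio.imread(path))
            if img.ndim == 3:  # collapse any color channels
                img = img.max(axis=-1)
            mask = img != 0
    else:
        raise ReadoutError(f"unsupported mask source type: {type(source)!r}")
    if mask.shape != tuple(frame_shape):
        raise ReadoutError(
            f"mask shape {mask.shape} does not match frame shape {tuple(frame_shape)}"
        )
    if not mask.any():
        raise ReadoutError("background mask is empty")
    return RegionMask(mask)


def normalized_intensity_trace(
    stack: TimeLapseStack, background: RegionMask
) -> NormalizedTrace:
    """values[t] = mean(all pixels of frame t) / mean(background pixels of frame t).

    Exactly invariant (to float rounding) under multiplication of any frame by
    a positive per-frame gain.  A zero background mean makes the ratio
    undefined and raises, naming the first offending frame.
    """
    if background.shape != stack.frame_shape:
        raise ReadoutError(
            f"mask shape {background.shape} != frame shape {stack.frame_shape}"
        )
    frame_means = stack.frames.mean(axis=(1, 2))
    bg_means = stack.frames[:, background.mask].mean(axis=1)
    bad = np.flatnonzero(bg_means <= 0)
    if bad.size:
        raise ReadoutError(
            f"background mean is zero at frame {bad[0]}; ratio undefined"
        )
    return NormalizedTrace(
        values=frame_means / bg_means,
        frame_times_min=stack.frame_times_min(),
    )


def annotate_protocol(
    trace: NormalizedTrace,
    protocol: StimulusProtocol,
    frame_interval_min: float = 1.0,
) -> NormalizedTrace:
    """Attach half-open (label, start_frame, end_frame) phase annotations.

    Phase boundaries are floored to frame indices.  A protocol extending past
    the end of the trace is clipped with a warning; a shorter protocol leaves
    trailing frames unannotated.
    """
    if frame_interval_min <= 0:
        raise ProtocolError("frame_interval_min must be positive")
    n = len(trace)
    bounds = protocol.boundary_frames(frame_interval_min)
    annotations = []
    clipped = False
    for phase, lo, hi in zip(protocol.phases, bounds[:-1], bounds[1:]):
        if lo >= n:
            clipped = True
            break
        if hi > n:
            hi, clipped = n, True
        annotations.append((phase.label, lo, hi))
    if clipped:
        warnings.warn(
            f"protocol ({protocol.total_duration_min:g} min) extends past the "
            f"{n}-frame trace; trailing phases clipped",
            stacklevel=2,
        )
    return dataclasses.replace(trace, annotations=tuple(annotations))
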