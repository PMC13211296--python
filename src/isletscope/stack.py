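"""Time-lapse stack container and TIFF round-tripping.

A :class:`TimeLapseStack` is an ordered set of single-channel frames with a
uniform acquisition interval.  Frames are held as float64 internally; on disk
stacks are multi-page 16-bit unsigned TIFF (one page per time point), the
interchange format of the perfusion-imaging pipeline.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile


class StackError(ValueError):
    """Raised for malformed stacks or unreadable stack files."""


@dataclasses.dataclass
class TimeLapseStack:
    """Ordered nonnegative-intensity frames with uniform time spacing.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``; finite, nonnegative.
    frame_interval_s
        Seconds between consecutive frames (default 60 s: one frame per
        minute, the usual perfusion acquisition rate).
    provenance
        Free-text source tag carried through the pipeline.
    """

    frames: np.ndarray
    frame_interval_s: float = 60.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise StackError(
                f"stack must be (n_frames, rows, cols); got shape {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise StackError("stack contains non-finite intensities")
        if np.any(self.frames < 0):
            raise StackError("stack contains negative intensities")
        if self.frame_interval_s <= 0:
            raise StackError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0

    def frame_times_min(self) -> np.ndarray:
        """Minutes from acquisition start, one entry per frame."""
        return np.arange(self.n_frames) * self.frame_interval_min

    # ------------------------------------------------------------------ IO

    def to_tiff(self, path: str | Path) -> None:
        """Write as multi-page uint16 TIFF, clipping and rounding intensities."""
        data = np.clip(np.rint(self.frames), 0, np.iinfo(np.uint16).max)
        tifffile.imwrite(str(path), data.astype(np.uint16))

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        frame_interval_s: float = 60.0,
        provenance: str | None = None,
    ) -> "TimeLapseStack":
        """Read a multi-page TIFF (incl. OME-TIFF and TIFF-based dialects).

        Non-TIFF or unreadable files raise :class:`StackError` naming the
        format, rather than propagating a low-level parser error.
        """
        path = Path(path)
        try:
            data = tifffile.imread(str(path))
        except Exception as exc:  # tifffile raises several concrete types
            raise StackError(
                f"could not read {path} as a TIFF-compatible stack "
                f"(format not supported by the reader): {exc}"
            ) from exc
        data = np.asarray(data, dtype=np.float64)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise StackError(
                f"{path}: expected a single-channel time series, got shape {data.shape}"
            )
        return cls(
            frames=data,
            frame_interval_s=frame_interval_s,
            provenance=provenance if provenance is not None else str(path),
        )
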