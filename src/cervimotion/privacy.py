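"""Mosaic (pixelation) anonymization of face regions.

The face box is tiled into squares of side ``mosaic_size`` anchored at
the box's top-left corner; every pixel in a square takes the color of the
square's top-left pixel in the original image::

    x' = x_left + floor((x - x_left)/s) * s
    y' = y_top  + floor((y - y_top)/s)  * s
    color(x, y) <- color(x', y')

The operation discards information (many input images map to the same
output), which is what makes the anonymization practically irreversible;
it is not cryptographic. Squares overhanging the right/bottom box edge
still anchor at their own top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landmarks import FaceBox

__all__ = ["MosaicConfig", "mosaic_region", "anonymize_video"]


@dataclass(frozen=True)
class MosaicConfig:
    """Mosaic grain: the square side length in pixels (>= 1)."""

    mosaic_size: int = 20

    def __post_init__(self) -> None:
        if self.mosaic_size < 1:
            raise ValueError("mosaic_size must be >= 1")


def mosaic_region(img: np.ndarray, box: FaceBox, cfg: MosaicConfig) -> np.ndarray:
    """Return a copy of ``img`` with the boxed region mosaicked.

    ``img`` is ``(H, W)`` or ``(H, W, C)``; the box must lie within the
    image. Pixels outside the box are untouched, and anchor colors are
    read from the unmodified input, so the result does not depend on any
    block-processing order and the operation is idempotent.
    """
    if img.ndim not in (2, 3):
        raise ValueError(f"expected (H, W[, C]) image, got shape {img.shape}")
    h, w = img.shape[:2]
    if not (0 <= box.x_left < box.x_right <= w and 0 <= box.y_top < box.y_bottom <= h):
        raise ValueError(
            f"box ({box.x_left},{box.y_top})-({box.x_right},{box.y_bottom}) "
            f"outside {w}x{h} image"
        )
    s = cfg.mosaic_size
    out = img.copy()
    xs = np.arange(box.x_left, box.x_right)
    ys = np.arange(box.y_top, box.y_bottom)
    ax = box.x_left + ((xs - box.x_left) // s) * s  # anchor column per column
    ay = box.y_top + ((ys - box.y_top) // s) * s  # anchor row per row
    out[box.y_top : box.y_bottom, box.x_left : box.x_right] = img[np.ix_(ay, ax)]
    return out


def anonymize_video(
    frames: Sequence[np.ndarray],
    boxes: Sequence[FaceBox],
    cfg: MosaicConfig,
) -> list[np.ndarray]:
    """Mosaic each boxed frame of an image sequence independently.

    ``boxes`` may cover any subset of frames (matched by ``frame_index``);
    frames without a box pass through unchanged. A box referencing a
    nonexistent frame is an error.
    """
    by_frame: dict[int, FaceBox] = {}
    for b in boxes:
        if not 0 <= b.frame_index < len(frames):
            raise ValueError(f"box references frame {b.frame_index} of {len(frames)} frames")
        if b.frame_index in by_frame:
            raise ValueError(f"multiple boxes for frame {b.frame_index}")
        by_frame[b.frame_index] = b
    out = []
    for i, frame in enumerate(frames):
        if i in by_frame:
            out.append(mosaic_region(frame, by_frame[i], cfg))
        else:
            out.append(frame.copy())
    return out
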