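"""File I/O: 8-bit SLM mask images, float32 TIFF stacks, CSV traces.

Mask images use the exact SLM payload convention: gray level
``floor(phase/(2*pi) * 256) mod 256``, i.e. level 0..255 spans one 2*pi
wrap.  PSFs and scanned images go to 32-bit float TIFF with the pixel size
recorded in the ImageJ-style metadata.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .ga import OptimizationTrace
from .optics import PhaseMask, QuantizedMask, dequantize, quantize

__all__ = [
    "save_mask_image",
    "load_mask_image",
    "save_tiff",
    "load_tiff",
    "save_trace_csv",
    "load_trace_csv",
]


def save_mask_image(mask: PhaseMask | QuantizedMask, path: str | Path) -> None:
    """Write a phase mask as an 8-bit grayscale PNG or BMP."""
    path = Path(path)
    if path.suffix.lower() not in (".png", ".bmp"):
        raise ValueError(f"mask images must be .png or .bmp, got {path.suffix!r}")
    q = mask if isinstance(mask, QuantizedMask) else quantize(mask)
    iio.imwrite(path, q.levels.astype(np.uint8))


def load_mask_image(path: str | Path) -> PhaseMask:
    """Read an 8-bit grayscale image back into a phase mask (radians)."""
    levels = np.asarray(iio.imread(path))
    if levels.ndim == 3:  # accept grayscale saved with redundant channels
        levels = levels[..., 0]
    return dequantize(QuantizedMask(levels.astype(np.uint8)))


def save_tiff(
    data: np.ndarray, path: str | Path, pixel_size_nm: float, description: str = ""
) -> None:
    """Write a float32 TIFF with pixel size (nm) in the metadata."""
    tifffile.imwrite(
        Path(path),
        np.asarray(data, dtype=np.float32),
        metadata={"pixel_size_nm": pixel_size_nm, "description": description},
    )


def load_tiff(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a TIFF; returns (data, pixel_size_nm or None)."""
    with tifffile.TiffFile(Path(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    px = meta.get("pixel_size_nm")
    return data, None if px is None else float(px)


def save_trace_csv(trace: OptimizationTrace, path: str | Path, header_comment: str = "") -> None:
    """Fitness history to CSV: generation, best, mean, sd."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["generation", "best", "mean", "sd"])
        for row in trace.to_rows():
            writer.writerow([row[0], f"{row[1]:.12g}", f"{row[2]:.12g}", f"{row[3]:.12g}"])


def load_trace_csv(path: str | Path) -> list[dict[str, float]]:
    with open(path) as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows)
    return [
        {k: float(v) for k, v in row.items()} for row in reader
    ]
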