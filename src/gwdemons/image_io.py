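"""Image and deformation-field I/O.

Images are plain 2-D ``float64`` numpy arrays with intensities normalized to
[0, 1].  The package-wide coordinate convention is (row, col), 0-based, origin
at the top-left; displacement component 0 is a row shift, component 1 a column
shift.

Normalization divides by the dtype maximum (255 for 8-bit input), not by the
per-image maximum, so intensity-based metrics are comparable across images.
Color photographs are reduced to grayscale with ITU-R 601 luminance weights
(0.299 R + 0.587 G + 0.114 B), the weighting fundus-imaging pipelines
conventionally use.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ShapeError
from .fields import DeformationField

__all__ = [
    "as_image",
    "load_image",
    "save_image",
    "save_field",
    "load_field",
    "LUMA_WEIGHTS",
]

# ITU-R 601 luma coefficients for R, G, B.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Maximum field size for which the CSV container is accepted.
_CSV_MAX_SIDE = 64


def as_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce ``arr`` to a normalized 2-D float image.

    Raises :class:`ShapeError` for non-2-D or degenerate (< 2 px per axis)
    input and :class:`FormatError` for non-finite values.
    """
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got ndim={a.ndim}")
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ShapeError(f"image must be at least 2x2, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise FormatError("image contains non-finite values")
    return a


def _to_gray(raw: np.ndarray) -> np.ndarray:
    if raw.ndim == 2:
        return raw.astype(np.float64)
    if raw.ndim == 3 and raw.shape[2] in (3, 4):
        return raw[..., :3].astype(np.float64) @ LUMA_WEIGHTS
    raise FormatError(f"unsupported image layout with shape {raw.shape}")


def load_image(path: str | os.PathLike, as_gray: bool = True) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as a normalized grayscale float array.

    Integer inputs are scaled by their dtype maximum so an 8-bit 255 maps to
    1.0; float inputs are assumed to already be on [0, 1] and are clipped.
    ``as_gray=False`` is rejected — the registration stack is grayscale-only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not as_gray:
        raise FormatError("only grayscale output is supported; pass as_gray=True")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise FormatError(f"could not decode image {path}: {exc}") from exc
    if raw.size == 0:
        raise FormatError(f"zero-area image: {path}")
    gray = _to_gray(np.asarray(raw))
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        scale = float(np.iinfo(np.asarray(raw).dtype).max)
        gray = gray / scale
    else:
        gray = np.clip(gray, 0.0, 1.0)
    return as_image(gray)


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG/TIFF/JPEG."""
    img = as_image(img)
    u8 = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), u8)


def save_field(field: DeformationField, path: str | os.PathLike) -> None:
    """Persist a deformation field.

    Two containers, selected by extension:

    ``.npz``
        numpy's portable zipped-array container holding the two float64
        planes; the round trip is bit-exact.
    ``.csv``
        plain text for fields up to 64x64: a header row ``rows,cols`` then one
        ``r,c,u_row,u_col`` line per pixel, full ``repr`` precision.
    """
    u_row, u_col = field.u_row, field.u_col
    if not (np.all(np.isfinite(u_row)) and np.all(np.isfinite(u_col))):
        raise FormatError("field contains non-finite values")
    path = Path(path)
    if path.suffix == ".csv":
        h, w = u_row.shape
        if h > _CSV_MAX_SIDE or w > _CSV_MAX_SIDE:
            raise FormatError(
                f"CSV container limited to {_CSV_MAX_SIDE}x{_CSV_MAX_SIDE}, got {u_row.shape}"
            )
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([h, w])
            for r in range(h):
                for c in range(w):
                    writer.writerow([r, c, repr(float(u_row[r, c])), repr(float(u_col[r, c]))])
    else:
        np.savez(path, u_row=u_row, u_col=u_col)


def load_field(path: str | os.PathLike) -> DeformationField:
    """Load a deformation field written by :func:`save_field`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        return _load_field_csv(path)
    try:
        with np.load(path) as data:
            u_row = data["u_row"]
            u_col = data["u_col"]
    except Exception as exc:
        raise FormatError(f"could not read field container {path}: {exc}") from exc
    if u_row.shape != u_col.shape:
        raise FormatError("field container components have mismatched shapes")
    return DeformationField(u_row, u_col)


def _load_field_csv(path: Path) -> DeformationField:
    try:
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        h, w = int(rows[0][0]), int(rows[0][1])
        u_row = np.empty((h, w))
        u_col = np.empty((h, w))
        seen = 0
        for rec in rows[1:]:
            r, c = int(rec[0]), int(rec[1])
            u_row[r, c] = float(rec[2])
            u_col[r, c] = float(rec[3])
            seen += 1
        if seen != h * w:
            raise ValueError(f"expected {h * w} records, got {seen}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"corrupt field CSV {path}: {exc}") from exc
    return DeformationField(u_row, u_col)
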