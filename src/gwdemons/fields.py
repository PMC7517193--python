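"""The dense displacement-field container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError

__all__ = ["DeformationField"]


@dataclass(frozen=True)
class DeformationField:
    """Per-pixel 2-component displacement vectors, in pixels.

    ``u_row[r, c]`` / ``u_col[r, c]`` give the row/column offset added to
    pixel (r, c) when sampling the moving image (backward warping:
    ``out(p) = F(p + u(p))``).  Both planes share the shape of the image
    they deform.
    """

    u_row: np.ndarray
    u_col: np.ndarray

    def __post_init__(self) -> None:
        u_row = np.asarray(self.u_row, dtype=np.float64)
        u_col = np.asarray(self.u_col, dtype=np.float64)
        if u_row.ndim != 2 or u_row.shape != u_col.shape:
            raise ShapeError(
                f"field components must be 2-D and same-shaped: {u_row.shape} vs {u_col.shape}"
            )
        object.__setattr__(self, "u_row", u_row)
        object.__setattr__(self, "u_col", u_col)

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_row.shape

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "DeformationField":
        return cls(np.zeros(shape), np.zeros(shape))

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.u_row)) and np.all(np.isfinite(self.u_col)))

    def max_abs(self) -> float:
        """Largest displacement component magnitude, in pixels."""
        if self.u_row.size == 0:
            return 0.0
        return float(max(np.abs(self.u_row).max(), np.abs(self.u_col).max()))

    def magnitude(self) -> np.ndarray:
        """Per-pixel Euclidean displacement length."""
        return np.hypot(self.u_row, self.u_col)

    def __add__(self, other: "DeformationField") -> "DeformationField":
        if self.shape != other.shape:
            raise ShapeError(f"cannot add fields of shapes {self.shape} and {other.shape}")
        return DeformationField(self.u_row + other.u_row, self.u_col + other.u_col)

    def allclose(self, other: "DeformationField", atol: float = 1e-12) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.u_row, other.u_row, atol=atol)
            and np.allclose(self.u_col, other.u_col, atol=atol)
        )
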