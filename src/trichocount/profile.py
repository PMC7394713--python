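"""Per-column curve profiles.

A :class:`CurveProfile` stores, for every image column, the row coordinate of
a curve (the leaf-surface line or one of its vertical translations).  Columns
where no information exists are NaN and are filled by linear interpolation on
demand.  Rows follow raster convention: row 0 is the top of the image, so the
leaf surface sits at large row values and "upward" means decreasing row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrichocountError

__all__ = ["CurveProfile"]


@dataclass(frozen=True)
class CurveProfile:
    """Row coordinate of a curve at each image column.

    Parameters
    ----------
    rows
        Length-W float array; ``rows[c]`` is the row of the curve at column
        ``c`` and NaN marks an undefined column.
    """

    rows: np.ndarray = field()

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 1 or rows.size == 0:
            raise TrichocountError("profile rows must be a non-empty 1-D array")
        if not np.isnan(rows).all() and np.nanmin(rows) < 0:
            raise TrichocountError("profile rows must be non-negative")
        object.__setattr__(self, "rows", rows)

    @property
    def width(self) -> int:
        return self.rows.size

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of columns where the curve is defined."""
        return ~np.isnan(self.rows)

    @property
    def defined_span(self) -> tuple[int, int]:
        """First and last defined column (inclusive)."""
        idx = np.flatnonzero(self.defined)
        if idx.size == 0:
            raise TrichocountError("profile has no defined columns")
        return int(idx[0]), int(idx[-1])

    def interpolated(self) -> np.ndarray:
        """Rows with gaps filled by linear interpolation.

        Interior gaps are interpolated between the nearest defined columns;
        columns beyond the defined span take the nearest defined value.
        """
        defined = self.defined
        if not defined.any():
            raise TrichocountError("cannot interpolate an empty profile")
        if defined.all():
            return self.rows.copy()
        cols = np.arange(self.width)
        return np.interp(cols, cols[defined], self.rows[defined])

    def translated(self, offset: float) -> "CurveProfile":
        """Profile moved vertically upward by ``round(offset)`` pixels.

        Rows are clipped at 0 so the curve never leaves the image; undefined
        columns stay undefined.  The curve's shape is otherwise preserved.
        """
        if offset <= 0:
            raise TrichocountError("translation offset must be positive")
        shifted = self.rows - round(offset)
        return CurveProfile(np.clip(shifted, 0.0, None))

    @classmethod
    def constant(cls, row: float, width: int) -> "CurveProfile":
        return cls(np.full(width, float(row)))
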