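"""Machine geometry: Millennium-120-style MLC and aS1200-style EPID.

All positions in this package are expressed in millimetres at the isocenter
plane on the Varian IEC X scale (X1 jaw on the negative side, X2 positive).
At SID = 100 cm the imager plane coincides with isocenter scale, so no
magnification handling is needed anywhere downstream.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator


class MachineModel(BaseModel):
    """Collimation and imaging geometry of the treatment machine.

    The MLC has 60 opposing leaf pairs per bank side; leaves 1-30 ("lower"
    leaves, Y < 0) and 31-60 ("upper" leaves, Y > 0).  The central 40 pairs
    project to 5 mm width at isocenter and the 10 outermost pairs on each
    side to 10 mm, spanning Y in [-200, +200] mm.  The EPID is a square
    flat-panel detector; column ``c`` maps to ``x = (c - (N-1)/2) * pitch``
    and row ``r`` to ``y = ((N-1)/2 - r) * pitch`` (Y2 up).
    """

    model_config = ConfigDict(frozen=True)

    mlc_leaf_count: int = 120
    lower_leaf_ids: tuple[int, int] = (1, 30)
    upper_leaf_ids: tuple[int, int] = (31, 60)
    central_leaf_width: float = 5.0
    outer_leaf_width: float = 10.0
    outer_leaves_per_side: int = 10
    epid_pixels: int = 1280
    epid_pitch: float = 0.336
    sid: float = 100.0
    y_jaw_half_field: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "MachineModel":
        lo0, lo1 = self.lower_leaf_ids
        up0, up1 = self.upper_leaf_ids
        n_pairs = self.mlc_leaf_count // 2
        if self.mlc_leaf_count % 2 != 0:
            raise ValueError("mlc_leaf_count must be even")
        if not (lo0 == 1 and lo1 + 1 == up0 and up1 == n_pairs):
            raise ValueError(
                "lower and upper leaf id ranges must be disjoint and cover "
                f"1..{n_pairs}"
            )
        if self.epid_pitch <= 0:
            raise ValueError("epid_pitch must be positive")
        if self.epid_pixels % 2 != 0:
            raise ValueError("epid_pixels must be even")
        if 2 * self.outer_leaves_per_side >= n_pairs:
            raise ValueError("too many outer leaves")
        return self

    # ------------------------------------------------------------------ MLC

    @property
    def n_leaf_pairs(self) -> int:
        return self.mlc_leaf_count // 2

    def leaf_edges(self) -> np.ndarray:
        """Y boundaries of the leaf pairs, ascending; shape (n_pairs + 1,).

        Leaf ``i`` (1-based, leaf 1 on the Y1 side) spans
        ``[edges[i-1], edges[i]]``.
        """
        n_out = self.outer_leaves_per_side
        n_central = self.n_leaf_pairs - 2 * n_out
        widths = np.concatenate(
            [
                np.full(n_out, self.outer_leaf_width),
                np.full(n_central, self.central_leaf_width),
                np.full(n_out, self.outer_leaf_width),
            ]
        )
        edges = np.concatenate([[0.0], np.cumsum(widths)])
        return edges - edges[-1] / 2.0

    def leaf_band(self, leaf_id: int) -> tuple[float, float]:
        """(y_low, y_high) of one leaf pair's projection, mm at isocenter."""
        if not 1 <= leaf_id <= self.n_leaf_pairs:
            raise ValueError(f"leaf_id {leaf_id} outside 1..{self.n_leaf_pairs}")
        edges = self.leaf_edges()
        return float(edges[leaf_id - 1]), float(edges[leaf_id])

    def central_leaf_ids(self) -> list[int]:
        """Ids of the thin central leaves (the ones PF analysis scores)."""
        n_out = self.outer_leaves_per_side
        return list(range(n_out + 1, self.n_leaf_pairs - n_out + 1))

    def is_upper_leaf(self, leaf_id: int) -> bool:
        up0, up1 = self.upper_leaf_ids
        return up0 <= leaf_id <= up1

    # ----------------------------------------------------------------- EPID

    def pixel_x(self) -> np.ndarray:
        """x coordinate (mm) of each detector column center."""
        n = self.epid_pixels
        return (np.arange(n) - (n - 1) / 2.0) * self.epid_pitch

    def pixel_y(self) -> np.ndarray:
        """y coordinate (mm) of each detector row center (row 0 at +Y)."""
        n = self.epid_pixels
        return ((n - 1) / 2.0 - np.arange(n)) * self.epid_pitch
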