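"""Bidirectional picket fence (BPF) plan geometry.

The BPF pattern is a picket-fence variant designed so that collimator jaw
edges remain visible on EPID cine frames during jaw tracking.  The upper
half of the MLC (leaves 31-60) sweeps a narrow slit from X2 toward X1 while
the lower half (leaves 1-30) sweeps in the opposite direction; at each of
the eight static stopping points ("segments") the X jaws are retracted a
fixed distance from the nearest leaf tips.  Because the two slits travel in
opposite directions, each jaw edge always sits in an MLC-transmission
region well separated from the nearest slit, so a faint but clean jaw
shadow edge is imaged in every segment.

With aperture width ``w``, retraction ``r`` and per-segment slit centers
``c_up`` / ``c_low``::

    x1 = min(c_low + w/2, c_up - w/2) - r
    x2 = max(c_up + w/2, c_low - w/2) + r

which reduces, for the half of the delivery where the jaw trails the upper
slit, to "5 mm behind the upper-slit near tip", and for the other half to
"5 mm beyond the lower-slit far tip".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .machine import MachineModel

GantryMode = Literal["static_0", "static_90", "static_270", "rotation"]
PlanKind = Literal["jaw_tracking", "static_jaw", "error_added"]

_GANTRY_STATIC = {"static_0": 0.0, "static_90": 90.0, "static_270": 270.0}


class PlanGeometryError(ValueError):
    """Raised when a plan would require crossed jaws or crossed leaves."""


class BPFConfig(BaseModel):
    """Delivery parameters of the BPF pattern.

    Defaults are the standard pattern: 2 mm aperture, slits stopping every
    20 mm from +/-70 mm, 5 mm jaw retraction, 120 MU at 600 MU/min, 6 MV.
    """

    model_config = ConfigDict(frozen=True)

    aperture_width: float = 2.0
    upper_centers: tuple[float, ...] = (70.0, 50.0, 30.0, 10.0, -10.0, -30.0, -50.0, -70.0)
    lower_centers: tuple[float, ...] = (-70.0, -50.0, -30.0, -10.0, 10.0, 30.0, 50.0, 70.0)
    retraction: float = 5.0
    total_mu: float = 120.0
    dose_rate: float = 600.0
    energy_label: str = "6 MV"
    gantry_mode: GantryMode = "static_0"

    @model_validator(mode="after")
    def _check(self) -> "BPFConfig":
        if len(self.upper_centers) != len(self.lower_centers):
            raise ValueError("upper_centers and lower_centers must have equal length")
        if len(self.upper_centers) == 0:
            raise ValueError("at least one segment is required")
        if self.aperture_width <= 0:
            raise ValueError("aperture_width must be positive")
        if self.retraction < 0:
            raise ValueError("retraction must be non-negative")
        if self.total_mu <= 0 or self.dose_rate <= 0:
            raise ValueError("total_mu and dose_rate must be positive")
        return self

    @property
    def n_segments(self) -> int:
        return len(self.upper_centers)


@dataclass
class Segment:
    """One static stopping point: slit geometry, jaw edges, meterset share.

    ``bank_a`` / ``bank_b`` hold the leaf-tip x coordinates of the X1-side
    and X2-side banks respectively (one value per leaf pair, mm at
    isocenter); the open slit of leaf pair ``i`` is ``[bank_a[i], bank_b[i]]``.
    """

    index: int
    upper_center: float
    lower_center: float
    x1: float
    x2: float
    bank_a: np.ndarray
    bank_b: np.ndarray
    mu_fraction: float
    gantry_deg: float = 0.0

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        if self.bank_a.shape != self.bank_b.shape or self.bank_a.ndim != 1:
            raise PlanGeometryError("leaf banks must be 1-D arrays of equal length")
        if not (np.isfinite(self.bank_a).all() and np.isfinite(self.bank_b).all()):
            raise PlanGeometryError("leaf positions must be finite")
        if np.any(self.bank_a > self.bank_b):
            bad = int(np.argmax(self.bank_a > self.bank_b)) + 1
            raise PlanGeometryError(
                f"segment {self.index}: leaf pair {bad} tips cross "
                f"({self.bank_a[bad - 1]:.2f} > {self.bank_b[bad - 1]:.2f})"
            )
        if not self.x1 < self.x2:
            raise PlanGeometryError(
                f"segment {self.index}: jaws cross (x1={self.x1:.2f} >= x2={self.x2:.2f})"
            )
        if not 0 < self.mu_fraction <= 1:
            raise PlanGeometryError("mu_fraction must lie in (0, 1]")

    @property
    def leaf_positions(self) -> np.ndarray:
        """Leaf tips as a (2, n_pairs) array: row 0 bank A, row 1 bank B."""
        return np.vstack([self.bank_a, self.bank_b])

    @property
    def slit_centers(self) -> np.ndarray:
        return (self.bank_a + self.bank_b) / 2.0


@dataclass(frozen=True)
class ErrorSpec:
    """Artificial positioning errors for validation plans.

    ``jaw_offsets`` maps 1-based segment index to ``(dx1, dx2)`` in mm;
    ``leaf_offsets`` maps leaf id to a shift applied to both tips of that
    leaf pair (i.e. the whole slit of that row moves).  Absent entries
    mean zero.
    """

    jaw_offsets: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    leaf_offsets: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seg, (d1, d2) in self.jaw_offsets.items():
            if not (math.isfinite(d1) and math.isfinite(d2)):
                raise ValueError(f"non-finite jaw offset for segment {seg}")
        for leaf, d in self.leaf_offsets.items():
            if not math.isfinite(d):
                raise ValueError(f"non-finite leaf offset for leaf {leaf}")

    @property
    def empty(self) -> bool:
        return not self.jaw_offsets and not self.leaf_offsets

    def negated(self) -> "ErrorSpec":
        return ErrorSpec(
            jaw_offsets={k: (-a, -b) for k, (a, b) in self.jaw_offsets.items()},
            leaf_offsets={k: -v for k, v in self.leaf_offsets.items()},
        )


@dataclass
class BPFPlan:
    """A complete BPF delivery: machine, pattern parameters and segments."""

    machine: MachineModel
    config: BPFConfig
    segments: list[Segment]
    plan_kind: PlanKind = "jaw_tracking"

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment(self, index: int) -> Segment:
        """Look up a segment by its 1-based index."""
        for seg in self.segments:
            if seg.index == index:
                return seg
        raise KeyError(f"no segment with index {index}")


# --------------------------------------------------------------------------
# construction


def jaw_positions(
    c_up: float, c_low: float, w: float, r: float
) -> tuple[float, float]:
    """Planned (x1, x2) jaw edges for one segment of the BPF pattern.

    The jaw edge is retracted ``r`` mm from the nearest leaf tip: X1 sits
    ``r`` mm on the negative side of whichever slit edge is leftmost-facing
    (the upper slit's near tip while the upper slit leads, the lower slit's
    near tip afterwards), and symmetrically for X2.
    """
    if w <= 0:
        raise ValueError("aperture width must be positive")
    if r < 0:
        raise ValueError("retraction must be non-negative")
    x1 = min(c_low + w / 2.0, c_up - w / 2.0) - r
    x2 = max(c_up + w / 2.0, c_low - w / 2.0) + r
    if x1 >= x2:
        raise PlanGeometryError(f"jaw rule yields crossed jaws: x1={x1:.2f}, x2={x2:.2f}")
    return x1, x2


def _gantry_angles(config: BPFConfig) -> list[float]:
    n = config.n_segments
    if config.gantry_mode == "rotation":
        # equally spaced stopping angles over a full arc
        return [360.0 * i / n for i in range(n)]
    angle = _GANTRY_STATIC[config.gantry_mode]
    return [angle] * n


def _slit_banks(
    machine: MachineModel, config: BPFConfig, c_up: float, c_low: float
) -> tuple[np.ndarray, np.ndarray]:
    n = machine.n_leaf_pairs
    half_w = config.aperture_width / 2.0
    centers = np.empty(n)
    for leaf in range(1, n + 1):
        centers[leaf - 1] = c_up if machine.is_upper_leaf(leaf) else c_low
    return centers - half_w, centers + half_w


def build_bpf_plan(
    machine: MachineModel | None = None, config: BPFConfig | None = None
) -> BPFPlan:
    """Build the jaw-tracking BPF plan: one segment per slit-center pair.

    Every upper leaf pair opens to the 2 mm slit at the segment's upper
    center and every lower pair at the lower center; jaws follow the
    retraction rule; MU is split evenly over segments.
    """
    machine = machine or MachineModel()
    config = config or BPFConfig()
    angles = _gantry_angles(config)
    mu_fraction = 1.0 / config.n_segments
    segments = []
    for i, (c_up, c_low) in enumerate(zip(config.upper_centers, config.lower_centers)):
        x1, x2 = jaw_positions(c_up, c_low, config.aperture_width, config.retraction)
        bank_a, bank_b = _slit_banks(machine, config, c_up, c_low)
        segments.append(
            Segment(
                index=i + 1,
                upper_center=c_up,
                lower_center=c_low,
                x1=x1,
                x2=x2,
                bank_a=bank_a,
                bank_b=bank_b,
                mu_fraction=mu_fraction,
                gantry_deg=angles[i],
            )
        )
    return BPFPlan(machine=machine, config=config, segments=segments, plan_kind="jaw_tracking")


def build_static_jaw_plan(
    machine: MachineModel | None = None,
    config: BPFConfig | None = None,
    x1_fixed: float = -90.0,
    x2_fixed: float = 90.0,
) -> BPFPlan:
    """Same MLC motion as the BPF plan with jaws parked at fixed positions.

    Raises :class:`PlanGeometryError` if the fixed jaws would shadow any
    part of any slit.
    """
    if not x1_fixed < x2_fixed:
        raise PlanGeometryError("x1_fixed must be smaller than x2_fixed")
    plan = build_bpf_plan(machine, config)
    for seg in plan.segments:
        lo = float(seg.bank_a.min())
        hi = float(seg.bank_b.max())
        if x1_fixed > lo or x2_fixed < hi:
            raise PlanGeometryError(
                f"fixed jaws ({x1_fixed:.2f}, {x2_fixed:.2f}) block the slit "
                f"[{lo:.2f}, {hi:.2f}] of segment {seg.index}"
            )
    segments = [replace(seg, x1=x1_fixed, x2=x2_fixed) for seg in plan.segments]
    return BPFPlan(
        machine=plan.machine, config=plan.config, segments=segments, plan_kind="static_jaw"
    )


def inject_errors(plan: BPFPlan, spec: ErrorSpec) -> BPFPlan:
    """Return a new plan with artificial jaw and leaf offsets applied.

    The input plan is not modified.  Jaw offsets are added to the planned
    jaw edges segment by segment; a leaf offset shifts both tips of that
    leaf pair in every segment.  Offsets that would make jaws or leaves
    cross raise :class:`PlanGeometryError`.
    """
    segments = []
    for seg in plan.segments:
        d1, d2 = spec.jaw_offsets.get(seg.index, (0.0, 0.0))
        bank_a = seg.bank_a.copy()
        bank_b = seg.bank_b.copy()
        for leaf, d in spec.leaf_offsets.items():
            if not 1 <= leaf <= plan.machine.n_leaf_pairs:
                raise ValueError(f"leaf id {leaf} outside the MLC")
            bank_a[leaf - 1] += d
            bank_b[leaf - 1] += d
        segments.append(
            replace(seg, x1=seg.x1 + d1, x2=seg.x2 + d2, bank_a=bank_a, bank_b=bank_b)
        )
    kind: PlanKind = plan.plan_kind if spec.empty else "error_added"
    return BPFPlan(machine=plan.machine, config=plan.config, segments=segments, plan_kind=kind)


# --------------------------------------------------------------------------
# expectations


def expected_positions(plan: BPFPlan) -> pd.DataFrame:
    """Per-segment reference table for detection: jaws and slit centers.

    Columns: ``segment, x1, x2, upper_center, lower_center``; the centers
    are the means of the actual per-leaf slit centers in each half, so an
    error-injected plan's expectations include its offsets.
    """
    machine = plan.machine
    upper = np.array([machine.is_upper_leaf(i + 1) for i in range(machine.n_leaf_pairs)])
    rows = []
    for seg in plan.segments:
        centers = seg.slit_centers
        rows.append(
            {
                "segment": seg.index,
                "x1": seg.x1,
                "x2": seg.x2,
                "upper_center": float(centers[upper].mean()),
                "lower_center": float(centers[~upper].mean()),
            }
        )
    return pd.DataFrame(rows)


def picket_centers(plan: BPFPlan) -> np.ndarray:
    """Distinct nominal picket x positions (union of the two center lists)."""
    cfg = plan.config
    return np.unique(np.asarray(cfg.upper_centers + cfg.lower_centers, dtype=float))
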