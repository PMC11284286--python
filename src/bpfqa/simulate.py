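"""Synthetic EPID cine frames for a BPF delivery.

The imaging model is deliberately minimal: every pixel carries the product
of an MLC attenuation factor (1 inside the open slit of that pixel's leaf
row, the MLC transmission fraction elsewhere) and a jaw attenuation factor
(1 inside the X/Y jaw field, the jaw transmission fraction outside -- the
jaws always sit behind closed leaves in the BPF pattern, so the two factors
multiply).  Edges are anti-aliased by exact fractional pixel coverage, the
finite source size / detector glare penumbra is a single Gaussian blur, and
frame-to-frame variation is additive white Gaussian noise clipped at zero.
Frames are rendered directly at isocenter scale.

Not modelled: scatter, beam profile (flatness/horns), tongue-and-groove,
rounded leaf ends, Poisson statistics, acquisition during leaf motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.ndimage import gaussian_filter

from .dicom_io import CineFrame, CineSeries
from .machine import MachineModel
from .plan import BPFPlan, Segment


class SimConfig(BaseModel):
    """Detector/imaging parameters of the simulator.

    ``t_mlc`` is the transmission through closed leaves relative to the
    open beam (about 1.5%); ``t_jaw`` the additional transmission through a
    jaw; ``blur_sigma_mm`` the Gaussian penumbra width; ``noise_rel`` the
    per-pixel noise sigma relative to the open-field signal;
    ``gantry_offset_mm`` a rigid shift of every collimator edge, usable to
    emulate a gantry-angle-dependent systematic offset.
    """

    model_config = ConfigDict(frozen=True)

    t_mlc: float = 0.015
    t_jaw: float = 0.005
    blur_sigma_mm: float = 0.7
    noise_rel: float = 0.01
    frames_per_segment: int = 5
    seed: int = 0
    gantry_offset_mm: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if not 0 < self.t_mlc < 1:
            raise ValueError("t_mlc must lie in (0, 1)")
        if not 0 <= self.t_jaw < 1:
            raise ValueError("t_jaw must lie in [0, 1)")
        if self.blur_sigma_mm < 0:
            raise ValueError("blur_sigma_mm must be non-negative")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be non-negative")
        if self.frames_per_segment < 1:
            raise ValueError("frames_per_segment must be at least 1")
        return self


@dataclass
class FluenceGrid:
    """Noise-free relative fluence in [0, 1] on the EPID pixel grid."""

    values: np.ndarray
    pitch_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("fluence must be 2-D")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("fluence values must lie in [0, 1]")


def _frac_inside(coords: np.ndarray, pitch: float, lo: float, hi: float) -> np.ndarray:
    """Fraction of each pixel (interval of width ``pitch``) inside [lo, hi]."""
    left = np.maximum(coords - pitch / 2.0, lo)
    right = np.minimum(coords + pitch / 2.0, hi)
    return np.clip((right - left) / pitch, 0.0, 1.0)


def segment_fluence(
    segment: Segment, machine: MachineModel, sim: SimConfig
) -> FluenceGrid:
    """Render the ideal (unblurred, noiseless) fluence of one segment."""
    if len(segment.bank_a) != machine.n_leaf_pairs:
        raise ValueError(
            f"segment has {len(segment.bank_a)} leaf pairs, machine expects "
            f"{machine.n_leaf_pairs}"
        )
    x = machine.pixel_x()
    y = machine.pixel_y()
    pitch = machine.epid_pitch
    off = sim.gantry_offset_mm

    # MLC attenuation row by row: open within the slit, t_mlc elsewhere.
    mlc = np.full((machine.epid_pixels, machine.epid_pixels), sim.t_mlc)
    edges = machine.leaf_edges()
    for leaf in range(1, machine.n_leaf_pairs + 1):
        y_lo, y_hi = edges[leaf - 1], edges[leaf]
        rows = np.nonzero((y >= y_lo) & (y < y_hi))[0]
        if rows.size == 0:
            continue
        slit = _frac_inside(
            x, pitch, segment.bank_a[leaf - 1] + off, segment.bank_b[leaf - 1] + off
        )
        mlc[rows, :] = slit + (1.0 - slit) * sim.t_mlc

    # jaw attenuation: inside the X-by-Y field -> 1, outside -> t_jaw;
    # the region outside the MLC-covered Y span is treated as jaw-covered.
    jaw_x = _frac_inside(x, pitch, segment.x1 + off, segment.x2 + off)
    y_half = machine.y_jaw_half_field
    jaw_y = _frac_inside(y, pitch, -y_half, y_half)
    inside = np.outer(jaw_y, jaw_x)
    jaw = sim.t_jaw + (1.0 - sim.t_jaw) * inside

    return FluenceGrid(values=mlc * jaw, pitch_mm=pitch)


def render_frames(
    fluence: FluenceGrid,
    sim: SimConfig,
    rng: np.random.Generator | None = None,
    n_frames: int | None = None,
) -> list[CineFrame]:
    """Blur a fluence map and emit noisy cine frames.

    Frames differ only by their independent noise realisations; the result
    is deterministic for a given generator state (``rng`` defaults to
    ``default_rng(sim.seed)``).
    """
    rng = rng if rng is not None else np.random.default_rng(sim.seed)
    n_frames = n_frames if n_frames is not None else sim.frames_per_segment
    sigma_px = sim.blur_sigma_mm / fluence.pitch_mm
    blurred = (
        gaussian_filter(fluence.values, sigma_px) if sigma_px > 0 else fluence.values
    )
    frames = []
    for i in range(n_frames):
        pixels = blurred
        if sim.noise_rel > 0:
            pixels = blurred + rng.normal(0.0, sim.noise_rel, size=blurred.shape)
        pixels = np.clip(pixels, 0.0, None).astype(np.float32)
        frames.append(CineFrame(pixels=pixels, pitch_mm=fluence.pitch_mm, frame_index=i))
    return frames


def simulate_delivery(plan: BPFPlan, sim: SimConfig) -> CineSeries:
    """Simulate a full BPF delivery: all segments, in order, labelled.

    Reproducible for a given ``sim.seed``: a single generator is threaded
    through the segments.
    """
    rng = np.random.default_rng(sim.seed)
    frames: list[CineFrame] = []
    for seg in plan.segments:
        fluence = segment_fluence(seg, plan.machine, sim)
        for frame in render_frames(fluence, sim, rng=rng):
            frames.append(
                CineFrame(
                    pixels=frame.pixels,
                    pitch_mm=frame.pitch_mm,
                    frame_index=len(frames),
                    segment_label=seg.index,
                    gantry_deg=seg.gantry_deg,
                )
            )
    return CineSeries(frames=frames, machine=plan.machine)
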