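"""Jaw-edge detection on EPID cine frames.

The workflow per frame mirrors the classic field-edge recipe: contrast
enhancement by global histogram equalisation, Otsu binarisation into
radiation-detected vs radiation-blocked areas, morphological cleaning
(closing), Canny edge extraction, a vertical sum of the edge image into a
one-dimensional horizontal profile, and sub-pixel peak localisation.  The
profile of a BPF segment shows the two jaw edges (full-height peaks,
because a jaw edge crosses the whole field) and the two MLC aperture
clusters (half-height, because each slit spans only one half of the field).

Because the jaw shadow lives entirely in the MLC-transmission region, its
contrast against the transmitted background is tiny (about 1% of the open
beam).  Three measures keep the pipeline well conditioned at that contrast:

* each frame is lightly Gaussian-denoised before the pipeline, so the two
  intensity classes that Otsu must separate do not overlap;
* the aperture columns (found from the raw frame as columns brighter than
  a fraction of the maximum) are masked out by horizontal interpolation
  before equalisation, and equalisation + Otsu run on a band centred on
  each expected jaw edge -- inside the band the two classes are balanced,
  which removes the threshold bias that a whole-frame histogram would
  inherit from the very unequal jaw/field areas;
* the coarse, pixel-quantised peak from the binary pipeline is refined to
  sub-pixel precision by the 50%-level crossing of the row-averaged
  intensity ramp (the standard half-maximum field-edge convention), which
  is unbiased under symmetric penumbra blur.

Peak-to-role assignment is expectation-guided: each expected jaw edge is
matched to the nearest detected peak within a capture window, with the
full-height/half-height distinction as a secondary check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from scipy.signal import find_peaks
from skimage import exposure, feature

from .dicom_io import CineFrame, CineSeries
from .machine import MachineModel
from .plan import BPFPlan, expected_positions

log = logging.getLogger(__name__)


class DetectionError(RuntimeError):
    """Raised when a jaw edge cannot be located on a frame or segment."""


class DetectParams(BaseModel):
    """Tunable parameters of the detection pipeline (mm unless noted)."""

    model_config = ConfigDict(frozen=True)

    denoise_sigma_px: float = 1.5
    band_mm: float = 10.0
    capture_mm: float = 3.0
    min_separation_mm: float = 3.0
    y_margin_mm: float = 3.0
    se_radius_px: int = 1
    aperture_threshold: float = 0.3
    aperture_pad_mm: float = 1.3
    level_clearance_mm: float = 4.0
    refine: bool = True


# --------------------------------------------------------------------------
# elementary operations


@dataclass
class EdgeProfile:
    """A 1-D horizontal profile of column sums with its x coordinates."""

    values: np.ndarray
    x_mm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        if self.values.shape != self.x_mm.shape or self.values.ndim != 1:
            raise ValueError("profile values and coordinates must be matching 1-D arrays")

    @property
    def pitch_mm(self) -> float:
        return float(self.x_mm[1] - self.x_mm[0]) if self.x_mm.size > 1 else 1.0


@dataclass
class PeakSet:
    """Detected profile peaks with their assigned roles.

    Roles are ``x1_jaw``, ``x2_jaw``, ``aperture_edge`` or ``unassigned``;
    each jaw role appears at most once and positions are strictly
    increasing.
    """

    positions: np.ndarray
    heights: np.ndarray
    roles: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if not (len(self.positions) == len(self.heights) == len(self.roles)):
            raise ValueError("positions, heights and roles must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("peak positions must be strictly increasing")
        for role in ("x1_jaw", "x2_jaw"):
            if self.roles.count(role) > 1:
                raise ValueError(f"role {role} assigned more than once")

    def position(self, role: str) -> float:
        return float(self.positions[self.roles.index(role)])


def equalize(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Global histogram equalisation onto [0, 1].

    The mapping is the (monotone) empirical CDF over ``nbins`` bins of the
    min-max normalised input, so the rank order of distinct input levels is
    preserved.  A constant image cannot be equalised; it is returned
    unchanged with a logged warning.
    """
    img = np.asarray(image, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("image must be finite")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        log.warning("equalize: constant image, returned unchanged")
        return img.copy()
    return exposure.equalize_hist((img - lo) / (hi - lo), nbins=nbins)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximise between-class variance over a histogram.

    Returns the center of the highest bin of the lower class, as is
    conventional; pixels strictly above the threshold form the upper
    (radiation-detected) class.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise ValueError("Otsu threshold undefined for a constant image")
    counts, edges = np.histogram(img, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    # Maximise sigma_b^2(k) = (m0*w1 - (M - m0)*w0)^2 / (w0*w1) over splits k,
    # using bin indices as values (an affine rescaling of the bin centers,
    # which leaves the argmax unchanged) and exact integer arithmetic so that
    # plateau ties are broken deterministically at the first maximising split.
    total_w = int(counts.sum())
    total_m = int((counts * np.arange(nbins)).sum())
    w0 = 0
    m0 = 0
    best_k = 0
    best: tuple[int, int] | None = None  # variance as a fraction (num, den)
    for k in range(nbins - 1):
        w0 += int(counts[k])
        m0 += int(counts[k]) * k
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        a = m0 * w1 - (total_m - m0) * w0
        num, den = a * a, w0 * w1
        if best is None or num * best[1] > best[0] * den:
            best = (num, den)
            best_k = k
    return float(centers[best_k])


def otsu_binarize(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Binarise into radiation-detected (True) vs blocked (False)."""
    return np.asarray(image, dtype=float) > otsu_threshold(image, nbins=nbins)


def morph_clean(mask: np.ndarray, se_radius_px: int = 1) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a square element.

    Fills holes smaller than the element; idempotent on already-clean
    masks.  The mask is edge-padded first so regions touching the image
    border are not eroded away.
    """
    mask = np.asarray(mask, dtype=bool)
    if se_radius_px <= 0:
        return mask.copy()
    r = int(se_radius_px)
    se = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    padded = np.pad(mask, r, mode="edge")
    closed = binary_erosion(binary_dilation(padded, structure=se), structure=se)
    return closed[r:-r, r:-r]


def edge_map(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide boundary of a binary mask (Canny, sigma = 1 px)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or not mask.any():
        return np.zeros_like(mask)
    return feature.canny(mask.astype(float), sigma=1.0)


def vertical_profile(
    edges: np.ndarray,
    x_mm: np.ndarray | None = None,
    pitch_mm: float | None = None,
) -> EdgeProfile:
    """Sum a binary edge image over rows into a horizontal profile.

    The profile total equals the edge-pixel count.  ``x_mm`` gives the
    column coordinates; if omitted they are derived from ``pitch_mm`` with
    the centered convention ``x = (c - (N-1)/2) * pitch``.
    """
    edges = np.asarray(edges)
    values = edges.sum(axis=0).astype(float)
    n = values.size
    if x_mm is None:
        if pitch_mm is None:
            raise ValueError("either x_mm or pitch_mm is required")
        x_mm = (np.arange(n) - (n - 1) / 2.0) * pitch_mm
    return EdgeProfile(values=values, x_mm=np.asarray(x_mm, dtype=float))


def locate_peaks(
    profile: EdgeProfile, min_separation_mm: float = 3.0
) -> list[tuple[float, float]]:
    """Local profile maxima with 3-point parabolic sub-pixel refinement.

    Peaks closer than ``min_separation_mm`` are suppressed (the higher
    wins).  Returns ``(position_mm, height)`` pairs sorted by position;
    empty for an all-zero profile.
    """
    v = profile.values
    if not np.any(v > 0):
        return []
    pitch = profile.pitch_mm
    distance = max(1, int(round(min_separation_mm / pitch)))
    idx, props = find_peaks(v, distance=distance, height=0.0)
    peaks = []
    for i in idx:
        dx = 0.0
        if 0 < i < v.size - 1:
            denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
            if denom < 0:
                dx = 0.5 * (v[i - 1] - v[i + 1]) / denom
                dx = float(np.clip(dx, -0.5, 0.5))
        peaks.append((float(profile.x_mm[i] + dx * pitch), float(v[i])))
    peaks.sort(key=lambda p: p[0])
    return peaks


def classify_peaks(
    peaks: list[tuple[float, float]],
    expected: dict,
    capture_mm: float = 3.0,
    image_height: float | None = None,
) -> PeakSet:
    """Assign roles to profile peaks, guided by the expected positions.

    ``expected`` carries ``x1``, ``x2`` and optionally ``slit_centers``.
    Each expected jaw edge must have a peak within ``capture_mm``;
    full-height peaks (height in [0.6, 1.05] x ``image_height``) are
    preferred for jaw roles when ``image_height`` is given.  Slit centers
    are matched to the nearest remaining peak within the capture window.
    """
    remaining = list(enumerate(peaks))
    roles: dict[int, str] = {}

    def take(target: float, role: str, require: bool, full_height: bool) -> None:
        cands = [(i, p) for i, p in remaining if abs(p[0] - target) <= capture_mm]
        if full_height and image_height:
            tall = [
                (i, p)
                for i, p in cands
                if 0.6 * image_height <= p[1] <= 1.05 * image_height
            ]
            if tall:
                cands = tall
        if not cands:
            if require:
                raise DetectionError(
                    f"no profile peak within {capture_mm:.1f} mm of the expected "
                    f"{role} position {target:.2f} mm"
                )
            return
        i, _ = min(cands, key=lambda c: abs(c[1][0] - target))
        roles[i] = role
        remaining[:] = [(j, p) for j, p in remaining if j != i]

    take(float(expected["x1"]), "x1_jaw", require=True, full_height=True)
    take(float(expected["x2"]), "x2_jaw", require=True, full_height=True)
    for center in expected.get("slit_centers", ()):
        take(float(center), "aperture_edge", require=False, full_height=False)

    order = np.argsort([p[0] for p in peaks])
    return PeakSet(
        positions=np.asarray([peaks[i][0] for i in order]),
        heights=np.asarray([peaks[i][1] for i in order]),
        roles=[roles.get(int(i), "unassigned") for i in order],
    )


def pipeline_edges(
    image: np.ndarray,
    x_mm: np.ndarray,
    min_separation_mm: float = 3.0,
    se_radius_px: int = 1,
) -> list[tuple[float, float]]:
    """Run the full binary edge pipeline on an image and return its peaks.

    equalize -> Otsu -> morphological closing -> Canny -> vertical sum ->
    sub-pixel peak location.
    """
    eq = equalize(image)
    mask = otsu_binarize(eq)
    mask = morph_clean(mask, se_radius_px)
    edges = edge_map(mask)
    profile = vertical_profile(edges, x_mm=x_mm)
    return locate_peaks(profile, min_separation_mm)


# --------------------------------------------------------------------------
# frame-level detection


def _interpolate_columns(image: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace flagged columns by per-row linear interpolation."""
    if not bad.any():
        return image
    good_idx = np.nonzero(~bad)[0]
    if good_idx.size < 2:
        raise DetectionError("too few clean columns to interpolate the aperture away")
    bad_idx = np.nonzero(bad)[0]
    pos = np.searchsorted(good_idx, bad_idx)
    right = good_idx[np.clip(pos, 0, good_idx.size - 1)]
    left = good_idx[np.clip(pos - 1, 0, good_idx.size - 1)]
    span = (right - left).astype(float)
    w = np.where(span > 0, (bad_idx - left) / np.where(span > 0, span, 1.0), 0.0)
    out = image.copy()
    out[:, bad_idx] = image[:, left] * (1.0 - w) + image[:, right] * w
    return out


@dataclass
class _Prepared:
    masked: np.ndarray  # denoised, aperture columns interpolated away
    raw: np.ndarray  # denoised only
    x: np.ndarray
    aperture_cols: np.ndarray
    y: np.ndarray  # y of the retained rows


def _prepare(frame: CineFrame, machine: MachineModel, params: DetectParams) -> _Prepared:
    img = frame.pixels.astype(np.float64)
    if params.denoise_sigma_px > 0:
        img = gaussian_filter(img, params.denoise_sigma_px)
    y = machine.pixel_y()
    keep = np.abs(y) <= machine.y_jaw_half_field - params.y_margin_mm
    sub = img[keep]
    x = machine.pixel_x()
    colmax = sub.max(axis=0)
    vmax = float(colmax.max())
    if vmax <= 0 or vmax < 5.0 * float(np.median(colmax)):
        raise DetectionError("degenerate frame: no aperture signal")
    core = colmax > params.aperture_threshold * vmax
    pad_px = max(1, int(math.ceil(params.aperture_pad_mm / machine.epid_pitch)))
    aperture = binary_dilation(core, structure=np.ones(3, bool), iterations=pad_px)
    masked = _interpolate_columns(sub, aperture)
    return _Prepared(masked=masked, raw=sub, x=x, aperture_cols=aperture, y=y[keep])


def _slit_center(
    prepared: _Prepared, expected_center: float, upper: bool, window_mm: float = 5.0
) -> float | None:
    """Half-maximum center of one slit from the raw (unmasked) half-image."""
    rows = prepared.y > 2.0 if upper else prepared.y < -2.0
    profile = prepared.raw[rows].mean(axis=0)
    sel = np.abs(prepared.x - expected_center) <= window_mm
    if not sel.any():
        return None
    p = profile[sel]
    xs = prepared.x[sel]
    base = float(np.median(profile))
    peak = float(p.max())
    if peak <= base:
        return None
    half = base + 0.5 * (peak - base)
    above = p >= half
    if not above.any():
        return None
    i0, i1 = np.nonzero(above)[0][[0, -1]]

    def cross(i_out: int, i_in: int) -> float:
        if i_out < 0 or i_out >= p.size or p[i_in] == p[i_out]:
            return float(xs[i_in])
        t = (half - p[i_out]) / (p[i_in] - p[i_out])
        return float(xs[i_out] + t * (xs[i_in] - xs[i_out]))

    left = cross(i0 - 1, i0)
    right = cross(i1 + 1, i1)
    return 0.5 * (left + right)


def _transmission_columns(prepared: _Prepared, expected: dict, params: DetectParams) -> np.ndarray:
    """Clean in-field MLC-transmission columns (away from jaws and slits)."""
    x = prepared.x
    clear = params.level_clearance_mm
    sel = (x > expected["x1"] + clear) & (x < expected["x2"] - clear)
    sel &= ~prepared.aperture_cols
    for c in expected.get("slit_centers", ()):
        sel &= np.abs(x - c) > clear
    if not sel.any():
        raise DetectionError("no clean transmission region to estimate levels from")
    return sel


def _refine_profile(prepared: _Prepared, expected: dict, jaw_pos: float) -> np.ndarray:
    """Row-averaged ramp profile for refining one jaw edge.

    The bidirectional pattern guarantees that one of the two slits is far
    from each jaw; averaging only the half-field whose slit is farther
    keeps the near slit's penumbra tail out of the jaw-edge profile (which
    matters when an inward jaw error narrows the jaw-to-slit gap) and lets
    the raw, un-interpolated image be used there.  Without slit
    expectations the aperture-masked full image is the fallback.
    """
    y = prepared.y
    upper = expected.get("upper_center")
    lower = expected.get("lower_center")
    if upper is None or lower is None:
        return prepared.masked.mean(axis=0)
    if abs(float(upper) - jaw_pos) >= abs(float(lower) - jaw_pos):
        rows = y > 2.0
    else:
        rows = y < -2.0
    return prepared.raw[rows].mean(axis=0)


def _refine_edge(
    prepared: _Prepared,
    coarse: float,
    rising: bool,
    p: np.ndarray,
    trans_cols: np.ndarray,
    params: DetectParams,
) -> float:
    """Sub-pixel jaw edge: 50%-level crossing of the row-averaged ramp."""
    hi_level = float(np.median(p[trans_cols]))
    x = prepared.x
    out_sel = (
        (x >= coarse - 8.0) & (x <= coarse - 3.0)
        if rising
        else (x >= coarse + 3.0) & (x <= coarse + 8.0)
    )
    if not out_sel.any():
        return coarse
    lo_level = float(np.median(p[out_sel]))
    mid = 0.5 * (lo_level + hi_level)
    search = np.abs(x - coarse) <= params.capture_mm + 0.5
    idx = np.nonzero(search)[0]
    best = None
    for i in idx[:-1]:
        a, b = p[i], p[i + 1]
        if rising and not (a <= mid < b):
            continue
        if not rising and not (a > mid >= b):
            continue
        t = (mid - a) / (b - a) if b != a else 0.5
        xc = float(x[i] + t * (x[i + 1] - x[i]))
        if best is None or abs(xc - coarse) < abs(best - coarse):
            best = xc
    if best is None:
        log.warning("refinement found no %s crossing near %.2f mm", "rising" if rising else "falling", coarse)
        return coarse
    return best


def _jaw_coarse(
    prepared: _Prepared, expected_pos: float, role: str, params: DetectParams
) -> float:
    band = np.abs(prepared.x - expected_pos) <= params.band_mm
    band_img = prepared.masked[:, band]
    try:
        peaks = pipeline_edges(
            band_img,
            prepared.x[band],
            min_separation_mm=params.min_separation_mm,
            se_radius_px=params.se_radius_px,
        )
    except ValueError as exc:
        raise DetectionError(
            f"no usable contrast near the expected {role} position "
            f"{expected_pos:.2f} mm: {exc}"
        ) from exc
    n_rows = band_img.shape[0]
    cands = [p for p in peaks if abs(p[0] - expected_pos) <= params.capture_mm]
    if not cands:
        raise DetectionError(
            f"no edge peak within {params.capture_mm:.1f} mm of the expected "
            f"{role} position {expected_pos:.2f} mm"
        )
    tall = [p for p in cands if 0.6 * n_rows <= p[1] <= 1.05 * n_rows]
    pool = tall if tall else cands
    return min(pool, key=lambda p: abs(p[0] - expected_pos))[0]


@dataclass
class FrameDetection:
    """Detected jaw positions and the classified peak set of one frame."""

    x1: float
    x2: float
    peaks: PeakSet


def detect_frame(
    frame: CineFrame,
    expected: dict,
    machine: MachineModel,
    params: DetectParams | None = None,
) -> FrameDetection:
    """Locate both jaw edges on a single cine frame.

    ``expected`` must provide ``x1`` and ``x2`` (planned jaw edges) and may
    provide ``upper_center`` / ``lower_center`` for the aperture peaks.
    """
    params = params or DetectParams()
    prepared = _prepare(frame, machine, params)
    slit_centers = []
    slits = {}
    for key, upper in (("upper_center", True), ("lower_center", False)):
        if key in expected and expected[key] is not None:
            c = _slit_center(prepared, float(expected[key]), upper)
            if c is not None:
                slits[key] = c
                slit_centers.append(float(expected[key]))
    exp = {
        "x1": float(expected["x1"]),
        "x2": float(expected["x2"]),
        "slit_centers": slit_centers,
    }
    trans_cols = _transmission_columns(prepared, exp, params)
    positions = {}
    for role, rising in (("x1", True), ("x2", False)):
        coarse = _jaw_coarse(prepared, exp[role], role, params)
        if params.refine:
            profile = _refine_profile(prepared, expected, exp[role])
            positions[role] = _refine_edge(
                prepared, coarse, rising, profile, trans_cols, params
            )
        else:
            positions[role] = coarse
    n_rows = prepared.masked.shape[0]
    entries = [
        (positions["x1"], float(n_rows), "x1_jaw"),
        (positions["x2"], float(n_rows), "x2_jaw"),
    ]
    for key in slits:
        entries.append((slits[key], 0.5 * n_rows, "aperture_edge"))
    entries.sort(key=lambda e: e[0])
    peaks = PeakSet(
        positions=np.array([e[0] for e in entries]),
        heights=np.array([e[1] for e in entries]),
        roles=[e[2] for e in entries],
    )
    return FrameDetection(x1=positions["x1"], x2=positions["x2"], peaks=peaks)


# --------------------------------------------------------------------------
# segment- and plan-level detection


@dataclass
class SegmentDetection:
    """Per-segment jaw statistics over frames (mean, SD, planned - detected)."""

    segment: int
    planned_x1: float
    planned_x2: float
    x1_mean: float
    x1_sd: float
    x2_mean: float
    x2_sd: float
    n_frames: int
    x1_frames: list[float] = field(default_factory=list)
    x2_frames: list[float] = field(default_factory=list)

    @property
    def x1_diff(self) -> float:
        return self.planned_x1 - self.x1_mean

    @property
    def x2_diff(self) -> float:
        return self.planned_x2 - self.x2_mean


def detect_segment(
    frames: list[CineFrame],
    expected: dict,
    machine: MachineModel,
    params: DetectParams | None = None,
) -> SegmentDetection:
    """Run the detection pipeline on every frame of one segment.

    Degenerate (beam-off or constant) frames are discarded with a warning;
    at least one usable frame is required.
    """
    params = params or DetectParams()
    x1s, x2s = [], []
    for frame in frames:
        try:
            det = detect_frame(frame, expected, machine, params)
        except DetectionError as exc:
            if "degenerate" in str(exc):
                log.warning("frame %d discarded: %s", frame.frame_index, exc)
                continue
            raise DetectionError(f"frame {frame.frame_index}: {exc}") from exc
        x1s.append(det.x1)
        x2s.append(det.x2)
    if not x1s:
        raise DetectionError(
            f"segment {expected.get('segment', '?')}: no usable frames"
        )
    return SegmentDetection(
        segment=int(expected.get("segment", 0)),
        planned_x1=float(expected["x1"]),
        planned_x2=float(expected["x2"]),
        x1_mean=float(np.mean(x1s)),
        x1_sd=float(np.std(x1s)),
        x2_mean=float(np.mean(x2s)),
        x2_sd=float(np.std(x2s)),
        n_frames=len(x1s),
        x1_frames=x1s,
        x2_frames=x2s,
    )


@dataclass
class JawDetectionResult:
    """Plan-level detection result.

    ``table`` holds one row per (segment, jaw) with planned, detected
    mean, SD and diff = planned - detected; ``summary`` the mean and SD of
    |diff| per jaw over segments.
    """

    table: pd.DataFrame
    summary: pd.DataFrame

    def to_wide(self) -> pd.DataFrame:
        """Pivot to the conventional report layout: one row per segment."""
        wide = self.table.pivot(index="segment", columns="jaw")
        wide.columns = [f"{jaw}_{col}" for col, jaw in wide.columns]
        order = [
            f"{jaw}_{col}"
            for jaw in ("X1", "X2")
            for col in ("planned", "detected", "sd", "diff")
        ]
        return wide[order].reset_index()

    @property
    def mean_abs_diff(self) -> float:
        return float(self.table["diff"].abs().mean())


def assign_frames(
    series: CineSeries, plan: BPFPlan, params: DetectParams | None = None
) -> CineSeries:
    """Label each frame with the segment whose slit centers it best matches.

    Frames whose best-match residual exceeds 1 mm are discarded as
    transition frames; a segment left without frames raises
    :class:`DetectionError` naming it.
    """
    machine = plan.machine
    expected = expected_positions(plan)
    centers = expected[["segment", "upper_center", "lower_center"]].to_numpy()
    if len({(round(u, 3), round(l, 3)) for _, u, l in centers}) < len(centers):
        raise DetectionError("segments do not have distinct slit centers")
    y = machine.pixel_y()
    y_half = machine.y_jaw_half_field
    upper_rows = (y > 2.0) & (y < y_half - 3.0)
    lower_rows = (y < -2.0) & (y > -(y_half - 3.0))
    x = machine.pixel_x()

    def half_center(img: np.ndarray, rows: np.ndarray) -> float | None:
        p = img[rows].mean(axis=0)
        vmax = float(p.max())
        if vmax <= 0 or vmax < 5.0 * float(np.median(p)):
            return None
        w = np.where(p > 0.5 * vmax, p, 0.0)
        return float((w * x).sum() / w.sum())

    labeled = []
    for frame in series.frames:
        img = gaussian_filter(frame.pixels.astype(np.float64), 1.0)
        c_up = half_center(img, upper_rows)
        c_low = half_center(img, lower_rows)
        if c_up is None or c_low is None:
            log.warning("frame %d discarded: no aperture signal", frame.frame_index)
            continue
        residuals = np.maximum(
            np.abs(centers[:, 1] - c_up), np.abs(centers[:, 2] - c_low)
        )
        best = int(np.argmin(residuals))
        if residuals[best] > 1.0:
            log.warning(
                "frame %d discarded as transition (residual %.2f mm)",
                frame.frame_index,
                residuals[best],
            )
            continue
        labeled.append(
            CineFrame(
                pixels=frame.pixels,
                pitch_mm=frame.pitch_mm,
                frame_index=frame.frame_index,
                segment_label=int(centers[best, 0]),
                gantry_deg=frame.gantry_deg,
            )
        )
    got = {f.segment_label for f in labeled}
    for seg in expected["segment"]:
        if int(seg) not in got:
            raise DetectionError(f"segment {int(seg)} received no frames")
    return CineSeries(frames=labeled, machine=series.machine)


def detect_plan(
    series: CineSeries, plan: BPFPlan, params: DetectParams | None = None
) -> JawDetectionResult:
    """Detect jaw positions for every segment of a plan.

    Frames without segment labels are first assigned by slit matching.
    Returns the per-segment table and the per-jaw summary of |planned -
    detected|.
    """
    params = params or DetectParams()
    if any(f.segment_label is None for f in series.frames):
        series = assign_frames(series, plan, params)
    expected = expected_positions(plan)
    rows = []
    errors = []
    for _, exp in expected.iterrows():
        frames = [f for f in series.frames if f.segment_label == int(exp["segment"])]
        if not frames:
            errors.append(f"segment {int(exp['segment'])} received no frames")
            continue
        try:
            det = detect_segment(frames, exp.to_dict(), plan.machine, params)
        except DetectionError as exc:
            errors.append(str(exc))
            continue
        rows.append((det.segment, "X1", det.planned_x1, det.x1_mean, det.x1_sd, det.x1_diff))
        rows.append((det.segment, "X2", det.planned_x2, det.x2_mean, det.x2_sd, det.x2_diff))
    if errors:
        raise DetectionError("; ".join(errors))
    table = pd.DataFrame(
        rows, columns=["segment", "jaw", "planned", "detected", "sd", "diff"]
    )
    summary = (
        table.assign(abs_diff=table["diff"].abs())
        .groupby("jaw")["abs_diff"]
        .agg(["mean", "std"])
        .rename(columns={"mean": "mean_abs_diff", "std": "sd_abs_diff"})
        .reset_index()
    )
    return JawDetectionResult(table=table, summary=summary)
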