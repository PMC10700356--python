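"""Spatial distribution of fluorescent proteins along and around migrating cells.

Implements the polarity readouts used on migrating T cells: direction-aligned
mean-intensity projections, 12-bin intensity profiles along the cell length
(leading edge first), LE/TE anchoring from CDC42/CD44 peak positions,
perimeter polarization (fraction of total perimeter fluorescence in the 25% of
the perimeter centred on the maximum), and the MPAct/CaaX membrane-proximal
actin ratio with its front-3-over-back-3 polarity scalar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure, transform

__all__ = [
    "BinnedProfile",
    "PerimeterProfile",
    "PerimeterPolarization",
    "align_and_project",
    "length_profile",
    "normalize01",
    "anchor_le_te",
    "perimeter_polarization",
    "mpact_polarity",
    "sample_perimeter",
    "profile_ci_band",
]


@dataclass
class BinnedProfile:
    """12-bin intensity (or ratio) profile along the migration axis.

    ``values[0]`` is the leading-edge bin when ``oriented_le_first``.
    ``normalization`` is one of ``raw``, ``unit01`` (min-max) or ``unit_max``
    (divide-by-max).  ``degenerate`` flags a constant input profile that could
    not be normalized.
    """

    values: np.ndarray
    oriented_le_first: bool = True
    normalization: str = "raw"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise ValueError("a binned profile has exactly 12 bins")

    def reversed(self) -> "BinnedProfile":
        return replace(self, values=self.values[::-1].copy())


@dataclass
class PerimeterProfile:
    """Arc-length-ordered intensity samples along a closed cell contour."""

    intensities: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 8:
            raise ValueError("perimeter profile needs >= 8 ordered samples")
        if not self.closed:
            raise ValueError("perimeter profile must be a closed contour")


@dataclass
class PerimeterPolarization:
    ratio: float
    window_size: int
    argmax: int


def align_and_project(cell_crops: list[np.ndarray],
                      directions: list[float],
                      roi_um: float | tuple[float, float],
                      pixel_size_um: float) -> np.ndarray:
    """Rotate each crop so migration points to +x, then pixel-wise mean.

    ``roi_um`` is the box captured around each cell, either a length (with
    height = half the length, emulating the fixed-length region of interest
    drawn along the cell) or an explicit ``(length, height)`` pair such as the
    14.4 x 7.5 µm box used for nuclear-excluded reporters.  Crops smaller than
    the box are zero-padded, larger ones centre-cropped.
    """
    if len(cell_crops) == 0:
        raise ValueError("need at least one cell crop")
    if len(cell_crops) != len(directions):
        raise ValueError("one direction per crop required")
    if isinstance(roi_um, (int, float)):
        roi_um = (float(roi_um), float(roi_um) / 2.0)
    box_w = max(2, int(round(roi_um[0] / pixel_size_um)))
    box_h = max(2, int(round(roi_um[1] / pixel_size_um)))

    acc = np.zeros((box_h, box_w), dtype=float)
    for crop, direction in zip(cell_crops, directions):
        rotated = transform.rotate(np.asarray(crop, dtype=float),
                                   math.degrees(direction),
                                   resize=True, order=1, preserve_range=True)
        acc += _center_box(rotated, box_h, box_w)
    return acc / len(cell_crops)


def _center_box(image: np.ndarray, h: int, w: int) -> np.ndarray:
    """Centre-crop/pad ``image`` to (h, w)."""
    out = np.zeros((h, w), dtype=float)
    ih, iw = image.shape
    sy, sx = max(0, (ih - h) // 2), max(0, (iw - w) // 2)
    dy, dx = max(0, (h - ih) // 2), max(0, (w - iw) // 2)
    cy, cx = min(h, ih), min(w, iw)
    out[dy:dy + cy, dx:dx + cx] = image[sy:sy + cy, sx:sx + cx]
    return out


def length_profile(image: np.ndarray, mask: np.ndarray, direction: float,
                   n_bins: int = 12) -> BinnedProfile:
    """Mean intensity in equal-length bins along the cell's migration axis.

    The axial coordinate of each mask pixel is its projection onto the
    migration-direction unit vector through the mask centroid; the cell length
    (axial extent of the mask) is split into ``n_bins`` equal bins spanning the
    full cell width, ordered leading edge first.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    ys, xs = np.nonzero(mask)
    t = (xs - xs.mean()) * math.cos(direction) + (ys - ys.mean()) * math.sin(direction)
    length = t.max() - t.min()
    if length < n_bins:
        raise ValueError(
            f"mask spans {length:.1f} px along the axis; need >= {n_bins}"
        )
    edges = np.linspace(t.min(), t.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    vals = np.asarray(image, dtype=float)[ys, xs]
    means = np.array([vals[idx == i].mean() if np.any(idx == i) else np.nan
                      for i in range(n_bins)])
    # idx increases along +direction; leading edge = largest axial coordinate.
    return BinnedProfile(means[::-1], oriented_le_first=True, normalization="raw")


def normalize01(profile: BinnedProfile) -> BinnedProfile:
    """Min-max normalize to [0, 1]; a constant profile becomes zeros + flag."""
    v = profile.values
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return replace(profile, values=np.zeros(12), normalization="unit01",
                       degenerate=True)
    return replace(profile, values=(v - lo) / (hi - lo), normalization="unit01",
                   degenerate=False)


def normalize_max(profile: BinnedProfile) -> BinnedProfile:
    """Divide by the profile maximum (per-fluorophore, per-cell)."""
    hi = np.nanmax(profile.values)
    if hi <= 0:
        return replace(profile, values=np.zeros(12), normalization="unit_max",
                       degenerate=True)
    return replace(profile, values=profile.values / hi, normalization="unit_max",
                   degenerate=False)


def anchor_le_te(profiles: dict[str, BinnedProfile],
                 le_marker: str = "CDC42", te_marker: str = "CD44",
                 ) -> tuple[dict[str, BinnedProfile], bool]:
    """Orient all profiles so the LE marker peaks before the TE marker.

    CDC42 anchors the leading edge and CD44 the trailing edge: if the CDC42
    peak bin comes after the CD44 peak bin, every profile is flipped.  A
    conflict flag is raised when the two marker peaks are within 2 bins of
    each other (orientation is then unreliable; ties leave the orientation
    unchanged).
    """
    for name in (le_marker, te_marker):
        if name not in profiles:
            raise KeyError(f"profile {name!r} required for LE/TE anchoring")
    le_peak = int(np.nanargmax(profiles[le_marker].values))
    te_peak = int(np.nanargmax(profiles[te_marker].values))
    conflict = abs(le_peak - te_peak) <= 2
    if le_peak > te_peak:
        return {k: p.reversed() for k, p in profiles.items()}, conflict
    return dict(profiles), conflict


def perimeter_polarization(contour_intensity: PerimeterProfile | np.ndarray
                           ) -> PerimeterPolarization:
    """Fraction of perimeter fluorescence in the 25% centred on the maximum.

    The window is ``ceil(0.25 N)`` contiguous samples centred on the argmax
    (wrapping around the closed contour; argmax ties break to the lowest
    index); the ratio is the window sum over the total sum, so a uniform
    contour gives ~0.25 and a single bright sample gives 1.
    """
    if isinstance(contour_intensity, PerimeterProfile):
        v = contour_intensity.intensities
    else:
        v = np.asarray(contour_intensity, dtype=float)
        if v.ndim != 1 or v.size < 8:
            raise ValueError("perimeter profile needs >= 8 ordered samples")
    if np.any(v < 0):
        raise ValueError("perimeter intensities must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("total perimeter fluorescence must be positive")
    n = v.size
    win = int(math.ceil(0.25 * n))
    peak = int(np.argmax(v))
    offsets = np.arange(win) - (win - 1) // 2
    window = (peak + offsets) % n
    return PerimeterPolarization(float(v[window].sum() / total), win, peak)


def sample_perimeter(image: np.ndarray, mask: np.ndarray) -> PerimeterProfile:
    """Sample intensity along the cell contour at ~1 px arc spacing.

    The contour comes from marching squares at the mask half-level and is
    resampled to uniform unit arc spacing; intensities are bilinear samples of
    ``image`` along it.
    """
    contours = measure.find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    contour = max(contours, key=len)  # (row, col) vertices, closed
    pts = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    seg = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)[:-1]])
    total = s[-1] + seg[-1]
    n = max(8, int(round(total)))
    s_new = np.linspace(0.0, total, n, endpoint=False)
    rows = np.interp(s_new, s, pts[:, 0], period=total)
    cols = np.interp(s_new, s, pts[:, 1], period=total)
    vals = ndimage.map_coordinates(np.asarray(image, dtype=float),
                                   np.array([rows, cols]), order=1)
    return PerimeterProfile(vals)


def mpact_polarity(mpact_profile: BinnedProfile, caax_profile: BinnedProfile,
                   k: int = 3, denominator_guard: float = 0.05,
                   ) -> tuple[BinnedProfile, float]:
    """MPAct/CaaX ratio profile and its front-k over back-k polarity.

    Both profiles are normalized with the highest intensity per fluorophore
    set to 1 (divide-by-max), the normalized MPAct signal is divided bin-wise
    by the normalized CaaX signal, and the polarity scalar is the mean of the
    front ``k`` ratio bins over the mean of the back ``k``.  Bins where the
    normalized CaaX value falls below ``denominator_guard`` are excluded
    (near-zero denominators would otherwise dominate the ratio).
    """
    if not (mpact_profile.oriented_le_first and caax_profile.oriented_le_first):
        raise ValueError("profiles must be oriented leading-edge first")
    m = normalize_max(mpact_profile)
    c = normalize_max(caax_profile)
    if c.degenerate:
        raise ValueError("CaaX profile has no signal")
    ratio = np.where(c.values >= denominator_guard, m.values / np.where(
        c.values >= denominator_guard, c.values, 1.0), np.nan)
    front = ratio[:k]
    back = ratio[-k:]
    if np.all(np.isnan(back)) or np.nanmean(back) == 0:
        raise ValueError("back-bin ratio mean is zero or undefined")
    polarity = float(np.nanmean(front) / np.nanmean(back))
    return BinnedProfile(ratio, oriented_le_first=True,
                         normalization="unit_max"), polarity


def profile_ci_band(profiles: list[BinnedProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and 95% CI half-width (1.96 SEM) across cells."""
    if not profiles:
        raise ValueError("need at least one profile")
    arr = np.vstack([p.values for p in profiles])
    mean = np.nanmean(arr, axis=0)
    sem = np.nanstd(arr, axis=0, ddof=1) / math.sqrt(arr.shape[0]) \
        if arr.shape[0] > 1 else np.zeros(12)
    return mean, 1.96 * sem
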