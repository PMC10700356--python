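"""Synthetic fluorescence-microscopy data with known ground truth.

Everything the quantification pipelines consume can be generated here with the
generating parameters recorded per cell, so every downstream estimator can be
validated by parameter recovery: migrating polarized cells with a cortical
F-actin band displaced inward from the plasma membrane (~174 nm at the leading
edge, ~43 nm at the sides by default), membrane-tethered reporter channels with
configurable front/back polarization, cortical speckles advecting rearward,
propidium-iodide-positive dead cells, z-stacks for volumetry, modal-volume
populations, TIRF-like speckle-flow movies, and raw ICP-MS intensity plates
with internal standard, blanks and a six-point calibration series.

Cell geometry is two half-ellipses joined at the widest point: a blunt front
half (semi-axis ``a_f``) and a longer tapered rear half (``a_r``), sharing the
semi-width ``b``, so area and perimeter are analytic.  Per-cell randomness is
drawn from counter-based substreams of one root seed
(``SeedSequence(seed, spawn_key=...)``), so changing ``n_cells`` does not
reshuffle the cells already generated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates
from scipy.spatial import cKDTree

from .imaging_io import CellMovie

__all__ = [
    "GeneratorConfig",
    "CellTruth",
    "GroundTruth",
    "ConfigurationError",
    "generate_cell_movie",
    "generate_cell_zstack",
    "generate_speckle_movie",
    "generate_edge_profile_stack",
    "generate_volume_population",
    "generate_icpms_batch",
]

CHANNEL_NAMES = ["membrane", "actin", "reporter", "viability"]

# Rendering constants (counts before noise).
_AMP_MEMBRANE = 800.0
_AMP_ACTIN = 1000.0
_AMP_VIABILITY = 600.0
_MEMBRANE_SIGMA_UM = 0.03     # intrinsic membrane line width before PSF
_ACTIN_CYTO_FRACTION = 0.08   # diffuse G-actin floor relative to cortex peak
_LE_ACTIN_ENRICHMENT = 0.7    # extra cortical F-actin amplitude at the front arc
_SPECKLE_CONTRAST = 0.45
_SPECKLE_GRID_UM = 0.05


class ConfigurationError(ValueError):
    """Raised when a generator configuration cannot be realised."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic imaging generator.

    Defaults emulate the acquisition the measurements were designed for:
    iSIM-like 0.1083 µm pixels, 15 s frame interval, cells of 38-60 µm²,
    membrane-to-peak-F-actin spacing 174 nm at the leading edge and 43 nm at
    the side, and 1 µm z-spacing with 7-9 slices for volumetry.
    """

    image_size_px: tuple[int, int] = (256, 256)     # (rows, cols)
    pixel_size_um: float = 0.1083                   # 0.325 for widefield-like
    frame_interval_s: float = 15.0
    n_frames: int = 40
    n_cells: int = 5
    cell_area_um2_range: tuple[float, float] = (38.0, 60.0)
    speed_um_min: float = 12.0
    le_spacing_nm: float = 174.0
    side_spacing_nm: float = 43.0
    cortex_sigma_nm: float = 80.0
    reporter_front_enrichment: float = 1.0          # >= 0; 1 = uniform
    mpact_front_depletion: float = 1.0              # in [0, 1]; 1 = uniform
    flow_um_min: float = 5.0
    psf_sigma_um: float = 0.1
    noise_gaussian_sd: float = 0.0
    noise_poisson: bool = False
    dead_fraction: float = 0.0
    z_spacing_um: float = 1.0
    n_z: int = 8
    condition_multipliers: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "frame_interval_s", "speed_um_min",
                     "le_spacing_nm", "side_spacing_nm", "cortex_sigma_nm",
                     "flow_um_min", "psf_sigma_um", "z_spacing_um"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.pixel_size_um == 0 or self.frame_interval_s == 0:
            raise ConfigurationError("pixel size and frame interval must be > 0")
        if not (0 <= self.mpact_front_depletion <= 1):
            raise ConfigurationError("mpact_front_depletion must be in [0, 1]")
        if self.reporter_front_enrichment < 0:
            raise ConfigurationError("reporter_front_enrichment must be >= 0")
        if not (0 <= self.dead_fraction <= 1):
            raise ConfigurationError("dead_fraction must be in [0, 1]")
        lo, hi = self.cell_area_um2_range
        if not (0 < lo <= hi):
            raise ConfigurationError("cell_area_um2_range must be positive and ordered")
        # The largest admissible cell must fit inside the image.
        max_len_um = 2.0 * math.sqrt(hi * 2.8 / math.pi)  # length at max aspect
        fov_um = min(self.image_size_px) * self.pixel_size_um
        if max_len_um >= fov_um:
            raise ConfigurationError(
                f"cell diameter (~{max_len_um:.1f} µm) exceeds the "
                f"{fov_um:.1f} µm field of view"
            )

    def multipliers_for(self, condition: str) -> dict:
        if condition == "default" and condition not in self.condition_multipliers:
            return {}
        try:
            return dict(self.condition_multipliers[condition])
        except KeyError:
            raise KeyError(
                f"unknown condition {condition!r}; known: "
                f"{sorted(self.condition_multipliers) + ['default']}"
            ) from None


@dataclass
class CellTruth:
    """Generating parameters of one synthetic cell, the recovery targets."""

    cell_id: int
    speed_um_min: float = math.nan
    direction_rad: float = math.nan
    area_um2: float = math.nan
    circularity: float = math.nan
    le_spacing_nm: float = math.nan
    side_spacing_nm: float = math.nan
    polarity_ratio: float = math.nan
    perimeter_polarization: float = math.nan
    flow_um_min: float = math.nan
    volume_um3: float = math.nan
    is_dead: bool = False
    start_x_um: float = math.nan
    start_y_um: float = math.nan


@dataclass
class GroundTruth:
    """Per-cell ground-truth records for a generated dataset."""

    cells: list[CellTruth]

    def __len__(self) -> int:
        return len(self.cells)

    def __getitem__(self, i: int) -> CellTruth:
        return self.cells[i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.cells])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps([asdict(c) for c in self.cells], indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        records = json.loads(Path(path).read_text())
        return cls([CellTruth(**r) for r in records])


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Substream generator: one root seed, counter-based spawn keys."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Polarized-cell geometry
# ---------------------------------------------------------------------------

@dataclass
class _CellShape:
    """Two half-ellipses joined at the widest point, in cell-frame µm.

    +x is the migration direction; the front half-ellipse (semi-axis ``a_f``)
    is shorter than the rear one (``a_r``), giving a blunt front and a tapered
    rear.  A circle is the degenerate case ``a_f == a_r == b``.
    """

    a_f: float
    a_r: float
    b: float

    @classmethod
    def from_area(cls, area_um2: float, aspect: float, front_fraction: float
                  ) -> "_CellShape":
        b = math.sqrt(area_um2 / (math.pi * aspect))
        length = 2.0 * aspect * b
        return cls(a_f=front_fraction * length, a_r=(1 - front_fraction) * length, b=b)

    @property
    def length(self) -> float:
        return self.a_f + self.a_r

    def boundary(self, n: int = 720) -> tuple[np.ndarray, np.ndarray]:
        """Uniform-arc-length boundary polyline.

        Returns ``(points (n, 2) [x, y] in µm, u (n,))`` where ``u`` is the
        normalized axial coordinate of each boundary point (0 = rear tip,
        1 = front tip).
        """
        tau = np.linspace(0.0, 2.0 * math.pi, 8 * n, endpoint=False)
        a = np.where(np.cos(tau) >= 0, self.a_f, self.a_r)
        pts = np.column_stack([a * np.cos(tau), self.b * np.sin(tau)])
        seg = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)[:-1]])
        total = s[-1] + seg[-1]
        s_new = np.linspace(0.0, total, n, endpoint=False)
        x = np.interp(s_new, s, pts[:, 0], period=total)
        y = np.interp(s_new, s, pts[:, 1], period=total)
        out = np.column_stack([x, y])
        u = (out[:, 0] + self.a_r) / self.length
        return out, np.clip(u, 0.0, 1.0)

    def inside(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        a = np.where(x >= 0, self.a_f, self.a_r)
        return (x / a) ** 2 + (y / self.b) ** 2 <= 1.0

    def area(self) -> float:
        return math.pi * self.b * (self.a_f + self.a_r) / 2.0

    def perimeter(self, n: int = 4096) -> float:
        pts, _ = self.boundary(n)
        return float(np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1).sum())

    def circularity(self) -> float:
        p = self.perimeter()
        return 4.0 * math.pi * self.area() / p**2


def _outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals of a closed polyline (centroid-based orientation)."""
    tangent = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    centroid = points.mean(axis=0)
    flip = np.einsum("ij,ij->i", normal, points - centroid) < 0
    normal[flip] *= -1.0
    return normal


def _front_weight(cos_phi: np.ndarray) -> np.ndarray:
    """Leading-edge membership of a boundary point from its outward normal.

    1 where the normal is within 60 deg of the migration direction, 0 beyond
    80 deg, smooth in between, so the whole front arc carries the leading-edge
    spacing and the lateral arcs the side spacing.
    """
    c60, c80 = math.cos(math.radians(60)), math.cos(math.radians(80))
    t = np.clip((cos_phi - c80) / (c60 - c80), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)  # smoothstep


def _reporter_modulation(u: np.ndarray, enrichment: float, depletion: float
                         ) -> np.ndarray:
    """Axial intensity modulation of the membrane-tethered reporter.

    ``u`` = 0 at the rear tip, 1 at the front tip.  ``enrichment`` > 1 enriches
    the front (GFP-fusion-like polarization); ``depletion`` < 1 depletes the
    front (MPAct-like loss of membrane-proximal actin at the leading edge).
    """
    return (1.0 + (enrichment - 1.0) * u) * (1.0 - (1.0 - depletion) * u)


def _axial_bin_ratio(u: np.ndarray, values: np.ndarray, n_bins: int = 12,
                     k: int = 3) -> float:
    """Front-k over back-k bin-mean ratio of a boundary signal.

    This is the generator-side definition of the polarity ground truth: the
    boundary samples (uniform in arc length, mimicking membrane pixels) are
    binned into ``n_bins`` equal axial bins and the mean of the front ``k``
    bins is divided by the mean of the back ``k`` bins.
    """
    bins = np.clip((u * n_bins).astype(int), 0, n_bins - 1)
    means = np.array([values[bins == i].mean() for i in range(n_bins)])
    return float(means[-k:].mean() / means[:k].mean())


# ---------------------------------------------------------------------------
# Movie generation
# ---------------------------------------------------------------------------

def _realize_cell(cfg: GeneratorConfig, condition: str, i: int) -> CellTruth:
    mult = cfg.multipliers_for(condition)
    rng = _rng(cfg.seed, 0, i)
    lo, hi = cfg.cell_area_um2_range
    area = float(rng.uniform(lo, hi))
    is_dead = bool(rng.random() < cfg.dead_fraction)
    direction = float(rng.uniform(0.0, 2.0 * math.pi))
    speed = cfg.speed_um_min * mult.get("speed", 1.0)
    speed = float(speed * math.exp(rng.normal(0.0, 0.12))) if speed > 0 else 0.0
    le = cfg.le_spacing_nm * mult.get("le_spacing", mult.get("spacing", 1.0))
    side = cfg.side_spacing_nm * mult.get("side_spacing", mult.get("spacing", 1.0))
    flow = cfg.flow_um_min * mult.get("flow", 1.0)
    if is_dead:
        shape = _CellShape.from_area(area, 1.0, 0.5)
        speed = 0.0
        polarity = 1.0
        perim_pol = math.nan
    else:
        aspect = float(np.clip(rng.normal(2.1, 0.2), 1.6, 2.8))
        shape = _CellShape.from_area(area, aspect, front_fraction=0.42)
        _, u = shape.boundary(1024)
        m = _reporter_modulation(u, cfg.reporter_front_enrichment,
                                 cfg.mpact_front_depletion)
        polarity = _axial_bin_ratio(u, m)
        from .polarity_profiles import perimeter_polarization
        perim_pol = perimeter_polarization(m).ratio if m.max() > 0 else math.nan
    truth = CellTruth(
        cell_id=i, speed_um_min=speed, direction_rad=direction,
        area_um2=area, circularity=shape.circularity(),
        le_spacing_nm=le, side_spacing_nm=side,
        polarity_ratio=polarity, perimeter_polarization=perim_pol,
        flow_um_min=flow, is_dead=is_dead,
    )
    truth._shape = shape  # type: ignore[attr-defined]  # internal plumbing
    return truth


def _place_cells(cfg: GeneratorConfig, truths: list[CellTruth]) -> None:
    """Choose start positions so every trajectory stays inside the image."""
    h, w = cfg.image_size_px
    fov_y = h * cfg.pixel_size_um
    fov_x = w * cfg.pixel_size_um
    duration_min = (cfg.n_frames - 1) * cfg.frame_interval_s / 60.0
    placed: list[np.ndarray] = []
    for t in truths:
        shape: _CellShape = t._shape  # type: ignore[attr-defined]
        margin = max(shape.a_f, shape.a_r, shape.b) + 1.0
        disp = t.speed_um_min * duration_min
        dx, dy = disp * math.cos(t.direction_rad), disp * math.sin(t.direction_rad)
        x_lo, x_hi = margin + max(0.0, -dx), fov_x - margin - max(0.0, dx)
        y_lo, y_hi = margin + max(0.0, -dy), fov_y - margin - max(0.0, dy)
        if x_lo >= x_hi or y_lo >= y_hi:
            raise ConfigurationError(
                f"cell {t.cell_id}: trajectory of {disp:.1f} µm does not fit the "
                f"{fov_x:.1f} x {fov_y:.1f} µm field; enlarge the image or slow "
                "the cells"
            )
        rng = _rng(cfg.seed, 1, t.cell_id)
        times = np.arange(cfg.n_frames) * cfg.frame_interval_s / 60.0
        vel = t.speed_um_min * np.array([math.cos(t.direction_rad),
                                         math.sin(t.direction_rad)])

        def _traj(start: np.ndarray) -> np.ndarray:
            return start[None, :] + times[:, None] * vel[None, :]

        # Keep cells separated in every frame (same-frame proximity is what
        # merges masks), not just at the start.
        pos = None
        for _ in range(256):
            cand = np.array([rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)])
            traj = _traj(cand)
            ok = True
            for prev_traj, prev_len in placed:
                gap = np.linalg.norm(traj - prev_traj, axis=1).min()
                if gap < 0.75 * (shape.length + prev_len) + 1.5:
                    ok = False
                    break
            if ok:
                pos = cand
                break
        if pos is None:  # crowded field: accept overlap rather than fail
            pos = np.array([rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)])
        placed.append((_traj(pos), shape.length))
        t.start_x_um, t.start_y_um = float(pos[0]), float(pos[1])


def _speckle_pattern(cfg: GeneratorConfig, cell_id: int, perimeter_um: float
                     ) -> tuple[np.ndarray, float]:
    """Frozen 1-D cortical speckle pattern over arc length (periodic)."""
    n = max(16, int(round(perimeter_um / _SPECKLE_GRID_UM)))
    raw = _rng(cfg.seed, 2, cell_id).standard_normal(n)
    pat = gaussian_filter1d(raw, sigma=2.0, mode="wrap")
    pat /= max(np.abs(pat).max(), 1e-12)
    return pat, perimeter_um / n


def _render_cell_frame(images: np.ndarray, cfg: GeneratorConfig,
                       truth: CellTruth, t_s: float) -> None:
    """Accumulate one cell into the 4 channel images of one frame (no noise)."""
    px = cfg.pixel_size_um
    shape: _CellShape = truth._shape  # type: ignore[attr-defined]
    center = np.array([truth.start_x_um, truth.start_y_um])
    center = center + truth.speed_um_min * (t_s / 60.0) * np.array(
        [math.cos(truth.direction_rad), math.sin(truth.direction_rad)])

    n_b = max(400, int(round(shape.perimeter() / px * 2)))
    pts_cell, u = shape.boundary(n_b)
    cos_d, sin_d = math.cos(truth.direction_rad), math.sin(truth.direction_rad)
    rot = np.array([[cos_d, -sin_d], [sin_d, cos_d]])
    pts_um = pts_cell @ rot.T + center
    pts_px = pts_um / px  # (x, y) in pixel units

    normals = _outward_normals(pts_cell)
    front_w = _front_weight(normals[:, 0])
    spacing_um = (truth.side_spacing_nm
                  + (truth.le_spacing_nm - truth.side_spacing_nm) * front_w) / 1000.0
    modulation = _reporter_modulation(u, cfg.reporter_front_enrichment,
                                      cfg.mpact_front_depletion)

    # Cortical speckles advected rearward (front tip -> rear along both sides).
    seg = np.linalg.norm(np.diff(pts_um, axis=0, append=pts_um[:1]), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)[:-1]])
    perim = arc[-1] + seg[-1]
    pat, ds = _speckle_pattern(cfg, truth.cell_id, perim)
    phase = truth.flow_um_min * t_s / 60.0
    idx_f = ((arc + phase) / ds) % len(pat)
    speck = pat[idx_f.astype(int)]

    h, w = cfg.image_size_px
    margin = int(math.ceil((3 * cfg.psf_sigma_um + 4 * _MEMBRANE_SIGMA_UM
                            + truth.le_spacing_nm / 1000.0
                            + 4 * cfg.cortex_sigma_nm / 1000.0) / px)) + 3
    x0 = max(0, int(np.floor(pts_px[:, 0].min())) - margin)
    x1 = min(w, int(np.ceil(pts_px[:, 0].max())) + margin + 1)
    y0 = max(0, int(np.floor(pts_px[:, 1].min())) - margin)
    y1 = min(h, int(np.ceil(pts_px[:, 1].max())) + margin + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    dist_px, nearest = cKDTree(pts_px).query(pix)
    p_cell = (pix * px - center) @ rot
    inside = shape.inside(p_cell[:, 0], p_cell[:, 1])
    d_um = dist_px * px * np.where(inside, -1.0, 1.0)

    # The PSF is folded analytically into the normal-direction profile widths
    # (exact for a straight edge, accurate for curvature radius >> sigma);
    # image-space blurring of a sub-pixel membrane line would alias badly at
    # widefield sampling.
    sig_m = math.hypot(_MEMBRANE_SIGMA_UM, cfg.psf_sigma_um)
    sig_a = math.hypot(max(cfg.cortex_sigma_nm / 1000.0, 1e-3),
                       cfg.psf_sigma_um)
    sig_edge = max(cfg.psf_sigma_um, 0.25 * px)
    membrane = _AMP_MEMBRANE * np.exp(-0.5 * (d_um / sig_m) ** 2)
    inside_soft = 1.0 / (1.0 + np.exp(d_um / sig_edge))
    if truth.is_dead:
        actin = 0.3 * _AMP_ACTIN * np.exp(-0.5 * (d_um / sig_a) ** 2)
        reporter = membrane.copy()
        viability = _AMP_VIABILITY * inside_soft
    else:
        sp = spacing_um[nearest]
        amp = _AMP_ACTIN * (1.0 + _LE_ACTIN_ENRICHMENT * front_w[nearest])
        amp = amp * (1.0 + _SPECKLE_CONTRAST * speck[nearest])
        actin = amp * np.exp(-0.5 * ((d_um + sp) / sig_a) ** 2)
        actin += _ACTIN_CYTO_FRACTION * _AMP_ACTIN * inside_soft
        reporter = _AMP_MEMBRANE * modulation[nearest] * np.exp(
            -0.5 * (d_um / sig_m) ** 2)
        viability = np.zeros_like(membrane)

    sub = (slice(y0, y1), slice(x0, x1))
    for ch, img in enumerate((membrane, actin, reporter, viability)):
        images[ch][sub] += img.reshape(yy.shape)


def generate_cell_movie(config: GeneratorConfig, condition: str = "default"
                        ) -> tuple[CellMovie, GroundTruth]:
    """Generate a multi-channel time-lapse of migrating polarized cells.

    Channels are ``(membrane, actin, reporter, viability)``.  Live cells
    translate at their realized speed in their realized direction with a
    cortical actin band displaced inward from the membrane by the leading-edge
    spacing on the front arc and the side spacing laterally; dead cells are
    round, stationary and viability-positive.  Identical ``(config,
    condition)`` including the seed give bit-identical output.
    """
    truths = [_realize_cell(config, condition, i) for i in range(config.n_cells)]
    _place_cells(config, truths)

    h, w = config.image_size_px
    data = np.zeros((config.n_frames, 4, h, w), dtype=np.float32)
    for f in range(config.n_frames):
        frame = np.zeros((4, h, w), dtype=np.float64)
        t_s = f * config.frame_interval_s
        for truth in truths:
            _render_cell_frame(frame, config, truth, t_s)
        if config.noise_poisson:
            noise_rng = _rng(config.seed, 3, f)
            frame = noise_rng.poisson(np.clip(frame, 0, None)).astype(np.float64)
        if config.noise_gaussian_sd > 0:
            noise_rng2 = _rng(config.seed, 4, f)
            frame = frame + noise_rng2.normal(0.0, config.noise_gaussian_sd,
                                              frame.shape)
        data[f] = frame.astype(np.float32)

    movie = CellMovie(data, config.pixel_size_um, list(CHANNEL_NAMES),
                      axis_kind="time", dt_s=config.frame_interval_s)
    for t in truths:  # drop internal plumbing before handing truth out
        if hasattr(t, "_shape"):
            del t._shape  # type: ignore[attr-defined]
    return movie, GroundTruth(truths)


def generate_cell_zstack(volume_um3: float, pixel_size_um: float = 0.1083,
                         dz_um: float = 1.0, n_z: int = 8,
                         image_size_px: tuple[int, int] = (96, 96),
                         ) -> tuple[np.ndarray, CellTruth]:
    """Z-stack of boolean slice masks of a spherical cell of known volume.

    Slices are cut at ``n_z`` planes spaced ``dz_um`` apart, centred on the
    sphere, mimicking the membrane-mask volumetry readout (sum of slice areas
    times spacing).
    """
    if volume_um3 <= 0 or n_z < 1:
        raise ValueError("volume and n_z must be positive")
    radius = (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    h, w = image_size_px
    if 2 * radius >= min(h, w) * pixel_size_um:
        raise ConfigurationError("cell diameter exceeds image size")
    cy, cx = (h - 1) / 2.0 * pixel_size_um, (w - 1) / 2.0 * pixel_size_um
    yy, xx = np.mgrid[0:h, 0:w].astype(float) * pixel_size_um
    masks = np.zeros((n_z, h, w), dtype=bool)
    for k in range(n_z):
        z = (k - (n_z - 1) / 2.0) * dz_um
        r2 = radius**2 - z**2
        if r2 > 0:
            masks[k] = (yy - cy) ** 2 + (xx - cx) ** 2 <= r2
    truth = CellTruth(cell_id=0, volume_um3=volume_um3)
    return masks, truth


def generate_speckle_movie(flow_um_min: float, pixel_size_um: float = 0.1,
                           dt_s: float = 1.0, n_frames: int = 60,
                           image_size_px: tuple[int, int] = (64, 128),
                           speckle_sigma_um: float = 0.25, snr: float = 10.0,
                           seed: int = 0) -> tuple[CellMovie, CellTruth]:
    """TIRF-like movie of a cortical speckle field advecting at a known rate.

    Emulates the retrograde-flow assay geometry: the cell stays in place and
    the F-actin texture slips along +x at ``flow_um_min``.  A frozen random
    field is advected with sub-pixel (spline) resampling; Gaussian noise is
    scaled by ``1/snr``.
    """
    if flow_um_min < 0 or n_frames < 2:
        raise ValueError("flow must be >= 0 and n_frames >= 2")
    h, w = image_size_px
    rng = _rng(seed, 10)
    v_px = flow_um_min / 60.0 * dt_s / pixel_size_um  # px per frame
    pad = int(math.ceil(v_px * n_frames)) + 4
    base = rng.standard_normal((h, w + pad))
    base = gaussian_filter(base, speckle_sigma_um / pixel_size_um)
    base = (base - base.mean()) / base.std()
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    data = np.empty((n_frames, 1, h, w), dtype=np.float32)
    noise_rng = _rng(seed, 11)
    for f in range(n_frames):
        coords = np.array([yy, xx + (n_frames - 1 - f) * v_px])
        frame = map_coordinates(base, coords, order=3, mode="nearest")
        if snr > 0 and math.isfinite(snr):
            frame = frame + noise_rng.normal(0.0, 1.0 / snr, frame.shape)
        data[f, 0] = frame
    movie = CellMovie(data, pixel_size_um, ["actin"], "time", dt_s=dt_s)
    return movie, CellTruth(cell_id=0, flow_um_min=flow_um_min)


# ---------------------------------------------------------------------------
# Leading-edge profile stacks
# ---------------------------------------------------------------------------

def generate_edge_profile_stack(n_lines: int, true_spacing_nm: float,
                                pixel_size_um: float = 0.0433,
                                snr: float = 10.0, seed: int = 0,
                                pm_sigma_nm: float = 90.0,
                                actin_sigma_nm: float = 110.0,
                                spacing_jitter_nm: float = 5.0,
                                ) -> tuple["ProfileStack", CellTruth]:
    """Direct fixture for the membrane-to-F-actin spacing estimator.

    Each line is a pair of Gaussian peaks sampled on a signed-distance axis
    (0 = plasma-membrane peak, positive towards the cell interior): the PM
    peak at 0 and the actin peak at ``true_spacing_nm`` plus per-line jitter.
    Additive Gaussian noise is scaled by ``1/snr``.
    """
    from .edge_spacing import ProfileStack

    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if true_spacing_nm < 0:
        raise ValueError("true_spacing_nm must be >= 0")
    step_nm = pixel_size_um * 1000.0
    positions = np.arange(-round(500 / step_nm), round(900 / step_nm) + 1) * step_nm
    rng = _rng(seed, 20)
    pm = np.empty((n_lines, positions.size))
    actin = np.empty_like(pm)
    centers = true_spacing_nm + rng.normal(0.0, spacing_jitter_nm, n_lines)
    amp_pm = rng.uniform(0.9, 1.0, n_lines)
    amp_ac = rng.uniform(0.8, 1.0, n_lines)
    noise_sd = 0.0 if (snr <= 0 or math.isinf(snr)) else 1.0 / snr
    for i in range(n_lines):
        pm[i] = amp_pm[i] * np.exp(-0.5 * (positions / pm_sigma_nm) ** 2)
        actin[i] = amp_ac[i] * np.exp(
            -0.5 * ((positions - centers[i]) / actin_sigma_nm) ** 2)
        if noise_sd:
            pm[i] += rng.normal(0.0, noise_sd, positions.size)
            actin[i] += rng.normal(0.0, noise_sd, positions.size)
    stack = ProfileStack(
        positions_nm=np.broadcast_to(positions, pm.shape).copy(),
        pm=pm, actin=actin, step_nm=step_nm, source="synthetic",
    )
    truth = CellTruth(cell_id=0, le_spacing_nm=true_spacing_nm)
    return stack, truth


# ---------------------------------------------------------------------------
# Volume populations and ICP-MS plates
# ---------------------------------------------------------------------------

def generate_volume_population(n: int, mode_fl: float, sd_fl: float,
                               seed: int = 0) -> np.ndarray:
    """Log-normal-like cell-volume sample whose histogram mode is ``mode_fl``.

    Parametrised so the density mode of the log-normal equals ``mode_fl``
    (mode = exp(mu - sigma^2)) with shape ``sigma ~ sd_fl / mode_fl``.
    """
    if n < 1 or mode_fl <= 0 or sd_fl < 0:
        raise ValueError("need n >= 1, mode_fl > 0, sd_fl >= 0")
    sigma = sd_fl / mode_fl
    mu = math.log(mode_fl) + sigma**2
    rng = _rng(seed, 30)
    return np.exp(rng.normal(mu, sigma, n)) if sigma > 0 else np.full(n, mode_fl)


def generate_icpms_batch(true_conc_ppb: list[float],
                         calib_levels_ppb: list[float] | None = None,
                         is_counts: float = 2.0e5,
                         blank_counts: float = 500.0,
                         sensitivity: float = 4.0e3,
                         noise_cv: float = 0.0,
                         n_blanks: int = 3,
                         cell_counts: list[int] | None = None,
                         seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Raw ICP-MS intensity plate with internal standard, blanks and standards.

    Model: per run, an instrument drift factor multiplies both the analyte and
    the internal-standard channel (removed by the IS ratio); the blank level
    adds to every analyte signal; ``sensitivity`` is counts per ppb at nominal
    IS.  At ``noise_cv = 0`` the concentration chain inverts the plate exactly.
    Returns the plate table and the true concentrations.
    """
    if calib_levels_ppb is None:
        calib_levels_ppb = [1.0, 2.0, 5.0, 10.0, 20.0, 50.0]
    if len(set(calib_levels_ppb)) != 6:
        raise ValueError("exactly six distinct calibration levels required")
    if sensitivity <= 0 or is_counts <= 0:
        raise ValueError("sensitivity and is_counts must be positive")
    true_conc = np.asarray(true_conc_ppb, dtype=float)
    if cell_counts is None:
        cell_counts = [1] * len(true_conc)
    rng = _rng(seed, 40)

    rows = []

    def _row(kind: str, conc: float, n_cells: int | None) -> None:
        drift = 1.0 + (noise_cv * rng.normal() if noise_cv > 0 else 0.0)
        meas = 1.0 + (noise_cv * rng.normal() if noise_cv > 0 else 0.0)
        analyte = (blank_counts + sensitivity * conc) * drift * meas
        rows.append({
            "sample_type": kind,
            "analyte_counts": analyte,
            "is_counts": is_counts * drift,
            "known_conc_ppb": conc if kind == "standard" else np.nan,
            "cell_count": n_cells if n_cells is not None else np.nan,
        })

    for _ in range(n_blanks):
        _row("blank", 0.0, None)
    for level in calib_levels_ppb:
        _row("standard", level, None)
    for conc, n_cells in zip(true_conc, cell_counts):
        _row("sample", conc, n_cells)
    return pd.DataFrame(rows), true_conc
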