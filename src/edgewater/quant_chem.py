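"""Volumetry, media tonicity design, and ICP-MS / NMR normalization chains.

Osmolarity arithmetic is linear in concentration (ideal-solution assumption):
replacing a fraction f of an isotonic medium's osmotically active content
with osmotically inactive solution scales its osmolarity to iso*(1-f), which
reproduces the tonicity series used in the migration-rescue experiments
(292, 277.4, 262.8, 248.2, 233.6 mOsm/l for f = 0..0.20); non-ionic
osmolytes (d-sorbitol, L-glucose) contribute 1 mOsm/l per mM.

The ICP-MS chain is: internal-standard normalization of raw intensities,
blank correction by the mean of repeat blanks, external standardization on a
six-point calibration curve (ordinary least squares with free intercept),
then per-cell and vs-control normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MediumRecipe",
    "CalibrationCurve",
    "IcpmsResult",
    "stack_volume",
    "modal_volume",
    "median_volume",
    "replace_fraction_osmolarity",
    "percent_tonicity_reduction",
    "isotonic_supplement",
    "fit_calibration",
    "icpms_concentration",
    "icpms_from_table",
    "fold_vs_control",
    "nmr_water_signal",
]

ISO_OSM_DEFAULT = 292.0  # mOsm/l, the study's isotonic baseline


@dataclass
class MediumRecipe:
    """A tonicity-series medium: partial NaCl replacement plus an optional
    non-ionic osmolyte supplement restoring isotonicity."""

    iso_osm: float = ISO_OSM_DEFAULT
    replaced_fraction: float = 0.0
    supplement: str = "none"  # d-sorbitol | L-glucose | Na-gluconate | none
    supplement_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.replaced_fraction <= 1.0):
            raise ValueError("replaced_fraction must be in [0, 1]")
        if self.supplement not in ("d-sorbitol", "L-glucose", "Na-gluconate",
                                   "none"):
            raise ValueError(f"unknown supplement {self.supplement!r}")
        if self.supplement == "none" and self.supplement_mm != 0:
            raise ValueError("supplement_mm requires a supplement")

    @property
    def osmolarity(self) -> float:
        """Resulting osmolarity: iso*(1-f) plus 1 mOsm/l per mM supplement."""
        return round(self.iso_osm * (1.0 - self.replaced_fraction)
                     + self.supplement_mm, 1)


def stack_volume(zstack_masks: np.ndarray, dz_um: float,
                 pixel_size_um: float = 1.0) -> float:
    """Cell volume by summing slice mask areas across a z-stack (µm³).

    ``zstack_masks`` is (n_z, y, x) boolean (or a list of 2-D masks); each
    slice contributes ``area_um2 * dz_um``.  Additive over disjoint slices.
    """
    masks = np.asarray(zstack_masks)
    if masks.ndim == 2:
        masks = masks[None]
    if masks.ndim != 3 or masks.shape[0] < 1:
        raise ValueError("need >= 1 z-slice mask")
    if dz_um <= 0 or pixel_size_um <= 0:
        raise ValueError("dz_um and pixel_size_um must be positive")
    areas = masks.astype(bool).sum(axis=(1, 2)) * pixel_size_um**2
    return float(areas.sum() * dz_um)


def modal_volume(volumes, bin_fl: float = 1.0) -> float:
    """Modal cell volume: centre of the tallest ``bin_fl``-wide histogram bin.

    This is the Coulter-counter readout (the mode of ~2000 single-cell
    volumes); ties resolve to the lower bin.  Requires >= 100 values (the
    mode of a smaller sample is unstable).
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 100:
        raise ValueError("modal volume needs >= 100 values")
    if bin_fl <= 0:
        raise ValueError("bin_fl must be positive")
    # Bin centres sit on the instrument granularity grid (multiples of bin_fl).
    lo = math.floor(v.min() / bin_fl) * bin_fl
    nbins = int(math.ceil((v.max() - lo) / bin_fl)) + 1
    edges = lo - bin_fl / 2.0 + bin_fl * np.arange(nbins + 2)
    hist, _ = np.histogram(v, bins=edges)
    best = int(np.argmax(hist))  # argmax takes the first (lower) tie
    return float(lo + best * bin_fl)


def median_volume(volumes) -> float:
    """Median cell volume (alternative aggregator to the modal readout)."""
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume list")
    return float(np.median(v))


def replace_fraction_osmolarity(iso_osm: float, f: float) -> float:
    """Osmolarity after replacing fraction ``f`` of the medium with
    NaCl-free (osmotically inactive) solution: iso*(1-f), to 1 decimal."""
    if not (0.0 <= f <= 1.0):
        raise ValueError("replacement fraction must be in [0, 1]")
    return round(iso_osm * (1.0 - f), 1)


def percent_tonicity_reduction(iso_osm: float, hypo_osm: float) -> float:
    """Percent reduction of tonicity relative to the isotonic baseline."""
    if not (0.0 < hypo_osm <= iso_osm):
        raise ValueError("need 0 < hypo_osm <= iso_osm")
    return 100.0 * (iso_osm - hypo_osm) / iso_osm


def isotonic_supplement(base_osm: float, target_osm: float) -> float:
    """mM of non-ionic osmolyte restoring ``base_osm`` up to ``target_osm``
    (1 mM non-ionic osmolyte = 1 mOsm/l)."""
    if target_osm < base_osm:
        raise ValueError("target osmolarity below the base medium")
    return target_osm - base_osm


@dataclass
class CalibrationCurve:
    """Six-point external calibration: blank-corrected intensity vs ppb."""

    concentrations_ppb: np.ndarray
    intensities: np.ndarray  # blank-corrected, IS-normalized
    slope: float = field(init=False)       # counts/ppb
    intercept: float = field(init=False)   # counts

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_ppb, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if c.size != 6 or y.size != 6:
            raise ValueError("calibration needs exactly six points")
        if np.unique(c).size != 6:
            raise ValueError("calibration concentrations must be distinct")
        slope, intercept = np.polyfit(c, y, 1)
        if slope <= 0:
            raise ValueError("degenerate calibration: non-positive slope")
        self.concentrations_ppb = c
        self.intensities = y
        self.slope = float(slope)
        self.intercept = float(intercept)

    def concentration(self, corrected_intensity: float) -> float:
        return (corrected_intensity - self.intercept) / self.slope


def fit_calibration(concentrations_ppb, intensities) -> CalibrationCurve:
    """Ordinary-least-squares calibration fit with free intercept."""
    return CalibrationCurve(np.asarray(concentrations_ppb, float),
                            np.asarray(intensities, float))


@dataclass
class IcpmsResult:
    conc_ppb: float
    per_cell: float
    clamped: bool  # blank-corrected signal was negative and set to zero


def icpms_concentration(raw_counts: float, is_counts: float,
                        blank_norm_counts, curve: CalibrationCurve,
                        cell_count: int = 1) -> IcpmsResult:
    """Full ICP-MS reduction for one sample.

    ``normalized = raw / internal standard``; ``corrected = normalized -
    mean(IS-normalized blanks)``; the calibration curve converts the
    corrected intensity to ppb and the concentration is normalized to the
    cell number.  A negative blank-corrected signal is clamped to zero
    concentration with a flag.
    """
    if is_counts <= 0:
        raise ValueError("internal-standard counts must be positive")
    blanks = np.asarray(blank_norm_counts, dtype=float)
    if blanks.size < 1:
        raise ValueError("need >= 1 blank measurement")
    if cell_count <= 0:
        raise ValueError("cell_count must be positive")
    corrected = raw_counts / is_counts - blanks.mean()
    conc = curve.concentration(corrected)
    clamped = False
    if corrected < 0 or conc < 0:
        conc, clamped = 0.0, True
    return IcpmsResult(conc, conc / cell_count, clamped)


def icpms_from_table(plate: pd.DataFrame) -> pd.DataFrame:
    """Reduce a raw ICP-MS plate (as from the synthetic batch generator).

    Expects columns ``sample_type`` (blank / standard / sample),
    ``analyte_counts``, ``is_counts``, ``known_conc_ppb`` and ``cell_count``;
    returns the sample rows with ``conc_ppb``, ``per_cell`` and ``clamped``.
    """
    norm = plate["analyte_counts"] / plate["is_counts"]
    blanks = norm[plate["sample_type"] == "blank"].to_numpy()
    std = plate["sample_type"] == "standard"
    curve = fit_calibration(plate.loc[std, "known_conc_ppb"],
                            norm[std].to_numpy() - blanks.mean())
    rows = []
    for _, row in plate[plate["sample_type"] == "sample"].iterrows():
        n_cells = int(row["cell_count"]) if np.isfinite(row["cell_count"]) else 1
        res = icpms_concentration(row["analyte_counts"], row["is_counts"],
                                  blanks, curve, n_cells)
        rows.append({"conc_ppb": res.conc_ppb, "per_cell": res.per_cell,
                     "clamped": res.clamped})
    return pd.DataFrame(rows)


def fold_vs_control(values, control_values) -> np.ndarray:
    """Each value divided by the mean of the control group."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0 or control.mean() <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) / control.mean()


def nmr_water_signal(water_integral: float, dioxane_integral: float) -> float:
    """Heavy-water NMR peak integral normalized to the deuterated-dioxane
    internal standard."""
    if dioxane_integral <= 0:
        raise ValueError("internal-standard integral must be positive")
    return water_integral / dioxane_integral
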