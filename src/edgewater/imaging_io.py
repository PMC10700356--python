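"""Readers and writers for the standard formats every pipeline stage consumes.

Images travel as OME-TIFF with axes ``TCYX`` (time series) or ``ZCYX``
(z-stacks); physical pixel size, frame interval / z-spacing and channel names
are carried in the OME metadata.  Track tables are plain CSV with columns
``track_id,frame,x_um,y_um,viable``.

Coordinate conventions used across the package: pixel indices are 0-based,
physical coordinates are pixel-centre positions in micrometres, ``x`` is the
column axis and ``y`` the row axis, and angles are measured from +x towards
+y (i.e. clockwise on screen).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CellMovie",
    "TrackTable",
    "MetadataError",
    "read_movie",
    "write_movie",
    "read_tracks",
    "write_tracks",
]

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "viable"]


class MetadataError(ValueError):
    """Raised when required physical metadata is absent and not overridden."""


@dataclass
class CellMovie:
    """Multi-channel time-lapse (or z-stack) with physical calibration.

    ``data`` is ordered ``(time-or-z, channel, y, x)``.  Exactly one of
    ``dt_s`` (time series) or ``dz_um`` (z-stack) is set, matching
    ``axis_kind``.
    """

    data: np.ndarray
    pixel_size_um: float
    channel_names: list[str]
    axis_kind: str = "time"  # "time" | "z"
    dt_s: float | None = None
    dz_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("movie data must be 4-D (t/z, channel, y, x)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channels in array but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.axis_kind not in ("time", "z"):
            raise ValueError("axis_kind must be 'time' or 'z'")
        if self.axis_kind == "time" and (self.dt_s is None or self.dz_um is not None):
            raise ValueError("time-series movies set dt_s and not dz_um")
        if self.axis_kind == "z" and (self.dz_um is None or self.dt_s is not None):
            raise ValueError("z-stacks set dz_um and not dt_s")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (t/z, y, x) stack of the named channel."""
        return self.data[:, self.channel_names.index(name)]


def write_movie(movie: CellMovie, path: str | Path) -> Path:
    """Write a :class:`CellMovie` as OME-TIFF; returns the path written."""
    path = Path(path)
    axes = "TCYX" if movie.axis_kind == "time" else "ZCYX"
    metadata: dict = {
        "axes": axes,
        "PhysicalSizeX": movie.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": movie.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": list(movie.channel_names)},
    }
    if movie.axis_kind == "time":
        metadata["TimeIncrement"] = movie.dt_s
        metadata["TimeIncrementUnit"] = "s"
    else:
        metadata["PhysicalSizeZ"] = movie.dz_um
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, movie.data, ome=True, metadata=metadata)
    return path


def _ome_pixels_element(ome_xml: str) -> ET.Element | None:
    root = ET.fromstring(ome_xml)
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    image = root.find(f"{ns}Image")
    if image is None:
        return None
    return image.find(f"{ns}Pixels")


def read_movie(
    path: str | Path,
    pixel_size_um: float | None = None,
    dt_s: float | None = None,
    dz_um: float | None = None,
    channel_names: list[str] | None = None,
) -> CellMovie:
    """Read an OME-TIFF movie.

    Keyword arguments override (or, for plain TIFFs, supply) the physical
    metadata.  A file without a pixel size and no override raises
    :class:`MetadataError`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_px = meta_dt = meta_dz = None
        meta_channels: list[str] | None = None
        if tif.ome_metadata:
            pixels = _ome_pixels_element(tif.ome_metadata)
            if pixels is not None:
                if "PhysicalSizeX" in pixels.attrib:
                    meta_px = float(pixels.attrib["PhysicalSizeX"])
                if "TimeIncrement" in pixels.attrib:
                    meta_dt = float(pixels.attrib["TimeIncrement"])
                if "PhysicalSizeZ" in pixels.attrib:
                    meta_dz = float(pixels.attrib["PhysicalSizeZ"])
                names = [
                    ch.attrib.get("Name")
                    for ch in pixels.iter()
                    if ch.tag.endswith("Channel")
                ]
                if names and all(n is not None for n in names):
                    meta_channels = list(names)  # type: ignore[arg-type]

    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise MetadataError(
            f"{path} carries no pixel-size metadata; pass pixel_size_um explicitly"
        )

    # Normalise axis order to (t/z, c, y, x).
    order = [ax for ax in axes if ax in "TZCYX"]
    if (len(order) == data.ndim and len(set(order)) == len(order)
            and "Y" in order and "X" in order):
        if "C" not in order:
            data = np.expand_dims(data, axis=0)
            order = ["C"] + order
        if "T" not in order and "Z" not in order:
            data = np.expand_dims(data, axis=0)
            order = ["T"] + order
        lead = "T" if "T" in order else "Z"
        data = np.transpose(data, [order.index(a) for a in (lead, "C", "Y", "X")])
    else:
        # Plain TIFF without interpretable axes: assume trailing (y, x) and
        # leading (frames[, channels]) dimensions.
        if data.ndim == 2:
            data = data[None, None]
        elif data.ndim == 3:
            data = data[:, None]
        elif data.ndim != 4:
            raise ValueError(f"unsupported TIFF layout {axes!r} {data.shape}")
        lead = "T" if dz_um is None else "Z"

    axis_kind = "time" if lead == "T" else "z"
    names = channel_names or meta_channels
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[1])]
    if axis_kind == "time":
        dt = dt_s if dt_s is not None else meta_dt
        if dt is None:
            raise MetadataError(
                f"{path} carries no frame-interval metadata; pass dt_s explicitly"
            )
        return CellMovie(data, px, names, "time", dt_s=dt)
    dz = dz_um if dz_um is not None else meta_dz
    if dz is None:
        raise MetadataError(
            f"{path} carries no z-spacing metadata; pass dz_um explicitly"
        )
    return CellMovie(data, px, names, "z", dz_um=dz)


@dataclass
class TrackTable:
    """Per-frame positions of linked cells in physical units."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TRACK_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        self.df = self.df[TRACK_COLUMNS].reset_index(drop=True)
        if len(self.df):
            if not np.isfinite(self.df[["x_um", "y_um"]].to_numpy()).all():
                raise ValueError("track coordinates must be finite")
            for tid, sub in self.df.groupby("track_id"):
                frames = sub["frame"].to_numpy()
                if not np.all(np.diff(frames) > 0):
                    raise ValueError(
                        f"track {tid}: frames must be strictly increasing"
                    )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def track_ids(self) -> np.ndarray:
        return self.df["track_id"].unique()

    def track(self, track_id: int) -> pd.DataFrame:
        return self.df[self.df["track_id"] == track_id]


def write_tracks(table: TrackTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path


def read_tracks(path: str | Path) -> TrackTable:
    """Read a tracks CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed tracks CSV: {exc}") from exc
    for col, kind in (("track_id", int), ("frame", int),
                      ("x_um", float), ("y_um", float), ("viable", int)):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        try:
            df[col] = df[col].astype(kind)
        except (TypeError, ValueError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise ValueError(
                f"{path}: column {col!r} unparseable on line(s) {lines}"
            ) from exc
    return TrackTable(df)
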