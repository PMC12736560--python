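"""Localization-table I/O, histogram reconstruction, and rigid rotation.

A localization table is a :class:`pandas.DataFrame` with columns
``frame, x, y, intensity, uncertainty`` (coordinates in nm, intensity in
photons, uncertainty in nm).  Reconstruction renders the table as a 2D
count histogram -- the standard visualisation of SMLM data -- at a chosen
pixel size (20 nm by default, matching the resolution of the STORM
technique).  Rotation acts on the continuous localization list, never on
the rendered image, so downstream width measurements carry no
interpolation bias.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ReconstructedImage",
    "read_localizations",
    "write_localizations",
    "render_histogram_image",
    "rotate_localizations",
]

logger = logging.getLogger(__name__)

LOC_COLUMNS = ("frame", "x", "y", "intensity", "uncertainty")

#: ThunderSTORM CSV export column names -> internal names.
THUNDERSTORM_MAP = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "intensity [photon]": "intensity",
    "uncertainty [nm]": "uncertainty",
    "uncertainty_xy [nm]": "uncertainty",
}

_THUNDERSTORM_HEADER = 'frame,"x [nm]","y [nm]","intensity [photon]","uncertainty [nm]"'


class FormatError(ValueError):
    """The localization file does not match a supported dialect."""


def read_localizations(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read a localization table from CSV.

    Supported dialects: ``"thunderstorm"`` (columns ``frame, "x [nm]",
    "y [nm]", "intensity [photon]", "uncertainty [nm]"``) and
    ``"minimal"`` (bare ``x, y``, assumed nm).  ``"auto"`` picks from the
    header.  Unknown extra columns are ignored with a logged warning.
    Missing x/y columns raise :class:`FormatError` listing the columns
    actually found.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if dialect == "auto":
        dialect = "thunderstorm" if "x [nm]" in cols or "y [nm]" in cols else "minimal"

    if dialect == "thunderstorm":
        mapping = {c: THUNDERSTORM_MAP[c] for c in cols if c in THUNDERSTORM_MAP}
        missing = {"x", "y"} - set(mapping.values())
        if missing:
            raise FormatError(
                f"missing mandatory column(s) {sorted(missing)}; found columns: {cols}"
            )
        extra = [c for c in cols if c not in THUNDERSTORM_MAP]
        if extra:
            logger.warning("ignoring unknown columns: %s", extra)
        df = df[list(mapping)].rename(columns=mapping)
    elif dialect == "minimal":
        missing = {"x", "y"} - set(cols)
        if missing:
            raise FormatError(
                f"missing mandatory column(s) {sorted(missing)}; found columns: {cols}"
            )
        extra = [c for c in cols if c not in LOC_COLUMNS]
        if extra:
            logger.warning("ignoring unknown columns: %s", extra)
        df = df[[c for c in cols if c in LOC_COLUMNS]]
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    out = pd.DataFrame(
        {
            "frame": df.get("frame", pd.Series(np.zeros(len(df), dtype=np.int64))),
            "x": df["x"].astype(float),
            "y": df["y"].astype(float),
            "intensity": df.get("intensity", pd.Series(np.ones(len(df)))).astype(float),
            "uncertainty": df.get(
                "uncertainty", pd.Series(np.full(len(df), np.nan))
            ).astype(float),
        }
    )
    if not np.all(np.isfinite(out[["x", "y"]].to_numpy())):
        raise FormatError("non-finite x/y coordinates in localization table")
    return out


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table as ThunderSTORM-style CSV."""
    with open(path, "w", newline="") as fh:
        fh.write(_THUNDERSTORM_HEADER + "\n")
        writer = csv.writer(fh, quoting=csv.QUOTE_NONE)
        for row in table.itertuples(index=False):
            writer.writerow(
                [
                    int(row.frame),
                    repr(float(row.x)),
                    repr(float(row.y)),
                    repr(float(row.intensity)),
                    repr(float(row.uncertainty)),
                ]
            )


@dataclass(frozen=True)
class ReconstructedImage:
    """2D localization-count histogram.

    ``counts[i, j]`` is the number of localizations in the half-open pixel
    ``[origin + j*px, origin + (j+1)*px)`` in x and likewise row ``i`` in
    y.  ``origin`` is the nm offset of the corner of pixel (0, 0).
    """

    counts: np.ndarray  # (ny, nx) int
    pixel_size: float  # nm
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) nm

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def render_histogram_image(
    locs: pd.DataFrame,
    pixel_size: float,
    origin: tuple[float, float] = (0.0, 0.0),
    shape: tuple[int, int] | None = None,
) -> ReconstructedImage:
    """Render a localization table as a 2D count histogram.

    Pixel index = ``floor((coord - origin) / pixel_size)``; bins are
    half-open, so the sum of counts equals the number of localizations
    inside the grid extent.  ``shape`` is (ny, nx); when omitted it is
    derived from the data so every localization is in-extent.  An empty
    table yields an all-zero image.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    x = locs["x"].to_numpy(dtype=float)
    y = locs["y"].to_numpy(dtype=float)
    ox, oy = origin
    ix = np.floor((x - ox) / pixel_size).astype(np.int64)
    iy = np.floor((y - oy) / pixel_size).astype(np.int64)
    if shape is None:
        if len(x) == 0:
            shape = (1, 1)
        else:
            if ix.min() < 0 or iy.min() < 0:
                raise ValueError("localizations left/above the origin; pass shape")
            shape = (int(iy.max()) + 1, int(ix.max()) + 1)
    ny, nx = shape
    keep = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    counts = np.bincount(iy[keep] * nx + ix[keep], minlength=ny * nx).reshape(ny, nx)
    return ReconstructedImage(counts=counts, pixel_size=float(pixel_size), origin=(float(ox), float(oy)))


def rotate_localizations(
    locs: pd.DataFrame, angle: float, center: tuple[float, float] = (0.0, 0.0)
) -> pd.DataFrame:
    """Rigidly rotate localization coordinates about ``center``.

    ``angle`` is in radians, rotating +x towards +y (image convention).
    All non-coordinate columns are preserved unchanged.
    """
    cx, cy = center
    c, s = np.cos(angle), np.sin(angle)
    x = locs["x"].to_numpy(dtype=float) - cx
    y = locs["y"].to_numpy(dtype=float) - cy
    out = locs.copy()
    out["x"] = cx + c * x - s * y
    out["y"] = cy + s * x + c * y
    return out


def write_image_tiff(image: ReconstructedImage, path: str | Path) -> None:
    """Write the count image as 16-bit TIFF with the pixel size in metadata."""
    import tifffile

    data = np.clip(image.counts, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={"pixel_size_nm": image.pixel_size, "origin_nm": list(image.origin)},
    )
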