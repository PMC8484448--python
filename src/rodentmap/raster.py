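"""Lightweight georeferenced raster containers.

All rasters use a top-left origin with row-major, 0-based indexing. Map
coordinates are continuous; the centre of pixel (row, col) sits at
``(origin_x + (col + 0.5) * pixel_size, origin_y - (row + 0.5) * pixel_size)``
with y decreasing downwards, matching the north-up convention of aerial
orthomosaics. Float rasters mark nodata with NaN; categorical rasters use an
explicit nodata code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "GridTransform",
    "Raster",
    "SceneRaster",
    "NDVIRaster",
    "ChangeRaster",
    "HabitatMap",
    "BANDS",
]

#: Band order of the multispectral sensor: green, red, red-edge, near-infrared.
BANDS = ("G", "R", "RE", "NIR")


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference of an axis-aligned, square-pixel grid.

    Parameters
    ----------
    origin_x, origin_y
        Map coordinates (m) of the outer corner of pixel (0, 0) — the
        top-left corner of the raster.
    pixel_size
        Side length of a pixel in metres. Must be positive.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 0.12

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of all pixel centres, each shaped ``shape``."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        x = self.origin_x + (cols + 0.5) * self.pixel_size
        y = self.origin_y - (rows + 0.5) * self.pixel_size
        return x, y

    def index_of(self, x, y):
        """Fractional (row, col) grid position of map coordinates."""
        col = (np.asarray(x, float) - self.origin_x) / self.pixel_size
        row = (self.origin_y - np.asarray(y, float)) / self.pixel_size
        return row, col

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.origin_x,
            self.origin_y - shape[0] * self.pixel_size,
            self.origin_x + shape[1] * self.pixel_size,
            self.origin_y,
        )


def _check_same_grid(a: "Raster", b: "Raster", hint: str = "") -> None:
    if a.shape != b.shape or a.transform != b.transform:
        msg = (
            f"rasters are not on a common grid: shapes {a.shape} vs {b.shape}, "
            f"transforms {a.transform} vs {b.transform}"
        )
        if hint:
            msg += f"; {hint}"
        raise ValueError(msg)


@dataclass
class Raster:
    """A single-band float raster with NaN nodata."""

    values: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected 2-D values, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the pixel holds valid data."""
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SceneRaster:
    """One year's multiband reflectance scene (bands G, R, RE, NIR).

    Reflectances are unitless in [0, 1]; NaN marks nodata. All bands share
    one grid and one transform.
    """

    bands: np.ndarray  # (4, H, W) float, order BANDS
    transform: GridTransform = field(default_factory=GridTransform)
    year: int | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(BANDS):
            raise ValueError(
                f"bands must be ({len(BANDS)}, H, W) in order {BANDS}, "
                f"got shape {self.bands.shape}"
            )
        valid = self.bands[np.isfinite(self.bands)]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError("reflectance values must lie in [0, 1] or be nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]  # type: ignore[return-value]

    def band(self, name: str) -> np.ndarray:
        return self.bands[BANDS.index(name)]

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.bands).all(axis=0)


@dataclass
class NDVIRaster(Raster):
    """NDVI = (NIR - R) / (NIR + R), unitless in [-1, 1]; NaN nodata."""

    year: int | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        valid = self.values[np.isfinite(self.values)]
        if valid.size and (np.abs(valid) > 1 + 1e-12).any():
            raise ValueError("NDVI values must lie in [-1, 1] where not nodata")


@dataclass
class ChangeRaster(Raster):
    """Per-pixel NDVI change, year1 - year0; browning is negative."""

    def __post_init__(self) -> None:
        super().__post_init__()
        valid = self.values[np.isfinite(self.values)]
        if valid.size and (np.abs(valid) > 2 + 1e-12).any():
            raise ValueError("dNDVI must lie in [-2, 2]")


@dataclass
class HabitatMap:
    """Categorical land-cover raster with a code -> class-name legend."""

    codes: np.ndarray  # integer raster; NODATA_CODE marks nodata
    legend: Mapping[int, str]
    transform: GridTransform = field(default_factory=GridTransform)
    water_name: str = "water"
    provenance: str = ""

    NODATA_CODE = 255

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("habitat codes must be a 2-D raster")
        self.legend = dict(self.legend)
        present = set(np.unique(self.codes)) - {self.NODATA_CODE}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"codes {sorted(unknown)} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        return self.codes != self.NODATA_CODE

    def code_of(self, name: str) -> int:
        for code, cls in self.legend.items():
            if cls == name:
                return code
        raise KeyError(f"class {name!r} not in legend {self.legend}")

    @property
    def water_code(self) -> int | None:
        try:
            return self.code_of(self.water_name)
        except KeyError:
            return None

    def class_mask(self, name: str) -> np.ndarray:
        return self.codes == self.code_of(name)
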