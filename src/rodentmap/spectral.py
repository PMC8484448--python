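"""NDVI extraction and nearest-neighbour co-registration of paired-year rasters."""

from __future__ import annotations

import numpy as np

from .raster import GridTransform, NDVIRaster, SceneRaster

__all__ = ["compute_ndvi", "coregister_nearest"]


def compute_ndvi(scene: SceneRaster) -> NDVIRaster:
    """Normalized difference vegetation index, (NIR - R) / (NIR + R).

    Pixels where NIR + R = 0 or any input band is nodata become nodata.
    """
    nir = scene.band("NIR")
    red = scene.band("R")
    if nir.shape != red.shape:
        raise ValueError(f"band shape mismatch: NIR {nir.shape} vs R {red.shape}")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / denom, np.nan)
    ndvi = np.where(np.isfinite(nir) & np.isfinite(red), ndvi, np.nan)
    return NDVIRaster(values=ndvi, transform=scene.transform, year=scene.year)


def coregister_nearest(source: NDVIRaster, target: NDVIRaster) -> NDVIRaster:
    """Resample ``source`` onto ``target``'s grid by nearest pixel centre.

    Each target pixel takes the value of the source pixel whose centre is
    nearest to the target pixel's centre; half-pixel ties resolve toward the
    lower index. Target cells whose nearest source centre falls outside the
    source raster become nodata. Extents must overlap.
    """
    sxmin, symin, sxmax, symax = source.transform.bounds(source.shape)
    txmin, tymin, txmax, tymax = target.transform.bounds(target.shape)
    if sxmax <= txmin or txmax <= sxmin or symax <= tymin or tymax <= symin:
        raise ValueError("source and target extents are disjoint; cannot coregister")

    tx, ty = target.transform.pixel_centers(target.shape)
    frow, fcol = source.transform.index_of(tx, ty)
    # Nearest centre: centre of pixel i lies at fractional index i + 0.5.
    # ceil(u - 1) is the nearest-centre index with exact ties going to the
    # lower index.
    rows = np.ceil(frow - 1.0).astype(int)
    cols = np.ceil(fcol - 1.0).astype(int)
    inside = (
        (rows >= 0) & (rows < source.shape[0]) & (cols >= 0) & (cols < source.shape[1])
    )
    out = np.full(target.shape, np.nan)
    out[inside] = source.values[rows[inside], cols[inside]]
    return NDVIRaster(values=out, transform=target.transform, year=source.year)
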