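"""File interchange: TIFF rasters with georeference metadata carried as JSON
in the image description tag, GeoJSON vectors, and YAML run configuration.

Raster layout on disk: float rasters are float32 with nodata written as
-9999; categorical rasters are uint8 with 255 nodata. The description tag
holds ``{"transform": {origin_x, origin_y, pixel_size}, ...}`` plus
type-specific keys (year, band order, legend).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .raster import (
    BANDS,
    ChangeRaster,
    GridTransform,
    HabitatMap,
    NDVIRaster,
    Raster,
    SceneRaster,
)
from .synthetic_scenes import HabitatClass, ImpactTruth, SimConfig

NODATA_FLOAT = -9999.0

__all__ = [
    "write_scene", "read_scene",
    "write_ndvi", "read_ndvi",
    "write_change", "read_change",
    "write_habitat_map", "read_habitat_map",
    "write_truth", "read_truth",
    "write_impact_mask", "read_impact_mask",
    "write_plots_geojson", "read_plots_geojson",
    "load_config", "save_config",
]


def _meta(transform: GridTransform, **extra) -> str:
    return json.dumps({"transform": dataclasses.asdict(transform), **extra})


def _read(path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or "{}"
    return data, json.loads(desc)


def _transform_of(meta: dict) -> GridTransform:
    return GridTransform(**meta.get("transform", {}))


def write_scene(path, scene: SceneRaster) -> None:
    data = np.where(np.isfinite(scene.bands), scene.bands, NODATA_FLOAT)
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        photometric="minisblack",
        description=_meta(
            scene.transform, kind="scene", year=scene.year, bands=list(BANDS),
            nodata=NODATA_FLOAT,
        ),
    )


def read_scene(path) -> SceneRaster:
    data, meta = _read(path)
    bands = np.where(data == NODATA_FLOAT, np.nan, data.astype(float))
    return SceneRaster(bands=bands, transform=_transform_of(meta),
                       year=meta.get("year"))


def _write_float(path, raster: Raster, kind: str, **extra) -> None:
    data = np.where(np.isfinite(raster.values), raster.values, NODATA_FLOAT)
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        description=_meta(raster.transform, kind=kind, nodata=NODATA_FLOAT, **extra),
    )


def write_ndvi(path, ndvi: NDVIRaster) -> None:
    _write_float(path, ndvi, "ndvi", year=ndvi.year)


def read_ndvi(path) -> NDVIRaster:
    data, meta = _read(path)
    vals = np.where(data == NODATA_FLOAT, np.nan, data.astype(float))
    return NDVIRaster(values=vals, transform=_transform_of(meta), year=meta.get("year"))


def write_change(path, change: ChangeRaster) -> None:
    _write_float(path, change, "dndvi")


def read_change(path) -> ChangeRaster:
    data, meta = _read(path)
    vals = np.where(data == NODATA_FLOAT, np.nan, data.astype(float))
    return ChangeRaster(values=vals, transform=_transform_of(meta))


def write_habitat_map(path, habitats: HabitatMap) -> None:
    """uint8 class raster; the legend also goes to a JSON sidecar next to the
    TIFF for tools that cannot read the description tag."""
    path = Path(path)
    legend = {str(k): v for k, v in habitats.legend.items()}
    tifffile.imwrite(
        path,
        habitats.codes.astype(np.uint8),
        description=_meta(
            habitats.transform, kind="habitats", legend=legend,
            water_name=habitats.water_name, nodata=HabitatMap.NODATA_CODE,
        ),
    )
    path.with_suffix(".legend.json").write_text(json.dumps(legend, indent=2))


def read_habitat_map(path) -> HabitatMap:
    data, meta = _read(path)
    legend = {int(k): v for k, v in meta.get("legend", {}).items()}
    return HabitatMap(
        codes=data, legend=legend, transform=_transform_of(meta),
        water_name=meta.get("water_name", "water"),
    )


def write_truth(path, truth: ImpactTruth) -> None:
    """Two-band TIFF: uint8 labels and float32 intensity."""
    tifffile.imwrite(
        Path(path),
        truth.labels.astype(np.uint8),
        description=_meta(truth.transform, kind="truth_labels"),
    )
    ipath = Path(path).with_suffix(".intensity.tif")
    tifffile.imwrite(
        ipath,
        truth.intensity.astype(np.float32),
        description=_meta(truth.transform, kind="truth_intensity"),
    )


def read_truth(path) -> ImpactTruth:
    labels, meta = _read(path)
    intensity, _ = _read(Path(path).with_suffix(".intensity.tif"))
    return ImpactTruth(
        labels=labels, intensity=intensity.astype(float),
        transform=_transform_of(meta),
    )


def write_impact_mask(path, impacted: np.ndarray, transform: GridTransform,
                      scenario: str = "") -> None:
    tifffile.imwrite(
        path,
        np.asarray(impacted, dtype=np.uint8),
        description=_meta(transform, kind="impact", scenario=scenario),
    )


def read_impact_mask(path) -> tuple[np.ndarray, GridTransform, str]:
    data, meta = _read(path)
    return data.astype(bool), _transform_of(meta), meta.get("scenario", "")


def write_plots_geojson(path, plots) -> None:
    """Ground plots as GeoJSON features: footprint geometry plus role,
    habitat, score and the flattened quadrant flag matrix in properties."""
    from .ground_truth import score_plot

    features = []
    for p in plots:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.footprint),
                "properties": {
                    "role": p.role,
                    "habitat": p.habitat,
                    "score": score_plot(p),
                    "flags_shape": list(p.flags.shape),
                    "flags": p.flags.astype(int).ravel().tolist(),
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_plots_geojson(path):
    from .ground_truth import GroundPlot

    doc = json.loads(Path(path).read_text())
    plots = []
    for feat in doc["features"]:
        props = feat["properties"]
        flags = np.array(props["flags"], dtype=bool).reshape(props["flags_shape"])
        plots.append(
            GroundPlot(
                footprint=shape(feat["geometry"]),
                flags=flags,
                role=props.get("role", "impacted"),
                habitat=props.get("habitat", ""),
            )
        )
    return plots


def save_config(path, cfg: SimConfig) -> None:
    d = dataclasses.asdict(cfg)
    d["class_levels"] = [dataclasses.asdict(c) for c in cfg.class_levels]
    Path(path).write_text(yaml.safe_dump(_plain(d), sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_config(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "class_levels" in d and d["class_levels"]:
        d["class_levels"] = [
            HabitatClass(**{**c, "reflectance": tuple(c["reflectance"])})
            for c in d["class_levels"]
        ]
    for key in ("nest_diameter_range", "runway_length_range",
                "thinning_radius_range", "impact_mix", "coreg_shift"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimConfig(**d)
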