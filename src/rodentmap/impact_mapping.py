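"""Threshold-based mapping of rodent impact from paired-year NDVI change.

Impact is mapped per pixel as dNDVI = NDVI(year 1) - NDVI(year 0) falling at
or below a negative threshold, with habitat classes judged artefact-prone
masked out. Three scenarios — best estimate, minimum, maximum — bracket the
mapped impact by varying the threshold within the plausible band
(-0.10 to -0.04 NDVI) and the breadth of the habitat mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import ChangeRaster, GridTransform, HabitatMap, NDVIRaster, _check_same_grid

__all__ = [
    "ScenarioConfig",
    "ImpactMap",
    "ndvi_change",
    "map_impact",
    "impact_fraction",
    "run_scenarios",
    "default_scenarios",
]

_THRESHOLD_BAND = (-0.10, -0.04)


@dataclass(frozen=True)
class ScenarioConfig:
    """A (threshold, habitat-mask) pair defining one impact scenario.

    ``threshold`` is in NDVI units and must be negative (impact is a
    reduction); ``masked_classes`` are habitat names excluded from mapping,
    always including water.
    """

    name: str
    threshold: float
    masked_classes: frozenset[str] = field(default_factory=lambda: frozenset({"water"}))

    def __post_init__(self) -> None:
        if self.threshold >= 0:
            raise ValueError(
                f"scenario {self.name!r}: threshold must be a negative NDVI "
                f"change, got {self.threshold}"
            )
        if not _THRESHOLD_BAND[0] <= self.threshold <= _THRESHOLD_BAND[1]:
            raise ValueError(
                f"scenario {self.name!r}: threshold {self.threshold} outside the "
                f"plausible band {_THRESHOLD_BAND}"
            )
        if "water" not in self.masked_classes:
            object.__setattr__(
                self, "masked_classes", frozenset(self.masked_classes) | {"water"}
            )


def default_scenarios() -> dict[str, ScenarioConfig]:
    """Best estimate at the mid-band threshold; minimum at the strictest
    threshold with artefact-prone classes also masked (canopy occlusion in
    birch forest; surface-moisture and melt-timing variability in wetland,
    snowbed and meadow); maximum at the most permissive threshold, masking
    only water."""
    return {
        "best": ScenarioConfig("best", -0.07),
        "min": ScenarioConfig(
            "min",
            -0.10,
            frozenset({"water", "birch forest", "wetland", "snowbed", "meadow"}),
        ),
        "max": ScenarioConfig("max", -0.04),
    }


@dataclass
class ImpactMap:
    """Binary impact raster plus the scenario that produced it."""

    impacted: np.ndarray  # bool; True = mapped impact
    scenario: ScenarioConfig
    transform: GridTransform
    provenance: str = ""

    def __post_init__(self) -> None:
        self.impacted = np.asarray(self.impacted, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.impacted.shape  # type: ignore[return-value]


def ndvi_change(ndvi0: NDVIRaster, ndvi1: NDVIRaster) -> ChangeRaster:
    """dNDVI = year1 - year0 per pixel; negative = browning. Nodata in either
    year propagates. Grids must match (coregister first if they do not)."""
    _check_same_grid(ndvi0, ndvi1, hint="resample with spectral.coregister_nearest")
    return ChangeRaster(values=ndvi1.values - ndvi0.values, transform=ndvi0.transform)


def map_impact(
    change: ChangeRaster, habitats: HabitatMap, scenario: ScenarioConfig
) -> ImpactMap:
    """A pixel is impacted iff dNDVI <= threshold, its habitat is not masked,
    and neither input is nodata. The comparison is inclusive."""
    if change.shape != habitats.shape:
        raise ValueError(
            f"change {change.shape} and habitats {habitats.shape} grids differ"
        )
    masked = np.zeros(change.shape, dtype=bool)
    for name in scenario.masked_classes:
        try:
            masked |= habitats.class_mask(name)
        except KeyError:
            continue  # scenario may name classes absent from this legend
    with np.errstate(invalid="ignore"):
        impacted = (
            (change.values <= scenario.threshold)
            & ~masked
            & change.mask
            & habitats.mask
        )
    return ImpactMap(impacted=impacted, scenario=scenario, transform=change.transform)


def impact_fraction(impact: ImpactMap, habitats: HabitatMap) -> pd.DataFrame:
    """Impact fractions per habitat class and in total.

    The total row uses all non-nodata, non-water pixels as denominator;
    per-class rows use the class's own pixel count. ``area_share`` is the
    class share of the non-water area. Classes with no pixels get NaN
    fractions (undefined, not zero).
    """
    if impact.shape != habitats.shape:
        raise ValueError("impact map and habitat map grids differ")
    water = habitats.water_code
    land = habitats.mask.copy()
    if water is not None:
        land &= habitats.codes != water
    n_land = int(land.sum())
    rows = []
    for code, name in sorted(habitats.legend.items()):
        in_class = habitats.codes == code
        n_class = int(in_class.sum())
        n_hit = int((impact.impacted & in_class).sum())
        rows.append(
            {
                "class": name,
                "pixels": n_class,
                "area_share": n_class / n_land if (n_land and code != water) else np.nan,
                "fraction": n_hit / n_class if n_class else np.nan,
            }
        )
    n_total = int((impact.impacted & land).sum())
    rows.append(
        {
            "class": "__total__",
            "pixels": n_land,
            "area_share": 1.0,
            "fraction": n_total / n_land if n_land else np.nan,
        }
    )
    return pd.DataFrame(rows)


def total_fraction(impact: ImpactMap, habitats: HabitatMap) -> float:
    """Impacted share of the non-water, non-nodata area."""
    df = impact_fraction(impact, habitats)
    return float(df.loc[df["class"] == "__total__", "fraction"].iloc[0])


def run_scenarios(
    change: ChangeRaster,
    habitats: HabitatMap,
    scenarios: dict[str, ScenarioConfig] | None = None,
) -> dict[str, dict]:
    """Run the best/min/max scenario set and check the bracketing contract.

    Scenarios must be ordered: |threshold(max)| <= |threshold(best)| <=
    |threshold(min)| and masks nested (max's mask within best's within
    min's). The returned fractions then satisfy min <= best <= max.
    """
    scenarios = scenarios if scenarios is not None else default_scenarios()
    for key in ("best", "min", "max"):
        if key not in scenarios:
            raise ValueError(f"scenario set must contain {key!r}")
    s = scenarios
    if not (
        abs(s["max"].threshold) <= abs(s["best"].threshold) <= abs(s["min"].threshold)
    ):
        raise ValueError("scenario thresholds violate |max| <= |best| <= |min|")
    if not (
        s["max"].masked_classes <= s["best"].masked_classes <= s["min"].masked_classes
    ):
        raise ValueError("scenario masks must be nested: max <= best <= min")
    out: dict[str, dict] = {}
    for key in ("best", "min", "max"):
        imap = map_impact(change, habitats, s[key])
        out[key] = {
            "impact_map": imap,
            "fractions": impact_fraction(imap, habitats),
            "total_fraction": total_fraction(imap, habitats),
        }
    if not (
        out["min"]["total_fraction"]
        <= out["best"]["total_fraction"]
        <= out["max"]["total_fraction"]
    ):
        raise AssertionError("scenario bracketing violated: min <= best <= max failed")
    return out
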