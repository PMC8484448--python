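"""Synthetic paired-year tundra scenes with known rodent-impact truth.

The generator emulates the inputs of a UAV herbivory-change survey: a
heterogeneous Arctic land-cover mosaic (heath, shrub, snowbed, wetland,
meadow, forest, barren, water), a baseline-summer multispectral scene, and a
following-summer scene in which rodent activity has removed vegetation in
three morphologies — cleared circular patches at nests (0.3–1 m diameter),
narrow linear runways, and diffuse thinning over larger areas — each
lowering NDVI in proportion to the fraction of vegetation removed. Sensor
nuisances (band noise, illumination drift between flights, a few pixels of
residual co-registration error) are applied on top so that the detection
pipeline can be exercised under realistic artefact conditions.

Every stage draws from a generator seeded from ``SimConfig.seed``, so a
given configuration reproduces bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .fields import smoothed_gaussian_field
from .raster import BANDS, GridTransform, HabitatMap, SceneRaster

__all__ = [
    "HabitatClass",
    "SimConfig",
    "ImpactTruth",
    "simulate_habitats",
    "simulate_covariates",
    "simulate_impact",
    "render_scene_pair",
    "LABEL_NONE",
    "LABEL_NEST",
    "LABEL_RUNWAY",
    "LABEL_THINNING",
]

LABEL_NONE, LABEL_NEST, LABEL_RUNWAY, LABEL_THINNING = 0, 1, 2, 3
LABEL_NAMES = {
    LABEL_NONE: "none",
    LABEL_NEST: "nest",
    LABEL_RUNWAY: "runway",
    LABEL_THINNING: "thinning",
}


@dataclass(frozen=True)
class HabitatClass:
    """One land-cover class with its spectral baseline and rodent susceptibility.

    ``reflectance`` is the (G, R, RE, NIR) baseline; ``ndvi_mean``/``ndvi_sd``
    set the within-class NDVI distribution (the R and NIR bands are rendered
    from the NDVI field at constant class brightness R + NIR);
    ``susceptibility`` weights where impact can occur (0 = never impacted);
    ``proportion`` is the target areal share.
    """

    name: str
    reflectance: tuple[float, float, float, float]
    ndvi_mean: float
    ndvi_sd: float
    susceptibility: float
    proportion: float

    def __post_init__(self) -> None:
        if any(not (0.0 <= r <= 1.0) for r in self.reflectance):
            raise ValueError(f"{self.name}: reflectances must lie in [0, 1]")
        if self.proportion <= 0:
            raise ValueError(f"{self.name}: proportion must be positive")

    @property
    def brightness(self) -> float:
        """R + NIR, held constant while NDVI varies within the class."""
        return self.reflectance[1] + self.reflectance[3]


def _baseline(name, ndvi, brightness, g, re_edge, susceptibility, proportion):
    r = brightness * (1 - ndvi) / 2
    nir = brightness * (1 + ndvi) / 2
    return HabitatClass(name, (g, r, re_edge, nir), ndvi, 0.05, susceptibility, proportion)


def default_class_levels() -> list[HabitatClass]:
    """Eight tundra land-cover classes with plausible peak-season spectra."""
    return [
        _baseline("dry heath", 0.55, 0.45, 0.06, 0.25, 0.6, 0.18),
        _baseline("mesic heath", 0.65, 0.45, 0.05, 0.27, 1.0, 0.22),
        _baseline("willow shrub", 0.70, 0.50, 0.05, 0.30, 0.8, 0.12),
        _baseline("snowbed", 0.45, 0.40, 0.07, 0.22, 0.8, 0.08),
        _baseline("wetland", 0.60, 0.35, 0.05, 0.22, 0.7, 0.10),
        _baseline("meadow", 0.68, 0.48, 0.07, 0.30, 0.3, 0.10),
        _baseline("birch forest", 0.72, 0.42, 0.04, 0.26, 0.5, 0.10),
        _baseline("barren", 0.10, 0.50, 0.20, 0.28, 0.0, 0.05),
        _baseline("water", -0.30, 0.10, 0.04, 0.05, 0.0, 0.05),
    ]


@dataclass
class SimConfig:
    """Study conditions for one synthetic scene pair.

    Lengths are metres; reflectances unitless in [0, 1]. The defaults follow
    the surveyed system: ~0.12 m ground resolution, nest patches 0.3–1 m
    across, residual co-registration error of about 2 px.
    """

    grid_size: int = 256
    pixel_size: float = 0.12
    habitat_field_range: float = 6.0
    class_levels: Sequence[HabitatClass] = field(default_factory=default_class_levels)
    impact_fraction_target: float = 0.10
    nest_diameter_range: tuple[float, float] = (0.3, 1.0)
    runway_width: float = 0.15
    runway_step: int = 2
    runway_persistence: float = 0.85
    runway_length_range: tuple[float, float] = (2.0, 10.0)
    thinning_radius_range: tuple[float, float] = (0.8, 2.5)
    thinning_intensity: float = 0.5
    impact_mix: tuple[float, float, float] = (0.3, 0.3, 0.4)  # nest/runway/thinning
    ndvi_depression: float = 0.3
    ndvi_field_range: float = 2.0
    noise_sd: float = 0.005
    illumination_gain: float = 0.98
    illumination_offset: float = 0.002
    coreg_shift: tuple[float, float] = (1.2, -1.6)  # (dx, dy) pixels, |shift| = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.impact_fraction_target <= 1.0:
            raise ValueError("impact_fraction_target must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.nest_diameter_range[0] > self.nest_diameter_range[1]:
            raise ValueError("nest_diameter_range must be (low, high)")
        if not 0.3 <= self.nest_diameter_range[0] <= self.nest_diameter_range[1] <= 1.0:
            raise ValueError("nest diameters must stay within 0.3–1.0 m")
        if len(self.class_levels) < 2:
            raise ValueError("need at least two habitat class levels")
        if self.habitat_field_range < 0:
            raise ValueError("habitat_field_range must be >= 0")
        if not np.isclose(sum(self.impact_mix), 1.0):
            raise ValueError("impact_mix must sum to 1")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, self.grid_size * self.pixel_size, self.pixel_size)

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed generator so each pipeline stage has an independent,
        reproducible stream derived from the one configured seed."""
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class ImpactTruth:
    """Per-pixel impact truth: morphology label and fractional vegetation removal.

    ``labels`` is 0 = none, 1 = nest, 2 = runway, 3 = thinning; ``intensity``
    is the removed vegetation fraction in [0, 1] (positive exactly where the
    label is non-zero).
    """

    labels: np.ndarray
    intensity: np.ndarray
    transform: GridTransform

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.labels.shape != self.intensity.shape:
            raise ValueError("labels and intensity must share one grid")
        if ((self.labels != LABEL_NONE) != (self.intensity > 0)).any():
            raise ValueError("label != none must coincide with intensity > 0")
        if (self.intensity < 0).any() or (self.intensity > 1).any():
            raise ValueError("intensity must lie in [0, 1]")

    @property
    def impacted(self) -> np.ndarray:
        return self.labels != LABEL_NONE

    def fraction(self, habitats: HabitatMap) -> float:
        """Truth impact fraction over non-water, non-nodata pixels."""
        denom = habitats.mask.copy()
        water = habitats.water_code
        if water is not None:
            denom &= habitats.codes != water
        return float(self.impacted[denom].sum() / denom.sum())


def simulate_habitats(cfg: SimConfig, rng: np.random.Generator | None = None) -> HabitatMap:
    """Draw a categorical habitat mosaic by quantile-thresholding a smoothed
    Gaussian random field into the configured class proportions.

    A zero ``habitat_field_range`` disables smoothing and yields spatially
    independent labels with the same class frequencies.
    """
    rng = rng if rng is not None else cfg.rng(0)
    shape = (cfg.grid_size, cfg.grid_size)
    sigma_px = cfg.habitat_field_range / cfg.pixel_size
    z = smoothed_gaussian_field(shape, sigma_px, rng)
    props = np.array([c.proportion for c in cfg.class_levels], dtype=float)
    props = props / props.sum()
    cuts = np.quantile(z, np.cumsum(props)[:-1])
    codes = np.searchsorted(cuts, z, side="left").astype(np.uint8)
    legend = {i: c.name for i, c in enumerate(cfg.class_levels)}
    return HabitatMap(codes=codes, legend=legend, transform=cfg.transform,
                      provenance=f"simulated seed={cfg.seed}")


def simulate_covariates(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Smooth nuisance fields standing in for the topographic covariates of a
    real survey (elevation, wetness index, vegetation height)."""
    rng = rng if rng is not None else cfg.rng(3)
    shape = (cfg.grid_size, cfg.grid_size)
    sigma = max(cfg.habitat_field_range / cfg.pixel_size, 1.0)
    return {
        "elevation": smoothed_gaussian_field(shape, 2 * sigma, rng),
        "wetness": smoothed_gaussian_field(shape, sigma, rng),
        "veg_height": smoothed_gaussian_field(shape, sigma / 2, rng),
    }


def _disc(center: tuple[int, int], radius_px: float, shape) -> tuple[np.ndarray, np.ndarray]:
    return skdraw.disk(center, max(radius_px, 0.51), shape=shape)


class _Painter:
    """Accumulates impact elements onto label/intensity rasters, keeping the
    pixel order of each element so overshoot past the target can be trimmed
    from the element's rim inward (the element stays contiguous)."""

    def __init__(self, shape, susceptible: np.ndarray):
        self.labels = np.zeros(shape, dtype=np.uint8)
        self.intensity = np.zeros(shape, dtype=float)
        self.susceptible = susceptible
        self.count = 0

    def paint(self, rows, cols, label, intensity, center) -> None:
        keep = self.susceptible[rows, cols] & (self.labels[rows, cols] == LABEL_NONE)
        rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            return
        # remember rim-first trim order for the last element
        d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
        order = np.argsort(-d2, kind="stable")
        self._last = (rows[order], cols[order])
        self.labels[rows, cols] = label
        self.intensity[rows, cols] = intensity
        self.count += rows.size

    def trim_to(self, target: int) -> None:
        excess = self.count - target
        if excess <= 0:
            return
        rows, cols = self._last
        rows, cols = rows[:excess], cols[:excess]
        self.labels[rows, cols] = LABEL_NONE
        self.intensity[rows, cols] = 0.0
        self.count -= excess


def simulate_impact(
    habitats: HabitatMap, cfg: SimConfig, rng: np.random.Generator | None = None
) -> ImpactTruth:
    """Place nests (discs), runways (correlated random walks from nests) and
    thinning patches (elliptical blobs) on susceptible habitat until the
    realized impacted-pixel count reaches the configured target fraction of
    the non-water area.

    The element stream is independent of the target, so raising the target
    only extends the same sequence of elements (realized impact is monotone
    in the target). The final element is trimmed rim-inward so the realized
    count matches the target exactly.
    """
    rng = rng if rng is not None else cfg.rng(1)
    shape = habitats.shape
    ps = cfg.pixel_size
    susc_by_code = {i: c.susceptibility for i, c in enumerate(cfg.class_levels)}
    susceptible = np.zeros(shape, dtype=bool)
    for code, w in susc_by_code.items():
        if w > 0:
            susceptible |= habitats.codes == code

    water = habitats.water_code
    denom = habitats.mask.copy()
    if water is not None:
        denom &= habitats.codes != water
    target = int(round(cfg.impact_fraction_target * denom.sum()))

    painter = _Painter(shape, susceptible)
    if target == 0:
        return ImpactTruth(painter.labels, painter.intensity, habitats.transform)
    n_susc = int(susceptible.sum())
    if n_susc == 0:
        raise ValueError(
            "impact_fraction_target > 0 but no habitat class is susceptible"
        )
    if target > 0.9 * n_susc:
        raise ValueError(
            f"impact_fraction_target needs {target} px but only {n_susc} susceptible "
            f"px exist (shortfall {target - int(0.9 * n_susc)} px at 90% occupancy)"
        )

    susc_rows, susc_cols = np.nonzero(susceptible)
    weights = np.array([susc_by_code[c] for c in habitats.codes[susc_rows, susc_cols]])
    weights = weights / weights.sum()
    mix = np.cumsum(cfg.impact_mix)
    nest_centers: list[tuple[int, int]] = []
    runway_halfwidth = max(int(round(cfg.runway_width / ps / 2)), 0)
    max_iter = 100 * (1 + target)

    def random_susceptible_pixel():
        k = rng.choice(susc_rows.size, p=weights)
        return int(susc_rows[k]), int(susc_cols[k])

    def add_nest():
        center = random_susceptible_pixel()
        diam = rng.uniform(*cfg.nest_diameter_range)
        rr, cc = _disc(center, diam / 2 / ps, shape)
        painter.paint(rr, cc, LABEL_NEST, 1.0, center)
        nest_centers.append(center)

    def add_runway():
        if not nest_centers:
            add_nest()
            if painter.count >= target:
                return
        start = nest_centers[rng.integers(len(nest_centers))]
        length_px = rng.uniform(*cfg.runway_length_range) / ps
        n_steps = max(int(length_px / max(cfg.runway_step, 1)), 1)
        heading = rng.uniform(0, 2 * np.pi)
        turn_sd = (1.0 - cfg.runway_persistence) * np.pi
        pts = [start]
        r, c = float(start[0]), float(start[1])
        for _ in range(n_steps):
            heading += rng.normal(0.0, turn_sd)
            r += cfg.runway_step * np.sin(heading)
            c += cfg.runway_step * np.cos(heading)
            pts.append((int(round(r)), int(round(c))))
        path = np.zeros(shape, dtype=bool)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = skdraw.line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            path[rr[ok], cc[ok]] = True
        if runway_halfwidth > 0:
            path = ndimage.binary_dilation(path, iterations=runway_halfwidth)
        rr, cc = np.nonzero(path)
        painter.paint(rr, cc, LABEL_RUNWAY, 1.0, start)

    def add_thinning():
        center = random_susceptible_pixel()
        r_a = rng.uniform(*cfg.thinning_radius_range) / ps
        r_b = r_a * rng.uniform(0.4, 1.0)
        rot = rng.uniform(0, np.pi)
        rr, cc = skdraw.ellipse(*center, r_a, r_b, shape=shape, rotation=rot)
        painter.paint(rr, cc, LABEL_THINNING, cfg.thinning_intensity, center)

    iters = 0
    while painter.count < target:
        iters += 1
        if iters > max_iter:
            raise RuntimeError(
                f"impact placement stalled at {painter.count}/{target} px"
            )
        u = rng.random()
        if u < mix[0]:
            add_nest()
        elif u < mix[1]:
            add_runway()
        else:
            add_thinning()
    painter.trim_to(target)
    return ImpactTruth(painter.labels, painter.intensity, habitats.transform)


def _render_bands(
    cfg: SimConfig, habitats: HabitatMap, ndvi: np.ndarray
) -> np.ndarray:
    """Bands from the NDVI field at constant per-class brightness R + NIR;
    G and RE take the class baselines."""
    shape = habitats.shape
    bands = np.zeros((len(BANDS),) + shape, dtype=float)
    for code, cls in enumerate(cfg.class_levels):
        m = habitats.codes == code
        s = cls.brightness
        bands[0][m] = cls.reflectance[0]
        bands[1][m] = s * (1.0 - ndvi[m]) / 2.0
        bands[2][m] = cls.reflectance[2]
        bands[3][m] = s * (1.0 + ndvi[m]) / 2.0
    return bands


def render_scene_pair(
    habitats: HabitatMap,
    truth: ImpactTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SceneRaster, SceneRaster]:
    """Render the baseline-year and impact-year scenes.

    The baseline NDVI field is the per-class mean plus a shared smooth
    anomaly field; impacted pixels of the second year lose
    ``ndvi_depression x intensity`` NDVI (vegetation removal browns the
    surface: NIR falls, R rises, at constant band sum). Band noise, an
    illumination gain/offset, and the residual co-registration shift are
    then applied to the second year; band noise to both. Out-of-range
    reflectances are clipped with a warning.
    """
    rng = rng if rng is not None else cfg.rng(2)
    if habitats.shape != truth.labels.shape:
        raise ValueError("habitats and truth must share one grid")
    shape = habitats.shape
    sigma_px = cfg.ndvi_field_range / cfg.pixel_size
    anomaly = smoothed_gaussian_field(shape, sigma_px, rng)
    ndvi0 = np.zeros(shape)
    for code, cls in enumerate(cfg.class_levels):
        m = habitats.codes == code
        ndvi0[m] = cls.ndvi_mean + cls.ndvi_sd * anomaly[m]
    ndvi0 = np.clip(ndvi0, -0.95, 0.95)
    ndvi1 = ndvi0 - cfg.ndvi_depression * truth.intensity

    bands0 = _render_bands(cfg, habitats, ndvi0)
    bands1 = _render_bands(cfg, habitats, ndvi1)

    if cfg.noise_sd > 0:
        bands0 = bands0 + rng.normal(0.0, cfg.noise_sd, bands0.shape)
        bands1 = bands1 + rng.normal(0.0, cfg.noise_sd, bands1.shape)
    bands1 = cfg.illumination_gain * bands1 + cfg.illumination_offset
    dx, dy = cfg.coreg_shift
    if dx != 0 or dy != 0:
        # content shift with unchanged georeference = residual misregistration
        bands1 = np.stack(
            [ndimage.shift(b, (dy, dx), order=1, mode="nearest") for b in bands1]
        )

    clipped = ((bands0 < 0) | (bands0 > 1) | (bands1 < 0) | (bands1 > 1)).sum()
    if clipped:
        warnings.warn(
            f"{clipped} band samples left [0, 1] after perturbation; clipped",
            stacklevel=2,
        )
        bands0 = np.clip(bands0, 0.0, 1.0)
        bands1 = np.clip(bands1, 0.0, 1.0)

    t = habitats.transform
    return (
        SceneRaster(bands=bands0, transform=t, year=2018),
        SceneRaster(bands=bands1, transform=t, year=2019),
    )
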