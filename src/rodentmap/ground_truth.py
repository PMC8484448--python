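"""Field-plot protocol for rodent impact, its synthetic survey simulator, and
the validation regression of plot scores against UAV-derived NDVI change.

The field protocol scores a 2 m x 2 m plot as a 20 x 20 grid of 0.1 m
quadrants (400 per plot). In each quadrant four impact categories — bite
marks, feces, runway, burrow — are flagged independently, one point each, so
a plot score ranges from 0 to 1600. Paired plots (one heavily impacted, one
control) are placed in representative habitats; validation regresses plot
score on the plot-mean dNDVI extracted from the imagery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from shapely.geometry import Polygon, box

from .raster import ChangeRaster, HabitatMap
from .synthetic_scenes import (
    LABEL_NEST,
    LABEL_NONE,
    LABEL_RUNWAY,
    LABEL_THINNING,
    ImpactTruth,
)

__all__ = [
    "CATEGORIES",
    "GroundPlot",
    "DetectionModel",
    "ValidationFit",
    "score_plot",
    "simulate_plot_survey",
    "place_plot_pairs",
    "extract_plot_change",
    "validate",
    "catch_rate",
]

CATEGORIES = ("bite_marks", "feces", "runway", "burrow")
PLOT_SIDE_M = 2.0
QUADRANT_M = 0.1
GRID_N = int(round(PLOT_SIDE_M / QUADRANT_M))  # 20


@dataclass
class GroundPlot:
    """One 2 m x 2 m field plot: footprint polygon plus the 20 x 20 x 4
    boolean quadrant-by-category flag grid."""

    footprint: Polygon
    flags: np.ndarray  # (20, 20, 4) bool
    role: str = "impacted"  # impacted | control
    habitat: str = ""

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.shape != (GRID_N, GRID_N, len(CATEGORIES)):
            raise ValueError(
                f"plot must hold {GRID_N}x{GRID_N} quadrants x {len(CATEGORIES)} "
                f"categories, got {self.flags.shape}"
            )
        if self.role not in ("impacted", "control"):
            raise ValueError(f"role must be impacted or control, got {self.role!r}")

    @property
    def n_quadrants(self) -> int:
        return self.flags.shape[0] * self.flags.shape[1]


def score_plot(plot: GroundPlot) -> int:
    """Plot impact score: one point per flagged category per quadrant,
    summed over the 400 quadrants (0..1600)."""
    if plot.n_quadrants != GRID_N * GRID_N:
        raise ValueError(f"expected {GRID_N * GRID_N} quadrants")
    return int(plot.flags.sum())


@dataclass(frozen=True)
class DetectionModel:
    """Probability that a field surveyor flags each category in a quadrant,
    given the underlying impact morphology there. The realised probability
    scales with the local removal intensity."""

    per_label: dict = field(
        default_factory=lambda: {
            LABEL_NEST: {"bite_marks": 0.7, "feces": 0.6, "runway": 0.3, "burrow": 0.9},
            LABEL_RUNWAY: {"bite_marks": 0.3, "feces": 0.4, "runway": 0.9, "burrow": 0.05},
            LABEL_THINNING: {"bite_marks": 0.6, "feces": 0.25, "runway": 0.05, "burrow": 0.0},
        }
    )

    def prob(self, label: int, category: str, intensity: float) -> float:
        if label == LABEL_NONE:
            return 0.0
        return self.per_label.get(label, {}).get(category, 0.0) * float(intensity)


def _quadrant_truth(truth: ImpactTruth, footprint: Polygon):
    """Majority truth label and mean intensity per 0.1 m quadrant."""
    minx, miny, maxx, maxy = footprint.bounds
    t = truth.transform
    labels = np.zeros((GRID_N, GRID_N), dtype=np.uint8)
    intensity = np.zeros((GRID_N, GRID_N))
    h, w = truth.labels.shape
    for qi in range(GRID_N):
        for qj in range(GRID_N):
            x0 = minx + qj * QUADRANT_M
            y1 = maxy - qi * QUADRANT_M
            # pixel indices overlapped by this quadrant (centre-based)
            r0, c0 = t.index_of(x0 + 1e-9, y1 - 1e-9)
            r1, c1 = t.index_of(x0 + QUADRANT_M - 1e-9, y1 - QUADRANT_M + 1e-9)
            rs, cs = int(np.floor(r0)), int(np.floor(c0))
            re, ce = int(np.floor(r1)) + 1, int(np.floor(c1)) + 1
            if rs < 0 or cs < 0 or re > h or ce > w:
                raise ValueError("plot footprint extends outside the truth raster")
            lab = truth.labels[rs:re, cs:ce]
            inten = truth.intensity[rs:re, cs:ce]
            hit = lab != LABEL_NONE
            if hit.any():
                vals, cnt = np.unique(lab[hit], return_counts=True)
                labels[qi, qj] = vals[np.argmax(cnt)]
                intensity[qi, qj] = float(inten[hit].mean())
    return labels, intensity


def simulate_plot_survey(
    truth: ImpactTruth,
    footprints: list[Polygon],
    model: DetectionModel | None = None,
    rng: np.random.Generator | None = None,
    roles: list[str] | None = None,
    habitats: HabitatMap | None = None,
) -> list[GroundPlot]:
    """Emulate the field survey on synthetic truth: per quadrant, each
    category is flagged with the detection model's probability given the
    quadrant's majority impact label and mean intensity."""
    model = model if model is not None else DetectionModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    plots = []
    for k, fp in enumerate(footprints):
        qlab, qint = _quadrant_truth(truth, fp)
        flags = np.zeros((GRID_N, GRID_N, len(CATEGORIES)), dtype=bool)
        for ci, cat in enumerate(CATEGORIES):
            p = np.zeros((GRID_N, GRID_N))
            for lab in (LABEL_NEST, LABEL_RUNWAY, LABEL_THINNING):
                m = qlab == lab
                if m.any():
                    base = model.per_label.get(lab, {}).get(cat, 0.0)
                    p[m] = base * qint[m]
            flags[:, :, ci] = rng.random((GRID_N, GRID_N)) < p
        habitat = ""
        if habitats is not None:
            cx, cy = fp.centroid.x, fp.centroid.y
            r, c = habitats.transform.index_of(cx, cy)
            code = int(habitats.codes[int(r), int(c)])
            habitat = habitats.legend.get(code, "")
        role = roles[k] if roles is not None else "impacted"
        plots.append(GroundPlot(footprint=fp, flags=flags, role=role, habitat=habitat))
    return plots


def place_plot_pairs(
    truth: ImpactTruth,
    habitats: HabitatMap,
    n_pairs: int = 5,
    habitat_names: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Polygon], list[str]]:
    """Place impacted/control plot pairs the way the field design does:
    impacted plots centred on heavily impacted ground, controls on
    impact-free ground of the same habitat subset (the most representative,
    non-water classes by default)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    t = truth.transform
    h, w = truth.labels.shape
    side_px = PLOT_SIDE_M / t.pixel_size
    margin = int(np.ceil(side_px / 2)) + 1
    if habitat_names is None:
        water = habitats.water_code
        counts = {
            name: int((habitats.codes == code).sum())
            for code, name in habitats.legend.items()
            if code != water
        }
        habitat_names = [n for n, _ in sorted(counts.items(), key=lambda kv: -kv[1])[:4]]
    eligible = np.zeros_like(truth.labels, dtype=bool)
    for name in habitat_names:
        eligible |= habitats.class_mask(name)
    interior = np.zeros_like(eligible)
    interior[margin:-margin, margin:-margin] = True
    # plot-scale impact density to rank candidate centres
    from scipy import ndimage as _ndi

    k = max(int(round(side_px)), 1)
    density = _ndi.uniform_filter(truth.impacted.astype(float), size=k)
    footprints: list[Polygon] = []
    roles: list[str] = []

    def centre_to_box(r, c):
        x = t.origin_x + (c + 0.5) * t.pixel_size
        y = t.origin_y - (r + 0.5) * t.pixel_size
        return box(x - PLOT_SIDE_M / 2, y - PLOT_SIDE_M / 2,
                   x + PLOT_SIDE_M / 2, y + PLOT_SIDE_M / 2)

    for role, want_impact in (("impacted", True), ("control", False)):
        pool = eligible & interior
        pool &= (density > np.quantile(density[pool], 0.85)) if want_impact else (
            density == 0
        )
        rows, cols = np.nonzero(pool)
        if rows.size < n_pairs:
            raise ValueError(
                f"cannot place {n_pairs} {role} plots; only {rows.size} candidate "
                f"centres available"
            )
        pick = rng.choice(rows.size, size=n_pairs, replace=False)
        for idx in pick:
            footprints.append(centre_to_box(rows[idx], cols[idx]))
            roles.append(role)
    return footprints, roles


def extract_plot_change(change: ChangeRaster, footprint: Polygon) -> float:
    """Mean dNDVI over pixels whose centres fall inside the footprint;
    nodata pixels excluded. Raises if no pixel centre is covered."""
    minx, miny, maxx, maxy = footprint.bounds
    cxmin, cymin, cxmax, cymax = change.transform.bounds(change.shape)
    if maxx < cxmin or minx > cxmax or maxy < cymin or miny > cymax:
        raise ValueError("plot footprint does not overlap the change raster")
    x, y = change.transform.pixel_centers(change.shape)
    inside = shapely.contains_xy(footprint, x.ravel(), y.ravel()).reshape(x.shape)
    inside &= change.mask
    if not inside.any():
        raise ValueError("no valid pixel centres inside the plot footprint")
    return float(change.values[inside].mean())


@dataclass(frozen=True)
class ValidationFit:
    """OLS of plot score on plot-mean dNDVI for one habitat stratum."""

    stratum: str
    slope: float
    intercept: float
    r2: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError("r^2 must lie in [0, 1]")


def validate(
    plots: list[GroundPlot],
    changes: list[float] | np.ndarray,
    min_per_stratum: int = 3,
) -> list[ValidationFit]:
    """Regress plot scores on plot dNDVI, pooled and per habitat stratum.

    Strata with fewer than ``min_per_stratum`` plots are skipped. Zero
    variance in dNDVI makes the slope undefined and raises.
    """
    if len(plots) != len(changes):
        raise ValueError("plots and changes must align")
    scores = np.array([score_plot(p) for p in plots], dtype=float)
    x = np.asarray(changes, dtype=float)
    fits = [_ols_fit("pooled", x, scores)]
    strata = sorted({p.habitat for p in plots if p.habitat})
    for stratum in strata:
        sel = np.array([p.habitat == stratum for p in plots])
        if sel.sum() >= min_per_stratum:
            fits.append(_ols_fit(stratum, x[sel], scores[sel]))
    return fits


def _ols_fit(stratum: str, x: np.ndarray, y: np.ndarray) -> ValidationFit:
    if x.size < 3:
        raise ValueError(f"stratum {stratum!r}: need >= 3 plots")
    if np.ptp(x) == 0:
        raise ValueError(f"stratum {stratum!r}: zero variance in dNDVI")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ValidationFit(
        stratum=stratum,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        n=int(x.size),
        p_value=float(res.pvalues[1]),
    )


def fits_frame(fits: list[ValidationFit]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in fits])


def simulate_validation_replicate(
    rng: np.random.Generator,
    n_pairs: int = 20,
    rho: float = -0.735,
    slope_per_point: float = -2e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic (plot score, plot dNDVI) data set with a prescribed
    score–dNDVI correlation.

    Scores follow the paired field design — half the plots heavily impacted,
    half near-zero controls; dNDVI is the linear response
    ``slope_per_point x score`` plus Gaussian noise whose spread is set so
    the population correlation is ``rho`` given the realised score spread
    (more impact = lower dNDVI, so rho must be negative). Used to study the
    sampling distribution of the validation regression's r-squared.
    """
    if not -1.0 < rho < 0.0:
        raise ValueError("rho must lie in (-1, 0): more impact lowers dNDVI")
    impacted = rng.uniform(150, 900, size=n_pairs)
    controls = rng.uniform(0, 60, size=n_pairs)
    scores = np.concatenate([impacted, controls])
    signal = slope_per_point * scores
    sigma = abs(slope_per_point) * scores.std() * np.sqrt(1.0 / rho**2 - 1.0)
    changes = signal + rng.normal(0.0, sigma, size=scores.size)
    return np.round(scores).astype(int).astype(float), changes


def catch_rate(individuals: int, trap_nights: int) -> float:
    """Trapping index: individuals per 100 trap nights."""
    if trap_nights <= 0:
        raise ValueError("trap_nights must be positive")
    if individuals < 0:
        raise ValueError("individuals must be nonnegative")
    return 100.0 * individuals / trap_nights
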