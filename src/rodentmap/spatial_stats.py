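"""Spatial aggregation statistics for impact rasters: Moran's I under rook or
queen contiguity, empirical semivariograms from sampled pixel pairs, and
weighted least-squares fits of the double-exponential variogram model

    gamma(h) = c0 + c1 (1 - e^(-h/a1)) + c2 (1 - e^(-h/a2)),

with nugget c0, partial sills c1, c2 and range parameters a1, a2. The
effective range of an exponential component (95 % of its sill) is 3 a; the
"max range" summary is the larger effective range among components carrying
non-negligible sill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .raster import Raster

__all__ = [
    "MoranResult",
    "EmpiricalVariogram",
    "VariogramModel",
    "morans_i",
    "empirical_variogram",
    "fit_variogram",
]


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with the weight scheme that produced it (self-describing)."""

    i: float
    scheme: str  # rook | queen
    standardize: str  # row | binary
    n: int


_SHIFTS = {
    "rook": [(-1, 0), (1, 0), (0, -1), (0, 1)],
    "queen": [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)],
}


def morans_i(
    raster: Raster | np.ndarray,
    scheme: str = "queen",
    standardize: str = "row",
) -> MoranResult:
    """Moran's I of a raster under grid-contiguity weights.

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with z the mean
    deviations, w the contiguity weights (row-standardized or binary), and
    S0 the weight total. Nodata pixels are excluded from n and from the
    weights. A constant raster has no defined I and raises.
    """
    values = raster.values if isinstance(raster, Raster) else np.asarray(raster, float)
    if scheme not in _SHIFTS:
        raise ValueError(f"scheme must be rook or queen, got {scheme!r}")
    if standardize not in ("row", "binary"):
        raise ValueError(f"standardize must be row or binary, got {standardize!r}")
    valid = np.isfinite(values)
    n = int(valid.sum())
    vals = np.where(valid, values, 0.0)
    if n < 2 or np.ptp(values[valid]) == 0:
        raise ValueError("Moran's I is undefined for a constant (or empty) raster")
    z = np.where(valid, vals - values[valid].mean(), 0.0)

    def shifted(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
        out = np.zeros_like(a)
        src = a[
            max(dr, 0) : a.shape[0] + min(dr, 0), max(dc, 0) : a.shape[1] + min(dc, 0)
        ]
        out[
            max(-dr, 0) : a.shape[0] + min(-dr, 0),
            max(-dc, 0) : a.shape[1] + min(-dc, 0),
        ] = src
        return out

    neigh_sum = np.zeros_like(z)
    neigh_cnt = np.zeros_like(z)
    vmask = valid.astype(float)
    for dr, dc in _SHIFTS[scheme]:
        neigh_sum += shifted(z, dr, dc)
        neigh_cnt += shifted(vmask, dr, dc)

    if standardize == "row":
        with np.errstate(invalid="ignore", divide="ignore"):
            lag = np.where(neigh_cnt > 0, neigh_sum / neigh_cnt, 0.0)
        use = valid & (neigh_cnt > 0)
        s0 = float(use.sum())  # each row of W sums to 1
        cross = float((z * lag)[use].sum())
    else:
        use = valid
        s0 = float(neigh_cnt[valid].sum())
        cross = float((z * neigh_sum)[use].sum())
    denom = float((z[valid] ** 2).sum())
    i = (n / s0) * cross / denom
    return MoranResult(i=float(i), scheme=scheme, standardize=standardize, n=n)


@dataclass
class EmpiricalVariogram:
    """Binned semivariances gamma(h) with lag-bin centres (m) and pair counts."""

    lags: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    lag_width: float
    n_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.gamma = np.asarray(self.gamma, float)
        self.counts = np.asarray(self.counts, int)
        if (self.gamma < 0).any():
            raise ValueError("semivariance must be nonnegative")
        if (self.counts <= 0).any():
            raise ValueError("reported bins must have positive pair counts")


def empirical_variogram(
    raster: Raster | np.ndarray,
    n_samples: int = 100_000,
    lag_width: float = 0.3,
    max_lag: float | None = None,
    seed: int | None = None,
    pixel_size: float | None = None,
    max_pairs: int = 2_000_000,
) -> EmpiricalVariogram:
    """Empirical semivariogram from a random pixel sample.

    Pixels are sampled without replacement and every pair within ``max_lag``
    is enumerated. When the expected pair count would exceed ``max_pairs``
    the pixel sample is first thinned to the size whose all-pairs count fits
    the cap (additional samples would add no information at fixed pair
    budget, and an unthinned enumeration does not fit memory at the
    100,000-pixel default). gamma(h) = (1 / 2N(h)) sum (z_i - z_j)^2 over
    pairs binned by centre-to-centre distance with bins of ``lag_width``
    metres.
    """
    if isinstance(raster, Raster):
        values, ps = raster.values, raster.transform.pixel_size
    else:
        values = np.asarray(raster, float)
        ps = pixel_size if pixel_size is not None else 1.0
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if lag_width <= 0:
        raise ValueError("lag_width must be > 0")
    if max_lag is None:
        max_lag = 0.25 * max(values.shape) * ps
    if max_lag < lag_width:
        raise ValueError(f"max_lag {max_lag} must be >= lag_width {lag_width}")

    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(np.isfinite(values))
    if rows.size < 2:
        raise ValueError("need at least two data pixels")
    k = min(n_samples, rows.size)
    # thin the pixel sample so the expected all-pairs count fits max_pairs
    area = (values.shape[0] * ps) * (values.shape[1] * ps)
    pair_density = min(np.pi * max_lag**2 / area, 1.0)
    k_cap = int(np.sqrt(2.0 * max_pairs / pair_density))
    k = min(k, max(k_cap, 2))
    pick = rng.choice(rows.size, size=k, replace=False)
    xy = np.column_stack([cols[pick] * ps, rows[pick] * ps]).astype(float)
    z = values[rows[pick], cols[pick]]

    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=max_lag, output_type="ndarray")
    if pairs.shape[0] > 2 * max_pairs:  # density estimate was off; enforce cap
        keep = rng.choice(pairs.shape[0], size=2 * max_pairs, replace=False)
        pairs = pairs[keep]
    ii, jj = pairs[:, 0], pairs[:, 1]
    d = np.hypot(xy[ii, 0] - xy[jj, 0], xy[ii, 1] - xy[jj, 1])
    ok = d > 0
    d, ii, jj = d[ok], ii[ok], jj[ok]
    if d.size == 0:
        raise ValueError("no pixel pairs within max_lag; increase max_lag or sample")
    sq = 0.5 * (z[ii] - z[jj]) ** 2
    nbins = int(np.ceil(max_lag / lag_width))
    bins = np.minimum((d / lag_width).astype(int), nbins - 1)
    counts = np.bincount(bins, minlength=nbins)
    sums = np.bincount(bins, weights=sq, minlength=nbins)
    nonempty = counts > 0
    centres = (np.arange(nbins) + 0.5) * lag_width
    return EmpiricalVariogram(
        lags=centres[nonempty],
        gamma=sums[nonempty] / counts[nonempty],
        counts=counts[nonempty],
        lag_width=lag_width,
        n_samples=k,
        seed=seed,
    )


@dataclass(frozen=True)
class VariogramModel:
    """Fitted double-exponential variogram.

    Note: the "max range" summary is defined here as the larger of the two
    components' effective ranges (lag reaching 95 % of the component sill,
    i.e. 3 a for an exponential term), counting only components whose
    partial sill is non-negligible against the total.
    """

    nugget: float
    sill1: float
    range1: float
    sill2: float
    range2: float

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        return (
            self.nugget
            + self.sill1 * (1.0 - np.exp(-h / self.range1))
            + self.sill2 * (1.0 - np.exp(-h / self.range2))
        )

    @property
    def effective_ranges(self) -> tuple[float, float]:
        return 3.0 * self.range1, 3.0 * self.range2

    @property
    def dominant_range(self) -> float:
        """Effective range of the component carrying the larger partial sill
        (the natural range estimate when the field has one true structure)."""
        return 3.0 * (self.range1 if self.sill1 >= self.sill2 else self.range2)

    @property
    def max_range(self) -> float:
        total = self.sill1 + self.sill2
        if total <= 0:
            return 0.0
        ranges = [
            3.0 * a
            for c, a in ((self.sill1, self.range1), (self.sill2, self.range2))
            if c > 0.01 * total
        ]
        return float(max(ranges)) if ranges else 0.0


def _double_exp(h, c0, c1, a1, c2, a2):
    return c0 + c1 * (1 - np.exp(-h / a1)) + c2 * (1 - np.exp(-h / a2))


def fit_variogram(emp: EmpiricalVariogram) -> VariogramModel:
    """Weighted least-squares fit (weights = pair counts) of the
    double-exponential model with nonnegative sills.

    Range parameters are constrained to the window [lag width, max sampled
    lag]: below the binning resolution an exponential term is
    indistinguishable from nugget (a flat pure-nugget variogram would be
    unidentifiable), and beyond the sampled lags a range is unconstrained by
    the data (an unbounded long-range term otherwise chases finite-domain
    drift in the far bins with an arbitrarily large sill). Sills are capped
    at five times the largest binned semivariance for the same reason.
    """
    if emp.lags.size < 5:
        raise ValueError("need at least 5 variogram bins to fit")
    h, g, w = emp.lags, emp.gamma, emp.counts.astype(float)
    sill = float(g[-3:].mean()) if g.size >= 3 else float(g.max())
    sill = max(sill, 1e-12)
    hmax = float(h.max())
    a_lo, a_hi = emp.lag_width, hmax
    cap = max(5.0 * float(g.max()), 1e-9)
    p0 = [
        min(max(float(g[0]) * 0.5, 1e-9), cap),
        min(max(sill * 0.5, 1e-9), cap),
        min(max(hmax / 6.0, a_lo * 1.1), a_hi),
        min(max(sill * 0.25, 1e-9), cap),
        min(max(hmax / 2.0, a_lo * 1.2), a_hi),
    ]
    bounds = ([0.0, 0.0, a_lo, 0.0, a_lo], [cap, cap, a_hi, cap, a_hi])
    try:
        popt, _ = curve_fit(
            _double_exp,
            h,
            g,
            p0=p0,
            sigma=1.0 / np.sqrt(w),
            absolute_sigma=False,
            bounds=bounds,
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:  # non-convergence
        raise RuntimeError(f"variogram fit did not converge (last p0 {p0})") from exc
    c0, c1, a1, c2, a2 = (float(v) for v in popt)
    if a2 < a1:  # canonical order: shorter-range component first
        c1, a1, c2, a2 = c2, a2, c1, a1
    return VariogramModel(nugget=c0, sill1=c1, range1=a1, sill2=c2, range2=a2)
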