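"""Object-based land-cover classification: joint spatial/spectral mode-seeking
segmentation at a coarsened working resolution, per-segment feature
extraction, random-forest classification of segments, and the standard
accuracy metrics (confusion matrix, overall accuracy, Cohen's kappa,
out-of-bag error).

The segmentation is an iterative joint-domain mode-seeking pass with flat
kernels (spatial radius in metres, range radius in reflectance units)
followed by connected-components relabelling and small-segment merging; the
contract is the behaviour on homogeneous and separable inputs, not
equivalence with any particular toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion

from .raster import BANDS, GridTransform, HabitatMap, SceneRaster
from .spectral import compute_ndvi

__all__ = [
    "SegmentMap",
    "AccuracyReport",
    "segment",
    "classify_segments",
    "accuracy_metrics",
]


@dataclass
class SegmentMap:
    """Integer segment-label raster (at the working resolution) with a
    per-segment feature table: mean band reflectances, mean NDVI, optional
    covariate means, and segment size in pixels."""

    labels: np.ndarray
    features: pd.DataFrame  # indexed by segment id
    transform: GridTransform
    work_factor: int  # native pixels per working pixel (per axis)

    @property
    def n_segments(self) -> int:
        return int(self.features.shape[0])


@dataclass(frozen=True)
class AccuracyReport:
    """Confusion matrix with overall accuracy, Cohen's kappa and (when from a
    forest fit) the out-of-bag error."""

    confusion: np.ndarray
    classes: tuple
    overall_accuracy: float
    kappa: float
    oob_error: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.overall_accuracy <= 1.0:
            raise ValueError("overall accuracy must lie in [0, 1]")
        if not -1.0 - 1e-9 <= self.kappa <= 1.0 + 1e-9:
            raise ValueError("kappa must lie in [-1, 1]")


def _block_mean(a: np.ndarray, f: int) -> np.ndarray:
    h, w = a.shape[-2:]
    hh, ww = h // f, w // f
    a = a[..., : hh * f, : ww * f]
    return a.reshape(*a.shape[:-2], hh, f, ww, f).mean(axis=(-3, -1))


def segment(
    scene: SceneRaster,
    work_resolution: float = 0.3,
    spatial_radius: float = 1.5,
    range_radius: float = 0.02,
    min_size: int = 10,
    max_iter: int = 8,
    max_segment_size: int | None = None,
) -> SegmentMap:
    """Segment a multiband scene.

    The scene is aggregated to ``work_resolution`` (block mean), smoothed by
    iterative flat-kernel joint filtering (each pixel moves toward the mean
    of spectrally similar pixels within the spatial window), then cut into
    connected components of spectrally similar neighbours; components below
    ``min_size`` working pixels merge into their most similar neighbour.
    ``max_segment_size`` (working pixels) optionally caps segment extent by
    intersecting large components with a spatial block grid — useful when a
    downstream classifier needs several training segments per class rather
    than one segment per contiguous habitat patch.
    """
    ps = scene.transform.pixel_size
    if work_resolution < ps:
        raise ValueError(
            f"work_resolution {work_resolution} below native pixel size {ps}"
        )
    f = max(int(round(work_resolution / ps)), 1)
    bands = _block_mean(scene.bands, f)
    n_work = bands.shape[1] * bands.shape[2]
    if min_size > n_work:
        raise ValueError(f"min_size {min_size} exceeds image size {n_work} px")
    wps = ps * f
    win = max(int(round(spatial_radius / wps)), 1)

    img = _mode_seek(bands, win, range_radius, max_iter)

    labels = _connected_components(img, range_radius)
    if max_segment_size is not None:
        labels = _split_by_blocks(labels, block=int(np.ceil(np.sqrt(max_segment_size))))
    labels = _merge_small(labels, img, min_size)

    ndvi_work = _block_mean(compute_ndvi(scene).values[None], f)[0]
    features = _segment_features(labels, img, ndvi_work)
    return SegmentMap(
        labels=labels,
        features=features,
        transform=GridTransform(
            scene.transform.origin_x, scene.transform.origin_y, wps
        ),
        work_factor=f,
    )


def _mode_seek(
    bands: np.ndarray, win: int, range_radius: float, max_iter: int
) -> np.ndarray:
    """Iterative joint-domain mode seeking with flat kernels: each pixel
    moves to the mean of the window pixels within ``range_radius`` of it
    spectrally. Mixed boundary pixels converge to the nearer class mode, so
    boundaries sharpen rather than blur."""
    img = bands.copy()
    offsets = [
        (dr, dc)
        for dr in range(-win, win + 1)
        for dc in range(-win, win + 1)
    ]
    h, w = img.shape[1:]
    for _ in range(max_iter):
        num = np.zeros_like(img)
        den = np.zeros((h, w))
        for dr, dc in offsets:
            src = np.s_[
                max(dr, 0) : h + min(dr, 0), max(dc, 0) : w + min(dc, 0)
            ]
            dst = np.s_[
                max(-dr, 0) : h + min(-dr, 0), max(-dc, 0) : w + min(-dc, 0)
            ]
            shifted = img[:, src[0], src[1]]
            center = img[:, dst[0], dst[1]]
            close = np.linalg.norm(shifted - center, axis=0) <= range_radius
            num[:, dst[0], dst[1]] += np.where(close, shifted, 0.0)
            den[dst] += close
        new = num / den  # den >= 1: the (0, 0) offset always matches
        if np.allclose(new, img, atol=1e-7):
            return new
        img = new
    return img


def _connected_components(img: np.ndarray, range_radius: float) -> np.ndarray:
    """Union-find over 4-neighbour pairs whose spectral distance is within
    the range radius."""
    _, h, w = img.shape
    n = h * w
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    flat = img.reshape(img.shape[0], -1)
    for (sl_a, sl_b) in (
        (np.s_[:, :-1, :], np.s_[:, 1:, :]),  # vertical neighbours
        (np.s_[:, :, :-1], np.s_[:, :, 1:]),  # horizontal neighbours
    ):
        da = img[sl_a].reshape(img.shape[0], -1)
        db = img[sl_b].reshape(img.shape[0], -1)
        close = np.linalg.norm(da - db, axis=0) <= range_radius
        idx = np.arange(n).reshape(h, w)
        ia = idx[sl_a[1:]].ravel()[close]
        ib = idx[sl_b[1:]].ravel()[close]
        for a, b in zip(ia, ib):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    del flat
    return labels.reshape(h, w).astype(np.int64)


def _split_by_blocks(labels: np.ndarray, block: int) -> np.ndarray:
    """Intersect components with a coarse spatial block grid so one segment
    cannot extend arbitrarily far — the spatial-bandwidth counterpart of the
    joint-domain kernel. Pieces split off below the size floor are re-merged
    afterwards by the small-segment pass."""
    h, w = labels.shape
    rows, cols = np.mgrid[0:h, 0:w]
    block_id = (rows // block) * (w // block + 1) + cols // block
    combined = labels.astype(np.int64) * (block_id.max() + 1) + block_id
    _, out = np.unique(combined, return_inverse=True)
    return out.reshape(h, w).astype(np.int64)


def _merge_small(labels: np.ndarray, img: np.ndarray, min_size: int) -> np.ndarray:
    """Merge every segment below min_size into its spectrally most similar
    adjacent segment, iterating until all segments meet the floor."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if ids.size <= 1:
            break
        small = ids[counts < min_size]
        if small.size == 0:
            break
        means = {
            i: img[:, labels == i].mean(axis=1) for i in ids
        }
        merged_any = False
        for sid in sorted(small, key=lambda i: counts[list(ids).index(i)]):
            m = labels == sid
            if not m.any():
                continue
            dil = ndimage.binary_dilation(m)
            neigh = set(np.unique(labels[dil & ~m])) - {sid}
            if not neigh:
                continue
            target = min(neigh, key=lambda j: np.linalg.norm(means[sid] - means[j]))
            labels[m] = target
            merged_any = True
        if not merged_any:
            break
    _, relabeled = np.unique(labels, return_inverse=True)
    return relabeled.reshape(labels.shape).astype(np.int64)


def _segment_features(
    labels: np.ndarray, img: np.ndarray, ndvi: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    ids = np.unique(labels)
    rows = {}
    flat = labels.ravel()
    counts = np.bincount(flat)
    for k, name in enumerate(BANDS):
        sums = np.bincount(flat, weights=img[k].ravel())
        rows[f"mean_{name}"] = sums[ids] / counts[ids]
    rows["mean_NDVI"] = np.bincount(flat, weights=ndvi.ravel())[ids] / counts[ids]
    if covariates:
        for name, cov in covariates.items():
            rows[f"mean_{name}"] = (
                np.bincount(flat, weights=cov.ravel())[ids] / counts[ids]
            )
    rows["size_px"] = counts[ids]
    return pd.DataFrame(rows, index=pd.Index(ids, name="segment"))


def add_covariate_features(
    segmap: SegmentMap, covariates: dict[str, np.ndarray]
) -> SegmentMap:
    """Attach per-segment means of extra covariate rasters (given at the
    native grid; block-averaged to the working grid)."""
    f = segmap.work_factor
    flat = segmap.labels.ravel()
    ids = segmap.features.index.to_numpy()
    counts = np.bincount(flat)
    feats = segmap.features.copy()
    for name, cov in covariates.items():
        covw = _block_mean(np.asarray(cov, float)[None], f)[0]
        if covw.shape != segmap.labels.shape:
            covw = covw[: segmap.labels.shape[0], : segmap.labels.shape[1]]
        feats[f"mean_{name}"] = (
            np.bincount(flat, weights=covw.ravel())[ids] / counts[ids]
        )
    return SegmentMap(segmap.labels, feats, segmap.transform, segmap.work_factor)


def majority_training_labels(segmap: SegmentMap, habitats) -> pd.Series:
    """Per-segment class name by majority vote of a reference habitat map
    (given at the native grid) — the synthetic stand-in for manually
    digitised training areas."""
    f = segmap.work_factor
    hh, ww = segmap.labels.shape
    codes = habitats.codes[: hh * f, : ww * f]
    blocks = codes.reshape(hh, f, ww, f).transpose(0, 2, 1, 3).reshape(hh, ww, f * f)
    out = {}
    for sid in segmap.features.index:
        m = segmap.labels == sid
        vals, cnts = np.unique(blocks[m], return_counts=True)
        out[sid] = habitats.legend[int(vals[np.argmax(cnts)])]
    return pd.Series(out, name="class")


def classify_segments(
    segmap: SegmentMap,
    training: pd.Series,
    native_shape: tuple[int, int] | None = None,
    n_estimators: int = 200,
    seed: int = 0,
    water_name: str = "water",
) -> tuple[HabitatMap, AccuracyReport]:
    """Fit a random forest on labelled training segments and classify all
    segments; accuracy is reported from the out-of-bag predictions.

    ``training`` maps segment id -> class name; every class needs at least
    two training segments. The class map is rasterized back to the native
    grid by pixel replication.
    """
    feat_cols = [c for c in segmap.features.columns if c != "size_px"]
    X_all = segmap.features[feat_cols]
    if not np.isfinite(X_all.to_numpy()).all():
        raise ValueError("segment features must be finite")
    training = training.dropna()
    classes, class_counts = np.unique(training.to_numpy(), return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two training classes")
    thin = classes[class_counts < 2]
    if thin.size:
        raise ValueError(f"classes with < 2 training segments: {list(thin)}")
    X_tr = X_all.loc[training.index]
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X_tr.to_numpy(), training.to_numpy())
    oob_error = 1.0 - float(forest.oob_score_)
    oob_pred = forest.classes_[np.argmax(forest.oob_decision_function_, axis=1)]
    report = accuracy_metrics(oob_pred, training.to_numpy(), oob_error=oob_error)

    pred = pd.Series(
        forest.predict(X_all.to_numpy()), index=segmap.features.index
    )
    legend = {i: name for i, name in enumerate(sorted(set(pred)))}
    name_to_code = {v: k for k, v in legend.items()}
    code_of_segment = pred.map(name_to_code)
    codes_work = code_of_segment.to_numpy()[
        np.searchsorted(segmap.features.index.to_numpy(), segmap.labels)
    ].astype(np.uint8)
    f = segmap.work_factor
    codes = np.kron(codes_work, np.ones((f, f), dtype=np.uint8))
    if native_shape is not None:
        out = np.full(native_shape, HabitatMap.NODATA_CODE, dtype=np.uint8)
        h = min(native_shape[0], codes.shape[0])
        w = min(native_shape[1], codes.shape[1])
        out[:h, :w] = codes[:h, :w]
        # edge rows/cols lost to block aggregation inherit their neighbour
        if native_shape[0] > codes.shape[0]:
            out[codes.shape[0]:, :w] = out[codes.shape[0] - 1, :w]
        if native_shape[1] > codes.shape[1]:
            out[:, codes.shape[1]:] = out[:, codes.shape[1] - 1][:, None]
        codes = out
    native_transform = GridTransform(
        segmap.transform.origin_x,
        segmap.transform.origin_y,
        segmap.transform.pixel_size / f,
    )
    habmap = HabitatMap(
        codes=codes,
        legend=legend,
        transform=native_transform,
        water_name=water_name,
        provenance=f"random forest, {n_estimators} trees, seed {seed}",
    )
    return habmap, report


def accuracy_metrics(
    predicted, truth, oob_error: float | None = None
) -> AccuracyReport:
    """Confusion matrix, overall accuracy trace/total, and Cohen's kappa
    (OA - pe) / (1 - pe) with pe the chance agreement from the marginals."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size == 0 or truth.size == 0:
        raise ValueError("empty label vectors")
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    classes = np.unique(np.concatenate([truth, predicted]))
    cm = _sk_confusion(truth, predicted, labels=classes)
    total = cm.sum()
    oa = float(np.trace(cm)) / total
    pe = float((cm.sum(axis=0) * cm.sum(axis=1)).sum()) / total**2
    kappa = (oa - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return AccuracyReport(
        confusion=cm,
        classes=tuple(classes),
        overall_accuracy=oa,
        kappa=float(kappa),
        oob_error=oob_error,
    )
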