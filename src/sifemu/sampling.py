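"""Image segmentation and training-sample selection.

Three allocation strategies decide where training pixels come from:

* ``random`` — uniform without replacement over all pixels;
* ``absolute`` — a k-means segmentation first, then the same number of
  pixels from every class regardless of its area;
* ``relative`` — quotas proportional to class area (largest-remainder
  rounding so they sum exactly to ``n``).

Classes smaller than their quota contribute everything they have; the
deficit is redistributed proportionally among the remaining classes until
resolved. Segmentation clusters the top-10 input-PCA scores of each pixel
(PCA fit on a random subsample of at most 10,000 pixels) with k-means++,
5 restarts, 300 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from . import pca
from .datamodel import RadianceCube, SampleTable, SIFCube, SpectralMatrix, extract_pixels
from .errors import ArgumentError, ConsistencyError

_SEGMENT_PCA_COMPONENTS = 10
_SEGMENT_PCA_SUBSAMPLE = 10_000


@dataclass
class SegmentationMap:
    labels: np.ndarray     # [rows, cols] in 0..k-1
    k: int
    centroids: np.ndarray  # [k, q] in segmentation feature space
    inertia: float


@dataclass
class SamplingPlan:
    strategy: str = "random"          # random | absolute | relative
    n_samples: int = 1000
    k: int = 40                       # segmentation classes (ignored for random)
    scene_quotas: tuple | None = None # per-scene counts for multi-scene pooling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("random", "absolute", "relative"):
            raise ArgumentError(f"unknown sampling strategy '{self.strategy}'")
        if self.n_samples < 1:
            raise ArgumentError("n_samples must be >= 1")


def kmeans_segment(cube: RadianceCube, k: int, seed: int = 0) -> SegmentationMap:
    """Unsupervised k-means classification of a radiance cube."""
    rows, cols, n_bands = cube.values.shape
    n_pix = rows * cols
    if k < 1:
        raise ArgumentError("k must be >= 1")
    if k > n_pix:
        raise ArgumentError(f"k={k} exceeds pixel count {n_pix}")
    flat = np.asarray(cube.values, dtype=float).reshape(n_pix, n_bands)

    rng = np.random.default_rng(seed)
    n_sub = min(_SEGMENT_PCA_SUBSAMPLE, n_pix)
    sub_idx = np.sort(rng.choice(n_pix, n_sub, replace=False))
    q = min(_SEGMENT_PCA_COMPONENTS, n_bands, n_sub - 1) if n_sub > 1 else 1
    if n_sub > 1:
        model = pca.fit_pca(SpectralMatrix(flat[sub_idx], cube.grid), q)
        features = pca.project(model, SpectralMatrix(flat, cube.grid)).values
    else:
        features = flat
    km = KMeans(n_clusters=k, n_init=5, max_iter=300, init="k-means++",
                random_state=int(rng.integers(2 ** 31)))
    labels = km.fit_predict(features)
    return SegmentationMap(labels=labels.reshape(rows, cols).astype(np.int32),
                           k=k, centroids=km.cluster_centers_,
                           inertia=float(km.inertia_))


def _largest_remainder(weights: np.ndarray, n: int) -> np.ndarray:
    """Integer quotas proportional to ``weights`` summing exactly to ``n``."""
    exact = n * weights / weights.sum()
    quotas = np.floor(exact).astype(int)
    remainder = exact - quotas
    short = n - quotas.sum()
    # hand the leftover units to the largest remainders; ties to lower index
    order = np.lexsort((np.arange(weights.size), -remainder))
    quotas[order[:short]] += 1
    return quotas


def _class_quotas(strategy: str, counts: np.ndarray, n: int) -> np.ndarray:
    k = counts.size
    if strategy == "absolute":
        quotas = np.full(k, n // k, dtype=int)
        quotas[: n % k] += 1
    else:  # relative
        quotas = _largest_remainder(counts.astype(float), n)
    # classes smaller than their quota give everything; redistribute the
    # deficit proportionally among classes that still have spare pixels
    quotas = np.minimum(quotas, counts)
    while quotas.sum() < n:
        spare = counts - quotas
        open_cls = spare > 0
        if not open_cls.any():
            raise ArgumentError("not enough pixels to satisfy the sampling plan")
        deficit = n - quotas.sum()
        if strategy == "absolute":
            weights = open_cls.astype(float)
        else:
            weights = np.where(open_cls, counts.astype(float), 0.0)
        extra = _largest_remainder(weights, min(deficit, int(spare.sum())))
        quotas = np.minimum(quotas + extra, counts)
    return quotas


def draw_samples(plan: SamplingPlan, seg: SegmentationMap | None,
                 rng: np.random.Generator, shape: tuple[int, int] | None = None
                 ) -> list[tuple[int, int]]:
    """Pixel coordinates for one scene according to the plan.

    ``shape`` gives (rows, cols) for the random strategy; stratified
    strategies take the shape from the segmentation map.
    """
    if plan.strategy == "random":
        if shape is None:
            if seg is None:
                raise ArgumentError("random sampling needs the image shape")
            shape = seg.labels.shape
        rows, cols = shape
        n_pix = rows * cols
        if plan.n_samples > n_pix:
            raise ArgumentError(f"n_samples={plan.n_samples} exceeds {n_pix} pixels")
        flat = rng.choice(n_pix, plan.n_samples, replace=False)
        return [tuple(x) for x in np.column_stack(np.unravel_index(flat, shape))]

    if seg is None:
        raise ArgumentError(f"'{plan.strategy}' sampling needs a segmentation map")
    labels = seg.labels
    n_pix = labels.size
    if plan.n_samples > n_pix:
        raise ArgumentError(f"n_samples={plan.n_samples} exceeds {n_pix} pixels")
    counts = np.bincount(labels.ravel(), minlength=seg.k)
    quotas = _class_quotas(plan.strategy, counts, plan.n_samples)
    coords: list[tuple[int, int]] = []
    for c in range(seg.k):
        if quotas[c] == 0:
            continue
        cls_flat = np.flatnonzero(labels.ravel() == c)
        pick = rng.choice(cls_flat.size, quotas[c], replace=False)
        picked = cls_flat[np.sort(pick)]
        coords.extend(tuple(x) for x in
                      np.column_stack(np.unravel_index(picked, labels.shape)))
    return coords


def split_train_val(samples: list, fraction: float = 0.7, seed: int = 0
                    ) -> tuple[list, list]:
    """One random split: ``round(fraction * n)`` to train, rest to validate."""
    if not (0.0 < fraction < 1.0):
        raise ArgumentError("fraction must be in (0, 1)")
    n = len(samples)
    if n < 2:
        raise ArgumentError("need at least 2 samples to split")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ArgumentError(f"split leaves an empty side (n={n}, fraction={fraction})")
    order = np.random.default_rng(seed).permutation(n)
    return ([samples[i] for i in order[:n_train]],
            [samples[i] for i in order[n_train:]])


def build_training_set(cubes: list[tuple[RadianceCube, SIFCube, str]],
                       plan: SamplingPlan) -> SampleTable:
    """Sample pixels from one or more scenes into a paired table.

    ``plan.scene_quotas`` fixes the per-scene counts (they must sum to
    ``plan.n_samples``); otherwise the total is split as evenly as possible.
    Stratified strategies segment each scene independently with ``plan.k``
    classes.
    """
    if not cubes:
        raise ArgumentError("no scenes given")
    n_scenes = len(cubes)
    if plan.scene_quotas is not None:
        quotas = np.asarray(plan.scene_quotas, dtype=int)
        if quotas.size != n_scenes or quotas.sum() != plan.n_samples:
            raise ArgumentError("scene quotas must match scene count and sum to n_samples")
    else:
        quotas = np.full(n_scenes, plan.n_samples // n_scenes, dtype=int)
        quotas[: plan.n_samples % n_scenes] += 1

    in_grid = cubes[0][0].grid
    out_grid = cubes[0][1].grid
    ss = np.random.SeedSequence(plan.seed)
    seeds = ss.spawn(n_scenes)

    scenes, rows_, cols_, labels_, xs, ys = [], [], [], [], [], []
    for (cube, sif, scene_id), quota, sub_ss in zip(cubes, quotas, seeds):
        if cube.grid != in_grid or sif.grid != out_grid:
            raise ConsistencyError(f"scene '{scene_id}' is on a different band grid")
        if quota == 0:
            continue
        rng = np.random.default_rng(sub_ss)
        scene_plan = SamplingPlan(strategy=plan.strategy, n_samples=int(quota),
                                  k=plan.k, seed=plan.seed)
        if plan.strategy == "random":
            coords = draw_samples(scene_plan, None, rng,
                                  shape=(cube.rows, cube.cols))
            labels = np.full(len(coords), -1, dtype=int)
        else:
            seg = kmeans_segment(cube, plan.k, seed=int(rng.integers(2 ** 31)))
            coords = draw_samples(scene_plan, seg, rng)
            labels = np.array([seg.labels[r, c] for r, c in coords], dtype=int)
        scenes.append(np.full(len(coords), scene_id, dtype=object))
        rows_.append(np.array([r for r, _ in coords], dtype=int))
        cols_.append(np.array([c for _, c in coords], dtype=int))
        labels_.append(labels)
        xs.append(extract_pixels(cube, coords).values)
        ys.append(extract_pixels(sif, coords).values)

    return SampleTable(
        scene=np.concatenate(scenes),
        row=np.concatenate(rows_),
        col=np.concatenate(cols_),
        label=np.concatenate(labels_),
        X=SpectralMatrix(np.vstack(xs), in_grid),
        Y=SpectralMatrix(np.vstack(ys), out_grid),
    )
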