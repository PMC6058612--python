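"""Unsupervised spatial segmentation of MSI data.

The segmentation follows the workflow used for histology-free delineation of
tissue compartments: pixel spectra are binned into a spectral feature stack,
weakly denoised with a masked Gaussian filter, and partitioned by a bisecting
k-means that operates under *correlation distance* (1 − Pearson between pixel
feature vectors).  Correlation distance makes the clustering sensitive to the
shape of the local spectrum rather than its overall brightness, which is the
property that separates histological compartments in TIC-normalized data.

Bisecting k-means is greedy and top-down: start from one segment holding every
on-mask pixel, and repeatedly split the segment with the largest within-segment
scatter (sum of correlation distances to its centroid) with a 2-means until k
segments exist.  Segments are then given histological names by marker
enrichment (:func:`segments_to_rois`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .msi_core import IonImage, MSIDataset, TissueMask

logger = logging.getLogger(__name__)

COMPARTMENTS = (
    "alveolar",
    "sub_epithelium",
    "epithelium",
    "lumen_or_background",
    "vessel",
    "unassigned",
)

QUANTIFIED_COMPARTMENTS = ("alveolar", "sub_epithelium", "epithelium")


# ---------------------------------------------------------------------------
# Feature construction and denoising
# ---------------------------------------------------------------------------

def build_feature_stack(
    dataset: MSIDataset, bin_width: float = 0.5, drop_empty: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Bin every pixel spectrum onto a common m/z grid.

    Returns ``(stack, bin_centers)`` where ``stack`` has shape
    ``(n_rows, n_cols, n_bins)``; cells without an acquired pixel are zero.
    Bins with no signal anywhere are dropped by default (they carry no
    clustering information and would only dilute correlation distances).
    """
    lo, hi = dataset.mz_range
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)

    n = dataset.n_pixels
    feats = np.zeros((n, n_bins), dtype=np.float64)
    if dataset.mode == "continuous":
        idx = np.clip(np.searchsorted(edges, dataset.mz_axis, side="right") - 1, 0, n_bins - 1)
        for b in np.unique(idx):
            feats[:, b] = dataset.intensity_matrix[:, idx == b].sum(axis=1)
    else:
        for i in range(n):
            m, y = dataset.spectrum(i)
            b = np.clip(np.searchsorted(edges, m, side="right") - 1, 0, n_bins - 1)
            np.add.at(feats[i], b, y)

    centers = (edges[:-1] + edges[1:]) / 2
    if drop_empty:
        used = feats.any(axis=0)
        feats = feats[:, used]
        centers = centers[used]

    stack = np.zeros(dataset.grid_shape + (feats.shape[1],), dtype=np.float64)
    rows, cols = dataset.pixel_rows_cols()
    stack[rows, cols] = feats
    return stack, centers


def denoise_weak(
    feature_stack: np.ndarray,
    sigma_px: float = 1.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Weak spatial denoising: masked Gaussian smoothing per feature channel.

    Off-mask pixels are excluded from the kernel and the remaining weights are
    renormalized, so smoothing never bleeds background into tissue (or vice
    versa) across the mask boundary.  ``sigma_px = 0`` is the identity.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if sigma_px == 0:
        return feature_stack.copy()
    if mask is None:
        mask = np.ones(feature_stack.shape[:2], dtype=bool)
    m = mask.astype(np.float64)
    weight = ndimage.gaussian_filter(m, sigma=sigma_px, mode="constant")
    out = np.zeros_like(feature_stack)
    with np.errstate(invalid="ignore", divide="ignore"):
        for c in range(feature_stack.shape[2]):
            num = ndimage.gaussian_filter(
                feature_stack[:, :, c] * m, sigma=sigma_px, mode="constant"
            )
            out[:, :, c] = np.where(weight > 0, num / weight, 0.0)
    out[~mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# Correlation distance
# ---------------------------------------------------------------------------

_warned_zero_variance = False


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − Pearson correlation between two feature vectors, in [0, 2].

    A zero-variance (flat) vector has no defined correlation; such vectors get
    the maximal non-informative distance 1 (logged once per session).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size < 2:
        raise ValueError("vectors must have length >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt((du * du).sum())
    nv = np.sqrt((dv * dv).sum())
    if nu == 0 or nv == 0:
        global _warned_zero_variance
        if not _warned_zero_variance:
            logger.warning("correlation_distance: zero-variance vector, distance set to 1")
            _warned_zero_variance = True
        return 1.0
    return float(1.0 - (du * dv).sum() / (nu * nv))


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale each row so corr-dist(x, c) = 1 − (zx · zc)/d.

    Returns (Z, flat) where ``flat`` marks zero-variance rows (Z row = 0).
    """
    mu = X.mean(axis=1, keepdims=True)
    centered = X - mu
    norm = np.sqrt((centered * centered).sum(axis=1, keepdims=True))
    flat = norm[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(norm > 0, centered / norm, 0.0)
    return Z, flat


def _distances_to_centroid(Z: np.ndarray, flat: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Correlation distances of standardized rows to a raw centroid vector."""
    dc = centroid - centroid.mean()
    nc = np.sqrt((dc * dc).sum())
    if nc == 0:
        return np.ones(Z.shape[0])
    d = 1.0 - Z @ (dc / nc)
    d[flat] = 1.0
    return d


# ---------------------------------------------------------------------------
# Bisecting k-means
# ---------------------------------------------------------------------------

@dataclass
class SegmentationMap:
    """Per-pixel segment labels with the record of how they were produced.

    ``labels`` is −1 off mask, 0..k_actual−1 on mask.  ``bisection_tree`` has
    one entry per executed split recording which segment was divided and the
    2-means objective of the accepted split.
    """

    labels: np.ndarray
    k: int
    k_actual: int
    bisection_tree: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def segment_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids >= 0]

    def segment_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def pixel_counts(self) -> dict[int, int]:
        return {int(l): int((self.labels == l).sum()) for l in self.segment_ids}

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.labels, delimiter=",", fmt="%d")


def _two_means(
    X: np.ndarray,
    Z: np.ndarray,
    flat: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int,
    max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """Best-of-restarts 2-means under correlation distance.

    Returns (assignment in {0,1}, objective = sum of distances to own centroid).
    Empty clusters are re-seeded at the farthest point from the survivor.
    """
    n = X.shape[0]
    best_assign: np.ndarray | None = None
    best_obj = np.inf
    for _ in range(max(1, n_restarts)):
        # k-means++-style random init: second seed sampled with probability
        # proportional to squared correlation distance from the first, so
        # small but very distinct sub-populations are reliably discovered
        i = int(rng.integers(n))
        d = _distances_to_centroid(Z, flat, X[i])
        d[i] = 0.0
        w = d * d
        total = w.sum()
        if total > 0:
            j = int(rng.choice(n, p=w / total))
        else:
            j = int((i + 1) % n)
        centroids = [X[i].copy(), X[j].copy()]
        assign = np.zeros(n, dtype=np.int8)
        for _it in range(max_iter):
            d0 = _distances_to_centroid(Z, flat, centroids[0])
            d1 = _distances_to_centroid(Z, flat, centroids[1])
            new_assign = (d1 < d0).astype(np.int8)
            for side in (0, 1):
                if not (new_assign == side).any():
                    far = int(np.argmax(np.where(new_assign == 1 - side, np.minimum(d0, d1), -np.inf)))
                    new_assign[far] = side
            if (new_assign == assign).all() and _it > 0:
                break
            assign = new_assign
            centroids = [X[assign == side].mean(axis=0) for side in (0, 1)]
        d0 = _distances_to_centroid(Z, flat, centroids[0])
        d1 = _distances_to_centroid(Z, flat, centroids[1])
        obj = float(np.where(assign == 0, d0, d1).sum())
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_assign = assign.copy()
    return best_assign, best_obj


def _scatter(X: np.ndarray, Z: np.ndarray, flat: np.ndarray, members: np.ndarray) -> float:
    centroid = X[members].mean(axis=0)
    return float(_distances_to_centroid(Z[members], flat[members], centroid).sum())


def bisecting_kmeans(
    feature_stack: np.ndarray,
    mask: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 4,
) -> SegmentationMap:
    """Greedy top-down bisecting k-means under correlation distance.

    At each of the k−1 steps the segment with the largest within-segment
    scatter is split by 2-means (ties broken by pixel count, then lower label
    id); singleton segments are skipped.  If no segment is splittable the
    bisection stops early and ``k_actual < k`` is recorded.
    """
    mask = np.asarray(mask, dtype=bool)
    n_on = int(mask.sum())
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_on < k:
        raise ValueError(f"k={k} exceeds on-mask pixel count {n_on}")

    X = feature_stack[mask].astype(np.float64)
    Z, flat = _standardize_rows(X)
    if flat.any():
        logger.info("bisecting_kmeans: %d zero-variance pixels (distance 1 to all)", int(flat.sum()))
    rng = np.random.default_rng(seed)

    assignments = np.zeros(n_on, dtype=np.int32)
    scatters = {0: _scatter(X, Z, flat, np.arange(n_on) >= 0)}
    tree: list[dict] = []
    next_label = 1
    while next_label < k:
        # candidate order: largest scatter, then larger count, then lower id
        order = sorted(
            scatters,
            key=lambda l: (-scatters[l], -(assignments == l).sum(), l),
        )
        split_done = False
        for label in order:
            members = np.flatnonzero(assignments == label)
            if members.size < 2:
                continue
            sub_assign, obj = _two_means(
                X[members], Z[members], flat[members], rng, n_restarts
            )
            assignments[members[sub_assign == 1]] = next_label
            tree.append(
                {
                    "step": next_label,
                    "split_label": int(label),
                    "objective": obj,
                    "sizes": [int((sub_assign == 0).sum()), int((sub_assign == 1).sum())],
                }
            )
            scatters[label] = _scatter(X, Z, flat, assignments == label)
            scatters[next_label] = _scatter(X, Z, flat, assignments == next_label)
            split_done = True
            break
        if not split_done:
            logger.warning(
                "bisecting_kmeans: no splittable segment left, stopping at k=%d", next_label
            )
            break
        next_label += 1

    labels = np.full(mask.shape, -1, dtype=np.int32)
    labels[mask] = assignments
    return SegmentationMap(
        labels=labels, k=k, k_actual=next_label, bisection_tree=tree, seed=seed
    )


def segment_dataset(
    dataset: MSIDataset,
    mask: np.ndarray | TissueMask | None = None,
    k: int = 6,
    seed: int = 0,
    sigma_px: float = 1.0,
    bin_width: float = 0.5,
    n_restarts: int = 4,
) -> SegmentationMap:
    """Convenience wrapper: feature stack → weak denoise → bisecting k-means.

    The default mask is the full acquired grid so that off-tissue background
    and airway lumens form their own segments, mirroring how segmentation maps
    are read against histology.
    """
    stack, _ = build_feature_stack(dataset, bin_width=bin_width)
    if mask is None:
        grid_mask = dataset.acquired_mask()
    elif isinstance(mask, TissueMask):
        grid_mask = mask.grid
    else:
        grid_mask = np.asarray(mask, dtype=bool)
    stack = denoise_weak(stack, sigma_px=sigma_px, mask=grid_mask)
    return bisecting_kmeans(stack, grid_mask, k=k, seed=seed, n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# Segment -> ROI naming
# ---------------------------------------------------------------------------

@dataclass
class ROISet:
    """Mapping from segment labels to named histological compartments."""

    segmentation: SegmentationMap | None
    mapping: dict[int, str]
    pixel_counts: dict[str, int] = field(default_factory=dict)
    _label_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in self.mapping.values():
            if name not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {name!r}")
        if not self.pixel_counts:
            grid = self.labels
            self.pixel_counts = {
                name: int(sum((grid == l).sum() for l, n in self.mapping.items() if n == name))
                for name in set(self.mapping.values())
            }

    @property
    def labels(self) -> np.ndarray:
        if self._label_grid is not None:
            return self._label_grid
        return self.segmentation.labels

    @classmethod
    def from_label_grid(cls, labels: np.ndarray, mapping: Mapping[int, str]) -> "ROISet":
        """Build an ROISet directly from a ground-truth label grid."""
        return cls(segmentation=None, mapping=dict(mapping), _label_grid=np.asarray(labels))

    def mask_for(self, compartment: str) -> np.ndarray:
        grid = self.labels
        out = np.zeros(grid.shape, dtype=bool)
        for label, name in self.mapping.items():
            if name == compartment:
                out |= grid == label
        return out

    def has_quantified_compartments(self) -> bool:
        return all(self.mask_for(c).any() for c in QUANTIFIED_COMPARTMENTS)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        payload = {
            "mapping": {int(k): v for k, v in self.mapping.items()},
            "pixel_counts": {k: int(v) for k, v in self.pixel_counts.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _ring_score(mask: np.ndarray) -> float:
    """Perimeter²/area of a segment; thin rings score far above compact blobs."""
    from skimage import measure

    labelled = measure.label(mask, connectivity=1)
    perimeter = 0.0
    area = 0.0
    for region in measure.regionprops(labelled):
        perimeter += region.perimeter
        area += region.area
    if area == 0:
        return 0.0
    return perimeter**2 / area


def _adjacent(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    grown = ndimage.binary_dilation(mask_a, structure=np.ones((3, 3), dtype=bool))
    return bool((grown & mask_b).any())


def segments_to_rois(
    segmentation: SegmentationMap,
    marker_images: Mapping[str, IonImage],
    tic_grid: np.ndarray,
    ring_score_threshold: float = 25.0,
    min_segment_fraction: float = 0.005,
    marker_gate_fraction: float = 0.5,
) -> ROISet:
    """Name segments as histological compartments by marker enrichment.

    Ranking rules (all thresholds configurable):

    1. highest mean PC(32:0) (``marker_alveolar``) → ``alveolar``;
    2. among the rest, the highest-mean PC(36:4) (``marker_bronchiolar``)
       segment whose shape is ring-like (perimeter²/area above
       ``ring_score_threshold``) → ``epithelium``;
    3. the segment adjacent to the epithelium with the next-highest PC(36:4)
       → ``sub_epithelium``;
    4. highest mean Heme b (``marker_vessel``) among the rest → ``vessel``;
    5. the lowest-TIC segment → ``lumen_or_background``; leftovers are
       ``unassigned``.

    Robustness guards: segments smaller than ``min_segment_fraction`` of the
    labelled area are excluded from the marker rankings (noise scraps can
    otherwise narrowly win a mean-intensity contest), and only segments whose
    bronchiolar-marker mean reaches ``marker_gate_fraction`` of the top
    candidate's are eligible for the ring-shape test (a background frame also
    has a high perimeter²/area and must never inherit the epithelium name).

    ``marker_images`` must be TIC-normalized and keyed by role
    (``marker_alveolar``, ``marker_bronchiolar``, ``marker_vessel``).
    """
    if segmentation.k_actual < 3:
        raise ValueError(
            f"need at least 3 segments for ROI naming, got k={segmentation.k_actual}"
        )
    for role in ("marker_alveolar", "marker_bronchiolar", "marker_vessel"):
        if role not in marker_images:
            raise ValueError(f"segments_to_rois: missing marker image for {role}")
        if not marker_images[role].normalized:
            raise ValueError(f"marker image {role} must be TIC-normalized")

    labels = segmentation.labels
    ids = [int(l) for l in segmentation.segment_ids]
    counts = segmentation.pixel_counts()
    min_count = min_segment_fraction * sum(counts.values())
    ranked_pool = [l for l in ids if counts[l] >= min_count]
    if len(ranked_pool) < 3:
        ranked_pool = list(ids)

    def seg_mean(image: IonImage, label: int) -> float:
        vals = image.values(mask=labels == label)
        return float(vals.mean()) if vals.size else 0.0

    mapping: dict[int, str] = {}
    remaining = list(ids)
    pool = list(ranked_pool)

    def claim(label: int, name: str) -> None:
        mapping[label] = name
        remaining.remove(label)
        if label in pool:
            pool.remove(label)

    alveolar = max(pool, key=lambda l: seg_mean(marker_images["marker_alveolar"], l))
    claim(alveolar, "alveolar")

    by_bronchiolar = sorted(
        pool,
        key=lambda l: seg_mean(marker_images["marker_bronchiolar"], l),
        reverse=True,
    )
    epithelium = None
    if by_bronchiolar:
        top_mean = seg_mean(marker_images["marker_bronchiolar"], by_bronchiolar[0])
        eligible = [
            l for l in by_bronchiolar
            if seg_mean(marker_images["marker_bronchiolar"], l)
            >= marker_gate_fraction * top_mean
        ]
        for cand in eligible:
            if _ring_score(labels == cand) >= ring_score_threshold:
                epithelium = cand
                break
        if epithelium is None:
            # no ring-shaped candidate among enriched segments: marker only
            epithelium = by_bronchiolar[0]
            logger.warning(
                "segments_to_rois: no ring-like segment; epithelium by marker only"
            )
    if epithelium is not None:
        claim(epithelium, "epithelium")
        sub_candidates = [
            l for l in pool if _adjacent(labels == epithelium, labels == l)
        ]
        if sub_candidates:
            sub = max(
                sub_candidates,
                key=lambda l: seg_mean(marker_images["marker_bronchiolar"], l),
            )
            claim(sub, "sub_epithelium")

    if pool:
        vessel = max(pool, key=lambda l: seg_mean(marker_images["marker_vessel"], l))
        claim(vessel, "vessel")

    if remaining:
        def seg_tic(label: int) -> float:
            sel = (labels == label) & np.isfinite(tic_grid)
            return float(tic_grid[sel].mean()) if sel.any() else 0.0

        low = min(remaining, key=seg_tic)
        mapping[low] = "lumen_or_background"
        remaining.remove(low)

    for l in remaining:
        mapping[l] = "unassigned"

    roiset = ROISet(segmentation=segmentation, mapping=mapping)
    logger.info("segments_to_rois: %s", {l: n for l, n in sorted(mapping.items())})
    return roiset
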