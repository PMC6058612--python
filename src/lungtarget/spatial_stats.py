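"""Image statistics: pixel heterogeneity, spatial correlation, ROI means, t-test.

These are the whole-section statistics used to characterise drug distribution:

* pixel-to-pixel relative standard deviation (RSD in %) quantifies how patchy
  a distribution is — an inhaled aerosol deposits in a localized, sporadic
  manner and shows far higher RSD than the same drug arriving via blood;
* Pearson correlation between ion images (reported in %) measures spatial
  colocalization of a drug with endogenous histology markers;
* per-ROI mean intensity is the quantity that plasma normalization and
  targeting factors are built on;
* a classical two-sided Student's t-test compares groups of such statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .msi_core import IonImage


@dataclass
class HeterogeneityResult:
    """Pixel-to-pixel heterogeneity of one ion image over a mask."""

    rsd_percent: float
    n_pixels: int
    analyte: str
    route: str = ""

    def __post_init__(self) -> None:
        if self.rsd_percent < 0:
            raise ValueError("rsd_percent must be >= 0")
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")


def pixel_rsd(
    ion_image: IonImage, mask: np.ndarray, route: str = ""
) -> HeterogeneityResult:
    """Relative standard deviation (%) over masked pixels.

    Uses the sample (n−1) standard deviation divided by the mean, times 100.
    """
    values = ion_image.values(mask=mask)
    if values.size < 2:
        raise ValueError("pixel_rsd requires at least 2 masked pixels")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("pixel_rsd undefined: mean intensity is not positive")
    sd = values.std(ddof=1)
    return HeterogeneityResult(
        rsd_percent=float(sd / mean * 100.0),
        n_pixels=int(values.size),
        analyte=ion_image.analyte.name,
        route=route,
    )


def pearson_image_correlation(
    image_a: IonImage, image_b: IonImage, mask: np.ndarray | None = None
) -> float:
    """Pearson r between two ion images over shared masked pixels, in %."""
    if image_a.shape != image_b.shape:
        raise ValueError("images have different grid shapes")
    shared = image_a.finite_mask & image_b.finite_mask
    if mask is not None:
        shared &= mask
    a = image_a.grid[shared]
    b = image_b.grid[shared]
    if a.size < 3:
        raise ValueError("need at least 3 shared masked pixels")
    for name, v in ((image_a.analyte.name, a), (image_b.analyte.name, b)):
        if np.ptp(v) == 0:
            raise ValueError(f"image {name!r} is constant on the mask")
    r, _p = stats.pearsonr(a, b)
    return float(r * 100.0)


def correlation_table(
    images: Mapping[str, IonImage], mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Symmetric table of pairwise Pearson correlations between ion images (%).

    Full precision is retained; round for display to match conventional
    whole-percent reporting.
    """
    names = list(images)
    table = pd.DataFrame(np.eye(len(names)) * 100.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = pearson_image_correlation(images[a], images[b], mask)
            table.loc[a, b] = r
            table.loc[b, a] = r
    return table


def roi_mean_intensity(
    ion_image: IonImage, roi_mask: np.ndarray
) -> tuple[float, int]:
    """Arithmetic mean intensity over an ROI; missing pixels excluded.

    Returns ``(mean, n_pixels)``.
    """
    values = ion_image.values(mask=roi_mask)
    if values.size == 0:
        raise ValueError("roi_mean_intensity: ROI is empty")
    return float(values.mean()), int(values.size)


def two_sided_t_test(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False
) -> float:
    """Two-sided two-sample Student's t-test p-value (pooled variance).

    Set ``welch=True`` for the unequal-variance variant.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    result = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(result.pvalue)
    if np.isnan(p):  # identical constant groups: t = 0/0, no evidence at all
        return 1.0
    return p
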