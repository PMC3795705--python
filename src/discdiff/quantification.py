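"""ROI-level enhancement and CSF-adjusted T2 signal quantification.

Enhancement of a region at a post-contrast time point is the difference of
ROI-mean signal intensities, post minus pre, with no normalization by the
pre-contrast value (normalizing would only re-introduce variability that
has nothing to do with contrast-agent concentration).  Disc hydration is
summarized by the CSF-adjusted T2-weighted signal intensity: the mean T2
signal over the central + peripheral disc divided by the mean of a 3x5
pixel reference rectangle placed in cerebrospinal fluid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import ImageSeries
from .segmentation import DiscROIs, ROI_LABELS

log = logging.getLogger(__name__)

__all__ = [
    "QuantResult",
    "roi_mean",
    "csf_mask",
    "compute_enhancement",
    "compute_csf_adj_t2",
    "assemble_timecurves",
]

#: CSF reference rectangle: 5 rows x 3 columns (a vertically elongated
#: patch matching the canal), anchored by its top-left corner.
CSF_RECT_SHAPE = (5, 3)


@dataclass(frozen=True)
class QuantResult:
    """CSF-adjusted T2 signal intensity of one disc."""

    disc_id: str
    csf_adj_t2: float
    disc_mean: float  # mean T2 over Central + both Peripheral layers
    csf_mean: float


def roi_mean(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the pixel intensities under a boolean mask."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI mask")
    return float(image[mask].mean())


def csf_mask(image_shape: tuple[int, int], rect: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the 5x3 CSF reference rectangle at top-left ``rect``."""
    r0, c0 = rect
    nr, nc = CSF_RECT_SHAPE
    rows, cols = image_shape
    if r0 < 0 or c0 < 0 or r0 + nr > rows or c0 + nc > cols:
        raise ValueError("CSF rectangle does not fit inside the image")
    m = np.zeros(image_shape, dtype=bool)
    m[r0:r0 + nr, c0:c0 + nc] = True
    return m


def compute_enhancement(series: ImageSeries, rois: DiscROIs) -> pd.DataFrame:
    """Per-ROI, per-time-point enhancement table for one disc.

    Returns a tidy frame with one row per (roi, post-contrast time point):
    columns ``disc_id, roi, time, enhancement, pre_mean, post_mean,
    pixel_count`` where ``enhancement = post_mean - pre_mean`` exactly.
    A missing time point is skipped with a log message.
    """
    labels = series.labels
    if "PRE" not in series.images:
        raise ValueError("series lacks a PRE image")
    pre = series.images["PRE"]
    rows = []
    for roi in ROI_LABELS:
        mask = rois.masks[roi]
        if not mask.any():
            log.warning("disc %s: ROI %s is empty, skipped", series.disc_id, roi)
            continue
        pre_mean = roi_mean(pre, mask)
        for label in labels:
            if label == "PRE":
                continue
            if label not in series.images:
                log.warning("disc %s: time point %s missing, column absent",
                            series.disc_id, label)
                continue
            post_mean = roi_mean(series.images[label], mask)
            rows.append({
                "disc_id": series.disc_id,
                "roi": roi,
                "time": label,
                "enhancement": post_mean - pre_mean,
                "pre_mean": pre_mean,
                "post_mean": post_mean,
                "pixel_count": int(mask.sum()),
            })
    return pd.DataFrame(rows)


def compute_csf_adj_t2(
    t2_image: np.ndarray, rois: DiscROIs, csf_rect: tuple[int, int]
) -> QuantResult:
    """CSF-adjusted T2-weighted signal intensity of one disc.

    Ratio of the mean T2 intensity over Central + upper/lower Peripheral
    disc to the mean over the 5x3 CSF reference rectangle.  Invariant to
    global intensity scaling; requires a positive CSF mean.
    """
    disc = rois.combined(("Central", "Peripheral_upper", "Peripheral_lower"))
    csf = csf_mask(t2_image.shape, csf_rect)
    disc_mean = roi_mean(t2_image, disc)
    csf_mean = roi_mean(t2_image, csf)
    if csf_mean <= 0:
        raise ValueError("CSF reference mean is non-positive")
    return QuantResult(
        disc_id=rois.disc_id,
        csf_adj_t2=disc_mean / csf_mean,
        disc_mean=disc_mean,
        csf_mean=csf_mean,
    )


def assemble_timecurves(
    table: pd.DataFrame, subset: list[str] | None = None
) -> pd.DataFrame:
    """Median and quartiles of enhancement per ROI per time point.

    ``subset`` restricts the summary to the given disc ids (the
    defect-free subset for time-curve profiling).  Quantiles use linear
    interpolation (numpy default).
    """
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("subset is empty")
        table = table[table["disc_id"].isin(subset)]
    if table.empty:
        raise ValueError("no enhancement rows to summarize")

    def q(s: pd.Series) -> pd.Series:
        return pd.Series({
            "median": s.median(),
            "q25": s.quantile(0.25),
            "q75": s.quantile(0.75),
            "n": s.size,
        })

    out = (
        table.groupby(["roi", "time"])["enhancement"].apply(q).unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
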