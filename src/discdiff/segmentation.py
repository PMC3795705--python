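"""Landmark-based layered ROI construction for sagittal disc slices.

An operator (or the phantom generator) supplies three points per endplate
border — ``A`` anterior, ``B`` intermediate, ``C`` posterior — for each
intervertebral disc.  From those six points this module derives

* the disc height (mean of the two border-to-border distances at the A and
  C columns, converted to mm),
* five layered disc ROIs — upper/lower endplate zone (EPZ), upper/lower
  peripheral disc, and central disc — each endplate-adjacent band being
  one fifth of the local disc thickness,
* a subchondral-bone (SCB) band of fixed 6-pixel thickness on either side
  of the disc, separated from it by a 1-pixel gap,

plus the cohort bookkeeping: exclusion of unsegmentable levels (height
<= 3 mm, severe spondylolisthesis) and selection of the defect-free,
Modic-free subset used for time-curve profiling.

Coordinates are 0-based ``(row, col)`` with row increasing downward; a
pixel's center sits at its integer index.  Sub-pixel landmark positions
are allowed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "DiscGeometry",
    "DiscROIs",
    "ROI_LABELS",
    "DISC_LAYERS",
    "SCB_THICKNESS_PX",
    "SCB_GAP_PX",
    "estimate_disc_height",
    "build_disc_rois",
    "apply_exclusions",
    "select_timecurve_subset",
]

#: All seven ROI labels, cranial to caudal.
ROI_LABELS = (
    "SCB_upper",
    "EPZ_upper",
    "Peripheral_upper",
    "Central",
    "Peripheral_lower",
    "EPZ_lower",
    "SCB_lower",
)

#: The five disc layers (ROI labels between the two borders).
DISC_LAYERS = ROI_LABELS[1:-1]

#: Fixed SCB band thickness in pixels (4.98 mm at 0.83 mm/pixel).
SCB_THICKNESS_PX = 6
#: One-pixel band separating SCB from the disc (the grey bone-disc border).
SCB_GAP_PX = 1

# Normalized-depth band edges for the five disc layers.
_BAND_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class LandmarkSet:
    """Six labelled border points for one disc.

    ``upper`` and ``lower`` are ``(3, 2)`` arrays of ``(row, col)`` pixel
    coordinates for points A, B, C (anterior to posterior) on the upper
    and lower endplate border respectively.
    """

    disc_id: str
    upper: np.ndarray
    lower: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        up = np.asarray(self.upper, dtype=float)
        lo = np.asarray(self.lower, dtype=float)
        object.__setattr__(self, "upper", up)
        object.__setattr__(self, "lower", lo)
        if up.shape != (3, 2) or lo.shape != (3, 2):
            raise ValueError("each border needs exactly 3 (row, col) points")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        for pts, name in ((up, "upper"), (lo, "lower")):
            if not (pts[0, 1] < pts[1, 1] < pts[2, 1]):
                raise ValueError(
                    f"{name} border points must be ordered anterior->posterior "
                    "(strictly increasing column)"
                )
        # Upper border must lie strictly above (smaller row) the lower one
        # at the anterior and posterior landmark columns.
        if not (up[0, 0] < lo[0, 0] and up[2, 0] < lo[2, 0]):
            raise ValueError("upper border must lie above lower border at A and C")


@dataclass(frozen=True)
class DiscGeometry:
    """Disc height and the rasterized border ordinates per image column."""

    height_mm: float
    columns: np.ndarray  # integer image columns spanned by the disc
    upper_rows: np.ndarray  # border row ordinate at each column (float)
    lower_rows: np.ndarray


@dataclass
class DiscROIs:
    """Seven labelled boolean masks plus the disc geometry."""

    disc_id: str
    masks: dict[str, np.ndarray]
    geometry: DiscGeometry

    def layer_area(self) -> int:
        return int(sum(self.masks[k].sum() for k in DISC_LAYERS))

    def combined(self, labels) -> np.ndarray:
        out = np.zeros_like(self.masks[ROI_LABELS[0]])
        for k in labels:
            out |= self.masks[k]
        return out


def estimate_disc_height(lms: LandmarkSet) -> float:
    """Disc height in mm: pixel spacing times the mean of |A1A2| and |C1C2|."""
    d_a = float(np.linalg.norm(lms.upper[0] - lms.lower[0]))
    d_c = float(np.linalg.norm(lms.upper[2] - lms.lower[2]))
    if d_a == 0.0 or d_c == 0.0:
        raise ValueError("degenerate landmark pair: coincident border points")
    return lms.pixel_spacing * 0.5 * (d_a + d_c)


def _border_interp(points: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Row ordinate of the piecewise-linear border through A, B, C."""
    return np.interp(cols, points[:, 1], points[:, 0])


def _band_index(u: np.ndarray) -> np.ndarray:
    """Map normalized depth u in [0,1] to layer index 0..4.

    A u value exactly on an interior band edge is assigned to the band
    closer to the disc center (u=0.2 -> peripheral upper, u=0.4 and 0.6 ->
    central, u=0.8 -> peripheral lower).
    """
    scaled = u * 5.0
    idx = np.floor(scaled).astype(int)
    on_edge = scaled == np.round(scaled)
    idx = np.where(on_edge & (idx >= 3), idx - 1, idx)
    return np.clip(idx, 0, 4)


def build_disc_rois(lms: LandmarkSet, image_shape: tuple[int, int]) -> DiscROIs:
    """Construct the layered disc ROIs and SCB bands from six landmarks.

    The endplate borders are piecewise-linear polylines through (A, B, C).
    For every image column between the anterior and posterior landmark
    columns a normalized depth u runs from the upper border (u=0) to the
    lower border (u=1); a pixel joins the u-band containing its center.
    The five disc layers partition the inter-border region into fifths of
    the local thickness (the central band spanning [0.4, 0.6]).  SCB bands
    extend ``SCB_THICKNESS_PX`` pixels beyond each border along the image
    column direction, after a ``SCB_GAP_PX`` gap.
    """
    n_rows, n_cols = image_shape
    c_lo = max(lms.upper[0, 1], lms.lower[0, 1])
    c_hi = min(lms.upper[2, 1], lms.lower[2, 1])
    cols = np.arange(math.ceil(c_lo), math.floor(c_hi) + 1)
    if cols.size == 0:
        raise ValueError("disc spans no pixel column")
    up = _border_interp(lms.upper, cols)
    lo = _border_interp(lms.lower, cols)
    if np.any(lo <= up):
        raise ValueError("endplate borders cross or touch between A and C")

    masks = {k: np.zeros((n_rows, n_cols), dtype=bool) for k in ROI_LABELS}
    clipped = False

    rows = np.arange(n_rows, dtype=float)[:, None]  # pixel-center row ordinates
    upg = up[None, :]
    log = lo[None, :]
    inside = (rows >= upg) & (rows <= log)
    u = np.zeros_like(inside, dtype=float)
    u[inside] = ((rows - upg) / (log - upg))[inside]
    band = _band_index(u)
    layer_names = ("EPZ_upper", "Peripheral_upper", "Central",
                   "Peripheral_lower", "EPZ_lower")
    for b, name in enumerate(layer_names):
        sel = inside & (band == b)
        masks[name][:, cols] = sel

    gap = float(SCB_GAP_PX)
    thick = float(SCB_THICKNESS_PX)
    scb_u = (rows >= upg - gap - thick) & (rows < upg - gap)
    scb_l = (rows > log + gap) & (rows <= log + gap + thick)
    masks["SCB_upper"][:, cols] = scb_u
    masks["SCB_lower"][:, cols] = scb_l

    # The analytic SCB extent may poke past the image; report, don't fail.
    if np.any(up - gap - thick < -0.5) or np.any(lo + gap + thick > n_rows - 0.5):
        clipped = True
    if clipped:
        warnings.warn(
            f"disc {lms.disc_id}: SCB band clipped at the image boundary",
            stacklevel=2,
        )

    geometry = DiscGeometry(
        height_mm=estimate_disc_height(lms),
        columns=cols,
        upper_rows=up,
        lower_rows=lo,
    )
    return DiscROIs(disc_id=lms.disc_id, masks=masks, geometry=geometry)


#: Disc height at or below this value (mm) is unsegmentable and excluded.
HEIGHT_EXCLUSION_MM = 3.0


def apply_exclusions(
    meta: pd.DataFrame, heights: dict[str, float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop unsegmentable levels and return (retained metadata, exclusion log).

    A level is excluded for severe spondylolisthesis (flag in ``meta``), for
    a disc height <= 3 mm (inclusive), or when no height is available at
    all.  ``heights`` optionally overrides/augments the ``height_mm``
    column (keyed by disc_id).
    """
    meta = meta.copy()
    if heights is not None:
        meta["height_mm"] = meta["disc_id"].map(heights).combine_first(
            meta.get("height_mm", pd.Series(np.nan, index=meta.index))
        )
    if "height_mm" not in meta.columns:
        meta["height_mm"] = np.nan

    records = []
    keep = np.ones(len(meta), dtype=bool)
    for i, row in enumerate(meta.itertuples(index=False)):
        if getattr(row, "spondylolisthesis", False):
            records.append((row.disc_id, "severe spondylolisthesis"))
            keep[i] = False
        elif pd.isna(row.height_mm):
            records.append((row.disc_id, "unsegmentable"))
            keep[i] = False
        elif row.height_mm <= HEIGHT_EXCLUSION_MM:
            records.append((row.disc_id, f"height <= {HEIGHT_EXCLUSION_MM} mm"))
            keep[i] = False
    log = pd.DataFrame(records, columns=["disc_id", "reason"])
    return meta.loc[keep].reset_index(drop=True), log


def select_timecurve_subset(meta: pd.DataFrame) -> list[str]:
    """Disc ids with smooth, defect-free, Modic-free endplates.

    Keeps discs with no endplate defect on either side, no irregular
    endplate, and Modic type "0" at both endplates — the subset on which
    the enhancement-over-time profile is meaningful.
    """
    ok = (
        ~meta["defect_upper"].astype(bool)
        & ~meta["defect_lower"].astype(bool)
        & ~meta["irregular"].astype(bool)
        & (meta["mc_upper"].astype(str) == "0")
        & (meta["mc_lower"].astype(str) == "0")
    )
    return meta.loc[ok, "disc_id"].tolist()
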