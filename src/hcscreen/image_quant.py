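"""Per-nucleus image quantification for the high-content screen readout.

Mirrors the screen's image-analysis chain: nuclei are segmented from the
DAPI channel, each nucleus ROI is measured for mean intensity in the
reporter (YFP) channel, shape outliers (roundness below threshold, mostly
segmentation artifacts) and border-touching nuclei are discarded, and the
well value is the unweighted average of the surviving per-nucleus means.

Segmentation recipe (deterministic, standard): Gaussian smoothing, global
Otsu threshold, hole filling, distance-transform-seeded watershed to split
touching nuclei, then a minimum-area speckle filter.

Roundness is 4*pi*area / perimeter**2 clipped to [0, 1].  The perimeter
estimator is the 4-direction Crofton approximation (each 2x2 pixel
configuration contributes a fixed length increment from the Crofton
integral-geometry formula), implemented here directly.  A digitized disk
scores ~1 under this estimator while thin or ragged objects score far
below it, so the conventional 0.775 cutoff separates round nuclei from
segmentation artifacts as intended.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi, sqrt

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

DEFAULT_MIN_ROUNDNESS = 0.775
DEFAULT_MIN_AREA = 50  # px, at the default 256x256 render scale

_SQRT2 = sqrt(2.0)
# Crofton length increment per 2x2 pixel configuration, indexed by
# code = BR + 4*BL + 2*TR + 8*TL over the window's four pixels
_CROFTON_WEIGHTS = np.zeros(16)
_CROFTON_WEIGHTS[[1, 5]] = pi / 4.0 * (1.0 + 1.0 / _SQRT2)
_CROFTON_WEIGHTS[[2, 7, 10, 11]] = pi / (4.0 * _SQRT2)
_CROFTON_WEIGHTS[3] = pi / (2.0 * _SQRT2)
_CROFTON_WEIGHTS[[8, 12]] = pi / 4.0
_CROFTON_WEIGHTS[[9, 13]] = pi / 2.0


def region_perimeter(mask: np.ndarray) -> float:
    """Perimeter of a binary region by the 4-direction Crofton formula.

    Every 2x2 window of the zero-padded mask is classified into one of 16
    configurations; each configuration contributes a fixed length increment
    derived from the Crofton integral over 4 directions.  Image edges count
    as background.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    p = np.pad(mask, 1).astype(np.uint8)
    tl = p[:-1, :-1]
    tr = p[:-1, 1:]
    bl = p[1:, :-1]
    br = p[1:, 1:]
    code = br + 4 * bl + 2 * tr + 8 * tl
    return float(_CROFTON_WEIGHTS[code].sum())


def compute_roundness(mask: np.ndarray) -> float:
    """Roundness 4*pi*A/P^2 of a binary region, clipped to [0, 1].

    Raises ``ValueError`` on an empty region.  Tiny regions whose Crofton
    ratio exceeds 1 (single pixels, small squares) clip to 1.0.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty region has no roundness")
    perim = region_perimeter(mask)
    if perim == 0.0:
        return 1.0
    return float(np.clip(4.0 * pi * area / perim**2, 0.0, 1.0))


def segment_nuclei(
    dapi: np.ndarray,
    *,
    smooth_sigma: float = 1.0,
    min_area: int = DEFAULT_MIN_AREA,
    min_seed_distance: int = 8,
) -> np.ndarray:
    """Segment nuclei from a DAPI image into a labeled mask.

    Gaussian smoothing -> global Otsu threshold -> hole fill ->
    distance-transform-seeded watershed (splits touching nuclei) ->
    minimum-area filter.  A constant image yields an empty (all-zero) mask.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("DAPI image must be 2D")
    if np.ptp(dapi) == 0:
        return np.zeros(dapi.shape, dtype=np.int32)
    smoothed = gaussian(dapi, sigma=smooth_sigma, preserve_range=True)
    thr = threshold_otsu(smoothed)
    binary = smoothed > thr
    binary = ndi.binary_fill_holes(binary)
    if min_area > 1:
        comp = cc_label(binary)
        sizes = np.bincount(comp.ravel())
        binary = (comp > 0) & (sizes[comp] >= min_area)
    if not binary.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=min_seed_distance,
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return cc_label(binary).astype(np.int32)
    labels = watershed(-distance, markers, mask=binary)
    if min_area > 1:
        # watershed fragments below the area floor are dropped
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_area)
        labels[np.isin(labels, small[small > 0])] = 0
    return _relabel_sequential(labels)


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def measure_nuclei(labels: np.ndarray, yfp: np.ndarray) -> pd.DataFrame:
    """Measure every labeled nucleus: geometry, roundness, border contact,
    and mean reporter intensity over the ROI.

    Returns a table with columns ``label, area, perimeter, roundness,
    touches_border, centroid_row, centroid_col, mean_yfp``.
    """
    labels = np.asarray(labels)
    yfp = np.asarray(yfp, dtype=float)
    if labels.shape != yfp.shape:
        raise ValueError("label mask and intensity image differ in shape")
    rows = []
    nrow, ncol = labels.shape
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        area = int(mask.sum())
        perim = region_perimeter(mask)
        roundness = compute_roundness(mask)
        rr, cc = np.nonzero(mask)
        touches = bool(
            rr.min() == 0 or cc.min() == 0 or rr.max() == nrow - 1 or cc.max() == ncol - 1
        )
        rows.append(
            (
                int(lab),
                area,
                perim,
                roundness,
                touches,
                float(rr.mean()),
                float(cc.mean()),
                float(yfp[mask].mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "area",
            "perimeter",
            "roundness",
            "touches_border",
            "centroid_row",
            "centroid_col",
            "mean_yfp",
        ],
    )


def filter_nuclei(
    records: pd.DataFrame,
    min_roundness: float = DEFAULT_MIN_ROUNDNESS,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Keep nuclei with roundness >= threshold (boundary value kept) that do
    not touch the image border (when border exclusion is on)."""
    keep = records["roundness"] >= min_roundness
    if exclude_border:
        keep &= ~records["touches_border"].astype(bool)
    return records.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class WellQuant:
    """Per-well summary of the nucleus measurements."""

    n_nuclei_total: int
    n_nuclei_kept: int
    well_mean_of_means: float  # NaN when no nucleus survives filtering
    yfp_per_nucleus_ratio: float

    @property
    def is_missing(self) -> bool:
        return self.n_nuclei_kept == 0


def summarize_well(kept: pd.DataFrame, n_total: int | None = None) -> WellQuant:
    """Summarize filtered nucleus records into the well readout.

    The well value is the unweighted mean of the per-nucleus mean reporter
    intensities (every cell weighted equally, not pooled by pixel).  The
    companion ratio readout divides the summed per-nucleus mean signal by
    the total nucleus count.  A well with zero kept nuclei is flagged
    missing (NaN value) and is excluded downstream.
    """
    n_kept = len(kept)
    if n_total is None:
        n_total = n_kept
    if n_kept == 0:
        return WellQuant(int(n_total), 0, float("nan"), float("nan"))
    means = kept["mean_yfp"].to_numpy(dtype=float)
    mom = float(means.mean())
    ratio = float(means.sum() / n_total) if n_total > 0 else float("nan")
    return WellQuant(int(n_total), n_kept, mom, ratio)


def quantify_well(
    dapi: np.ndarray,
    yfp: np.ndarray,
    *,
    min_roundness: float = DEFAULT_MIN_ROUNDNESS,
    exclude_border: bool = True,
    smooth_sigma: float = 1.0,
    min_area: int = DEFAULT_MIN_AREA,
) -> tuple[pd.DataFrame, WellQuant]:
    """Full per-well chain: segment, measure, filter, summarize."""
    labels = segment_nuclei(dapi, smooth_sigma=smooth_sigma, min_area=min_area)
    records = measure_nuclei(labels, yfp)
    kept = filter_nuclei(records, min_roundness=min_roundness, exclude_border=exclude_border)
    return records, summarize_well(kept, n_total=len(records))
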