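"""Spot-level quantitative immunofluorescence.

Measures fluorescence at annotated centromeric / non-centromeric spots on
chromosome-spread images: the maximum pixel value in a small square box
(default 8x8 px) at each spot, background-corrected by the average of the
per-box maxima of four seeded-random, mutually disjoint 8x8 boxes placed in
the cytoplasm of the same cell.  Corrected intensity = spot max - background
(negative values are kept, not clipped, and flagged).  Per-condition
summaries report mean +/- s.e.m. and fold change against a reference
condition, and two significance tests are provided: the unpaired two-tailed
t-test (equal-variance Student's by default, Welch optional) and one-way
ANOVA with Tukey's HSD post hoc test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BOX_SIZE = 8
DEFAULT_N_BACKGROUND_BOXES = 4


def _box_origin(center: tuple[float, float], box_size: int) -> tuple[int, int]:
    """Top-left corner of a box_size x box_size box around a center.

    The center pixel sits at offset ``box_size // 2 - 1`` (for the default
    8x8 box the center is the 4th pixel, rows/cols center-3 .. center+4).
    """
    r = int(round(center[0])) - (box_size // 2 - 1) - 1
    c = int(round(center[1])) - (box_size // 2 - 1) - 1
    return r + 1, c + 1


def spot_max_in_box(
    image: np.ndarray, center: tuple[float, float], box_size: int = DEFAULT_BOX_SIZE
) -> float:
    """Maximum pixel value in the box drawn around a spot center.

    Raises ``ValueError`` when the box would be clipped by the image edge.
    """
    image = np.asarray(image)
    r0, c0 = _box_origin(center, box_size)
    r1, c1 = r0 + box_size, c0 + box_size
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise ValueError(
            f"{box_size}x{box_size} box at {center} extends outside the image"
        )
    return float(image[r0:r1, c0:c1].max())


def estimate_background(
    image: np.ndarray,
    cytoplasm_mask: np.ndarray,
    n_boxes: int = DEFAULT_N_BACKGROUND_BOXES,
    box_size: int = DEFAULT_BOX_SIZE,
    seed: int | np.random.Generator = 0,
) -> float:
    """Average of per-box maxima over seeded-random disjoint boxes in the
    cytoplasm.

    Boxes must lie entirely inside the mask and must not overlap each
    other.  Raises ``ValueError`` when the mask cannot host ``n_boxes``
    disjoint boxes.
    """
    image = np.asarray(image)
    mask = np.asarray(cytoplasm_mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # positions whose full box fits in the mask
    from scipy.ndimage import minimum_filter

    fits = minimum_filter(mask.astype(np.uint8), size=box_size, mode="constant", cval=0)
    # minimum_filter is centered; convert to top-left-corner indexing
    off = box_size // 2
    valid = np.zeros_like(mask)
    h, w = mask.shape
    valid[: h - box_size + 1, : w - box_size + 1] = (
        fits[off : h - box_size + 1 + off, off : w - box_size + 1 + off] == 1
    )
    candidates = np.flatnonzero(valid.ravel())
    if candidates.size < n_boxes:
        raise ValueError("cytoplasm mask too small for the requested boxes")

    chosen: list[tuple[int, int]] = []
    maxima: list[float] = []
    order = rng.permutation(candidates)
    for flat in order:
        r0, c0 = divmod(int(flat), w)
        if any(abs(r0 - pr) < box_size and abs(c0 - pc) < box_size for pr, pc in chosen):
            continue
        chosen.append((r0, c0))
        maxima.append(float(image[r0 : r0 + box_size, c0 : c0 + box_size].max()))
        if len(chosen) == n_boxes:
            break
    if len(chosen) < n_boxes:
        raise ValueError("could not place disjoint background boxes in the mask")
    return float(np.mean(maxima))


def corrected_intensity(raw_max: float, background: float) -> float:
    """Background-corrected spot intensity (may be negative; not clipped)."""
    return float(raw_max) - float(background)


@dataclass(frozen=True)
class SpotMeasurement:
    """One measured spot box."""

    row: float
    col: float
    box_size: int
    spot_class: str  # centromeric | noncentromeric
    raw_max: float
    background: float

    @property
    def corrected(self) -> float:
        return corrected_intensity(self.raw_max, self.background)


def measure_spots(
    image: np.ndarray,
    spots: pd.DataFrame,
    cytoplasm_mask: np.ndarray,
    *,
    box_size: int = DEFAULT_BOX_SIZE,
    n_background_boxes: int = DEFAULT_N_BACKGROUND_BOXES,
    seed: int = 0,
) -> pd.DataFrame:
    """Measure a list of annotated spots on one image.

    ``spots`` needs columns ``row, col, spot_class`` and optionally
    ``cell_id``; background is estimated once per cell (one set of four
    cytoplasm boxes per cell, as in the manual procedure), or once per
    image when no ``cell_id`` column is present.

    Returns the input annotations augmented with ``raw_max, background,
    corrected, negative_corrected`` columns.
    """
    rng = np.random.default_rng(seed)
    spots = spots.copy()
    if "cell_id" not in spots.columns:
        spots["cell_id"] = 0
    backgrounds = {
        cell: estimate_background(
            image, cytoplasm_mask, n_boxes=n_background_boxes, box_size=box_size, seed=rng
        )
        for cell in sorted(spots["cell_id"].unique())
    }
    raw = [
        spot_max_in_box(image, (r.row, r.col), box_size=box_size)
        for r in spots.itertuples()
    ]
    spots["raw_max"] = raw
    spots["background"] = spots["cell_id"].map(backgrounds)
    spots["corrected"] = spots["raw_max"] - spots["background"]
    spots["negative_corrected"] = spots["corrected"] < 0
    return spots


@dataclass(frozen=True)
class ConditionSummary:
    """Mean +/- s.e.m. of corrected spot intensities in one condition."""

    n: int
    mean: float
    sem: float
    fold_change_vs_reference: float  # NaN when no reference given


def condition_summary(
    values: np.ndarray | list[float],
    reference_values: np.ndarray | list[float] | None = None,
) -> ConditionSummary:
    """Summarize one condition: mean, s.e.m. (sample SD / sqrt(n)), and the
    mean ratio against a reference condition."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a summary")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    if reference_values is None:
        fold = float("nan")
    else:
        ref_mean = float(np.asarray(reference_values, dtype=float).mean())
        if ref_mean == 0.0:
            raise ValueError("reference condition has mean 0; fold change undefined")
        fold = mean / ref_mean
    return ConditionSummary(int(v.size), mean, sem, fold)


def two_sample_ttest(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Unpaired two-tailed t-test.  Returns ``(t, df, p)``.

    Equal-variance Student's test by default; ``equal_var=False`` gives
    Welch's test.  Two groups with zero variance and equal means return
    ``t = 0, p = 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0 and a.mean() == b.mean():
        df = a.size + b.size - 2 if equal_var else float(a.size + b.size - 2)
        return 0.0, float(df), 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anova_tukey(
    groups: list[np.ndarray | list[float]],
    labels: list[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey's HSD post hoc test.

    Returns ``(F, p, pairwise)`` where ``pairwise`` tabulates every group
    pair with its mean difference and studentized-range-adjusted p-value.
    Identical groups (zero between- and within-group variance) return
    ``F = 0, p = 1``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("ANOVA with Tukey post hoc needs >= 3 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]

    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0.0:
        pairwise = pd.DataFrame(
            [
                (labels[i], labels[j], 0.0, 1.0)
                for i in range(len(arrays))
                for j in range(i + 1, len(arrays))
            ],
            columns=["group_a", "group_b", "mean_diff", "p_adj"],
        )
        return 0.0, 1.0, pairwise

    fres = stats.f_oneway(*arrays)
    tres = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                (
                    labels[i],
                    labels[j],
                    float(arrays[i].mean() - arrays[j].mean()),
                    float(tres.pvalue[i, j]),
                )
            )
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adj"])
    return float(fres.statistic), float(fres.pvalue), pairwise
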