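"""Synthetic microscopy renders with exact ground truth.

Two fixture generators back the image-analysis stages:

* :func:`render_well_image` draws a two-channel (DAPI / reporter) field of
  nuclei as smoothed, optionally boundary-perturbed ellipses, and emits the
  ground-truth label mask and per-nucleus table alongside the images.
* :func:`render_metaphase_spread` draws Gaussian fluorescence spots (one
  bright centromeric focus per chromosome plus optional dimmer arm spots)
  on a flat background, emitting the ground-truth spot list and a
  cytoplasm mask for background-box placement.

All rendering is single-plane 2D.  Images default to unsigned 16-bit; the
number of saturated (clipped) pixels is logged.  Per-nucleus reporter means
are exact before blur and noise, so zero-noise renders round-trip exactly
through the quantification stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian

from .image_quant import compute_roundness

logger = logging.getLogger(__name__)

U16_MAX = 65535


@dataclass
class RenderParams:
    """Parameters of a synthetic well render."""

    image_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 50
    nucleus_radius_range: tuple[float, float] = (8.0, 14.0)
    irregularity: float = 0.0  # [0, 1]: boundary perturbation strength
    eccentricity: float = 0.15  # base ellipse axis asymmetry
    dapi_level: float = 3000.0
    focus_blur_sigma: float = 0.0
    poisson_noise: bool = False
    gaussian_noise_sd: float = 0.0
    foci_per_nucleus: int = 0
    foci_amplitude: float = 0.0
    foci_sigma: float = 1.2
    allow_overlap: bool = False
    placement_margin: float = 2.0
    dtype: str = "uint16"  # uint16 | float32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.irregularity <= 1.0):
            raise ValueError("irregularity must be in [0, 1]")
        if self.nucleus_radius_range[0] > self.nucleus_radius_range[1]:
            raise ValueError("nucleus_radius_range must be (low, high)")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.dtype not in ("uint16", "float32"):
            raise ValueError("dtype must be 'uint16' or 'float32'")


def _nucleus_polygon(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
    irregularity: float,
    eccentricity: float,
    n_vertices: int = 180,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertices of one nucleus boundary: an ellipse with optional smooth
    radial perturbation (low-frequency cosine modes)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ecc = rng.uniform(0.0, eccentricity)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    a = radius * (1.0 + ecc)
    b = radius / (1.0 + ecc)
    r_base = a * b / np.sqrt((b * np.cos(theta - phi0)) ** 2 + (a * np.sin(theta - phi0)) ** 2)
    if irregularity > 0:
        g = np.zeros_like(theta)
        for m in range(2, 7):
            g += rng.normal(0.0, 1.0 / m) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
        gmax = np.abs(g).max()
        if gmax > 0:
            g = g / gmax
        r_base = r_base * (1.0 + 0.6 * irregularity * g)
        r_base = np.maximum(r_base, 1.5)
    rr = center[0] + r_base * np.sin(theta)
    cc = center[1] + r_base * np.cos(theta)
    return rr, cc


def _place_nuclei(
    rng: np.random.Generator, params: RenderParams
) -> np.ndarray:
    """Ground-truth label mask with nuclei placed by rejection sampling."""
    h, w = params.image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    centers: list[tuple[float, float, float]] = []
    max_tries = 4000 * max(params.n_nuclei, 1)
    tries = 0
    lab = 0
    # boundary can bulge beyond the nominal radius through eccentricity and
    # irregularity; separation uses this worst-case effective radius so the
    # background corridor between nuclei is never pinched shut
    bulge = (1.0 + params.eccentricity) * (1.0 + 0.6 * params.irregularity)
    while lab < params.n_nuclei:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {params.n_nuclei} nuclei of radius "
                f"{params.nucleus_radius_range} in a {h}x{w} image "
                f"(placed {lab}); reduce n_nuclei or allow overlap"
            )
        tries += 1
        radius = rng.uniform(*params.nucleus_radius_range)
        margin = radius * bulge + 2.0
        cr = rng.uniform(margin, h - margin)
        cc = rng.uniform(margin, w - margin)
        if not params.allow_overlap:
            ok = True
            for pr, pc, prad in centers:
                limit = (radius + prad) * bulge + params.placement_margin
                if (cr - pr) ** 2 + (cc - pc) ** 2 < limit**2:
                    ok = False
                    break
            if not ok:
                continue
        rr, ccs = _nucleus_polygon(
            rng, (cr, cc), radius, params.irregularity, params.eccentricity
        )
        pr, pc = draw_polygon(rr, ccs, shape=(h, w))
        if pr.size == 0:
            continue
        if not params.allow_overlap and np.any(labels[pr, pc] > 0):
            continue
        lab += 1
        free = labels[pr, pc] == 0
        labels[pr[free], pc[free]] = lab
        centers.append((cr, cc, radius))
    return labels


def render_well_image(
    params: RenderParams, target_mean_yfp: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one synthetic well.

    Returns ``(dapi, yfp, truth_labels, truth_table)``.  Inside each
    nucleus the reporter channel is set so that its ROI mean equals
    ``target_mean_yfp`` exactly before blur and noise (centromere-like
    foci, if any, are compensated by lowering the diffuse level).  The
    truth table lists label, area, centroid, true mean reporter intensity,
    roundness of the emitted mask, and border contact.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    labels = _place_nuclei(rng, params)

    dapi = np.zeros((h, w), dtype=float)
    yfp = np.zeros((h, w), dtype=float)
    rows = []
    for lab in range(1, params.n_nuclei + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area == 0:  # fully occluded under allow_overlap
            continue
        dapi[mask] = params.dapi_level * rng.uniform(0.85, 1.15)
        patch = np.full(area, float(target_mean_yfp))
        if params.foci_per_nucleus > 0 and params.foci_amplitude > 0:
            rr, cc = np.nonzero(mask)
            foci = np.zeros(area)
            for _ in range(params.foci_per_nucleus):
                k = rng.integers(0, area)
                fr, fc = rr[k], cc[k]
                d2 = (rr - fr) ** 2.0 + (cc - fc) ** 2.0
                foci += params.foci_amplitude * np.exp(-d2 / (2.0 * params.foci_sigma**2))
            patch = patch + foci - foci.mean()  # keeps the ROI mean exact
            rr_idx, cc_idx = rr, cc
        else:
            rr_idx, cc_idx = np.nonzero(mask)
        yfp[rr_idx, cc_idx] = patch
        rr, cc = np.nonzero(mask)
        rows.append(
            (
                lab,
                area,
                float(rr.mean()),
                float(cc.mean()),
                float(target_mean_yfp),
                compute_roundness(mask),
                bool(rr.min() == 0 or cc.min() == 0 or rr.max() == h - 1 or cc.max() == w - 1),
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "label",
            "area",
            "centroid_row",
            "centroid_col",
            "true_mean_yfp",
            "true_roundness",
            "touches_border",
        ],
    )

    dapi = _finalize_channel(dapi, params, rng)
    yfp = _finalize_channel(yfp, params, rng)
    return dapi, yfp, labels, truth


def _finalize_channel(
    img: np.ndarray, params: RenderParams, rng: np.random.Generator
) -> np.ndarray:
    if params.focus_blur_sigma > 0:
        img = gaussian(img, sigma=params.focus_blur_sigma, preserve_range=True)
    if params.poisson_noise:
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
    if params.gaussian_noise_sd > 0:
        img = img + rng.normal(0.0, params.gaussian_noise_sd, size=img.shape)
    if params.dtype == "uint16":
        clipped = int(np.count_nonzero(img > U16_MAX))
        if clipped:
            logger.warning("render: %d pixels clipped at 16-bit saturation", clipped)
        return np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)
    return img.astype(np.float32)


def render_metaphase_spread(
    n_chromosomes: int,
    centromere_amplitude: float,
    noncentromeric_amplitude: float = 0.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    *,
    image_shape: tuple[int, int] = (512, 512),
    spot_sigma: float = 1.5,
    arm_spots_per_chromosome: int = 1,
    min_spot_distance: float = 14.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Render a metaphase-spread-like field of fluorescence spots.

    Each chromosome contributes one bright centromeric Gaussian spot and
    ``arm_spots_per_chromosome`` dimmer non-centromeric spots (omitted when
    their amplitude is 0) on a flat background.  Spot centers sit on integer
    pixels so the noiseless pixel maximum at a center is exactly
    ``background + amplitude``.

    Returns ``(image, truth_spots, cytoplasm_mask)``; the truth table has
    columns ``spot_id, spot_class, row, col, amplitude``, and the cytoplasm
    mask marks background regions far from every spot (for background-box
    placement).
    """
    if centromere_amplitude < 0 or noncentromeric_amplitude < 0:
        raise ValueError("spot amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    img = np.full((h, w), float(background))

    spots: list[tuple[str, int, int, float]] = []
    margin = 12
    max_tries = 20000
    tries = 0
    want = [("centromeric", centromere_amplitude)] * n_chromosomes
    if noncentromeric_amplitude > 0:
        want += [("noncentromeric", noncentromeric_amplitude)] * (
            n_chromosomes * arm_spots_per_chromosome
        )
    for spot_class, amp in want:
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("could not place all spots; image too small")
            r = int(rng.integers(margin, h - margin))
            c = int(rng.integers(margin, w - margin))
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_spot_distance**2 for _, pr, pc, _ in spots):
                break
        spots.append((spot_class, r, c, float(amp)))

    yy, xx = np.mgrid[0:h, 0:w]
    spot_dist2 = np.full((h, w), np.inf)
    for spot_class, r, c, amp in spots:
        d2 = (yy - r) ** 2.0 + (xx - c) ** 2.0
        img += amp * np.exp(-d2 / (2.0 * spot_sigma**2))
        spot_dist2 = np.minimum(spot_dist2, d2)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)

    cytoplasm = spot_dist2 > (6.0 * spot_sigma) ** 2

    truth = pd.DataFrame(
        [(i + 1, sc, r, c, a) for i, (sc, r, c, a) in enumerate(spots)],
        columns=["spot_id", "spot_class", "row", "col", "amplitude"],
    )
    return img, truth, cytoplasm
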