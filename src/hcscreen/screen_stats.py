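"""Screen statistics: B-score plate normalization and robust hit calling.

The analysis chain, per the screening convention, is:

1. per-plate **B-score**: a two-way median polish fitted on library wells
   only decomposes the plate into overall + row + column effects +
   residuals; residuals are re-centered on the plate's library median and
   divided by 1.4826 x MAD of the plate's library residuals ("per-plate
   variance adjustment").  Control wells are scored against the fitted
   surface but never enter the fit or the scale.
2. per-replicate **Z-score**: all B-scores of a biological replicate are
   centered and scaled against that replicate's library wells (robust
   median/MAD by default, classical mean/SD as an option).
3. **siRNA-level** score: mean of the replicate Z-scores of each siRNA.
4. **gene-level** score: median of the gene's siRNA-level scores — with
   three siRNAs per gene this is the second strongest oligo, which
   suppresses single-siRNA off-target artifacts.
5. ranking (descending gene median Z, ties broken by gene id) and
   thresholded hit calling.

Everything stays on the additive scale; missing wells propagate as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import PlateLayout
from .plates import parse_well

MAD_SCALE = 1.4826  # consistency factor: 1.4826 * MAD estimates a Gaussian SD


@dataclass
class MedianPolishFit:
    """Additive decomposition of a grid: value = overall + row + col + residual."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return self.overall + self.row_effects[:, None] + self.col_effects[None, :]


def median_polish(
    grid: np.ndarray, max_iter: int = 20, tol: float = 1e-6, warn_missing: bool = True
) -> MedianPolishFit:
    """Two-way median polish with missing-value (NaN) support.

    Alternating row-then-column median sweeps starting from zero effects.
    NaN cells are ignored in every median and stay NaN in the residuals.
    Iteration stops when the total absolute change of a sweep falls below
    ``tol`` times the scale of the data, or at ``max_iter``.  An all-NaN
    row or column keeps a zero effect (with a warning).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("median polish needs a 2D grid with >= 2 rows and cols")
    resid = grid.copy()
    nr, nc = grid.shape
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    overall = 0.0

    empty_rows = np.all(np.isnan(grid), axis=1)
    empty_cols = np.all(np.isnan(grid), axis=0)
    if warn_missing and (empty_rows.any() or empty_cols.any()):
        warnings.warn(
            "median_polish: all-missing row(s)/column(s); their effects stay 0",
            stacklevel=2,
        )

    finite = grid[np.isfinite(grid)]
    scale = float(np.abs(finite).max()) if finite.size else 1.0
    if scale == 0.0:
        scale = 1.0

    n_iter = 0
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for n_iter in range(1, max_iter + 1):
            delta = 0.0

            rmed = np.nanmedian(resid, axis=1)
            rmed[~np.isfinite(rmed)] = 0.0
            resid -= rmed[:, None]
            row_eff += rmed
            delta += float(np.abs(rmed).sum())

            cmed_r = np.nanmedian(row_eff) if np.isfinite(row_eff).any() else 0.0
            row_eff -= cmed_r
            overall += cmed_r

            cmed = np.nanmedian(resid, axis=0)
            cmed[~np.isfinite(cmed)] = 0.0
            resid -= cmed[None, :]
            col_eff += cmed
            delta += float(np.abs(cmed).sum())

            cmed_c = np.nanmedian(col_eff) if np.isfinite(col_eff).any() else 0.0
            col_eff -= cmed_c
            overall += cmed_c

            if delta < tol * scale:
                converged = True
                break

    return MedianPolishFit(
        overall=float(overall),
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=resid,
        n_iter=n_iter,
        converged=converged,
    )


@dataclass
class PlateMatrix:
    """One plate of one replicate as a value grid plus a library mask."""

    plate_id: str
    replicate: int
    values: np.ndarray  # rows x cols, NaN = missing
    library_mask: np.ndarray  # True = library well

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.library_mask = np.asarray(self.library_mask, dtype=bool)
        if self.values.shape != self.library_mask.shape:
            raise ValueError("values and library_mask shapes differ")


@dataclass
class BScoreResult:
    bscores: np.ndarray
    fit: MedianPolishFit
    scale: float  # 1.4826 * MAD of library residuals
    center: float  # median of library residuals (library-median centrality)
    degenerate: bool


def bscore_plate(
    plate: PlateMatrix, max_iter: int = 20, tol: float = 1e-6, min_library: int = 8
) -> BScoreResult:
    """B-score one plate: library-only median polish, then residuals for all
    wells centered on the library residual median and divided by
    1.4826 x MAD of the library residuals.

    If the library residual MAD is 0 (an exactly additive plate) all
    B-scores are set to 0 and the degeneracy flag is raised.
    """
    lib = plate.library_mask
    n_lib = int((lib & np.isfinite(plate.values)).sum())
    if n_lib < min_library:
        raise ValueError(
            f"plate {plate.plate_id} rep {plate.replicate}: only {n_lib} "
            f"library wells with data (need >= {min_library})"
        )
    # control/empty columns are all-missing in the library-only fit by
    # construction, so the missing-data warning is suppressed here
    fit_grid = np.where(lib, plate.values, np.nan)
    fit = median_polish(fit_grid, max_iter=max_iter, tol=tol, warn_missing=False)

    # residuals for every well (controls included) against the fitted surface
    resid_all = plate.values - fit.fitted()
    lib_resid = resid_all[lib & np.isfinite(resid_all)]
    center = float(np.median(lib_resid))
    mad = float(np.median(np.abs(lib_resid - center)))
    scale = MAD_SCALE * mad
    # an exactly additive plate leaves only float round-off in the
    # residuals; treat a MAD at that level as zero
    value_scale = float(np.nanmax(np.abs(plate.values))) or 1.0
    if scale <= 1e-9 * value_scale:
        bscores = np.where(np.isfinite(resid_all), 0.0, np.nan)
        return BScoreResult(bscores, fit, 0.0, center, degenerate=True)
    bscores = (resid_all - center) / scale
    return BScoreResult(bscores, fit, scale, center, degenerate=False)


def robust_z(values: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float, float, bool]:
    """Median/MAD z-scores of ``values`` against a reference population."""
    ref = reference[np.isfinite(reference)]
    center = float(np.median(ref))
    scale = MAD_SCALE * float(np.median(np.abs(ref - center)))
    if scale == 0.0:
        return np.where(np.isfinite(values), 0.0, np.nan), center, 0.0, True
    return (values - center) / scale, center, scale, False


def classical_z(values: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float, float, bool]:
    """Mean/SD z-scores of ``values`` against a reference population."""
    ref = reference[np.isfinite(reference)]
    center = float(ref.mean())
    scale = float(ref.std(ddof=1)) if ref.size > 1 else 0.0
    if scale == 0.0:
        return np.where(np.isfinite(values), 0.0, np.nan), center, 0.0, True
    return (values - center) / scale, center, scale, False


def zscore_replicate(
    bscore_plates: Sequence[tuple[PlateMatrix, np.ndarray]],
    method: str = "robust",
    min_library: int = 8,
) -> tuple[list[np.ndarray], dict]:
    """Z-score the B-scores of one biological replicate.

    The reference population is all library wells of the replicate (across
    its plates); control wells are scored against that same reference.

    Parameters
    ----------
    bscore_plates:
        ``(PlateMatrix, bscore_grid)`` pairs, one per plate of the replicate.
    method:
        ``"robust"`` (median / 1.4826*MAD, default) or ``"classical"``
        (mean / SD).

    Returns the per-plate Z grids and an info dict with center, scale and a
    degeneracy flag.
    """
    if method not in ("robust", "classical"):
        raise ValueError("method must be 'robust' or 'classical'")
    lib_values = np.concatenate(
        [b[pm.library_mask].ravel() for pm, b in bscore_plates]
    )
    lib_values = lib_values[np.isfinite(lib_values)]
    if lib_values.size < min_library:
        raise ValueError("too few library wells in the replicate to z-score")
    zfun = robust_z if method == "robust" else classical_z
    z_grids = []
    info: dict = {}
    for pm, b in bscore_plates:
        z, center, scale, degenerate = zfun(b, lib_values)
        z_grids.append(z)
        info = {"center": center, "scale": scale, "degenerate": degenerate}
    return z_grids, info


def plate_matrices(
    well_table: pd.DataFrame, layouts: Sequence[PlateLayout]
) -> dict[tuple[int, str], PlateMatrix]:
    """Pivot a long per-well table into (replicate, plate) value grids.

    Wells absent from the table, or with NaN ``raw_value``, stay missing.
    """
    by_id = {p.plate_id: p for p in layouts}
    out: dict[tuple[int, str], PlateMatrix] = {}
    for (rep, plate_id), sub in well_table.groupby(["replicate", "plate_id"]):
        plate = by_id[plate_id]
        values = np.full((plate.n_rows, plate.n_cols), np.nan)
        lib_mask = np.zeros((plate.n_rows, plate.n_cols), dtype=bool)
        for well, assign in plate.wells.items():
            r, c = parse_well(well)
            lib_mask[r, c] = assign.content_class == "library"
        for _, row in sub.iterrows():
            r, c = parse_well(row["well"])
            values[r, c] = row["raw_value"]
        out[(int(rep), plate_id)] = PlateMatrix(plate_id, int(rep), values, lib_mask)
    return out


@dataclass
class ScreenScores:
    """Full scoring output of a screen."""

    well_scores: pd.DataFrame  # per well: bscore and z per replicate
    sirna_scores: pd.DataFrame  # per siRNA: replicate z's and their mean
    gene_scores: pd.DataFrame  # per gene: median z, rank, hit flag
    flags: list[str] = field(default_factory=list)


def sirna_scores(well_scores: pd.DataFrame) -> pd.DataFrame:
    """Aggregate well-level Z-scores to siRNA level (mean over replicates).

    Expects columns ``sirna_id, gene_id, replicate, z``.  The number of
    contributing replicates is recorded; an siRNA with no finite Z in any
    replicate raises.
    """
    lib = well_scores.dropna(subset=["sirna_id"])
    rows = []
    for (sid, gene), sub in lib.groupby(["sirna_id", "gene_id"], sort=True):
        z = sub["z"].to_numpy(dtype=float)
        z = z[np.isfinite(z)]
        if z.size == 0:
            raise ValueError(f"siRNA {sid} has no finite Z-score in any replicate")
        rows.append((sid, gene, float(z.mean()), int(z.size)))
    return pd.DataFrame(rows, columns=["sirna_id", "gene_id", "sirna_level_z", "n_replicates"])


def gene_scores(sirna_table: pd.DataFrame) -> pd.DataFrame:
    """Gene-level score: median of the gene's siRNA-level Z-scores.

    With three siRNAs the median is the second strongest oligo, so one
    strong off-target siRNA cannot make a gene a hit.  Genes are ranked by
    descending median Z, ties broken lexicographically by gene id.
    """
    rows = []
    for gene, sub in sirna_table.groupby("gene_id", sort=True):
        z = sub["sirna_level_z"].to_numpy(dtype=float)
        z = z[np.isfinite(z)]
        rows.append((gene, float(np.median(z)), int(z.size)))
    out = pd.DataFrame(rows, columns=["gene_id", "gene_median_z", "n_sirnas"])
    out = out.sort_values(
        ["gene_median_z", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def call_hits(gene_table: pd.DataFrame, z_threshold: float) -> pd.DataFrame:
    """Flag genes with gene-level median Z >= threshold, ordered by rank."""
    if not np.isfinite(z_threshold) and not np.isinf(z_threshold):
        raise ValueError("threshold must be a number")
    out = gene_table.copy()
    out["hit"] = out["gene_median_z"] >= z_threshold
    return out


def score_screen(
    well_table: pd.DataFrame,
    layouts: Sequence[PlateLayout],
    *,
    zscore_method: str = "robust",
    z_threshold: float = 3.0,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> ScreenScores:
    """Run the full chain raw wells -> B-scores -> Z -> siRNA -> gene -> hits."""
    matrices = plate_matrices(well_table, layouts)
    flags: list[str] = []

    bscored: dict[tuple[int, str], tuple[PlateMatrix, np.ndarray]] = {}
    for key, pm in matrices.items():
        res = bscore_plate(pm, max_iter=max_iter, tol=tol)
        if res.degenerate:
            flags.append(f"W_BSCORE_DEGENERATE plate={key[1]} replicate={key[0]}")
        bscored[key] = (pm, res.bscores)

    replicates = sorted({rep for rep, _ in bscored})
    z_by_key: dict[tuple[int, str], np.ndarray] = {}
    for rep in replicates:
        pairs = [(pm, b) for (r, _), (pm, b) in sorted(bscored.items()) if r == rep]
        z_grids, info = zscore_replicate(pairs, method=zscore_method)
        if info.get("degenerate"):
            flags.append(f"W_ZSCORE_DEGENERATE replicate={rep}")
        for (pm, _), z in zip(pairs, z_grids):
            z_by_key[(rep, pm.plate_id)] = z

    by_id = {p.plate_id: p for p in layouts}
    rows = []
    for (rep, plate_id), (pm, b) in sorted(bscored.items()):
        z = z_by_key[(rep, plate_id)]
        plate = by_id[plate_id]
        for well, assign in plate.wells.items():
            r, c = parse_well(well)
            if not np.isfinite(pm.values[r, c]) and assign.content_class == "empty":
                continue
            rows.append(
                (
                    plate_id,
                    well,
                    rep,
                    assign.content_class,
                    assign.sirna_id,
                    assign.gene_id,
                    pm.values[r, c],
                    b[r, c],
                    z[r, c],
                )
            )
    well_scores = pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "well",
            "replicate",
            "content_class",
            "sirna_id",
            "gene_id",
            "raw_value",
            "bscore",
            "z",
        ],
    )

    lib_scores = well_scores[well_scores["content_class"] == "library"]
    sirna_table = sirna_scores(lib_scores)
    gene_table = call_hits(gene_scores(sirna_table), z_threshold)
    return ScreenScores(well_scores, sirna_table, gene_table, flags)
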