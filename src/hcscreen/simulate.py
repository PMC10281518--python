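"""Generative model for well-level screen readouts with known ground truth.

The model is strictly additive, matching the scale on which the downstream
normalization operates:

    raw = baseline + gene_effect * sirna_potency   (library wells)
        + off_target_effect                        (per-siRNA, optional)
        + pos_control_effect                       (positive-control wells)
        + row_effect[r] + col_effect[c]            (per plate x replicate)
        + N(0, noise_sd)

Row/column artifacts are drawn independently for every (replicate, plate)
pair unless explicit vectors are supplied, emulating plate-to-plate gradients
(edge evaporation, dispenser bias) that the B-score normalization is meant to
remove.  A per-well imaged-nuclei count is drawn from a Poisson law around
the seeded cell number times an attrition factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import PlateLayout, ScreenDesign
from .plates import parse_well


@dataclass
class TruthModel:
    """Ground-truth parameters of the simulated screen.

    Parameters
    ----------
    baseline:
        Mean readout of an untreated well, arbitrary intensity units.
    gene_effect:
        Additive shift caused by full knockdown of each gene; genes absent
        from the map have effect 0.
    sirna_potency:
        Per-siRNA multiplier in [0, 1] applied to its gene's effect.  siRNAs
        absent from the map get a potency drawn from Uniform(0.5, 1).
    sirna_offtarget:
        Additional additive shift attached to individual siRNAs regardless
        of their gene (models off-target activity of a single oligo).
    row_effect_range, col_effect_range:
        Uniform ranges from which per-(replicate, plate) additive row and
        column artifact vectors are drawn when not given explicitly.
    row_effects, col_effects:
        Optional explicit artifact vectors keyed by (replicate, plate_id).
    noise_sd:
        SD of the Gaussian measurement noise.
    pos_control_effect:
        Additive shift of positive-control wells (large and positive: the
        control depletion increases the readout).
    cells_per_well_mean:
        Cells seeded per well; the imaged nuclei count is Poisson with mean
        ``cells_per_well_mean * imaging_attrition``.
    """

    baseline: float = 1000.0
    gene_effect: Mapping[str, float] = field(default_factory=dict)
    sirna_potency: Mapping[str, float] = field(default_factory=dict)
    sirna_offtarget: Mapping[str, float] = field(default_factory=dict)
    row_effect_range: tuple[float, float] = (0.0, 0.0)
    col_effect_range: tuple[float, float] = (0.0, 0.0)
    row_effects: Mapping[tuple[int, str], Sequence[float]] | None = None
    col_effects: Mapping[tuple[int, str], Sequence[float]] | None = None
    noise_sd: float = 10.0
    pos_control_effect: float = 300.0
    cells_per_well_mean: float = 1500.0
    imaging_attrition: float = 0.35

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for sid, p in self.sirna_potency.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"potency of {sid} outside [0, 1]: {p}")
        if self.imaging_attrition <= 0 or self.imaging_attrition > 1:
            raise ValueError("imaging_attrition must be in (0, 1]")


def sample_truth_model(
    design: ScreenDesign,
    seed: int,
    *,
    baseline: float = 1000.0,
    noise_sd: float = 10.0,
    hit_genes: Mapping[str, float] | None = None,
    decoy_sirnas: Mapping[str, float] | None = None,
    hit_potency: float = 1.0,
    row_effect_range: tuple[float, float] = (0.0, 0.0),
    col_effect_range: tuple[float, float] = (0.0, 0.0),
    pos_control_effect: float = 300.0,
) -> TruthModel:
    """Build a TruthModel with random potencies and designated hits.

    ``hit_genes`` maps gene ids to additive effects applied to all of the
    gene's siRNAs (scaled by ``hit_potency``); ``decoy_sirnas`` maps single
    siRNA ids to off-target additive effects, exercising the median-of-three
    aggregation that suppresses single-oligo artifacts.
    """
    rng = np.random.default_rng(seed)
    potency: dict[str, float] = {}
    for gene in design.gene_ids():
        for sid in design.sirna_ids(gene):
            potency[sid] = float(rng.uniform(0.5, 1.0))
    gene_effect = dict(hit_genes or {})
    for gene in gene_effect:
        for sid in design.sirna_ids(gene):
            potency[sid] = hit_potency
    return TruthModel(
        baseline=baseline,
        gene_effect=gene_effect,
        sirna_potency=potency,
        sirna_offtarget=dict(decoy_sirnas or {}),
        row_effect_range=row_effect_range,
        col_effect_range=col_effect_range,
        noise_sd=noise_sd,
        pos_control_effect=pos_control_effect,
    )


def simulate_well_values(
    layouts: Sequence[PlateLayout],
    truth: TruthModel,
    design: ScreenDesign,
    seed: int,
) -> pd.DataFrame:
    """Simulate the per-well raw readout table for all replicates.

    Returns a long-format table with one row per (plate, well, replicate)
    and columns ``plate_id, well, replicate, content_class, sirna_id,
    gene_id, raw_value, n_nuclei, provenance``.  The same seed always yields
    a bit-identical table.
    """
    if not layouts:
        raise ValueError("no plate layouts given")
    rng = np.random.default_rng(seed)
    nuclei_mean = truth.cells_per_well_mean * truth.imaging_attrition

    records = []
    for rep in range(1, design.n_replicates + 1):
        for plate in layouts:
            key = (rep, plate.plate_id)
            if truth.row_effects is not None:
                row_eff = np.asarray(truth.row_effects[key], dtype=float)
            else:
                row_eff = rng.uniform(*truth.row_effect_range, size=plate.n_rows)
            if truth.col_effects is not None:
                col_eff = np.asarray(truth.col_effects[key], dtype=float)
            else:
                col_eff = rng.uniform(*truth.col_effect_range, size=plate.n_cols)
            if len(row_eff) != plate.n_rows or len(col_eff) != plate.n_cols:
                raise ValueError(
                    f"artifact vector length mismatch on plate {plate.plate_id}"
                )
            for well, assign in plate.wells.items():
                r, c = parse_well(well)
                value = truth.baseline + row_eff[r] + col_eff[c]
                if assign.content_class == "library":
                    effect = truth.gene_effect.get(assign.gene_id, 0.0)
                    potency = truth.sirna_potency.get(assign.sirna_id, 1.0)
                    value += effect * potency
                    value += truth.sirna_offtarget.get(assign.sirna_id, 0.0)
                elif assign.content_class == "pos_control":
                    value += truth.pos_control_effect
                if truth.noise_sd > 0:
                    value += rng.normal(0.0, truth.noise_sd)
                n_nuclei = int(rng.poisson(nuclei_mean))
                records.append(
                    (
                        plate.plate_id,
                        well,
                        rep,
                        assign.content_class,
                        assign.sirna_id,
                        assign.gene_id,
                        float(value),
                        n_nuclei,
                        "simulated",
                    )
                )
    return pd.DataFrame(
        records,
        columns=[
            "plate_id",
            "well",
            "replicate",
            "content_class",
            "sirna_id",
            "gene_id",
            "raw_value",
            "n_nuclei",
            "provenance",
        ],
    )
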