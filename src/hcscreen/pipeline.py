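"""End-to-end simulated-screen pipeline with a serializable configuration.

One global seed governs every stochastic stage through fixed sub-seeding:
stage seeds are the first 31 bits of the children of
``numpy.random.SeedSequence(seed)`` spawned in the documented order
(truth, simulate, render, spots), so any stage can be re-run independently
and reproducibly.  Runs with the same config and seed produce bit-identical
CSV outputs; wall-clock timings go only to the run log.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .design import ScreenDesign, build_screen_layout
from .image_quant import quantify_well
from .plates import parse_well
from .render import RenderParams, render_well_image
from .screen_stats import ScreenScores, score_screen
from .simulate import sample_truth_model, simulate_well_values

logger = logging.getLogger(__name__)

_STAGES = ("truth", "simulate", "render", "spots")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Per-stage seeds derived from the global seed (fixed spawn order)."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class DesignConfig:
    n_genes: int = 521
    sirnas_per_gene: int = 3
    n_replicates: int = 2
    plate_rows: int = 16
    plate_cols: int = 24


@dataclass
class TruthConfig:
    baseline: float = 1000.0
    noise_sd: float = 10.0
    row_effect_range: list[float] = field(default_factory=lambda: [-50.0, 50.0])
    col_effect_range: list[float] = field(default_factory=lambda: [-25.0, 25.0])
    pos_control_effect: float = 300.0
    hit_genes: dict[str, float] = field(default_factory=dict)
    decoy_sirnas: dict[str, float] = field(default_factory=dict)
    hit_potency: float = 1.0


@dataclass
class RenderConfig:
    enabled: bool = False
    image_shape: list[int] = field(default_factory=lambda: [128, 128])
    n_nuclei_range: list[int] = field(default_factory=lambda: [8, 15])
    nucleus_radius_range: list[float] = field(default_factory=lambda: [6.0, 10.0])
    irregularity: float = 0.0
    focus_blur_sigma: float = 0.0
    gaussian_noise_sd: float = 0.0
    foci_per_nucleus: int = 0
    foci_amplitude: float = 0.0
    save_images: bool = False


@dataclass
class SegmentationConfig:
    min_roundness: float = 0.775
    exclude_border: bool = True
    smooth_sigma: float = 1.0
    min_area: int = 30


@dataclass
class ScoringConfig:
    zscore_method: str = "robust"
    z_threshold: float = 3.0
    max_iter: int = 20
    tol: float = 1.0e-6


@dataclass
class RunConfig:
    """Complete, serializable configuration of one pipeline run."""

    design: DesignConfig = field(default_factory=DesignConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    seed: int = 1
    top_n: int = 20
    verbosity: str = "info"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            design=DesignConfig(**d.get("design", {})),
            truth=TruthConfig(**d.get("truth", {})),
            render=RenderConfig(**d.get("render", {})),
            segmentation=SegmentationConfig(**d.get("segmentation", {})),
            scoring=ScoringConfig(**d.get("scoring", {})),
            seed=d.get("seed", 1),
            top_n=d.get("top_n", 20),
            verbosity=d.get("verbosity", "info"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: RunConfig
    layouts: list
    well_table: pd.DataFrame
    scores: ScreenScores
    qc: pd.DataFrame
    log_lines: list[str]


def _quantify_from_renders(
    well_table: pd.DataFrame,
    config: RunConfig,
    render_seed: int,
    out_dir: Path | None,
) -> pd.DataFrame:
    """Replace simulated raw values by values measured from rendered images.

    Every non-empty well is rendered with its simulated value as the target
    nuclear reporter mean, then quantified through the image stage.  Empty
    wells stay missing (they carry no treatment and never enter scoring).
    """
    rc = config.render
    sc = config.segmentation
    rng = np.random.default_rng(render_seed)
    rows = []
    img_dir = None
    if rc.save_images and out_dir is not None:
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
    for rec in well_table.itertuples():
        if rec.content_class == "empty":
            continue
        n_nuclei = int(rng.integers(rc.n_nuclei_range[0], rc.n_nuclei_range[1] + 1))
        well_seed = int(rng.integers(0, 2**31))
        params = RenderParams(
            image_shape=tuple(rc.image_shape),
            n_nuclei=n_nuclei,
            nucleus_radius_range=tuple(rc.nucleus_radius_range),
            irregularity=rc.irregularity,
            focus_blur_sigma=rc.focus_blur_sigma,
            gaussian_noise_sd=rc.gaussian_noise_sd,
            foci_per_nucleus=rc.foci_per_nucleus,
            foci_amplitude=rc.foci_amplitude,
            seed=well_seed,
        )
        dapi, yfp, _, _ = render_well_image(params, target_mean_yfp=rec.raw_value)
        if img_dir is not None:
            stem = f"{rec.plate_id}_{rec.well}_r{rec.replicate}"
            d_path, y_path = hio.well_image_paths(img_dir, stem)
            hio.write_image(d_path, dapi)
            hio.write_image(y_path, yfp)
        _, quant = quantify_well(
            dapi,
            yfp,
            min_roundness=sc.min_roundness,
            exclude_border=sc.exclude_border,
            smooth_sigma=sc.smooth_sigma,
            min_area=sc.min_area,
        )
        rows.append(
            (
                rec.plate_id,
                rec.well,
                rec.replicate,
                rec.content_class,
                rec.sirna_id,
                rec.gene_id,
                quant.well_mean_of_means,
                quant.n_nuclei_kept,
                "measured",
            )
        )
    return pd.DataFrame(rows, columns=well_table.columns)


def _plate_qc(scores: ScreenScores) -> pd.DataFrame:
    """Row/column median profiles of library B-scores per (replicate, plate),
    plus control separation — the data behind a plate QC heat map."""
    rows = []
    ws = scores.well_scores
    for (rep, plate_id), sub in ws.groupby(["replicate", "plate_id"]):
        lib = sub[sub["content_class"] == "library"]
        rr = lib["well"].map(lambda w: parse_well(w)[0])
        cc = lib["well"].map(lambda w: parse_well(w)[1])
        for r, grp in lib.groupby(rr):
            rows.append((rep, plate_id, "row", int(r), float(grp["bscore"].median())))
        for c, grp in lib.groupby(cc):
            rows.append((rep, plate_id, "col", int(c), float(grp["bscore"].median())))
        neg = sub[sub["content_class"] == "neg_control"]["z"]
        pos = sub[sub["content_class"] == "pos_control"]["z"]
        if len(neg) and len(pos):
            rows.append(
                (rep, plate_id, "control_separation", -1, float(pos.mean() - neg.mean()))
            )
    return pd.DataFrame(
        rows, columns=["replicate", "plate_id", "profile", "index", "median_bscore"]
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute simulate -> (optional render + quantify) -> score -> report.

    When ``out_dir`` is given, writes platemap.csv, wells.csv,
    sirna_scores.csv, gene_scores.csv, qc_rowcol.csv, report.txt,
    resolved_config.yaml and run_log.txt there.
    """
    t0 = time.perf_counter()
    seeds = stage_seeds(config.seed)
    log: list[str] = [f"seed={config.seed}", f"stage_seeds={seeds}"]

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return time.perf_counter()

    try:
        stage("design")
        d = config.design
        design = ScreenDesign(
            n_genes=d.n_genes,
            sirnas_per_gene=d.sirnas_per_gene,
            n_replicates=d.n_replicates,
            plate_rows=d.plate_rows,
            plate_cols=d.plate_cols,
            seed=config.seed,
        )
        layouts = build_screen_layout(design)
    except Exception as e:
        raise RuntimeError(f"[design] {e}") from e

    try:
        stage("simulate")
        t = config.truth
        truth = sample_truth_model(
            design,
            seeds["truth"],
            baseline=t.baseline,
            noise_sd=t.noise_sd,
            hit_genes=t.hit_genes,
            decoy_sirnas=t.decoy_sirnas,
            hit_potency=t.hit_potency,
            row_effect_range=tuple(t.row_effect_range),
            col_effect_range=tuple(t.col_effect_range),
            pos_control_effect=t.pos_control_effect,
        )
        well_table = simulate_well_values(layouts, truth, design, seeds["simulate"])
    except Exception as e:
        raise RuntimeError(f"[simulate] {e}") from e

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    if config.render.enabled:
        try:
            stage("render+quantify")
            well_table = _quantify_from_renders(
                well_table, config, seeds["render"], out_path
            )
        except Exception as e:
            raise RuntimeError(f"[render] {e}") from e

    try:
        stage("score")
        s = config.scoring
        scores = score_screen(
            well_table,
            layouts,
            zscore_method=s.zscore_method,
            z_threshold=s.z_threshold,
            max_iter=s.max_iter,
            tol=s.tol,
        )
        log.extend(scores.flags)
    except Exception as e:
        raise RuntimeError(f"[score] {e}") from e

    qc = _plate_qc(scores)
    log.append(f"elapsed_s={time.perf_counter() - t0:.2f}")

    if out_path is not None:
        hio.write_platemap(layouts, out_path / "platemap.csv")
        well_table.to_csv(out_path / "wells.csv", index=False)
        scores.sirna_scores.to_csv(out_path / "sirna_scores.csv", index=False)
        scores.gene_scores.to_csv(out_path / "gene_scores.csv", index=False)
        qc.to_csv(out_path / "qc_rowcol.csv", index=False)
        config.save(out_path / "resolved_config.yaml")
        write_report(scores, qc, out_path / "report.txt", top_n=config.top_n)
        (out_path / "run_log.txt").write_text("\n".join(log) + "\n")

    return PipelineResult(config, layouts, well_table, scores, qc, log)


def write_report(
    scores: ScreenScores, qc: pd.DataFrame, path: str | Path, top_n: int = 20
) -> str:
    """Human-readable summary: top-N gene table, hit count, control separation."""
    gene = scores.gene_scores
    lines = ["# screen report", ""]
    n_hits = int(gene["hit"].sum())
    if n_hits == 0:
        lines.append("zero hits at the configured threshold")
    else:
        lines.append(f"{n_hits} hit gene(s) at the configured threshold")
    lines.append("")
    lines.append(f"top {min(top_n, len(gene))} genes by gene-level median Z:")
    head = gene.head(top_n)
    lines.append("rank\tgene_id\tgene_median_z\thit")
    for rec in head.itertuples():
        lines.append(f"{rec.rank}\t{rec.gene_id}\t{rec.gene_median_z:.4f}\t{rec.hit}")
    sep = qc[qc["profile"] == "control_separation"]
    if len(sep):
        lines.append("")
        lines.append(
            "control separation (mean positive-control z - mean negative-control z) "
            f"averaged over plates: {sep['median_bscore'].mean():.3f}"
        )
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
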