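"""End-to-end orchestration: mask -> sample -> select -> fit -> scan -> report.

Each stage's artifact is written before the next begins; a run can resume
from a previously fitted model.  Re-running with an identical configuration
and seed yields byte-identical outputs, independent of the thread count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import features as ft
from . import io as hio
from .lasso import stability_select
from .model import BackgroundModel, ProbabilityField, fit_background, zvalue_table
from .plots import plot_feature_importance, plot_lollipop, plot_manhattan
from .sampling import build_design_matrix, sample_sites
from .scan import call_hotspots

logger = logging.getLogger("hotscan")


@dataclass
class RunConfig:
    genome: str
    mutations: str
    output_dir: str
    mappability_mask: str | None = None
    blacklist: str | None = None
    coding_regions: str | None = None
    regions: str | None = None           # region mode when set
    mode: str = "genome"
    variant_class: str = hio.SNV
    binary_tracks: dict = dc_field(default_factory=dict)      # name -> path
    continuous_tracks: dict = dc_field(default_factory=dict)  # name -> path
    # sequence-context granularity: full | nopenta | basic | none
    # (small cohorts cannot support the full one-hot expansion)
    context: str = "full"
    local_rate_bin: int = 100_000
    window_length: int = 21
    min_samples: int = 2
    fdr_threshold: float = 0.05
    max_mutated_sites: int = 1_000_000
    run_selection: bool = True
    n_bootstraps: int = 100
    subsample_fraction: float = 0.5
    selection_thresholds: dict = dc_field(
        default_factory=lambda: {"sequence": 0.90, "default": 0.75}
    )
    n_folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0
    n_threads: int = 1
    flank_plot: int = 50
    n_lollipops: int = 3

    def validate(self) -> None:
        if self.mode not in ("genome", "region"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "region" and not self.regions:
            raise ValueError("region mode requires a regions BED")
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        for path in [self.genome, self.mutations]:
            if not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def run_pipeline(config: RunConfig, resume: bool = False):
    """Execute the full hotspot-discovery workflow; returns the call list."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir, resume)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, resume: bool):
    stage = "load-inputs"
    try:
        logger.info("run seed: %d; mode: %s; variant class: %s",
                    config.seed, config.mode, config.variant_class)
        genome = hio.read_genome(config.genome)
        catalog = hio.read_mutations(config.mutations, genome)
        logger.info("loaded %d mutations from %d samples",
                    len(catalog), len(catalog.samples))
        mappability = (
            hio.read_regions(config.mappability_mask)
            if config.mappability_mask else None
        )
        blacklist = hio.read_regions(config.blacklist) if config.blacklist else None
        coding = (
            hio.read_regions(config.coding_regions)
            if config.coding_regions else None
        )
        regions = hio.read_regions(config.regions) if config.regions else None

        stage = "mask"
        mask = ft.build_mask(genome, mappability, blacklist, coding)
        logger.info("analyzable mask: %d bp", mask.total_length)
        if config.mode == "region":
            fit_mask = mask.intersect(regions)
        else:
            fit_mask = mask

        stage = "features"
        specs = _build_specs(config, catalog, genome)
        burden = ft.sample_burden(catalog, config.variant_class)
        assembler = ft.FeatureAssembler(genome, specs, sample_covariates=burden)

        model_path = outdir / "model.json"
        sel_path = outdir / "selection.tsv"
        if resume and model_path.exists():
            stage = "resume"
            model = BackgroundModel.from_json(model_path)
            logger.info("resumed model from %s", model_path)
        else:
            stage = "sample-sites"
            table = sample_sites(
                catalog, fit_mask, genome, config.variant_class,
                max_mutated=config.max_mutated_sites, seed=config.seed,
                assembler=assembler,
            )
            logger.info(
                "sampled %d mutated + %d non-mutated sites (f1=%.3g f0=%.3g)",
                table.n_mutated, table.n_unmutated, table.f1, table.f0,
            )
            X, y, names, standardizer = build_design_matrix(table, assembler)

            stage = "feature-selection"
            n_pos = len(assembler.position_columns)
            if config.run_selection and n_pos > 0:
                sel = stability_select(
                    X[:, :n_pos], y,
                    assembler.position_columns, assembler.position_categories,
                    n_boot=config.n_bootstraps,
                    frac=config.subsample_fraction,
                    thresholds=config.selection_thresholds,
                    seed=config.seed + 1,
                    n_folds=config.n_folds,
                    n_lambdas=config.n_lambdas,
                    lambda_min_ratio=config.lambda_min_ratio,
                )
                sel.to_tsv(sel_path)
                selected = sel.selected
                logger.info("selected %d/%d position features: %s",
                            len(selected), n_pos, selected)
            else:
                selected = assembler.position_columns
                logger.info("selection skipped; all %d features retained",
                            len(selected))

            stage = "fit-model"
            keep_cols = selected + assembler.sample_columns
            col_idx = [names.index(c) for c in keep_cols]
            cats = dict(zip(assembler.column_names, assembler.column_categories))
            model = fit_background(
                X[:, col_idx], y, keep_cols,
                {c: cats[c] for c in keep_cols},
                table.sampling_fractions,
                standardizer=standardizer,
                variant_class=config.variant_class,
            )
            model.to_json(model_path)
        ztab = zvalue_table(model)
        ztab.to_csv(outdir / "zvalues.tsv", sep="\t", index=False)

        stage = "scan"
        field = ProbabilityField(model, assembler, mask)
        calls = call_hotspots(
            field, catalog, mask,
            l=config.window_length, n=config.min_samples,
            fdr_threshold=config.fdr_threshold,
            mode=config.mode, regions=regions,
            variant_class=config.variant_class,
            n_threads=config.n_threads,
            genome_lengths=genome.lengths,
        )
        logger.info("called %d hotspots at FDR < %g", len(calls),
                    config.fdr_threshold)

        stage = "report"
        hio.write_hotspots(calls, outdir / "hotspots.tsv")
        m_total = (
            mask.intersect(regions).total_length
            if config.mode == "region" else mask.total_length
        )
        manifest = {
            "config": _jsonable(config.to_dict()),
            "seed": config.seed,
            "m_total": int(m_total),
            "n_candidates_called": len(calls),
            "selected_features": model.feature_names,
            "model_hash": model.manifest_hash,
        }
        with open(outdir / "manifest.json", "wt") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        logger.info("m_total for BH correction: %d", m_total)

        stage = "plots"
        plot_manhattan(calls, mask, config.fdr_threshold,
                       outdir / "manhattan.png")
        if len(ztab):
            plot_feature_importance(ztab, outdir / "feature_importance.png")
        for i, call in enumerate(calls[: config.n_lollipops]):
            plot_lollipop(call, catalog, config.flank_plot,
                          outdir / f"lollipop_{i + 1}.png",
                          variant_class=config.variant_class)
        return calls
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise PipelineError(stage)


class PipelineError(RuntimeError):
    def __init__(self, stage: str):
        super().__init__(f"pipeline failed at stage {stage!r}")
        self.stage = stage


def _build_specs(config: RunConfig, catalog, genome):
    if config.variant_class == hio.SNV:
        if config.context == "full":
            specs = ft.default_snv_specs(True)
        elif config.context == "nopenta":
            specs = ft.default_snv_specs(False)
        elif config.context == "basic":
            specs = [
                ft.FeatureSpec(g, ft.SEQUENCE, ft.ONEHOT_CONTEXT)
                for g in ("center_class", "left1", "right1")
            ]
        elif config.context == "none":
            specs = []
        else:
            raise ValueError(f"unknown context granularity {config.context!r}")
    else:
        specs = ft.default_indel_specs()
    local = ft.compute_local_rate(
        catalog, genome, config.local_rate_bin, config.variant_class
    )
    specs.append(
        ft.FeatureSpec("local_rate", ft.STRUCTURAL, ft.CONTINUOUS_ENC,
                       source="computed", track=local)
    )
    for name, path in config.binary_tracks.items():
        track = hio.read_track(path, hio.BINARY, name=name)
        specs.append(
            ft.FeatureSpec(name, ft.EPIGENETIC, ft.BINARY_OVERLAY,
                           source="user_track", track=track)
        )
    for name, path in config.continuous_tracks.items():
        track = hio.read_track(path, hio.CONTINUOUS, name=name)
        specs.append(
            ft.FeatureSpec(name, ft.EPIGENETIC, ft.CONTINUOUS_ENC,
                           source="user_track", track=track)
        )
    return specs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
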