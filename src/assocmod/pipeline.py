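"""Pipeline configuration and stage orchestration.

Stages (simulate -> discover -> validate -> fdr -> pls -> enrich) are plain
functions writing TSV/JSON artifacts plus a manifest (config hash, seed,
input checksums, package version, timing) into one output directory.  Each
stage only ever overwrites its own artifacts.  Every stochastic routine
derives its generator from the global seed plus a stage-specific offset, so
stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discovery import DiscoveryConfig, discover_modules
from .enrichment import geneset_enrichment, top_cited_intersection
from .fdr import module_level_fdr, pairwise_fdr, write_fdr_report
from .io import (
    CohortBundle,
    DataError,
    load_cohort,
    read_citation_counts,
    read_gmt,
    read_modules_json,
    write_gmt,
    write_modules_json,
    write_modules_tsv,
    write_validation_report,
)
from .pls import cumulative_r2, correlation_circle, fit_pls
from .preprocess import arm_cnv_matrix, ecdf_normalize, tumor_normal_ratio
from .simulate import (
    PlantedTruth,
    SimulationSpec,
    default_spec,
    score_recovery,
    simulate_training_cohort,
    simulate_validation_cohorts,
    write_cohort,
)
from .validation import ValidationConfig, prepare_validation_cohort, validate_modules

logger = logging.getLogger(__name__)

STAGES = ("simulate", "discover", "validate", "fdr", "pls", "enrich")


@dataclasses.dataclass
class PipelineConfig:
    """Validated knobs of the whole pipeline (YAML-loadable)."""

    seed: int = 0
    screen_r: float = 0.5
    coherence_alpha: float = 0.05
    cox_alpha: float = 0.05
    logrank_alpha: float = 0.1
    min_module_size: int = 5
    n_background: int = 1000
    n_adjust: int = 1000
    n_perm: int = 100
    n_runs: int = 200
    required_cohorts: list[str] = dataclasses.field(default_factory=list)
    simulation: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("screen_r", "coherence_alpha", "cox_alpha", "logrank_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DataError(f"config field {name!r} must lie in (0, 1); got {v}")
        for name in ("min_module_size", "n_background", "n_adjust", "n_perm", "n_runs"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise DataError(f"config field {name!r} must be a positive integer; got {v}")

    def build_spec(self) -> SimulationSpec:
        spec = default_spec(seed=self.seed)
        for key, value in (self.simulation or {}).items():
            if not hasattr(spec, key):
                raise DataError(f"unknown simulation field {key!r}")
            setattr(spec, key, value)
        spec.validate()
        declared = {c.name for c in spec.validation_cohorts}
        bad = set(self.required_cohorts) - declared
        if bad:
            raise DataError(f"required_cohorts not declared: {sorted(bad)}")
        return spec

    def discovery(self) -> DiscoveryConfig:
        return DiscoveryConfig(screen_threshold=self.screen_r, min_module_size=self.min_module_size)

    def validation(self) -> ValidationConfig:
        return ValidationConfig(
            n_background=self.n_background,
            n_adjust=self.n_adjust,
            coherence_alpha=self.coherence_alpha,
            cox_alpha=self.cox_alpha,
            logrank_alpha=self.logrank_alpha,
            required_cohorts=self.required_cohorts or None,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# shared preprocessing
# ---------------------------------------------------------------------------

def preprocess_training(bundle: CohortBundle):
    """Training bundle -> (expression CDF, arm CNV, methylation contrast).

    Applies tumor/normal contrasts per role, CDF-normalizes the expression
    ratios and aggregates CNV probe ratios to chromosome-arm medians.
    """
    m = bundle.matrices
    expr_ratio = tumor_normal_ratio(m["expression_tumor"], m["expression_normal"])
    expr_cdf = ecdf_normalize(expr_ratio)
    cnv_ratio = tumor_normal_ratio(m["cnv_tumor"], m["cnv_normal"])
    arm_cnv = arm_cnv_matrix(cnv_ratio, bundle.annotation)
    meth_diff = None
    if "methylation_tumor" in m and "methylation_normal" in m:
        meth_diff = tumor_normal_ratio(m["methylation_tumor"], m["methylation_normal"]).data
    return expr_cdf, arm_cnv, meth_diff


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir, stage, config: PipelineConfig, inputs: list[str], started: float) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {os.path.basename(p): _sha256(p) for p in inputs if os.path.exists(p)},
        "version": __version__,
        "elapsed_s": round(time.time() - started, 3),
    }
    with open(os.path.join(outdir, f"manifest_{stage}.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def _stage_done(outdir, stage) -> bool:
    return os.path.exists(os.path.join(outdir, f"manifest_{stage}.json"))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir) -> None:
    started = time.time()
    os.makedirs(outdir, exist_ok=True)
    spec = config.build_spec()
    training, truth = simulate_training_cohort(spec)
    cohorts, _ = simulate_validation_cohorts(spec)

    data_dir = os.path.join(outdir, "data")
    entries = {"training": write_cohort(training, os.path.join(data_dir, "training"))}
    for bundle in cohorts:
        entries[bundle.name] = write_cohort(bundle, os.path.join(data_dir, bundle.name))
    truth.to_json(os.path.join(data_dir, "truth.json"))

    # synthetic annotation resources for the enrichment stage: citation
    # counts biased toward planted targets, gene sets overlapping them
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 55]))
    genes = list(training.matrices["expression_tumor"].feature_ids)
    counts = rng.poisson(5, size=len(genes)).astype(float)
    counts_series = pd.Series(counts, index=genes)
    sets: dict[str, list[str]] = {}
    for i, tm in enumerate(truth.modules):
        counts_series.loc[tm["targets"][: max(3, len(tm["targets"]) // 4)]] += rng.poisson(120)
        members = list(tm["targets"][: max(6, len(tm["targets"]) // 2)])
        members += list(rng.choice(genes, size=20, replace=False))
        sets[f"planted_process_{i + 1}"] = sorted(set(members))
    for i in range(10):
        sets[f"random_set_{i + 1}"] = sorted(rng.choice(genes, size=30, replace=False))
    counts_series.to_frame("count").rename_axis("gene_id").to_csv(
        os.path.join(data_dir, "citations.tsv"), sep="\t"
    )
    write_gmt(sets, os.path.join(data_dir, "genesets.gmt"))

    with open(os.path.join(data_dir, "cohorts.json"), "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=1)
    _write_manifest(outdir, "simulate", config, [os.path.join(data_dir, "truth.json")], started)


def _load_entries(outdir) -> dict:
    path = os.path.join(outdir, "data", "cohorts.json")
    if not os.path.exists(path):
        raise DataError("simulate stage outputs missing; run 'simulate' first")
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def stage_discover(config: PipelineConfig, outdir) -> None:
    started = time.time()
    entries = _load_entries(outdir)
    training = load_cohort(entries["training"])
    expr_cdf, arm_cnv, meth_diff = preprocess_training(training)
    modules, models = discover_modules(
        expr_cdf, arm_cnv, meth_diff, training.annotation, config.discovery()
    )
    write_modules_tsv(modules, os.path.join(outdir, "modules.tsv"))
    write_modules_json(modules, os.path.join(outdir, "modules.json"))

    truth_path = os.path.join(outdir, "data", "truth.json")
    if os.path.exists(truth_path):
        truth = PlantedTruth.from_json(truth_path)
        if truth.modules:
            score_recovery(modules, truth).to_csv(
                os.path.join(outdir, "recovery.tsv"), sep="\t", index=False, float_format="%.6g"
            )
    _write_manifest(outdir, "discover", config, [os.path.join(outdir, "modules.json")], started)


def _load_validation_bundles(config: PipelineConfig, outdir) -> list[CohortBundle]:
    entries = _load_entries(outdir)
    return [load_cohort(e) for name, e in entries.items() if name != "training"]


def stage_validate(config: PipelineConfig, outdir) -> None:
    started = time.time()
    modules = read_modules_json(os.path.join(outdir, "modules.json"))
    bundles = _load_validation_bundles(config, outdir)
    if not bundles:
        raise DataError("no validation cohorts available")
    results = validate_modules(modules, bundles, config.validation())
    if results:
        write_validation_report(results, os.path.join(outdir, "validation_report.tsv"))
    else:
        logger.warning("no modules to validate; empty result list")
        pd.DataFrame(columns=["module_id"]).to_csv(
            os.path.join(outdir, "validation_report.tsv"), sep="\t", index=False
        )
    _write_manifest(outdir, "validate", config, [os.path.join(outdir, "validation_report.tsv")], started)


def stage_fdr(config: PipelineConfig, outdir) -> None:
    started = time.time()
    entries = _load_entries(outdir)
    training = load_cohort(entries["training"])
    expr_cdf, arm_cnv, meth_diff = preprocess_training(training)
    reports = pairwise_fdr(
        expr_cdf, arm_cnv, meth_diff, training.annotation,
        config.discovery(), n_perm=config.n_perm, seed=config.seed,
    )
    modules = read_modules_json(os.path.join(outdir, "modules.json"))
    if modules:
        bundles = _load_validation_bundles(config, outdir)
        prepared = [prepare_validation_cohort(b) for b in bundles]
        module_reports, _ = module_level_fdr(
            [m.size for m in modules], prepared,
            n_runs=config.n_runs, n_adjust=min(config.n_adjust, 200),
            seed=config.seed, config=config.validation(),
        )
        reports = reports + module_reports
    write_fdr_report(reports, os.path.join(outdir, "fdr.tsv"), seed=config.seed)
    _write_manifest(outdir, "fdr", config, [os.path.join(outdir, "fdr.tsv")], started)


def stage_pls(config: PipelineConfig, outdir) -> None:
    started = time.time()
    entries = _load_entries(outdir)
    modules = read_modules_json(os.path.join(outdir, "modules.json"))
    if len(modules) < 2:
        truth_path = os.path.join(outdir, "data", "truth.json")
        truth = PlantedTruth.from_json(truth_path) if os.path.exists(truth_path) else None
        blocks = [tm["targets"] for tm in (truth.modules if truth else [])]
        labels = [";".join(tm["effectors"]) for tm in (truth.modules if truth else [])]
    else:
        ordered = sorted(modules, key=lambda m: -m.size)[:2]
        blocks = [m.targets for m in ordered]
        labels = [m.module_id for m in ordered]
    training = load_cohort(entries["training"])
    expr_cdf, _, _ = preprocess_training(training)
    if len(blocks) < 2:
        # fall back to two random blocks: still demonstrates the null geometry
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 66]))
        genes = expr_cdf.index.to_numpy()
        blocks = [list(rng.choice(genes, 30, replace=False)) for _ in range(2)]
        labels = ["random_block_1", "random_block_2"]
    X = expr_cdf.loc[[g for g in blocks[0] if g in expr_cdf.index]].T
    Y = expr_cdf.loc[[g for g in blocks[1] if g in expr_cdf.index]].T
    model = fit_pls(X, Y, n_components=2)
    r2 = [cumulative_r2(model, Y, m) for m in (1, 2)]
    pd.DataFrame(
        {"block_x": labels[0], "block_y": labels[1], "component": [1, 2], "cumulative_r2": r2}
    ).to_csv(os.path.join(outdir, "pls.tsv"), sep="\t", index=False, float_format="%.6g")
    correlation_circle(model, X, Y).to_csv(
        os.path.join(outdir, "correlation_circle.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    _write_manifest(outdir, "pls", config, [os.path.join(outdir, "pls.tsv")], started)


def stage_enrich(config: PipelineConfig, outdir) -> None:
    started = time.time()
    data_dir = os.path.join(outdir, "data")
    counts = read_citation_counts(os.path.join(data_dir, "citations.tsv"))
    sets = read_gmt(os.path.join(data_dir, "genesets.gmt"))
    modules = read_modules_json(os.path.join(outdir, "modules.json"))
    background = list(counts.index)
    rows = []
    frames = []
    for m in modules:
        targets = [g for g in m.targets if g in counts.index]
        hits = top_cited_intersection(counts, targets)
        rows.append({"module_id": m.module_id, "top_cited_targets": ";".join(hits)})
        enr = geneset_enrichment(targets, sets, background)
        enr.insert(0, "module_id", m.module_id)
        frames.append(enr)
    pd.DataFrame(rows, columns=["module_id", "top_cited_targets"]).to_csv(
        os.path.join(outdir, "top_cited.tsv"), sep="\t", index=False
    )
    enrich = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    enrich.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False, float_format="%.6g")
    _write_manifest(outdir, "enrich", config, [os.path.join(outdir, "enrichment.tsv")], started)


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "discover": stage_discover,
    "validate": stage_validate,
    "fdr": stage_fdr,
    "pls": stage_pls,
    "enrich": stage_enrich,
}


def run_pipeline(subcommand: str, config: PipelineConfig, outdir, force: bool = False) -> None:
    """Run one stage or all of them in order."""
    os.makedirs(outdir, exist_ok=True)
    stages = STAGES if subcommand == "all" else (subcommand,)
    for stage in stages:
        if _stage_done(outdir, stage) and not force:
            logger.info("stage %s already complete (use --force to rerun)", stage)
            continue
        logger.info("running stage %s", stage)
        STAGE_FUNCS[stage](config, outdir)
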