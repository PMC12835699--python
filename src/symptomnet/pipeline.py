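"""End-to-end orchestration: generate/ingest, preprocess, learn, average,
SEM, centrality and probability queries, with a manifest of every output.

All randomness derives from one global seed through stage-specific
sub-seeds, so a rerun with the identical configuration reproduces every
numeric output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .averaging import (arc_confidence, averaged_network, bootstrap_networks,
                        compare_edges, significance_threshold)
from .centrality import centrality
from .clg import fit_parameters
from .dag import Dag
from .data import MixedDataset
from .preprocess import (categorize_age, filter_rows_by_missingness,
                         impute_random_forest, standardize_columns)
from .queries import query_battery
from .search import default_blacklist, hill_climb, tabu_search
from .sem import PathFit, encode_for_sem, fit_path_model
from .synthetic import GeneratorConfig, generate, make_catie_like_truth

_MATRICS = ("matrics_verbal", "matrics_vigilance", "matrics_processing_speed",
            "matrics_reasoning", "matrics_working_memory")

# Median-split query battery mirroring the reported conditional-probability
# table: MATRICS pairs plus the parents of QOL.
DEFAULT_QUERY_PAIRS: tuple[tuple[str, str, str, str], ...] = (
    ("matrics_processing_speed", "<", "matrics_working_memory", "<"),
    ("matrics_processing_speed", "<", "matrics_reasoning", "<"),
    ("matrics_processing_speed", "<", "matrics_vigilance", "<"),
    ("matrics_processing_speed", "<", "matrics_verbal", "<"),
    ("matrics_processing_speed", "<", "panss_negative", ">"),
    ("matrics_processing_speed", "<", "qol_total", ">"),
    ("panss_negative", ">", "qol_total", "<"),
    ("employment", "=working", "qol_total", ">"),
    ("cdss_total", ">", "qol_total", "<"),
    ("dai_total", ">", "qol_total", ">"),
    ("cgi_severity", ">", "qol_total", "<"),
)


@dataclass
class PipelineConfig:
    """Structured configuration of a full run.

    Exactly one of ``generator`` / (``data_csv`` + ``variable_spec``)
    selects the input.  The generator default draws 1460 records with ten
    heavily incomplete rows so that the row filter leaves the emulated
    analysis sample of 1450.
    """

    output_dir: str = "results"
    seed: int = 7
    # input: synthetic generator ...
    generator: dict[str, Any] | None = field(
        default_factory=lambda: {"n": 1460, "missing_rate": 0.024,
                                 "n_bad_rows": 10, "effect_scale": 1.0})
    # ... or files
    data_csv: str | None = None
    variable_spec: str | None = None
    # preprocessing
    filter_threshold: float = 0.5
    impute_max_iter: int = 10
    impute_n_trees: int = 100
    age_column: str | None = None          # raw age years column to bin
    standardize: tuple[str, ...] = _MATRICS
    # learning
    learner: str = "hill_climb"            # or "tabu"
    tabu_length: int = 10
    max_worsening_moves: int = 20
    # averaging
    B: int = 200
    averaging_threshold: float | str = "auto"
    # SEM / queries
    run_sem: bool = True
    query_pairs: tuple = DEFAULT_QUERY_PAIRS
    query_samples: int = 200_000

    def __post_init__(self) -> None:
        has_gen = self.generator is not None
        has_files = self.data_csv is not None and self.variable_spec is not None
        if has_gen == has_files:
            raise ValueError("configure exactly one of generator settings or "
                             "input file paths")
        for name in ("B", "impute_max_iter", "impute_n_trees", "query_samples",
                     "tabu_length"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "query_pairs" in payload:
            payload = dict(payload)
            payload["query_pairs"] = tuple(tuple(p) for p in payload["query_pairs"])
        if "standardize" in payload:
            payload = dict(payload)
            payload["standardize"] = tuple(payload["standardize"])
        return cls(**payload)


def _stage_seed(seed: int, stage: int) -> int:
    ss = np.random.SeedSequence([int(seed), stage])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class ResultsBundle:
    output_dir: Path
    config: PipelineConfig
    network: Dag
    averaged: Dag
    fit_network: PathFit | None
    fit_averaged: PathFit | None
    selected: str | None
    manifest: dict

    @property
    def files(self) -> dict[str, str]:
        return self.manifest["files"]


def select_reporting_network(fit_a: PathFit, fit_b: PathFit) -> tuple[str, dict]:
    """Choose which network to report from: lower RMSEA, then higher CFI,
    then lower BIC; records both fit blocks and the deciding rule."""
    record = {"first": fit_a.global_block(), "second": fit_b.global_block()}
    if fit_a.rmsea != fit_b.rmsea:
        choice = "first" if fit_a.rmsea < fit_b.rmsea else "second"
        record["rule"] = "lower RMSEA"
    elif fit_a.cfi != fit_b.cfi:
        choice = "first" if fit_a.cfi > fit_b.cfi else "second"
        record["rule"] = "higher CFI"
    elif fit_a.bic != fit_b.bic:
        choice = "first" if fit_a.bic < fit_b.bic else "second"
        record["rule"] = "lower BIC"
    else:
        choice = "first"
        record["rule"] = "tie: identical fit statistics, first kept"
    record["choice"] = choice
    return choice, record


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    stages: list[dict] = []
    manifest: dict = {"config": _config_payload(config), "seed": config.seed,
                      "symptomnet_version": __version__, "files": files,
                      "stages": stages}

    def register(key: str, path: Path) -> None:
        files[key] = path.name

    def stage_done(name: str, t0: float) -> None:
        stages.append({"stage": name,
                       "wall_seconds": round(time.perf_counter() - t0, 3)})

    try:
        # ---- stage 1: input -------------------------------------------
        t0 = time.perf_counter()
        if config.generator is not None:
            gen = GeneratorConfig(seed=_stage_seed(config.seed, 1),
                                  **config.generator)
            raw, truth = generate(gen)
            truth.save(out)
            register("truth_graphml", out / "truth.graphml")
            register("truth_params", out / "truth_params.json")
            register("truth_annotations", out / "truth_annotations.json")
        else:
            raw = MixedDataset.from_csv(config.data_csv, config.variable_spec)
            truth = None
        raw.to_csv(out / "data.csv", out / "variables.json")
        register("data", out / "data.csv")
        register("variables", out / "variables.json")
        stage_done("input", t0)

        # ---- stage 2: preprocess --------------------------------------
        t0 = time.perf_counter()
        filtered, n_removed = filter_rows_by_missingness(raw, config.filter_threshold)
        imputed, report = impute_random_forest(
            filtered, max_iter=config.impute_max_iter,
            n_trees=config.impute_n_trees, seed=_stage_seed(config.seed, 2))
        report.n_rows_removed = n_removed
        if config.age_column is not None:
            imputed = _bin_age_column(imputed, config.age_column)
        analysis = standardize_columns(
            imputed, [c for c in config.standardize if c in imputed.columns])
        analysis.to_csv(out / "analysis_data.csv")
        (out / "imputation.json").write_text(report.to_json())
        register("analysis_data", out / "analysis_data.csv")
        register("imputation", out / "imputation.json")
        stage_done("preprocess", t0)

        # ---- stage 3: learn -------------------------------------------
        t0 = time.perf_counter()
        blacklist = default_blacklist(analysis.specs)
        if config.learner == "tabu":
            network, trace = tabu_search(
                analysis, blacklist=blacklist, tabu_length=config.tabu_length,
                max_worsening_moves=config.max_worsening_moves,
                seed=_stage_seed(config.seed, 3))
        else:
            network, trace = hill_climb(analysis, blacklist=blacklist,
                                        seed=_stage_seed(config.seed, 3))
        network.write_graphml(out / "network.graphml")
        network.write_dot(out / "network.dot")
        trace.to_jsonl(out / "search_trace.jsonl")
        register("network_graphml", out / "network.graphml")
        register("network_dot", out / "network.dot")
        register("search_trace", out / "search_trace.jsonl")
        stage_done("learn", t0)

        # ---- stage 4: averaging ---------------------------------------
        t0 = time.perf_counter()
        dags = bootstrap_networks(analysis, B=config.B,
                                  seed=_stage_seed(config.seed, 4))
        conf = arc_confidence(dags)
        conf.to_dataframe().to_csv(out / "arc_confidence.csv", index=False)
        averaged = averaged_network(conf, threshold=config.averaging_threshold,
                                    blacklist=blacklist)
        averaged.write_graphml(out / "averaged_network.graphml")
        averaged.write_dot(out / "averaged_network.dot")
        thr = significance_threshold(conf) if config.averaging_threshold == "auto" \
            else float(config.averaging_threshold)
        (out / "averaging.json").write_text(json.dumps(
            {"B": config.B, "threshold_mode": str(config.averaging_threshold),
             "threshold": thr, "n_arcs": len(averaged.arcs)}, indent=2))
        register("arc_confidence", out / "arc_confidence.csv")
        register("averaged_graphml", out / "averaged_network.graphml")
        register("averaged_dot", out / "averaged_network.dot")
        register("averaging", out / "averaging.json")
        stage_done("average", t0)

        # ---- stage 5: edge comparison ---------------------------------
        t0 = time.perf_counter()
        cmp_dir = compare_edges(network, averaged, ignore_direction=False)
        cmp_skel = compare_edges(network, averaged, ignore_direction=True)
        (out / "edge_comparison.json").write_text(json.dumps({
            "directed": dataclasses.asdict(cmp_dir),
            "skeleton": dataclasses.asdict(cmp_skel)}, indent=2))
        register("edge_comparison", out / "edge_comparison.json")
        stage_done("compare", t0)

        # ---- stage 6: SEM ---------------------------------------------
        fit_net = fit_avg = None
        selected = None
        if config.run_sem:
            t0 = time.perf_counter()
            sem_data = encode_for_sem(analysis)
            (out / "sem_coding.json").write_text(
                json.dumps(sem_data.coding_report, indent=2))
            register("sem_coding", out / "sem_coding.json")
            fit_net = fit_path_model(network, sem_data)
            fit_avg = fit_path_model(averaged, sem_data)
            fit_net.save(out / "pathfit_network.csv", out / "pathfit_network.json")
            fit_avg.save(out / "pathfit_averaged.csv", out / "pathfit_averaged.json")
            for key in ("pathfit_network.csv", "pathfit_network.json",
                        "pathfit_averaged.csv", "pathfit_averaged.json"):
                register(key.replace(".", "_"), out / key)
            choice, record = select_reporting_network(fit_net, fit_avg)
            record["first_name"] = "network"
            record["second_name"] = "averaged_network"
            selected = "network" if choice == "first" else "averaged_network"
            record["selected"] = selected
            (out / "network_selection.json").write_text(json.dumps(record, indent=2))
            register("network_selection", out / "network_selection.json")
            stage_done("sem", t0)
        else:
            manifest["sem"] = "skipped"

        # ---- stage 7: centrality --------------------------------------
        t0 = time.perf_counter()
        centrality(network).to_csv(out / "centrality_network.csv")
        centrality(averaged).to_csv(out / "centrality_averaged.csv")
        register("centrality_network", out / "centrality_network.csv")
        register("centrality_averaged", out / "centrality_averaged.csv")
        stage_done("centrality", t0)

        # ---- stage 8: queries -----------------------------------------
        if config.query_pairs:
            t0 = time.perf_counter()
            reporting = network if selected in (None, "network") else averaged
            params = fit_parameters(reporting, analysis)
            table = query_battery(params, reporting, analysis,
                                  config.query_pairs,
                                  n_samples=config.query_samples,
                                  seed=_stage_seed(config.seed, 8))
            table.to_csv(out / "queries.csv", index=False)
            register("queries", out / "queries.csv")
            stage_done("queries", t0)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "stage", None) or \
            (stages[-1]["stage"] if stages else "input")
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["hashes"] = {k: _sha256(out / v) for k, v in files.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ResultsBundle(output_dir=out, config=config, network=network,
                         averaged=averaged, fit_network=fit_net,
                         fit_averaged=fit_avg, selected=selected,
                         manifest=manifest)


def _bin_age_column(data: MixedDataset, column: str) -> MixedDataset:
    """Replace a raw age-in-years column with the three ordered age bands."""
    from .variables import VariableSpec

    spec = data.spec_of(column)
    if not spec.is_continuous:
        raise ValueError(f"age column {column!r} must be continuous")
    frame = data.frame.copy()
    frame[column] = categorize_age(frame[column].to_numpy(dtype=float))
    specs = [VariableSpec(column, "discrete", ("<30", "31-45", ">45"),
                          role="demographic", ordered=True)
             if s.name == column else s for s in data.specs]
    return MixedDataset(frame, specs)


def _config_payload(config: PipelineConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["query_pairs"] = [list(p) for p in config.query_pairs]
    payload["standardize"] = list(config.standardize)
    return payload


def default_config(**overrides: Any) -> PipelineConfig:
    base = {"output_dir": "results", "seed": 7}
    base.update(overrides)
    return PipelineConfig(**base)
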