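"""End-to-end pipeline orchestration.

Stages: preprocess -> differential -> concordance (correlation/clustering)
-> gene-set scoring (AFC pathways, AAFC injury modules) -> MFA flux
constraints -> TIMBR production scoring -> evaluation -> shuffled-gene
control. Every stage writes its outputs as TSV/JSON under the configured
output directory, and the run report records the file manifest, the config
echo and all derived seeds, which together are sufficient to reproduce the
run exactly. Stages communicate only through the documented file formats.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    AFC,
    PermutationConfig,
    activate_modules,
    score_gene_sets,
    set_scores_frame,
)
from .flux_constraints import (
    apply_constraints,
    constraints_from_mfa,
    read_flux_table,
    relative_to_absolute,
)
from .model_io import read_gene_sets, read_network
from .omics_stats import (
    SampleTable,
    correlation_matrix,
    differential,
    hier_cluster,
    preprocess,
)
from .timbr import (
    TimbrConfig,
    evaluate_predictions,
    production_scores,
    randomized_control,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.manifest = manifest or {}


@dataclass
class PipelineConfig:
    """Paths, thresholds and sub-configs for one pipeline run."""

    network: str
    gene_values: str
    gene_groups: str
    metabolite_values: str
    metabolite_groups: str
    modules: str
    pathways: str | None = None          # AFC gene sets; defaults to modules
    fluxes: str | None = None            # MFA flux TSV (optional stage)
    extra_conditions: dict = field(default_factory=dict)
    # {name: {"gene_values": path, "gene_groups": path}} for concordance
    flux_anchor_reaction: str = "UPTAKE"
    flux_anchor_absolute: float = 20.0   # umol kg^-1 min^-1 at relative 100
    flux_k: float = 2.0                  # half-width in sds for MFA bounds
    q_threshold: float = 0.1
    score_threshold: float = 0.1
    timbr_fraction: float = 0.9
    timbr_fc_clip: float = 4.0
    timbr_standardize: bool = True
    n_draws: int = 10_000
    seed: int = 1
    outdir: str = "toxsig_out"

    def timbr_config(self) -> TimbrConfig:
        return TimbrConfig(
            fraction=self.timbr_fraction,
            score_threshold=self.score_threshold,
            fc_clip=self.timbr_fc_clip,
            standardize=self.timbr_standardize,
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        # relative paths resolve against the config file's directory
        base = path.parent
        for name in ("network", "gene_values", "gene_groups", "metabolite_values",
                     "metabolite_groups", "modules", "pathways", "fluxes"):
            value = getattr(cfg, name)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, name, str(base / value))
        for cond in cfg.extra_conditions.values():
            for key, value in cond.items():
                if not Path(value).is_absolute():
                    cond[key] = str(base / value)
        return cfg

    def validate(self) -> None:
        if self.q_threshold <= 0 or self.score_threshold <= 0:
            raise ValueError("thresholds must be positive")
        required = {
            "network": self.network,
            "gene_values": self.gene_values,
            "gene_groups": self.gene_groups,
            "metabolite_values": self.metabolite_values,
            "metabolite_groups": self.metabolite_groups,
            "modules": self.modules,
        }
        optional = {"pathways": self.pathways, "fluxes": self.fluxes}
        for cond, paths in self.extra_conditions.items():
            for key, value in paths.items():
                optional[f"extra_conditions[{cond}].{key}"] = value
        missing = [
            f"{name}: {p}" for name, p in {**required, **optional}.items()
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError("missing input files: " + "; ".join(missing))


def _derived_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, filename: str) -> Path:
        path = outdir / filename
        manifest[name] = str(path)
        return path

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # -- load ---------------------------------------------------------------
    current = stage("load")
    try:
        network = read_network(config.network)
        gene_table = SampleTable.from_tsv(config.gene_values, config.gene_groups)
        met_table = SampleTable.from_tsv(config.metabolite_values, config.metabolite_groups)
        modules = read_gene_sets(config.modules)
        pathways = read_gene_sets(config.pathways) if config.pathways else modules
    except Exception as exc:
        raise PipelineError(current, str(exc), manifest) from exc

    # -- differential statistics -------------------------------------------
    current = stage("differential")
    try:
        gene_diff = differential(preprocess(gene_table, log_base="2"),
                                 q_threshold=config.q_threshold)
        met_diff = differential(preprocess(met_table, log_base="e"),
                                q_threshold=config.q_threshold)
        gene_diff.to_csv(emit("gene_differential", "gene_differential.tsv"), sep="\t")
        met_diff.to_csv(emit("metabolite_differential", "metabolite_differential.tsv"),
                        sep="\t")
    except Exception as exc:
        raise PipelineError(current, str(exc), manifest) from exc

    # -- concordance --------------------------------------------------------
    current = stage("concordance")
    try:
        profiles = {"primary": gene_diff}
        for name, paths in config.extra_conditions.items():
            table = SampleTable.from_tsv(paths["gene_values"], paths["gene_groups"])
            profiles[name] = differential(preprocess(table, log_base="2"),
                                          q_threshold=config.q_threshold)
        newick = None
        if len(profiles) >= 2:
            for mode, fname in (("all", "correlation_all.tsv"),
                                ("significant-only", "correlation_significant.tsv")):
                correlation_matrix(profiles, mode=mode,
                                   q_threshold=config.q_threshold).to_csv(
                    emit(f"correlation_{mode}", fname), sep="\t")
            merged = pd.DataFrame(
                {name: prof["log_fc"] for name, prof in profiles.items()}
            ).dropna().T
            tree = hier_cluster(merged)
            newick = tree.to_newick()
            emit("cluster_tree", "cluster_tree.nwk").write_text(newick + "\n")
        else:
            logger.info("single condition: concordance stage skipped")
    except Exception as exc:
        raise PipelineError(current, str(exc), manifest) from exc

    # -- gene-set scoring ----------------------------------------------------
    current = stage("enrichment")
    try:
        perm = PermutationConfig(seed=_derived_seed(config.seed, 1),
                                 n_draws=config.n_draws)
        module_scores = activate_modules(gene_diff, modules, perm,
                                         q_threshold=config.q_threshold)
        afc_scores = score_gene_sets(gene_diff["log_fc"].to_dict(), pathways, AFC, perm)
        set_scores_frame(module_scores).to_csv(
            emit("module_scores", "module_scores.tsv"), sep="\t", index=False)
        set_scores_frame(afc_scores).to_csv(
            emit("pathway_scores", "pathway_scores.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(current, str(exc), manifest) from exc

    # -- MFA constraints ------------------------------------------------------
    current = stage("flux_constraints")
    try:
        if config.fluxes:
            estimates = relative_to_absolute(
                read_flux_table(config.fluxes),
                config.flux_anchor_reaction, config.flux_anchor_absolute,
            )
            cs = constraints_from_mfa(estimates, network, k=config.flux_k)
            network_for_timbr = apply_constraints(network, cs)
            pd.DataFrame(
                [{"reaction": rid, "lower": lo, "upper": hi}
                 for rid, (lo, hi) in sorted(cs.bounds.items())]
            ).to_csv(emit("mfa_bounds", "mfa_bounds.tsv"), sep="\t", index=False)
        else:
            network_for_timbr = network
    except Exception as exc:
        raise PipelineError(current, str(exc), manifest) from exc

    # -- TIMBR ----------------------------------------------------------------
    current = stage("timbr")
    try:
        gene_fc = gene_diff["log_fc"].to_dict()
        tconf = config.timbr_config()
        results = production_scores(network_for_timbr, gene_fc, config=tconf)
        results.to_csv(emit("timbr_scores", "timbr_scores.tsv"), sep="\t")
    except Exception as exc:
        raise PipelineError(current, str(exc), manifest) from exc

    # -- evaluation + shuffled-gene control -----------------------------------
    current = stage("evaluation")
    try:
        report_real = evaluate_predictions(results, met_diff,
                                           q_threshold=config.q_threshold)
        v_max_cache = results["v_max"].to_dict()
        report_rand = randomized_control(
            network_for_timbr, gene_fc, None, met_diff,
            seed=_derived_seed(config.seed, 2), config=tconf,
            q_threshold=config.q_threshold, v_max_cache=v_max_cache,
        )
        evaluation = {"real": report_real.to_dict(), "randomized": report_rand.to_dict()}
        emit("evaluation", "evaluation.json").write_text(
            json.dumps(evaluation, indent=1) + "\n")
    except Exception as exc:
        raise PipelineError(current, str(exc), manifest) from exc

    # -- report ---------------------------------------------------------------
    report = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "derived_seeds": {"permutation": perm.seed, "randomized_control": report_rand.seed},
        "manifest": manifest,
        "evaluation": evaluation,
        "newick": newick,
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1) + "\n")
    report["manifest"]["run_report"] = str(outdir / "run_report.json")
    return report
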