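"""Synthetic toy networks and omics/flux datasets with known ground truth.

The generator emulates the structure of a two-group (control/treated, n = 8
per group) toxicant study: a small metabolic network of parallel pathways
from a shared substrate to distinct blood-facing products, gene expression
tables whose designed effects are concentrated on chosen pathways, plasma
metabolite tables whose products shift in the matching direction, and MFA
flux estimates reported relative to an anchor reaction fixed at 100. Effect
directions for metabolites are imposed directly rather than simulated
through kinetics: the claim under test is concordance detection, not
mechanistic simulation.

Everything is bit-reproducible given (scenario, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import (
    GeneSet,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    write_gene_sets,
    write_network,
)
from .omics_stats import SampleTable
from .flux_constraints import FluxEstimate

__all__ = [
    "SyntheticScenario",
    "SyntheticTruth",
    "make_toy_network",
    "simulate_omics",
    "simulate_fluxes",
    "generate_dataset",
]

UPTAKE_ID = "UPTAKE"
UPTAKE_CAPACITY = 10.0

#: Default designed perturbations: one flagship pathway (the designed
#: "active" injury module, delta = 2 on log2 scale for genes and natural-log
#: scale for its product) plus three satellite pathways at delta = 1 so the
#: significant-gene pool and the direction-evaluation set are non-trivial.
DEFAULT_PERTURBATIONS = (
    ("pathway_1", "up", 2.0),
    ("pathway_2", "up", 1.0),
    ("pathway_3", "down", 1.0),
    ("pathway_4", "down", 1.0),
)


@dataclass(frozen=True)
class SyntheticScenario:
    n_pathways: int = 6
    reactions_per_pathway: int = 4
    genes_per_reaction: int = 2
    n_background_genes: int = 150
    n_background_metabolites: int = 20
    perturbations: tuple = DEFAULT_PERTURBATIONS
    noise_sd: float = 0.25
    n_per_group: int = 8
    missing_rate: float = 0.05
    seed: int = 1

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_rate <= 0.3:
            raise ValueError("missing_rate must lie in [0, 0.3]")
        if self.n_pathways < 1 or self.reactions_per_pathway < 2:
            raise ValueError("need >= 1 pathway with >= 2 reactions each")
        known = {f"pathway_{p}" for p in range(1, self.n_pathways + 1)}
        for subsys, direction, delta in self.perturbations:
            if subsys not in known:
                raise ValueError(f"perturbed subsystem {subsys!r} not in the network")
            if direction not in ("up", "down"):
                raise ValueError(f"direction must be up/down, got {direction!r}")
            if delta < 0:
                raise ValueError("effect size delta must be >= 0")
        object.__setattr__(self, "perturbations", tuple(
            (s, d, float(x)) for s, d, x in self.perturbations
        ))

    @classmethod
    def from_file(cls, path) -> "SyntheticScenario":
        data = json.loads(Path(path).read_text())
        if "perturbations" in data:
            data["perturbations"] = tuple(tuple(p) for p in data["perturbations"])
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")


@dataclass
class SyntheticTruth:
    """Designed ground truth for recovery testing."""

    metabolite_directions: dict  # product metabolite id -> "up" | "down"
    active_modules: dict         # module name -> bool
    gene_effects: dict           # gene id -> designed log2 shift (signed)
    primary_module: str | None = None  # module with the largest designed effect

    def to_file(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items() if not k.startswith("_")}
        Path(path).write_text(json.dumps(data, indent=1) + "\n")

    @classmethod
    def from_file(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _pathway_product(p: int) -> str:
    return f"P{p}_e"


def make_toy_network(scenario: SyntheticScenario) -> tuple[MetabolicNetwork, SyntheticTruth]:
    """Build the toy network and the truth skeleton.

    Each pathway is a linear route from the shared substrate to its own
    extracellular product, with one parallel alternative for a middle step
    to exercise flux routing. GPR forms cycle through single-gene, AND-pair
    and OR-pair rules over fresh gene ids. Construction is deterministic.
    """
    mets = [Metabolite(id="A_c", name="shared substrate", compartment="c")]
    rxns = [
        Reaction(id=UPTAKE_ID, stoichiometry={"A_c": 1.0}, lower_bound=0.0,
                 upper_bound=UPTAKE_CAPACITY, gpr="", subsystem="uptake")
    ]
    module_genes: dict[str, list[str]] = {}
    k = scenario.reactions_per_pathway

    def gpr_for(p: int, j: int, tag: str = "") -> tuple[str, list[str]]:
        form = (p + j) % 3
        if scenario.genes_per_reaction == 1 or form == 0:
            genes = [f"g_p{p}_r{j}{tag}_1"]
            return genes[0], genes
        genes = [f"g_p{p}_r{j}{tag}_{i}" for i in range(1, scenario.genes_per_reaction + 1)]
        op = " and " if form == 1 else " or "
        return op.join(genes), genes

    for p in range(1, scenario.n_pathways + 1):
        subsystem = f"pathway_{p}"
        module_genes[subsystem] = []
        chain = ["A_c"] + [f"M_p{p}_{j}" for j in range(1, k)] + [_pathway_product(p)]
        for j in range(1, k):
            mets.append(Metabolite(id=f"M_p{p}_{j}", compartment="c"))
        mets.append(Metabolite(id=_pathway_product(p), name=f"product of pathway {p}",
                               compartment="e", extracellular=True))
        mid = max(1, k // 2)
        for j in range(1, k + 1):
            gpr, genes = gpr_for(p, j)
            module_genes[subsystem].extend(genes)
            rxns.append(Reaction(
                id=f"R_p{p}_{j}",
                stoichiometry={chain[j - 1]: -1.0, chain[j]: 1.0},
                lower_bound=0.0, upper_bound=math.inf,
                gpr=gpr, subsystem=subsystem,
            ))
            if j == mid:  # parallel isoenzyme route for the middle step
                gpr_alt, genes_alt = gpr_for(p, j, tag="alt")
                module_genes[subsystem].extend(genes_alt)
                rxns.append(Reaction(
                    id=f"R_p{p}_{j}alt",
                    stoichiometry={chain[j - 1]: -1.0, chain[j]: 1.0},
                    lower_bound=0.0, upper_bound=math.inf,
                    gpr=gpr_alt, subsystem=subsystem,
                ))
        # secretion exchange so the product can always leave the system
        rxns.append(Reaction(
            id=f"EX_{_pathway_product(p)}",
            stoichiometry={_pathway_product(p): -1.0},
            lower_bound=0.0, upper_bound=math.inf,
            gpr="", subsystem="exchange",
        ))
    network = MetabolicNetwork(mets, rxns)

    gene_effects: dict[str, float] = {}
    metabolite_directions: dict[str, str] = {}
    active = {f"module_{s}": False for s in module_genes}
    primary, primary_delta = None, -1.0
    for subsys, direction, delta in scenario.perturbations:
        signed = delta if direction == "up" else -delta
        for g in module_genes[subsys]:
            gene_effects[g] = signed
        p = int(subsys.split("_")[1])
        metabolite_directions[_pathway_product(p)] = direction
        active[f"module_{subsys}"] = True
        if delta > primary_delta:
            primary, primary_delta = f"module_{subsys}", delta
    truth = SyntheticTruth(
        metabolite_directions=metabolite_directions,
        active_modules=active,
        gene_effects=gene_effects,
        primary_module=primary,
    )
    truth._module_genes = module_genes  # carried to simulate_omics for GMT output
    return network, truth


def pathway_modules(network: MetabolicNetwork) -> list[GeneSet]:
    """Per-pathway gene sets (the synthetic stand-in for injury modules)."""
    from .model_io import gpr_genes, parse_gpr

    by_subsystem: dict[str, list[str]] = {}
    for r in network.reactions:
        if not r.subsystem.startswith("pathway_"):
            continue
        genes = sorted(gpr_genes(parse_gpr(r.gpr)))
        by_subsystem.setdefault(r.subsystem, []).extend(genes)
    return [
        GeneSet(name=f"module_{s}", genes=tuple(dict.fromkeys(genes)),
                description=f"genes of {s}")
        for s, genes in sorted(by_subsystem.items())
    ]


def simulate_omics(
    network: MetabolicNetwork,
    scenario: SyntheticScenario,
    truth: SyntheticTruth,
) -> tuple[SampleTable, SampleTable, SyntheticTruth]:
    """Simulate the gene and metabolite abundance tables.

    Gene abundances are log-normal on the log2 scale: per-gene baseline
    log2-mean ~ Normal(5, 1), treated samples shifted by the designed signed
    effect, within-group noise sd = ``noise_sd``. Metabolite abundances are
    log-normal on the natural-log scale with the product of each perturbed
    pathway shifted by the pathway's delta in its designed direction.
    Missing values are inserted completely at random (metabolite table only,
    as in plasma profiling data) at ``missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 11]))
    n = scenario.n_per_group
    samples = [f"ctrl_{i+1}" for i in range(n)] + [f"trt_{i+1}" for i in range(n)]
    groups = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}

    module_genes = getattr(truth, "_module_genes", None)
    if module_genes is None:
        module_genes = {
            m.name.removeprefix("module_"): list(m.genes) for m in pathway_modules(network)
        }
    pathway_gene_list = [g for genes in module_genes.values() for g in genes]
    bg_genes = [f"bg_{i:04d}" for i in range(1, scenario.n_background_genes + 1)]
    genes = pathway_gene_list + bg_genes

    mu = rng.normal(5.0, 1.0, size=len(genes))
    shift = np.array([truth.gene_effects.get(g, 0.0) for g in genes])
    log2_ctrl = rng.normal(mu[:, None], scenario.noise_sd, size=(len(genes), n))
    log2_trt = rng.normal((mu + shift)[:, None], scenario.noise_sd, size=(len(genes), n))
    gene_values = pd.DataFrame(
        np.power(2.0, np.hstack([log2_ctrl, log2_trt])), index=genes, columns=samples
    )
    gene_table = SampleTable(values=gene_values, groups=groups)

    products = [_pathway_product(p) for p in range(1, scenario.n_pathways + 1)]
    bg_mets = [f"bgmet_{i:03d}" for i in range(1, scenario.n_background_metabolites + 1)]
    met_ids = products + bg_mets
    delta_by_product = {}
    for subsys, direction, delta in scenario.perturbations:
        p = int(subsys.split("_")[1])
        delta_by_product[_pathway_product(p)] = delta if direction == "up" else -delta
    nu = rng.normal(3.0, 1.0, size=len(met_ids))
    met_shift = np.array([delta_by_product.get(m, 0.0) for m in met_ids])
    ln_ctrl = rng.normal(nu[:, None], scenario.noise_sd, size=(len(met_ids), n))
    ln_trt = rng.normal((nu + met_shift)[:, None], scenario.noise_sd, size=(len(met_ids), n))
    met_values = pd.DataFrame(
        np.exp(np.hstack([ln_ctrl, ln_trt])), index=met_ids, columns=samples
    )
    if scenario.missing_rate > 0:
        mask = rng.random(met_values.shape) < scenario.missing_rate
        # keep at least one observed value per feature
        full = mask.all(axis=1)
        mask[full, 0] = False
        met_values = met_values.mask(mask)
    met_table = SampleTable(values=met_values, groups=groups)
    return gene_table, met_table, truth


def simulate_fluxes(
    network: MetabolicNetwork,
    scenario: SyntheticScenario,
    anchor_reaction: str = UPTAKE_ID,
    min_production: float = 0.2,
    with_anchor_absolute: bool = False,
) -> list[FluxEstimate] | tuple[list[FluxEstimate], float]:
    """Sample one feasible steady-state flux vector and report it MFA-style.

    Requires every product's secretion exchange to carry at least
    ``min_production``, picks a vertex of the flux polytope with a random
    LP objective,
    rescales so the anchor reaction reads exactly 100, and attaches relative
    sds of 5-15% (floored at 0.5 relative units for near-zero fluxes).
    Only the original network's reactions are reported.

    With ``with_anchor_absolute=True`` also returns the anchor reaction's
    flux in network units — the "known infusion-rate" value a user must
    supply to convert the relative table back to absolute bounds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 23]))
    net = network
    S = net.stoichiometric_matrix()
    lb, ub = net.bounds()
    lb, ub = np.clip(lb, -100.0, 100.0), np.clip(ub, -100.0, 100.0)
    for met in network.extracellular_metabolites():
        ex = f"EX_{met}"
        if ex in net.reaction_index:
            lb[net.reaction_index[ex]] = min_production
    j_anchor = net.reaction_index[anchor_reaction]
    for _ in range(20):
        c = rng.normal(size=net.n_reactions)
        res = linprog(c, A_eq=S, b_eq=np.zeros(net.n_metabolites),
                      bounds=list(zip(lb, ub)), method="highs")
        if res.status == 0 and abs(res.x[j_anchor]) > 1e-6:
            break
    else:
        raise ValueError("could not find a feasible flux vector with nonzero anchor")
    v = res.x
    scale = 100.0 / v[j_anchor]
    estimates = []
    for r in network.reactions:
        rel = float(v[net.reaction_index[r.id]] * scale)
        sd = float(max(abs(rel) * rng.uniform(0.05, 0.15), 0.5))
        estimates.append(FluxEstimate(reaction=r.id, relative_value=rel, sd_relative=sd))
    if with_anchor_absolute:
        return estimates, float(v[j_anchor])
    return estimates


def generate_dataset(scenario: SyntheticScenario, outdir) -> dict:
    """Write the complete synthetic dataset in the pipeline's file formats.

    Emits network JSON, gene and metabolite TSV tables with group sidecars,
    the per-pathway module GMT, the MFA-style flux TSV, the ground-truth
    JSON and the scenario echo. Returns the manifest (name -> path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, truth = make_toy_network(scenario)
    gene_table, met_table, truth = simulate_omics(network, scenario, truth)
    fluxes, anchor_absolute = simulate_fluxes(network, scenario, with_anchor_absolute=True)

    manifest = {
        "network": outdir / "network.json",
        "gene_values": outdir / "genes.tsv",
        "gene_groups": outdir / "gene_groups.tsv",
        "metabolite_values": outdir / "metabolites.tsv",
        "metabolite_groups": outdir / "metabolite_groups.tsv",
        "modules": outdir / "modules.gmt",
        "fluxes": outdir / "fluxes.tsv",
        "truth": outdir / "truth.json",
        "scenario": outdir / "scenario.json",
    }
    write_network(network, manifest["network"])
    gene_table.to_tsv(manifest["gene_values"], manifest["gene_groups"])
    met_table.to_tsv(manifest["metabolite_values"], manifest["metabolite_groups"])
    write_gene_sets(pathway_modules(network), manifest["modules"])
    pd.DataFrame(
        [{"reaction": e.reaction, "relative_value": e.relative_value, "sd": e.sd_relative}
         for e in fluxes]
    ).to_csv(manifest["fluxes"], sep="\t", index=False)
    truth.to_file(manifest["truth"])
    scenario.to_file(manifest["scenario"])
    out = {k: str(v) for k, v in manifest.items()}
    out["flux_anchor_reaction"] = UPTAKE_ID
    out["flux_anchor_absolute"] = anchor_absolute
    return out
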