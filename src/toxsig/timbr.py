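"""TIMBR metabolite production scoring.

Transcriptionally inferred metabolic biomarker response (TIMBR) asks, for
each blood-facing metabolite, how much global network effort is needed to
produce it under control-like versus treatment-like enzyme availability:

1. Gene log2 fold changes are pushed through each reaction's GPR rule
   (AND = min, OR = max) to a per-reaction fold change.
2. Reaction fold changes become positive flux weights: with
   ``c = clip(fc, -L, L)``, the treatment weight is ``2**(-c/2)`` and the
   control weight ``2**(+c/2)`` — up-regulated reactions are cheap to use
   under treatment and expensive under control, and fc = 0 is neutral
   (weight 1) in both conditions.
3. For each scoreable metabolite a demand (sink) reaction is added; the
   maximal demand flux ``v_max`` is found by LP, then the minimal weighted
   sum of absolute fluxes ``D = min sum_r w_r |v_r|`` subject to steady
   state (S v = 0), the flux bounds, and demand >= f * v_max is solved for
   each condition's weights.
4. The raw production score is ``log2(D_control / D_treatment)``: positive
   when treatment makes production cheaper, i.e. predicts an increased
   plasma level. Scores are optionally standardized across metabolites and
   classified as increased / decreased / unchanged at +-0.1.

Predictions are evaluated against observed metabolite changes (direction
agreement over significantly altered metabolites), and a shuffled-gene
control re-runs the whole scoring with gene labels randomly permuted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import (
    MetabolicNetwork,
    GprParseError,
    add_demand_reaction,
    demand_reaction_id,
    evaluate_gpr,
    parse_gpr,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimbrConfig",
    "ConditionWeights",
    "EvaluationReport",
    "reaction_fold_changes",
    "condition_weights",
    "max_production",
    "network_demand",
    "production_scores",
    "evaluate_predictions",
    "randomized_control",
    "proportional_chance_rate",
]

CONTROL = "control"
TREATED = "treated"

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class TimbrConfig:
    """Knobs of the production-scoring LP layer.

    fraction
        Fraction f of the maximal production capacity the demand constraint
        enforces; f = 1 leaves no routing freedom, so a strict-interior
        default of 0.9 is used.
    score_threshold
        Classification cut-off: score > +t is increased, < -t decreased.
    fc_clip
        Reaction fold changes are clipped to [-L, L] before weight
        conversion so a single extreme gene cannot dominate the objective.
    standardize
        Z-score the raw production scores across feasible metabolites.
    infinity
        Finite sentinel replacing unbounded flux bounds inside the LPs.
    """

    fraction: float = 0.9
    score_threshold: float = 0.1
    fc_clip: float = 4.0
    standardize: bool = True
    infinity: float = 1e6
    lp_tol: float = 1e-9

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if self.fc_clip <= 0:
            raise ValueError("fc_clip must be positive")


@dataclass(frozen=True)
class ConditionWeights:
    condition: str  # "control" | "treated"
    weights: Mapping[str, float]

    def __post_init__(self):
        for rid, w in self.weights.items():
            if not (w > 0 and math.isfinite(w)):
                raise ValueError(f"weight for {rid!r} must be positive finite, got {w}")
        object.__setattr__(self, "weights", dict(self.weights))

    def weight(self, reaction_id: str) -> float:
        return self.weights.get(reaction_id, 1.0)


def reaction_fold_changes(
    network: MetabolicNetwork, gene_fc: Mapping[str, float]
) -> dict[str, float]:
    """Per-reaction fold change via GPR evaluation (missing genes -> 0)."""
    out = {}
    for r in network.reactions:
        try:
            tree = parse_gpr(r.gpr)
        except GprParseError as exc:
            raise ValueError(f"reaction {r.id!r}: bad GPR: {exc}") from exc
        out[r.id] = evaluate_gpr(tree, gene_fc, default=0.0) if tree is not None else 0.0
    return out


def condition_weights(
    reaction_fc: Mapping[str, float],
    condition: str,
    config: TimbrConfig = TimbrConfig(),
) -> ConditionWeights:
    """Convert reaction log2 fold changes into positive flux weights.

    With c = clip(fc, -L, L): treated weight = 2**(-c/2), control weight =
    2**(+c/2). The symmetric form makes negating every fold change swap the
    two conditions exactly, and fc = 0 gives weight 1 in both.
    """
    if condition not in (CONTROL, TREATED):
        raise ValueError(f"condition must be 'control' or 'treated', got {condition!r}")
    sign = -1.0 if condition == TREATED else 1.0
    L = config.fc_clip
    weights = {
        rid: float(2.0 ** (sign * np.clip(fc, -L, L) / 2.0))
        for rid, fc in reaction_fc.items()
    }
    return ConditionWeights(condition=condition, weights=weights)


# ---------------------------------------------------------------------------
# LP layer
# ---------------------------------------------------------------------------

def _finite_bounds(network: MetabolicNetwork, infinity: float):
    lb, ub = network.bounds()
    return np.clip(lb, -infinity, infinity), np.clip(ub, -infinity, infinity)


def _with_demand(network: MetabolicNetwork, metabolite_id: str) -> tuple[MetabolicNetwork, str]:
    did = demand_reaction_id(metabolite_id)
    if did in network.reaction_index:
        return network, did
    return add_demand_reaction(network, metabolite_id), did


def max_production(
    network: MetabolicNetwork,
    metabolite_id: str,
    config: TimbrConfig = TimbrConfig(),
) -> float:
    """Maximal steady-state demand flux for one metabolite.

    Solves max v_demand s.t. S v = 0 and the flux bounds. A demand sink is
    added automatically if the network does not already carry one. Returns
    0.0 when the network has no producing route; NaN when the LP is
    infeasible outright (inconsistent bounds).
    """
    net, did = _with_demand(network, metabolite_id)
    S = net.stoichiometric_matrix()
    lb, ub = _finite_bounds(net, config.infinity)
    c = np.zeros(net.n_reactions)
    c[net.reaction_index[did]] = -1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(net.n_metabolites), bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status != 0:
        logger.warning("max_production(%s): LP status %s", metabolite_id, res.status)
        return math.nan
    return float(-res.fun)


def network_demand(
    network: MetabolicNetwork,
    weights: ConditionWeights,
    metabolite_id: str,
    v_max: float,
    config: TimbrConfig = TimbrConfig(),
) -> float:
    """Minimal weighted total flux needed to sustain f * v_max production.

    Minimizes sum_r w_r |v_r| subject to S v = 0, the flux bounds, and
    demand flux >= fraction * v_max. Reversible reactions are split into
    non-negative forward/backward components so the absolute value is
    linear. Returns NaN when infeasible.
    """
    if not (v_max > 0):
        raise ValueError("network_demand requires v_max > 0")
    net, did = _with_demand(network, metabolite_id)
    S = net.stoichiometric_matrix()
    lb, ub = _finite_bounds(net, config.infinity)
    j_d = net.reaction_index[did]
    lb[j_d] = max(lb[j_d], config.fraction * v_max)
    if lb[j_d] > ub[j_d]:
        return math.nan
    n = net.n_reactions
    w = np.array([weights.weight(r.id) for r in net.reactions])
    # v = plus - minus with plus, minus >= 0; objective sum w (plus + minus)
    A_eq = np.hstack([S, -S])
    c = np.concatenate([w, w])
    bounds = [(max(0.0, lb[j]), max(0.0, ub[j])) for j in range(n)] + [
        (max(0.0, -ub[j]), max(0.0, -lb[j])) for j in range(n)
    ]
    res = linprog(
        c, A_eq=A_eq, b_eq=np.zeros(net.n_metabolites), bounds=bounds, method="highs",
    )
    if res.status != 0:
        return math.nan
    return float(res.fun)


# ---------------------------------------------------------------------------
# Production scores
# ---------------------------------------------------------------------------

def classify(score: float, threshold: float) -> str:
    if score > threshold:
        return INCREASED
    if score < -threshold:
        return DECREASED
    return UNCHANGED


def production_scores(
    network: MetabolicNetwork,
    gene_fc: Mapping[str, float],
    scoreable_metabolites: Sequence[str] | None = None,
    config: TimbrConfig = TimbrConfig(),
    v_max_cache: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """TIMBR production scores for a set of blood-facing metabolites.

    Returns a DataFrame indexed by metabolite with columns ``v_max``,
    ``D_control``, ``D_treatment``, ``raw_score``, ``score``, ``class`` and
    ``feasible``. ``raw_score = log2(D_control / D_treatment)``; ``score``
    is the across-metabolite z-score of ``raw_score`` when standardization
    is enabled (falling back to the raw value when the spread is zero).
    Metabolites with no producing capacity (v_max = 0) or an infeasible
    demand LP are reported with ``feasible=False`` and no class.

    ``v_max_cache`` lets callers reuse maximal capacities across repeated
    scorings (v_max does not depend on the weights).
    """
    if scoreable_metabolites is None:
        scoreable_metabolites = network.extracellular_metabolites()
    if not scoreable_metabolites:
        raise ValueError("no scoreable metabolites")
    # Each condition aggregates the GPR from its own perspective: treated
    # sees the fold changes as given, control sees them sign-reversed (and
    # the result is flipped back to the treated-over-control convention).
    # For single-gene rules both maps coincide; for AND/OR trees this makes
    # negating every gene fold change swap the two conditions exactly.
    rfc_treated = reaction_fold_changes(network, gene_fc)
    neg_fc = {g: -v for g, v in gene_fc.items()}
    rfc_control = {r: -v for r, v in reaction_fold_changes(network, neg_fc).items()}
    w_ctrl = condition_weights(rfc_control, CONTROL, config)
    w_trt = condition_weights(rfc_treated, TREATED, config)
    rows = []
    for met in scoreable_metabolites:
        net, _ = _with_demand(network, met)
        if v_max_cache is not None and met in v_max_cache:
            v_max = v_max_cache[met]
        else:
            v_max = max_production(net, met, config)
        if not (v_max > config.lp_tol * 1e3):
            rows.append((met, 0.0 if v_max == 0 else v_max, math.nan, math.nan,
                         math.nan, False))
            continue
        d_c = network_demand(net, w_ctrl, met, v_max, config)
        d_t = network_demand(net, w_trt, met, v_max, config)
        if not (d_c > 0 and d_t > 0):
            rows.append((met, v_max, d_c, d_t, math.nan, False))
            continue
        rows.append((met, v_max, d_c, d_t, math.log2(d_c) - math.log2(d_t), True))
    df = pd.DataFrame(
        rows, columns=["metabolite", "v_max", "D_control", "D_treatment",
                       "raw_score", "feasible"],
    ).set_index("metabolite")
    if not df["feasible"].any():
        raise ValueError("all scoreable metabolites are infeasible")
    raw = df.loc[df["feasible"], "raw_score"]
    if config.standardize:
        sd = float(raw.std(ddof=0))
        if sd > config.lp_tol:
            score = (raw - float(raw.mean())) / sd
        else:
            score = raw
    else:
        score = raw
    df["score"] = score
    df["class"] = [
        classify(s, config.score_threshold) if feas else ""
        for s, feas in zip(df["score"], df["feasible"])
    ]
    return df


# ---------------------------------------------------------------------------
# Evaluation against observed metabolite changes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    n_scored: int
    n_observed_significant: int
    n_correct: int
    fraction_correct: float
    n_predicted_increased: int
    n_predicted_decreased: int
    n_predicted_unchanged: int
    mode: str = "real"  # "real" | "randomized"
    seed: int | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate_predictions(
    results: pd.DataFrame,
    observed: pd.DataFrame,
    q_threshold: float = 0.1,
    mode: str = "real",
    seed: int | None = None,
) -> EvaluationReport:
    """Direction agreement between production scores and observed changes.

    Over the observed-significant (q < ``q_threshold``) metabolites that are
    scoreable and feasible: a prediction is correct iff class = increased
    with observed log_fc > 0, or class = decreased with observed log_fc < 0.
    An "unchanged" call is never counted correct (the breakdown of calls is
    reported alongside).
    """
    common = results.index.intersection(observed.index)
    if len(common) == 0:
        raise ValueError("no metabolite ids shared between predictions and observations")
    obs = observed.loc[common]
    res = results.loc[common]
    keep = (obs["q"] < q_threshold) & res["feasible"]
    obs, res = obs[keep], res[keep]
    n_corr = int(
        (((res["class"] == INCREASED) & (obs["log_fc"] > 0))
         | ((res["class"] == DECREASED) & (obs["log_fc"] < 0))).sum()
    )
    n_obs = int(len(obs))
    return EvaluationReport(
        n_scored=int(results["feasible"].sum()),
        n_observed_significant=n_obs,
        n_correct=n_corr,
        fraction_correct=(n_corr / n_obs) if n_obs else math.nan,
        n_predicted_increased=int((res["class"] == INCREASED).sum()),
        n_predicted_decreased=int((res["class"] == DECREASED).sum()),
        n_predicted_unchanged=int((res["class"] == UNCHANGED).sum()),
        mode=mode,
        seed=seed,
    )


def shuffle_gene_fc(gene_fc: Mapping[str, float], seed: int) -> dict[str, float]:
    """Randomly permute the gene-id -> fold-change assignment."""
    rng = np.random.default_rng(seed)
    genes = list(gene_fc)
    values = np.array([gene_fc[g] for g in genes], dtype=float)
    return dict(zip(genes, values[rng.permutation(len(genes))]))


def randomized_control(
    network: MetabolicNetwork,
    gene_fc: Mapping[str, float],
    scoreable_metabolites: Sequence[str] | None,
    observed: pd.DataFrame,
    seed: int,
    config: TimbrConfig = TimbrConfig(),
    q_threshold: float = 0.1,
    v_max_cache: Mapping[str, float] | None = None,
) -> EvaluationReport:
    """Shuffled-gene robustness control.

    Permutes gene labels against fold-change values with the given seed,
    re-runs the full scoring, and evaluates against the same observations.
    """
    shuffled = shuffle_gene_fc(gene_fc, seed)
    results = production_scores(
        network, shuffled, scoreable_metabolites, config, v_max_cache=v_max_cache
    )
    return evaluate_predictions(
        results, observed, q_threshold=q_threshold, mode="randomized", seed=seed
    )


def proportional_chance_rate(
    observed_directions: Sequence[str], reports: Sequence[EvaluationReport]
) -> float:
    """No-information base rate for direction prediction.

    If predictions are independent of metabolite identity, the expected
    fraction correct is sum_d P(observed = d) * P(predicted = d) over
    d in {increased, decreased}, with the prediction shares pooled across
    the supplied (randomized-control) reports.
    """
    obs = pd.Series(observed_directions).value_counts(normalize=True)
    tot = sum(
        r.n_predicted_increased + r.n_predicted_decreased + r.n_predicted_unchanged
        for r in reports
    )
    if tot == 0:
        return math.nan
    p_inc = sum(r.n_predicted_increased for r in reports) / tot
    p_dec = sum(r.n_predicted_decreased for r in reports) / tot
    return float(obs.get(INCREASED, 0.0) * p_inc + obs.get(DECREASED, 0.0) * p_dec)
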