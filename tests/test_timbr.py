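import math

import numpy as np
import pandas as pd
import pytest

from toxsig.model_io import MetabolicNetwork, Reaction, add_demand_reaction
from toxsig.timbr import (
    ConditionWeights,
    TimbrConfig,
    classify,
    condition_weights,
    evaluate_predictions,
    max_production,
    network_demand,
    production_scores,
    proportional_chance_rate,
    randomized_control,
    reaction_fold_changes,
    shuffle_gene_fc,
)

FULL = TimbrConfig(fraction=1.0, standardize=False)


def _weights(mapping, condition="control"):
    return ConditionWeights(condition=condition, weights=mapping)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def test_reaction_fold_changes(chain_network):
    fc = reaction_fold_changes(chain_network, {"g1": 1.2, "g2": 0.3})
    assert fc == {"SRC": 0.0, "R2": 1.2}  # empty GPR -> 0


def test_reaction_fold_changes_gpr_forms():
    from toxsig.model_io import Metabolite

    net = MetabolicNetwork(
        [Metabolite(id="a", compartment="c")],
        [
            Reaction(id="r_or", stoichiometry={"a": 1.0}, gpr="g1 or g2"),
            Reaction(id="r_and", stoichiometry={"a": -1.0}, gpr="g1 and g2"),
        ],
    )
    fc = reaction_fold_changes(net, {"g1": 1.2, "g2": 0.3})
    assert fc["r_or"] == 1.2
    assert reaction_fold_changes(net, {"g1": 1.2})["r_and"] == 0.0  # default 0


@pytest.mark.parametrize(
    "fc, condition, expected",
    [
        (1.0, "treated", 2 ** -0.5),
        (1.0, "control", 2 ** 0.5),
        (0.0, "treated", 1.0),
        (0.0, "control", 1.0),
        (10.0, "treated", 0.25),   # clipped at L = 4
        (-10.0, "control", 0.25),
    ],
)
def test_condition_weights(fc, condition, expected):
    w = condition_weights({"r": fc}, condition)
    assert w.weight("r") == pytest.approx(expected, rel=1e-12)
    assert w.weight("unmapped") == 1.0


def test_condition_weights_positive_invariant():
    with pytest.raises(ValueError, match="positive"):
        ConditionWeights(condition="control", weights={"r": 0.0})


# ---------------------------------------------------------------------------
# LP layer
# ---------------------------------------------------------------------------

def test_max_production_chain(chain_network):
    assert max_production(chain_network, "B_e") == pytest.approx(10.0, abs=1e-7)


def test_max_production_bottleneck(chain_network):
    throttled = chain_network.with_bounds({"R2": (0.0, 4.0)})
    assert max_production(throttled, "B_e") == pytest.approx(4.0, abs=1e-7)


def test_max_production_no_route(chain_network):
    blocked = chain_network.with_bounds({"SRC": (0.0, 0.0), "R2": (0.0, 0.0)})
    assert max_production(blocked, "B_e") == pytest.approx(0.0, abs=1e-9)


def test_network_demand_chain(chain_network):
    w = _weights({"SRC": 1.0, "R2": 1.0, "DM_B_e": 1.0})
    assert network_demand(chain_network, w, "B_e", 10.0, FULL) == pytest.approx(30.0, abs=1e-6)
    half = TimbrConfig(fraction=0.5, standardize=False)
    assert network_demand(chain_network, w, "B_e", 10.0, half) == pytest.approx(15.0, abs=1e-6)


def test_network_demand_prefers_cheap_parallel_route(parallel_network):
    w = _weights({"SRC": 1.0, "R2": 1.0, "R2b": 0.5, "DM_B_e": 1.0})
    assert network_demand(parallel_network, w, "B_e", 10.0, FULL) == pytest.approx(25.0, abs=1e-6)


def test_network_demand_scale_invariance(parallel_network):
    w1 = {"SRC": 1.0, "R2": 1.0, "R2b": 0.5, "DM_B_e": 1.0}
    d1 = network_demand(parallel_network, _weights(w1), "B_e", 10.0, FULL)
    d2 = network_demand(parallel_network,
                        _weights({k: 2 * v for k, v in w1.items()}), "B_e", 10.0, FULL)
    assert d2 == pytest.approx(2 * d1, rel=1e-9)


def test_network_demand_requires_positive_vmax(chain_network):
    with pytest.raises(ValueError):
        network_demand(chain_network, _weights({}), "B_e", 0.0, FULL)


# ---------------------------------------------------------------------------
# production scores
# ---------------------------------------------------------------------------

def test_production_score_worked_example(parallel_network):
    # g2 up by 2: R2b costs 0.5 under treatment, 2 under control
    results = production_scores(parallel_network, {"g1": 0.0, "g2": 2.0}, config=FULL)
    row = results.loc["B_e"]
    assert row["D_control"] == pytest.approx(30.0, abs=1e-6)
    assert row["D_treatment"] == pytest.approx(25.0, abs=1e-6)
    assert row["raw_score"] == pytest.approx(math.log2(1.2), abs=1e-6)
    assert row["class"] == "increased"


def test_production_scores_neutral_when_fc_zero(strong_signal_data):
    _, network, _, _, _ = strong_signal_data
    results = production_scores(network, {}, config=TimbrConfig())
    assert (results.loc[results["feasible"], "raw_score"] == 0.0).all()
    assert (results.loc[results["feasible"], "class"] == "unchanged").all()


def test_production_scores_antisymmetric(strong_signal_data):
    """Negating every gene fold change swaps conditions and negates scores
    exactly, including through AND/OR GPR rules."""
    _, network, truth, _, _ = strong_signal_data
    rng = np.random.default_rng(17)
    genes = sorted({g for r in network.reactions for g in r.gpr.split()
                    if g not in ("and", "or")})
    fc = {g: float(v) for g, v in zip(genes, rng.normal(scale=1.5, size=len(genes)))}
    cfg = TimbrConfig(standardize=False)
    fwd = production_scores(network, fc, config=cfg)
    rev = production_scores(network, {g: -v for g, v in fc.items()}, config=cfg)
    feas = fwd["feasible"]
    assert feas.equals(rev["feasible"])
    assert np.array_equal(fwd.loc[feas, "D_control"], rev.loc[feas, "D_treatment"])
    assert np.array_equal(fwd.loc[feas, "D_treatment"], rev.loc[feas, "D_control"])
    assert np.array_equal(fwd.loc[feas, "raw_score"], -rev.loc[feas, "raw_score"])


def test_production_scores_monotone_in_route_expression(chain_network):
    """Raising the producing route's gene never lowers the raw score."""
    scores = []
    for fc in (-1.0, 0.0, 1.0, 2.0):
        df = production_scores(chain_network, {"g1": fc}, config=FULL)
        scores.append(df.loc["B_e", "raw_score"])
    assert all(a <= b + 1e-9 for a, b in zip(scores, scores[1:]))


def test_classification_thresholds():
    assert classify(0.05, 0.1) == "unchanged"
    assert classify(-0.2, 0.1) == "decreased"
    assert classify(0.1, 0.1) == "unchanged"   # ties are unchanged
    assert classify(0.100001, 0.1) == "increased"


# ---------------------------------------------------------------------------
# evaluation and shuffled-gene control
# ---------------------------------------------------------------------------

def _results(classes, feasible=None):
    feasible = feasible or [True] * len(classes)
    return pd.DataFrame(
        {"class": classes, "feasible": feasible,
         "v_max": 1.0, "D_control": 1.0, "D_treatment": 1.0,
         "raw_score": 0.0, "score": 0.0},
        index=[f"m{i}" for i in range(len(classes))],
    )


def _observed(log_fcs, qs=None):
    qs = qs or [0.01] * len(log_fcs)
    return pd.DataFrame({"log_fc": log_fcs, "q": qs},
                        index=[f"m{i}" for i in range(len(log_fcs))])


def test_evaluate_predictions_counting():
    report = evaluate_predictions(
        _results(["increased", "unchanged", "decreased"]),
        _observed([1.0, -1.0, 1.0]),
    )
    assert report.n_correct == 1 and report.n_observed_significant == 3
    assert report.fraction_correct == pytest.approx(1 / 3)


def test_evaluate_predictions_perfect_and_filters():
    report = evaluate_predictions(
        _results(["increased"] * 3 + ["decreased"] * 2),
        _observed([1.0, 2.0, 0.5, -1.0, -2.0]),
    )
    assert report.fraction_correct == 1.0
    # non-significant observations are excluded from the denominator
    report = evaluate_predictions(
        _results(["increased", "increased"]),
        _observed([1.0, 1.0], qs=[0.01, 0.9]),
    )
    assert report.n_observed_significant == 1


def test_evaluate_predictions_requires_shared_ids():
    with pytest.raises(ValueError, match="shared"):
        evaluate_predictions(
            _results(["increased"]),
            pd.DataFrame({"log_fc": [1.0], "q": [0.01]}, index=["other"]),
        )


def test_shuffle_determinism_and_degenerate_identity(chain_network):
    fc = {f"g{i}": float(i) for i in range(10)}
    assert shuffle_gene_fc(fc, 5) == shuffle_gene_fc(fc, 5)
    # a constant fold-change table is invariant under any permutation, so
    # the randomized control must reproduce the real-mode report
    const_fc = {"g1": 0.8}
    obs = pd.DataFrame({"log_fc": [1.0], "q": [0.01]}, index=["B_e"])
    real = evaluate_predictions(
        production_scores(chain_network, const_fc, config=FULL), obs)
    rand1 = randomized_control(chain_network, const_fc, None, obs, seed=3, config=FULL)
    rand2 = randomized_control(chain_network, const_fc, None, obs, seed=3, config=FULL)
    assert rand1.fraction_correct == real.fraction_correct
    assert rand1 == rand2


def test_proportional_chance_rate():
    from toxsig.timbr import EvaluationReport

    reports = [EvaluationReport(4, 4, 2, 0.5, 2, 1, 1, mode="randomized", seed=0)]
    rate = proportional_chance_rate(["increased", "increased", "decreased"], reports)
    assert rate == pytest.approx((2 / 3) * (2 / 4) + (1 / 3) * (1 / 4))
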