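"""Independent reference computations used by the tests.

These deliberately avoid the code paths they check: the LP oracle minimizes
by exhaustive enumeration of basic feasible solutions (vertices) instead of
calling a solver, and the FDR reference applies the step-up rule as a direct
per-element minimum instead of a cumulative scan.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from toxsig.model_io import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    add_demand_reaction,
    demand_reaction_id,
)


def bh_reference(p_values) -> np.ndarray:
    """Brute-force Benjamini-Hochberg q-values.

    q_i = min(1, min over {j : p_j >= p_i} of p_j / (r_j / m)) where r_j is
    the number of p-values <= p_j (ties take the largest rank). O(m^2).
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    ranks = np.array([(p <= pj).sum() for pj in p])
    terms = p / (ranks / m)
    q = np.empty(m)
    for i in range(m):
        q[i] = min(1.0, terms[p >= p[i]].min())
    return q


# ---------------------------------------------------------------------------
# Brute-force LP by vertex enumeration
# ---------------------------------------------------------------------------

def enumerate_vertices(A, b, lower, upper, tol=1e-7):
    """All basic feasible solutions of {x : A x = b, lower <= x <= upper}.

    Requires finite bounds. For every choice of rank(A) candidate basic
    columns, solves for all assignments of the remaining variables to their
    bounds in one batched least-squares call and keeps feasible solutions.
    Returns an array of shape (n_vertices, n).
    """
    A = np.asarray(A, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    assert np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))
    m, n = A.shape
    r = np.linalg.matrix_rank(A, tol=1e-10)
    found = []
    for free in itertools.combinations(range(n), r):
        B = A[:, list(free)]
        if np.linalg.matrix_rank(B, tol=1e-10) < r:
            continue
        fixed = [j for j in range(n) if j not in free]
        options = [(lower[j],) if lower[j] == upper[j] else (lower[j], upper[j])
                   for j in fixed]
        choices = np.array(list(itertools.product(*options))).T  # (n_fixed, K)
        if choices.size == 0:
            choices = np.zeros((0, 1))
        K = choices.shape[1]
        rhs = np.tile(b[:, None], (1, K)) - (A[:, fixed] @ choices if fixed else 0.0)
        sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
        X = np.empty((n, K))
        X[fixed, :] = choices
        X[list(free), :] = sol
        scale = 1.0 + np.abs(X).max(axis=0)
        ok = (np.abs(A @ X - b[:, None]).max(axis=0) < tol * scale)
        ok &= (X >= lower[:, None] - tol).all(axis=0)
        ok &= (X <= upper[:, None] + tol).all(axis=0)
        if ok.any():
            found.append(np.clip(X[:, ok].T, lower, upper))
    if not found:
        return np.zeros((0, n))
    return np.vstack(found)


def _split_formulation(network, infinity=1e6):
    """Split-variable system with degenerate (frozen-at-zero) columns folded.

    x = [v_plus; v_minus] restricted to columns whose bounds are not pinned;
    returns (A, b, lower, upper, col_ids) with col_ids[i] = (reaction_index,
    +1 | -1) identifying the surviving columns.
    """
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds()
    lb = np.clip(lb, -infinity, infinity)
    ub = np.clip(ub, -infinity, infinity)
    A_full = np.hstack([S, -S])
    lower = np.concatenate([np.maximum(0.0, lb), np.maximum(0.0, -ub)])
    upper = np.concatenate([np.maximum(0.0, ub), np.maximum(0.0, -lb)])
    keep = lower != upper
    b = -(A_full[:, ~keep] @ lower[~keep])
    n = network.n_reactions
    col_ids = [(j % n, +1 if j < n else -1) for j in np.nonzero(keep)[0]]
    return A_full[:, keep], b, lower[keep], upper[keep], col_ids


def oracle_max_production(network, metabolite_id, infinity=1e6):
    """Maximal demand flux by vertex enumeration (demand must be present)."""
    A, b, lower, upper, col_ids = _split_formulation(network, infinity)
    j_d = network.reaction_index[demand_reaction_id(metabolite_id)]
    sign = np.array([s if j == j_d else 0 for j, s in col_ids], dtype=float)
    verts = enumerate_vertices(A, b, lower, upper)
    if verts.shape[0] == 0:
        return math.nan
    return float((verts @ sign).max())


def oracle_network_demand(network, weights, metabolite_id, v_max, fraction,
                          infinity=1e6):
    """Minimal weighted total |flux| by vertex enumeration."""
    A, b, lower, upper, col_ids = _split_formulation(network, infinity)
    j_d = network.reaction_index[demand_reaction_id(metabolite_id)]
    lower = lower.copy()
    for i, (j, s) in enumerate(col_ids):
        if j == j_d and s > 0:
            lower[i] = max(lower[i], fraction * v_max)
            if lower[i] > upper[i]:
                return math.nan
    w = np.array([weights.weight(network.reactions[j].id) for j, _ in col_ids])
    verts = enumerate_vertices(A, b, lower, upper)
    if verts.shape[0] == 0:
        return math.nan
    return float((verts @ w).min())


def random_small_network(rng) -> tuple[MetabolicNetwork, dict]:
    """A random producible toy network with <= 8 reactions (demand included),
    integer stoichiometry and small finite bounds, plus random weights."""
    k = int(rng.integers(1, 4))  # internal chain length
    mets = [Metabolite(id=f"m{i}", compartment="c") for i in range(1, k + 1)]
    mets.append(Metabolite(id="prod_e", compartment="e", extracellular=True))
    chain = [f"m{i}" for i in range(1, k + 1)] + ["prod_e"]
    rxns = [Reaction(id="SRC", stoichiometry={"m1": 1.0},
                     lower_bound=0.0, upper_bound=float(rng.integers(2, 9)))]
    for step in range(k):
        n_par = int(rng.integers(1, 3)) if len(rxns) < 6 else 1
        for branch in range(n_par):
            coef_in = float(rng.choice([1.0, 1.0, 2.0]))
            reversible = bool(rng.random() < 0.25)
            ub = float(rng.integers(2, 11))
            rxns.append(Reaction(
                id=f"R{step}_{branch}",
                stoichiometry={chain[step]: -coef_in, chain[step + 1]: 1.0},
                lower_bound=-ub if reversible else 0.0,
                upper_bound=ub,
            ))
    net = MetabolicNetwork(mets, rxns)
    net = add_demand_reaction(net, "prod_e")
    weights = {r.id: float(rng.choice([0.25, 0.5, 1.0, 2.0, 4.0]))
               for r in net.reactions}
    return net, weights
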