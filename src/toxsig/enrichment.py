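"""Gene-set activation scoring with permutation nulls.

Two aggregate scores over per-gene log fold changes:

* AFC (aggregated fold change): signed sum over member genes; the sign of
  the score gives the direction of pathway regulation.
* AAFC (absolute aggregated fold change): sum of |log FC| over member genes;
  a magnitude-only activation score used for injury modules.

Significance is assessed against a size-matched permutation null: random
gene subsets are drawn from the fold-change pool (10,000 draws by default),
p is the upper-tail probability that a random set scores at least as high as
the actual set, and z is the number of null standard deviations separating
the actual score from the null mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_io import GeneSet

__all__ = [
    "PermutationConfig",
    "SetScore",
    "set_score",
    "permutation_test",
    "score_gene_sets",
    "activate_modules",
    "set_scores_frame",
]

AFC = "afc"
AAFC = "aafc"


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-null settings. The seed is mandatory for reproducibility
    and is echoed into every output row."""

    seed: int
    n_draws: int = 10_000
    with_replacement: bool = False

    def __post_init__(self):
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")


@dataclass(frozen=True)
class SetScore:
    name: str
    mode: str  # "afc" | "aafc"
    n_genes_used: int
    score: float
    z: float
    p: float
    seed: int
    n_draws: int
    null_result: bool = False  # no member gene present in the FC table


def _aggregate(values: np.ndarray, mode: str) -> float:
    if mode == AFC:
        return float(values.sum())
    if mode == AAFC:
        return float(np.abs(values).sum())
    raise ValueError(f"unknown mode {mode!r}")


def set_score(fc: Mapping[str, float], genes: GeneSet | Sequence[str], mode: str) -> float:
    """Aggregate score of one gene set; absent genes are skipped.

    Raises if no member gene is present in ``fc``.
    """
    members = genes.genes if isinstance(genes, GeneSet) else genes
    present = np.array([fc[g] for g in members if g in fc], dtype=float)
    if present.size == 0:
        name = genes.name if isinstance(genes, GeneSet) else "<set>"
        raise ValueError(f"gene set {name!r}: no member gene present in the FC table")
    return _aggregate(present, mode)


def permutation_test(
    fc_pool: Sequence[float],
    set_size: int,
    actual_score: float,
    mode: str,
    config: PermutationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Size-matched permutation null for one set score.

    Draws ``n_draws`` random subsets of ``set_size`` values from the pool
    (without replacement by default), scores each under ``mode`` and returns

    * ``z = (actual - mean(null)) / sd(null)``
    * ``p = (1 + #{null >= actual}) / (n_draws + 1)``

    Ties count as extreme and the add-one smoothing keeps p strictly
    positive. A degenerate null (sd = 0) yields z = 0 when the actual score
    equals the null mean and a signed infinity otherwise.
    """
    pool = np.asarray(fc_pool, dtype=float)
    if not (1 <= set_size <= pool.size):
        raise ValueError(f"set_size {set_size} outside [1, {pool.size}]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_draws
    if config.with_replacement:
        draws = rng.choice(pool, size=(n, set_size), replace=True)
    else:
        # row-wise subsets without replacement, vectorized via random keys
        keys = rng.random((n, pool.size))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        draws = pool[idx]
    null_scores = draws.sum(axis=1) if mode == AFC else np.abs(draws).sum(axis=1)
    mu = float(null_scores.mean())
    sd = float(null_scores.std(ddof=1))
    if sd == 0.0:
        z = 0.0 if math.isclose(actual_score, mu, abs_tol=1e-12) else math.copysign(
            math.inf, actual_score - mu
        )
    else:
        z = (actual_score - mu) / sd
    p = (1.0 + int(np.count_nonzero(null_scores >= actual_score - 1e-12))) / (n + 1.0)
    return float(z), float(p)


def score_gene_sets(
    fc: Mapping[str, float],
    sets: Iterable[GeneSet],
    mode: str,
    config: PermutationConfig,
) -> list[SetScore]:
    """Score each gene set against the pool of all values in ``fc``.

    Sets with no member in the table are reported with ``null_result=True``
    (score/z/p are NaN) rather than silently dropped. Each set gets a fresh
    generator seeded from the config, so identically-defined sets receive
    identical (z, p) regardless of their position in the list.
    """
    pool = np.array(list(fc.values()), dtype=float)
    out = []
    for s in sets:
        present = [g for g in s.genes if g in fc]
        if not present:
            out.append(
                SetScore(s.name, mode, 0, math.nan, math.nan, math.nan,
                         config.seed, config.n_draws, null_result=True)
            )
            continue
        score = set_score(fc, present, mode)
        z, p = permutation_test(pool, len(present), score, mode, config)
        out.append(
            SetScore(s.name, mode, len(present), score, z, p,
                     config.seed, config.n_draws)
        )
    return out


def activate_modules(
    diff: pd.DataFrame,
    modules: Iterable[GeneSet],
    config: PermutationConfig,
    q_threshold: float = 0.1,
) -> list[SetScore]:
    """AAFC activation scores for injury modules on significant genes only.

    Filters the differential table to q < ``q_threshold``; both the module
    scores and the permutation pool come from the filtered table.
    """
    sig = diff[diff["q"] < q_threshold]
    if sig.empty:
        raise ValueError(
            f"no genes significant at q < {q_threshold}; relax the threshold"
        )
    fc = sig["log_fc"].to_dict()
    return score_gene_sets(fc, modules, AAFC, config)


def set_scores_frame(scores: Iterable[SetScore]) -> pd.DataFrame:
    """Tabular view (the TSV output surface) of a list of set scores."""
    return pd.DataFrame(
        [
            {
                "set": s.name,
                "mode": s.mode,
                "n_genes_used": s.n_genes_used,
                "score": s.score,
                "z": s.z,
                "p": s.p,
                "seed": s.seed,
                "n_draws": s.n_draws,
                "null_result": s.null_result,
            }
            for s in scores
        ]
    )
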