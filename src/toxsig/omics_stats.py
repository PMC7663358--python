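"""Differential statistics and cross-condition concordance.

Metabolite (or gene) abundance tables are analysed the standard untargeted
way: minimum-value imputation per feature, log transform, Welch's two-sample
t-test treated vs control, and Benjamini-Hochberg FDR (q-values). Concordance
between conditions is quantified by Pearson correlation of log fold-change
profiles and by hierarchical clustering with correlation distance.

Log-base convention: natural log for metabolite fold changes, log2 for gene
fold changes destined for reaction-weight conversion; both are explicit
parameters and recorded in output metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SampleTable",
    "CorrelationReport",
    "ClusterTree",
    "preprocess",
    "welch_test",
    "bh_fdr",
    "differential",
    "pairwise_correlation",
    "correlation_matrix",
    "hier_cluster",
]

CONTROL = "control"
TREATED = "treated"


@dataclass
class SampleTable:
    """A features x samples abundance matrix with a two-group design.

    ``values`` holds raw (non-negative) abundances with NaN for missing
    entries until :func:`preprocess` is applied, after which it holds
    log-transformed values and ``log_base`` records the transform.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    log_base: str | None = None  # None = raw scale; "e" or "2" once logged

    def __post_init__(self):
        self.groups = dict(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        bad = sorted(set(self.groups.values()) - {CONTROL, TREATED})
        if bad:
            raise ValueError(f"unknown group labels {bad}; use 'control'/'treated'")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @classmethod
    def from_tsv(cls, values_path, groups_path, **kw) -> "SampleTable":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        gdf = pd.read_csv(groups_path, sep="\t", index_col=0)
        groups = gdf.iloc[:, 0].astype(str).to_dict()
        return cls(values=values, groups=groups, **kw)

    def to_tsv(self, values_path, groups_path) -> None:
        self.values.to_csv(values_path, sep="\t")
        pd.Series(self.groups, name="group").rename_axis("sample").to_csv(
            groups_path, sep="\t"
        )


def preprocess(
    table: SampleTable, log_base: str = "e", drop_all_missing: bool = True
) -> SampleTable:
    """Impute missing values with the per-feature minimum, then log-transform.

    Missing entries in each feature row are replaced by that feature's
    minimum observed value; values are then transformed with the requested
    log base. Features with no observed value at all are dropped with a
    warning (or raise when ``drop_all_missing=False``).
    """
    if table.log_base is not None:
        raise ValueError("table is already log-transformed")
    if log_base not in ("e", "2"):
        raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}")
    values = table.values.copy()
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        if not drop_all_missing:
            raise ValueError(
                f"features with no observed values: {list(values.index[all_missing])}"
            )
        logger.warning(
            "dropping %d feature(s) with no observed values", int(all_missing.sum())
        )
        values = values.loc[~all_missing]
    row_min = values.min(axis=1)
    values = values.apply(lambda row: row.fillna(row_min[row.name]), axis=1)
    if (values <= 0).any().any():
        raise ValueError("non-positive abundances cannot be log-transformed")
    logged = np.log(values) if log_base == "e" else np.log2(values)
    return SampleTable(values=logged, groups=dict(table.groups), log_base=log_base)


def welch_test(a, b) -> tuple[float, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (mean(a) - mean(b)) / sqrt(s2a/na + s2b/nb) with Welch-Satterthwaite
    degrees of freedom. Degenerate zero-variance-in-both-groups inputs return
    (0, 1) when the means are equal and raise otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test needs at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def differential(
    table: SampleTable, q_threshold: float = 0.1
) -> pd.DataFrame:
    """Per-feature differential statistics on a preprocessed (log) table.

    Returns a DataFrame indexed by feature with columns ``log_fc`` (treated
    mean minus control mean, in the table's log base), ``t``, ``p``, ``q``
    and ``significant`` (q < ``q_threshold``).
    """
    if table.log_base is None:
        raise ValueError("differential() expects a preprocessed (log) table")
    ctrl = table.samples_in(CONTROL)
    trt = table.samples_in(TREATED)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for feature, row in table.values.iterrows():
        a = row[trt].to_numpy(dtype=float)
        b = row[ctrl].to_numpy(dtype=float)
        t, p = welch_test(a, b)
        rows.append((feature, float(a.mean() - b.mean()), t, p))
    if not rows:
        return pd.DataFrame(
            columns=["log_fc", "t", "p", "q", "significant"]
        ).rename_axis("feature")
    df = pd.DataFrame(rows, columns=["feature", "log_fc", "t", "p"]).set_index("feature")
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] < q_threshold
    df.attrs["log_base"] = table.log_base
    df.attrs["q_threshold"] = q_threshold
    return df


@dataclass(frozen=True)
class CorrelationReport:
    pair: tuple[str, str]
    n_common: int
    r: float
    mode: str  # "all" | "significant-only"


def pairwise_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    mode: str = "all",
    q_threshold: float = 0.1,
    labels: tuple[str, str] = ("a", "b"),
) -> CorrelationReport:
    """Pearson r between two conditions' log-FC profiles.

    ``a`` and ``b`` are :func:`differential` outputs (need ``log_fc`` and,
    for significant-only mode, ``q``). The correlation runs over the feature
    intersection; in ``significant-only`` mode only features significant in
    both conditions (q < ``q_threshold``) are used.
    """
    if mode not in ("all", "significant-only"):
        raise ValueError(f"unknown mode {mode!r}")
    common = a.index.intersection(b.index)
    if mode == "significant-only":
        sig = (a.loc[common, "q"] < q_threshold) & (b.loc[common, "q"] < q_threshold)
        common = common[sig.to_numpy()]
    if len(common) < 3:
        raise ValueError(
            f"pair {labels}: only {len(common)} common feature(s) after filtering "
            "(>= 3 required)"
        )
    r, _ = stats.pearsonr(a.loc[common, "log_fc"], b.loc[common, "log_fc"])
    return CorrelationReport(pair=labels, n_common=len(common), r=float(r), mode=mode)


def correlation_matrix(
    profiles: Mapping[str, pd.DataFrame], mode: str = "all", q_threshold: float = 0.1
) -> pd.DataFrame:
    """Symmetric matrix of pairwise log-FC correlations across conditions."""
    names = list(profiles)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            rep = pairwise_correlation(
                profiles[x], profiles[y], mode=mode, q_threshold=q_threshold,
                labels=(x, y),
            )
            mat.loc[x, y] = mat.loc[y, x] = rep.r
    return mat


@dataclass
class ClusterTree:
    """Average-linkage tree over conditions, correlation distance (1 - r)."""

    linkage: np.ndarray  # scipy linkage matrix, (n-1, 4)
    labels: list[str]

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hier_cluster(profiles: pd.DataFrame) -> ClusterTree:
    """Agglomerative clustering of conditions by log-FC profile similarity.

    ``profiles`` is conditions x features (complete, inner-joined upstream).
    Distance is 1 - Pearson r between condition rows, linkage is average
    (UPGMA).
    """
    if profiles.shape[0] < 2:
        raise ValueError("hier_cluster needs >= 2 conditions")
    if profiles.isna().any().any():
        raise ValueError("profiles must be complete (inner-join features first)")
    corr = np.corrcoef(profiles.to_numpy(dtype=float))
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ClusterTree(linkage=Z, labels=list(profiles.index))
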