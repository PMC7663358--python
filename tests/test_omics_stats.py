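import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bh_reference
from toxsig.omics_stats import (
    SampleTable,
    bh_fdr,
    correlation_matrix,
    differential,
    hier_cluster,
    pairwise_correlation,
    preprocess,
    welch_test,
)


def _table(values, groups=None):
    df = pd.DataFrame(values)
    if groups is None:
        n = df.shape[1] // 2
        groups = {c: ("control" if i < n else "treated")
                  for i, c in enumerate(df.columns)}
    return SampleTable(values=df, groups=groups)


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

def test_preprocess_minimum_value_imputation():
    t = _table({"s1": [4.0], "s2": [np.nan], "s3": [8.0], "s4": [8.0]})
    out = preprocess(t, log_base="e")
    np.testing.assert_allclose(out.values.iloc[0], np.log([4.0, 4.0, 8.0, 8.0]))
    assert out.log_base == "e"


def test_preprocess_without_missing_is_pure_log():
    t = _table({"s1": [1.0, 2.0], "s2": [4.0, 8.0], "s3": [2.0, 2.0], "s4": [1.0, 1.0]})
    out = preprocess(t, log_base="2")
    assert out.values.shape == t.values.shape
    np.testing.assert_allclose(out.values.to_numpy(), np.log2(t.values.to_numpy()))


def test_preprocess_drops_all_missing_feature(caplog):
    t = _table({"s1": [1.0, np.nan], "s2": [2.0, np.nan],
                "s3": [1.0, np.nan], "s4": [2.0, np.nan]})
    with caplog.at_level("WARNING"):
        out = preprocess(t)
    assert len(out.values) == 1
    assert "dropping" in caplog.text
    with pytest.raises(ValueError, match="no observed values"):
        preprocess(t, drop_all_missing=False)


# ---------------------------------------------------------------------------
# welch_test
# ---------------------------------------------------------------------------

def test_welch_worked_example():
    # closed form: means 2 vs 3, s^2 = 1 each, se = sqrt(2/3), df = 4
    t, p = welch_test([1, 2, 3], [2, 3, 4])
    assert t == pytest.approx(-1.224745, abs=1e-6)
    assert p == pytest.approx(0.287823, abs=1e-4)


def test_welch_degenerate_and_errors():
    assert welch_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)
    assert welch_test([2, 2], [2, 2]) == (0.0, 1.0)
    with pytest.raises(ValueError):
        welch_test([1, 2], [5])
    with pytest.raises(ValueError, match="zero variance"):
        welch_test([1, 1], [2, 2])


@settings(derandomize=True, max_examples=40)
@given(
    a=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
    b=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
)
def test_welch_antisymmetric(a, b):
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) != np.mean(b):
        return  # degenerate case raises by contract
    t1, p1 = welch_test(a, b)
    t2, p2 = welch_test(b, a)
    assert t1 == pytest.approx(-t2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


# ---------------------------------------------------------------------------
# bh_fdr
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.005, 0.5], [0.01, 0.5]),
    ],
)
def test_bh_hand_examples(p, expected):
    np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([-0.1])


def test_bh_matches_bruteforce_reference():
    rng = np.random.default_rng(0)
    for _ in range(100):
        m = int(rng.integers(1, 60))
        p = rng.random(m)
        if rng.random() < 0.3:  # inject ties
            p = np.round(p, 1)
        assert np.array_equal(bh_fdr(p), bh_reference(p))


# ---------------------------------------------------------------------------
# differential
# ---------------------------------------------------------------------------

def test_differential_exact_fold_change():
    # treated = control * e for one feature => natural-log FC of exactly 1
    ctrl = np.array([1.0, 2.0, 3.0, 4.0])
    t = _table({f"c{i}": [v, 5.0] for i, v in enumerate(ctrl)}
               | {f"t{i}": [v * math.e, 5.0] for i, v in enumerate(ctrl)},
               groups={f"c{i}": "control" for i in range(4)}
                      | {f"t{i}": "treated" for i in range(4)})
    diff = differential(preprocess(t, log_base="e"))
    assert diff.loc[0, "log_fc"] == pytest.approx(1.0, abs=1e-12)
    assert set(diff.columns) == {"log_fc", "t", "p", "q", "significant"}


def test_differential_requires_log_table():
    t = _table({"s1": [1.0], "s2": [2.0], "s3": [3.0], "s4": [4.0]})
    with pytest.raises(ValueError, match="preprocessed"):
        differential(t)


def test_differential_null_fdr_control():
    """Under a pure null the flagged fraction stays near the nominal level."""
    rng = np.random.default_rng(123)
    n_rep, n_feat, n = 100, 40, 5
    props = []
    for _ in range(n_rep):
        values = pd.DataFrame(
            np.exp(rng.normal(3, 0.5, size=(n_feat, 2 * n))),
            columns=[f"s{i}" for i in range(2 * n)],
        )
        table = SampleTable(values=values,
                            groups={f"s{i}": ("control" if i < n else "treated")
                                    for i in range(2 * n)})
        diff = differential(preprocess(table))
        props.append(diff["significant"].mean())
    mc_se = np.std(props, ddof=1) / math.sqrt(n_rep)
    assert np.mean(props) <= 0.1 + 3 * mc_se


# ---------------------------------------------------------------------------
# correlation & clustering
# ---------------------------------------------------------------------------

def _profile(fc, q=None, features=None):
    features = features or [f"f{i}" for i in range(len(fc))]
    return pd.DataFrame({"log_fc": fc, "q": q if q is not None else [0.01] * len(fc)},
                        index=features)


def test_pairwise_correlation_worked_examples():
    a = _profile([1.0, 2.0, 3.0])
    assert pairwise_correlation(a, a).r == pytest.approx(1.0)
    rep = pairwise_correlation(a, _profile([3.0, 2.0, 1.0]))
    assert rep.r == pytest.approx(-1.0)
    rep = pairwise_correlation(a, _profile([1.0, 2.0, 4.0]))
    assert rep.r == pytest.approx(0.981981, abs=1e-5)
    assert rep.n_common == 3


def test_pairwise_correlation_significant_only_and_errors():
    a = _profile([1.0, 2.0, 3.0, 4.0], q=[0.01, 0.01, 0.01, 0.5])
    b = _profile([1.0, 2.0, 3.5, -9.0], q=[0.01, 0.01, 0.01, 0.01])
    rep = pairwise_correlation(a, b, mode="significant-only")
    assert rep.n_common == 3  # f3 dropped: not significant in a
    sym = pairwise_correlation(b, a, mode="significant-only")
    assert rep.r == pytest.approx(sym.r)
    with pytest.raises(ValueError, match="pair"):
        pairwise_correlation(_profile([1, 2]), _profile([1, 2]))


def test_correlation_matrix_symmetric_unit_diagonal():
    rng = np.random.default_rng(5)
    profiles = {k: _profile(rng.normal(size=20).tolist()) for k in "abc"}
    mat = correlation_matrix(profiles)
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 1.0)
    assert (mat.abs() <= 1 + 1e-12).all().all()


def test_hier_cluster_merges_most_correlated_first():
    rng = np.random.default_rng(42)
    z = rng.normal(size=300)
    profiles = pd.DataFrame(
        {
            "A": z,
            "B": z + rng.normal(scale=0.1, size=300),   # corr(A,B) ~ 0.995
            "C": rng.normal(size=300),                   # independent
        }
    ).T
    tree = hier_cluster(profiles)
    assert len(tree.merges) == 2
    first_children = {tree.labels[tree.merges[0][0]], tree.labels[tree.merges[0][1]]}
    assert first_children == {"A", "B"}
    heights = [h for _, _, h in tree.merges]
    assert heights == sorted(heights)
    assert tree.to_newick().endswith(";")


def test_hier_cluster_degenerate_cases():
    two = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}).T
    tree = hier_cluster(two)
    assert len(tree.merges) == 1
    assert tree.merges[0][2] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match=">= 2 conditions"):
        hier_cluster(two.iloc[:1])
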