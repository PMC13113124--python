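"""Normalization arithmetic and group-comparison statistics vs references."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoquant import (
    GroupData,
    autophagic_index,
    densitometry_normalize,
    kruskal_wallis,
    normality_report,
    normalize_percent_of_vehicle,
    posthoc,
    rm_anova,
    welch_anova,
)


# --------------------------------------------------------------------------
# normalization arithmetic

def test_percent_of_vehicle():
    vehicle = np.array([140.0, 150.0, 160.0])
    out = normalize_percent_of_vehicle(vehicle, vehicle, background=50.0)
    assert np.mean(out) == pytest.approx(100.0)
    assert normalize_percent_of_vehicle(50.0, vehicle, background=50.0) == pytest.approx(0.0)
    assert normalize_percent_of_vehicle(125.0, np.array([150.0]), background=50.0) == pytest.approx(75.0)
    with pytest.raises(ValueError):
        normalize_percent_of_vehicle(1.0, np.array([10.0]), background=20.0)


def test_densitometry_normalization():
    # control sample normalizes to 1; doubling the target doubles the level
    assert densitometry_normalize(5.0, 2.0, control_ratio=2.5) == pytest.approx(1.0)
    assert densitometry_normalize(10.0, 2.0, control_ratio=2.5) == pytest.approx(2.0)
    rng = np.random.default_rng(3)
    target = rng.uniform(1, 5, 6)
    ref = rng.uniform(1, 5, 6)
    out = densitometry_normalize(target, ref, control_ratio=1.7)
    assert np.allclose(out, (target / ref) / 1.7)
    with pytest.raises(ValueError):
        densitometry_normalize(1.0, 0.0, control_ratio=1.0)


def test_autophagic_index():
    assert autophagic_index(2.0, 2.0) == pytest.approx(1.0)
    assert autophagic_index(3.0, 2.0) == pytest.approx(1.5)
    out = autophagic_index(np.array([2.0, 4.0]), np.array([1.0, 2.0]))
    assert np.allclose(out, [2.0, 2.0])
    with pytest.raises(ValueError):
        autophagic_index(1.0, 0.0)


# --------------------------------------------------------------------------
# omnibus tests

def test_welch_anova_matches_reference():
    import pingouin as pg
    rng = np.random.default_rng(42)
    g = {"a": rng.normal(0, 1, 8), "b": rng.normal(0.5, 2, 10), "c": rng.normal(1, 0.5, 7)}
    res = welch_anova(g)
    df = pd.DataFrame([(k, x) for k, v in g.items() for x in v], columns=["g", "y"])
    ref = pg.welch_anova(dv="y", between="g", data=df)
    assert res.statistic == pytest.approx(float(ref["F"][0]), abs=1e-8)
    assert res.p_value == pytest.approx(float(ref["p_unc"][0]), abs=1e-8)
    assert res.df[1] == pytest.approx(float(ref["ddof2"][0]), abs=1e-8)


def test_identical_groups_give_null_statistics():
    same = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]}
    assert welch_anova(same).statistic == 0.0
    assert welch_anova(same).p_value == 1.0
    kw = kruskal_wallis(same)
    assert kw.statistic == 0.0 and kw.p_value == 1.0
    for method in ("tukey", "bonferroni", "dunn"):
        assert (posthoc(same, method)["p_adj"] == 1.0).all()
    assert (posthoc(same, "dunnett", control="a")["p_adj"] == 1.0).all()


def test_kruskal_matches_scipy(rng):
    g = {"a": rng.normal(0, 1, 9), "b": rng.normal(1, 1, 9), "c": rng.normal(0, 2, 9)}
    res = kruskal_wallis(g)
    h, p = sps.kruskal(*g.values())
    assert res.statistic == pytest.approx(h, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_rm_anova_matches_reference():
    import pingouin as pg
    rng = np.random.default_rng(7)
    data = rng.normal(0, 1, (6, 3)) + rng.normal(0, 1, (6, 1))
    data[:, 1] += 0.4
    g = GroupData({"c1": data[:, 0], "c2": data[:, 1], "c3": data[:, 2]}, paired=True)
    res = rm_anova(g)
    long = pd.DataFrame({
        "y": data.T.ravel(),
        "cond": np.repeat(["c1", "c2", "c3"], 6),
        "subj": np.tile(np.arange(6), 3),
    })
    ref = pg.rm_anova(dv="y", within="cond", subject="subj", data=long)
    assert res.statistic == pytest.approx(float(ref["F"][0]), abs=1e-8)
    assert res.p_value == pytest.approx(float(ref["p_unc"][0]), abs=1e-8)


def test_rm_anova_requires_complete_blocks():
    with pytest.raises(ValueError):
        GroupData({"a": [1.0, 2], "b": [1.0, 2, 3]}, paired=True)
    with pytest.raises(ValueError):
        rm_anova(GroupData({"a": [1.0, 2], "b": [2.0, 3]}, paired=False))


def test_group_data_averages_technical_replicates():
    df = pd.DataFrame({
        "condition": ["ctrl"] * 4 + ["drug"] * 4,
        "replicate": [1, 1, 2, 2, 1, 1, 2, 2],
        "value": [1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0],
    })
    g = GroupData.from_tidy(df)
    assert np.allclose(sorted(g.values["ctrl"]), [2.0, 6.0])
    assert np.allclose(sorted(g.values["drug"]), [3.0, 7.0])


# --------------------------------------------------------------------------
# post hoc procedures

def test_bonferroni_multiplies_and_caps():
    rng = np.random.default_rng(11)
    g = {"a": rng.normal(0, 1, 6), "b": rng.normal(2, 1, 6), "c": rng.normal(0, 1, 6)}
    tab = posthoc(g, "bonferroni")
    assert len(tab) == 3
    for _, row in tab.iterrows():
        assert row["p_adj"] == pytest.approx(min(1.0, 3 * row["p_raw"]))


def test_adjusted_p_never_below_raw(rng):
    g = {"a": rng.normal(0, 1, 8), "b": rng.normal(0.3, 2, 8), "c": rng.normal(1, 1, 8)}
    for method, kw in [("tukey", {}), ("bonferroni", {}), ("dunn", {}),
                       ("dunnett", {"control": "a"})]:
        tab = posthoc(g, method, **kw)
        assert (tab["p_adj"] >= tab["p_raw"] - 1e-12).all()
        assert tab["p_adj"].between(0, 1).all()


def test_dunn_matches_independent_computation(rng):
    g = {"a": rng.normal(0, 1, 7), "b": rng.normal(1, 1, 9), "c": rng.normal(0.5, 2, 8)}
    tab = posthoc(g, "dunn").set_index(["group1", "group2"])
    # independent route: pandas ranking and explicit formulas
    pooled = pd.Series(np.concatenate([g["a"], g["b"], g["c"]]))
    labels = np.repeat(["a", "b", "c"], [7, 9, 8])
    ranks = pooled.rank()
    n = len(pooled)
    ties = pooled.value_counts()
    tie_corr = float(((ties**3 - ties).sum()) / (12 * (n - 1)))
    for g1, g2 in [("a", "b"), ("a", "c"), ("b", "c")]:
        r1 = ranks[labels == g1].mean()
        r2 = ranks[labels == g2].mean()
        n1, n2 = (labels == g1).sum(), (labels == g2).sum()
        se = np.sqrt((n * (n + 1) / 12 - tie_corr) * (1 / n1 + 1 / n2))
        z = (r1 - r2) / se
        p_raw = 2 * sps.norm.sf(abs(z))
        assert tab.loc[(g1, g2), "statistic"] == pytest.approx(z, abs=1e-6)
        assert tab.loc[(g1, g2), "p_adj"] == pytest.approx(min(1, 3 * p_raw), abs=1e-6)


def test_dunnett_agrees_with_classical_under_homoscedasticity():
    # with equal variances/sizes the Welch-SE variant approaches scipy's
    # classical Dunnett; Monte Carlo adjustment adds small jitter
    rng = np.random.default_rng(5)
    g = {"ctrl": rng.normal(0, 1, 40), "x": rng.normal(0.6, 1, 40), "y": rng.normal(0.1, 1, 40)}
    tab = posthoc(g, "dunnett", control="ctrl").set_index("group1")
    ref = sps.dunnett(g["x"], g["y"], control=g["ctrl"])
    for lab, stat, p in zip(["x", "y"], ref.statistic, ref.pvalue):
        assert tab.loc[lab, "statistic"] == pytest.approx(stat, abs=0.15)
        assert tab.loc[lab, "p_adj"] == pytest.approx(p, abs=0.03)
    with pytest.raises(ValueError):
        posthoc(g, "dunnett")
    with pytest.raises(ValueError):
        posthoc(g, "dunnett", control="nope")


def test_normality_report_shapes():
    rng = np.random.default_rng(1)
    rep = normality_report({"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)})
    assert set(rep["group"]) == {"a", "b"}
    assert rep["p"].between(0, 1).all()
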