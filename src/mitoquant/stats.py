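"""Normalization arithmetic and group-comparison statistics.

Implements the workflow's scalar normalizations (percent-of-vehicle with
background subtraction, densitometry relative to a loading control,
autophagic index as the Baf A1 / untreated ratio) and the tests used on
per-replicate summaries: Welch's heteroscedastic one-way ANOVA with
Dunnett-style comparisons against a control, the Kruskal–Wallis test
with Dunn's rank post hoc, and one-way repeated-measures ANOVA with
Tukey or Bonferroni post hoc.  Biological replicates are the statistical
unit; technical values are averaged within replicate before testing.

Welch's ANOVA and the repeated-measures ANOVA are computed from their
textbook sums-of-squares forms.  The Dunnett comparisons use unpooled
(Welch-style) standard errors with Welch–Satterthwaite degrees of
freedom; the familywise adjustment integrates the correlated
multivariate-t maximum via a fixed-seed quasi-Monte-Carlo sample, so
results are deterministic.  Dunn's z statistics carry the standard tie
correction and a Bonferroni familywise adjustment by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "TestResult",
    "normalize_percent_of_vehicle",
    "densitometry_normalize",
    "autophagic_index",
    "welch_anova",
    "kruskal_wallis",
    "rm_anova",
    "posthoc",
    "normality_report",
]

_MC_SAMPLES = 200_000
_MC_SEED = 20260924  # fixed so adjusted p-values are reproducible


@dataclass
class GroupData:
    """Per-condition biological-replicate values.

    ``values`` maps condition label → 1D array (one entry per biological
    replicate).  ``paired=True`` marks a repeated-measures design where
    position i in every array is the same biological replicate.
    """

    values: dict[str, np.ndarray]
    paired: bool = False

    def __post_init__(self) -> None:
        self.values = {k: np.asarray(v, dtype=float).ravel() for k, v in self.values.items()}
        if len(self.values) < 2:
            raise ValueError("at least two conditions are required")
        for k, v in self.values.items():
            if v.size < 1:
                raise ValueError(f"condition {k!r} has no values")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"condition {k!r} contains non-finite values")
        if self.paired:
            sizes = {v.size for v in self.values.values()}
            if len(sizes) != 1:
                raise ValueError("paired design requires complete blocks (equal n per condition)")

    @classmethod
    def from_tidy(
        cls,
        df: pd.DataFrame,
        condition: str = "condition",
        replicate: str = "replicate",
        value: str = "value",
        paired: bool = False,
    ) -> "GroupData":
        """Average technical values within each biological replicate, then group."""
        agg = df.groupby([condition, replicate], sort=True)[value].mean().reset_index()
        values = {str(c): g[value].to_numpy() for c, g in agg.groupby(condition, sort=True)}
        return cls(values=values, paired=paired)

    @property
    def labels(self) -> list[str]:
        return list(self.values)


@dataclass
class TestResult:
    """An omnibus test outcome with optional post hoc table."""

    method: str
    statistic: float
    p_value: float
    df: tuple[float, ...] = ()
    posthoc: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# normalization arithmetic

def normalize_percent_of_vehicle(values, vehicle_values, background: float = 0.0) -> np.ndarray:
    """100·(v − background) / mean(vehicle − background)."""
    values = np.asarray(values, dtype=float)
    vehicle = np.asarray(vehicle_values, dtype=float)
    denom = float(np.mean(vehicle - background))
    if denom <= 0:
        raise ValueError("mean background-subtracted vehicle signal must be > 0")
    return 100.0 * (values - background) / denom


def densitometry_normalize(target, reference, control_ratio: float) -> np.ndarray:
    """(target/reference) relative to the control sample's target/reference ratio."""
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference (loading control / total protein) must be > 0")
    if control_ratio <= 0:
        raise ValueError("control ratio must be > 0")
    return (target / reference) / float(control_ratio)


def autophagic_index(p62_baf, p62_untreated) -> np.ndarray:
    """Ratio of p62/SQSTM1 with lysosomal block (Baf A1) over without."""
    baf = np.asarray(p62_baf, dtype=float)
    untreated = np.asarray(p62_untreated, dtype=float)
    if np.any(untreated <= 0):
        raise ValueError("untreated p62 level must be > 0")
    return baf / untreated


# --------------------------------------------------------------------------
# omnibus tests

def _as_groups(groups: GroupData | dict) -> GroupData:
    return groups if isinstance(groups, GroupData) else GroupData(values=dict(groups))


def welch_anova(groups: GroupData | dict) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA (no pooled-variance assumption)."""
    g = _as_groups(groups)
    arrs = list(g.values.values())
    k = len(arrs)
    n = np.array([a.size for a in arrs], dtype=float)
    if np.any(n < 2):
        raise ValueError("Welch's ANOVA needs at least 2 values per group")
    m = np.array([a.mean() for a in arrs])
    if np.ptp(m) == 0.0:
        return TestResult("welch_anova", 0.0, 1.0, (k - 1.0, float("inf")))
    v = np.array([a.var(ddof=1) for a in arrs])
    if np.any(v == 0):
        raise ValueError("Welch's ANOVA undefined for zero-variance groups")
    w = n / v
    mw = float((w * m).sum() / w.sum())
    a_num = float((w * (m - mw) ** 2).sum()) / (k - 1)
    t = float((((1 - w / w.sum()) ** 2) / (n - 1)).sum())
    b_den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * t
    f = a_num / b_den
    df2 = (k**2 - 1) / (3.0 * t)
    p = float(sps.f.sf(f, k - 1, df2))
    return TestResult("welch_anova", float(f), p, (float(k - 1), float(df2)))


def kruskal_wallis(groups: GroupData | dict) -> TestResult:
    """Kruskal–Wallis rank test; identical pooled data gives H = 0, p = 1."""
    g = _as_groups(groups)
    arrs = list(g.values.values())
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0.0:
        return TestResult("kruskal_wallis", 0.0, 1.0, (float(len(arrs) - 1),))
    h, p = sps.kruskal(*arrs)
    return TestResult("kruskal_wallis", float(h), float(p), (float(len(arrs) - 1),))


def rm_anova(groups: GroupData | dict) -> TestResult:
    """One-way repeated-measures ANOVA on complete blocks."""
    g = _as_groups(groups)
    if not isinstance(groups, GroupData):
        g = GroupData(values=g.values, paired=True)
    if not g.paired:
        raise ValueError("rm_anova requires paired GroupData (paired=True)")
    data = np.column_stack(list(g.values.values()))  # subjects × conditions
    n, k = data.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_cond == 0.0:
        return TestResult("rm_anova", 0.0, 1.0, (float(df_cond), float(df_err)))
    if ms_err == 0.0:
        raise ValueError("zero residual variance: repeated-measures F undefined")
    f = ms_cond / ms_err
    p = float(sps.f.sf(f, df_cond, df_err))
    return TestResult("rm_anova", float(f), p, (float(df_cond), float(df_err)))


# --------------------------------------------------------------------------
# post hoc procedures

def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, its SE and Welch–Satterthwaite df."""
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    se = np.sqrt(va + vb)
    if se == 0.0:
        return 0.0, 0.0, float(a.size + b.size - 2)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float((a.mean() - b.mean()) / se), float(se), float(df)


def _dunnett_welch(g: GroupData, control: str) -> pd.DataFrame:
    """Dunnett-style many-to-one comparisons on Welch standard errors.

    Familywise adjustment: p_adj(i) = P(max_j |T_j| ≥ |t_i|) under the
    null, where (T_1..T_m) share the control-induced correlation
    ρ_ij = λ_i λ_j and each |T_j| is taken as t with its own
    Welch–Satterthwaite df, evaluated by a fixed-seed Monte Carlo draw.
    """
    others = [lab for lab in g.labels if lab != control]
    if not others:
        raise ValueError("dunnett needs at least one non-control group")
    c = g.values[control]
    vc = c.var(ddof=1) / c.size
    t_obs, dfs, lams = [], [], []
    for lab in others:
        a = g.values[lab]
        t, se, df = _welch_t(a, c)
        t_obs.append(t)
        dfs.append(df)
        denom = a.var(ddof=1) / a.size + vc
        lams.append(np.sqrt(vc / denom) if denom > 0 else 0.0)
    m = len(others)
    rng = np.random.default_rng(_MC_SEED)
    z0 = rng.standard_normal(_MC_SAMPLES)
    zi = rng.standard_normal((_MC_SAMPLES, m))
    lam = np.asarray(lams)
    corr_z = lam * z0[:, None] + np.sqrt(1 - lam**2) * zi  # correlated numerators
    chi = rng.chisquare(np.asarray(dfs), size=(_MC_SAMPLES, m))
    tt = np.abs(corr_z) / np.sqrt(chi / np.asarray(dfs))
    tmax = tt.max(axis=1)
    rows = []
    for lab, t, df in zip(others, t_obs, dfs):
        p_raw = 2.0 * float(sps.t.sf(abs(t), df))
        p_adj = float((tmax >= abs(t)).mean())
        rows.append({"group1": lab, "group2": control, "statistic": t, "df": df,
                     "p_raw": min(p_raw, 1.0), "p_adj": min(max(p_adj, p_raw), 1.0)})
    return pd.DataFrame(rows)


def _dunn(g: GroupData, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-sum z tests with tie correction."""
    labels = g.labels
    pooled = np.concatenate([g.values[lab] for lab in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for lab in labels:
        n = g.values[lab].size
        mean_ranks[lab] = ranks[start:start + n].mean()
        sizes[lab] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * float(sps.norm.sf(abs(z)))
        if adjust == "bonferroni":
            p_adj = min(1.0, m * p_raw)
        elif adjust == "holm":
            p_adj = p_raw  # filled below
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append({"group1": a, "group2": b, "statistic": z,
                     "p_raw": min(p_raw, 1.0), "p_adj": p_adj})
    df = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(df["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    return df


def _tukey(g: GroupData) -> pd.DataFrame:
    arrs = [g.values[lab] for lab in g.labels]
    res = sps.tukey_hsd(*arrs)
    rows = []
    for i, j in combinations(range(len(arrs)), 2):
        rows.append({"group1": g.labels[i], "group2": g.labels[j],
                     "statistic": float(res.statistic[i, j]),
                     "p_raw": float(res.pvalue[i, j]),
                     "p_adj": float(res.pvalue[i, j])})
    return pd.DataFrame(rows)


def _bonferroni(g: GroupData) -> pd.DataFrame:
    pairs = list(combinations(g.labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = g.values[a], g.values[b]
        if g.paired:
            if np.ptp(xa - xb) == 0.0:
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(xa, xb)
        else:
            if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0 and xa.mean() == xb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append({"group1": a, "group2": b, "statistic": float(t),
                     "p_raw": float(p), "p_adj": min(1.0, m * float(p))})
    return pd.DataFrame(rows)


def posthoc(
    groups: GroupData | dict,
    method: str = "tukey",
    control: str | None = None,
) -> pd.DataFrame:
    """Pairwise comparisons with familywise-adjusted p-values.

    ``dunnett`` compares every group against ``control`` (required);
    ``dunn`` is the rank-based companion to Kruskal–Wallis; ``tukey``
    and ``bonferroni`` cover all pairs.  Columns: group1, group2,
    statistic, p_raw, p_adj (p_adj ≥ p_raw always).
    """
    g = _as_groups(groups)
    if method == "dunnett":
        if control is None:
            raise ValueError("dunnett requires a control label")
        if control not in g.values:
            raise ValueError(f"unknown control {control!r}; have {g.labels}")
        return _dunnett_welch(g, control)
    if method == "dunn":
        return _dunn(g)
    if method == "tukey":
        return _tukey(g)
    if method == "bonferroni":
        return _bonferroni(g)
    raise ValueError(f"unknown post hoc method {method!r}")


def normality_report(groups: GroupData | dict, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro–Wilk per group, reported as a gatekeeper — never auto-switching."""
    g = _as_groups(groups)
    rows = []
    for lab, v in g.values.items():
        if v.size < 3 or np.ptp(v) == 0.0:
            rows.append({"group": lab, "W": float("nan"), "p": float("nan"), "normal": None})
            continue
        w, p = sps.shapiro(v)
        rows.append({"group": lab, "W": float(w), "p": float(p), "normal": bool(p >= alpha)})
    return pd.DataFrame(rows)
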