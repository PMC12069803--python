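"""Univariate comparison battery: t tests, two-way ANOVA, protected LSD.

Seasonal effects on each stoichiometric metric are tested with independent
two-sample t tests (Welch by default); season × management structure with
a two-way ANOVA; pairwise management differences with the least-significant-
difference (LSD) test on the ANOVA residual mean square, summarised as a
compact letter display.  Following common field practice, data are
log-transformed when a Levene check (median-centred) rejects homogeneity
of variance and all values are positive.

Balanced two-way designs use the classical orthogonal sum-of-squares
partition computed in-package (SS_A + SS_B + SS_AB + SS_resid = SS_total);
unbalanced designs fall back to Type-II sums of squares via statsmodels.
LSD is *protected*: letters are collapsed to a single group when the
omnibus F is not significant at alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class StatsError(ValueError):
    """Raised for designs the comparison battery cannot analyse."""


#: stoichiometric metrics the comparison battery runs over by default
METRIC_NAMES_DEFAULT = ["soil_cn", "soil_cp", "soil_np", "ees_cn", "ees_cp",
                        "ees_np", "vector_length", "vector_angle"]


@dataclass
class ComparisonResult:
    metric: str
    test: str
    statistic: float
    df: float
    p_value: float
    group_summaries: list[dict] = field(default_factory=list)
    transform_applied: str = "none"  # none | log
    flags: list[str] = field(default_factory=list)


@dataclass
class AnovaTable:
    """Two-way ANOVA rows: factor A, factor B, A×B, residual."""

    source: list[str]
    ss: list[float]
    df: list[float]
    ms: list[float]
    f: list[float]
    p: list[float]
    balanced: bool
    ss_total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"source": self.source, "ss": self.ss, "df": self.df,
                             "ms": self.ms, "F": self.f, "p": self.p})

    def row(self, source: str) -> dict:
        i = self.source.index(source)
        return {"source": source, "ss": self.ss[i], "df": self.df[i],
                "ms": self.ms[i], "F": self.f[i], "p": self.p[i]}


def _summaries(groups, labels=None) -> list[dict]:
    labels = labels or [f"group{i}" for i in range(len(groups))]
    out = []
    for label, g in zip(labels, groups):
        g = np.asarray(g, dtype=float)
        out.append({"label": label, "n": int(g.size), "mean": float(g.mean()),
                    "sd": float(g.std(ddof=1)) if g.size > 1 else math.nan})
    return out


# --- t test ------------------------------------------------------------------

def independent_t(group_a, group_b, welch: bool = True,
                  metric: str = "value") -> ComparisonResult:
    """Two-sided independent-samples t test.

    Welch–Satterthwaite degrees of freedom by default; pooled-variance
    variant mirrors legacy LSD-style analyses.  Degenerate zero-variance
    inputs are resolved by convention: equal means → t = 0, p = 1;
    unequal means → infinite statistic, p = 0, flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs n ≥ 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise StatsError("non-finite values in t-test input")
    test_name = "welch_t" if welch else "pooled_t"
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return ComparisonResult(metric, test_name, 0.0, float(a.size + b.size - 2),
                                    1.0, _summaries([a, b]))
        return ComparisonResult(metric, test_name, math.inf, float(a.size + b.size - 2),
                                0.0, _summaries([a, b]), flags=["zero-variance"])
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(metric, test_name, float(res.statistic), float(res.df),
                            float(res.pvalue), _summaries([a, b]))


# --- homogeneity of variance and the log-transform rule ----------------------

def homogeneity_check(groups, alpha: float = 0.05):
    """Levene-type check: one-way ANOVA on absolute deviations from group
    medians (Brown–Forsythe).  Returns (verdict, statistic, p)."""
    if len(groups) < 2:
        raise StatsError("homogeneity check needs ≥ 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise StatsError("each group needs n ≥ 2")
    if all(np.ptp(a) == 0 for a in arrays):
        return "homogeneous", 0.0, 1.0  # constant data by convention
    stat, p = stats.levene(*arrays, center="median")
    verdict = "heterogeneous" if p < alpha else "homogeneous"
    return verdict, float(stat), float(p)


def auto_transform(groups, alpha: float = 0.05):
    """Apply the log-on-heteroscedasticity rule.

    Heterogeneous variance with all-positive values → natural log and
    re-check; non-positive values block the transform (flagged).  Returns
    (groups, transform_applied, flags).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    verdict, _, _ = homogeneity_check(arrays, alpha=alpha)
    if verdict == "homogeneous":
        return arrays, "none", []
    if any((a <= 0).any() for a in arrays):
        return arrays, "none", ["heterogeneous-nonpositive-not-transformed"]
    logged = [np.log(a) for a in arrays]
    verdict2, _, _ = homogeneity_check(logged, alpha=alpha)
    flags = [] if verdict2 == "homogeneous" else ["still-heterogeneous-after-log"]
    return logged, "log", flags


# --- two-way ANOVA -----------------------------------------------------------

def _balanced_partition(values, fa, fb):
    """Classical orthogonal partition for a balanced crossed design."""
    levels_a = sorted(set(fa))
    levels_b = sorted(set(fb))
    cells = {(a, b): values[(fa == a) & (fb == b)] for a in levels_a for b in levels_b}
    n_cell = len(next(iter(cells.values())))
    grand = values.mean()
    n_a, n_b = len(levels_a), len(levels_b)
    ss_a = n_cell * n_b * sum((values[fa == a].mean() - grand) ** 2 for a in levels_a)
    ss_b = n_cell * n_a * sum((values[fb == b].mean() - grand) ** 2 for b in levels_b)
    ss_cells = n_cell * sum((c.mean() - grand) ** 2 for c in cells.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_resid = sum(((c - c.mean()) ** 2).sum() for c in cells.values())
    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_resid = values.size - n_a * n_b
    return (ss_a, ss_b, ss_ab, ss_resid), (df_a, df_b, df_ab, df_resid)


def two_way_anova(values, factor_a, factor_b,
                  names: tuple[str, str] = ("season", "management")) -> AnovaTable:
    """Crossed two-factor ANOVA with interaction.

    Balanced designs use the classical partition; unbalanced designs use
    Type-II sums of squares (statsmodels).  Interaction requires every
    cell to hold at least two observations; empty cells are an error.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (values.size == fa.size == fb.size):
        raise StatsError("values and factors must have equal length")
    levels_a, levels_b = sorted(set(fa)), sorted(set(fb))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise StatsError("each factor needs ≥ 2 levels")
    cell_sizes = {}
    for a in levels_a:
        for b in levels_b:
            n = int(((fa == a) & (fb == b)).sum())
            if n == 0:
                raise StatsError(f"empty design cell ({a}, {b})")
            if n < 2:
                raise StatsError(f"cell ({a}, {b}) has n={n}; interaction needs n ≥ 2")
            cell_sizes[(a, b)] = n
    balanced = len(set(cell_sizes.values())) == 1
    ss_total = float(((values - values.mean()) ** 2).sum())

    if balanced:
        (ss_a, ss_b, ss_ab, ss_resid), (df_a, df_b, df_ab, df_resid) = \
            _balanced_partition(values, fa, fb)
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = pd.DataFrame({"y": values, "A": fa, "B": fb})
        fit = smf.ols("y ~ C(A) * C(B)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        ss_a, ss_b = float(table.loc["C(A)", "sum_sq"]), float(table.loc["C(B)", "sum_sq"])
        ss_ab = float(table.loc["C(A):C(B)", "sum_sq"])
        ss_resid = float(table.loc["Residual", "sum_sq"])
        df_a, df_b = float(table.loc["C(A)", "df"]), float(table.loc["C(B)", "df"])
        df_ab, df_resid = float(table.loc["C(A):C(B)", "df"]), float(table.loc["Residual", "df"])

    ms_resid = ss_resid / df_resid if df_resid > 0 else math.nan
    rows = []
    for ss, dfree in [(ss_a, df_a), (ss_b, df_b), (ss_ab, df_ab)]:
        ms = ss / dfree
        if ms_resid > 0:
            f = ms / ms_resid
            p = float(stats.f.sf(f, dfree, df_resid))
        else:  # zero residual variance: identical responses within cells
            f, p = (0.0, 1.0) if ss <= 1e-12 * max(ss_total, 1.0) else (math.inf, 0.0)
        rows.append((ss, dfree, ms, f, p))
    source = [names[0], names[1], f"{names[0]}:{names[1]}", "residual"]
    ss_list = [rows[0][0], rows[1][0], rows[2][0], ss_resid]
    df_list = [rows[0][1], rows[1][1], rows[2][1], float(df_resid)]
    ms_list = [rows[0][2], rows[1][2], rows[2][2], ms_resid]
    f_list = [rows[0][3], rows[1][3], rows[2][3], math.nan]
    p_list = [rows[0][4], rows[1][4], rows[2][4], math.nan]
    return AnovaTable(source, ss_list, df_list, ms_list, f_list, p_list,
                      balanced, ss_total)


# --- protected LSD post hoc --------------------------------------------------

def _compact_letters(labels, means, sig):
    """Greedy compact letter display: groups sharing a letter do not differ
    significantly.  Letters assigned in descending-mean order."""
    order = sorted(range(len(labels)), key=lambda i: -means[i])
    letter_sets: list[set[int]] = []  # indices covered by each letter
    for i in order:
        placed = False
        for members in letter_sets:
            if all(not sig[frozenset((i, j))] for j in members if j != i):
                members.add(i)
                placed = True
        if not placed:
            # new letter containing i and every earlier group not different from i
            members = {i}
            for j in order:
                if j == i:
                    break
                if all(not sig[frozenset((k, j))] for k in members):
                    members.add(j)
            letter_sets.append(members)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for li, members in enumerate(letter_sets):
        for i in sorted(members, key=lambda i: -means[i]):
            letters[labels[i]] += alphabet[li % len(alphabet)]
    return letters


def lsd_posthoc(values, group_labels, alpha: float = 0.05):
    """Fisher's LSD pairwise comparisons with a compact letter display.

    Pairwise t statistics use the one-way residual mean square and its
    degrees of freedom.  Protection: when the omnibus one-way F is not
    significant at ``alpha`` every group shares letter "a" (the pairwise
    p matrix is still returned).  Returns (p_matrix DataFrame, letters
    dict, omnibus_p).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    labels = sorted(set(group_labels))
    if len(labels) < 2:
        raise StatsError("LSD needs ≥ 2 groups")
    groups = {lab: values[group_labels == lab] for lab in labels}
    if any(g.size < 2 for g in groups.values()):
        raise StatsError("each group needs n ≥ 2")

    grand = values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_between = len(labels) - 1
    df_resid = values.size - len(labels)
    ms_resid = ss_within / df_resid
    if ms_resid > 0:
        f = (ss_between / df_between) / ms_resid
        omnibus_p = float(stats.f.sf(f, df_between, df_resid))
    else:
        omnibus_p = 1.0 if ss_between <= 1e-12 * max(values.var() * values.size, 1.0) else 0.0

    pmat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    sig = {}
    for la, lb in itertools.combinations(labels, 2):
        ga, gb = groups[la], groups[lb]
        if ms_resid > 0:
            se = math.sqrt(ms_resid * (1 / ga.size + 1 / gb.size))
            t = (ga.mean() - gb.mean()) / se
            p = float(2 * stats.t.sf(abs(t), df_resid))
        else:
            p = 1.0 if ga.mean() == gb.mean() else 0.0
        pmat.loc[la, lb] = pmat.loc[lb, la] = p
        sig[frozenset((labels.index(la), labels.index(lb)))] = p < alpha

    if omnibus_p >= alpha:  # protected LSD: no pairwise claims without omnibus
        letters = {lab: "a" for lab in labels}
    else:
        means = [groups[lab].mean() for lab in labels]
        letters = _compact_letters(labels, means, sig)
    return pmat, letters, omnibus_p


# --- battery over a stoichiometry table --------------------------------------

def seasonal_comparisons(results: pd.DataFrame, metrics, alpha: float = 0.05,
                         welch: bool = True, auto_log: bool = True) -> pd.DataFrame:
    """Season t test (pooled across managements) per metric, with the
    log-transform rule applied before testing when requested."""
    rows = []
    for metric in metrics:
        sub = results[["season", metric]].dropna()
        groups = [sub.loc[sub["season"] == s, metric].to_numpy(dtype=float)
                  for s in sorted(sub["season"].unique())]
        if len(groups) != 2 or any(g.size < 2 for g in groups):
            continue
        transform, flags = "none", []
        if auto_log:
            groups, transform, flags = auto_transform(groups, alpha=alpha)
        res = independent_t(groups[0], groups[1], welch=welch, metric=metric)
        res.transform_applied = transform
        res.flags.extend(flags)
        seasons = sorted(sub["season"].unique())
        rows.append({
            "metric": metric, "test": res.test, "statistic": res.statistic,
            "df": res.df, "p_value": res.p_value, "transform": res.transform_applied,
            "group_a": seasons[0], "mean_a": res.group_summaries[0]["mean"],
            "group_b": seasons[1], "mean_b": res.group_summaries[1]["mean"],
            "flags": ";".join(res.flags),
        })
    return pd.DataFrame(rows)


def anova_comparisons(results: pd.DataFrame, metrics, alpha: float = 0.05,
                      auto_log: bool = True) -> pd.DataFrame:
    """Two-way season × management ANOVA per metric plus LSD letters for
    management groups."""
    rows = []
    for metric in metrics:
        sub = results[["season", "management", metric]].dropna()
        if sub.empty:
            continue
        vals = sub[metric].to_numpy(dtype=float)
        transform = "none"
        if auto_log:
            cells = [g[metric].to_numpy(dtype=float)
                     for _, g in sub.groupby(["season", "management"])]
            if all(len(c) >= 2 for c in cells) and len(cells) >= 2:
                _, transform, _ = auto_transform(cells, alpha=alpha)
                if transform == "log":
                    vals = np.log(vals)
        try:
            table = two_way_anova(vals, sub["season"].to_numpy(),
                                  sub["management"].to_numpy())
        except StatsError:
            continue
        _, letters, omnibus_p = lsd_posthoc(vals, sub["management"].to_numpy(), alpha=alpha)
        for source in ("season", "management", "season:management"):
            row = table.row(source)
            rows.append({"metric": metric, "source": source, "ss": row["ss"],
                         "df": row["df"], "ms": row["ms"], "F": row["F"],
                         "p_value": row["p"], "transform": transform,
                         "lsd_letters": ";".join(f"{k}={v}" for k, v in sorted(letters.items()))
                         if source == "management" else ""})
    return pd.DataFrame(rows)
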