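"""Group-comparison statistics: heatmap z-score matrices, normality-gated
two-group tests, Benjamini-Hochberg correction, volcano tables, omnibus
multi-group tests with post hoc comparisons, and cohort summary tables.

Conventions fixed here and relied on elsewhere:

* log2 fold difference is always mean(b) - mean(a) on the log2 scale;
  for volcano tables a=R (resolvers), b=NR (non-resolvers).
* A volcano row is significant iff |log2fc| >= log2(1.5) and BH-adjusted
  p < 0.05.
* The normality gate is Shapiro-Wilk at alpha 0.05 per group: both normal
  -> Welch's t; otherwise Mann-Whitney U (exact when group sizes <= 8 and
  there are no ties, normal approximation with tie correction otherwise).
* Heatmap z-scores standardize the per-(group, timepoint) cell means of an
  analyte using the sample (n-1) standard deviation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, PanelError

__all__ = [
    "TwoGroupResult",
    "GroupComparison",
    "HeatmapMatrix",
    "FOLD_THRESHOLD_LOG2",
    "compare_two_groups",
    "adjust_bh",
    "zscore_matrix",
    "volcano_table",
    "compare_multi_groups",
    "dunn_posthoc",
    "cohort_summary",
]

FOLD_THRESHOLD_LOG2 = float(np.log2(1.5))
ALPHA = 0.05
MIN_GROUP_N = 3


@dataclass(frozen=True)
class TwoGroupResult:
    p_raw: Optional[float]
    test_used: Optional[str]  # "t" | "mann_whitney"
    log2fc: float
    testable: bool = True


@dataclass(frozen=True)
class GroupComparison:
    """One volcano row."""

    analyte_id: str
    timepoint: str
    group_a: str
    group_b: str
    log2fc: float
    p_raw: float
    p_adj: float
    test_used: str
    significant: bool


@dataclass
class HeatmapMatrix:
    """Analytes x (group, timepoint) cells of row-standardized means."""

    z: pd.DataFrame  # columns are "group_timepoint" labels; NaN = absent cell
    cell_means: pd.DataFrame
    degenerate: pd.Series  # True where the row of cell means was constant
    on_map_p: pd.DataFrame = field(default_factory=pd.DataFrame)


def _mwu(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Mann-Whitney U p: exact for small tie-free groups, normal
    approximation with tie correction otherwise."""
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    if ties and np.all(pooled == pooled[0]):
        return 1.0  # all values identical: no evidence either way
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_two_groups(
    a: Iterable[float],
    b: Iterable[float],
    normality_alpha: float = ALPHA,
    force: Optional[str] = None,
) -> TwoGroupResult:
    """Normality-gated two-group test on log2 values.

    Shapiro-Wilk is applied to each group; if both look normal a Welch
    two-sample t-test is used, otherwise Mann-Whitney U.  ``force`` pins the
    test ("t" or "mann_whitney") and bypasses the gate and the minimum group
    size.  log2fc = mean(b) - mean(a).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    log2fc = float(np.mean(b) - np.mean(a)) if len(a) and len(b) else np.nan
    if force is None and (len(a) < MIN_GROUP_N or len(b) < MIN_GROUP_N):
        return TwoGroupResult(None, None, log2fc, testable=False)
    if force is not None:
        test = force
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = all(
                len(np.unique(g)) > 1 and stats.shapiro(g).pvalue > normality_alpha
                for g in (a, b)
            )
        test = "t" if normal else "mann_whitney"
    if test == "t":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    elif test == "mann_whitney":
        p = _mwu(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return TwoGroupResult(p, test, log2fc, testable=True)


def adjust_bh(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("adjust_bh: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def zscore_matrix(
    matrix: ExpressionMatrix,
    grouping: Callable[[str], tuple],
    compare: Optional[tuple] = ("R", "NR"),
) -> HeatmapMatrix:
    """Heatmap matrix of row-standardized (group, timepoint) cell means.

    ``grouping`` maps a sample id to its (group, timepoint) cell.  Cells with
    no samples (ENS beyond 0 h) are absent, not zero, and are excluded from
    the standardization.  Constant rows get z = 0 and a degenerate flag.
    When ``compare`` names two groups, per-cell Mann-Whitney p-values for
    that contrast at each timepoint are attached for on-map annotation.
    """
    if matrix.scale != "log2":
        raise PanelError("zscore_matrix: requires a log2 matrix")
    cells = pd.DataFrame(
        [grouping(s) for s in matrix.sample_ids],
        index=matrix.sample_ids,
        columns=["group", "timepoint"],
    )
    labels = [
        f"{g}_{t}"
        for g, t in cells.drop_duplicates().itertuples(index=False)
    ]
    means = {}
    for label in labels:
        g, t = label.rsplit("_", 1)
        sel = cells.index[(cells["group"] == g) & (cells["timepoint"] == t)]
        means[label] = matrix.values[sel].mean(axis=1)
    cell_means = pd.DataFrame(means)

    mu = cell_means.mean(axis=1)
    sd = cell_means.std(axis=1, ddof=1)
    degenerate = sd.fillna(0.0) == 0.0
    z = cell_means.sub(mu, axis=0).div(sd.where(~degenerate, 1.0), axis=0)
    z[degenerate] = 0.0
    z = z.where(cell_means.notna(), np.nan)

    on_map = pd.DataFrame(index=matrix.values.index)
    if compare is not None:
        ga, gb = compare
        tps = sorted(cells.loc[cells["group"].isin(compare), "timepoint"].unique())
        for t in tps:
            sa = cells.index[(cells["group"] == ga) & (cells["timepoint"] == t)]
            sb = cells.index[(cells["group"] == gb) & (cells["timepoint"] == t)]
            if len(sa) == 0 or len(sb) == 0:
                continue
            pvals = [
                _mwu(
                    matrix.values.loc[aid, sa].dropna().to_numpy(),
                    matrix.values.loc[aid, sb].dropna().to_numpy(),
                )
                for aid in matrix.values.index
            ]
            on_map[f"{ga}_vs_{gb}_{t}"] = adjust_bh(pvals)
    return HeatmapMatrix(z=z, cell_means=cell_means, degenerate=degenerate,
                         on_map_p=on_map)


def volcano_table(
    matrix: ExpressionMatrix,
    grouping: Callable[[str], tuple],
    timepoint: str,
    group_a: str = "R",
    group_b: str = "NR",
) -> pd.DataFrame:
    """Per-analyte NR-vs-R (by default) volcano rows at one timepoint.

    Always uses Mann-Whitney U; BH adjustment is applied across analytes
    within the timepoint.  x = log2fc = mean(group_b) - mean(group_a);
    y = -log10(p_adj); significant iff |x| >= log2(1.5) and p_adj < 0.05.
    """
    if matrix.scale != "log2":
        raise PanelError("volcano_table: requires a log2 matrix")
    cells = pd.DataFrame(
        [grouping(s) for s in matrix.sample_ids],
        index=matrix.sample_ids,
        columns=["group", "timepoint"],
    )
    sa = cells.index[(cells["group"] == group_a) & (cells["timepoint"] == timepoint)]
    sb = cells.index[(cells["group"] == group_b) & (cells["timepoint"] == timepoint)]
    if len(sa) == 0 or len(sb) == 0:
        raise PanelError(
            f"volcano_table: timepoint {timepoint!r} absent for "
            f"{group_a if len(sa) == 0 else group_b}"
        )
    rows = []
    for aid in matrix.values.index:
        va = matrix.values.loc[aid, sa].dropna().to_numpy(dtype=float)
        vb = matrix.values.loc[aid, sb].dropna().to_numpy(dtype=float)
        rows.append({
            "analyte_id": aid,
            "log2fc": float(np.mean(vb) - np.mean(va)),
            "p_raw": _mwu(va, vb),
        })
    df = pd.DataFrame(rows).set_index("analyte_id")
    df["p_adj"] = adjust_bh(df["p_raw"])
    df["significant"] = (df["log2fc"].abs() >= FOLD_THRESHOLD_LOG2) & (df["p_adj"] < ALPHA)
    df["neg_log10_p_adj"] = -np.log10(df["p_adj"].clip(lower=np.finfo(float).tiny))
    df["timepoint"] = timepoint
    df["group_a"] = group_a
    df["group_b"] = group_b
    df["test_used"] = "mann_whitney"
    return df


def dunn_posthoc(groups: dict) -> dict:
    """Dunn's rank-based post hoc z-test for all group pairs after a
    Kruskal-Wallis omnibus, with tie correction; p-values BH-adjusted
    across the pairs.  Returns {(label_i, label_j): p_adj}."""
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g, v in zip(labels, values):
        mean_ranks[g] = ranks[start:start + len(v)].mean()
        sizes[g] = len(v)
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    raw = []
    for gi, gj in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        if se == 0:
            raw.append(1.0)
            continue
        z = (mean_ranks[gi] - mean_ranks[gj]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    adj = adjust_bh(raw)
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def compare_multi_groups(groups: dict, normality_alpha: float = ALPHA):
    """Omnibus + post hoc comparison of >= 3 groups.

    All groups Shapiro-normal -> one-way ANOVA with Tukey HSD post hoc;
    otherwise Kruskal-Wallis with Dunn's post hoc (BH-adjusted pairwise p).
    Returns (omnibus_p, {pair: p}).
    """
    if len(groups) < 3:
        raise ValueError("compare_multi_groups: need >= 3 groups")
    values = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in values.items():
        if len(v) < MIN_GROUP_N:
            raise ValueError(f"compare_multi_groups: group {g!r} has n < {MIN_GROUP_N}")
    pooled = np.concatenate(list(values.values()))
    if np.all(pooled == pooled[0]):
        pairs = itertools.combinations(values, 2)
        return 1.0, {pair: 1.0 for pair in pairs}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal = all(
            len(np.unique(v)) > 1 and stats.shapiro(v).pvalue > normality_alpha
            for v in values.values()
        )
    labels = list(values)
    if normal:
        omnibus = float(stats.f_oneway(*values.values()).pvalue)
        tk = stats.tukey_hsd(*values.values())
        pairwise = {
            (labels[i], labels[j]): float(tk.pvalue[i, j])
            for i, j in itertools.combinations(range(len(labels)), 2)
        }
    else:
        omnibus = float(stats.kruskal(*values.values()).pvalue)
        pairwise = dunn_posthoc(values)
    return omnibus, pairwise


NUMERIC_COVARIATES = ("age", "iss", "hospital_days", "icu_days", "vent_days")
CATEGORICAL_COVARIATES = ("sex", "arm")


def cohort_summary(
    patients: pd.DataFrame,
    grouping: pd.Series,
    contrast: tuple = ("R", "NR"),
) -> pd.DataFrame:
    """Per-group covariate summary with a between-group p for the named
    contrast: mean +/- SD and a normality-gated two-group test for numeric
    covariates; level counts and a Pearson chi-square (no continuity
    correction) for categoricals."""
    groups = [g for g in pd.unique(grouping)]
    for g in groups:
        if (grouping == g).sum() == 0:
            raise ValueError(f"cohort_summary: empty group {g!r}")
    ga, gb = contrast
    ia = grouping.index[grouping == ga]
    ib = grouping.index[grouping == gb]
    rows = []
    for cov in NUMERIC_COVARIATES:
        if cov not in patients.columns:
            continue
        row = {"covariate": cov, "type": "numeric"}
        for g in groups:
            vals = patients.loc[grouping.index[grouping == g], cov].dropna()
            row[g] = f"{vals.mean():.3g} ± {vals.std(ddof=1):.3g}"
        res = compare_two_groups(
            patients.loc[ia, cov].dropna(), patients.loc[ib, cov].dropna()
        )
        row["p_value"] = res.p_raw
        row["test_used"] = res.test_used
        rows.append(row)
    for cov in CATEGORICAL_COVARIATES:
        if cov not in patients.columns:
            continue
        row = {"covariate": cov, "type": "categorical"}
        for g in groups:
            counts = patients.loc[grouping.index[grouping == g], cov].value_counts()
            row[g] = ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
        table = pd.crosstab(
            patients.loc[ia.union(ib), cov],
            grouping.loc[ia.union(ib)],
        ).to_numpy()
        if table.shape[0] < 2 or (table.sum(axis=1) == 0).any() or (
            table.sum(axis=0) == 0
        ).any():
            row["p_value"] = np.nan
            row["test_used"] = "chi2_degenerate"
        else:
            row["p_value"] = float(
                stats.chi2_contingency(table, correction=False)[1]
            )
            row["test_used"] = "chi2"
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")
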