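"""Relative qPCR quantification and the study's statistical tests.

Covers the 2^-ddCt fold-change computation against a housekeeping gene and
a declared reference group, an exact small-n Spearman trend screen for
monotone increase across an ordered series, the two-sample
Kolmogorov-Smirnov comparison of aggregate-size distributions, and the
group tests (Student's t, one-way ANOVA with Tukey HSD) with the study's
significance tiers (* p<0.05, ** p<0.005, *** p<0.0005).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_TIERS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))

#: exact permutation enumeration is used up to this series length (8! = 40320)
EXACT_PERMUTATION_MAX_N = 8


def significance_tier(p: float) -> str:
    for cutoff, tier in SIGNIFICANCE_TIERS:
        if p < cutoff:
            return tier
    return ""


@dataclass
class FoldChangeResult:
    gene: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


@dataclass
class TrendResult:
    rho: float
    p_value: float
    passes_screen: bool
    all_tied: bool = False


@dataclass
class GroupTestResult:
    test: str
    comparison: str
    statistic: float
    p_value: float
    tier: str


# ---------------------------------------------------------------------------
# 2^-ddCt fold change
# ---------------------------------------------------------------------------

def fold_change(
    table: pd.DataFrame,
    housekeeping: str = "GAPDH",
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Technical replicates are averaged per sample x gene; dCt is the gene Ct
    minus the housekeeping Ct of the same sample (which cancels any common
    loading shift); ddCt subtracts the reference group's mean dCt; the fold
    change is 2^-ddCt, exactly 1 for the reference group of every gene.
    """
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    if reference_group is None:
        raise ValueError("a reference group must be declared explicitly")
    if reference_group not in set(table["group"]):
        raise ValueError(f"reference group {reference_group!r} not in table")

    mean_ct = (
        table.groupby(["sample", "group", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    hk = mean_ct[mean_ct["gene"] == housekeeping].set_index("sample")["ct"]
    for sample in mean_ct["sample"].unique():
        if sample not in hk.index:
            raise ValueError(f"sample {sample!r} lacks housekeeping gene {housekeeping!r}")

    genes = mean_ct[mean_ct["gene"] != housekeeping]
    dct = genes.assign(delta_ct=genes["ct"].to_numpy() - hk.loc[genes["sample"]].to_numpy())

    per_group = (
        dct.groupby(["gene", "group"], sort=False)["delta_ct"].mean().reset_index()
    )
    ref = per_group[per_group["group"] == reference_group].set_index("gene")["delta_ct"]
    per_group["delta_delta_ct"] = per_group["delta_ct"] - ref.loc[per_group["gene"]].to_numpy()
    per_group["fold_change"] = 2.0 ** (-per_group["delta_delta_ct"])
    return per_group[["gene", "group", "delta_ct", "delta_delta_ct", "fold_change"]]


# ---------------------------------------------------------------------------
# Spearman trend screen
# ---------------------------------------------------------------------------

def _spearman_rho(positions: np.ndarray, values: np.ndarray) -> float:
    return float(stats.spearmanr(positions, values).statistic)


def spearman_trend(
    values,
    rho_threshold: float = 0.9,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> TrendResult:
    """Rank-correlation screen for a monotone trend along an ordered series.

    ``values`` are taken in their given order (positions 1..n). For
    n <= 8 the p-value is exact, from exhaustive enumeration of all n!
    orderings of the observed values; beyond that the asymptotic
    approximation is used. The screen passes when rho exceeds
    ``rho_threshold`` and p is below ``alpha``. All-tied input has no
    defined rank correlation and is reported as non-passing.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if np.ptp(values) == 0:
        return TrendResult(rho=float("nan"), p_value=1.0, passes_screen=False,
                           all_tied=True)

    positions = np.arange(1, n + 1, dtype=float)
    rho = _spearman_rho(positions, values)

    if n <= EXACT_PERMUTATION_MAX_N:
        value_ranks = stats.rankdata(values)
        perms = np.array(list(itertools.permutations(value_ranks)))
        pos_ranks = positions  # already ranks
        # Pearson correlation of rank vectors, vectorized over permutations
        pr = (pos_ranks - pos_ranks.mean()) / pos_ranks.std()
        vr = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
        rhos = (vr @ pr) / n
        eps = 1e-12
        if alternative == "greater":
            p = float(np.mean(rhos >= rho - eps))
        elif alternative == "less":
            p = float(np.mean(rhos <= rho + eps))
        else:
            p = float(np.mean(np.abs(rhos) >= abs(rho) - eps))
    else:
        p = float(stats.spearmanr(positions, values, alternative=alternative).pvalue)

    passes = bool(rho > rho_threshold and p < alpha)
    return TrendResult(rho=rho, p_value=p, passes_screen=passes)


def screen_trends(
    features: dict,
    rho_threshold: float = 0.9,
    alpha: float = 0.05,
    alternative: str = "greater",
    fdr: bool = False,
) -> pd.DataFrame:
    """Apply the trend screen to many ordered series at once.

    ``features`` maps a feature name to its ordered values. By default the
    screen applies no multiple-testing correction; ``fdr=True`` switches the
    pass rule to Benjamini-Hochberg adjusted p-values at ``alpha``.
    """
    rows = []
    for name, values in features.items():
        t = spearman_trend(values, rho_threshold, alpha, alternative)
        rows.append({"feature": name, "rho": t.rho, "p_value": t.p_value,
                     "passes_screen": t.passes_screen, "all_tied": t.all_tied})
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
        out["passes_screen"] = (out["rho"] > rho_threshold) & (out["p_adjusted"] < alpha)
    return out


# ---------------------------------------------------------------------------
# distribution and group comparisons
# ---------------------------------------------------------------------------

def ks_two_sample(a, b) -> GroupTestResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF_a - ECDF_b|.

    Exact p for small samples (scipy switches to asymptotic for large ones).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="exact" if len(a) * len(b) <= 10_000 else "auto")
    return GroupTestResult(
        test="KS", comparison="a_vs_b",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        tier=significance_tier(float(res.pvalue)),
    )


def group_tests(groups: dict, design: str | None = None) -> list[GroupTestResult]:
    """Student's t for two groups; one-way ANOVA plus Tukey HSD beyond.

    ``groups`` maps group name to a sample; every group needs n >= 2. The
    design is inferred from the group count unless given explicitly.
    """
    names = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for name, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    if design is None:
        design = "two_group" if len(samples) == 2 else "multi_group"

    results: list[GroupTestResult] = []
    if design == "two_group":
        if len(samples) != 2:
            raise ValueError("two_group design requires exactly two groups")
        t = stats.ttest_ind(samples[0], samples[1])
        p = float(t.pvalue)
        results.append(GroupTestResult(
            test="t", comparison=f"{names[0]}_vs_{names[1]}",
            statistic=float(t.statistic), p_value=p, tier=significance_tier(p),
        ))
    elif design == "multi_group":
        f = stats.f_oneway(*samples)
        p = float(f.pvalue)
        results.append(GroupTestResult(
            test="ANOVA", comparison="omnibus",
            statistic=float(f.statistic), p_value=p, tier=significance_tier(p),
        ))
        hsd = stats.tukey_hsd(*samples)
        for i, j in itertools.combinations(range(len(samples)), 2):
            pij = float(hsd.pvalue[i, j])
            results.append(GroupTestResult(
                test="Tukey", comparison=f"{names[i]}_vs_{names[j]}",
                statistic=float(hsd.statistic[i, j]), p_value=pij,
                tier=significance_tier(pij),
            ))
    else:
        raise ValueError(f"unknown design {design!r}")
    return results


def results_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
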