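"""Correlation analyses linking feature methylation to expression.

Covers the Spearman decile correlation per gene feature, the variance
comparison across tissue x decile groups (Brown-Forsythe residuals followed
by Tukey's HSD), the methylated/unmethylated state classification and the
odds-ratio association between features with Wald 99.9% confidence
intervals, the expression-extremes analysis, first-intron length
stratification, and the Tukey-fence Wilcoxon comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .constants import METH_CUTOFF, OR_CI_ALPHA, UNMETH_CUTOFF

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- Spearman

def decile_correlation(
    feature_meth: pd.DataFrame,
    expr: pd.DataFrame,
    deciles: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman rho of feature methylation vs expression, per tissue/feature.

    ``feature_meth``: long table (gene_id, feature, tissue, mean_percent);
    ``expr``: per-tissue mean log2cpm (genes x tissues);
    ``deciles``: per-tissue decile assignment (genes x tissues, NaN = not
    expressed).  Only expressed genes enter.  Also returns per-decile
    median/Q1/Q3 of methylation in ``summaries``-style long rows.
    """
    results = []
    summaries = []
    for (tissue, feature), sub in feature_meth.groupby(["tissue", "feature"]):
        if tissue not in expr.columns:
            continue
        joined = sub.set_index("gene_id")[["mean_percent"]].join(
            pd.DataFrame({"log2cpm": expr[tissue], "decile": deciles[tissue]}), how="inner"
        )
        joined = joined.dropna(subset=["decile"])
        n = len(joined)
        if n < 3:
            raise ValueError(f"decile_correlation: fewer than 3 genes for {tissue}/{feature}")
        meth = joined["mean_percent"].to_numpy(float)
        if np.ptp(meth) == 0 or np.ptp(joined["log2cpm"].to_numpy(float)) == 0:
            log.warning("constant input for %s/%s; rho undefined", tissue, feature)
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(meth, joined["log2cpm"].to_numpy(float))
        results.append((tissue, feature, n, rho, p))
        for d, grp in joined.groupby("decile"):
            q1, med, q3 = np.quantile(grp["mean_percent"].to_numpy(float), [0.25, 0.5, 0.75])
            summaries.append((tissue, feature, int(d), len(grp), med, q1, q3))
    res = pd.DataFrame(results, columns=["tissue", "feature", "n_genes", "rho", "p_value"])
    summ = pd.DataFrame(
        summaries,
        columns=["tissue", "feature", "decile", "n_genes", "median", "q1", "q3"],
    )
    return res, summ


def compare_decile_variance(
    values: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Variance heterogeneity across groups: Brown-Forsythe residuals + Tukey HSD.

    ``values`` are methylation percents; ``groups`` parallel labels (e.g.
    "tissue/decile").  Absolute deviations from each group's median are
    compared by one-way ANOVA across all groups and then by all-pairs
    Tukey HSD; returns the pairwise table with adjusted p-values.
    Groups with fewer than 2 observations are dropped with a warning.
    """
    df = pd.DataFrame({"value": values.to_numpy(float), "group": groups.to_numpy()})
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index
    if len(small):
        log.warning("dropping groups with <2 observations: %s", list(small))
        df = df[~df["group"].isin(small)]
    if df["group"].nunique() < 2:
        raise ValueError("variance comparison needs at least two groups")
    med = df.groupby("group")["value"].transform("median")
    df["absdev"] = (df["value"] - med).abs()
    tuk = pairwise_tukeyhsd(df["absdev"].to_numpy(), df["group"].to_numpy())
    out = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    out["p-adj"] = tuk.pvalues
    return out


# ---------------------------------------------------------------- OR

def feature_state(mean_percent: float,
                  unmeth_cutoff: float = UNMETH_CUTOFF,
                  meth_cutoff: float = METH_CUTOFF) -> str:
    """Classify a feature mean as methylated (>90), unmethylated (<10) or intermediate."""
    if mean_percent > meth_cutoff:
        return "methylated"
    if mean_percent < unmeth_cutoff:
        return "unmethylated"
    return "intermediate"


@dataclass
class ORResult:
    feature_a: str
    feature_b: str
    n00: int  # both unmethylated
    n01: int  # A unmethylated, B methylated
    n10: int  # A methylated, B unmethylated
    n11: int  # both methylated
    odds_ratio: float
    log2_or: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool


def odds_ratio_association(
    feature_meth: pd.DataFrame,
    pair: tuple[str, str],
    tissue: str,
    alpha: float = OR_CI_ALPHA,
) -> ORResult:
    """Association of the methylation state of two features across genes.

    Counts genes by joint state (unmethylated <10%, methylated >90%;
    intermediate genes excluded): OR = (N00*N11)/(N01*N10) with the Wald
    confidence interval exp(ln OR +/- z_{1-alpha/2} * sqrt(sum 1/N)).
    Zero cells trigger the Haldane-Anscombe +0.5 correction (flagged).
    """
    fa, fb = pair
    sub = feature_meth[feature_meth["tissue"] == tissue]
    wide = sub.pivot_table(index="gene_id", columns="feature", values="mean_percent")
    if fa not in wide.columns or fb not in wide.columns:
        raise ValueError(f"features {pair} not present for tissue {tissue}")
    wide = wide[[fa, fb]].dropna()
    sa = wide[fa].map(feature_state)
    sb = wide[fb].map(feature_state)
    keep = (sa != "intermediate") & (sb != "intermediate")
    sa, sb = sa[keep], sb[keep]
    if len(sa) == 0:
        raise ValueError("all genes intermediate; odds ratio undefined")
    n00 = int(((sa == "unmethylated") & (sb == "unmethylated")).sum())
    n01 = int(((sa == "unmethylated") & (sb == "methylated")).sum())
    n10 = int(((sa == "methylated") & (sb == "unmethylated")).sum())
    n11 = int(((sa == "methylated") & (sb == "methylated")).sum())
    return odds_ratio_from_counts(n00, n01, n10, n11, fa, fb, alpha)


def odds_ratio_from_counts(
    n00: int, n01: int, n10: int, n11: int,
    feature_a: str = "A", feature_b: str = "B",
    alpha: float = OR_CI_ALPHA,
) -> ORResult:
    cells = np.array([n00, n01, n10, n11], dtype=float)
    corrected = bool((cells == 0).any())
    work = cells + 0.5 if corrected else cells
    or_ = (work[0] * work[3]) / (work[1] * work[2])
    z = stats.norm.ppf(1 - alpha / 2)
    se = float(np.sqrt((1.0 / work).sum()))
    ci_low = float(np.exp(np.log(or_) - z * se))
    ci_high = float(np.exp(np.log(or_) + z * se))
    return ORResult(
        feature_a, feature_b, n00, n01, n10, n11,
        float(or_), float(np.log2(or_)), ci_low, ci_high, corrected,
    )


# ---------------------------------------------------------------- extremes

def extremes_analysis(
    feature_meth: pd.DataFrame,
    deciles: pd.DataFrame,
    feature: str = "first_intron",
    unmeth_cutoff: float = UNMETH_CUTOFF,
    meth_cutoff: float = METH_CUTOFF,
) -> pd.DataFrame:
    """Methylation-extreme fractions among lowest/highest expressed genes.

    For each tissue, genes in expression deciles 1-2 (low) and 9-10 (high)
    whose feature methylation is below 10% or above 90% are counted; within
    each expression class the fractions in the two extremes sum to 1.
    """
    rows = []
    sub = feature_meth[feature_meth["feature"] == feature]
    for tissue, tsub in sub.groupby("tissue"):
        if tissue not in deciles.columns:
            continue
        j = tsub.set_index("gene_id")[["mean_percent"]].join(
            deciles[tissue].rename("decile"), how="inner"
        ).dropna()
        for label, lo, hi in (("low", 1, 2), ("high", 9, 10)):
            grp = j[(j["decile"] >= lo) & (j["decile"] <= hi)]
            below = int((grp["mean_percent"] < unmeth_cutoff).sum())
            above = int((grp["mean_percent"] > meth_cutoff).sum())
            tot = below + above
            rows.append(
                (
                    tissue, label, tot,
                    below / tot if tot else np.nan,
                    above / tot if tot else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["tissue", "expression_class", "n_genes", "frac_below", "frac_above"]
    )


# ---------------------------------------------------------------- length quartiles

def stratify_by_intron_length(
    feature_meth: pd.DataFrame,
    intron_lengths: pd.Series,
    expr: pd.DataFrame,
    deciles: pd.DataFrame,
    feature: str = "first_intron",
) -> pd.DataFrame:
    """Spearman rho per first-intron length quartile.

    Genes are ranked by intron length (ties broken by gene_id) and split
    into four equal-size groups (Q1 = shortest).  Within each group the
    methylation-expression Spearman correlation is recomputed per tissue.
    """
    sub = feature_meth[feature_meth["feature"] == feature]
    genes = sorted(set(sub["gene_id"]) & set(intron_lengths.dropna().index))
    if len(genes) < 12:
        raise ValueError("length stratification needs at least 12 genes")
    ordered = (
        intron_lengths.loc[genes].rename("length").reset_index()
        .sort_values(["length", "gene_id"], kind="mergesort")
    )
    n = len(ordered)
    ordered["quartile"] = (np.arange(n) * 4) // n + 1
    qmap = ordered.set_index("gene_id")["quartile"]
    rows = []
    for tissue, tsub in sub.groupby("tissue"):
        if tissue not in expr.columns:
            continue
        j = tsub.set_index("gene_id")[["mean_percent"]].join(
            pd.DataFrame({"log2cpm": expr[tissue], "decile": deciles[tissue], "quartile": qmap}),
            how="inner",
        ).dropna()
        for q, grp in j.groupby("quartile"):
            if len(grp) < 3:
                continue
            rho, p = stats.spearmanr(grp["mean_percent"], grp["log2cpm"])
            rows.append(
                (tissue, int(q), len(grp), float(grp["length"].median())
                 if "length" in grp else np.nan, rho, p)
            )
    out = pd.DataFrame(rows, columns=["tissue", "quartile", "n_genes", "median_length", "rho", "p_value"])
    med = ordered.groupby("quartile")["length"].median()
    out["median_length"] = out["quartile"].map(med)
    return out


# ---------------------------------------------------------------- Wilcoxon

def tukey_fences(values: np.ndarray) -> np.ndarray:
    """Drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]


def wilcoxon_extremes(
    group_a: Sequence[float],
    group_b: Sequence[float],
    remove_outliers: bool = True,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Rank-sum test with continuity correction after Tukey-fence cleaning.

    Outliers are removed per group; the two-sample Wilcoxon rank-sum
    (Mann-Whitney) test with continuity correction is then applied.
    Returns (U statistic for group A, p-value).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if remove_outliers:
        a = tukey_fences(a)
        b = tukey_fences(b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("fewer than 3 observations per group after outlier removal")
    res = stats.mannwhitneyu(a, b, alternative=alternative, use_continuity=True,
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)
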