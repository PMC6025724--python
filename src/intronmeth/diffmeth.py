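"""Differentially methylated cytosines and tissue-DMRs.

Per-site differential methylation between two tissues is tested with a
binomial logistic regression of methylation proportion on tissue: read
counts are pooled within each tissue, so the likelihood-ratio statistic has
a closed form (the G-test of the pooled 2x2 table) and can be computed
vectorized over hundreds of thousands of sites.  P-values are adjusted by
Benjamini-Hochberg.  A DMC requires |difference| > 15 percentage points and
q < 0.01.

Regions are formed by chaining consecutive united CpGs whose gap does not
exceed ``max_gap`` bp; a region qualifies as a tDMR when it holds at least
5 CpGs and 3 DMCs, its mean difference exceeds 15 points in absolute value,
and its Stouffer-combined, BH-adjusted q-value is below 0.001.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import (
    DMC_DIFF,
    DMC_Q,
    DMR_DIFF,
    DMR_MAX_GAP,
    DMR_MIN_CPG,
    DMR_MIN_DMC,
    DMR_Q,
    FLANK_BP,
)
from .features import GeneFeatureSet, GeneModel, flank_window
from .methylation import MethylationMatrix

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300


def _binom_ll(m: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel (terms not involving p omitted)."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return m * np.log(p) + (n - m) * np.log(1 - p)


def test_dmc(
    matrix: MethylationMatrix,
    tissue_a: str,
    tissue_b: str,
    diff_thresh: float = DMC_DIFF,
    q_thresh: float = DMC_Q,
) -> pd.DataFrame:
    """Per-site logistic-regression test of tissue on methylation.

    meth_diff is the pooled percent of ``tissue_b`` minus ``tissue_a``
    (positive = hyper-methylation in B).  Sites with zero pooled reads in
    either tissue are skipped.
    """
    data = matrix.data

    def pooled(tissue: str) -> tuple[np.ndarray, np.ndarray]:
        samples = matrix.tissue_samples(tissue)
        if not samples:
            raise ValueError(f"no samples for tissue {tissue!r}")
        cov = data[[f"cov_{s}" for s in samples]].to_numpy(float)
        pct = data[[f"percent_{s}" for s in samples]].to_numpy(float)
        if np.isnan(cov).any():
            raise ValueError("DMC testing requires read counts in all samples")
        meth = np.rint(pct / 100.0 * cov)
        return meth.sum(axis=1), cov.sum(axis=1)

    ma, na = pooled(tissue_a)
    mb, nb = pooled(tissue_b)
    ok = (na > 0) & (nb > 0)
    if not ok.all():
        log.warning("skipping %d sites with zero pooled reads in a tissue", int((~ok).sum()))

    pa = np.divide(ma, na, out=np.zeros_like(ma), where=na > 0)
    pb = np.divide(mb, nb, out=np.zeros_like(mb), where=nb > 0)
    p0 = np.divide(ma + mb, na + nb, out=np.zeros_like(ma), where=(na + nb) > 0)
    # LRT of the tissue term: full model fits each tissue's proportion
    lr = 2.0 * (
        _binom_ll(ma, na, pa) + _binom_ll(mb, nb, pb) - _binom_ll(ma + mb, na + nb, p0)
    )
    lr = np.clip(lr, 0.0, None)
    pval = stats.chi2.sf(lr, df=1)

    out = pd.DataFrame(
        {
            "chrom": data.index.get_level_values(0),
            "pos": data.index.get_level_values(1),
            "meth_diff": 100.0 * (pb - pa),
            "lr_stat": lr,
            "p_value": pval,
        }
    )
    out = out.loc[ok].reset_index(drop=True)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    out["is_dmc"] = (out["meth_diff"].abs() > diff_thresh) & (out["q_value"] < q_thresh)
    return out


def call_tdmrs(
    dmc_table: pd.DataFrame,
    max_gap: int = DMR_MAX_GAP,
    min_cpg: int = DMR_MIN_CPG,
    min_dmc: int = DMR_MIN_DMC,
    diff_thresh: float = DMR_DIFF,
    q_thresh: float = DMR_Q,
) -> pd.DataFrame:
    """Chain united CpGs into candidate regions and filter to tDMRs.

    ``dmc_table`` is the output of :func:`test_dmc` over ALL united sites
    (not only DMCs).  Candidate regions are maximal runs of consecutive
    sites on one chromosome with inter-CpG gap <= ``max_gap``.  The region
    p-value combines the site p-values by Stouffer's method; q-values are
    BH over the candidate regions.
    """
    if dmc_table.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpg", "n_dmc", "mean_diff",
                     "p_value", "q_value", "direction"]
        )
    df = dmc_table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    new_chrom = df["chrom"].ne(df["chrom"].shift())
    gap = df["pos"].diff()
    region_id = (new_chrom | (gap > max_gap)).cumsum()

    df = df.assign(
        _z=stats.norm.isf(df["p_value"].clip(_P_FLOOR, 1 - 1e-16).to_numpy()),
        _region=region_id,
    )
    agg = df.groupby("_region").agg(
        chrom=("chrom", "first"),
        start=("pos", "min"),
        end=("pos", "max"),
        n_cpg=("pos", "size"),
        n_dmc=("is_dmc", "sum"),
        mean_diff=("meth_diff", "mean"),
        z_sum=("_z", "sum"),
    )
    agg["end"] += 2  # the CpG dinucleotide covers pos..pos+2
    agg["p_value"] = stats.norm.sf(agg["z_sum"] / np.sqrt(agg["n_cpg"]))
    cand = agg.drop(columns="z_sum").reset_index(drop=True)
    cand["n_dmc"] = cand["n_dmc"].astype(int)
    cand["q_value"] = multipletests(cand["p_value"], method="fdr_bh")[1]
    keep = (
        (cand["n_cpg"] >= min_cpg)
        & (cand["n_dmc"] >= min_dmc)
        & (cand["mean_diff"].abs() > diff_thresh)
        & (cand["q_value"] < q_thresh)
    )
    out = cand.loc[keep].reset_index(drop=True)
    out["direction"] = np.where(out["mean_diff"] > 0, "hyper", "hypo")
    return out


OVERLAP_CLASSES = ("gene_flank", "promoter", "first_exon", "first_intron")


def overlap_tdmrs(
    tdmrs: pd.DataFrame,
    genes: Sequence[GeneModel],
    features: Sequence[GeneFeatureSet],
    flank: int = FLANK_BP,
) -> pd.DataFrame:
    """Assign tDMRs to genes by any-overlap (>=1 bp) with feature windows.

    ``gene_flank`` is the gene body extended by ``flank`` bp on both sides
    (gene +/- 4 kb).  A tDMR may hit several genes and several classes; one
    row is emitted per (tDMR, gene, class).
    """
    trees: dict[str, IntervalTree] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        s, e = flank_window(g, flank)
        if e > s:
            tree.addi(s, e, (g.gene_id, "gene_flank"))
    for fs in features:
        tree = trees.setdefault(fs.chrom, IntervalTree())
        for feat in ("promoter", "first_exon", "first_intron"):
            for s, e in fs.intervals(feat):
                if e > s:
                    tree.addi(s, e, (fs.gene_id, feat))
    rows = []
    for i, r in tdmrs.iterrows():
        tree = trees.get(r["chrom"])
        if tree is None:
            continue
        for iv in sorted(tree.overlap(int(r["start"]), int(r["end"])), key=lambda v: v.data):
            gene_id, cls = iv.data
            rows.append((i, r["chrom"], int(r["start"]), int(r["end"]),
                         float(r["mean_diff"]), r["direction"], gene_id, cls))
    return pd.DataFrame(
        rows,
        columns=["tdmr_index", "chrom", "start", "end", "mean_diff",
                 "direction", "gene_id", "overlap_class"],
    )


def quadrant_analysis(overlaps: pd.DataFrame, degs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair significant DEGs with their tDMRs and classify quadrants.

    Quadrants combine the DEG direction (up/down in the reference tissue)
    with the tDMR direction (hyper/hypo).  up+hypo and down+hyper form the
    negative-correlation set; up+hyper and down+hypo the positive set.
    Returns (pair table, per overlap-class/correlation-set Spearman rho of
    log2fc vs mean_diff plus gene counts).
    """
    sig = degs[degs["significant"]][["gene_id", "log2fc"]]
    pairs = overlaps.merge(sig, on="gene_id", how="inner")
    if pairs.empty:
        return (
            pairs.assign(quadrant=pd.Series(dtype=str), corr_set=pd.Series(dtype=str)),
            pd.DataFrame(columns=["overlap_class", "corr_set", "n_pairs", "n_genes", "rho", "p_value"]),
        )
    up = pairs["log2fc"] > 0
    hyper = pairs["mean_diff"] > 0
    pairs["quadrant"] = np.select(
        [up & hyper, up & ~hyper, ~up & hyper, ~up & ~hyper],
        ["up+hyper", "up+hypo", "down+hyper", "down+hypo"],
        default="",
    )
    pairs["corr_set"] = np.where(
        pairs["quadrant"].isin(["up+hypo", "down+hyper"]), "negative", "positive"
    )
    rows = []
    for (cls, cset), grp in pairs.groupby(["overlap_class", "corr_set"]):
        if len(grp) >= 3 and grp["log2fc"].nunique() > 1 and grp["mean_diff"].nunique() > 1:
            rho, p = stats.spearmanr(grp["log2fc"], grp["mean_diff"])
        else:
            rho, p = np.nan, np.nan
        rows.append((cls, cset, len(grp), grp["gene_id"].nunique(), rho, p))
    summary = pd.DataFrame(
        rows, columns=["overlap_class", "corr_set", "n_pairs", "n_genes", "rho", "p_value"]
    )
    return pairs, summary


def boundary_distance(
    overlaps: pd.DataFrame,
    features: Sequence[GeneFeatureSet],
) -> pd.DataFrame:
    """Distance of first-intron tDMRs from the first exon-first intron boundary.

    The boundary is the transcription-order start of the first intron
    (genomic start on +, genomic end on -).  Distance is measured from the
    boundary to the nearest edge of the tDMR clipped to the intron;
    relative distance divides by the intron length.
    """
    fmap = {fs.gene_id: fs for fs in features}
    rows = []
    for _, r in overlaps[overlaps["overlap_class"] == "first_intron"].iterrows():
        fs = fmap.get(r["gene_id"])
        if fs is None or fs.first_intron is None:
            continue
        s, e = fs.first_intron
        cs, ce = max(s, int(r["start"])), min(e, int(r["end"]))
        if ce <= cs:
            continue
        length = e - s
        if fs.strand == "+":
            dist = cs - s
        else:
            dist = e - ce
        rows.append((r["gene_id"], int(r["tdmr_index"]), dist, dist / length, length))
    return pd.DataFrame(
        rows, columns=["gene_id", "tdmr_index", "distance_bp", "relative_distance", "intron_length"]
    )
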