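"""Per-CpG methylation calls: parsing, filtering, uniting, aggregation.

Calls are held in pandas DataFrames with columns ``chrom``, ``pos`` (0-based
coordinate of the C of the CpG on the plus strand), ``coverage``,
``meth_count`` and ``percent``.  Dialects that report the two strands of a
CpG separately are strand-merged by summing read counts, since CpG
methylation is symmetric.

The aggregation order for feature-level methylation is: per site, average
the percent values of the samples of one tissue; then average sites within
the feature (unweighted by coverage).
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .constants import MAX_COVERAGE_QUANTILE, MIN_COVERAGE
from .features import FEATURE_CLASSES, GeneFeatureSet

log = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "coverage", "meth_count", "percent"]


def _finish(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if ((df["percent"] < 0) | (df["percent"] > 100)).any():
        raise ValueError("percent methylation outside [0, 100]")
    return df[CALL_COLUMNS]


def read_meth_calls(path: str | os.PathLike, dialect: str) -> pd.DataFrame:
    """Read per-CpG calls in one of three dialects.

    ``methratio``: BSMAP methratio TSV with header
    (chr, pos 1-based, strand, context, ratio, eff_CT_count, C_count,
    CT_count, ...); plus and minus strand calls of one CpG are merged by
    summing counts.

    ``bismark_cov``: chrom, start 1-based, end, percent, count_methylated,
    count_unmethylated (no header).

    ``bedgraph``: chrom, start 0-based, end, percent (no header); carries no
    counts, so coverage and meth_count are NaN and count-requiring
    operations reject it.
    """
    if dialect == "methratio":
        df = pd.read_csv(str(path), sep="\t")
        cols = {c.lower(): c for c in df.columns}
        need = ["chr", "pos", "strand", "c_count", "ct_count"]
        missing = [c for c in need if c not in cols]
        if missing:
            raise ValueError(f"methratio file missing columns: {missing}")
        if df.empty:
            return pd.DataFrame(columns=CALL_COLUMNS)
        out = pd.DataFrame(
            {
                "chrom": df[cols["chr"]].astype(str),
                "pos": df[cols["pos"]].astype(int) - 1,
                "strand": df[cols["strand"]].astype(str),
                "meth_count": df[cols["c_count"]].astype(int),
                "coverage": df[cols["ct_count"]].astype(int),
            }
        )
        # the G of a CpG on the minus strand sits one base right of the C
        out.loc[out["strand"] == "-", "pos"] -= 1
        g = out.groupby(["chrom", "pos"], as_index=False)[["meth_count", "coverage"]].sum()
        if (g["meth_count"] > g["coverage"]).any():
            raise ValueError("meth_count exceeds coverage")
        g["percent"] = np.where(
            g["coverage"] > 0, 100.0 * g["meth_count"] / g["coverage"], np.nan
        )
        return _finish(g)

    if dialect == "bismark_cov":
        df = pd.read_csv(
            str(path),
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "percent", "count_m", "count_u"],
        )
        if df.empty:
            return pd.DataFrame(columns=CALL_COLUMNS)
        if df[["count_m", "count_u"]].isna().any().any():
            raise ValueError("bismark coverage file with missing counts")
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["start"].astype(int) - 1,
                "meth_count": df["count_m"].astype(int),
                "coverage": df["count_m"].astype(int) + df["count_u"].astype(int),
            }
        )
        g = out.groupby(["chrom", "pos"], as_index=False)[["meth_count", "coverage"]].sum()
        g["percent"] = 100.0 * g["meth_count"] / g["coverage"]
        return _finish(g)

    if dialect == "bedgraph":
        df = pd.read_csv(
            str(path), sep="\t", header=None, names=["chrom", "start", "end", "percent"]
        )
        if df.empty:
            return pd.DataFrame(columns=CALL_COLUMNS)
        out = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["start"].astype(int),
                "coverage": np.nan,
                "meth_count": np.nan,
                "percent": df["percent"].astype(float),
            }
        )
        return _finish(out)

    raise ValueError(f"unknown dialect {dialect!r}")


def filter_coverage(
    calls: pd.DataFrame,
    min_cov: int = MIN_COVERAGE,
    max_quantile: float = MAX_COVERAGE_QUANTILE,
) -> pd.DataFrame:
    """Drop low- and extreme-coverage sites of one sample.

    Retains sites with ``min_cov <= coverage <= Q``, where Q is the
    per-sample ``max_quantile`` coverage quantile (linear interpolation)
    computed before any filtering.  Sites exactly at Q are kept.
    """
    if calls.empty:
        return calls
    if calls["coverage"].isna().any():
        raise ValueError("coverage filtering requires read counts")
    hi = float(np.quantile(calls["coverage"].to_numpy(float), max_quantile))
    keep = (calls["coverage"] >= min_cov) & (calls["coverage"] <= hi)
    return calls.loc[keep].reset_index(drop=True)


class MethylationMatrix:
    """United CpG sites x samples.

    ``data`` is indexed by (chrom, pos) and holds ``percent_<sample>`` and
    ``cov_<sample>`` columns; every retained site has a value in all
    samples.  ``tissue_map`` maps sample name -> tissue.
    """

    def __init__(self, data: pd.DataFrame, samples: Sequence[str], tissue_map: Mapping[str, str]):
        self.data = data
        self.samples = list(samples)
        self.tissue_map = dict(tissue_map)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.tissue_map[s], None)
        return list(seen)

    def tissue_samples(self, tissue: str) -> list[str]:
        return [s for s in self.samples if self.tissue_map[s] == tissue]

    def tissue_percent(self, tissue: str) -> pd.Series:
        """Per-site mean percent over the samples of one tissue."""
        cols = [f"percent_{s}" for s in self.tissue_samples(tissue)]
        return self.data[cols].mean(axis=1)


def unite(
    per_sample_calls: Mapping[str, pd.DataFrame],
    tissue_map: Mapping[str, str],
) -> MethylationMatrix:
    """Intersect site sets across samples (sites covered in all samples)."""
    if not per_sample_calls:
        raise ValueError("unite requires at least one sample")
    samples = list(per_sample_calls)
    merged: Optional[pd.DataFrame] = None
    for s in samples:
        df = per_sample_calls[s].set_index(["chrom", "pos"])
        part = df[["percent", "coverage"]].rename(
            columns={"percent": f"percent_{s}", "coverage": f"cov_{s}"}
        )
        merged = part if merged is None else merged.join(part, how="inner")
    assert merged is not None
    if merged.empty:
        log.warning("unite: empty intersection of covered sites")
    merged = merged.sort_index()
    return MethylationMatrix(merged, samples, tissue_map)


def average_replicates_wgbs(
    replicate_calls: Iterable[pd.DataFrame], min_cov: int = MIN_COVERAGE
) -> pd.DataFrame:
    """Whole-genome bisulfite replicate averaging.

    Each replicate is first restricted to positions with at least
    ``min_cov`` reads; the per-site percent (100 * methylated / total) is
    then averaged over the replicates covering the site.
    """
    pieces = []
    for i, df in enumerate(replicate_calls):
        if df["coverage"].isna().any():
            raise ValueError("replicate averaging requires read counts")
        kept = df.loc[df["coverage"] >= min_cov, ["chrom", "pos", "percent"]]
        pieces.append(kept.set_index(["chrom", "pos"])["percent"].rename(i))
    if not pieces:
        raise ValueError("no replicates")
    wide = pd.concat(pieces, axis=1)
    out = wide.mean(axis=1).rename("percent").reset_index()
    out["coverage"] = np.nan
    out["meth_count"] = np.nan
    return _finish(out)


def _feature_tree(features: Sequence[GeneFeatureSet]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for fs in features:
        tree = trees.setdefault(fs.chrom, IntervalTree())
        for feat in FEATURE_CLASSES:
            for s, e in fs.intervals(feat):
                if e > s:
                    tree.addi(s, e, (fs.gene_id, feat))
    return trees


def feature_methylation(
    matrix: MethylationMatrix,
    features: Sequence[GeneFeatureSet],
) -> pd.DataFrame:
    """Per gene x feature x tissue mean methylation.

    For each united site falling inside a feature interval the tissue-level
    percent (mean over that tissue's samples) is taken; the feature value is
    the unweighted mean over its sites.  Genes/features with no covered site
    are omitted.  Returns a long DataFrame (gene_id, feature, tissue, n_cpg,
    mean_percent).
    """
    trees = _feature_tree(features)
    tissues = matrix.tissues
    tissue_percent = {t: matrix.tissue_percent(t).to_numpy(float) for t in tissues}
    idx = matrix.data.index
    chroms = idx.get_level_values(0).to_numpy()
    poss = idx.get_level_values(1).to_numpy()

    # accumulate site indices per (gene, feature)
    hits: dict[tuple[str, str], list[int]] = {}
    for i in range(len(idx)):
        tree = trees.get(chroms[i])
        if tree is None:
            continue
        for iv in tree.at(int(poss[i])):
            hits.setdefault(iv.data, []).append(i)

    rows = []
    for (gene_id, feat), site_idx in hits.items():
        site_idx = np.asarray(site_idx)
        for t in tissues:
            rows.append(
                (gene_id, feat, t, len(site_idx), float(np.mean(tissue_percent[t][site_idx])))
            )
    out = pd.DataFrame(rows, columns=["gene_id", "feature", "tissue", "n_cpg", "mean_percent"])
    return out.sort_values(["gene_id", "feature", "tissue"], kind="mergesort").reset_index(
        drop=True
    )


def cpg_density(seq: str) -> float:
    """CG dinucleotides per bp of sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return seq.count("CG") / len(seq)
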