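"""Gene-level expression: cpm normalization, deciles, tissue specificity.

Expression enters the methylation analyses as log2(cpm + 1).  Deciles are
assigned per tissue among expressed genes (cpm > 0), decile 1 being the
lowest expression; rank ties are broken by gene identifier so the
assignment is deterministic.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .constants import CPM_OFFSET, DEG_FDR, DEG_LFC


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Gene x sample integer count matrix (TSV, first column gene_id)."""
    df = pd.read_csv(str(path), sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    if (df < 0).any().any():
        raise ValueError("negative counts")
    return df


def compute_cpm(counts: pd.DataFrame, offset: float = CPM_OFFSET) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-per-million per sample and log2(cpm + offset)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for samples {bad}")
    cpm = counts.astype(float) / lib * 1e6
    return cpm, np.log2(cpm + offset)


def tissue_mean_log2cpm(log2cpm: pd.DataFrame, tissue_map: Mapping[str, str]) -> pd.DataFrame:
    """Per-tissue mean of log2cpm over that tissue's samples."""
    tissues: dict[str, list[str]] = {}
    for s in log2cpm.columns:
        tissues.setdefault(tissue_map[s], []).append(s)
    return pd.DataFrame({t: log2cpm[cols].mean(axis=1) for t, cols in tissues.items()})


def assign_deciles(values: pd.Series, expressed: Optional[pd.Series] = None) -> pd.Series:
    """Split expressed genes into 10 equal-size rank groups (decile 1 = lowest).

    ``values`` is indexed by gene_id; ``expressed`` is a boolean mask (all
    True if omitted).  Group sizes differ by at most one; ties in value are
    broken lexicographically on gene_id.  Non-expressed genes get NaN.
    """
    if expressed is None:
        expressed = pd.Series(True, index=values.index)
    sub = values[expressed.reindex(values.index, fill_value=False)]
    n = len(sub)
    if n < 10:
        raise ValueError(f"need at least 10 expressed genes, got {n}")
    order = sub.reset_index()
    order.columns = ["gene_id", "value"]
    order = order.sort_values(["value", "gene_id"], kind="mergesort")
    # rank r (0-based) -> decile floor(r*10/n) + 1 gives sizes within +-1
    ranks = np.arange(n)
    deciles = (ranks * 10) // n + 1
    out = pd.Series(np.nan, index=values.index, name="decile")
    out.loc[order["gene_id"].to_numpy()] = deciles.astype(float)
    return out


def flag_tissue_specific(cpm: pd.DataFrame, tissue_map: Mapping[str, str]) -> pd.Series:
    """Genes expressed (cpm > 0 in every sample) in exactly one of two tissues.

    Returns a Series of tissue name (the tissue the gene is specific to) or
    NaN, indexed by gene_id.
    """
    tissues: dict[str, list[str]] = {}
    for s in cpm.columns:
        tissues.setdefault(tissue_map[s], []).append(s)
    if len(tissues) != 2:
        raise ValueError(f"tissue-specific flag requires exactly two tissues, got {list(tissues)}")
    (ta, cols_a), (tb, cols_b) = tissues.items()
    on_a = (cpm[cols_a] > 0).all(axis=1)
    off_a = (cpm[cols_a] == 0).all(axis=1)
    on_b = (cpm[cols_b] > 0).all(axis=1)
    off_b = (cpm[cols_b] == 0).all(axis=1)
    out = pd.Series(np.nan, index=cpm.index, dtype=object)
    out[on_a & off_b] = ta
    out[on_b & off_a] = tb
    return out


def read_deg_table(
    path: str | os.PathLike,
    lfc_thresh: float = DEG_LFC,
    fdr_thresh: float = DEG_FDR,
) -> pd.DataFrame:
    """Read a differential-expression table and flag significant genes.

    Requires columns gene_id, log2fc, fdr.  Positive log2fc means
    up-regulation in the designated reference tissue.  Significant iff
    |log2fc| strictly exceeds ``lfc_thresh`` and fdr < ``fdr_thresh``.
    """
    df = pd.read_csv(str(path), sep="\t", comment="#")
    missing = {"gene_id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    df = df.copy()
    df["significant"] = (df["log2fc"].abs() > lfc_thresh) & (df["fdr"] < fdr_thresh)
    return df
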