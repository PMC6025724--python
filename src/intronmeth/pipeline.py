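"""End-to-end orchestration of the analysis stages.

Stage order: features -> aggregate -> expression -> integrate -> diffmeth
-> motifs.  Each stage writes TSV outputs with a provenance header block
(package version, configuration hash, seed) so that identical configs give
byte-identical outputs.  Later stages reload earlier outputs from the
output directory when they are not run in the same invocation; a missing
prerequisite raises an error naming the stage and file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import constants as C
from .diffmeth import (
    boundary_distance,
    call_tdmrs,
    overlap_tdmrs,
    quadrant_analysis,
    test_dmc,
)
from .expression import (
    assign_deciles,
    compute_cpm,
    flag_tissue_specific,
    read_counts,
    read_deg_table,
    tissue_mean_log2cpm,
)
from .features import (
    FEATURE_CLASSES,
    GeneFeatureSet,
    GeneModel,
    derive_features,
    read_gff3,
    write_feature_bed,
)
from .integrate import (
    decile_correlation,
    extremes_analysis,
    odds_ratio_association,
    stratify_by_intron_length,
)
from .methylation import feature_methylation, filter_coverage, read_meth_calls, unite
from .motifs import (
    ancova_expression,
    classify_motif_cpgs,
    cpg_windows,
    enrich_motifs,
    filter_cpg_motifs,
    intersect_tissues,
    motif_cpg_hits,
    read_jaspar_pfm,
    relative_distance,
    symmetric_background,
)

log = logging.getLogger(__name__)

STAGES = ("features", "aggregate", "expression", "integrate", "diffmeth", "motifs")


@dataclass
class RunConfig:
    """Input paths, tissue maps and analysis thresholds for one run."""

    annotation: str
    methylation: dict[str, str]
    counts: str
    meth_tissue_map: dict[str, str]
    rna_tissue_map: dict[str, str]
    tissue_a: str
    tissue_b: str
    fasta: Optional[str] = None
    deg: Optional[str] = None
    pwms: Optional[str] = None
    meth_dialect: str = "bismark_cov"
    seed: int = 1

    min_cov: int = C.MIN_COVERAGE
    cov_quantile: float = C.MAX_COVERAGE_QUANTILE
    promoter_length: int = C.PROMOTER_LENGTH
    flank: int = C.FLANK_BP
    unmeth_cutoff: float = C.UNMETH_CUTOFF
    meth_cutoff: float = C.METH_CUTOFF
    or_ci_alpha: float = C.OR_CI_ALPHA
    dmc_diff: float = C.DMC_DIFF
    dmc_q: float = C.DMC_Q
    dmr_diff: float = C.DMR_DIFF
    dmr_q: float = C.DMR_Q
    dmr_min_cpg: int = C.DMR_MIN_CPG
    dmr_min_dmc: int = C.DMR_MIN_DMC
    dmr_max_gap: int = C.DMR_MAX_GAP
    deg_lfc: float = C.DEG_LFC
    deg_fdr: float = C.DEG_FDR
    cpg_window: int = C.CPG_WINDOW
    motif_hit_p: float = C.MOTIF_HIT_P
    enrich_p: float = C.ENRICH_P

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        """Load a config; relative input paths resolve against the YAML dir."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).resolve().parent

        def resolve(p):
            return str(base / p) if p and not Path(p).is_absolute() else p

        for key in ("annotation", "fasta", "counts", "deg", "pwms"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        if "methylation" in raw:
            raw["methylation"] = {s: resolve(p) for s, p in raw["methylation"].items()}
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: RunConfig, outdir: str):
        self.cfg = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._genes: Optional[list[GeneModel]] = None
        self._features: Optional[list[GeneFeatureSet]] = None
        self._matrix = None
        self._expr = None  # dict with cpm, log2cpm, tissue means, deciles
        self._feature_meth: Optional[pd.DataFrame] = None

    # ------------------------------------------------ provenance I/O

    def _write_tsv(self, df: pd.DataFrame, name: str, stage: str, index: bool = False) -> None:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(f"# intronmeth {__version__}\n")
            fh.write(f"# stage: {stage}\n")
            fh.write(f"# config: {self.cfg.digest()}\n")
            fh.write(f"# seed: {self.cfg.seed}\n")
            df.to_csv(fh, sep="\t", index=index, float_format="%.6g")
        log.info("%s: wrote %s (%d rows)", stage, path, len(df))

    def _require(self, name: str, stage: str) -> Path:
        path = self.outdir / name
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' requires {path}; run its producing stage first"
            )
        return path

    # ------------------------------------------------ lazy inputs

    @property
    def genes(self) -> list[GeneModel]:
        if self._genes is None:
            self._genes = read_gff3(self.cfg.annotation)
        return self._genes

    @property
    def features(self) -> list[GeneFeatureSet]:
        if self._features is None:
            self._features = [
                derive_features(g, self.cfg.promoter_length) for g in self.genes
            ]
        return self._features

    @property
    def matrix(self):
        if self._matrix is None:
            calls = {}
            for sample, path in self.cfg.methylation.items():
                df = read_meth_calls(path, self.cfg.meth_dialect)
                calls[sample] = filter_coverage(df, self.cfg.min_cov, self.cfg.cov_quantile)
            self._matrix = unite(calls, self.cfg.meth_tissue_map)
        return self._matrix

    @property
    def expr(self) -> dict:
        if self._expr is None:
            counts = read_counts(self.cfg.counts)
            cpm, log2cpm = compute_cpm(counts)
            means = tissue_mean_log2cpm(log2cpm, self.cfg.rna_tissue_map)
            mean_cpm = tissue_mean_log2cpm(cpm, self.cfg.rna_tissue_map)
            deciles = pd.DataFrame(
                {
                    t: assign_deciles(means[t], mean_cpm[t] > 0)
                    for t in means.columns
                }
            )
            self._expr = {
                "counts": counts,
                "cpm": cpm,
                "log2cpm": log2cpm,
                "tissue_log2cpm": means,
                "deciles": deciles,
                "tissue_specific": flag_tissue_specific(cpm, self.cfg.rna_tissue_map),
            }
        return self._expr

    @property
    def feature_meth(self) -> pd.DataFrame:
        if self._feature_meth is None:
            path = self._require("feature_methylation.tsv", "integrate")
            self._feature_meth = pd.read_csv(path, sep="\t", comment="#")
        return self._feature_meth

    # ------------------------------------------------ stages

    def run_features(self) -> None:
        write_feature_bed(self.features, self.outdir / "features.bed")
        log.info("features: %d genes", len(self.features))

    def run_aggregate(self) -> None:
        table = feature_methylation(self.matrix, self.features)
        self._feature_meth = table
        self._write_tsv(table, "feature_methylation.tsv", "aggregate")

    def run_expression(self) -> None:
        e = self.expr
        out = pd.DataFrame(index=e["counts"].index)
        for t in e["tissue_log2cpm"].columns:
            out[f"log2cpm_{t}"] = e["tissue_log2cpm"][t]
            out[f"decile_{t}"] = e["deciles"][t]
        out["tissue_specific"] = e["tissue_specific"]
        self._write_tsv(out.reset_index(), "expression.tsv", "expression")

    def run_integrate(self) -> None:
        fm = self.feature_meth
        e = self.expr
        res, summ = decile_correlation(fm, e["tissue_log2cpm"], e["deciles"])
        self._write_tsv(res, "decile_correlation.tsv", "integrate")
        self._write_tsv(summ, "decile_summary.tsv", "integrate")

        rows = []
        feats = [f for f in FEATURE_CLASSES]
        for tissue in (self.cfg.tissue_a, self.cfg.tissue_b):
            for i, fa in enumerate(feats):
                for fb in feats[i + 1:]:
                    try:
                        r = odds_ratio_association(
                            fm, (fa, fb), tissue, self.cfg.or_ci_alpha
                        )
                    except ValueError:
                        continue
                    rows.append(
                        (tissue, fa, fb, r.n00, r.n01, r.n10, r.n11, r.odds_ratio,
                         r.log2_or, r.ci_low, r.ci_high, r.continuity_corrected)
                    )
        self._write_tsv(
            pd.DataFrame(
                rows,
                columns=["tissue", "feature_a", "feature_b", "n00", "n01", "n10",
                         "n11", "odds_ratio", "log2_or", "ci_low", "ci_high",
                         "continuity_corrected"],
            ),
            "odds_ratio.tsv", "integrate",
        )

        self._write_tsv(
            extremes_analysis(fm, e["deciles"], "first_intron",
                              self.cfg.unmeth_cutoff, self.cfg.meth_cutoff),
            "extremes.tsv", "integrate",
        )

        lengths = pd.Series(
            {
                fs.gene_id: fs.first_intron[1] - fs.first_intron[0]
                for fs in self.features
                if fs.first_intron is not None
            },
            name="length",
        )
        lengths.index.name = "gene_id"
        try:
            lq = stratify_by_intron_length(fm, lengths, e["tissue_log2cpm"], e["deciles"])
            self._write_tsv(lq, "length_quartiles.tsv", "integrate")
        except ValueError as err:
            log.warning("length stratification skipped: %s", err)

    def run_diffmeth(self) -> None:
        cfg = self.cfg
        dmc = test_dmc(self.matrix, cfg.tissue_a, cfg.tissue_b, cfg.dmc_diff, cfg.dmc_q)
        self._write_tsv(dmc, "dmcs.tsv", "diffmeth")
        tdmrs = call_tdmrs(dmc, cfg.dmr_max_gap, cfg.dmr_min_cpg, cfg.dmr_min_dmc,
                           cfg.dmr_diff, cfg.dmr_q)
        self._write_tsv(tdmrs, "tdmrs.tsv", "diffmeth")
        # BED6+ export
        bed = tdmrs.assign(
            name=[f"tdmr{i}" for i in range(len(tdmrs))], score=0, strand="."
        )[["chrom", "start", "end", "name", "mean_diff", "strand", "n_cpg", "n_dmc", "q_value"]]
        bed.to_csv(self.outdir / "tdmrs.bed", sep="\t", header=False, index=False,
                   float_format="%.6g")
        overlaps = overlap_tdmrs(tdmrs, self.genes, self.features, cfg.flank)
        self._write_tsv(overlaps, "tdmr_overlaps.tsv", "diffmeth")
        if cfg.deg:
            degs = read_deg_table(cfg.deg, cfg.deg_lfc, cfg.deg_fdr)
            pairs, summary = quadrant_analysis(overlaps, degs)
            self._write_tsv(pairs, "quadrants.tsv", "diffmeth")
            self._write_tsv(summary, "quadrant_summary.tsv", "diffmeth")
        self._write_tsv(boundary_distance(overlaps, self.features),
                        "tdmr_boundary.tsv", "diffmeth")

    def run_motifs(self) -> None:
        cfg = self.cfg
        if not (cfg.pwms and cfg.fasta):
            raise FileNotFoundError("stage 'motifs' requires pwms and fasta inputs")
        from pyfaidx import Fasta

        genome = Fasta(cfg.fasta)
        sites = self.matrix.data.reset_index()[["chrom", "pos"]]
        windows = cpg_windows(self.features, sites, genome, cfg.cpg_window)
        if windows.empty:
            log.warning("motifs: no first-intron CpG windows; stage skipped")
            return
        bg = symmetric_background(windows["seq"].tolist())
        pwms = read_jaspar_pfm(cfg.pwms, background=bg)
        e = self.expr

        # per-tissue enrichment over windows of genes expressed in that tissue
        enriched = {}
        fmap = {fs.gene_id: fs for fs in self.features}
        for t in (cfg.tissue_a, cfg.tissue_b):
            expressed = e["deciles"][t].dropna().index
            wsub = windows[windows["gene_id"].isin(expressed)]
            res = enrich_motifs(wsub["seq"].tolist(), pwms, seed=cfg.seed,
                                alpha=cfg.enrich_p)
            res.insert(0, "tissue", t)
            enriched[t] = res
        self._write_tsv(pd.concat(enriched.values(), ignore_index=True),
                        "motif_enrichment.tsv", "motifs")

        common = intersect_tissues(enriched[cfg.tissue_a], enriched[cfg.tissue_b])
        selected = filter_cpg_motifs(common, pwms)
        by_id = {p.motif_id: p for p in pwms}
        sel_pwms = [by_id[m] for m in selected]
        if not sel_pwms:
            log.warning("motifs: no common CpG-containing enriched motifs")
            self._write_tsv(pd.DataFrame(
                columns=["gene_id", "chrom", "pos", "motif_id", "tissue", "percent",
                         "meth_class", "relative_distance", "log2cpm"]),
                "motif_cpgs.tsv", "motifs")
            return

        hits = motif_cpg_hits(windows, sel_pwms, cfg.motif_hit_p)
        recs = []
        for t in (cfg.tissue_a, cfg.tissue_b):
            tp = self.matrix.tissue_percent(t)
            expressed = set(e["deciles"][t].dropna().index)
            for _, h in hits.iterrows():
                if h["gene_id"] not in expressed:
                    continue
                fs = fmap[h["gene_id"]]
                pct = tp.get((h["chrom"], h["pos"]))
                if pct is None or fs.first_intron is None:
                    continue
                recs.append(
                    (h["gene_id"], h["chrom"], int(h["pos"]), h["motif_id"], t,
                     float(pct),
                     relative_distance(int(h["pos"]), fs.first_intron, fs.strand),
                     float(e["tissue_log2cpm"].loc[h["gene_id"], t]))
                )
        rec_df = pd.DataFrame(
            recs, columns=["gene_id", "chrom", "pos", "motif_id", "tissue",
                           "percent", "relative_distance", "log2cpm"],
        )
        if rec_df.empty or rec_df.groupby("tissue")["percent"].count().min() < 4:
            log.warning("motifs: too few motif CpGs for classification")
            self._write_tsv(rec_df.assign(meth_class=pd.Series(dtype=str)),
                            "motif_cpgs.tsv", "motifs")
            return
        rec_df = classify_motif_cpgs(rec_df)
        self._write_tsv(rec_df, "motif_cpgs.tsv", "motifs")

        anc_rows = []
        for t, grp in rec_df.groupby("tissue"):
            try:
                table, shapiro_p = ancova_expression(grp)
            except ValueError as err:
                log.warning("ANCOVA skipped for %s: %s", t, err)
                continue
            for factor, row in table.iterrows():
                anc_rows.append(
                    (t, factor, row["sum_sq"], row["df"],
                     row.get("F", np.nan), row.get("PR(>F)", np.nan), shapiro_p)
                )
        self._write_tsv(
            pd.DataFrame(anc_rows, columns=["tissue", "factor", "SS", "df", "F",
                                            "p_value", "shapiro_p"]),
            "ancova.tsv", "motifs",
        )

    # ------------------------------------------------ driver

    def run(self, stages: Optional[Sequence[str]] = None) -> Path:
        stages = list(stages) if stages else list(STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage in stages:
                getattr(self, f"run_{stage}")()
        return self.outdir


def run(config: RunConfig, outdir: str, stages: Optional[Sequence[str]] = None) -> Path:
    """Execute the requested stages (all by default) into ``outdir``."""
    return Pipeline(config, outdir).run(stages)
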