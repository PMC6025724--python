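"""Synthetic corpus generator.

Emulates the statistical structure the analysis assumes, so that every
pipeline stage can be exercised offline:

* gene models with log-normal exon/intron lengths on a handful of
  chromosomes, written as GFF3;
* a genome sequence with CG dinucleotides planted at the simulated CpG
  sites and TF-binding-motif instances embedded in first introns;
* bimodal per-CpG methylation (a near-0% / near-100% beta mixture), with
  hypomethylated promoters and first exons, and a planted monotone
  decreasing first-intron methylation vs expression-decile ramp
  (decile medians running from ``ramp_high`` down to ``ramp_low``);
* beta-binomial read counts per replicate at negative-binomial coverage,
  written in Bismark coverage format;
* negative-binomial RNA-seq counts with tissue effects and a fabricated
  differential-expression table;
* planted tissue-DMRs whose direction is coupled to the expression fold
  change, giving the negative- and positive-correlation quadrant sets.

Ground truth (true feature means, expression, planted DMRs and motif
instances) is written alongside as JSON.  Identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .features import GeneFeatureSet, GeneModel, derive_features
from .methylation import MethylationMatrix

# synthetic PFMs: consensus sequences with (motif_id, consensus); the four
# CpG-containing ones mimic the CREB1/ZBTB33/ZBTB7A/E2F4 class of motifs,
# the other two are CpG-free fillers.  Matrices are synthetic stand-ins,
# not database entries.
SYNTH_MOTIFS: dict[str, str] = {
    "SYN_CREB1": "TGACGTCA",
    "SYN_ZBTB33": "TCTCGCGAGA",
    "SYN_E2F4": "GGCGGGAA",
    "SYN_ZBTB7A": "AACCGCCA",
    "SYN_EBOX": "CAGCTG",
    "SYN_TATA": "TATAAATA",
}


@dataclass
class SynthConfig:
    """Study conditions of the synthetic corpus."""

    n_genes: int = 3000
    n_chroms: int = 5
    seed: int = 1
    tissues: tuple[str, str] = ("muscle", "testis")
    n_meth_replicates: int = 3
    n_rna_replicates: int = 4

    # gene geometry (lengths log-normal, counts Poisson)
    exon_count_mean: float = 5.0
    single_exon_frac: float = 0.08
    exon_len_log_mean: float = math.log(180.0)
    exon_len_log_sd: float = 0.5
    intron_len_log_mean: float = math.log(700.0)
    intron_len_log_sd: float = 0.9
    min_exon_len: int = 50
    min_intron_len: int = 150
    intergenic_gap: int = 9000

    # CpG sites per bp of feature
    cpg_density: dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.020,
            "first_exon": 0.030,
            "first_intron": 0.012,
            "rest_exons": 0.008,
            "rest_introns": 0.006,
        }
    )

    # methylation beta-mixture (percent scale); each gene carries a latent
    # body-methylation state so feature states within a gene are correlated
    meth_low_mean: float = 7.0
    meth_high_mean: float = 91.0
    gene_low_weight: float = 0.35
    #: P(feature in the low component | gene state low, gene state high);
    #: promoter and first exon instead share a 5' CGI state (below)
    cond_low_weight: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "first_intron": (0.90, 0.15),
            "rest_exons": (0.90, 0.05),
            "rest_introns": (0.90, 0.05),
        }
    )
    #: P(5' CGI unmethylated | gene state low, high); promoter and first
    #: exon follow this shared state with probability cgi_coupling each
    cgi_low_weight: tuple[float, float] = (0.95, 0.70)
    cgi_coupling: float = 0.95
    #: first-intron decile-median ramp (decile 1 -> 10); None = mixture like rest
    ramp_high: Optional[float] = 60.0
    ramp_low: Optional[float] = 10.0
    ramp_sd: float = 12.0
    kappa_gene: float = 60.0
    kappa_site: float = 50.0
    kappa_rep: float = 60.0

    # bisulfite coverage (negative binomial)
    coverage_mean: float = 30.0
    coverage_disp: float = 5.0

    # expression (log2 cpm scale) and counts (negative binomial)
    expr_log2_mean: float = 4.0
    expr_log2_sd: float = 2.2
    not_expressed_frac: float = 0.05
    tissue_specific_frac: float = 0.02
    count_dispersion: float = 0.1
    deg_frac: float = 0.15
    deg_lfc_mean: float = 2.5
    deg_lfc_sd: float = 0.8

    # planted tissue-DMRs
    dmr_gene_frac: float = 0.08
    dmr_n_cpg: int = 12
    dmr_site_spacing: int = 20
    dmr_delta: float = 40.0
    dmr_negative_frac: float = 0.6
    #: fraction of DMR host genes drawn from the differentially expressed set
    dmr_deg_frac: float = 0.7

    # motif planting in first introns
    motif_frac: float = 0.30

    def validate(self) -> None:
        for name, (lo, hi) in self.cond_low_weight.items():
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError(f"cond_low_weight[{name}] outside [0,1]")
        if not 0 <= self.gene_low_weight <= 1:
            raise ValueError("gene_low_weight outside [0,1]")
        for name, v in self.cpg_density.items():
            if v < 0:
                raise ValueError(f"cpg_density[{name}] negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


# ------------------------------------------------------------------ helpers

def _beta_pct(rng: np.random.Generator, mean_pct: np.ndarray | float, kappa: float,
              size=None) -> np.ndarray:
    """Beta draw on the percent scale with given mean and concentration."""
    m = np.clip(np.asarray(mean_pct, dtype=float) / 100.0, 1e-3, 1 - 1e-3)
    a = m * kappa
    b = (1 - m) * kappa
    return 100.0 * rng.beta(a, b, size=size)


def _nbinom(rng: np.random.Generator, mean, disp, size=None) -> np.ndarray:
    """Negative binomial with mean ``mean`` and size parameter ``disp``."""
    mean = np.asarray(mean, dtype=float)
    p = disp / (disp + np.maximum(mean, 1e-12))
    return rng.negative_binomial(disp, p, size=size)


# ------------------------------------------------------------------ generator

class SynthCorpus:
    """In-memory synthetic corpus; see :func:`generate` for the file form."""

    def __init__(self, config: SynthConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.genes: list[GeneModel] = []
        self.features: list[GeneFeatureSet] = []
        self.truth: dict = {}
        self.sites: pd.DataFrame = pd.DataFrame()
        self.site_truth: dict[str, np.ndarray] = {}
        self.genome: dict[str, np.ndarray] = {}
        self.meth_samples: dict[str, str] = {}
        self.rna_samples: dict[str, str] = {}
        self._build()

    # -------------------------------------------------- geometry

    def _build_geometry(self) -> None:
        cfg, rng = self.config, self.rng
        cursors = {f"chr{i+1}": cfg.intergenic_gap for i in range(cfg.n_chroms)}
        for gi in range(cfg.n_genes):
            chrom = f"chr{gi % cfg.n_chroms + 1}"
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < cfg.single_exon_frac:
                n_exons = 1
            else:
                n_exons = 2 + int(rng.poisson(max(cfg.exon_count_mean - 2, 0.1)))
            exon_lens = np.maximum(
                cfg.min_exon_len,
                rng.lognormal(cfg.exon_len_log_mean, cfg.exon_len_log_sd, n_exons).astype(int),
            )
            intron_lens = np.maximum(
                cfg.min_intron_len,
                rng.lognormal(cfg.intron_len_log_mean, cfg.intron_len_log_sd,
                              max(n_exons - 1, 0)).astype(int),
            )
            start = cursors[chrom]
            exons = []
            pos = start
            for i in range(n_exons):
                exons.append((pos, pos + int(exon_lens[i])))
                pos += int(exon_lens[i])
                if i < n_exons - 1:
                    pos += int(intron_lens[i])
            cursors[chrom] = pos + cfg.intergenic_gap
            self.genes.append(
                GeneModel(f"gene{gi:05d}", chrom, strand, exons)
            )
        self.chrom_lengths = {c: cur + cfg.intergenic_gap for c, cur in cursors.items()}
        for g in self.genes:
            g.chrom_length = self.chrom_lengths[g.chrom]
        self.features = [derive_features(g) for g in self.genes]

    # -------------------------------------------------- expression

    def _build_expression(self) -> None:
        cfg, rng = self.config, self.rng
        n = cfg.n_genes
        base = rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sd, n)
        base = np.clip(base, 0.1, None)
        status = np.full(n, "both", dtype=object)
        u = rng.random(n)
        status[u < cfg.not_expressed_frac] = "off"
        lo = cfg.not_expressed_frac
        status[(u >= lo) & (u < lo + cfg.tissue_specific_frac)] = cfg.tissues[0]
        lo += cfg.tissue_specific_frac
        status[(u >= lo) & (u < lo + cfg.tissue_specific_frac)] = cfg.tissues[1]

        is_deg = rng.random(n) < cfg.deg_frac
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        delta = np.where(
            is_deg,
            sign * np.maximum(rng.normal(cfg.deg_lfc_mean, cfg.deg_lfc_sd, n), 1.6),
            rng.normal(0.0, 0.15, n),
        )
        ta, tb = cfg.tissues
        log2cpm = {
            ta: np.where(np.isin(status, ["off", tb]), -np.inf, base - delta / 2),
            tb: np.where(np.isin(status, ["off", ta]), -np.inf, base + delta / 2),
        }
        self.expr_truth = {
            "base": base, "status": status, "delta": delta, "is_deg": is_deg,
            "log2cpm": log2cpm,
        }
        # truth deciles per tissue among expressed genes
        self.decile_truth = {}
        for t in cfg.tissues:
            vals = log2cpm[t]
            expressed = np.isfinite(vals)
            idx = np.nonzero(expressed)[0]
            order = idx[np.lexsort((idx, vals[idx]))]
            dec = np.full(n, np.nan)
            m = len(order)
            dec[order] = (np.arange(m) * 10) // m + 1
            self.decile_truth[t] = dec

    # -------------------------------------------------- methylation truth

    def _feature_mean(self, feat: str, gi: int, tissue: str, gene_low: bool,
                      cgi_low: bool) -> float:
        cfg, rng = self.config, self.rng
        if feat == "first_intron" and cfg.ramp_high is not None:
            d = self.decile_truth[tissue][gi]
            if np.isnan(d):
                d = 1.0
            m = cfg.ramp_high - (d - 1) * (cfg.ramp_high - cfg.ramp_low) / 9.0
            return float(np.clip(m + rng.normal(0, cfg.ramp_sd), 1.0, 99.0))
        if feat in ("promoter", "first_exon"):
            # both 5' features track the shared CGI state of the gene
            low = cgi_low if rng.random() < cfg.cgi_coupling else not cgi_low
        else:
            w_lo, w_hi = cfg.cond_low_weight.get(feat, (0.9, 0.05))
            low = rng.random() < (w_lo if gene_low else w_hi)
        mean = cfg.meth_low_mean if low else cfg.meth_high_mean
        return float(_beta_pct(rng, mean, cfg.kappa_gene))

    def _build_methylation(self) -> None:
        cfg, rng = self.config, self.rng
        ta, tb = cfg.tissues
        n = cfg.n_genes

        multi = [i for i, fs in enumerate(self.features) if fs.first_intron is not None]
        n_dmr = int(round(cfg.dmr_gene_frac * len(multi)))
        # tissue-DMRs accompany differential expression: draw most DMR hosts
        # from the differentially expressed genes
        deg_multi = [i for i in multi if self.expr_truth["is_deg"][i]]
        other_multi = [i for i in multi if not self.expr_truth["is_deg"][i]]
        n_deg_hosts = min(len(deg_multi), int(round(cfg.dmr_deg_frac * n_dmr)))
        dmr_genes: set[int] = set()
        if n_deg_hosts:
            dmr_genes |= set(rng.choice(deg_multi, size=n_deg_hosts, replace=False).tolist())
        n_rest = min(len(other_multi), n_dmr - n_deg_hosts)
        if n_rest > 0:
            dmr_genes |= set(rng.choice(other_multi, size=n_rest, replace=False).tolist())

        site_rows: list[tuple[str, int, int, str]] = []  # chrom, pos, gene idx, feature
        mean_rows = []
        site_pct = {ta: [], tb: []}
        dmr_truth = []

        feature_order = ("promoter", "first_exon", "first_intron", "rest_exons", "rest_introns")
        for gi, fs in enumerate(self.features):
            gene_low = rng.random() < cfg.gene_low_weight
            w_cgi = cfg.cgi_low_weight[0] if gene_low else cfg.cgi_low_weight[1]
            cgi_low = rng.random() < w_cgi
            gene_sites: dict[str, list[int]] = {}
            for feat in feature_order:
                ivs = fs.intervals(feat)
                positions: list[int] = []
                for (s, e) in ivs:
                    length = e - s
                    if length < 4:
                        continue
                    k = int(round(length * cfg.cpg_density.get(feat, 0.008)))
                    if feat in ("promoter", "first_exon", "first_intron"):
                        k = max(k, 1)
                    if k == 0:
                        continue
                    grid = np.arange(s, e - 2, 4)
                    if len(grid) == 0:
                        continue
                    k = min(k, len(grid))
                    chosen = np.sort(rng.choice(grid, size=k, replace=False))
                    positions.extend(int(p) for p in chosen)
                gene_sites[feat] = positions

            # planted DMR: dense run of sites at a random spot in the first intron
            if gi in dmr_genes and fs.first_intron is not None:
                s, e = fs.first_intron
                span = (cfg.dmr_n_cpg - 1) * cfg.dmr_site_spacing + 2
                if e - s > span + 4:
                    start = int(s + rng.integers(0, e - s - span - 2))
                    run = [start + j * cfg.dmr_site_spacing for j in range(cfg.dmr_n_cpg)]
                    run_set = set(run)
                    gene_sites["first_intron"] = sorted(
                        run_set | {p for p in gene_sites["first_intron"]
                                   if all(abs(p - q) >= 4 for q in run)}
                    )
                    dmr_truth.append(
                        {"gene": fs.gene_id, "chrom": fs.chrom, "start": run[0],
                         "end": run[-1] + 2, "sites": run, "feature": "first_intron"}
                    )
                else:
                    dmr_genes.discard(gi)

            # tissue deltas for DMR genes are applied to the run sites below
            delta_fc = self.expr_truth["delta"][gi]
            if gi in dmr_genes:
                if self.expr_truth["is_deg"][gi]:
                    if rng.random() < cfg.dmr_negative_frac:
                        md = -np.sign(delta_fc) * (18 + 10 * abs(delta_fc) + rng.normal(0, 8))
                    else:
                        md = np.sign(delta_fc) * (18 + 4 * abs(delta_fc) + rng.normal(0, 10))
                    md = float(np.clip(md, -80, 80))
                    if abs(md) < 18:
                        md = 18.0 * np.sign(md) if md != 0 else 18.0
                else:
                    md = float(cfg.dmr_delta * (1 if rng.random() < 0.5 else -1))
                dmr_truth[-1]["mean_diff"] = md
            run_sites = set(dmr_truth[-1]["sites"]) if gi in dmr_genes else set()

            for feat in feature_order:
                positions = gene_sites.get(feat, [])
                if not positions:
                    continue
                m_a = self._feature_mean(feat, gi, ta, gene_low, cgi_low)
                m_b_base = (
                    self._feature_mean(feat, gi, tb, gene_low, cgi_low)
                    if feat == "first_intron" and cfg.ramp_high is not None
                    else m_a
                )
                pa = _beta_pct(rng, m_a, cfg.kappa_site, size=len(positions))
                if feat == "first_intron" and cfg.ramp_high is not None:
                    pb = _beta_pct(rng, m_b_base, cfg.kappa_site, size=len(positions))
                else:
                    pb = pa + rng.normal(0, 2.0, size=len(positions))
                pb = np.clip(pb, 0.2, 99.8)
                if run_sites and feat == "first_intron":
                    md = dmr_truth[-1]["mean_diff"]
                    for j, p in enumerate(positions):
                        if p in run_sites:
                            base_a = float(np.clip(50 - md / 2 + rng.normal(0, 5), 1, 99))
                            pa[j] = base_a
                            pb[j] = float(np.clip(base_a + md + rng.normal(0, 3), 0.2, 99.8))
                for j, p in enumerate(positions):
                    site_rows.append((fs.chrom, p, gi, feat))
                    site_pct[ta].append(float(pa[j]))
                    site_pct[tb].append(float(pb[j]))
                mean_rows.append((fs.gene_id, feat, float(np.mean(pa)), float(np.mean(pb))))

        sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "gene_index", "feature"])
        sites["pct_a"] = site_pct[ta]
        sites["pct_b"] = site_pct[tb]
        # de-duplicate overlapping sites (promoters can overlap neighbours)
        sites = sites.drop_duplicates(subset=["chrom", "pos"], keep="first")
        sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.sites = sites
        self.feature_mean_truth = pd.DataFrame(
            mean_rows, columns=["gene_id", "feature", f"mean_{ta}", f"mean_{tb}"]
        )
        self.dmr_truth = dmr_truth

    # -------------------------------------------------- sequence + motifs

    def _build_sequence(self) -> None:
        cfg, rng = self.config, self.rng
        base_probs = np.array([0.3, 0.2, 0.2, 0.3])
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        self.genome = {
            c: alphabet[rng.choice(4, size=length, p=base_probs)]
            for c, length in sorted(self.chrom_lengths.items())
        }

        # motif instances in first introns, biased toward the intron start in
        # high-expression genes, with the motif CpG methylation increasing
        # with the relative planting position
        ta, tb = cfg.tissues
        cpg_motifs = [m for m in SYNTH_MOTIFS if "CG" in SYNTH_MOTIFS[m]]
        base_expr = self.expr_truth["base"]
        expr_med = float(np.median(base_expr))
        motif_truth = []
        extra_sites = []
        forbidden: dict[str, list[tuple[int, int]]] = {}
        for gi, fs in enumerate(self.features):
            if fs.first_intron is None or rng.random() > cfg.motif_frac:
                continue
            s, e = fs.first_intron
            motif_id = cpg_motifs[int(rng.integers(len(cpg_motifs)))]
            cons = SYNTH_MOTIFS[motif_id]
            w = len(cons)
            if e - s < w + 8:
                continue
            hi = base_expr[gi] >= expr_med
            u = float(rng.beta(1.5, 5.0) if hi else rng.beta(5.0, 1.5))
            if fs.strand == "+":
                off = int(s + round(u * (e - s - w)))
            else:
                off = int(e - w - round(u * (e - s - w)))
            seq = self.genome[fs.chrom]
            seq[off:off + w] = np.frombuffer(cons.encode(), dtype=np.uint8)
            cg_idx = cons.find("CG")
            cpg_pos = off + cg_idx
            meth = float(np.clip(5 + 85 * u + rng.normal(0, 8), 0.5, 99.5))
            extra_sites.append((fs.chrom, cpg_pos, gi, "first_intron", meth))
            motif_truth.append(
                {"gene": fs.gene_id, "motif": motif_id, "offset": off,
                 "cpg_pos": cpg_pos, "rel_pos": u, "meth": meth}
            )
            forbidden.setdefault(fs.chrom, []).append((off - 1, off + w))

        # drop regular sites whose CG would overwrite a planted motif instance
        if forbidden:
            keep = np.ones(len(self.sites), dtype=bool)
            for chrom, spans in forbidden.items():
                pos = self.sites["pos"].to_numpy(int)
                on_chrom = (self.sites["chrom"] == chrom).to_numpy()
                for (a, b) in spans:
                    keep &= ~(on_chrom & (pos >= a) & (pos < b))
            self.sites = self.sites.loc[keep].reset_index(drop=True)

        # plant CG at every registered site
        for chrom, grp in self.sites.groupby("chrom"):
            seq = self.genome[chrom]
            pos = grp["pos"].to_numpy(int)
            seq[pos] = ord("C")
            seq[pos + 1] = ord("G")

        if extra_sites:
            extra = pd.DataFrame(
                extra_sites, columns=["chrom", "pos", "gene_index", "feature", "pct_a"]
            )
            extra["pct_b"] = extra["pct_a"] + self.rng.normal(0, 2.0, len(extra))
            extra["pct_b"] = extra["pct_b"].clip(0.2, 99.8)
            merged = pd.concat([self.sites, extra], ignore_index=True)
            merged = merged.drop_duplicates(subset=["chrom", "pos"], keep="last")
            self.sites = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.motif_truth = motif_truth

    # -------------------------------------------------- reads & counts

    def _build_reads(self) -> None:
        cfg, rng = self.config, self.rng
        ta, tb = cfg.tissues
        n_sites = len(self.sites)
        truth_pct = {ta: self.sites["pct_a"].to_numpy(), tb: self.sites["pct_b"].to_numpy()}
        self.meth_calls: dict[str, pd.DataFrame] = {}
        for tissue in cfg.tissues:
            for r in range(cfg.n_meth_replicates):
                sample = f"{tissue}_meth_{r+1}"
                cov = np.maximum(_nbinom(rng, cfg.coverage_mean, cfg.coverage_disp, n_sites), 1)
                rep_p = _beta_pct(rng, truth_pct[tissue], cfg.kappa_rep) / 100.0
                meth = rng.binomial(cov, rep_p)
                self.meth_calls[sample] = pd.DataFrame(
                    {
                        "chrom": self.sites["chrom"],
                        "pos": self.sites["pos"],
                        "coverage": cov,
                        "meth_count": meth,
                        "percent": 100.0 * meth / cov,
                    }
                )
                self.meth_samples[sample] = tissue

        # RNA-seq counts: expected cpm = 2^log2cpm
        n = cfg.n_genes
        counts = {}
        for tissue in cfg.tissues:
            mu_cpm = np.where(
                np.isfinite(self.expr_truth["log2cpm"][tissue]),
                np.exp2(self.expr_truth["log2cpm"][tissue]), 0.0
            )
            total = mu_cpm.sum()
            for r in range(cfg.n_rna_replicates):
                sample = f"{tissue}_rna_{r+1}"
                lib = rng.uniform(0.8, 1.2) * 2e7
                mu = mu_cpm / max(total, 1.0) * lib
                c = np.where(mu > 0, _nbinom(rng, np.maximum(mu, 1e-9), 1.0 / cfg.count_dispersion, None), 0)
                counts[sample] = c
                self.rna_samples[sample] = tissue
        self.counts = pd.DataFrame(counts, index=[g.gene_id for g in self.genes])
        self.counts.index.name = "gene_id"

        # fabricated DEG table from the true tissue effects
        delta = self.expr_truth["delta"]
        is_deg = self.expr_truth["is_deg"]
        log2fc = delta + rng.normal(0, 0.05, n)
        fdr = np.where(
            is_deg, np.power(10.0, -rng.uniform(3, 9, n)), rng.uniform(0.1, 1.0, n)
        )
        self.deg = pd.DataFrame(
            {"gene_id": self.counts.index, "log2fc": log2fc, "fdr": fdr}
        )

    def _build(self) -> None:
        self._build_geometry()
        self._build_expression()
        self._build_methylation()
        self._build_sequence()
        self._build_reads()

    # -------------------------------------------------- convenience

    def methylation_matrix(self) -> MethylationMatrix:
        """United matrix of the simulated replicate calls (no coverage filter)."""
        from .methylation import unite

        return unite(self.meth_calls, self.meth_samples)

    def genome_strings(self) -> dict[str, str]:
        return {c: arr.tobytes().decode() for c, arr in self.genome.items()}


# ------------------------------------------------------------------ writers

def _write_gff3(corpus: SynthCorpus, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(corpus.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {corpus.chrom_lengths[chrom]}\n")
        for g in corpus.genes:
            s, e = g.gene_body
            fh.write(
                f"{g.chrom}\tsynth\tgene\t{s+1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsynth\tmRNA\t{s+1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tsynth\texon\t{xs+1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i+1};Parent={mrna}\n"
                )


def _write_fasta(corpus: SynthCorpus, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(corpus.genome):
            fh.write(f">{chrom}\n")
            seq = corpus.genome[chrom].tobytes().decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _write_bismark_cov(df: pd.DataFrame, path: Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"] + 1,
            "end": df["pos"] + 1,
            "percent": df["percent"].map(lambda v: f"{v:.6g}"),
            "count_m": df["meth_count"],
            "count_u": df["coverage"] - df["meth_count"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_pfm(path: Path, motifs: Optional[dict[str, str]] = None,
              match_count: int = 18, other_count: int = 1) -> None:
    """Write JASPAR-format PFMs built from consensus sequences."""
    motifs = motifs or SYNTH_MOTIFS
    with open(path, "w") as fh:
        for mid, cons in motifs.items():
            fh.write(f">{mid}\t{mid}\n")
            for base in "ACGT":
                row = [str(match_count) if c == base else str(other_count) for c in cons]
                fh.write(f"{base}  [ " + "  ".join(row) + " ]\n")


def generate(config: SynthConfig, outdir: str | os.PathLike) -> dict[str, object]:
    """Write the full corpus to ``outdir`` and return the file paths."""
    out = Path(outdir)
    (out / "meth").mkdir(parents=True, exist_ok=True)
    corpus = SynthCorpus(config)

    paths: dict[str, object] = {}
    paths["gff3"] = str(out / "annotation.gff3")
    _write_gff3(corpus, Path(paths["gff3"]))
    paths["fasta"] = str(out / "genome.fa")
    _write_fasta(corpus, Path(paths["fasta"]))

    meth_paths = {}
    for sample, df in corpus.meth_calls.items():
        p = out / "meth" / f"{sample}.cov"
        _write_bismark_cov(df, p)
        meth_paths[sample] = str(p)
    paths["meth"] = meth_paths

    paths["counts"] = str(out / "counts.tsv")
    corpus.counts.to_csv(paths["counts"], sep="\t")
    paths["deg"] = str(out / "deg.tsv")
    corpus.deg.to_csv(paths["deg"], sep="\t", index=False, float_format="%.6g")
    paths["pwms"] = str(out / "motifs.pfm")
    write_pfm(Path(paths["pwms"]))

    ta, tb = config.tissues
    truth = {
        "config": {k: v for k, v in asdict(config).items() if not isinstance(v, dict)},
        "genes": [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "n_exons": len(g.exons),
                "base_log2cpm": float(corpus.expr_truth["base"][i]),
                "delta_log2fc": float(corpus.expr_truth["delta"][i]),
                "is_deg": bool(corpus.expr_truth["is_deg"][i]),
                "status": str(corpus.expr_truth["status"][i]),
                "decile": {
                    t: (None if np.isnan(corpus.decile_truth[t][i])
                        else int(corpus.decile_truth[t][i]))
                    for t in config.tissues
                },
            }
            for i, g in enumerate(corpus.genes)
        ],
        "feature_means": corpus.feature_mean_truth.to_dict(orient="records"),
        "dmrs": corpus.dmr_truth,
        "motifs": corpus.motif_truth,
    }
    paths["truth"] = str(out / "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)

    # paths inside the config are relative to the corpus directory, so the
    # corpus is relocatable and byte-identical across output locations
    run_cfg = {
        "annotation": "annotation.gff3",
        "fasta": "genome.fa",
        "methylation": {s: f"meth/{s}.cov" for s in meth_paths},
        "meth_dialect": "bismark_cov",
        "counts": "counts.tsv",
        "deg": "deg.tsv",
        "pwms": "motifs.pfm",
        "meth_tissue_map": corpus.meth_samples,
        "rna_tissue_map": corpus.rna_samples,
        "tissue_a": ta,
        "tissue_b": tb,
        "seed": config.seed,
    }
    paths["config"] = str(out / "config.yaml")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return paths


# ------------------------------------------------------------------ focused simulators

def simulate_null_matrix(
    n_sites: int,
    n_replicates: int = 3,
    coverage_mean: float = 30.0,
    kappa_rep: float = 60.0,
    seed: int = 0,
    meth_low: float = 8.0,
    meth_high: float = 85.0,
    low_weight: float = 0.5,
) -> MethylationMatrix:
    """Two tissues drawn from identical per-site beta-binomials (null)."""
    rng = np.random.default_rng(seed)
    mix = rng.random(n_sites) < low_weight
    truth = np.where(mix, meth_low, meth_high)
    truth = _beta_pct(rng, truth, 60.0)
    data = {}
    tissue_map = {}
    for tissue in ("A", "B"):
        for r in range(n_replicates):
            sample = f"{tissue}{r+1}"
            cov = np.maximum(_nbinom(rng, coverage_mean, 5.0, n_sites), 1)
            p = _beta_pct(rng, truth, kappa_rep) / 100.0
            m = rng.binomial(cov, p)
            data[f"percent_{sample}"] = 100.0 * m / cov
            data[f"cov_{sample}"] = cov.astype(float)
            tissue_map[sample] = tissue
    idx = pd.MultiIndex.from_arrays(
        [np.repeat("chr1", n_sites), np.arange(n_sites) * 50], names=["chrom", "pos"]
    )
    return MethylationMatrix(pd.DataFrame(data, index=idx), list(tissue_map), tissue_map)


def simulate_planted_dmc_matrix(
    n_sites: int,
    planted_frac: float = 0.1,
    delta: float = 40.0,
    n_replicates: int = 3,
    coverage_mean: float = 30.0,
    kappa_rep: float = 60.0,
    seed: int = 0,
) -> tuple[MethylationMatrix, np.ndarray]:
    """Null sites plus a planted fraction with a fixed tissue difference."""
    rng = np.random.default_rng(seed)
    truth_a = _beta_pct(rng, np.where(rng.random(n_sites) < 0.5, 10.0, 80.0), 60.0)
    planted = rng.random(n_sites) < planted_frac
    sign = np.where(truth_a < 50, 1.0, -1.0)
    truth_b = np.where(planted, np.clip(truth_a + sign * delta, 0.5, 99.5), truth_a)
    data = {}
    tissue_map = {}
    for tissue, truth in (("A", truth_a), ("B", truth_b)):
        for r in range(n_replicates):
            sample = f"{tissue}{r+1}"
            cov = np.maximum(_nbinom(rng, coverage_mean, 5.0, n_sites), 1)
            p = _beta_pct(rng, truth, kappa_rep) / 100.0
            m = rng.binomial(cov, p)
            data[f"percent_{sample}"] = 100.0 * m / cov
            data[f"cov_{sample}"] = cov.astype(float)
            tissue_map[sample] = tissue
    idx = pd.MultiIndex.from_arrays(
        [np.repeat("chr1", n_sites), np.arange(n_sites) * 50], names=["chrom", "pos"]
    )
    return MethylationMatrix(pd.DataFrame(data, index=idx), list(tissue_map), tissue_map), planted


def simulate_motif_cpg_records(
    n: int = 150,
    effect: bool = True,
    slope: float = 3.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif-CpG records with (or without) a planted distance x status interaction.

    Under ``effect`` the methylated class loses expression with relative
    distance (slope per unit distance) and sits further from the intron
    start; under the null both classes are exchangeable.
    """
    rng = np.random.default_rng(seed)
    status = np.where(np.arange(n) % 2 == 0, "unmethylated", "methylated")
    if effect:
        dist = np.where(
            status == "unmethylated", rng.beta(1.5, 4.0, n), rng.beta(4.0, 1.5, n)
        )
        drop = np.where(status == "methylated", slope * dist, 0.0)
    else:
        dist = rng.uniform(0, 1, n)
        drop = 0.0
    log2cpm = 6.0 - drop + rng.normal(0, sigma, n)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "tissue": "sim",
            "relative_distance": dist,
            "meth_class": status,
            "log2cpm": log2cpm,
        }
    )
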