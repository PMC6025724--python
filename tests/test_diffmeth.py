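"""DMC testing, tDMR calling, feature overlap and quadrant analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intronmeth.diffmeth import (
    boundary_distance,
    call_tdmrs,
    overlap_tdmrs,
    quadrant_analysis,
)
from intronmeth.diffmeth import test_dmc as dmc_test
from intronmeth.features import GeneModel, derive_features
from intronmeth.methylation import MethylationMatrix


def make_matrix(meth_a, cov_a, meth_b, cov_b, positions=None):
    """Single-replicate two-tissue matrix from count vectors."""
    n = len(meth_a)
    positions = positions if positions is not None else np.arange(n) * 10
    data = {
        "percent_a1": 100.0 * np.asarray(meth_a) / np.asarray(cov_a),
        "cov_a1": np.asarray(cov_a, float),
        "percent_b1": 100.0 * np.asarray(meth_b) / np.asarray(cov_b),
        "cov_b1": np.asarray(cov_b, float),
    }
    idx = pd.MultiIndex.from_arrays([["chr1"] * n, positions], names=["chrom", "pos"])
    return MethylationMatrix(pd.DataFrame(data, index=idx), ["a1", "b1"],
                             {"a1": "A", "b1": "B"})


class TestDmc:
    def test_identical_proportions_null(self):
        m = make_matrix([50, 20], [100, 100], [50, 20], [100, 100])
        out = dmc_test(m, "A", "B")
        assert (out["meth_diff"] == 0).all()
        assert not out["is_dmc"].any()

    def test_lrt_matches_glm_oracle(self):
        """The closed-form likelihood-ratio statistic equals a binomial GLM
        (logistic regression of methylation on tissue) fit by IRLS."""
        import statsmodels.api as sm

        cases = [((95, 100), (5, 100)), ((30, 60), (45, 80)), ((10, 40), (12, 35))]
        m = make_matrix(
            [c[0][0] for c in cases], [c[0][1] for c in cases],
            [c[1][0] for c in cases], [c[1][1] for c in cases],
        )
        out = dmc_test(m, "A", "B")
        for i, ((ma, na), (mb, nb)) in enumerate(cases):
            endog = np.array([[ma, na - ma], [mb, nb - mb]])
            full = sm.GLM(endog, np.array([[1.0, 0.0], [1.0, 1.0]]),
                          family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.array([[1.0], [1.0]]),
                          family=sm.families.Binomial()).fit()
            lr_oracle = 2 * (full.llf - null.llf)
            assert out.loc[i, "lr_stat"] == pytest.approx(lr_oracle, rel=1e-6)
            assert out.loc[i, "p_value"] == pytest.approx(stats.chi2.sf(lr_oracle, 1), rel=1e-6)

    def test_small_difference_not_dmc(self):
        # 14.9-point difference stays below the 15-point cutoff no matter
        # how significant
        m = make_matrix([0, 500], [1000, 1000], [149, 500], [1000, 1000])
        out = dmc_test(m, "A", "B")
        assert out.loc[0, "meth_diff"] == pytest.approx(14.9)
        assert out.loc[0, "q_value"] < 1e-6
        assert not out.loc[0, "is_dmc"]

    def test_direction_convention(self):
        m = make_matrix([10], [100], [90], [100])
        out = dmc_test(m, "A", "B")
        assert out.loc[0, "meth_diff"] == pytest.approx(80.0)  # B minus A


def _dmc_frame(diffs, qs, positions, is_dmc=None):
    n = len(diffs)
    if is_dmc is None:
        is_dmc = (np.abs(diffs) > 15) & (np.asarray(qs) < 0.01)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": positions,
            "meth_diff": diffs,
            "p_value": np.asarray(qs) / 2,
            "q_value": qs,
            "is_dmc": is_dmc,
        }
    )


class TestTdmrs:
    def test_five_dmcs_form_region(self):
        df = _dmc_frame([30.0] * 5, [1e-8] * 5, np.arange(5) * 20)
        out = call_tdmrs(df)
        assert len(out) == 1
        assert out.loc[0, "direction"] == "hyper"
        assert out.loc[0, "n_cpg"] == 5
        assert out.loc[0, "start"] == 0 and out.loc[0, "end"] == 82

    def test_four_cpgs_rejected(self):
        df = _dmc_frame([30.0] * 4, [1e-8] * 4, np.arange(4) * 20)
        assert call_tdmrs(df).empty

    def test_two_dmcs_rejected(self):
        diffs = [30.0, 30.0, 1.0, 1.0, 1.0, 1.0]
        df = _dmc_frame(diffs, [1e-8] * 6, np.arange(6) * 20)
        assert call_tdmrs(df).empty

    def test_gap_splits_regions(self):
        pos = np.array([0, 20, 40, 60, 80, 500, 520, 540, 560, 580])
        df = _dmc_frame([30.0] * 10, [1e-9] * 10, pos)
        out = call_tdmrs(df, max_gap=100)
        assert len(out) == 2

    def test_emitted_regions_satisfy_filters(self):
        """Adversarial random tables never yield a region violating the
        count, difference and q-value criteria."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = 300
            pos = np.cumsum(rng.integers(5, 200, n))
            diffs = rng.uniform(-60, 60, n)
            qs = rng.uniform(0, 0.05, n)
            out = call_tdmrs(_dmc_frame(diffs, qs, pos))
            assert (out["n_cpg"] >= 5).all()
            assert (out["n_dmc"] >= 3).all()
            assert (out["mean_diff"].abs() > 15).all()
            assert (out["q_value"] < 0.001).all()


class TestOverlap:
    def _setup(self):
        g = GeneModel("g1", "chr1", "+", [(10000, 10200), (11000, 11200)],
                      chrom_length=10**6)
        return [g], [derive_features(g)]

    def _tdmr(self, start, end, diff=30.0):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [start], "end": [end], "n_cpg": [6],
             "n_dmc": [4], "mean_diff": [diff], "p_value": [1e-9],
             "q_value": [1e-6], "direction": ["hyper" if diff > 0 else "hypo"]}
        )

    def test_inside_first_intron(self):
        genes, feats = self._setup()
        ov = overlap_tdmrs(self._tdmr(10400, 10500), genes, feats)
        assert set(ov["overlap_class"]) == {"gene_flank", "first_intron"}

    def test_three_kb_upstream_only_flank(self):
        genes, feats = self._setup()
        ov = overlap_tdmrs(self._tdmr(7000, 7100), genes, feats)
        assert set(ov["overlap_class"]) == {"gene_flank"}

    def test_five_kb_upstream_no_class(self):
        genes, feats = self._setup()
        ov = overlap_tdmrs(self._tdmr(4000, 4100), genes, feats)
        assert ov.empty

    def test_counts_match_brute_force(self):
        """Overlap assignment equals a quadratic interval-intersection
        check on random instances."""
        rng = np.random.default_rng(17)
        genes, feats = [], []
        pos = 20000
        for i in range(15):
            exons = []
            p = pos
            for _ in range(int(rng.integers(1, 4))):
                exons.append((p, p + int(rng.integers(100, 300))))
                p = exons[-1][1] + int(rng.integers(200, 800))
            g = GeneModel(f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                          exons, chrom_length=10**7)
            genes.append(g)
            feats.append(derive_features(g))
            pos = p + int(rng.integers(1000, 12000))
        tdmrs = pd.concat(
            [self._tdmr(int(s), int(s + rng.integers(50, 3000)))
             for s in rng.integers(10000, pos, 40)],
            ignore_index=True,
        )
        ov = overlap_tdmrs(tdmrs, genes, feats)
        got = set(zip(ov["tdmr_index"], ov["gene_id"], ov["overlap_class"]))
        expected = set()
        from intronmeth.features import flank_window

        for ti, t in tdmrs.iterrows():
            for g, fs in zip(genes, feats):
                spans = {"gene_flank": [flank_window(g)]}
                for cls in ("promoter", "first_exon", "first_intron"):
                    spans[cls] = fs.intervals(cls)
                for cls, ivs in spans.items():
                    for (s, e) in ivs:
                        if t["start"] < e and s < t["end"]:
                            expected.add((ti, g.gene_id, cls))
        assert got == expected


class TestQuadrants:
    def _overlaps(self, rows):
        return pd.DataFrame(
            rows,
            columns=["tdmr_index", "chrom", "start", "end", "mean_diff",
                     "direction", "gene_id", "overlap_class"],
        )

    def _degs(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr"])
        df["significant"] = (df["log2fc"].abs() > 1.5) & (df["fdr"] < 0.05)
        return df

    def test_quadrant_labels(self):
        ov = self._overlaps(
            [(0, "chr1", 0, 10, -30.0, "hypo", "g1", "gene_flank"),
             (1, "chr1", 50, 60, -30.0, "hypo", "g2", "gene_flank")]
        )
        degs = self._degs([("g1", 2.0, 0.01), ("g2", -2.0, 0.01)])
        pairs, _ = quadrant_analysis(ov, degs)
        assert pairs.set_index("gene_id").loc["g1", "quadrant"] == "up+hypo"
        assert pairs.set_index("gene_id").loc["g1", "corr_set"] == "negative"
        assert pairs.set_index("gene_id").loc["g2", "quadrant"] == "down+hypo"
        assert pairs.set_index("gene_id").loc["g2", "corr_set"] == "positive"

    def test_insignificant_degs_excluded(self):
        ov = self._overlaps([(0, "chr1", 0, 10, 30.0, "hyper", "g1", "promoter")])
        degs = self._degs([("g1", 1.0, 0.01)])
        pairs, summary = quadrant_analysis(ov, degs)
        assert pairs.empty

    def test_planted_correlation_recovered(self):
        """A planted rho = -0.7 between fold change and methylation
        difference in the negative set is recovered within (-0.8, -0.6)."""
        rng = np.random.default_rng(23)
        n = 300
        lfc = rng.uniform(1.6, 6, n)
        # target correlation about -0.7 via noisy linear map
        diff = -(10 * lfc + rng.normal(0, 10.2 * np.std(lfc), n))
        diff = np.clip(diff, -80, -16)
        rows = [(i, "chr1", 0, 10, diff[i], "hypo", f"g{i}", "gene_flank")
                for i in range(n)]
        degs = self._degs([(f"g{i}", lfc[i], 1e-6) for i in range(n)])
        pairs, summary = quadrant_analysis(self._overlaps(rows), degs)
        rho = summary.set_index(["overlap_class", "corr_set"]).loc[
            ("gene_flank", "negative"), "rho"]
        assert -0.8 < rho < -0.6


class TestBoundaryDistance:
    def test_distances(self):
        gp = GeneModel("gp", "chr1", "+", [(1000, 2000), (12000, 13000)])
        gm = GeneModel("gm", "chr1", "-", [(21000, 22000), (32000, 33000)])
        feats = [derive_features(gp), derive_features(gm)]
        ov = pd.DataFrame(
            [
                (0, "chr1", 2000, 2100, 30.0, "hyper", "gp", "first_intron"),
                (1, "chr1", 6500, 7500, 30.0, "hyper", "gp", "first_intron"),
                (2, "chr1", 31900, 32000, 30.0, "hyper", "gm", "first_intron"),
            ],
            columns=["tdmr_index", "chrom", "start", "end", "mean_diff",
                     "direction", "gene_id", "overlap_class"],
        )
        out = boundary_distance(ov, feats).set_index("tdmr_index")
        assert out.loc[0, "distance_bp"] == 0
        assert out.loc[1, "relative_distance"] == pytest.approx(0.45)
        # minus strand: measured from the genomic end of the intron
        assert out.loc[2, "distance_bp"] == 0
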