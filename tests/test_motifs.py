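"""PWM parsing/scanning, shuffling, enrichment and the CpG ANCOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from intronmeth.motifs import (
    PWM,
    ancova_expression,
    average_odds_score,
    classify_motif_cpgs,
    dinucleotide_counts,
    dinucleotide_shuffle,
    enrich_motifs,
    filter_cpg_motifs,
    intersect_tissues,
    read_jaspar_pfm,
    relative_distance,
    revcomp,
    scan_pwm,
    LATTICE_SCALE,
)
from intronmeth.synth import simulate_motif_cpg_records, write_pfm

BASES = "ACGT"


def make_pwm(consensus, match=18, other=1, bg=None):
    counts = np.array(
        [[match if c == b else other for c in consensus] for b in BASES], float
    )
    return PWM("M1", "M1", counts, background=bg if bg is not None else np.full(4, 0.25))


class TestJaspar:
    def test_pseudocount_arithmetic(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(">M1 M1\nA [ 10 ]\nC [ 0 ]\nG [ 0 ]\nT [ 10 ]\n")
        (pwm,) = read_jaspar_pfm(p, pseudocount=1.0)
        assert pwm.probs[:, 0] == pytest.approx([11 / 24, 1 / 24, 1 / 24, 11 / 24])

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.pfm"
        p.write_text("")
        assert read_jaspar_pfm(p) == []

    def test_too_wide_rejected(self, tmp_path):
        p = tmp_path / "wide.pfm"
        width = 32
        p.write_text(
            ">W W\n" + "\n".join(f"{b} [ " + " ".join(["5"] * width) + " ]" for b in BASES)
        )
        with pytest.raises(ValueError):
            read_jaspar_pfm(p)

    def test_synth_pfm_roundtrip(self, tmp_path):
        p = tmp_path / "synth.pfm"
        write_pfm(p)
        pwms = read_jaspar_pfm(p)
        assert {m.motif_id for m in pwms} >= {"SYN_CREB1", "SYN_TATA"}
        creb = next(m for m in pwms if m.motif_id == "SYN_CREB1")
        assert creb.consensus == "TGACGTCA"


class TestScan:
    @pytest.mark.parametrize("consensus", ["ACGT", "TGACGT", "GGCGGGAA"])
    def test_pvalues_match_exhaustive_enumeration(self, consensus):
        """Score p-values from the lattice DP equal brute-force enumeration
        of all 4^w words under the background."""
        rng = np.random.default_rng(1)
        bgv = np.array([0.3, 0.2, 0.2, 0.3])
        counts = rng.integers(0, 20, size=(4, len(consensus))).astype(float)
        pwm = PWM("X", "X", counts, background=bgv)
        w = pwm.width
        # oracle: enumerate every word, accumulate background probability
        word_scores = []
        word_probs = []
        for word in itertools.product(range(4), repeat=w):
            s = sum(int(pwm.lattice[b, j]) for j, b in enumerate(word))
            pr = float(np.prod([bgv[b] for b in word]))
            word_scores.append(s)
            word_probs.append(pr)
        word_scores = np.array(word_scores)
        word_probs = np.array(word_probs)
        for s in np.unique(word_scores)[:: max(1, len(word_scores) // 64)]:
            oracle_p = word_probs[word_scores >= s].sum()
            assert pwm.score_pvalue(int(s)) == pytest.approx(oracle_p, abs=1e-12)

    def test_consensus_is_best_hit(self):
        pwm = make_pwm("TGACGTCA")
        seq = "AATT" + "TGACGTCA" + "TTAA"
        hits = scan_pwm(seq, pwm, p_thresh=1e-3)
        assert any(h.offset == 4 and h.strand == "+" for h in hits)
        best = max(hits, key=lambda h: h.score)
        assert best.offset == 4
        assert best.score == pytest.approx(pwm.lattice[:, 0].max() * 0 +
                                           sum(pwm.lattice[np.argmax(pwm.probs[:, j]), j]
                                               for j in range(pwm.width)) / LATTICE_SCALE)

    def test_reverse_complement_symmetry(self):
        # non-palindromic consensus so the strands are distinguishable
        pwm = make_pwm("GGCGGGAA")
        fwd_seq = "AATT" + "GGCGGGAA" + "TTAA"
        rc_seq = "AATT" + revcomp("GGCGGGAA") + "TTAA"
        fwd_hits = scan_pwm(fwd_seq, pwm, both_strands=True, p_thresh=1e-3)
        rc_hits = scan_pwm(rc_seq, pwm, both_strands=True, p_thresh=1e-3)
        assert fwd_hits and rc_hits
        assert max(h.score for h in rc_hits) == pytest.approx(
            max(h.score for h in fwd_hits))
        best = max(rc_hits, key=lambda h: h.score)
        assert best.strand == "-"

    def test_all_n_sequence_has_no_hits(self):
        pwm = make_pwm("ACGT")
        assert scan_pwm("N" * 30, pwm, p_thresh=0.99) == []

    def test_short_window_no_hits(self):
        pwm = make_pwm("ACGTACGT")
        assert scan_pwm("ACG", pwm, p_thresh=0.99) == []


class TestShuffle:
    def test_dinucleotide_counts_preserved(self):
        """The Eulerian shuffle preserves the exact dinucleotide count
        vector (and endpoints) for 1000 random sequences."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(2, 60))
            seq = "".join(rng.choice(list("ACGT"), n))
            sh = dinucleotide_shuffle(seq, rng)
            assert dinucleotide_counts(sh) == dinucleotide_counts(seq)
            assert sh[0] == seq[0] and sh[-1] == seq[-1]

    def test_homopolymer_fixed_point(self):
        rng = np.random.default_rng(0)
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"

    def test_actually_shuffles(self):
        rng = np.random.default_rng(0)
        seq = "ACGTACGTACGTAAGGTTCCACGT" * 3
        outs = {dinucleotide_shuffle(seq, rng) for _ in range(20)}
        assert len(outs) > 1


class TestEnrichment:
    def _windows(self, rng, n, planted_frac=0.0, consensus="TGACGTCA", length=60):
        out = []
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), length, p=[0.3, 0.2, 0.2, 0.3]))
            if rng.random() < planted_frac:
                off = int(rng.integers(0, length - len(consensus)))
                seq = seq[:off] + consensus + seq[off + len(consensus):]
            out.append(seq)
        return out

    def test_planted_motif_enriched(self):
        rng = np.random.default_rng(8)
        windows = self._windows(rng, 100, planted_frac=0.8)
        pwms = [make_pwm("TGACGTCA"), make_pwm("TATAAATA")]
        res = enrich_motifs(windows, pwms, seed=1).set_index("motif_id")
        assert bool(res.loc["M1", "enriched"].iloc[0] if hasattr(res.loc["M1", "enriched"], "iloc") else res.loc["M1", "enriched"])

    def test_identical_inputs_and_controls_null(self):
        rng = np.random.default_rng(9)
        windows = self._windows(rng, 60)
        pwms = [make_pwm("TGACGTCA")]
        res = enrich_motifs(windows, pwms, controls=list(windows), seed=1)
        assert not res["enriched"].any()
        assert (res["p_adj"] > 0.5).all()

    def test_bonferroni_over_motifs(self):
        rng = np.random.default_rng(10)
        windows = self._windows(rng, 40, planted_frac=0.9)
        pwms = [make_pwm("TGACGTCA")] + [
            make_pwm("".join(rng.choice(list("ACGT"), 8))) for _ in range(19)
        ]
        res = enrich_motifs(windows, pwms, seed=2)
        target = res.iloc[0]
        assert target["p_adj"] == pytest.approx(min(1.0, target["p_split_adj"] * 20))


def test_intersect_and_cpg_filter():
    def res(ids, flags):
        return pd.DataFrame({"motif_id": ids, "enriched": flags})

    a = res(["A", "B", "C"], [True, True, True])
    b = res(["B", "C", "D"], [True, True, True])
    common = intersect_tissues(a, b)
    assert common == ["B", "C"]
    pwms = [make_pwm("TGACGTCA"), make_pwm("TTTTT")]
    pwms[0].motif_id, pwms[1].motif_id = "B", "C"
    assert filter_cpg_motifs(common, pwms) == ["B"]


class TestClassify:
    def test_quartile_classes(self):
        df = pd.DataFrame(
            {"tissue": "m", "percent": [0.0, 10.0, 50.0, 90.0, 100.0]}
        )
        out = classify_motif_cpgs(df)
        assert list(out["meth_class"]) == [
            "unmethylated", "intermediate", "intermediate", "intermediate", "methylated"
        ]

    def test_too_few_cpgs(self):
        df = pd.DataFrame({"tissue": "m", "percent": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            classify_motif_cpgs(df)


class TestRelativeDistance:
    def test_plus_strand(self):
        assert relative_distance(1000, (1000, 2000), "+") == 0.0
        assert relative_distance(1500, (1000, 2000), "+") == 0.5

    def test_minus_strand_mirror(self):
        assert relative_distance(1999, (1000, 2000), "-") == 0.0
        assert relative_distance(1900, (1000, 2000), "-") == pytest.approx(0.1, abs=2e-3)

    def test_outside_errors(self):
        with pytest.raises(ValueError):
            relative_distance(2500, (1000, 2000), "+")


class TestAncova:
    def test_orthogonal_design_sequential_equals_marginal(self):
        """In a perfectly balanced orthogonal design the sequential SS of
        each term equals its marginal SS (order does not matter)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        dist = np.tile([0.25, 0.75], 40)
        status = np.repeat(["unmethylated", "methylated"], 40)
        rng = np.random.default_rng(2)
        y = rng.normal(5, 1, 80)
        df = pd.DataFrame({"relative_distance": dist, "meth_class": status, "log2cpm": y})
        table, _ = ancova_expression(df)
        # marginal: refit with reversed order
        model = smf.ols("log2cpm ~ C(meth_class) * relative_distance", data=df).fit()
        rev = sm.stats.anova_lm(model, typ=1)
        assert table.loc["relative_distance", "sum_sq"] == pytest.approx(
            rev.loc["relative_distance", "sum_sq"])
        assert table.loc["meth_status", "sum_sq"] == pytest.approx(
            rev.loc["C(meth_class)", "sum_sq"])

    def test_planted_interaction_detected(self):
        df = simulate_motif_cpg_records(n=150, effect=True, seed=0)
        table, shapiro_p = ancova_expression(df)
        assert table.loc["interaction", "PR(>F)"] < 0.05
        assert table.loc["residuals", "df"] == len(df) - 4

    def test_single_class_errors(self):
        df = simulate_motif_cpg_records(n=40, effect=False, seed=4)
        df["meth_class"] = "methylated"
        with pytest.raises(ValueError):
            ancova_expression(df)
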