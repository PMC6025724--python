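"""TF-binding-motif analysis of first-intron CpGs.

A position frequency matrix (JASPAR text format) is turned into a
pseudocount-smoothed probability matrix and a log-odds matrix against a
strand-symmetric background.  Scanning reports hits whose score p-value —
computed exactly by dynamic programming over the integer-quantized score
lattice — falls below 1e-4, the conventional scanning threshold.

Enrichment follows the shuffled-control design: each input window is paired
with dinucleotide-preserving shuffles (Altschul-Erickson Eulerian-path
shuffle), sequences are scored by their average odds score, a
positive/negative split threshold is optimized over score ranks, and the
2x2 input/control x positive/negative table is tested by a one-sided
Fisher's exact test, Bonferroni-corrected over the splits tested and over
motifs.

The downstream CpG analysis classifies motif CpGs as unmethylated (below
the first quartile of the analyzed set) or methylated (above the third
quartile), measures their relative distance from the first exon-first
intron boundary, and tests distance x methylation-status effects on host
gene expression by ANCOVA with sequential (Type-I) sums of squares.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .constants import CPG_WINDOW, ENRICH_P, MAX_MOTIF_WIDTH, MOTIF_HIT_P
from .features import GeneFeatureSet

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: integer lattice resolution for exact score p-values (log2-odds * SCALE)
LATTICE_SCALE = 1000


def encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes (A=0..T=3, anything else = 4)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A TF-binding motif with smoothed probabilities and log-odds scores."""

    motif_id: str
    name: str
    counts: np.ndarray  # 4 x width, rows ACGT
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: PFM must have 4 rows")
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()
        smoothed = self.counts + self.pseudocount
        self.probs = smoothed / smoothed.sum(axis=0, keepdims=True)
        self.log_odds = np.log2(self.probs / self.background[:, None])
        # integer lattice used for the exact score distribution
        self.lattice = np.rint(self.log_odds * LATTICE_SCALE).astype(np.int64)
        self._sf: Optional[tuple[int, np.ndarray]] = None

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    def reverse_complement(self) -> "PWM":
        rc = PWM(
            self.motif_id,
            self.name,
            self.counts[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )
        return rc

    # -------------------------------------------------- exact p-values

    def _score_distribution(self) -> tuple[int, np.ndarray]:
        """Exact distribution of the lattice score under the background.

        Returns (minimum achievable score, survival array) where
        survival[s - minimum] = P(score >= s).
        """
        if self._sf is not None:
            return self._sf
        lo = self.lattice
        mins = lo.min(axis=0)
        maxs = lo.max(axis=0)
        total_min, total_max = int(mins.sum()), int(maxs.sum())
        size = total_max - total_min + 1
        dist = np.zeros(size)
        # probabilities over partial sums, offset by the partial minimum
        dist[0] = 1.0
        cur_min = 0
        cur_len = 1
        for j in range(self.width):
            col = lo[:, j]
            new_min = cur_min + int(col.min())
            new_len = cur_len + int(col.max() - col.min())
            new = np.zeros(size)
            for b in range(4):
                shift = int(col[b]) - (new_min - cur_min)
                new[shift:shift + cur_len] += self.background[b] * dist[:cur_len]
            dist = new
            cur_min, cur_len = new_min, new_len
        sf = np.cumsum(dist[::-1])[::-1]
        self._sf = (total_min, sf)
        return self._sf

    def score_pvalue(self, lattice_score: int) -> float:
        """P(background score >= lattice_score), exact on the lattice."""
        total_min, sf = self._score_distribution()
        idx = int(lattice_score) - total_min
        if idx < 0:
            return 1.0
        if idx >= len(sf):
            return 0.0
        return float(sf[idx])

    def lattice_threshold(self, p_thresh: float) -> int:
        """Smallest lattice score whose p-value is below ``p_thresh``."""
        total_min, sf = self._score_distribution()
        below = np.nonzero(sf < p_thresh)[0]
        if len(below) == 0:
            return np.iinfo(np.int64).max
        return total_min + int(below[0])


def read_jaspar_pfm(
    path: str | os.PathLike,
    pseudocount: float = 1.0,
    background: Optional[Sequence[float]] = None,
    max_width: int = MAX_MOTIF_WIDTH,
) -> list[PWM]:
    """Parse JASPAR-format PFM text into :class:`PWM` objects.

    Motifs wider than ``max_width`` (the maximum admissible TF-binding
    motif length) are rejected with an error.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    out: list[PWM] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            if counts.shape[1] > max_width:
                raise ValueError(
                    f"motif {m.matrix_id or m.name} has width {counts.shape[1]} > {max_width}"
                )
            out.append(
                PWM(m.matrix_id or m.name, m.name or m.matrix_id, counts,
                    background=bg.copy(), pseudocount=pseudocount)
            )
    return out


def symmetric_background(seqs: Sequence[str]) -> np.ndarray:
    """Strand-symmetric base composition of a sequence set (A=T, C=G)."""
    counts = np.zeros(4)
    for s in seqs:
        codes = encode(s)
        for b in range(4):
            counts[b] += int((codes == b).sum())
    if counts.sum() == 0:
        return np.full(4, 0.25)
    at = (counts[0] + counts[3]) / 2
    cg = (counts[1] + counts[2]) / 2
    sym = np.array([at, cg, cg, at])
    return sym / sym.sum()


@dataclass
class MotifHit:
    motif_id: str
    offset: int  # 0-based start of the hit on the forward sequence
    strand: str
    score: float  # log2-odds
    p_value: float


#: sentinel per-position contribution for non-ACGT codes; any offset touching
#: one sums below _INVALID_CUTOFF and is treated as unscorable
_SENTINEL = -(2 ** 40)
_INVALID_CUTOFF = -(2 ** 39)


def _with_sentinel(lattice: np.ndarray) -> np.ndarray:
    return np.vstack([lattice, np.full((1, lattice.shape[1]), _SENTINEL, dtype=np.int64)])


def _batch_lattice_scores(codes2d: np.ndarray, lattice: np.ndarray) -> np.ndarray:
    """Lattice scores at every offset for a batch of equal-length sequences.

    ``codes2d`` is (n_seqs, L) with codes 0..3 (4 = non-ACGT); offsets
    touching a non-ACGT base come out below ``_INVALID_CUTOFF``.
    """
    n, L = codes2d.shape
    w = lattice.shape[1]
    m = L - w + 1
    if m <= 0:
        return np.zeros((n, 0), dtype=np.int64)
    lat5 = _with_sentinel(lattice)
    scores = np.zeros((n, m), dtype=np.int64)
    for j in range(w):
        scores += lat5[codes2d[:, j:j + m], j]
    return scores


def _window_lattice_scores(codes: np.ndarray, lattice: np.ndarray) -> np.ndarray:
    return _batch_lattice_scores(codes[None, :], lattice)[0]


def scan_pwm(
    seq: str,
    pwm: PWM,
    both_strands: bool = True,
    p_thresh: float = MOTIF_HIT_P,
) -> list[MotifHit]:
    """Score every offset (and strand) and report hits with p-value < p_thresh.

    The reverse strand is scored by scanning the forward sequence with the
    reverse-complement matrix, so hit offsets are forward coordinates in
    both cases; the score p-value table is shared (the background is
    strand-symmetric).
    """
    hits: list[MotifHit] = []
    codes = encode(seq)
    thresh = pwm.lattice_threshold(p_thresh)
    lattices = [("+", pwm.lattice)]
    if both_strands:
        lattices.append(("-", pwm.lattice[::-1, ::-1]))
    for strand, lat in lattices:
        scores = _window_lattice_scores(codes, lat)
        for off in np.nonzero(scores >= thresh)[0]:
            sc = int(scores[off])
            hits.append(MotifHit(pwm.motif_id, int(off), strand,
                                 sc / LATTICE_SCALE, pwm.score_pvalue(sc)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# -------------------------------------------------------------- shuffle

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving the exact dinucleotide counts.

    Builds the multigraph whose edges are the consecutive dinucleotides and
    samples a uniform random Eulerian path with the original first and last
    characters fixed.
    """
    s = seq.upper()
    if len(s) < 3 or len(set(s)) == 1:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    verts = list(edges.keys())
    for v in set(s):
        edges.setdefault(v, [])

    def connects_to_last(last_edge: dict[str, str]) -> bool:
        for v in verts:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last and cur in last_edge and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                return False
        return True

    # sample a random in-tree toward the terminal vertex (rejection sampling)
    while True:
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))]
            for v in verts
            if v != last and edges[v]
        }
        if connects_to_last(last_edge):
            break

    arranged: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v != last and v in last_edge:
            pool.remove(last_edge[v])
        perm = list(rng.permutation(len(pool)))
        shuffled = [pool[i] for i in perm]
        if v != last and v in last_edge:
            shuffled.append(last_edge[v])
        arranged[v] = shuffled

    out = [s[0]]
    ptr = {v: 0 for v in arranged}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = arranged[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    s = seq.upper()
    for a, b in zip(s, s[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out


# -------------------------------------------------------------- enrichment

def _encoded_groups(seqs: Sequence[str]) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Group sequences by length and encode each group into a 2D array."""
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    return {
        L: (np.asarray(idxs), np.stack([encode(seqs[i]) for i in idxs]))
        for L, idxs in by_len.items()
    }


def _avg_odds_from_groups(
    groups: Mapping[int, tuple[np.ndarray, np.ndarray]], n_seqs: int, pwm: PWM
) -> np.ndarray:
    out = np.full(n_seqs, np.nan)
    rc_lattice = pwm.lattice[::-1, ::-1]
    for L, (idxs, codes2d) in groups.items():
        if L < pwm.width:
            continue
        fwd = _batch_lattice_scores(codes2d, pwm.lattice)
        rev = _batch_lattice_scores(codes2d, rc_lattice)
        scores = np.concatenate([fwd, rev], axis=1)
        valid = scores > _INVALID_CUTOFF
        odds = np.where(valid, np.exp2(scores / LATTICE_SCALE), 0.0)
        n_valid = valid.sum(axis=1)
        out[idxs] = np.where(n_valid > 0, odds.sum(axis=1) / np.maximum(n_valid, 1), np.nan)
    return out


def average_odds_scores(seqs: Sequence[str], pwm: PWM) -> np.ndarray:
    """AME-style sequence scores: mean over offsets/strands of the odds score.

    Vectorized over sequences (grouped by length); sequences shorter than
    the motif get NaN.
    """
    return _avg_odds_from_groups(_encoded_groups(seqs), len(seqs), pwm)


def average_odds_score(seq: str, pwm: PWM) -> float:
    """Average odds score of a single sequence (see :func:`average_odds_scores`)."""
    return float(average_odds_scores([seq], pwm)[0])


def enrich_motifs(
    windows: Sequence[str],
    pwms: Sequence[PWM],
    n_shuffles: int = 1,
    seed: int = 0,
    alpha: float = ENRICH_P,
    controls: Optional[Sequence[str]] = None,
    max_splits: int = 200,
) -> pd.DataFrame:
    """Motif enrichment of input windows against dinucleotide-shuffled controls.

    Per motif, every input and control sequence receives its average odds
    score; the positive/negative threshold is optimized over score split
    points (at most ``max_splits`` quantile-spaced candidates among the
    distinct scores), each split tested by a one-sided Fisher's exact test,
    with Bonferroni correction for the splits tested and then for the
    number of motifs.  A motif is enriched when the adjusted p < ``alpha``.
    Pass ``controls`` explicitly to bypass shuffling (e.g. for calibration).
    """
    if not pwms:
        raise ValueError("no motifs supplied")
    if len(windows) < 10:
        raise ValueError("need at least 10 input windows")
    rng = np.random.default_rng(seed)
    if controls is None:
        controls = [
            dinucleotide_shuffle(w, rng) for w in windows for _ in range(n_shuffles)
        ]
    n_pos, n_neg = len(windows), len(controls)
    n_tot = n_pos + n_neg
    win_groups = _encoded_groups(list(windows))
    ctl_groups = _encoded_groups(list(controls))
    rows = []
    for pwm in pwms:
        sp = _avg_odds_from_groups(win_groups, n_pos, pwm)
        sn = _avg_odds_from_groups(ctl_groups, n_neg, pwm)
        scores = np.concatenate([sp, sn])
        labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
        order = np.lexsort((labels, -scores))  # descending score, controls first on ties
        s_sorted = scores[order]
        l_sorted = labels[order]
        cum_pos = np.cumsum(l_sorted)
        k = np.arange(1, n_tot + 1)
        # split after rank k only where the score strictly drops
        boundary = np.ones(n_tot, dtype=bool)
        boundary[:-1] = s_sorted[:-1] > s_sorted[1:]
        boundary[-1] = False  # everything positive is no split
        ks = k[boundary]
        if len(ks) == 0:
            rows.append((pwm.motif_id, pwm.name, np.nan, 1.0, 1.0, False))
            continue
        if len(ks) > max_splits:
            pick = np.unique(
                np.round(np.linspace(0, len(ks) - 1, max_splits)).astype(int)
            )
            ks = ks[pick]
        a = cum_pos[ks - 1]
        pvals = stats.hypergeom.sf(a - 1, n_tot, n_pos, ks)
        best = int(np.argmin(pvals))
        p_split = float(min(1.0, pvals[best] * len(ks)))
        thresh = float(s_sorted[ks[best] - 1])
        rows.append((pwm.motif_id, pwm.name, thresh, float(pvals[best]), p_split, False))
    out = pd.DataFrame(
        rows, columns=["motif_id", "name", "threshold", "p_raw", "p_split_adj", "enriched"]
    )
    out["p_adj"] = np.minimum(1.0, out["p_split_adj"] * len(pwms))
    out["enriched"] = out["p_adj"] < alpha
    return out


def intersect_tissues(enriched_a: pd.DataFrame, enriched_b: pd.DataFrame) -> list[str]:
    """Motifs enriched in both tissues."""
    a = set(enriched_a.loc[enriched_a["enriched"], "motif_id"])
    b = set(enriched_b.loc[enriched_b["enriched"], "motif_id"])
    return sorted(a & b)


def filter_cpg_motifs(
    motif_ids: Sequence[str],
    pwms: Sequence[PWM],
    use_probability: bool = False,
) -> list[str]:
    """Keep motifs whose binding site contains a CpG.

    By default the judgement is on the consensus (argmax base per
    position); with ``use_probability`` any adjacent position pair with
    P(C) > 0.5 followed by P(G) > 0.5 qualifies.
    """
    by_id = {p.motif_id: p for p in pwms}
    kept = []
    for mid in motif_ids:
        pwm = by_id[mid]
        if use_probability:
            pc, pg = pwm.probs[1], pwm.probs[2]
            has = any(pc[j] > 0.5 and pg[j + 1] > 0.5 for j in range(pwm.width - 1))
        else:
            has = "CG" in pwm.consensus
        if has:
            kept.append(mid)
    return kept


# -------------------------------------------------------------- CpG windows

def cpg_windows(
    features: Sequence[GeneFeatureSet],
    sites: pd.DataFrame,
    genome: Mapping[str, str],
    window: int = CPG_WINDOW,
) -> pd.DataFrame:
    """Sequence windows of +/- ``window`` bp around first-intron CpGs.

    ``sites`` must have chrom/pos columns (0-based CpG positions).  Windows
    are clipped at the intron boundaries so that the analysis stays inside
    the declared feature.  Returns gene_id, chrom, pos, window sequence and
    the CpG offset inside the window.
    """
    site_by_chrom: dict[str, np.ndarray] = {
        c: g["pos"].to_numpy(int) for c, g in sites.groupby("chrom")
    }
    rows = []
    for fs in features:
        if fs.first_intron is None:
            continue
        s, e = fs.first_intron
        pos_arr = site_by_chrom.get(fs.chrom)
        if pos_arr is None:
            continue
        inside = pos_arr[(pos_arr >= s) & (pos_arr + 2 <= e)]
        if len(inside) == 0:
            continue
        chrom_seq = genome[fs.chrom]
        for p in inside:
            ws = max(s, int(p) - window)
            we = min(e, int(p) + 2 + window)
            seq = str(chrom_seq[ws:we]).upper()
            rows.append((fs.gene_id, fs.chrom, int(p), ws, seq, int(p) - ws))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "pos", "window_start", "seq", "cpg_offset"]
    )


def motif_cpg_hits(
    windows: pd.DataFrame,
    pwms: Sequence[PWM],
    p_thresh: float = MOTIF_HIT_P,
) -> pd.DataFrame:
    """Windows whose CpG lies inside a motif hit of one of the given PWMs.

    One record per window x motif (the best-scoring covering hit).
    """
    seqs = windows["seq"].tolist()
    cpg_off = windows["cpg_offset"].to_numpy(int)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    rows = []
    for pwm in pwms:
        w = pwm.width
        thresh = pwm.lattice_threshold(p_thresh)
        rc_lattice = pwm.lattice[::-1, ::-1]
        for L, idxs in by_len.items():
            if L < w:
                continue
            idx_arr = np.asarray(idxs)
            codes2d = np.stack([encode(seqs[i]) for i in idxs])
            fwd = _batch_lattice_scores(codes2d, pwm.lattice)
            rev = _batch_lattice_scores(codes2d, rc_lattice)
            m = fwd.shape[1]
            offs = np.arange(m)
            # offsets whose motif span covers the CpG dinucleotide
            for si in range(len(idx_arr)):
                co = cpg_off[idx_arr[si]]
                cover = (offs <= co) & (co + 2 <= offs + w)
                best_sc, best_strand = None, None
                for strand, sc_row in (("+", fwd[si]), ("-", rev[si])):
                    cand = sc_row[cover]
                    if cand.size and cand.max() >= thresh:
                        sc = int(cand.max())
                        if best_sc is None or sc > best_sc:
                            best_sc, best_strand = sc, strand
                if best_sc is not None:
                    r = windows.iloc[idx_arr[si]]
                    rows.append(
                        (r["gene_id"], r["chrom"], int(r["pos"]), pwm.motif_id,
                         best_strand, best_sc / LATTICE_SCALE,
                         pwm.score_pvalue(best_sc))
                    )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "pos", "motif_id", "strand", "score", "p_value"],
    )
    return out.sort_values(["gene_id", "pos", "motif_id"], kind="mergesort").reset_index(drop=True)


def classify_motif_cpgs(records: pd.DataFrame, value_col: str = "percent") -> pd.DataFrame:
    """Quartile classification of motif-CpG methylation, per tissue.

    Q1/Q3 are computed on the methylation values of the analyzed CpG set of
    each tissue (linear-interpolation quantiles); values below Q1 are
    unmethylated, above Q3 methylated, otherwise intermediate.
    """
    if records.groupby("tissue")[value_col].count().min() < 4:
        raise ValueError("quartile classification needs at least 4 CpGs per tissue")
    out = records.copy()
    out["meth_class"] = "intermediate"
    for tissue, grp in records.groupby("tissue"):
        vals = grp[value_col].to_numpy(float)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        idx = grp.index
        out.loc[idx[grp[value_col] < q1], "meth_class"] = "unmethylated"
        out.loc[idx[grp[value_col] > q3], "meth_class"] = "methylated"
    return out


def relative_distance(pos: int, intron: tuple[int, int], strand: str) -> float:
    """CpG offset from the first exon-first intron boundary / intron width."""
    s, e = intron
    if not (s <= pos < e):
        raise ValueError(f"CpG {pos} outside intron [{s},{e})")
    width = e - s
    off = pos - s if strand == "+" else e - 1 - pos
    return off / width


def ancova_expression(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """ANCOVA of host-gene expression on relative distance x methylation status.

    ``records`` needs columns log2cpm, relative_distance and meth_class with
    both extreme classes present (intermediate rows are dropped).  The
    linear model log2cpm ~ distance + status + distance:status is decomposed
    with sequential (Type-I) sums of squares in that order.  Returns the
    ANOVA table (rows: relative_distance, meth_class, interaction,
    residuals) and the Shapiro-Wilk residual-normality p-value as a
    diagnostic.
    """
    df = records[records["meth_class"].isin(["unmethylated", "methylated"])].copy()
    if len(df) < 8:
        raise ValueError("ANCOVA needs at least 8 records in the extreme classes")
    if df["meth_class"].nunique() < 2:
        raise ValueError("both methylation classes must be present")
    model = smf.ols("log2cpm ~ relative_distance * C(meth_class)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        index={
            "relative_distance": "relative_distance",
            "C(meth_class)": "meth_status",
            "relative_distance:C(meth_class)": "interaction",
            "Residual": "residuals",
        }
    )
    table = table.loc[["relative_distance", "meth_status", "interaction", "residuals"]]
    shapiro_p = float(stats.shapiro(model.resid).pvalue) if len(df) <= 5000 else float("nan")
    return table, shapiro_p
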