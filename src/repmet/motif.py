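"""Transcription-factor binding-motif enrichment in promoter sets.

Given the up/down-regulated neighbor-gene sets of reporter metabolites, this
module asks whether any known binding motif (a TRANSFAC-style position frequency
matrix) occurs in their promoters more often than in the promoters of all other
metabolic genes.

Pipeline: promoters are the -800..+200 window around the TSS (strand-oriented,
soft-masked bases as N); each PFM is scanned over both strands with log-odds
scores against an order-2 Markov background trained on the negative set; a
sequence "has" the motif when its best window reaches 70% of the matrix's
maximal achievable score; per-sequence presence counts feed a one-tailed
Fisher's exact (hypergeometric tail) test, and Storey q-values correct for the
many motifs tested per gene set.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _BASE_CODE[ord(_b)] = _i
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ENRICH_COLUMNS = (
    "gene_set_id",
    "motif_id",
    "motif_name",
    "a",
    "b",
    "c",
    "d",
    "p",
    "q",
    "significant",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> int8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------------
# position frequency matrices


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: 4 x L counts over A, C, G, T."""

    id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError(f"PFM {self.id}: counts must be 4 x L")
        if c.shape[1] < 4:
            raise ValueError(f"PFM {self.id}: motif length must be >= 4")
        if np.any(c < 0):
            raise ValueError(f"PFM {self.id}: negative counts")
        if np.any(c.sum(axis=0) == 0):
            raise ValueError(f"PFM {self.id}: all-zero column")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))

    def frequencies(self, pseudocount: float = 0.25) -> np.ndarray:
        """Column base frequencies with a per-cell pseudocount (avoids -inf)."""
        c = self.counts + pseudocount
        return c / c.sum(axis=0, keepdims=True)


class TransfacParseError(ValueError):
    pass


def parse_transfac(path_or_text) -> list[PFM]:
    """Parse TRANSFAC flat-file matrices (AC/ID/P0 rows, numbered lines, ``//``).

    The P0 header declares the column order, which is remapped to A, C, G, T.
    Accepts a path or raw text; an empty file yields an empty list.
    """
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str)
        and "\n" not in path_or_text
        and Path(path_or_text or ".").is_file()
    ):
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        text = str(path_or_text)

    pfms: list[PFM] = []
    ac = name = None
    order: list[int] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal ac, name, order, rows
        if ac is None and not rows:
            ac = name = None
            order = None
            rows = []
            return
        rid = ac or f"record{len(pfms) + 1}"
        if not rows:
            raise TransfacParseError(f"record {rid}: no matrix rows")
        mat = np.zeros((4, len(rows)))
        for j, vals in enumerate(rows):
            for col, v in enumerate(vals):
                mat[order[col], j] = v  # type: ignore[index]
        pfms.append(PFM(rid, name or rid, mat))
        ac = name = None
        order = None
        rows = []

    for raw in text.splitlines():
        line = raw.rstrip()
        if not line or line.startswith(("XX", "VV", "CC", "BF", "BA", "NA ")):
            continue
        if line.startswith("//"):
            flush()
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag == "AC":
            ac = rest
        elif tag == "ID":
            name = rest
        elif tag in ("P0", "PO"):
            letters = rest.split()
            if sorted(letters) != sorted(ALPHABET):
                raise TransfacParseError(
                    f"record {ac or '?'}: P0 header must name A C G T, got {letters}"
                )
            order = [ALPHABET.index(x) for x in letters]
        elif re.fullmatch(r"\d+", tag):
            if order is None:
                raise TransfacParseError(
                    f"record {ac or '?'}: position line before P0 header"
                )
            fields = rest.split()
            try:
                vals = [float(x) for x in fields[:4]]
            except ValueError as exc:
                raise TransfacParseError(
                    f"record {ac or '?'}: malformed position line {line!r}"
                ) from exc
            if len(vals) < 4:
                raise TransfacParseError(
                    f"record {ac or '?'}: position line {line!r} has <4 counts"
                )
            rows.append(vals)
    if ac is not None or rows:
        flush()
    return pfms


def write_transfac(pfms: Iterable[PFM], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("VV  repmet motif matrices\nXX\n//\n")
        for pfm in pfms:
            fh.write(f"AC  {pfm.id}\nXX\nID  {pfm.name}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            for j in range(pfm.length):
                vals = "".join(f"{pfm.counts[b, j]:7g}" for b in range(4))
                fh.write(f"{j + 1:02d}{vals}\n")
            fh.write("XX\n//\n")


# ---------------------------------------------------------------------------------
# promoter extraction


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_tss_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "gene_id": str})
    need = {"chrom", "tss", "strand", "gene_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"TSS table needs columns {sorted(need)}")
    return df


def extract_promoters(
    genome: Mapping[str, str] | str | Path,
    tss_table: pd.DataFrame,
    upstream: int = 800,
    downstream: int = 200,
) -> dict[str, str]:
    """Strand-oriented promoter windows around annotated TSSs.

    Plus strand: ``genome[tss-upstream, tss+downstream)``; minus strand: reverse
    complement of ``genome[tss-downstream+1, tss+upstream+1)`` — so the returned
    sequence always reads upstream -> downstream of the gene.  ``tss`` is the
    0-based coordinate of the transcription start base.  Soft-masked (lowercase)
    bases become N.  Windows are truncated at chromosome ends with a warning;
    TSSs outside the chromosome are skipped with a warning; an unknown
    chromosome raises, naming the gene.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), as_raw=True, sequence_always_upper=False)
        chroms: Mapping[str, str] = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        chroms = genome

    promoters: dict[str, str] = {}
    truncated: list[str] = []
    skipped: list[str] = []
    for row in tss_table.itertuples(index=False):
        chrom, tss, strand, gene = (
            str(row.chrom),
            int(row.tss),
            str(row.strand),
            str(row.gene_id),
        )
        if chrom not in chroms:
            raise KeyError(f"gene {gene}: unknown chromosome {chrom!r}")
        seq = chroms[chrom]
        if not 0 <= tss < len(seq):
            skipped.append(gene)
            continue
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        elif strand == "-":
            start, end = tss - downstream + 1, tss + upstream + 1
        else:
            raise ValueError(f"gene {gene}: unknown strand {strand!r}")
        if start < 0 or end > len(seq):
            truncated.append(gene)
        window = seq[max(start, 0) : min(end, len(seq))]
        window = re.sub(r"[a-z]", "N", window)
        window = re.sub(r"[^ACGTN]", "N", window.upper())
        if strand == "-":
            window = reverse_complement(window)
        promoters[gene] = window
    if truncated:
        warnings.warn(
            f"{len(truncated)} promoter windows truncated at chromosome ends: "
            + ",".join(truncated[:5])
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} genes with TSS outside the chromosome skipped: "
            + ",".join(skipped[:5])
        )
    return promoters


# ---------------------------------------------------------------------------------
# Markov background model


class MarkovBackground:
    """Order-m Markov model of promoter background sequence.

    Conditional probabilities P(base | previous m bases) with add-one
    pseudocounts; contexts containing N are skipped during training and fall
    back to the marginal base distribution during scoring.
    """

    def __init__(self, order: int, cond_logp: np.ndarray, marginal_logp: np.ndarray):
        self.order = order
        self.cond_logp = cond_logp  # shape (4**order, 4)
        self.marginal_logp = marginal_logp  # shape (4,)

    @classmethod
    def train(
        cls, sequences: Iterable[str], order: int = 2, min_factor: int = 10
    ) -> "MarkovBackground":
        seq_list = list(sequences)
        codes = [encode(s) for s in seq_list]
        usable = sum(int((c < 4).sum()) for c in codes)
        if usable < min_factor * 4 ** (order + 1):
            raise ValueError(
                f"only {usable} usable bases for an order-{order} model; "
                f"need >= {min_factor * 4 ** (order + 1)} — try a lower order"
            )
        n_ctx = 4**order
        counts = np.ones((n_ctx, 4))  # add-one pseudocounts
        base_counts = np.ones(4)
        for c in codes:
            valid = c < 4
            np.add.at(base_counts, c[valid], 1.0)
            if order == 0:
                continue
            ctx = np.zeros(len(c), dtype=np.int64)
            ok = np.ones(len(c), dtype=bool)
            for j in range(order, 0, -1):  # context most-significant-first
                prev = np.roll(c, j)
                prev[:j] = 4
                ok &= prev < 4
                ctx = ctx * 4 + np.where(prev < 4, prev, 0)
            use = ok & valid
            np.add.at(counts, (ctx[use], c[use]), 1.0)
        if order == 0:
            counts = base_counts[None, :].copy()
        cond = counts / counts.sum(axis=1, keepdims=True)
        marg = base_counts / base_counts.sum()
        return cls(order, np.log(cond), np.log(marg))

    # -- scoring -------------------------------------------------------------

    def position_logprobs(self, codes: np.ndarray) -> np.ndarray:
        """log P(base_i | context_i) per position; NaN at N bases; marginal
        fallback where the context is unavailable (sequence start or N)."""
        n = len(codes)
        valid = codes < 4
        safe = np.where(valid, codes, 0)
        out = np.where(valid, self.marginal_logp[safe], np.nan)
        if self.order == 0 or n == 0:
            if self.order == 0:
                out = np.where(valid, self.cond_logp[0, safe], np.nan)
            return out
        ctx = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for j in range(self.order, 0, -1):
            prev = np.roll(codes, j)
            prev[:j] = 4
            ok &= prev < 4
            ctx = ctx * 4 + np.where(prev < 4, prev, 0)
        ok[: self.order] = False
        use = ok & valid
        out[use] = self.cond_logp[ctx[use], safe[use]]
        return out

    # -- generation ----------------------------------------------------------

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Draw a sequence of the given length from the model."""
        marg = np.exp(self.marginal_logp)
        cond = np.exp(self.cond_logp)
        out = np.empty(length, dtype=np.int8)
        for i in range(length):
            if i < self.order or self.order == 0:
                probs = marg if self.order else cond[0]
            else:
                ctx = 0
                for j in range(self.order, 0, -1):
                    ctx = ctx * 4 + out[i - j]
                probs = cond[ctx]
            out[i] = rng.choice(4, p=probs / probs.sum())
        return "".join(ALPHABET[b] for b in out)


# ---------------------------------------------------------------------------------
# PWM scanning


@dataclass(frozen=True)
class ScanResult:
    hit: bool
    best_score: float
    n_hits: int
    threshold: float


def _score_range(pfm: PFM, bg: MarkovBackground, pseudocount: float = 0.25):
    """(logf, s_min, s_max): log column frequencies plus the extreme achievable
    log-odds scores against the background's stationary base distribution."""
    logf = np.log(pfm.frequencies(pseudocount))
    odds = logf - bg.marginal_logp[:, None]
    return logf, float(odds.min(axis=0).sum()), float(odds.max(axis=0).sum())


def _threshold(s_min: float, s_max: float, frac: float) -> float:
    # 70% of the maximal achievable score; when s_max <= 0 the raw fraction is
    # ill-defined, so the fraction is taken on the (s_min, s_max) range instead.
    if s_max > 0:
        return frac * s_max
    return s_min + frac * (s_max - s_min)

def _window_scores(
    codes: np.ndarray, logf: np.ndarray, bg: MarkovBackground
) -> np.ndarray:
    """Log-odds score of every window on one strand; -inf where the window
    contains an N."""
    n, L = len(codes), logf.shape[1]
    if n < L:
        return np.empty(0)
    valid = codes < 4
    safe = np.where(valid, codes, 0)
    m = np.zeros(n - L + 1)
    for j in range(L):
        m += logf[safe[j : n - L + 1 + j], j]
    bglp = bg.position_logprobs(codes)
    bglp_filled = np.where(valid, bglp, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(bglp_filled)))
    b = csum[L:] - csum[:-L]
    cbad = np.concatenate(([0], np.cumsum(~valid)))
    any_n = (cbad[L:] - cbad[:-L]) > 0
    scores = m - b
    scores[any_n] = -np.inf
    return scores


def scan_sequence(
    seq: str,
    pfm: PFM,
    bg: MarkovBackground,
    threshold_frac: float = 0.7,
    pseudocount: float = 0.25,
) -> ScanResult:
    """Scan both strands of ``seq`` for the motif; per-sequence hit call.

    A window scores ``sum_j log(f_j(base) / P_bg(base | context))``; windows
    containing N score -inf.  ``hit`` is True when the best window over either
    strand reaches ``threshold_frac`` of the matrix's maximal achievable score
    (range-normalized when that maximum is non-positive).
    """
    logf, s_min, s_max = _score_range(pfm, bg, pseudocount)
    thr = _threshold(s_min, s_max, threshold_frac)
    best = -np.inf
    n_hits = 0
    if len(seq) < pfm.length:
        logger.debug("sequence shorter than motif %s; no hit", pfm.id)
        return ScanResult(False, best, 0, thr)
    for strand_seq in (seq, reverse_complement(seq)):
        scores = _window_scores(encode(strand_seq), logf, bg)
        if scores.size:
            best = max(best, float(scores.max()))
            n_hits += int((scores >= thr).sum())
    return ScanResult(bool(best >= thr), best, n_hits, thr)


def best_scores(
    seqs: Mapping[str, str], pfm: PFM, bg: MarkovBackground, pseudocount: float = 0.25
) -> dict[str, float]:
    """Best window score per sequence (both strands), threshold-independent."""
    logf, _s_min, _s_max = _score_range(pfm, bg, pseudocount)
    out: dict[str, float] = {}
    for name, seq in seqs.items():
        best = -np.inf
        if len(seq) >= pfm.length:
            for strand_seq in (seq, reverse_complement(seq)):
                scores = _window_scores(encode(strand_seq), logf, bg)
                if scores.size:
                    best = max(best, float(scores.max()))
        out[name] = best
    return out


# ---------------------------------------------------------------------------------
# exact one-tailed Fisher test and Storey q-values


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher's exact p: P(X >= a) for the 2x2 table [[a,b],[c,d]].

    Exact hypergeometric tail sum in rational arithmetic, converted to float at
    the end; identical to the upper-tail hypergeometric probability of drawing
    ``a`` or more hit-positives.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n_pos = a + b
    n_hit = a + c
    total = a + b + c + d
    if total == 0 or a == 0:
        return 1.0
    denom = math.comb(total, n_pos)
    acc = Fraction(0)
    for x in range(a, min(n_pos, n_hit) + 1):
        acc += Fraction(math.comb(n_hit, x) * math.comb(total - n_hit, n_pos - x))
    p = acc / denom
    return min(float(p), 1.0)


def storey_q(
    pvals: Sequence[float],
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid
    (default 0.05..0.95 step 0.05) and extrapolated to lambda = 1 with a cubic
    smoothing fit; with fewer than 100 p-values the single-point estimate at
    lambda = 0.5 is used instead.  q_i = pi0 * min_{p_j >= p_i} (m p_j / rank_j),
    monotone in p and capped at 1.  With ``pi0`` given (e.g. 1.0) the estimate
    is skipped and the rank-based FDR formula is exact.
    """
    p = np.asarray(list(pvals), dtype=float)
    m = p.size
    if m == 0:
        return np.empty(0)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        if m < 100:
            lam = 0.5
            pi0 = float((p > lam).sum()) / (m * (1 - lam))
        else:
            lams = (
                np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
            )
            est = np.array([(p > l).sum() / (m * (1 - l)) for l in lams])
            coef = np.polyfit(lams, est, 3)
            pi0 = float(np.polyval(coef, 1.0))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------------
# gene-set selection and enrichment


def select_gene_sets(
    scores: pd.DataFrame, min_size: int = 5, alpha: float = 0.05
) -> list[tuple[str, tuple[str, ...]]]:
    """Up/down neighbor-gene sets of reporter metabolites with >= min_size genes.

    ``scores`` is the reporter score table; only metabolites at p <= alpha are
    considered, and each direction is emitted independently as
    ``<metabolite_id>:up`` / ``:down`` when it reaches min_size.
    """
    sets: list[tuple[str, tuple[str, ...]]] = []
    rep = scores[scores["p"] <= alpha]
    for _, row in rep.iterrows():
        for direction, col in (("up", "up_genes"), ("down", "down_genes")):
            genes = tuple(g for g in str(row.get(col, "")).split(";") if g)
            if len(genes) >= min_size:
                sets.append((f"{row['metabolite_id']}:{direction}", genes))
    return sets


def enrich(
    sets: Sequence[tuple[str, Sequence[str]]],
    promoters: Mapping[str, str],
    pfms: Sequence[PFM],
    background_gene_ids: Iterable[str],
    threshold_frac: float = 0.7,
    min_size: int = 5,
    q_cutoff: float = 0.05,
    bg_order: int = 2,
    q_mode: str = "per-set",
    threshold_mode: str = "matrix-max",
) -> pd.DataFrame:
    """Per-(gene set, motif) enrichment table.

    For each gene set the positives are its genes with promoters and the
    negatives are ``background_gene_ids`` minus the set; the Markov background
    is trained on the negative sequences.  ``a..d`` count sequences with/without
    a motif hit; p is the one-tailed Fisher exact tail and q the Storey q-value
    (within each set by default, pooled with ``q_mode="pooled"``).
    ``threshold_mode="observed-best"`` thresholds at 70% of the best score seen
    in the dataset instead of the matrix maximum.
    """
    background_gene_ids = set(background_gene_ids)
    rows: list[tuple] = []
    for set_id, genes in sets:
        pos = sorted(g for g in dict.fromkeys(genes) if g in promoters)
        if len(pos) < min_size:
            warnings.warn(
                f"gene set {set_id}: only {len(pos)} promoters available "
                f"(< {min_size}); skipped"
            )
            continue
        neg = sorted(
            g for g in background_gene_ids - set(genes) if g in promoters
        )
        if not neg:
            warnings.warn(f"gene set {set_id}: empty background; skipped")
            continue
        bg = MarkovBackground.train((promoters[g] for g in neg), order=bg_order)
        for pfm in pfms:
            if threshold_mode == "matrix-max":
                pos_hits = sum(
                    scan_sequence(promoters[g], pfm, bg, threshold_frac).hit
                    for g in pos
                )
                neg_hits = sum(
                    scan_sequence(promoters[g], pfm, bg, threshold_frac).hit
                    for g in neg
                )
            elif threshold_mode == "observed-best":
                bests = best_scores(
                    {g: promoters[g] for g in pos + neg}, pfm, bg
                )
                observed = max(bests.values())
                thr = threshold_frac * observed if observed > 0 else observed
                pos_hits = sum(bests[g] >= thr for g in pos)
                neg_hits = sum(bests[g] >= thr for g in neg)
            else:
                raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
            a, b = pos_hits, len(pos) - pos_hits
            c, d = neg_hits, len(neg) - neg_hits
            p = fisher_exact_greater(a, b, c, d)
            rows.append((set_id, pfm.id, pfm.name, a, b, c, d, p))

    df = pd.DataFrame(
        rows, columns=[c for c in ENRICH_COLUMNS if c not in ("q", "significant")]
    )
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df[list(ENRICH_COLUMNS)]
    if q_mode == "per-set":
        df["q"] = np.nan
        for set_id, idx in df.groupby("gene_set_id").groups.items():
            df.loc[idx, "q"] = storey_q(df.loc[idx, "p"].to_numpy())
    elif q_mode == "pooled":
        df["q"] = storey_q(df["p"].to_numpy())
    else:
        raise ValueError(f"unknown q_mode {q_mode!r}")
    df["significant"] = df["q"] <= q_cutoff
    return df[list(ENRICH_COLUMNS)].sort_values(
        ["gene_set_id", "q", "p", "motif_id"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------------
# model / results objects


class MotifEnrichmentAnalysis:
    """Motif-enrichment model over reporter gene sets and their promoters.

    Parameters mirror :func:`enrich`; ``fit()`` returns a
    :class:`MotifEnrichmentResults` with the enrichment table.
    """

    def __init__(
        self,
        gene_sets: Sequence[tuple[str, Sequence[str]]],
        promoters: Mapping[str, str],
        pfms: Sequence[PFM],
        background_gene_ids: Iterable[str],
        threshold_frac: float = 0.7,
        min_size: int = 5,
        q_cutoff: float = 0.05,
        bg_order: int = 2,
        q_mode: str = "per-set",
        threshold_mode: str = "matrix-max",
    ):
        self.gene_sets = list(gene_sets)
        self.promoters = promoters
        self.pfms = list(pfms)
        self.background_gene_ids = set(background_gene_ids)
        self.threshold_frac = threshold_frac
        self.min_size = min_size
        self.q_cutoff = q_cutoff
        self.bg_order = bg_order
        self.q_mode = q_mode
        self.threshold_mode = threshold_mode

    def fit(self) -> "MotifEnrichmentResults":
        table = enrich(
            self.gene_sets,
            self.promoters,
            self.pfms,
            self.background_gene_ids,
            threshold_frac=self.threshold_frac,
            min_size=self.min_size,
            q_cutoff=self.q_cutoff,
            bg_order=self.bg_order,
            q_mode=self.q_mode,
            threshold_mode=self.threshold_mode,
        )
        return MotifEnrichmentResults(self, table)


class MotifEnrichmentResults:
    def __init__(self, model: MotifEnrichmentAnalysis, table: pd.DataFrame):
        self.model = model
        self.table = table

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "Motif enrichment analysis",
            "=" * 60,
            f"gene sets tested:   {self.table['gene_set_id'].nunique()}",
            f"motifs tested:      {self.table['motif_id'].nunique()}",
            f"significant (q <= {self.model.q_cutoff:g}): {len(sig)}",
        ]
        if len(sig):
            lines += [
                "-" * 60,
                sig[["gene_set_id", "motif_id", "a", "b", "c", "d", "p", "q"]]
                .to_string(index=False, float_format=lambda v: f"{v:.3g}"),
            ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
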