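"""Promoters, TRANSFAC matrices, background models, scanning and enrichment."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repmet.motif import (
    PFM,
    MarkovBackground,
    TransfacParseError,
    encode,
    enrich,
    extract_promoters,
    fisher_exact_greater,
    parse_transfac,
    reverse_complement,
    scan_sequence,
    select_gene_sets,
    storey_q,
    write_transfac,
)

TOY_TRANSFAC = """\
AC  M00001
XX
ID  MOTIF_A
XX
P0      A      C      G      T
01      10      0      0      2
02      0      12      0      0
03      0      0      12      0
04      12      0      0      0
05      0      0      0      12
XX
//
AC  M00002
XX
ID  MOTIF_B
XX
P0      A      C      G      T
01      1      1      1      9
02      9      1      1      1
03      1      9      1      1
04      1      1      9      1
XX
//
"""


class TestParseTransfac:
    def test_two_records(self):
        pfms = parse_transfac(TOY_TRANSFAC)
        assert [m.id for m in pfms] == ["M00001", "M00002"]
        assert [m.length for m in pfms] == [5, 4]
        assert pfms[0].consensus == "ACGAT"

    def test_reordered_alphabet_header_remapped(self):
        reordered = (
            "AC  M00001\nXX\nID  MOTIF_A\nXX\n"
            "P0      T      G      C      A\n"
            "01      2      0      0      10\n"
            "02      0      0      12      0\n"
            "03      0      12      0      0\n"
            "04      0      0      0      12\n"
            "05      12      0      0      0\n"
            "XX\n//\n"
        )
        pfms = parse_transfac(reordered)
        np.testing.assert_array_equal(
            pfms[0].counts, parse_transfac(TOY_TRANSFAC)[0].counts
        )

    def test_malformed_position_line_names_record(self):
        bad = TOY_TRANSFAC.replace("02      0      12      0      0", "02      x y z w")
        with pytest.raises(TransfacParseError, match="M00001"):
            parse_transfac(bad)

    def test_empty_input(self):
        assert parse_transfac("") == []

    def test_write_round_trip(self, tmp_path):
        pfms = parse_transfac(TOY_TRANSFAC)
        path = tmp_path / "m.transfac"
        write_transfac(pfms, path)
        again = parse_transfac(path)
        assert [m.id for m in again] == [m.id for m in pfms]
        for a, b in zip(again, pfms):
            np.testing.assert_allclose(a.counts, b.counts)

    def test_pfm_validation(self):
        with pytest.raises(ValueError, match="all-zero"):
            PFM("x", "x", np.array([[1, 0], [0, 0], [0, 0], [1, 0]]).repeat(2, 1))
        with pytest.raises(ValueError, match=">= 4"):
            PFM("x", "x", np.ones((4, 3)))


class TestExtractPromoters:
    genome = {"chr1": "".join("ACGT"[(i // 3) % 4] for i in range(5000))}

    def tss(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "tss", "strand", "gene_id"])

    def test_plus_strand_window(self):
        out = extract_promoters(self.genome, self.tss([("chr1", 1000, "+", "g1")]))
        assert len(out["g1"]) == 1000
        assert out["g1"] == self.genome["chr1"][200:1200]

    def test_minus_strand_is_reverse_complement_of_mirror(self):
        out = extract_promoters(self.genome, self.tss([("chr1", 1000, "-", "g1")]))
        assert out["g1"] == reverse_complement(self.genome["chr1"][801:1801])

    def test_truncation_at_chromosome_start(self):
        with pytest.warns(UserWarning, match="truncated"):
            out = extract_promoters(self.genome, self.tss([("chr1", 100, "+", "g1")]))
        assert len(out["g1"]) == 300

    def test_tss_outside_chromosome_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = extract_promoters(self.genome, self.tss([("chr1", 99999, "+", "g1")]))
        assert out == {}

    def test_unknown_chromosome_names_gene(self):
        with pytest.raises(KeyError, match="g1"):
            extract_promoters(self.genome, self.tss([("chrX", 1000, "+", "g1")]))

    def test_soft_masked_bases_become_n(self):
        genome = {"c": "A" * 900 + "acgt" * 50 + "A" * 1200}
        out = extract_promoters(genome, self.tss([("c", 1000, "+", "g1")]))
        assert set(out["g1"][700:900]) == {"N"}


class TestMarkovBackground:
    def test_pure_repeat_concentrates_conditionals(self):
        bg = MarkovBackground.train(["A" * 2000], order=2)
        ctx_aa = 0  # A=0, context AA
        assert math.exp(bg.cond_logp[ctx_aa, 0]) > 0.99

    def test_uniform_sequence_near_quarter(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100_000))
        bg = MarkovBackground.train([seq], order=2)
        assert np.all(np.abs(np.exp(bg.cond_logp) - 0.25) < 0.02)

    def test_order_zero_equals_composition(self):
        seq = "AACG" * 500
        bg = MarkovBackground.train([seq], order=0)
        probs = np.exp(bg.cond_logp[0])
        assert probs[0] == pytest.approx(0.5, abs=0.01)

    def test_insufficient_sequence_suggests_lower_order(self):
        with pytest.raises(ValueError, match="lower order"):
            MarkovBackground.train(["ACGT"], order=2)

    def test_contexts_with_n_skipped(self):
        bg = MarkovBackground.train(["ACGN" * 500 + "ACGT" * 200], order=1)
        assert np.isfinite(bg.cond_logp).all()


def uniform_bg():
    return MarkovBackground(0, np.log(np.full((1, 4), 0.25)), np.log(np.full(4, 0.25)))


class TestScanSequence:
    pfm = parse_transfac(TOY_TRANSFAC)[0]  # consensus ACGAT

    def test_consensus_in_random_flanks_attains_max(self, rng):
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        seq = flank + self.pfm.consensus + flank
        res = scan_sequence(seq, self.pfm, uniform_bg())
        assert res.hit
        # consensus attains the matrix maximum against a uniform background
        logf = np.log(self.pfm.frequencies())
        smax = (logf.max(axis=0) - math.log(0.25)).sum()
        assert res.best_score == pytest.approx(smax, abs=1e-9)

    def test_all_n_sequence_no_hit(self):
        res = scan_sequence("N" * 50, self.pfm, uniform_bg())
        assert not res.hit and res.n_hits == 0

    def test_reverse_complement_hit(self, rng):
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        seq = flank + reverse_complement(self.pfm.consensus) + flank
        assert scan_sequence(seq, self.pfm, uniform_bg()).hit

    def test_shorter_than_motif(self):
        assert not scan_sequence("ACG", self.pfm, uniform_bg()).hit

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 12, size=(4, 6)) + 1
        pfm = PFM(f"S{seed}", "s", counts)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        bg = uniform_bg()
        fwd = scan_sequence(seq, pfm, bg)
        rev = scan_sequence(reverse_complement(seq), pfm, bg)
        assert fwd.hit == rev.hit
        assert fwd.best_score == pytest.approx(rev.best_score, abs=1e-9)
        assert fwd.n_hits == rev.n_hits


class TestSelectGeneSets:
    def table(self, rows):
        return pd.DataFrame(
            rows, columns=["metabolite_id", "p", "up_genes", "down_genes"]
        )

    def test_threshold_rule(self):
        t = self.table([("m1", 0.01, ";".join(f"u{i}" for i in range(7)),
                         ";".join(f"d{i}" for i in range(3)))])
        sets = select_gene_sets(t)
        assert [s[0] for s in sets] == ["m1:up"]
        assert len(sets[0][1]) == 7

    def test_boundary_inclusive_both_emitted(self):
        t = self.table([("m1", 0.05, ";".join(f"u{i}" for i in range(5)),
                         ";".join(f"d{i}" for i in range(5)))])
        assert [s[0] for s in select_gene_sets(t)] == ["m1:up", "m1:down"]

    def test_non_reporters_never_emitted(self):
        t = self.table([("m1", 0.2, ";".join(f"u{i}" for i in range(9)), "")])
        assert select_gene_sets(t) == []


class TestFisher:
    def brute_force(self, a, b, c, d):
        """Exact tail by direct enumeration of more-extreme tables."""
        n_pos, n_hit, total = a + b, a + c, a + b + c + d
        acc = Fraction(0)
        for x in range(a, min(n_pos, n_hit) + 1):
            acc += Fraction(
                math.comb(n_hit, x) * math.comb(total - n_hit, n_pos - x),
                math.comb(total, n_pos),
            )
        return float(acc)

    def test_extreme_table_closed_form(self):
        assert fisher_exact_greater(5, 0, 0, 20) == pytest.approx(
            1 / math.comb(25, 5), rel=1e-12
        )

    def test_no_evidence(self):
        assert fisher_exact_greater(0, 10, 5, 5) == 1.0

    def test_balanced_table_vs_enumeration(self):
        assert fisher_exact_greater(5, 5, 5, 5) == pytest.approx(
            self.brute_force(5, 5, 5, 5), abs=1e-12
        )

    def test_all_small_tables_vs_enumeration_and_scipy(self):
        for total in range(1, 16):
            for a, b, c in itertools.product(range(total + 1), repeat=3):
                d = total - a - b - c
                if d < 0:
                    continue
                p = fisher_exact_greater(a, b, c, d)
                assert p == pytest.approx(self.brute_force(a, b, c, d), abs=1e-12)
        # spot-check larger tables against the scipy implementation
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            p_sp = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert fisher_exact_greater(int(a), int(b), int(c), int(d)) == pytest.approx(
                p_sp, rel=1e-9, abs=1e-12
            )

    def test_monotone_in_a_for_fixed_margins(self):
        n_pos, n_hit, total = 10, 12, 40
        last = 2.0
        for a in range(max(0, n_pos + n_hit - total), min(n_pos, n_hit) + 1):
            b, c = n_pos - a, n_hit - a
            d = total - a - b - c
            p = fisher_exact_greater(a, b, c, d)
            assert p <= last + 1e-15
            last = p


class TestStoreyQ:
    def test_single_pvalue_pi0_one(self):
        assert storey_q([0.04], pi0=1.0)[0] == pytest.approx(0.04)

    def test_identical_pvalues_degenerate_ranks(self):
        q = storey_q([0.01] * 10, pi0=1.0)
        np.testing.assert_allclose(q, 0.01)

    def test_uniform_pi0_estimate_near_one(self, rng):
        p = rng.uniform(size=500)
        q = storey_q(p)
        # recover pi0 from any element: q = pi0 * BH
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(p, method="fdr_bh")[1]
        ratio = q / bh
        pi0 = ratio[~np.isclose(q, 1.0)].mean()
        assert 0.8 <= pi0 <= 1.0

    def test_equals_bh_when_pi0_forced_to_one(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        q = storey_q(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, rtol=1e-12)

    def test_never_below_pi0_times_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=300) ** 2
        q = storey_q(p)
        bh = multipletests(p, method="fdr_bh")[1]
        pi0 = (q / bh).min()
        assert np.all(q >= pi0 * bh - 1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=150)
        q = storey_q(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)

    def test_empty(self):
        assert storey_q([]).size == 0


class TestEnrich:
    @staticmethod
    def long_pfm(rng):
        from repmet.synthetic import make_pfm

        return make_pfm(rng, length=10)

    def promoters(self, rng, genes, planted, pfm):
        out = {}
        for g in genes:
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
            if g in planted:
                off = int(rng.integers(0, 300 - pfm.length))
                seq = seq[:off] + pfm.consensus + seq[off + pfm.length :]
            out[g] = seq
        return out

    def test_planted_set_enriched(self, rng):
        pfm = self.long_pfm(rng)
        genes = [f"g{i}" for i in range(60)]
        pos = genes[:8]
        prom = self.promoters(rng, genes, set(pos), pfm)
        table = enrich([("m:up", pos)], prom, [pfm], genes, bg_order=0)
        row = table.iloc[0]
        assert row["a"] == 8 and row["a"] + row["b"] == 8
        assert row["c"] + row["d"] == 52
        assert row["p"] < 1e-4

    def test_set_below_min_size_skipped_with_warning(self, rng):
        pfm = self.long_pfm(rng)
        genes = [f"g{i}" for i in range(30)]
        prom = self.promoters(rng, genes, set(), pfm)
        with pytest.warns(UserWarning, match="skipped"):
            table = enrich([("m:up", ["g0", "g1", "gMISSING", "gX", "gY"])],
                           prom, [pfm], genes, bg_order=0)
        assert table.empty

    def test_gene_order_invariance(self, rng):
        pfm = self.long_pfm(rng)
        genes = [f"g{i}" for i in range(40)]
        pos = genes[:6]
        prom = self.promoters(rng, genes, set(pos), pfm)
        t1 = enrich([("m:up", pos)], prom, [pfm], genes, bg_order=0)
        t2 = enrich([("m:up", pos[::-1])], prom, [pfm], genes[::-1], bg_order=0)
        assert t1.loc[0, "p"] == t2.loc[0, "p"]
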