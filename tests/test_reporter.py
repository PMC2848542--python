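"""Reporter scoring: transforms, background sampling and metabolite calls."""

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repmet.reporter import (
    EnzymeBackground,
    ReporterAnalysis,
    ReporterParams,
    aggregate_z,
    background_stats,
    call_reporters,
    p_to_z,
    score_metabolites,
    z_to_p,
)

from conftest import build_network


class TestPToZ:
    def test_median_maps_to_zero(self):
        assert p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_five_percent(self):
        assert p_to_z(0.05) == pytest.approx(1.6449, abs=1e-4)

    def test_p_one_clamps_to_large_negative(self):
        with pytest.warns(UserWarning, match="clamped"):
            z = p_to_z(1.0)
        assert np.isfinite(z) and z < -7

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            p_to_z(bad)

    def test_round_trip_precision(self):
        grid = np.concatenate(
            [np.logspace(-12, -1, 40), np.linspace(0.1, 0.999, 40)]
        )
        back = z_to_p(p_to_z(grid))
        assert np.max(np.abs(grid - back)) < 1e-12

    def test_monotone_smaller_p_larger_z(self):
        ps = np.linspace(0.001, 0.999, 100)
        assert np.all(np.diff(p_to_z(ps)) < 0)


class TestAggregateZ:
    @pytest.mark.parametrize(
        "zs,expected",
        [([1.7], 1.7), ([1, 1, 1, 1], 2.0), ([2, -2], 0.0)],
    )
    def test_normalized_sum(self, zs, expected):
        assert aggregate_z(zs) == pytest.approx(expected)

    def test_empty_is_undefined_marker(self):
        assert math.isnan(aggregate_z([]))


class TestBackground:
    zs = [0.4, -1.2, 2.5, 0.9, -0.3, 1.8, 0.0, 3.1]

    def brute_force(self, zs, k):
        aggs = [sum(c) / math.sqrt(k) for c in itertools.combinations(zs, k)]
        return statistics.fmean(aggs), statistics.pstdev(aggs)

    def test_exhaustive_matches_enumeration_oracle(self):
        mu_o, sd_o = self.brute_force(self.zs, 3)
        mu, sd = background_stats(self.zs, 3, ReporterParams(seed=0))
        assert mu == pytest.approx(mu_o, abs=1e-12)
        assert sd == pytest.approx(sd_o, abs=1e-12)

    def test_monte_carlo_close_to_exhaustive(self):
        mu_o, sd_o = self.brute_force(self.zs, 3)
        params = ReporterParams(seed=3, exhaustive_limit=1)  # force sampling
        mu, sd = background_stats(self.zs, 3, params)
        assert mu == pytest.approx(mu_o, rel=0.02)
        assert sd == pytest.approx(sd_o, rel=0.05)

    def test_monte_carlo_all_k_on_12_enzymes(self, rng):
        zs = rng.normal(1.0, 1.0, size=12)
        params = ReporterParams(seed=11, exhaustive_limit=1)
        for k in range(1, 7):
            mu_o, sd_o = self.brute_force(list(zs), k)
            mu, sd = background_stats(zs, k, params)
            assert mu == pytest.approx(mu_o, rel=0.02, abs=0.02)
            assert sd == pytest.approx(sd_o, rel=0.05)

    def test_identical_zs_degenerate_sigma(self):
        mu, sd = background_stats([1, 1, 1, 1], 2, ReporterParams(seed=0))
        assert mu == pytest.approx(math.sqrt(2), abs=1e-12)
        assert sd == 0.0

    def test_k_out_of_range(self):
        bg = EnzymeBackground([0.1, 0.2], ReporterParams(seed=0))
        with pytest.raises(ValueError):
            bg.stats(3)

    def test_cache_and_determinism(self):
        params = ReporterParams(seed=5, exhaustive_limit=1)
        a = background_stats(self.zs, 4, params)
        b = background_stats(self.zs, 4, params)
        assert a == b
        c = background_stats(self.zs, 4, ReporterParams(seed=6, exhaustive_limit=1))
        assert a != c


def chain_network(n_mets, genes_per_met):
    """Star-free chain: each metabolite gets its own reactions/genes."""
    rows, assoc = [], {}
    g = 0
    for m in range(n_mets):
        for j in range(genes_per_met):
            rid = f"R{m}_{j}"
            rows.append((rid, f"M{m}", "substrate"))
            assoc[rid] = [f"g{g}"]
            g += 1
    return build_network(rows, assoc)


class TestScoreMetabolites:
    def test_null_scores_centre_on_half(self):
        net = chain_network(6, 3)
        scores = {f"g{i}": 0.5 for i in range(18)}
        with pytest.warns(UserWarning):  # degenerate sigma (all Z identical)
            df = score_metabolites(net, scores, ReporterParams(seed=1))
        assert np.allclose(df["z_corrected"], 0.0)
        assert np.allclose(df["p"], 0.5)

    def test_single_metabolite_degenerate_background(self):
        net = build_network([("R1", "M", "substrate")], {"R1": ["g1"]})
        with pytest.warns(UserWarning, match="degenerate"):
            df = score_metabolites(net, {"g1": 0.01}, ReporterParams(seed=0))
        assert df.loc[0, "sigma_k"] == 0.0
        assert df.loc[0, "z_corrected"] == 0.0

    def test_invariants_of_output_table(self):
        net = chain_network(5, 2)
        rng = np.random.default_rng(0)
        gs = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "p": rng.uniform(0.001, 1.0, 10),
                "logfc": rng.normal(size=10),
            }
        )
        df = score_metabolites(net, gs, ReporterParams(seed=2))
        assert list(df["p"]) == sorted(df["p"])
        mask = df["sigma_k"] > 0
        np.testing.assert_allclose(
            df.loc[mask, "z_corrected"],
            (df.loc[mask, "z_raw"] - df.loc[mask, "mu_k"]) / df.loc[mask, "sigma_k"],
        )
        np.testing.assert_allclose(df["p"], z_to_p(df["z_corrected"].to_numpy()))
        for _, row in df.iterrows():
            up = set(filter(None, row["up_genes"].split(";")))
            down = set(filter(None, row["down_genes"].split(";")))
            assert not up & down
            assert len(up) == row["n_up"] and len(down) == row["n_down"]

    def test_metabolite_without_scored_enzymes_omitted(self):
        net = build_network(
            [("R1", "M1", "substrate"), ("T", "M2", "substrate")],
            {"R1": ["g1"], "T": []},
        )
        df = score_metabolites(net, {"g1": 0.2}, ReporterParams(seed=0))
        assert list(df["metabolite_id"]) == ["M1"]

    def test_monotone_in_gene_p(self):
        """Lowering a neighbor gene's p never raises the metabolite's p when the
        background is held fixed (checked at the corrected-score formula level)."""
        bg = EnzymeBackground(
            np.linspace(-2, 2, 30), ReporterParams(seed=0, exhaustive_limit=1)
        )
        mu, sd = bg.stats(3)
        last = None
        for p1 in [0.5, 0.2, 0.05, 0.01, 0.001]:
            zs = p_to_z(np.array([p1, 0.3, 0.4]))
            p_met = z_to_p((aggregate_z(zs) - mu) / sd)
            if last is not None:
                assert p_met < last
            last = p_met

    def test_aggregation_normalization_cancels(self):
        """Corrected scores are identical under sum and sum/sqrt(k) aggregation
        because mu_k and sigma_k scale with the same factor."""
        zs = np.array([0.3, 1.1, -0.4, 2.0, 0.7, -1.5])
        k = 3
        subs = list(itertools.combinations(zs, k))
        sums = np.array([sum(c) for c in subs])
        # library convention
        mu, sd = background_stats(zs, k, ReporterParams(seed=0))
        z_raw = aggregate_z(zs[:3])
        corrected = (z_raw - mu) / sd
        # plain-sum convention, computed independently
        corrected_sum = (zs[:3].sum() - sums.mean()) / sums.std()
        assert corrected == pytest.approx(corrected_sum, abs=1e-10)

    def test_determinism_bit_identical(self):
        net = chain_network(8, 2)
        rng = np.random.default_rng(7)
        gs = {f"g{i}": float(p) for i, p in enumerate(rng.uniform(0.01, 1, 16))}
        a = score_metabolites(net, gs, ReporterParams(seed=9, exhaustive_limit=1))
        b = score_metabolites(net, gs, ReporterParams(seed=9, exhaustive_limit=1))
        assert a.to_csv() == b.to_csv()


class TestCallReporters:
    table = pd.DataFrame(
        {"metabolite_id": ["a", "b", "c"], "p": [0.01, 0.05, 0.06]}
    )

    def test_boundary_inclusive(self):
        assert list(call_reporters(self.table, 0.05)["metabolite_id"]) == ["a", "b"]

    def test_empty_when_none_significant(self):
        assert len(call_reporters(self.table, 0.001)) == 0

    def test_alpha_one_keeps_all(self):
        assert len(call_reporters(self.table, 1.0)) == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            call_reporters(self.table.iloc[:0], 0.05)


def test_params_validation():
    with pytest.raises(ValueError):
        ReporterParams(alpha=1.5)
    with pytest.raises(ValueError):
        ReporterParams(n_background_samples=10)


def test_results_object_round_trip(tmp_path):
    net = chain_network(6, 2)
    rng = np.random.default_rng(3)
    gs = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(12)],
            "p": rng.uniform(0.001, 1, 12),
            "logfc": rng.normal(size=12),
        }
    )
    res = ReporterAnalysis(net, gs, ReporterParams(seed=4)).fit()
    assert "Reporter metabolite analysis" in res.summary()
    out = tmp_path / "rep.tsv"
    res.to_tsv(out)
    from repmet.reporter import read_reporter_tsv

    again = read_reporter_tsv(out)
    assert list(again.columns) == list(res.scores.columns)
    assert len(again) == len(res.scores)
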