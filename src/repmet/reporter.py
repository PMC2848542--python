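"""Reporter-metabolite scoring.

A reporter metabolite is one whose neighboring enzyme-coding genes show collective
differential expression.  Scoring proceeds in four steps:

1. every neighbor enzyme of a metabolite receives the p-value of its most
   significant gene (GPR min-collapse, :mod:`repmet.network`);
2. enzyme p-values are converted to Z-scores with the inverse normal CDF,
   ``Z_i = Phi^{-1}(1 - p_i)``;
3. the metabolite aggregate is ``Z_raw = (sum_i Z_i) / sqrt(k)`` over its k
   scored neighbor enzymes;
4. the aggregate is standardized against a size-matched background — the mean
   mu_k and SD sigma_k of the aggregate over random sets of k enzymes drawn from
   the whole network (exhaustive enumeration when feasible, otherwise seeded
   Monte-Carlo, 10000 draws by default) — and ``p = 1 - Phi(Z_corrected)``.

Metabolites at ``p <= alpha`` (default 0.05) are called reporters.  Because mu_k
and sigma_k are computed under the same aggregation rule, any fixed per-k
normalization of step 3 yields identical corrected scores.

The model/results interface mirrors the statsmodels convention:
``ReporterAnalysis(network, gene_scores).fit()`` returns a
:class:`ReporterResults` holding the per-metabolite score table.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .network import (
    EnzymeUnit,
    MetabolicNetwork,
    min_p_gene,
    neighbor_enzymes,
    network_enzyme_units,
)

logger = logging.getLogger(__name__)

SCORE_COLUMNS = (
    "metabolite_id",
    "name",
    "k",
    "z_raw",
    "mu_k",
    "sigma_k",
    "z_corrected",
    "p",
    "n_up",
    "n_down",
    "up_genes",
    "down_genes",
)


@dataclass(frozen=True)
class ReporterParams:
    """Tunable knobs of the reporter scoring.

    n_background_samples : Monte-Carlo draws per neighborhood size k (>= 1000).
    alpha                : reporter call threshold on the corrected p (inclusive).
    p_clamp              : gene p-values are clamped to [p_clamp, 1 - p_clamp]
                           before the inverse-normal transform.
    seed                 : seed of the background sampling streams.
    exhaustive_limit     : exact enumeration of all C(n, k) subsets is used when
                           C(n, k) does not exceed this.
    dedup                : merge enzyme units with identical gene sets (per
                           metabolite and in the background pool).
    """

    n_background_samples: int = 10000
    alpha: float = 0.05
    p_clamp: float = 1e-15
    seed: int = 0
    exhaustive_limit: int = 200_000
    dedup: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_background_samples < 1000:
            raise ValueError("n_background_samples must be >= 1000")


# ---------------------------------------------------------------------------------
# elementary transforms


def p_to_z(p, p_clamp: float = 1e-15):
    """Inverse-normal transform ``Phi^{-1}(1 - p)``; smaller p -> larger Z.

    Accepts a scalar or array with values in (0, 1]; values outside
    ``[p_clamp, 1 - p_clamp]`` are clamped with a warning so the transform stays
    finite.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    clipped = np.clip(arr, p_clamp, 1.0 - p_clamp)
    if np.any(clipped != arr):
        warnings.warn(f"p-values clamped to [{p_clamp}, 1-{p_clamp}]")
    z = -special.ndtri(clipped)  # = ndtri(1 - p) computed at full precision
    return float(z) if np.isscalar(p) else z


def z_to_p(z):
    """Upper-tail normal probability ``1 - Phi(z)`` (exact complement of p_to_z)."""
    arr = np.asarray(z, dtype=float)
    p = special.ndtr(-arr)
    return float(p) if np.isscalar(z) else p


def aggregate_z(zs: Sequence[float]) -> float:
    """Aggregate k enzyme Z-scores: ``(sum z_i) / sqrt(k)``; NaN for an empty list."""
    k = len(zs)
    if k == 0:
        return math.nan
    return float(np.sum(zs) / math.sqrt(k))


# ---------------------------------------------------------------------------------
# background distribution of the aggregate


class EnzymeBackground:
    """Size-matched null for the aggregate Z over random enzyme sets.

    Holds the Z-scores of every scored enzyme in the network and returns, per
    neighborhood size k, the mean and SD of ``(sum z)/sqrt(k)`` over k-subsets:
    exhaustively when ``C(n, k) <= exhaustive_limit``, otherwise by seeded
    Monte-Carlo sampling without replacement within each draw.  Each k uses an
    independent child generator derived from the single configured seed, so
    results do not depend on the order in which sizes are requested.
    """

    def __init__(self, enzyme_zs: Sequence[float], params: ReporterParams):
        self.zs = np.asarray(list(enzyme_zs), dtype=float)
        if self.zs.size == 0:
            raise ValueError("background requires at least one scored enzyme")
        self.params = params
        self._cache: dict[int, tuple[float, float]] = {}

    @property
    def n(self) -> int:
        return int(self.zs.size)

    def stats(self, k: int) -> tuple[float, float]:
        """(mu_k, sigma_k) of the aggregate Z for size k."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k={k} outside 1..{self.n} scored enzymes")
        if k not in self._cache:
            if math.comb(self.n, k) <= self.params.exhaustive_limit:
                self._cache[k] = self._exhaustive(k)
            else:
                self._cache[k] = self._monte_carlo(k)
        return self._cache[k]

    def _exhaustive(self, k: int) -> tuple[float, float]:
        sums = np.fromiter(
            (s for s in map(sum, combinations(self.zs, k))),
            dtype=float,
            count=math.comb(self.n, k),
        )
        agg = sums / math.sqrt(k)
        return float(agg.mean()), float(agg.std(ddof=0))

    def _monte_carlo(self, k: int) -> tuple[float, float]:
        rng = np.random.default_rng([self.params.seed, k])
        n_samp = self.params.n_background_samples
        total = 0.0
        total_sq = 0.0
        chunk = max(1, min(n_samp, 50_000_000 // max(self.n, 1)))
        done = 0
        while done < n_samp:
            m = min(chunk, n_samp - done)
            keys = rng.random((m, self.n))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            agg = self.zs[idx].sum(axis=1) / math.sqrt(k)
            total += float(agg.sum())
            total_sq += float((agg * agg).sum())
            done += m
        mu = total / n_samp
        var = max(total_sq / n_samp - mu * mu, 0.0)
        return mu, math.sqrt(var)


def background_stats(
    enzyme_zs: Sequence[float], k: int, params: ReporterParams
) -> tuple[float, float]:
    """Convenience wrapper: (mu_k, sigma_k) for one size from fresh enzyme Zs."""
    return EnzymeBackground(enzyme_zs, params).stats(k)


# ---------------------------------------------------------------------------------
# scoring


def _gene_score_maps(
    gene_scores,
) -> tuple[dict[str, float], dict[str, str]]:
    """Normalize gene scores to (gene -> p, gene -> direction) dicts.

    Accepts a DataFrame with columns (gene_id, p[, logfc, direction]) or a
    mapping gene -> p (directions then default to "down").
    """
    if isinstance(gene_scores, pd.DataFrame):
        if not {"gene_id", "p"}.issubset(gene_scores.columns):
            raise ValueError("gene scores need columns gene_id, p")
        pmap = dict(
            zip(gene_scores["gene_id"].astype(str), gene_scores["p"].astype(float))
        )
        if "direction" in gene_scores.columns:
            dmap = dict(
                zip(gene_scores["gene_id"].astype(str), gene_scores["direction"])
            )
        elif "logfc" in gene_scores.columns:
            dmap = {
                g: ("up" if f > 0 else "down")
                for g, f in zip(
                    gene_scores["gene_id"].astype(str),
                    gene_scores["logfc"].astype(float),
                )
            }
        else:
            dmap = {g: "down" for g in pmap}
    else:
        pmap = {str(g): float(p) for g, p in dict(gene_scores).items()}
        dmap = {g: "down" for g in pmap}
    bad = [g for g, p in pmap.items() if not 0 < p <= 1]
    if bad:
        raise ValueError(f"{len(bad)} gene p-values outside (0,1]")
    return pmap, dmap


def score_metabolites(
    network: MetabolicNetwork,
    gene_scores,
    params: ReporterParams | None = None,
) -> pd.DataFrame:
    """Score every metabolite of the network; returns the table sorted by p.

    Columns: metabolite_id, name, k, z_raw, mu_k, sigma_k, z_corrected, p, n_up,
    n_down, up_genes, down_genes (semicolon-joined).  Metabolites without scored
    neighbor enzymes (k = 0) are omitted and counted in the log.  sigma_k = 0
    (all background aggregates identical) gives z_corrected = 0 with a warning.
    """
    params = params or ReporterParams()
    pmap, dmap = _gene_score_maps(gene_scores)

    pool = network_enzyme_units(network, dedup=params.dedup)
    pool_scored = [u for u in pool if min_p_gene(u, pmap) is not None]
    if not pool_scored:
        raise ValueError("no enzyme in the network has a scored gene")
    pool_z = p_to_z(
        np.array([min_p_gene(u, pmap)[0] for u in pool_scored]), params.p_clamp
    )
    background = EnzymeBackground(pool_z, params)
    logger.info(
        "background pool: %d scored enzyme units (of %d)", len(pool_scored), len(pool)
    )

    rows = []
    skipped = 0
    degenerate = 0
    for mid in sorted(network.metabolites):
        units = neighbor_enzymes(network, mid, dedup=params.dedup)
        scored: list[tuple[float, str]] = []
        for u in units:
            hit = min_p_gene(u, pmap)
            if hit is not None:
                scored.append(hit)
        k = len(scored)
        if k == 0:
            skipped += 1
            continue
        enzyme_p = np.array([p for p, _g in scored])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clamp warnings surfaced once upstream
            zs = p_to_z(enzyme_p, params.p_clamp)
        z_raw = aggregate_z(np.atleast_1d(zs))
        mu_k, sigma_k = background.stats(k)
        if sigma_k > 0:
            z_corr = (z_raw - mu_k) / sigma_k
        else:
            degenerate += 1
            z_corr = 0.0
        p = z_to_p(z_corr)
        up = sorted({g for _p, g in scored if dmap.get(g) == "up"})
        down = sorted({g for _p, g in scored if dmap.get(g) != "up"})
        rows.append(
            (
                mid,
                network.metabolites[mid].name,
                k,
                z_raw,
                mu_k,
                sigma_k,
                z_corr,
                p,
                len(up),
                len(down),
                ";".join(up),
                ";".join(down),
            )
        )
    if skipped:
        logger.info("%d metabolites without scored neighbor enzymes omitted", skipped)
    if degenerate:
        warnings.warn(
            f"{degenerate} metabolites hit a degenerate background (sigma_k = 0); "
            "corrected score set to 0"
        )
    df = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    df = df.sort_values(["p", "metabolite_id"], kind="mergesort").reset_index(
        drop=True
    )
    return df


def call_reporters(scores: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Subset of the score table with p <= alpha (boundary inclusive), order kept."""
    if scores.empty:
        raise ValueError("empty score table")
    return scores[scores["p"] <= alpha].reset_index(drop=True)


# ---------------------------------------------------------------------------------
# model / results objects


class ReporterAnalysis:
    """Reporter-metabolite model: a metabolic network plus gene-level scores.

    Parameters
    ----------
    network : MetabolicNetwork
    gene_scores : DataFrame (gene_id, p[, logfc, direction]) or mapping gene -> p
    params : ReporterParams, optional

    ``fit()`` computes the corrected score for every metabolite and returns a
    :class:`ReporterResults`.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        gene_scores,
        params: ReporterParams | None = None,
    ):
        self.network = network
        self.gene_scores = gene_scores
        self.params = params or ReporterParams()

    @classmethod
    def from_expression(
        cls,
        network: MetabolicNetwork,
        expr: pd.DataFrame,
        probe_map: pd.DataFrame,
        groups: Mapping[str, str],
        contrast: tuple[str, str],
        method: str = "moderated",
        params: ReporterParams | None = None,
    ) -> "ReporterAnalysis":
        """Build the model from a probe-level matrix via the diffexp stage."""
        from . import diffexp

        probe_scores = diffexp.differential_expression(
            expr, groups, contrast, method=method
        )
        probe_scores = diffexp.attach_probe_map(probe_scores, probe_map)
        gene_scores = diffexp.summarize_probes(probe_scores)
        return cls(network, gene_scores, params)

    def fit(self, seed: int | None = None) -> "ReporterResults":
        params = self.params if seed is None else replace(self.params, seed=seed)
        scores = score_metabolites(self.network, self.gene_scores, params)
        return ReporterResults(self, scores, params)


class ReporterResults:
    """Fitted reporter scores: per-metabolite table plus convenience accessors."""

    def __init__(
        self, model: ReporterAnalysis, scores: pd.DataFrame, params: ReporterParams
    ):
        self.model = model
        self.scores = scores
        self.params = params

    def reporters(self, alpha: float | None = None) -> pd.DataFrame:
        return call_reporters(self.scores, alpha or self.params.alpha)

    def reporter_ids(self, alpha: float | None = None) -> set[str]:
        return set(self.reporters(alpha)["metabolite_id"])

    def gene_sets(
        self, min_size: int = 5, alpha: float | None = None
    ) -> list[tuple[str, tuple[str, ...]]]:
        """Up/down neighbor-gene sets of the reporters with >= min_size genes.

        Set ids are ``<metabolite_id>:up`` / ``<metabolite_id>:down``; each
        direction is emitted independently when it reaches min_size.
        """
        sets: list[tuple[str, tuple[str, ...]]] = []
        for _, row in self.reporters(alpha).iterrows():
            for direction, col in (("up", "up_genes"), ("down", "down_genes")):
                genes = tuple(g for g in str(row[col]).split(";") if g)
                if len(genes) >= min_size:
                    sets.append((f"{row['metabolite_id']}:{direction}", genes))
        return sets

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the top-ranked metabolites."""
        n_rep = len(self.reporters())
        head = self.scores.head(top)[
            ["metabolite_id", "k", "z_corrected", "p", "n_up", "n_down"]
        ]
        lines = [
            "Reporter metabolite analysis",
            "=" * 60,
            f"metabolites scored:      {len(self.scores)}",
            f"reporters (p <= {self.params.alpha:g}): {n_rep}",
            f"background samples:      {self.params.n_background_samples}"
            f" (seed {self.params.seed})",
            "-" * 60,
            head.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# repmet reporter scores; seed={self.params.seed} "
                f"samples={self.params.n_background_samples} "
                f"alpha={self.params.alpha} dedup={self.params.dedup}\n"
            )
            self.scores.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_reporter_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"metabolite_id": str})
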