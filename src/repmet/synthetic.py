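"""Synthetic data generator for every stage of the reporter pipeline.

Emulates, at desk scale, the statistical structure the analysis assumes in real
inputs: a bipartite metabolite-reaction network with heavy-tailed metabolite
connectivity and isozyme/complex gene associations; two-group probe-level
expression with coordinated shifts planted around chosen metabolites;
multi-probeset genes; promoters drawn from an order-2 Markov background with
planted motif instances, column-shuffled decoy matrices and masked runs; and a
phenotype linearly coupled to a metabolite's centroid expression.

The generators also write the exact text formats the pipeline reads, plus a
truth JSON that records what was planted, so recovery can be checked end to end
without any external data.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import PFM, ALPHABET, MarkovBackground, reverse_complement, write_fasta, write_transfac
from .network import MetabolicNetwork, Metabolite, Reaction, neighbor_enzymes, write_network_tsv
from .postanalysis import centroid_profile

logger = logging.getLogger(__name__)

#: per-gene baseline mean / SD and per-observation probe noise SD (log2 scale)
BASELINE_MEAN = 8.0
BASELINE_SD = 1.0
PROBE_NOISE_SD = 0.4

GROUP_CASE = "case"
GROUP_CONTROL = "control"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    effect_size is the planted mean shift in units of the between-gene baseline
    SD (1 log2 unit), so the default 1.5 is a 1.5 log2-fold-change (~2.8x) —
    a strongly differential gene whose two-group p-value lands around 1e-4 at
    10 samples per group.  frac_neighbors_affected is the fraction of a planted
    metabolite's neighbor genes that receive the shift, with one coherent sign
    per metabolite.
    """

    n_metabolites: int = 50
    n_reactions: int = 140
    n_genes: int = 280
    degree_power: float = 2.2
    complex_rate: float = 0.15
    isozyme_rate: float = 0.15
    n_planted_reporters: int = 5
    effect_size: float = 1.5
    frac_neighbors_affected: float = 0.8
    n_samples_per_group: int = 10
    probes_per_gene_law: tuple[tuple[int, float], ...] = ((1, 0.6), (2, 0.3), (3, 0.1))
    promoter_length: int = 1000
    motif_plant_rate: float = 0.9
    bg_order: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_metabolites",
            "n_reactions",
            "n_genes",
            "n_samples_per_group",
            "promoter_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "complex_rate",
            "isozyme_rate",
            "frac_neighbors_affected",
            "motif_plant_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_reactions < self.n_metabolites / 2:
            raise ValueError("need n_reactions >= n_metabolites / 2")


# ---------------------------------------------------------------------------------
# network generation


def _metabolite_weights(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed popularity weights: Pareto with density ~ w^-degree_power,
    truncated at 100x the minimum so hubs stay finite."""
    u = rng.random(cfg.n_metabolites)
    w = (1.0 - u) ** (-1.0 / (cfg.degree_power - 1.0))
    return np.minimum(w, 100.0)


def gen_network(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[MetabolicNetwork, list[str]]:
    """Bipartite metabolite-reaction network with planted reporter candidates.

    Metabolite degrees follow a truncated power law (hubs mimic ATP/NAD+
    connectivity); each reaction carries 2-4 metabolites and a 1-3 gene
    association (single enzyme, AND complex or OR isozyme group by the
    configured rates).  Planted reporters are drawn among metabolites with at
    least 5 neighbor reactions and a localized gene neighborhood (5-15
    distinct neighbor genes): a coordinated transcriptional program perturbs a
    pathway-sized neighborhood, not the global cofactor hubs, which remain in
    the network as unplanted high-degree nodes.  Generation is retried (fresh
    weights) up to 100 times if too few candidates arise.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    mids = [f"M{i:04d}" for i in range(cfg.n_metabolites)]
    gids = [f"G{i:04d}" for i in range(cfg.n_genes)]

    last_err = "no attempt made"
    for _attempt in range(100):
        weights = _metabolite_weights(cfg, rng)
        probs = weights / weights.sum()
        reactions: dict[str, Reaction] = {}
        gene_assoc: dict[str, tuple[str, ...]] = {}
        gpr_rules: dict[str, str] = {}
        for r in range(cfg.n_reactions):
            rid = f"R{r:04d}"
            size = int(rng.choice([2, 3, 4], p=[0.35, 0.40, 0.25]))
            part_idx = rng.choice(cfg.n_metabolites, size=size, replace=False, p=probs)
            roles = rng.random(size) < 0.5
            participants = tuple(
                (mids[i], "substrate" if s else "product")
                for i, s in zip(part_idx, roles)
            )
            reactions[rid] = Reaction(rid, participants)
            u = rng.random()
            if u < cfg.complex_rate:
                k = int(rng.integers(2, 4))
                genes = sorted(rng.choice(gids, size=k, replace=False))
                gpr_rules[rid] = " and ".join(genes)
            elif u < cfg.complex_rate + cfg.isozyme_rate:
                k = int(rng.integers(2, 4))
                genes = sorted(rng.choice(gids, size=k, replace=False))
                gpr_rules[rid] = " or ".join(genes)
            else:
                genes = [str(rng.choice(gids))]
                gpr_rules[rid] = genes[0]
            gene_assoc[rid] = tuple(genes)

        # guarantee every metabolite appears in at least one reaction
        used = {mid for rxn in reactions.values() for mid, _ in rxn.participants}
        orphan = [m for m in mids if m not in used]
        rids = sorted(reactions)
        for m in orphan:
            rid = rids[int(rng.integers(len(rids)))]
            old = reactions[rid]
            reactions[rid] = Reaction(
                rid, old.participants + ((m, "substrate"),)
            )

        network = MetabolicNetwork(
            {m: Metabolite(m, name=m) for m in mids}, reactions, gene_assoc, gpr_rules
        )
        candidates = [
            m
            for m in mids
            if len(network.neighbor_reactions(m)) >= 5
            and 5
            <= len({g for u_ in neighbor_enzymes(network, m) for g in u_.gene_ids})
            <= 15
        ]
        if len(candidates) >= cfg.n_planted_reporters:
            truth = sorted(
                rng.choice(candidates, size=cfg.n_planted_reporters, replace=False)
            )
            return network, [str(m) for m in truth]
        last_err = (
            f"only {len(candidates)} metabolites with degree >= 5 "
            f"(need {cfg.n_planted_reporters})"
        )
    raise RuntimeError(f"could not realize degree sequence after 100 attempts: {last_err}")


# ---------------------------------------------------------------------------------
# expression generation


def planted_effects(
    network: MetabolicNetwork,
    truth: Sequence[str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, float], dict[str, str]]:
    """(gene -> shift, metabolite -> direction) for the planted reporters.

    A coherent sign is drawn per metabolite; frac_neighbors_affected of its
    distinct neighbor genes receive shift = sign * effect_size * BASELINE_SD.
    A gene touched by several planted metabolites keeps its first assignment.
    """
    shifts: dict[str, float] = {}
    directions: dict[str, str] = {}
    for m in sorted(truth):
        genes = sorted({g for u in neighbor_enzymes(network, m) for g in u.gene_ids})
        n_aff = max(1, round(cfg.frac_neighbors_affected * len(genes)))
        chosen = sorted(rng.choice(genes, size=n_aff, replace=False))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        directions[m] = "up" if sign > 0 else "down"
        for g in chosen:
            shifts.setdefault(str(g), sign * cfg.effect_size * BASELINE_SD)
    return shifts, directions


def gen_expression(
    network: MetabolicNetwork,
    truth: Sequence[str],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], dict[str, str]]:
    """Two-group probe-level matrix with planted coordinated shifts.

    Returns (expr probes x samples, probe_map, groups, metabolite directions).
    Per-gene baseline ~ Normal(8, 1); observation noise SD 0.4; genes
    neighboring planted metabolites are shifted in the case group; all other
    genes are null.  Probes per gene follow the configured law, all rank tier 1.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    # the simulated chip carries the whole gene pool, not only the genes the
    # network happens to use — as with real arrays, where network coverage is
    # partial in both directions
    pool = {f"G{i:04d}" for i in range(cfg.n_genes)}
    genes = sorted(pool | network.genes())
    shifts, directions = planted_effects(network, truth, cfg, rng)

    n = cfg.n_samples_per_group
    samples = [f"case{i:02d}" for i in range(n)] + [f"ctrl{i:02d}" for i in range(n)]
    groups = {s: (GROUP_CASE if s.startswith("case") else GROUP_CONTROL) for s in samples}
    is_case = np.array([groups[s] == GROUP_CASE for s in samples])

    counts, probs = zip(*cfg.probes_per_gene_law)
    probe_rows = []
    data = []
    for g in genes:
        baseline = BASELINE_MEAN + BASELINE_SD * rng.standard_normal()
        shift = shifts.get(g, 0.0)
        n_probes = int(rng.choice(counts, p=np.asarray(probs) / sum(probs)))
        for j in range(n_probes):
            pid = f"{g}_p{j + 1}"
            probe_rows.append((pid, g, 1))
            mean = baseline + np.where(is_case, shift, 0.0)
            data.append(mean + PROBE_NOISE_SD * rng.standard_normal(len(samples)))
    expr = pd.DataFrame(
        np.asarray(data), index=[r[0] for r in probe_rows], columns=samples
    )
    expr.index.name = "probe_id"
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id", "rank_tier"])
    return expr, probe_map, groups, directions


# ---------------------------------------------------------------------------------
# promoter / motif generation


def make_pfm(
    rng: np.random.Generator, length: int = 10, pfm_id: str = "TRUE01", depth: int = 12
) -> PFM:
    """Informative random motif: per column a dominant base (count ``depth``)
    plus light noise counts on the other bases.

    Dominant-base assignments are redrawn until no base dominates more than
    half the columns: a near-homopolymeric motif would be invariant under
    column shuffling, which would break the decoys' role as negative controls.
    """
    for _ in range(200):
        doms = rng.integers(0, 4, size=length)
        if np.bincount(doms, minlength=4).max() <= length // 2:
            break
    counts = np.zeros((4, length))
    for j, dom in enumerate(doms):
        counts[:, j] = rng.integers(0, 3, size=4)
        counts[dom, j] = depth
    return PFM(pfm_id, f"motif_{pfm_id}", counts)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def shuffle_columns(pfm: PFM, rng: np.random.Generator, decoy_id: str) -> PFM:
    """Decoy matrix: same columns, permuted order (information content kept).

    Permutations whose consensus stays within Hamming distance 3 of the
    original consensus (or its reverse complement — scanning is
    strand-symmetric) are rejected: such a shuffle would still recognise the
    planted sites and be no negative control at all.
    """
    cons = pfm.consensus
    rc = reverse_complement(cons)
    best_perm, best_d = None, -1
    for _ in range(500):
        perm = rng.permutation(pfm.length)
        shuffled = "".join(cons[i] for i in perm)
        d = min(_hamming(shuffled, cons), _hamming(shuffled, rc))
        if d >= 3:
            best_perm = perm
            break
        if d > best_d:
            best_perm, best_d = perm, d
    return PFM(decoy_id, f"motif_{decoy_id}", pfm.counts[:, best_perm])


def _plant_instance(pfm: PFM, rng: np.random.Generator) -> str:
    """Motif instance to insert: the consensus sequence.

    Planting the consensus (rather than a column-sampled realisation) makes the
    generator's guarantee exact: under the scanner's 70%-of-maximum threshold a
    planted promoter always contains a hit, so the planting rate is the hit
    rate.  Site-to-site degeneracy in real promoters is instead represented by
    the matrix itself when scanning.
    """
    del rng  # strand choice randomised by the caller
    return pfm.consensus


def _sample_background(
    bg: MarkovBackground, length: int, rng: np.random.Generator
) -> str:
    """Fast inverse-CDF sampling from the Markov model."""
    cond_cum = np.cumsum(np.exp(bg.cond_logp), axis=1)
    cond_cum /= cond_cum[:, -1:]
    marg_cum = np.cumsum(np.exp(bg.marginal_logp))
    marg_cum /= marg_cum[-1]
    us = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    n_ctx = max(4**bg.order, 1)
    ctx = 0
    for i in range(length):
        if bg.order and i >= bg.order:
            b = int(np.searchsorted(cond_cum[ctx], us[i]))
        else:
            b = int(np.searchsorted(marg_cum, us[i]))
        b = min(b, 3)
        ctx = (ctx * 4 + b) % n_ctx
        out[i] = b
    return "".join(ALPHABET[b] for b in out)


def gen_promoters(
    genes: Sequence[str],
    planted_genes: Iterable[str],
    pfm: PFM,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_decoys: int = 10,
    mask_frac: float = 0.05,
    mask_run: int = 8,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame, list[PFM]]:
    """Promoters from an order-``bg_order`` Markov background with planted motifs.

    Genes in ``planted_genes`` receive one consensus-sampled motif instance at a
    uniform offset on a random strand with probability motif_plant_rate; 5% of
    bases are masked to N in short runs that never overlap a planted instance;
    ``n_decoys`` column-shuffled decoys of the true matrix are returned.

    Returns (promoters by gene, genome by chromosome, TSS table, decoys); the
    genome/TSS pair reproduces exactly the returned promoters through
    :func:`repmet.motif.extract_promoters`.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    planted_genes = set(planted_genes)
    L = cfg.promoter_length
    if pfm.length >= L:
        raise ValueError("motif longer than promoter")

    train_genome = "".join(
        ALPHABET[b] for b in rng.integers(0, 4, size=30_000)
    )
    bg = MarkovBackground.train([train_genome], order=cfg.bg_order)

    promoters: dict[str, str] = {}
    genome_parts: list[str] = []
    tss_rows = []
    pos = 0
    for gene in genes:
        seq = _sample_background(bg, L, rng)
        planted_span: tuple[int, int] | None = None
        if gene in planted_genes and rng.random() < cfg.motif_plant_rate:
            inst = _plant_instance(pfm, rng)
            if rng.random() < 0.5:
                inst = reverse_complement(inst)
            off = int(rng.integers(0, L - pfm.length + 1))
            seq = seq[:off] + inst + seq[off + pfm.length :]
            planted_span = (off, off + pfm.length)
        # mask short runs to N, never inside the planted instance
        n_runs = int(mask_frac * L / mask_run)
        chars = list(seq)
        for _ in range(n_runs):
            for _try in range(20):
                s = int(rng.integers(0, L - mask_run + 1))
                if planted_span and not (
                    s + mask_run <= planted_span[0] or s >= planted_span[1]
                ):
                    continue
                chars[s : s + mask_run] = "N" * mask_run
                break
        seq = "".join(chars)
        promoters[gene] = seq

        spacer = "".join(ALPHABET[b] for b in rng.integers(0, 4, size=100))
        strand = "+" if rng.random() < 0.5 else "-"
        start = pos + len(spacer)
        if strand == "+":
            genome_parts.append(spacer + seq)
            tss = start + 800
        else:
            genome_parts.append(spacer + reverse_complement(seq))
            tss = start + (L - 800 - 1)
        tss_rows.append(("chr1", tss, strand, gene))
        pos = start + L

    genome = {"chr1": "".join(genome_parts)}
    tss_table = pd.DataFrame(tss_rows, columns=["chrom", "tss", "strand", "gene_id"])
    decoys = [
        shuffle_columns(pfm, rng, f"DECOY{i + 1:02d}") for i in range(n_decoys)
    ]
    return promoters, genome, tss_table, decoys


# ---------------------------------------------------------------------------------
# phenotype generation


def gen_phenotype(
    expr: pd.DataFrame,
    probe_map: pd.DataFrame,
    network: MetabolicNetwork,
    metabolite_id: str,
    groups: Mapping[str, str],
    slope: float = 1.0,
    noise_sd: float = 0.3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Phenotype linearly coupled to a metabolite's centroid expression.

    value(sample) = slope * centroid(sample) + Normal(0, noise_sd).
    Returns a (sample, value, group) table.
    """
    rng = rng or np.random.default_rng(0)
    gene_expr = gene_level_expression(expr, probe_map)
    centroid = centroid_profile(gene_expr, network, metabolite_id)
    noise = noise_sd * rng.standard_normal(len(centroid))
    return pd.DataFrame(
        {
            "sample": centroid.index,
            "value": slope * centroid.to_numpy() + noise,
            "group": [groups[s] for s in centroid.index],
        }
    )


def gene_level_expression(expr: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Mean expression per gene over its probes (genes x samples)."""
    m = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))
    genes = expr.index.map(lambda p: m.get(str(p)))
    out = expr.groupby(genes.astype(str)).mean()
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------------
# full dataset on disk


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete synthetic study to ``outdir``.

    Files: network.tsv, expression.tsv, probe_map.tsv, groups.tsv,
    promoters.fasta, motifs.transfac, phenotype.tsv, plus truth.json recording
    everything planted.  Byte-identical for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    network, truth = gen_network(cfg, rng)
    expr, probe_map, groups, directions = gen_expression(network, truth, cfg, rng)
    shift_rng = np.random.default_rng([cfg.seed, 1])
    true_pfm = make_pfm(shift_rng)
    planted_gene_sets = {
        m: sorted({g for u in neighbor_enzymes(network, m) for g in u.gene_ids})
        for m in truth
    }
    planted_genes = sorted({g for gs in planted_gene_sets.values() for g in gs})
    promoters, _genome, _tss, decoys = gen_promoters(
        sorted(network.genes()), planted_genes, true_pfm, cfg, shift_rng
    )
    phenotype = gen_phenotype(
        expr, probe_map, network, truth[0], groups, rng=np.random.default_rng([cfg.seed, 2])
    )

    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "groups": outdir / "groups.tsv",
        "promoters": outdir / "promoters.fasta",
        "motifs": outdir / "motifs.transfac",
        "phenotype": outdir / "phenotype.tsv",
        "truth": outdir / "truth.json",
    }
    write_network_tsv(network, paths["network"])
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    probe_map.to_csv(paths["probe_map"], sep="\t", index=False)
    pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(paths["groups"], sep="\t", index=False)
    write_fasta(promoters, paths["promoters"])
    write_transfac([true_pfm] + decoys, paths["motifs"])
    phenotype.to_csv(paths["phenotype"], sep="\t", index=False, float_format="%.6f")
    truth_doc = {
        "planted_reporters": truth,
        "directions": directions,
        "neighbor_genes": planted_gene_sets,
        "true_motif": true_pfm.id,
        "decoy_motifs": [d.id for d in decoys],
        "phenotype_metabolite": truth[0],
        "contrast": [GROUP_CASE, GROUP_CONTROL],
        "seed": cfg.seed,
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    logger.info("synthetic dataset written to %s", outdir)
    return paths
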