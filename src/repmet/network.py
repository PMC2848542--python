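"""Metabolic network topology: metabolites, reactions and gene-protein-reaction rules.

The reporter-metabolite statistic walks the bipartite metabolite-reaction graph of a
genome-scale reconstruction: every metabolite is scored from the enzymes catalysing
the reactions in which it participates as substrate or product.  This module parses
networks (SBML with gene associations, or a 4-column TSV), validates them, and
exposes the metabolite -> neighbor-enzyme -> gene mapping with the min-p GPR
collapse used by the scoring.

Only topology matters here: stoichiometric coefficients, reversibility and flux
semantics are deliberately ignored.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

ROLES = ("substrate", "product")

#: default pattern recognising compartment suffixes such as "atp_c", "atp[m]",
#: "glc_D_e"; the trailing 1-2 character tag is stripped when collapsing.
DEFAULT_COMPARTMENT_PATTERN = r"(?:_[a-z0-9]{1,2}|\[[a-z0-9]{1,2}\])$"


class NetworkError(Exception):
    """Base class for network parsing/validation problems."""


class NetworkParseError(NetworkError):
    """Unreadable or malformed input; message names the offending line/element."""


class NetworkValidationError(NetworkError):
    """Structurally invalid network; message lists the offenders."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    #: (metabolite_id, role) pairs, role in ROLES
    participants: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class EnzymeUnit:
    """One enzyme attached to a metabolite: a distinct set of coding genes.

    Two units with identical ``gene_ids`` around the same metabolite are merged so a
    single transcript signal is never counted twice; ``source_reaction_ids`` records
    which reactions contributed the unit.
    """

    gene_ids: frozenset[str]
    source_reaction_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("EnzymeUnit requires a non-empty gene set")


@dataclass
class MetabolicNetwork:
    """Validated bipartite metabolite-reaction graph with gene associations.

    ``gene_associations`` maps reaction id to the flattened list of gene ids
    (possibly empty for spontaneous/transport reactions); ``gpr_rules`` optionally
    retains the original boolean AND/OR rule strings for provenance.
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    gene_associations: dict[str, tuple[str, ...]]
    gpr_rules: dict[str, str] = field(default_factory=dict)
    _neighbors: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        self._index()

    # -- construction / validation -------------------------------------------------

    def validate(self) -> None:
        problems: list[str] = []
        for rid, rxn in self.reactions.items():
            if not rxn.participants:
                problems.append(f"reaction {rid!r} has no participants")
            for mid, role in rxn.participants:
                if role not in ROLES:
                    problems.append(f"reaction {rid!r}: unknown role {role!r}")
                if mid not in self.metabolites:
                    problems.append(
                        f"reaction {rid!r}: dangling metabolite reference {mid!r}"
                    )
        for rid in self.gene_associations:
            if rid not in self.reactions:
                problems.append(f"gene association for unknown reaction {rid!r}")
        if problems:
            raise NetworkValidationError(
                "invalid network: " + "; ".join(sorted(problems))
            )

    def _index(self) -> None:
        nbr: dict[str, list[str]] = {mid: [] for mid in self.metabolites}
        for rid in sorted(self.reactions):
            for mid, _role in self.reactions[rid].participants:
                if rid not in nbr[mid]:
                    nbr[mid].append(rid)
        self._neighbors = {mid: tuple(rids) for mid, rids in nbr.items()}

    # -- queries -------------------------------------------------------------------

    def neighbor_reactions(self, metabolite_id: str) -> tuple[str, ...]:
        try:
            return self._neighbors[metabolite_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id {metabolite_id!r}") from None

    def genes(self) -> frozenset[str]:
        """All gene ids appearing in any gene association."""
        return frozenset(g for gs in self.gene_associations.values() for g in gs)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


# ---------------------------------------------------------------------------------
# neighbor enzymes and GPR scoring


def neighbor_enzymes(
    network: MetabolicNetwork, metabolite_id: str, dedup: bool = True
) -> list[EnzymeUnit]:
    """Enzymes catalysing reactions that involve ``metabolite_id``.

    One :class:`EnzymeUnit` per distinct gene set over the metabolite's neighbor
    reactions (substrate and product roles are equivalent).  Reactions without gene
    association contribute nothing.  With ``dedup=False`` every gene-associated
    neighbor reaction yields its own unit (sensitivity-analysis mode).
    """
    units: dict[frozenset[str], set[str]] = {}
    out: list[EnzymeUnit] = []
    for rid in network.neighbor_reactions(metabolite_id):
        genes = frozenset(network.gene_associations.get(rid, ()))
        if not genes:
            continue
        if dedup:
            units.setdefault(genes, set()).add(rid)
        else:
            out.append(EnzymeUnit(genes, frozenset({rid})))
    if dedup:
        out = [EnzymeUnit(gs, frozenset(rids)) for gs, rids in units.items()]
    out.sort(key=lambda u: (sorted(u.gene_ids), sorted(u.source_reaction_ids)))
    return out


def score_enzyme(
    unit: EnzymeUnit, gene_scores: Mapping[str, float]
) -> float | None:
    """Collapse a GPR group to one p-value: the minimum over its scored genes.

    Isozymes (OR) and complexes (AND) are treated alike — the most significant gene
    speaks for the enzyme.  Genes without a score are ignored; ``None`` is returned
    when no gene of the unit is scored (the unit is then excluded from k).
    """
    scored = min_p_gene(unit, gene_scores)
    return None if scored is None else scored[0]


def min_p_gene(
    unit: EnzymeUnit, gene_scores: Mapping[str, float]
) -> tuple[float, str] | None:
    """(min p, argmin gene) over the unit's scored genes; ties break to the
    lexicographically smallest gene id for determinism."""
    best: tuple[float, str] | None = None
    for g in sorted(unit.gene_ids):
        p = gene_scores.get(g)
        if p is None:
            continue
        if best is None or p < best[0]:
            best = (float(p), g)
    return best


# ---------------------------------------------------------------------------------
# compartment collapse


def collapse_compartments(
    network: MetabolicNetwork, pattern: str = DEFAULT_COMPARTMENT_PATTERN
) -> MetabolicNetwork:
    """Merge metabolites that differ only in a compartment suffix.

    The merged node keeps the stripped id, the first-seen name, an empty
    compartment, and the union of neighbor reactions.
    """
    rx = re.compile(pattern)
    mapping = {mid: rx.sub("", mid) or mid for mid in network.metabolites}
    merged: dict[str, Metabolite] = {}
    for mid in sorted(network.metabolites):
        new_id = mapping[mid]
        if new_id not in merged:
            old = network.metabolites[mid]
            merged[new_id] = Metabolite(new_id, old.name, "")
    reactions = {
        rid: Reaction(
            rid, tuple((mapping[mid], role) for mid, role in rxn.participants)
        )
        for rid, rxn in network.reactions.items()
    }
    return MetabolicNetwork(
        merged, reactions, dict(network.gene_associations), dict(network.gpr_rules)
    )


# ---------------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ("reaction_id", "metabolite_id", "role", "gene_ids")


def load_network(
    path: str | Path,
    format: str | None = None,
    collapse_compartments: bool = False,
    compartment_pattern: str = DEFAULT_COMPARTMENT_PATTERN,
) -> MetabolicNetwork:
    """Load a metabolic network from SBML or tab-delimited reaction table.

    ``format`` is ``"sbml"`` or ``"tsv"``; when omitted it is inferred from the
    file suffix (.xml/.sbml -> sbml, otherwise tsv).
    """
    path = Path(path)
    if not path.exists():
        raise NetworkParseError(f"network file not found: {path}")
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tsv"
    if format == "sbml":
        net = _load_sbml(path)
    elif format == "tsv":
        net = _load_tsv(path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    if collapse_compartments:
        net = globals()["collapse_compartments"](net, compartment_pattern)
    logger.info(
        "loaded network: %d metabolites, %d reactions, %d genes",
        net.n_metabolites,
        net.n_reactions,
        len(net.genes()),
    )
    return net


def _load_tsv(path: Path) -> MetabolicNetwork:
    metabolites: dict[str, Metabolite] = {}
    participants: dict[str, list[tuple[str, str]]] = {}
    gene_assoc: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != _TSV_COLUMNS:
            raise NetworkParseError(
                f"{path}:1: expected header {_TSV_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise NetworkParseError(f"{path}:{lineno}: expected >=3 columns")
            rid, mid, role = parts[0], parts[1], parts[2]
            genes_field = parts[3] if len(parts) > 3 else ""
            if role not in ROLES:
                raise NetworkValidationError(
                    f"{path}:{lineno}: unknown role token {role!r}"
                )
            metabolites.setdefault(mid, Metabolite(mid))
            participants.setdefault(rid, []).append((mid, role))
            genes = tuple(g for g in genes_field.split(";") if g)
            prev = gene_assoc.get(rid)
            if prev is not None and genes and prev != genes:
                raise NetworkParseError(
                    f"{path}:{lineno}: inconsistent gene_ids for reaction {rid!r}"
                )
            if genes or prev is None:
                gene_assoc[rid] = genes
    reactions = {
        rid: Reaction(rid, tuple(parts)) for rid, parts in participants.items()
    }
    return MetabolicNetwork(metabolites, reactions, gene_assoc)


def _load_sbml(path: Path) -> MetabolicNetwork:
    import cobra.io

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml reports element-level errors
            raise NetworkParseError(f"cannot parse SBML {path}: {exc}") from exc
    metabolites = {
        m.id: Metabolite(m.id, m.name or "", m.compartment or "")
        for m in model.metabolites
    }
    reactions: dict[str, Reaction] = {}
    gene_assoc: dict[str, tuple[str, ...]] = {}
    gpr_rules: dict[str, str] = {}
    for rxn in model.reactions:
        parts = tuple(
            (m.id, "substrate" if coef < 0 else "product")
            for m, coef in rxn.metabolites.items()
        )
        reactions[rxn.id] = Reaction(rxn.id, parts)
        gene_assoc[rxn.id] = tuple(sorted(g.id for g in rxn.genes))
        rule = rxn.gene_reaction_rule
        if rule:
            gpr_rules[rxn.id] = rule
    return MetabolicNetwork(metabolites, reactions, gene_assoc, gpr_rules)


def write_network_tsv(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the 4-column reaction table; round-trips through :func:`load_network`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for rid in sorted(network.reactions):
            genes = ";".join(network.gene_associations.get(rid, ()))
            for mid, role in network.reactions[rid].participants:
                fh.write(f"{rid}\t{mid}\t{role}\t{genes}\n")


def network_enzyme_units(
    network: MetabolicNetwork, dedup: bool = True
) -> list[EnzymeUnit]:
    """All enzyme units of the network (the background population for sampling).

    With ``dedup`` (default) one unit per distinct gene set network-wide; otherwise
    one per gene-associated reaction.
    """
    units: dict[frozenset[str], set[str]] = {}
    out: list[EnzymeUnit] = []
    for rid in sorted(network.reactions):
        genes = frozenset(network.gene_associations.get(rid, ()))
        if not genes:
            continue
        if dedup:
            units.setdefault(genes, set()).add(rid)
        else:
            out.append(EnzymeUnit(genes, frozenset({rid})))
    if dedup:
        out = [EnzymeUnit(gs, frozenset(rids)) for gs, rids in units.items()]
    out.sort(key=lambda u: (sorted(u.gene_ids), sorted(u.source_reaction_ids)))
    return out
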