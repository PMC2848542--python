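import numpy as np
import pytest

from repmet.network import MetabolicNetwork, Metabolite, Reaction


def build_network(rows, gene_assoc):
    """Construct a network from (reaction, metabolite, role) triples."""
    mets = {}
    parts = {}
    for rid, mid, role in rows:
        mets.setdefault(mid, Metabolite(mid))
        parts.setdefault(rid, []).append((mid, role))
    reactions = {rid: Reaction(rid, tuple(p)) for rid, p in parts.items()}
    return MetabolicNetwork(mets, reactions, {r: tuple(g) for r, g in gene_assoc.items()})


@pytest.fixture
def toy_network():
    """One metabolite M hit by three reactions; gene sets {g1}, {g1}, {g2,g3}."""
    return build_network(
        rows=[
            ("R1", "M", "substrate"),
            ("R1", "X", "product"),
            ("R2", "M", "product"),
            ("R2", "Y", "substrate"),
            ("R3", "M", "substrate"),
            ("R3", "X", "product"),
            ("R4", "Y", "product"),
            ("R4", "X", "substrate"),
        ],
        gene_assoc={"R1": ["g1"], "R2": ["g1"], "R3": ["g2", "g3"], "R4": []},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
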