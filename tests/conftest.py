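"""Shared fixtures: small motifs, trees, and a reusable simulated
bundle."""

from __future__ import annotations

import numpy as np
import pytest

from tfbsbench.motif_models import CountMatrix, KmerSet, SubstitutionMatrix
from tfbsbench.phylo import PhyloTree
from tfbsbench.synth_sim import SimConfig, default_motif, simulate


@pytest.fixture(scope="session")
def high_ic_motif() -> CountMatrix:
    return default_motif("high")


@pytest.fixture(scope="session")
def low_ic_motif() -> CountMatrix:
    return default_motif("low")


@pytest.fixture
def small_kmers() -> KmerSet:
    return KmerSet(["TGACGTCATG", "TGACGTCCTG", "TGACGTAATG"],
                   motif_id="toy")


@pytest.fixture
def flat_submatrix() -> SubstitutionMatrix:
    s = np.full((4, 4), 0.4)
    np.fill_diagonal(s, 1.0)
    return SubstitutionMatrix(s)


@pytest.fixture(scope="session")
def four_leaf_tree() -> PhyloTree:
    return PhyloTree.from_newick(
        "((hg:0.12,(mm:0.25,rn:0.22):0.18):0.08,canFam:0.45);"
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """A small, fully conserved, indel-free bundle reused across tests."""
    cfg = SimConfig(length=12_000, n_sites=8, seed=7, n_decoy_peaks=2,
                    site_conservation=1.0, substitution_rate=0.4)
    return simulate(cfg)


def random_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary topology with uniform(0.05, 1) branch lengths."""
    nodes = [f"l{i}:{rng.uniform(0.05, 1.0):.4f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b})")
        else:
            nodes.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.4f}")
    return nodes[0] + ";"
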