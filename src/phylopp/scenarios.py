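"""Synthetic-data scenarios with the statistical pathologies the pipeline is
designed to detect: among-lineage compositional shifts, per-site restriction
to few residues (low biochemical diversity), and long-branch homoplasy in an
LBA-prone quartet. Every generator is a pure function of its knobs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .likelihood import simulate_alignment
from .models import (CompositionField, MixtureModel, ModelSpec, load_matrix,
                     mixture_model, ndch_model, single_model)
from .tree import PhyloTree, balanced_tree, quartet_tree


@dataclass
class Scenario:
    """Provenance of a simulated dataset: truth plus generator knobs."""

    name: str
    true_tree: str  # newick
    model: ModelSpec
    knobs: dict
    seed: int


def _paint_two_clades(tree: PhyloTree, K: int) -> dict[int, int]:
    """Assign composition vectors to nodes: the principal subtrees of the
    root trifurcation get vectors 1, 2, … (cycled); the root keeps vector 0."""
    assign = {tree.root.id: 0}
    for i, top in enumerate(tree.root.children):
        vec = i % K
        stack = [top]
        while stack:
            n = stack.pop()
            assign[n.id] = vec
            stack.extend(n.children)
    return assign


def make_composition_scenario(taxa: int = 8, K: int = 2, divergence: float = 20.0,
                              n_sites: int = 300, seed: int = 0,
                              matrix: str = "LG", alpha: float = 0.8,
                              branch_length: float = 0.15) -> tuple[Alignment, Scenario]:
    """Balanced tree whose principal clades evolve under different amino-acid
    compositions.

    ``divergence`` scales how far the K clade vectors scatter around the
    matrix's frequencies: vectors are Dirichlet draws with concentration
    ``200/divergence`` (divergence 1 ≈ negligible shifts; ≥20 produces shifts
    strong enough to fail a homogeneity X² test at a few hundred sites).
    """
    if K < 1 or taxa < 4:
        raise ValueError("need K >= 1 and taxa >= 4")
    rng = np.random.default_rng(seed)
    tree = balanced_tree(taxa, branch_length)
    ex = load_matrix(matrix)
    if K == 1:
        vectors = ex.pi[None, :]
    else:
        conc = 200.0 / divergence
        vectors = np.vstack([ex.pi]
                            + [rng.dirichlet(conc * ex.pi) for _ in range(K - 1)])
        vectors = np.maximum(vectors, 1e-4)
        vectors /= vectors.sum(axis=1, keepdims=True)
    field = CompositionField(vectors, _paint_two_clades(tree, K))
    model = ndch_model(ex, field, alpha=alpha)
    aln = simulate_alignment(tree, model, n_sites, rng)
    scen = Scenario("composition", tree.to_newick(), model,
                    dict(taxa=taxa, K=K, divergence=divergence,
                         n_sites=n_sites, matrix=matrix, alpha=alpha), seed)
    return aln, scen


def sparse_profile_mixture(profile_size: int, n_profiles: int = 8,
                           seed: int = 1234, base_matrix: str = "poisson") -> ModelSpec:
    """A profile mixture whose components allow only *profile_size* residues,
    emulating per-site biochemical restriction."""
    if not 1 <= profile_size <= 20:
        raise ValueError("profile_size must be in [1, 20]")
    rng = np.random.default_rng(seed)
    profiles = np.full((n_profiles, 20), 1e-6)
    for i in range(n_profiles):
        subset = rng.choice(20, size=profile_size, replace=False)
        profiles[i, subset] = rng.dirichlet(np.full(profile_size, 5.0))
    profiles /= profiles.sum(axis=1, keepdims=True)
    lib = MixtureModel(f"sparse{profile_size}", "profile-mixture", profiles,
                       np.full(n_profiles, 1.0 / n_profiles))
    return mixture_model(lib, alpha=1.0, base_matrix=base_matrix)


def make_diversity_scenario(profile_size: int = 3, n_sites: int = 300, seed: int = 0,
                            taxa: int = 8,
                            branch_length: float = 0.2) -> tuple[Alignment, Scenario]:
    """Data whose sites are restricted to small residue subsets, so that a
    single-matrix model overpredicts site diversity."""
    rng = np.random.default_rng(seed)
    tree = balanced_tree(taxa, branch_length)
    model = sparse_profile_mixture(profile_size, seed=seed + 7919)
    aln = simulate_alignment(tree, model, n_sites, rng)
    scen = Scenario("diversity", tree.to_newick(), model,
                    dict(profile_size=profile_size, n_sites=n_sites, taxa=taxa), seed)
    return aln, scen


def make_lba_scenario(long_branch_multiplier: float = 8.0, n_sites: int = 200,
                      seed: int = 0, short: float = 0.1, internal: float = 0.03,
                      profile_size: int = 3) -> tuple[Alignment, Scenario]:
    """Quartet-plus-outgroup with two *non-sister* long branches.

    True split AB|CD; leaves A and C carry branches ``multiplier`` times
    longer. Sites evolve under a sparse profile mixture, so the long branches
    accumulate convergent substitutions — the regime in which single-matrix
    models are drawn to the wrong AC|BD split.
    """
    if long_branch_multiplier < 1:
        raise ValueError("long-branch multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    tree = quartet_tree(short, short * long_branch_multiplier, internal)
    model = sparse_profile_mixture(profile_size, seed=seed + 104729)
    aln = simulate_alignment(tree, model, n_sites, rng)
    scen = Scenario("lba", tree.to_newick(), model,
                    dict(multiplier=long_branch_multiplier, n_sites=n_sites,
                         short=short, internal=internal,
                         profile_size=profile_size), seed)
    return aln, scen


_QUARTET_KEYS = {
    frozenset({"C", "D"}): "AB|CD", frozenset({"C", "D", "O"}): "AB|CD",
    frozenset({"B", "D"}): "AC|BD", frozenset({"B", "D", "O"}): "AC|BD",
    frozenset({"B", "C"}): "AD|BC", frozenset({"B", "C", "O"}): "AD|BC",
}
#: the planted quartet topology and the LBA artefact (long branches united)
TRUE_QUARTET = "AB|CD"
WRONG_QUARTET = "AC|BD"


def quartet_resolution(tree: PhyloTree) -> str | None:
    """Induced topology on {A,B,C,D}, ignoring where the outgroup attaches."""
    for side in tree.splits():
        topo = _QUARTET_KEYS.get(side)
        if topo:
            return topo
    return None


def quartet_frequencies(trees: list[PhyloTree]) -> dict[str, float]:
    """Posterior frequency of each quartet resolution in a tree sample."""
    out = {"AB|CD": 0.0, "AC|BD": 0.0, "AD|BC": 0.0}
    for t in trees:
        topo = quartet_resolution(t)
        if topo:
            out[topo] += 1.0 / len(trees)
    return out
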