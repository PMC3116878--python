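"""Felsenstein pruning likelihood and forward simulation on a tree.

The kernel is alphabet-generic (20-state amino acid or 6-state recoded) and
covers four model classes: a single reversible matrix, mixtures of matrices,
mixtures of frequency profiles, and node-discrete compositional heterogeneity
(NDCH), in which the generator on each branch uses the composition vector
assigned to the branch's child node and the root prior uses the root node's
vector. Partial likelihoods are rescaled per node with accumulated log
factors so 80-taxon 20-state trees do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import ALPHABETS, Alignment
from .models import ModelSpec, RateMatrix, transition_probabilities
from .tree import Node, PhyloTree


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods and, for mixtures, per-site component weights."""

    per_site: np.ndarray
    total: float
    component_weights: np.ndarray | None = None  # sites x components


def _leaf_partials(tree: PhyloTree, aln: Alignment) -> dict[int, np.ndarray]:
    """Indicator partials for each leaf; missing symbols become all-ones."""
    tree_leaves = set(tree.leaf_map)
    aln_taxa = set(aln.taxa)
    if tree_leaves != aln_taxa:
        raise ValueError(
            f"taxa mismatch: tree-only {sorted(tree_leaves - aln_taxa)}, "
            f"alignment-only {sorted(aln_taxa - tree_leaves)}"
        )
    enc = aln.encode()
    k = len(aln.states)
    out: dict[int, np.ndarray] = {}
    eye = np.eye(k)
    ones = np.ones(k)
    for row, taxon in enumerate(aln.taxa):
        codes = enc[row]
        part = np.where(codes[None, :] >= 0, eye[:, np.clip(codes, 0, None)].reshape(k, -1), ones[:, None])
        out[tree.leaf_map[taxon].id] = part
    return out


def _branch_rate_matrix(model: ModelSpec, node: Node, comp: int) -> RateMatrix:
    if model.kind == "ndch":
        return model.components[model.field.assignment[node.id]]
    return model.components[comp]


def _root_pi(model: ModelSpec, tree: PhyloTree, comp: int) -> np.ndarray:
    if model.kind == "ndch":
        return model.components[model.field.assignment[tree.root.id]].pi
    return model.components[comp].pi


def _prune_one(tree: PhyloTree, leaf_parts: dict[int, np.ndarray],
               model: ModelSpec, comp: int, rate: float) -> np.ndarray:
    """Per-site log-likelihood under one (component, rate-category) pair."""
    n_sites = next(iter(leaf_parts.values())).shape[1]
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_sites)
    for node in tree.postorder():
        if node.is_leaf:
            partial[node.id] = leaf_parts[node.id]
            continue
        acc = None
        for child in node.children:
            rm = _branch_rate_matrix(model, child, comp)
            P = transition_probabilities(rm, child.length, rate)
            contrib = P @ partial[child.id]
            acc = contrib if acc is None else acc * contrib
        m = acc.max(axis=0)
        m = np.where(m > 0, m, 1.0)
        partial[node.id] = acc / m
        logscale += np.log(m)
    pi = _root_pi(model, tree, comp)
    site_l = pi @ partial[tree.root.id]
    with np.errstate(divide="ignore"):
        return np.log(site_l) + logscale


def log_likelihood(tree: PhyloTree, aln: Alignment, model: ModelSpec) -> SiteLikelihoods:
    """Pruning log-likelihood summed over rate categories and mixture components."""
    if ALPHABETS[model.alphabet] != aln.states:
        raise ValueError(
            f"model alphabet {model.alphabet!r} does not match alignment {aln.alphabet!r}"
        )
    n_comp = 1 if model.kind == "ndch" else len(model.components)
    gam = model.gamma
    # log weight for each (component, category) pair
    terms = np.empty((n_comp, gam.K, aln.n_sites))
    leaf_parts = _leaf_partials(tree, aln)
    for c in range(n_comp):
        for g in range(gam.K):
            terms[c, g] = _prune_one(tree, leaf_parts, model, c, gam.rates[g])
    logw = (np.log(model.weights[:n_comp])[:, None]
            + np.log(gam.weights)[None, :])
    flat = terms.reshape(n_comp * gam.K, -1) + logw.reshape(-1, 1)
    per_site = logsumexp(flat, axis=0)
    comp_weights = None
    if n_comp > 1:
        comp_log = logsumexp(terms + np.log(gam.weights)[None, :, None], axis=1)
        comp_log = comp_log + np.log(model.weights[:n_comp])[:, None]
        comp_weights = np.exp(comp_log - logsumexp(comp_log, axis=0)).T
    return SiteLikelihoods(per_site, float(per_site.sum()), comp_weights)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _sample_rows(P: np.ndarray, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw next states from the transition-matrix rows indexed by *states*."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(states))
    return (u[:, None] > cum[states]).sum(axis=1)


def draw_site_classes(model: ModelSpec, n_sites: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mixture component and rate-category indices."""
    n_comp = 1 if model.kind == "ndch" else len(model.components)
    comp = rng.choice(n_comp, size=n_sites, p=model.weights[:n_comp]) if n_comp > 1 \
        else np.zeros(n_sites, dtype=int)
    cat = rng.choice(model.gamma.K, size=n_sites, p=model.gamma.weights)
    return comp, cat


def simulate_states(tree: PhyloTree, model: ModelSpec, n_sites: int,
                    rng: np.random.Generator,
                    comp: np.ndarray | None = None,
                    cat: np.ndarray | None = None) -> np.ndarray:
    """Simulate states at every node; returns an (n_nodes, n_sites) array."""
    if comp is None or cat is None:
        comp, cat = draw_site_classes(model, n_sites, rng)
    n_nodes = len(tree.nodes)
    states = np.zeros((n_nodes, n_sites), dtype=np.int64)
    n_comp = 1 if model.kind == "ndch" else len(model.components)
    for c in range(n_comp):
        sel = comp == c
        if not sel.any():
            continue
        pi = _root_pi(model, tree, c)
        states[tree.root.id, sel] = rng.choice(len(pi), size=int(sel.sum()), p=pi)
    for node in tree.preorder():
        if node.parent is None:
            continue
        for c in range(n_comp):
            rm = _branch_rate_matrix(model, node, c)
            for g in range(model.gamma.K):
                sel = (comp == c) & (cat == g)
                if not sel.any():
                    continue
                P = transition_probabilities(rm, node.length, model.gamma.rates[g])
                states[node.id, sel] = _sample_rows(P, states[node.parent.id, sel], rng)
    return states


def simulate_alignment(tree: PhyloTree, model: ModelSpec, n_sites: int,
                       seed: int | np.random.Generator) -> Alignment:
    """Simulate a gap-free alignment of *n_sites* columns on *tree*."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = simulate_states(tree, model, n_sites, rng)
    letters = np.array(list(ALPHABETS[model.alphabet]))
    taxa = sorted(tree.leaf_map)
    matrix = np.stack([letters[states[tree.leaf_map[t].id]] for t in taxa])
    return Alignment(taxa, matrix, model.alphabet)
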