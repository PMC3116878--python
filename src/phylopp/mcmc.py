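"""Metropolis–Hastings sampler over topology, branch lengths and model
parameters, with convergence diagnostics and majority-rule consensus trees.

Priors: branch lengths Exponential(mean 0.1), gamma shape alpha
Exponential(mean 1), flat Dirichlet on composition vectors and on free
exchangeabilities, uniform NDCH node assignment. The number of composition
vectors K is fixed per run and raised manually across runs, mirroring the
iterative add-a-vector workflow. A single unheated chain is the default;
independent replicate chains are compared for convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.stats import dirichlet as dirichlet_dist

from .alignment import Alignment
from .likelihood import log_likelihood
from .models import (CompositionField, ModelSpec, build_rate_matrix,
                     free_exchangeabilities)
from .tree import Node, PhyloTree, random_topology

DEFAULT_PROPOSAL_WEIGHTS = {
    "blen": 4.0, "nni": 2.0, "spr": 0.5, "alpha": 1.0,
    "pi": 2.0, "exch": 1.0, "assign": 1.0,
}


@dataclass
class ChainConfig:
    generations: int = 2000
    sample_every: int = 10
    burnin: float = 0.25
    seed: int = 0
    proposal_weights: dict = dfield(default_factory=dict)
    bl_prior_mean: float = 0.1
    alpha_prior_mean: float = 1.0
    sample_topology: bool = True
    sample_pi: bool = False           # resample stationary frequencies of a single model
    pi_concentration: float = 300.0   # Dirichlet proposal concentration
    prior_only: bool = False          # drop the likelihood term (validation runs)

    def __post_init__(self) -> None:
        if self.generations < self.sample_every or self.sample_every < 1:
            raise ValueError("need generations >= sample_every >= 1")
        if not 0 <= self.burnin < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")


@dataclass
class PosteriorSample:
    generation: int
    tree: PhyloTree
    model: ModelSpec
    alpha: float
    log_likelihood: float
    log_prior: float

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior

    @property
    def tree_length(self) -> float:
        return self.tree.total_length()


@dataclass
class ConvergenceReport:
    variable_discrepancies: dict[str, float]
    effective_sizes: dict[str, float]
    max_split_discrepancy: float
    asdsf: float

    def converged(self, max_split: float = 0.1, min_ess: float = 100.0) -> bool:
        return (self.max_split_discrepancy <= max_split
                and all(v >= min_ess for v in self.effective_sizes.values()))


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class _ChainState:
    def __init__(self, tree: PhyloTree, model: ModelSpec, alpha: float):
        self.tree = tree
        self.model = model
        self.alpha = alpha


def _log_prior(state: _ChainState, cfg: ChainConfig) -> float:
    lam_bl = 1.0 / cfg.bl_prior_mean
    lp = 0.0
    n_br = 0
    for n in state.tree.nodes:
        if n.parent is not None:
            lp += -lam_bl * n.length
            n_br += 1
    lp += n_br * math.log(lam_bl)
    lam_a = 1.0 / cfg.alpha_prior_mean
    lp += math.log(lam_a) - lam_a * state.alpha
    # flat Dirichlet terms are constant on the simplex; uniform assignment too
    return lp


def _log_lik(state: _ChainState, aln: Alignment, cfg: ChainConfig) -> float:
    if cfg.prior_only:
        return 0.0
    return log_likelihood(state.tree, aln, state.model).total


def _propose_dirichlet(vec: np.ndarray, conc: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Dirichlet(conc·vec) proposal around *vec*; returns (new, log-Hastings)."""
    floor = 1e-6
    prop = rng.dirichlet(np.maximum(conc * vec, 1e-2))
    prop = np.maximum(prop, floor)
    prop = prop / prop.sum()
    fwd = dirichlet_dist.logpdf(prop, np.maximum(conc * vec, 1e-2))
    rev = dirichlet_dist.logpdf(vec, np.maximum(conc * prop, 1e-2))
    return prop, rev - fwd


def _rebuild_ndch(model: ModelSpec, vectors: np.ndarray,
                  assignment: dict) -> ModelSpec:
    field = CompositionField(vectors, dict(assignment))
    comps = [build_rate_matrix(model.exchange, v) for v in vectors]
    return ModelSpec("ndch", model.alphabet, comps, np.array([1.0]),
                     model.gamma, model.exchange, field)


def _repair_assignment(model: ModelSpec, tree: PhyloTree,
                       rng: np.random.Generator) -> ModelSpec:
    """Ensure the NDCH assignment covers every node id after topology surgery."""
    if model.kind != "ndch":
        return model
    assign = dict(model.field.assignment)
    ids = {n.id for n in tree.nodes}
    changed = False
    for n in tree.preorder():
        if n.id not in assign:
            assign[n.id] = assign.get(n.parent.id, 0) if n.parent else 0
            changed = True
    for k in list(assign):
        if k not in ids:
            del assign[k]
            changed = True
    if not changed:
        return model
    return ModelSpec("ndch", model.alphabet, model.components, model.weights,
                     model.gamma, model.exchange,
                     CompositionField(model.field.vectors, assign))


def run_chain(aln: Alignment, model: ModelSpec, config: ChainConfig,
              tree: PhyloTree | None = None) -> list[PosteriorSample]:
    """Run one Metropolis–Hastings chain; returns samples at the configured
    interval (burn-in is applied downstream by consumers)."""
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = random_topology(list(aln.taxa), rng,
                               branch_length_mean=config.bl_prior_mean)
    else:
        tree = tree.copy()
    model = _repair_assignment(model, tree, rng)
    state = _ChainState(tree, model, model.gamma.alpha)

    moves = dict(DEFAULT_PROPOSAL_WEIGHTS)
    moves.update(config.proposal_weights)
    if not config.sample_topology or state.tree.n_leaves < 4:
        moves["nni"] = moves["spr"] = 0.0
    if model.kind != "ndch" and not config.sample_pi:
        moves["pi"] = 0.0
    if model.exchange is None or not model.exchange.name.startswith("free"):
        moves["exch"] = 0.0
    if model.kind != "ndch" or model.field.K < 2:
        moves["assign"] = 0.0
    names = [k for k, w in moves.items() if w > 0]
    probs = np.array([moves[k] for k in names])
    probs = probs / probs.sum()

    cur_ll = _log_lik(state, aln, config)
    cur_lp = _log_prior(state, config)
    if not np.isfinite(cur_ll + cur_lp):
        raise ValueError(
            f"non-finite log posterior at initialization (logL={cur_ll}, prior={cur_lp})"
        )

    samples: list[PosteriorSample] = []
    accepted = {k: 0 for k in names}
    attempted = {k: 0 for k in names}

    for gen in range(1, config.generations + 1):
        kind = names[rng.choice(len(names), p=probs)]
        attempted[kind] += 1
        log_hastings = 0.0
        new_state = _ChainState(state.tree, state.model, state.alpha)
        undo = None

        if kind == "blen":
            branches = [n for n in state.tree.nodes if n.parent is not None]
            node = branches[rng.integers(len(branches))]
            mult = math.exp(1.0 * (rng.random() - 0.5))
            undo = (node, node.length)
            node.length = max(node.length * mult, 1e-9)
            log_hastings = math.log(mult)
        elif kind == "alpha":
            mult = math.exp(0.7 * (rng.random() - 0.5))
            new_alpha = state.alpha * mult
            new_state.alpha = new_alpha
            new_state.model = state.model.with_gamma(new_alpha)
            log_hastings = math.log(mult)
        elif kind in ("nni", "spr"):
            cand = state.tree.copy()
            if kind == "nni":
                edges = cand.internal_edges()
                if not edges:
                    continue
                cand.nni(edges[rng.integers(len(edges))], rng)
            else:
                if not cand.spr(rng):
                    continue
            new_state.tree = cand
            new_state.model = _repair_assignment(state.model, cand, rng)
        elif kind == "pi":
            if state.model.kind == "ndch":
                k = int(rng.integers(state.model.field.K))
                vecs = state.model.field.vectors.copy()
                vecs[k], log_hastings = _propose_dirichlet(
                    vecs[k], config.pi_concentration, rng)
                new_state.model = _rebuild_ndch(state.model, vecs,
                                                state.model.field.assignment)
            else:
                pi, log_hastings = _propose_dirichlet(
                    state.model.components[0].pi, config.pi_concentration, rng)
                comp = build_rate_matrix(state.model.exchange, pi)
                new_state.model = ModelSpec(
                    state.model.kind, state.model.alphabet, [comp],
                    state.model.weights, state.model.gamma, state.model.exchange)
        elif kind == "exch":
            ex = state.model.exchange
            iu = np.triu_indices(len(ex.states), 1)
            rates = ex.R[iu]
            rates = rates / rates.sum()
            new_rates, log_hastings = _propose_dirichlet(
                rates, config.pi_concentration, rng)
            new_ex = free_exchangeabilities(new_rates, ex.pi, ex.states)
            if state.model.kind == "ndch":
                m = ModelSpec("ndch", state.model.alphabet, state.model.components,
                              state.model.weights, state.model.gamma, new_ex,
                              state.model.field)
                new_state.model = _rebuild_ndch(m, m.field.vectors, m.field.assignment)
            else:
                comp = build_rate_matrix(new_ex, state.model.components[0].pi)
                new_state.model = ModelSpec(
                    state.model.kind, state.model.alphabet, [comp],
                    state.model.weights, state.model.gamma, new_ex)
        elif kind == "assign":
            assign = dict(state.model.field.assignment)
            node = state.tree.nodes[rng.integers(len(state.tree.nodes))]
            assign[node.id] = int(rng.integers(state.model.field.K))
            new_state.model = ModelSpec(
                "ndch", state.model.alphabet, state.model.components,
                state.model.weights, state.model.gamma, state.model.exchange,
                CompositionField(state.model.field.vectors, assign))

        new_ll = _log_lik(new_state, aln, config)
        new_lp = _log_prior(new_state, config)
        log_ratio = (new_ll + new_lp) - (cur_ll + cur_lp) + log_hastings
        if np.isfinite(new_ll) and math.log(rng.random() + 1e-300) < log_ratio:
            state = new_state
            cur_ll, cur_lp = new_ll, new_lp
            accepted[kind] += 1
        elif undo is not None:  # in-place branch change rejected: restore
            node, old = undo
            node.length = old

        if gen % config.sample_every == 0:
            samples.append(PosteriorSample(
                generation=gen,
                tree=state.tree.copy(),
                model=state.model,
                alpha=state.alpha,
                log_likelihood=cur_ll,
                log_prior=cur_lp,
            ))

    run_chain.last_acceptance = {
        k: accepted[k] / attempted[k] if attempted[k] else float("nan")
        for k in names
    }
    return samples


def discard_burnin(samples: list[PosteriorSample], burn_in: float) -> list[PosteriorSample]:
    if not 0 <= burn_in < 1:
        raise ValueError("burn-in fraction must be in [0, 1)")
    start = int(len(samples) * burn_in)
    return samples[start:]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def _split_frequencies(trees: list[PhyloTree]) -> dict[frozenset, float]:
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    return {s: c / len(trees) for s, c in counts.items()}


def consensus_tree(samples: list[PosteriorSample], burn_in: float = 0.0) -> PhyloTree:
    """Strict-majority-rule consensus: splits with frequency > 0.5 are kept and
    annotated with their frequency; everything else collapses to polytomies."""
    kept = discard_burnin(samples, burn_in)
    if not kept:
        raise ValueError("no post-burn-in samples to summarize")
    trees = [s.tree for s in kept]
    freqs = _split_frequencies(trees)
    majority = {s: f for s, f in freqs.items() if f > 0.5}

    taxa = trees[0].leaf_names
    # mean terminal branch lengths; internal lengths averaged per split
    leaf_len = {t: [] for t in taxa}
    split_len: dict[frozenset, list] = {s: [] for s in majority}
    all_leaves = frozenset(taxa)
    anchor = min(all_leaves)
    for t in trees:
        for name, node in t.leaf_map.items():
            leaf_len[name].append(node.length)
        below: dict[int, frozenset] = {}
        for node in t.postorder():
            if node.is_leaf:
                below[node.id] = frozenset([node.name])
            else:
                below[node.id] = frozenset().union(*(below[c.id] for c in node.children))
            if node.parent is None:
                continue
            side = below[node.id]
            if anchor in side:
                side = all_leaves - side
            if side in split_len:
                split_len[side].append(node.length)

    root = Node(0)
    top: dict[str, Node] = {}
    for name in taxa:
        leaf = Node(0, name, float(np.mean(leaf_len[name])))
        leaf.parent = root
        root.children.append(leaf)
        top[name] = leaf
    for split in sorted(majority, key=len):
        members = {top[name] for name in split}
        parent = next(iter(members)).parent
        group = [c for c in parent.children if c in members]
        if len(group) != len(members):  # incompatible with an earlier split
            continue
        new = Node(0, length=float(np.mean(split_len[split])) if split_len[split] else 0.0)
        new.support = majority[split]
        new.parent = parent
        new.children = group
        for g in group:
            g.parent = new
            parent.children.remove(g)
        parent.children.append(new)
        for name in split:
            top[name] = new
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the autocorrelation time (Geyer initial-positive-sequence)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.std(x) == 0:
        return float(n)
    xc = x - x.mean()
    # biased autocovariance (divide by n), the standard choice here
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (n * xc.var())
    tau = -1.0
    for k in range(0, n // 2):
        pair = acf[2 * k] + (acf[2 * k + 1] if 2 * k + 1 < n else 0.0)
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / max(tau, 1.0)))


def _summary_traces(samples: list[PosteriorSample]) -> dict[str, np.ndarray]:
    return {
        "log_likelihood": np.array([s.log_likelihood for s in samples]),
        "tree_length": np.array([s.tree_length for s in samples]),
        "alpha": np.array([s.alpha for s in samples]),
    }


def convergence_report(chain_a: list[PosteriorSample],
                       chain_b: list[PosteriorSample],
                       asdsf_min_freq: float = 0.1) -> ConvergenceReport:
    """Between-chain diagnostics.

    Per-variable discrepancy is 2·|mean_A − mean_B| / (sd_A + sd_B); a zero
    pooled sd with unequal means reports an infinite discrepancy. The split
    discrepancy is the maximum |PP_A − PP_B| over the union of sampled splits,
    and the ASDSF averages the two-run standard deviation of split frequencies
    over splits reaching *asdsf_min_freq* in at least one run.
    """
    if not chain_a or not chain_b:
        raise ValueError("both chains must be non-empty")
    var_disc: dict[str, float] = {}
    ess: dict[str, float] = {}
    ta, tb = _summary_traces(chain_a), _summary_traces(chain_b)
    for name in ta:
        ma, mb = ta[name].mean(), tb[name].mean()
        sa, sb = ta[name].std(ddof=1) if len(ta[name]) > 1 else 0.0, \
            tb[name].std(ddof=1) if len(tb[name]) > 1 else 0.0
        if sa + sb == 0:
            var_disc[name] = 0.0 if np.isclose(ma, mb) else float("inf")
        else:
            var_disc[name] = float(2 * abs(ma - mb) / (sa + sb))
        ess[name] = min(effective_sample_size(ta[name]),
                        effective_sample_size(tb[name]))
    fa = _split_frequencies([s.tree for s in chain_a])
    fb = _split_frequencies([s.tree for s in chain_b])
    union = set(fa) | set(fb)
    max_disc = max((abs(fa.get(s, 0.0) - fb.get(s, 0.0)) for s in union), default=0.0)
    sd_terms = [abs(fa.get(s, 0.0) - fb.get(s, 0.0)) / math.sqrt(2.0)
                for s in union
                if max(fa.get(s, 0.0), fb.get(s, 0.0)) >= asdsf_min_freq]
    asdsf = float(np.mean(sd_terms)) if sd_terms else 0.0
    return ConvergenceReport(var_disc, ess, float(max_disc), asdsf)


def information_criteria(logL: float, k: int, n: int) -> tuple[float, float]:
    """AIC = −2·logL + 2k; BIC = −2·logL + k·ln n."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    return (-2.0 * logL + 2.0 * k, -2.0 * logL + k * math.log(n))
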