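"""Posterior predictive model-adequacy tests.

Three checks of whether a fitted model could have generated the observed
alignment:

* compositional heterogeneity — the Pearson X² over taxa × residues,
* site-specific biochemical diversity — mean distinct residues per column,
* homoplasy — substitution events beyond the parsimony minimum per site,
  estimated by stochastic substitution mapping: histories sampled
  conditionally on the data are compared with unconstrained forward mappings.

For each statistic the observed value is compared with its distribution over
alignments (or mappings) simulated from posterior parameter draws; the model
fails when the observed value leaves the central 95% of the predicted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .alignment import ALPHABETS, Alignment, composition_chisq, site_diversity
from .likelihood import (_branch_rate_matrix, _leaf_partials, _root_pi,
                         draw_site_classes, simulate_alignment)
from .models import ModelSpec, RateMatrix, transition_probabilities
from .mcmc import PosteriorSample, discard_burnin
from .tree import PhyloTree

STATISTICS = ("composition_chisq", "site_diversity")


@dataclass
class AdequacyResult:
    statistic: str
    observed: float
    predicted: np.ndarray
    p_value: float

    @property
    def predicted_mean(self) -> float:
        return float(self.predicted.mean())

    @property
    def predicted_sd(self) -> float:
        return float(self.predicted.std(ddof=1)) if len(self.predicted) > 1 else 0.0

    @property
    def verdict(self) -> str:
        lo, hi = np.percentile(self.predicted, [2.5, 97.5])
        return "fit" if lo <= self.observed <= hi else "fail"


def _evaluate_statistic(aln: Alignment, statistic: str) -> float:
    if statistic == "composition_chisq":
        return composition_chisq(aln).chisq
    if statistic == "site_diversity":
        return site_diversity(aln).mean
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")


def tail_area(observed: float, predicted: np.ndarray) -> float:
    """Two-sided tail-area p = 2·min(r, 1−r), r the mid-rank fraction of
    predicted values below the observed (observed excluded from its own
    reference distribution)."""
    below = np.sum(predicted < observed)
    ties = np.sum(predicted == observed)
    r = (below + 0.5 * ties) / len(predicted)
    return float(min(1.0, 2.0 * min(r, 1.0 - r)))


def posterior_predictive(samples: list[PosteriorSample], aln: Alignment,
                         statistic: str, seed: int = 0,
                         burn_in: float = 0.0, min_samples: int = 20) -> AdequacyResult:
    """Simulate one replicate alignment per posterior draw and locate the
    observed statistic in the predicted distribution."""
    kept = discard_burnin(samples, burn_in)
    if len(kept) < min_samples:
        raise ValueError(
            f"{len(kept)} post-burn-in samples; at least {min_samples} required"
        )
    rng = np.random.default_rng(seed)
    observed = _evaluate_statistic(aln, statistic)
    predicted = np.empty(len(kept))
    for i, s in enumerate(kept):
        sim = simulate_alignment(s.tree, s.model, aln.n_sites, rng)
        predicted[i] = _evaluate_statistic(sim, statistic)
    return AdequacyResult(statistic, observed, predicted, tail_area(observed, predicted))


# ---------------------------------------------------------------------------
# Stochastic substitution mapping
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMapping:
    """Explicit substitution histories for every site and branch.

    ``events[(node_id, site)]`` lists ``(time, from_state, to_state)`` with
    times increasing in ``[0, branch_length]`` measured from the parent end.
    ``node_states`` holds the realized state at every node; ``observed_leaf``
    marks leaf cells that were non-missing in the conditioning data (all True
    for unconstrained mappings).
    """

    tree: PhyloTree
    node_states: np.ndarray           # nodes x sites
    events: dict = dfield(default_factory=dict)
    conditional: bool = False
    observed_leaf: np.ndarray | None = None  # leaves(sorted) x sites

    def events_at_site(self, site: int) -> int:
        total = 0
        for node in self.tree.nodes:
            if node.parent is None:
                continue
            total += len(self.events.get((node.id, site), ()))
        return total

    def n_sites(self) -> int:
        return self.node_states.shape[1]

    def validate(self) -> None:
        """Endpoint-consistency: event chains connect parent to child state."""
        for node in self.tree.nodes:
            if node.parent is None:
                continue
            for site in range(self.n_sites()):
                ev = self.events.get((node.id, site), [])
                state = self.node_states[node.parent.id, site]
                last_t = -1.0
                for t, a, b in ev:
                    if a != state or not (last_t < t <= node.length + 1e-12) or a == b:
                        raise ValueError(
                            f"inconsistent mapping at node {node.id} site {site}"
                        )
                    state, last_t = b, t
                if state != self.node_states[node.id, site]:
                    raise ValueError(
                        f"endpoint mismatch at node {node.id} site {site}"
                    )


def _forward_branch(rm: RateMatrix, a: int, t: float,
                    rng: np.random.Generator) -> tuple[int, list]:
    """Free forward CTMC simulation along one branch, recording events."""
    events = []
    state, clock = a, 0.0
    while True:
        rate = -rm.Q[state, state]
        if rate <= 0:
            break
        clock += rng.exponential(1.0 / rate)
        if clock >= t:
            break
        probs = rm.Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        new = int(rng.choice(len(probs), p=probs))
        events.append((clock, state, new))
        state = new
    return state, events


def map_unconstrained(tree: PhyloTree, model: ModelSpec, n_sites: int,
                      seed: int | np.random.Generator) -> SubstitutionMapping:
    """Forward-simulate full substitution histories (no conditioning on data)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp, cat = draw_site_classes(model, n_sites, rng)
    n_nodes = max(n.id for n in tree.nodes) + 1
    states = np.zeros((n_nodes, n_sites), dtype=np.int64)
    events: dict = {}
    n_comp = 1 if model.kind == "ndch" else len(model.components)
    for c in range(n_comp):
        sel = np.where(comp == c)[0]
        if len(sel):
            pi = _root_pi(model, tree, c)
            states[tree.root.id, sel] = rng.choice(len(pi), size=len(sel), p=pi)
    for node in tree.preorder():
        if node.parent is None:
            continue
        for site in range(n_sites):
            rm = _branch_rate_matrix(model, node, comp[site])
            rate = model.gamma.rates[cat[site]]
            end, ev = _forward_branch(rm, states[node.parent.id, site],
                                      node.length * rate, rng)
            states[node.id, site] = end
            if ev:
                scale = node.length / (node.length * rate) if rate > 0 else 0.0
                events[(node.id, site)] = [(t * scale, a, b) for t, a, b in ev]
    leaves = sorted(tree.leaf_map)
    observed = np.ones((len(leaves), n_sites), dtype=bool)
    return SubstitutionMapping(tree, states, events, conditional=False,
                               observed_leaf=observed)


def _sample_node_states(tree: PhyloTree, model: ModelSpec, aln: Alignment,
                        comp: np.ndarray, cat: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Joint posterior draw of all node states: pruning up, sampling down."""
    leaf_parts = _leaf_partials(tree, aln)
    n_sites = aln.n_sites
    n_nodes = max(n.id for n in tree.nodes) + 1
    k = len(ALPHABETS[model.alphabet])
    states = np.zeros((n_nodes, n_sites), dtype=np.int64)
    n_comp = 1 if model.kind == "ndch" else len(model.components)
    for c in range(n_comp):
        for g in range(model.gamma.K):
            sel = np.where((comp == c) & (cat == g))[0]
            if not len(sel):
                continue
            rate = model.gamma.rates[g]
            partial: dict[int, np.ndarray] = {}
            for node in tree.postorder():
                if node.is_leaf:
                    partial[node.id] = leaf_parts[node.id][:, sel]
                    continue
                acc = np.ones((k, len(sel)))
                for child in node.children:
                    rm = _branch_rate_matrix(model, child, c)
                    P = transition_probabilities(rm, child.length, rate)
                    acc *= P @ partial[child.id]
                m = acc.max(axis=0)
                partial[node.id] = acc / np.where(m > 0, m, 1.0)
            pi = _root_pi(model, tree, c)
            w = pi[:, None] * partial[tree.root.id]
            w = w / w.sum(axis=0)
            u = rng.random(len(sel))
            states[tree.root.id, sel] = (u > np.cumsum(w, axis=0).T[:, :-1].T).sum(axis=0)
            for node in tree.preorder():
                if node.parent is None:
                    continue
                rm = _branch_rate_matrix(model, node, c)
                P = transition_probabilities(rm, node.length, rate)
                w = P[states[node.parent.id, sel]].T * partial[node.id]
                w = w / w.sum(axis=0)
                u = rng.random(len(sel))
                states[node.id, sel] = (u > np.cumsum(w, axis=0).T[:, :-1].T).sum(axis=0)
    return states


def _bridge_branch(rm: RateMatrix, a: int, b: int, t: float,
                   rng: np.random.Generator,
                   max_jumps: int = 200) -> list:
    """Endpoint-conditioned path by uniformization with μ = 1.1·max|Q_ii|."""
    if t <= 0:
        return []
    mu = 1.1 * float(np.max(-np.diag(rm.Q)))
    if mu <= 0:
        return []
    k = rm.n_states
    Rj = np.eye(k) + rm.Q / mu
    # transition probability for the endpoint pair
    P_ab = transition_probabilities(rm, t)[a, b]
    if P_ab <= 0:
        raise ValueError("impossible endpoint pair for bridge sampling")
    # sample number of uniformized jumps n | endpoints
    log_pois = -mu * t
    term = np.exp(log_pois)
    Rpow = np.eye(k)
    u = rng.random() * P_ab
    acc = term * Rpow[a, b]
    n = 0
    while acc < u and n < max_jumps:
        n += 1
        term *= mu * t / n
        Rpow = Rpow @ Rj
        acc += term * Rpow[a, b]
    # sample the jump chain given n, then keep real (state-changing) jumps
    if n == 0:
        return []
    times = np.sort(rng.random(n) * t)
    # backward products R^(n-i) for sequential state sampling
    powers = [np.eye(k)]
    for _ in range(n):
        powers.append(powers[-1] @ Rj)
    path = [a]
    for i in range(1, n + 1):
        w = Rj[path[-1], :] * powers[n - i][:, b]
        w = np.clip(w, 0, None)
        s = w.sum()
        if s <= 0:
            path.append(b)
            continue
        path.append(int(rng.choice(k, p=w / s)))
    events = []
    for i in range(1, n + 1):
        if path[i] != path[i - 1]:
            events.append((float(times[i - 1]), path[i - 1], path[i]))
    return events


def map_conditional(tree: PhyloTree, model: ModelSpec, aln: Alignment,
                    seed: int | np.random.Generator) -> SubstitutionMapping:
    """Sample a substitution history conditional on the observed alignment.

    Per-site mixture components and rate categories are drawn from their
    posterior, ancestral states by pruning plus backward sampling, and branch
    histories by endpoint-conditioned uniformization. Missing leaf symbols are
    marginalized and then sampled like internal nodes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp, cat = _posterior_site_classes(tree, model, aln, rng)
    states = _sample_node_states(tree, model, aln, comp, cat, rng)
    events: dict = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        for site in range(aln.n_sites):
            rm = _branch_rate_matrix(model, node, comp[site])
            rate = model.gamma.rates[cat[site]]
            ev = _bridge_branch(rm, int(states[node.parent.id, site]),
                                int(states[node.id, site]),
                                node.length * rate, rng)
            if ev:
                scale = 1.0 / rate
                events[(node.id, site)] = [(t * scale, x, y) for t, x, y in ev]
    observed = ~aln.missing_mask()
    order = np.argsort(aln.taxa)
    return SubstitutionMapping(tree, states, events, conditional=True,
                               observed_leaf=observed[order])


def _posterior_site_classes(tree: PhyloTree, model: ModelSpec, aln: Alignment,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-site (component, category) from their joint posterior."""
    from .likelihood import _prune_one  # local import to avoid cycle at module load

    n_comp = 1 if model.kind == "ndch" else len(model.components)
    K = model.gamma.K
    leaf_parts = _leaf_partials(tree, aln)
    logs = np.empty((n_comp * K, aln.n_sites))
    for c in range(n_comp):
        for g in range(K):
            logs[c * K + g] = (_prune_one(tree, leaf_parts, model, c, model.gamma.rates[g])
                               + np.log(model.weights[:n_comp][c])
                               + np.log(model.gamma.weights[g]))
    logs -= logs.max(axis=0)
    w = np.exp(logs)
    w /= w.sum(axis=0)
    u = rng.random(aln.n_sites)
    idx = (u > np.cumsum(w, axis=0).T[:, :-1].T).sum(axis=0)
    return idx // K, idx % K


# ---------------------------------------------------------------------------
# Homoplasy
# ---------------------------------------------------------------------------

def homoplasy_per_site(mapping: SubstitutionMapping, site: int) -> int:
    """Events beyond the minimum needed for the distinct observed leaf states:
    (total events at the site) − (distinct non-missing leaf states − 1)."""
    leaves = sorted(mapping.tree.leaf_map)
    ids = [mapping.tree.leaf_map[t].id for t in leaves]
    leaf_states = mapping.node_states[ids, site]
    if mapping.observed_leaf is not None:
        keep = mapping.observed_leaf[:, site]
        leaf_states = leaf_states[keep]
    n_distinct = len(np.unique(leaf_states)) if len(leaf_states) else 1
    h = mapping.events_at_site(site) - (n_distinct - 1)
    if h < 0:
        raise ValueError(f"negative homoplasy at site {site}: inconsistent mapping")
    return int(h)


def mean_homoplasy(mapping: SubstitutionMapping) -> float:
    return float(np.mean([homoplasy_per_site(mapping, s)
                          for s in range(mapping.n_sites())]))


@dataclass
class HomoplasyResult:
    observed_draws: np.ndarray   # conditional-mapping means, one per sample
    predicted_draws: np.ndarray  # unconstrained-mapping means, one per sample
    p_value: float

    @property
    def observed_mean(self) -> float:
        return float(self.observed_draws.mean())

    @property
    def observed_variance(self) -> float:
        return float(self.observed_draws.var(ddof=1))

    @property
    def predicted_mean(self) -> float:
        return float(self.predicted_draws.mean())

    @property
    def predicted_variance(self) -> float:
        return float(self.predicted_draws.var(ddof=1))

    @property
    def verdict(self) -> str:
        return "fit" if self.p_value > 0.05 else "fail"


def homoplasy_test(samples: list[PosteriorSample], aln: Alignment,
                   seed: int = 0, burn_in: float = 0.0,
                   min_samples: int = 20) -> HomoplasyResult:
    """Conditional vs unconstrained mapping comparison, one of each per
    posterior draw; P is the two-sided tail area of the mean conditional
    homoplasy within the unconstrained distribution."""
    kept = discard_burnin(samples, burn_in)
    if len(kept) < min_samples:
        raise ValueError(
            f"{len(kept)} post-burn-in samples; at least {min_samples} required"
        )
    rng = np.random.default_rng(seed)
    obs = np.empty(len(kept))
    pred = np.empty(len(kept))
    for i, s in enumerate(kept):
        obs[i] = mean_homoplasy(map_conditional(s.tree, s.model, aln, rng))
        pred[i] = mean_homoplasy(map_unconstrained(s.tree, s.model, aln.n_sites, rng))
    return HomoplasyResult(obs, pred, tail_area(obs.mean(), pred))


def run_all_tests(samples: list[PosteriorSample], aln: Alignment, seed: int = 0,
                  burn_in: float = 0.0, min_samples: int = 20) -> dict:
    """All three adequacy tests; returns a name → result dict."""
    out = {}
    for i, stat in enumerate(STATISTICS):
        out[stat] = posterior_predictive(samples, aln, stat, seed=seed + i,
                                         burn_in=burn_in, min_samples=min_samples)
    out["homoplasy"] = homoplasy_test(samples, aln, seed=seed + 17,
                                      burn_in=burn_in, min_samples=min_samples)
    return out
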