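"""Substitution-model algebra.

Builds reversible amino-acid (and recoded 6-state) rate matrices from
exchangeabilities and stationary frequencies, discrete-gamma rate
heterogeneity, mixtures of matrices or of frequency profiles, and
node-discrete composition fields in which equilibrium frequencies change
across the tree.

Empirical matrices (JTT, WAG, LG) are shipped as plain-text package data.
The CAT-style profile libraries shipped here are *synthetic* stand-ins
(k-means centroids of simulated sparse site profiles) with the structure of
the empirical sets: 10 or 60 low-diversity equilibrium-frequency profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.special import gammainc, gammaincinv

from .alignment import ALPHABETS, AMINO20

PAML_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # order used in the matrix data files


def _canonicalize(R: np.ndarray, pi: np.ndarray, states: str) -> tuple[np.ndarray, np.ndarray]:
    """Permute a matrix read in data-file order into the canonical
    alphabetical amino-acid order used by alignments."""
    perm = [states.index(s) for s in AMINO20]
    return R[np.ix_(perm, perm)], pi[perm]


# ---------------------------------------------------------------------------
# Exchangeabilities and rate matrices
# ---------------------------------------------------------------------------

@dataclass
class ExchangeabilityMatrix:
    """Symmetric exchangeabilities R plus default stationary frequencies π."""

    name: str
    R: np.ndarray
    pi: np.ndarray
    states: str

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        k = len(self.states)
        if self.R.shape != (k, k):
            raise ValueError(f"{self.name}: R must be {k}x{k}")
        if not np.allclose(self.R, self.R.T):
            raise ValueError(f"{self.name}: R is not symmetric")
        off = self.R[~np.eye(k, dtype=bool)]
        if (off < 0).any():
            raise ValueError(f"{self.name}: negative exchangeability")
        if (self.pi <= 0).any() or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError(f"{self.name}: frequencies must be positive and sum to 1")


@dataclass
class RateMatrix:
    """Reversible generator Q with unit mean rate, plus its eigensystem.

    The eigendecomposition of the symmetrized generator is stored so that
    transition matrices exp(r·t·Q) are cheap for any branch length.
    """

    Q: np.ndarray
    pi: np.ndarray
    evals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]


def build_rate_matrix(R: ExchangeabilityMatrix | np.ndarray, pi: np.ndarray,
                      scale: float | None = None) -> RateMatrix:
    """Q_ij = R_ij π_j, diagonal closing rows to zero.

    With ``scale=None`` the generator is normalized to unit mean rate (so
    branch lengths are expected substitutions/site). Mixture builders pass an
    explicit shared ``scale`` so that the *mixture-averaged* rate is one while
    components keep their relative speeds.
    """
    Rm = R.R if isinstance(R, ExchangeabilityMatrix) else np.asarray(R, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if (pi <= 0).any():
        raise ValueError("stationary frequencies must be strictly positive")
    pi = pi / pi.sum()
    Q = Rm * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q)) if scale is None else float(scale)
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    Q = Q / mean_rate
    # symmetrize: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
    d = np.sqrt(pi)
    B = Q * (d[:, None] / d[None, :])
    B = (B + B.T) / 2.0
    evals, V = np.linalg.eigh(B)
    right = V / d[:, None]          # D^{-1/2} V
    left = (V * d[:, None]).T       # V' D^{1/2}
    return RateMatrix(Q=Q, pi=pi, evals=evals, _left=left, _right=right)


def transition_probabilities(Q: RateMatrix, t: float, r: float = 1.0) -> np.ndarray:
    """P(t) = exp(r·t·Q); rows sum to 1."""
    if t < 0 or r < 0:
        raise ValueError("branch length and rate multiplier must be non-negative")
    P = (Q._right * np.exp(Q.evals * (t * r))) @ Q._left
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Discrete gamma rates
# ---------------------------------------------------------------------------

@dataclass
class GammaRates:
    """K equal-weight rate categories from a mean-1 gamma distribution."""

    alpha: float
    rates: np.ndarray
    weights: np.ndarray

    @property
    def K(self) -> int:
        return len(self.rates)


def discretize_gamma(alpha: float, K: int = 4) -> GammaRates:
    """Category-mean discretization of Gamma(alpha, alpha).

    Category boundaries are gamma quantiles at i/K; each category rate is the
    conditional mean over its quantile slice, so the weighted mean is exactly 1
    after renormalization.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if K < 1:
        raise ValueError("need at least one rate category")
    if K == 1:
        return GammaRates(alpha, np.array([1.0]), np.array([1.0]))
    cuts = gammaincinv(alpha, np.arange(1, K) / K) / alpha
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X; a<X<b] for X~Gamma(alpha, rate alpha) is gammainc(alpha+1, alpha*b)
    # - gammainc(alpha+1, alpha*a) (regularized); each category has mass 1/K.
    upper = gammainc(alpha + 1, alpha * np.minimum(edges[1:], 1e300))
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = K * (upper - lower)
    rates = rates / (rates.mean())
    return GammaRates(alpha, rates, np.full(K, 1.0 / K))


# ---------------------------------------------------------------------------
# Mixtures and composition fields
# ---------------------------------------------------------------------------

@dataclass
class MixtureModel:
    """Mixture of exchangeability matrices or of frequency profiles."""

    name: str
    kind: str  # "matrix-mixture" | "profile-mixture"
    components: list  # ExchangeabilityMatrix list, or ndarray profiles
    weights: np.ndarray
    states: str = AMINO20

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class CompositionField:
    """Node-discrete composition: K frequency vectors painted onto tree nodes."""

    vectors: np.ndarray  # K x n_states
    assignment: dict  # node id -> vector index

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a K x states array")
        if (self.vectors <= 0).any() or not np.allclose(self.vectors.sum(axis=1), 1.0):
            raise ValueError("each composition vector must be strictly positive and sum to 1")
        K = self.vectors.shape[0]
        for node, idx in self.assignment.items():
            if not 0 <= idx < K:
                raise ValueError(f"node {node}: vector index {idx} out of range")

    @property
    def K(self) -> int:
        return self.vectors.shape[0]


# ---------------------------------------------------------------------------
# Library loading
# ---------------------------------------------------------------------------

def _read_matrix_file(fname: str, name: str) -> ExchangeabilityMatrix:
    text = resources.files("phylopp.data").joinpath(fname).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    states = "".join(lines[0].split())
    k = len(states)
    R = np.zeros((k, k))
    for i in range(1, k):
        vals = [float(x) for x in lines[i].split()]
        R[i, :i] = vals
        R[:i, i] = vals
    pi = np.array([float(x) for x in lines[k].split()])
    pi = pi / pi.sum()
    R, pi = _canonicalize(R, pi, states)
    return ExchangeabilityMatrix(name, R, pi, AMINO20)


@lru_cache(maxsize=None)
def load_matrix(name: str) -> ExchangeabilityMatrix:
    """Load a shipped exchangeability matrix: JTT, WAG, LG, or poisson{20,6}."""
    key = name.lower()
    if key in ("jtt", "wag", "lg"):
        return _read_matrix_file(f"{key}.txt", key.upper())
    if key in ("poisson", "poisson20"):
        return poisson_matrix(20)
    if key == "poisson6":
        return poisson_matrix(6)
    raise KeyError(f"unknown matrix {name!r}; available: JTT, WAG, LG, poisson, poisson6")


def poisson_matrix(k: int) -> ExchangeabilityMatrix:
    """Equal exchangeabilities and uniform frequencies (F81/Poisson model)."""
    states = AMINO20 if k == 20 else ALPHABETS["dayhoff6"][:k]
    R = np.ones((k, k))
    np.fill_diagonal(R, 0.0)
    return ExchangeabilityMatrix(f"poisson{k}", R, np.full(k, 1.0 / k), states)


def free_exchangeabilities(rates: np.ndarray, pi: np.ndarray, states: str = "ABCDEF") -> ExchangeabilityMatrix:
    """A free symmetric matrix from its upper-triangle rates (6-state default).

    Used for Dayhoff-recoded runs where the exchangeabilities are estimated
    from the data during the MCMC under a flat Dirichlet prior.
    """
    k = len(states)
    rates = np.asarray(rates, dtype=float)
    if len(rates) != k * (k - 1) // 2:
        raise ValueError(f"need {k*(k-1)//2} upper-triangle rates")
    R = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    R[iu] = rates
    R = R + R.T
    return ExchangeabilityMatrix(f"free{k}", R, np.asarray(pi, float), states)


def _read_profile_library(fname: str, name: str) -> MixtureModel:
    text = resources.files("phylopp.data").joinpath(fname).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    states = "".join(lines[0].split())
    weights, profiles = [], []
    perm = [states.index(s) for s in AMINO20]
    for ln in lines[1:]:
        vals = [float(x) for x in ln.split()]
        weights.append(vals[0])
        prof = np.array(vals[1:])[perm]
        profiles.append(prof / prof.sum())
    return MixtureModel(name, "profile-mixture", np.array(profiles),
                        np.array(weights) / sum(weights), AMINO20)


def load_component_library(name: str) -> MixtureModel:
    """Load a mixture-component library by style name.

    ``UL3-style``: three empirical matrices (JTT, WAG, LG) with equal weights —
    a labelled stand-in with the structure of a three-matrix mixture.
    ``CAT10-style`` / ``CAT60-style``: 10 or 60 synthetic low-diversity
    frequency profiles (see the data-file headers).
    """
    key = name.lower().replace("_", "-")
    if key in ("ul3-style", "ul3"):
        comps = [load_matrix(m) for m in ("JTT", "WAG", "LG")]
        return MixtureModel("UL3-style", "matrix-mixture", comps,
                            np.full(3, 1 / 3), AMINO20)
    if key in ("cat10-style", "cat10"):
        return _read_profile_library("c10_synthetic.txt", "CAT10-style")
    if key in ("cat60-style", "cat60"):
        return _read_profile_library("c60_synthetic.txt", "CAT60-style")
    raise KeyError(
        f"unknown component library {name!r}; available: UL3-style, CAT10-style, CAT60-style"
    )


# ---------------------------------------------------------------------------
# The model specification consumed by the likelihood kernel
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Everything the pruning kernel and simulator need, in one object.

    ``kind`` is one of ``single`` (one matrix), ``matrix-mixture``,
    ``profile-mixture`` (weighted sum over per-site components), or ``ndch``
    (one exchangeability matrix, composition changing across the tree).
    For ``ndch`` the per-branch generator uses the composition vector of the
    branch's *child* node; the root prior uses the root node's vector.
    """

    kind: str
    alphabet: str
    components: list[RateMatrix]
    weights: np.ndarray
    gamma: GammaRates
    exchange: ExchangeabilityMatrix | None = None  # retained for ndch / resampling
    field: CompositionField | None = None

    @property
    def n_states(self) -> int:
        return len(ALPHABETS[self.alphabet])

    def with_gamma(self, alpha: float) -> "ModelSpec":
        g = discretize_gamma(alpha, self.gamma.K)
        return ModelSpec(self.kind, self.alphabet, self.components, self.weights,
                         g, self.exchange, self.field)


def single_model(matrix: str | ExchangeabilityMatrix, alpha: float = 1.0, K: int = 4,
                 pi: np.ndarray | None = None, alphabet: str = "amino20") -> ModelSpec:
    ex = load_matrix(matrix) if isinstance(matrix, str) else matrix
    rm = build_rate_matrix(ex, ex.pi if pi is None else pi)
    return ModelSpec("single", alphabet, [rm], np.array([1.0]),
                     discretize_gamma(alpha, K), exchange=ex)


def mixture_model(library: str | MixtureModel, alpha: float = 1.0, K: int = 4,
                  base_matrix: str = "poisson") -> ModelSpec:
    """Mixture ModelSpec from a component library.

    Profile mixtures place each profile on a shared exchangeability skeleton
    (Poisson by default, switchable to LG etc.).
    """
    lib = load_component_library(library) if isinstance(library, str) else library
    if lib.kind == "matrix-mixture":
        pairs = [(ex, ex.pi) for ex in lib.components]
    else:
        base = load_matrix(base_matrix)
        pairs = [(base, prof) for prof in lib.components]

    def raw_rate(ex, pi):
        # mean substitution rate of the unscaled generator (R has zero diagonal)
        pi = np.asarray(pi, float) / np.sum(pi)
        return float(pi @ ex.R @ pi)

    # one shared scale: the mixture-averaged substitution rate is 1, so
    # low-diversity components run slower and demand longer branches
    scale = float(sum(w * raw_rate(ex, pi)
                      for w, (ex, pi) in zip(lib.weights, pairs)))
    comps = [build_rate_matrix(ex, pi, scale=scale) for ex, pi in pairs]
    return ModelSpec(lib.kind, "amino20", comps, lib.weights, discretize_gamma(alpha, K))


def ndch_model(matrix: str | ExchangeabilityMatrix, field: CompositionField,
               alpha: float = 1.0, K: int = 4, alphabet: str = "amino20") -> ModelSpec:
    ex = load_matrix(matrix) if isinstance(matrix, str) else matrix
    comps = [build_rate_matrix(ex, v) for v in field.vectors]
    return ModelSpec("ndch", alphabet, comps, np.array([1.0]),
                     discretize_gamma(alpha, K), exchange=ex, field=field)
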