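# Methods

`phylopp` implements Bayesian phylogenetic inference for amino-acid (and
Dayhoff-recoded) alignments together with posterior predictive checks of
model adequacy. The package exists to answer one question quantitatively:
*could the fitted substitution model have generated data that look like the
observed alignment*, with respect to three statistics that are known to
mislead tree inference when mismodelled — among-lineage compositional
heterogeneity, site-specific biochemical diversity, and homoplasy.

## Models

**Single-matrix models.** A reversible generator is built from a symmetric
exchangeability matrix R and stationary frequencies π as Q_ij = R_ij·π_j,
normalized to one expected substitution per site per unit branch length.
JTT, WAG and LG are shipped as plain-text data files (exported from the R
package phangorn's published copies); `poisson`/`poisson6` give equal-rate
models for either alphabet. Among-site rate variation uses the discrete
gamma with K equal-weight categories (default 4) whose rates are category
means of Gamma(α, α); the weighted mean is renormalized to exactly 1.
Category means (rather than medians) are the dominant convention.

**Mixture models.** Two kinds: mixtures of exchangeability matrices and
mixtures of equilibrium-frequency profiles on a shared exchangeability
skeleton (Poisson by default, switchable). All components share one scale
factor so the mixture-averaged substitution rate is 1; normalizing each
component separately would make low-diversity profiles artificially fast
and systematically shrink inferred trees. The shipped component libraries
are **synthetic stand-ins**, clearly labelled as such in the data files:
`CAT10-style`/`CAT60-style` are medoids of k-means clusters of simulated
sparse site profiles (≤5 residues per profile), reproducing the *structure*
of empirical profile libraries (few residues carry almost all mass);
`UL3-style` combines the three shipped empirical matrices with equal
weights. The published UL3/C10/C60 parameter sets are not bundled; plugging
them in is a matter of dropping files in the documented text format
(alphabet header line, then one `weight f1 … f20` line per component).

**Node-discrete compositional heterogeneity (NDCH).** K composition vectors
are painted onto tree nodes; the generator on a branch uses the vector of
the branch's *child* node, and the root prior uses the root's vector. This
is the simplest well-defined convention and reduces bit-for-bit to the
homogeneous model at K = 1 (a tested invariant). Because non-stationary
models are not root-invariant, NDCH likelihoods are computed on the rooted
representation with the root fixed at the input tree's trifurcation anchor;
the root position is not sampled. K is fixed per run and raised manually
across runs, mirroring the iterative add-a-vector workflow; no reversible
jump is attempted.

**Dayhoff recoding** collapses the 20 residues into 6 classes
({A,G,P,S,T}, {C}, {D,E,N,Q}, {F,W,Y}, {H,K,R}, {I,L,M,V} — shipped as a
data file so alternative schemes can be substituted). Recoded data run
through the identical alphabet-generic likelihood kernel with a free
6-state exchangeability matrix (flat Dirichlet prior on the 15 relative
rates) estimated during the MCMC. Ambiguity codes (X, B, Z, J, \*) are
treated as missing everywhere; a class letter that collides with an
ambiguity code (recoded 'B') is never treated as missing in the 6-state
alphabet.

## Likelihood and simulation

Felsenstein pruning with per-node rescaling (accumulated per-site log
factors), vectorized over sites; transition matrices come from the
eigendecomposition of the symmetrized generator, so any branch length costs
one small matrix multiply. Missing symbols contribute all-ones partial
vectors. Mixtures sum per-site likelihoods over components × gamma
categories in log space; per-site posterior component weights are returned.
Forward simulation draws one component and one rate category per site,
evolves states preorder, and is a pure function of its seed.

## MCMC

Single-chain Metropolis–Hastings over topology (NNI and SPR), branch
lengths (multiplier moves), α (multiplier), composition vectors and free
exchangeabilities (Dirichlet proposals with concentration 300 around the
current value, floored at 1e-6 to keep generators valid), and NDCH node
assignments (uniform reassignment). Priors: Exponential(mean 0.1) on branch
lengths, Exponential(mean 1) on α, flat Dirichlet on simplex parameters,
uniform on assignments. Heated-chain coupling is not implemented; replicate
independent chains serve convergence assessment. The SPR proposal treats
forward and reverse choices as symmetric, which is exact for NNI and a
slight approximation for SPR on multifurcating anchors; NNI carries most of
the topology mixing (SPR weight 0.5 of NNI's 2.0 by default).

Convergence diagnostics follow the two-run conventions: per-variable
discrepancy 2·|m_A − m_B|/(s_A + s_B) for mean log-likelihood, tree length
and α; maximum split posterior-probability discrepancy; ASDSF over splits
reaching frequency 0.1 in either run; effective sample sizes from the
Geyer initial-positive-sequence autocorrelation estimator. Default
thresholds (max split discrepancy ≤ 0.1, ESS ≥ 100) are package choices,
configurable per run. Consensus trees are strict-majority rule: splits with
frequency > 0.5 annotated with their frequency, ties at exactly 0.5
excluded, everything else collapsed.

## Adequacy tests

For each posterior draw an alignment of the observed dimensions is
simulated under the drawn tree and parameters and the statistic of interest
recomputed; the two-sided tail area is p = 2·min(r, 1−r) with r the
mid-rank fraction of predicted values below the observed one (the observed
value is not added to its own reference distribution). A model *fails* a
test when the observed value leaves the central 95% of the predicted
values. Simulated replicates carry no gaps; an option to copy the observed
missing-data mask is deliberately not applied by default.

* **Compositional X²:** the taxa × residues Pearson statistic with pooled,
  gap-excluded frequencies as expectations. Constant columns are included;
  residues absent from the pooled data contribute nothing.
* **Site diversity:** mean count of distinct non-missing residues per
  column (the raw count, not an entropy-based effective number);
  all-missing columns are excluded with a warning.
* **Homoplasy:** per site, (substitution events) − (distinct non-missing
  leaf states − 1), which is non-negative for any consistent history.
  "Observed" draws come from substitution histories sampled *conditionally*
  on the data (per-site component/category from their posterior, ancestral
  states by pruning + backward sampling, branch paths by endpoint-
  conditioned uniformization with μ = 1.1·max|Q_ii|); "predicted" draws
  come from unconstrained forward mappings of the same size, one of each
  per posterior draw. The single P value is the two-sided tail area of the
  mean conditional homoplasy within the unconstrained distribution — a
  documented convention isolated in one function, since comparing two
  distributions by a single P admits several readings.

## Synthetic scenarios

The generators produce data with the pathologies the tests target, as pure
functions of knobs and seed:

* `make_composition_scenario`: balanced tree (default 8 taxa, branch length
  0.15) whose two principal clades evolve under different composition
  vectors drawn Dirichlet(200/divergence · π_LG). Default divergence 20
  produces shifts comfortably detected by the X² test at 300 sites while
  K = 1 reduces to homogeneous LG.
* `make_diversity_scenario`: sites restricted to `profile_size` residues
  (default 3) via a sparse profile mixture; a single-matrix analysis then
  overpredicts site diversity and underpredicts homoplasy.
* `make_lba_scenario`: quartet-plus-outgroup, true split AB|CD, the
  *non-sister* leaves A and C on branches `multiplier`× longer (default 8×
  0.1), internal branch 0.03, sites from a 3-residue profile mixture so the
  long branches accumulate convergent states. At multiplier 1 the true
  quartet is comfortably recoverable; at 8 a single-matrix analysis is
  usually drawn to the wrong AC|BD split while a profile mixture is less
  often misled. Quartet outcomes are scored by the induced topology on
  {A,B,C,D} regardless of where the outgroup attaches.

What the generators do *not* emulate: indels and alignment uncertainty,
covarion-style rate shifts, real gene-family biology, and empirical profile
libraries (ours are synthetic). Passing calibration on these scenarios
shows the machinery is correct and directionally faithful, not that any
particular real alignment is fit by any particular model.

## Problem sizes and numerical choices

Calibration suites use 8-taxon trees, 200–500 sites and chains of
800–2500 generations sampled every 10 with 25% burn-in — sizes chosen by
pilot power analysis so each 20-replicate suite completes in minutes on one
CPU while leaving the planted effects far from the decision boundary.
Matched-model calibration chains are initialized at the generating tree:
the quantity under test is posterior predictive calibration, not burn-in
behaviour. The homoplasy test thins posteriors to ≤25 draws (one
conditional + one unconstrained mapping each). Dirichlet proposals are
floored at 1e-6; partial-likelihood rescaling guards 80-taxon × 20-state
underflow; `transition_probabilities` clips tiny negative eigenvalue
round-off and renormalizes rows.

## Known limitations

* The published UL3/CAT10/CAT60 parameter sets are not included; the
  synthetic stand-ins reproduce the structure (few-residue profiles) but
  not the empirical values. In particular the `UL3-style` JTT/WAG/LG
  mixture does **not** reproduce the higher-predicted-homoplasy behaviour
  of the true UL3 model on our synthetic data — that direction is
  demonstrated with profile mixtures.
* SPR Hastings ratios are approximate (see above); topology posteriors at
  the scale tested are dominated by NNI moves.
* No Metropolis coupling; long production runs (millions of generations,
  80 taxa) are outside the intended scale of this implementation.
* NDCH assumes a fixed root anchor and user-fixed K.
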