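# Methods

## Model

A chimeric protein assembled from `p` aligned parents at `n` crossovers is
described at the level of its residue–residue contacts. Assuming a fixed
structure (a set `k` of alignment-column pairs in 3D contact), the energy
of a chimera is the sum of one energy term per contact, where the term
depends on the specific residue pair the chimera realizes there. Each
*distinct* (contact, residue-pair) state carries its own independent
Gaussian energy term:

- parental states (the pair occurs in at least one parent at those
  columns): `theta ~ N(mu_P, var_P)`,
- novel states (the pair occurs in no parent): `theta ~ N(mu_N, var_N)`,

all in kT units, interpreted as Gibbs free-energy differences between the
functional and nonfunctional forms. Negative energies favor function and
`P(functional) = sigma(-E)`, the logistic sigmoid, so the two-state
Boltzmann weight and the logistic likelihood coincide. The same residue
pair occurring at two different contacts carries two independent terms;
this is what lets the covariance between any two chimeras be written as a
count of shared indicator columns.

With `n_c` the number of novel states chimera `c` realizes (its SCHEMA
disruption), the field's mean and covariance are

```
E[E(c)]        = (k - n_c) mu_P + n_c mu_N
Cov(E(c),E(c')) = var_P * #shared parental states + var_N * #shared novel states
```

### Library statistics

For a fixed landscape, library energies are treated as Gaussian with mean
`m_L` and variance `v_L`, and the fraction functional is `F_L =
Phi(-m_L / sqrt(v_L))` (degenerate `v_L = 0` collapses to an indicator on
the sign of `m_L`, 0.5 at zero). Averaging over landscapes:

- `E[m_L] = k mu_P + <n_c> (mu_N - mu_P)` exactly;
- `E[v_L] = Var_c(E[E(c)]) + sum_s var_s p_s (1 - p_s)` exactly, where
  `p_s` is the fraction of the library realizing state `s` — a state
  shared by all or none of the library contributes nothing;
- `E[F_L] ≈ Phi(-E[m_L] / sqrt(E[v_L]))`, a leading-order expansion of
  the expectation of a ratio. Tests document the size of this bias by
  comparing against the mean of per-landscape `F_L` over seeded draws.

The additivity `A = v_add / v_L` is the fraction of the library's energy
variance explained by per-block main effects, computed over the uniform
distribution on the full `p^B` factorial (where it equals the
block-indicator least-squares R²). `v_add(theta)` is a quadratic form in
the state energies, so `E[v_add]` has the same exact closed form as
`E[v_L]`: with `A` the centered additive-projection operator and `x_s`
state `s`'s indicator column, `L E[v_add] = ||A X mu||^2 + sum_s var_s
||A x_s||^2`. `expected_additivity` returns this exact ratio of
expectations by default; a seeded Monte-Carlo path (draw landscapes,
decompose each, average `v_add`) serves as the independent oracle and
reports its standard error. A constant library (`v_L = 0`) is reported as
`A = 1`: there is no variance left to explain.

For sampled (non-factorial) property data, additivity is estimated as the
in-sample R² of an ordinary least-squares fit on reference-coded
block–parent indicator dummies with intercept; rank deficiency is
reported with the unobserved block–parent combinations listed.

### Contact classification details

- Gap policy: a contact touching a column gapped in *any* parent is
  excluded from the state table (with a logged count). Gaps have no
  energy semantics in the model; exclusion is deterministic.
- Conserved-column contacts stay in `k`: they are parental and shift
  every chimera's energy equally.
- Consensus maps from structures: a column pair is a contact in one chain
  iff any two heavy atoms of the mapped residues are within 4.5 Å
  (boundary inclusive); retained iff contacting in strictly more than 50%
  of usable chains. Chains below 50% identity to every parent are
  discarded. Chains are mapped to columns by a deterministic global
  alignment (BLOSUM62, gap open −11 / extend −1, first optimal
  alignment) to their best-identity parent; identity is matches over
  aligned non-gap positions. Altloc atoms resolve to the highest
  occupancy copy; only the first model of multi-model files is read.

## Hyperparameter estimation

Given records `(chimera, T ∈ {0,1})`, the state energies are integrated
out of the Bernoulli-logistic likelihood under the Gaussian priors. The
log posterior over energies is strictly concave; its unique mode is found
by damped Newton (backtracking line search, convergence at gradient
∞-norm < 1e−8 or Newton decrement < 1e−20 — the decrement criterion keeps
the solver meaningful in the var → 0 limit, where the raw gradient scales
as 1/var). Laplace's method then gives the log evidence
`f(theta*) + (d/2) log 2π − (1/2) log det(−H)` with `d` the number of
energy dimensions integrated.

Two exact reductions keep the Newton system small:

- only states realized by observed chimeras enter the design matrix
  (unrealized states integrate out exactly);
- identical (indicator column, state-class) pairs are merged, the merged
  sum of `m` iid energies carrying an `N(m mu, m var)` prior. Conserved
  contacts, which all share the all-ones column, collapse to a single
  dimension. On the default synthetic scale this shrinks ~1100 columns to
  ~220.

The four hyperparameters `(mu_P, mu_N, log var_P, log var_N)` are chosen
by Nelder–Mead (simplex and function tolerance 1e−6, at most 2000
evaluations per start) from an 8-point grid spanning
stabilizing/destabilizing means and variances 0.25/4; the log
parameterization keeps variances positive.

The variance search is confined to `var ∈ [0.01, 4]` kT² by default (a
`fit_params` argument). This is a deliberate estimator property: Laplace's
method overestimates the evidence increasingly as the prior variances
grow (the energy posterior turns strongly non-Gaussian where the logistic
likelihood saturates), and on some datasets this manufactures a spurious
high-variance optimum whose approximate evidence beats the genuine one —
verified by comparing Laplace against wide-t importance sampling on
systems small enough for the latter to be reliable. Per-contact energy
spreads beyond ~2 kT are also outside the physical regime of marginally
stable proteins, so the bound (the top of the initialization grid)
excludes only the region where the approximation is untrustworthy and the
parameters uninterpretable. Datasets with a single
functional class, or with no novel states, raise identifiability errors.
Duplicate records enter with multiplicative weight; conflicting
duplicates are rejected at dataset construction.

## Synthetic systems

The generator produces every ingredient with the model's own generative
structure, from explicit seeds (every generator is a pure function of its
arguments; sub-seeds are spawned with `numpy.random.SeedSequence`):

- *Alignments*: each column conserved with probability chosen so the
  expected pairwise identity hits the target (for p > 2 the accidental
  match rate of non-conserved columns is corrected for); otherwise
  parents draw uniform residues conditioned on not all being equal.
- *Contact maps*: `random_pairs` draws a fixed number of uniform column
  pairs; `geometric` grows a greedy self-avoiding walk on the cubic
  lattice and thresholds Euclidean distance, giving the chain locality of
  real folds.
- *Crossovers*: uniform over valid designs honoring a minimum block
  length, via the stars-and-bars bijection.
- *Functional data*: one landscape realization is drawn and held fixed;
  chimeras are sampled uniformly **without replacement** and labeled
  `T ~ Bernoulli(sigma(-E))`. (Sampling with replacement could assign a
  duplicated chimera conflicting outcomes, which the dataset contract
  forbids.)
- *Property data*: block-additive effects plus double-centered
  cross-block interaction tables plus iid noise, with the realized true
  additivity recorded.

Default scale: M = 120 columns, p ∈ {2, 3}, 7 crossovers, ~300 contacts,
identity 0.45 with true parameters (−0.3, 0.5, 2.0, 1.0) — chosen so
expected chimera energies straddle zero and libraries show the mixed
functional fractions (roughly 10–70%) that real SCHEMA libraries show;
far from that balance the data carry no sign information and the fit is
rightly unidentifiable. What the generator does **not** emulate:
phylogenetic structure and substitution-matrix biases in real families,
gaps, oligomeric (inter-chain) contacts, and any correlation between
contact energies — so passing tests demonstrate correctness of the
machinery under the model's own assumptions, not fidelity to any
particular protein family.

## Simulation experiments and problem sizes

- *Parameter recovery*: 20 replicate systems at the default scale, 2000
  records each. Replicate fits use a reduced two-start grid and a 1e−3
  simplex tolerance: the evidence surface has shown a single optimum from
  all starts, and the looser polish perturbs estimates orders of
  magnitude below the recovery tolerances while cutting wall time
  several-fold. Replicates whose realized landscape yields a one-class
  dataset are redrawn, mirroring the fact that only informative libraries
  can parametrize the model.
- *Substitution curves*: libraries are binned into 15 equal-width groups
  by default (bin edges are reported); for two-parent symmetry and
  scattered-vs-contiguous comparisons the reference-parent distance is
  used so the curve spans 0..D. The log-parabola is fit through the
  origin as `ln P(m) = lambda m (D - m)/(D - 1)`, pinning
  `P(0) = P(D) = 1` and making `rho = exp(lambda)` the modeled
  single-substitution tolerance; nonpositive bins are dropped with a
  warning and at least three usable bins are required. The exact
  functional form of the historical log-parabolic fit is not restated in
  the sources this package draws on; this operational form is labeled as
  such.
- *Scattered vs contiguous substitutions*: the claim that random
  homologous substitutions do no better than recombination at matched m
  is a statement about contact locality — contiguous blocks preserve the
  contacts interior to each block. It is checked on M = 60 systems with
  geometric (chain-local) contact maps and blocks of at least 8 columns,
  with the recombination side fully enumerated; on very small systems
  with non-local random-pair maps it is demonstrably false pointwise.
- *Variance components*: 3 synthetic folds × 9 identity levels
  (10–90%) × 8 random 7-crossover designs, one random two-parent
  alignment per (fold, identity) cell. The nested sums of squares
  attribute between-fold variance to the protein fold,
  between-alignment-within-fold variance to parent identity, and
  between-design-within-alignment variance to crossover locations; with
  one value per cell the decomposition is exact and the residual is
  zero. The headline check is the ordering (identity dominant), not the
  specific percentages, which depend on the real fold census.

## Numerical choices

- Population (not sample) variance throughout library moments; R² is the
  ordinary in-sample coefficient of determination.
- Consensus comparison is strict (> 0.5); distance comparison inclusive
  (≤ 4.5 Å).
- Enumeration is capped at 10^6 chimeras; larger libraries must be
  sampled.
- Gap symbol counts as an ordinary 21st symbol in Hamming distances.
- State energy draws are ordered by (contact index, state index), so a
  seed reproduces a realization on any platform.
- Clopper–Pearson intervals use exact Beta quantiles, with lower bound 0
  at zero successes and upper bound 1 at zero failures. The
  construction-error correction propagates the interval by evaluating the
  corrected fraction at the interval endpoints and caps at 1.

## Known limitations

- `E[F_L]` and `E[A]` are leading-order (ratio-of-expectations)
  approximations; the tests quantify the bias on enumerable systems but
  no higher-order correction is attempted.
- The Laplace evidence is asymptotically exact in the data but is used at
  finite n; the quadrature comparison covers up to 3 energy dimensions.
- Only intra-chain contacts are modeled; mmCIF input and inter-subunit
  contacts of oligomers are out of scope.
- Crossover-site optimization (library design) is not implemented;
  designs are inputs.
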