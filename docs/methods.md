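# Methods

## Model

`gromm` implements a dimension-grouped mixed membership model for
multivariate categorical data. Subjects `i = 1..n` answer items `j = 1..p`;
item `j` has `d_j` unordered categories. The model posits `K` *extreme
latent profiles*; each item carries a `d_j × K` conditional probability
table `Λ_j` whose column `k` is the response distribution under profile
`k`. Each subject holds a membership vector `π_i` on the `(K−1)`-simplex,
drawn i.i.d. from `Dirichlet(α)`.

The distinguishing structural parameter is a partition of the `p` items
into `G` groups, written as a label vector `s` (or a binary `p × G` matrix
`L`). Given `π_i`, the subject realizes one profile per *group*,
`z_{i,g} ~ Categorical(π_i)`, and answers every item `j` in group `g` from
column `z_{i,g}` of `Λ_j`. Items in a group therefore share a latent
realization, items in different groups share only the membership vector.
The two degenerate groupings recover classical models: one group
(`G = 1`) is a latent class model (CP decomposition of the contingency
probability tensor, class weights `α/α₀`); one group per item (`G = p`)
is the grade-of-membership model (Tucker decomposition). In between, the
marginal response distribution is a hybrid decomposition whose `G`-mode
core tensor holds the Dirichlet product moments
`E[π_{k₁}···π_{k_G}] = ∏_k α_k^{(m_k)} / α₀^{(G)}` (rising factorials,
`m_k` the multiplicity of profile `k` among the indices). `model_core`
evaluates these moments in closed form; the test-suite verifies them
against Monte Carlo averages over Dirichlet draws.

## Identifiability checkers

`identifiability` turns the model's identifiability conditions into
numerical preflight checks on concrete parameter values:

- **strict, per-item** — every group has ≥3 items whose table has full
  column rank `K` (identifies `Λ` and the core); additionally no item may
  have all table columns identical (then the grouping `L` is identified
  too). Ranks are numerical: singular values above `1e-8 ×` the largest.
- **strict, Khatri-Rao** — each group's items split into three parts whose
  chained column-wise Kronecker products have full column rank `K`; this
  accommodates `d_j < K`.
- **generic** — each part's category-count product must reach `K`; the
  rank condition then holds outside a Lebesgue-null parameter set. The
  partition is searched greedily (balancing `log d_j`), with exhaustive
  enumeration for groups of ≤12 items.

Note a sharp corner: with five three-category items per group, every
three-way split leaves a singleton part with product `3`, so the generic
bound is satisfiable only for `K ≤ 3`. The `(p, G) = (30, 6)` and
`(60, 12)` benchmark layouts therefore pass the generic check for
`K ∈ {2, 3}` but not `K = 4`; the `(90, 15)` layout (six items per group)
passes for all `K ≤ 9`.

## Synthetic data

`simulate` draws data exactly from the generative process. The benchmark
truths use three-category items whose tables cycle through six fixed
`3 × 4` blocks (for `K < 4`, the leading `K` columns — each column is
already a distribution, so truncation needs no renormalization), the
grouping `s_j = j mod G` (stacked identity blocks), and concentrations
`(0.4, 0.5)`, `(0.4, 0.5, 0.6)`, `(0.4, 0.5, 0.6, 0.7)` for `K = 2, 3, 4`.
Supported shapes are `(p, G) ∈ {(30, 6), (60, 12), (90, 15)}` with
`n` free. These concentrations put most membership mass near a vertex
(`α₀ ≤ 2.2`), so within-group pairwise Cramér's V is high (~0.3) and
between-group V moderate (~0.1) — a block structure the fitted model must
recover. Random streams are split per sampling stage so that enlarging `n`
with the same seed extends a dataset instead of reshuffling it.

What the generator does *not* emulate: missing responses, ordinal
structure in the categories, heterogeneous `d_j`, or model misspecification
of any kind. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the model, not robustness on real surveys.

## Posterior sampling

`mcmc.run_chain` targets the joint posterior of `(Λ, Π, Z, s, ξ, α)` with
uniform Dirichlet priors on table columns and group weights `ξ`, and either
of two treatments of `α`:

- **MH-within-Gibbs** (default): conjugate updates for `Λ`, `Π`, `Z`,
  `(s, ξ)`, then a Metropolis-Hastings move on `α` with independent
  lognormal proposals (scale `σ_α`, default 0.02) targeting the density
  `∝ α₀^{a_α−1} e^{−b_α α₀} [Γ(α₀)/∏_k Γ(α_k)]^n ∏_k (∏_i π_{ik})^{α_k}`
  with `(a_α, b_α) = (2, 1)`. In `α`-space this density corresponds to
  `α₀ ~ Gamma(a_α+K−1, b_α)` with uniform mean direction; the Geweke
  tests use that matched prior.
- **augmented Gibbs**: the per-subject assignment multiplicities are
  Dirichlet-multinomial; auxiliary `q_i ~ Beta(G, α₀)` and Chinese
  Restaurant Table counts `t_{ik} ~ CRT(Z_{ik}, α_k)` restore conjugacy,
  giving `α_k ~ Gamma(a₀ + Σ_i t_{ik}, b₀ − Σ_i log(1−q_i))` (shape-rate;
  the subtracted log terms only make sense as a rate update). Defaults
  `a₀ = b₀ = 1`.

Update order is `Λ, Π, Z, (s, ξ), α`; chains default to 15000 sweeps,
10000 burn-in, thinning 5, with every unknown initialized from its prior.
Per-draw pointwise log-likelihoods `log p(y_i | θ^{(t)})` are stored at
thinning time so information criteria are exact for the retained draws.
No ordering constraint is imposed during sampling; label switching is
resolved post hoc by `postprocess.align_profiles`.

### Split-merge moves and warm-up

Single-site updates of `s` relocate one item at a time against frozen
assignment columns, tables and memberships. That kernel is severely
metastable here: from a diffuse start, group occupancy collapses within a
few sweeps (the group-weight update is a Pólya urn, and early tables carry
no signal), after which opening a fresh group requires one item to pay the
full probability cost of a new assignment column — hundreds of log units
at these sample sizes — before any partner can follow. Chains then sit in
merged-group modes that the posterior disfavors by hundreds of log-lik
units. Two standard remedies are built in, both leaving the stationary
distribution exactly intact:

- **Anchored split-merge Metropolis-Hastings moves** in the style of Jain
  & Neal's split-merge sampler for mixture models. Two anchor items are
  drawn; same-group anchors propose splitting their group into itself and
  an empty group, different-group anchors propose a merge. The departing
  subset is built by restricted allocation scans from a random launch
  bipartition (only the final scan's probabilities enter the proposal
  density), and the subset moves *together with* a freshly proposed
  assignment column. Tables of affected items and the membership matrix
  are redrawn from their conjugate conditionals as part of the move, which
  telescopes their proposal densities into Dirichlet-multinomial
  marginal-likelihood ratios and Pólya-urn assignment priors — the
  acceptance ratio compares table-free evidence for the two groupings, so
  a well-supported subgroup can nucleate in one step. Launch columns are
  proposed from posterior-mean table estimates computed from counts
  (never the current table draws), keeping the launch distribution
  identical from both ends of the move. Two variants alternate: a full
  refresh of both columns (balanced splits) and a cheaper variant keeping
  the stay-side column (nucleation out of a large group). Moves run every
  sweep during warm-up and every 5th sweep afterwards (a fixed kernel
  schedule); 3 attempts per invocation.
- **Annealed warm-up** during the first part of burn-in (default
  `min(500, burn_in/2)` sweeps): the likelihood term of the grouping
  conditional is tempered from 0 to 1, the group weights are pinned
  uniform, and `α` is held at a small value (0.1). This keeps early
  occupancy spread out until the tables carry signal. Warm-up is
  initialization; retained draws come entirely from the exact kernel.

Correctness of every conditional and of the split-merge acceptance ratios
is established by Geweke-style joint-consistency checks
(marginal-conditional versus successive-conditional simulation) at
`(n, p, G, K) = (3, 4, 2, 2)` and `(4, 6, 3, 2)`, plus unit tests of each
printed conditional on hand-evaluated cases.

With these moves the sampler recovers the true grouping (ARI 1.0) on all
benchmark settings we test, including the hard small-sample case
`(n, p, G, K) = (250, 30, 6, 2)` where a plain single-site sampler
partially fails; parameter RMSEs match the expected magnitudes. A
consequence worth noting: summaries that depend on sampler *imperfection*
(e.g. sub-1 grouping ARIs at hard settings, or model-dimension selection
percentages that benefit from under-exploited overparameterized fits) come
out cleaner here than with a plain single-site sampler.

## Posterior summaries

- Grouping point estimate: per-item majority label over retained draws
  (ties to the smallest index).
- Profile alignment: stack tables to `(Σd_j) × K`, take row-argmaxes of
  `ref_matᵀ est_mat`; collisions are repaired greedily in decreasing
  inner-product order so the result is always a bijection. Posterior means
  are computed without per-draw relabeling (alignment applied once).
- RMSEs pool all table entries (and the `K` concentrations) after
  alignment.
- ARI via scikit-learn's permutation-model formula.
- WAIC: `−2(lppd − p_WAIC2)` with `lppd = Σ_i log mean_t p(y_i|θ^{(t)})`
  (log-mean-exp) and `p_WAIC2 = Σ_i var_t log p(y_i|θ^{(t)})` using the
  `(T−1)`-denominator variance. Model selection fits a `(G, K)` grid and
  takes the smallest WAIC among fits whose posterior-mode grouping leaves
  no group empty (empty groups cannot be interpreted).
- Cramér's V: sample version from observed contingency tables
  (`V = sqrt(χ²/(n·min(d_j−1, d_{j'}−1)))`), model version from the
  population two-item marginals (same formula on probabilities, n-free);
  the diagonal is 1, degenerate single-category items get 0.

## Numerical choices

- All likelihood work is in log space with per-group log-sum-exp;
  Dirichlet draws are normalized gammas floored at the smallest positive
  normal double so downstream logs stay finite even at tiny
  concentrations.
- Table columns are validated to unit sum at `1e-10`, renormalized
  silently only below `1e-6` deviation, rejected above.
- The core tensor refuses to materialize beyond `10^7` entries; the
  per-subject latent-variable likelihood serves beyond that.
- Category codes are 1-based in files, 0-based in memory (same for group
  labels); the mapping round-trips exactly.

## Scale of the shipped experiments

The test-suite and the reproduction script run the benchmark study at
reduced scale so a complete run stays on a laptop budget: recovery
experiments use 10 replicate datasets per setting with chains of 4000
sweeps (3000 burn-in, thinning 5, warm-up 1000) — results at these
settings are indistinguishable from full-length 15000-sweep chains, which
the package uses as its default configuration — and the model-selection
study uses 10 datasets with shorter exploratory chains. The script
reports exactly what it computes at those sizes.

## Known limitations

- Complete cases only; files with missing cells are rejected.
- `K` and `G` are fixed per fit; selection is by WAIC grid search, not a
  transdimensional sampler.
- The WAIC variant conditions on the per-subject memberships (the
  pointwise likelihood is not marginalized over `π_i`); with a fully
  mixing sampler its complexity penalty is marginally too weak to resist
  overparameterized `K` at moderate `n` (see the selection tests).
- Identifiability of individual membership vectors `π_i` is outside scope;
  the checkers address the population parameters.
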