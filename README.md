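# gromm — dimension-grouped mixed membership models for categorical data

`gromm` fits mixed membership (grade-of-membership) models for multivariate
categorical data — survey items, disability checklists, personality
inventories — with one extra structural ingredient: the `p` items are
partitioned into `G` groups, and a subject realizes one latent profile per
*group* rather than per item. Each subject `i` has a membership vector
`π_i ~ Dirichlet(α)` over `K` extreme profiles; for each group `g` a
realization `z_{i,g} ~ Categorical(π_i)` is drawn, and every item `j` in
group `g` is answered from column `z_{i,g}` of its `d_j × K` conditional
probability table `Λ_j`:

    y_{i,j} | z_{i,s_j} = k  ~  Categorical(Λ_j[:, k]),   s_j = group of item j.

`G = 1` recovers the latent class model (CP decomposition of the response
probability tensor) and `G = p` the classical grade-of-membership model
(Tucker decomposition); in between the marginal likelihood is a hybrid
decomposition whose `G`-mode core holds the Dirichlet moments
`E[π_{k_1}···π_{k_G}]`. The grouping buys identifiability: the package
ships executable checkers for the strict (per-item rank and Khatri-Rao
rank) and generic (category-count) identifiability conditions.

The package provides:

- exact simulation from the generative process plus the benchmark
  ground-truth scenarios used in the test-bed (`gromm.simulate`);
- two MCMC samplers for the full posterior of `(Λ, Π, Z, s, ξ, α)` —
  Metropolis-Hastings-within-Gibbs and a fully conjugate augmented Gibbs
  sampler — accelerated by anchored split-merge moves on the grouping and
  an annealed warm-up (`gromm.mcmc`; see `docs/methods.md`);
- posterior summaries: posterior-mode grouping, label-switching-safe
  profile alignment, parameter RMSEs, adjusted Rand index, WAIC and
  WAIC-based selection of `(G, K)` with the empty-group exclusion rule,
  and sample/model-based Cramér's V association matrices
  (`gromm.postprocess`);
- identifiability checkers (`gromm.identifiability`), CSV/JSON file
  formats and a CLI (`gromm.io_cli`, `gromm.cli`).

## Worked example

Simulate 500 subjects from the benchmark truth with `K = 2` profiles and
`p = 90` three-category items in `G = 15` groups, fit it, and compare with
the truth:

```sh
$ gromm simulate --scenario K2_p90_G15 --n 500 --seed 7 --out data.csv
wrote 500 x 90 responses to data.csv (seed 7)

$ gromm fit data.csv --G 15 --K 2 --sampler mh --seed 1 --out run/
fit G=15 K=2 in 41.2s, 1000 draws, MH acceptance 0.798

$ gromm summarize run/ --truth data_truth/
{
 "grouping": [...],
 "alpha_mean": [0.410, 0.496],
 "waic": 72244.6,
 ...
 "ari": 1.0,
 "rmse_lambda": 0.0226,
 "rmse_alpha": 0.0079
}
```

The fitted grouping matches the truth exactly (`ari = 1.0`: the adjusted
Rand index of the posterior-mode grouping against the generating
partition), the pooled error of the aligned posterior-mean conditional
probability tables is about 0.023 per entry, and the Dirichlet
concentrations `(0.4, 0.5)` are recovered to ~0.01. `gromm check
data_truth/` confirms the generating parameters satisfy the generic
identifiability conditions, and `gromm select` scans a `(G, K)` grid by
WAIC.

The same pipeline is available as a library:

```python
import gromm

truth = gromm.paper_scenario(K=2, p=90, G=15)
data = gromm.sample_dataset(truth, n=500, seed=7)
samples = gromm.run_chain(data.responses, G=15, K=2,
                          config=gromm.MCMCConfig(seed=1))
summary = gromm.summarize_fit(samples, ref_tables=truth.tables)
```

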