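# Methods

## Models

`mmctm` implements a family of probabilistic topic models for somatic
mutation signature analysis. Mutation *signatures* are discrete
distributions φ_k over mutation categories (96 trinucleotide-context SNV
classes; 63 SV classes built from rearrangement type, breakpoint-homology
bin and breakpoint-distance bin). Each tumour sample d carries a
distribution θ_d over signatures, and each of its N_d mutations is
generated by first drawing a signature z ~ Cat(θ_d) and then a category
x ~ Cat(φ_z).

The variants differ only in the prior on θ_d:

- **LDA** — θ_d ~ Dirichlet(α). Signatures and samples are otherwise
  exchangeable; no correlation structure.
- **CTM** — θ_d = softmax(η_d) with η_d ~ N(μ, Σ). The Gaussian
  covariance captures how signature probabilities co-vary across samples.
- **MMCTM** — the multi-modal extension. Each modality m (SNV, SV, …) has
  its own signatures and counts, but a single Gaussian vector
  η_d ∈ R^{ΣK^(m)} is shared: modality m's θ_d^(m) is the softmax of its
  block of η_d. Off-block entries of Σ encode *cross-modality* signature
  correlations, which is what lets sparse modalities (typically SVs, with
  two orders of magnitude fewer events than SNVs) borrow strength from
  dense ones. With one modality the MMCTM is exactly the CTM, and the
  implementation realizes CTM as the single-modality case, so the two
  produce bitwise-identical trajectories given the same seed.

The independent-feature variants (ILDA/ICTM/IMMCTM) factorize each SNV
signature into per-feature categorical distributions — substitution type
(6 values), 5′ flank (4), 3′ flank (4) — reducing 96 parameters per
signature to 14. They consume per-feature count matrices (the concatenated
6+4+4 layout produced by the independent encoder). Because only marginal
feature tallies are supplied, the features of a mutation are treated as
conditionally independent observations sharing the sample's signature
distribution; a formulation in which all features of one mutation share a
single latent signature indicator would require joint 96-category counts
and is intentionally out of scope here. All contract-level properties
(single-signature marginals, product normalization over the 96 full
categories, factorized-signature recovery) hold for this treatment.

## Inference

Parameters are inferred by mean-field variational EM. The variational
family is fully factorized:

- q(η_d) = N(λ_d, diag(ν_d²));
- one responsibility vector per (sample, category), aggregated by count —
  exact for exchangeable tokens;
- q(φ_k) = Dirichlet(γ_k), with symmetric prior Dirichlet(β), β = 1 by
  default.

The intractable E[log Σ_k exp η_k] term in the evidence lower bound is
handled with the standard first-order auxiliary-variable upper bound, one
auxiliary normalizer ζ per sample per modality block, updated in closed
form. λ and log ν² are optimized jointly for all samples with a bounded
quasi-Newton step (L-BFGS with analytic gradients; the per-sample problems
are independent, so one stacked solve covers the cohort). With ζ fixed the
objective is concave in (λ, ν²); a candidate step is accepted only if it
does not decrease the bound, so every update is a coordinate ascent step
and the ELBO is non-decreasing across iterations (the test suite enforces
this at 1e-8 relative tolerance on every fit).

The M-step re-estimates μ as the mean of λ_d and Σ as the empirical second
moment of the variational means plus the mean of the variational
variances, with a 1e-6 ridge on the diagonal for invertibility in small
cohorts. `fix_covariance_identity=True` holds Σ = I throughout, which
removes the correlation machinery while keeping the logistic-normal link.

Initialization draws random positive integers
(1–100) for the variational signature Dirichlet parameters; λ starts at 0
and ν² at 1. All randomness flows through a seeded generator, so a fixed
(config, seed) pair reproduces a fit exactly.

Point estimates are posterior means: φ̂_k is the Dirichlet mean of γ_k and,
for the correlated models, θ̂_d is the blockwise softmax of λ_d. The
softmax of the Gaussian mean is an approximation to the mean of the
logistic-normal posterior (which has no closed form); it is the
conventional choice and is recorded in fit metadata.

Convergence is declared when the relative change in the training
per-mutation predictive log-likelihood (token-weighted across modalities)
falls below the tolerance: 1e-4 during restart screening, 1e-5 for the
final fit.

### Restart protocol

Topic-model posteriors are multi-modal, so fitting uses random restarts:
`n_restarts` short fits (tolerance 1e-4, at most 100 iterations each —
configurable) are ranked within each modality by training predictive
log-likelihood, and the restart with the best (lowest) mean rank across
modalities is continued to full convergence. Ties break toward the lowest
restart index.

### Held-out inference

`infer_theta` freezes the signatures (through their posterior means) and
the Gaussian prior, and runs only the per-sample updates on new counts. A
sample with zero counts keeps the prior mean, so its θ is the
prior-induced softmax(μ); such samples are flagged.

## Evaluation

The benchmark metric is the average per-mutation predictive
log-likelihood: each test sample's mutations are split into observed and
hidden halves (binomial thinning per category; default fraction 0.5, the
symmetric document-completion convention), θ is inferred from the observed
half, and the hidden half is scored by the mean log mixture probability.
For comparator methods whose normalized outputs can contain exact zeros, a
1e-16 floor can be added inside the log. Cross-validation plans are
stratified (by histotype or any caller-supplied label), repeated, and
seeded; strata smaller than the fold count are spread round-robin with a
warning.

Count downsampling retains each mutation independently with the stated
probability (per-category binomial thinning), which selects mutations
according to their category proportions in expectation; an exact
without-replacement mode (multivariate hypergeometric) is available behind
a flag.

The classifier benchmark mirrors a label-prediction harness: the majority
class is subsampled to balance, and an L2-regularized logistic regression
(C = 1, up to 10,000 iterations) is scored by plain accuracy over
stratified folds.

Signature-number selection produces the likelihood-vs-K curve either by
cross-validation or by fitting to half of each sample's mutations and
scoring the other half. The suggested K — the smallest K whose successor
improves the mean by less than one standard error — is advisory and
logged, never binding; the intended use is visual inspection of the curve.

## Synthetic data

The generator draws counts X_dv ~ Poisson(N_d · (θ_d φ)_v), the standard
signature-simulation scheme, and is the package's test substrate.
Reference signatures are sparse Dirichlet(0.1) draws, redrawn until all
pairwise cosine similarities fall below 0.5 (clearly distinct processes);
reference probabilities come from a symmetric Dirichlet or from a
blockwise logistic-normal when correlated structure is wanted. Any
signature TSV can be supplied instead, so published reference signatures
drop in directly.

The generator emulates the count structure the models assume — Poisson
category counts from mixed signatures — and deliberately not other
features of real cohorts: no clustered-breakpoint SV classes, no
sequencing-error or purity noise, no inter-sample burden heterogeneity
beyond the supplied totals. Passing recovery tests therefore demonstrates
correctness of inference under the model's own assumptions, not robustness
to model misspecification on real genomes.

The headline recovery study (also run by `scripts/acceptance.py`) uses 4
SNV signatures, 200 samples, 5000 mutations per sample, 10 replicate
corpora and 50 restarts per corpus — a desk-scale analogue of
cohort-level simulation studies (560 samples, 500 restarts) that runs in
minutes on one CPU while preserving the per-sample information content.

## Stratification

Sample stratification z-scores each signature's probabilities across
samples (n−1 SD; zero-variance columns map to zero and are flagged) so
that low-prevalence signatures contribute on the same scale as dominant
ones, then applies Ward-linkage agglomerative clustering on Euclidean
distances. The default cut (`dynamic_hybrid_like`) scans merge heights and
keeps the cut producing the most clusters subject to a minimum cluster
size of 3; it is a deliberately simple stand-in for dynamic tree-cutting,
with `fixed_k` and `fixed_height` as alternatives, and the chosen mode and
parameters are recorded in the output.

Association tests are cluster-vs-rest: one-sided Welch t-tests for
signature enrichment; two-tailed Fisher exact tests for binary
annotations; two-tailed Welch tests for continuous ones, optionally on
midranks (robust when, e.g., a hypermutated outlier dominates counts); and
a blocked permutation test for annotations confounded with known strata.
Permuted clusters preserve the original cluster's per-block composition,
and the two-tailed add-one p-value (1 + #{|s′| ≥ |s|}) / (1 + N) is
bounded below by 1/(N+1). Benjamini–Hochberg correction is applied
separately to the signature-enrichment and annotation tables.
Welch-based confidence intervals are emitted for t-tests; no interval is
emitted for permutation tests.

## Numerical notes and limitations

- Degenerate inputs: all-zero count matrices are rejected; zero-count
  samples within a cohort are retained, flagged, and receive
  prior-mean θ.
- The ζ terms guard division by zero for empty modalities; responsibilities
  use log-space softmax throughout.
- Greedy signature matching breaks ties lexicographically by (estimated,
  reference) index, making scoring deterministic.
- The ridge on Σ means the ELBO can move by O(1e-6) relative to the exact
  M-step optimum; the monotonicity contract is therefore stated at 1e-8
  *relative* tolerance.
- Model selection for K is heuristic; on real data the curve should be
  inspected, as automated elbow detection is sensitive to noise in the
  fold-level likelihoods.
- The clustering cut is not the R dynamicTreeCut "hybrid" algorithm;
  cluster boundaries on real cohorts can differ from analyses using that
  package.
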