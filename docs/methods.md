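# Methods

## Model

For a cluster of K proteins sharing peptides, one TMT mixture at a time, the
observed log2 intensity of feature (peptide ion) f in channel c is

    X_cf = mu + Feature_f + sum_{k in V(f)} Weight_fk (Protein_k + Channel_kc) + eps_cf

where V(f) is the set of proteins whose sequence contains the peptide. The
per-protein channel term allows non-parallel profiles within a cluster; a
purely additive channel term would force every protein in the cluster to
share one profile shape. Weights are constrained to the simplex over V(f)
(non-negative, summing to one per feature), so a shared feature's profile is
a convex combination of its candidate proteins' profiles; unique features
have weight exactly 1. No distributional assumption is placed on eps; the
fitting loss determines the behavior (below). Each mixture is fitted
independently; weights are not pooled across mixtures.

### Identifiability

The constraints sum_f Feature_f = 0, sum_k Protein_k = 0 and
sum_c Channel_kc = 0 per protein do not fully identify the decomposition:
for K >= 3 (and some balanced K = 2 layouts) one can shift Protein_k by
delta_k and absorb -sum_k Weight_fk delta_k into the feature effects without
changing any fitted value. We therefore impose the stronger convention

    sum_f Weight_fk * Feature_f = 0   for every protein k,

which reduces to the usual per-protein feature centering when K = 1 and
implies the global feature sum-to-zero (each feature's weights sum to one).
The synthetic-data generator records its ground truth in the same
representative, so recovery on residual-free data is exact. All centering is
applied post hoc after each profile step; because the shifts lie in the null
space of the model, this is equivalent to constrained solving and exactly
verifiable.

Weights themselves are identified only where protein profiles differ in
*shape*: two proteins whose channel profiles differ by a constant (the
constant is absorbed by the feature effect) make the objective flat in the
corresponding weights. In that case the previous iterate — ultimately the
uniform 1/|V(f)| initialization — is retained, a deterministic tie rule.

## Loss and optimization

The objective is sum over observed cells of a loss L applied to the
residual. The default is the Huber loss

    L_H(x, M) = x^2            if |x| < M
                2M|x| - M^2    otherwise

with threshold M = 1e-3 (1e-6 available) on the log2 scale: effectively an
absolute-deviation loss with a smooth vertex, giving median-like robustness
to interference and outlier features while remaining differentiable.
Squared (L2) and absolute (L1) losses are provided as alternatives; L1 is
prone to convergence problems because of its non-differentiability and is
not recommended.

The model is biconvex: linear in (mu, Feature, Protein, Channel) given the
weights, and linear in the weights given the profiles. Fitting alternates:

1. **Initialization.** Each protein's channel profile is the median-polish
   summary of its unique features; proteins without unique features fall
   back to a uniform-weight (inclusion) fit of the whole cluster. Feature
   effects start at residual feature means; weights start uniform over V(f).
2. **Weight step.** For each shared feature independently, minimize the loss
   over the simplex on V(f) holding the protein/channel profiles fixed. The
   feature's own offset is profiled out: for every candidate weight vector
   the optimal offset is the robust location of the residuals (computed in
   closed form for the piecewise-linear Huber score). The step is therefore
   a joint convex minimization over (Weight_f, Feature_f) — one coordinate
   block of the full objective — which keeps the alternation monotone and
   makes the step exact on residual-free data. (Holding the feature offset
   fixed instead couples the weight estimate to the stale offset and slows
   convergence by an order of magnitude.) Two-membership features use a
   derivative-based line search; larger membership sets use an SLSQP solve
   of the simplex-constrained program. A candidate is accepted only if it
   strictly decreases the objective, which implements the tie rule and
   guards against solver failure.
3. **Profile step.** For fixed weights, minimize over (mu, Feature, Protein,
   Channel) by iteratively reweighted least squares using the exact
   quadratic majorizer of the loss (weights min(1, M/|r|) for Huber), so
   each sweep is a weighted least-squares solve and the objective never
   increases. Rank deficiency of the unconstrained parameterization is
   absorbed by a tiny relative ridge (1e-10) and resolved by the canonical
   re-centering. Proteins with zero total weight are unidentifiable; their
   effects are kept at initialization and flagged.

Convergence is declared when the largest absolute weight change between
consecutive iterations falls below `weight_tol` = 1e-3, with `max_iter` =
100. During the alternation the profile step runs a small number of IRLS
sweeps (8); a full-precision profile step (30 sweeps, parameter tolerance
1e-9) polishes the final fit. Alternating convex search carries no global
optimality guarantee; in practice clusters whose proteins all have unique
peptides converge in a few iterations, while null-like clusters whose
profiles differ only by noise can wander along near-flat directions of the
objective until `max_iter` — the convergence record (`converged`, `n_iter`,
`final_weight_change`, objective trace) is attached to every fit.

The summary for protein k in channel c is Y_kc = mu + Protein_k +
Channel_kc. Single-protein ("trivial") clusters bypass the weighted model
and use the classical median-polish summarizer.

### Baselines

Two reference summarization strategies are built in for comparison:
*unique-only* (median polish of each protein's unique features; proteins
without unique features yield nothing) and *naive inclusion / all-peptides*
(every feature assigned to every matching protein as if unique, median
polish per protein). A third variant — the weighted model with weights
frozen at 1/|V(f)| — is available through
`fit_weighted_model(update_weights=False)`.

## Graph preparation

Clusters are connected components of the peptide-protein bipartite graph.
Before fitting, proteins identified by exactly the same feature set are
merged under a ";"-joined label (they are indistinguishable), and *subset
proteins* — identified by shared peptides only — are removed unless
`keep_subset` is set. Removal iterates to a fixed point: deleting a protein
can promote a shared feature to unique for a remaining protein, which can in
turn rescue that protein, so membership is recomputed and the rule
re-applied until stable (a single pass can leave proteins whose uniqueness
status changed). A separate, stricter filter removing proteins whose entire
evidence is a single shared peptide is also provided. Raw intensities <= 0
are treated as missing (log2 undefined). No normalization is applied by
default; an optional centering of mixtures on a user-named reference
channel (`normalize_to_reference_channel`) is available for multi-mixture
experiments that carry reference material.

## Differential testing

Per protein, summaries are modeled as Y = mu + Condition_g + Mixture_m + eps
(cell means for condition or condition-time, one-hot mixture with the first
level as reference). Mixture enters as a **fixed** additive effect rather
than a random intercept: in the balanced designs targeted here the contrast
estimates coincide, and variance-component estimation is avoided; degrees of
freedom are the residual df of the fixed-effects fit. Contrasts must sum to
zero; two-sided t-tests give p-values, adjusted by Benjamini-Hochberg.
Non-estimable contrasts (a condition with no data) are reported as absent
rows rather than NaNs. A zero standard error is flagged degenerate (p = 0
for a nonzero estimate, 1 otherwise).

For PTM data, sites take the role of proteins: singly-modified peptides are
unique features of their site, multiply-modified peptides are shared among
their sites, and site clusters never span proteins. The occupancy test
adjusts the site-level fold change by the protein-level one:
log2FC_adj = log2FC_site - log2FC_protein, se_adj^2 = se_site^2 +
se_protein^2, with Satterthwaite degrees of freedom
(se_site^2+se_protein^2)^2 / (se_site^4/df_site + se_protein^4/df_protein).

## Synthetic data generator

The generator emulates a single-mixture TMT group-comparison experiment on
one protein cluster with pairwise peptide sharing. Defaults (the study
conditions used throughout the tests and the acceptance script):

| parameter | default | meaning |
|---|---|---|
| n_proteins | 5 | cluster size |
| n_unique_per_protein | 2 | unique peptides per protein |
| n_shared_per_pair | 5 | shared peptides per protein pair |
| n_conditions / n_bioreps | 5 / 2 | group-comparison design, 10 channels |
| n_differential | 3 | proteins with nonzero fold changes |
| effect magnitudes | 0.5/1.0/1.5/2.0 | per-condition log2FC vs reference, sign alternating across changed proteins |
| noise_sd | 0.2 | feature-level (measurement) error sd |
| channel_sd | 0.2 | channel-level (biological replicate) error sd |
| feature_sd | 0.5 | spread of feature effects |
| baseline | N(16, 1) | per-protein log2 abundance level |

Protein channel abundances follow the group-comparison linear model
(baseline + condition effect + iid channel error); feature intensities
follow the weighted model with generating weights that assign each shared
peptide wholly to one protein of its pair, alternating (a mixed-weight
option draws a random convex combination instead). Feature effects are
drawn iid normal and projected to the identification convention above, so
the recorded truth is the identified representative. All randomness flows
from one master seed through per-replicate substreams, so competing methods
see identical data.

What the generator does **not** emulate: between-mixture reference-channel
normalization, intensity-dependent missingness (dropout is ignorable here),
correlated or heavy-tailed interference, peptide identification errors, and
protein-level FDR. Passing benchmarks therefore demonstrate correctness of
the estimation machinery under the stated model, not robustness to every
artifact of real acquisitions.

## Benchmark and calibration

The benchmark simulates replicates of the default cluster, summarizes each
with the three strategies, fits the same differential model to each, and
tests every protein against the reference condition at unadjusted p < 0.05
(adjusted p-values would couple the comparison to the differing numbers of
tests per method). Reported metrics: sensitivity over truly changed
(protein, contrast) pairs, specificity over null pairs, and MSE/bias of
log2FC estimation. Problem sizes used by the test suite and acceptance
script — 20 benchmark replicates, 26 null replicates (520 protein-tests),
20 weight-recovery seeds — were chosen to keep the full run in the
few-minute range while leaving the Monte-Carlo checks well clear of their
tolerance bands.

## Numerical choices

- Huber M default 1e-3 (log2 scale); small M favors robustness and stable
  alternation. M = 1e-6 mimics the near-L1 regime.
- weight_tol 1e-3 (max absolute weight change), max_iter 100.
- IRLS: exact Huber majorizer, ridge 1e-10 relative, parameter tolerance
  1e-9, 30 sweeps (8 during alternation).
- Median polish: row-first sweeps, convergence on relative change of the sum
  of absolute residuals (1e-10), 100 sweeps max; all-missing rows/columns
  excluded with a warning.
- Robust location (weight step): exact closed form via the piecewise-linear
  Huber score; midpoint of a flat zero segment for determinism.
- Ties in the weight objective keep the previous iterate (ultimately the
  uniform initialization).
- Degenerate tests (se = 0): p fixed at 0/1 and flagged, not NaN.

## Known limitations

- No pooling of weights across mixtures; no uncertainty quantification for
  the estimated weights.
- The fixed-effect mixture term is exact for balanced designs; strongly
  unbalanced multi-mixture designs would warrant a random-intercept (REML)
  backend, for which the model surface leaves a hook.
- Alternating convex search can stop at non-stationary points for clusters
  with weakly identified weights; inspect the convergence record.
- Site-level and protein-level results are combined assuming independence
  of their errors (the usual convention when the unmodified-protein data
  are disjoint from the modified peptides).
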