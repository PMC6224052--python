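# Methods

## The model

`trajmix` clusters variable-length monthly count series — one per claimant,
recording visits to a healthcare service after a transport injury — with a
finite mixture of hidden Markov models (MHMM). Each trajectory
`x_{1:T}` is assumed to be generated by first drawing a cluster indicator
`z ~ Categorical(w)` and then running the cluster-specific HMM:

    p(x_{1:T}, y_{1:T}, z) = w_z · π_z[y_1] · ∏_t A_z[y_{t−1}, y_t] · ∏_t B_z[y_t, x_t]

with `y_t` a latent monthly utilization level and `B_z` a categorical
emission over the count support `{0, …, K−1}` (default `K = 25`). Fitting
maximizes the marginal likelihood over all series at once by EM: the E step
computes per-series cluster responsibilities together with
responsibility-weighted state posteriors (forward–backward), the M step
renormalizes the expected counts. Hard cluster labels are the posterior
argmax; state paths are Viterbi decodes under the assigned component.

Assumptions worth keeping in mind:

- the mixture likelihood does not model the series length `T`; duration
  separates clusters only through state dynamics (e.g. the persistence of a
  near-zero state), not through an explicit length factor;
- all components share the number of states `N`;
- emissions are exchangeable categorical — no ordinal smoothness across
  neighbouring counts is imposed.

## Numerical choices

- The public per-sequence recursions (`trajmix.hmm`) run in log space with
  log-sum-exp; a scaled linear-space implementation batched over padded,
  masked sequences backs the EM loop for speed. The two routes are
  cross-checked against each other and against exhaustive path enumeration
  in the tests.
- Viterbi ties break toward the lower state index, making decodes
  deterministic.
- M-step emission rows receive a floor of 1e−10 before renormalization so
  no later E step meets an exactly-zero probability.
- EM stops when the relative log-likelihood improvement drops below `tol`
  (default 1e−6; the parameter-recovery experiments use 1e−7 with
  `max_iter = 1000`, because the slow tail of EM — where overlapping states
  finish separating — matters for parameter accuracy even after the
  likelihood has nearly plateaued).
- Restarts (default 5) combine two structured initializations with
  perturbed variants: series are pre-grouped by k-means on (mean count,
  log length, zero fraction), and within each group months get provisional
  states either by 1-d k-means on counts ("value" flavor) or by position in
  the series ("time" flavor — early/mid/late). The value flavor captures
  count bands; the time flavor captures left-to-right phase structure that
  count bands cannot express when two states share a count range but differ
  in dwell. Fully random restarts at `M·N ≈ 9` almost never reach a
  competitive optimum, so only the last restart is fully random. The best
  restart by final log-likelihood wins; clusters are then relabeled by
  descending membership so "cluster 1" is always the largest.
- BIC uses `n_obs = Σ T_i` (total observed months): every month contributes
  one factor to the likelihood. This convention is configurable.
- Grid-search ties break toward smaller `M`, then smaller `N`.

## The synthetic scenario

Because the claims data that motivated this design are restricted, the
package ships a fully specified generative scenario (`default_scenario`)
that emulates their published structure, and every downstream stage is
validated by parameter recovery against it.

- Three clusters with weights (0.67, 0.27, 0.06): "brief" (short series,
  medium → low → zero), "intermediate" (moderate lengths, high → low →
  zero) and "sustained" (long series, very-high ↔ high → zero).
- Counts live on {0..24}. The nine states map onto five qualitative labels
  by expected emission value (zero < 0.5 ≤ low < 2 ≤ medium < 5 ≤ high < 10
  ≤ very high).
- Series lengths are shifted negative binomials (support ≥ 2, truncated at
  106) with cluster means (21, 44, 80) months and dispersions (2, 4, 8);
  the truncated mixture mean is ≈ 29.9 months.
- Off-diagonal transition rates follow the magnitudes a claims analyst
  would recognize from published state diagrams of this kind of service:
  0.28 (medium→low) and 0.13/0.15 (low↔zero exchange) in the brief cluster,
  0.068/0.062 in the intermediate one, 0.057/0.045 in the sustained one.
- Emission rows for the active states are peaked on a narrow band of
  typical appointment frequencies rather than Poisson-wide; the "zero"
  state emits 0 with probability 0.62 and small counts otherwise (mean
  0.48).

Two generator details were driven by identifiability analysis and are worth
recording. First, the observed series is trimmed at the first and last
utilization month, so its endpoint counts are positive by construction; the
generator reproduces this by redrawing the endpoint emissions conditional
on positivity. That truncation contaminates the per-state emission
frequencies at roughly one observation per series, concentrated in whatever
state hosts the series end — about `2·P(0|state)/T̄` of L1 error. A "zero"
state emitting hard zeros would therefore be unrecoverable to within the
tested tolerance at the brief cluster's mean length (~21 months), which is
why the zero state has substantial positive mass. Second, the smallest
cluster (6% of n = 800 ≈ 48 series) bounds how well its emission rows can
be estimated at all: even the supervised maximum-likelihood estimate with
known state paths has row-L1 noise of ~0.05–0.08 for a wide row at that
occupancy, so the sustained cluster's states use concentrated emissions.
With these choices the maximum-likelihood fit at n = 800 recovers every
transition and emission row to L1 ≤ 0.10 at the default seed; across seeds
the worst row typically spans ≈ 0.06–0.15 — the spread of the MLE itself,
not of the optimizer (fits reach or exceed the likelihood of an EM run
started at the true parameters).

Covariates (gender, age group, road-user role, nine injury flags, elapsed
time from accident to first utilization) are drawn with realistic marginal
shares, and cluster labels relate to them through a known multinomial-logit
with cluster-1 as reference. Two sampling directions are provided:
`sample_labels_given_covariates` draws covariates from the margins and then
`z ~ logit(c)` — exactly the model the regression estimates, used for
calibration and recovery tests — and `sample_covariates` draws covariates
*given* labels by rejection (accept `c` with probability `p(z|c)`), which
yields exactly `p(c|z) ∝ p(z|c)·m(c)`. When the mixture weights differ from
the logit-implied marginal shares, the induced conditional differs from the
scenario logit by a per-class intercept shift only; the scenario's
intercepts (−2.139, −3.744) are calibrated so the implied shares match the
weights and the shift is negligible. The elapsed time is exponential with
mean 0.5 years.

What the generator does **not** emulate: calendar seasonality, covariate
effects on the trajectory shape itself (covariates influence only the
cluster label), within-month service substitution, and the administrative
censoring of the few longest series. Passing recovery tests therefore
demonstrates the correctness of the machinery under the stated model, not
robustness to real-data violations of it.

## Baselines and validity indexes

PAM is implemented as greedy BUILD followed by steepest-descent SWAP on a
precomputed distance matrix; it is a local search, and tests assert
swap-optimality (plus global optimality on separated instances) rather than
global optimality in general. CLARA runs PAM on random subsamples (default
size 50, 5 samples) and keeps the clustering with the lowest full-data
cost; with a full-size sample it reduces to PAM exactly. Fuzzy C-means uses
the standard alternating updates with fuzzifier 2, seeded by mutually
distant data points because a near-uniform membership start is a saddle of
its objective. Since medoid and fuzzy methods need fixed-length vectors,
variable-length series are right-padded with zeros and compared with
Euclidean distance — an assumption of the benchmark, made explicit and
pluggable, not a property of the trajectories. Silhouette values come from
scikit-learn on the precomputed distances; the Dunn index and classical
(Torgerson) MDS are implemented directly, the latter with deterministic
axis signs and zero-clamping of numerically-negative eigenvalues.

## Membership regression

Hard cluster labels (not posteriors) are regressed on covariates with
multinomial logit (statsmodels MNLogit, Newton), the largest cluster as
reference response, "pedestrian" and "<30" as reference levels, male coded
1 against a female reference, elapsed time in years numeric. Four nested
covariate sets are fitted on the complete cases of the largest set so
log-likelihoods are comparable: demographics; + brain-head, soft-tissue and
non-limb-fracture flags; + elapsed time; + roles. Wald p-values are starred
at 0.1/0.05/0.01 with no multiplicity correction. Perfect separation is
reported as an error naming the covariate; at small n the pipeline logs the
failure and continues, since sparse dummies (witness × smallest cluster)
separate easily.

One statistical note: within a single simulated sample the coefficient
errors are correlated, so "share of coefficients within 2 SE" fluctuates
far more than binomial thinking suggests. Calibration tests therefore pool
three replicate samples (84 coefficients) and null-rejection tests pool 20
permutations.

## Problem sizes in tests

The recovery experiment uses n = 800 series (the scale of the motivating
population) with 5 restarts; model-selection recovery uses 10 replicates of
n = 400 with 3 restarts per grid cell; regression simulations use n = 5000.
These sizes keep the full suite comfortably reproducible on a single CPU
while leaving the statistical conclusions unchanged at larger n.

## Known limitations

- Shared `N` across clusters; no per-cluster state count search.
- No covariate-dependent mixture weights (the regression is descriptive,
  post-hoc, as in the assignment-then-regress workflow it mirrors).
- The endpoint-positivity truncation is reproduced by the generator but not
  modeled by the likelihood; its residual bias is quantified above.
- BIC's sample-size convention is a documented choice, not a theorem.
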