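# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `jartask`, in the spirit of a
model-documentation page: what is computed, under which assumptions, and
what the package's tests do and do not establish.

## Task and ideal observer

A block is defined by the rare-ball fractions (h₊, h₋) of two a-priori
equally likely jars, balanced over jar × sample length n ∈ {2, 5, 10}.
The ideal observer's belief is the log-likelihood ratio
zₙ = Σ Ψ(ξⱼ) with Ψ(+1) = log(h₊/h₋) and Ψ(−1) = log((1−h₊)/(1−h₋))
(natural log).  Decisions follow the sign of zₙ; an exactly zero belief is
resolved by a fair coin, and in closed-form response probabilities half of
the zero-LLR binomial bin's mass is assigned to each response.  The
rare-ball threshold B(n) is the smallest count with positive belief; for
symmetric jars and even n the boundary count has zero LLR and B = n/2 is
reported with the tie convention.  Exact response probabilities are
binomial tail sums above B; at the level of a whole block (lengths mixed
equally) asymmetric conditions always favor the low jar, but the
per-length asymmetry is sawtooth-shaped and can dip below ½ at individual
lengths (hard asymmetric, n = 5), so tests assert the block-level
asymmetry only.

## Observer models

The three Bayesian models act on the rescaled belief m = z₀ + ρk − (n−k)
(common-ball weight normalized to −1; ρ_IO = |log(h₊/h₋)/log((1−h₊)/(1−h₋))|
is the ideal weight) and respond "high" with probability
½[1 + erf(m/√(2a²))].  Two noise conventions are possible: a per-ball
noise term summed over the sample (trial variance n·a²) and a trial-level
variance a².  The likelihood evaluated throughout is the trial-level
form — it is the closed form the fitting procedure uses — with
`noise_scaling="per_ball"` available as an option.  The a = 0 limit is the
deterministic sign rule with the ½ tie convention.

The heuristics ignore likelihoods: the threshold models respond high with
probability P_rare when at least θ rare balls are present (θ free in the
variable model, θ = 1 in the reduced model) and low with probability P_no
otherwise; the guess model responds high with a fixed P_guess.  Because
their response probabilities depend only on the rare count, not on n, they
are decoupled from the LLR — the mechanism that generates
observation-specific "variance" in the psychometric decomposition.

## Synthetic cohorts

A session mirrors the study design: a 24-trial control pre-test, four
42-trial test blocks in randomized order, and 12 control trials between
consecutive test blocks (60 control trials pooled for fitting).  Exclusion
follows the study rules: pre-test accuracy below 80%, or accuracy at or
below 50% on two or more interspersed control mini-blocks.

Each simulated subject is assigned one strategy and one parameter set for
the whole session.  Two distribution presets exist:

* **Defaults** (neutral, wide): a ~ U(0, 1); ρ ~ U(1, 24.16);
  z₀ ~ U(−3, 0); heuristic probabilities ~ U(0.5, 1); θ ~ {1, 2, 3}.
* **Study preset** (`study_preset_config`): narrower, low-noise ranges
  mimicking the qualitative pattern of the reported subject fits — set-ρ
  subjects with a ~ U(0.05, 0.4); free-ρ subjects underweighting toward
  ρ ~ U(1, 8); biased priors z₀ ~ U(−3, −0.5) (leaning toward the low
  jar); heuristic reliabilities U(0.6, 0.95); P_guess ~ U(0.35, 0.65); and
  a strategy mix dominated by Bayesian models.  In the preset, control
  segments are answered by a low-noise set-ρ observer
  (`control_strategy="ideal"`): every retained human subject passed the
  easy control pre-test even when using a heuristic on the test blocks, so
  a generator that applied a heuristic to the control block would exclude
  nearly the whole heuristic class at the pre-test.

The generator emulates the study's design exactly (balanced stimulus
sampling, session structure, exclusions) but not several features of real
data: no learning or adaptation across blocks, no lapses of attention
correlated in time, a single strategy per subject rather than per block,
and parameter distributions that are stand-ins for the unpublished fitted
distributions.  Passing tests therefore establish that the *pipeline*
recovers what this generative family produces — not that human cohorts
follow these distributions.

## Grid fitting and priors

All likelihoods are analytic, so posteriors are computed exactly on dense
grids: a ∈ [0, 1] step 0.01; ρ ∈ (0, 24.16] step 0.08; z₀ ∈ [−5, 5] step
0.1 (the range is a package choice wide enough that a 42-trial block
cannot distinguish larger biases from saturation); response probabilities
step 0.01; θ exhaustive.  A block of trials reduces to a count matrix over
the 21 observation classes (n, k) × response, and the whole grid evaluates
with two matrix products — this is what makes the 100-datasets-per-model
recovery protocols run in seconds.  Per-trial response probabilities are
floored at 1e-10 so that deterministic heuristics remain fittable; a
posterior whose best cell still required the floor is flagged.

Two grid-support choices depart from the widest conceivable supports, both
for mutual identifiability of the model set (the model set was designed to
be identifiable; a support on which two models coincide defeats Bayes-factor
comparison):

* θ ∈ {2, 3, 4}: θ = 1 is definitionally the reduced rare-ball model, and
  thresholds of 5 or more trigger with probability below a few percent per
  trial at the study's rare-ball rates (never for n = 2), making those
  slices indistinguishable from guessing within 42 trials.
* P_rare, P_no ∈ [0.5, 1]: below chance the observer systematically
  contradicts its own rule, and on the line P_rare = 1 − P_no the
  threshold models collapse onto the guess model.

**Informative prior.**  Flat-prior posteriors of the free-ρ noisy Bayesian
model are computed for 20 pilot subjects, averaged per block, and
smoothed: the ρ-marginal is multiplied by a normal density centered at the
marginal's argmax, with the variance calibrated as the largest value in
{16, 8, 4, 2, 1} for which the median squared error of recovered ρ over
100 synthetic datasets stays below one; the a-marginal passes through
x → (x + c)/(1 + cL) applied to the marginal as a *density* (c = 5, L = 2
for symmetric blocks; c = 2, L = 1 for asymmetric).  The joint prior is
rebuilt as the product of the smoothed marginals (an independence
assumption; the recombination is otherwise underdetermined).  The set-ρ
model receives the smoothed a-marginal; the biased-prior model receives
the a-marginal × a z₀-marginal averaged over the pilot subjects whose
responses are best described by the biased-prior model (mixed with a 10%
uniform floor) — averaging over *all* pilot subjects would center the z₀
prior at 0, exactly where the model degenerates to its set-ρ submodel.
If no pilot subject expresses a prior bias on a block (typical for
control), the z₀ axis stays flat.  Heuristic priors are flat.

**Estimates.**  The point estimate is the posterior argmax (ties to the
lowest flat index); the credible region is the smallest highest-density
set of cells holding ≥ 95% posterior mass.

## Model comparison and identifiability

Marginal likelihoods are prior-weighted sums over grid cells.  Log Bayes
factors are taken against the free-ρ Noisy Bayesian baseline; the
alternative with the largest positive log BF is selected, the baseline is
kept when none is positive, and |log BF| > 1 flags strong evidence.
Cross-validation is 10-fold 90/10 over a seed-shuffled trial order,
predicting the most-probable response from the training-set MLE
(probability-weighted scoring available).

The identifiability protocol simulates 100 datasets per generating model
per block, with parameters drawn from the model's fitting prior
(informative for Bayesian models, flat for heuristics), and reports two
quantities: the full six-way selection confusion matrix and, for the five
alternatives, the fraction of datasets whose log BF against the baseline
is positive.  The pairwise fraction is the identifiability criterion
proper: the baseline itself cannot have a six-way identification bar,
because parameters drawn near ρ_IO generate data identical to the set-ρ
submodel and parsimony then correctly selects the reduced model.

A structural limit worth stating: a biased-prior dataset whose |z₀| lies
inside the block's smallest decision margin (about ±1.9 rescaled-LLR units
on the hard asymmetric block, ±2.2 on control) is *exactly* set-ρ data, so
its pairwise Bayes factor compares two near-equal parsimony factors and
the identification of such draws is near chance.  With the generator's
pilot biases spanning U(−3, −0.5), the informative z₀ prior retains
roughly a fifth of its mass in that window, which caps the biased-prior
model's identifiability near 75–80% on those blocks; the other
twenty-three model × block cells sit at 0.83–1.00.

## Psychometrics

The three-parameter logistic
p(high | LLR) = α + (1 − 2α)/(1 + e^(−β(LLR − φ))) is fit per
subject-block by Bernoulli maximum likelihood on per-trial outcomes
(L-BFGS-B, bounds α ∈ [0, 0.5], β ∈ (0, 50], φ ∈ [−20, 20], one
deterministic start plus 9 seeded random restarts; a least-squares fit to
binned proportions is available).  Bias is φ clipped to [−10, 10]
(positive = toward the low jar), noise is 1/|β|, and variance is
v = (1/x) Σᵢ nᵢ |P_obs,i − p_fit,i| over the x distinct exact LLR values
(weighting by nᵢ while dividing by x, as defined; a Σnᵢ-normalized variant
is exposed for interpretability).  LLR values are discrete rational
combinations of the two increments, so binning uses exact values (rounded
at 1e-9 to absorb float noise).  Group summaries report medians,
1000-resample bootstrap means and 95% CIs, Wilcoxon rank-sum and Welch
t-tests against the nearly-ideal group, and Spearman correlations.

## Strategy complexity

Mutual information is the plug-in estimator on the empirical joint of the
observation class (|ξ|, n) and the response, in bits, summing only over
observed cells; a second estimator conditions the observation on the
previous response (dropping the first trial).  Bootstrap distributions use
1000 uniform trial resamples.

The accuracy bound V*(C) maximizes the expected accuracy
Σ_c p(c) Σ_r π(r|c) Q(c, r) over stochastic policies with I(π) = C, where
Q(c, high) = 1/(1 + e^(−zₙ)) and p(c) mixes the three sample lengths
equally (the design samples them equally) and the two jars by the prior.
The equality-constrained program is solved with SLSQP from 20 seeded
starts (constraint violation tolerance 1e-5); the endpoints are exact
identities — V*(0) is the best constant policy and V*(I_ideal) the ideal
observer's accuracy — and V*(C) is checked numerically to be
nondecreasing.  Finite-sample subject points can exceed the asymptotic
bound; the large-sample test simulates 30 000 trials.

Algorithmic complexity counts per-trial operations: guess reads and
stores one parameter (2); rare-ball adds a presence test (4); the variable
threshold model adds a count and a stored threshold (6); the set-ρ model
performs n multiplications and n − 1 additions (2n − 1); the free-ρ and
biased-prior models add read/store pairs for their extra parameters
(2n + 1, 2n + 3).  The constant reflexive cost defaults to 0 since it
shifts every model equally.

## Problem sizes

The shipped protocols use the study's own sizes: 42-trial test blocks
(60 for control), 20 pilot subjects, 100 datasets per model and block for
identifiability and calibration, 1000 bootstrap resamples.  The
qualitative bias-variance analyses in the test suite run on a 60-subject
preset cohort over the two asymmetric blocks, large enough for stable
group medians with three strategy groups.

## Known limitations

* Exact nesting limits identifiability at the submodel boundary (set-ρ
  inside both the free-ρ and biased-prior models; rare-ball inside the
  variable threshold model); supports and priors are chosen so these
  overlaps have small prior mass, but draws near the boundary remain
  ambiguous in principle.
* The informative prior depends on the pilot cohort's composition; the
  shipped preset is a stand-in for the unpublished pilot fits.
* The rate-distortion bound relies on a local constrained optimizer with
  multistart; the monotonicity and endpoint checks guard against gross
  failures but do not certify global optimality at interior budgets.
* Bias and variance estimates from 42-trial blocks are noisy; group-level
  conclusions in the tests use medians across tens of subjects.
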