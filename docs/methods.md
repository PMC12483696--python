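# Methods

## Model

Let α = (α_1, …, α_K) be an examinee's attribute pattern, with attribute k
taking ordered levels 0, …, M_k − 1 (M_k ≥ 2, possibly unequal across
attributes). The latent-class space has C = ∏ M_k classes. The Q-matrix
entry q_jk ∈ {0, …, M_k − 1} gives the level of attribute k that item j
requires (0 = not required; every item must require at least one
attribute). Classes agreeing on item j's required attributes are
indistinguishable by that item and form a latent group; an item with
required attributes R_j has ∏_{k∈R_j} M_k groups, regardless of the
required levels themselves.

Each item's response function is linear on a link scale:

    f(P_j(α*)) = D_j(α*) · δ_j,      f ∈ {identity, logit, log}

with design row D_j(α*) built from cumulative step indicators I(α_k ≥ m).
**Coding choice.** Main effects use cumulative steps rather than level
dummies, so δ_jkm is the increment for reaching level m from m − 1. The two
codings span the same saturated space; cumulative coding makes each
single-attribute block a lower-triangular matrix of ones, so the saturated
design (one column per attribute-subset × step-level combination) is a
Kronecker product of invertible blocks and hence square and invertible,
and it gives the additive models their natural "each step adds its own
effect" reading. Column order is intercept, main effects
(attribute-major, level-minor), then interactions by increasing order.

Reduced models constrain the column set (see README table). The
`pgdina` kind first collapses each required attribute to the dichotomy
I(α_k ≥ q_jk) — the specific-attribute-level-mastery assumption — and
applies the dichotomous G-DINA design to the collapsed indicators, so
groups with equal collapsed vectors share a probability. An optional
`equal_steps` constraint merges an attribute's step columns into a single
linear-in-level column (additive kinds only).

Probabilities implied by identity- or log-link parameters can leave
[0, 1]; they are *checked* against an absolute tolerance of 1e−8 and
rejected, never silently clipped. Estimation respects the bounds through
linear constraints instead.

## Estimation

Marginal maximum likelihood with EM over the latent-class posterior.
The structural model is a saturated multinomial π over classes (estimated
by the posterior mean each iteration); `fix_pi_uniform` pins it at uniform
for replication runs where the generating distribution is known uniform.

- **E-step.** Class posteriors via log-sum-exp; expected group counts
  N_jl (examinees) and R_jl (correct) aggregate posterior mass through
  each item's class-to-group map.
- **M-step, saturated identity.** Closed form P̂_jl = R_jl / N_jl. Groups
  with N_jl < 1e−3 keep their previous value. With monotonicity enabled,
  a violating item is replaced by the weighted isotonic fit of R/N (weights
  N) on the group lattice, computed by cyclic per-attribute PAVA sweeps —
  exact on chains, and on the full partial order a fast monotone
  approximation guarded as below.
- **M-step, reduced/link models.** SLSQP (or L-BFGS-B when unconstrained)
  maximizes the weighted Bernoulli likelihood in δ. All constraints are
  linear in δ: identity-link probability bounds, the log-link upper bound
  on the linear predictor, and monotonicity on adjacent group pairs
  (logit/log inverse links are increasing, so monotonicity transfers to
  the linear predictor).
- **Generalized-EM guard.** An item update is accepted only if it does not
  decrease that item's weighted complete-data likelihood; otherwise the
  previous value is kept. This preserves the EM ascent property even when
  an inner solver terminates early, and the test suite asserts a
  non-decreasing marginal log-likelihood on every fit.
- **Initialization.** Group probabilities start on a linear grid from 0.2
  to 0.8 along each item's monotone group order, perturbed by seeded
  uniform noise of ±0.05 — a flat start is a symmetric stationary point of
  EM. π starts uniform. Fits are deterministic given the seed.
- **Convergence.** Max absolute change in any group probability < 1e−4
  *and* relative log-likelihood change < 1e−7, capped at 2000 iterations;
  non-convergence is flagged on the result, not raised.
- **Numerics.** Probabilities are floored to [1e−10, 1 − 1e−10] inside
  likelihoods only; reported estimates are unfloored, so boundary groups
  can legitimately be 0 or 1.

Monotonicity enforcement defaults to ON (the simulation studies impose
it); real-data analyses that prefer the unconstrained saturated MLE can
switch it off per fit.

**Standard errors** use the item-block empirical cross-product of
per-examinee incomplete-data scores (posterior-expected complete-data
scores). Parameter blocks with singular information — e.g. a saturated
parameter behind an empty group — are flagged unavailable rather than
pseudo-inverted. Cross-item information is ignored by construction
(item-block approximation).

**Classification.** MAP takes the argmax posterior class, ties broken
toward the lowest pattern index for determinism; EAP reports the argmax
of each attribute's marginal posterior over levels. MAP is the default
for PCA/PCV evaluation.

**Fit statistics.** deviance = −2·loglik; the parameter count is the sum
of item parameters plus C − 1 structural proportions. Including the
structural count is a convention choice: it shifts AIC/BIC by a constant
shared across measurement models on the same attribute space, so model
orderings within a fixed structure are unaffected.

## Simulation design

The generator reproduces a uniform-attribute replication study: attribute
patterns i.i.d. uniform over all classes; binary responses Bernoulli in
the class's group probability; K ∈ {3, 5} three-level attributes;
J ∈ {26, 52} with the 52-item form tiling the 26-item Q-matrix; N ∈
{1000, 2000}; item quality high/moderate/low with intercepts g = .05, .10,
.15, mean main effects .16, .15, .13, and mean interactions .10, .08, .07.
Slip is set equal to guessing (symmetric quality), so the top group's
probability is 1 − s = 1 − g.

**Per-parameter generating values.** Only class means are specified for
the effect sizes, so the generator sets every effect equal to its class
mean and rescales all non-intercept effects by one common factor so the
all-mastery group's probability equals exactly 1 − s. This makes item
quality exactly controlled, all effects non-negative (hence monotone
probabilities in [g, 1 − s]), and the generating parameters deterministic
per condition — replications differ only in patterns and responses. Real
item banks would show effect heterogeneity across items that this scheme
deliberately omits.

**Q-matrix.** The `balanced` template places, for every attribute and
level m ≥ 1, two single-attribute items requiring exactly that level
(so every level is identified by at least two pure items), then fills the
test with two-attribute items cycling through level combinations and a
pair of three-attribute items. A published or bespoke matrix can be
supplied as CSV instead.

**Seeding.** One root seed per design; per-replication generators derive
from `SeedSequence([root, rep])`, and study-level fits derive child seeds
the same way, so entire studies are bit-reproducible.

What passing simulation tests show — and what they do not: the generator
emulates uniform, independent attribute patterns, exactly calibrated
monotone items, and complete binary data. Real assessments have correlated
attributes, heterogeneous item parameters, possible Q-matrix
misspecification, and missingness, none of which these conditions probe.

## Evaluation metrics

- **Bias / RMSE** of estimated group probabilities across replications.
  Three averaging orders are provided: `group_first` (per-group
  across-replication RMSE, averaged over groups then items — the default
  summary), `rep_first` (per-replication RMS over groups, averaged over
  replications), and `mean_estimate` (RMS over groups of the error of the
  replication-*mean* estimate — the measure a replication-averaged
  recovery summary reports; it tends to the RMS bias as replications
  accumulate, which is why well-calibrated studies report values near
  zero on it).
- **PCA / PCV** in percent; PCV ≤ min_k PCA_k always, since a correct
  vector requires every attribute correct.
- **RMSD** between two models' group-probability profiles on an item,
  weighted by the reference model's posterior group mass
  w_jl = Σ_i Σ_{c∈l} posterior_ic / N; symmetric, non-negative, zero iff
  the weighted profiles coincide.

`run_study` executes a condition grid × fitted-model list, records per-
replication classification rows and per-condition recovery summaries, and
logs (rather than raises) per-replication fit failures.

## Problem sizes used in the shipped checks

The replication suite runs the four high-quality three-attribute
conditions at 25 replications each; directional misspecification checks
(under-fitting the additive or SALM models on saturated-truth data lowers
PCV; over-fitting the saturated model on reduced-truth data does not) use
3 replications of one condition; the grid-search oracle uses two
dichotomous-attribute items at N = 200 with a 0.05 parameter grid. These
sizes were chosen so the whole suite exercises every claim at desk scale.

## Known limitations

- Dichotomous responses only; polytomous *responses* are a different
  model family.
- No missing-data handling: incomplete response files are rejected.
- Q-matrix checking is a coverage heuristic (every attribute level should
  be required by ≥ 2 items), not an identifiability proof.
- Saturated fits on small samples leave sparse groups: estimates for such
  groups are frozen at their last value and their standard errors flagged
  unavailable; whole-vector classification deteriorates when C is large
  relative to N.
- The item-block cross-product SEs ignore cross-item and structural
  information and are approximate in small samples.
- Higher-order or correlated attribute distributions are not implemented;
  the structural model is a saturated multinomial.
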