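# Methods

## Scope and data model

All ages are Ma before present (present = 0); trees are rooted, binary and
ultrametric, with branch lengths in Myr.  Branching times (internal-node
ages, crown age first) are the sufficient statistics for every likelihood
here: the models are lineage-homogeneous, so topology beyond the node ages
carries no information.  Trees within a relative tolerance of 1e-6 × crown
age of ultrametricity are snapped exactly by averaging tip depths (newick
round-trips otherwise accumulate float noise); anything worse is rejected
with the offending tip pair named.

## Reconstructed-tree likelihood

We use the coalescent-point-process likelihood for a reconstructed tree
under time-varying birth–death rates with Bernoulli(ρ) tip sampling,
conditioned on the crown age and on both crown lineages surviving to the
sample.  With E(t) the probability that a lineage at age t leaves no
sampled descendant and q(t) = (1−E)² e^{−R}/ρ, R = ∫₀ᵗ(λ−μ):

L = q(x₁)²/(1−E(x₁))² · ∏_{i≥2} λ(x_i) q(x_i).

Three evaluation routes are implemented and continuously cross-checked:

* **Constant rates** — the closed form, with the λ→μ removable singularity
  switched to its analytic limit below |λ−μ| < 1e-9, and the denominator
  rewritten so that no exponential overflows for strongly subcritical
  parameters.
* **Smooth time-varying rates** — fixed-fine-grid RK4 integration of
  Y = log(1−E) (the logistic form Y′ = (λ−μ) − λeʸ is stable even when
  extinction dominates and Y → −10⁴; integrating E itself and clamping near
  1 silently corrupts q, which we learned the hard way).  The grid is the
  union of a 0.05-Myr mesh and the branching times, so node ages are hit
  exactly; around any pulse covariate the mesh is refined to sd/50 within
  ±6 sd of the peak, because exp(α·φ) varies on a scale ≪ sd once α ≳ 5.
  Agreement with an independent LSODA solve at rtol 1e-10 is ~1e-8 in logL,
  and halving the step changes logL by < 1e-4 (the suite asserts both).
* **Piecewise-constant rates with events** — analytic segment-by-segment
  propagation of (log(1−E), log q); a mass-extinction event at t_e with
  survival s maps 1−E ↦ s(1−E) and q ↦ s·q (instantaneous Bernoulli
  thinning of lineages, not a rate spike).  This route is exact, broadcasts
  over parameter arrays, and doubles as the quadrature engine for marginal
  likelihoods.

Rates above 10³ per lineage per Myr are rejected as outside the admissible
domain; they arise only as optimizer excursions and would otherwise cost
integration accuracy for no biological content.

## Fitting and model comparison

Maximum likelihood uses Nelder–Mead with seeded multi-starts (default 10;
restart 0 at the supplied template, later restarts perturbed on the
optimizer scale).  Base rates are optimized as log-rates, event survivals
on the logit scale, sensitivities free — except that in the pulse scan the
pulse sensitivity is sign-constrained (α ≥ 0 for an extinction pulse,
α ≤ 0 for a speciation drop).  The constraint is part of the hypothesis:
the scan asks whether a *mass extinction* (or a speciation crash) at age c
beats no perturbation.  Unconstrained, the optimizer discovers saturated
"extinction holiday" solutions (α → −10⁵ and beyond) that are
unidentifiable beyond their saturation point and answer a different
question.

AICc uses n = number of tips.  The scan fits the null (constant λ, μ; k=2)
first with a full multi-start budget, then warm-starts every covariate and
time-varying model from the null MLE with 3 restarts and a capped
function-evaluation budget (fatol 1e-6 — two orders below any AICc
difference that could change a support class).  A failed fit is recorded
with infinite AICc and the scan continues.

The default candidate grid is integer ages strictly inside (0, crown); for
the Bayesian profile, 1.25-Myr steps.  The null is parameterized with α
fixed at zero (k = 2) rather than as an unidentifiable k = 3 model.

## Bayesian event profile

For each candidate age the marginal likelihood of the single-event episodic
model is integrated over (λ, μ, s) by prior-CDF-transformed Gauss–Legendre
tensor quadrature (32 nodes per dimension; the transform handles the
truncated-Normal rate priors and the Beta survival prior uniformly), using
the exact episodic likelihood broadcast over the full tensor grid.  Support
is reported as 2 ln BF against the no-event marginal.  Rate hyperpriors
default to Normal(MLE, 0.5·MLE) truncated at zero, centred on the input
tree's constant-rate fit — a documented stand-in for priors elicited from a
separate rate analysis, recorded in every output.  An optional refinement
check recomputes the profile at double the node count and flags ages moving
by more than 0.1% (floored at 0.05 on the 2 ln BF scale).

Survival priors are Beta distributions least-squares-fitted to a stated
mean and 95% interval (e.g. mean 0.05, CI 0.01–0.10); the fit must
reproduce the mean within 0.01 and the quantiles within 0.03 or it is
rejected.

## Synthetic data

`simulate_tree` runs a forward Gillespie birth–death from two crown
lineages (default crown 50 Ma), applies each event as an independent
Bernoulli(s) kill on the lineages alive at the event age (before any
same-instant speciation), prunes extinct lineages, samples extant tips by
Bernoulli(ρ = 0.74), and rejection-resamples until the sampled tip count
lies in [60, 130] with at least one sampled descendant on each side of the
root — the same conditioning the likelihood uses, which removes a known
recovery bias.  All randomness flows from one seed through a counter-based
Philox generator.

Study conditions for the scan experiments: the event regime uses λ = 0.25,
μ = 0.11 with a 95%-kill event at 34 Ma, chosen so that a crown-50 tree
that survives the bottleneck lands near 90 sampled tips (the empirical tree
has 89); the no-event regime uses λ = 0.11, μ = 0.028 (net diversification
0.082, close to the ~0.085 the best-fitting pulse model implies) to hit the
same window.  The 200-tip parameter-recovery trees use λ = 0.25, μ = 0.19
with crown age 77 Ma (2e^{rT} ≈ 200).

The temperature generator produces a warm plateau with a sigmoid drop
(default 8 units wide 0.12 Myr, i.e. a maximum cooling rate of ~17 per Myr
at the 34 Ma midpoint) plus Gaussian noise; its smoother is a penalized
cubic B-spline (P-spline) with the penalty chosen by generalized
cross-validation, the knot count capped at the number of unique ages minus
one.  What the generator does **not** emulate: rate variation across
lineages, diversity dependence, non-contemporaneous (fossil) tips,
autocorrelated measurement noise in the covariate, and dating error in the
input tree.  Passing tests therefore show the machinery is correct under
the stated model, not that the model describes any particular empirical
system.

## What the scans can and cannot recover

Specificity is good: on no-event trees the null stays within 4 AICc units
of every competitor in the large majority of replicates, and the
Bayes-factor profile rarely crosses the moderate-support line.

Event-age recovery is *systematically biased young*.  On reconstructed
trees the information about a bottleneck is the gap between the event and
the onset of the surviving lineages' radiation; the fitted pulse (and the
ML event age of the exact episodic model, which we use as an independent
check) tracks the oldest post-bottleneck branching time, which lags the
true event by roughly the reciprocal of the reconstructed branching rate —
5–10 Myr under the study conditions (median 7 Myr in our replicates).  The
weight-profile mode falls within ±3 Myr of the true 34 Ma event in only
~28% of event trees (and the Bayes-factor peak in ~23%), while falling
at-or-below the event almost always.  This is a property of the
estimator on this data type, not of the implementation: point estimates on
the empirical lemur tree behave the same way (pulse profile peaking at 33,
episodic-shift and Bayesian analyses at ~31, for a hypothesized 34 Ma
trigger).  Users should read a profile peak as "the radiation began here;
the extinction was at or before this age".

## Backbone-and-patch assembly

Dated clades from a divergence-date table are nested into a topology; graft
patches (topology-only newick fragments) resolve local structure or add
taxa; every node with a tabulated age keeps it exactly, and an undated node
heading a chain of k undated nodes above a dated age b splits the span from
its dated ancestor a into equal segments, age = a − (a−b)/(k+1) applied
recursively (a 24 → 0 Ma branch receiving two nested undated splits gets
nodes at 16 and 8 Ma).  Conflicting ages for one clade, age inversions, and
unresolvable polytomies are hard errors naming both sources.  When a graft
could attach on either side of a dated node it attaches tipward, preserving
backbone ages.

## Fossil-table conventions

Flags are tri-state (yes/no/unknown); unknowns are excluded per test with
an explicit count, except where the published tables' own reading — "no
positive evidence of colonization" counts as a non-colonizer — is requested
explicitly via `unknown_as`.  The two-sided Fisher test uses the
point-probability method (sum of hypergeometric probabilities ≤ the
observed table's, relative tolerance 1e-7) in exact integer arithmetic;
two-sided Fisher conventions differ across software, and this is the one
that matches the standard implementations on every 2×2 table with total
≤ 40 (asserted in the suite).  The missing-colonizer projection rounds
half-to-even (its canonical case, 50·11/25 = 22, is exact).  The
constant-hazard survival model assumes uniform clade arrivals over
[66, 0] Ma and solves
(e^{−m·34} − e^{−m·66})/(1 − e^{−m·34}) = pre/post for the hazard m; the
calibration target is exposed because the choice is genuinely open, and the
model is reported as a sensitivity analysis over a hazard grid rather than
as a single number.

## The packaged tables

`malagasy_clades.csv` is a transcription of the published arrival lists,
one row per colonization (a Malagasy clade in the strict sense descends
from a single arrival; lineages recorded as colonizing twice appear as two
rows).  `african_families_synthetic.csv` is, as the name says, partly a
synthetic stand-in: the published material prints this table's *margins*
(75 families: 50 extinct of which 11 crossed the E-O boundary; 25 extant of
which 11 colonized early, with names and dispersal codings for those 11)
but not the full table, so the remaining rows carry placeholder names and
unknown codings.  Every computation shipped here depends only on the
printed margins.
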