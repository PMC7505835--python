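# Methods

## Model and estimands

Each analysis unit is a pair of species-by-plot matrices from one forest
affected by one natural disturbance (fire, windstorm or insect outbreak):
T₁ reference plots in the unlogged, disturbed portion and T₂ plots in the
salvage-logged portion, surveyed with the same effort.  Counts are reduced
to incidence frequencies Qᵢ ∈ {1, …, T} (number of plots occupied); any
positive count is an occurrence, and fractional counts are rejected rather
than thresholded, so corrupted inputs fail loudly.

The within-habitat estimated species-area relationship is the sample-based
rarefaction/extrapolation curve for incidence data.  The probability that a
species with frequency Qᵢ is missed by t of T plots drawn without
replacement is the hypergeometric term

m(t; T, Qᵢ) = C(T−Qᵢ, t)/C(T, t),

evaluated for real t with log-gamma functions:
exp[lnΓ(T−Qᵢ+1) − lnΓ(T−Qᵢ−t+1) − lnΓ(T+1) + lnΓ(T−t+1)].  This form is
used wherever its gamma arguments are positive, i.e. for t < T−Qᵢ+1; it
decays continuously to zero at t = T−Qᵢ+1 (a gamma pole) and is defined as
zero beyond, which reproduces C(T−Qᵢ, t) = 0 at every integer t > T−Qᵢ
while keeping the curve continuous and monotone in between.  The
alternative — forcing zero already for all real t > T−Qᵢ — would make the
detection curve of a frequency-1 species non-linear near full retention and
break the closed-form identity u(p) = p used to validate the benchmark
inversion, so it was rejected.  Expected richness at t ≤ T is
Σᵢ [1 − m(t; T, Qᵢ)].  Beyond the reference sample the curve continues with
the Chao2 estimate of undetected richness Q̂₀ = ((T−1)/T)·Q₁²/(2Q₂) (the
bias-corrected ((T−1)/T)·Q₁(Q₁−1)/2 when Q₂ = 0, avoiding division by zero
while preserving the Q₁ signal):

S(T + t*) = S_obs + Q̂₀·[1 − (1 − Q₁/(Q₁ + T·Q̂₀))^t*].

Transforming a proportion of the area by logging is modelled as *plot
replacement*: t₂ of the T₁ unlogged plots are replaced by t₂ plots drawn
from the logged reference sample, so total effort is fixed at T₁ and the
retention proportion is p = t₁/T₁.  Species classes (unique-to-unlogged,
unique-to-logged, shared) are fixed at the *reference-sample* level:
"unique to unlogged" means detected in the full T₁ unlogged plots and never
in the T₂ logged plots.  With that convention the unique-to-unlogged curve
at p = 1 equals the observed count of unique species, which is the quantity
reported per taxon in field syntheses.  An alternative subsample-level
classification (a shared species undetected in the drawn logged plots
counts as unique there) is available behind `unique_definition="subsample"`;
both definitions give identical totals, and the reference-level default is
used throughout.

Mixture components for t₂ ≤ T₂ are exact expectations over independent
subsampling of the two reference samples (the shared term
1 − m_U(t₁)·m_L(t₂) uses the independence of the two draws).  When a design
is unbalanced with T₁ − t₁ > T₂, the logged side is evaluated at its full
sample and the Chao2-driven extrapolation increment of the logged curve is
attributed entirely to the unique-to-logged component (policy switch
`extrapolation_policy`).  That attribution is a modelling choice — species
in the unlogged classes are already accounted for by their unlogged-sample
detection terms, and no finer allocation is identifiable from incidence
frequencies alone.  The headline benchmarks depend only on the
unique-to-unlogged curve, which never extrapolates, so they are insensitive
to this policy.

## Benchmarks

The normalized unique curve is u(p) = U(p·T₁)/U(T₁) with
U(t₁) = Σ_{unique} [1 − m_U(t₁)].  Reported per dataset:

* p\*(q): the smallest p with u(p) ≥ q, default q = 0.90, found by Brent
  root-finding on the continuous curve (grid-free; residual |u(p\*) − q|
  bounded by 10⁻⁶);
* u(0.5): unique richness maintained at 50 % retention.

Datasets with no unique-to-unlogged species get status
`undefined_no_unique_species` and are excluded from summaries with a logged
count; the analysis cannot define a retention demand for them.  Group
summaries are unweighted means with sample SD (n−1) across species
matrices; matrices, not studies, are the unit of replication (study-level
weighting is a config option, off by default).  Summaries by year bin on
the rounded integer year since disturbance.

## Beta regression in time since disturbance

Benchmarks are fractions, so their trend in years since disturbance is
modelled as Beta(μφ, (1−μ)φ) with logit(μ) = Xβ and a single precision φ.
Responses touching {0, 1} are first squeezed with (y(n−1)+0.5)/n.  The
years term is a B-spline basis (degree min(3, df), interior knots at
quantiles, first column dropped against the intercept; df = 1 is exactly
the linear term).  df is selected from {1, …, 4} by AIC with the parsimony
rule — the smallest df within 2 AIC units of the minimum.  Plain min-AIC
was measured to pick spurious curvature on roughly a third of
linear-truth simulations; the parsimony rule restores a high probability of
selecting the linear term when the truth is linear and keeps the
post-selection likelihood-ratio test near its nominal level.  The smooth's
p-value is the LRT of the selected model against the model without the
years term, on the selected df; the reported effective df is the selected
df.  Pseudo-r² is the squared correlation of logit-fitted means with
logit-squeezed responses, and is labelled as such (it is not the adjusted
r² of a penalized-spline fit).

Fitting is maximum likelihood over (β, ln φ): L-BFGS-B with the analytic
gradient, started from a logit-scale least-squares fit with a
method-of-moments precision, then polished by safeguarded Newton steps
(finite-difference Hessian of the analytic gradient) so the optimum is
independent of equivalent reparameterizations to < 10⁻⁸ in fitted values.
Standard errors come from the observed information.  Categorical covariates
are dummy-coded with the first level dropped; a rank-deficient design
raises an error naming the aliased columns rather than silently dropping
them.  In particular, the saproxylic flag is a property of the taxon group
and study identity is nested within disturbance type, so the default
covariate set is disturbance type + taxon group; adding study identity is
possible via config when a collection's studies span disturbance types.
Study identity enters as fixed-effect categories, not random effects.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated.  A community has three true classes — unique-to-unlogged,
unique-to-logged, shared — and each species carries a detection probability
per habitat (zero in the other habitat for unique classes), drawn
logit-normal: p = logistic(Normal(logit(0.15), 1.0)), median 0.15.  Each
species × plot cell is an independent Bernoulli draw.  The low median makes
singletons and duplicates (Q₁, Q₂ > 0) common, exercising the Chao2
branches, and the independence makes the truth analytic: the expected
unique-to-unlogged richness of t₁ plots is Σᵢ [1 − (1−pᵢ)^t₁], so the
generating model's own retention benchmark is available in closed form for
parameter-recovery checks.

The packaged reference collection holds 24 datasets: 3 disturbance types ×
(saproxylic / non-saproxylic) × 4 taxon labels, with per-dataset plot
counts drawn from 8–30 (unlogged) and 5–25 (logged), class sizes 12–40 /
6–25 / 20–80, and integer years since disturbance 1–25.  Saproxylic
communities use a lower detection median (0.08 vs 0.18): rarer species make
their unique curves closer to linear and their retention demands higher,
mirroring how deadwood-dependent taxa behave in field data.  All seeds are
fixed, so the collection and every pipeline output are byte-reproducible.

What the generator does *not* emulate: spatial autocorrelation among plots,
abundance structure beyond incidence, detection heterogeneity across plots,
and taxon-specific sampling protocols.  Passing tests therefore demonstrate
the estimator machinery is correct under independent Bernoulli detection —
not that field designs meet those assumptions.

Two oracles verify the analytic mixture: exhaustive enumeration of all
C(T₁,t₁)·C(T₂,t₂) subset pairs (budget 10⁶ pairs) and a Monte-Carlo
subsampler with standard errors.  The analytic components match enumeration
to < 10⁻¹⁰ and sit within 3 SE of 2000-replicate Monte-Carlo means at
≥ 99 % of checked points.

## Numerical choices

* Miss probabilities are clamped into [0, 1] (round-off tolerance 10⁻¹²);
  the rarefaction and extrapolation branches join at t = T to < 10⁻¹².
* Benchmark inversion uses Brent's method on [0, 1] with xtol ≤ 10⁻⁹, so
  the residual bound 10⁻⁶ on the fraction scale holds with margin; the
  mixture-curve grid (default 201 points) is for export only and never
  feeds the inversion.
* Degenerate inputs: empty species lists are valid matrices (flagged);
  species recorded at zero abundance everywhere are dropped at the
  incidence reduction; metadata failing sanity bounds (unknown disturbance
  type, years > 100) excludes the dataset with a logged reason.
* Problem sizes used in the validation suite — 50 enumeration fixtures with
  T ≤ 6, 10 Monte-Carlo datasets at T₁ = T₂ = 30 with 2000 replicates, 200
  recovery datasets at T₁ = T₂ = 50 with 100 species, and 100 + 100
  regression replicates at n = 200, φ = 20 — were chosen so the whole suite
  completes in well under a minute while leaving the stochastic checks
  comfortable margins.

## Limitations

* Point estimates only: no bootstrap intervals on curves or benchmarks, and
  no coverage-based (sample-completeness) standardization; richness is the
  only diversity order handled (Hill q = 0).
* The extrapolated-mixture allocation among components beyond T₂ is a
  stated convention, not an identified quantity.
* The beta regression substitutes AIC-selected fixed-df splines for
  penalized smooths; effective df is an integer and will not reproduce
  penalized estimates such as 1.001, only their qualitative conclusion.
* Retention proportion is a proxy for area: plots are assumed
  interchangeable and of similar size, with no spatial planning of which
  patches to retain.
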