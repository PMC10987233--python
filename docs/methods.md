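# Methods

`pondvarpart` estimates how much of the structure of a metacommunity —
a set of pond communities linked by dispersal — is attributable to the
environment (E), to space (S) and, when sampling is repeated over a
hydroperiod, to time (T).  It does so with a nonlinear variation
partitioning built from penalized-regression-spline GAMs fitted to latent
ordination axes, in two modes: a *spatial approach* that analyses each
sampling occasion as an independent snapshot and partitions into
(E | S), (S | E) and (E ∩ S), and a *spatio-temporal approach* that pools
all occasions into one model with a temporal predictor and partitions into
the seven unique and shared fractions of {E, S, T}.

## The response: latent ordination axes

Raw presence–absence matrices mix shared community structure with
species-specific noise.  The multivariate response used for partitioning
is therefore the site-score matrix of a binomial generalized linear latent
variable model with no covariates,

    P(y_ij = 1) = logit⁻¹(β0_j + z_iᵀ γ_j),   z_i ~ N(0, I_d),

fitted by a variational Gaussian approximation: q(z_i) = N(m_i, diag s_i²),
with the intractable Bernoulli-logit expectation evaluated by 12-point
Gauss–Hermite quadrature and the evidence lower bound maximized by L-BFGS
with analytic gradients.  Identifiability uses the standard constraint
γ_jk = 0 for k > j with positive diagonal (imposed post hoc by column sign
flips, which the likelihood cannot distinguish).  Three starts are used by
default — one informed by an SVD of the centred data, the rest random —
and the best bound wins.  The number of axes d is chosen by the lowest
AIC over d = 1..d_max (default 5), with the ELBO standing in for the
log-likelihood and p = m + m·d − d(d−1)/2 parameters (species intercepts
plus constrained loadings; variational parameters are not counted).
Species that are present everywhere or nowhere carry no information about
the axes and are dropped with a warning.

Downstream results are invariant to the rotation/reflection indeterminacy
of the scores because every axis is modelled separately and the component
R² is an average over axes.

## The predictors

* **Environment.**  Raw variables are transformed per their tag —
  arcsin√x for proportions, log(x + c) for right-skewed positive variables
  (c = half the minimum positive value when zeros occur) — and untagged
  tables are auto-tagged: values all in [0, 1] → arcsine-square-root,
  strictly positive with sample skewness > 1 → log, otherwise none.
  Transformed variables are reduced by PCA on the correlation matrix
  (variables mix units, so the covariance matrix would let high-variance
  units dominate), and the first three PC score columns are the
  environmental predictors everywhere.  The sign convention makes each
  loading vector's largest-magnitude entry positive.  The spatial approach
  recomputes the PCA per occasion on that occasion's samples; the pooled
  approach computes one PCA on all samples.
* **Space.**  Longitude/latitude are projected to planar km by an
  equirectangular projection about the site centroid (exact to well under
  1% at the ~100 km extents the package targets) and entered as a single
  bivariate thin-plate-style smooth, which models interactions between the
  coordinates that two additive 1-D smooths would miss.
* **Time.**  Days since each pond's first sampling, entered as a 1-D
  smooth.  With only three occasions the basis collapses to three knots,
  which is the resolution the data support.

## The GAM engine

Each latent axis is regressed on smooth terms by penalized least squares.
The 1-D basis is a natural cubic spline through k = 9 knots at covariate
quantiles, parameterized by its knot values, with the exact integrated
squared second derivative as penalty (Green–Silverman form D'B⁻¹D); the
2-D basis uses the radial kernel r²·log r on k space-filling knots (greedy
maximin subset of sites) with null space {1, x, y}.  Sum-to-zero centring
constraints are absorbed, penalties are normalized to unit spectral norm
so one λ grid serves all terms, and per-term λ minimizes the GCV score
n·RSS/(n − edf)² by cyclic coordinate descent over a log-spaced grid
(step 1.0 from 10⁻⁶ to 10⁷, then a ±0.6 refinement at step 0.15), iterated
until fitted values change by < 1e-8.  The grid is scanned from smooth to
wiggly so that flat GCV curves resolve to the smoothest fit.  λ = ∞ is
honoured exactly as the null-space (linear) limit rather than by a huge
finite value, which would drown the data in round-off.

Model quality is the adjusted R²,
r²adj = 1 − (RSS/(n − edf)) / (TSS/(n − 1)), with edf the trace of the hat
matrix.  Term p-values are Wald-type: the penalized coefficient block
against its Bayesian posterior covariance (X'X + S)⁻¹σ² at rank
⌈edf⌉, referred to an F distribution.  The frequentist sandwich covariance
was measurably anti-conservative here (null rejection ~12% at nominal 5%
versus ~7.5% for the Bayesian form); some residual liberality is
unavoidable after data-driven smoothing selection and is one reason the
forward selection carries a second stopping rule.

Terms whose centred design blocks are numerically identical (a predictor
shared between components) are deduplicated before fitting, and a
pseudoinverse fallback handles any remaining collinearity — together these
make the redundancy identities of the partition (e.g. pure T exactly zero
when T duplicates a spatial predictor) hold to machine precision.

### Forward selection with the double stopping criterion

Per component, a global model with all candidate smooths sets an adjusted-
R² ceiling.  Candidates are added greedily by largest adjusted R²;
selection stops when the incoming term's p-value is not below α = 0.05,
when the selected model reaches the global ceiling, or when the term cap
is reached (three environmental predictors in the per-period analysis,
where n ≈ 30).  If nothing survives but some candidate is significant
alone, that single most significant candidate is kept.  Ties in adjusted
R² break by candidate order, deterministically.  In the pipeline the
selection runs per latent axis and the union is taken, ranked by how many
axes kept each term; if environmental plus spatial selections exceed three
terms in the per-period analysis, the environmental selection is re-run
with a tightened cap.

## The partition

Per predictor subset M ⊆ {E, S, T} a GAM is fitted per axis and the
subset's R²(M) is the unweighted mean of adjusted R² across axes.  The
two-component fractions are pure_E = R²(ES) − R²(S),
pure_S = R²(ES) − R²(E), common = R²(E) + R²(S) − R²(ES); the
three-component case applies Möbius inversion to the seven union values,
with the triple overlap taken as the residual so the seven fractions sum
to R²(EST) exactly.  Adjusted-R² fractions can be negative; raw values are
always reported, and the relative view divides zero-truncated fractions by
their sum.  When nothing is explained (total ≤ 0) the relative view is
undefined and flagged rather than fabricated.

### Correcting the environmental fractions

A spatially (or spatio-temporally) structured environment inflates the
environmental fractions even for species that ignore the environment.
The correction builds Moran eigenvector bases — Gabriel-graph connectivity
over pond coordinates, doubly centred, eigendecomposed on the orthogonal
complement of the constant vector so the constant direction cannot leak
into near-zero eigenvectors — and generates surrogate environments by
Moran spectral randomization: the coefficients of each (centred) variable
in the orthonormal eigenbasis are sign-flipped at random, an orthogonal
remix that preserves each variable's mean, variance and Moran's I exactly,
and (because one sign vector is shared across variables per draw) their
cross-covariances too.  For pooled data the basis is the Kronecker product
of the spatial basis with a temporal basis from the chain graph over
occasions, which diagonalizes the combined spatio-temporal quadratic form.

For every fitted model containing E, the surrogate environments are
substituted (n_null = 199 draws by default) and the model is refitted with
its smoothing parameters held at their observed GCV-chosen values; the
spurious increment is the null mean of that model's R² minus the observed
R² of the same model without E, measured on an unbiased-risk adjusted-R²
scale (denominator n − edf* with edf* = 2·tr H − tr H'H, whose null
expectation is exactly zero for a fixed smoother).  Holding λ fixed and
using the unbiased scale is deliberate: re-running GCV inside the nulls
would charge the environment for the smoother's own adaptive-fitting
optimism rather than for spatial leakage (empirically ~0.08 of spurious
"correction" for a spatially unstructured environment, versus ~0.01–0.05
with the scheme used).  All fractions are then recomputed by
inclusion–exclusion from the corrected model R²s, so corrected fractions
sum to a corrected total and the removed environmental mass reappears in
the spatial/temporal fractions where it belongs.

## Auxiliary inference

* **PERMDISP.**  Environmental heterogeneity is compared between groups as
  the spread of samples around their group's multivariate centre:
  variables standardized, Euclidean distances to the group's geometric
  median (Weiszfeld iteration; a centroid option exists), one-way ANOVA F
  on the distances, and p = (#{F* ≥ F} + 1)/(n_perm + 1) over label
  permutations of the distance values.  The spatial median is the default
  because it is robust to the outlying ponds these surveys regularly
  contain.  Separate runs for all/climatic/limnological variable subsets
  (disjoint by construction) contrast regions when several are present,
  otherwise sampling occasions.
* **Exact paired Wilcoxon.**  The two approaches are compared per taxon:
  the spatial value of a fraction is its mean relative share over periods;
  the spatio-temporal value maps pure E ← E|(S+T), pure S ← S|(E+T),
  common ← (E∩S)|T and renormalizes over that E+S mass, i.e. excludes the
  temporal fractions.  With seven taxa the exact null is mandatory: zero
  differences are dropped, |differences| get midranks, V sums the positive
  ranks, and the two-sided p enumerates all 2ⁿ sign assignments (as a
  generating-function convolution over doubled midranks — identical to
  brute-force enumeration, feasible to n = 25), p = 2·min(P(V* ≤ V),
  P(V* ≥ V)) capped at 1.  Seven direction-consistent pairs give V ∈
  {0, 28} and p = 2/2⁷ ≈ 0.016, the resolution limit of the design.

## The synthetic generator

Ponds are placed uniformly in a 120 km square; environmental variables are
Gaussian random fields over pond locations (exponential covariance, range
30 km by default) plus independent noise, warped through
plain/lognormal/proportion shapes so the transform-tagging stage operates
on realistic marginals.  Climatic variables are constant over the
hydroperiod; limnological ones receive occasion shifts and occasion-level
noise.  Species occupancy follows
logit⁻¹(a_s + β_E·f_s(env) + β_S·u_s(x, y) + β_T·g_s(t)) with f_s linear
or Gaussian-unimodal on a species-specific environmental gradient, u_s a
residual spatial field, and g_s a half-sine over the hydroperiod (a
minimal succession signal); each component is standardized so the β's are
comparable effect sizes.  Defaults (30 ponds × 3 occasions at 0/150/250
days, 60 species, 4 climatic + 6 limnological variables) mirror the kind
of field design the pipeline targets.

What the generator does *not* emulate: species interactions, dispersal
kernels and mass effects, pond drying/refilling dynamics, clustered pond
configurations, and detection error.  Passing recovery tests therefore
demonstrate that the estimator attributes variation correctly when its
generating assumptions hold — not that field data meet those assumptions.

## Validation experiments (what the tests compute)

* Scenario recovery: occupancy driven by an unstructured environment, by a
  residual spatial field, or by a strongly spatialized environment
  (range 80 km) must place the dominant fraction in pure E, pure S and
  E ∩ S respectively, in ≥ 8/10 seeded replicates at the default design
  size.  The dominant effect uses β = 2 with the other effects at 0.
* Correction: with β_E = 0 and a strongly spatialized environment the
  corrected environmental mass must fall below the uncorrected mean, while
  the surrogates preserve variance and Moran's I to 1e-6.
* Latent recovery: d = 2 communities (90 samples × 60 species) must have
  AIC select d = 2 in ≥ 60% of replicates (candidates 1..3 in the
  harness, for runtime) with Procrustes correlation ≥ 0.8 to the true
  scores.
* Identities: 2- and 3-way fractions sum to the full-model adjusted R² to
  1e-10 across 1,000 random instances; the linear-limit partition equals
  classical (Ezekiel-adjusted OLS) variation partitioning to 1e-8.
* PERMDISP type-I error at α = 0.05 within [0.02, 0.09] over 200 null
  replicates.

`scripts/acceptance.py` reruns these experiments from scratch at fixed
problem sizes (200 identity instances, 10 replicates per recovery
experiment, 99 MSR nulls, 200 PERMDISP replicates, a 3-taxon end-to-end
run) and writes the numbers as JSON.

## Numerical choices and degenerate inputs

* GCV convergence: Δfitted < 1e-8, ≤ 10 backfit cycles; λ searches hitting
  a grid bound warn.
* Covariates with fewer distinct values than k reduce k (warning); two
  distinct values degrade to a linear column; constants are errors.
* Empty component selections give R² = 0 for that component and a flagged
  degenerate partition when all components are empty.
* A single sampling occasion makes every temporal fraction exactly zero
  and the pooled analysis degrades to two-component semantics.
* Fewer than 4 ponds: the MSR correction is unavailable and raw fractions
  are returned flagged.
* Seeds thread through everything (field draws, Bernoulli draws, optimizer
  starts, MSR draws, permutations); equal seeds give bit-identical output
  files.

## Known limitations

* Equality with any particular software's latent axes or smoothing is not
  claimed; recovery of simulated structure is the validation target.
* Wald-type p-values after GCV selection remain slightly liberal; the
  selection's global-R² stopping rule and term caps mitigate but do not
  remove this.
* The MSR correction assumes a balanced pond × occasion design for the
  Kronecker basis; unbalanced pooled data fall back to the spatial-only
  basis (flagged).
* Adjusted-R² fractions are noisy at n ≈ 30 with k = 9 smooths; per-period
  results should be read through the relative view and across taxa, as the
  pipeline reports them.
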