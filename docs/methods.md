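# Methods

`culturekin` estimates how much of the variance of a behavioral trait is
transmitted across generations genetically and how much socially
("culturally"), using an extended pedigree-based animal model fitted by
REML together with a simulator of the partial cross-fostering designs that
make the two components separable.

## Model

The trait of individual *i* is modeled as

    y_i = mu + (fixed covariates) + a_i + c_i + m_{dam(i)} + cb_{brood(i)}
          + envt_i + e_i

with variance partition

    sigma2_P = sigma2_A + sigma2_C + sigma2_M + sigma2_CB + sigma2_ENVT
               + sigma2_R.

The breeding values `a` have covariance `sigma2_A * A`, where `A` is the
additive genetic relationship matrix computed from the genealogy:
`A_ij = 2 * theta_ij`, with `theta_ij` the coefficient of coancestry (the
probability that random alleles drawn from *i* and *j* are identical by
descent) and `diag(A) = 1 + F` for inbreeding coefficients
`F_i = theta(sire_i, dam_i)`. The culturally transmitted values `c` have
covariance `sigma2_C * C`, where `C` is a cultural relationship matrix (see
below). Maternal, common-brood and environment effects are i.i.d. group
effects; `e` is i.i.d. residual noise. Narrow-sense heritability is
`h2 = sigma2_A / sigma2_P` and the cultural component of inclusive
heritability is `sigma2_C / sigma2_P`; the package reports the analogous
ratio for every fitted component, so the reported ratios always sum to one.

### The cultural relationship matrix

Three interchangeable forms are implemented:

1. **culture identity** — `C_ij = 1` iff *i* and *j* were reared in the same
   culture (block matrix over cultures);
2. **social contacts** — accumulated pairwise encounter weights,
   symmetrized, scaled by the largest entry and given a unit diagonal;
   per-relation "social inertia" weights (e.g. grandparent vs competitor
   encounters) multiply the raw weights and default to one — no weighting
   scheme is canonical, so they are user configuration;
3. **cultural coancestry** — the same tabular recursion used for `A`, run
   over *rearing* links (rearing sire/dam) instead of genetic ones.

Form 3 is a design choice rather than an established formula. It is chosen
because it makes the central confounding exact: when every offspring is
reared by its genetic parents, `C` equals `A` entrywise, and a model
containing both explains the data equally well along the whole line
`sigma2_A + sigma2_C = const`. Founders of the same culture are treated as
culturally unrelated so that form 3 stays non-redundant with form 1. The
0.5/0.5 split of cultural coancestry between two rearing parents mirrors
the genetic recursion; whether social learning should instead "saturate"
through one tutor is an open modeling question, and a different split would
require replacing the recursion, not the surrounding machinery.

### Relationship-matrix numerics

Pedigrees are validated (unique ids, no self-parentage, acyclic) and
ordered parent-first by Kahn's algorithm with ties broken by input order,
which makes matrix construction deterministic and independent of input row
order. Unknown parents are treated as unique, unrelated, non-inbred
founders (the standard tabular-method convention; missing tokens `0`,
empty, `NA`). All relationship matrices are symmetric PSD in exact
arithmetic; if a Cholesky fails from rounding, `1e-8 * I` is added once and
the event logged. The gene-by-culture interaction structure is the
elementwise (Hadamard) product `A∘C`, PSD by the Schur product theorem; it
is not rescaled, so `C = all-ones` leaves `A` unchanged.

## REML fitting

The restricted log-likelihood

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X'V^-1X| + y'Py ],
    V = sum_k sigma2_k K_k + sigma2_R I

is maximized directly. Internally the residual variance is profiled out:
with `V = sigma2_R (sum_k gamma_k K_k + I)` the optimum over `sigma2_R` is
closed-form, leaving a search over the log variance ratios `log gamma_k`
only (bounded in [-18, 12], the lower bound serving as the numerical
boundary of the nonnegative orthant). The search uses Nelder-Mead with 3
seeded random starts (log ratios uniform in [-2, 2]), stopping early when
two starts agree to 1e-6 relative tolerance; convergence tolerance is 1e-8
on the relative log-likelihood change, at most 500 iterations per ratio
dimension. Random starts matter scientifically here: on confounded data
(`A = C`) the restricted likelihood is exactly flat along the ridge, every
ridge point is a maximizer, and the reported estimate is whichever point
the best start reached — the across-replicate instability this produces
*is* the identifiability failure the diagnostics quantify, not an
optimizer defect to be hidden.

Standard errors come from the observed information (central-difference
Hessian of `l_R` on the variance scale, step `1e-4` relative), reported
only when the information matrix is invertible; they are unreliable when an
estimate sits on the boundary. AIC is `-2 l_R + 2 * (number of variance
parameters)`; fixed effects are not counted, and AIC comparison across
different fixed-effect structures is refused because restricted likelihoods
live on different contrast spaces. Dropping a single variance component is
tested with the boundary-corrected LRT whose null distribution is the
50:50 mixture of a point mass at zero and chi-square(1); the naive
chi-square(1) p-value is reported alongside. Fits are dense-linear-algebra
throughout and practical to a few thousand records.

## The simulator

The generator emulates the factorial cross-fostering protocol: monogamous
founder pairs in every culture x environment x family cell, a fixed brood
size per pair and generation (at least two, so within-brood contrasts
remain for the residual), and per-brood reciprocal exchanges:
`round(swap_fraction * brood_size)` offspring move to the same family slot
of the *next* culture (a cyclic exchange, so brood sizes are conserved for
any number of cultures) and `round(control_swap_fraction * brood_size)`
move to the next family within the same culture, mimicking the handling
without changing culture. Rounding is half-away-from-zero and at least one
natal offspring is always retained when `swap_fraction < 1`, so
unmanipulated siblings remain as controls. In multi-generation designs the
parents of generation g+1 are generation-g offspring of different families
within a cell (rotating family index), linking families across the
factorial. A hook adds a constant phenotypic shift to manipulated
offspring (default 0) for studying handling artifacts.

Phenotypes are drawn jointly: `a ~ MVN(0, sigma2_A A)` over the whole
pedigree via Cholesky, similarly for `c`, plus i.i.d. group effects and
residuals. This makes `cov(y)` exact by construction — sharp for
parameter-recovery tests — at the cost of not modeling the
transmission-plus-Mendelian-sampling mechanism explicitly; the two are
distributionally equivalent for a neutral, non-selected trait. Environment
is a fixed effect by default (`env_as_fixed=False` switches to an i.i.d.
random environment component with variance `sigma2_ENVT`). The maternal
effect follows the rearing dam by default — the dam that provides care —
with the genetic dam one switch away (`maternal="genetic"`).

What the generator does **not** emulate: extrapair paternity, brood
parasitism, adoption, pedigree errors, mortality and unbalanced broods
(the fitter tolerates unbalanced data, but death processes are not
simulated), horizontal or oblique social transmission within a generation,
selection, and non-Gaussian traits. Passing tests therefore demonstrate
correctness of the estimation machinery under the stated generative model,
not robustness to these real-data complications.

## Diagnostics

`power_analysis` simulates R replicate populations per design, fits the
full (A + C) and reduced (A-only) models, and reports per-component mean,
bias and RMSE, the LRT rejection rate at level alpha, the mean off-diagonal
Pearson correlation between A and C, and the across-replicate correlation
of the genetic and cultural estimates. `misattribution_experiment` fits the
genetic-only model to data whose inheritance is purely cultural, at the
design's swap fraction and at zero, to show the cultural variance being
absorbed into the genetic estimate when pedigrees overlap. Per-replicate
seeds are spawned from the master seed by a counter-based scheme
(`SeedSequence([seed, scenario, replicate])`), so single scenarios can be
re-run without shifting any other scenario's draws. Failed or non-converged
fits are excluded from moment summaries but counted in a `n_failed` column,
and a scenario whose fits all fail is flagged, never silently dropped.
When the off-diagonal entries of A or C are constant the overlap
correlation is undefined and flagged as such rather than returned as a
number.

## Problem sizes

Default analysis problem sizes were chosen to be desk-scale: the recovery
grid uses 992 phenotyped offspring (2 cultures x 2 environments x 62
families x brood 4) over 20 replicates, LRT calibration 304 offspring over
400 replicates, and the oracle cross-checks use pedigrees up to n = 200
with exact (bitwise) agreement required between the tabular matrix builder
and the pairwise coancestry recursion. The `scripts/acceptance.py` report
uses a 608-offspring variant of the recovery grid with 10 replicates and
150 calibration replicates.

## Known limitations

* On fully confounded data the reported (sigma2_A, sigma2_C) split is an
  arbitrary point on the likelihood ridge; only their sum is meaningful
  there. The overlap diagnostics exist precisely to detect this regime.
* Boundary estimates make the observed-information SEs and the naive LRT
  unreliable; the mixture-corrected p-value addresses the simplest
  (single-component) boundary case only.
* The diploid coancestry recursion is used as-is; selfing systems and
  separate-sex chromosomes are out of scope.
* Only the vertical component of cultural transmission is represented;
  horizontal/oblique learning requires a different covariance model.
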