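# Methods

## Scope and assumptions

`emuflux` performs *stationary* ¹³C-MFA: cells are assumed at metabolic
steady state (constant intracellular pools, so `S · v = 0`) and isotopic
steady state (labeling patterns no longer change in time).  Only carbon is
traced; isotopically nonstationary simulation, tandem-MS observables and
positional enrichments are out of scope.  Reversible reactions are
represented as two nonnegative directional fluxes; net and exchange values
are derived quantities in reporting.

## Null-space parameterization

The stoichiometric matrix is built over the *balanced* metabolites only.
A metabolite that appears on just one side of the network (pure source or
sink, e.g. uptake precursors and biomass drains) is classified unbalanced
automatically; explicit `# balanced:` / `# unbalanced:` directives in the
model file override this.

Free fluxes are the non-pivot columns of the reduced row echelon form
(rref) of the column-permuted matrix.  The block permutation
(reversible-forward, irreversible, user-preferred, basis & measured,
reversible-reverse) pushes the basis, measured and exchange fluxes to the
right so they become free whenever the network admits it; the package
raises a structured error if a basis/measured reaction cannot be made
free.  The numeric rref uses partial pivoting with a relative pivot
tolerance of 1e-10 — stoichiometric entries are small integers or halves,
so the scale separation between true pivots and round-off is many orders
of magnitude.  The kernel produced this way is cross-checked against an
SVD null space in the test suite.

Bounds: every directional flux lies in `[0, 15 × basis]` (basis default
1).  The cap also applies to reverse/exchange fluxes, which have no
natural upper limit; a finite box keeps the optimizer well-posed and the
cap is exposed as a parameter.  Measured reactions are bounded to
mean ± 3 SD intersected with the cap.  The initial feasible point solves a
linear program with uniform(−1, 1) objective coefficients from a seeded
generator, so "random interior point" is reproducible.

## EMU simulation

The decomposition walks backwards from the measured fragment EMUs, so
every EMU kept is an ancestor of a measurement (minimality).  Symmetric
molecules are expressed in the model file as a product written twice with
coefficient 0.5 and two atom maps; each variant yields its own elementary
EMU reaction carrying half the flux, rather than a post-hoc averaging
step.  Per size level the flux-weighted balance is solved by dense LU —
networks at this scale yield systems of at most a few dozen unknowns.
Before solving, any internal EMU with zero total inflow at the current
flux vector raises a dead-end error instead of a singular-matrix failure.

Fragment-forming reactions (type `S`) are outside the mass balance and
carry no flux variable; they are assigned unit flux.  For a fragment with
a single forming reaction the weight cancels exactly in the balance.
Their product occurrences are ignored for metabolites that participate in
the mass balance (e.g. CO₂ released during amino-acid synthesis), so the
pseudo-reactions cannot perturb network labeling — this is also what makes
simulated MIDs exactly invariant under global flux scaling.

An independent brute-force simulator iterates the complete isotopomer
balance (all `2^k` labeling states per metabolite, Jacobi fixed point to
1e-13) and marginalizes to mass groups.  It shares no code with the EMU
cascade and is used as the oracle in tests and in the reproduction script;
agreement is required to 1e-9.

## Natural-isotope correction

Measured fragments carry derivatization atoms whose heavy isotopes shift
the mass distribution.  The correction file lists, per fragment, natural
abundance vectors and atom counts of the non-traced atoms; their combined
mass-shift distribution is the count-fold self-convolution per element
convolved across elements.  Simulated backbone MIDs are *inflated* by this
vector (matching the direction raw measurements are reported in) and then
truncated to the number of measured mass isotopomers without
renormalization, so residuals compare like-for-like truncated vectors.
Backbone carbon natural abundance is handled in the substrate
specification (residual ¹³C fraction of unlabeled positions, default
0.0107), not in the correction file.

## Estimation

The objective is the variance-weighted SSR over measured MID entries.
Measured fluxes contribute no residual term; they act purely as bounded
parameters, so `n` counts MID entries only and `p` counts adjustable free
fluxes (the basis is frozen; the TCA fixture gives n = 18, p = 6).
Each of the default 10 starts draws the free fluxes uniformly within
bounds, resampling (up to 1000 draws) until all dependent fluxes are
nonnegative, with the LP point as fallback.  Optimization uses a bounded
trust-region least-squares solver (Levenberg–Marquardt class) with
ftol = xtol = gtol = 1e-10 and at most 2000 evaluations per start.
Dependent-flux nonnegativity is not a box constraint on the free fluxes;
it is enforced by a quadratic exterior penalty (weight 1e6) appended to
the residual vector, which keeps the problem in least-squares form.  A
simulation failure inside the objective (dead-end EMU at an extreme flux
draw) returns a large finite residual rather than raising.

## Goodness of fit and uncertainty

The SSR acceptance range uses χ² quantiles at `df = n − p`.  The default
probabilities are (α, 1 − α) = (0.05, 0.95): this is the convention that
reproduces the field's customary printed limits (upper bound ≈ 21 at
df = 12; range 1.15–11.07 at df = 5); the two-sided α/2 convention is
available via `halved=True`.  The report's verdict applies only the upper
limit — an SSR below the lower quantile indicates overestimated errors,
not a rejected model — while both bounds are written out.

Monte Carlo: each of the (default 500) datasets perturbs every measured
entry with Gaussian noise at its SD, clips negatives to zero, does not
renormalize, and refits from the base optimum with a single start to keep
hundreds of refits tractable (multi-start per set is available).
Bootstrap: 1000 resamples with replacement of the Monte-Carlo solutions;
percentiles 2.5/16/50/84/97.5 computed with linear interpolation between
order statistics; the median of each percentile across resamples is the
reported CI bound.

## Synthetic TCA fixture

The bundled TCA network reproduces a standard teaching topology: pyruvate
and glutamate inputs, one reversible reaction pair, three measured sink
fluxes (0.20/0.23/0.15 ± 0.01 relative to pyruvate uptake = 1), seven free
fluxes.  Atom maps are reconstructed from canonical biochemistry (citrate
synthase and isocitrate dehydrogenase carbon fates, succinate symmetry as
0.5-coefficient twins, valine from two pyruvates, lysine from
oxaloacetate + pyruvate via the diaminopimelate route); the substrate
mixture is 50% 1-¹³C / 50% U-¹³C pyruvate with 100% 1-¹³C glutamate, and
each fragment's correction assumes eight derivative carbons and two
silicon atoms at natural abundance.  These are plausible synthetic
defaults chosen once — the fixture supports closure and recovery
experiments, not reproduction of any published flux table.

What the generator does *not* emulate: correlated measurement errors,
tracer impurity beyond a scalar enrichment, fragment-specific proton loss,
and real amino-acid fragmentation chemistry.  Passing closure tests
therefore demonstrates correctness of the computational chain, not
field-readiness of any particular experimental design.

### Identifiability of the fixture

Sink fluxes never alter labeling (an outflow does not change a pool's
MID), so the measured sinks V16–V18 are constrained only by their ± 3 SD
bounds and the exchange flux V07/V08 only weakly by scrambling; both drift
to their bounds under measurement noise, exactly as their wide Monte-Carlo
intervals show.  With user preferences the uptake/branch fluxes V02 and
V09 become free parameters that the labeling genuinely determines.  The
linearized information limit of this synthetic design at MID noise
SD 0.005 is σ(V02) ≈ 0.022 and σ(V09) ≈ 0.11 before bound regularization;
the multi-seed recovery experiment observes median absolute errors of
≈ 0.013 for these fluxes, i.e. the estimator operates at the information
limit of the design.  A recovery target of 0.01 at this noise level is
below what the bundled labeling design can support.

## Problem sizes used in tests and the reproduction script

Multi-seed recovery: 20 datasets at noise SD 0.005, 4 optimizer starts
each.  Monte Carlo in the reproduction script: 120 sets with 400 bootstrap
resamples; unit tests use smaller counts (5–30 sets).  EMU-vs-enumeration
checks run all four toy networks (≤ 12 traced carbons in total each) at
three random feasible flux vectors plus the full TCA fixture.  These sizes
are the package's own defaults for a quick, deterministic reproduction;
all counts are parameters of the respective functions.

## Known limitations

* No analytic Jacobian of the EMU cascade; finite differences are adequate
  at this scale but would dominate runtime for genome-scale models.
* No profile-likelihood or covariance-based CIs; Monte Carlo only.
* The LP feasibility step reports infeasibility with the pinned
  constraints, but does not compute an irreducible infeasible subsystem.
* Exchange fluxes are capped at 15× basis like all others; estimates at
  the cap should be read as "indistinguishable from fast exchange".
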