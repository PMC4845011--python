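# Methods

## Chains, species and indexing

A species is a sequence *d*₁…*d*ₙ over {S, U} with position 1 at the
non-reducing end (NRE). Position 1 contributes to no supported measurement
(digest fragments containing it are not counted and the overall composition
ρ is defined over positions 2..*n*) but is part of the species identity, so
a length-*n* pool has 2ⁿ species. Species are indexed by the bit code
S → 1, U → 0 with position 1 as the most significant bit; mixture spaces
concatenate length blocks in ascending order. All builders stream blocks of
bit codes and never materialize sequence objects, which keeps the
2,096,128-species mixture space (lengths 10–20) workable.

## Cleavage calculus

The lyase convention: the bond on the non-reducing side of disaccharide
*d*ᵢ is cut independently with probability *c*(*d*ᵢ), *i* = 2..*n*; after
cutting, the fragment containing position 1 is discarded. The expected
number of counted fragments of length *l* from sequence *s* is

    q(s, l) = Σ_{i=2..n−l+1} c_i · Π_{k=i+1..i+l−1} (1 − c_k) · t_{i,l}

with *t* = *c*ᵢ₊ₗ for interior fragments and 1 for the reducing-end
fragment. Summing over *l* gives the cut-counting identity
Q(*s*) = Σᵢ *c*ᵢ: every cut starts exactly one counted fragment. This
identity is what makes the N&I normalization α = (*n* − 1)·c̄ exact and is
enforced as a test invariant. Cap pooling (*l* ≥ *l_z*) always happens on
expected counts, before normalization; length mixtures likewise pool
counts (weight × α × per-length distribution) before renormalizing.

Closed forms for the three parametric families follow by taking
expectations of q under the model:

* **H&I** (i.i.d. positions, marginal ρ): cuts are i.i.d. Bernoulli(c̄)
  with c̄ = Σ_b c(b)ρ(b), giving
  g(l) = (1 − c̄)^{l−1}[(n − l − 1)c̄ + 1]/(n − 1). The geometric factor
  makes log g(l) nearly linear in l — the fingerprint the measured
  heparinase I digest violates (R² ≥ 0.99 under the model for every
  n in 10..20, versus a pronounced monomer excess in the data).
* **H&C** (homogeneous Markov, ρ stationary via the balance equation
  ρᵀP = ρᵀ): expected counts propagate 2-vectors through diag(c), P and
  diag(1 − c); the same routine accepts per-position transition matrices,
  which is how N&C ground truths are synthesized exactly.
* **N&I** (independent positions with profile Γ): the single-species
  formula evaluated at cᵢ = Σ_b c(b)Γᵢ(b), normalized by α.

All three are certified against a seeded Monte-Carlo simulator (chains
drawn from the model, bonds cut independently, NRE fragment discarded)
within three standard errors per bin; the simulator itself is validated on
hand-enumerable cut patterns.

## The measurement polytope

Measurements become equality rows on **p**:

* normalization (sum-to-one, or one row per length with mass w(n));
* composition: Σ r(s, S) p_s = ρ(S)(n − 1); for mixtures the ratio is
  linearized to Σ [r(s, S) − ρ(S)(len(s) − 1)] p_s = 0. Ratio
  linearization is exact, not an approximation: the p-dependent
  denominator is multiplied through;
* digest bins: Σ [q_z(s, l) − f_z(l) Q_z(s)] p_s = 0 for l = 1..l_z.
  Because Σ_l q = Q and Σ_l f = 1, each enzyme's rows sum to the zero
  row — a structural rank deficiency of one per enzyme, which is why
  1 + 1 + 11 + 6 = 19 rows carry 17 independent constraints;
* optional positional-homogeneity rows Σ_{s: d_i = S} p_s = ρ(S), and
  per-length composition rows for the mixture analyses.

Numerical rank uses SVD after scaling rows to unit ∞-norm (digest
coefficients span orders of magnitude), with relative tolerance 1e-10.

**Infeasibility** is the phase-I optimum min_{p≥0} ‖Ap − b‖₁, computed with
paired nonnegative artificial variables per row on the row-scaled system
(HiGHS). Values at or below 1e-8 are treated as "numerical precision", i.e.
feasible; the scale of positive values depends on the row scaling and only
the threshold behavior is meaningful. Measurement uncertainty could be
expressed as ±ε bands via slack columns; the headline analyses use exact
equalities (ε = 0) because the printed measurement vectors are already
normalized.

**LP bounds**: the extent of characterization of any linear property is
[min, max] over the polytope. Positional bounds use the indicator of a
category at an (aligned) position. For mixtures, reported bounds are
conditional on chains long enough to have the position; the conditioning
mass is fixed by the per-length rows (verified by two auxiliary LPs), so
conditional bounds are the unconditional optima divided by that mass. This
is what makes NRE-aligned bounds at the longest-chain positions (0, 1)
while RE-aligned bounds stay informative.

**Maximum entropy** is solved in the dual: p(λ) = softmax(Aᵀλ) over the
species, with λ (one per row, ~17–30 variables) found by damped Newton with
line search on the log-partition objective log Σ exp(Aᵀλ) − λᵀb.
Redundant rows make the Hessian singular; the Newton step is taken in the
least-squares sense, which converges to the same (unique) primal point.
Convergence requires the primal residual ‖Ap − b‖∞ ≤ 1e-7; with only
normalization + composition rows the solution coincides with the analytic
product model to 1e-8, a test oracle. Profile extraction (per-position
marginals, transition probabilities with their independence reference) is
direct summation over index blocks; zero-denominator transition entries are
reported as NaN, not errors.

## Parametric fitting

The fit objective is Σ_z Σ_l (f_z(l) − g_z(l))² over both enzymes'
cap-pooled bins — zero iff the model reproduces every bin. Minimization is
simulated annealing: Gaussian proposals on the free parameters, Euclidean
projection onto the constraint set after every proposal, Metropolis
acceptance, geometric cooling (300 levels, factor 0.95), initial
temperature auto-tuned to ~80% acceptance of uphill probe moves, and 100
independent seeded restarts by default. The proposal scale is additionally
adapted each level toward a moderate acceptance rate (up 15% above 50%
acceptance, down 15% below 30%); without this the annealer stalls near
1e-4 even on zero-noise synthetic problems whose true optimum is 0,
whereas with it synthetic ground truths are recovered to ~1e-8.

Projections: the H&C transition matrix is projected by Dykstra alternation
between the affine set {rows sum to 1, ρᵀP = ρᵀ} and the box [0,1]⁴
(tolerance 1e-10, capped iterations). The N&I profile reduces, within each
row-sum-1 line, to the S-column vector; its projection onto
{0 ≤ γᵢ ≤ uᵢ, mean γ = ρ(S)} is the exact clip-and-shift solution found by
bisection on the shift, which also handles per-position caps (e.g. an
LP-derived reducing-end cap). Row 1 of Γ is data-free and only clipped to
the simplex; it is excluded from the objective.

The elimination argument combines the three families: on the bundled BKHS
measurements at n = 16 the best objectives order as f(H&I) ≈ 0.107 >
f(H&C) ≈ 0.013 > f(N&I) ≈ 2×10⁻⁴ > 0 while the nonparametric polytope is
feasible — so among the four structure classes only nonhomogeneity
combined with correlation reproduces all measurements. Note the N&I floor
under this squared-error convention is small but strictly positive and
highly reproducible across seeds; its absolute scale is
convention-dependent (a χ²- or likelihood-weighted objective would weight
the tiny hepIII tail bins very differently), so cross-study comparisons
should compare fits under a single convention only. The capped fit
(Γ₁₆(S) ≤ 0.56, the LP upper bound) degrades the objective several-fold,
confirming that the uncapped N&I optimum relies on a reducing-end
sulfation level the polytope excludes.

## Chain-length mixtures

Length distributions w over n⁻..n⁺ are Gaussian bin integrals over
[n, n+1) (mean 16, σ = 1.5 or 3.5 in the bundled configuration) projected
by Dykstra alternation onto {w ≥ 0, Σw = 1, Σ n w = mean}. Note the
[n, n+1) binning is intentionally not mirror-symmetric about the mean.
The mixture polytope adds one mass row per length; per-length composition
extraction and the equal-composition feasibility test (does the data force
composition to vary with length? — it does not, the equal-composition
polytope remains feasible) follow directly.

## Synthetic data

Ground truths (HI, HC, NI, or NC = position-dependent Markov) generate
measurement sets whose composition is the exact model marginal and whose
digests are exact closed-form expectations — so noise-free synthetic
measurements are feasible by construction and LP bounds must bracket the
truth's positional composition, the package's parameter-recovery check.
The optional noise model is independent zero-truncated Gaussian
perturbation of each reported proportion followed by renormalization — a
pragmatic stand-in for measurement error, not an instrument model: it
ignores correlations between bins and the count nature of the underlying
data, so noise-robustness results indicate trends (infeasibility grows
with noise) rather than calibrated error rates.

## Problem sizes and numerical defaults

Analyses of the bundled measurements run at the measured n = 16 (65,536
species). The feasibility scans cover n = 10..16 (composition variant) and
n = 10..20 (homogeneity variant, up to 1,048,576 species); the
end-alignment demonstration uses the lengths-12..18 mixture (~520k
species) as a scaled-down stand-in for the full 10..20 mixture, which the
CLI can still run where memory allows. Tolerances: feasibility threshold
1e-8; LP solver HiGHS defaults on row-scaled systems; maxent primal
residual 1e-7; projection tolerances 1e-10; rank tolerance 1e-10 relative.
Every stochastic routine takes an explicit seed and is reproducible
bit-for-bit given it.

## Known limitations

* Only the binary S/U grouping is modeled; the full 16-state sulfation
  alphabet makes species enumeration prohibitive and would require the
  partial-independence reductions discussed in the literature.
* The digest calculus covers fragment lengths, not fragment compositions,
  though q(s, l) generalizes to composition spectra.
* The N&C class is quantified nonparametrically (via the polytope), not
  fitted as a parametric position-dependent Markov model.
* Fit-objective values are comparable only within one objective
  convention; see above.
* Vertex enumeration, polytope sampling and confidence intervals on
  measurements are out of scope.
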