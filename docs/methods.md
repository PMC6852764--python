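# Methods

## Model

Cells are assumed to be sampled independently and uniformly at random from a
population partitioned into subpopulations with fixed frequencies
p₁, …, p_k (Σpᵢ = 1). The per-subpopulation counts of n sampled cells are
then jointly multinomial, and every question the package answers reduces to
a *rectangular* multinomial probability

P(E) = P(aᵢ < Nᵢ ≤ bᵢ for all i),  N ~ Multinomial(p, n),

with strict lower and inclusive upper bounds. Detection of every
subpopulation with at least c representatives is the lower-only event
aᵢ = c − 1, bᵢ = ∞. The assumptions worth keeping in mind: sampling is
without replacement from a population large enough that multinomial
(with-replacement) sampling is accurate; doublets, dropout and
classification error are not modeled — c can be raised to hedge against
imperfect downstream labeling.

## Truncated-Poisson factorization

Direct summation of the multinomial pmf over E is exponential in k. Instead,
Poissonization: if Xᵢ ~ Poisson(αpᵢ) independently, then N is distributed
as X conditioned on ΣXᵢ = n, for *any* α > 0. Bayes' theorem turns the
conditional probability into

P(E) = ∏ᵢ P(aᵢ < Xᵢ ≤ bᵢ) · P(ΣᵢXᵢ^(aᵢ,bᵢ) = n) / P(ΣᵢXᵢ = n),

where Xᵢ^(aᵢ,bᵢ) is the truncated (interval-conditioned) Poisson. The only
nontrivial factor is the pmf of the truncated sum at n, for which two
backends exist (`method=` in `pmultinom`):

- **exact** — each component pmf is tabulated on
  {max(aᵢ+1, 0), …, min(bᵢ, n)} and the components are convolved pairwise
  with FFTs. Truncating each intermediate support at n is exact for the
  mass *at* n because all summands are nonnegative. Normalization of each
  component uses the full interval mass P(aᵢ < Xᵢ ≤ bᵢ), so mass above the
  cap is genuinely discarded, which is what correctness requires.
  Cost O(k·n·log n).
- **approximate** — an Edgeworth series around the normal density (below).

`method="auto"` (the default) uses convolution for n ≤ 20,000 and the
Edgeworth series above. The switch point is a throughput choice —
convolution is comfortably interactive below it — and the two backends are
required by the test suite to agree to 1e-5 absolute on fixed events and to
produce identical inverted sample sizes on the reference grid, so the
precise value is not load-bearing.

We fix α = n, putting the denominator Poisson(α) pmf at its mode, which
maximizes the dynamic range available to the ratio. The identity holds for
any α, and an internal override (`_alpha`) exists purely so tests can verify
that invariance (α = n vs α = n/2 agree to 1e-8).

### Numerical handling

All pmfs are generated in log space (Poisson log-pmf via the log-gamma
function; interval masses via the regularized upper incomplete gamma, with a
log-sum-exp fallback when an sf difference would cancel below ~1e-290).
Arrays are stored max-normalized with an accumulated log factor, so
convolution chains whose true values sit far below 1e-300 remain
representable; the final probability is assembled in log space and
exponentiated once, then clamped to [0, 1]. FFT round-off can produce small
negative entries: values within −1e-12 of zero (relative to the array peak)
are clamped to 0; anything more negative raises an internal error rather
than being silently absorbed.

Degenerate cases short-circuit: n = 0 (probability is the indicator that the
all-zero vector lies in E), an all-unbounded event (probability exactly 1),
a zero-frequency category with a lower bound (probability 0), and a
truncation interval with zero mass (probability 0, signalled internally as
an impossible-constraint error).

## Edgeworth backend

Each truncated component's cumulants κ₁…κ₂₂ are computed exactly by
summation over its support — infinite upper tails cut where the residual
Poisson mass is below 1e-16, the negligible lower tail likewise trimmed for
rates above 50 — with central moments accumulated first and converted by the
standard recursion (centering keeps the conversion stable at large rates).
Cumulants add across components. With μ, σ² the sum's mean and variance and
x = (n − μ)/σ, the pmf is approximated by the local expansion

P(S = n) ≈ φ(x)/σ · [1 + Σₛ Σ_{partitions of s} He_{s+2r}(x) ∏ₘ (1/kₘ!) (S_{m+2}/(m+2)!)^{kₘ}],

with S_j = κ_j/σʲ the scaled cumulants, He the probabilists' Hermite
polynomials, and the inner sum over partitions of s into parts m with
multiplicities kₘ (r = Σkₘ). Orders s = 1, 2, … are added until the last
term is below 1e-9 of the accumulated value (absolute floor 1e-15), up to
order 20.

Two refinements to that stop rule matter in practice. First, a single
negligible term is not accepted as convergence: odd-order terms contain only
odd Hermite polynomials, which vanish identically at the symmetric point
x = 0, so the rule demands two negligible orders in a row. Second,
negligible terms are dropped rather than added, which makes the
leading-order limit exact: with a huge tolerance the result is precisely
the normal density over σ. The series is asymptotic, not convergent; if
term magnitudes grow for three consecutive orders it is declared divergent
and the caller falls back to exact convolution.

## Sample-size inversion

For lower-only events the probability is nondecreasing in n (adding a draw
can only help each category), so n* = min{n : P ≥ p*} is well defined and
found by doubling from the pigeonhole minimum Σ(aᵢ+1) until the target is
met, then binary search. Finite upper bounds are rejected with an explicit
error: the probability is then non-monotone and "the" required n is
ill-posed. The bracket start can be seeded with a previous solution, which
the posterior machinery uses to amortize thousands of inversions over
correlated frequency draws. Default search ceiling: n = 10⁶.

Prospective designs place k copies of the rarest frequency f, any extra
higher frequencies, and one *unconstrained* remainder category of mass
1 − kf − Σextras (omitted when below 1e-9, in which case the supplied
frequencies are rescaled onto the simplex exactly). The probability curve
extends 25% past n* by default.

## Posterior uncertainty (retrospective mode)

Observed counts n₁, …, n_k from a previous experiment are combined with the
improper Dirichlet(0, …, 0) prior — the choice appropriate when the set of
possible outcomes is not known before the experiment — giving a
Dirichlet(n₁, …, n_k) posterior over frequencies, proper exactly when every
count is ≥ 1; zero counts are rejected rather than smoothed. Draws are
generated as independent Gamma(nᵢ, 1) variates normalized by their sum,
from a seeded generator (the seed is a required argument; there is no
hidden global state).

Each posterior draw is pushed through the probability (at a given n) or the
inversion (at a given p*), yielding posterior samples of the quantity of
interest. One-sided summaries: the empirical (1 − level) quantile of the
probability (linear interpolation) as a *lower* bound, and the nearest-rank
level quantile of n* (smallest integer holding at least `level` posterior
mass at or below it) as an *upper* bound. Defaults: level 0.95, 10,000
draws. The full retrospective report shares a single draw matrix across the
scalar summaries and the curve, so a fixed seed reproduces the report
byte-for-byte; the curve grid spans k·c to 25% past the largest of the
upper bound and the cells actually sequenced, on ~40 integer points.

## Independence baseline

The equal-frequency independence approximation P(N ≥ c)^k (binomial
survival computed in log space) ignores the negative correlation among
multinomial counts and therefore *over*states the joint detection
probability, understating the required cells. Over the 11-scenario
reference grid (c = 10, p* = 0.95) the shortfall is at most one cell —
reproduced by `scripts/acceptance.py`, which first recovers c by brute
force from the symmetric f = 0.5, k = 2 scenario (30 cells required pins
c = 10 uniquely in 1..30).

## Validation oracles and what they show

`simulate.py` holds deliberately independent checks: exhaustive composition
enumeration of the multinomial pmf (guarded to ≤ 10⁶ compositions), seeded
multinomial Monte-Carlo, and two scenario generators — a generic one for
oracle-equivalence sweeps, and one for Monte-Carlo comparison that pins the
first category's requirement at its expected count so the event probability
stays away from 0 and 1, where the binomial standard error degenerates and
a 3·SE comparison is meaningless. These fixtures validate the calculation
under its own multinomial assumptions; they cannot speak to how far a real
tissue deviates from random uniform sampling (dissociation bias, doublets,
spatial structure), which is the main caveat when applying the numbers.

## Problem sizes used in the test suite

Module tests run small instances throughout (n ≤ a few hundred; posterior
summaries at a few hundred draws, with 10⁴ draws where a moment check needs
them). The end-to-end suite inverts all 11 reference scenarios with both
backends, sweeps 200 random small instances against the enumeration oracle,
and checks backend agreement on fixed events at n = 10³ and 10⁴ — sizes at
which the whole suite completes in well under a minute while exercising
every code path, including the auto-switch region via the Edgeworth-only
method flag.

## Known limitations

- Only rectangular events are supported; arbitrary multinomial events are
  out of scope.
- Inversion requires lower-only events (see above).
- The Edgeworth backend is an asymptotic approximation; accuracy at small n
  is empirically excellent (identical inversions on the reference grid) but
  not guaranteed, and the convolution fallback triggers only on detected
  divergence, not on silent inaccuracy.
- The retrospective analysis conditions on the observed subpopulations; it
  says nothing about undiscovered subpopulations, which is a different
  estimation problem.
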