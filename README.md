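# raredetect

Sample-size calculations for single-cell sequencing experiments: how many
cells must be sequenced so that every subpopulation of interest — a cell type
in normal tissue, a clone in a tumor — is represented by at least *c* cells?

## The calculation

When *n* cells are drawn at random from a tissue with subpopulation
frequencies *p₁, …, p_k*, the per-subpopulation counts *N = (N₁, …, N_k)*
are multinomial. A successful experiment is the rectangular event
*E = {aᵢ < Nᵢ ≤ bᵢ for all i}* — for detection, *Nᵢ ≥ c*, i.e. *aᵢ = c − 1*
with no upper bound. The probability of *E* is computed exactly through a
truncated-Poisson representation: with independent *Xᵢ ~ Poisson(αpᵢ)*,

```
P(N ∈ E) = ∏ᵢ P(aᵢ < Xᵢ ≤ bᵢ) · P(Σᵢ Xᵢ^(aᵢ,bᵢ) = n) / P(Σᵢ Xᵢ = n)
```

where *Xᵢ^(aᵢ,bᵢ)* is *Xᵢ* conditioned on the interval *(aᵢ, bᵢ]*. The pmf
of the truncated sum is evaluated either exactly, by FFT convolution of the
component pmfs in log scale, or — for large *n* — by an Edgeworth series
built from the components' exact cumulants. The required sample size

```
n* = min { n : P(N₁ ≥ c, …, N_k ≥ c) ≥ p* }
```

is obtained by exponential bracketing plus binary search (the detection
probability is nondecreasing in *n*).

Two modes of use:

- **Prospective** — before an experiment, specify the frequency *f* of the
  rarest subpopulations and how many of them (*k*) you need to find; the
  tool reports *n\** and the probability curve.
- **Retrospective** — after an experiment, supply the observed
  per-subpopulation cell counts; the tool reports how many cells a replicate
  experiment would need, with one-sided 95% credible bounds from the
  Dirichlet(n₁, …, n_k) posterior over the unknown frequencies
  (improper Dirichlet(0, …, 0) prior).

An independence baseline — *P(N ≥ c)^k* with equal-frequency binomials — is
included for comparison; across the standard scenario grid it understates
the exact requirement by at most one cell.

## Worked example

Planning an experiment to find six subpopulations at 10% frequency, with at
least 10 cells from each, at 95% certainty:

```bash
$ raredetect prospective -f 0.1 -k 6 -c 10 -p 0.95
{
  "n_star": 186,
  ...
}
```

186 cells are required; the seventh listed frequency (0.4) is the
unconstrained remainder of the population. Evaluating a finished experiment
that sequenced 84 cells and found two clones of 42 cells each:

```bash
$ printf 'cloneA\t42\ncloneB\t42\n' > counts.tsv
$ raredetect retrospective --counts counts.tsv -c 10 -p 0.95 --seed 1 --draws 2000
{
  "n_star_point": 30,
  "n_star_upper95": 37,
  "cells_sequenced": 84,
  "oversampled": true,
  "p_at_sequenced": 0.9999999999999916,
  "p_lower95_at_sequenced": 0.9999999920405334,
  ...
}
```

A replicate experiment would need only 30 cells at the empirical frequencies
(at most 37 cells under frequency uncertainty, at 95% credibility), so 84
cells comfortably oversampled the two clones. The same computations are
available as library functions (`pmultinom`, `invert_pmultinom`,
`prospective_design`, `retrospective_report`, ...):

```python
>>> from raredetect import BoundsSpec, FrequencyVector, pmultinom
>>> pmultinom(BoundsSpec.at_least(10, 2), 30, FrequencyVector([0.5, 0.5]))
0.957226054742926
```

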