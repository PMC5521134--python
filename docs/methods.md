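# Methods

`screensim` is a discrete Monte Carlo simulator of pooled CRISPRi/CRISPRn
genetic screens. Every stage of a real screen — library composition, lentiviral
infection, phenotypic selection by FACS or by growth, library preparation and
sequencing, and hit calling — is modelled as an explicit stochastic sampling
step, so that the impact of design parameters (representation, bin size,
passage number, library quality) on hit detection can be explored in silico.
The absolute metric values depend on unobservable inputs (reporter noise,
library quality), so comparisons between parameter settings are relative, not
absolute performance predictions.

## The simulated genome

A genome of `N` genes (default 500) assigns each gene a class and a true
phenotype `l`: 75% wild-type (`l = 0`), 5% negative controls (`l = 0` by
definition; these later provide the null distribution for p-values and the
noise metric), 10% positive hits with `l ~ Normal(0.55, 0.2)` clamped to
[0.1, 1.0], and 10% negative hits from the mirrored distribution clamped to
[-1.0, -0.1]. Clamping clips out-of-range draws to the boundary rather than
redrawing, so small probability mass accumulates at the clamp edges. Class
counts are deterministic given `(N, fractions)` — `floor(N * fraction)` with
the remainder assigned in fixed class order — so two runs differ only in the
drawn phenotype values, never in the class composition.

Each gene carries a knockdown-response function `f(x)` giving the fraction of
the full phenotype shown at knockdown level `x in [0, 1]`:

* **Linear genes** (75%): `f(x) = x`.
* **Sigmoidal genes** (25%): switch-like, with inflection point `p` and
  half-width `k`:

  ```
  f(x) = 0                      for x <= p - k
       = 1                      for x >= p + k
       = (sign(d) * 1.05|d| / (|d| + 1) + 1) / 2   otherwise,
  d = (x - p) / min(p, min(1 - p, k))
  ```

  `p ~ Normal(0.8, 0.2)` and `k ~ Normal(0.1, 0.05)`. Because those Gaussians
  can produce `k <= 0` or `p` outside (0, 1), where `d` is undefined, draws
  are rejected until `k >= 0.01` and `0.05 <= p <= 0.99`; this sanitizes the
  tails without reshaping the bulk of the distribution. The function is
  implemented exactly as written, including its jump discontinuities at
  `x = p ± k` (from 0.2375/0.7625 to the plateaus when `k <= min(p, 1-p)`)
  and the convention `sign(0) = 0`, which makes `f(p) = 0.5` exactly. A
  cell's phenotype is `l * f(x)`.

## The sgRNA library

Each gene is targeted by `m = 5` guides. Guide activity is bimodal: 10% of
guides are low-activity, `Normal(0.05, 0.07)` clipped to [0, 1]; the 90%
high-activity guides draw from `Normal(0.90, 0.1)` (CRISPRi) or have
efficiency exactly 1.0 (CRISPRn — an active nuclease guide always cuts; what
varies is the repair outcome, realized per cell at infection). Activity is a
guide property, drawn once.

Plasmid frequencies are log-normal. The only stated constraint is the shape:
a guide at the 95th percentile of frequency is 10-fold more frequent than one
at the 5th. Since normalization cancels the log-scale mean, the constraint
determines only `sigma_log = ln(ratio) / (z(0.95) - z(0.05)) ≈ 0.6998`, which
`lognormal_sigma_for_ratio` solves in closed form.

## Infection

`representation x n_guides` cells each receive `Poisson(lambda)` integrations
(`lambda = 0.25` by default); only single-integrant cells (a fraction
`lambda e^-lambda ≈ 19.5%`) are retained, and each draws its guide from the
plasmid frequencies. CRISPRi cells realize the guide's knockdown directly.
CRISPRn cells with an active guide realize 0%, 50% or 100% knockdown with
probabilities 1/9, 4/9, 4/9 — the outcome mix for a diploid locus when 2/3 of
repair events cause a frameshift, counting a monoallelic knockout as 50%
knockdown. The outcome is drawn once at infection and inherited by daughter
cells (it is a genotype), which matters for growth screens.

Cells are tracked as counts per (guide, realized-knockdown) bucket, not
individually; every downstream step depends only on bucket membership, so
this is distributionally exact and orders of magnitude faster.

## Selection

**FACS.** The pool is bottlenecked (multinomial resampling with replacement)
to `bottleneck_representation` cells per guide. Each cell's observed reporter
phenotype is its theoretical phenotype plus `Normal(0, sigma)` noise
(`sigma = 1.0` by default — one noise SD per maximal phenotype unit; reporter
noise of real screens is not directly measurable, so this is a tunable
assumption and SNR comparisons across settings are relative). Cells are
ranked by observed phenotype; the bottom and top `X` fractions
(`0 < X <= 0.5`) are the two comparison bins, each of exactly
`round(X * bottleneck)` cells. Observed phenotypes are simulated per cell
(the bottlenecked pools of interest are small enough that this is cheap);
ties, which can only occur at `sigma = 0`, are broken in random order by a
pre-shuffle.

**Growth.** The pool is bottlenecked once to give the `t0` sample; then, for
each of `n` passages, every cell divides and the pool is bottlenecked again
(including after the last passage, so both endpoints carry one final round of
sampling noise). In the time a wild-type cell divides once, a cell with
phenotype `phi` behaves like the relevant extreme with probability `|phi|`:
it becomes 4 cells (`phi = +1` divides twice) or 1 cell (`phi = -1` does not
divide), and otherwise doubles. The expected per-step growth factor is
therefore `2 + 2 phi` for `phi >= 0` and `2 - |phi|` for `phi <= 0`. The
per-cell Bernoulli choice is realized per bucket as a Binomial draw, which is
the exact distribution of the per-cell rule.

## Sequencing

Each bin is sequenced to `seq_representation x n_guides` reads by a single
multinomial draw from the categorical distribution of guide frequencies in
the bin (knockdown buckets of a guide are merged first — sequencing sees
guides, not repair outcomes). Sampling with replacement reflects PCR
amplification before sequencing; both bins get the same depth.

## Hit calling

Guide phenotypes are `log2` ratios of pseudocounted frequencies,
`freq_b(g) = (reads_b(g) + c) / (depth_b + c G)` with pseudocount `c = 0.5`
and `G` guides, bin 2 (high/tn) over bin 1 (low/t0). Guides with zero reads
in *both* bins are dropped from all downstream statistics; the pseudocount
keeps strongly depleted guides (zero in one bin) informative. Gene phenotype
is the arithmetic mean of member guide phenotypes. Significance is a
two-sided Mann–Whitney rank-sum test of member phenotypes against all
non-dropped negative-control guide phenotypes: the exact permutation
distribution of U (computed by the standard partition-count recursion) is
used for tie-free comparisons with `n1 + n2 <= 30`, and the normal
approximation with tie and continuity corrections otherwise — in practice
the gene-vs-controls comparisons (5 vs ~125) always take the asymptotic
path, and the exact path guarantees correctness on small inputs. Genes are
ranked by `|phenotype| * -log10 p` (capped at 300 to avoid underflow
infinities), ties broken by ascending gene id; genes whose guides all
dropped get phenotype 0, `p = 1`, score 0.

## Performance metrics

* **Top-n overlap**: fraction of the called top-50 genes that are among the
  actual top-50 by `|l|` (ties by gene id).
* **AUPRC** for recovering genes with `l != 0` (wild-type and negative
  controls are both negatives), using the lower trapezoidal estimator:
  linear interpolation between successive achievable precision–recall
  points, anchored at recall 0 with the first point's precision. PR curves
  are preferred over ROC because hits are rare (20% prevalence). A
  per-class variant (`class_auprc`) scores one hit class with the other
  excluded, for asymmetric questions such as negative-hit detection in
  growth screens.
* **Signal / noise / SNR**: per true-hit gene, the mean over non-dropped
  guides of `log2fc / theoretical phenotype`; signal is the median over hit
  genes, noise the SD of negative-control guide phenotypes, SNR their
  ratio. The theoretical phenotype of a guide maps its expected knockdown
  through the gene's response: CRISPRi guides use their efficiency; active
  CRISPRn guides use the expectation over the 1/9–4/9–4/9 outcome mix,
  `l * (f(0)/9 + 4 f(0.5)/9 + 4 f(1)/9)` — the true expected per-cell
  phenotype, chosen over `f(E[kd])` because the quantity divides an
  expectation of per-cell log ratios. Guides with theoretical phenotype 0
  are excluded (no division by zero); SNR is reported missing when the
  noise is exactly 0.

## Orchestration and reproducibility

A screen is fully determined by `(config, seed)`; a single `numpy`
`Generator` is threaded through the stages, so equal seeds give bit-identical
count tables and metrics. Sweeps derive the seed of each (grid cell,
replicate) run as `SeedSequence([base_seed, cell_index, replicate_index])` —
a pure function, so any cell can be re-run in isolation — and report per-cell
means with 95%/99% normal-approximation confidence half-widths. Failed runs
(e.g. an MOI of 0 retaining no cells) are recorded in the tidy results table
and do not abort the sweep.

## Problem sizes and defaults used in the shipped analyses

The packaged experiments use the standard study conditions: `N = 500` genes,
`m = 5` guides, MOI 0.25, 100x representation at transfection, bottleneck and
sequencing unless swept. The bin-size SNR curve sweeps
`X in {5, 10, ..., 45}%` with 25 replicates per point (the replicate count
such curves are typically averaged over); under these conditions the mean SNR
peaks in the 20–30% range — the quartile-bin rule — while signal and noise
individually decrease with bin size. Representation sweeps use
{10, 100, 1000}x with 10 replicates; the passage-number experiment uses a
genome with 10% negative hits and 2% strong positive hits
(`l ~ Normal(1.0, 0.1)` clamped to [0.5, 1.0]) over {1, 2, 4, 6, 8, 10}
passages, where negative-hit detection peaks at intermediate duration and
declines as the positive hits take over the pool.

## What the generator does and does not emulate

The simulation captures Poisson infection statistics, heritable CRISPRn
repair outcomes, bottleneck jackpot effects, reporter noise and sequencing
sampling noise. It does not model off-target activity, guide-position
effects, multi-integrant cells after selection against them, cell death as
distinct from non-division, sequencing error or PCR jackpotting beyond
multinomial noise, or gene–gene interactions. Passing tests therefore show
that design-parameter trade-offs behave as the model predicts, not that any
particular real screen will attain the simulated metric values.

## Numerical and degenerate-input choices

Efficiencies and phenotype draws are clipped to their domains; the p-value
floor is 1e-300 and `-log10 p` is capped at 300; empty pools, empty bins,
single-class label sets, missing negative controls and invalid fractions all
raise errors at the stage boundary rather than propagating NaNs. Sweep
parameter assignment coerces whole-number values into integer fields
(representations, passage counts) so YAML/CLI grids round-trip cleanly.
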