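# Methods

## Model

The two-state (telegraph) model treats a promoter as a Markov switch:
activation at rate k_on, inactivation at rate k_off, transcription at rate
s while active, decay of transcripts at rate d. Dividing all rates by d
expresses them per mean mRNA lifetime and fixes d = 1. The steady-state
count distribution is the Poisson-beta mixture: the auxiliary variable
p ~ Beta(k_on, k_off) is the (random) fraction of time spent active, and
x | p ~ Poisson(s·p). Closed-form moments:

- mean  m = s·k_on/(k_on+k_off)
- variance  m + s²·k_on·k_off / ((k_on+k_off)²·(k_on+k_off+1))
- Fano factor  φ = 1 + s·k_off / ((k_on+k_off)(k_on+k_off+1))

φ → 1 as switching accelerates at fixed occupancy, which is why fast
switching is statistically indistinguishable from a Poisson (or, with
moderate speed, a negative binomial): this motivates the identifiability
test below.

Derived burst quantities: burst size s/k_off (mean transcripts per active
period), burst frequency k_on, inactive fraction k_off/(k_on+k_off).

## pmf evaluation

The closed form of the pmf involves the confluent hypergeometric function
₁F₁, which cannot be evaluated fast and reliably in double precision over
the full parameter range. The production path therefore evaluates the
mixing integral ∫₀¹ Poisson(x | s·p)·Beta(p | k_on, k_off) dp with
tanh-sinh (double-exponential) quadrature carried out entirely in log
space. The tanh-sinh substitution maps the integrable endpoint
singularities (k_on < 1 or k_off < 1) to double-exponentially decaying
tails; all node quantities (log p, log(1−p), log dp/dt) are elementary and
stable. The step size starts at 0.12 and is halved until two levels agree
to ~1e-10 relative on every requested point; the t-range is set so the
slower-decaying singular tail has fallen below e⁻⁴⁶. A Gauss-Jacobi rule
was considered and rejected: high-order Jacobi nodes/weights computed in
double precision lose ~1e-6 relative accuracy when a shape parameter is
near −1, which is the generic case here. Against the arbitrary-precision
₁F₁ closed form (mpmath, 50 digits) the quadrature agrees to better than
1e-12 relative across k_on, k_off ∈ [1e-2, 1e2], s ∈ [1, 500].

Support truncation for normalization checks: a mean + 12·sd rule fails for
strongly skewed mixing betas (small k_on with large k_off), where rare
large-p excursions carry ~1e-3 of mass beyond the two-moment bound. The
bound used instead takes q, the 1−1e-12 quantile of Beta(k_on, k_off), and
truncates at s·q + 12·sqrt(s·q + 1) + 2; counts are stochastically
dominated by Poisson(s·q) up to the 1e-12 beta tail, so the neglected mass
is ≲1e-8 for every parameter combination.

## Preprocessing

Counts are read from TSV (gene × cell, header row) or MatrixMarket plus a
two-column gene-length TSV. Per-cell scale factors t_j are library size ×
TMM factor, rescaled to geometric mean 1. TMM uses the canonical settings:
log-ratio trim 0.30, average-abundance trim 0.05, reference cell chosen by
the 75th count-fraction percentile closest to its across-cell mean, and
inverse delta-method variance weights; the implementation reproduces
Bioconductor edgeR's factors to ~1e-8 on a fixed test matrix. Factors are
computed once on the full matrix, before filtering.

The expression filter removes genes whose maximum *normalized count*
max_j x_ij/t_j is below 50 (default): at lower counts, technical
variability of single-cell library preparation dominates the biological
signal. The normalized count deliberately involves t_j only — the filter
is about read-count magnitude, not per-kb expression density — and this
choice is surfaced here because length-normalized filtering would retain a
different gene set.

Inside the model the gene-length offset is t_i = length / median length
over the current genes, so the transcription rate s_i stays on the scale
of normalized read counts rather than counts per bp (raw bp offsets would
shrink s_i by ~10³ and collide with its empirical-Bayes prior scale).

## Hierarchical inference

Generative model per gene i, cell j:

1. s_i ~ Gamma(α_s, β_s,i) (scale parameterization)
2. k_on,i ~ Gamma(α_kon, β_kon)
3. k_off,i ~ Gamma(α_koff, β_koff)
4. p_ij ~ Beta(k_on,i, k_off,i)
5. x_ij ~ Poisson(t_i·t_j·s_i·p_ij)

Hyperparameter defaults: α_s = 1 with the empirical-Bayes scale
β_s,i = max_j x_ij (near-flat over the range the data can support), and
α_kon = α_koff = 1 with β_kon = β_koff = 100, spreading the switching-rate
priors over the identifiable region. Estimates of identifiable genes are
insensitive to replacing 100 by 10,000 (checked in the tests); a
concentrated prior (β = 10) penalizes only the large-rate tail.

All four full conditionals are non-standard univariate densities and are
updated by slice sampling (step-out + shrinkage). The rates are sampled on
the log scale with the Jacobian correction, width 1.0 log units, because
their posteriors span orders of magnitude; p_ij is sampled on (0,1) with
width 0.2; step-outs are capped at 50. One iteration updates every p_ij
(gene-major), then k_on,i, k_off,i, s_i per gene; the log posterior — the
Poisson likelihood, beta densities and the three gamma priors (prior terms
summed per gene) — is recorded every iteration as a convergence monitor.
Initialization is moment-flavored: p from shifted normalized counts, s
from the per-gene maximum, k_on = k_off = 1. Chains are reproducible from
a single integer seed; the inner loop is numba-compiled, with the slice
updates transcribed one-to-one from the pure-Python reference
implementations that the unit tests exercise.

Point estimates are posterior means over the second half of the chain
(10,000 iterations by default), with batch-means Monte-Carlo standard
errors (20 batches). The trace has long memory on weakly identified genes
— lag-200 autocorrelation around 0.3 is typical — so diagnostics based on
batching must use batch sizes well above that.

## Identifiability testing

For a fitted parameter triple, n = 1000 counts are drawn from the
Poisson-beta distribution (this is a test of the *distribution shape at
the fitted parameters*, not of the handful of observed cells), and both a
Poisson and a negative binomial are fitted to the draws by maximum
likelihood — the NB by profile likelihood over log r with the closed-form
success probability given r; samples with variance ≤ mean are degenerate
(the NB likelihood climbs toward its Poisson limit) and count as fitting.
The discrepancy statistic is KS_n = max_i |F_n(X_i) − F(X_i)| over the
observed points, with the right-continuous empirical CDF. Because the null
parameters are estimated, the null distribution of KS_n comes from a
parametric bootstrap (B = 1000 by default): simulate n draws from the fit,
refit, recompute the statistic against the refit, and report the fraction
strictly exceeding the observed value. Ties therefore do not count as
exceedances. The gene is *identifiable* iff both bootstrap P values fall
below α = 0.1 — only then is the Poisson-beta shape distinguishable from
both simpler limits. Reduced-cost settings (n = B = 200) are used in the
test suite; the calibration of the bootstrap (type-I error ≈ α, P values
near-uniform under the null) is itself tested.

## Synthetic data and recovery experiments

`simulate_dataset` draws from exactly the generative model above
(default t_i = t_j = 1); `sample_parameter_grid` draws (k_on, k_off)
log-uniformly on [0.01, 100]² with s fixed at 100 — a grid that spans the
full identifiable-to-non-identifiable landscape.

`recovery_study` mirrors how recovery is assessed in practice when truths
must come from data: a pilot dataset of 12 cells is simulated from the
grid and fitted, and the pilot *posterior means* become the truths for the
actual experiment — fresh datasets at 3, 6, 12, 20 and 100 cells,
refitted, then compared with the truths by Spearman rank correlation
across genes and by two bias measures. Seeding the truths with fitted
values keeps the experiment inside the parameter region a small-cell fit
can represent; raw grid truths instead mix in strongly non-identifiable
genes whose estimates are dominated by prior drift, which measures the
prior more than the method.

Two bias measures are reported because they answer different questions.
The mean signed relative error, mean((est − truth)/truth), is bounded below
by −1 but unbounded above, so a few genes whose switching rates drift up
the fast-switching ridge (inflating s) can dominate it. The mean log
ratio, mean(log(est/truth)), is the bias on the multiplicative scale
natural to a positive rate and reflects the typical gene. At 12 cells the
transcription rate s is underestimated on the log scale — the prior scale
β_s = max_j x_ij caps s near the largest observed count, and with few
cells no cell reaches the gene's maximal expression — and the
underestimation shrinks as cells are added. Correlations between truth and
estimate increase with the number of cells; because each cell count is an
independent simulation, the monotonicity is asserted up to Monte-Carlo
noise, quantified as twice the large-sample Spearman standard error
(1−ρ²)/√(G−1) with G = 50 genes.

The generator emulates biological sampling only: no dropout, amplification
noise, or other technical variation is simulated, so passing recovery
tests demonstrates correctness of the inference under the model, not
robustness to the technical noise of real single-cell protocols.

## PolII pausing metrics

Coordinates are BED-style 0-based half-open; the TSS is `start` on the
plus strand and `end − 1` on the minus strand, and all metrics use
coverage on the gene's own strand. Gene body activity is N/L over the
region from 1 kb downstream of the TSS to the gene end (genes ≤ 1 kb have
no body region and the metric is undefined, reported as None/NA). Promoter
activity is the maximum 50-bp window sum, windows stepping by 1 bp and
fully contained in the ±1 kb flank around the TSS; the flank is defined by
transcription-direction offsets [−1000, +1000), which makes the two
strands exactly symmetric under coordinate reflection. The pause index is
(promoter activity / 50) / body activity — per-bp promoter signal over
per-bp body signal — so uniform coverage gives exactly 1, and the index is
invariant under global scaling of the track. "Reads in a window" means the
sum of per-base coverage: with 5′-end tracks this is the literal read
count, with full-length coverage it weights reads by overlap.

## Problem sizes and numerical settings used in the tests

The test suite runs reduced but structurally identical versions of every
experiment: 10⁶-draw sampler checks on a 5×5×3 parameter grid; bootstrap
calibration with 100 replicates of n = 200 at B = 200; the 5×5
identifiability landscape at n = B = 200; and the recovery study with 50
genes and 2,000-iteration chains. These sizes were chosen so the whole
suite completes in a few minutes on one CPU while every Monte-Carlo
tolerance remains dominated by sampling error, not systematic error.

## Known limitations

- Technical noise is not modeled; the expression filter (≥ 50 normalized
  counts) is the only defense against it.
- The model assumes a single rate-limiting activation step and identical
  kinetics across alleles.
- s_i is only identified up to the proportionality between reads and
  transcripts; rates are per mRNA lifetime, not per unit clock time.
- Genes in the fast-switching regime yield posterior mass spread along the
  (c·k_on, c·k_off) ridge; their raw or derived parameters should not be
  interpreted, which is what the identifiability flag communicates.
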