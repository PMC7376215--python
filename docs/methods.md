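# Methods

## Count model and normalization

Transcript counts are modeled as negative binomial with the
mean–dispersion parameterization `Var(Y) = mu + alpha * mu^2`. The
pipeline entry point is an integer count matrix (RSEM-style expected
counts are assumed rounded upstream; the NB likelihood is defined on
integers and rounding is the standard convention).

Size factors use the median-of-ratios estimator: for each sample the
median, over transcripts positive in every sample, of the count divided
by the transcript's geometric mean. No post-hoc rescaling is applied.
Consequences worth knowing: (a) if no transcript is positive everywhere
the strict estimator raises, and a positive-entry pseudo-reference is
available behind an explicit flag; (b) scaling one of `n` libraries by
`c` shifts the geometric reference by `c^(1/n)`, so individual factors
are equivariant only up to that common constant — factor *ratios* are
exactly equivariant, which is what normalization uses.

## Dispersion estimation

Per transcript, a within-group method of moments on normalized counts:
`alpha_g = (s_g^2 - m_g) / m_g^2` per group, combined across the two
groups with weights `n_g - 1`, clipped at a floor of 1e-8, then shrunk
toward the across-transcript median on the log scale with weight 0.5.
The shrinkage stabilizes the very noisy per-transcript moments at 2–3
replicates per cell.

This is deliberately simpler than the Cox–Reid adjusted profile
likelihood with a fitted mean–dispersion trend used by the standard
differential-expression packages. The operating consequence, measured by
simulation: with *known* dispersions the Wald test is well calibrated
(empirical type-I error 0.049 at nominal 0.05; null NB simulation with
20,000 transcripts, six samples per group, dispersions log-uniform on
[0.01, 0.3], means on [50, 2000]); with *estimated* dispersions at the
same design the test is anti-conservative (≈0.08–0.09 empirical at
nominal 0.05), because plug-in dispersion noise at ~10 residual degrees
of freedom inflates the normal-reference tails. Calibration claims in
the test suite therefore condition on known dispersions; threshold-based
calls on estimated dispersions rely on the fold-change filter and the
discrimination rule to suppress the extra false positives, and the
end-to-end recovery simulations quantify the net effect (see below).

## Wald test

Each contrast is a per-transcript NB GLM with log link, intercept plus
group indicator, and offsets `log s_j`, fitted by IRLS with
expected-information weights `w = mu / (1 + alpha*mu)` (tolerance 1e-8
on coefficients, at most 100 iterations, coefficients clamped to ±50).
For the two-level design the normal equations reduce to closed 2×2
algebra and `Var(beta1) = 1/W_test + 1/W_ref` with `W_g` the summed
weights per group. `log2fc = beta1 / ln 2`; the Wald z uses the
natural-log SE; p-values are two-sided normal. No fold-change shrinkage
is applied. All-zero transcripts and non-converged fits carry missing
p-values rather than crashing. Benjamini–Hochberg step-up runs over the
transcripts passing a fixed mean-normalized-count filter (default
mean ≥ 1); filtered transcripts keep their statistics but get missing
adjusted p and do not count toward the BH `m`.

## Calls and the induced set

Enrichment calls require `padj < padj_max` (default 0.1; analyses of
stronger exposures conventionally use 0.05) and fold change > 2 on the
linear scale, i.e. `log2fc > 1`. Differential expression on the input
fraction uses `padj < 0.05` with fold change > 2 (up) or < 0.5 (down).

The induced-set rule takes the two enriched sets: a transcript is
induced iff enriched in the exposed condition and either absent from the
control enriched set, or its linear enrichment ratio
`2^(lfc_exp - lfc_ctl)` strictly exceeds 1.5. Ratios are computed on the
raw (unshrunken) fold-change estimates. The reported `min_log2fc` is the
minimum exposed-condition enrichment over induced members — the noise
floor of the called set.

## Selectivity, clustering, over-representation

"Averagely divided" expression bins are equal-count deciles of detected
transcripts (base mean > 0) ranked by mean normalized input expression,
ties broken by transcript ID; the remainder when the count is not
divisible is spread one per bin from the top-expression bin downward. An
equal-width alternative on the expression scale is available behind a
flag. The chi-square goodness-of-fit of per-bin oxidized counts against
the proportional-to-detected expectation (bins with expected < 1 pooled
into a neighbor) is an added uniformity summary, not a claim the display
depends on.

Enrichment profiles are clustered by average-linkage agglomeration on
Euclidean distance (scipy), with missing entries imputed as zero for the
distance computation (flagged in the result) and rows pre-sorted by
transcript ID so the merge sequence and leaf order are deterministic
under input permutation. Linkage and metric are package choices; only
the clustered display, not a specific linkage, is inherent to the
analysis.

Over-representation uses the one-sided hypergeometric upper tail per
gene set (members intersected with the universe first; the universe
defaults to detected transcripts, not the genome), BH across sets, and a
combined score `-ln(p) * z` where `z` is the analytic hypergeometric
z-score `(k - nK/N)/sd`. The popular web-tool variant of this score
calibrates `z` on a corpus of random input lists; the analytic form is
deterministic and corpus-free, so rankings (not the Fisher p-values) can
differ from that tool.

## Bench assays

The competitive ELISA curve is linearized as
`logit(B/B0) = a + b ln(conc)` and fitted by OLS over points inside the
assay's linear range (default 10.3–3000 pg/ml) with `B/B0 >= 1` points
excluded; a non-negative slope is rejected as non-competitive. Within
the linear range this coincides with the four-parameter logistic while
having an exact closed-form inverse; 4PL is intentionally not
implemented. Sensitivity is the concentration at 80% B/B0, midpoint at
50% (`exp(-a/b)`).

Cross-reactivity correction defaults to *dividing* the apparent
concentration by the factor (default 0.38): a 38%-reactive antibody
under-reads the RNA analyte. Because both conventions differ only by a
constant relabeling of the factor, the mode is exposed as an argument.
Between-dilution disparity is `100*(max-min)/mean` with a < 20% pass
rule; the mean denominator is a package choice since "disparity" has no
canonical definition.

Unit conversion uses the molar mass of 8-oxoguanosine (299.24 g/mol)
and an effective assay volume of 0.1505 ml per µg RNA, reconstructed
from matched nM and pg/µg readouts of the assay; both are parameters,
not constants, and the exact inverse is provided. IP efficiency is
`100*(eluted - bg)/(input - bg)` clipped to [0, 100] with a flag.
Dot-blot linearity is OLS of signal on marks with R². The RT-truncation
index is the loading-normalized distal/proximal product ratio of the
exposed sample over the control; the default call threshold of 0.8 is a
package choice — the underlying readout is only "a reduction in the
ratio". Densitometry normalization reports the loading-normalized
control/exposed fold change.

## Synthetic data

The generator emulates the targeted study design: two conditions ×
two fractions × replicates (default 3), baseline log2 means
Normal(5, 2), dispersions log-uniform on [0.01, 0.3], library factors
log-uniform on [0.5, 2]. Planted effects: 100 transcripts enriched in
the exposed IP only (log2 effects Uniform[3, 8]), 50 enriched in both
conditions with exposed-to-control linear effect ratio Uniform[1, 3]
(control effect Uniform[3, 8]), and 50 up / 50 down expression effects
(|log2| Uniform[1, 3]) applied to both fractions of the exposed
condition. The count mean is
`s_j * mu_i * 2^(e_i(cond) * [frac=rip]) * 2^(d_i * [cond=exposed])`.
The ground-truth induced set used for recovery scoring is the
exposed-only set plus the both-condition transcripts whose *true* effect
ratio exceeds the 1.5 discrimination threshold; both-condition
transcripts near that boundary are intrinsically ambiguous and account
for part of the empirical FDR.

Three replicates (not two) are the default because moments dispersion
estimation at two replicates per cell is unstable; the two-replicate
minimal design is available and its weaker recovery is characterized,
not asserted. One root seed is split into independent per-component
streams (truth, counts, gene sets, ELISA) via `SeedSequence.spawn`, so
adding a generator never shifts existing streams.

What the simulation does *not* model: transcript-length effects, GC or
sequence composition, antibody affinity heterogeneity, partial IP
efficiency and carry-over background in the rip fraction, correlated
library preparation batches, and isoform structure. Passing recovery
tests therefore demonstrate correctness of the statistical chain under
the stated NB design, not performance on any real library.

ELISA simulation draws triplicate standard readings around a planted
logit-log curve (defaults a = 3.12, b = −0.72, giving midpoint
≈ 76 pg/ml and sensitivity ≈ 11 pg/ml, inside the kit-style linear
range) with Gaussian noise on the logit scale, plus two sample dilutions
of a known concentration.

## Problem sizes and numerical choices

Simulation-based checks use 2,000 transcripts for recovery runs and
20,000 for the null-calibration run; oracle-equivalence checks use
1,000 random p-vectors (BH), 500 tables (Fisher), 100 small instances
(Wald MLE vs brute-force likelihood maximization, agreement 1e-4), and
≤ 6-point instances for linkage. These sizes give stable estimates of
the quantities being checked while keeping a full run in seconds.
Dispersion floor 1e-8; IRLS tolerance 1e-8; ties in medians use the
standard midpoint; BH uses stable sorting; all stages are deterministic
functions of their inputs and seeds.

## Known limitations

- Single two-level contrast per fit: no multi-factor designs,
  interactions, likelihood-ratio tests, or outlier handling.
- Anti-conservative raw p-values with estimated dispersions at very
  small replicate numbers (quantified above).
- The combined score is not numerically comparable to rank-calibrated
  web-tool scores.
- The fixed mean filter is cruder than optimized independent filtering;
  it is documented, monotone and deterministic.
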