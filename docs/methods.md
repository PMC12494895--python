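# Methods

This note documents the models, parameter choices and numerical policies
behind each module, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Convergence test (`convergence`)

**Model.** Mutations accumulate independently and uniformly over a gene's
selection target — its CDS plus 500 bp of regulatory sequence on each side
(target length N = CDS + 1000). Under this null, the pooled count for a
gene across all populations of one background is Poisson(λN), with
λ = total mutations / total target bp estimated per background (control
and perturbed lines separately, since their retention of mutations
differs). The model ignores linkage, clonal interference and local
mutation-rate variation; it is a screening null, not a population-genetic
model.

**Tail convention.** `poisson_tail(n, mu)` returns P(X ≥ n) via the
regularized lower incomplete gamma function, P(n, μ) — the probability of
*at least* n hits, which is the quantity the test needs (P(X ≥ 0) = 1). A
`tail="gt"` switch returns P(X > n) = 1 − Γ(n+1, μ)/n!, one pmf term
smaller; both are cross-checked in the test suite against direct pmf
summation (agreement ≤ 1e−10 for μ ∈ [1e−6, 50], n ≤ 100).

**Multiple testing.** BH step-up at α = 0.05 over the family of genes with
n ≥ 1 (zero-hit genes have p = 1 and carry no evidence; testing them only
dilutes the correction). Genes in the caller-supplied exclusion set —
typically genes already significant in the control background — are
removed *before* BH, mirroring a workflow in which control-background hits
are filtered out of the perturbed background's mutation list. Hits are
counted per mutation event by default (two mutations in one gene in one
population contribute 2); `dedup_per_population=True` counts each
(population, gene) pair once, since published pipelines are not always
explicit about this choice.

**GO terms.** The same machinery with terms as units: a term's count is the
sum over member genes, its expectation λ × Σ member N. The gene→term map is
a user-supplied flat table; no ontology is downloaded, keeping runs
deterministic and independent of database versions.

## Variant annotation (`variant_annotation`)

Categories follow a three-way rule: non-synonymous substitution in a CDS,
indel in a CDS (`frameshift_or_indel`), or position within 500 bp of a CDS
boundary (`regulatory`) count as mutations; synonymous in-CDS substitutions
are labelled and kept for the synonymous-count analysis but excluded from
the mutation set; everything else is intergenic. Substitutions are
translated codon-by-codon on the coding strand (minus-strand genes via
reverse complement); a multi-nucleotide substitution is non-synonymous if
any affected codon changes its amino acid. Ancestor subtraction matches
exact (chrom, pos, ref, alt) keys — no fuzzy indel matching, as no
tolerance convention exists to justify one. A variant inside two genes'
targets is assigned to both (conservative for gene-level counting; with the
default synthetic genome, gene targets never overlap). The minimum
read-fraction filter defaults to 0: the upstream caller's output is
trusted, and the threshold is exposed for callers that want one.

## Fitness dynamics (`fitness_dynamics`)

**Estimator.** w is the OLS slope of ln r on cumulative generations, all
timepoints unweighted, the earliest sample anchored at generation 0.
Generations per passage default to log2 of the 24 h total-count expansion
(doublings); `gen_log="e"` uses the natural log, which rescales w by
1/ln 2 and is provided because both conventions appear in practice. The
estimator is exactly linear in ln r, hence invariant to rescaling all event
counts (instrument gain, acquisition volume).

**Normalization and epistasis.** Fitness is normalized by *subtracting* a
same-condition reference (not dividing): fitness effects are treated
additively throughout, consistent with the additive epistasis definition
w_ab − (w_a + w_b). `adaptation_rate` is Δw / generations;
`recovery_fraction` is Δw / |ancestral defect|.

**Power-law fit.** w̄ = (b·t)^a + w0 with w0 fixed at the measured
ancestral fitness — freeing w0 lets the fit trade it against b on short
series. Nonlinear least squares (trust-region, bounds a ∈ (0, 2], b ≥ 0)
with multi-start over a ∈ {0.25, 0.5, 1} and b seeded from the end-point
slope; tight tolerances (1e−15) so noise-free trajectories are recovered
to ≤ 1e−6. Non-convergence is reported via a flag rather than raised —
flat or degenerate trajectories are expected in real data — and an
all-flat series returns b = 0 with a `degenerate` flag. A straight-line
fit through the same points is always reported alongside (slope and R²)
for model comparison.

## CNV analysis (`cnv`)

Fixed 100-bp windows; depths divided by the genome-wide median
(normalization is idempotent and scale-invariant); ancestor subtracted
window-wise to cancel mappability artifacts shared with the ancestor;
centered 5-window moving average with shrinking windows at chromosome ends
(no padding — averaging only observed data). Amplified segments are
maximal runs of ≥ 5 consecutive windows with difference ≥ 0.5: on the
ancestor-subtracted normalized scale a clean single-copy gain sits at
+1.0, so 0.5 is its midpoint. This run-length rule is deliberately at the
level of a visual scan plus thresholding — no HMM or circular binary
segmentation. Recurrence of amplification across populations uses the
exact binomial upper tail P(X ≥ k | n, p₀); the null probability p₀ is a
mandatory explicit parameter, with `locus_null_probability` (locus bp /
genome bp — the chance a random segmental event lands on the locus)
provided as the natural default.

## Physiology (`physiology`)

**Growth.** Rate = maximum slope of ln(OD − background) over a sliding
window of 8 consecutive points (80 min at 10-min sampling: ≥ 2 doublings
of signal at typical yeast rates while resisting single-point noise);
doubling time = ln 2 / rate; max OD from a 3-point smoothed curve. The
background defaults to 0 rather than an estimate from early readings:
subtracting the initial biomass from a pure exponential biases the early
log-slope upward, and blank correction is better done by the caller who
knows the plate layout. `background="min3"` (minimum of the first three
readings) or any float is available when the series includes a media
blank.

**Cell cycle.** The 1C peak is located on a 128-bin histogram
(prominence-filtered peaks; a 1C/2C pair is accepted when the positions
are within ratio 1.7–2.3, a lone peak is treated as 1C, and a featureless
histogram sets `gating_ok=False`). Events are gated at fixed multiples of
the 1C position — G1 below 1.5×, G2/M above 1.75×, S between. Because hard
gates assign the flanks of the S distribution to G1 and G2/M, the default
estimator unmixes the raw gated fractions assuming a uniform S bridge
spanning 1C→2C: the S density is measured in the pure-S band between the
gates, and the bridge mass falling inside the G1/G2M gates is returned to
S (fractions clipped at 0 and renormalized). This keeps recovery within
±0.03 at 10⁴ events and CV 5%; `s_bridge_correction=False` gives plain
gated fractions. Gates are config parameters, not constants. Phase
durations are fractions × doubling time, with G2/M defined as the exact
remainder so the doubling time is conserved bit-for-bit.

## Serial-dilution design (`popdesign`)

n = log2(D) generations per passage; Ne = N0 × n. The planner solves
(final/D) · log2(D) = target Ne for D on the branch D ≥ e, where Ne is
monotone decreasing in D (note the consequence: at fixed final size, a
*smaller* dilution factor yields a *larger* Ne — the bottleneck grows
faster than the generation count shrinks). Log-grid bracketing plus
bisection to relative tolerance 1e−6; targets above the attainable maximum
(final × log2 e / e ≈ 0.53 × final) raise a planning error. Bottleneck
values at specific passages are caller inputs, never hardcoded.

## Synthetic data (`synthetic_data`)

The generators produce the *marginal* statistical structure each estimator
assumes, from a single seeded `numpy.random.Generator` per call (identical
seed ⇒ byte-identical output):

- **Genome**: 2 contigs, 200 genes by default, CDS lengths log-normal with
  mean ≈ 1500 bp (codon-rounded, min 300) — small enough for seconds-scale
  tests, large enough for multiple-testing behaviour. Genes alternate
  strands and are spaced ≥ 1100 bp so regulatory windows do not overlap.
- **Variant tables**: per-gene per-population counts Poisson(multiplier ×
  rate × N); positions uniform over the target window; ~10% 1-bp
  insertions; read fractions from a two-component Beta mixture — a
  near-fixed component Beta(20, 1.5) with weight 0.7 for the perturbed
  genotype (0.3 for the control, mimicking the higher clonality of
  populations under strong selection) and a low-frequency component
  Beta(1.5, 8). These mixture parameters are plausible placeholders, not
  calibrated to any measured read-fraction distribution. The default
  layout is 12 populations × 4 glucose conditions × 2 genotypes with the
  perturbed genotype at 3.5× the control's retained-mutation rate.
- **Competition counts**: ln(ratio) grows by s_true per generation; totals
  encode the passage's doublings; `noise="multinomial"` draws integer
  counts, otherwise counts are continuous so the estimator is exact.
- **Depth tracks**: flat mean depth with an optional amplified interval at
  copy_number × depth and Gaussian noise.
- **DNA content**: Gaussian 1C and 2C peaks (2C at exactly twice 1C, widths
  ∝ position at the given CV) with a *uniform* S bridge — S-phase DNA
  content is in truth nonuniform, but no quantitative S model is assumed
  anywhere downstream, so the simplest bridge is used.
- **OD curves**: logistic growth sampled every 10 min over 48 h.

What passing tests on these data do **not** show: robustness to clonal
interference and linkage (no forward-time simulation), to mappability and
GC artifacts in depth tracks, to non-Gaussian cytometry noise or doublets,
or to mutation-rate heterogeneity along the genome. They do show that each
estimator is correct for the data-generating process it assumes, at the
study's sample sizes.

## Problem sizes used by the acceptance script

`scripts/acceptance.py` uses 500 null convergence datasets and 200
planted-gene datasets (200 genes, 48 populations each), 200 multinomial
competition assays per selection coefficient at 10⁴ events, 100 noisy
trajectories at 10 timepoints, 20 DNA-content samples at 10⁴ events, and
single noise-free CNV/growth round trips — sizes chosen to give stable
Monte-Carlo estimates (s.e. of the FDR proportion ≈ 0.007 at 500
replicates) on a single CPU.

## Known limitations

- The convergence null assumes a single genome-wide λ per background;
  genes in mutational hotspots will inflate false positives on real data.
- The CNV caller targets amplifications only (the difference-track
  threshold is one-sided); deletions would need the symmetric rule.
- The cell-cycle unmixing is tied to the two-peak-plus-bridge model; badly
  skewed or >2N ploidy histograms should be gated manually.
- The VCF reader is deliberately minimal (CHROM/POS/REF/ALT + one INFO
  tag); richly annotated VCFs should be converted upstream.
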