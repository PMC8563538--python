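# Methods

`cismr` implements a drug-target genetic-evidence workflow on GWAS summary
statistics: Bayesian colocalisation of a disease-liability signal with
cardiometabolic outcome signals at candidate gene regions, a
colocalisation-gated cis-Mendelian-randomisation (MR) analysis scaled per
halving of disease odds, and a formal contrast against a genome-wide
comparator. A synthetic-data module generates inputs with the statistical
structure the analysis assumes, so the whole pipeline is testable without any
external download.

## Colocalisation

For each variant *i* and trait *t* with estimate β̂ and standard error *s*,
the approximate Bayes factor compares a normal prior N(0, w) on the true
effect against a point null:

    log ABF = ½ [ log(1 − r) + r z² ],    r = w / (w + s²),  z = β̂ / s.

Under a single-causal-variant-per-trait model with per-variant priors p₁
(trait 1 only), p₂ (trait 2 only) and p₁₂ (shared), the five hypothesis
weights are

    H0: 1
    H1: p₁ Σᵢ e^{L1ᵢ}
    H2: p₂ Σᵢ e^{L2ᵢ}
    H3: p₁ p₂ ( Σᵢ e^{L1ᵢ} Σⱼ e^{L2ⱼ} − Σᵢ e^{L1ᵢ + L2ᵢ} )
    H4: p₁₂ Σᵢ e^{L1ᵢ + L2ᵢ}

normalised to posterior probabilities PP0–PP4. Defaults: p₁ = p₂ = 10⁻⁴,
p₁₂ = 10⁻⁵ (the method's published defaults); prior effect SD 0.2 for
quantitative traits (SD units) and 0.15 for binary traits (log-odds). All
accumulation uses log-sum-exp; the H3 cross term is a guarded log-subtraction
clamped to exactly zero when round-off would make it negative, so a
single-variant region has H3 ≡ 0. Posteriors sum to one to 10⁻⁹ and the
implementation is tested for exact (10⁻¹⁰) agreement with brute-force
enumeration over all causal-configuration pairs on small regions.

Colocalisation is declared when PP4 strictly exceeds 0.8. When the initial
run instead favours two distinct causal variants (H3 modal), a conditional
re-run masks the outcome's most likely causal variant — the argmax of its log
ABF, ties broken by smaller position then identifier — together with every
variant at r² > 0.2 against it, and the gate may then be passed on the
re-run's PP4. If masking removes every variant the result is reported as
undeterminable rather than raised as an error. Masking and clumping
thresholds are strict inequalities throughout (r² exactly at the threshold is
retained; p exactly at the threshold is rejected; PP4 exactly at the
threshold does not pass).

## Instrument selection

Cis instruments for the exposure are variants within a target gene region
with disease p < 5 × 10⁻⁶, glycaemic-biomarker p < 0.05, and a concordant
direction of effect after harmonisation to a common effect allele, thinned by
greedy LD clumping at r² > 0.1 (leads by ascending p, ties by position then
identifier). The genome-wide comparator applies identical filters outside the
target regions (flanks included). When the initial colocalisation favoured
distinct causal variants, instruments in LD (r² > 0.2) with the
outcome-specific top variant are removed as potential horizontal pleiotropy —
the same masking set the conditional re-run uses. Every filter appends its
removal count to a provenance trail; removal counts sum to candidates minus
retained. An approximate per-instrument F statistic is available for
information only; no F-based pruning is applied.

Harmonisation matches variants by identifier (position is a logged
cross-check), resolves swapped and strand-complement codings, orients
palindromic (A/T, C/G) variants by allele frequency and drops them as
ambiguous when the minor-allele frequency exceeds 0.42 on either trait.
These conventions are configurable; the defaults are widely used heuristics.
Coordinates are 1-based inclusive everywhere.

## Mendelian randomisation

Per-instrument Wald ratios rᵢ = byᵢ/bxᵢ carry first-order standard errors
se(rᵢ) = se(byᵢ)/|bxᵢ| (a second-order delta-method option adds
by² se_x²/bx⁴). IVW pools with weights wᵢ = 1/se(rᵢ)² — algebraically a
weighted least-squares fit of outcome on exposure associations through the
origin, which the tests verify to 10⁻¹⁰. Cochran's Q is computed on the same
weights and the standard error is inflated by √max(1, Q/(k−1)): multiplicative
random effects, which never deflate below the fixed-effect error. The
additive (DerSimonian–Laird) variant is deliberately not implemented.

Estimates computed per one unit *higher* disease log-odds are re-expressed
per *halving* of disease odds by multiplying by ln 2 and inverting the sign —
the one place in the package where direction is flipped, so downstream code
never reasons about orientation. Being an exact affine map it leaves p-values
unchanged; binary outcomes are additionally exponentiated to an odds ratio
with monotone CI mapping. Double application is rejected via the scale
descriptor.

The cis-vs-comparator contrast is a two-sided z-test on the difference with
se(Δ) = √(se₁² + se₂²), treating the two estimates as independent — an
approximation justified by excluding the cis regions from the comparator set.
The sensitivity analysis re-expresses the same instruments with the biomarker
association as the exposure (reported per 1 SD *lower* biomarker so
directions align with the per-halving scale) and reports the Pearson
correlation between the two sets of MR betas. A user-supplied list of
functional variants triggers additional single-variant Wald-ratio rows.

## Pipeline gating

An outcome enters MR only where it colocalises. The pooled (multi-region)
analysis requires colocalisation at *every* gene region (configurable);
outcomes colocalising at a single region receive that region's MR only. The
comparator and contrast are computed for any outcome with at least one MR
row, against the pooled estimate when available, otherwise the single-region
estimate. Every gate decision is one plain-text log line; the run is fully
deterministic given inputs and configuration, and a configuration fingerprint
(SHA-256 over thresholds, priors and input paths) is recorded with the
outputs.

## Synthetic data

The generator draws marginal summary statistics under the standard
large-sample model: for causal per-allele effects **b** and LD correlation
**R**, estimates are β̂ = **R b** + **S L z** with **L L**ᵀ = **R**,
**S** = diag(se) and z standard normal — expectation **R b**, noise
covariance **S R S**. Correlated noise is essential: distinguishing distinct
from shared causal variants is meaningless under independent noise. Standard
errors are 1/√(2 N v (1−v)) for quantitative traits (SD units) and
1/√(2 N v (1−v) φ (1−φ)) for binary traits (log-odds; φ the case fraction).
P-values are floored at 10⁻³⁰⁰ so extreme signals remain valid under the
(0, 1] invariant. LD panels are first-order autoregressive by variant index
(adjacent correlation = `decay`, default 0.9), positive definite by
construction, with one parameter controlling clumping and conditioning
behaviour; multi-locus genomes are block-diagonal (mutually unlinked loci).
All randomness flows from explicit seeds.

The default study emulates the conditions of contemporary large-scale GWAS of
diabetes liability and cardiometabolic traits: a case-control exposure GWAS
of N ≈ 1.4 million with case fraction 0.162, a quantitative glycaemic
biomarker GWAS of N ≈ 344 000, outcome GWAS of 180 000–750 000, two 50-variant
cis gene regions (labelled GIP and GIPR after the incretin-pathway target the
design mirrors) each with one causal variant of 0.15 on the disease log-odds
scale, and 20 independent 10-variant background loci with alternating-sign
disease effects of 0.12. Outcome effects are mediated through disease
liability with a per-log-odds slope of −0.25 at the target genes versus −0.1
genome-wide, so the per-halving truths are 0.25·ln 2 ≈ 0.173 and
0.1·ln 2 ≈ 0.069 — magnitudes comparable to published drug-target MR effects
on lipid and adiposity traits. The binary outcome uses a slope of 0.97,
giving an odds ratio near 0.5 per halving. One outcome carries an additional
outcome-only causal variant placed at low LD (r ≈ 0.09) with the shared
variant, exercising the conditional-colocalisation and pleiotropy-filter
paths; one outcome has no cis signal and must never pass the gate.

What the generator does *not* emulate: realistic human LD maps (AR(1) is a
stand-in, not a claim about any real locus), individual-level genotypes,
sample overlap between GWAS, ancestry structure, winner's-curse selection at
the discovery stage, and allele-frequency mismatch between studies. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to those real-data complications.

## Numerical and testing choices

- Problem sizes in the test suite and acceptance script: 50-variant regions,
  20 background loci, 200 replicates for calibration and coverage
  experiments, 100 replicates in the acceptance script's coverage block —
  enough that Monte-Carlo error is small relative to the asserted margins.
- The end-to-end coverage check asserts the pooled per-halving CI covers the
  simulated truth in 89–99% of gated runs around the nominal 95%. Instruments
  retained after clumping may still share r² up to 0.1, and their noise is
  correlated by design, so IVW's independence assumption yields mild
  undercoverage (a known property of summary-data MR with clumped
  instruments); the band accommodates that plus binomial noise at 200 runs.
- Degenerate inputs have defined behaviour: empty region extraction is
  allowed; empty instrument sets are explicit and IVW refuses them with an
  instructive error; a conditional run that masks everything is
  "undeterminable", not an exception; a single-variant region has H3 exactly
  zero.
- Tie-breaks (top variant: largest log ABF, then smallest position, then
  identifier; clump leads: smallest p, then position, then identifier) make
  every output deterministic.
- Writing the forest table uses `%.17g`; exact numeric round-trip on re-read
  requires pandas' `round_trip` float parser.

## Known limitations

Single-causal-variant colocalisation only (no multi-signal fine-mapping);
when an outcome-specific signal sits in moderate LD with a shared signal, the
conditional re-run may be unable to reveal the shared variant at high
precision. First-order Wald SEs ignore exposure-side noise (negligible for
the strong instruments selected here, optionally corrected via the
second-order switch). The cis-vs-comparator z-test assumes independence.
Only biallelic SNPs with A/C/G/T alleles are supported; no VCF parsing or
build liftover.
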