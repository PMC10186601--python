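# Methods

This note documents the statistical model, the defaults and their
rationale, the synthetic-data generator's scope, and the numerical choices
that are otherwise invisible in the API.

## Haplotype frame and counting rules

The ε alphabet is {ε2, ε3, ε4}, mapped to the two defining SNPs as
ε4 = rs429358-C/rs7412-C, ε3 = T/C, ε2 = T/T. ε1 (C/T) is excluded
everywhere: it is vanishingly rare in Europeans, and excluding it makes the
haplotype decomposition of every non-double-heterozygous diplotype unique.
ε4 and ε2 frequencies use only their defining variant (denominator = 2 ×
samples with that site called), which maximizes usable samples at low
coverage; ε3 requires both sites (denominator = 2 × both-site samples).
Double heterozygotes are unphaseable between ε2/ε4 and ε1/ε3; we resolve
them as ε2/ε4 — the only decomposition inside the three-allele frame — and
report their count (`n_ambiguous_dhet`) so the sensitivity of ε3 counts to
the alternative resolution is always assessable. With this rule,
x_ε2 + x_ε3 + x_ε4 = 2 × both-site samples exactly.

## Genotype calling and damage handling

Inputs are per-site pileup counts assumed pre-filtered to base and mapping
quality > 20. The caller maximizes the binomial read-sampling likelihood
over {AA, AB, BB} for the two most frequent observed bases with symmetric
per-read error e: P(read = B) is e, 1/2, 1−e respectively. Calls with
depth < 3 are MISSING; no pseudo-haploid calls are ever produced. The
reported QUAL is the phred-scaled complement of the genotype posterior
under a uniform prior over the three genotypes — any monotone confidence
would serve for the downstream QUAL > 50 site filter; this one is fixed and
documented so results are bit-reproducible.

Deamination trimming is operationalized as the contiguous run of terminal
positions whose C→T rate exceeds 0.05: `decide_trim` returns the smallest
m such that every position at distance ≥ m from the read end is at or
below the threshold, and `apply_trim` zeroes counts in those bins. The
pipeline estimates per-distance rates from the data itself, as the excess
terminal T fraction over the interior, scaled by the interior C fraction.

Sample filters: for allele counting, a sample is kept iff at least one of
the two focal sites has a diploid call; for the selection scans, a sample
needs chromosome coverage ≥ 0.70 (computed over the site universe present
in the input, not physical bp) and local mean depth strictly > 5.

## Supervised ancestry

With parental per-site frequencies f_A, f_B fixed, the ancestry proportion
q of one individual maximizes Σ_l log Binomial(g_l | 2, q·f_Al + (1−q)·f_Bl).
The success probability is linear in q, so the log-likelihood is concave
and the bounded maximizer unique unless f_A = f_B at every used site (then
the fit returns 0.5 with a degenerate flag). Optimization is bounded scalar
minimization to xatol = 1e-8. Parental frequencies estimated from reference
genotypes use a 0.5 pseudocount, keeping them strictly inside (0,1).
Uncertainty is a site bootstrap (sites resampled with replacement, default
B = 100; SE = SD of replicate estimates). The panel is assumed LD-pruned;
the generator emits unlinked sites, and no pruning algorithm is included.
Note that frequencies estimated from small reference panels attenuate q
toward 0.5 (error-in-variables); the pipeline default of 100 reference
individuals per parent keeps this bias below ~0.02 at divergence 0.1.

## Expectations and the deviation test

f_exp = k_A·f_A + k_B·f_B per allele; since the combination is linear, a
parental frequency vector summing to 1 yields an expected vector summing
to 1. Chains always consume the parents' *observed* frequencies — the
second step uses the first offspring's measured frequencies, not its
expectation — so each test is conditional on what the parents actually
looked like. The two-sided binomial test uses the minimum-likelihood
ordering (total null probability of outcomes no more likely than the
observed count); point estimates of k and f enter the test and their
sampling uncertainty is *not* propagated, a deliberate simplification and
a known limitation: the test is exact for the stated null but anticonservative
if k or parental f are poorly estimated.

## Selection scans

F_ST is the Weir & Cockerham (1984) two-population estimator from diploid
genotype counts with all three variance components (a, b, c; θ = a/(a+b+c)).
Sites where either population has < 2 called chromosomes, or where
a+b+c = 0 (shared monomorphism), are flagged undefined and excluded from
percentile construction. Negative estimates are retained as computed —
clamping would distort the empirical background the thresholds are drawn
from. Thresholds are linear-interpolated empirical percentiles (95th,
97.5th), and a focal site is an outlier iff strictly above the threshold.

Tajima's D follows the 1989 definition with constants a1…e2 derived from
the number of sampled chromosomes; π is computed from per-site allele
counts as Σ 2x(n−x)/(n(n−1)). Windows are half-open [start, start+L) with
L = 15 kb, tiled from origin 0 (0-based internally; VCF positions are
1-based), so a site at exactly a boundary belongs to the right-hand
window. The window phase relative to the locus is a free choice we fix at
the chromosome origin. The focal locus is a configurable set of three
consecutive windows; its summary is the mean of *defined* focal D values,
compared against the chromosome distribution (median, quartiles, 5th/95th
percentiles), with a below-median indicator reported alongside the
stronger percentile flags because a consistent below-median pattern across
populations is itself informative of old sweeps.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes and
no more:

- **Cohorts** — haplotypes i.i.d. from per-population ε frequencies;
  admixed individuals draw each haplotype from parent A with probability
  k_A. Defaults for the five-population scenario: WHG-like (0, 0.60,
  0.40), EF-like (0.08, 0.87, 0.05), Steppe-like (0.06, 0.72, 0.22);
  LF = 0.18 WHG + 0.82 EF; a modern-like group = 0.45 Steppe + 0.55 LF.
  The 0.18/0.82 late-farmer mixture is the anchor of the scenario; the
  parental ε frequencies and the second-step 0.45 are chosen to reproduce
  the qualitative European pattern (an ε2-free, ε4-rich hunter-gatherer
  group; an ε3-rich early-farmer group; intermediate later populations).
- **Pileups** — depth Poisson(mean 8 by default, a realistic order for
  usable ancient genomes); each read samples one genotype allele
  uniformly, flips to the other segregating allele with probability
  `base_error` (0.005), and terminal reads flip C→T with
  `deamination_rate` (0.15 across the 2 outermost positions; these damage
  defaults are plausible placeholders, not calibrated to any sample set).
  The chance a covered site is terminal is 2·L_damage/read_len with
  read_len 60. Counts carry per-distance annotations so trimming is exact.
- **SNP panels** — ancestral frequencies uniform(0.05, 0.95); parental
  frequencies independent Balding–Nichols draws with divergence parameter
  F, giving realized Hudson-style F_ST ≈ F; sites unlinked by
  construction.
- **Windows** — neutral windows draw S ~ Poisson(θ_w · a1(n)) sites with
  derived-allele counts ∝ 1/i (the neutral SFS, under which E[π] = E[S]/a1
  so E[D] ≈ 0); sweep windows use counts ∝ i^(−s) (rare-variant excess)
  and divide the expected S by the same skew s (diversity loss). This is a
  caricature of post-sweep coalescent structure, not a coalescent: it has
  no linkage, no recovery gradient, and its D magnitudes are not
  calibrated to any sweep strength. It is adequate for testing the sign,
  ranking and percentile behaviour of the scan, which is all the scan
  consumes.

What passing tests therefore show: the estimators and exact tests are
correct, the filters implement their stated rules, ancestry and mixing
components are recovered under the model's own assumptions, and the scans
rank sweeps below neutral backgrounds. What they do not show: robustness
to contamination, reference bias, LD between panel sites, phasing error,
or real demographic complexity — none of which the generator emulates.

## Randomness and determinism

One top-level seed drives a run; each stage derives an independent child
stream keyed by a stable hash of the stage name (`stage_rng`), so adding a
stage never perturbs another stage's draws. Reruns with identical config
and seed are byte-identical, verified via the SHA-256 manifest the
pipeline writes. The file-path fields are excluded from the config hash.

## Problem sizes

Defaults were chosen so a full run is interactive on one CPU: cohorts of
25–80 individuals (the acceptance checks use 2,000-replicate calibration,
500-replicate scan simulations, a 10,000-site recovery panel and all
~45,000 Fisher tables with total ≤ 30), completing the whole suite in
about a minute each for the tests and the acceptance script.
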