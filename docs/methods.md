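# Methods

## Problem and data

A tumor sample is a mixture of normal cells and one or more subclonal
populations, each subclone defined by a distinct set of somatic copy-number
alterations (SCNAs) and present at a cellular prevalence φ ∈ (0, 1).
`subclonemix` estimates the number of subclones K, their prevalences, and
per-segment allele-specific copy-number states from two count summaries of
a paired normal–tumor whole-genome experiment:

* per-segment read totals `D_j^N`, `D_j^T` over a tumor-genome
  segmentation (J segments);
* per-site B-allele and total read counts `(b, d)` in both samples at
  sites heterozygous in the normal genome (`I_j` sites in segment j).

All coordinates are 0-based half-open internally; 1-based-inclusive input
is converted at the file boundary.

## State spaces

**Allelic configurations H.** A configuration is an unordered pair of
parental-haplotype copy counts {a, b}, a + b ≤ max copy number (default 6;
the experiments in this repository use 3, which is the largest copy number
the bundled simulator emits). Mirror images (PP vs MM) are merged because
unphased short reads cannot distinguish them. Balanced states other than
the diploid PM (PPMM, …) are excluded: with both alleles at equal dosage
they are indistinguishable from diploid in BAF and poorly identifiable in
depth, and are rare in practice. Enumeration order is fixed (copy number
ascending, more-imbalanced class first); at max copy 3 this gives
∅, P/M, PP/MM, PM, PPP/MMM, PPM/PMM with copy numbers 0,1,2,2,3,3.

**Genotypes G.** One genotype per (copy number c, B-count 0..c) plus ∅;
at max copy 3: ∅, A, B, AA, AB, BB, AAA, AAB, ABB, BBB. The BAF of a
genotype is its B-allele fraction with boundary values clamped: 0 → ε and
1 → 1 − ε, ε = 0.01 by default, corresponding to a Phred base quality of
20 (−10·log₁₀ 0.01). ∅ is assigned BAF ½ (reads covering a homozygous
deletion come from the contaminating normal cells).

**Consistency table Q.** At a site heterozygous in the normal genome, a
genotype is consistent with a configuration iff its allele-count multiset
{b, c − b} equals the configuration's haplotype counts — every
configuration admits exactly one (balanced) or two (mirror pair)
genotypes. Inconsistent genotypes receive a small probability σ (default
0.01, configurable); the remaining mass is split equally among the
consistent ones. σ > 0 keeps every mixture term finite on noisy data.

## Likelihood

Given subclone k and configuration h, the mixture-average copy number of a
segment is C̄ = φ_k·n_h + (1 − φ_k)·2. Expected tumor depth is anchored on
the baseline segment set S (below): with per-segment mappability ratios
taken from the normal sample, λ_j = (C̄/2)·D_j^N·B where
B = (1/|S|) Σ_s D_s^T/D_s^N, and D_j^T ~ Poisson(λ_j). The
mixture-average BAF at a site with genotype g is
μ̄ = (φ n_h μ_g + (1 − φ)·2·μ₀)/(φ n_h + (1 − φ)·2), μ₀ = ½, and
b ~ Binomial(d, μ̄). The per-segment likelihood multiplies the Poisson
depth term by the product over sites of Σ_g Q_gh·Binomial terms; the full
likelihood mixes over (Z_j, H_j) with weights π_k and ρ_jh.

Numerical conventions:

* every mixture sum runs in log space (log-sum-exp);
* normalization constants (binomial coefficients, Poisson factorial) are
  **included** in reported log-likelihoods — the model-selection ratio
  |Δ/L₁| depends on the absolute value of L₁, so the convention is part of
  the method's definition here;
* λ is floored at 1e-10 (copy number 0 at φ → 1) and μ̄ falls back to μ₀
  when its denominator vanishes, keeping the likelihood finite on the
  closed parameter cube;
* φ is constrained to [0.01, 0.99]: at the boundaries a subclone is
  indistinguishable from normal background or a clonal population.

## Baseline curation

S is curated in two steps. (1) LOH filter: keep segments with ≥ 10 het
sites where at most 20% of sites have tumor BAF outside [0.35, 0.65].
(2) Depth-outlier filter, iterated to a fixed point: keep segments whose
ratio r_j = D_j^T/D_j^N lies inside the intersection of
[0.8, 1.2] × median(r) and median(r) ± 5 scaled-MAD. The adaptive MAD band
matters at whole-genome depths: the diploid ratio cluster is tight to a
fraction of a percent, while a single-copy loss carried by a
20%-prevalence subclone shifts r by only 10% — inside any fixed band a
practitioner would tolerate, yet enough to bias B and, through segments
with ~10⁶ reads, corrupt every prevalence estimate. Iterating to a fixed
point makes curation idempotent. All members of S are treated downstream
as PM with copy number 2; if curation fails the user can supply
`is_baseline` flags directly.

Known limitation: a copy-neutral LOH or shallow-loss segment carried by a
low-prevalence subclone is genuinely baseline-like (BAF shift ~0.05,
ratio 0.9–1.0) and no count-level policy separates it reliably at 60X;
such segments are rejected only when their BAF or depth signature clears
the thresholds above.

Heterozygous-site calling uses a transparent window rule rather than a
genotype-likelihood model: normal depth ≥ 10 and normal BAF in [0.3, 0.7],
both configurable.

## EM fitting

The latent variables are (Z_j, H_j); the genotype sum stays inside the
objective. E-step: γ_j(k, h) ∝ π_k ρ_jh P(segment j | h, φ_k). M-step:
π is the mean responsibility, ρ_j the segment's posterior over h (the
single-observation categorical MLE), and each φ_k maximizes its weighted
expected log-likelihood by a 100-point grid over [0.01, 0.99] (the grid
table is precomputed once per fit and reused across iterations) followed
by bounded golden-section refinement (tolerance 1e-4) around the best grid
point. The previous φ_k is always retained as a candidate, so every
iteration's observed-data log-likelihood is non-decreasing (asserted in
tests). Prevalences are reported sorted ascending, π and γ permuted to
match; ties break to the lowest index, making runs bit-reproducible given
a seed. Convergence: relative log-likelihood change below 1e-6 (default),
at most 100 iterations.

**Initialization.** With segment read totals in the millions the Poisson
term makes the likelihood basins in φ extremely narrow, and uniform-random
starts essentially never reach the global optimum. Initialization is
therefore data driven: each segment votes for the prevalence that best
explains it (the argmax over the φ grid of its own profile,
logsumexp over configurations), votes weighted by the segment's profile
range so that near-diploid segments — whose nearly flat profiles would
otherwise flood the histogram with noise votes — contribute almost
nothing. Restart 0 seeds from the weighted vote modes (greedy
mode-seeking with a 2-grid-step suppression radius), restart 1 from the
pooled-profile peak (the best single shared prevalence), and later
restarts alternate vote resampling with uniform draws. Default 10
restarts; the best final likelihood wins.

## Model selection

The model is fitted for K = 1..5 with shared options; each K ≥ 2
additionally warm-starts from the (K−1) solution with the heaviest
component duplicated or split ±0.05, which makes L_K effectively
non-decreasing in K and stabilizes the selection statistics. With
Δ = L₅ − L₁: if |Δ/L₁| < 0.01, K = 1 (no subclonal event); otherwise the
smallest i with δ_i = |L_i − L₁|/Δ ≥ 0.9 is chosen (δ₁ := 0, so the
two-sided condition "δ_i ≥ 0.9 and δ_{i−1} < 0.9" reduces to the
smallest-i rule; Δ = 0 is treated as ratio 0 → K = 1; Δ < 0 indicates an
optimization failure, warns, and falls back to K = 1). The criterion is a
heuristic guide — subclones with similar prevalences cannot be separated
by likelihood alone — and the full list of fits is returned for
inspection.

## Simulator

The bundled simulator draws directly from the generative model at the
*count* level (no reads, no aligner), so parameter-recovery experiments
test the inference machinery in isolation; real-data effects it does not
emulate — mappability and GC bias beyond the normal-depth ratio
convention, segmentation error, overdispersion beyond Poisson/binomial,
contamination of the het-site list — are deliberately out of its scope,
and passing recovery tests bound inference error only under the model's
own assumptions.

Defaults emulate a 60X whole-genome experiment on a large chromosome:
segment lengths uniform on 2–10 Mb; normal segment totals Poisson with
mean 2.4 M reads at 6 Mb (60X at 150 bp reads), scaled by length; tumor
totals Poisson(λ) with an overall tumor/normal sequencing ratio of 1;
~20 het sites per segment, site depths Poisson(60) in both samples;
normal B counts Binomial(d, ½). Half the segments are forced diploid PM
(the ground-truth baseline); the rest draw a configuration from
{P/M: 0.3, PP/MM: 0.2, PPP/MMM: 0.2, PPM/PMM: 0.3} — copy-neutral LOH is
included deliberately, being the state depth-only methods miss — and a
subclone by a shuffled balanced assignment so every subclone carries SCNA
signal regardless of seed. Genotypes at each site are drawn uniformly from
the 1–2 states consistent with the segment's configuration.

## Experiment scales

The repository's experiments use reduced but representative scales chosen
so the whole suite runs in minutes: J = 40–60 segments, max copy number 3,
site depth 60, EM with 3 restarts, 30 iterations and a 50-point φ grid.
The clonal-cohort experiment places the single population at prevalence
0.8, a typical tumor purity; the two- and three-subclone experiments use
prevalences (0.2, 0.8) and (0.2, 0.5, 0.8). At these scales the
selection statistics are far from their thresholds (ratio ≈ 0.003 vs
0.01; δ₃ ≈ 1.0 vs 0.9) and two-subclone prevalence recovery is accurate
to ~0.001.

## Known limitations

* Poisson/binomial counts have no overdispersion terms; real WGS depth
  ratios are wider than Poisson, which would loosen the selection ratio.
* Subclones closer in prevalence than the likelihood can resolve merge
  into one component; lineage information would be needed to split them.
* Balanced non-diploid states (PPMM) are unmodeled; such segments would
  be absorbed into the baseline or mis-assigned.
* The baseline policy assumes a substantial diploid-heterozygous fraction
  of the genome; heavily rearranged genomes may require manual
  `is_baseline` flags.
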