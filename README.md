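# subclonemix

Inference of tumor subclonal populations — how many there are and what
fraction of the sample each one occupies — from paired normal–tumor
whole-genome sequencing read counts.

Tumor samples are mixtures: normal cells plus one or more subclones, each
subclone carrying its own somatic copy-number alterations (SCNAs).
`subclonemix` deconvolves that mixture using two complementary count
summaries that standard point-mutation-based methods ignore, and therefore
needs no deep sequencing of somatic SNVs:

* **segment read depth** — a segment's tumor read total scales with its
  average copy number across the cell mixture;
* **B-allele frequencies (BAF)** — at sites heterozygous in the matched
  normal, allelic imbalance in the tumor reveals *which* alleles changed
  copy number, resolving states that depth alone cannot (e.g. copy-neutral
  loss of heterozygosity).

## Model

The tumor genome is partitioned into `J` segments. Segment `j` carries two
latent variables: a subclone label `Z_j ∈ {1..K}` with cellular prevalence
`φ_k`, and an allelic configuration `H_j ∈ H` (haplotype copy counts, e.g.
`PM`, `PP/MM`, `PPM/PMM`) with total copy number `n_h`. Averaged over the
cell mixture,

```
C̄_j = φ_k n_h + (1 − φ_k)·2
λ_j  = (C̄_j / 2) · D_j^N · B,     B = (1/|S|) Σ_{s∈S} D_s^T / D_s^N
D_j^T ~ Poisson(λ_j)
```

where `D^N, D^T` are segment read totals and `S` is a curated set of
diploid-heterozygous *baseline* segments that anchors the absolute depth
scale. At SNP site `i` with tumor genotype `G_ij = g` (BAF `μ_g`),

```
μ̄_ij = (φ_k n_h μ_g + (1 − φ_k)·2·μ_0) / (φ_k n_h + (1 − φ_k)·2),  μ_0 = ½
b_ij^T ~ Binomial(d_ij^T, μ̄_ij)
```

Genotypes are tied to configurations by a consistency table `Q_gh`
(inconsistent genotypes keep a small leak probability σ). With categorical
priors `π` over subclones and `ρ_j` over configurations, the observed-data
likelihood is a finite mixture over `(Z_j, H_j)` with the genotype
marginalized inside; it is maximized by EM with multiple data-driven
restarts. The number of subclones is chosen by fitting `K = 1..5` and
examining the log-likelihood increase: if `|Δ/L_1| < 0.01`
(`Δ = L_5 − L_1`) no subclonal event is declared (`K = 1`); otherwise the
smallest `i` with `δ_i = |L_i − L_1|/Δ ≥ 0.9` is selected.

## Worked example

A synthetic cohort with two subclones at prevalences 20% and 80%,
simulated from the generative model itself, then deconvolved end to end:

```python
import numpy as np
import subclonemix as sm

cfg = sm.SimConfig(J=40, phi_true=(0.2, 0.8), seed=7)
dataset, truth = sm.simulate_dataset(cfg)

baseline_ids = sm.curate_baseline(dataset)
baseline = sm.compute_baseline_scale(dataset, baseline_ids)
print(f"baseline segments: {len(baseline_ids)}   scale B = {baseline.scale:.4f}")

space = sm.ConfigSpace.build(3)
fits, sel = sm.run_selection(
    dataset, baseline, space,
    options=sm.EMOptions(seed=1, restarts=3, max_iter=30, phi_grid=50))
print(f"log-likelihoods L_1..L_5: {[round(L, 1) for L in sel.logliks]}")
print(f"ratio |Delta/L_1| = {sel.ratio:.4f}   chosen K = {sel.chosen_K}")
best = fits[sel.chosen_K - 1]
print(f"fitted prevalences phi = {np.round(best.params.phi, 3)}")
metrics = sm.score_against_truth(best.params.phi, best.map_subclone,
                                 best.map_config_labels, truth)
print(f"prevalence MAE vs truth = {metrics['prevalence_mae']:.4f}")
```

Output:

```
baseline segments: 24   scale B = 1.0000
log-likelihoods L_1..L_5: [-66928.0, -2687.7, -2687.7, -2687.6, -2687.6]
ratio |Delta/L_1| = 0.9598   chosen K = 2
fitted prevalences phi = [0.2 0.8]
prevalence MAE vs truth = 0.0003
```

Reading this: 24 of the 40 segments were curated as diploid baseline and
fix the depth scale `B ≈ 1` (equal sequencing effort in both samples).
One shared prevalence cannot explain the cohort (`L_1` is far below the
rest), two can — the likelihood is flat from `K = 2` on, so `K = 2` is
selected — and the fitted prevalences recover the simulated 20%/80%
almost exactly. Per-segment MAP subclone assignments, allelic
configurations and absolute copy numbers are in `best.map_subclone`,
`best.map_config_labels` and `best.segment_copy_number`.

The same pipeline is available from the shell:

```sh
subclonemix simulate --out-prefix demo -J 40 --phi 0.2,0.8 --seed 7
subclonemix select --segments demo.segments.tsv --snp-sites demo.snp_sites.tsv \
    --max-copy-number 3 --out-prefix demo --seed 1
```

which writes `demo.selection.json`, `demo.segments_fit.tsv`,
`demo.fit_summary.json` and the diagnostic figures (prevalence vs copy
number, log-likelihood vs K, per-segment tumor BAF histograms).

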