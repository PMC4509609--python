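# refmatch

Choosing an imputation reference panel is usually done by ancestry
intuition: CEU for Europeans, JPT+CHB for East Asians. `refmatch` makes the
choice quantitative. It measures the population-genetic distance between a
target sample and each candidate phased reference panel — Nei's G_ST and
three F_ST estimators — and relates those distances to the imputation
accuracy actually achieved, via a masking benchmark: good-quality (GQ) SNPs
are hidden, re-imputed with a haplotype-copying HMM, and the posterior
genotype distributions are scored against the hidden truth. The package is
aimed at statistical geneticists who run reference-based imputation
(MaCH/minimac/IMPUTE2-style workflows) and want a principled, pre-imputation
predictor of how well a given panel will work.

## The statistics at its core

Every distance is a two-population estimator aggregated as a **ratio of
averages**: per-marker numerator and denominator components are summed over
markers first, then divided once. With counted-allele frequencies p₁, p₂
(the counted allele is the file's REF allele, identical across populations),
sample sizes n₁, n₂ and allele counts aᵢ of mᵢ = 2nᵢ:

* **G_ST** = Σₖ(p₁−p₂)² / Σₖ 2p̄(1−p̄), p̄ = (p₁+p₂)/2 — the printed
  two-population form (twice the classical Nei value; range [0, 2]), no
  finite-sample correction.
* **F_ST^R** (Reich/Hudson-type, unbiased): N = (a₁/m₁−a₂/m₂)² − h₁/m₁ −
  h₂/m₂, D = N + h₁ + h₂, hᵢ = aᵢ(mᵢ−aᵢ)/(mᵢ(mᵢ−1)), with a 20-block
  delete-one jackknife standard error.
* **F_ST^WC** and a modified **F_ST^mWC** (Weir–Cockerham forms; see
  `docs/methods.md` for the exact components and conventions).

Imputation accuracy is scored per genotype by the **Hellinger score**
1 − √(1 − √P_g) (cut-off 0.45 ≈ "best guess is correct"), the **SEN score**
1 − |g − dose|/2 (cut-off 0.95), and best-guess concordance; and per SNP by
the truth-free **MaCH-Rsq** (dosage-variance ratio) and **IMPUTE-info**
scores. The built-in imputer is a diploid Li–Stephens haplotype-copying HMM
(forward–backward over ordered template pairs, factorized transitions,
per-allele emission error) — a transparent stand-in reproducing the
posterior-probability contract of production imputation software.

A synthetic-data module generates structured populations with controlled
divergence: Balding–Nichols independent-SNP panels (closed-form oracles for
the estimators) and founder-mosaic panels with LD, Dirichlet founder-usage
divergence, a complex-haplotype mode and platform-style missingness, so the
whole pipeline runs end to end with known truth and no external data.

## Worked example

One 40-individual target, a genetically matched and a distant reference
panel (120 haplotypes each), 2,000 SNPs with LD; mask every GQ SNP,
re-impute, score:

```python
from refmatch import qc, masking, imputer, scoring, study
from refmatch.distance import allele_count_summary, gst, fst_reich

refs, targets = study.simulate_study(seed=7, n_targets=1, n_snps=2000,
                                     ref_divergence=(0.0, 0.3))
target = targets[0]
gq, report = qc.select_gq_snps(targets)
print(f"{len(gq)} of {target.n_markers} SNPs pass the GQ filters")

plan = masking.build_mask_plan(gq, fractions=(1.0,), seed=7)
masked, truth = masking.apply_mask(target, plan, 1.0)

for ref in refs:
    st, sr = allele_count_summary(target), allele_count_summary(ref)
    d_gst, d_r = gst(st, sr), fst_reich(st, sr)
    post = imputer.impute(masked, ref)
    scores = scoring.score_genotypes(truth, post)
    print(f"{ref.panel_name}: G_ST={d_gst.value:.4f}  "
          f"F_ST^R={d_r.value:.4f} (SE {d_r.se:.4f})  "
          f"%correct={100*scores.correct.mean():.1f}  "
          f"%Hellinger>=0.45={100*(scores.hellinger>=0.45).mean():.1f}")
```

Output:

```
501 of 2000 SNPs pass the GQ filters
ref0: G_ST=0.0226  F_ST^R=0.0100 (SE 0.0014)  %correct=98.9  %Hellinger>=0.45=98.9
ref1: G_ST=0.3265  F_ST^R=0.2707 (SE 0.0075)  %correct=49.6  %Hellinger>=0.45=49.2
```

Reading it: 501 stringently filtered SNPs are treated as truth and hidden.
Against the matched panel (printed-scale G_ST 0.023 — near the
finite-sample floor of this uncorrected estimator; the corrected F_ST^R is
0.010) nearly 99 % of the 20,000 hidden genotypes are re-imputed correctly.
Against the distant panel (G_ST 0.33) barely half are — the distance knew
this before any imputation was run. Note F_ST^R sits below G_ST because it
subtracts the within-population sampling terms that inflate the printed
G_ST at these sample sizes.

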