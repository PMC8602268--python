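# mutaccum

Somatic mutation accumulation analysis for clonal genomes.

When single stem cells are clonally expanded (for example as organoids)
and whole-genome sequenced against a matched reference sample, each
clone's somatic variant catalog reports the mutations its founding cell
accumulated in vivo. `mutaccum` takes per-clone somatic VCFs and answers
the questions such studies ask:

* **How fast do mutations accumulate with age?** Mutation burden is
  regressed on donor age with a zero-intercept linear mixed model
  (`count = m·age`, patient as a random effect on the slope, since clones
  from one donor are not independent), giving a rate *m* in
  mutations/year with a 95% CI.
* **Do disease groups differ?** Two regressions are compared with
  `Z = (m₁ − m₂)/√(SE₁² + SE₂²)` (two-sided normal p), and a one-sided
  `F = var_d/var_h` test asks whether the disease regression is noisier.
  Per-context loads are compared with Wilcoxon rank-sum tests under
  Bonferroni control; Shapiro–Wilk checks are advisory.
* **What mutational processes are active?** Variants are classified into
  the standard context catalogs — SBS96 trinucleotide, DBS78 doublet,
  ID83 indel (homopolymer/repeat/microhomology), and 16 SV type×length
  categories — and per-clone spectra are refit to a signature catalog by
  non-negative least squares (min ‖Sx − c‖₂, x ≥ 0), with candidate
  signatures chosen by prevalence in a per-cancer-type exposure table.
* **Are driver genes hit?** Annotated variants are tallied per clone over
  a configurable driver-gene interval list into an oncoprint-style table.

A first-class synthetic cohort generator inverts the burden model
(clones nested in patients, linear-in-age counts with Poisson noise and
patient random slopes, spectra drawn from known signature mixtures, VCFs
placed on a toy reference) so the whole pipeline is testable with known
ground truth — no controlled-access data needed.

## Worked example

Simulate a healthy and a disease cohort at a typical study scale
(7 patients × 2 clones per group, ages 20–70, healthy rate 46 SBS/year),
fit both regressions and compare:

```python
import mutaccum as ma
from mutaccum.burden import compare_groups, summary

healthy = ma.simulate_cohort(ma.SimConfig(group="healthy", seed=42))
alc = ma.simulate_cohort(ma.SimConfig(group="ALC", seed=43))

fit_h = ma.fit_burden_regression(healthy.class_counts("SBS"), healthy.meta)
fit_a = ma.fit_burden_regression(alc.class_counts("SBS"), alc.meta)
print(summary([fit_h, fit_a], [compare_groups(fit_a, fit_h)]))
```

prints

```
Mutation accumulation regressions (zero intercept, patient random effect)
  healthy    m =    43.68 ± 3.24 /year   (SE 1.32, var 1657.1, 14 clones / 7 patients, mixed)
  ALC        m =    44.21 ± 4.54 /year   (SE 1.86, var 3330.9, 14 clones / 7 patients, mixed)
Pairwise comparisons vs reference
  ALC vs healthy:  Z =  0.233 (p = 0.816),  F =  2.010 (p = 0.111, df = 13/13)
```

Both cohorts were generated at the same true rate, and the fits agree:
the healthy estimate 43.68 ± 3.24 covers the generating 46/year, the
Z-test finds no rate difference (p = 0.816), and the one-sided F-test no
significant excess variance in the disease group (p = 0.111).

The same analysis runs from the shell on a directory of VCFs:

```sh
mutaccum run-all --config analysis.yaml --seed 11
# or stage by stage:
mutaccum simulate --outdir cohort --seed 7
mutaccum classify --vcf-dir cohort/vcf --reference cohort/reference.fa \
    --meta cohort/metadata.tsv --out spectra.tsv
mutaccum stats --meta cohort/metadata.tsv --counts cohort/counts.tsv \
    --reference-group healthy
```

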