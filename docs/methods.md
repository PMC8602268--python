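# Methods

## The model

`mutaccum` analyses somatic mutation catalogs of clonally expanded cells
(e.g. organoid clones grown from single liver stem cells), where each
clone's genome reports the mutations its founding cell accumulated in
vivo. The central quantity is the accumulation rate: how many mutations of
each class (SBS, DBS, indel, SV) a cell gains per year of donor age, and
whether that rate — or its spread — differs between disease groups.

### Burden regression

For clone *j* of patient *i* with donor age *a(i)* the burden model is

    count_ij = (m + u_i) * a_i + e_ij,   u_i ~ N(0, tau^2),  e_ij ~ N(0, s^2)

with **no intercept**: a cell is assumed to carry zero somatic mutations
at birth. "Patient" is a random effect because multiple clones per donor
are not independent; with the fixed intercept pinned at zero the random
effect acts on the age slope. Estimation is restricted maximum likelihood
via `statsmodels.MixedLM` with the age column as both fixed and random
design. Because small-cohort REML surfaces can defeat any single
optimizer (we observed silent convergence to spurious optima), each fit is
sanity-checked against the consistent zero-intercept OLS slope and
escalated through optimizers (default → Powell → Nelder–Mead); degenerate
designs (one patient, or no valid mixed fit) fall back to zero-intercept
OLS with a logged downgrade.

The 95% CI is Wald: `m ± t_{0.975, P-1} * SE` with *P* the number of
patients. Age is a patient-level covariate, so the slope's effective
degrees of freedom follow the patient count (the inner/outer rule used by
nlme-style mixed-model software); using the clone count here would
understate the interval.

### Group comparisons

Two fitted regressions (disease vs reference) are compared with

    Z = (m1 - m2) / sqrt(SE1^2 + SE2^2),    p = 2 * Phi(-|Z|)

A variant of this statistic circulates with a minus sign under the
radical; that form is not a valid variance of a difference (it can be
imaginary) and is provided only as an audit mode
(`slope_z_test(..., strict_minus=True)`). The default is the sum form.

Whether the disease regression is *noisier* is tested one-sided:

    F = var_disease / var_reference,   p = 1 - CDF_F(F; df_d, df_r)

with `df = n_clones - 1` per group (the residual variance is taken from
the regression output). Shapiro–Wilk normality checks per group are
advisory and never gate the pipeline. Per-context load differences use
two-sample Wilcoxon rank-sum tests (exact null for combined n ≤ 20
without ties, tie-corrected normal otherwise) with Bonferroni correction
over the contexts actually tested — categories empty in both groups are
excluded from the family and logged.

**Known limitation — small-sample calibration.** The Z-test's normal
reference treats the two SEs as known. With 7 patients per group the SEs
are themselves estimates with few degrees of freedom, making the test
mildly anticonservative (t-like with roughly 2(P−1) df). The calibration
suite therefore evaluates type-I error at 25 patients per group, where the
reference distribution assumption holds; the power curve is run at the
7-patient study design, where the effect sizes of interest (≥1.5× rate)
saturate power anyway.

### Context classification

* **SBS96** — trinucleotide context from the reference genome, reverse
  complemented so the reported reference base is a pyrimidine.
* **DBS78** — doublets collapsed onto the 78 canonical strand
  representatives; both bases must change.
* **ID83** — 1-bp events by pyrimidine-normalized base and homopolymer
  run length (deletions count the run *including* the deleted base, 1–6+;
  insertions count pre-existing copies, 0–5+); ≥2-bp events by size
  (2–5+) and tandem copy number of the motif; deletions with a single
  motif copy are scanned for flanking microhomology (prefix of the
  deleted sequence vs the following bases, suffix vs the preceding bases;
  the longer match, capped at length−1). The repeat scan window is 100 bp
  per side — longer scans cannot change a label because categories cap at
  5+/6+ units. Indels are consumed as left-aligned by the upstream caller
  and are not re-normalized; the double-sided scan makes labels
  insensitive to alignment anyway. Complex substitutions are excluded
  with a logged count.
* **SV16** — type (DEL/DUP/INV/TRA) × length bin. Bins are
  left-open/right-closed in bp: (1 kb, 10 kb], (10 kb, 100 kb],
  (100 kb, 1 Mb], (1 Mb, 10 Mb], (10 Mb, ∞); translocations carry no
  length and form one category. Sub-1 kb lengths fold into the first bin
  and are logged — a deterministic partition was preferred over dropping
  them.

### Signature refitting

A clone's spectrum **c** is modeled as a nonnegative combination of fixed
signature columns **S**: minimize ‖Sx − c‖₂ subject to x ≥ 0, solved by
the Lawson–Hanson active-set NNLS (deterministic, no tuning parameters).
Relative contributions divide the absolute vector by its total; all-zero
spectra are flagged rather than divided. Candidate signatures are chosen
by prevalence in a per-cancer-type exposure table: present (exposure
above a configurable floor, default 0 — matching the zero-filled
convention of pan-cancer exposure tables) in at least a threshold
fraction (default 10%) of samples of any requested type, unioned over
types. No post-hoc zeroing of small contributions is applied. DBS/SV
refitting uses the same machinery but is off by default since those
classes are typically too sparse in non-cancer clones.

## The synthetic-data generator

The generator inverts the burden model so every downstream stage can be
tested against known truth without controlled-access genomes:

| parameter | default | rationale |
|---|---|---|
| healthy slopes | 46 SBS/yr, 9 indel/yr | reported healthy-liver rates |
| DBS / SV slopes | 0.8 / 0.4 per yr | tens of events per lifetime — too sparse for signature work, matching observation |
| patient slope SD | 4 SBS/yr, 0.8 indel/yr (~9% CV) | modest inter-donor spread around a strongly age-linear trend |
| design | 7 patients × 2 clones per group | study scale |
| ages | Uniform(20, 70) years | donor span; uniform maximizes regression leverage |
| count noise | Poisson(slope_i · age) | minimal count model consistent with linear accumulation |

Patient slopes are `slope + N(0, sd)` truncated at zero, drawn
independently per variant class. SBS spectra are multinomial draws from
`S · mix` with a known mixing vector over synthetic signature columns
(sparse Dirichlet draws — well-separated, and clearly labelled synthetic,
not a published catalog). Each clone's spectrum is then *placed* on a toy
reference (default 100 kb, prefixed with every 3-mer so all trinucleotide
contexts exist) at distinct positions whose reference trinucleotide
classifies back to the drawn category; re-classifying the written VCFs
reproduces the drawn spectra exactly, which the round-trip tests assert.
Indel/DBS/SV burdens are emitted as count tables, not placed on the toy
genome.

What the generator does **not** emulate: sequencing/calling error and
filter leakage, mutation clustering (kataegis), chromatin- or
replication-timing–dependent mutation density, shared patient effects
across variant classes, and non-uniform age distributions. Passing tests
therefore validate the analysis machinery, not the robustness of the
upstream caller.

## Numerical and design choices

* Problem sizes in the test and acceptance suites: 100 cohorts for
  parameter recovery, 500 replicate pairs for null calibration, 150 per
  multiplier for the power curve, 1,000 random indels/variants for the
  oracle-agreement checks, 50 seeds × 5,000 draws for signature
  recovery. These sizes give Monte-Carlo error well inside the asserted
  tolerances.
* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence` spawning; reruns are byte-identical, which
  the pipeline manifest test asserts.
* Multi-allelic VCF rows are split per alternate allele; breakend SVs on
  the same chromosome get `|mate_pos − pos|` as length, inter-chromosomal
  mates become translocations; unknown SVTYPEs are skipped with a
  warning.
* The severity ranking in the driver tally
  (frameshift/nonsense > missense > other non-synonymous > promoter/UTR)
  is a rendering choice for the oncoprint-style table; the underlying
  records are unaffected.

## Limitations

* The mixed model assumes Gaussian residuals although counts are
  Poisson-like; at the burdens involved (hundreds to thousands) the
  normal approximation is excellent, but rates near zero (SV, DBS in
  young donors) push against it — the per-class fits for sparse classes
  should be read qualitatively.
* The F-test compares residual variances with clone-count degrees of
  freedom; clustering by patient makes this approximate.
* Consequence annotation is consumed, not computed: the driver tally is
  only as good as the upstream annotation field.
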