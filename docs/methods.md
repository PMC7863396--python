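# Methods

This note documents the models, defaults, and numerical choices behind
`dietmetab`, and what the synthetic validation does and does not establish.

## Synthetic study model

The generator emulates a three-group pediatric diet study: 24 omnivores,
10 vegetarians, 6 vegans; ages i.i.d. uniform on 1.42–7.07 years; sex
Bernoulli(0.5). These defaults are the study conditions every downstream
check assumes and are not tuned per analysis. One master seed is split into
named substreams (cohort / metabolome / biomarkers) via `SeedSequence`
spawn keys, so enabling or reconfiguring one stage never perturbs the draws
of another.

**Anthropometrics.** Each child draws independent N(0,1) height, BMI, and
MUAC z-scores, inverted through a synthetic LMS reference (smooth,
physiologically plausible preschool curves, ages 1–8 y, both sexes) to
measurements; weight is reconstructed from BMI and height. The synthetic
reference exists so the full z-scoring machinery runs without
redistributing the licensed national/WHO tables, which remain user-supplied
CSV inputs in production use.

**Metabolome.** log10 intensity of ion i in child j is

    baseline_i + σ·(√ρ·u_{b(i),j} + √(1−ρ)·ε_ij) + shift_i(diet_j)·log10(2) + β_age·age_j

with baseline_i ~ U(3, 6) (arbitrary-unit decades), residual σ = 0.25
log10 units (≈ 78% CV, the upper range of biological plus flow-injection
technical variation), exchangeable within-pathway correlation ρ = 0.3
(realistic for co-regulated serum metabolites), and planted vegan shifts on
the log2 scale; vegetarians receive the vegan shift times an attenuation
factor (default 0.5), encoding the intermediate vegetarian phenotype. The
optional age slope is in log10 units per year. Intensities are
exponentiated to the linear scale, hence strictly positive log-normals.
The default plants five affected pathways of 20 ions each among 872
(bile-acid synthesis strongly up in vegans, essential amino acids and
long-chain fatty acids down, folate and medium-chain species up, three
null pathways) — the qualitative pattern of the emulated study.

**Biomarkers.** Per-analyte Gaussian (or log-normal) draws with
group-specific means; draws above a configured assay limit are stored at
the limit with a censored flag (never dropped), so censoring logic is
exercised downstream. Default means encode the reported group patterns:
vegan RBP well below the 1.17 µmol/l insufficiency cut-off, vegan
transcobalamin-bound B12 mostly above the 128 pmol/l detection ceiling
(~2/3 censored), vegan total 25(OH)D mean 60 / SD 3.5 nmol/l (≈95% of
draws in 53–67), vegan erythrocyte folate frequently above the 972 nmol/l
reference ceiling, and no group difference in zinc. Negative normal draws
are clipped at zero (practically irrelevant at these means).

What the generator does **not** emulate: raw spectra or m/z drift,
non-collinear vegetarian effects (the vegetarian profile is by construction
a scaled vegan profile), skewed or heavy-tailed biomarker distributions,
missingness other than detection-limit censoring, and any correlation
between biomarkers and the metabolome. Passing tests therefore demonstrate
correctness of the machinery under this stylized model, not performance on
real cohort data.

## Inferential engine

The two-group statistic is the probabilistic index
PI = P(X > Y) + ½P(X = Y), computed through pooled midranks
(PI = (R₁ − n₁(n₁+1)/2)/(n₁n₂)), identical to exact pairwise enumeration
with half-weighted ties. The two-sided test statistic is |PI − 0.5|.

* **Exhaustive mode** enumerates all C(n, n₁) label splits (refused above
  2·10⁵ splits) and returns p = #{T\* ≥ T}/C(n, n₁), with ties counted ≥
  (conservative).
* **Monte-Carlo mode** draws independent uniform shuffles (duplicates
  permitted) and applies the +1 correction, p ≥ 1/(n_perm+1); the default
  47,500 shuffles make the smallest attainable p ≈ 2·10⁻⁵.
* **Covariate adjustment** (default scheme) residualizes the outcome on
  (intercept, age, sex) — a label-free fit — and uses the Freedman–Lane
  null: each permuted residual vector is re-residualized on the same design
  before ranking. The simpler shortcut of permuting the residuals as-is is
  measurably conservative when group membership is correlated with age
  (rejection ≈ 0.026 at nominal 0.05 under a +1.5-year vegan age shift):
  permuted residuals are no longer orthogonal to the design, and leverage
  shrinks the observed statistic relative to the null. Re-residualization
  restores the level (measured 0.045 confounded, 0.050 under the plain
  null). Because this null ranges over full permutations rather than label
  splits, adjusted tests are Monte-Carlo only. The stratified alternative
  permutes labels within sex × age-tertile strata on the raw values.
* **Multiplicity** is Benjamini–Hochberg, applied within each reported
  panel (anthropometrics; biomarkers; per-ion untargeted tests; enrichment
  sets) and never pooled across panels.
* Welch tests use the Welch–Satterthwaite df; Behrens–Fisher 95% intervals
  are (x̄−ȳ) ± t_df,0.975·√(s²ₓ/nₓ + s²ᵧ/nᵧ).

Analytes censored at an assay ceiling (transcobalamin-bound B12) are
excluded from probability-index testing — a point mass at the limit would
make PI an artifact of the assay — and summarized by their censored
fraction instead.

## Untargeted metabolomics

Only the [M−H]⁻ adduct is modeled (negative-mode acquisition); m/z =
monoisotopic neutral mass − 1.007276. The element mass table covers
C/H/N/O/P/S plus Na/K/Cl and is extensible. Annotation keeps **every**
compound within an absolute 0.001 m/z tolerance (isomers included — the
ambiguity is propagated, not resolved; an ambiguously annotated ion
contributes to every pathway any candidate belongs to). A 10⁻⁹ Th slack
absorbs float rounding at the tolerance boundary. Isotopologue support
checks for a partner ion at +1.003355 Th whose intensities correlate at
Pearson r ≥ 0.7 — a documented approximation to full isotope-pattern
scoring. Zeros are replaced per ion by half the smallest positive value
before any log (order-preserving); fold changes are log2 of intensity over
the arithmetic omnivore mean, so the reference mean maps to exactly 0.
Pooled metabolite classes (e.g. three medium-chain species over 24
omnivores pooling to n = 72) are summarized by box statistics only; member
ions get individual Welch tests with BH across members, and no test is run
on the pooled values because they are dependent across members.

## Enrichment

Ions are ranked by Welch t on log10 intensities (descending, ties broken
by ion id). The enrichment score is the classic weighted running sum:
members add |score|^p / Σ_members |score|^p (p = 1 by default; equal steps
if all member scores are exactly zero), non-members subtract 1/(N−N_mem);
ES is the extremum of the walk, signed, bounded in [−1, 1]. The default
null permutes **sample labels** and re-ranks all ions per shuffle —
correct under inter-metabolite correlation, which block-correlated data
certainly has — with p = (#{|ES\*| ≥ |ES|}+1)/(n_perm+1),
NES = ES / mean(|null ES| of the same sign), and BH across sets (minimum
set size 3 after intersection; smaller sets are skipped with a warning). A
metabolite-shuffling null is available behind a flag; it is faster but
anti-conservative under correlated blocks. Known limitation: with six
vegans against 24 omnivores and ρ = 0.3 blocks, the sample-permutation
null is wide enough that a single 20-ion pathway shifted by +1 log2 is
detected at q < 0.05 in roughly 80% of cohorts, not near-certainly; the
same design is detected essentially always when the block correlation is
absent. This is the price of the statistically correct null at this sample
size, not an implementation defect.

## Clustering

Participants are clustered on log10, per-ion autoscaled intensities
(constant ions dropped; an sd floor of 10⁻¹⁰ relative guards against
one-ULP "variance" in constant columns). Ward linkage is implemented via
the Lance–Williams recurrence on squared Euclidean distances with ties
broken by the smallest cluster-index pair; reported heights equal twice
the within-cluster sum-of-squares increase (the classic Ward objective),
or their square root under the "euclidean" convention flag, which
reproduces scipy's heights — the merge sequence is identical either way.
The tree is cut at k = 4 by undoing the last k−1 merges; labels A, B, …
follow first-participant order. The co-clustering validation uses a
strong-contrast scenario (±3 log2 on 60 of 100 ions in two opposing
blocks) mirroring the pronounced vegan separation the emulated study
reports; at weak contrasts the vegan/vegetarian boundary is noise-dominated
because vegetarian effects are exactly collinear with vegan ones, and the
four-cluster cut slices that continuum arbitrarily.

## Status classification

Cut-off classifiers treat the boundary as belonging to the better category
(pathology is strictly *below* a cut-off). Units are checked before any
comparison (µ/u normalized). The inflammation-adjusted vitamin A model
(linear in RBP, transthyretin, and transformed CRP; default transform
log(1+CRP); deficiency threshold 0.70 µmol/l estimated retinol) ships
**unconfigured**: its published coefficients are not reproduced here, and
the model refuses to run until they are supplied via configuration. The
taurine:glycine bile-acid conjugation ratio returns a `not_evaluable`
status, not an exception, when the glycine denominator is zero.

## Pipeline and reproducibility

`run_pipeline` executes the enabled stages in dependency order into one
run directory. Every table carries a header (tool version, master seed,
config hash — no timestamps), and `manifest.json` lists each artifact with
its SHA-256; identical config + seed reproduces every byte. Per-outcome
test seeds derive from the master seed through a dedicated substream. The
synthetic compound database written by the simulate stage assigns [M−H]⁻
identities to the first 60 ions so the annotation stage is exercised; it
is synthetic, not a curated metabolite database.

## Problem sizes used in validation

The test suite exercises reduced but structurally complete instances
chosen for tight feedback loops: 120–160-ion matrices for unit tests; the
full 872-ion, 47,500-permutation default for the end-to-end
reproducibility check; 1,000-replicate calibration simulations at the
study design (24 vs 6) with 999 shuffles; 2,000-replicate interval
coverage; 50-cohort clustering and 20-cohort enrichment power batches;
brute-force oracles at n ≤ 8 (Ward) and ≤ 10 observations (exhaustive
permutation enumeration).
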