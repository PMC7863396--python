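# dietmetab

Statistical and metabolomics analysis toolkit for small diet-group cohort
studies in children — the setting where a few dozen participants split into
omnivore (OMN), vegetarian (VGTR), and vegan (VGN) groups, and the questions
are whether circulating biomarkers, anthropometric z-scores, and an
untargeted serum metabolome differ between diets. It is written for
nutrition and metabolomics researchers who need the full analysis chain —
covariate-adjusted nonparametric group tests, accurate-mass annotation,
fold-change and pathway analysis, participant clustering, and clinical
cut-off classification — as reusable, seeded, testable code. Because
participant-level data from such studies is rarely shareable, the package
ships a synthetic-cohort generator that reproduces the statistical structure
of this design (group sizes 24/10/6, ages ~1.4–7.1 y, log-normal ion
intensities with pathway-block correlation, group shifts with the vegetarian
effect intermediate, biomarker censoring at assay limits), so every stage
can be exercised and validated end to end.

## The statistics at the core

**Probability index.** For groups A and B the test statistic is the
probabilistic index

    PI = P(X_A > X_B) + ½ P(X_A = X_B) = U / (n₁ n₂),

the Mann–Whitney U scaled to [0, 1]; PI = 0.5 means stochastic equality.
Significance is two-sided via T = |PI − 0.5| under permutation of group
labels — exhaustive over all C(n, n₁) splits when feasible, otherwise
Monte Carlo (default n = 47,500 shuffles, p = (#{T\* ≥ T} + 1)/(n+1)).

**Age and sex adjustment.** The default scheme residualizes the outcome on
(1, age, sex) — a fit that never sees group labels — and builds the null by
the Freedman–Lane construction: each permuted residual vector is
re-residualized on the same design before ranking, which keeps the test at
nominal level even when group membership is confounded with age. A
restricted-permutation alternative (shuffles within sex × age-tertile
strata) is available behind `scheme="stratified"`.

**Everything downstream.** Benjamini–Hochberg correction applied per
reported panel; Welch tests and Behrens–Fisher (Welch–Satterthwaite) 95%
CIs for fold-change comparisons; GSEA-style weighted running-sum enrichment
of metabolite sets with a sample-label permutation null (correct under
inter-metabolite correlation); Ward clustering on squared Euclidean
distances via the Lance–Williams recurrence; LMS (Box–Cox) growth-reference
z-scores z = ((x/M)^L − 1)/(L·S); [M−H]⁻ accurate-mass annotation at
absolute tolerance 0.001 m/z with isotopologue-correlation support; and
clinical cut-off classification (RBP 1.17/0.83 µmol/l, 25(OH)D 50 nmol/l,
erythrocyte folate 208–972 nmol/l, B12 censoring at 128 pmol/l).

## Worked example

Generate a synthetic study and test vegan-vs-omnivore retinol-binding
protein with the adjusted permutation test:

```bash
$ dietmetab simulate --seed 7 --n-ions 872 --out fixtures
wrote 5 files to fixtures

$ dietmetab test --cohort fixtures/cohort.csv --biomarkers fixtures/biomarkers.csv \
    --outcome rbp --groups VGN,OMN --n-perm 47500 --seed 7
outcome,PI,p_raw,n_perm,mode,n1,n2
rbp,0.013888888888888888,4.210437674996316e-05,47500,monte_carlo,6,24
```

PI = 0.014 means a randomly chosen vegan's RBP exceeds a randomly chosen
omnivore's in only ~1.4% of pairs — vegans are shifted far down, and the
Monte-Carlo p (~4·10⁻⁵) is the smallest resolvable at 47,500 shuffles.
Pathway enrichment on the same cohort:

```bash
$ dietmetab enrich --matrix fixtures/matrix.tsv --ions fixtures/ions.csv \
    --cohort fixtures/cohort.csv --sets fixtures/pathways.gmt --n-perm 999 --seed 7
pathway,es,nes,p,q,n_members,n_perm,seed
bile_acid_synthesis,0.9073982170781961,1.9260654970108226,0.002,0.016,20,999,7
essential_amino_acids,-0.7545524004541228,-1.633618177714839,0.035,0.07,20,999,7
lcfa_vlcfa,-0.8303190271145307,-1.7642336260344764,0.005,0.02,20,999,7
folate_metabolism,0.7809082723470847,1.8227038256615147,0.012,0.032,20,999,7
...
```

The generator plants a strong bile-acid perturbation and lower essential
amino acids / long-chain fatty acids in vegans; the enrichment recovers
exactly those sets (positive ES = higher in vegans), with q-values from the
sample-permutation null and BH across sets. `dietmetab run` executes the
whole chain (simulate → zscore → test → annotate → foldchange → enrich →
cluster → status) into one seeded, bit-reproducible run directory with a
manifest; `dietmetab report` joins the results into one summary table.

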