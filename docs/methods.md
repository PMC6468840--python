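# Methods

## Data model

A peak table is a feature × sample matrix of non-negative intensities keyed
by (m/z, retention time in seconds), with a two-level group factor over
samples. Missing cells are NaN and are semantically distinct from measured
zeros: the imputation step treats a zero as evidence of absence-at-noise-
floor and a missing cell as a below-detection dropout. Readers therefore
never coerce empty cells to 0, and short rows are hard errors (silent
truncation in a feature table corrupts downstream statistics invisibly).

A compound/pathway library holds compounds (id, name, elemental formula,
monoisotopic mass — computed from the formula if absent) and named compound
sets. Element masses are frozen in-code (CODATA/AME atomic masses) so every
theoretical m/z is bit-reproducible. Adduct rules map a neutral mass M to
an ion m/z = (n·M + Δ)/|z|. Arithmetic is on ions: deprotonation subtracts
the proton mass 1.00727646 Da (not the hydrogen atom mass), and cationized
adducts ([M+Na]⁺ …) subtract the electron mass explicitly. The shipped rule
table carries the common singly charged electrospray species per ion mode
plus the ¹³C isotopologue; doubly charged species are excluded by default
(small-molecule ESI data is overwhelmingly z = 1) but the table is an
editable CSV.

## Preprocessing

Default order: missingness filter (strict >50%), half-minimum imputation,
IQR filter (lowest 25% of features by intensity IQR, stable ties), sample-
median normalization (every sample's median becomes exactly 1), glog,
auto-scaling (n−1 standard deviation). Two deliberate choices:

* The missingness filter runs on the *raw* missingness mask before
  imputation. Imputing features that are about to be dropped wastes work,
  and a wholly missing feature has no defined half-minimum, so the reverse
  order is not even well-posed.
* The glog parameter λ defaults to one tenth of the smallest positive
  intensity in the table. Any positive λ gives a monotone, C¹ transform
  that is log₂-like for x ≫ λ and linear near zero; tying it to the data's
  detection floor keeps the compression of small values comparable across
  tables of different absolute scale. The chosen value is recorded in the
  run log.

Rank-based tests are invariant to monotone per-feature transforms but not
to per-sample normalization, so the pipeline returns both tables: the
median-normalized ("untransformed") table feeds the Mann–Whitney tests and
fold changes, the glog+autoscaled table feeds the latent-variable models.
The alternative median convention — rescaling by a reference median so
values keep their original magnitude — changes no test statistic and is
not implemented.

## Univariate statistics

Mann–Whitney U uses U = #{(i,j): xᵢ > yⱼ} + ½#{ties}. The two-sided p is
exact — full enumeration of all C(n+m, n) label assignments, extremity
measured as |U − nm/2| — when n+m ≤ 12 with no ties, and otherwise the
normal approximation with tie correction and a 0.5 continuity correction.
Welch's t (unequal variances) is used purely as a signed ranking score;
p-values always come from the rank test. Fold change is the ratio of group
means on the untransformed scale. The joint significance rule is
(FC > 2 or FC < 0.5) and BH-FDR ≤ 0.05 (inclusive); the raw p ≤ 0.05 rule
is exposed separately because the over-representation analysis is defined
on a raw-p feature cutoff, not on the FDR+FC volcano rule.

## Latent-variable models

The class vector is dummy-coded {0, 1} in sorted label order (so a group
swap flips score signs rather than silently re-encoding) and centered.
PLS-DA is NIPALS PLS1 (tolerance 1e-10, max 500 iterations); OPLS-DA
removes the requested number of y-orthogonal components (Trygg–Wold
orthogonal signal correction) before fitting one predictive component.
Q² = 1 − PRESS/TSS is computed over stratified k-folds (k capped at the
smaller class count), centering X and y by training-fold means; TSS is
taken about the training-fold mean of y. Permutation tests permute labels
uniformly, recompute R²Y or Q² per permutation, and report
p = (#{null ≥ observed} + 1)/(n_perm + 1): the add-one rule means p is
never 0 and its floor at n_perm = 1000 is 1/1001, matching the "< 0.001"
reporting convention. A permutation can reproduce the observed labeling
(or its complement) by chance; the add-one rule accounts for exactly this.

## Annotation

All (feature, compound, adduct) candidates within tolerance are retained;
ppm error is computed against the theoretical m/z (the denominator had to
be fixed one way; theoretical masses are exact while observed ones carry
the measurement error being bounded). Retention time plays no role in
matching — the pathway methods are mass-only — and no best-hit collapse
happens at this stage: ORA takes the set union of candidates, GSEA
collapses per compound by max |t| with ties broken toward the larger m/z.
Known caveat for users of real data: published worked examples of this
kind of annotation contain occasional inconsistencies (a printed measured
mass ~7 ppm from its claimed formula's [M−H]⁻, a "formate adduct" whose
mass gap matches acetate); the matcher does not widen tolerances or add
rules to force such matches, it simply reports what lies within tolerance.

## Pathway activity

**ORA.** Counting is at the compound level (a compound hit by three
features is still one piece of pathway evidence; feature-level counting
would triple it). Both the Fisher tail P(X ≥ n_sig) and the EASE variant
P(X ≥ n_sig − 1) are reported; EASE is the calibrated statistic because it
damps the small-pathway instability of the raw tail. The resampling null
redraws |significant features| features uniformly from all features and
re-annotates, preserving the many-to-many feature→compound structure. The
default empirical p fits a Gamma distribution (method of moments) to the
pooled −log(null EASE p) and takes its survival value — the original
mummichog's pooled-calibration idea, cheap at small n_perm. Diagnosed
limitation: the EASE null is discrete (an atom at p = 1 whenever a pathway
has ≤1 significant compound) and the Gamma's mid-range fit is approximate,
so Gamma-calibrated p-values are a well-behaved *ranking* score but can
deviate from uniformity under the null. The `calibration="rank"` mode
(per-pathway empirical rank, add-one rule) is exactly calibrated by
construction and is what the null-uniformity test exercises.

**GSEA.** Weighted KS running sum with weight exponent 1: hits advance by
|score|/Σ|score over hits|, misses retreat by 1/(N − N_h); ES is the
extremum of larger magnitude. Because the input is a single ranked compound
list (not a sample × gene matrix), significance permutes set membership:
n_perm random same-size compound sets, cached per set size. The p-value is
sign-matched — ES is compared only against null ES of the same sign — and
NES divides ES by the mean |null ES| of that sign. Pathways with fewer than
2 matched compounds are skipped with a log entry.

**Integration.** Fisher's method, X² = −2(ln p_ORA + ln p_GSEA) against
χ² with 4 df. The two p-values are not strictly independent (same data),
so the combined p is an evidence summary, not a calibrated test — which is
also its role in the two-method scatter plot, where "transformed" p means
−log₁₀. Zeros are clamped to 1/1001 with a warning; a permutation p of
exactly 0 is an artefact of too few permutations, not evidence.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
each library compound emits each adduct feature with a per-rule probability
(deprotonated/protonated ion at 0.9, satellites 0.15–0.25), observed m/z is
theoretical × (1 + ε) with ε ~ N(0, (2 ppm)²) — comfortably inside the
5 ppm matching window — intensities are log-normal (base level
lognormal(10, 0.25), per-sample noise lognormal(0, 1), i.e. ~e-fold
biological variation), group A is multiplied by 2^effect on every feature
of an active-pathway compound, uniform-m/z noise features are appended, and
cells go missing completely at random (default 10%). Defaults: 12 samples
per group, two-group design. Everything derives from one seed.

Not emulated: chromatographic peak shape, correlated adduct intensities
within a co-elution group, intensity-dependent (left-censored) missingness,
batch and drift effects, retention-time structure. Passing tests on these
tables validate the statistical machinery — filters, tests, matching,
enrichment, calibration — not raw-data processing, and real-data
missingness (not MCAR) will make half-minimum imputation more favorable
than it appears here.

`random_library` generates CHNO compound libraries with random pathway
sets (optionally disjoint, to remove between-pathway dependence in
calibration studies); masses spread over roughly 100–700 Da like a
small-molecule library.

## Study designs used by the test suite

Chosen once, as the package's own experimental designs:

* *Null calibration*: 300 compounds, 200 pathways of 50, ~3.5 features per
  compound (~1070 features), no group effect. The pathway/universe ratio is
  deliberately high so the hypergeometric contingency is densely populated;
  in a sparse design the EASE statistic degenerates to p = 1 for most
  pathways and no calibration can make a point mass uniform. Uniformity is
  checked by KS at α = 0.01 on rank-calibrated ORA p and on GSEA p.
* *Power*: disjoint 10×20-compound pathways, one active at effect 2.0 in
  log₂ (4×), over 20 seeded runs; the active pathway must rank first by
  ORA in ≥90%.
* *Complementarity*: same layout, one feature per compound (satellite
  adducts off), effect 0.55 in log₂ (≈1.46×) so that per-feature power at
  p = 0.05 is ~0.15 and at most a handful of the 20 pathway compounds pass
  the cutoff. GSEA must detect (p < 0.05) while ORA misses (p ≥ 0.05) in a
  majority of 11 seeded runs: the cutoff-free statistic sees the
  coordinated shift the cutoff discards.
* *Permutation floor*: 20+20 samples × 50 features, +3 SD shift on 10
  features; Q² permutation test with n_perm = 1000 must return exactly
  1/1001.

These sizes keep the full suite under a minute of pathway-method compute
while leaving each check's Monte-Carlo error well inside its margin.

## Known limitations

* The EASE/Gamma empirical p is a calibrated ranking, not an exactly
  uniform p (see above); use `calibration="rank"` when downstream analysis
  assumes uniformity.
* Fisher integration ignores the dependence between ORA and GSEA p-values.
* Two-group designs only; no paired tests, no multi-class models, no
  VIP-based feature selection.
* The matcher has no retention-time or MS2 evidence; annotation remains
  tentative by construction, and ambiguous candidates propagate into
  pathway counts for all their compounds.
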