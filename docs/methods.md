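# Methods

## Data model and conventions

Genotypes are alternate-allele dosages in {0, 1, 2} with a distinct
missing sentinel; a dosage of 0 always means homozygous reference, never
"no call". At candidate sites the alternate allele is the declared risk
allele from the candidate-variant table; at undeclared markers it is the
lexicographically later of the two observed alleles, a deterministic
convention for PLINK text files that carry no allele declaration. All
coordinates are 1-based and all region arithmetic uses closed intervals,
matching PLINK/VCF convention. Array files are assumed forward-strand: an
allele matching neither declared allele is an error, never silently
complemented. The two array panels a cohort may combine (170K/220K) are
read independently; no marker-set merging policy is imposed.

## Fixation screen

For each marker, genotype classes are tallied and the minor allele
frequency computed as `min(p_alt, 1 − p_alt)` over called genotypes; at
exactly 0.5 the alternate allele is reported as minor. Call-rate
filtering (default ≥ 0.90; the threshold is a config knob because no
canonical value exists) precedes every frequency computation, so regional
marker counts are reported both pre- and post-filter in the manifest.

A candidate region — an explicit window when configured, otherwise the
candidate positions ± 500 kb — is flagged *potential fixation* when its
mean marker MAF is strictly below 0.05. The strict inequality makes a
region averaging exactly at the threshold polymorphic, the conservative
direction for a screen whose positives trigger follow-up.

Reported frequencies round half away from zero to two decimals (so
9/360 = 0.025 reports as 0.03), the spreadsheet convention; full
precision is retained internally and in all statistics.

### Predictive-marker selection

An off-array candidate variant is proxied by: (i) a marker at its exact
position; else (ii) the nearest higher-coordinate ("3′" on the forward
strand) marker if within `max_downstream_bp` (default 8 000); else (iii)
the nearest lower-coordinate marker. Published variant→marker tables do
not always obey a distance cutoff, so a candidate table that carries an
explicit representative-array-location column takes precedence over the
rule; the rule serves tables without one.

## Linkage disequilibrium

Default estimator is the composite (Burrows-type) dosage correlation:
r² is the squared Pearson correlation of dosages over pairwise-complete
samples. It is phase-free and deterministic, and in the perfect-LD
configurations the haplotype collapse relies on it equals the
haplotype-frequency r² exactly. The EM estimator (maximum-likelihood
haplotype frequencies from the 3×3 genotype table, double heterozygotes
being the only ambiguous class; r² = D²/(p_A q_A p_B q_B)) is available
by flag. The two estimators coincide on perfect-LD data and converge on
data generated by random union of gametes, but they are different
statistics and can disagree on small samples inconsistent with
Hardy–Weinberg pairing — the test suite checks exact agreement only in
the perfect-LD case and close agreement on large haplotype-sampled data.

LD against a monomorphic locus is undefined and raised as an error, not
reported as r² = 0: a fixed marker carries no information, and a silent
zero would mask that. Missing data use pairwise deletion with the joint
call count recorded.

Markers joined by r² ≥ 1 − tol (tol = 1e-9) form haplotype groups as
connected components; the component rule means two markers can share a
group without a direct perfect edge (transitivity), which matches the
genetic interpretation of a shared haplotype. The representative is the
lowest-position member.

## Echo severity metrics

LVIDdN = LVIDd(cm)/BW(kg)^0.294 applies the standard canine allometric
exponent; LA:Ao is the plain diameter ratio. Both rise with age in an
aging screening cohort, so each is corrected to a common reference age
(8 years): an OLS line of metric on age gives expected(age), and
`corrected = expected(8) + observed − expected(age)`. Correcting with a
cohort-estimated line leaves the corrected values with zero OLS slope on
age (residual orthogonality) and preserves within-age rank order.

Each metric is corrected with its own fitted line by default. A config
option forces the LA:Ao coefficients onto LVIDdN for reproducing
single-equation workflows, but reusing coefficients across metrics with
different units is dimensionally implausible, so refitting per metric is
the default.

ACVIM staging: D if refractory CHF, C if CHF, B2 if murmur with
enlargement (LA:Ao ≥ 1.6 **and** LVIDdN ≥ 1.7 by default — the
consensus-guideline cutoffs, config-exposed; an *or* policy is available),
B1 if murmur without enlargement, A otherwise. Staging uses raw metrics
by default (clinical convention) while group statistics use the
age-corrected metrics; both choices are switchable.

## Association tests

Within each haplotype group or singleton predictive marker, risk-allele
homozygotes are compared with wild-type carriers. The default grouping
compares heterozygotes only, with homozygous-reference dogs reported
separately (a lone hom-ref animal would otherwise distort a two-group
contrast); a pooled-carriers mode exists.

The F statistic puts the risk-homozygote variance in the numerator,
df1 = n_hom − 1, df2 = n_comparison − 1; the reported critical value is
the upper-α quantile of F(df1, df2) at α = 0.05, and the one-tailed p is
P(F ≥ f) for f ≥ 1 else P(F ≤ f). When a rejection *rule* is needed
(e.g. the type-I-error simulation), `f ≥ f_crit` is used — thresholding
the two-sided-by-orientation p at α would double the error rate. The
means test is Welch's unequal-variance t with Welch–Satterthwaite df,
signed by (hom − comparison); report tables print its magnitude. No
multiple-testing correction is applied; the number of tests run is
recorded in the manifest. Groups with fewer than two phenotyped dogs
skip the tests with a recorded reason.

## Synthetic cohorts

The generator emulates a single-breed array screening study: biallelic
markers at Hardy–Weinberg proportions (no inbreeding coefficient is
modelled by default; real closed-breed data will show excess
homozygosity), optional perfect-LD blocks realized by copying one draw
across member markers, uniform random missingness, and echo metrics
`intercept + 0.038·age + effect·carrier + N(0, sd_group)` with
heteroscedasticity by genotype group built in — the variance contrast is
as much a finding surface as the mean contrast. Default condition is 180
dogs with a three-marker wild-type haplotype at carrier frequency ~0.017,
carrier effects −0.37 (LA:Ao) and −0.26 (LVIDdN), group SDs 0.63/0.21 and
0.46/0.16, ages ~N(10, 1.96²) years, weights ~N(8.4, 1.4²) kg, aortic
root ~N(1.45, 0.12²) cm. The LA:Ao intercept default (1.436) anchors the
risk-homozygote group mean at 1.74 at the 8-year reference age, the
screening-cohort value; note this is deliberately higher than a
healthy-reference age line (slope 0.038, intercept 1.2458, giving 1.5498
at 8 years) would predict, since a screening cohort is sicker than the
reference population such a line is estimated from. Raw LA, Ao, LVIDd
and weight are back-computed from the simulated ratios so the analysis
path genuinely recomputes them.

The deterministic fixture (`make_printed_fixture`, internal fixed seed)
mirrors a published cohort's composition exactly where counts are known —
180 genotyped/178 phenotyped, 6/17/3 wild-type heterozygotes at the
proximal/mid/distal nebulette markers (the 6 nested within the 17),
7 het + 1 hom-ref at the HDGFL1 marker, stage composition
A:3/B1:95/B2:40/C:36/D:4, sexes 80 M/98 F, 45 poor-call-rate markers in
one region — and draws per-dog metric values from stage-consistent
truncated normals around the known group summaries. Count-derived
quantities (genotype tallies, MAFs, proportions, degrees of freedom,
perfect-LD structure) are therefore exact test surfaces, while raw t/F
statistics are only statistically similar to any real cohort's: they
derive from per-dog values no summary table determines. The generator
also omits pedigree structure, LD decay with distance, and
genotype-phenotype confounding through age — passing tests show the
machinery is correct under the stated model, not that real cohorts meet
the model.

## Numerical choices

- MAF/percentage reporting rounds half away from zero; statistics round
  to 2 decimals in report tables only.
- Composite r² within 1e-12 of 1 snaps to exactly 1.0 (identical-vector
  float jitter); the perfect-LD collapse tolerance (1e-9) is orders of
  magnitude wider, so the snap cannot change grouping.
- EM iterates to a 1e-12 frequency tolerance, max 200 iterations; on
  phase-unambiguous tables it converges in one step to the counting
  estimate.
- Degenerate inputs fail loudly: zero called genotypes, monomorphic LD
  input, zero denominator variance, identical ages in the regression all
  raise typed validation errors rather than returning sentinel values.
- The analysis path contains no randomness; simulation randomness is a
  single integer seed, logged in every manifest.

## Problem sizes

The fixture runs 180 × 577 markers; property simulations use up to
10 000–12 000 replicates or dogs per check. The full suite and the
acceptance script each complete in well under a minute.
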