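# mmvdscreen

Screening of candidate disease-risk loci for allele fixation in closed dog
breeds, with genotype-stratified analysis of echocardiographic severity.

Myxomatous mitral valve disease (MMVD) is the most common cardiac disease
of dogs, and the Cavalier King Charles Spaniel (CKCS) suffers unusually
early and severe disease. Candidate risk alleles (in *NEBL*, *HDGFL1* and
other genes) have been reported as fixed in the breed. `mmvdscreen` asks,
on dense array genotypes plus echo phenotypes: are the risk alleles truly
fixed, which array markers predict the off-array risk variants, and do the
rare carriers of wild-type (reference) alleles have smaller hearts?

The pipeline, for each candidate gene region:

1. **Call-rate filtering** — markers below a call-rate threshold
   (default 0.90) are dropped before any frequency computation.
2. **Fixation screen** — per-marker minor allele frequency
   `MAF = min(p_alt, 1 − p_alt)` with
   `p_alt = (n_het + 2·n_hom_alt) / (2·n_called)`; a region whose mean MAF
   falls below 0.05 is flagged *potential fixation*, otherwise
   *polymorphic*.
3. **Predictive-marker mapping** — each off-array candidate variant is
   proxied by a marker at its exact position when one exists, else the
   nearest downstream (3′) marker within 8 kb, else the nearest upstream
   marker; an explicit representative-array-location column in the
   candidate table overrides the rule.
4. **Linkage disequilibrium** — pairwise r² between markers, by default
   the composite estimator (squared Pearson correlation of allele dosages
   over pairwise-complete samples), with an EM haplotype-frequency
   estimator (`r² = D²/(p_A q_A p_B q_B)`) available. Markers in mutual
   perfect LD collapse into a single haplotype group.
5. **Echo phenotypes** — weight-normalised LV diameter
   `LVIDdN = LVIDd(cm) / BW(kg)^0.294` and the left-atrium-to-aorta ratio
   `LA:Ao = LA/Ao`; each metric is age-corrected to 8 years by an OLS
   regression on age:
   `metric₈ = expected(8) + (observed − expected(age))`.
   ACVIM stages A/B1/B2/C/D are assigned from murmur/CHF flags and
   enlargement cutoffs (LA:Ao ≥ 1.6 and LVIDdN ≥ 1.7 for B2).
6. **Association** — risk-allele homozygotes vs wild-type carriers per
   haplotype group: a variance F-test (`F = s²_hom/s²_carrier`, df
   `n_hom−1, n_carrier−1`, upper-0.05 critical value) and a Welch
   unequal-variance t-test with Welch–Satterthwaite df.

A synthetic-cohort generator reproduces the statistical structure of a
breed screening study — Hardy–Weinberg genotypes, perfect-LD blocks,
age-trending heteroscedastic metrics — so the entire pipeline runs and is
tested without any external data.

## Worked example

Write the deterministic 180-dog study-composition cohort and screen it:

```sh
mmvdscreen fixture --out fx
mmvdscreen screen --map fx/cohort.map --ped fx/cohort.ped \
    --phenotypes fx/phenotypes.csv --variants fx/variants.tsv \
    --use-published-windows --out fx_results
```

which prints:

```
NEBL: mean MAF 0.011 -> potential_fixation
LPHN2: mean MAF 0.170 -> polymorphic
HDGFL1: mean MAF 0.033 -> potential_fixation
SORBS2: mean MAF 0.183 -> polymorphic
HTR1F: mean MAF 0.119 -> polymorphic
3 haplotype groups; 14 statistical tests; report in fx_results/
```

The proximal *NEBL* and *HDGFL1* regions show regionally depressed MAF
(risk alleles near fixation), the other three candidate regions are
normally polymorphic and screen out. The three proximal *NEBL* predictive
markers sit in perfect LD (r² = 1) and collapse to one haplotype, carried
heterozygously by 6 of 178 phenotyped dogs. `fx_results/` then holds the
report tables: `frequency.tsv` (per-marker MAFs: 0.02 at the proximal
*NEBL* markers, 0.05 at NEBL4/5, 0.01 at NEBL6, 0.03 at *HDGFL1*),
`regions.tsv`, `ld.tsv`, `adjusted.tsv` (per-dog age-corrected metrics and
stages), `comparisons.tsv` (F and Welch-t per haplotype/phenotype — the
six-dog wild-type carrier group has significantly smaller and less
variable LA:Ao and LVIDdN than the 172 risk homozygotes), `summary.tsv`
and a `run_manifest.json` with every parameter. Runs are byte-for-byte
reproducible.

The same `screen` command accepts a VCF (`--vcf`) instead of PLINK text,
or a YAML config (`--config`) exposing every threshold (MAF cutoff,
call rate, LD tolerance, staging cutoffs, reference age, α, grouping
policy).

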