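# Methods

This note documents the statistical procedures the package implements, the
choices made where the underlying design was open, and what the synthetic
data generator does and does not emulate.

## Study design being modelled

The pipeline targets the family-based candidate-gene design: a panel of
tag SNPs in one or a few genes, genotyped in (a) case–parent trios
ascertained on an affected child, (b) additional unrelated cases in one or
more clinical groups, and (c) unrelated community controls.  The concrete
template is a study of *SHANK2* (13 post-QC SNPs, chr11) and *SHANK3*
(7 post-QC SNPs, chr22) in 298 ADHD boys (256 complete trios), 134 ASD
boys, 109 comorbid boys and 232 controls; its published per-group
minor-allele frequencies and sample sizes are carried in
`trioassoc.published` and serve both as reconstruction inputs (the
aggregated allele tables are recomputable exactly to printed precision)
and as the defaults of the synthetic generator.

## Pseudo-controls (haplotype-relative-risk)

For each trio, the two parental alleles not transmitted to the affected
child form one synthetic control genotype.  We compute it on the dosage
scale as `pseudo = father + mother − child`, which is algebraically
identical to the non-transmitted-pair definition by the allele-multiset
identity and avoids the ambiguous phase assignment of the
double-heterozygote case, making the construction deterministic.
Trio-markers that are Mendel-inconsistent or incompletely observed give a
missing pseudo-genotype at that marker; the trio is kept (the alternative
— dropping whole trios — discards information and is not what the design
requires).  Downstream, pseudo-controls are pooled with community controls
as ordinary independent controls; no matched (conditional) analysis is
performed.

## Quality control

Four per-marker filters, all strict inequalities so boundary values pass:
MAF < 0.05 (all individuals), missing rate > 0.10 (all individuals),
Hardy–Weinberg exact p < 0.001, trio Mendel-error rate > 0.05.  The HWE
exact test is the classic two-sided conditional enumeration (sum of all
heterozygote configurations no more probable than the observed one; no
mid-p), computed with the stable two-directional recurrence and a relative
tie tolerance of 1e-9 so exactly tied configurations are always included.
Monomorphic markers return p = 1.  HWE is evaluated separately on the
community controls and on trio founders — never on pseudo-controls, which
are synthetic — and a marker fails if either sample is below threshold
(the conservative choice; which sample such studies use is typically not
stated).  Mendel errors are child genotypes impossible under biallelic
transmission; trios with a missing member at the marker leave the
denominator.

## Association tests

Allelic tests are Pearson χ² (df 1) on the 2×2 minor/major allele-count
table without continuity correction — with Yates' correction the strongest
reconstructed SNP no longer reproduces its printed p-value, and the
standard toolchain for such analyses defaults to the uncorrected
statistic.  Dominant and recessive models collapse genotypes with respect
to the minor (effect) allele and reuse the same machinery; "best model" is
the smallest p with ties broken allelic > dominant > recessive.  Odds
ratios are cross-products with Woolf log-scale 95% intervals
(z = 1.959964); Haldane's +0.5 is applied to all four cells only when some
cell is zero, and such results carry a `flagged` marker.  Multi-group
homogeneity uses Pearson χ² on the k×2 allele table.

Multiple testing is corrected family-wise by max-T permutation: genotype
rows (hence LD) fixed, case/control labels permuted uniformly over all
individuals — including pseudo-controls as exchangeable units, an
assumption we flag because a permutation that respected trio structure
would be slightly more conservative — and each marker's observed χ²
compared with the permutation distribution of the per-permutation maximum.
Adjusted p-values use (1 + b)/(n_perm + 1), which cannot be zero; an
exhaustive mode enumerates all label assignments exactly for small
samples and is pinned against an independent enumeration oracle in the
tests.

## Analytic power

Power of the two-sided allelic test by the two-proportion normal
approximation on allele counts.  The case allele frequency comes from
applying the per-allele odds ratio to the control allele odds
(p1 = ψ·odds0/(1+ψ·odds0)); the null standard error pools the two
frequencies weighted by allele totals; the alternative standard error uses
each group's own frequency; both rejection tails are accumulated, so ψ = 1
returns exactly α.  This formulation reproduces all four of the template
study's printed power values (90/72/36/28% at OR 1.5, MAF 0.4, α = 0.001).

## Linkage disequilibrium and tag SNPs

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM: all genotype pairs except the double heterozygote resolve to known
haplotype pairs; the double heterozygote splits between the coupling and
repulsion phases in proportion to their current expected frequencies.
Initialisation is linkage equilibrium; convergence when the largest
frequency change is below 1e-10, capped at 1000 iterations; the
log-likelihood trace is exposed and asserted non-decreasing in the tests.
r² = D²/(pA qA pB qB) and D′ = |D|/D_max follow from the fitted
frequencies; this EM-based r² (rather than the composite genotype
correlation) matches the convention of the usual LD visualisation tools.
LD is computed on the control sample by default because case LD is
distorted wherever markers are truly associated.  Tag selection is greedy
maximum-degree binning at r² > 0.8: the unassigned marker covering the
most unassigned neighbours becomes a tag (ties broken by smaller base-pair
position for determinism), its neighbours join its bin, and the process
repeats; the cited cluster principle leaves tie-breaking unspecified, so
the position rule is this package's choice.

## Gene-level combination (GATES)

`p_gene = min_j m_e·p_(j)/m_e(j)` over the ascending-sorted SNP p-values,
where m_e = m − Σ(λ_i − 1)·1[λ_i > 1] from the eigenvalues of the p-value
correlation matrix, and m_e(j) is the same quantity on the top-j submatrix.
The p-value correlation is approximated from the genotype (dosage)
correlation r by the published sixth-order polynomial (coefficients in
`gene_level.GATES_P_CORRELATION_COEFFS`); |r| = 1 is mapped to exactly 1
since perfectly collinear dosages carry the same two-sided test, which
makes the perfect-LD limit return min p exactly (the raw polynomial gives
0.98 at |r| = 1).  With an identity correlation the statistic reduces to
the Simes-type form min_j m·p_(j)/j.  Genotype correlations are estimated
on the control sample, consistent with the LD module.  The optional
gene-level permutation p applies the same label-swapping scheme to the
gene statistic with the correlation matrix held fixed at its observed
control estimate — an interpretation, since gene-level permutation schemes
are generally undocumented in this design; it is off by default.  Because
gene-level reference values require the original individual genotypes,
this module is validated by its limiting cases and null calibration, not
by number-matching.

## Synthetic cohorts

Haplotypes are drawn from a latent-Gaussian (copula) threshold model:
within each LD block the latent variables follow an AR(1) process with
correlation ρ (default 0.8) between adjacent markers; blocks are
independent; thresholding at Φ⁻¹(MAF) gives the minor-allele indicator.
The implied pairwise r² has a closed numeric form (bivariate-normal
orthant probability), used as an oracle in the tests.  This choice — a
copula rather than a coalescent simulator — is sufficient to exercise EM
LD estimation, tag binning and correlation-aware gene combination, and its
LD is directly controllable; it does not attempt recombination maps,
mutation, population structure or sex linkage.

Disease risk is logistic and log-additive in minor-allele dosage with
baseline prevalence 0.05 — low enough that odds ratios approximate
relative risks, the reading such studies themselves adopt; the template
study states no prevalence, so this is a package default.  Default
per-allele odds ratios are the template study's six published significant
ORs (0.720–1.275) with all other markers null, and the default panel uses
the published control-group MAFs (0.29–0.49) with one block per gene.
Case/control sampling is rejection sampling from the pool; trios draw two
parents from the pool, transmit one uniformly chosen haplotype each, and
ascertain on an affected child when requested — so simulated trios are
Mendel-consistent by construction and founders are in HWE.  Every
stochastic operation takes an explicit seed and is reproducible.

What passing tests on these cohorts shows: correct mechanics, calibrated
type-I error, and parameter recovery under the model's own assumptions.
What they cannot show: robustness to genotyping artefacts, population
stratification, non-random missingness, or real human LD patterns.

## Problem sizes and numerical choices

The test suite uses pools of 2,000–200,000 haplotypes, up to 20,000
simulated trios for transmission-distortion checks, 2,000 replicates for
null-calibration checks (tolerance ±2 binomial standard errors), and 100
seeds at 5,000+5,000 individuals for odds-ratio recovery; the exhaustive
HWE cross-check covers every genotype table with n ≤ 50 at 1e-12.
Pipeline-level replicate tests run at reduced permutation counts
(n_perm = 300) since the permutation estimator's Monte-Carlo error, not
the pipeline logic, is what larger counts refine.  Degenerate inputs are
flagged rather than fatal throughout: empty table margins give undefined
results, monomorphic markers give r² = 0 and HWE p = 1, and
Mendel-inconsistent trio-markers become missing pseudo-genotypes with a
logged warning.

## Known limitations

- Pseudo-control exchangeability in the permutation ignores the trio
  origin of half the control sample.
- The power formula is a normal approximation on allele counts; it has no
  finite-sample continuity adjustment.
- The latent-Gaussian LD model produces smooth monotone decay within
  blocks, not the patchy hotspot structure of real haplotypes.
- X-chromosome dosage rules, multi-allelic markers and binary PLINK
  formats are out of scope.
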