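# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the conventions of the field leave room.

## Genotype calling and locus filtering

Targeted genotyping panels report per-allele read depths per individual and
locus. Calling is depth-thresholded diploid calling: alleles with depth
below `min_allele_count` (default 8 reads) are treated as absent — the
threshold exists to exclude alleles created by sequencing error, and the
boundary is inclusive (depth = 8 is retained; the operational rule is
"fewer than eight reads is missing"). A cell with one retained allele is a
homozygote, two a heterozygote, none missing. Cells where three or more
alleles pass the threshold are set missing and counted for audit rather
than discarding the locus: such cells isolate a sequencing-error artefact
without losing the marker.

Loci are classified by the union of retained alleles across all individuals
(monomorphic / bi- / tri- / tetra-allelic). Only biallelic loci are
analysed; among them, loci with a missing fraction ≥ `max_missing_fraction`
(default 5%, strict inequality retained) are removed. Class percentages are
rounded to one decimal in reports. Tetraploid samples are deliberately
genotype-called as diploid — any mixed tetraploid genotype becomes a
heterozygote call — which is the single modelling decision that produces
the strongly negative F_IS of tetraploid accessions downstream.

## Diversity estimators

Per locus, over the s populations with at least two called individuals
(populations below that drop out of that locus pairwise, not listwise),
with ñ the harmonic mean of per-population called sample sizes:

    H_O = (1/s) Σ_s het_s
    H_S = ñ/(ñ−1) · (1 − (1/s) Σ_s Σ_a x²_sa − H_O/(2ñ))
    H_T = 1 − Σ_a ((1/s) Σ_s x_sa)² + H_S/(ñ·s)

These are the bias-corrected Nei–Chesser estimators; the formulas are fixed
exactly as written so that results are bit-reproducible and testable
against an independently coded direct-summation oracle (agreement to
1e-10 is enforced in the tests). Components are averaged over loci and the
fixation indices are ratios of the averages (F_IS = 1 − H_O/H_S, F_ST =
1 − H_S/H_T, F_IT = 1 − H_O/H_T) — ratio-of-averages, not
average-of-ratios, the convention of this estimator family. Per-accession
F_IS with H_S = 0 (accession monomorphic at every locus) is reported as
NaN, never as 0. %PL counts a locus polymorphic when both alleles are seen
at least once within the accession; no minor-allele-frequency floor is
applied.

Two estimator consequences worth knowing: identical populations give a
small *negative* F_ST of order −1/n (the price of unbiasedness), and H_T
carries the H_S/(ñs) correction term, so H_T ≠ H_S even without
differentiation.

## AMOVA

Each diploid individual is expanded into two pseudo-haplotypes
(heterozygote → one reference + one alternative copy; phase arbitrary —
the squared distance counts per-locus allele differences, so all results
are phase-invariant, which a test asserts). The squared distance between
haplotypes is the number of co-called loci with differing alleles
(pairwise-complete over missing data).

Variance components come from the standard three-stratum method-of-moments
equations on sums of squared distances, with the unequal-sample-size
coefficients n', n'', n'''. Two designs share this machinery:

* ungrouped — groups = accessions, populations = individuals, units =
  haplotypes; strata: among accessions / among individuals within
  accessions / within individuals; indices F_ST = V_a/V_tot,
  F_IS = V_b/(V_b+V_c), F_IT = (V_a+V_b)/V_tot;
* grouped (origin / type / ploidy / custom) — groups = accession groups,
  populations = accessions; indices F_CT, F_SC, F_ST analogously.

Negative components are reported as estimated. Permutation schemes per
stratum: (1) whole populations among groups (ungrouped: whole individuals
among accessions); (2) units among populations within groups (ungrouped:
haplotypes among individuals within accessions); (3) units among
populations across groups. p = (hits+1)/(n_perm+1), upper tail of the
corresponding index; under heterozygote excess the F_IS p-value is
therefore ≈ 1 by construction. Degenerate designs (a single population per
group) yield NaN components and p-values, flagged rather than fabricated.

## Distances, trees, ordination

*Nei distances.* D = −ln(J_xy/√(J_x·J_y)) with locus-averaged gene
identities; the unbiased variant replaces J_x, J_y per locus by
(2n·J − 1)/(2n − 1). Pairs with no informative shared loci are flagged;
J_xy = 0 yields +inf, flagged.

*Pairwise F_ST.* The two-population version of the diversity estimators,
computed on each pair alone; negative estimates are floored at zero for
reporting (raw values retained); significance by permuting individuals
between the two accessions.

*Neighbor joining.* Classic Saitou–Nei agglomeration. Ties in the Q
criterion break to the lowest (row, column) pair in the current order, so
degenerate (e.g. equidistant) inputs are deterministic. Negative branch
lengths are clamped to zero with the deficit moved to the sibling branch,
preserving leaf-to-leaf path lengths; the number of clamped branches is
recorded. Accession trees use the Nei unbiased matrix; individual trees
use TN93, mirroring the two levels at which such surveys are analysed.

*TN93.* Individuals are spelled as pseudo-sequences over the SNP loci:
homozygous reference → reference base, homozygous alternative →
alternative base, heterozygous or missing → excluded pairwise. Excluding
heterozygous sites (rather than IUPAC fractional counting) is a documented
assumption — the handling is not standardised for SNP pseudo-sequences.
Base composition is estimated per pair from the compared sites. Saturated
pairs (log argument ≤ 0) are +inf and flagged; pairs with fewer than 10
comparable sites are flagged unreliable. The closed form reduces to
Jukes–Cantor under equal base frequencies and evenly spread substitutions
(a limit test enforces this at 1e-9).

*PCoA.* Classical metric scaling: double-centre −d²/2, eigendecompose,
scale eigenvectors by √λ. Negative eigenvalues (non-Euclidean input) are
excluded from the percent-variance denominator and reported separately;
requesting more axes than positive eigenvalues truncates with a warning.

*DAPC.* Dosages are mean-imputed per locus (≤5% missingness makes this
benign), centred but not scaled — dosage variance is informative. PC
retention by stratified k-fold cross-validation of LDA assignment accuracy
(ties → fewest PCs); de-novo clusters by k-means on PC scores with
BIC(k) = n·log(WSS/n) + k·log(n); posteriors from the LDA model;
per-accession membership = mean posterior over its individuals (rounded to
the nearest 10% only in the report view). Both entry points — de-novo
clusters and prior accession labels — are exposed; the pipeline falls back
to prior labels when the BIC search selects k = 1, which is the expected
outcome under a plain island model with no hierarchical structure.

## Hardy–Weinberg tests

The exact test uses the conditional (Levene/Haldane) distribution of the
heterozygote count given the allele counts, in exact rational arithmetic so
the two-sided tail (total probability of outcomes no more probable than
the observed) involves no floating-point tie ambiguity; the test suite
checks exact equality against an exhaustive allele-placement enumeration.
Direction (excess/deficit) compares the observed heterozygote count with
its conditional expectation n_a·n_b/(2n−1). A Metropolis chain over the
heterozygote-count states (default 1,000,000 steps after 100,000
dememorization steps) is provided as a validation mode; for biallelic data
the enumeration is always cheap and is the default. The scan runs on the
pooled sample for headline counts — pooling across differentiated
accessions means Wahlund effects are part of what the pooled test sees —
and a per-accession view is produced alongside, since the level at which
such tests are reported varies between studies.

## fdist outlier scan

Observed per-locus F_ST (1 − H_S/H_T per locus) and heterozygosity (H_S
scale, the conventional conditioning axis) are compared with the joint
neutral distribution under a non-hierarchical finite island model
(default 100 demes, a conventional setting; configurable). The scan:

1. computes the observed mean F_ST (ratio of locus-averaged components);
2. calibrates the scaled migration rate M = 4Nm by geometric bisection
   until simulated mean F_ST matches, within 0.003, using 800 loci per
   evaluation (bracketing failure raises with diagnostics);
3. simulates `n_simulations` (default 20,000) independent biallelic loci:
   each is one single-mutation coalescent genealogy of the observed
   deme/sample configuration embedded in the island model, with the
   mutation dropped uniformly on total branch length;
4. assigns each observed locus the empirical tail quantile of its F_ST
   among the `bin_size` (default 500) simulated loci nearest in
   heterozygosity, with the (hits+1)/(k+1) correction; the upper tail is
   the "under selection" flag, and the lower tail is reported alongside.

The island-model sampler is purpose-built (`cloverpop.island`): because
only the per-deme descendant counts of one uniformly placed mutation are
needed, it tracks deme occupancies and per-lineage descendant-count
vectors through the structured coalescent and reservoir-samples the
mutated branch — O(events) per locus, no genealogy construction, ~5 ms per
locus at the 290-sample design. Its distribution is cross-checked in the
tests against msprime's island-model coalescent on a small configuration.
Derived alleles are assigned to haploid slots uniformly within demes
(lineage exchangeability) and paired into individuals, emulating random
union of gametes.

Type-I calibration is enforced in the acceptance tests: on a fully neutral
island-model cohort at the study scale, the fraction of loci with
upper-tail p < α matches α within two binomial standard errors for
α ∈ {0.01, 0.05}.

## Variant-effect classification

For each CDS the longest ATG-initiated ORF is found over the three forward
frames (inputs are CDS-oriented; a six-frame option exists); "longest" is
measured in nucleotides including the stop codon, ties break to the
smaller start then the smaller frame index, and an ORF without an
in-sequence stop extends to the last complete codon. The ORF is translated
(standard code, table 1) with the reference and the alternative allele:
identical proteins → same-sense; a stop introduced before the reference
stop → nonsense; any other amino-acid change → missense (this includes the
rare stop-loss case); a variant outside the longest ORF → noncoding.

## The synthetic cohort: what it emulates, what it does not

`SimulationConfig` defaults define the emulated survey: 29 accessions × 10
plants (290 individuals), 400 targeted + 296 de-novo biallelic loci,
island-model differentiation F = 0.05, four tetraploid accessions placed
last (collapsed to diploid coding), mean coverage 500×, per-read error
0.009, 3.75% of target loci monomorphic, 5% of loci with near-zero capture
efficiency. Population frequencies follow the Balding–Nichols law — for
ancestral frequency p (uniform on [0.05, 0.95]) each population draws from
Beta(p(1−F)/F, (1−p)(1−F)/F), mean p and variance F·p(1−p) — chosen
because F is an explicit, recoverable parameter: the acceptance tests
verify the estimated F_ST lands within ±0.015 of F and diploid F_IS within
±0.03 of 0 at the design scale over 20 fixed seeds. Read depths are
Poisson; each read is drawn from the individual's true allele proportions
and with probability `error_rate` substituted by a uniformly random other
base, which is what creates spurious third/fourth alleles at deep
coverage. The error rate of 0.009 was chosen so that, under the ≥8-read
threshold, roughly 8–10% of loci acquire a spurious allele somewhere in
the sample — the error-driven multi-allelic fraction characteristic of
this assay class; the near-zero-coverage locus fraction likewise emulates
uneven capture efficiency and supplies the missingness that the <5% filter
acts on.

Deliberately not emulated: linkage disequilibrium between loci (loci are
independent; such panels choose well-spaced SNPs in distinct genes),
hierarchical population structure or admixture clines (all accessions are
exchangeable island-model demes, so de-novo cluster searches correctly
find k = 1), allele-frequency spectra of real ascertainment (the uniform
ancestral law yields higher average heterozygosity than a
mutation-drift spectrum), genotyping batch effects, and true tetraploid
allele dosage. Passing tests therefore demonstrate estimator and pipeline
correctness under the stated generative model — not robustness to
admixture, LD or ascertainment bias in real panels.

CDS fixtures are synthetic sequences (random non-stop codons between ATG
and a stop, pyrimidine-only UTR padding that cannot introduce competing
start codons) with one variant each whose effect class is forced via the
genetic code; the classifier must recover 100% of the labels.

## Reproducibility and problem sizes

One master seed drives everything; each stage derives a child seed from
the master seed and the stage name (SHA-256, < 2³¹), so any stage re-run
in isolation reproduces its slice of a full run. Identical seed + config →
byte-identical outputs; every table carries the config hash and seed in
its header, and the genotype stage is reused from disk when the hash
matches. Default analysis sizes: 1000 AMOVA permutations, 200 permutations
per pairwise-F_ST cell, 8000 fdist replicates in the drivers (the scan
accepts 20,000; the p-value floor at bin size 500 is 1/501 either way),
800 calibration loci per bisection step. The test suite and the acceptance
script use these or smaller sizes, chosen so Monte-Carlo error stays well
inside the tolerances they assert.

## Known limitations

* Pairwise F_ST p-values are raw; no multiple-testing correction is
  applied anywhere (by design — the flags are per-locus screens).
* The fdist null conditions on the realised mean F_ST; with few loci the
  calibration error propagates into tail quantiles.
* TN93 on SNP-only pseudo-sequences overstates divergence per site
  (every locus is polymorphic by ascertainment); the trees are valid as
  relative topology, not as evolutionary time.
* The AMOVA haplotype expansion assumes diploid coding throughout —
  tetraploid accessions are analysed under the same collapse rule as
  everywhere else in the pipeline.
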