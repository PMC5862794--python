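# Methods

This note documents the models, decision rules and numerical choices
behind `herdqc`, and what the simulation-based tests do and do not show
about real data.

## Genotype coding

All genotypes are integer-coded `2 = AA`, `1 = AB`, `0 = BB`, `9 =
missing`, aligned to a `SnpMap` sorted by (chromosome, position).  The
coding doubles as the numeric-string encoding used by the duplicate
search, so a call vector renders directly as a string such as
`001290021`.  AB-allele input is coded without strand handling (AB is
strand-free); TOP-nucleotide input is converted through explicit per-SNP
`top_a`/`top_b` columns in the SNP map, and the converter refuses to
guess when those are absent.

## Genotype QC

Four checks, all of which must pass before a genotype is used anywhere:

| check | rule | boundary |
|---|---|---|
| animal call rate | non-missing / usable SNPs >= `animal_cr_min` | **0.90, inclusive** |
| usable SNP | per-SNP cohort call rate >= `snp_cr_min_for_use` | 0.85 |
| genotype classes | AA, AB and BB all observed | — |
| format purity | allele symbols within the declared alphabet | — |
| class frequency | min(fAA, fAB, fBB) >= `geno_class_freq_min` | **0.20, fail strictly below** |

The usable-SNP mask is recomputed from the supplied cohort rather than
frozen from a database, since the package has no national database
behind it.  Class frequencies are computed over all non-missing calls
including chrX; on genome-wide chips the chrX contribution is negligible,
and an `autosomes_only` restriction is available through the SNP-map
index properties for users who want it.  The rationale for the 20% rule
is empirical: across a large QC'd population essentially no real sample
has a genotype class that rare, so a low class frequency flags a
technical artifact (wrong clustering, mixed sample) rather than biology.

## Parentage

A duo "mismatch" is an opposing-homozygote site: one animal AA, the other
BB.  This is the only Mendelian impossibility testable without the second
parent and is the standard exclusion statistic.  Decision rule on the
800-SNP panel:

* `<= 4` mismatches (0.5%) — validated;
* `>= 13` mismatches (1.5%) — failed;
* 5–12 — gray zone, re-checked on all shared **autosomal** SNPs; the
  parentage validates iff the full misconcordance rate is `<= 1%`.

The bounds are absolute counts even when fewer than 800 panel SNPs
overlap (`n_compared` is reported so users can audit); at least 600
shared panel calls are required for any verdict.  The gray-zone
boundaries place 4 mismatches on the validated side and 5–12 in the gray
zone, matching the observed distribution of validated parents (which
includes 4-mismatch cases).

The full-SNP re-check uses autosomes only.  chrX cannot enter a duo
test without conditioning on the pair's sexes and direction: a
hemizygous male call is coded homozygous, so a sire and his son are
*legitimately* opposite homozygotes at any nPAR X SNP where the son's
maternal allele differs — roughly `2pq` per SNP, enough to push a true
sire's rate over 1%.  chrY yields no calls in females.  Restricting to
autosomes preserves the exclusion logic the rates were designed for.

Whole-database parent prediction builds a candidate table (one genotype
per animal — most panel calls wins, newest genotyping date breaks ties;
animals under 600 panel calls excluded) and scans every other row with
early termination once a candidate exceeds 12 mismatches.  The scan is
chunked over SNPs, so eliminated candidates stop accumulating work; the
surviving candidate set is provably identical to an exhaustive count and
a test verifies this against the brute-force scan.  Survivors must be at
least 15 **calendar months** older than the target (a parent was at
least 6 months old at conception plus 9 months of gestation — this also
removes the target's own genotyped progeny, which would otherwise match
perfectly) and of the role-appropriate sex.  Batching is treated purely
as checkpointing: results are independent of batch size by construction.

Mating validation counts Mating SNP Misconcordances — calf AB while both
validated parents are homozygous for the same allele — over panel SNPs
with all three genotypes present; trios above a 1% MSM rate are flagged.
A high-MSM trio with two individually validated parents is the signature
of a swapped dam/calf sample pair.

## Duplicate detection

The panel string is cut into non-overlapping blocks (default 20 SNPs =
40 blocks; the legacy 50-SNP/16-block size is kept for comparison) and
exact within-block string matches generate candidate pairs.  Missing
(`9`) must match `9` byte-for-byte — this is deliberate: heavy random
missingness is exactly what defeats larger blocks, and the package
reproduces that failure mode (a pair with one spoiled site per 50-SNP
block is invisible at 16×50 and found at 40×20).  Candidates are
confirmed by SNP-by-SNP identity with missing sites excluded, first on
the panel, then on all shared SNPs; both identities must reach 0.99.
Confirmed duplicates between different animals are held `unresolved` for
animal QC — except pairs consistent with identical twins (same dam, DOB
within 7 days), which are labelled and left valid, twins being the one
genuinely unresolvable case.  Repeat genotypes of the same animal use the
same machinery with the conflict condition inverted: a pair under 99% on
both tiers indicates the genotypes are not from one animal.

## Sex prediction and the PAR

chrY SNPs only yield calls in males.  With the 7-SNP chrY set: 0–1 calls
female, 6–7 male, 2–5 ambiguous; for chips with a different chrY count
the cutoffs scale proportionally (floor(n/7) / ceil(6n/7)).  The chrX
verdict uses the non-PAR heterozygosity rate `#AB / (#AA+#AB+#BB)`:
<= 5% male, >= 15% female, between ambiguous.  At least 20 non-PAR calls
are required for an X verdict — highly inbred females can look male on
too few SNPs.  Verdict combination: agreement or a single informative
verdict wins; two ambiguous verdicts stay ambiguous; opposite definite
verdicts are a conflict for manual review (X0/XXY karyotypes, or a
sex-sorted-semen sample).

The PAR is located empirically from animals of known sex: chrX SNPs
failing MAF >= 0.01 or call rate >= 0.90 are excluded, SNPs with male
heterozygosity >= 0.05 are PAR-like (diploid in males), and the PAR
interval is the longest contiguous positional run of PAR-like SNPs.  The
0.05 male-het threshold and longest-run smoothing are this package's
choices; male het in the true PAR (~24%) and nPAR (~0.2%) is separated by
two orders of magnitude, so the classification is insensitive to the
exact threshold.

## Breed composition

Supervised admixture with fixed frequencies: the reference allele-A
frequency matrix `P (J x K)` is estimated from animals listed purebred
(32/32) in a reference breed, smoothed with half a pseudo-allele
(`P = (count_A + 0.5) / (2n + 1)`) so no entry reaches 0 or 1 and
off-reference animals never produce zero likelihoods.  Autosomal SNPs
only; breeds below a minimum purebred count (default 25 at desk scale;
production references use 500–2,000 per breed) are dropped because they
predict poorly.  An animal's genotype is modelled as
`g_j ~ Binomial(2, sum_k q_k P[j,k])` and `q` is maximised on the simplex
by EM — with `P` fixed the log-likelihood is concave in `q`, the EM step
is the standard fractional allele attribution, and the likelihood is
non-decreasing every iteration (asserted in tests).  Convergence:
relative log-likelihood change below 1e-7 or 2,000 iterations.

The listed-vs-predicted comparison flags only gross conflicts (any
breed's fractions differing by more than 0.40, e.g. listed 100% of one
breed but predicted 100% of another); the 0.40 tolerance is a package
default, since only the categorical example is specified upstream.
Listed breeds absent from the reference make the comparison unevaluable:
such ancestry is predicted as a spurious mixture of reference breeds.  A
pedigree animal with a breed mismatch has its genotype invalidated;
other animals are flagged.  Reference PCA (mean-imputed, centered, SVD)
is provided as a diagnostic for stray reference animals and plays no
role in decisions.

## Animal QC and conflict resolution

Every sample runs the full battery before any decision: duplicates,
multi-genotype reconciliation, sex, breed, parentage, offspring pattern,
post-death flag.  No single check invalidates a genotype except the
pedigree breed mismatch; a confirmed duplicate or multi-genotype
conflict holds both genotypes invalid pending resolution.  Offspring
patterns: a dam with >= 2 genotyped offspring all failing, a stock bull
with >= 5 and >= 80% failing ("80%" read as >= 80%, consistent with the
other floors), or an AI sire with >= 10 and >= 80% failing is flagged;
when such a genotype is invalidated, parentage verdicts that used it are
reset.  Tissue collected more than 45 days (strictly) after recorded
death draws a warning flag, with AI straws exempt.

Conflict resolution evaluates both possible attributions of two
genotypes to two animals against evidence in fixed priority: parentage
validation against each animal's listed parents, offspring validation,
sex vs recorded sex, breed vs listed composition, herd co-residence
(never co-resident is logged as a lab-error hypothesis).  Attribution is
made iff exactly one assignment has no contradicting evidence and at
least one supporting item; otherwise both genotypes stay unresolved.
Geographic plausibility is implemented as herd co-residence only — the
data model carries no coordinates.

## The simulator

`simulate.simulate_herd` gene-drops a multi-breed pedigree: founder
allele frequencies per breed are Balding–Nichols draws around shared
base frequencies (default divergence Fst = 0.05 within the herd
simulator, 0.1 in the breed-reference generator), panel SNPs draw
allele-A frequencies Uniform(0.42, 0.58) so panel MAF is ~U(0.42, 0.50),
and offspring receive one Mendelian allele per parent per SNP with no
recombination model (the QC checks nowhere depend on LD).  Sex
chromosomes are explicit: males hemizygous in nPAR X, a Y-borne PAR
strand keeping the PAR diploid in both sexes, chrY calls male-only.
Per-call error (default 0.2%, a uniform flip to another class) and
missingness (0.5%) are applied last.  Listed parents are misrecorded at
8% per parent slot (the middle of the reported 7–9% national range) by
substituting a random same-sex animal of the parent generation.  Fault
scenarios — duplicate submission with fresh noise, sample swaps, sex
mislabels, format corruption of long-format exports — are all written to
a truth ledger, so every downstream detection is scored exactly.

Generations are spaced 24 months apart with up to ~3 months of
within-generation DOB jitter, so within-generation relatives (full sibs)
are excluded from parent prediction by the 15-month age rule, as in a
real herd where candidate parents are a generation older.

What the simulations do *not* emulate: linkage disequilibrium, selection
and inbreeding, cluster-intensity artifacts (cluster quality enters only
as a boolean SNP flag), microsatellite data, and the 1/32 quantisation
noise plus recombination variance that dominate real listed-vs-predicted
breed discrepancies.  Passing recovery tests therefore demonstrates the
correctness of the decision rules under their stated assumptions, not
the field error rates of a national database.

## Problem sizes and numerics

The recovery suites use a 1,000-animal herd (two breeds, 800 panel +
200 other autosomal SNPs, 120 chrX, 7 chrY) for parentage, a 500-animal
herd with 3% duplicate submissions for duplicate recall, 1,000 animals
for sex prediction, and a 3-breed × 5,000-SNP design with 500 reference
purebreds per breed for breed composition — sizes at which every
rate of interest is estimated from hundreds to thousands of events while
the whole suite runs in well under a minute per component.  Ties in
panel selection break by map position; candidate-table ties break by
newest genotyping date; all simulations are seeded and byte-reproducible.

Known limitations: duo parentage ignores genotyping-error modelling
beyond the hard count thresholds (no likelihood weighting); the
duplicate search is exact block matching, not locality-sensitive
hashing, so its recall under extreme missingness is bounded by block
survival; supervised admixture assumes reference breeds are the complete
ancestry space; and conflict resolution abstains (leaves genotypes
unresolved) whenever evidence is contradictory or absent.
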