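# herdqc

Genotype and sample quality control for national-herd SNP data: parentage
verification on a high-MAF SNP panel, duplicate-sample detection, sex and
breed-composition prediction, and the animal-level logic that decides which
genotypes to trust.

## Who this is for

National evaluation centres, breed societies and labs that receive SNP
genotypes at scale face a class of errors that per-SNP QC never sees: the
genotype is technically fine but belongs to the wrong animal — the same cow
sampled twice under two ear tags, a dam and calf's swabs swapped on the
farm, a sex recorded wrong, a tissue sample arriving months after the
animal died.  `herdqc` implements a two-part pipeline for this setting: a
**Genotype QC** stage (is the genotype technically sound?) and an **Animal
QC** stage (does it belong to the animal it is assigned to?), plus a seeded
gene-drop simulator so every decision rule can be scored against known
truth.

## The core statistics

**Parentage** uses opposing-homozygote exclusion on a parentage panel of
~800 high-MAF SNPs.  For a putative parent–offspring duo, a mismatch is a
SNP where one animal is AA and the other BB — impossible for a true duo
absent genotyping error.  With mismatch count *m* on the panel:

```
m <= 4   (0.5%)  ->  validated
m >= 13  (1.5%)  ->  failed
5 <= m <= 12     ->  re-check all shared autosomal SNPs;
                     validate iff misconcordance rate <= 1%
```

For an unrelated pair under Hardy–Weinberg the expected mismatch count is
`sum_i 2 p_i^2 q_i^2` over panel SNPs — about 98 of 800 at panel MAF
0.42–0.50 — so true parents (expected ~0.5 mismatches at 0.2% call error)
and wrong parents are separated by two orders of magnitude.  Parent
*prediction* scans every genotyped animal with early termination past 12
mismatches, then filters candidates by age (a parent is at least 15 months
older) and sex.  Trio validation counts Mating SNP Misconcordances (calf AB
while both validated parents are homozygous for the same allele); a rate
over 1% flags the trio as a likely sample swap.

**Duplicates** are found by cutting each sample's 800-character genotype
string (`2=AA, 1=AB, 0=BB, 9=missing`) into 40 non-overlapping 20-SNP
blocks and exact-matching blocks, then confirming candidate pairs at >= 99%
SNP-by-SNP identity on the panel and on all shared SNPs.

**Sex** is predicted from the chrY call count (0–1 of 7 female, 6–7 male)
combined with the chrX non-PAR heterozygosity rate (<= 5% male, >= 15%
female); the pseudoautosomal region is located as the longest run of chrX
SNPs with high male heterozygosity.

**Breed composition** is supervised admixture: ancestry fractions `q` over
K reference breeds maximising the binomial likelihood
`g_j ~ Bin(2, sum_k q_k P_jk)` with the reference allele frequencies `P`
fixed from listed purebreds, fitted by EM on the simplex.

See `docs/methods.md` for the full rules, boundaries and design choices.

## Worked example

Simulate a two-breed herd with the default study conditions (0.2% call
error, 0.5% missingness, 8% of listed parents misrecorded) and run the
full pipeline:

```bash
herdqc simulate --seed 42 --out demo --n-founders 30 --n-generations 2
# wrote 360 records to demo

herdqc run --genotypes demo/genotypes_matrix.tsv --snp-map demo/snp_map.tsv \
           --animals demo/animals.csv --samples demo/samples.csv \
           --out demo/reports
# 0 genotypes invalidated or unresolved
```

`demo/reports/parentage_validation.tsv` then contains one row per
animal × listed parent:

```
verdict
validated         559
failed             40
gray_validated      1
```

The 40 failures are the misrecorded listed parents (the simulator wrote
the truth to `demo/truth.json`); the gray-zone case had 5 panel mismatches
and validated on the full autosomal SNP set.  For every animal without two
validated parents the pipeline predicted parents from the whole candidate
table (78 predicted parentages in `parentage_predictions.tsv` — the true
parents of the misrecorded animals), and `animal_qc.tsv` shows 321 samples
fully clean and 39 flagged (parentage failures awaiting the predicted
correction), none invalidated — no single animal-QC check invalidates a
genotype on its own.

Every stage is also available separately (`herdqc geno-qc`, `herdqc
parentage verify|predict|trio`, `herdqc duplicates`, `herdqc sexcheck`,
`herdqc breed build-ref|predict`, `herdqc panel audit|select|power`), and
everything the CLI does is a thin wrapper over importable functions:

```python
from herdqc import parentage
from herdqc.simulate import SimConfig, simulate_herd

sim = simulate_herd(SimConfig(seed=1))
panel = sim.snp_map.panel_index
table = parentage.build_candidate_table(sim.records, panel)
results = parentage.predict_parents(
    "B0G2A0003", table, sim.animals, panel, sim.snp_map.autosomal_index
)
```

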