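"""Animal-level QC: the checks that ask whether a (technically clean)
genotype actually belongs to the animal it is assigned to.

Every sample runs through the full battery — duplicate check,
multi-genotype reconciliation, sex check, breed check, parentage check,
offspring-pattern check, post-death flag — before any decision is made.
A single failed check never invalidates a genotype on its own; the two
exceptions the rules state are a pedigree animal whose predicted breed
composition grossly contradicts its listed one, and a confirmed
duplicate / multi-genotype conflict, which leaves both genotypes invalid
until evidence-based resolution attributes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np

from . import breedcomp, duplicates, parentage, sexcheck
from .types import (
    Animal,
    AnimalClass,
    DEFAULT_THRESHOLDS,
    GenotypeRecord,
    QCFlag,
    Sex,
    SnpMap,
    Thresholds,
    Validity,
)


@dataclass
class AnimalQCReport:
    sample_id: str
    animal_id: str
    outcomes: dict[str, str] = field(default_factory=dict)
    final_state: Validity = Validity.VALID
    evidence_log: list[tuple[str, str, str]] = field(default_factory=list)

    def log(self, check: str, result: str, detail: str = "") -> None:
        self.outcomes[check] = result
        self.evidence_log.append((check, result, detail))


def offspring_pattern_check(
    parent_results: list[parentage.ParentageResult],
    parent_class: AnimalClass,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Flag a parent genotype whose genotyped offspring fail en masse.

    A dam with >= 2 genotyped offspring all failing, a stock bull with
    >= 5 and >= 80% failing, or an AI sire with >= 10 and >= 80% failing
    is flagged for manual check — the genotype may belong to another
    animal (e.g. a same-sex fraternal twin).
    """
    decided = [r for r in parent_results if not r.verdict
               is parentage.ParentageVerdict.INSUFFICIENT_DATA]
    n = len(decided)
    if n == 0:
        return False
    n_fail = sum(r.verdict.is_failed for r in decided)
    if parent_class is AnimalClass.AI_SIRE:
        return n >= thresholds.aibull_offspring_flag_n and (
            n_fail / n >= thresholds.offspring_fail_frac
        )
    if parent_class is AnimalClass.STOCK_BULL:
        return n >= thresholds.stockbull_offspring_flag_n and (
            n_fail / n >= thresholds.offspring_fail_frac
        )
    # dams (and any other class): all offspring must fail
    return n >= thresholds.dam_offspring_flag_n and n_fail == n


def post_death_flag(
    record: GenotypeRecord,
    animal: Animal,
    is_straw_sample: bool = False,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Warn when tissue was collected more than 45 days after recorded death.

    Never invalidates by itself; AI sires are exempt when the sample is an
    AI straw (straws legitimately outlive the bull).
    """
    if record.sample_collection_date is None or animal.death_date is None:
        return False
    if animal.animal_class is AnimalClass.AI_SIRE and is_straw_sample:
        return False
    limit = animal.death_date + timedelta(days=thresholds.dead_sample_days)
    return record.sample_collection_date > limit


@dataclass
class QCContext:
    """Everything the animal-QC checks need to evaluate one genotype."""

    snp_map: SnpMap
    records: list[GenotypeRecord]
    animals: dict[str, Animal]
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    breed_reference: breedcomp.BreedReference | None = None

    def __post_init__(self) -> None:
        self.panel = self.snp_map.panel_index
        # duo parentage tests use autosomes only (chrX/chrY are not valid
        # duo-exclusion territory); duplicate identity uses every SNP
        self.autosomal = self.snp_map.autosomal_index
        self.all_snps = np.arange(len(self.snp_map))
        self._by_animal: dict[str, list[GenotypeRecord]] = {}
        for r in self.records:
            self._by_animal.setdefault(r.animal_id, []).append(r)
        self._offspring_of: dict[str, list[str]] = {}
        for a in self.animals.values():
            for p in (a.listed_sire, a.listed_dam):
                if p:
                    self._offspring_of.setdefault(p, []).append(a.animal_id)

    def genotype_of(self, animal_id: str) -> GenotypeRecord | None:
        recs = [
            r for r in self._by_animal.get(animal_id, ())
            if r.valid in (Validity.VALID, Validity.FLAGGED)
        ]
        if not recs:
            return None
        return max(recs, key=lambda r: r.n_called(self.panel))

    def offspring_ids(self, parent_id: str) -> list[str]:
        return self._offspring_of.get(parent_id, [])


def _parentage_evidence(
    rec: GenotypeRecord, animal: Animal, ctx: QCContext
) -> tuple[int, int]:
    """(supports, contradictions) from validating *rec* against the listed
    parents of *animal*."""
    sup = con = 0
    for pid in (animal.listed_sire, animal.listed_dam):
        if not pid:
            continue
        parent_rec = ctx.genotype_of(pid)
        if parent_rec is None or parent_rec.sample_id == rec.sample_id:
            continue
        res = parentage.validate_parent(
            rec, parent_rec, ctx.panel, ctx.autosomal, thresholds=ctx.thresholds
        )
        if res.verdict.is_validated:
            sup += 1
        elif res.verdict.is_failed:
            con += 1
    return sup, con


def _offspring_evidence(
    rec: GenotypeRecord, animal: Animal, ctx: QCContext
) -> tuple[int, int]:
    results = []
    for oid in ctx.offspring_ids(animal.animal_id):
        off_rec = ctx.genotype_of(oid)
        if off_rec is None or off_rec.sample_id == rec.sample_id:
            continue
        results.append(
            parentage.validate_parent(
                off_rec, rec, ctx.panel, ctx.autosomal, thresholds=ctx.thresholds
            )
        )
    sup = sum(r.verdict.is_validated for r in results)
    n_fail = sum(r.verdict.is_failed for r in results)
    con = 1 if (len(results) >= 2 and n_fail == len(results)) else 0
    return sup, con


def _sex_evidence(rec: GenotypeRecord, animal: Animal, ctx: QCContext) -> tuple[int, int]:
    pred = sexcheck.predict_sex(rec, ctx.snp_map, ctx.thresholds).predicted_sex
    if pred is Sex.UNKNOWN or animal.recorded_sex is Sex.UNKNOWN:
        return 0, 0
    return (1, 0) if pred is animal.recorded_sex else (0, 1)


def _breed_evidence(rec: GenotypeRecord, animal: Animal, ctx: QCContext) -> tuple[int, int]:
    if ctx.breed_reference is None:
        return 0, 0
    try:
        est = breedcomp.estimate_q(rec, ctx.breed_reference, thresholds=ctx.thresholds)
    except ValueError:
        return 0, 0
    status = breedcomp.compare_to_listed(est, animal, thresholds=ctx.thresholds)
    if status == "match":
        return 1, 0
    if status == "mismatch":
        return 0, 1
    return 0, 0


@dataclass
class ConflictResolution:
    attribution: dict[str, str] | None   # sample_id -> animal_id
    notes: list[str] = field(default_factory=list)


def resolve_conflict(
    rec_a: GenotypeRecord,
    rec_b: GenotypeRecord,
    animal_a: Animal,
    animal_b: Animal,
    ctx: QCContext,
) -> ConflictResolution:
    """Attribute two conflicted genotypes to two animals by evidence.

    Evidence is gathered in fixed priority — parentage validation,
    offspring validation, sex vs recorded sex, breed vs listed composition,
    herd co-residence — for both possible assignments (as labelled, or
    swapped).  Attribution is made iff exactly one assignment is consistent
    with all non-ambiguous evidence (no contradictions, at least one
    support); otherwise both genotypes stay unresolved.
    """
    notes: list[str] = []
    evidence_fns = [
        ("parentage", _parentage_evidence),
        ("offspring", _offspring_evidence),
        ("sex", _sex_evidence),
        ("breed", _breed_evidence),
    ]
    assignments = {
        "as_labelled": ((rec_a, animal_a), (rec_b, animal_b)),
        "swapped": ((rec_a, animal_b), (rec_b, animal_a)),
    }
    score: dict[str, tuple[int, int]] = {}
    for name, pairs in assignments.items():
        sup = con = 0
        for check, fn in evidence_fns:
            for rec, an in pairs:
                s, c = fn(rec, an, ctx)
                sup += s
                con += c
        score[name] = (sup, con)
        notes.append(f"{name}: supports={sup} contradictions={con}")

    if not (set(animal_a.herds_ever()) & set(animal_b.herds_ever())):
        notes.append("animals never co-resident: possible lab error")

    consistent = [n for n, (s, c) in score.items() if c == 0 and s > 0]
    if len(consistent) != 1:
        return ConflictResolution(attribution=None, notes=notes)
    pairs = assignments[consistent[0]]
    return ConflictResolution(
        attribution={rec.sample_id: an.animal_id for rec, an in pairs},
        notes=notes,
    )


def run_animal_qc(
    records: list[GenotypeRecord],
    animals: dict[str, Animal],
    snp_map: SnpMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    breed_reference: breedcomp.BreedReference | None = None,
    straw_samples: set[str] = frozenset(),
) -> list[AnimalQCReport]:
    """Run the full animal-QC battery on genotype-QC-passed records."""
    ctx = QCContext(snp_map, records, animals, thresholds, breed_reference)
    reports = {r.sample_id: AnimalQCReport(r.sample_id, r.animal_id) for r in records}

    # 1. SNP duplicates across the cohort
    cands = duplicates.find_duplicate_candidates(records, ctx.panel, thresholds.block_size)
    dup_results = duplicates.confirm_duplicates(
        cands, records, ctx.panel, ctx.all_snps, thresholds, animals
    )
    confirmed_pairs = []
    for d in dup_results:
        if d.status is duplicates.DupStatus.CONFIRMED:
            for sid in (d.sample_a, d.sample_b):
                detail = f"pair {d.sample_a}/{d.sample_b} identity {d.panel_identity:.3f}"
                if d.possible_twins:
                    reports[sid].log("duplicate", "possible_twins", detail)
                else:
                    reports[sid].log("duplicate", "confirmed", detail)
            if not d.possible_twins:
                confirmed_pairs.append(d)

    # 2. multiple genotypes per animal
    by_animal: dict[str, list[GenotypeRecord]] = {}
    for r in records:
        by_animal.setdefault(r.animal_id, []).append(r)
    for aid, recs in by_animal.items():
        if len(recs) < 2:
            continue
        status, pair_results = duplicates.reconcile_multi_genotypes(
            aid, recs, ctx.panel, ctx.all_snps, thresholds
        )
        for r in recs:
            reports[r.sample_id].log("multi_genotype", status)

    # 3. sex check
    for rec in records:
        pred = sexcheck.predict_sex(rec, snp_map, thresholds)
        an = animals.get(rec.animal_id)
        rep = reports[rec.sample_id]
        if pred.combined is sexcheck.SexVerdict.CONFLICT:
            rep.log("sex", "xy_conflict")
            rec.flags.add(QCFlag.SEX_AMBIGUOUS)
        elif an is None or an.recorded_sex is Sex.UNKNOWN or pred.predicted_sex is Sex.UNKNOWN:
            rep.log("sex", "unevaluable")
        elif pred.predicted_sex is an.recorded_sex:
            rep.log("sex", "match")
        else:
            rep.log("sex", "mismatch", f"predicted {pred.predicted_sex.value}")
            rec.flags.add(QCFlag.SEX_MISMATCH)

    # 4. breed check
    for rec in records:
        an = animals.get(rec.animal_id)
        rep = reports[rec.sample_id]
        if breed_reference is None or an is None:
            rep.log("breed", "unevaluable")
            continue
        try:
            est = breedcomp.estimate_q(rec, breed_reference, thresholds=thresholds)
        except ValueError:
            rep.log("breed", "unevaluable", "insufficient SNP overlap")
            continue
        status = breedcomp.compare_to_listed(est, an, thresholds=thresholds)
        rep.log("breed", status)
        if status == "mismatch":
            rec.flags.add(QCFlag.BREED_MISMATCH)
            if an.animal_class is AnimalClass.PEDIGREE:
                rec.valid = Validity.INVALID
                rep.log("breed", "pedigree_invalidated")

    # 5. parentage vs listed parents
    parentage_results: dict[str, list[parentage.ParentageResult]] = {}
    for rec in records:
        an = animals.get(rec.animal_id)
        rep = reports[rec.sample_id]
        if an is None:
            rep.log("parentage", "unevaluable")
            continue
        outcomes = []
        for role, pid in (("sire", an.listed_sire), ("dam", an.listed_dam)):
            if not pid:
                continue
            parent_rec = ctx.genotype_of(pid)
            if parent_rec is None:
                continue
            res = parentage.validate_parent(
                rec, parent_rec, ctx.panel, ctx.autosomal, role, thresholds
            )
            parentage_results.setdefault(pid, []).append(res)
            outcomes.append(res)
            if res.verdict.is_failed:
                rec.flags.add(QCFlag.PARENTAGE_FAIL)
        if not outcomes:
            rep.log("parentage", "unevaluable")
        elif any(r.verdict.is_failed for r in outcomes):
            rep.log("parentage", "fail",
                    "; ".join(f"{r.role}:{r.verdict.value}" for r in outcomes))
        else:
            rep.log("parentage", "pass",
                    "; ".join(f"{r.role}:{r.verdict.value}" for r in outcomes))

    # 6. offspring pattern per parent genotype
    for rec in records:
        an = animals.get(rec.animal_id)
        rep = reports[rec.sample_id]
        res = parentage_results.get(rec.animal_id, [])
        if an is None or not res:
            rep.log("offspring", "unevaluable")
            continue
        cls = an.animal_class
        if an.recorded_sex is Sex.FEMALE and cls is AnimalClass.COMMERCIAL:
            cls = AnimalClass.COMMERCIAL  # dam rule applies
        if offspring_pattern_check(res, cls, thresholds):
            rep.log("offspring", "flag", f"{len(res)} genotyped offspring")
            rec.flags.add(QCFlag.OFFSPRING_FAIL_PATTERN)
        else:
            rep.log("offspring", "clear")

    # 7. post-death flag
    for rec in records:
        an = animals.get(rec.animal_id)
        rep = reports[rec.sample_id]
        if an is None:
            rep.log("post_death", "unevaluable")
            continue
        if post_death_flag(rec, an, rec.sample_id in straw_samples, thresholds):
            rep.log("post_death", "flag")
            rec.flags.add(QCFlag.POST_DEATH_SAMPLE)
        else:
            rep.log("post_death", "clear")

    # 8. resolution of confirmed duplicate conflicts
    by_sample = {r.sample_id: r for r in records}
    for d in confirmed_pairs:
        ra, rb = by_sample[d.sample_a], by_sample[d.sample_b]
        if ra.animal_id == rb.animal_id:
            continue
        an_a, an_b = animals.get(ra.animal_id), animals.get(rb.animal_id)
        if an_a is None or an_b is None:
            continue
        resolution = resolve_conflict(ra, rb, an_a, an_b, ctx)
        for sid in (d.sample_a, d.sample_b):
            if resolution.attribution is None:
                reports[sid].log("resolution", "unresolved", "; ".join(resolution.notes))
            else:
                reports[sid].log(
                    "resolution",
                    f"attributed_to:{resolution.attribution[sid]}",
                    "; ".join(resolution.notes),
                )

    # final decision per record
    for rec in records:
        rep = reports[rec.sample_id]
        if rec.valid is Validity.INVALID:
            rep.final_state = Validity.INVALID
        elif rec.valid is Validity.UNRESOLVED:
            rep.final_state = Validity.UNRESOLVED
        elif rec.flags:
            rec.valid = Validity.FLAGGED
            rep.final_state = Validity.FLAGGED
        else:
            rep.final_state = Validity.VALID
    return reports_list(reports, records)


def reports_list(
    reports: dict[str, AnimalQCReport], records: list[GenotypeRecord]
) -> list[AnimalQCReport]:
    return [reports[r.sample_id] for r in records]
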