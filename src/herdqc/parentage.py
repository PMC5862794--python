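"""SNP parentage validation, fast whole-database parent prediction and
trio mating validation.

A putative parent-offspring duo is tested by counting opposing homozygotes
(one animal AA, the other BB at the same SNP) on a high-MAF ~800-SNP
parentage panel.  Opposing homozygosity is the only Mendelian impossibility
testable at the duo level, so "mismatch" means exactly that throughout.

Decision rule (panel of 800):
  * <= 4 mismatches (0.5% misconcordance)  -> validated
  * >= 13 mismatches (> 1.5%)              -> failed
  * 5-12 (the gray zone)                   -> re-checked on ALL SNPs shared
    by the two genotypes; the parentage validates iff that full-SNP
    misconcordance rate is <= 1%.

The "all SNPs" set for parentage is the autosomal SNPs shared by both
genotypes: chrX cannot be used for a duo test without knowing the pair's
sexes and direction (a sire and his son are legitimately opposite
homozygotes at hemizygous non-PAR X SNPs), and chrY yields no calls in
females.

Mating validation tests a calf against both validated parents jointly:
a Mating SNP Misconcordance (MSM) is a site where the calf is AB while
sire and dam are homozygous for the same allele.  Trios with an MSM rate
above 1% of panel SNPs are flagged for manual review (the signature of a
swapped dam/calf sample pair).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .types import (
    CALL_MISSING,
    DEFAULT_THRESHOLDS,
    Animal,
    GenotypeRecord,
    Sex,
    Thresholds,
    Validity,
)


class ParentageVerdict(enum.Enum):
    VALIDATED = "validated"
    FAILED = "failed"
    GRAY_VALIDATED = "gray_validated"
    GRAY_FAILED = "gray_failed"
    INSUFFICIENT_DATA = "insufficient_data"

    @property
    def is_validated(self) -> bool:
        return self in (ParentageVerdict.VALIDATED, ParentageVerdict.GRAY_VALIDATED)

    @property
    def is_failed(self) -> bool:
        return self in (ParentageVerdict.FAILED, ParentageVerdict.GRAY_FAILED)


@dataclass
class ParentageResult:
    animal_id: str
    candidate_id: str
    role: str  # "sire" | "dam"
    n_compared_panel: int
    n_mismatch_panel: int
    verdict: ParentageVerdict
    full_snp_rate: float | None = None


@dataclass
class TrioResult:
    animal_id: str
    sire_id: str
    dam_id: str
    n_msm: int
    n_informative: int
    flagged: bool

    @property
    def msm_rate(self) -> float:
        return self.n_msm / self.n_informative if self.n_informative else 0.0


def count_parent_offspring_mismatches(
    a: np.ndarray, b: np.ndarray, snp_index: np.ndarray
) -> tuple[int, int]:
    """Opposing-homozygote count over *snp_index*.

    Returns ``(n_compared, n_mismatch)``: SNPs where both calls are
    non-missing, and among those, SNPs where one animal is AA (2) and the
    other BB (0).  Symmetric in its two arguments.
    """
    if len(snp_index) == 0:
        raise ValueError("empty SNP index")
    av, bv = a[snp_index], b[snp_index]
    both = (av != CALL_MISSING) & (bv != CALL_MISSING)
    n_compared = int(both.sum())
    n_mismatch = int((np.abs(av.astype(np.int16) - bv) == 2)[both].sum())
    return n_compared, n_mismatch


def _two_stage_verdict(
    n_panel_mm: int,
    animal: GenotypeRecord,
    parent: GenotypeRecord,
    all_snps: np.ndarray,
    thresholds: Thresholds,
) -> tuple[ParentageVerdict, float | None]:
    if n_panel_mm <= thresholds.validate_max_mm:
        return ParentageVerdict.VALIDATED, None
    if n_panel_mm >= thresholds.fail_min_mm:
        return ParentageVerdict.FAILED, None
    n_cmp, n_mm = count_parent_offspring_mismatches(animal.calls, parent.calls, all_snps)
    rate = n_mm / n_cmp if n_cmp else 1.0
    if rate <= thresholds.gray_full_snp_rate_max:
        return ParentageVerdict.GRAY_VALIDATED, rate
    return ParentageVerdict.GRAY_FAILED, rate


def validate_parent(
    animal: GenotypeRecord,
    parent: GenotypeRecord,
    panel: np.ndarray,
    all_snps: np.ndarray,
    role: str = "sire",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ParentageResult:
    """Two-stage validation of a listed parent against its offspring.

    Requires at least ``predict_min_panel_calls`` (600) mutually called
    panel SNPs for a usable verdict; otherwise ``insufficient_data``.
    """
    n_cmp, n_mm = count_parent_offspring_mismatches(animal.calls, parent.calls, panel)
    if n_cmp < thresholds.predict_min_panel_calls:
        return ParentageResult(animal.animal_id, parent.animal_id, role,
                               n_cmp, n_mm, ParentageVerdict.INSUFFICIENT_DATA)
    verdict, rate = _two_stage_verdict(n_mm, animal, parent, all_snps, thresholds)
    return ParentageResult(animal.animal_id, parent.animal_id, role,
                           n_cmp, n_mm, verdict, rate)


@dataclass
class CandidateTable:
    """One genotype per animal, restricted to animals with >= 600 panel calls.

    When an animal has several valid genotypes, the one with the most panel
    calls wins (ties broken by newest genotyping date).  ``calls`` holds the
    panel-subset call matrix, one row per animal.
    """

    animal_ids: list[str]
    calls: np.ndarray  # (n_animals, n_panel_snps) int8
    records: dict[str, GenotypeRecord]

    def __len__(self) -> int:
        return len(self.animal_ids)

    def row_of(self, animal_id: str) -> int:
        return self.animal_ids.index(animal_id)


def build_candidate_table(
    records: list[GenotypeRecord],
    panel: np.ndarray,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> CandidateTable:
    best: dict[str, GenotypeRecord] = {}
    for rec in records:
        if rec.valid is not Validity.VALID:
            continue
        n_panel = rec.n_called(panel)
        if n_panel < thresholds.predict_min_panel_calls:
            continue
        cur = best.get(rec.animal_id)
        if cur is None:
            best[rec.animal_id] = rec
            continue
        cur_n = cur.n_called(panel)
        if n_panel > cur_n or (
            n_panel == cur_n
            and (rec.genotyping_date or date.min) > (cur.genotyping_date or date.min)
        ):
            best[rec.animal_id] = rec
    ids = sorted(best)
    calls = (
        np.stack([best[i].calls[panel] for i in ids])
        if ids else np.empty((0, len(panel)), dtype=np.int8)
    )
    return CandidateTable(animal_ids=ids, calls=calls, records=best)


def _panel_mismatch_scan(
    target_row: np.ndarray,
    table_calls: np.ndarray,
    fail_above: int,
    chunk: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch and comparison counts of one animal against every table row.

    SNPs are processed in chunks with early termination: once a candidate
    exceeds *fail_above* mismatches it is dropped from further chunks.  The
    surviving counts are exactly what an exhaustive scan would produce for
    candidates at or below the bound; counts for eliminated candidates are
    lower bounds (> fail_above either way).
    """
    n, m = table_calls.shape
    mism = np.zeros(n, dtype=np.int32)
    comp = np.zeros(n, dtype=np.int32)
    alive = np.ones(n, dtype=bool)
    for start in range(0, m, chunk):
        sl = slice(start, start + chunk)
        t = target_row[sl]
        c = table_calls[np.flatnonzero(alive)][:, sl]
        both = (t != CALL_MISSING) & (c != CALL_MISSING)
        mm = (np.abs(c.astype(np.int16) - t) == 2) & both
        idx = np.flatnonzero(alive)
        mism[idx] += mm.sum(axis=1)
        comp[idx] += both.sum(axis=1)
        alive[idx] &= mism[idx] <= fail_above
        if not alive.any():
            break
    return comp, mism


def _months_between(earlier: date, later: date) -> int:
    """Whole calendar months from *earlier* to *later*."""
    m = (later.year - earlier.year) * 12 + later.month - earlier.month
    if later.day < earlier.day:
        m -= 1
    return m


def predict_parents(
    target: str,
    table: CandidateTable,
    animals: dict[str, Animal],
    panel: np.ndarray,
    all_snps: np.ndarray,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    early_termination: bool = True,
) -> list[ParentageResult]:
    """Scan the whole candidate table for possible parents of *target*.

    Candidates exceeding 12 panel mismatches are excluded (with early
    termination during the scan; the surviving set is identical to an
    exhaustive count).  Survivors must be at least 15 months older than the
    target (a parent was >= 6 months old at conception plus 9 months
    gestation) — this also removes the target's own genotyped progeny — and
    of the role-appropriate sex.  Gray-zone candidates (5-12 mismatches)
    are confirmed on all shared SNPs at the 1% rule.
    """
    if target not in table.records:
        raise KeyError(f"target {target!r} not in candidate table")
    t_row = table.row_of(target)
    t_animal = animals.get(target)
    if early_termination:
        comp, mism = _panel_mismatch_scan(
            table.calls[t_row], table.calls, fail_above=thresholds.fail_min_mm - 1
        )
    else:
        t = table.calls[t_row]
        both = (t != CALL_MISSING) & (table.calls != CALL_MISSING)
        comp = both.sum(axis=1)
        mism = ((np.abs(table.calls.astype(np.int16) - t) == 2) & both).sum(axis=1)

    results: list[ParentageResult] = []
    for i, cand_id in enumerate(table.animal_ids):
        if cand_id == target or mism[i] >= thresholds.fail_min_mm:
            continue
        if comp[i] < thresholds.predict_min_panel_calls:
            continue
        cand = animals.get(cand_id)
        if cand is None or cand.dob is None or t_animal is None or t_animal.dob is None:
            continue
        if _months_between(cand.dob, t_animal.dob) < thresholds.parent_age_gap_months:
            continue
        if cand.recorded_sex is Sex.MALE:
            role = "sire"
        elif cand.recorded_sex is Sex.FEMALE:
            role = "dam"
        else:
            continue
        verdict, rate = _two_stage_verdict(
            int(mism[i]), table.records[target], table.records[cand_id],
            all_snps, thresholds,
        )
        if verdict.is_validated:
            results.append(
                ParentageResult(target, cand_id, role, int(comp[i]), int(mism[i]),
                                verdict, rate)
            )
    return results


def count_msm(
    calf: GenotypeRecord,
    sire: GenotypeRecord,
    dam: GenotypeRecord,
    panel: np.ndarray,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> TrioResult:
    """Mating validation: count Mating SNP Misconcordances for a trio."""
    c, s, d = calf.calls[panel], sire.calls[panel], dam.calls[panel]
    informative = (c != CALL_MISSING) & (s != CALL_MISSING) & (d != CALL_MISSING)
    msm = informative & (c == 1) & (s == d) & ((s == 0) | (s == 2))
    n_inf, n_msm = int(informative.sum()), int(msm.sum())
    rate = n_msm / n_inf if n_inf else 0.0
    return TrioResult(calf.animal_id, sire.animal_id, dam.animal_id,
                      n_msm, n_inf, flagged=rate > thresholds.msm_flag_rate)


def results_to_frame(results: list[ParentageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "candidate_id": r.candidate_id,
                "role": r.role,
                "n_compared_panel": r.n_compared_panel,
                "n_mismatch_panel": r.n_mismatch_panel,
                "full_snp_rate": r.full_snp_rate,
                "verdict": r.verdict.value,
            }
            for r in results
        ]
    )
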