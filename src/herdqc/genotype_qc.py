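"""Genotype-level quality control.

Every incoming genotype passes through four checks before any downstream
use: (1) animal call rate >= 0.90 over usable SNPs (a SNP is usable when
its cohort call rate is >= 0.85); (2) all three genotype classes AA/AB/BB
present; (3) allele symbols purely in the declared format (no AB data mixed
with nucleotide calls); (4) no genotype class with frequency below 20%
among non-missing calls.  A genotype failing any check is invalidated and
never reaches the parentage or animal-QC stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    CALL_AA,
    CALL_AB,
    CALL_BB,
    CALL_MISSING,
    DEFAULT_THRESHOLDS,
    GenotypeRecord,
    QCFlag,
    SnpMap,
    Thresholds,
    Validity,
)


@dataclass
class GenotypeQCResult:
    sample_id: str
    call_rate: float
    class_freqs: tuple[float, float, float]  # (fAA, fAB, fBB)
    checks: dict[str, bool] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.checks.values())


def snp_call_rates(
    records: list[GenotypeRecord],
    snp_map: SnpMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP call rate across the cohort and the usable-SNP mask.

    A SNP with cohort call rate below ``snp_cr_min_for_use`` (default 0.85)
    is excluded from the denominator of every animal call rate.
    """
    if not records:
        raise ValueError("no records supplied")
    calls = np.stack([r.calls for r in records])
    cr = (calls != CALL_MISSING).mean(axis=0)
    return cr, cr >= thresholds.snp_cr_min_for_use


def animal_call_rate(record: GenotypeRecord, usable_mask: np.ndarray) -> float:
    """Fraction of usable SNPs with a non-missing call; pass is >= 0.90."""
    n_usable = int(usable_mask.sum())
    if n_usable == 0:
        raise ValueError("usable-SNP mask is empty")
    return float((record.calls[usable_mask] != CALL_MISSING).sum() / n_usable)


def genotype_classes_present(record: GenotypeRecord) -> tuple[set[int], bool]:
    """Which of AA/AB/BB appear; pass iff all three are observed."""
    present = set(np.unique(record.calls).tolist()) - {CALL_MISSING}
    return present, {CALL_BB, CALL_AB, CALL_AA} <= present


def detect_mixed_format(
    raw_alleles: list[tuple[str, str, str]], declared: str
) -> tuple[bool, list[tuple[str, str, str]]]:
    """Check raw (sample, snp, allele) symbols against the declared format.

    AB-declared data containing nucleotides (or TOP data containing 'B')
    indicates a format mix-up; the affected genotype is invalidated.
    Returns (pass, offending rows).
    """
    declared = declared.upper()
    allowed = {"A", "B"} if declared == "AB" else {"A", "C", "G", "T"}
    allowed |= {"-", "--", "0", ""}
    offending = [row for row in raw_alleles if row[2] not in allowed]
    return not offending, offending


def class_frequency_check(
    record: GenotypeRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[tuple[float, float, float], bool]:
    """Genotype-class frequencies over non-missing calls.

    Fails when any class frequency is strictly below 20%: across a large
    QC'd population virtually no real sample has a class that rare, so a
    low class frequency signals a technical problem rather than biology.
    """
    called = record.calls[record.calls != CALL_MISSING]
    if called.size == 0:
        raise ValueError(f"sample {record.sample_id}: no non-missing calls")
    f_aa = float((called == CALL_AA).sum() / called.size)
    f_ab = float((called == CALL_AB).sum() / called.size)
    f_bb = float((called == CALL_BB).sum() / called.size)
    ok = min(f_aa, f_ab, f_bb) >= thresholds.geno_class_freq_min
    return (f_aa, f_ab, f_bb), ok


def run_genotype_qc(
    records: list[GenotypeRecord],
    snp_map: SnpMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    raw_alleles: dict[str, list[tuple[str, str, str]]] | None = None,
    declared_format: str = "AB",
) -> list[GenotypeQCResult]:
    """Run the full genotype-QC battery and mark failing records invalid.

    *raw_alleles* (sample_id -> raw symbol rows) enables the mixed-format
    check for long-format input; matrix input is already integer-coded so
    the check passes vacuously there.
    """
    _, usable = snp_call_rates(records, snp_map, thresholds)
    results = []
    for rec in records:
        cr = animal_call_rate(rec, usable)
        cr_ok = cr >= thresholds.animal_cr_min
        _, classes_ok = genotype_classes_present(rec)
        if raw_alleles is not None and rec.sample_id in raw_alleles:
            fmt_ok, _ = detect_mixed_format(raw_alleles[rec.sample_id], declared_format)
        else:
            fmt_ok = True
        if (rec.calls != CALL_MISSING).any():
            freqs, freq_ok = class_frequency_check(rec, thresholds)
        else:
            freqs, freq_ok = (0.0, 0.0, 0.0), False
        res = GenotypeQCResult(
            sample_id=rec.sample_id,
            call_rate=cr,
            class_freqs=freqs,
            checks={
                "call_rate": cr_ok,
                "classes_present": classes_ok,
                "format_pure": fmt_ok,
                "class_freq": freq_ok,
            },
        )
        if not res.overall:
            rec.valid = Validity.INVALID
            if not cr_ok:
                rec.flags.add(QCFlag.LOW_CALL_RATE)
            if not classes_ok:
                rec.flags.add(QCFlag.MISSING_GENO_CLASS)
            if not fmt_ok:
                rec.flags.add(QCFlag.MIXED_FORMAT)
            if not freq_ok:
                rec.flags.add(QCFlag.LOW_CLASS_FREQ)
        results.append(res)
    return results
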