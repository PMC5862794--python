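"""Sex prediction from chrY call counts and chrX heterozygosity, and
determination of the pseudoautosomal region (PAR) boundary.

chrY SNPs only yield calls in males (in females the probes have nothing to
hybridise to), so with the 7-SNP chrY set: 0-1 calls predicts female, 6-7
male, 2-5 ambiguous.  chrX outside the PAR is hemizygous in males, so the
non-PAR heterozygosity rate ``#AB / (#AA + #AB + #BB)`` separates the
sexes: <= 5% male, >= 15% female, between ambiguous.  The two verdicts are
combined; opposite non-ambiguous verdicts are a conflict needing manual
review (possible X0/XXY karyotypes, or a sex-sorted-semen sample).

The PAR itself is located empirically: among animals of known sex, PAR
SNPs show high male heterozygosity (they are diploid in males) while
non-PAR X SNPs show almost none, so after MAF/call-rate filtering the PAR
is the longest positional run of chrX SNPs whose male het rate exceeds a
threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .types import (
    CALL_AB,
    CALL_MISSING,
    DEFAULT_THRESHOLDS,
    GenotypeRecord,
    Sex,
    SnpMap,
    Thresholds,
)


class SexVerdict(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    AMBIGUOUS = "ambiguous"
    CONFLICT = "conflict"


@dataclass
class SexPrediction:
    sample_id: str
    n_chry_called: int | None
    chrx_npar_het: float | None
    verdict_y: SexVerdict | None
    verdict_x: SexVerdict | None
    combined: SexVerdict

    @property
    def predicted_sex(self) -> Sex:
        if self.combined is SexVerdict.MALE:
            return Sex.MALE
        if self.combined is SexVerdict.FEMALE:
            return Sex.FEMALE
        return Sex.UNKNOWN


def predict_sex_y(
    record: GenotypeRecord,
    chry_index: np.ndarray,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[int, SexVerdict] | None:
    """Sex from the chrY call count; None when the chip has no chrY SNPs.

    Cutoffs are stated for a 7-SNP chrY set (0-1 female, 6-7 male) and
    scale proportionally for chips carrying a different number.
    """
    n_snps = len(chry_index)
    if n_snps == 0:
        return None
    n_called = record.n_called(chry_index)
    if n_snps == 7:
        female_max, male_min = thresholds.chry_female_max, thresholds.chry_male_min
    else:
        female_max = int(np.floor(n_snps * thresholds.chry_female_max / 7))
        male_min = int(np.ceil(n_snps * thresholds.chry_male_min / 7))
    if n_called <= female_max:
        return n_called, SexVerdict.FEMALE
    if n_called >= male_min:
        return n_called, SexVerdict.MALE
    return n_called, SexVerdict.AMBIGUOUS


def chrx_npar_het(record: GenotypeRecord, npar_index: np.ndarray) -> float | None:
    """Heterozygosity rate #AB / (#AA + #AB + #BB) over non-PAR chrX SNPs."""
    calls = record.calls[npar_index]
    called = calls[calls != CALL_MISSING]
    if called.size == 0:
        return None
    return float((called == CALL_AB).sum() / called.size)


def predict_sex_x(
    record: GenotypeRecord,
    npar_index: np.ndarray,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[float | None, SexVerdict | None]:
    """Sex verdict from the chrX non-PAR het rate.

    Fewer than ``chrx_min_npar_calls`` informative calls yields an
    ambiguous verdict: highly inbred females can look male when too few
    SNPs are used.
    """
    if len(npar_index) == 0:
        return None, None
    calls = record.calls[npar_index]
    n_called = int((calls != CALL_MISSING).sum())
    het = chrx_npar_het(record, npar_index)
    if het is None or n_called < thresholds.chrx_min_npar_calls:
        return het, SexVerdict.AMBIGUOUS
    if het <= thresholds.chrx_male_het_max:
        return het, SexVerdict.MALE
    if het >= thresholds.chrx_female_het_min:
        return het, SexVerdict.FEMALE
    return het, SexVerdict.AMBIGUOUS


def combine_sex(
    verdict_y: SexVerdict | None, verdict_x: SexVerdict | None
) -> SexVerdict:
    """Merge the chrY and chrX verdicts.

    Agreement (or one side absent/ambiguous) yields the informative
    verdict; two ambiguous verdicts stay ambiguous; opposite non-ambiguous
    verdicts are a conflict for manual review.
    """
    verdicts = [v for v in (verdict_y, verdict_x) if v is not None]
    if not verdicts:
        return SexVerdict.AMBIGUOUS
    definite = {v for v in verdicts if v in (SexVerdict.MALE, SexVerdict.FEMALE)}
    if len(definite) == 2:
        return SexVerdict.CONFLICT
    if len(definite) == 1:
        return definite.pop()
    return SexVerdict.AMBIGUOUS


def predict_sex(
    record: GenotypeRecord,
    snp_map: SnpMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> SexPrediction:
    y = predict_sex_y(record, snp_map.chry_index, thresholds)
    n_y, v_y = y if y is not None else (None, None)
    het, v_x = predict_sex_x(record, snp_map.chrx_npar_index, thresholds)
    return SexPrediction(
        sample_id=record.sample_id,
        n_chry_called=n_y,
        chrx_npar_het=het,
        verdict_y=v_y,
        verdict_x=v_x,
        combined=combine_sex(v_y, v_x),
    )


@dataclass
class ParRegion:
    start_bp: int | None
    end_bp: int | None
    snp_ids: list[str]
    male_het: dict[str, float]
    classification: dict[str, str]  # snp_id -> "PAR" | "nPAR" | "excluded"


def determine_par(
    records: list[GenotypeRecord],
    sexes: dict[str, Sex],
    snp_map: SnpMap,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    min_sexed: int = 50,
) -> ParRegion:
    """Locate the chrX pseudoautosomal region from known-sex animals.

    chrX SNPs failing MAF >= 0.01 or call rate >= 0.90 (over all supplied
    animals) are excluded.  Among the rest, SNPs with male heterozygosity
    >= ``par_male_het_min`` are PAR-like; the PAR interval is the longest
    contiguous positional run of PAR-like SNPs.
    """
    chrx = snp_map.chrx_index
    if len(chrx) == 0:
        raise ValueError("SNP map contains no chrX SNPs")
    males = [r for r in records if sexes.get(r.sample_id) is Sex.MALE]
    females = [r for r in records if sexes.get(r.sample_id) is Sex.FEMALE]
    if len(males) < min_sexed or len(females) < min_sexed:
        raise ValueError(
            f"need >= {min_sexed} known males and females "
            f"(got {len(males)} / {len(females)})"
        )
    all_calls = np.stack([r.calls[chrx] for r in records])
    male_calls = np.stack([r.calls[chrx] for r in males])

    called = all_calls != CALL_MISSING
    cr = called.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq_a = np.where(
            called.sum(axis=0) > 0,
            np.where(called, all_calls, 0).sum(axis=0) / (2 * np.maximum(called.sum(axis=0), 1)),
            np.nan,
        )
    maf = np.minimum(freq_a, 1 - freq_a)

    m_called = male_calls != CALL_MISSING
    m_n = m_called.sum(axis=0)
    male_het = np.where(
        m_n > 0, ((male_calls == CALL_AB) & m_called).sum(axis=0) / np.maximum(m_n, 1), 0.0
    )

    usable = (cr >= thresholds.par_snp_cr_min) & (maf >= thresholds.par_snp_maf_min)
    par_like = usable & (male_het >= thresholds.par_male_het_min)

    # longest run of PAR-like among usable SNPs, in positional order
    usable_pos = np.flatnonzero(usable)
    best_run: tuple[int, int] | None = None
    run_start = None
    for k, j in enumerate(usable_pos):
        if par_like[j]:
            if run_start is None:
                run_start = k
            if best_run is None or k - run_start > best_run[1] - best_run[0]:
                best_run = (run_start, k)
        else:
            run_start = None

    classification: dict[str, str] = {}
    het_by_id: dict[str, float] = {}
    par_ids: list[str] = []
    start_bp = end_bp = None
    run_set: set[int] = set()
    if best_run is not None:
        run_set = {int(usable_pos[k]) for k in range(best_run[0], best_run[1] + 1)}
        start_bp = snp_map[int(chrx[usable_pos[best_run[0]]])].position_bp
        end_bp = snp_map[int(chrx[usable_pos[best_run[1]]])].position_bp
    for local_j, global_i in enumerate(chrx):
        snp = snp_map[int(global_i)]
        het_by_id[snp.snp_id] = float(male_het[local_j])
        if not usable[local_j]:
            classification[snp.snp_id] = "excluded"
        elif local_j in run_set:
            classification[snp.snp_id] = "PAR"
            par_ids.append(snp.snp_id)
        else:
            classification[snp.snp_id] = "nPAR"
    return ParRegion(start_bp, end_bp, par_ids, het_by_id, classification)
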