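"""Core domain types shared by every pipeline stage.

Genotypes are integer-coded throughout the package: ``2 = AA``, ``1 = AB``,
``0 = BB``, ``9 = missing``.  This coding matches the numeric-string encoding
used for duplicate-sample detection, so a call vector can be rendered as a
string (e.g. ``"001290021"``) without translation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: valid integer genotype codes
CALL_AA = 2
CALL_AB = 1
CALL_BB = 0
CALL_MISSING = 9
VALID_CALLS = frozenset({0, 1, 2, 9})

#: recognised chromosome labels: 1..29 autosomes, X, Y, MT
AUTOSOMES = tuple(str(c) for c in range(1, 30))
CHROMOSOMES = AUTOSOMES + ("X", "Y", "MT")


class QCFlag(enum.Enum):
    """Per-genotype quality flags.

    No Animal-QC flag alone invalidates a genotype; only Genotype-QC
    failures (and the pedigree breed-mismatch rule) do.
    """

    LOW_CALL_RATE = "low_call_rate"
    MISSING_GENO_CLASS = "missing_geno_class"
    MIXED_FORMAT = "mixed_format"
    LOW_CLASS_FREQ = "low_class_freq"
    SNP_DUPLICATE = "snp_duplicate"
    MULTI_GENOTYPE_CONFLICT = "multi_genotype_conflict"
    SEX_MISMATCH = "sex_mismatch"
    SEX_AMBIGUOUS = "sex_ambiguous"
    BREED_MISMATCH = "breed_mismatch"
    PARENTAGE_FAIL = "parentage_fail"
    OFFSPRING_FAIL_PATTERN = "offspring_fail_pattern"
    POST_DEATH_SAMPLE = "post_death_sample"


class Validity(enum.Enum):
    VALID = "valid"
    INVALID = "invalid"
    FLAGGED = "flagged"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class SnpDef:
    """One SNP: identity, genomic location and panel membership."""

    snp_id: str
    chromosome: str
    position_bp: int
    in_icbf800: bool = False
    in_isag100: bool = False
    in_isag200: bool = False
    is_par: bool = False
    cluster_ok: bool = True
    #: TOP-format A/B nucleotide assignments; required only for TOP input
    top_a: str | None = None
    top_b: str | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(
                f"unknown chromosome {self.chromosome!r} for SNP {self.snp_id}"
            )
        if self.position_bp <= 0:
            raise ValueError(
                f"non-positive position {self.position_bp} for SNP {self.snp_id}"
            )
        if self.is_par and self.chromosome != "X":
            raise ValueError(f"is_par set on non-X SNP {self.snp_id}")


def _chrom_sort_key(chrom: str) -> tuple[int, int]:
    if chrom == "X":
        return (1, 0)
    if chrom == "Y":
        return (2, 0)
    if chrom == "MT":
        return (3, 0)
    return (0, int(chrom))


class SnpMap:
    """Ordered collection of :class:`SnpDef`, sorted by (chromosome, position).

    Provides stable integer indexing (the order every call vector follows)
    and precomputed index arrays for the common SNP subsets.
    """

    def __init__(self, snps: Iterable[SnpDef]):
        snps = sorted(snps, key=lambda s: _chrom_sort_key(s.chromosome) + (s.position_bp,))
        seen: dict[str, int] = {}
        for i, s in enumerate(snps):
            if s.snp_id in seen:
                raise ValueError(f"duplicate snp_id {s.snp_id!r} in SNP map")
            seen[s.snp_id] = i
        self._snps: list[SnpDef] = snps
        self._index: dict[str, int] = seen

    def __len__(self) -> int:
        return len(self._snps)

    def __iter__(self) -> Iterator[SnpDef]:
        return iter(self._snps)

    def __getitem__(self, i: int) -> SnpDef:
        return self._snps[i]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def index_of(self, snp_id: str) -> int:
        return self._index[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self._snps]

    def _mask(self, pred) -> np.ndarray:
        return np.fromiter((pred(s) for s in self._snps), dtype=bool, count=len(self._snps))

    @property
    def panel_index(self) -> np.ndarray:
        """Integer indices of ICBF800-style parentage-panel SNPs, map order."""
        return np.flatnonzero(self._mask(lambda s: s.in_icbf800))

    @property
    def autosomal_index(self) -> np.ndarray:
        return np.flatnonzero(self._mask(lambda s: s.chromosome in AUTOSOMES))

    @property
    def chrx_index(self) -> np.ndarray:
        return np.flatnonzero(self._mask(lambda s: s.chromosome == "X"))

    @property
    def chrx_npar_index(self) -> np.ndarray:
        return np.flatnonzero(self._mask(lambda s: s.chromosome == "X" and not s.is_par))

    @property
    def chrx_par_index(self) -> np.ndarray:
        return np.flatnonzero(self._mask(lambda s: s.chromosome == "X" and s.is_par))

    @property
    def chry_index(self) -> np.ndarray:
        return np.flatnonzero(self._mask(lambda s: s.chromosome == "Y"))


@dataclass
class GenotypeRecord:
    """One genotyped sample: integer calls aligned to a SnpMap."""

    sample_id: str
    animal_id: str
    calls: np.ndarray
    chip_name: str = ""
    sample_collection_date: date | None = None
    genotyping_date: date | None = None
    valid: Validity = Validity.VALID
    flags: set[QCFlag] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        bad = ~np.isin(self.calls, (0, 1, 2, 9))
        if bad.any():
            raise ValueError(
                f"sample {self.sample_id}: calls outside {{0,1,2,9}} at "
                f"indices {np.flatnonzero(bad)[:5].tolist()}"
            )

    def n_called(self, index: np.ndarray | None = None) -> int:
        calls = self.calls if index is None else self.calls[index]
        return int((calls != CALL_MISSING).sum())

    def copy(self) -> "GenotypeRecord":
        return replace(self, calls=self.calls.copy(), flags=set(self.flags))


class AnimalClass(enum.Enum):
    COMMERCIAL = "commercial"
    PEDIGREE = "pedigree"
    AI_SIRE = "ai_sire"
    STOCK_BULL = "stock_bull"


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


@dataclass
class Animal:
    """Pedigree/metadata record for one animal.

    Breed composition uses the national convention of 32 discrete parts;
    parts not assigned to any breed are "unknown" ancestry.
    """

    animal_id: str
    recorded_sex: Sex = Sex.UNKNOWN
    dob: date | None = None
    death_date: date | None = None
    listed_sire: str | None = None
    listed_dam: str | None = None
    breed_composition_32nds: Mapping[str, int] = field(default_factory=dict)
    animal_class: AnimalClass = AnimalClass.COMMERCIAL
    herd_intervals: Sequence[tuple[str, date, date | None]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        total = sum(self.breed_composition_32nds.values())
        if total > 32:
            raise ValueError(
                f"animal {self.animal_id}: breed parts sum to {total} > 32"
            )

    def herd_at(self, when: date) -> str | None:
        for herd, start, end in self.herd_intervals:
            if start <= when and (end is None or when <= end):
                return herd
        return None

    def herds_ever(self) -> set[str]:
        return {h for h, _, _ in self.herd_intervals}


@dataclass(frozen=True)
class Thresholds:
    """Every numeric constant of the QC and parentage rules, in one record.

    Defaults follow the national-pipeline operating points: animal call rate
    >= 0.90 to use a genotype, per-SNP call rate >= 0.85 for a SNP to count,
    parentage validated at <= 4 panel mismatches / failed at >= 13, the
    5-12 gray zone resolved on all shared SNPs at a 1% misconcordance rate,
    and so on.
    """

    animal_cr_min: float = 0.90
    snp_cr_min_for_use: float = 0.85
    geno_class_freq_min: float = 0.20
    validate_max_mm: int = 4
    fail_min_mm: int = 13
    gray_full_snp_rate_max: float = 0.01
    predict_min_panel_calls: int = 600
    parent_age_gap_months: int = 15
    duplicate_identity_min: float = 0.99
    block_size: int = 20
    legacy_block_size: int = 50
    msm_flag_rate: float = 0.01
    chry_female_max: int = 1
    chry_male_min: int = 6
    chrx_male_het_max: float = 0.05
    chrx_female_het_min: float = 0.15
    chrx_min_npar_calls: int = 20
    par_snp_maf_min: float = 0.01
    par_snp_cr_min: float = 0.90
    par_male_het_min: float = 0.05
    dam_offspring_flag_n: int = 2
    stockbull_offspring_flag_n: int = 5
    aibull_offspring_flag_n: int = 10
    offspring_fail_frac: float = 0.80
    dead_sample_days: int = 45
    panel_maf_min: float = 0.25
    panel_cr_min: float = 0.90
    breed_mismatch_tol: float = 0.40
    breed_min_ref_per_breed: int = 25
    breed_min_overlap_snps: int = 1000

    def __post_init__(self) -> None:
        if not self.validate_max_mm < self.fail_min_mm:
            raise ValueError("validate_max_mm must be < fail_min_mm")
        for name in (
            "animal_cr_min", "snp_cr_min_for_use", "geno_class_freq_min",
            "gray_full_snp_rate_max", "duplicate_identity_min", "msm_flag_rate",
            "chrx_male_het_max", "chrx_female_het_min", "par_snp_maf_min",
            "par_snp_cr_min", "offspring_fail_frac", "panel_maf_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


DEFAULT_THRESHOLDS = Thresholds()
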