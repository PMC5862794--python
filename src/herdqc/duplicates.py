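"""Duplicate-sample discovery via genotype block strings.

Two different animals should never share a genotype, so (identical twins
aside) a pair of near-identical genotypes signals a farm or lab error.
Comparing every pair of samples across a national database is infeasible,
so candidate pairs are found cheaply first: each sample's panel calls are
rendered as a numeric string over {0,1,2,9} (e.g. ``"001290021"``), the
string is cut into fixed non-overlapping blocks, and two samples become a
candidate pair when at least one block matches byte-for-byte.  Because a
missing call ('9') only matches another '9', random missingness can spoil
every 50-SNP block of a true duplicate — the reason the default block size
is 20 (40 blocks per 800-SNP string) rather than the original 50 (16
blocks).  Candidates are then confirmed by SNP-by-SNP identity, missing
sites excluded, first on the panel and then on all shared SNPs; both
identities must reach 99%.
"""

from __future__ import annotations

import enum
import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .types import (
    CALL_MISSING,
    DEFAULT_THRESHOLDS,
    Animal,
    GenotypeRecord,
    QCFlag,
    Thresholds,
    Validity,
)


class DupStatus(enum.Enum):
    CANDIDATE = "candidate"
    CONFIRMED = "confirmed"
    REJECTED = "rejected"


@dataclass
class DuplicateResult:
    sample_a: str
    sample_b: str
    status: DupStatus
    matched_blocks: list[int] = field(default_factory=list)
    panel_identity: float | None = None
    full_identity: float | None = None
    possible_twins: bool = False


def encode_panel_string(record: GenotypeRecord, panel: np.ndarray) -> str:
    """Render the panel calls as a numeric string over {0,1,2,9}."""
    return "".join(chr(48 + c) for c in record.calls[panel])


def block_index(
    strings: dict[str, str], block_size: int
) -> dict[tuple[int, str], list[str]]:
    """Group samples by exact block content.

    Key ``(block_no, substring)`` maps to the samples whose string has that
    exact substring in that block; a missing '9' only matches another '9'.
    """
    lengths = {len(s) for s in strings.values()}
    if len(lengths) > 1:
        raise ValueError("all panel strings must have equal length")
    (length,) = lengths or {0}
    if length % block_size != 0:
        raise ValueError(f"block size {block_size} does not divide string length {length}")
    index: dict[tuple[int, str], list[str]] = defaultdict(list)
    for sample_id in sorted(strings):
        s = strings[sample_id]
        for b in range(length // block_size):
            index[(b, s[b * block_size : (b + 1) * block_size])].append(sample_id)
    return dict(index)


def find_duplicate_candidates(
    records: list[GenotypeRecord],
    panel: np.ndarray,
    block_size: int = DEFAULT_THRESHOLDS.block_size,
) -> list[tuple[str, str]]:
    """Unordered unique sample pairs sharing at least one exact block."""
    strings = {r.sample_id: encode_panel_string(r, panel) for r in records}
    pairs: set[tuple[str, str]] = set()
    for (_, _), samples in block_index(strings, block_size).items():
        if len(samples) > 1:
            for a, b in itertools.combinations(samples, 2):
                pairs.add((a, b) if a < b else (b, a))
    return sorted(pairs)


def matched_block_numbers(s_a: str, s_b: str, block_size: int) -> list[int]:
    return [
        b
        for b in range(len(s_a) // block_size)
        if s_a[b * block_size : (b + 1) * block_size]
        == s_b[b * block_size : (b + 1) * block_size]
    ]


def genotype_identity(
    a: np.ndarray, b: np.ndarray, index: np.ndarray
) -> tuple[float, int]:
    """Fraction of mutually non-missing sites in *index* with equal calls."""
    av, bv = a[index], b[index]
    both = (av != CALL_MISSING) & (bv != CALL_MISSING)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no mutually non-missing SNPs")
    return float((av[both] == bv[both]).sum() / n), n


def _possible_twins(an_a: Animal | None, an_b: Animal | None) -> bool:
    # identical twins: different animals, shared dam, DOB within a week
    if an_a is None or an_b is None or an_a.animal_id == an_b.animal_id:
        return False
    if not an_a.listed_dam or an_a.listed_dam != an_b.listed_dam:
        return False
    if an_a.dob is None or an_b.dob is None:
        return False
    return abs((an_a.dob - an_b.dob).days) <= 7


def confirm_duplicates(
    pairs: list[tuple[str, str]],
    records: list[GenotypeRecord],
    panel: np.ndarray,
    all_snps: np.ndarray,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    animals: dict[str, Animal] | None = None,
    block_size: int | None = None,
) -> list[DuplicateResult]:
    """Confirm candidate pairs by panel and full-SNP identity (both >= 99%).

    Confirmed pairs between different animal_ids have both genotypes set to
    ``unresolved`` pending animal-QC resolution, except pairs consistent
    with identical twins (same dam, same DOB +/- 7 days), which are labeled
    and left alone — twins genuinely share a genotype.
    """
    by_sample = {r.sample_id: r for r in records}
    block_size = block_size or thresholds.block_size
    out = []
    for a_id, b_id in pairs:
        ra, rb = by_sample[a_id], by_sample[b_id]
        blocks = matched_block_numbers(
            encode_panel_string(ra, panel), encode_panel_string(rb, panel), block_size
        )
        panel_id, _ = genotype_identity(ra.calls, rb.calls, panel)
        full_id, _ = genotype_identity(ra.calls, rb.calls, all_snps)
        confirmed = (
            panel_id >= thresholds.duplicate_identity_min
            and full_id >= thresholds.duplicate_identity_min
        )
        twins = False
        if confirmed and animals is not None:
            twins = _possible_twins(animals.get(ra.animal_id), animals.get(rb.animal_id))
        if confirmed and not twins and ra.animal_id != rb.animal_id:
            for r in (ra, rb):
                r.valid = Validity.UNRESOLVED
                r.flags.add(QCFlag.SNP_DUPLICATE)
        out.append(
            DuplicateResult(
                sample_a=a_id,
                sample_b=b_id,
                status=DupStatus.CONFIRMED if confirmed else DupStatus.REJECTED,
                matched_blocks=blocks,
                panel_identity=panel_id,
                full_identity=full_id,
                possible_twins=twins,
            )
        )
    return out


def reconcile_multi_genotypes(
    animal_id: str,
    records: list[GenotypeRecord],
    panel: np.ndarray,
    all_snps: np.ndarray,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[str, list[DuplicateResult]]:
    """Check that repeat genotypes of one animal agree.

    Cross-platform concordance for a true resample exceeds 99%, so any pair
    of this animal's genotypes below 99% on both the panel and the full
    shared SNP set indicates that at least one genotype belongs to a
    different animal.  Returns ("consistent" | "conflict", pairwise results);
    on conflict all involved genotypes become unresolved.
    """
    if len(records) < 2:
        raise ValueError(f"animal {animal_id}: need >= 2 genotypes to reconcile")
    results = []
    conflict = False
    for ra, rb in itertools.combinations(records, 2):
        panel_id, _ = genotype_identity(ra.calls, rb.calls, panel)
        full_id, _ = genotype_identity(ra.calls, rb.calls, all_snps)
        ok = (
            panel_id >= thresholds.duplicate_identity_min
            or full_id >= thresholds.duplicate_identity_min
        )
        results.append(
            DuplicateResult(
                sample_a=ra.sample_id,
                sample_b=rb.sample_id,
                status=DupStatus.CONFIRMED if ok else DupStatus.REJECTED,
                panel_identity=panel_id,
                full_identity=full_id,
            )
        )
        if not ok:
            conflict = True
            for r in (ra, rb):
                r.valid = Validity.UNRESOLVED
                r.flags.add(QCFlag.MULTI_GENOTYPE_CONFLICT)
    return ("conflict" if conflict else "consistent"), results
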