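"""Seeded gene-drop herd simulator with a complete truth ledger.

Founder allele frequencies are drawn per breed around shared base
frequencies (Balding-Nichols Beta divergence); genotypes descend through a
discrete-generation pedigree by Mendelian sampling with no recombination
model (the QC checks nowhere depend on LD).  Sex chromosomes are explicit:
males are hemizygous on non-PAR chrX (a second PAR-only haplotype rides on
Y, so the PAR is diploid in both sexes) and only males yield chrY calls.
Per-call error and missingness are applied last.

Fault scenarios reproduce the error taxonomy a national database sees:
the same animal sampled twice under different labels (duplicate
submission), genotypes assigned to the wrong sample (swap), mislabelled
sex, misrecorded listed parents, and format-corrupted exports.  Every
fault is written to the truth ledger so downstream detections can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .types import (
    Animal,
    AnimalClass,
    CALL_MISSING,
    GenotypeRecord,
    Sex,
    SnpDef,
    SnpMap,
)


@dataclass
class SimConfig:
    """Study conditions for the simulated herd.

    Panel allele-A frequencies are drawn Uniform(0.42, 0.58) so panel MAF
    is ~Uniform(0.42, 0.50), matching a high-MAF parentage panel; per-call
    error is 0.2% (typical array discordance) and the listed-pedigree
    misrecording rate defaults to 8%, the middle of the 7-9% national
    range.
    """

    seed: int = 0
    n_breeds: int = 2
    n_panel: int = 800
    n_extra_autosomal: int = 200
    n_chrx: int = 120
    n_chry: int = 7
    par_fraction: float = 0.10        # distal fraction of chrX in the PAR
    n_founders_per_breed: int = 50
    n_generations: int = 2            # offspring generations below founders
    n_offspring_per_breed_per_gen: int = 75
    fst: float = 0.05                 # founder divergence between breeds
    panel_freq_low: float = 0.42
    panel_freq_high: float = 0.58
    error_rate: float = 0.002
    missing_rate: float = 0.005
    parent_misrecording: float = 0.08
    sample_swap: float = 0.0
    duplicate_submission: float = 0.0
    sex_mislabel: float = 0.0
    mixed_format_corruption: float = 0.0
    n_herds: int = 4
    generation_gap_months: int = 24
    base_dob: date = date(2010, 3, 1)


@dataclass
class TruthLedger:
    """Ground truth for every emitted record — the scoring oracle."""

    true_sire: dict[str, str | None] = field(default_factory=dict)
    true_dam: dict[str, str | None] = field(default_factory=dict)
    true_sex: dict[str, Sex] = field(default_factory=dict)
    true_breed: dict[str, dict[str, float]] = field(default_factory=dict)
    sample_to_animal: dict[str, str] = field(default_factory=dict)
    true_calls: dict[str, np.ndarray] = field(default_factory=dict)
    misrecorded_parents: dict[str, set[str]] = field(default_factory=dict)
    faults: list[dict] = field(default_factory=list)


@dataclass
class SimResult:
    snp_map: SnpMap
    records: list[GenotypeRecord]
    animals: dict[str, Animal]
    ledger: TruthLedger
    config: SimConfig


def _balding_nichols(base: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    if fst <= 0:
        return base.copy()
    a = base * (1 - fst) / fst
    b = (1 - base) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 0.01, 0.99)


def build_sim_snp_map(config: SimConfig) -> tuple[SnpMap, dict[str, np.ndarray]]:
    """SNP map for the simulator plus named index arrays.

    Autosomal SNPs are spread over chromosomes 1..29 (panel SNPs flagged
    in_icbf800); chrX carries the distal ``par_fraction`` of its positions
    as PAR; chrY holds ``n_chry`` SNPs.
    """
    if config.n_chrx < 2 or not 0 < config.par_fraction < 1:
        raise ValueError(
            "chrX needs at least 2 SNPs with a PAR fraction strictly inside "
            f"(0, 1); got n_chrx={config.n_chrx}, par_fraction={config.par_fraction}"
        )
    snps = []
    n_auto = config.n_panel + config.n_extra_autosomal
    for j in range(n_auto):
        chrom = str(j % 29 + 1)
        snps.append(
            SnpDef(
                snp_id=f"AUT{j:05d}",
                chromosome=chrom,
                position_bp=1000 + (j // 29) * 1000,
                in_icbf800=j < config.n_panel,
                cluster_ok=True,
            )
        )
    n_par = max(1, int(round(config.n_chrx * config.par_fraction)))
    for j in range(config.n_chrx):
        is_par = j >= config.n_chrx - n_par  # distal end of the chromosome
        snps.append(
            SnpDef(
                snp_id=f"CHRX{j:04d}",
                chromosome="X",
                position_bp=1000 + j * 1000,
                is_par=is_par,
            )
        )
    for j in range(config.n_chry):
        snps.append(
            SnpDef(snp_id=f"CHRY{j:02d}", chromosome="Y", position_bp=1000 + j * 1000)
        )
    snp_map = SnpMap(snps)
    return snp_map, {
        "panel": snp_map.panel_index,
        "autosomal": snp_map.autosomal_index,
        "chrx": snp_map.chrx_index,
        "chrx_par": snp_map.chrx_par_index,
        "chrx_npar": snp_map.chrx_npar_index,
        "chry": snp_map.chry_index,
    }


def _draw_frequencies(
    snp_map: SnpMap, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n_breeds, n_snps) allele-A frequencies."""
    n = len(snp_map)
    base = np.empty(n)
    for i, s in enumerate(snp_map):
        if s.in_icbf800:
            base[i] = rng.uniform(config.panel_freq_low, config.panel_freq_high)
        else:
            base[i] = rng.uniform(0.10, 0.90)
    return np.stack([_balding_nichols(base, config.fst, rng) for _ in range(config.n_breeds)])


class _Haplotypes:
    """Per-animal haplotypes: two autosome/X strands plus a Y strand.

    ``x2`` is the second X strand: a real X in females; in males its
    non-PAR part is unused and its PAR part is the Y-borne PAR strand.
    """

    __slots__ = ("x1", "x2", "y")

    def __init__(self, x1: np.ndarray, x2: np.ndarray, y: np.ndarray):
        self.x1, self.x2, self.y = x1, x2, y


def _founder_haps(freqs: np.ndarray, chry_freq: np.ndarray,
                  rng: np.random.Generator) -> _Haplotypes:
    n = freqs.size
    return _Haplotypes(
        x1=(rng.random(n) < freqs).astype(np.int8),
        x2=(rng.random(n) < freqs).astype(np.int8),
        y=(rng.random(chry_freq.size) < chry_freq).astype(np.int8),
    )


def _gamete(h: _Haplotypes, rng: np.random.Generator) -> np.ndarray:
    pick = rng.integers(0, 2, h.x1.size).astype(np.int8)
    return np.where(pick == 0, h.x1, h.x2)


def _calls_for(
    h: _Haplotypes, sex: Sex, idx: dict[str, np.ndarray], n_snps: int
) -> np.ndarray:
    calls = np.empty(n_snps, dtype=np.int8)
    diploid = h.x1 + h.x2
    calls[:] = diploid
    if sex is Sex.MALE:
        npar = idx["chrx_npar"]
        calls[npar] = 2 * h.x1[npar]  # hemizygous: appears homozygous
        calls[idx["chry"]] = 2 * h.y
    else:
        calls[idx["chry"]] = CALL_MISSING
    return calls


def apply_noise(
    calls: np.ndarray,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-call error (uniform flip to another class) then missingness."""
    out = calls.copy()
    called = out != CALL_MISSING
    flip = called & (rng.random(out.size) < error_rate)
    shift = rng.integers(1, 3, out.size).astype(np.int8)
    out[flip] = (out[flip] + shift[flip]) % 3
    out[called & (rng.random(out.size) < missing_rate)] = CALL_MISSING
    return out


def simulate_herd(config: SimConfig) -> SimResult:
    """Gene-drop a multi-breed pedigreed herd; every truth is ledgered."""
    rng = np.random.default_rng(config.seed)
    snp_map, idx = build_sim_snp_map(config)
    n_snps = len(snp_map)
    freqs = _draw_frequencies(snp_map, config, rng)
    chry_freq = rng.uniform(0.3, 0.7, size=len(idx["chry"]))
    breeds = [f"B{k}" for k in range(config.n_breeds)]

    ledger = TruthLedger()
    animals: dict[str, Animal] = {}
    haps: dict[str, _Haplotypes] = {}
    by_gen_breed: dict[tuple[int, int], list[str]] = {}

    def register(aid, sex, gen, breed_k, sire, dam, cls):
        dob = config.base_dob + timedelta(
            days=int(gen * config.generation_gap_months * 30.44)
            + int(rng.integers(0, 90))
        )
        herd = f"H{int(rng.integers(0, config.n_herds))}"
        animals[aid] = Animal(
            animal_id=aid,
            recorded_sex=sex,
            dob=dob,
            listed_sire=sire,
            listed_dam=dam,
            breed_composition_32nds={breeds[breed_k]: 32},
            animal_class=cls,
            herd_intervals=((herd, dob, None),),
        )
        ledger.true_sex[aid] = sex
        ledger.true_sire[aid] = sire
        ledger.true_dam[aid] = dam
        ledger.true_breed[aid] = {breeds[breed_k]: 1.0}
        by_gen_breed.setdefault((gen, breed_k), []).append(aid)

    # founders
    for k in range(config.n_breeds):
        for i in range(config.n_founders_per_breed):
            aid = f"{breeds[k]}G0A{i:04d}"
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            haps[aid] = _founder_haps(freqs[k], chry_freq, rng)
            cls = AnimalClass.STOCK_BULL if sex is Sex.MALE else AnimalClass.COMMERCIAL
            register(aid, sex, 0, k, None, None, cls)

    # descendant generations
    for gen in range(1, config.n_generations + 1):
        for k in range(config.n_breeds):
            prev = by_gen_breed[(gen - 1, k)]
            sires = [a for a in prev if ledger.true_sex[a] is Sex.MALE]
            dams = [a for a in prev if ledger.true_sex[a] is Sex.FEMALE]
            for i in range(config.n_offspring_per_breed_per_gen):
                aid = f"{breeds[k]}G{gen}A{i:04d}"
                sire = sires[int(rng.integers(0, len(sires)))]
                dam = dams[int(rng.integers(0, len(dams)))]
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                h_s, h_d = haps[sire], haps[dam]
                from_dam = _gamete(h_d, rng)
                if sex is Sex.MALE:
                    # son: dam X + sire Y (PAR strand rides on Y: x2's PAR part)
                    x2 = np.zeros(n_snps, dtype=np.int8)
                    par = idx["chrx_par"]
                    sire_par_pick = rng.integers(0, 2, par.size)
                    x2[par] = np.where(sire_par_pick == 0, h_s.x1[par], h_s.x2[par])
                    auto = idx["autosomal"]
                    from_sire_auto = _gamete(h_s, rng)
                    x2[auto] = from_sire_auto[auto]
                    haps[aid] = _Haplotypes(x1=from_dam, x2=x2, y=h_s.y.copy())
                else:
                    from_sire = _gamete(h_s, rng)
                    x = idx["chrx"]
                    from_sire = from_sire.copy()
                    from_sire[x] = h_s.x1[x]  # daughters get the paternal X
                    par = idx["chrx_par"]
                    sire_par_pick = rng.integers(0, 2, par.size)
                    from_sire[par] = np.where(
                        sire_par_pick == 0, h_s.x1[par], h_s.x2[par]
                    )
                    haps[aid] = _Haplotypes(
                        x1=from_dam, x2=from_sire,
                        y=np.full(len(idx["chry"]), 0, dtype=np.int8),
                    )
                register(aid, sex, gen, k, sire, dam, AnimalClass.COMMERCIAL)

    # misrecord listed parents
    all_ids = list(animals)
    for aid in all_ids:
        for role, pool_sex in (("sire", Sex.MALE), ("dam", Sex.FEMALE)):
            listed = getattr(animals[aid], f"listed_{role}")
            if listed is None or rng.random() >= config.parent_misrecording:
                continue
            gen = next(g for (g, k), ids in by_gen_breed.items() if aid in ids)
            pool = [
                a
                for (g, k), ids in by_gen_breed.items()
                if g == gen - 1
                for a in ids
                if ledger.true_sex[a] is pool_sex and a != listed
            ]
            if not pool:
                continue
            wrong = pool[int(rng.integers(0, len(pool)))]
            if role == "sire":
                animals[aid].listed_sire = wrong
            else:
                animals[aid].listed_dam = wrong
            ledger.misrecorded_parents.setdefault(aid, set()).add(role)
            ledger.faults.append(
                {"kind": "parent_misrecording", "animal": aid, "role": role,
                 "listed": wrong, "true": listed}
            )

    # emit genotype records
    records: list[GenotypeRecord] = []
    for aid in all_ids:
        true_calls = _calls_for(haps[aid], ledger.true_sex[aid], idx, n_snps)
        ledger.true_calls[aid] = true_calls
        sid = f"S_{aid}"
        rec = GenotypeRecord(
            sample_id=sid,
            animal_id=aid,
            calls=apply_noise(true_calls, config.error_rate, config.missing_rate, rng),
            chip_name="SIMLD",
            sample_collection_date=animals[aid].dob + timedelta(days=30),
            genotyping_date=animals[aid].dob + timedelta(days=60),
        )
        ledger.sample_to_animal[sid] = aid
        records.append(rec)

    result = SimResult(snp_map, records, animals, ledger, config)
    inject_faults(result, rng)
    return result


def inject_faults(result: SimResult, rng: np.random.Generator) -> None:
    """Apply the configured fault scenarios in place, updating the ledger."""
    config, ledger = result.config, result.ledger
    records, animals = result.records, result.animals

    if config.duplicate_submission > 0:
        n_dup = rng.binomial(len(records), config.duplicate_submission)
        for i in rng.choice(len(records), size=n_dup, replace=False):
            src = records[int(i)]
            aid = src.animal_id
            new_sid = f"DUP_{src.sample_id}"
            dup = GenotypeRecord(
                sample_id=new_sid,
                animal_id=aid,
                calls=apply_noise(
                    ledger.true_calls[aid], config.error_rate,
                    config.missing_rate, rng,
                ),
                chip_name="SIMLD2",
                sample_collection_date=src.sample_collection_date,
                genotyping_date=src.genotyping_date,
            )
            ledger.sample_to_animal[new_sid] = aid
            ledger.faults.append(
                {"kind": "duplicate_submission", "sample": new_sid, "of": src.sample_id}
            )
            records.append(dup)

    if config.sample_swap > 0:
        n_swap = rng.binomial(len(records) // 2, config.sample_swap)
        pool = rng.permutation(len(records))
        for p in range(n_swap):
            i, j = int(pool[2 * p]), int(pool[2 * p + 1])
            records[i].animal_id, records[j].animal_id = (
                records[j].animal_id, records[i].animal_id,
            )
            ledger.faults.append(
                {"kind": "sample_swap",
                 "samples": [records[i].sample_id, records[j].sample_id]}
            )

    if config.sex_mislabel > 0:
        ids = list(animals)
        n_mis = rng.binomial(len(ids), config.sex_mislabel)
        for i in rng.choice(len(ids), size=n_mis, replace=False):
            a = animals[ids[int(i)]]
            a.recorded_sex = Sex.FEMALE if a.recorded_sex is Sex.MALE else Sex.MALE
            ledger.faults.append({"kind": "sex_mislabel", "animal": a.animal_id})


def to_long_frame(
    records: list[GenotypeRecord],
    snp_map: SnpMap,
    corrupt_samples: set[str] = frozenset(),
    corrupt_rate: float = 0.02,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Render records as a long AB-format allele table.

    Samples in *corrupt_samples* have a fraction of their allele symbols
    rewritten as TOP nucleotides, emulating a mixed-format export.
    """
    rng = rng or np.random.default_rng(0)
    pair_for = {0: ("B", "B"), 1: ("A", "B"), 2: ("A", "A"), 9: ("-", "-")}
    rows = []
    ids = snp_map.snp_ids
    for rec in records:
        corrupt = rec.sample_id in corrupt_samples
        for i, call in enumerate(rec.calls):
            a1, a2 = pair_for[int(call)]
            if corrupt and call != 9 and rng.random() < corrupt_rate:
                a1 = "T" if a1 == "A" else "G"
            rows.append((rec.sample_id, ids[i], a1, a2))
    return pd.DataFrame(rows, columns=["sample_id", "snp_id", "allele1", "allele2"])


def simulate_breed_reference(
    n_breeds: int = 3,
    n_snps: int = 5000,
    n_ref_per_breed: int = 500,
    fst: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Divergent per-breed allele frequencies plus purebred reference calls.

    Returns ``(freqs (K, J), ref_calls (K*n_ref, J), breed_of_row)`` —
    enough to exercise supervised-admixture recovery without a pedigree.
    The default of 500 purebreds per breed is the floor a production
    reference population uses; fewer reference animals leave visible
    sampling noise in the frequency matrix and degrade recovery.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.1, 0.9, n_snps)
    freqs = np.stack([_balding_nichols(base, fst, rng) for _ in range(n_breeds)])
    calls = []
    breed_of_row = []
    for k in range(n_breeds):
        calls.append(rng.binomial(2, freqs[k], size=(n_ref_per_breed, n_snps)))
        breed_of_row += [f"B{k}"] * n_ref_per_breed
    return freqs, np.concatenate(calls).astype(np.int8), breed_of_row


def sample_admixed_genotypes(
    q: np.ndarray, freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n genotype vectors for ancestry fractions q over breed freqs.

    Each of the two alleles independently picks a breed ~ q then an allele
    ~ that breed's frequency (the admixture model itself).
    """
    k, j = freqs.shape
    out = np.zeros((n, j), dtype=np.int8)
    for allele in range(2):
        origin = rng.choice(k, size=(n, j), p=q)
        out += (rng.random((n, j)) < freqs[origin, np.arange(j)]).astype(np.int8)
    return out
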