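"""Readers and writers for the file formats the pipeline exchanges.

Formats
-------
snp_map.tsv
    Tab-separated, header ``snp_id  chromosome  position_bp  in_icbf800
    in_isag100  in_isag200  is_par  cluster_ok  [top_a  top_b]``.
    Boolean columns accept 0/1 or true/false.
genotypes_long.csv
    Comma-separated, header ``sample_id,snp_id,allele1,allele2``; missing
    alleles written ``-`` (or the pair ``--``).  Alleles are Illumina AB
    symbols, or TOP nucleotides when the reader is told ``fmt="TOP"``.
genotypes_matrix.tsv
    Tab-separated; first column ``sample_id``, one column per SNP in map
    order, cells in {0,1,2,9}.
PLINK .ped/.map
    Text PED with the 6 leading columns and two allele columns per SNP;
    ``0`` is the missing allele.  Alleles may be A/B or TOP nucleotides.
animals.csv
    Animal metadata/pedigree (see :func:`read_animals`).

SNPs present in genotype data but absent from the SNP map are dropped with
a count, not errors: national databases mix chips and the pipeline operates
on the intersection.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

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

logger = logging.getLogger(__name__)

_MISSING_ALLELES = {"-", "--", "0", ""}
_AB_ALPHABET = {"A", "B"} | _MISSING_ALLELES
_TOP_ALPHABET = {"A", "C", "G", "T"} | _MISSING_ALLELES


class FormatAnomalyError(ValueError):
    """Raised when allele symbols fall outside the declared format.

    Carries the offending ``(sample_id, snp_id, allele)`` rows so the
    genotype-QC mixed-format check can report them.
    """

    def __init__(self, declared: str, rows: list[tuple[str, str, str]]):
        self.declared = declared
        self.rows = rows
        shown = ", ".join(f"({s},{m},{a})" for s, m, a in rows[:5])
        super().__init__(
            f"{len(rows)} allele(s) outside the {declared} alphabet: {shown}"
        )


def _parse_bool(v: str) -> bool:
    return str(v).strip().lower() in {"1", "true", "t", "yes"}


def read_snp_map(path: str | Path) -> SnpMap:
    """Read a SNP map TSV; returns SNPs sorted by (chromosome, position)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "chromosome", "position_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP map missing columns: {sorted(missing)}")
    dupes = df["snp_id"][df["snp_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate snp_id in map: {dupes.iloc[0]!r}")
    snps = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        snps.append(
            SnpDef(
                snp_id=d["snp_id"],
                chromosome=str(d["chromosome"]),
                position_bp=int(d["position_bp"]),
                in_icbf800=_parse_bool(d.get("in_icbf800", "0")),
                in_isag100=_parse_bool(d.get("in_isag100", "0")),
                in_isag200=_parse_bool(d.get("in_isag200", "0")),
                is_par=_parse_bool(d.get("is_par", "0")),
                cluster_ok=_parse_bool(d.get("cluster_ok", "1")),
                top_a=d.get("top_a") if pd.notna(d.get("top_a")) else None,
                top_b=d.get("top_b") if pd.notna(d.get("top_b")) else None,
            )
        )
    return SnpMap(snps)


def write_snp_map(snp_map: SnpMap, path: str | Path) -> None:
    rows = []
    for s in snp_map:
        rows.append(
            {
                "snp_id": s.snp_id,
                "chromosome": s.chromosome,
                "position_bp": s.position_bp,
                "in_icbf800": int(s.in_icbf800),
                "in_isag100": int(s.in_isag100),
                "in_isag200": int(s.in_isag200),
                "is_par": int(s.is_par),
                "cluster_ok": int(s.cluster_ok),
                "top_a": s.top_a or "",
                "top_b": s.top_b or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _encode_pair(a1: str, a2: str, a_sym: str, b_sym: str) -> int:
    if a1 in _MISSING_ALLELES or a2 in _MISSING_ALLELES:
        return CALL_MISSING
    n_a = (a1 == a_sym) + (a2 == a_sym)
    n_b = (a1 == b_sym) + (a2 == b_sym)
    if n_a + n_b != 2:
        raise ValueError(f"alleles ({a1},{a2}) not in {{{a_sym},{b_sym}}}")
    return n_a  # 2=AA, 1=AB, 0=BB


def read_genotypes_long(
    path: str | Path,
    snp_map: SnpMap,
    fmt: str = "AB",
) -> list[GenotypeRecord]:
    """Read a long-format genotype CSV into records aligned to *snp_map*.

    ``fmt="AB"`` expects Illumina AB symbols; ``fmt="TOP"`` expects TOP
    nucleotides and converts to AB through the per-SNP ``top_a``/``top_b``
    columns of the map (refusing to guess when they are absent).  Any allele
    symbol outside the declared alphabet raises :class:`FormatAnomalyError`
    listing the offending rows.
    """
    fmt = fmt.upper()
    if fmt not in {"AB", "TOP"}:
        raise ValueError(f"unknown genotype format {fmt!r}")
    alphabet = _AB_ALPHABET if fmt == "AB" else _TOP_ALPHABET

    df = pd.read_csv(
        path, dtype=str, keep_default_na=False,
        usecols=["sample_id", "snp_id", "allele1", "allele2"],
    )
    bad_rows: list[tuple[str, str, str]] = []
    for col in ("allele1", "allele2"):
        bad = ~df[col].isin(alphabet)
        for r in df[bad].itertuples(index=False):
            bad_rows.append((r.sample_id, r.snp_id, getattr(r, col)))
    if bad_rows:
        raise FormatAnomalyError(fmt, sorted(set(bad_rows)))

    known = df["snp_id"].isin(set(snp_map.snp_ids))
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropped %d rows with snp_ids absent from map", n_dropped)
        df = df[known]

    records: list[GenotypeRecord] = []
    n_snps = len(snp_map)
    for sample_id, grp in df.groupby("sample_id", sort=True):
        calls = np.full(n_snps, CALL_MISSING, dtype=np.int8)
        for r in grp.itertuples(index=False):
            i = snp_map.index_of(r.snp_id)
            snp = snp_map[i]
            if fmt == "AB":
                a_sym, b_sym = "A", "B"
            else:
                if snp.top_a is None or snp.top_b is None:
                    raise ValueError(
                        f"TOP input but SNP {snp.snp_id} has no top_a/top_b "
                        "alleles in the map"
                    )
                a_sym, b_sym = snp.top_a, snp.top_b
            calls[i] = _encode_pair(r.allele1, r.allele2, a_sym, b_sym)
        records.append(GenotypeRecord(sample_id=str(sample_id),
                                      animal_id=str(sample_id), calls=calls))
    return records


def read_genotypes_matrix(path: str | Path, snp_map: SnpMap) -> list[GenotypeRecord]:
    """Read an integer genotype matrix TSV (samples x SNPs)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns[1:]) != snp_map.snp_ids:
        raise ValueError("matrix columns do not match the SNP map")
    values = df.iloc[:, 1:].to_numpy()
    bad = ~np.isin(values, (0, 1, 2, 9))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"cell value {values[r, c]!r} outside {{0,1,2,9}} at "
            f"sample {df.iloc[r, 0]!r}, SNP {df.columns[c + 1]!r}"
        )
    return [
        GenotypeRecord(sample_id=str(sid), animal_id=str(sid),
                       calls=values[i].astype(np.int8))
        for i, sid in enumerate(df["sample_id"])
    ]


def write_genotypes_matrix(
    records: Iterable[GenotypeRecord], snp_map: SnpMap, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_id"] + snp_map.snp_ids)
        for rec in records:
            w.writerow([rec.sample_id] + rec.calls.astype(int).tolist())


def read_plink_ped(
    map_path: str | Path, ped_path: str | Path, snp_map: SnpMap | None = None
) -> list[GenotypeRecord]:
    """Read a text PLINK PED/MAP pair.

    The .map file gives SNP order; when *snp_map* is provided the calls are
    re-aligned to it (SNPs absent from it are dropped).  Alleles may be A/B
    symbols or TOP nucleotides resolved through the map's top_a/top_b.
    """
    ped_snp_ids: list[str] = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed .map line: {line!r}")
            ped_snp_ids.append(parts[1])

    records: list[GenotypeRecord] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 or (len(parts) - 6) % 2 != 0:
                raise ValueError(
                    f"PED line {lineno}: expected 6 + 2*n_snps fields, "
                    f"got {len(parts)}"
                )
            alleles = parts[6:]
            if len(alleles) != 2 * len(ped_snp_ids):
                raise ValueError(
                    f"PED line {lineno}: {len(alleles) // 2} genotypes for "
                    f"{len(ped_snp_ids)} map SNPs"
                )
            sample_id = parts[1]
            ped_calls = np.full(len(ped_snp_ids), CALL_MISSING, dtype=np.int8)
            for j, snp_id in enumerate(ped_snp_ids):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if snp_map is not None and snp_id in snp_map:
                    snp = snp_map[snp_map.index_of(snp_id)]
                    if snp.top_a is not None and a1 in "ACGT":
                        a_sym, b_sym = snp.top_a, snp.top_b
                    else:
                        a_sym, b_sym = "A", "B"
                else:
                    a_sym, b_sym = "A", "B"
                ped_calls[j] = _encode_pair(a1, a2, a_sym, b_sym)
            if snp_map is None:
                calls = ped_calls
            else:
                calls = np.full(len(snp_map), CALL_MISSING, dtype=np.int8)
                for j, snp_id in enumerate(ped_snp_ids):
                    if snp_id in snp_map:
                        calls[snp_map.index_of(snp_id)] = ped_calls[j]
            records.append(
                GenotypeRecord(sample_id=sample_id, animal_id=sample_id, calls=calls)
            )
    return records


def read_sample_manifest(path: str | Path) -> dict[str, dict]:
    """Read the sample manifest CSV: sample_id -> animal and provenance.

    Columns: ``sample_id, animal_id, chip_name, sample_collection_date,
    genotyping_date`` (dates optional, ISO format).  Matrix files carry
    only sample ids, so the manifest is how a cohort whose sample ids are
    not animal ids (re-genotyped or duplicate-submitted animals) declares
    the mapping.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, dict] = {}
    for r in df.itertuples(index=False):
        d = r._asdict()
        out[d["sample_id"]] = {
            "animal_id": d.get("animal_id") or d["sample_id"],
            "chip_name": d.get("chip_name", ""),
            "sample_collection_date": _parse_date(d.get("sample_collection_date", "")),
            "genotyping_date": _parse_date(d.get("genotyping_date", "")),
        }
    return out


def apply_sample_manifest(
    records: list[GenotypeRecord], manifest: Mapping[str, dict]
) -> None:
    for rec in records:
        meta = manifest.get(rec.sample_id)
        if meta is None:
            continue
        rec.animal_id = meta["animal_id"]
        rec.chip_name = meta.get("chip_name") or rec.chip_name
        rec.sample_collection_date = meta.get("sample_collection_date")
        rec.genotyping_date = meta.get("genotyping_date")


def write_sample_manifest(records: Iterable[GenotypeRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "animal_id": r.animal_id,
            "chip_name": r.chip_name,
            "sample_collection_date": (
                r.sample_collection_date.isoformat() if r.sample_collection_date else ""
            ),
            "genotyping_date": (
                r.genotyping_date.isoformat() if r.genotyping_date else ""
            ),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_date(v: str) -> date | None:
    if v is None or v == "" or (isinstance(v, float) and np.isnan(v)):
        return None
    return datetime.strptime(str(v), "%Y-%m-%d").date()


def _parse_breed(v: str) -> dict[str, int]:
    # "LM:24,AA:8" -> {"LM": 24, "AA": 8}
    if not v:
        return {}
    out: dict[str, int] = {}
    for part in str(v).split(","):
        code, _, n = part.partition(":")
        out[code.strip()] = int(n)
    return out


def read_animals(path: str | Path) -> dict[str, Animal]:
    """Read the animal metadata/pedigree CSV.

    Columns: ``animal_id, recorded_sex, dob, death_date, listed_sire,
    listed_dam, breed_composition, animal_class, herd_intervals``.
    ``breed_composition`` is ``CODE:parts`` pairs in 32nds
    (``"LM:24,AA:8"``); ``herd_intervals`` is ``herd:from:to`` triples
    separated by ``;`` with an empty ``to`` for open intervals.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    animals: dict[str, Animal] = {}
    for r in df.itertuples(index=False):
        d = r._asdict()
        intervals = []
        for iv in d.get("herd_intervals", "").split(";"):
            if not iv:
                continue
            herd, start, end = iv.split(":")
            intervals.append((herd, _parse_date(start), _parse_date(end) if end else None))
        a = Animal(
            animal_id=d["animal_id"],
            recorded_sex=Sex(d.get("recorded_sex") or "unknown"),
            dob=_parse_date(d.get("dob", "")),
            death_date=_parse_date(d.get("death_date", "")),
            listed_sire=d.get("listed_sire") or None,
            listed_dam=d.get("listed_dam") or None,
            breed_composition_32nds=_parse_breed(d.get("breed_composition", "")),
            animal_class=AnimalClass(d.get("animal_class") or "commercial"),
            herd_intervals=tuple(intervals),
        )
        animals[a.animal_id] = a
    return animals


def write_animals(animals: Iterable[Animal], path: str | Path) -> None:
    rows = []
    for a in animals:
        rows.append(
            {
                "animal_id": a.animal_id,
                "recorded_sex": a.recorded_sex.value,
                "dob": a.dob.isoformat() if a.dob else "",
                "death_date": a.death_date.isoformat() if a.death_date else "",
                "listed_sire": a.listed_sire or "",
                "listed_dam": a.listed_dam or "",
                "breed_composition": ",".join(
                    f"{k}:{v}" for k, v in sorted(a.breed_composition_32nds.items())
                ),
                "animal_class": a.animal_class.value,
                "herd_intervals": ";".join(
                    f"{h}:{s.isoformat()}:{e.isoformat() if e else ''}"
                    for h, s, e in a.herd_intervals
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
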