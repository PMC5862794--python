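"""Parentage-panel construction and audit utilities.

A good parentage panel wants SNPs that genotype reliably (high call rate,
clean clusters) and are maximally informative for exclusion (MAF close to
0.5 — the opposing-homozygote probability for an unrelated pair at one SNP
is ``2 p^2 q^2``, maximal at p = 0.5).  Selection keeps ISAG-recommended
SNPs that pass QC and fills the remaining slots by descending MAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    CALL_MISSING,
    DEFAULT_THRESHOLDS,
    Animal,
    GenotypeRecord,
    SnpMap,
    Thresholds,
)


@dataclass
class PanelAudit:
    snp_ids: list[str]
    maf: np.ndarray
    call_rate: np.ndarray
    cluster_ok: np.ndarray
    per_breed_maf: pd.DataFrame | None = None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"snp_id": self.snp_ids, "maf": self.maf, "call_rate": self.call_rate,
             "cluster_ok": self.cluster_ok}
        )
        if self.per_breed_maf is not None:
            df = df.join(self.per_breed_maf, on=None)
        return df


def compute_maf(
    records: list[GenotypeRecord],
    snp_map: SnpMap,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing calls.

    *subset* optionally restricts to a boolean/integer selection of records
    (e.g. listed purebreds of one breed).
    """
    if not records:
        raise ValueError("no records supplied")
    calls = np.stack([r.calls for r in records])
    if subset is not None:
        calls = calls[subset]
    called = calls != CALL_MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_a = np.where(called, calls, 0).sum(axis=0) / (2 * n)
    freq_a = np.where(n > 0, freq_a, np.nan)
    return np.minimum(freq_a, 1.0 - freq_a)


def audit_panel(
    records: list[GenotypeRecord],
    snp_map: SnpMap,
    animals: dict[str, Animal] | None = None,
) -> PanelAudit:
    """MAF / call-rate / cluster audit of every SNP, optionally per breed."""
    calls = np.stack([r.calls for r in records])
    cr = (calls != CALL_MISSING).mean(axis=0)
    maf = compute_maf(records, snp_map)
    per_breed = None
    if animals is not None:
        cols = {}
        breeds: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            a = animals.get(rec.animal_id)
            if a and len(a.breed_composition_32nds) == 1:
                (breed, parts), = a.breed_composition_32nds.items()
                if parts == 32:
                    breeds.setdefault(breed, []).append(i)
        for breed, idx in sorted(breeds.items()):
            cols[f"maf_{breed}"] = compute_maf(records, snp_map, np.array(idx))
        if cols:
            per_breed = pd.DataFrame(cols)
    return PanelAudit(
        snp_ids=snp_map.snp_ids,
        maf=maf,
        call_rate=cr,
        cluster_ok=np.array([s.cluster_ok for s in snp_map]),
        per_breed_maf=per_breed,
    )


def select_panel(
    audit: PanelAudit,
    snp_map: SnpMap,
    size: int = 800,
    must_include: set[str] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[str]:
    """Select a parentage panel of *size* SNPs.

    Hard filters (applied to everything, including *must_include* SNPs):
    clean clustering, call rate >= 0.90, MAF >= 0.25.  Eligible
    must-include SNPs (e.g. the ISAG200) are kept; remaining slots fill by
    descending MAF, ties broken by (chromosome, position).
    """
    must_include = must_include or set()
    eligible = []
    for i, snp_id in enumerate(audit.snp_ids):
        if not audit.cluster_ok[i]:
            continue
        if np.isnan(audit.maf[i]) or audit.maf[i] < thresholds.panel_maf_min:
            continue
        if audit.call_rate[i] < thresholds.panel_cr_min:
            continue
        eligible.append((snp_id, float(audit.maf[i])))
    chosen = [s for s, _ in eligible if s in must_include]
    if len(chosen) > size:
        raise ValueError("panel size smaller than eligible must-include set")
    fill = [(s, m) for s, m in eligible if s not in must_include]
    # descending MAF, then map order (chromosome, position) for determinism
    fill.sort(key=lambda sm: (-sm[1], snp_map.index_of(sm[0])))
    chosen += [s for s, _ in fill[: size - len(chosen)]]
    if len(chosen) < size:
        raise ValueError(
            f"only {len(chosen)} eligible SNPs for a panel of {size}"
        )
    return sorted(chosen, key=snp_map.index_of)


def expected_unrelated_mismatches(freq_a: np.ndarray) -> float:
    """Closed-form expected opposing-homozygote count for an unrelated pair.

    Under Hardy-Weinberg, P(one AA, other BB) at a SNP with allele-A
    frequency p is ``2 p^2 q^2``; the expectation is the sum over the panel.
    """
    p = np.asarray(freq_a, dtype=float)
    q = 1.0 - p
    return float((2.0 * p**2 * q**2).sum())


def panel_power_report(
    freq_a: np.ndarray,
    error_rate: float = 0.002,
    n_sims: int = 2000,
    seed: int = 0,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Monte-Carlo separation of true-pair vs unrelated-pair mismatch counts.

    Simulates parent-offspring duos (one allele shared by descent) and
    unrelated duos under HWE at the given allele frequencies, applies the
    per-call error rate, and reports P(mismatches >= k) at the validation
    (4) and failure (13) bounds plus the distribution means.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(freq_a, dtype=float)
    j = p.size

    def genotype(n):
        return rng.binomial(2, p, size=(n, j)).astype(np.int8)

    def with_errors(g):
        flip = rng.random(g.shape) < error_rate
        shift = rng.integers(1, 3, size=g.shape)
        return np.where(flip, (g + shift) % 3, g).astype(np.int8)

    # unrelated pairs
    g1, g2 = with_errors(genotype(n_sims)), with_errors(genotype(n_sims))
    unrel_mm = (np.abs(g1.astype(np.int16) - g2) == 2).sum(axis=1)
    # true parent-offspring pairs: offspring inherits one parental allele
    parent = genotype(n_sims)
    from_parent = np.where(
        parent == 1, rng.integers(0, 2, size=(n_sims, j)), parent // 2
    )
    other = rng.binomial(1, p, size=(n_sims, j))
    child = (from_parent + other).astype(np.int8)
    po_mm = (
        np.abs(with_errors(parent).astype(np.int16) - with_errors(child)) == 2
    ).sum(axis=1)

    rows = []
    for k in (1, thresholds.validate_max_mm + 1, thresholds.fail_min_mm):
        rows.append(
            {
                "threshold_k": k,
                "p_true_pair_ge_k": float((po_mm >= k).mean()),
                "p_unrelated_ge_k": float((unrel_mm >= k).mean()),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_unrelated_mm"] = float(unrel_mm.mean())
    df.attrs["mean_true_pair_mm"] = float(po_mm.mean())
    df.attrs["expected_unrelated_mm"] = expected_unrelated_mismatches(p)
    return df
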