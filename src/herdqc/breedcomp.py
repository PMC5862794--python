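"""Supervised breed-composition estimation.

An animal's ancestry fractions q over K reference breeds are estimated by
maximum likelihood with the per-breed allele frequencies held FIXED at
values computed from labeled purebred reference animals (supervised
admixture).  Each autosomal genotype is modelled as
``g_j ~ Binomial(2, sum_k q_k P[j,k])`` with P the reference allele-A
frequency matrix; with P fixed the log-likelihood is concave in q and an
EM iteration on the simplex converges to the global maximum.

The estimate is compared with the animal's listed breed composition
(recorded in 32nds); a gross conflict (e.g. listed 100% of one breed,
predicted 100% of another) invalidates a pedigree animal's genotype and
flags any other animal's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    CALL_MISSING,
    DEFAULT_THRESHOLDS,
    Animal,
    GenotypeRecord,
    SnpMap,
    Thresholds,
)


@dataclass
class BreedReference:
    """Fixed per-breed allele-A frequencies from purebred reference animals."""

    breeds: list[str]
    snp_index: np.ndarray          # global SnpMap indices (autosomal)
    freqs: np.ndarray              # (n_snps, K), pseudocount-smoothed, in (0,1)
    n_per_breed: dict[str, int]

    @property
    def k(self) -> int:
        return len(self.breeds)


@dataclass
class BreedEstimate:
    sample_id: str
    breeds: list[str]
    q: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_snps_used: int
    loglik_trace: list[float] | None = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.breeds, self.q.tolist()))


def build_reference(
    records: list[GenotypeRecord],
    animals: dict[str, Animal],
    snp_map: SnpMap,
    min_per_breed: int | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> BreedReference:
    """Estimate the reference frequency matrix from listed 32/32 purebreds.

    Only animals whose listed composition is a single breed at 32/32 enter
    the reference; breeds with too few such animals are dropped (they
    predict poorly).  Frequencies are smoothed with half a pseudo-allele:
    ``P = (count_A + 0.5) / (2 n + 1)``, keeping every entry strictly
    inside (0, 1) so no genotype has zero likelihood.  Autosomal SNPs only.
    """
    if min_per_breed is None:
        min_per_breed = thresholds.breed_min_ref_per_breed
    auto = snp_map.autosomal_index
    by_breed: dict[str, list[np.ndarray]] = {}
    for rec in records:
        a = animals.get(rec.animal_id)
        if a is None:
            continue
        comp = a.breed_composition_32nds
        if len(comp) == 1 and next(iter(comp.values())) == 32:
            by_breed.setdefault(next(iter(comp)), []).append(rec.calls[auto])
    breeds = sorted(b for b, recs in by_breed.items() if len(recs) >= min_per_breed)
    if not breeds:
        raise ValueError("no breed reaches the minimum purebred reference count")
    freqs = np.empty((len(auto), len(breeds)))
    n_per_breed = {}
    for k, breed in enumerate(breeds):
        calls = np.stack(by_breed[breed])
        called = calls != CALL_MISSING
        a_count = np.where(called, calls, 0).sum(axis=0)
        n_called = called.sum(axis=0)
        freqs[:, k] = (a_count + 0.5) / (2 * n_called + 1)
        n_per_breed[breed] = calls.shape[0]
    return BreedReference(breeds=breeds, snp_index=auto, freqs=freqs,
                          n_per_breed=n_per_breed)


def _loglik(g: np.ndarray, mean_p: np.ndarray) -> float:
    # Binomial(2, mean_p) log-likelihood up to the constant binom coefficient
    return float((g * np.log(mean_p) + (2 - g) * np.log1p(-mean_p)).sum())


def estimate_q(
    record: GenotypeRecord,
    reference: BreedReference,
    tol: float = 1e-7,
    max_iter: int = 2000,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> BreedEstimate:
    """Maximum-likelihood ancestry fractions by EM with fixed frequencies.

    Each EM step attributes the animal's A and B alleles fractionally to
    breeds in proportion to ``q_k P[j,k]`` (resp. ``q_k (1-P[j,k])``) and
    renormalises; the log-likelihood is non-decreasing at every step.
    Stops when its relative change falls below *tol*.
    """
    calls = record.calls[reference.snp_index]
    mask = calls != CALL_MISSING
    n_used = int(mask.sum())
    if n_used < thresholds.breed_min_overlap_snps:
        raise ValueError(
            f"sample {record.sample_id}: only {n_used} reference SNPs called "
            f"(need >= {thresholds.breed_min_overlap_snps})"
        )
    g = calls[mask].astype(np.float64)
    p = reference.freqs[mask]          # (J, K)
    k = reference.k
    q = np.full(k, 1.0 / k)
    ll_old = -np.inf
    converged = False
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        qa = q * p                      # (J, K) unnormalised A-allele shares
        qb = q * (1.0 - p)
        mean_p = qa.sum(axis=1)
        ll = _loglik(g, mean_p)
        trace.append(ll)
        # expected allele counts attributed to each breed
        e_a = (g[:, None] * qa / mean_p[:, None]).sum(axis=0)
        e_b = ((2 - g)[:, None] * qb / (1.0 - mean_p)[:, None]).sum(axis=0)
        q_new = (e_a + e_b) / (2.0 * g.size)
        q_new /= q_new.sum()
        if ll_old != -np.inf and (ll - ll_old) < tol * abs(ll):
            converged = True
            q = q_new
            break
        q, ll_old = q_new, ll
    final_ll = _loglik(g, (q * p).sum(axis=1))
    return BreedEstimate(
        sample_id=record.sample_id,
        breeds=list(reference.breeds),
        q=q,
        loglik=final_ll,
        n_iter=it,
        converged=converged,
        n_snps_used=n_used,
        loglik_trace=trace,
    )


def compare_to_listed(
    estimate: BreedEstimate,
    animal: Animal,
    tolerance: float | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Compare predicted q with the listed composition: match / mismatch /
    unevaluable.

    Listed breeds absent from the reference make the comparison
    unevaluable — such ancestry gets predicted as a spurious mixture of
    reference breeds.  A mismatch requires a gross conflict: some breed's
    predicted and listed fractions differing by more than *tolerance*
    (default 0.40).
    """
    if tolerance is None:
        tolerance = thresholds.breed_mismatch_tol
    listed = animal.breed_composition_32nds
    if not listed:
        return "unevaluable"
    known = set(estimate.breeds)
    if any(b not in known for b in listed):
        return "unevaluable"
    q = estimate.as_dict()
    max_dev = max(
        abs(q.get(b, 0.0) - listed.get(b, 0) / 32.0)
        for b in set(listed) | {b for b, v in q.items() if v > tolerance}
    )
    return "mismatch" if max_dev > tolerance else "match"


def reference_pca(
    records: list[GenotypeRecord], reference: BreedReference, n_components: int = 2
) -> np.ndarray:
    """PCA coordinates of reference animals (diagnostic for stray animals).

    Mean-imputed, column-centered genotype matrix; principal axes via SVD.
    """
    calls = np.stack([r.calls[reference.snp_index] for r in records]).astype(float)
    calls[calls == CALL_MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    calls = np.where(np.isnan(calls), col_mean, calls) - col_mean
    u, s, _ = np.linalg.svd(calls, full_matrices=False)
    return u[:, :n_components] * s[:n_components]
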