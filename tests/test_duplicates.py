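"""Duplicate detection: panel strings, block matching and identity rules."""

import itertools
from datetime import date

import numpy as np
import pytest

from herdqc import duplicates
from herdqc.duplicates import DupStatus
from herdqc.simulate import SimConfig, apply_noise, simulate_herd
from herdqc.types import Animal, CALL_MISSING, GenotypeRecord


def _rec(calls, sample_id, animal_id=None):
    return GenotypeRecord(sample_id, animal_id or sample_id, np.asarray(calls, np.int8))


class TestEncoding:
    def test_worked_example_string(self):
        # BB BB AB AA missing BB BB AA AB -> "001290021"
        calls = [0, 0, 1, 2, 9, 0, 0, 2, 1]
        rec = _rec(calls, "s")
        assert duplicates.encode_panel_string(rec, np.arange(9)) == "001290021"

    def test_all_missing(self):
        rec = _rec([9] * 800, "s")
        s = duplicates.encode_panel_string(rec, np.arange(800))
        assert s == "9" * 800

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1, 2, 9], 800).astype(np.int8)
        s = duplicates.encode_panel_string(_rec(calls, "s"), np.arange(800))
        decoded = np.array([ord(c) - 48 for c in s], dtype=np.int8)
        np.testing.assert_array_equal(decoded, calls)


class TestBlockIndex:
    def test_block_counts_for_800(self):
        s = {"a": "0" * 800}
        assert len(duplicates.block_index(s, 50)) == 16
        assert len(duplicates.block_index(s, 20)) == 40

    def test_identical_strings_colisted_everywhere(self):
        s = {"a": "012" * 100, "b": "012" * 100}
        idx = duplicates.block_index(s, 20)
        assert all(v == ["a", "b"] for v in idx.values())

    def test_single_missing_breaks_only_its_block(self):
        a = "0" * 300
        b = a[:55] + "9" + a[56:]  # inside block 2 (50-SNP blocks)
        idx = duplicates.block_index({"a": a, "b": b}, 50)
        colisted = {blk for (blk, _), v in idx.items() if v == ["a", "b"]}
        assert colisted == {0, 2, 3, 4, 5}  # block 1 (positions 50-99) split

    def test_non_divisor_block_size_rejected(self):
        with pytest.raises(ValueError):
            duplicates.block_index({"a": "0" * 10}, 3)


class TestCandidates:
    def test_true_duplicate_found_at_both_sizes(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 1, 2], 800).astype(np.int8)
        recs = [_rec(calls.copy(), "a"), _rec(calls.copy(), "b")]
        for bs in (50, 20):
            assert duplicates.find_duplicate_candidates(recs, np.arange(800), bs) == [
                ("a", "b")
            ]

    def test_one_discordance_per_50_block_needs_20_blocks(self):
        """Missing sites at {25, 75, ..., 775} spoil every 50-SNP block but
        leave clean 20-SNP blocks — the rationale for the smaller blocks."""
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 1, 2], 800).astype(np.int8)
        dup = calls.copy()
        dup[np.arange(25, 800, 50)] = CALL_MISSING  # one per 50-block
        recs = [_rec(calls, "a"), _rec(dup, "b")]
        assert duplicates.find_duplicate_candidates(recs, np.arange(800), 50) == []
        assert duplicates.find_duplicate_candidates(recs, np.arange(800), 20) == [
            ("a", "b")
        ]

    def test_unrelated_animals_no_candidates(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.42, 0.58, 800)
        recs = [
            _rec(rng.binomial(2, p), f"s{i}") for i in range(60)
        ]
        assert duplicates.find_duplicate_candidates(recs, np.arange(800), 20) == []

    def test_candidates_at_20_superset_of_50(self):
        cfg = SimConfig(seed=21, duplicate_submission=0.05, missing_rate=0.02,
                        n_founders_per_breed=25, n_generations=1,
                        n_offspring_per_breed_per_gen=25)
        sim = simulate_herd(cfg)
        panel = sim.snp_map.panel_index
        c20 = set(duplicates.find_duplicate_candidates(sim.records, panel, 20))
        c50 = set(duplicates.find_duplicate_candidates(sim.records, panel, 50))
        assert c50 <= c20

    def test_determinism_under_record_order(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([0, 1, 2], 800).astype(np.int8)
        recs = [_rec(calls.copy(), s) for s in ("a", "b", "c")]
        fwd = duplicates.find_duplicate_candidates(recs, np.arange(800), 20)
        rev = duplicates.find_duplicate_candidates(recs[::-1], np.arange(800), 20)
        assert fwd == rev == [("a", "b"), ("a", "c"), ("b", "c")]


class TestConfirmation:
    def test_identical_records_confirmed(self):
        calls = np.full(1000, 1, np.int8)
        recs = [_rec(calls.copy(), "a"), _rec(calls.copy(), "b")]
        (res,) = duplicates.confirm_duplicates(
            [("a", "b")], recs, np.arange(800), np.arange(1000)
        )
        assert res.status is DupStatus.CONFIRMED
        assert res.panel_identity == 1.0 and res.full_identity == 1.0

    def test_95pct_panel_identity_rejected(self):
        calls = np.full(1000, 1, np.int8)
        other = calls.copy()
        other[:40] = 2  # 760/800 = 95% panel identity
        recs = [_rec(calls, "a"), _rec(other, "b")]
        (res,) = duplicates.confirm_duplicates(
            [("a", "b")], recs, np.arange(800), np.arange(1000)
        )
        assert res.status is DupStatus.REJECTED

    def test_both_tiers_required(self):
        # identical on panel, 90% on the non-panel remainder -> rejected
        calls = np.full(1000, 1, np.int8)
        other = calls.copy()
        other[800:900] = 0
        recs = [_rec(calls, "a"), _rec(other, "b")]
        (res,) = duplicates.confirm_duplicates(
            [("a", "b")], recs, np.arange(800), np.arange(1000)
        )
        assert res.panel_identity == 1.0
        assert res.status is DupStatus.REJECTED

    def test_identical_twins_labelled_not_invalidated(self):
        calls = np.full(1000, 1, np.int8)
        recs = [_rec(calls.copy(), "a", "twin1"), _rec(calls.copy(), "b", "twin2")]
        animals = {
            "twin1": Animal("twin1", dob=date(2019, 3, 1), listed_dam="mum"),
            "twin2": Animal("twin2", dob=date(2019, 3, 2), listed_dam="mum"),
        }
        (res,) = duplicates.confirm_duplicates(
            [("a", "b")], recs, np.arange(800), np.arange(1000), animals=animals
        )
        assert res.status is DupStatus.CONFIRMED and res.possible_twins
        from herdqc.types import Validity

        assert all(r.valid is Validity.VALID for r in recs)


class TestReconcileMultiGenotypes:
    def test_rechip_of_same_animal_consistent(self):
        rng = np.random.default_rng(7)
        truth = rng.choice([0, 1, 2], 1000).astype(np.int8)
        a = apply_noise(truth, 0.002, 0.005, rng)
        b = apply_noise(truth, 0.002, 0.005, rng)
        status, _ = duplicates.reconcile_multi_genotypes(
            "A1", [_rec(a, "s1", "A1"), _rec(b, "s2", "A1")],
            np.arange(800), np.arange(1000),
        )
        assert status == "consistent"

    def test_two_different_animals_conflict(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.42, 0.58, 1000)
        a, b = rng.binomial(2, p), rng.binomial(2, p)
        status, pairs = duplicates.reconcile_multi_genotypes(
            "A1", [_rec(a, "s1", "A1"), _rec(b, "s2", "A1")],
            np.arange(800), np.arange(1000),
        )
        assert status == "conflict"
        # unrelated-pair expected identity is far below 99%
        assert pairs[0].panel_identity < 0.8

    def test_odd_one_out_identified(self):
        rng = np.random.default_rng(9)
        truth = rng.choice([0, 1, 2], 1000).astype(np.int8)
        good1 = apply_noise(truth, 0.002, 0.0, rng)
        good2 = apply_noise(truth, 0.002, 0.0, rng)
        bad = rng.choice([0, 1, 2], 1000).astype(np.int8)
        recs = [_rec(good1, "g1", "A1"), _rec(good2, "g2", "A1"), _rec(bad, "bad", "A1")]
        status, pairs = duplicates.reconcile_multi_genotypes(
            "A1", recs, np.arange(800), np.arange(1000)
        )
        assert status == "conflict"
        bad_pairs = {
            frozenset((p.sample_a, p.sample_b))
            for p in pairs
            if p.status is DupStatus.REJECTED
        }
        assert bad_pairs == {frozenset({"g1", "bad"}), frozenset({"g2", "bad"})}

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError):
            duplicates.reconcile_multi_genotypes(
                "A1", [_rec([1] * 10, "s")], np.arange(5), np.arange(10)
            )


def test_block_candidate_recall_vs_exhaustive(noisy_sim):
    """On a simulated herd with injected duplicates, block candidates at
    size 20 find every pair an exhaustive >=99%-identity scan finds."""
    cfg = SimConfig(seed=31, duplicate_submission=0.04,
                    n_founders_per_breed=30, n_generations=1,
                    n_offspring_per_breed_per_gen=40)
    sim = simulate_herd(cfg)
    panel = sim.snp_map.panel_index
    records = sim.records
    exhaustive = set()
    for ra, rb in itertools.combinations(records, 2):
        ident, _ = duplicates.genotype_identity(ra.calls, rb.calls, panel)
        if ident >= 0.99:
            pair = (ra.sample_id, rb.sample_id)
            exhaustive.add(pair if pair[0] < pair[1] else pair[::-1])
    cands = set(duplicates.find_duplicate_candidates(records, panel, 20))
    assert exhaustive  # the scenario did inject duplicates
    assert exhaustive <= cands
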