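"""Parentage: opposing-homozygote counting, two-stage verdicts, fast
prediction with early termination, and trio mating validation."""

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from herdqc import parentage
from herdqc.parentage import ParentageVerdict
from herdqc.types import (
    Animal,
    CALL_MISSING,
    DEFAULT_THRESHOLDS,
    GenotypeRecord,
    Sex,
    Thresholds,
)


def _rec(calls, sample_id="s", animal_id=None):
    return GenotypeRecord(sample_id, animal_id or sample_id, np.asarray(calls, np.int8))


class TestMismatchCounting:
    @pytest.mark.parametrize(
        "a,b,n_cmp,n_mm",
        [
            ([2], [0], 1, 1),        # AA vs BB: opposing homozygotes
            ([0], [2], 1, 1),
            ([1], [0], 1, 0),        # heterozygote never mismatches
            ([1], [2], 1, 0),
            ([2], [2], 1, 0),
            ([2], [9], 0, 0),        # missing excluded from comparison
            ([9], [9], 0, 0),
        ],
    )
    def test_single_snp_cases(self, a, b, n_cmp, n_mm):
        idx = np.array([0])
        assert parentage.count_parent_offspring_mismatches(
            np.array(a, np.int8), np.array(b, np.int8), idx
        ) == (n_cmp, n_mm)

    def test_empty_index_rejected(self):
        with pytest.raises(ValueError):
            parentage.count_parent_offspring_mismatches(
                np.array([1], np.int8), np.array([1], np.int8), np.array([], int)
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=arrays(np.int8, 50, elements=st.sampled_from([0, 1, 2, 9])),
        b=arrays(np.int8, 50, elements=st.sampled_from([0, 1, 2, 9])),
    )
    def test_symmetry(self, a, b):
        idx = np.arange(50)
        assert parentage.count_parent_offspring_mismatches(
            a, b, idx
        ) == parentage.count_parent_offspring_mismatches(b, a, idx)


class TestTwoStageValidation:
    def _pair_with_mismatches(self, n_mm, n_snps=800, extra=200):
        """Animal/parent identical AA except n_mm opposing-homozygote panel
        sites; *extra* non-panel SNPs agree."""
        total = n_snps + extra
        a = np.full(total, 2, np.int8)
        b = np.full(total, 2, np.int8)
        b[:n_mm] = 0
        return _rec(a, "kid"), _rec(b, "par")

    @pytest.mark.parametrize(
        "n_mm,verdict",
        [
            (0, ParentageVerdict.VALIDATED),
            (3, ParentageVerdict.VALIDATED),
            (4, ParentageVerdict.VALIDATED),
            (13, ParentageVerdict.FAILED),
            (40, ParentageVerdict.FAILED),
        ],
    )
    def test_clear_zone_verdicts(self, n_mm, verdict):
        kid, par = self._pair_with_mismatches(n_mm)
        res = parentage.validate_parent(
            kid, par, np.arange(800), np.arange(1000)
        )
        assert res.verdict is verdict
        assert res.n_mismatch_panel == n_mm
        assert res.full_snp_rate is None

    @pytest.mark.parametrize("n_mm", [5, 8, 12])
    def test_gray_zone_resolved_on_full_snp_rate(self, n_mm):
        # 8 mismatches on 1000 shared SNPs: rate 0.008 <= 1% -> validates
        kid, par = self._pair_with_mismatches(n_mm)
        res = parentage.validate_parent(kid, par, np.arange(800), np.arange(1000))
        expected_rate = n_mm / 1000
        assert res.full_snp_rate == pytest.approx(expected_rate)
        if expected_rate <= 0.01:
            assert res.verdict is ParentageVerdict.GRAY_VALIDATED
        else:
            assert res.verdict is ParentageVerdict.GRAY_FAILED

    def test_gray_zone_fails_above_1pct_full_rate(self):
        # 12 panel mismatches, no extra SNPs: full rate 12/800 = 1.5% > 1%
        kid, par = self._pair_with_mismatches(12, extra=0)
        res = parentage.validate_parent(kid, par, np.arange(800), np.arange(800))
        assert res.verdict is ParentageVerdict.GRAY_FAILED
        assert res.full_snp_rate == pytest.approx(0.015)

    def test_insufficient_overlap(self):
        kid, par = self._pair_with_mismatches(0)
        par.calls[:300] = CALL_MISSING  # only 500 shared panel calls remain
        res = parentage.validate_parent(kid, par, np.arange(800), np.arange(1000))
        assert res.verdict is ParentageVerdict.INSUFFICIENT_DATA


class TestCandidateTable:
    def test_best_genotype_per_animal(self):
        panel = np.arange(800)
        full = _rec(np.full(800, 1), "g_full", "A1")
        sparse = _rec(np.full(800, 1), "g_sparse", "A1")
        sparse.calls[:160] = CALL_MISSING  # 640 panel calls
        table = parentage.build_candidate_table([sparse, full], panel)
        assert len(table) == 1
        assert table.records["A1"].sample_id == "g_full"

    def test_under_600_panel_calls_excluded(self):
        panel = np.arange(800)
        rec = _rec(np.full(800, 1), "g", "A1")
        rec.calls[:210] = CALL_MISSING  # 590 < 600
        table = parentage.build_candidate_table([rec], panel)
        assert len(table) == 0

    def test_empty_input(self):
        table = parentage.build_candidate_table([], np.arange(800))
        assert len(table) == 0


def _herd_table(sim):
    panel = sim.snp_map.panel_index
    table = parentage.build_candidate_table(sim.records, panel)
    return panel, sim.snp_map.autosomal_index, table


class TestPrediction:
    def test_true_parents_recovered_uniquely(self, noisy_sim):
        """Gene-drop herd: the genotyped true sire/dam are the only
        predicted candidates for their roles."""
        panel, all_snps, table = _herd_table(noisy_sim)
        checked = 0
        for aid in table.animal_ids:
            t_sire = noisy_sim.ledger.true_sire[aid]
            if t_sire is None:
                continue
            preds = parentage.predict_parents(
                aid, table, noisy_sim.animals, panel, all_snps
            )
            sires = sorted(p.candidate_id for p in preds if p.role == "sire")
            dams = sorted(p.candidate_id for p in preds if p.role == "dam")
            assert sires == [t_sire]
            assert dams == [noisy_sim.ledger.true_dam[aid]]
            checked += 1
            if checked >= 40:
                break
        assert checked == 40

    def test_early_termination_equals_exhaustive(self, noisy_sim):
        panel, all_snps, table = _herd_table(noisy_sim)
        for aid in table.animal_ids[:15]:
            fast = parentage.predict_parents(
                aid, table, noisy_sim.animals, panel, all_snps, early_termination=True
            )
            slow = parentage.predict_parents(
                aid, table, noisy_sim.animals, panel, all_snps, early_termination=False
            )
            assert [(r.candidate_id, r.role, r.n_mismatch_panel, r.verdict) for r in fast] == [
                (r.candidate_id, r.role, r.n_mismatch_panel, r.verdict) for r in slow
            ]

    def test_age_rule_excludes_close_and_younger_candidates(self):
        """A perfect genotype match born <15 months before the target (or
        after it, e.g. the target's own son) is never predicted."""
        panel = np.arange(800)
        all_snps = np.arange(800)
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 1, 2], 800).astype(np.int8)
        recs = [
            _rec(calls.copy(), "t", "target"),
            _rec(calls.copy(), "d", "decoy14"),   # full match, 14 months older
            _rec(calls.copy(), "s", "son"),       # full match, younger
            _rec(calls.copy(), "p", "parent16"),  # full match, 16 months older
        ]
        animals = {
            "target": Animal("target", Sex.FEMALE, dob=date(2015, 6, 1)),
            "decoy14": Animal("decoy14", Sex.MALE, dob=date(2014, 4, 2)),
            "son": Animal("son", Sex.MALE, dob=date(2017, 1, 1)),
            "parent16": Animal("parent16", Sex.MALE, dob=date(2014, 2, 1)),
        }
        table = parentage.build_candidate_table(recs, panel)
        preds = parentage.predict_parents("target", table, animals, panel, all_snps)
        assert [p.candidate_id for p in preds] == ["parent16"]

    def test_sex_routes_roles(self):
        panel = all_snps = np.arange(800)
        calls = np.full(800, 1, np.int8)
        recs = [_rec(calls.copy(), s, s) for s in ("kid", "m", "f")]
        animals = {
            "kid": Animal("kid", Sex.FEMALE, dob=date(2018, 1, 1)),
            "m": Animal("m", Sex.MALE, dob=date(2014, 1, 1)),
            "f": Animal("f", Sex.FEMALE, dob=date(2014, 1, 1)),
        }
        table = parentage.build_candidate_table(recs, panel)
        preds = parentage.predict_parents("kid", table, animals, panel, all_snps)
        roles = {p.candidate_id: p.role for p in preds}
        assert roles == {"m": "sire", "f": "dam"}

    def test_missing_target_raises(self):
        table = parentage.build_candidate_table([], np.arange(800))
        with pytest.raises(KeyError):
            parentage.predict_parents("nope", table, {}, np.arange(800), np.arange(800))


class TestMatingValidation:
    def test_msm_definition(self):
        panel = np.arange(4)
        calf = _rec([1, 1, 1, 0], "c")
        sire = _rec([2, 2, 0, 0], "s")
        dam = _rec([2, 0, 0, 0], "d")
        # SNP0: calf AB, both parents AA -> MSM
        # SNP1: calf AB, parents AA/BB -> valid mating, not MSM
        # SNP2: calf AB, both parents BB -> MSM
        # SNP3: calf BB -> not MSM
        res = parentage.count_msm(calf, sire, dam, panel)
        assert (res.n_msm, res.n_informative) == (2, 4)

    def test_missing_site_not_informative(self):
        panel = np.arange(2)
        res = parentage.count_msm(
            _rec([1, 1], "c"), _rec([2, 9], "s"), _rec([2, 2], "d"), panel
        )
        assert res.n_informative == 1

    def test_flagging_above_1pct(self):
        panel = np.arange(800)
        calf = _rec(np.full(800, 1), "c")
        sire = _rec(np.full(800, 1), "s")
        dam = _rec(np.full(800, 1), "d")
        res = parentage.count_msm(calf, sire, dam, panel)
        assert res.n_msm == 0 and not res.flagged
        sire.calls[:9] = 2
        dam.calls[:9] = 2
        res = parentage.count_msm(calf, sire, dam, panel)  # 9/800 = 1.125%
        assert res.flagged

    def test_clean_trio_in_simulation(self, clean_sim):
        """Noise-free Mendelian trios have exactly zero MSM."""
        panel, all_snps, table = _herd_table(clean_sim)
        n = 0
        for aid in table.animal_ids:
            s, d = clean_sim.ledger.true_sire[aid], clean_sim.ledger.true_dam[aid]
            if s is None or s not in table.records or d not in table.records:
                continue
            res = parentage.count_msm(
                table.records[aid], table.records[s], table.records[d], panel
            )
            assert res.n_msm == 0
            n += 1
        assert n > 20


def test_unrelated_mismatch_count_matches_closed_form():
    """Mean opposing-homozygote count for unrelated pairs equals the
    closed form sum(2 p^2 q^2) within 3 Monte-Carlo standard errors."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.42, 0.58, 800)
    n_pairs = 4000
    g1 = rng.binomial(2, p, size=(n_pairs, 800))
    g2 = rng.binomial(2, p, size=(n_pairs, 800))
    counts = (np.abs(g1 - g2) == 2).sum(axis=1)
    expected = float((2 * p**2 * (1 - p) ** 2).sum())
    se = counts.std(ddof=1) / np.sqrt(n_pairs)
    assert abs(counts.mean() - expected) < 3 * se
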