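"""Duplex rule engine: pairing, cleavage scoring, eTM rules vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cerna.mimic import (
    CleavageParams,
    MimicRuleParams,
    PairState,
    evaluate_etm_site,
    find_etm_sites,
    pair_state,
    scan_cleavage_sites,
    score_cleavage_site,
)
from cerna.seq import random_dna, revcomp_rna, to_rna

from oracles import (
    enumerate_etm_sites,
    literal_cleavage_penalty,
    literal_cleavage_scan,
)

rna = st.text(alphabet="ACGU", min_size=15, max_size=17)


def random_rna(rng, n):
    return to_rna(random_dna(rng, n))


class TestPairState:
    def test_exhaustive_enumeration(self):
        states = [pair_state(a, b) for a in "ACGU" for b in "ACGU"]
        assert states.count(PairState.WC) == 4
        assert states.count(PairState.GU) == 2
        assert states.count(PairState.MISMATCH) == 10
        assert pair_state("A", "U") is PairState.WC
        assert pair_state("G", "U") is PairState.GU

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            pair_state("A", "N")


class TestCleavageScoring:
    def test_perfect_complement_scores_zero(self, rng):
        mir = random_rna(rng, 21)
        d = score_cleavage_site(mir, revcomp_rna(mir))
        assert d.penalty == 0.0 and d.accepted

    def test_single_gu_in_core_scores_one(self):
        mir = "A" * 21
        mir = mir[:4] + "G" + mir[5:]  # G at position 5, inside 2-13
        window = list(revcomp_rna(mir))
        window[21 - 5] = "U"  # G:U wobble at position 5
        d = score_cleavage_site(mir, "".join(window))
        assert d.penalty == pytest.approx(1.0)  # 0.5 weight x 2.0 core

    def test_window_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_cleavage_site("ACGUACGUACGUACGUACGUA", "ACGU")

    def test_scan_matches_window_oracle(self, rng):
        mir = random_rna(rng, 21)
        target = random_rna(rng, 500)
        # embed two near-perfect sites so the accepted set is non-trivial
        site = revcomp_rna(mir)
        target = target[:50] + site + target[50 + len(site) :]
        noisy = site[:3] + ("A" if site[3] != "A" else "C") + site[4:]
        target = target[:300] + noisy + target[300 + len(noisy) :]
        got = {d.start for d in scan_cleavage_sites(mir, target)}
        assert got == literal_cleavage_scan(mir, target)
        assert {50, 300} <= got

    def test_penalty_agrees_with_literal_summation(self, rng):
        mir = random_rna(rng, 21)
        for _ in range(50):
            window = random_rna(rng, 21)
            d = score_cleavage_site(mir, window)
            assert d.penalty == pytest.approx(
                literal_cleavage_penalty(mir, window)
            )


def perfect_mimic(rng, mir, bulge_len=3, flank=20):
    """lncRNA = revcomp(miRNA) with a bulge between positions 10 and 11."""
    m = len(mir)
    site = (
        revcomp_rna(mir[10:])
        + random_rna(rng, bulge_len)
        + revcomp_rna(mir[:10])
    )
    return random_rna(rng, flank) + site + random_rna(rng, flank), flank


class TestEtmRules:
    def test_constructed_perfect_mimic_found(self, rng):
        mir = random_rna(rng, 21)
        lnc, start = perfect_mimic(rng, mir, bulge_len=3)
        sites = find_etm_sites(mir, lnc)
        # the planted register is the unique perfect (zero-mismatch) site;
        # overlapping registers absorbed by the mismatch budget may also be
        # reported, by design (all accepted sites are reported)
        perfect = [
            (s.duplex.start, s.duplex.bulge_len)
            for s in sites
            if s.duplex.weighted_mismatches == 0
        ]
        assert perfect == [(start, 3)]

    def test_bulge_of_six_fails_rule_one(self, rng):
        mir = random_rna(rng, 21)
        lnc, start = perfect_mimic(rng, mir, bulge_len=6)
        site = evaluate_etm_site(mir, lnc, start, 6)
        assert not site.accepted and site.failing_rule == "central_bulge"

    def test_three_consecutive_mismatches_fail_rule_two(self, rng):
        mir = random_rna(rng, 21)
        lnc, start = perfect_mimic(rng, mir, bulge_len=4)
        # corrupt the bases pairing miRNA positions 3, 4, 5 (5' arm)
        m = len(mir)
        idx0 = start + (m - 10) + 4
        lnc = list(lnc)
        for p in (3, 4, 5):
            i = idx0 + (10 - p)
            lnc[i] = {"A": "C", "C": "A", "G": "A", "U": "C"}[mir[p - 1]]
        site = evaluate_etm_site(mir, "".join(lnc), start, 4)
        assert not site.accepted and site.failing_rule == "mismatch_budget"
        assert site.duplex.max_consecutive == 3

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_etm_sites("ACGUACGUACGUAC", "ACGU" * 30)

    def test_engine_equals_oracle_random_cases(self, rng):
        for _ in range(300):
            mir = random_rna(rng, int(rng.integers(15, 18)))
            lnc = random_rna(rng, int(rng.integers(40, 81)))
            if rng.integers(0, 2):  # plant something site-like half the time
                b = int(rng.integers(2, 7))
                site = (
                    revcomp_rna(mir[10:])
                    + random_rna(rng, b)
                    + revcomp_rna(mir[:10])
                )
                pos = int(rng.integers(0, len(lnc) - len(site) + 1))
                lnc = lnc[:pos] + site + lnc[pos + len(site) :]
            got = {
                (s.duplex.start, s.duplex.bulge_len)
                for s in find_etm_sites(mir, lnc)
            }
            assert got == enumerate_etm_sites(mir, lnc)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(mir=rna, lnc=st.text(alphabet="ACGU", min_size=30, max_size=80))
    def test_engine_equals_oracle_property(self, mir, lnc):
        got = {
            (s.duplex.start, s.duplex.bulge_len)
            for s in find_etm_sites(mir, lnc)
        }
        assert got == enumerate_etm_sites(mir, lnc)

    def test_tightening_mismatch_budget_is_monotone(self, rng):
        mir = random_rna(rng, 21)
        lnc = random_rna(rng, 400)
        prev = None
        for budget in (4.0, 3.0, 2.0, 1.0, 0.0):
            params = MimicRuleParams(max_noncentral_mismatches=budget)
            got = {
                (s.duplex.start, s.duplex.bulge_len)
                for s in find_etm_sites(mir, lnc, params)
            }
            if prev is not None:
                assert got <= prev
            prev = got

    def test_shifting_site_shifts_report(self, rng):
        mir = random_rna(rng, 21)
        site = revcomp_rna(mir[10:]) + random_rna(rng, 4) + revcomp_rna(mir[:10])
        flank = random_rna(rng, 120)
        for k in (0, 7, 31):
            lnc = flank[: 10 + k] + site + flank[10 + k :]
            starts = [s.duplex.start for s in find_etm_sites(mir, lnc)]
            assert 10 + k in starts

    def test_gu_counts_flag_relaxes_budget(self):
        # a site whose non-central arm carries many G:U wobbles
        mir = "G" * 9 + "AU" + "G" * 10  # positions 10,11 = A,U
        site_3p = "U" * 10  # pairs positions 21..12 as G:U wobbles
        site = site_3p + "A" + "UUU" + "U" + "C" * 9
        lnc = "A" * 10 + site + "A" * 10
        strict = find_etm_sites(mir, lnc, MimicRuleParams())
        relaxed = find_etm_sites(
            mir, lnc, MimicRuleParams(gu_counts_as_mismatch=False)
        )
        assert len(relaxed) >= len(strict)
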