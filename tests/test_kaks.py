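"""NG86 Ka/Ks: site counting, pathway averaging, JC correction, branch rule."""
import math
from itertools import permutations

import pytest
from hypothesis import given, settings, strategies as st

from divscreen.codon import GENETIC_CODE, STOP_CODONS
from divscreen.config import PipelineConfig
from divscreen.kaks import (KaKsResult, OrthologTriple, kaks_candidate_rule,
                            ng86_kaks, pathway_differences)

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def oracle_pathways(ca, cb):
    """Independent exhaustive minimal-pathway enumeration.

    Walks every permutation of the differing positions, tracks codon
    states, classifies each step by amino-acid identity (stop-involving
    steps are nonsynonymous), drops stop-crossing pathways when any
    stop-free pathway exists.
    """
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in permutations(diffs):
        state = ca
        steps = []
        hits_stop = False
        for pos in order:
            nxt = state[:pos] + cb[pos] + state[pos + 1 :]
            if nxt in STOP_CODONS:
                hits_stop = True
            syn = (
                nxt not in STOP_CODONS
                and state not in STOP_CODONS
                and GENETIC_CODE[nxt] == GENETIC_CODE[state]
            )
            steps.append(syn)
            state = nxt
        results.append((hits_stop, sum(steps), len(steps) - sum(steps)))
    clean = [(s, n) for hit, s, n in results if not hit]
    use = clean if clean else [(s, n) for _, s, n in results]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


class TestPathwayDifferences:
    def test_identical_codons_zero(self):
        assert pathway_differences("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous_difference(self):
        sd, nd = pathway_differences("GGA", "GGG")
        assert (sd, nd) == (1.0, 0.0)

    def test_two_position_textbook_average(self):
        # TTT (Phe) vs GTA (Val): both orders counted with equal weight
        sd, nd = pathway_differences("TTT", "GTA")
        assert sd + nd == pytest.approx(2.0)
        assert (sd, nd) == oracle_pathways("TTT", "GTA")

    @given(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_equals_exhaustive_enumeration(self, ca, cb):
        assert pathway_differences(ca, cb) == pytest.approx(oracle_pathways(ca, cb))


class TestNg86:
    def test_identical_sequences_undefined_zero(self):
        r = ng86_kaks("ATGGGA", "ATGGGA")
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_hand_computed_synonymous_example(self):
        """Thirteen codons, four synonymous sites, one synonymous change.

        Nine ATG + three GGC contribute S = 3 (third positions of GGC);
        the differing pair CTC/CTT adds one more synonymous site, so
        S = 4, Sd = 1, pS = 1/4 and Ks = -(3/4) ln(2/3); Ka = 0.
        """
        a = "ATG" * 9 + "GGC" * 3 + "CTC"
        b = "ATG" * 9 + "GGC" * 3 + "CTT"
        r = ng86_kaks(a, b)
        assert r.s_sites == pytest.approx(4.0)
        assert r.sd == pytest.approx(1.0) and r.nd == 0.0
        assert r.ks == pytest.approx(-0.75 * math.log(2.0 / 3.0))
        assert r.ka == 0.0
        assert r.ratio == 0.0 and not r.flags

    def test_site_count_conservation(self, rng):
        from divscreen.simulate import random_cds

        for _ in range(10):
            a = random_cds(rng, 50)
            b = random_cds(rng, 50)
            r = ng86_kaks(a, b)
            assert r.s_sites + r.n_sites == pytest.approx(3 * r.n_codons_compared)

    def test_symmetry_exact(self, rng):
        from divscreen.simulate import random_cds

        a = random_cds(rng, 60)
        b = random_cds(rng, 60)
        assert ng86_kaks(a, b) == ng86_kaks(b, a)

    def test_gap_and_n_columns_skipped(self):
        r = ng86_kaks("ATG---GGA", "ATGAAANGA")
        assert r.n_codons_compared == 1 and r.n_codons_skipped == 2

    def test_saturation_flagged(self):
        # every third position differs synonymously in a 4-fold family
        a = "GGA" * 10
        b = "GGC" * 10
        r = ng86_kaks(a, b)
        assert r.sd == 10.0
        assert "jc_saturated" in r.flags and r.ks is None

    def test_ks_zero_with_ka_positive_flagged(self):
        # one nonsynonymous difference, no synonymous change
        a = "ATG" * 20 + "AAA"
        b = "ATG" * 20 + "ACA"
        r = ng86_kaks(a, b)
        assert r.ka > 0 and r.ks == 0.0
        assert "ks_zero" in r.flags and math.isinf(r.ratio)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_kaks("ATGATG", "ATG")


def stub_result(ratio, flags=()):
    ka = None if ratio is None else 0.01 * (ratio if not math.isinf(ratio) else 1)
    ks = 0.01 if ratio is not None and not math.isinf(ratio) else (
        0.0 if ratio is not None else None)
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, s_sites=100, n_sites=200,
                      sd=1, nd=1, n_codons_compared=100, n_codons_skipped=0,
                      flags=set(flags))


def stub_triple(r_ab, r_aout, r_bout):
    t = OrthologTriple("g", "ATG", "ATG", "ATG")
    t.result_ab, t.result_a_out, t.result_b_out = r_ab, r_aout, r_bout
    return t


class TestCandidateRule:
    def test_elevated_ingroup_quiet_outgroup_is_candidate(self, config):
        """Ingroup 0.6038 with outgroup 0.1401 / 0.1281 passes the rule."""
        call = kaks_candidate_rule(
            stub_triple(stub_result(0.6038), stub_result(0.1401),
                        stub_result(0.1281)),
            config,
        )
        assert call.candidate and call.clean

    def test_low_ingroup_ratio_not_candidate(self, config):
        call = kaks_candidate_rule(
            stub_triple(stub_result(0.4), stub_result(0.1), stub_result(0.1)),
            config,
        )
        assert not call.candidate

    def test_high_outgroup_ratio_not_candidate(self, config):
        call = kaks_candidate_rule(
            stub_triple(stub_result(0.8), stub_result(0.6), stub_result(0.1)),
            config,
        )
        assert not call.candidate

    def test_threshold_inclusive_on_ingroup(self, config):
        call = kaks_candidate_rule(
            stub_triple(stub_result(0.5), stub_result(0.1), stub_result(0.1)),
            config,
        )
        assert call.candidate

    def test_ks_zero_goes_to_flagged_not_clean(self, config):
        call = kaks_candidate_rule(
            stub_triple(stub_result(math.inf, flags={"ks_zero"}),
                        stub_result(0.1), stub_result(0.1)),
            config,
        )
        assert call.candidate and not call.clean
        assert any("ks_zero" in r for r in call.rationale)

    def test_missing_pair_not_evaluable(self, config):
        t = stub_triple(stub_result(0.6), None, stub_result(0.1))
        with pytest.raises(ValueError, match="A_out"):
            kaks_candidate_rule(t, config)
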