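"""Winner-takes-all greedy assignment, the E-value alternative, and clan counts."""

import numpy as np
import pytest

from clanoverlap import (
    assign_by_evalue,
    count_overlapping_clans,
    detect_overlaps,
    greedy_assign,
    pairwise_overlap,
)
from clanoverlap.model import ClanMap

from conftest import greedy_oracle, mk_hit, random_hit_instance

CLANS = ClanMap(
    entries={"PF00001": "CL1", "PF00002": "CL2", "PF00003": "CL3", "PF00004": "CL4"}
)


def pair(fam_a, fam_b, seq="s1", ali=(1, 100), e_a=1e-5, e_b=1e-5, clans=CLANS):
    a = mk_hit(seq=seq, fam=fam_a, ali=ali, dom_e=e_a)
    b = mk_hit(seq=seq, fam=fam_b, ali=ali, dom_e=e_b)
    p = pairwise_overlap(a, b, clans)
    assert p is not None
    return p


class TestGreedyAssign:
    def test_star_topology_one_selection(self):
        # F1 holds three domains each overlapping a different partner;
        # partners overlapped only with F1 and disappear unassigned
        pairs = [
            pair("PF00001", "PF00002", seq="s1"),
            pair("PF00001", "PF00002", seq="s2"),
            pair("PF00001", "PF00003", seq="s3"),
        ]
        result = greedy_assign(pairs)
        assert result.selection_order == [("PF00001", 3)]
        assert set(result.family_domain_counts().items()) == {("PF00001", 3)}
        f1_domains = {d for d, fam in result.domain_to_family.items()}
        assert all(d.family_acc == "PF00001" for d in f1_domains)

    def test_triangle_with_tie_breaking(self):
        # One sequence; intervals arranged so the qualifying pairs are
        # exactly a(F1)xc(F2), b(F1)xd(F3) and c(F2)xd(F3). F1 wins with
        # 2 domains; the F2/F3 tie at 1 goes to F2 (smaller accession);
        # d overlapped two families, so it stays listed after its pairs
        # are gone and F3 finally claims it.
        a = mk_hit(fam="PF00001", ali=(1, 100))
        b = mk_hit(fam="PF00001", ali=(151, 250))
        c = mk_hit(fam="PF00002", ali=(51, 150))
        d = mk_hit(fam="PF00003", ali=(101, 200))
        pairs = detect_overlaps([a, b, c, d], CLANS, 0.01)
        assert {frozenset((p.hit_a, p.hit_b)) for p in pairs} == {
            frozenset((a, c)),
            frozenset((b, d)),
            frozenset((c, d)),
        }
        result = greedy_assign(pairs)
        assert result.selection_order == [("PF00001", 2), ("PF00002", 1), ("PF00003", 1)]
        counts = result.family_domain_counts()
        assert counts == {"PF00001": 2, "PF00002": 1, "PF00003": 1}

    def test_no_pairs_gives_empty_result(self):
        result = greedy_assign([])
        assert result.domain_to_family == {}
        assert result.selection_order == []

    def test_each_domain_assigned_at_most_once(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            hits, clans = random_hit_instance(rng, max_hits=30)
            pairs = detect_overlaps(hits, clans, 0.05)
            result = greedy_assign(pairs)
            assigned = list(result.domain_to_family)
            assert len(assigned) == len(set(assigned))
            # an assigned domain always goes to its own family
            assert all(
                fam == d.family_acc for d, fam in result.domain_to_family.items()
            )

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            hits, clans = random_hit_instance(rng, max_hits=25)
            pairs = detect_overlaps(hits, clans, 0.05)
            shuffled = list(pairs)
            rng.shuffle(shuffled)
            assert greedy_assign(pairs) == greedy_assign(shuffled)

    def test_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            hits, clans = random_hit_instance(rng, max_hits=25)
            pairs = detect_overlaps(hits, clans, 0.05)
            result = greedy_assign(pairs)
            oracle_assigned, oracle_order = greedy_oracle(pairs)
            assert result.domain_to_family == oracle_assigned
            assert result.selection_order == oracle_order


class TestAssignByEvalue:
    def test_higher_evalue_hit_is_suspect(self):
        p = pair("PF00001", "PF00002", e_a=1e-5, e_b=1e-3)
        result = assign_by_evalue([p])
        (dom,) = result.domain_to_family
        assert dom.family_acc == "PF00002"

    def test_tie_goes_to_larger_accession(self):
        p = pair("PF00001", "PF00002", e_a=1e-4, e_b=1e-4)
        result = assign_by_evalue([p])
        (dom,) = result.domain_to_family
        assert dom.family_acc == "PF00002"

    def test_multi_pair_domain_marked_once(self):
        d = mk_hit(seq="s1", fam="PF00003", ali=(1, 100), dom_e=0.009)
        p1 = pairwise_overlap(d, mk_hit(seq="s1", fam="PF00001", ali=(1, 100), dom_e=1e-6), CLANS)
        p2 = pairwise_overlap(d, mk_hit(seq="s1", fam="PF00002", ali=(1, 100), dom_e=1e-8), CLANS)
        result = assign_by_evalue([p1, p2])
        assert result.domain_to_family == {d: "PF00003"}
        assert result.selection_order == [("PF00003", 1)]


class TestClanCounts:
    def test_distinct_union_over_partner_clans(self):
        # F1's two domains overlap partners in clans {CL2, CL3} and {CL2}
        pairs = [
            pair("PF00001", "PF00002", seq="s1"),
            pair("PF00001", "PF00003", seq="s1"),
            pair("PF00001", "PF00002", seq="s2"),
        ]
        result = greedy_assign(pairs)
        counts = count_overlapping_clans(result, pairs, CLANS)
        assert counts["PF00001"] == 2

    def test_sum_mode_counts_per_domain(self):
        pairs = [
            pair("PF00001", "PF00002", seq="s1"),
            pair("PF00001", "PF00003", seq="s1"),
            pair("PF00001", "PF00002", seq="s2"),
        ]
        result = greedy_assign(pairs)
        counts = count_overlapping_clans(result, pairs, CLANS, mode="sum")
        assert counts["PF00001"] == 3  # domain on s1 sees 2 clans, s2 sees 1

    def test_clanless_partner_contributes_singleton(self):
        clans = ClanMap(entries={"PF00001": "CL1"})
        pairs = [pair("PF00001", "PF00009", clans=clans)]
        result = greedy_assign(pairs)
        counts = count_overlapping_clans(result, pairs, clans)
        assert counts == {"PF00001": 1}

    def test_family_without_assigned_domains_absent(self):
        pairs = [pair("PF00001", "PF00002", seq="s1")]
        result = greedy_assign(pairs)  # PF00002's domain disappears
        counts = count_overlapping_clans(result, pairs, CLANS)
        assert "PF00002" not in counts
        assert counts.keys() == {"PF00001"}
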