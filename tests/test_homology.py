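import itertools

import numpy as np
import pytest

from nclvkit import homology as hm
from nclvkit.synthetic_data import gen_hit_table
from tests.conftest import make_hit


def brute_force_rbh(hits_ab, hits_ba, e_max):
    """Independent oracle: enumerate all (a, b) and check both best conditions
    by explicit scans over the full hit lists."""

    def is_best(hits, query, subject):
        mine = [h for h in hits if h.query_id == query and h.evalue <= e_max]
        if not mine:
            return False
        best = min(mine, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        return best.subject_id == subject

    queries_a = {h.query_id for h in hits_ab}
    queries_b = {h.query_id for h in hits_ba}
    return {
        (a, b)
        for a, b in itertools.product(queries_a, queries_b)
        if is_best(hits_ab, a, b) and is_best(hits_ba, b, a)
    }


class TestBestHits:
    def test_lowest_evalue_wins(self):
        hits = [make_hit("a1", "b1", 1e-50), make_hit("a1", "b2", 1e-10)]
        assert hm.best_hits(hits, 1e-5) == {"a1": "b1"}

    def test_cutoff_excludes_weak_single_hit(self):
        hits = [make_hit("a1", "b1", 1e-4)]
        assert hm.best_hits(hits, 1e-5) == {}

    def test_tie_broken_by_bitscore(self):
        hits = [
            make_hit("a1", "b1", 1e-30, bitscore=150),
            make_hit("a1", "b2", 1e-30, bitscore=200),
        ]
        assert hm.best_hits(hits, 1e-5) == {"a1": "b2"}

    def test_full_tie_broken_lexicographically(self):
        hits = [
            make_hit("a1", "bZ", 1e-30, bitscore=200),
            make_hit("a1", "bA", 1e-30, bitscore=200),
        ]
        assert hm.best_hits(hits, 1e-5) == {"a1": "bA"}

    def test_input_order_irrelevant(self):
        hits = [
            make_hit("a1", "b2", 1e-10),
            make_hit("a1", "b1", 1e-50),
            make_hit("a2", "b3", 1e-20),
        ]
        for perm in itertools.permutations(hits):
            assert hm.best_hits(list(perm), 1e-5) == {"a1": "b1", "a2": "b3"}


class TestRBHPairs:
    def test_mutual_best(self):
        ab = [make_hit("a1", "b1", 1e-50)]
        ba = [make_hit("b1", "a1", 1e-45)]
        (pair,) = hm.rbh_pairs(ab, ba, 1e-5)
        assert (pair.a_id, pair.b_id) == ("a1", "b1")
        assert pair.evalue_ab == 1e-50 and pair.evalue_ba == 1e-45

    def test_asymmetric_bests_excluded(self):
        ab = [make_hit("a1", "b1", 1e-50)]
        ba = [make_hit("b1", "a2", 1e-60), make_hit("b1", "a1", 1e-45)]
        assert hm.rbh_pairs(ab, ba, 1e-5) == set()

    def test_symmetry_under_table_swap(self):
        ab, ba = gen_hit_table(
            {("a1", "b1"), ("a2", "b2")}, ({"a9"}, {"b9"}), 0.2, 0.1, seed=11
        )
        fwd = {(p.a_id, p.b_id) for p in hm.rbh_pairs(ab, ba, 1e-5)}
        rev = {(p.b_id, p.a_id) for p in hm.rbh_pairs(ba, ab, 1e-5)}
        assert fwd == rev

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a_ids = [f"a{i}" for i in range(20)]
        b_ids = [f"b{i}" for i in range(20)]
        hits_ab, hits_ba = [], []
        for _ in range(60):
            q = a_ids[rng.integers(0, 20)]
            s = b_ids[rng.integers(0, 20)]
            hits_ab.append(make_hit(q, s, 10.0 ** -rng.integers(0, 40),
                                    bitscore=float(rng.integers(20, 300))))
        for _ in range(60):
            q = b_ids[rng.integers(0, 20)]
            s = a_ids[rng.integers(0, 20)]
            hits_ba.append(make_hit(q, s, 10.0 ** -rng.integers(0, 40),
                                    bitscore=float(rng.integers(20, 300))))
        got = {(p.a_id, p.b_id) for p in hm.rbh_pairs(hits_ab, hits_ba, 1e-5)}
        assert got == brute_force_rbh(hits_ab, hits_ba, 1e-5)

    def test_monotone_in_cutoff(self):
        ab, ba = gen_hit_table(
            {(f"a{i}", f"b{i}") for i in range(10)}, (set(), set()), 0.0, 0.0, seed=3
        )
        loose = {(p.a_id, p.b_id) for p in hm.rbh_pairs(ab, ba, 1e-5)}
        tight = {(p.a_id, p.b_id) for p in hm.rbh_pairs(ab, ba, 1e-60)}
        assert tight <= loose


class TestClassifyOrfans:
    def test_labels_and_fractions(self):
        ids = {"p1", "p2", "p3"}
        ref = [make_hit("p1", "nr1", 1e-30)]
        env = [make_hit("p2", "env1", 1e-20), make_hit("p1", "env2", 1e-9)]
        labels, fractions = hm.classify_orfans(ids, ref, env, 1e-5)
        by_id = {l.protein_id: l.label for l in labels}
        assert by_id == {"p1": "HOMOLOG", "p2": "META_ORFAN", "p3": "ORFAN"}
        assert fractions == {"HOMOLOG": 1 / 3, "META_ORFAN": 1 / 3, "ORFAN": 1 / 3}

    def test_weak_hits_do_not_rescue(self):
        labels, _ = hm.classify_orfans(
            {"p1"}, [make_hit("p1", "x", 1e-4)], [make_hit("p1", "y", 1e-3)], 1e-5
        )
        assert labels[0].label == "ORFAN"

    def test_labels_partition_protein_set(self):
        ab, _ = gen_hit_table({(f"p{i}", f"s{i}") for i in range(30)},
                              (set(), set()), 0.0, 0.3, seed=5)
        ids = {f"p{i}" for i in range(40)}
        labels, fractions = hm.classify_orfans(ids, ab, [], 1e-5)
        assert len(labels) == 40
        assert abs(sum(fractions.values()) - 1.0) < 1e-12

    def test_unknown_query_errors(self):
        with pytest.raises(ValueError):
            hm.classify_orfans({"p1"}, [make_hit("zz", "x", 1e-30)], [], 1e-5)


class TestFindDuplicates:
    def test_self_match_excluded(self):
        assert hm.find_duplicates([make_hit("a1", "a1", 1e-80)], 1e-10) == set()

    def test_simple_pair(self):
        hits = [make_hit("a1", "a2", 1e-50), make_hit("a2", "a1", 1e-50)]
        assert hm.find_duplicates(hits, 1e-10) == {frozenset({"a1", "a2"})}

    def test_cutoff_excludes_weak_edge(self):
        assert hm.find_duplicates([make_hit("a1", "a2", 1e-8)], 1e-10) == set()

    def test_transitive_cluster(self):
        hits = [make_hit("a1", "a2", 1e-50), make_hit("a2", "a3", 1e-40)]
        assert hm.find_duplicates(hits, 1e-10) == {frozenset({"a1", "a2", "a3"})}

    def test_lowering_cutoff_never_adds_edges(self):
        hits = [make_hit("a1", "a2", 1e-12), make_hit("a3", "a4", 1e-30)]
        loose = hm.duplicated_genes(hits, 1e-10)
        tight = hm.duplicated_genes(hits, 1e-20)
        assert tight <= loose


class TestAssignFamilies:
    MAP = {"db1": "COG0001", "db2": "COG0002"}

    def test_qualifying_hit_assigned(self):
        t = hm.assign_families([make_hit("p1", "db1", 1e-6)], self.MAP, 1e-3)
        assert list(t.itertuples(index=False))[0][:2] == ("p1", "COG0001")

    def test_weak_hit_unassigned(self):
        t = hm.assign_families([make_hit("p1", "db1", 1e-2)], self.MAP, 1e-3)
        assert t.empty

    def test_tie_broken_by_bitscore_then_family(self):
        hits = [
            make_hit("p1", "db1", 1e-6, bitscore=100),
            make_hit("p1", "db2", 1e-6, bitscore=200),
        ]
        t = hm.assign_families(hits, self.MAP, 1e-3)
        assert t.family_id[0] == "COG0002"

    def test_missing_mapping_errors_naming_subject(self):
        with pytest.raises(KeyError, match="db_unknown"):
            hm.assign_families([make_hit("p1", "db_unknown", 1e-6)], self.MAP, 1e-3)


class TestHomologFilter:
    @pytest.mark.parametrize(
        "length,pid,kept",
        [(100, 25.0, True), (70, 25.0, False), (100, 20.0, False), (71, 20.1, True)],
    )
    def test_strict_inequalities(self, length, pid, kept):
        hits = [make_hit("q", "s", 1e-30, pid=pid, length=length)]
        out = hm.filter_homolog_candidates(hits, 70, 20.0)
        assert (len(out) == 1) is kept


def test_dedupe_keeps_best_hsp():
    hits = [make_hit("q", "s", 1e-10), make_hit("q", "s", 1e-30)]
    (kept,) = hm.dedupe_best_hsp(hits)
    assert kept.evalue == 1e-30


def test_threshold_defaults_match_analysis_cutoffs():
    t = hm.ThresholdConfig()
    assert (t.e_rbh, t.e_dup, t.e_family, t.e_synteny_grade) == (1e-5, 1e-10, 1e-3, 1e-100)
    assert (t.min_aln_len, t.min_pid) == (70, 20.0)
    with pytest.raises(ValueError):
        hm.ThresholdConfig(e_rbh=0.0)
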