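"""Presence/absence differential expression across libraries."""

import numpy as np
import pandas as pd
import pytest

from plantlinc.diffexpr import (
    LibrarySet,
    build_presence_matrix,
    call_differential,
    naive_similarity_hits,
    qualified_id,
)
from plantlinc.io import Transcript
from plantlinc.synthetic import gen_hit_table

COND4 = {"id9": "control", "id10": "treated", "id11": "control", "id12": "treated"}


def lib_set(n_per_lib=1, conditions=COND4, seqs=None, rng=None):
    libraries = []
    for lib in conditions:
        ts = []
        for i in range(n_per_lib):
            if seqs is not None:
                seq = seqs[(lib, i)]
            elif rng is not None:
                seq = "".join(rng.choice(list("ACGT"), size=300))
            else:
                seq = "ACGT" * 75
            ts.append(Transcript(id=f"s{i}", seq=seq))
        libraries.append((lib, ts))
    return LibrarySet.from_lists(libraries, conditions)


def brute_force_differential(matrix: pd.DataFrame, condition) -> set:
    """Independent row-by-row evaluation of the differential rule."""
    out = set()
    for rid, row in matrix.iterrows():
        yes_treated = any(row[c] for c in matrix.columns if condition[c] == "treated")
        yes_control = any(row[c] for c in matrix.columns if condition[c] == "control")
        if (yes_treated and not yes_control) or (yes_control and not yes_treated):
            out.add(rid)
    return out


class TestLibrarySet:
    def test_duplicate_library_ids_rejected(self):
        t = Transcript(id="a", seq="ACGT")
        with pytest.raises(ValueError, match="unique"):
            LibrarySet.from_lists([("L", [t]), ("L", [t])], {"L": "treated"})

    def test_missing_condition_rejected(self):
        t = Transcript(id="a", seq="ACGT")
        with pytest.raises(ValueError, match="without a condition"):
            LibrarySet.from_lists([("A", [t]), ("B", [t])], {"A": "treated"})

    def test_single_condition_rejected(self):
        t = Transcript(id="a", seq="ACGT")
        with pytest.raises(ValueError, match="at least one"):
            LibrarySet.from_lists([("A", [t]), ("B", [t])], {"A": "treated", "B": "treated"})


class TestBuildPresenceMatrix:
    def test_worked_example_row_pattern(self):
        # a sequence from library id10 similar to one in id12 and nothing
        # else is present exactly in id10 and id12
        ls = lib_set()
        hits = gen_hit_table([(qualified_id("id10", "s0"), qualified_id("id12", "s0"), 1e-20)])
        m = build_presence_matrix(ls, hits)
        row = m.loc[qualified_id("id10", "s0")]
        assert row.tolist() == [False, True, False, True]
        assert list(m.columns) == ["id9", "id10", "id11", "id12"]

    def test_no_hits_gives_identity_pattern(self):
        ls = lib_set()
        m = build_presence_matrix(ls, [])
        for lib in COND4:
            row = m.loc[qualified_id(lib, "s0")]
            assert row[lib] and row.sum() == 1

    def test_evalue_boundary_inclusive(self):
        ls = lib_set()
        q, s = qualified_id("id10", "s0"), qualified_id("id12", "s0")
        at = build_presence_matrix(ls, gen_hit_table([(q, s, 1e-12)]))
        above = build_presence_matrix(ls, gen_hit_table([(q, s, 2e-12)]))
        assert at.loc[q, "id12"]
        assert not above.loc[q, "id12"]

    def test_self_presence_forced(self):
        ls = lib_set()
        hits = gen_hit_table([(qualified_id("id9", "s0"), qualified_id("id9", "s0"), 1e-30)])
        m = build_presence_matrix(ls, hits)
        assert m.loc[qualified_id("id9", "s0"), "id9"]

    def test_unknown_hit_ids_warn(self):
        ls = lib_set()
        hits = gen_hit_table([("nowhere:s0", qualified_id("id9", "s0"), 1e-30)])
        with pytest.warns(UserWarning, match="absent from every library"):
            build_presence_matrix(ls, hits)


class TestCallDifferential:
    def test_worked_example_is_differential(self):
        ls = lib_set()
        q, s = qualified_id("id10", "s0"), qualified_id("id12", "s0")
        m = build_presence_matrix(ls, gen_hit_table([(q, s, 1e-20), (s, q, 1e-20)]))
        ids, count = call_differential(m, COND4)
        assert q in ids and s in ids
        assert count == len(ids)

    def test_all_yes_row_not_differential(self):
        m = pd.DataFrame(True, index=["r"], columns=list(COND4))
        ids, count = call_differential(m, COND4)
        assert count == 0

    def test_yes_on_both_sides_not_differential(self):
        m = pd.DataFrame(False, index=["r"], columns=list(COND4))
        m.loc["r", "id10"] = True  # treated
        m.loc["r", "id9"] = True  # control
        assert call_differential(m, COND4)[1] == 0

    def test_empty_hit_table_makes_every_row_differential(self):
        # present only at home -> one side occupied, the other empty
        ls = lib_set(n_per_lib=2)
        m = build_presence_matrix(ls, [])
        ids, count = call_differential(m, COND4)
        assert count == len(m)

    def test_label_swap_invariance(self, rng):
        m = pd.DataFrame(
            rng.random((40, 4)) < 0.4, index=[f"r{i}" for i in range(40)], columns=list(COND4)
        )
        swapped = {
            c: ("treated" if v == "control" else "control") for c, v in COND4.items()
        }
        assert call_differential(m, COND4)[0] == call_differential(m, swapped)[0]

    def test_column_order_invariance(self, rng):
        m = pd.DataFrame(
            rng.random((40, 4)) < 0.4, index=[f"r{i}" for i in range(40)], columns=list(COND4)
        )
        shuffled = m[["id12", "id9", "id10", "id11"]]
        assert call_differential(m, COND4)[0] == call_differential(shuffled, COND4)[0]

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            m = pd.DataFrame(
                rng.random((n, 4)) < rng.random(),
                index=[f"r{i}" for i in range(n)],
                columns=list(COND4),
            )
            ids, count = call_differential(m, COND4)
            assert ids == brute_force_differential(m, COND4)
            assert count == len(ids)

    def test_cross_condition_hits_only_reduce_count(self, rng):
        # connecting a row across conditions can only remove it from the
        # differential set; within-condition links never reduce the count
        for trial in range(10):
            ls = lib_set(n_per_lib=2)
            base_ids, base_count = call_differential(build_presence_matrix(ls, []), COND4)
            pairs = []
            rows = [qualified_id(lib, f"s{i}") for lib in COND4 for i in range(2)]
            for q in rows:
                if rng.random() < 0.5:
                    s = rows[int(rng.integers(len(rows)))]
                    pairs.append((q, s, 1e-20))
            m = build_presence_matrix(ls, gen_hit_table(pairs))
            ids, count = call_differential(m, COND4)
            within_only = all(
                COND4[q.split(":")[0]] == COND4[s.split(":")[0]] for q, s, _ in pairs
            )
            if within_only:
                assert count >= base_count
            else:
                assert count <= base_count


class TestNaiveSimilarityHits:
    def test_identical_sequences_hit_reciprocally(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        seqs = {(lib, 0): seq if lib in ("id10", "id12") else
                "".join(rng.choice(list("ACGT"), size=300)) for lib in COND4}
        ls = lib_set(seqs=seqs)
        hits = naive_similarity_hits(ls, min_shared_kmer_len=100)
        pairs = {(h.query_id, h.subject_id) for h in hits}
        q, s = qualified_id("id10", "s0"), qualified_id("id12", "s0")
        assert (q, s) in pairs and (s, q) in pairs

    def test_independent_sequences_do_not_hit(self, rng):
        ls = lib_set(rng=rng)
        hits = naive_similarity_hits(ls, min_shared_kmer_len=100)
        cross = [(h.query_id, h.subject_id) for h in hits if h.query_id != h.subject_id]
        assert cross == []

    def test_self_hits_emitted_and_harmless(self, rng):
        ls = lib_set(rng=rng)
        hits = naive_similarity_hits(ls, min_shared_kmer_len=100)
        selfs = {h.query_id for h in hits if h.query_id == h.subject_id}
        assert selfs == {rid for rid, _, _ in ls.pooled_rows()}
        m = build_presence_matrix(ls, hits)
        assert (m.sum(axis=1) == 1).all()
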