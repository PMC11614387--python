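"""Bitvector editing, constrained folding, element encoding, clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from bashmap.dagger import (
    ConstraintMask,
    StructureEnsemble,
    edit_bitvector,
    element_vector,
    ensemble_fold,
    fold_constrained,
    reduce_and_cluster,
    tertiary_g_set,
)
from bashmap.io_formats import BitVector, ReadSet, SequenceRecord
from bashmap.reactivity import ReactivityProfile
from bashmap.ring import PairMatrix
from conftest import make_readset

CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def exhaustive_max_pairs(seq, flags):
    """Plain recursive search over all nested structures (no memo): max pairs."""

    def rec(i, j):
        if j - i < 4:
            return 0
        best = rec(i + 1, j)
        if flags[i] == 0:
            for k in range(i + 4, j + 1):
                if flags[k] == 0 and (seq[i], seq[k]) in CANONICAL:
                    best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def pair_count(db):
    return db.count("(")


class TestEditBitvector:
    def _read(self, bits):
        return BitVector("r", 1, len(bits), np.array([int(c) for c in bits], dtype=np.uint8))

    def test_unmodified_read_gets_tertiary_forced(self):
        out = edit_bitvector(self._read("0" * 10), {5, 9}, {3, 5, 9})
        assert list(out.one_positions()) == [5, 9]

    def test_tertiary_hit_frees_all_tertiary_gs(self):
        out = edit_bitvector(self._read("0000100000"), {5, 9}, {3, 5, 9})
        assert list(out.one_positions()) == []

    def test_non_tertiary_g_bit_cleared(self):
        out = edit_bitvector(self._read("0010000000"), {5, 9}, {3, 5, 9})
        # the hit at non-tertiary G3 is cleared; tertiary G's forced on
        assert list(out.one_positions()) == [5, 9]

    def test_non_g_positions_untouched(self):
        out = edit_bitvector(self._read("1000000001"), {5}, {3, 5})
        assert set(out.one_positions()) == {1, 5, 10}

    def test_edited_tertiary_pattern_is_all_or_none(self):
        # after editing, tertiary G's are either all forced (1) or all freed (0),
        # every other G is 0, and re-editing is deterministic
        rng = np.random.default_rng(19)
        for _ in range(20):
            bits = "".join(rng.choice(["0", "1"], size=12))
            read = self._read(bits)
            once = edit_bitvector(read, {4, 8}, {2, 4, 8, 11})
            tert_bits = {once.bit_at(4), once.bit_at(8)}
            assert len(tert_bits) == 1
            assert once.bit_at(2) == 0 and once.bit_at(11) == 0
            again = edit_bitvector(read, {4, 8}, {2, 4, 8, 11})
            assert np.array_equal(once.bits, again.bits)


class TestFold:
    def test_simple_hairpin(self):
        db = fold_constrained("GGGGAAAACCCC", ConstraintMask(np.zeros(12, dtype=np.uint8)))
        assert db == "((((....))))"

    def test_masked_block_stays_unpaired(self):
        mask = ConstraintMask.from_positions(12, {1, 2, 3, 4})
        db = fold_constrained("GGGGAAAACCCC", mask, backend="builtin")
        assert all(db[i] == "." for i in range(4))
        flags = mask.flags
        assert pair_count(db) == exhaustive_max_pairs("GGGGAAAACCCC", flags)

    def test_all_masked_no_pairs(self):
        mask = ConstraintMask(np.ones(8, dtype=np.uint8))
        assert fold_constrained("GGGGCCCC", mask) == "........"

    def test_matches_exhaustive_oracle_random(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            L = int(rng.integers(6, 13))
            seq = "".join(rng.choice(list("ACGU"), size=L))
            flags = rng.choice([0, 1], size=L, p=[0.8, 0.2]).astype(np.uint8)
            db = fold_constrained(seq, ConstraintMask(flags))
            assert pair_count(db) == exhaustive_max_pairs(seq, flags)
            assert all(db[i] == "." for i in np.flatnonzero(flags))

    def test_external_backend_contract(self):
        cmd = (
            "python -c \"import sys; seq=sys.stdin.readline().strip(); "
            "print('.'*len(seq))\""
        )
        db = fold_constrained("GGGGAAAACCCC", ConstraintMask(np.zeros(12, dtype=np.uint8)),
                              backend="external", command=cmd)
        assert db == "." * 12

    def test_external_constraint_violation_hard_error(self):
        cmd = """python -c "print('((((....))))')" """
        mask = ConstraintMask.from_positions(12, {1})
        with pytest.raises(RuntimeError, match="constraint"):
            fold_constrained("GGGGAAAACCCC", mask, backend="external", command=cmd)

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            fold_constrained("AAAA", ConstraintMask(np.zeros(4, dtype=np.uint8)), backend="magic")


class TestElementVector:
    def test_single_hairpin(self):
        v = element_vector("((((....))))")
        assert v.tolist() == [1] * 4 + [4] * 4 + [1] * 4

    def test_all_unpaired_is_fiveprime(self):
        assert element_vector("." * 12).tolist() == [5] * 12

    def test_interior_and_hairpin_decomposition(self):
        v = element_vector("((..((...))..))")
        assert v.tolist() == [1, 1, 2, 2, 1, 1, 4, 4, 4, 1, 1, 2, 2, 1, 1]

    def test_multiloop_and_tails(self):
        #  0     5    10   15    20
        db = ".((...(((...)))(((...))).))."
        v = element_vector(db)
        assert v[0] == 5 and v[-1] == 6
        assert v[3] == 3 and v[24] == 3  # unpaired inside the two-branch loop
        assert v[10] == 4 and v[19] == 4

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            element_vector("((..)")


class TestTertiaryGSet:
    def _profile(self, seq, rates):
        return ReactivityProfile.from_rates(SequenceRecord("x", seq), rates)

    def _pm(self, seq, z_entries):
        L = len(seq)
        Z = np.full((L, L), np.nan)
        sign = np.zeros((L, L), dtype=int)
        for (i, j), z in z_entries.items():
            Z[i - 1, j - 1] = Z[j - 1, i - 1] = z
            sign[i - 1, j - 1] = sign[j - 1, i - 1] = 1
        valid = np.isfinite(Z)
        return PairMatrix(
            G=np.where(valid, 10.0, np.nan), sign=sign, n11=np.zeros((L, L)),
            N=np.full((L, L), 100), valid=valid, min_sep=1,
            reference=SequenceRecord("x", seq), Z=Z, z_population="GG",
        )

    def test_no_gg_pairs_empty(self):
        seq = "GGGGGGGG"
        prof = self._profile(seq, [0.01, 0.02, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3])
        assert tertiary_g_set(prof, self._pm(seq, {})) == set()

    def test_correlated_bottom_quartile_pair_selected(self):
        seq = "GGGGGGGG"
        prof = self._profile(seq, [0.01, 0.02, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3])
        pm = self._pm(seq, {(1, 2): 3.0})
        assert tertiary_g_set(prof, pm) == {1, 2}

    def test_low_g_correlated_only_with_high_g_excluded(self):
        seq = "GGGGGGGG"
        prof = self._profile(seq, [0.01, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.02])
        pm = self._pm(seq, {(1, 4): 5.0})  # G4 is highly reactive
        assert tertiary_g_set(prof, pm) == set()


class TestEnsembleFold:
    def _rs(self, seq, rows):
        return make_readset(seq, rows)

    def test_max_reads_larger_than_n_uses_all(self):
        rs = self._rs("GGGGAAAACCCC", ["0" * 12] * 3)
        se = ensemble_fold(rs, tertiary=set(), max_reads=100)
        assert len(se) == 3

    def test_most_modified_selected_stable_order(self):
        rows = ["000000000000", "110000000000", "100000000000", "110000000000"]
        rs = self._rs("GGGGAAAACCCC", rows)
        se = ensemble_fold(rs, tertiary=set(), max_reads=2)
        assert se.read_ids == ["r1", "r3"]  # two most modified, input order

    def test_structures_satisfy_own_masks(self):
        rng = np.random.default_rng(21)
        seq = "GGGGAAAACCCCAAAA"
        g_pos = {1, 2, 3, 4}
        rows = ["".join(rng.choice(["0", "1"], size=16, p=[0.8, 0.2])) for _ in range(12)]
        rs = self._rs(seq, rows)
        tert = {1, 2}
        se = ensemble_fold(rs, tertiary=tert, max_reads=50)
        for read, db in zip(rs.reads, se.structures):
            from bashmap.dagger import edit_bitvector

            edited = edit_bitvector(read, tert, g_pos)
            for p in edited.one_positions():
                assert db[p - 1] == "."

    def test_deterministic(self):
        rng = np.random.default_rng(22)
        rows = ["".join(rng.choice(["0", "1"], size=12, p=[0.7, 0.3])) for _ in range(10)]
        rs = self._rs("GGGGAAAACCCC", rows)
        a = ensemble_fold(rs, tertiary=set(), max_reads=10)
        b = ensemble_fold(rs, tertiary=set(), max_reads=10)
        assert a.structures == b.structures


class TestReduceAndCluster:
    def _ensemble(self, elements, seq="GGGGAAAACCCCAAAA"):
        elements = np.asarray(elements, dtype=np.int8)
        n = elements.shape[0]
        return StructureEnsemble(
            reference=SequenceRecord("x", seq[: elements.shape[1]]),
            read_ids=[f"r{i}" for i in range(n)],
            structures=["." * elements.shape[1]] * n,
            elements=elements,
        )

    def test_k1_representative_nearest_grand_centroid(self):
        elems = [[1, 1, 4, 4], [1, 1, 4, 4], [5, 5, 5, 5]]
        se = reduce_and_cluster(self._ensemble(elems), K=1, seed=0)
        assert se.clusters.tolist() == [0, 0, 0]
        d = np.linalg.norm(se.pca - se.pca.mean(axis=0), axis=1)
        assert se.representatives[0] == int(np.argmin(d))

    def test_identical_vectors_collapse_to_origin(self):
        se = reduce_and_cluster(self._ensemble([[1, 4, 1, 6]] * 5), K=1, seed=0)
        assert np.allclose(se.pca, 0.0)

    def test_two_planted_families_perfect_recovery(self):
        rng = np.random.default_rng(13)
        fam_a = np.tile([1, 1, 1, 4, 4, 4, 1, 1, 1, 5], (20, 1))
        fam_b = np.tile([5, 5, 5, 1, 1, 4, 4, 1, 1, 6], (15, 1))
        elems = np.vstack([fam_a, fam_b])
        order = rng.permutation(len(elems))
        truth = (np.arange(35) >= 20).astype(int)[order]
        se = reduce_and_cluster(self._ensemble(elems[order]), K=2, seed=13)
        assert adjusted_rand_score(truth, se.clusters) == pytest.approx(1.0)

    def test_cluster_proportions_sum_to_one(self):
        rng = np.random.default_rng(23)
        elems = rng.integers(1, 7, size=(30, 8))
        se = reduce_and_cluster(self._ensemble(elems), K=3, seed=0)
        assert se.cluster_proportions().sum() == pytest.approx(1.0)
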