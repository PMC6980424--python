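import numpy as np
import pytest

from conftest import GI, GE, brute_global, make_calibrated_model
from mountalign import (
    RnaSequence,
    load_ribosum,
    multi_calibration,
    progressive_align,
    sps,
    upgma,
)
from mountalign.multiple import (
    Profile,
    pairwise_similarity_matrix,
    profile_similarity_matrix,
    seqsim_columns,
    strsim_columns,
)
from mountalign.scoring import calibrate_pair, seq_moments, str_moments
from mountalign.seqio import nucleotide_frequencies
from mountalign.structure import base_pair_probabilities, incremental_mountain

RIB = load_ribosum()


def fold_profiles(seqs):
    return [
        incremental_mountain(base_pair_probabilities(s, "simple-bp")) for s in seqs
    ]


class TestMultiCalibration:
    def test_two_copies_match_pairwise_self_calibration(self):
        s = RnaSequence("s", "GGGCAAAAGCCC")
        profs = fold_profiles([s, RnaSequence("s2", s.residues)])
        cal = multi_calibration([s, RnaSequence("s2", s.residues)], profs, RIB)
        pair = calibrate_pair(s, s, profs[0].bracket_probs, profs[0].bracket_probs, RIB)
        assert cal.alpha_seq == pytest.approx(pair.alpha_seq, abs=1e-12)
        assert cal.alpha_str == pytest.approx(pair.alpha_str, abs=1e-12)

    def test_matches_direct_formula_evaluation(self):
        seqs = [RnaSequence("a", "GGGAAACCCU"), RnaSequence("b", "AAGCGCUU")]
        profs = fold_profiles(seqs)
        cal = multi_calibration(seqs, profs, RIB)
        concat = seqs[0].residues + seqs[1].residues
        p = np.array([concat.count(c) for c in "ACGU"]) / len(concat)
        b = np.mean([pr.bracket_probs for pr in profs], axis=0)
        mu_s, sd_s = seq_moments(p, p, RIB)
        mu_t, sd_t = str_moments(b, b)
        assert cal.alpha_seq == pytest.approx(sd_t / sd_s)
        assert cal.alpha_str == pytest.approx((sd_t / sd_s) * mu_s - mu_t)

    def test_order_invariance(self):
        seqs = [
            RnaSequence("a", "GGGAAACCCU"),
            RnaSequence("b", "AAGCGCUU"),
            RnaSequence("c", "GCGCAAAAGCGC"),
        ]
        profs = fold_profiles(seqs)
        cal1 = multi_calibration(seqs, profs, RIB)
        perm = [2, 0, 1]
        cal2 = multi_calibration(
            [seqs[i] for i in perm], [profs[i] for i in perm], RIB
        )
        assert cal1.alpha_seq == pytest.approx(cal2.alpha_seq, abs=1e-12)
        assert cal1.alpha_str == pytest.approx(cal2.alpha_str, abs=1e-12)


class TestColumnSimilarities:
    def test_single_sequence_columns_reduce_to_ribosum(self):
        fa = np.array([0, 0, 1.0, 0, 0])  # G
        fb = np.array([0, 1.0, 0, 0, 0])  # C
        assert seqsim_columns(fa, fb, RIB) == pytest.approx(-2.48)

    def test_all_gap_column_scores_zero(self):
        gap = np.array([0, 0, 0, 0, 1.0])
        any_col = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        assert seqsim_columns(gap, any_col, RIB) == 0.0

    def test_mixed_columns_equal_25_term_sum(self):
        rng = np.random.default_rng(0)
        fa, fb = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        r5 = np.zeros((5, 5))
        r5[:4, :4] = RIB.values
        direct = sum(
            fa[i] * fb[j] * r5[i, j] for i in range(5) for j in range(5)
        )
        assert seqsim_columns(fa, fb, RIB) == pytest.approx(direct)

    def test_strsim_columns(self):
        assert strsim_columns(0.4, 0.4) == 0.0
        assert strsim_columns(1.0, -1.0) == -2.0

    def test_column_mean_height_counts_gaps_as_zero(self):
        prof = Profile(
            ["x", "y", "z"],
            ["A", "A", "-"],
            np.array([[0.3], [-0.3], [0.0]]),
        )
        assert prof.mean_heights()[0] == pytest.approx(0.0)


class TestUpgma:
    def test_two_items_single_join(self):
        t = upgma(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert sorted(t.leaves()) == [0, 1]

    def test_greedy_first_merge(self):
        S = np.array([[0, 9.0, 1.0], [9.0, 0, 1.5], [1.0, 1.5, 0]])
        t = upgma(S)
        first = t.left if not t.left.is_leaf else t.right
        assert sorted(first.leaves()) == [0, 1]

    def test_four_taxon_merge_order_matches_hand_run(self):
        # hand-run: merge (0,1) [sim 10]; then {0,1}-2: (6+2)/2 = 4,
        # {0,1}-3: (1+1)/2 = 1, 2-3: 3 -> next merge ({0,1}, 2); 3 joins last
        S = np.array(
            [
                [0.0, 10.0, 6.0, 1.0],
                [10.0, 0.0, 2.0, 1.0],
                [6.0, 2.0, 0.0, 3.0],
                [1.0, 1.0, 3.0, 0.0],
            ]
        )
        t = upgma(S)
        assert sorted(t.right.leaves() if t.left.is_leaf else t.left.leaves()) == [
            0,
            1,
            2,
        ]
        # the deepest merge is {0,1}
        inner = t.left if not t.left.is_leaf else t.right
        sub = inner.left if not inner.left.is_leaf else inner.right
        assert sorted(sub.leaves()) == [0, 1]

    def test_matches_scipy_average_linkage_order(self):
        from scipy.cluster.hierarchy import average

        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 6
            S = rng.uniform(0, 5, (n, n))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 0)
            tree = upgma(S)
            # scipy on distances D = max - S gives the same merge heights order
            from scipy.spatial.distance import squareform

            D = S.max() - S
            np.fill_diagonal(D, 0)
            Z = average(squareform(D, checks=False))

            def merges(t, acc):
                if t.is_leaf:
                    return frozenset([t.index])
                l = merges(t.left, acc)
                r = merges(t.right, acc)
                s = l | r
                acc.append(s)
                return s

            ours = []
            merges(tree, ours)
            clusters = {i: frozenset([i]) for i in range(n)}
            scipy_merges = []
            for k, (i, j, _, _) in enumerate(Z):
                s = clusters[int(i)] | clusters[int(j)]
                clusters[n + k] = s
                scipy_merges.append(s)
            assert set(ours) == set(scipy_merges)


class TestProgressiveAlign:
    def test_identical_sequences_gapfree(self):
        seqs = [RnaSequence(f"s{i}", "GGGCAAAAGCCCA") for i in range(4)]
        aln = progressive_align(seqs, backend="simple-bp")
        assert all(r == seqs[0].residues for r in aln.rows)

    def test_rows_degap_to_inputs_and_no_allgap_columns(self):
        seqs = [
            RnaSequence("a", "GGGAAACUUUCCC"),
            RnaSequence("b", "GGGAAACUUUCC"),
            RnaSequence("c", "GGAAAGCUUUCCC"),
            RnaSequence("d", "GGGAAAGCUUCC"),
        ]
        aln = progressive_align(seqs, backend="simple-bp")
        for k, s in enumerate(seqs):
            assert aln.degapped(k).residues == s.residues
        for col in range(aln.ncols):
            assert any(r[col] != "-" for r in aln.rows)

    def test_sps_self_is_one_and_row_order_invariant(self):
        seqs = [
            RnaSequence("a", "GGGAAACUUUCCC"),
            RnaSequence("b", "GGGAAACUUUCC"),
            RnaSequence("c", "GGAAAGCUUUCCC"),
        ]
        aln = progressive_align(seqs, backend="simple-bp")
        assert sps(aln, aln) == 1.0
        shuffled = type(aln)(
            [aln.ids[2], aln.ids[0], aln.ids[1]],
            [aln.rows[2], aln.rows[0], aln.rows[1]],
        )
        assert sps(shuffled, aln) == 1.0

    def test_two_equal_sequences_reduce_to_pairwise_global(self):
        """With both sequences identical, the shared multi-calibration equals
        the pairwise calibration, so the profile merge must reproduce the
        pairwise global alignment."""
        from mountalign import align

        s = RnaSequence("s1", "GGGCAAAAGCCCAU")
        s2 = RnaSequence("s2", s.residues)
        aln = progressive_align([s, s2], backend="simple-bp")
        pw = align(s, s2, mode="global", backend="simple-bp")
        assert aln.rows == pw.alignment.rows
        assert aln.score == pytest.approx(pw.score, abs=1e-9)

    def test_three_tiny_sequences_match_bruteforce_profile_dp(self):
        """Root-merge score equals exhaustive enumeration over all profile
        alignments along the same guide tree."""
        seqs = [
            RnaSequence("a", "GCAUG"),
            RnaSequence("b", "GCAU"),
            RnaSequence("c", "CAUG"),
        ]
        model = make_calibrated_model()
        profs = fold_profiles(seqs)
        cal = multi_calibration(seqs, profs, model.ribosum)
        model = model.calibrated(cal)
        tree = upgma(pairwise_similarity_matrix(seqs, profs, model))
        aln = progressive_align(seqs, model, backend="simple-bp")

        # independent enumeration: first merge the tree's first pair by
        # enumerating alignments, then enumerate merges with the third row
        order = tree.leaves()
        first = (tree.left if not tree.left.is_leaf else tree.right)
        if first.is_leaf:  # balanced 2+1 shape: inner pair is below the root
            first = tree.left if tree.left.is_leaf else tree.right
        pair_idx = sorted(
            (tree.left.leaves() if len(tree.left.leaves()) == 2 else tree.right.leaves())
        )
        (third_idx,) = [i for i in range(3) if i not in pair_idx]

        def leaf_profile(i):
            return Profile([seqs[i].id], [seqs[i].residues], profs[i].m[None, :])

        def enumerate_merges(pa, pb):
            """All merged profiles of pa, pb with their column-sum scores."""
            from conftest import _op_paths

            Spp = profile_similarity_matrix(pa, pb, model)
            out = []
            for ops in _op_paths(pa.ncols, pb.ncols):
                i = j = 0
                score = 0.0
                last = None
                rows_a = [""] * pa.size
                rows_b = [""] * pb.size
                ha, hb = [], []
                for op in ops:
                    if op == "D":
                        score += Spp[i, j]
                    else:
                        score += GE if last == op else GI
                    if op in ("D", "P"):
                        for r in range(pa.size):
                            rows_a[r] += pa.rows[r][i]
                        ha.append(pa.heights[:, i])
                        i += 1
                    else:
                        for r in range(pa.size):
                            rows_a[r] += "-"
                        ha.append(np.zeros(pa.size))
                    if op in ("D", "Q"):
                        for r in range(pb.size):
                            rows_b[r] += pb.rows[r][j]
                        hb.append(pb.heights[:, j])
                        j += 1
                    else:
                        for r in range(pb.size):
                            rows_b[r] += "-"
                        hb.append(np.zeros(pb.size))
                    last = op
                prof = Profile(
                    pa.ids + pb.ids,
                    rows_a + rows_b,
                    np.vstack([np.array(ha).T, np.array(hb).T]),
                )
                out.append((prof, score))
            return out

        pa, pb = leaf_profile(pair_idx[0]), leaf_profile(pair_idx[1])
        best = -np.inf
        # the DP merges greedily (optimal first merge), then optimally merges
        # the third profile; enumerate both stages exhaustively
        first_best = max(s for _, s in enumerate_merges(pa, pb))
        for prof, s1 in enumerate_merges(pa, pb):
            if abs(s1 - first_best) > 1e-9:
                continue
            for _, s2 in enumerate_merges(prof, leaf_profile(third_idx)):
                best = max(best, s2)
        assert aln.score == pytest.approx(best, abs=1e-6)
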