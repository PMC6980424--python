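"""Affine-gap Gotoh dynamic programming: global, local and semiglobal modes.

Three (n+1) x (m+1) matrices are filled: M (last column aligns a_i with
b_j), P (last column is (a_i, -), a gap in the target row) and Q (last
column is (-, b_j)).  Gap runs cost g(k) = g_i + (k-1) * g_e.

Modes:

* ``global`` - both sequences aligned end to end; optimum at M[n][m].
* ``semiglobal`` - the query a is aligned end to end while gaps flanking
  the aligned region of the target b are free: M[0][j] = 0 and the optimum
  is the maximum over row n (ties broken toward the leftmost target end).
  This is the query-search mode used by the genome scanner.
* ``local`` - Smith-Waterman variant: M is clamped at 0, the optimum is
  taken over all cells, and traceback stops at a zero cell.

Traceback tie-breaking is deterministic: diagonal, then P (gap in target),
then Q (gap in query), so outputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .scoring import ScoringModel, calibrate_pair, similarity_matrix
from .seqio import GAP, GappedAlignment, RnaSequence
from .structure import (
    BasePairMatrix,
    MountainProfile,
    base_pair_probabilities,
    incremental_mountain,
)

NEG = -1e30

MODES = ("global", "local", "semiglobal")


@dataclass
class PairwiseAlignment:
    """A pairwise alignment plus score and 1-based aligned intervals."""

    alignment: GappedAlignment
    score: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    mode: str


@njit(cache=False)
def _fill(S, gi, ge, mode):  # mode: 0 global, 1 semiglobal, 2 local
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    P = np.full((n + 1, m + 1), NEG)
    Q = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        if mode == 2:
            M[i, 0] = 0.0
        else:
            M[i, 0] = gi + (i - 1) * ge
    for j in range(1, m + 1):
        if mode == 0:
            M[0, j] = gi + (j - 1) * ge
        else:
            M[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            p = M[i - 1, j] + gi
            if P[i - 1, j] + ge > p:
                p = P[i - 1, j] + ge
            P[i, j] = p
            q = M[i, j - 1] + gi
            if Q[i, j - 1] + ge > q:
                q = Q[i, j - 1] + ge
            Q[i, j] = q
            best = M[i - 1, j - 1] + S[i - 1, j - 1]
            if p > best:
                best = p
            if q > best:
                best = q
            if mode == 2 and best < 0.0:
                best = 0.0
            M[i, j] = best
    return M, P, Q


def _traceback(S, M, P, Q, gi, ge, mode, i, j):
    """Walk pointers from (i, j); returns column ops and the start cell."""
    ops = []  # 'D' diagonal, 'P' gap in target, 'Q' gap in query
    state = "M"
    eps = 1e-9
    while True:
        if mode == 2 and state == "M" and M[i, j] <= eps and M[i, j] >= -eps:
            break
        if state == "M":
            if i == 0 and j == 0:
                break
            if mode != 0 and i == 0:
                break  # free left target flank (semiglobal) / origin
            if i > 0 and j > 0 and abs(M[i, j] - (M[i - 1, j - 1] + S[i - 1, j - 1])) < eps:
                ops.append("D")
                i -= 1
                j -= 1
            elif i > 0 and abs(M[i, j] - P[i, j]) < eps:
                state = "P"
            elif j > 0 and abs(M[i, j] - Q[i, j]) < eps:
                state = "Q"
            elif j == 0:  # boundary gap run in target row
                ops.append("P")
                i -= 1
            elif i == 0:  # global boundary gap run in query row
                ops.append("Q")
                j -= 1
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed")
        elif state == "P":
            ops.append("P")
            if abs(P[i, j] - (M[i - 1, j] + gi)) < eps:
                state = "M"
            i -= 1
        else:
            ops.append("Q")
            if abs(Q[i, j] - (M[i, j - 1] + gi)) < eps:
                state = "M"
            j -= 1
    return ops[::-1], i, j


def align_with_profiles(
    a: RnaSequence,
    b: RnaSequence,
    prof_a: MountainProfile,
    prof_b: MountainProfile,
    model: ScoringModel,
    mode: str = "global",
) -> PairwiseAlignment:
    """Align two sequences whose mountain profiles are already computed.

    The model must already be calibrated (use :func:`align` for the
    one-call form that also folds and calibrates).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    S = similarity_matrix(a, b, prof_a, prof_b, model)
    gi, ge = model.gap_init, model.gap_extend
    mcode = {"global": 0, "semiglobal": 1, "local": 2}[mode]
    M, P, Q = _fill(S, gi, ge, mcode)
    n, m = S.shape
    if mode == "global":
        end = (n, m)
        score = float(M[n, m])
    elif mode == "semiglobal":
        j_end = int(np.argmax(M[n, :]))  # ties -> smallest j (leftmost end)
        end = (n, j_end)
        score = float(M[n, j_end])
    else:
        flat = int(np.argmax(M))
        end = (flat // (m + 1), flat % (m + 1))
        score = float(M[end])
        if score <= 0.0:  # no positive-scoring pair: empty local alignment
            empty = GappedAlignment([a.id, b.id], ["", ""], mode=mode, score=0.0)
            return PairwiseAlignment(empty, 0.0, (1, 0), (1, 0), mode)
    ops, i0, j0 = _traceback(S, M, P, Q, gi, ge, mcode, *end)
    ra, rb = [], []
    i, j = i0, j0
    for op in ops:
        if op == "D":
            ra.append(a.residues[i])
            rb.append(b.residues[j])
            i += 1
            j += 1
        elif op == "P":
            ra.append(a.residues[i])
            rb.append(GAP)
            i += 1
        else:
            ra.append(GAP)
            rb.append(b.residues[j])
            j += 1
    aln = GappedAlignment([a.id, b.id], ["".join(ra), "".join(rb)], mode=mode, score=score)
    return PairwiseAlignment(aln, score, (i0 + 1, end[0]), (j0 + 1, end[1]), mode)


def align(
    a: RnaSequence,
    b: RnaSequence,
    model: ScoringModel | None = None,
    mode: str = "global",
    backend: str = "thermodynamic",
    bpm_a: BasePairMatrix | None = None,
    bpm_b: BasePairMatrix | None = None,
) -> PairwiseAlignment:
    """Fold, calibrate and align a sequence pair.

    Calibration is recomputed for every pair from the two full-length
    sequences' nucleotide frequencies and expected bracket probabilities.
    """
    model = model or ScoringModel()
    bpm_a = bpm_a or base_pair_probabilities(a, backend)
    bpm_b = bpm_b or base_pair_probabilities(b, backend)
    prof_a = incremental_mountain(bpm_a)
    prof_b = incremental_mountain(bpm_b)
    cal = calibrate_pair(
        a, b, prof_a.bracket_probs, prof_b.bracket_probs, model.ribosum
    )
    return align_with_profiles(a, b, prof_a, prof_b, model.calibrated(cal), mode)


def rescore(
    aln: GappedAlignment, S: np.ndarray, model: ScoringModel, mode: str
) -> float:
    """Score an alignment column by column: sim for residue columns, g_i
    for each gap opening, g_e per extension; semiglobal target flanks and
    everything outside a local alignment cost nothing."""
    ra, rb = aln.rows
    i = j = 0
    total = 0.0
    run = None  # current gap row ('a' or 'b')
    ncols = len(ra)
    for k in range(ncols):
        ca, cb = ra[k], rb[k]
        if ca != GAP and cb != GAP:
            total += S[i, j]
            i += 1
            j += 1
            run = None
        elif cb == GAP:
            total += model.gap_extend if run == "b" else model.gap_init
            run = "b"
            i += 1
        else:
            free = mode == "semiglobal" and (
                all(c == GAP for c in ra[:k]) or all(c == GAP for c in ra[k:])
            )
            if not free:
                total += model.gap_extend if run == "a" else model.gap_init
            run = "a"
            j += 1
    return total
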