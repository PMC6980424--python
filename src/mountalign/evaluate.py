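"""Alignment and structure accuracy measures.

Pairwise sensitivity/PPV/F1 count *all* alignment pairs, including the
gap pairs (a_i, -) and (-, b_j), identified by the underlying residue
indices: TP is the number of pairs present in both predicted and reference
alignments, Sen = TP / reference length, PPV = TP / predicted length and
F1 is their harmonic mean.  The sum-of-pairs score (SPS) for multiple
alignments counts residue-residue pairs only.  Secondary structures are
compared by the Matthews correlation coefficient over base-pair sets, with
the true-negative universe taken as all (i, j) with j - i > theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .seqio import (
    CANONICAL_PAIRS,
    GAP,
    THETA,
    DotBracketStructure,
    GappedAlignment,
    SequenceError,
)


@dataclass
class AlignmentComparison:
    tp: int
    fp: int
    sensitivity: float
    ppv: float
    f1: float


@dataclass
class StructureComparison:
    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float


def _column_pairs(aln: GappedAlignment) -> set[tuple]:
    """Pairs of one pairwise alignment, keyed by residue indices."""
    ra, rb = aln.rows
    i = j = 0
    pairs = set()
    for ca, cb in zip(ra, rb):
        if ca != GAP and cb != GAP:
            pairs.add(("r", i, j))
            i += 1
            j += 1
        elif cb == GAP:
            pairs.add(("a", i))
            i += 1
        else:
            pairs.add(("b", j))
            j += 1
    return pairs


def pair_metrics(pred: GappedAlignment, ref: GappedAlignment) -> AlignmentComparison:
    """Sen/PPV/F1 of a predicted pairwise alignment against a reference."""
    for k in range(2):
        if pred.degapped(k).residues != ref.degapped(k).residues:
            raise SequenceError("predicted and reference alignments differ in sequence")
    pp, rp = _column_pairs(pred), _column_pairs(ref)
    tp = len(pp & rp)
    sen = tp / ref.ncols if ref.ncols else 0.0
    ppv = tp / pred.ncols if pred.ncols else 0.0
    f1 = 0.0 if tp == 0 else 2.0 / (1.0 / sen + 1.0 / ppv)
    return AlignmentComparison(tp, len(pp) - tp, sen, ppv, f1)


def _residue_pairs(aln: GappedAlignment, k: int, l: int) -> set[tuple[int, int]]:
    """Residue-residue aligned index pairs between rows k and l."""
    ra, rb = aln.rows[k], aln.rows[l]
    i = j = 0
    out = set()
    for ca, cb in zip(ra, rb):
        if ca != GAP and cb != GAP:
            out.add((i, j))
        if ca != GAP:
            i += 1
        if cb != GAP:
            j += 1
    return out


def sps(pred: GappedAlignment, ref: GappedAlignment) -> float:
    """Sum-of-pairs score: fraction of the reference's residue-residue
    aligned pairs (over all sequence pairs) recovered by the prediction."""
    if sorted(pred.ids) != sorted(ref.ids):
        raise SequenceError("alignments contain different sequence sets")
    rindex = {sid: k for k, sid in enumerate(ref.ids)}
    total = correct = 0
    for k, l in combinations(range(len(pred.ids)), 2):
        rk, rl = rindex[pred.ids[k]], rindex[pred.ids[l]]
        ref_pairs = _residue_pairs(ref, rk, rl)
        total += len(ref_pairs)
        correct += len(_residue_pairs(pred, k, l) & ref_pairs)
    return correct / total if total else 0.0


def mcc(
    pred: DotBracketStructure, ref: DotBracketStructure, n: int | None = None
) -> float:
    """Matthews correlation coefficient between base-pair sets; 0 when any
    denominator factor vanishes (e.g. an empty prediction)."""
    n = n or len(pred)
    if len(pred) != len(ref):
        raise SequenceError("structures differ in length")
    pp, rp = set(pred.pairs), set(ref.pairs)
    tp = len(pp & rp)
    fp = len(pp - rp)
    fn = len(rp - pp)
    universe = sum(max(n - i - THETA, 0) for i in range(1, n + 1))
    tn = universe - len(pp | rp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom <= 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def percent_identity(aln: GappedAlignment) -> float:
    """Percentage of alignment columns with identical residues (pairwise)."""
    ra, rb = aln.rows
    if not ra:
        return 0.0
    same = sum(1 for ca, cb in zip(ra, rb) if ca == cb and ca != GAP)
    return 100.0 * same / len(ra)


_WUSS_OPEN = "(<[{"
_WUSS_CLOSE = ")>]}"


def _consensus_pairs(consensus) -> tuple[int, list[tuple[int, int]]]:
    """Column pairs of an alignment-level consensus; WUSS brackets accepted
    and the steric constraint NOT enforced (it applies after projection)."""
    if isinstance(consensus, DotBracketStructure):
        return len(consensus), list(consensus.pairs)
    stack: list[int] = []
    pairs = []
    for k, c in enumerate(consensus.strip(), start=1):
        if c in _WUSS_OPEN:
            stack.append(k)
        elif c in _WUSS_CLOSE:
            if not stack:
                raise SequenceError(f"unbalanced consensus bracket at column {k}")
            pairs.append((stack.pop(), k))
    if stack:
        raise SequenceError("unbalanced consensus brackets")
    return len(consensus.strip()), pairs


def project_consensus(gapped_row: str, consensus) -> DotBracketStructure:
    """Project an alignment-level consensus structure onto one gapped row.

    Column pairs are mapped to ungapped sequence coordinates; pairs touching
    a gap in this row, pairs whose residues are not Watson-Crick/wobble, and
    pairs closer than the steric limit (j - i <= theta) are dropped.
    """
    ncols, cpairs = _consensus_pairs(consensus)
    if ncols != len(gapped_row):
        raise SequenceError("consensus length does not match alignment length")
    # column -> 1-based residue position, or None at gaps
    colmap: list[int | None] = []
    pos = 0
    for c in gapped_row:
        if c == GAP:
            colmap.append(None)
        else:
            pos += 1
            colmap.append(pos)
    residues = gapped_row.replace(GAP, "")
    kept = []
    for ci, cj in cpairs:
        i, j = colmap[ci - 1], colmap[cj - 1]
        if i is None or j is None:
            continue
        if j - i <= THETA:
            continue
        if (residues[i - 1], residues[j - 1]) not in CANONICAL_PAIRS:
            continue
        kept.append((i, j))
    symbols = ["."] * len(residues)
    for i, j in kept:
        symbols[i - 1] = "("
        symbols[j - 1] = ")"
    return DotBracketStructure("".join(symbols), tuple(sorted(kept)))
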