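"""UPGMA-guided progressive multiple alignment of profiles.

Sequences are first folded individually; a single calibration is computed
for the whole input set (nucleotide frequencies from the concatenation of
all sequences, bracket probabilities as the arithmetic mean of the
per-sequence expected bracket probabilities).  A similarity matrix of
length-normalized pairwise global alignment scores drives UPGMA (merging
the most similar pair; cluster similarity is the unweighted average over
member pairs), and profiles are aligned pairwise up the guide tree with
the same affine-gap DP, using the column similarity

    sim_gamma(A_i, B_j) = (1 - gamma) * alpha_seq * SEQSIM(A_i, B_j)
                          + gamma * (alpha_str + STRSIM(A_i, B_j))

where SEQSIM is the expected RIBOSUM score between column letter
distributions (gap letters scoring 0) and STRSIM = -|m_A(i) - m_B(j)| with
m_A(i) the column average of member incremental mountain heights, gaps
contributing 0.  Gaps inserted at a merge propagate to all member rows
("once a gap, always a gap").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairwise import _fill, _traceback, align_with_profiles
from .scoring import Calibration, RibosumMatrix, ScoringModel, calibrate, seq_moments, str_moments
from .seqio import ALPHABET, GAP, GappedAlignment, RnaSequence, nucleotide_frequencies
from .structure import MountainProfile, base_pair_probabilities, incremental_mountain


@dataclass
class Profile:
    """A gapped alignment block: member rows plus their mountain heights."""

    ids: list[str]
    rows: list[str]
    heights: np.ndarray  # (N, ncols) member incremental heights, 0.0 at gaps

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def size(self) -> int:
        return len(self.rows)

    def column_frequencies(self) -> np.ndarray:
        """(ncols, 5) frequencies over A, C, G, U, gap; each row sums to 1."""
        f = np.zeros((self.ncols, 5))
        letters = ALPHABET + GAP
        for row in self.rows:
            for k, c in enumerate(row):
                f[k, letters.index(c)] += 1
        return f / self.size

    def mean_heights(self) -> np.ndarray:
        """m_A(i): column average of member heights, gaps counting 0."""
        return self.heights.sum(axis=0) / self.size


@dataclass
class GuideTree:
    """Rooted binary merge tree; leaves are input indices."""

    index: int | None = None  # leaf
    left: "GuideTree | None" = None
    right: "GuideTree | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.index is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.index]
        return self.left.leaves() + self.right.leaves()


def multi_calibration(
    seqs: list[RnaSequence],
    profiles: list[MountainProfile],
    ribosum: RibosumMatrix,
) -> Calibration:
    """Shared calibration for a sequence set (see module docstring)."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    concat = RnaSequence("concat", "".join(s.residues for s in seqs))
    p = nucleotide_frequencies(concat)
    b = np.mean([pr.bracket_probs for pr in profiles], axis=0)
    mu_s, sd_s = seq_moments(p, p, ribosum)
    mu_t, sd_t = str_moments(b, b)
    return calibrate(mu_s, sd_s, mu_t, sd_t)


def _ribosum5(ribosum: RibosumMatrix) -> np.ndarray:
    r5 = np.zeros((5, 5))
    r5[:4, :4] = ribosum.values
    return r5


def seqsim_columns(freq_i: np.ndarray, freq_j: np.ndarray, ribosum: RibosumMatrix) -> float:
    """Expected RIBOSUM score between two column letter distributions;
    gap letters score 0 against everything."""
    return float(freq_i @ _ribosum5(ribosum) @ freq_j)


def strsim_columns(m_i: float, m_j: float) -> float:
    return -abs(m_i - m_j)


def profile_similarity_matrix(a: Profile, b: Profile, model: ScoringModel) -> np.ndarray:
    cal = model._require_calibration()
    r5 = _ribosum5(model.ribosum)
    seq = a.column_frequencies() @ r5 @ b.column_frequencies().T
    ma, mb = a.mean_heights(), b.mean_heights()
    struct = -np.abs(ma[:, None] - mb[None, :])
    g = model.gamma
    return (1 - g) * cal.alpha_seq * seq + g * (cal.alpha_str + struct)


def pairwise_similarity_matrix(
    seqs: list[RnaSequence],
    profiles: list[MountainProfile],
    model: ScoringModel,
) -> np.ndarray:
    """S[i, j]: global alignment score of i vs j divided by alignment length."""
    n = len(seqs)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = align_with_profiles(
                seqs[i], seqs[j], profiles[i], profiles[j], model, "global"
            )
            S[i, j] = S[j, i] = res.score / max(res.alignment.ncols, 1)
    return S


def upgma(S: np.ndarray) -> GuideTree:
    """UPGMA operating on similarities directly: merge the most similar
    pair; cluster similarity is the unweighted average over member pairs."""
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    nodes = {i: GuideTree(index=i) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    sim = {(i, j): S[i, j] for i in range(n) for j in range(i + 1, n)}
    nxt = n
    while len(nodes) > 1:
        (i, j), _ = max(sim.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
        merged = GuideTree(left=nodes[i], right=nodes[j])
        ni, nj = sizes[i], sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            sik = sim.pop((min(i, k), max(i, k)))
            sjk = sim.pop((min(j, k), max(j, k)))
            sim[(min(nxt, k), max(nxt, k))] = (ni * sik + nj * sjk) / (ni + nj)
        del sim[(i, j)], nodes[i], nodes[j], sizes[i], sizes[j]
        nodes[nxt] = merged
        sizes[nxt] = ni + nj
        nxt += 1
    return nodes.popitem()[1]


build_guide_tree = upgma


def _merge(a: Profile, b: Profile, model: ScoringModel) -> tuple[Profile, float]:
    Spp = profile_similarity_matrix(a, b, model)
    M, P, Q = _fill(Spp, model.gap_init, model.gap_extend, 0)
    ops, _, _ = _traceback(
        Spp, M, P, Q, model.gap_init, model.gap_extend, 0, a.ncols, b.ncols
    )
    rows_a = [[] for _ in a.rows]
    rows_b = [[] for _ in b.rows]
    ha = []
    hb = []
    i = j = 0
    for op in ops:
        if op in ("D", "P"):
            for r, out in zip(a.rows, rows_a):
                out.append(r[i])
            ha.append(a.heights[:, i])
            i += 1
        else:
            for out in rows_a:
                out.append(GAP)
            ha.append(np.zeros(a.size))
        if op in ("D", "Q"):
            for r, out in zip(b.rows, rows_b):
                out.append(r[j])
            hb.append(b.heights[:, j])
            j += 1
        else:
            for out in rows_b:
                out.append(GAP)
            hb.append(np.zeros(b.size))
    heights = np.vstack([np.array(ha).T, np.array(hb).T])
    prof = Profile(
        a.ids + b.ids,
        ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b],
        heights,
    )
    return prof, float(M[a.ncols, b.ncols])


def progressive_align(
    seqs: list[RnaSequence],
    model: ScoringModel | None = None,
    backend: str = "thermodynamic",
) -> GappedAlignment:
    """Progressive multiple alignment; rows come back in input order."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    model = model or ScoringModel()
    bpms = [base_pair_probabilities(s, backend) for s in seqs]
    mprofiles = [incremental_mountain(b) for b in bpms]
    cal = multi_calibration(seqs, mprofiles, model.ribosum)
    model = model.calibrated(cal)
    tree = upgma(pairwise_similarity_matrix(seqs, mprofiles, model))

    def build(node: GuideTree) -> tuple[Profile, float]:
        if node.is_leaf:
            k = node.index
            return (
                Profile([seqs[k].id], [seqs[k].residues], mprofiles[k].m[None, :]),
                0.0,
            )
        pa, _ = build(node.left)
        pb, _ = build(node.right)
        return _merge(pa, pb, model)

    prof, score = build(tree)
    order = {sid: k for k, sid in enumerate(prof.ids)}
    rows = [prof.rows[order[s.id]] for s in seqs]
    return GappedAlignment([s.id for s in seqs], rows, mode="global", score=score)
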