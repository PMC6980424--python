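"""Base-pairing probabilities and mountain-height representations.

The structural signal used throughout the package is the *incremental
ensemble mountain height* m(k): the Boltzmann-expected change in the number
of base pairs enclosing position k, a real number in [-1, 1] that is
positive where the ensemble tends to pair rightward, negative where it
pairs leftward, and near zero where it is unpaired.

Two backends produce the base-pairing probability matrix p[i][j]:

``thermodynamic``
    McCaskill partition function with Turner 2004 nearest-neighbor
    parameters, delegated to the ViennaRNA bindings.  Default.

``simple-bp``
    Exact Boltzmann pairing probabilities under a bespoke base-pair energy
    model (-1 kcal/mol per canonical pair, RT = 0.61633 kcal/mol at 37 C)
    computed by Nussinov-style partition-function recursions honoring the
    steric constraint theta = 3 and canonical pairs only.  Self-contained,
    intended for short RNAs and as an exhaustively checkable model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import CANONICAL_PAIRS, THETA, DotBracketStructure, RnaSequence

#: RT in kcal/mol at 37 C, used by the simple-bp backend
RT_SIMPLE = 0.61633
#: energy per canonical base pair in the simple-bp model, kcal/mol
PAIR_ENERGY = -1.0


@dataclass
class BasePairMatrix:
    """Upper-triangular Boltzmann pairing probabilities p[i][j], 0-based."""

    p: np.ndarray  # (n, n), entries only for i < j
    backend: str
    rt: float = RT_SIMPLE

    @property
    def n(self) -> int:
        return self.p.shape[0]

    def paired_probability(self, k: int) -> float:
        """Probability that 1-based position k is paired (left or right)."""
        i = k - 1
        return float(self.p[i, i + 1 :].sum() + self.p[:i, i].sum())

    def to_tsv(self) -> str:
        lines = ["i\tj\tp"]
        for i, j in zip(*np.nonzero(self.p)):
            lines.append(f"{i + 1}\t{j + 1}\t{self.p[i, j]:.10g}")
        return "\n".join(lines) + "\n"


@dataclass
class MountainProfile:
    """Incremental heights m(k), ensemble heights h(k), and the expected
    dot-bracket probabilities (p_left, p_dot, p_right)."""

    m: np.ndarray
    h: np.ndarray
    bracket_probs: tuple[float, float, float]


def _canonical_mask(residues: str) -> np.ndarray:
    n = len(residues)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + THETA + 1, n):
            if (residues[i], residues[j]) in CANONICAL_PAIRS:
                mask[i, j] = True
    return mask


def _bpp_thermodynamic(seq: RnaSequence) -> np.ndarray:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - env without ViennaRNA
        raise RuntimeError(
            "thermodynamic backend requires the ViennaRNA Python bindings; "
            "use backend='simple-bp' instead"
        ) from exc
    fc = RNA.fold_compound(seq.residues)
    fc.pf()
    full = np.array(fc.bpp())[1:, 1:]  # ViennaRNA returns a 1-indexed matrix
    return np.triu(full, 1)


def _bpp_simple(seq: RnaSequence) -> np.ndarray:
    """Exact pairing probabilities by inside-outside on the pair-energy model.

    Inside (unambiguous decomposition on the rightmost position j):
        Z(i, j) = Z(i, j-1) + sum_k Zb(k, j) * Z(i, k-1)
        Zb(k, j) = w * Z(k+1, j-1)   for canonical (k, j) with j-k > theta
    Outside:
        Zo(i, j) = Z(1, i-1) * Z(j+1, n)
                 + sum_{k<i, l>j} w * Zo(k, l) * Z(k+1, i-1) * Z(j+1, l-1)
    and p(i, j) = Zb(i, j) * Zo(i, j) / Z.
    """
    n = len(seq)
    w = float(np.exp(-PAIR_ENERGY / RT_SIMPLE))
    canon = _canonical_mask(seq.residues)

    # Zpad[i+1][j+1] = Z(i..j); empty intervals (j < i) have weight 1.
    Zpad = np.ones((n + 2, n + 2))
    Z = np.ones((n, n))
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            total = Z[i, j - 1] if j - 1 >= i else 1.0
            for k in range(i, j - THETA):
                if canon[k, j]:
                    left = Z[i, k - 1] if k - 1 >= i else 1.0
                    inner = Z[k + 1, j - 1] if j - 1 >= k + 1 else 1.0
                    total += left * w * inner
            Z[i, j] = total
            Zpad[i + 1, j + 1] = total
    Ztot = Z[0, n - 1] if n > 1 else 1.0

    def z(i: int, j: int) -> float:  # Z over 0-based closed [i, j], empty -> 1
        if j < i:
            return 1.0
        return Z[i, j]

    # Outside pass, spans descending so enclosing pairs are ready first.
    Zo = np.zeros((n, n))
    A = np.zeros((n, n))  # w * Zo[k, l] for canonical (k, l), filled as we go
    p = np.zeros((n, n))
    for span in range(n - 1, THETA, -1):
        for i in range(n - span):
            j = i + span
            if not canon[i, j]:
                continue
            ext = z(0, i - 1) * z(j + 1, n - 1)
            if i > 0 and j < n - 1:
                u = Zpad[np.arange(1, i + 1) + 1, i]  # Z(k+1, i-1), k = 0..i-1
                v = Zpad[j + 2, np.arange(j + 1, n)]  # Z(j+1, l-1), l = j+1..n-1
                ext += u @ A[:i, j + 1 :] @ v
            Zo[i, j] = ext
            A[i, j] = w * ext
            zb = w * z(i + 1, j - 1)
            p[i, j] = zb * ext / Ztot
    return p


def base_pair_probabilities(
    seq: RnaSequence, backend: str = "thermodynamic"
) -> BasePairMatrix:
    """Boltzmann base-pairing probability matrix of a sequence."""
    if backend == "thermodynamic":
        return BasePairMatrix(_bpp_thermodynamic(seq), backend)
    if backend == "simple-bp":
        return BasePairMatrix(_bpp_simple(seq), backend)
    raise ValueError(f"unknown backend {backend!r}")


def mountain_height(structure: DotBracketStructure, k: int | None = None):
    """Mountain height h_s(k) of a fixed structure: the running count of
    open minus closed parentheses over positions 1..k."""
    n = len(structure)
    opens = np.zeros(n)
    closes = np.zeros(n)
    for i, j in structure.pairs:
        opens[i - 1] = 1
        closes[j - 1] = 1
    h = np.cumsum(opens) - np.cumsum(closes)
    if k is None:
        return h
    if not 1 <= k <= n:
        raise IndexError(f"position {k} out of range 1..{n}")
    return int(h[k - 1])


def ensemble_mountain_height(bpm: BasePairMatrix) -> np.ndarray:
    """Expected mountain height <h(k)> = sum_{i<=k} sum_{j>k} p[i][j]."""
    return np.cumsum(incremental_mountain(bpm).m)


def incremental_mountain(bpm: BasePairMatrix) -> MountainProfile:
    """Incremental ensemble mountain height m(k) and derived quantities.

    m(k) = sum_{j>k} p[k][j] - sum_{i<=k} p[i][k] for k > 1, and
    m(1) = <h(1)> (consistent with h(0) = 0), so that <h> is exactly the
    prefix-sum of m.
    """
    P = np.triu(bpm.p, 1)
    right = P.sum(axis=1)  # prob. position k pairs to the right
    left = P.sum(axis=0)  # prob. position k pairs to the left
    m = right - left
    h = np.cumsum(m)
    n = bpm.n
    p_open = float(right.sum() / n)
    p_close = float(left.sum() / n)
    return MountainProfile(m, h, (p_open, 1.0 - p_open - p_close, p_close))


def expected_bracket_probs(bpm: BasePairMatrix) -> tuple[float, float, float]:
    """Expected dot-bracket probabilities (p_left, p_dot, p_right).

    p_left = (1/n) sum_k sum_{j>k} p[k][j]; p_right symmetrically; the two
    are equal because every pair contributes one left and one right bracket.
    """
    return incremental_mountain(bpm).bracket_probs
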