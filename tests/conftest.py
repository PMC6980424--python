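"""Shared fixtures and independent brute-force oracles.

The alignment oracle enumerates every alignment of two sequences as a
lattice path of D (diagonal), P ((a_i, -)) and Q ((-, b_j)) moves, scores
the diagonal cells against a similarity matrix and charges affine costs
g(k) = g_i + (k - 1) g_e per maximal gap run.  It never touches the Gotoh
recurrences it is used to check.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from mountalign import (
    Calibration,
    GappedAlignment,
    RnaSequence,
    ScoringModel,
)
from mountalign.seqio import example_trna_pair, example_trna_reference_alignment
from mountalign.structure import MountainProfile

GI, GE = -3.0, -1.0


@pytest.fixture(scope="session")
def trna_pair():
    return example_trna_pair()


@pytest.fixture(scope="session")
def trna_reference():
    return example_trna_reference_alignment()


@pytest.fixture()
def toy_pred():
    return GappedAlignment(["a", "b"], ["ACG-UA", "A--CUA"])


@pytest.fixture()
def toy_ref():
    return GappedAlignment(["a", "b"], ["ACGUA", "AC-UA"])


def make_profile(m: np.ndarray) -> MountainProfile:
    """A mountain profile with prescribed incremental heights (tests only)."""
    m = np.asarray(m, float)
    return MountainProfile(m, np.cumsum(m), (0.25, 0.5, 0.25))


def make_calibrated_model(**kwargs) -> ScoringModel:
    """Model with a fixed, arbitrary but valid calibration (tests only)."""
    cal = Calibration(mu_seq=-0.9, sigma_seq=1.4, mu_str=-0.8, sigma_str=0.7)
    return ScoringModel(**kwargs).calibrated(cal)


# ---------------------------------------------------------------------------
# brute-force alignment oracle


@lru_cache(maxsize=None)
def _op_paths(n: int, m: int) -> tuple[tuple[str, ...], ...]:
    """All D/P/Q op strings from (0, 0) to (n, m)."""
    if n == 0 and m == 0:
        return ((),)
    out = []
    if n > 0 and m > 0:
        out += [ops + ("D",) for ops in _op_paths(n - 1, m - 1)]
    if n > 0:
        out += [ops + ("P",) for ops in _op_paths(n - 1, m)]
    if m > 0:
        out += [ops + ("Q",) for ops in _op_paths(n, m - 1)]
    return tuple(out)


@lru_cache(maxsize=None)
def _path_arrays(n: int, m: int, gi: float, ge: float):
    """Indicator matrix over diagonal cells plus per-path constant gap cost."""
    paths = _op_paths(n, m)
    A = np.zeros((len(paths), n * m), dtype=np.float32)
    g = np.zeros(len(paths))
    for r, ops in enumerate(paths):
        i = j = 0
        last = None
        for op in ops:
            if op == "D":
                A[r, i * m + j] = 1.0
                i += 1
                j += 1
            elif op == "P":
                g[r] += ge if last == "P" else gi
                i += 1
            else:
                g[r] += ge if last == "Q" else gi
                j += 1
            last = op
    return A, g


@lru_cache(maxsize=None)
def _embedded_paths(n: int, m: int, gi: float, ge: float, mode: str):
    """Indicator matrix + gap constants for every admissible alignment.

    global      - all paths over the full n x m grid.
    semiglobal  - all paths of the full query against every contiguous
                  target slice (target flanks free), plus the all-gap-query
                  alignment of the empty slice.
    local       - all paths over every pair of non-empty slices, plus the
                  empty alignment (score 0).
    """
    blocks_A, blocks_g = [], []

    def add(i_off, j_off, a, b):
        A0, g0 = _path_arrays(a, b, gi, ge)
        A = np.zeros((A0.shape[0], n * m), dtype=np.float32)
        for cell in range(a * b):
            i, j = divmod(cell, b)
            A[:, (i + i_off) * m + (j + j_off)] = A0[:, cell]
        blocks_A.append(A)
        blocks_g.append(g0)

    if mode == "global":
        add(0, 0, n, m)
    elif mode == "semiglobal":
        gap_n = 0.0 if n == 0 else gi + (n - 1) * ge
        blocks_A.append(np.zeros((1, n * m), dtype=np.float32))
        blocks_g.append(np.array([gap_n]))
        for j1 in range(m):
            for j2 in range(j1 + 1, m + 1):
                add(0, j1, n, j2 - j1)
    else:
        blocks_A.append(np.zeros((1, n * m), dtype=np.float32))
        blocks_g.append(np.array([0.0]))
        for i1 in range(n):
            for i2 in range(i1 + 1, n + 1):
                for j1 in range(m):
                    for j2 in range(j1 + 1, m + 1):
                        add(i1, j1, i2 - i1, j2 - j1)
    return np.vstack(blocks_A), np.concatenate(blocks_g)


def _brute(S: np.ndarray, gi: float, ge: float, mode: str) -> float:
    n, m = S.shape
    A, g = _embedded_paths(n, m, gi, ge, mode)
    return float((A @ S.ravel().astype(np.float32) + g).max())


def brute_global(S: np.ndarray, gi: float = GI, ge: float = GE) -> float:
    return _brute(S, gi, ge, "global")


def brute_semiglobal(S: np.ndarray, gi: float = GI, ge: float = GE) -> float:
    return _brute(S, gi, ge, "semiglobal")


def brute_local(S: np.ndarray, gi: float = GI, ge: float = GE) -> float:
    return _brute(S, gi, ge, "local")


def random_instance(rng: np.random.Generator, max_len: int = 6):
    """A random sequence pair with random mountain profiles and the
    similarity matrix a calibrated default model assigns to it."""
    from mountalign.scoring import similarity_matrix

    n = int(rng.integers(1, max_len + 1))
    m = int(rng.integers(1, max_len + 1))
    a = RnaSequence("a", "".join(rng.choice(list("ACGU"), n)))
    b = RnaSequence("b", "".join(rng.choice(list("ACGU"), m)))
    pa = make_profile(rng.uniform(-1, 1, n))
    pb = make_profile(rng.uniform(-1, 1, m))
    model = make_calibrated_model()
    S = similarity_matrix(a, b, pa, pb, model)
    return a, b, pa, pb, model, S
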