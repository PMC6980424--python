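"""RIBOSUM matrices, structural similarity, calibration and the combined score.

The method scores an aligned position pair by mixing two channels:

* sequence similarity, a RIBOSUM log-odds substitution score R(x, y);
* ensemble structural similarity STRSIM(i, j) = -|m_a(i) - m_b(j)|, the
  negated absolute difference of incremental ensemble mountain heights,
  which lies in [-2, 0].

The two channels live on different scales, so before mixing the RIBOSUM
channel is multiplied by alpha_seq and the structural channel shifted by
alpha_str such that both score populations - RIBOSUM(x, y) under the product
of the two sequences' nucleotide distributions, and s0 between dot-bracket
symbols under the product of the two expected bracket distributions - end up
with identical mean and standard deviation:

    alpha_seq = sigma_str / sigma_seq
    alpha_str = alpha_seq * mu_seq - mu_str

and the final similarity, for mixing weight 0 <= gamma <= 1, is

    sim_gamma(a_i, b_j) = (1 - gamma) * alpha_seq * R(a_i, b_j)
                          + gamma * (alpha_str + STRSIM(i, j)).

Affine gaps cost g(k) = g_i + (k - 1) * g_e with defaults g_i = -3,
g_e = -1.

A distance formulation equivalent to this similarity formulation exists
(replace s by max(s) - s and gap weights accordingly); this package is
similarity-based throughout and does not compute the distance form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import ALPHABET, RnaSequence, nucleotide_frequencies
from .structure import BasePairMatrix, MountainProfile

BRACKETS = "(.)"
#: s0 = -d0, the similarity between dot-bracket symbols: -|sign(x) - sign(y)|
#: with sign(() = +1, sign(.) = 0, sign()) = -1
S0 = -np.abs(np.subtract.outer([1, 0, -1], [1, 0, -1])).astype(float)

_BUNDLED = {"RIBOSUM85-60": "ribosum85-60.txt"}


@dataclass(frozen=True)
class RibosumMatrix:
    name: str
    values: np.ndarray  # symmetric 4x4, indexed A, C, G, U

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4, 4) or not np.allclose(v, v.T):
            raise ValueError("RIBOSUM matrix must be a symmetric 4x4 matrix")
        object.__setattr__(self, "values", v)

    def score(self, x: str, y: str) -> float:
        return float(self.values[ALPHABET.index(x), ALPHABET.index(y)])


def load_ribosum(name_or_path: str = "RIBOSUM85-60") -> RibosumMatrix:
    """Load a bundled RIBOSUM matrix by name, or any whitespace-delimited
    matrix file with A/C/G/U row and column labels."""
    if name_or_path in _BUNDLED:
        text = (
            resources.files("mountalign") / "data" / _BUNDLED[name_or_path]
        ).read_text()
        name = name_or_path
    else:
        text = Path(name_or_path).read_text()
        name = Path(name_or_path).stem
    lines = [ln.split() for ln in text.strip().splitlines()]
    cols = lines[0]
    order = [cols.index(c) for c in ALPHABET]
    vals = np.zeros((4, 4))
    rows = {ln[0]: [float(v) for v in ln[1:]] for ln in lines[1:]}
    for i, x in enumerate(ALPHABET):
        for j in range(4):
            vals[i, j] = rows[x][order[j]]
    return RibosumMatrix(name, vals)


@dataclass(frozen=True)
class Calibration:
    """Moment-matching parameters for one query/target (or profile) pair."""

    mu_seq: float
    sigma_seq: float
    mu_str: float
    sigma_str: float

    @property
    def alpha_seq(self) -> float:
        return self.sigma_str / self.sigma_seq

    @property
    def alpha_str(self) -> float:
        return self.alpha_seq * self.mu_seq - self.mu_str


@dataclass
class ScoringModel:
    """All parameters of the combined similarity measure."""

    ribosum: RibosumMatrix = field(default_factory=load_ribosum)
    gamma: float = 0.5
    gap_init: float = -3.0
    gap_extend: float = -1.0
    calibration: Calibration | None = None
    mode: str = "mountalign"  # or "stral"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.gap_init > 0 or self.gap_extend > 0:
            raise ValueError("gap costs must be <= 0")

    def gap_cost(self, k: int) -> float:
        """Affine cost of a size-k gap: g(0) = 0, g(k) = g_i + (k-1) g_e."""
        return 0.0 if k == 0 else self.gap_init + (k - 1) * self.gap_extend

    def calibrated(self, calibration: Calibration) -> "ScoringModel":
        return replace(self, calibration=calibration)

    def _require_calibration(self) -> Calibration:
        if self.calibration is None:
            raise ValueError("model is not calibrated for a sequence pair")
        return self.calibration


def d0(x: str, y: str) -> int:
    """Distance between dot-bracket symbols: |sign(x) - sign(y)| in {0, 1, 2}."""
    try:
        return int(-S0[BRACKETS.index(x), BRACKETS.index(y)])
    except ValueError:
        raise ValueError(f"invalid dot-bracket symbol in ({x!r}, {y!r})") from None


def strsim(m_a: float, m_b: float) -> float:
    """Ensemble structural similarity -|m_a - m_b|, in [-2, 0]."""
    if abs(m_a) > 1 + 1e-9 or abs(m_b) > 1 + 1e-9:
        raise ValueError("incremental mountain heights must lie in [-1, 1]")
    return -abs(m_a - m_b)


def seq_moments(p, p2, ribosum: RibosumMatrix) -> tuple[float, float]:
    """Mean and s.d. of RIBOSUM(x, y) under the product distribution p x p2."""
    p = np.asarray(p, float)
    p2 = np.asarray(p2, float)
    r = ribosum.values
    mu = float(p @ r @ p2)
    var = float(p @ (r**2) @ p2) - mu**2
    if var < -1e-12:
        raise ValueError("negative variance: malformed matrix or probabilities")
    return mu, float(np.sqrt(max(var, 0.0)))


def str_moments(b, b2) -> tuple[float, float]:
    """Mean and s.d. of s0(x, y) under the product of bracket distributions."""
    b = np.asarray(b, float)
    b2 = np.asarray(b2, float)
    mu = float(b @ S0 @ b2)
    var = float(b @ (S0**2) @ b2) - mu**2
    return mu, float(np.sqrt(max(var, 0.0)))


def calibrate(
    mu_seq: float, sigma_seq: float, mu_str: float, sigma_str: float
) -> Calibration:
    if sigma_seq <= 0:
        raise ValueError("sigma_seq must be positive")
    return Calibration(mu_seq, sigma_seq, mu_str, sigma_str)


def calibrate_pair(
    a: RnaSequence,
    b: RnaSequence,
    bracket_a: tuple[float, float, float],
    bracket_b: tuple[float, float, float],
    ribosum: RibosumMatrix,
) -> Calibration:
    """Calibration from two sequences' nucleotide and bracket distributions."""
    mu_s, sd_s = seq_moments(
        nucleotide_frequencies(a), nucleotide_frequencies(b), ribosum
    )
    mu_t, sd_t = str_moments(bracket_a, bracket_b)
    return calibrate(mu_s, sd_s, mu_t, sd_t)


def combined_similarity(
    x: str, y: str, m_x: float, m_y: float, model: ScoringModel
) -> float:
    """sim_gamma for one aligned position pair (see module docstring)."""
    cal = model._require_calibration()
    g = model.gamma
    if model.mode == "stral":
        raise ValueError("use stral_similarity for the STRAL-mode measure")
    return (1 - g) * cal.alpha_seq * model.ribosum.score(x, y) + g * (
        cal.alpha_str + strsim(m_x, m_y)
    )


def stral_similarity(
    pl_a: float,
    pr_a: float,
    pl_b: float,
    pr_b: float,
    x: str,
    y: str,
    gamma: float,
    ribosum: RibosumMatrix | None = None,
) -> float:
    """STRAL's similarity: structure enters through the left/right pairing
    probabilities pl, pr of each position, and the sequence term is damped
    by each position's unpaired probability (one factor per sequence)."""
    ribosum = ribosum or load_ribosum()
    unpaired_a = 1.0 - pl_a - pr_a
    unpaired_b = 1.0 - pl_b - pr_b
    return gamma * (pl_a * pl_b + pr_a * pr_b) + unpaired_a * unpaired_b * (
        ribosum.score(x, y)
    )


def position_specific_gamma(
    bpm_a: BasePairMatrix, bpm_b: BasePairMatrix, i: int, j: int
) -> float:
    """Mean of P(position i paired in a) and P(position j paired in b);
    an opt-in alternative to the constant gamma.  Positions are 1-based."""
    return 0.5 * (bpm_a.paired_probability(i) + bpm_b.paired_probability(j))


def similarity_matrix(
    a: RnaSequence,
    b: RnaSequence,
    prof_a: MountainProfile,
    prof_b: MountainProfile,
    model: ScoringModel,
) -> np.ndarray:
    """n x m matrix of sim_gamma(a_i, b_j), vectorized."""
    cal = model._require_calibration()
    ia = np.array([ALPHABET.index(c) for c in a.residues])
    ib = np.array([ALPHABET.index(c) for c in b.residues])
    g = model.gamma
    seq_part = model.ribosum.values[np.ix_(ia, ib)]
    str_part = -np.abs(prof_a.m[:, None] - prof_b.m[None, :])
    return (1 - g) * cal.alpha_seq * seq_part + g * (cal.alpha_str + str_part)
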