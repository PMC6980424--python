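"""Alignment-score statistics: Karlin-Altschul theory and distribution fits.

For local alignment of random sequences whose pairwise score distribution
has negative mean and at least one positive score, the maximal gapless
segment score M obeys the asymptotic Gumbel tail

    P(M > ln(nm)/lambda* + z) <= exp(-K* exp(-lambda* z))

where lambda* is the unique positive root of E[exp(lambda * s(x, y))] = 1
under the product of the two letter distributions, and K* is given by the
classical series over the partial-sum variables S_k (sums of k i.i.d. pair
scores):

    K* = exp(-2 sum_{k>=1} (E[e^{lambda* S_k}; S_k < 0] + P(S_k >= 0)) / k)
         / (lambda* E[S_1 e^{lambda* S_1}]).

The combined sequence/structure scores here are real-valued, not lattice
scores, so the S_k laws are computed by deterministic convolution on a
score grid of width ``eps`` (default 1e-3); grid refinement stability is a
tested property.

For any alignment mode, score null distributions obtained by aligning the
query against random targets can be fit by a normal (moments), Gumbel-type
extreme value (maximum likelihood, tail P(X > s) ~ K e^{-lambda s}) or
gamma distribution (maximum likelihood), with p-value 1 - CDF(score).
Empirically, local scores are best fit by the EVD - as Karlin-Altschul
theory predicts - while semiglobal scores are best fit by the normal, so
those are the per-mode defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats as sps

from .scoring import S0, ScoringModel
from .seqio import ALPHABET, RnaSequence, nucleotide_frequencies, random_sequence

DEFAULT_FAMILY = {"local": "evd", "semiglobal": "nd", "global": "nd"}


@dataclass
class ScoreDistribution:
    """Finite support of pairwise position scores with probabilities."""

    scores: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.probs = np.asarray(self.probs, float)
        if abs(self.probs.sum() - 1.0) > 1e-9 or (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def mean(self) -> float:
        return float(self.scores @ self.probs)

    def validate_ka(self) -> None:
        if self.mean >= 0:
            raise ValueError("Karlin-Altschul requires negative expected score")
        if self.scores.max() <= 0:
            raise ValueError("Karlin-Altschul requires a positive score")


def pair_score_distribution(
    model: ScoringModel,
    p: np.ndarray,
    p2: np.ndarray,
    b: tuple[float, float, float],
    b2: tuple[float, float, float],
) -> ScoreDistribution:
    """Null distribution of sim_gamma over the product alphabet.

    Positions are modelled as independent (nucleotide, bracket-symbol)
    pairs; the structural channel is the discretized s0 similarity between
    bracket symbols - the same discretization the calibration moments use.
    With gamma = 0 this reduces to the 16 nucleotide combinations.
    """
    cal = model._require_calibration()
    g = model.gamma
    scores, probs = [], []
    for i in range(4):
        for j in range(4):
            seq_part = (1 - g) * cal.alpha_seq * model.ribosum.values[i, j]
            for k in range(3):
                for l in range(3):
                    scores.append(seq_part + g * (cal.alpha_str + S0[k, l]))
                    probs.append(p[i] * p2[j] * b[k] * b2[l])
    return ScoreDistribution(np.array(scores), np.array(probs))


def karlin_lambda(dist: ScoreDistribution) -> float:
    """Unique positive root of sum p_x p'_y exp(lambda s(x, y)) = 1."""
    dist.validate_ka()
    s, p = dist.scores, dist.probs

    def f(lam: float) -> float:
        return float(p @ np.exp(lam * s)) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover
            raise RuntimeError("failed to bracket lambda*")
    from scipy.optimize import brentq

    return float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12))


def _grid(dist: ScoreDistribution, eps: float) -> tuple[np.ndarray, int]:
    """Probability vector of S_1 on an eps grid starting at grid index
    round(min_score / eps)."""
    idx = np.round(dist.scores / eps).astype(int)
    lo, hi = idx.min(), idx.max()
    g = np.zeros(hi - lo + 1)
    np.add.at(g, idx - lo, dist.probs)
    return g, lo


def karlin_K(
    dist: ScoreDistribution,
    lam: float,
    eps: float = 1e-3,
    k_max: int = 150,
    tol: float = 1e-9,
) -> float:
    """K* via the classical series, S_k laws by grid convolution.

    Both series terms P~(S_k < 0) and P(S_k >= 0) decay geometrically (the
    tilted walk has positive drift, the original negative drift), so the
    series is summed until a term falls below ``tol`` or ``k_max`` terms;
    a term still above sqrt(tol) at the horizon signals a pathological
    score model and raises.
    """
    g1, lo1 = _grid(dist, eps)
    denom = lam * float(dist.probs @ (dist.scores * np.exp(lam * dist.scores)))
    total = 0.0
    gk, lok = g1.copy(), lo1
    for k in range(1, k_max + 1):
        vals = (lok + np.arange(len(gk))) * eps
        neg = vals < 0
        term = float(gk[neg] @ np.exp(lam * vals[neg])) + float(gk[~neg].sum())
        total += term / k
        if term < tol:
            break
        if k == k_max:
            if term > np.sqrt(tol):
                raise RuntimeError("Karlin-Altschul series did not converge")
            break
        gk = signal.fftconvolve(gk, g1)
        gk[gk < 0] = 0.0
        lok += lo1
    return float(np.exp(-2.0 * total) / denom)


def ka_pvalue(
    score: float, n: int, m: int, lam: float, K: float
) -> tuple[float, float]:
    """(p, E) for a local score against an n x m search space."""
    E = K * n * m * np.exp(-lam * score)
    p = -np.expm1(-E)
    return float(min(max(p, 0.0), 1.0)), float(E)


@dataclass
class DistributionFit:
    family: str  # nd | evd | gd | ka
    params: dict[str, float]
    n_samples: int = 0
    shift: float = 0.0  # applied to data before a gamma fit

    def pvalue(self, x: float) -> float:
        """Upper-tail p-value 1 - CDF(x) under the fitted law."""
        if self.family == "nd":
            return float(sps.norm.sf(x, self.params["mu"], self.params["sigma"]))
        if self.family == "evd":
            lam, K = self.params["lambda"], self.params["K"]
            return float(-np.expm1(-K * np.exp(-lam * x)))
        if self.family == "gd":
            return float(
                sps.gamma.sf(x + self.shift, self.params["shape"],
                             scale=1.0 / self.params["rate"])
            )
        raise ValueError(f"no p-value rule for family {self.family!r}")

    def evalue(self, x: float, n_searches: int = 1) -> float:
        """Expected number of null scores >= x among ``n_searches`` trials.

        For the EVD this is the uncapped exponential tail n K e^{-lambda x}
        (the form genome scanners report); other families use n * p."""
        if self.family == "evd":
            lam, K = self.params["lambda"], self.params["K"]
            return float(n_searches * K * np.exp(-lam * x))
        return n_searches * self.pvalue(x)


def fit_normal(scores) -> DistributionFit:
    """Method-of-moments normal fit."""
    x = np.asarray(scores, float)
    if x.size < 2:
        raise ValueError("need at least 2 scores")
    mu, sd = float(x.mean()), float(x.std())
    if sd == 0:
        raise ValueError("zero variance")
    return DistributionFit("nd", {"mu": mu, "sigma": sd}, x.size)


def fit_evd(scores, max_iter: int = 200, tol: float = 1e-8) -> DistributionFit:
    """Maximum-likelihood Gumbel fit, parameterized so that the upper tail
    is P(X > s) ~ K e^{-lambda s}; Newton iteration on lambda.

    The stationarity condition in lambda is
        1/lambda = mean(x) - sum(x e^{-lambda x}) / sum(e^{-lambda x});
    K then follows from the location condition K = n / sum(e^{-lambda x}).
    """
    x = np.asarray(scores, float)
    n = x.size
    xbar = float(x.mean())
    xs = x - xbar  # center for numerical stability; undo via K below
    lam = np.pi / (np.sqrt(6.0) * float(x.std()) + 1e-300)  # moment start

    def g_and_deriv(lam: float) -> tuple[float, float]:
        # stationarity: 1/lam - mean(x) + sum(x w)/sum(w) = 0, w = e^{-lam x};
        # with centered xs this is 1/lam + sum(xs w)/sum(w) = 0
        w = np.exp(-lam * xs)
        sw, sxw, sx2w = w.sum(), (xs * w).sum(), (xs**2 * w).sum()
        g = 1.0 / lam + sxw / sw
        dg = -1.0 / lam**2 - (sx2w * sw - sxw**2) / sw**2
        return g, dg

    for _ in range(max_iter):
        g, dg = g_and_deriv(lam)
        step = g / dg
        new = lam - step
        if new <= 0:
            new = lam / 2.0
        if abs(new - lam) < tol * max(lam, 1.0):
            lam = new
            break
        lam = new
    else:
        raise RuntimeError("EVD fit did not converge")
    K = n / float(np.exp(-lam * x).sum())
    return DistributionFit("evd", {"lambda": float(lam), "K": float(K)}, n)


def fit_gamma(scores) -> DistributionFit:
    """Maximum-likelihood gamma fit (shape, rate).  Samples containing
    non-positive values are shifted by 1 - min before fitting and the
    shift is recorded (p-values are evaluated on the shifted axis)."""
    x = np.asarray(scores, float)
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - float(x.min())
        x = x + shift
    shape, _, scale = sps.gamma.fit(x, floc=0.0)
    return DistributionFit(
        "gd", {"shape": float(shape), "rate": float(1.0 / scale)}, x.size, shift
    )


def empirical_pvalue(scores, z: float) -> float:
    """Fraction of null scores strictly exceeding z."""
    x = np.asarray(scores, float)
    return float((x > z).sum() / x.size)


def null_scores(
    query: RnaSequence,
    model: ScoringModel | None = None,
    mode: str = "semiglobal",
    n_targets: int = 1000,
    target_len: int = 400,
    seed: int = 0,
    backend: str = "thermodynamic",
) -> np.ndarray:
    """Alignment scores of the query against random targets drawn with the
    query's nucleotide frequencies; the null for p-value fitting."""
    from .pairwise import align  # deferred: avoid import cycle

    model = model or ScoringModel()
    freqs = nucleotide_frequencies(query)
    rng = np.random.default_rng(seed)
    out = np.empty(n_targets)
    for t in range(n_targets):
        target = random_sequence(
            freqs, target_len, seed=int(rng.integers(2**31)), id=f"null{t}"
        )
        out[t] = align(query, target, model, mode=mode, backend=backend).score
    return out


def fit_scores(scores, family: str) -> DistributionFit:
    if family == "nd":
        return fit_normal(scores)
    if family == "evd":
        return fit_evd(scores)
    if family == "gd":
        return fit_gamma(scores)
    raise ValueError(f"unknown distribution family {family!r}")
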