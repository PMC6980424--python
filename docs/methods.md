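# Methods

This note documents the models, numerical choices and design decisions
behind mountalign, and what the synthetic-data tests do and do not
establish.

## Structural signal

A secondary structure is a pseudoknot-free set of Watson–Crick/wobble pairs
(AU, UA, CG, GC, GU, UG) with at least θ = 3 unpaired bases between the two
ends of any pair and no base triples. These two constants are package-wide
constants. For a fixed structure, the mountain height h_s(k) is the running
count of open minus closed parentheses up to position k (the convention in
which a position's own opening bracket counts at that position; the variant
that counts it one position later differs immaterially).

Averaging over the Boltzmann ensemble turns h_s into ⟨h(k)⟩ =
Σ_{i≤k}Σ_{j>k} p_ij, and the per-position increment m(k) = ⟨h(k)⟩ −
⟨h(k−1)⟩ is the signal used everywhere. We define m(1) = ⟨h(1)⟩ (i.e.
h(0) = 0), so ⟨h⟩ is exactly the prefix sum of m; Σ_k m(k) = 0 and all
prefix sums are non-negative, both asserted in tests. The expected bracket
probabilities are p₍ = (1/n)Σ_k Σ_{j>k} p_kj, symmetrically p₎ (always
equal to p₍ — each pair contributes one left and one right bracket), and
p• = 1 − p₍ − p₎.

### Folding backends

* `thermodynamic` (default): McCaskill partition function with Turner 2004
  nearest-neighbor parameters through the ViennaRNA bindings. Different
  ViennaRNA releases shift base-pairing probabilities in the 4th decimal,
  so tests pin bracket probabilities to 3 decimals.
* `simple-bp`: exact Boltzmann pairing probabilities under a one-parameter
  energy model (−1 kcal/mol per canonical pair, RT = 0.61633 kcal/mol,
  37 °C), computed by unambiguous Nussinov-style inside recursions and an
  outside pass. The inside pass is O(n³); the outside pass is an O(n⁴)
  vectorized sum, entirely adequate for the short RNAs this backend is
  meant for. Its purpose is a dependency-free, exhaustively verifiable
  model: tests compare it to brute-force enumeration of all structures for
  every ≤8-nt sequence over {G, U} and random ≤12-nt ACGU sequences at
  1e−10.

## Scoring and calibration

Sequence similarity uses the RIBOSUM85-60 single-nucleotide block (bundled
as a whitespace text file; the loader also reads user-supplied matrices in
the same format). RIBOSUM base-pair substitution blocks are not used.
RIBOSUM70-25 is *not* bundled: its single-nucleotide values are not
reproducible from sources available to this package, and shipping
approximate numbers under a published matrix's name would be worse than
requiring the user to supply the file. For inputs below ~70% identity,
obtain RIBOSUM70-25 from the RSEARCH distribution and pass its path to
`load_ribosum`.

Calibration matches the first two moments of the two score populations
(RIBOSUM under the product of nucleotide frequency vectors; s₀ ∈ {0, −1,
−2} between dot-bracket symbols under the product of expected bracket
triples): α_seq = σ_str/σ_seq, α_str = α_seq·μ_seq − μ_str. The identity
"scaled means and standard deviations agree" is tested on random
probability vectors. Calibration is recomputed for every sequence pair from
the full-length sequences — including every window of a genome scan, each
calibrated against the query. For multiple alignment, one shared
calibration uses nucleotide frequencies of the concatenated input and the
arithmetic mean of per-sequence bracket triples.

The mixing weight γ (default ½, the benchmark setting) interpolates between
sequence-only (γ=0) and structure-only (γ=1) alignment. A position-specific
γ_ij — the mean of the two positions' pairing probabilities — is available
as an opt-in; all defaults use the constant γ. A STRAL-compatible
similarity (structure through left/right pairing probabilities) is provided
for benchmarking parity; its published formula repeats one sequence's
unpaired factor where the symmetric reading is clearly intended, and we
implement one unpaired factor per sequence.

An equivalent distance formulation exists (replace s(x, y) by max s − s and
gap weights accordingly); the package is similarity-based throughout and
documents rather than implements that transformation.

## Pairwise dynamic programming

Gotoh three-matrix DP with affine gaps g(k) = g_i + (k−1)·g_e (defaults
−3/−1): M (last column a residue pair), P (last column (aᵢ, −)), Q (last
column (−, bⱼ)). Numba-compiled fill; Python traceback with the
deterministic tie preference diagonal > P > Q.

Boundaries: global uses M[i][0] = g(i), M[0][j] = g(j), optimum M[n][m].
Semiglobal (query-search mode) uses M[i][0] = g(i), M[0][j] = 0, optimum =
max over row n, so gaps flanking the aligned target region are free while
internal and query gaps are penalized. Some published pseudocode for this
recurrence carries a stray `max(..., 0)` in the Q recurrence and P[0][j] =
Q[i][0] = 0 boundaries; taken literally these act as local-alignment resets
(a consumed query prefix escapes its gap penalty) and break both the
equality with exhaustive alignment enumeration and the invariant that a
returned alignment re-scores to its reported score. We use the standard
boundaries (impossible P/Q states = −∞). Semiglobal end ties are broken
toward the smallest target end column (leftmost hit). Local mode clamps M
at 0, takes the optimum over all cells, and returns an empty alignment with
score 0 when no positive-scoring pair exists.

Correctness rests on an independent oracle: every alignment of two tiny
sequences enumerated as a lattice path, scored by summing similarities on
diagonal cells plus affine costs per maximal gap run; the acceptance suite
runs >10⁴ random instances per mode (lengths ≤ 6, random mountain
profiles) against it, plus re-scoring, symmetry, flank-monotonicity and
gap-cost-monotonicity properties.

## Alignment statistics

For local alignment of letters with negative expected pair score and some
positive score, the maximal segment score M follows a Gumbel tail
P(M > ln(nm)/λ* + z) ≤ exp(−K* e^{−λ*z}). λ* is the unique positive root
of E[e^{λ s(x,y)}] = 1 (bracketing + Brent to 1e−12; the textbook "= 1"
form — one published rendering of the theorem drops it). K* uses the
classical series over partial sums S_k,

K* = exp(−2 Σ_{k≥1} k⁻¹ (E[e^{λ*S_k}; S_k<0] + P(S_k ≥ 0))) / (λ* E[S₁e^{λ*S₁}]).

Scores here are real-valued, not lattice, so the S_k laws are computed by
FFT convolution on a score grid (ε = 1e−3, a config knob; halving ε moves
K* by < 1e−3 relative, tested). Both series terms decay geometrically, so
the series is summed to term < 1e−9 with horizon k_max = 150; only a
still-large term at the horizon raises. Validation is two-fold: for the
±1 match/mismatch toy model, K*·λ/(1 − e^{−λ}) — the classical unit-lattice
span correction — equals the exact gambler's-ruin excursion constant 1/3,
and the Eq-style tail matches Monte-Carlo maximal-segment scores of random
200-nt 4-letter pairs at the 0.9/0.99 quantiles within 3 s.e.; for a
continuous model (steps Exp(1) − 2, exactly known λ = root of e^{−2λ} =
1 − λ), K* matches direct excursion counting on an 8·10⁶-step walk within
Monte-Carlo error.

The pair-score null for KA is the product alphabet (nucleotide ×
dot-bracket symbol, 144 outcomes), the same discretization the calibration
moments use; at γ = 0 it reduces to the 16 nucleotide combinations. KA is
asymptotic theory for gapless segments and is reported, as is conventional,
as an approximation under gapped local alignment.

Null-score fits: normal by moments; Gumbel/EVD by in-package maximum
likelihood in the tail parameterization P(X > s) ≈ K e^{−λs} (Newton on the
profile likelihood in λ, K from the location condition; agrees with an
independent ML implementation to 4 digits and recovers parameters within 5%
at n = 10⁵), one published form of this CDF prints e^{+λs} where only the
decaying tail is meaningful; gamma by ML (delegated to scipy), with data
containing non-positive values shifted by 1 − min and the shift recorded.
Default p-value family: EVD for local scores, normal for semiglobal/global
— the empirically best-fitting families for those modes. E-values are
reported in the uncapped exponential-tail form E = N·K·e^{−λs} (and K*nm
e^{−λ*s} for KA); the capped Poisson transform 1 − e^{−E} saturates
insignificant scores and is only used for p-values. On synthetic nulls the
two E-value routes correlate at r > 0.9, mirroring the strong agreement
reported for genome scans.

## Multiple alignment

Guide tree: UPGMA run directly on similarities (merge the most similar
pair; cluster similarity = unweighted average over member pairs),
equivalent in ordering to average-linkage on distances (tested against
scipy). The similarity S[i, j] is the pairwise global sim_γ score
normalized by alignment length — raw scores would bias merges toward long
sequences; this normalization is our choice where the method description
says only "(maximum) pairwise sequence similarity".

Profiles are pseudo-sequences: per column, letter frequencies over
{A, C, G, U, −} and the column-average incremental height m_A(i) with gap
positions contributing 0, recomputed from member rows at every merge.
Column similarity is Eq-for-Eq the pairwise mixture with SEQSIM (expected
RIBOSUM, gaps scoring 0) and STRSIM = −|m_A(i) − m_B(j)|; profile-profile
gaps use the same g_i/g_e with no gap-frequency weighting (the simplest
reading of profiles-as-pseudo-sequences). Inserted gaps propagate to all
member rows ("once a gap, always a gap"). A 3-sequence brute-force
enumeration of all profile merges along the same guide tree reproduces the
DP's root score exactly.

## Genome scanning

Windows start at 1, 1+step, …, with a trailing shorter window included iff
it is at least the query length; window count = ⌊(m−w)/s⌋ + 1 (+1 for the
partial window), an exact combinatorial test. Each window is aligned
semiglobally (calibrated against the query); p-values come from a null of
semiglobal scores against random targets with the query's nucleotide
frequencies, fitted once per query (normal family by default; windows share
the query and length, so a per-window null would only add noise). The
reverse strand is scanned on the reverse complement and reported on forward
coordinates. Overlapping hits are deduplicated — the published method does
not state a rule — keeping the lower p-value when two same-strand hits
overlap by proportion > 0.8 (|A∩B|/|B| against either hit); hits stream out
sorted by p-value, and only the current window's DP state is held in
memory.

## Evaluation measures

Sensitivity/PPV/F1 count all alignment pairs *including* gap pairs (aᵢ, −)
and (−, bⱼ), keyed by residue indices: Sen = TP/|ref|, PPV = TP/|pred|, F1
their harmonic mean (0 when TP = 0). SPS counts residue–residue pairs only,
over all sequence pairs of a multiple alignment. MCC compares base-pair
sets with the true-negative universe "all (i, j) with j − i > θ" — the
published definition leaves "potential base pairs" open; MCC is insensitive
to the TN magnitude in the tested regimes, and zero-denominator cases
return 0 by convention. Consensus-structure projection maps alignment-level
pairs (WUSS brackets accepted) to row coordinates and drops pairs touching
a gap in that row, non-canonical pairs, and pairs with j − i ≤ θ.

## A calibration constant that does not reproduce

For the bundled tRNA pair, the sequence-moment formula gives σ_seq = 1.4117
(hence α_seq = 0.4935, α_str = 0.3808), while the worked example
accompanying the method's original description quotes σ_seq = 1.5871
(α_seq = 0.4390, α_str = 0.4305) — internally consistent with each other
but not derivable from the stated formula and inputs, under any variant we
tried (self/cross/mixture/concatenated frequencies, alphabet permutations,
Bessel corrections, RMS forms). This package implements the formula as
stated. The end-to-end check is insensitive to the difference: the
reference global alignment of the pair is reproduced exactly under either
calibration.

## Synthetic data: what it shows and what it does not

Fixtures are i.i.d. random sequences with prescribed nucleotide
frequencies, planted-homolog embeddings (a query inserted at a random
position in a composition-matched background, default total length 4n), and
composition-matched nulls. These validate algorithmic correctness
(DP optimality, partition-function exactness, statistical calibration,
planted-signal recovery) — they do not emulate covariation between paired
columns, indels with biological length distributions, or genome base
composition heterogeneity, so passing tests quantify implementation
fidelity, not expected accuracy on real families. Problem sizes in the
default suite (tiny DP instances, ≤12-nt enumeration, 200-nt null targets,
10-kb scan targets, 3·10³–10⁵ Monte-Carlo samples) were chosen so the whole
suite runs in a couple of minutes on one core while keeping Monte-Carlo
standard errors well inside the asserted tolerances.

## Known limitations

* KA E-values under gapped alignment are approximations (no gapped-λ
  estimation, island statistics or finite-size edge corrections).
* The simple-bp backend's outside pass is O(n⁴); use the thermodynamic
  backend beyond a few hundred nucleotides.
* No consensus-structure prediction on output alignments (external
  consensus-folding tools do this), no SCI, no covariance-model search.
* Ambiguity codes are rejected rather than resolved; coordinates are
  1-based closed intervals everywhere user-facing.
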