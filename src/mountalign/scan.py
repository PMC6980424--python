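"""Genome query scanning: semiglobal search over sliding windows.

A query RNA is aligned semiglobally to sliding windows of a long target
(default window 300 nt, step 200 nt, i.e. 100 nt overlap); each window's
optimal score receives a p-value from a null distribution of scores of the
query against random sequences with the query's nucleotide composition,
fitted once per query (normal fit by default - the best-fitting family for
semiglobal scores).  Hits are reported on the forward coordinate axis,
optionally for both strands, deduplicated so that overlapping hits keep the
lower p-value, and sorted by p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pairwise import PairwiseAlignment, align
from .scoring import ScoringModel
from .seqio import GappedAlignment, RnaSequence, reverse_complement
from .stats import fit_scores, null_scores


@dataclass
class ScanHit:
    strand: str  # '+' or '-'
    window: tuple[int, int]  # 1-based closed, forward axis
    interval: tuple[int, int]  # aligned target subinterval, forward axis
    score: float
    p_value: float
    alignment: GappedAlignment

    def tsv_row(self) -> str:
        return "\t".join(
            [
                self.strand,
                str(self.window[0]),
                str(self.window[1]),
                str(self.interval[0]),
                str(self.interval[1]),
                f"{self.score:.4f}",
                f"{self.p_value:.4g}",
                self.alignment.rows[0],
                self.alignment.rows[1],
            ]
        )


TSV_HEADER = (
    "strand\twindow_start\twindow_end\thit_start\thit_end\tscore\tp_value"
    "\tgapped_query\tgapped_target"
)


def window_starts(target_len: int, query_len: int, window: int, step: int) -> list[int]:
    """1-based window start positions; a trailing shorter window is included
    iff it is at least as long as the query."""
    if step <= 0 or step > window:
        raise ValueError("need 0 < step <= window")
    starts = list(range(1, max(target_len - window + 1, 0) + 1, step))
    if not starts:
        return [1] if target_len >= 1 else []
    last_end = starts[-1] + window - 1
    if last_end < target_len:
        nxt = starts[-1] + step
        if target_len - nxt + 1 >= query_len:
            starts.append(nxt)
    return starts


def _overlap_proportion(a: tuple[int, int], b: tuple[int, int]) -> float:
    """|A intersect B| / |B| for 1-based closed intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    return max(inter, 0) / (b[1] - b[0] + 1)


def scan(
    query: RnaSequence,
    target: RnaSequence,
    model: ScoringModel | None = None,
    window: int = 300,
    step: int = 200,
    strands: str = "+",
    n_null: int = 1000,
    null_len: int = 400,
    family: str = "nd",
    seed: int = 0,
    backend: str = "thermodynamic",
    dedup_overlap: float = 0.8,
) -> list[ScanHit]:
    """Scan a target for windows with significant similarity to the query."""
    model = model or ScoringModel()
    n, m = len(query), len(target)
    if window <= n:
        raise ValueError("window must exceed the query length")
    fit = fit_scores(
        null_scores(
            query, model, "semiglobal", n_null, null_len, seed=seed, backend=backend
        ),
        family,
    )
    hits: list[ScanHit] = []
    for strand in "+-" if strands == "both" else strands:
        seq = target if strand == "+" else reverse_complement(target)
        for start in window_starts(m, n, window, step):
            end = min(start + window - 1, m)
            sub = RnaSequence(f"{target.id}:{start}-{end}", seq.residues[start - 1 : end])
            res: PairwiseAlignment = align(query, sub, model, "semiglobal", backend)
            lo = start + res.target_interval[0] - 1
            hi = start + res.target_interval[1] - 1
            if strand == "-":  # map back to the forward axis
                lo, hi = m - hi + 1, m - lo + 1
                wlo, whi = m - end + 1, m - start + 1
            else:
                wlo, whi = start, end
            hits.append(
                ScanHit(
                    strand,
                    (wlo, whi),
                    (lo, hi),
                    res.score,
                    fit.pvalue(res.score),
                    res.alignment,
                )
            )
    hits.sort(key=lambda h: (h.p_value, -h.score, h.interval))
    kept: list[ScanHit] = []
    for h in hits:
        dup = any(
            k.strand == h.strand
            and max(
                _overlap_proportion(k.interval, h.interval),
                _overlap_proportion(h.interval, k.interval),
            )
            > dedup_overlap
            for k in kept
        )
        if not dup:
            kept.append(h)
    return kept


def hits_to_tsv(hits: list[ScanHit]) -> str:
    return "\n".join([TSV_HEADER] + [h.tsv_row() for h in hits]) + "\n"
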