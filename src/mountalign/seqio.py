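"""Sequence, structure and alignment I/O, plus synthetic-benchmark fixtures.

All user-facing coordinates are 1-based closed intervals.  Input ``T`` is
silently normalized to ``U`` and lowercase is uppercased; any residue outside
``{A, C, G, U}`` after normalization is an error.  The gap character is ``-``
on output; ``.`` is accepted as a gap on alignment input (Stockholm dialect)
and normalized.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGU"
GAP = "-"
#: minimum number of unpaired bases between the two ends of a base pair
THETA = 3
#: Watson-Crick plus wobble pairs
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class SequenceError(ValueError):
    """Raised for malformed sequences, structures or alignments."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence: identifier plus residues over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        if not norm:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(norm) - set(ALPHABET)
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-ACGU characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class DotBracketStructure:
    """A pseudoknot-free secondary structure in dot-bracket notation.

    ``pairs`` holds 1-based (i, j) base pairs with i < j, extracted by stack
    matching; every pair satisfies the steric constraint j - i > THETA.
    """

    symbols: str
    pairs: tuple[tuple[int, int], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class GappedAlignment:
    """Two or more equal-length gapped rows; removing gaps recovers the inputs."""

    ids: list[str]
    rows: list[str]
    mode: str = "global"
    score: float = 0.0
    consensus: str | None = None  # optional dot-bracket over columns (SS_cons)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SequenceError("an alignment needs at least 2 rows")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise SequenceError("alignment rows differ in length")
        for k in range(n):
            if all(r[k] == GAP for r in self.rows):
                raise SequenceError(f"alignment column {k + 1} is all gaps")

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    def degapped(self, k: int) -> RnaSequence:
        """Input sequence k recovered from its row."""
        return RnaSequence(self.ids[k], self.rows[k].replace(GAP, ""))


def example_trna_pair() -> tuple[RnaSequence, RnaSequence]:
    """The bundled 72-nt/69-nt tRNA pair used in the worked examples.

    The 69-nt sequence circulates under two accessions (D16387.1 and
    D16498.1); it is stored once.
    """
    from importlib import resources

    path = resources.files("mountalign") / "data" / "trna_pair.fa"
    with resources.as_file(path) as p:
        a, b = read_fasta(p)
    return a, b


def example_trna_reference_alignment() -> GappedAlignment:
    """The curated reference alignment of the bundled tRNA pair."""
    from importlib import resources

    text = (
        resources.files("mountalign") / "data" / "trna_pair_reference.aln"
    ).read_text()
    return read_alignment(text, "gapped-fasta")


def read_fasta(path) -> list[RnaSequence]:
    """Read a multi-record FASTA file into RnaSequence objects (T -> U)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return [RnaSequence(r.id, str(r.seq)) for r in records]


def write_fasta(seqs: list[RnaSequence], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs],
        str(path),
        "fasta",
    )


def parse_dotbracket(text: str) -> DotBracketStructure:
    """Parse dot-bracket text into a structure by parenthesis stack matching."""
    text = text.strip()
    symbols = text.replace("•", ".")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, c in enumerate(symbols, start=1):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise SequenceError(f"unbalanced ')' at position {k}")
            i = stack.pop()
            if k - i <= THETA:
                raise SequenceError(
                    f"pair ({i},{k}) violates the steric constraint j-i > {THETA}"
                )
            pairs.append((i, k))
        elif c != ".":
            raise SequenceError(f"invalid dot-bracket symbol {c!r} at position {k}")
    if stack:
        raise SequenceError(f"unbalanced '(' at position {stack[-1]}")
    return DotBracketStructure(symbols, tuple(sorted(pairs)))


_FORMATS = {"gapped-fasta": "fasta", "clustal": "clustal", "stockholm": "stockholm"}


def _to_biopython(aln: GappedAlignment) -> MultipleSeqAlignment:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(r), id=i, description="") for i, r in zip(aln.ids, aln.rows)]
    )
    if aln.consensus is not None:
        msa.column_annotations["secondary_structure"] = aln.consensus
    return msa


def write_alignment(aln: GappedAlignment, fmt: str = "gapped-fasta") -> str:
    """Serialize an alignment; Stockholm carries #=GC SS_cons when present."""
    if fmt not in _FORMATS:
        raise SequenceError(f"unknown alignment format {fmt!r}")
    buf = io.StringIO()
    AlignIO.write(_to_biopython(aln), buf, _FORMATS[fmt])
    return buf.getvalue()


def read_alignment(text: str, fmt: str = "gapped-fasta", mode: str = "global") -> GappedAlignment:
    """Parse an alignment; '.' is normalized to '-' in the rows."""
    if fmt not in _FORMATS:
        raise SequenceError(f"unknown alignment format {fmt!r}")
    msa = AlignIO.read(io.StringIO(text), _FORMATS[fmt])
    rows = [str(r.seq).upper().replace(".", GAP).replace("T", "U") for r in msa]
    cons = msa.column_annotations.get("secondary_structure")
    return GappedAlignment([r.id for r in msa], rows, mode=mode, consensus=cons)


def nucleotide_frequencies(seq: RnaSequence) -> np.ndarray:
    """Relative frequencies (p_A, p_C, p_G, p_U); sums to 1."""
    counts = np.array([seq.residues.count(c) for c in ALPHABET], dtype=float)
    return counts / len(seq)


def reverse_complement(seq: RnaSequence) -> RnaSequence:
    return RnaSequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1])


def random_sequence(freqs, length: int, seed: int, id: str = "random") -> RnaSequence:
    """I.i.d. random RNA with the given nucleotide distribution."""
    freqs = np.asarray(freqs, dtype=float)
    if length < 1:
        raise SequenceError("length must be >= 1")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise SequenceError("frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=length, p=freqs / freqs.sum())
    return RnaSequence(id, "".join(ALPHABET[i] for i in draws))


def embed_in_random(
    seq: RnaSequence, factor: float = 4.0, seed: int = 0
) -> tuple[RnaSequence, tuple[int, int]]:
    """Plant ``seq`` at a random position inside a random background.

    The background has the same nucleotide frequencies as ``seq`` and the
    output length is round(factor * n), emulating the construction used to
    benchmark local alignment (a pair of sequences of lengths 4n and 4m).
    Returns the embedded sequence and the planted 1-based closed interval.
    """
    if factor < 1:
        raise SequenceError("factor must be >= 1")
    n = len(seq)
    total = int(round(factor * n))
    pad = total - n
    rng = np.random.default_rng(seed)
    if pad == 0:
        return RnaSequence(seq.id + "_embedded", seq.residues), (1, n)
    background = random_sequence(
        nucleotide_frequencies(seq), pad, seed=int(rng.integers(2**31))
    )
    start = int(rng.integers(pad + 1))  # residues before the insert
    residues = background.residues[:start] + seq.residues + background.residues[start:]
    return RnaSequence(seq.id + "_embedded", residues), (start + 1, start + n)
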