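"""Pairwise protein homology search with bit-score/E-value statistics.

This is the desk-scale stand-in for BLASTP in the mining procedure: optimal
Smith-Waterman local alignment with affine gaps (through Biopython's C
aligner) scored with BLOSUM62, converted to bit scores and E-values with the
Karlin-Altschul formulae

    bits = (lambda * raw - ln K) / ln 2,      E = m * n * 2**(-bits)

where m is the query length and n the residue count of the searched set.
Scores will not numerically match NCBI BLAST (no composition-based
adjustment, fixed gapped lambda/K); all thresholds consumed downstream are
plain config values so they can be re-calibrated.

'X' (unknown residue / masked stop codon) scores 0 against everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, List, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Gene

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = frozenset(AA_ALPHABET + "X")


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin-Altschul constants.

    Defaults are the standard gapped BLOSUM62/11/1 parameterization
    (lambda = 0.267, K = 0.041).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive integers")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    percent_identity: float
    aln_length: int


@lru_cache(maxsize=8)
def _matrix(name: str):
    mat = substitution_matrices.load(name).copy()
    if "X" in mat.alphabet:
        for ch in mat.alphabet:
            mat["X", ch] = 0.0
            mat[ch, "X"] = 0.0
    return mat


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _matrix(scheme.matrix_name)
    aligner.open_gap_score = -(scheme.gap_open)
    aligner.extend_gap_score = -(scheme.gap_extend)
    if mode == "global":
        # no penalty change for terminal gaps; plain NW
        pass
    return aligner


def _validate(seq: str, which: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in _VALID_CHARS:
            raise ValueError(
                f"illegal character {ch!r} at position {i} of {which} sequence"
            )


@dataclass(frozen=True)
class LocalAlignment:
    raw_score: int
    aligned_a: str
    aligned_b: str

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )

    @property
    def percent_identity(self) -> float:
        if self.length == 0:
            return 0.0
        return 100.0 * self.n_identical / self.length


def local_score(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Optimal Smith-Waterman score only (cheaper than a full traceback)."""
    _validate(a, "first")
    _validate(b, "second")
    if not a or not b:
        return 0
    return int(_aligner(scheme, "local").score(a, b))


def local_align(
    a: str, b: str, scheme: ScoringScheme = ScoringScheme()
) -> LocalAlignment:
    """Optimal local alignment of ``a`` vs ``b`` with affine gaps.

    Returns score 0 and an empty alignment when no positive-scoring local
    alignment exists (including empty inputs).
    """
    _validate(a, "first")
    _validate(b, "second")
    if not a or not b:
        return LocalAlignment(0, "", "")
    aligner = _aligner(scheme, "local")
    score = int(aligner.score(a, b))
    if score <= 0:
        return LocalAlignment(0, "", "")
    aln = aligner.align(a, b)[0]
    return LocalAlignment(score, str(aln[0]), str(aln[1]))


def bits_and_evalue(
    raw: int, scheme: ScoringScheme, m: int, n: int
) -> Tuple[float, float]:
    """Karlin-Altschul bit score and E-value for a raw score.

    ``m`` is the query length, ``n`` the total residue count of the searched
    set (search space m*n, no length correction).
    """
    if m < 1 or n < 1:
        raise ValueError(f"search-space dimensions must be >= 1, got m={m}, n={n}")
    bits = (scheme.lambda_ * raw - math.log(scheme.K)) / math.log(2.0)
    e_value = float(m) * float(n) * 2.0 ** (-bits)
    return bits, e_value


def _residue_count(proteome: Sequence[Gene]) -> int:
    return sum(len(g.protein) for g in proteome)


def _hit(
    query_id: str,
    query: str,
    subject: Gene,
    scheme: ScoringScheme,
    m: int,
    n: int,
) -> HomologyHit:
    aln = local_align(query, subject.protein, scheme)
    bits, e_value = bits_and_evalue(aln.raw_score, scheme, m, n)
    return HomologyHit(
        query_id=query_id,
        subject_id=subject.gene_id,
        raw_score=aln.raw_score,
        bit_score=bits,
        e_value=e_value,
        percent_identity=aln.percent_identity,
        aln_length=aln.length,
    )


def find_homologs(
    query: str,
    proteome: Sequence[Gene],
    scheme: ScoringScheme = ScoringScheme(),
    max_e: float = 1e-6,
    min_bits: float = 0.0,
    query_id: str = "query",
) -> List[HomologyHit]:
    """All subjects whose alignment to ``query`` passes both thresholds.

    Hits are sorted by bit score descending, then subject_id. The search
    space for every hit is query length x total residues in ``proteome``.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    _validate(query, "query")
    m = len(query)
    n = _residue_count(proteome)
    hits: List[HomologyHit] = []
    for subject in proteome:
        raw = local_score(query, subject.protein, scheme)
        bits, e_value = bits_and_evalue(raw, scheme, m, n)
        if e_value <= max_e and bits >= min_bits:
            hits.append(_hit(query_id, query, subject, scheme, m, n))
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits


def _best_subject(
    query: Gene, subjects: Sequence[Gene], scheme: ScoringScheme
) -> Tuple[str, int]:
    """Best-scoring subject id for a query; ties go to the lower subject_id."""
    best_id, best_raw = "", -1
    for subject in sorted(subjects, key=lambda g: g.gene_id):
        raw = local_score(query.protein, subject.protein, scheme)
        if raw > best_raw:
            best_id, best_raw = subject.gene_id, raw
    return best_id, best_raw


def bidirectional_best_hits(
    set_a: Sequence[Gene],
    set_b: Sequence[Gene],
    scheme: ScoringScheme = ScoringScheme(),
    max_e: float = 1e-6,
) -> List[Tuple[str, str, HomologyHit]]:
    """Bidirectional best hits between two gene sets.

    A pair (a, b) is reported iff b is a's best hit in B and a is b's best
    hit in A, and the hit passes ``max_e`` in both search-space directions.
    The result is a partial matching sorted by a_id. Equal-score ties are
    broken toward the lexicographically lower subject_id.
    """
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    n_a = _residue_count(set_a)
    n_b = _residue_count(set_b)
    best_in_b = {a.gene_id: _best_subject(a, set_b, scheme) for a in set_a}
    best_in_a = {b.gene_id: _best_subject(b, set_a, scheme) for b in set_b}
    by_id_a = {g.gene_id: g for g in set_a}
    by_id_b = {g.gene_id: g for g in set_b}
    pairs: List[Tuple[str, str, HomologyHit]] = []
    for a_id in sorted(best_in_b):
        b_id, raw = best_in_b[a_id]
        if raw < 0 or best_in_a.get(b_id, ("", -1))[0] != a_id:
            continue
        a, b = by_id_a[a_id], by_id_b[b_id]
        _, e_fwd = bits_and_evalue(raw, scheme, len(a.protein), n_b)
        _, e_rev = bits_and_evalue(raw, scheme, len(b.protein), n_a)
        if e_fwd > max_e or e_rev > max_e:
            continue
        pairs.append((a_id, b_id, _hit(a_id, a.protein, b, scheme, len(a.protein), n_b)))
    return pairs


HIT_TABLE_COLUMNS = (
    "query",
    "subject",
    "pident",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def write_hit_table(hits: Iterable[HomologyHit], path) -> int:
    """Export hits in a 12-column BLAST-outfmt6-style TSV.

    Alignment coordinates are not tracked by the search API, so positional
    columns are written as 0; they are placeholders kept for layout
    compatibility.
    """
    count = 0
    with open(path, "w") as fh:
        for h in hits:
            mismatches = max(
                0, h.aln_length - round(h.aln_length * h.percent_identity / 100.0)
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.aln_length,
                        mismatches,
                        0,
                        0,
                        0,
                        0,
                        0,
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )
            count += 1
    return count
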