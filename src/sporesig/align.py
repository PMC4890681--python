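"""Pairwise sequence comparison primitives.

Protein similarity (used by the orthology and gene-detection stages) is a
k-mer prefiltered exact local alignment: two sequences must share at least
``min_shared_kmers`` k-mers before an affine-gap Smith–Waterman alignment
under BLOSUM62 is computed. Identity is matches / aligned columns and
coverage is the fraction of the query spanned by the local alignment.

16S nucleotide identity is a global alignment with free end gaps; terminal
gap columns are excluded from the identity denominator so that a full-length
sequence can be compared fairly against a partial one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")  # X permitted, never a match
NUCLEOTIDE_LETTERS = frozenset("ACGTURYSWKMBDHVN")  # IUPAC; ambiguity never a match

GAP = ord("-")
_X = ord("X")
_UNAMBIGUOUS_NUC = frozenset(b"ACGT")


@dataclass(frozen=True)
class AlignParams:
    """Thresholds and scoring shared by orthology and signature-gene detection.

    min_identity is a percentage in [0, 100]; min_coverage a fraction of the
    query length. ``min_shared_kmers=0`` disables the prefilter (exhaustive
    mode, used by soundness checks).
    """

    min_identity: float = 40.0
    min_coverage: float = 0.7
    kmer_size: int = 4
    min_shared_kmers: int = 1
    gap_open: float = -11.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float
    identity: float  # percent, [0, 100]
    coverage: float  # query residues spanned / query length, [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity out of range: {self.identity}")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"coverage out of range: {self.coverage}")
        if not np.isfinite(self.score):
            raise ValueError("alignment score must be finite")


def validate_protein(seq: str, gene_id: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{gene_id}: empty protein sequence")
    bad = set(seq) - PROTEIN_LETTERS
    if bad:
        raise ValueError(f"{gene_id}: illegal protein characters {sorted(bad)!r}")


def validate_nucleotide(seq: str, seq_id: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{seq_id}: empty nucleotide sequence")
    bad = set(seq) - NUCLEOTIDE_LETTERS
    if bad:
        raise ValueError(f"{seq_id}: illegal nucleotide characters {sorted(bad)!r}")


def shared_kmer_count(a: str, b: str, k: int) -> int:
    """Number of distinct k-mers present in both sequences."""
    if len(a) < k or len(b) < k:
        return 0
    kmers_a = {a[i : i + k] for i in range(len(a) - k + 1)}
    kmers_b = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(kmers_a & kmers_b)


@lru_cache(maxsize=8)
def _protein_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@lru_cache(maxsize=8)
def _nucleotide_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def _column_stats(aligned_query: str, aligned_subject: str) -> tuple[int, int]:
    """(matches, columns) over an aligned pair; X and gaps never match."""
    q = np.frombuffer(aligned_query.encode(), dtype=np.uint8)
    s = np.frombuffer(aligned_subject.encode(), dtype=np.uint8)
    matches = int(np.sum((q == s) & (q != GAP) & (q != _X)))
    return matches, len(q)


def pairwise_similarity(
    query: str,
    subject: str,
    params: AlignParams = AlignParams(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> SimilarityHit | None:
    """Score one protein pair; None if the prefilter rejects it or no positive-score
    local alignment exists. Thresholds (min_identity/min_coverage) are NOT applied
    here — best-hit selection applies them, so callers can inspect weak hits."""
    validate_protein(query, query_id)
    validate_protein(subject, subject_id)
    if params.min_shared_kmers > 0:
        if shared_kmer_count(query, subject, params.kmer_size) < params.min_shared_kmers:
            return None
    aligner = _protein_aligner(params.gap_open, params.gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    alignment = aligner.align(query, subject)[0]
    matches, columns = _column_stats(alignment[0], alignment[1])
    if columns == 0:
        return None
    segments = alignment.aligned[0]  # query-side segments of the local alignment
    span = int(segments[-1][1] - segments[0][0])
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        identity=100.0 * matches / columns,
        coverage=span / len(query),
    )


def pairwise_identity_16s(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    a_id: str = "a",
    b_id: str = "b",
) -> float:
    """Percent identity of two 16S sequences under free-end-gap global alignment.

    Terminal gap columns are excluded from the denominator; IUPAC ambiguity
    codes are retained in the alignment but scored as mismatches for identity.
    """
    validate_nucleotide(a, a_id)
    validate_nucleotide(b, b_id)
    aligner = _nucleotide_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    qa = np.frombuffer(alignment[0].encode(), dtype=np.uint8)
    qb = np.frombuffer(alignment[1].encode(), dtype=np.uint8)
    both = (qa != GAP) & (qb != GAP)
    if not both.any():
        return 0.0
    lo, hi = np.flatnonzero(both)[[0, -1]]
    qa, qb = qa[lo : hi + 1], qb[lo : hi + 1]
    unambiguous = np.isin(qa, list(_UNAMBIGUOUS_NUC))
    matches = int(np.sum((qa == qb) & unambiguous))
    return 100.0 * matches / len(qa)
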