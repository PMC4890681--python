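"""Independent brute-force oracles used only by the test suite.

These re-derive alignment scores and best-hit structure with plain dynamic
programming and exhaustive enumeration, sharing no code path with the
package's aligner (which delegates to Biopython) or its k-mer prefilter.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# BLOSUM62 copied into a plain int array keyed by our own alphabet ordering,
# so the oracle does not consult the package's scoring machinery.
_B62_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_B62 = np.array(
    # fmt: off
    [
        [ 4,-1,-2,-2, 0,-1,-1, 0,-2,-1,-1,-1,-1,-2,-1, 1, 0,-3,-2, 0,-2,-1, 0,-4],
        [-1, 5, 0,-2,-3, 1, 0,-2, 0,-3,-2, 2,-1,-3,-2,-1,-1,-3,-2,-3,-1, 0,-1,-4],
        [-2, 0, 6, 1,-3, 0, 0, 0, 1,-3,-3, 0,-2,-3,-2, 1, 0,-4,-2,-3, 3, 0,-1,-4],
        [-2,-2, 1, 6,-3, 0, 2,-1,-1,-3,-4,-1,-3,-3,-1, 0,-1,-4,-3,-3, 4, 1,-1,-4],
        [ 0,-3,-3,-3, 9,-3,-4,-3,-3,-1,-1,-3,-1,-2,-3,-1,-1,-2,-2,-1,-3,-3,-2,-4],
        [-1, 1, 0, 0,-3, 5, 2,-2, 0,-3,-2, 1, 0,-3,-1, 0,-1,-2,-1,-2, 0, 3,-1,-4],
        [-1, 0, 0, 2,-4, 2, 5,-2, 0,-3,-3, 1,-2,-3,-1, 0,-1,-3,-2,-2, 1, 4,-1,-4],
        [ 0,-2, 0,-1,-3,-2,-2, 6,-2,-4,-4,-2,-3,-3,-2, 0,-2,-2,-3,-3,-1,-2,-1,-4],
        [-2, 0, 1,-1,-3, 0, 0,-2, 8,-3,-3,-1,-2,-1,-2,-1,-2,-2, 2,-3, 0, 0,-1,-4],
        [-1,-3,-3,-3,-1,-3,-3,-4,-3, 4, 2,-3, 1, 0,-3,-2,-1,-3,-1, 3,-3,-3,-1,-4],
        [-1,-2,-3,-4,-1,-2,-3,-4,-3, 2, 4,-2, 2, 0,-3,-2,-1,-2,-1, 1,-4,-3,-1,-4],
        [-1, 2, 0,-1,-3, 1, 1,-2,-1,-3,-2, 5,-1,-3,-1, 0,-1,-3,-2,-2, 0, 1,-1,-4],
        [-1,-1,-2,-3,-1, 0,-2,-3,-2, 1, 2,-1, 5, 0,-2,-1,-1,-1,-1, 1,-3,-1,-1,-4],
        [-2,-3,-3,-3,-2,-3,-3,-3,-1, 0, 0,-3, 0, 6,-4,-2,-2, 1, 3,-1,-3,-3,-1,-4],
        [-1,-2,-2,-1,-3,-1,-1,-2,-2,-3,-3,-1,-2,-4, 7,-1,-1,-4,-3,-2,-2,-1,-2,-4],
        [ 1,-1, 1, 0,-1, 0, 0, 0,-1,-2,-2, 0,-1,-2,-1, 4, 1,-3,-2,-2, 0, 0, 0,-4],
        [ 0,-1, 0,-1,-1,-1,-1,-2,-2,-1,-1,-1,-1,-2,-1, 1, 5,-2,-2, 0,-1,-1, 0,-4],
        [-3,-3,-4,-4,-2,-2,-3,-2,-2,-3,-2,-3,-1, 1,-4,-3,-2,11, 2,-3,-4,-3,-2,-4],
        [-2,-2,-2,-3,-2,-1,-2,-3, 2,-1,-1,-2,-1, 3,-3,-2,-2, 2, 7,-1,-3,-2,-1,-4],
        [ 0,-3,-3,-3,-1,-2,-2,-3,-3, 3, 1,-2, 1,-1,-2,-2, 0,-3,-1, 4,-3,-2,-1,-4],
        [-2,-1, 3, 4,-3, 0, 1,-1, 0,-3,-4, 0,-3,-3,-2, 0,-1,-4,-3,-3, 4, 1,-1,-4],
        [-1, 0, 0, 1,-3, 3, 4,-2, 0,-3,-3, 1,-1,-3,-1, 0,-1,-3,-2,-2, 1, 4,-1,-4],
        [ 0,-1,-1,-1,-2,-1,-1,-1,-1,-1,-1,-1,-1,-1,-2, 0, 0,-2,-1,-1,-1,-1,-1,-4],
        [-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4,-4, 1],
    ],
    # fmt: on
    dtype=np.int64,
)
_B62_INDEX = {c: i for i, c in enumerate(_B62_ALPHABET)}

NEG_INF = -(10**9)


def _encode(seq: str) -> np.ndarray:
    return np.array([_B62_INDEX[c] for c in seq], dtype=np.int64)


@njit
def _sw_affine(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            h = diag
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def sw_score(a: str, b: str, gap_open: int = -11, gap_extend: int = -1) -> float:
    """Smith-Waterman affine-gap local alignment score under BLOSUM62.

    Gap of length L costs open + (L-1)*extend, matching the package's
    aligner convention.
    """
    return float(_sw_affine(_encode(a), _encode(b), _B62, gap_open, gap_extend))


@njit
def _semiglobal_affine(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    for i in range(n + 1):
        H[i, 0] = 0  # free leading gaps
    for j in range(m + 1):
        H[0, j] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    best = NEG_INF
    for i in range(n + 1):  # free trailing gaps
        if H[i, m] > best:
            best = H[i, m]
    for j in range(m + 1):
        if H[n, j] > best:
            best = H[n, j]
    return best


def semiglobal_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> float:
    """Free-end-gap global alignment score with affine internal gaps."""
    ea = np.frombuffer(a.encode(), dtype=np.uint8).astype(np.int64)
    eb = np.frombuffer(b.encode(), dtype=np.uint8).astype(np.int64)
    return float(_semiglobal_affine(ea, eb, match, mismatch, gap_open, gap_extend))


def exhaustive_bbh(genomes, min_identity=40.0, min_coverage=0.7):
    """BBH pairs from the full similarity matrix, no prefilter.

    Uses the package's scorer with the prefilter disabled for identity and
    coverage but re-derives best hits and mutuality by exhaustive enumeration,
    and cross-checks every raw score against the DP oracle.
    """
    import itertools

    from sporesig.align import AlignParams, pairwise_similarity

    params = AlignParams(min_shared_kmers=0)
    gene_seqs = {}
    gene_genome = {}
    for g in genomes:
        for gid, seq in g.genes:
            gene_seqs[gid] = seq
            gene_genome[gid] = g.genome_id

    def directed_best(qgenome, sgenome):
        out = {}
        for qid, qseq in qgenome.genes:
            cands = []
            for sid, sseq in sgenome.genes:
                hit = pairwise_similarity(qseq, sseq, params, qid, sid)
                if hit is None:
                    continue
                assert hit.score == sw_score(qseq, sseq)
                if hit.identity >= min_identity and hit.coverage >= min_coverage:
                    cands.append((sid, hit.score, hit.identity))
            if cands:
                out[qid] = min(cands, key=lambda c: (-c[1], -c[2], c[0]))[0]
        return out

    pairs = set()
    for ga, gb in itertools.combinations(genomes, 2):
        fwd = directed_best(ga, gb)
        rev = directed_best(gb, ga)
        for q, s in fwd.items():
            if rev.get(s) == q:
                pairs.add(tuple(sorted((q, s))))
    return pairs
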