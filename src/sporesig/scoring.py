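"""Spore-former scoring: weighted signature-gene detection in a genome.

The score of a genome is s = Σ w_i · d_i where w are the (normalized)
signature weights and d_i indicates detection of signature family i in the
genome, so s always lies in [0, 1]. A genome with s strictly greater than
0.5 is called a spore-former. A genus is called spore-forming only when every
scored species within it exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .align import AlignParams, pairwise_similarity
from .orthology import GenomeRecord, OrthologMatrix
from .signature import SporeSignature


class GenusCall(str, Enum):
    SPORE_FORMING = "spore_forming"
    NON_SPORE_FORMING = "non_spore_forming"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SporeScoreResult:
    genome_id: str
    detections: tuple[float, ...]  # aligned to signature family order
    score: float
    is_spore_former: bool

    @property
    def n_detected(self) -> int:
        return int(sum(1 for d in self.detections if d > 0))


def detect_signature_genes(
    genome: GenomeRecord,
    signature: SporeSignature,
    representatives: Mapping[str, str],
    params: AlignParams = AlignParams(),
    mode: str = "binary",
) -> np.ndarray:
    """Per-family detection vector for one genome.

    Binary mode: d_i = 1 iff some genome gene aligns to family i's
    representative protein at >= min_identity and >= min_coverage (thresholds
    evaluated with the representative as the query, so a fragment in the
    genome cannot claim full detection). Fractional mode: d_i =
    identity × coverage of the best hit, capped at 1.
    """
    if mode not in ("binary", "fractional"):
        raise ValueError(f"unknown detection mode {mode!r}")
    if not signature.families:
        raise ValueError("signature is empty")
    missing = [f for f in signature.family_ids if f not in representatives]
    if missing:
        raise ValueError(f"missing representative sequences for families {missing}")
    detections = np.zeros(len(signature.families))
    for i, fam_id in enumerate(signature.family_ids):
        rep = representatives[fam_id]
        best = 0.0
        for gene_id, seq in genome.genes:
            hit = pairwise_similarity(
                rep, seq, params, query_id=f"rep:{fam_id}", subject_id=gene_id
            )
            if hit is None:
                continue
            if hit.identity >= params.min_identity and hit.coverage >= params.min_coverage:
                if mode == "binary":
                    best = 1.0
                    break
                best = max(best, min(1.0, (hit.identity / 100.0) * hit.coverage))
        detections[i] = best
    return detections


def detections_from_matrix(
    matrix: OrthologMatrix, genome_id: str, signature: SporeSignature
) -> np.ndarray:
    """Detection vector read off a presence/absence matrix (families not in
    the matrix count as undetected)."""
    if genome_id not in matrix.presence.columns:
        raise KeyError(f"genome {genome_id} not in matrix")
    col = matrix.presence[genome_id]
    return np.array(
        [float(col[f]) if f in matrix.presence.index else 0.0 for f in signature.family_ids]
    )


def spore_score(
    detections: Iterable[float],
    signature: SporeSignature,
    genome_id: str = "genome",
    threshold: float = 0.5,
) -> SporeScoreResult:
    """Weighted detection score in [0, 1]; spore-former iff score > threshold."""
    d = np.asarray(list(detections), dtype=float)
    if len(d) != len(signature.families):
        raise ValueError(
            f"detection vector length {len(d)} != signature size {len(signature.families)}"
        )
    if ((d < 0) | (d > 1)).any():
        raise ValueError("detections must lie in [0, 1]")
    s = float(np.dot(signature.weights, d))
    s = min(1.0, max(0.0, s))  # guard float round-off at the boundaries
    return SporeScoreResult(
        genome_id=genome_id,
        detections=tuple(d.tolist()),
        score=s,
        is_spore_former=s > threshold,
    )


def classify_genus(species_scores: Iterable[float], threshold: float = 0.5) -> GenusCall:
    """Genus rule: spore-forming only if every scored species scores > threshold."""
    scores = list(species_scores)
    if not scores:
        return GenusCall.UNCLASSIFIED
    if all(s > threshold for s in scores):
        return GenusCall.SPORE_FORMING
    return GenusCall.NON_SPORE_FORMING


def score_genomes(
    genomes: Iterable[GenomeRecord],
    signature: SporeSignature,
    representatives: Mapping[str, str],
    params: AlignParams = AlignParams(),
    mode: str = "binary",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score a set of genomes; returns a tidy table, one row per genome."""
    rows = []
    for genome in genomes:
        d = detect_signature_genes(genome, signature, representatives, params, mode)
        res = spore_score(d, signature, genome_id=genome.genome_id, threshold=threshold)
        rows.append(
            {
                "genome_id": genome.genome_id,
                "species": genome.species,
                "genus": genome.genus,
                "score": res.score,
                "is_spore_former": res.is_spore_former,
                "n_detected": res.n_detected,
            }
        )
    return pd.DataFrame(rows)


def genus_verdicts(scores: pd.DataFrame, threshold: float = 0.5) -> dict[str, GenusCall]:
    """Apply the genus rule per genus over a score_genomes() table."""
    out: dict[str, GenusCall] = {}
    for genus, grp in scores.groupby("genus"):
        out[genus] = classify_genus(grp["score"].tolist(), threshold)
    return out
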