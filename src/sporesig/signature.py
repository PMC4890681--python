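"""Weighted gene-signature mining from a presence/absence matrix.

A linear maximum-margin classifier (hinge loss, L2 penalty) is trained on the
binary family × genome matrix with ethanol-resistant genomes as the positive
class, then recursively pruned: each round removes the 10% of surviving
families with the smallest |coefficient| until at most ``target_size``
remain; families whose coefficient is negative (presence predicts the
sensitive phenotype) are then excluded and elimination continues until only
positively-oriented families survive. The retained coefficients, normalized
to sum to one, are the signature weights consumed by the scoring stage.

Stratified cross-validation accuracy is recorded at every elimination round;
an alternative one-standard-error stop rule picks the smallest family set
whose accuracy is within one SE of the best round.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

from .orthology import OrthologMatrix, Phenotype


@dataclass
class SporeSignature:
    """Ordered positively-weighted gene families predictive of sporulation."""

    families: list[tuple[str, float]]  # (family_id, weight), descending weight
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f for f, _ in self.families]
        if len(ids) != len(set(ids)):
            raise ValueError("signature family ids must be unique")
        if any(w <= 0 for _, w in self.families):
            raise ValueError("signature weights must be strictly positive")
        total = sum(w for _, w in self.families)
        if self.families and abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        expected = sorted(self.families, key=lambda fw: (-fw[1], fw[0]))
        if self.families != expected:
            raise ValueError("families must be sorted by descending weight, ties lexicographic")

    @property
    def family_ids(self) -> list[str]:
        return [f for f, _ in self.families]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.families])

    def to_json(self) -> str:
        return json.dumps(
            {
                "families": [
                    {"family_id": f, "weight": w} for f, w in self.families
                ],
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SporeSignature":
        obj = json.loads(text)
        return cls(
            families=[(d["family_id"], d["weight"]) for d in obj["families"]],
            metadata=obj.get("metadata", {}),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.families, columns=["family_id", "weight"])


def _ordered_signature(family_ids: list[str], raw_weights: np.ndarray) -> list[tuple[str, float]]:
    w = raw_weights / raw_weights.sum()
    pairs = sorted(zip(family_ids, w), key=lambda fw: (-fw[1], fw[0]))
    return [(str(f), float(wt)) for f, wt in pairs]


def _labels_vector(matrix: OrthologMatrix, labels: dict[str, Phenotype]) -> np.ndarray:
    y = []
    for gid in matrix.genome_ids:
        phen = labels.get(gid, Phenotype.UNKNOWN)
        if phen not in (Phenotype.RESISTANT, Phenotype.SENSITIVE):
            raise ValueError(f"genome {gid} lacks a resistant/sensitive label")
        y.append(1 if phen is Phenotype.RESISTANT else 0)
    return np.asarray(y)


def mine_signature(
    matrix: OrthologMatrix,
    labels: dict[str, Phenotype],
    target_size: int = 66,
    cv_folds: int = 5,
    seed: int = 0,
    C: float = 0.001,
    elimination_fraction: float = 0.1,
    stop_rule: str = "target_size",
) -> SporeSignature:
    """Mine the weighted signature separating resistant from sensitive genomes.

    ``stop_rule='target_size'`` prunes to at most ``target_size`` positively
    oriented families; ``'one_se'`` instead picks the smallest round whose
    cross-validation accuracy is within one standard error of the best round.
    """
    if matrix.presence.empty:
        raise ValueError("ortholog matrix is empty")
    if stop_rule not in ("target_size", "one_se"):
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    y = _labels_vector(matrix, labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("signature mining requires genomes of both phenotypes")
    if min(n_pos, n_neg) < 3:
        raise ValueError("need at least 3 genomes per phenotype class")
    X_full = matrix.presence.to_numpy(dtype=float).T  # genomes × families
    fam_ids = np.array(matrix.family_ids)
    if target_size > len(fam_ids):
        warnings.warn(
            f"target_size {target_size} exceeds the {len(fam_ids)} available "
            "families; returning all positively-oriented families",
            stacklevel=2,
        )

    def fit(cols: np.ndarray) -> LinearSVC:
        clf = LinearSVC(
            C=C, class_weight="balanced", dual=False, max_iter=20000, random_state=seed
        )
        clf.fit(X_full[:, cols], y)
        return clf

    def cv_accuracy(cols: np.ndarray) -> tuple[float, float]:
        folds = min(cv_folds, n_pos, n_neg)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        clf = LinearSVC(
            C=C, class_weight="balanced", dual=False, max_iter=20000, random_state=seed
        )
        scores = cross_val_score(clf, X_full[:, cols], y, cv=skf, scoring="accuracy")
        return float(scores.mean()), float(scores.std(ddof=1) / np.sqrt(len(scores)))

    active = np.arange(len(fam_ids))
    history: list[dict] = []
    snapshots: list[np.ndarray] = []
    while True:
        clf = fit(active)
        coef = clf.coef_.ravel()
        acc, se = cv_accuracy(active)
        history.append({"n_features": int(len(active)), "cv_accuracy": acc, "cv_se": se})
        snapshots.append(active.copy())
        # negatively-oriented features (presence predicts sensitivity) leave
        # first: the signature scores on detection, so only positive weights
        # are meaningful, and elimination continues among the rest
        negative = set(active[coef <= 0].tolist())
        if negative and len(negative) < len(active):
            active = np.array([a for a in active if a not in negative])
            continue
        if not negative and len(active) > target_size:
            n_drop = max(1, int(np.floor(elimination_fraction * len(active))))
            n_drop = min(n_drop, len(active) - target_size)
            # drop smallest |coef|; ties resolved by larger column index for determinism
            order = np.lexsort((-active, np.abs(coef)))
            drop = set(active[order[:n_drop]].tolist())
            active = np.array([a for a in active if a not in drop])
            continue
        if negative:
            raise ValueError("no positively-oriented families survive elimination")
        break

    if stop_rule == "one_se":
        best = max(history, key=lambda h: h["cv_accuracy"])
        floor = best["cv_accuracy"] - best["cv_se"]
        eligible = [
            (h["n_features"], i)
            for i, h in enumerate(history)
            if h["cv_accuracy"] >= floor
        ]
        _, pick = min(eligible)
        active = snapshots[pick]
        clf = fit(active)
        coef = clf.coef_.ravel()
        keep = coef > 0
        if not keep.any():
            raise ValueError("no positively-oriented families at the one-SE round")
        active, coef = active[keep], coef[keep]
        raw = coef
    else:
        clf = fit(active)
        raw = clf.coef_.ravel()
        keep = raw > 0
        active, raw = active[keep], raw[keep]
        if len(active) == 0:
            raise ValueError("no positively-oriented families survive elimination")

    families = _ordered_signature(list(fam_ids[active]), raw)
    return SporeSignature(
        families=families,
        metadata={
            "n_resistant": n_pos,
            "n_sensitive": n_neg,
            "target_size": target_size,
            "stop_rule": stop_rule,
            "C": C,
            "cv_folds": cv_folds,
            "seed": seed,
            "cv_history": history,
            "final_cv_accuracy": history[-1]["cv_accuracy"],
        },
    )


def evaluate_signature(
    signature: SporeSignature,
    matrix: OrthologMatrix,
    labels: dict[str, Phenotype],
    threshold: float = 0.5,
) -> dict:
    """Confusion-matrix metrics of the >threshold spore-former rule.

    Detection comes straight from the presence matrix (a family is detected in
    a genome iff the matrix says it is present).
    """
    from .scoring import detections_from_matrix, spore_score

    if not matrix.genome_ids:
        raise ValueError("evaluation set is empty")
    y_true, y_pred = [], []
    for gid in matrix.genome_ids:
        phen = labels.get(gid, Phenotype.UNKNOWN)
        if phen not in (Phenotype.RESISTANT, Phenotype.SENSITIVE):
            raise ValueError(f"genome {gid} lacks a resistant/sensitive label")
        d = detections_from_matrix(matrix, gid, signature)
        result = spore_score(d, signature, genome_id=gid, threshold=threshold)
        y_true.append(phen is Phenotype.RESISTANT)
        y_pred.append(result.is_spore_former)
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    return {
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        "n": len(y_true),
    }
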