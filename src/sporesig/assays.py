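"""Germination and aerotolerance assay statistics.

Germination response is expressed as the fold change in colony-forming units
recovered with a germinant relative to germinant-free plates; when a
germinant-free plate yields no countable colonies, the limit of detection
(200 c.f.u./ml by default) is substituted for the zero denominator so a fold
change can still be computed. Oxygen sensitivity is expressed as percent
viability relative to anaerobically incubated control cultures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import welch_ttest
from .simulate import AssayObservation

__all__ = [
    "AssayObservation",
    "FoldChangeSummary",
    "germination_fold_change",
    "percent_viability",
    "viability_curve",
    "spore_body_percentage",
]


@dataclass(frozen=True)
class FoldChangeSummary:
    strain_id: str
    condition: str
    fold_changes: tuple[float, ...]  # per replicate; NaN where undefined
    mean: float
    min: float
    max: float
    geometric_mean: float
    n_undefined: int
    welch_t: float | None = None  # log10(FC) vs 0, when requested
    welch_p: float | None = None


def germination_fold_change(
    obs: AssayObservation,
    lod_mode: str = "zero_only",
    test_log10: bool = False,
) -> FoldChangeSummary:
    """Per-replicate c.f.u. fold change with LOD handling, plus mean and range.

    ``lod_mode='zero_only'`` substitutes the limit of detection only when the
    germinant-free count is exactly zero (the rule used for strains whose
    control plates were below detection); ``'always_floor'`` floors every
    denominator at the LOD. Replicates where both counts are zero have an
    undefined fold change and are reported as NaN and counted in
    ``n_undefined``. With ``test_log10=True`` a Welch test of log10(FC)
    against 0 (no effect) is attached.
    """
    if lod_mode not in ("zero_only", "always_floor"):
        raise ValueError(f"unknown lod_mode {lod_mode!r}")
    if obs.counts_with.shape != obs.counts_without.shape:
        raise ValueError("with/without replicate arrays must be paired")
    lod = obs.limit_of_detection
    fc = np.full(len(obs.counts_with), np.nan)
    for i, (w, wo) in enumerate(zip(obs.counts_with, obs.counts_without)):
        if w == 0 and wo == 0:
            continue  # undefined: nothing recovered under either condition
        if lod_mode == "always_floor":
            denom = max(wo, lod)
        else:
            denom = lod if wo == 0 else wo
        fc[i] = w / denom
    defined = fc[~np.isnan(fc)]
    n_undefined = int(np.isnan(fc).sum())
    if defined.size == 0:
        raise ValueError(
            f"{obs.strain_id}/{obs.condition}: no replicate has a defined fold change"
        )
    positive = defined[defined > 0]
    geo = float(np.exp(np.mean(np.log(positive)))) if positive.size else float("nan")
    welch_t = welch_p = None
    if test_log10 and positive.size >= 2:
        logs = np.log10(positive)
        # one-sample t against 0 via Welch with a degenerate null is ill-posed;
        # use the exact one-sample t statistic instead
        sd = logs.std(ddof=1)
        if sd > 0:
            from scipy import stats

            t = logs.mean() / (sd / np.sqrt(len(logs)))
            welch_t = float(t)
            welch_p = float(2.0 * stats.t.sf(abs(t), df=len(logs) - 1))
    return FoldChangeSummary(
        strain_id=obs.strain_id,
        condition=obs.condition,
        fold_changes=tuple(fc.tolist()),
        mean=float(defined.mean()),
        min=float(defined.min()),
        max=float(defined.max()),
        geometric_mean=geo,
        n_undefined=n_undefined,
        welch_t=welch_t,
        welch_p=welch_p,
    )


def percent_viability(exposed: float, control: float) -> float:
    """Viability of an oxygen-exposed culture as % of its anaerobic control."""
    if control <= 0:
        raise ValueError("anaerobic control count must be positive")
    if exposed < 0:
        raise ValueError("exposed count must be non-negative")
    return 100.0 * exposed / control


def viability_curve(
    timepoints_h, exposed_counts, control_counts
) -> list[tuple[float, float]]:
    """(time in hours, percent viability) series for a survival curve."""
    t = list(timepoints_h)
    e = list(exposed_counts)
    c = list(control_counts)
    if not (len(t) == len(e) == len(c)):
        raise ValueError("time, exposed and control series must be the same length")
    return [(float(ti), percent_viability(ei, ci)) for ti, ei, ci in zip(t, e, c)]


def spore_body_percentage(n_spores: int, n_vegetative: int) -> float:
    """Spore bodies in a micrograph as % of vegetative cells present."""
    if n_vegetative <= 0:
        raise ValueError("vegetative cell count must be positive")
    if n_spores < 0:
        raise ValueError("spore count must be non-negative")
    return 100.0 * n_spores / n_vegetative
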