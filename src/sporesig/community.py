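"""Community-level statistics over taxonomic abundance tables.

Covers the quantitative rules applied to classifier-style (Kraken-like)
profiles: standardization of read counts to relative abundance (with a
log2(count+1) companion for sample-to-sample comparison), detection filters
(mean coverage >= 2x across the target; >= 100 unique reads), spore-former
fractions under genus verdicts, Spearman rank correlation, inverse Simpson
diversity, twofold temporal turnover, paired and Welch t tests, and the
coupon-collector estimate of how many colonies must be picked to observe
every species at least once given its relative abundance.

The rank/product-moment correlation and the t statistics are implemented
directly from their textbook definitions (scipy supplies only the t-
distribution tail); scipy.stats serves as the independent cross-check in the
test suite, not as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats


@dataclass
class AbundanceTable:
    """Tidy sample × taxon abundance rows.

    ``mode`` is "counts" (raw classified reads) or "relative" (per-sample
    proportions summing to one). Zeros are represented by absent rows.
    """

    data: pd.DataFrame  # sample_id, taxon_id, rank, genus, abundance[, spore_flag]
    mode: str = "relative"

    REQUIRED = ("sample_id", "taxon_id", "rank", "genus", "abundance")

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "counts"):
            raise ValueError(f"unknown abundance mode {self.mode!r}")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"abundance table missing columns {missing}")
        dup = self.data.duplicated(subset=["sample_id", "taxon_id"])
        if dup.any():
            offenders = self.data.loc[dup, ["sample_id", "taxon_id"]].values.tolist()
            raise ValueError(f"duplicate (sample, taxon) rows: {offenders[:5]}")
        if (self.data["abundance"] < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.mode == "relative":
            sums = self.data.groupby("sample_id")["abundance"].sum()
            bad = sums[(sums - 1.0).abs() > 1e-6]
            if len(bad):
                raise ValueError(
                    f"relative abundances must sum to 1 per sample; off: {dict(bad)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())


@dataclass(frozen=True)
class CoverageRecord:
    """Per-target alignment summary used by the detection filters."""

    target_id: str
    target_length: int  # bp
    aligned_bases: int
    unique_reads: int

    def __post_init__(self) -> None:
        if self.target_length < 0 or self.aligned_bases < 0 or self.unique_reads < 0:
            raise ValueError(f"{self.target_id}: coverage fields must be non-negative")

    @property
    def mean_coverage(self) -> float:
        if self.target_length == 0:
            raise ValueError(f"{self.target_id}: zero target length")
        return self.aligned_bases / self.target_length


def standardize(table: AbundanceTable) -> AbundanceTable:
    """Counts -> per-sample relative abundance, keeping log2(count+1)."""
    if table.mode != "counts":
        raise ValueError("standardize expects a counts-mode table")
    df = table.data.copy()
    totals = df.groupby("sample_id")["abundance"].transform("sum")
    zero = df.loc[totals == 0, "sample_id"].unique()
    if len(zero):
        raise ValueError(f"zero-total sample(s): {sorted(zero)}")
    df["log2_count"] = np.log2(df["abundance"] + 1.0)
    df["abundance"] = df["abundance"] / totals
    return AbundanceTable(data=df, mode="relative")


def sequence_present(record: CoverageRecord, fold_threshold: float = 2.0) -> bool:
    """Present iff mean coverage across the target is at least the threshold."""
    return record.mean_coverage >= fold_threshold


def metagenomic_species_detected(record: CoverageRecord, read_cutoff: int = 100) -> bool:
    """Detected iff the target attracted at least ``read_cutoff`` unique reads."""
    return record.unique_reads >= read_cutoff


def spore_fractions(table: AbundanceTable, verdicts: dict) -> pd.DataFrame:
    """Per-sample spore-former share of genera and of total abundance.

    Genera without a verdict (or with an 'unclassified' one) are excluded from
    both numerator and denominator. Returns one row per sample with columns
    fraction_of_genera and fraction_of_abundance.
    """
    from .scoring import GenusCall

    rows = []
    for sample_id, grp in table.data.groupby("sample_id", sort=True):
        genus_ab = grp.groupby("genus")["abundance"].sum()
        spore_g, nonspore_g = [], []
        for genus, ab in genus_ab.items():
            call = verdicts.get(genus, GenusCall.UNCLASSIFIED)
            if call == GenusCall.SPORE_FORMING:
                spore_g.append(ab)
            elif call == GenusCall.NON_SPORE_FORMING:
                nonspore_g.append(ab)
        n_classified = len(spore_g) + len(nonspore_g)
        if n_classified == 0:
            raise ValueError(f"sample {sample_id}: no classified genera")
        total = sum(spore_g) + sum(nonspore_g)
        rows.append(
            {
                "sample_id": sample_id,
                "fraction_of_genera": len(spore_g) / n_classified,
                "fraction_of_abundance": sum(spore_g) / total if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties sharing their average rank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_correlation(x, y) -> float:
    """Spearman's rho: product-moment correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    if len(x) < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    rx, ry = _average_ranks(x), _average_ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float((dx * dy).sum() / denom)


def inverse_simpson(abundances) -> float:
    """Effective number of equally abundant taxa, 1 / Σ p²; the vector is
    renormalized so subsets (e.g. spore-formers only) can be passed directly."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = p / total
    return float(1.0 / np.sum(p**2))


def turnover_fraction(
    t1: AbundanceTable,
    t2: AbundanceTable,
    spore_flags: dict[str, bool] | None = None,
    which: str = "all",
    fold: float = 2.0,
    single_timepoint_changed: bool = True,
) -> pd.Series:
    """Per-sample fraction of species changing ``fold``-fold or more.

    A species detected at exactly one time point counts as changed (its fold
    change exceeds any finite bound); species absent at both are excluded.
    ``which`` restricts the evaluation to 'spore', 'nonspore' or 'all'
    species via ``spore_flags``.
    """
    if which not in ("all", "spore", "nonspore"):
        raise ValueError(f"unknown class filter {which!r}")
    if which != "all" and spore_flags is None:
        raise ValueError("spore_flags required for a class-filtered turnover")
    shared = sorted(set(t1.sample_ids) & set(t2.sample_ids))
    if not shared:
        raise ValueError("tables share no sample ids")
    p1 = t1.data.set_index(["sample_id", "taxon_id"])["abundance"]
    p2 = t2.data.set_index(["sample_id", "taxon_id"])["abundance"]
    out = {}
    for sample in shared:
        a = p1.loc[sample] if sample in p1.index.get_level_values(0) else pd.Series(dtype=float)
        b = p2.loc[sample] if sample in p2.index.get_level_values(0) else pd.Series(dtype=float)
        species = set(a[a > 0].index) | set(b[b > 0].index)
        if which == "spore":
            species = {s for s in species if spore_flags.get(s, False)}
        elif which == "nonspore":
            species = {s for s in species if not spore_flags.get(s, False)}
        changed = n = 0
        for sp in species:
            x = float(a.get(sp, 0.0))
            y = float(b.get(sp, 0.0))
            n += 1
            if x == 0.0 or y == 0.0:
                changed += 1 if single_timepoint_changed else 0
            elif max(x / y, y / x) >= fold:
                changed += 1
        out[sample] = changed / n if n else float("nan")
    return pd.Series(out, name=f"turnover_{which}")


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-tailed paired t test on per-donor values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("paired t test needs equal-length vectors, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        raise ValueError("zero variance in paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch's unpaired two-tailed t test (Satterthwaite degrees of freedom)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch t test needs at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(p)


def colonies_required(
    abundances,
    target: str = "all_species_once",
    gamma: float = 0.95,
) -> float:
    """Expected number of colonies to pick to reach the detection target.

    'all_species_once': unequal-probability coupon collector,
    E[T] = ∫₀^∞ (1 − Π_i (1 − e^{−p_i t})) dt, evaluated by adaptive
    quadrature (exact for the discrete pick count by Poissonization).
    'per_species_probability': smallest N such that every species is seen
    with probability at least gamma, i.e. min_i 1 − (1 − p_i)^N ≥ gamma.
    """
    p = np.asarray(abundances, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("species probabilities must sum to 1")
    if target == "all_species_once":
        if (p <= 0).any():
            return float("inf")

        def survival(t: float) -> float:
            with np.errstate(divide="ignore"):
                return -np.expm1(np.sum(np.log1p(-np.exp(-p * t))))

        upper = 50.0 / p.min()  # far tail: P(T > upper) < S·e^{-50}
        value, _err = integrate.quad(
            survival, 0.0, upper, epsabs=1e-10, epsrel=1e-10, limit=500
        )
        return float(value)
    if target == "per_species_probability":
        if not (0.0 < gamma < 1.0):
            raise ValueError("gamma must be in (0, 1)")
        if (p <= 0).any():
            return float("inf")
        pmin = p.min()
        return float(np.ceil(np.log1p(-gamma) / np.log1p(-pmin)))
    raise ValueError(f"unknown target {target!r}")


def simulate_colony_picks(
    abundances, n_trials: int, rng: np.random.Generator, method: str = "exponential"
) -> np.ndarray:
    """Monte-Carlo validator for the coupon-collector expectation.

    'exponential' samples T = max_i Exp(p_i), the continuous-time embedding
    whose mean equals the discrete pick count exactly; 'discrete' simulates
    the pick process itself (small species counts only).
    """
    p = np.asarray(abundances, dtype=float)
    if method == "exponential":
        times = rng.exponential(1.0 / p, size=(n_trials, len(p)))
        return times.max(axis=1)
    if method == "discrete":
        out = np.empty(n_trials)
        for trial in range(n_trials):
            seen: set[int] = set()
            n = 0
            while len(seen) < len(p):
                block = rng.choice(len(p), size=64, p=p)
                for s in block:
                    n += 1
                    seen.add(int(s))
                    if len(seen) == len(p):
                        break
            out[trial] = n
        return out
    raise ValueError(f"unknown method {method!r}")
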