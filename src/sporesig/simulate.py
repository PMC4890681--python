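"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design end to end: a panel of
ethanol-resistant (spore-forming) and ethanol-sensitive genomes whose gene
content carries a planted phenotype-associated signature; log-normally
distributed community abundance profiles with genus/species structure; paired
time-point abundance tables with class-specific turnover; replicate
colony-count (c.f.u.) assay tables; and 16S sequence sets drawn from known
centroids.

The gene-content model: every genome carries all core families; each
accessory family is present with background probability q; each of the
``n_signature_families`` planted signature families is present with
probability ``penetrance_pos`` in resistant genomes and ``penetrance_neg`` in
sensitive ones. Each family has one ancestral protein (uniform over the
20-letter alphabet); every carrier receives an independently mutated copy
(per-site substitution probability ``within_family_divergence``).

All randomness flows through one ``numpy.random.Generator`` derived from the
config seed; fixed seed implies byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .orthology import GenomeRecord, Phenotype

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic panel and communities."""

    seed: int = 0
    # genome panel
    n_resistant: int = 30
    n_sensitive: int = 30
    n_core_families: int = 15
    n_accessory_families: int = 60
    accessory_presence: float = 0.3  # background presence probability q
    n_signature_families: int = 66
    penetrance_pos: float = 0.95
    penetrance_neg: float = 0.05
    within_family_divergence: float = 0.05
    protein_length_range: tuple[int, int] = (80, 150)
    # community
    n_samples: int = 6
    n_genera: int = 20
    species_per_genus: tuple[int, int] = (1, 5)
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.5
    spore_genus_prob: float = 0.5
    # temporal turnover (1-year resampling noise, per-species multiplicative)
    turnover_sdlog_spore: float = 1.0
    turnover_sdlog_nonspore: float = 0.3

    def validate(self) -> None:
        probs = {
            "accessory_presence": self.accessory_presence,
            "penetrance_pos": self.penetrance_pos,
            "penetrance_neg": self.penetrance_neg,
            "within_family_divergence": self.within_family_divergence,
            "spore_genus_prob": self.spore_genus_prob,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        counts = {
            "n_resistant": self.n_resistant,
            "n_sensitive": self.n_sensitive,
            "n_core_families": self.n_core_families,
            "n_accessory_families": self.n_accessory_families,
            "n_signature_families": self.n_signature_families,
            "n_samples": self.n_samples,
            "n_genera": self.n_genera,
        }
        for name, c in counts.items():
            if c < 0:
                raise ValueError(f"{name} must be >= 0, got {c}")
        if self.penetrance_pos <= self.penetrance_neg:
            raise ValueError(
                "penetrance_pos must exceed penetrance_neg for a learnable signal"
            )
        lo, hi = self.protein_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid protein_length_range {self.protein_length_range}")
        lo, hi = self.species_per_genus
        if not (0 < lo <= hi):
            raise ValueError(f"invalid species_per_genus {self.species_per_genus}")
        for name in ("abundance_sdlog", "turnover_sdlog_spore", "turnover_sdlog_nonspore"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_signature_families: set[str] = field(default_factory=set)
    genome_phenotypes: dict[str, Phenotype] = field(default_factory=dict)
    community_spore_flags: dict[str, bool] = field(default_factory=dict)
    gene_families: dict[str, str] = field(default_factory=dict)  # gene id -> family id
    family_presence: dict[str, set[str]] = field(default_factory=dict)  # fam -> genomes
    family_ancestors: dict[str, str] = field(default_factory=dict)  # fam -> protein
    warning: str | None = None


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(AMINO_ACIDS, size=length)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator,
            alphabet: np.ndarray = AMINO_ACIDS) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different letter."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = alphabet[alphabet != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_genomes(config: SimConfig) -> tuple[list[GenomeRecord], GroundTruth]:
    """Generate the labelled genome panel and record the planted truth."""
    config.validate()
    rng = config.rng()
    truth = GroundTruth()
    if config.n_resistant == 0 or config.n_sensitive == 0:
        truth.warning = (
            "one phenotype class is empty; signature mining will not be possible"
        )
        warnings.warn(truth.warning, stacklevel=2)

    fam_kinds: list[tuple[str, str]] = []
    fam_kinds += [(f"CORE{i:04d}", "core") for i in range(config.n_core_families)]
    fam_kinds += [(f"SIG{i:04d}", "signature") for i in range(config.n_signature_families)]
    fam_kinds += [(f"ACC{i:04d}", "accessory") for i in range(config.n_accessory_families)]

    lo, hi = config.protein_length_range
    ancestors: dict[str, np.ndarray] = {}
    for fam_id, kind in fam_kinds:
        length = int(rng.integers(lo, hi + 1))
        ancestors[fam_id] = _random_protein(rng, length)
        if kind == "signature":
            truth.planted_signature_families.add(fam_id)
        truth.family_ancestors[fam_id] = ancestors[fam_id].tobytes().decode()
        truth.family_presence[fam_id] = set()

    genome_specs = [(f"R{i:03d}", Phenotype.RESISTANT) for i in range(config.n_resistant)]
    genome_specs += [(f"S{i:03d}", Phenotype.SENSITIVE) for i in range(config.n_sensitive)]

    genomes: list[GenomeRecord] = []
    for genome_id, phenotype in genome_specs:
        truth.genome_phenotypes[genome_id] = phenotype
        genes: list[tuple[str, str]] = []
        for fam_id, kind in fam_kinds:
            if kind == "core":
                present = True
            elif kind == "signature":
                p = (
                    config.penetrance_pos
                    if phenotype is Phenotype.RESISTANT
                    else config.penetrance_neg
                )
                present = rng.random() < p
            else:
                present = rng.random() < config.accessory_presence
            if not present:
                continue
            copy = _mutate(ancestors[fam_id], config.within_family_divergence, rng)
            gene_id = f"{genome_id}|{fam_id}"
            genes.append((gene_id, copy.tobytes().decode()))
            truth.gene_families[gene_id] = fam_id
            truth.family_presence[fam_id].add(genome_id)
        genomes.append(
            GenomeRecord(
                genome_id=genome_id,
                species=f"Species_{genome_id}",
                genus=f"Genus_{genome_id[0]}{int(genome_id[1:]) % 10}",
                family=f"Family_{genome_id[0]}",
                phenotype=phenotype,
                genes=genes,
            )
        )
    return genomes, truth


def presence_matrix_from_truth(truth: GroundTruth, genomes: list[GenomeRecord]):
    """Family × genome 0/1 matrix straight from the planted presence sets.

    This is the generator-side counterpart of the orthology stage's
    OrthologMatrix, used to exercise mining/scoring at scales where all-vs-all
    alignment is not the question being asked.
    """
    from .orthology import OrthologMatrix

    genome_ids = [g.genome_id for g in genomes]
    fam_ids = sorted(truth.family_presence)
    data = np.zeros((len(fam_ids), len(genome_ids)), dtype=np.int8)
    members: dict[str, dict[str, str]] = {}
    for i, fam in enumerate(fam_ids):
        members[fam] = {}
        for j, gid in enumerate(genome_ids):
            if gid in truth.family_presence[fam]:
                data[i, j] = 1
                members[fam][gid] = f"{gid}|{fam}"
    presence = pd.DataFrame(data, index=fam_ids, columns=genome_ids)
    presence.index.name = "family_id"
    return OrthologMatrix(presence=presence, members=members)


def simulate_community(config: SimConfig, truth: GroundTruth):
    """Log-normal relative-abundance profiles with genus/species structure.

    Populates ``truth.community_spore_flags`` (whole genera are flagged
    spore-forming with probability ``spore_genus_prob``; species inherit the
    genus flag, matching the genus-level decision rule downstream).
    """
    from .community import AbundanceTable

    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # independent stream from genomes
    if not truth.community_spore_flags:
        lo, hi = config.species_per_genus
        for g in range(config.n_genera):
            genus = f"g{g:03d}"
            spore = bool(rng.random() < config.spore_genus_prob)
            for s in range(int(rng.integers(lo, hi + 1))):
                truth.community_spore_flags[f"{genus}.s{s:02d}"] = spore
    species = sorted(truth.community_spore_flags)
    if not species:
        raise ValueError("ground truth holds no community species")
    rows = []
    for sample_i in range(config.n_samples):
        sample_id = f"donor{sample_i + 1:02d}"
        weights = rng.lognormal(
            mean=config.abundance_meanlog, sigma=config.abundance_sdlog, size=len(species)
        )
        rel = weights / weights.sum()
        for sp, p in zip(species, rel):
            rows.append(
                {
                    "sample_id": sample_id,
                    "taxon_id": sp,
                    "rank": "species",
                    "genus": sp.split(".")[0],
                    "abundance": p,
                    "spore_flag": truth.community_spore_flags[sp],
                }
            )
    return AbundanceTable(data=pd.DataFrame(rows), mode="relative")


def simulate_timepoints(table, config: SimConfig, seed_offset: int = 2):
    """Second time point: per-species multiplicative log-normal drift.

    Spore-forming species drift with ``turnover_sdlog_spore``; the rest with
    ``turnover_sdlog_nonspore``; each sample is renormalized to sum 1.
    """
    from .community import AbundanceTable

    rng = np.random.default_rng(config.seed + seed_offset)
    df = table.data.copy()
    out = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("taxon_id").reset_index(drop=True)
        sd = np.where(
            grp["spore_flag"].to_numpy(dtype=bool),
            config.turnover_sdlog_spore,
            config.turnover_sdlog_nonspore,
        )
        # per-species sigma: z ~ N(0,1), factor = exp(sd * z)
        z = rng.standard_normal(len(grp))
        factor = np.exp(sd * z)
        newab = grp["abundance"].to_numpy() * factor
        newab = newab / newab.sum()
        grp = grp.assign(abundance=newab)
        out.append(grp)
    return AbundanceTable(data=pd.concat(out, ignore_index=True), mode="relative")


@dataclass
class AssayObservation:
    """Replicate c.f.u. counts for one strain/condition with paired controls."""

    strain_id: str
    condition: str
    counts_with: np.ndarray  # c.f.u./ml with germinant (or oxygen-exposed)
    counts_without: np.ndarray  # paired control counts
    limit_of_detection: float = 200.0

    def __post_init__(self) -> None:
        self.counts_with = np.asarray(self.counts_with, dtype=float)
        self.counts_without = np.asarray(self.counts_without, dtype=float)
        if self.counts_with.size == 0 or self.counts_without.size == 0:
            raise ValueError("replicate arrays must be non-empty")
        if (self.counts_with < 0).any() or (self.counts_without < 0).any():
            raise ValueError("c.f.u. counts must be non-negative")
        if self.limit_of_detection <= 0:
            raise ValueError("limit of detection must be positive")


def simulate_assay_counts(
    n_replicates: int,
    true_fold_change: float,
    baseline_cfu: float,
    lod: float = 200.0,
    seed: int = 0,
    strain_id: str = "strain",
    condition: str = "taurocholate",
) -> AssayObservation:
    """Poisson replicate counts around baseline and baseline × fold change.

    Counts that fall below the limit of detection are reported as 0 (the plate
    showed nothing countable); the LOD itself is recorded on the observation.
    """
    if baseline_cfu <= 0:
        raise ValueError("baseline_cfu must be positive")
    if true_fold_change < 0:
        raise ValueError("true_fold_change must be >= 0")
    rng = np.random.default_rng(seed)
    without = rng.poisson(baseline_cfu, size=n_replicates).astype(float)
    with_g = rng.poisson(baseline_cfu * true_fold_change, size=n_replicates).astype(float)
    without[without < lod] = 0.0
    with_g[with_g < lod] = 0.0
    return AssayObservation(
        strain_id=strain_id,
        condition=condition,
        counts_with=with_g,
        counts_without=without,
        limit_of_detection=lod,
    )


def simulate_16s(
    n_centroids: int = 3,
    members_per_centroid: int = 4,
    length: int = 800,
    within_divergence: float = 0.005,
    between_divergence: float = 0.05,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """16S-like sequences from mutated centroids, with centroid ground truth.

    Divergence parameters are expected *pairwise* divergences: two members of
    one centroid differ at about ``within_divergence`` of sites and members of
    different centroids at about ``between_divergence``; each copy is
    therefore mutated at half that rate. Returns (records, truth) where truth
    maps sequence id -> centroid index.
    """
    rng = np.random.default_rng(seed)
    root = rng.choice(NUCLEOTIDES, size=length)
    records: list[tuple[str, str]] = []
    truth: dict[str, int] = {}
    for c in range(n_centroids):
        centroid = _mutate(root, between_divergence / 2.0, rng, alphabet=NUCLEOTIDES)
        for m in range(members_per_centroid):
            seq = _mutate(centroid, within_divergence / 2.0, rng, alphabet=NUCLEOTIDES)
            sid = f"otu{c}_{m:02d}"
            records.append((sid, seq.tobytes().decode()))
            truth[sid] = c
    return records, truth


def holdout_split(
    genomes: list[GenomeRecord], n_holdout_per_class: int, seed: int = 0
) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Deterministic stratified train/holdout split of the genome panel."""
    rng = np.random.default_rng(seed)
    train: list[GenomeRecord] = []
    holdout: list[GenomeRecord] = []
    for phen in (Phenotype.RESISTANT, Phenotype.SENSITIVE):
        cls = [g for g in genomes if g.phenotype is phen]
        idx = rng.permutation(len(cls))
        held = set(idx[:n_holdout_per_class])
        for i, g in enumerate(cls):
            (holdout if i in held else train).append(g)
    return train, holdout
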