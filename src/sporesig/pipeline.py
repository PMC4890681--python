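"""End-to-end pipeline driver: simulate → orthology → mine → score → community.

Every run writes its artifacts plus a manifest recording inputs, parameters,
the seed and a SHA-256 hash of each output file, so identical configurations
produce byte-identical manifests. The default simulation profile is sized so
the full bidirectional-best-hit stage runs in seconds while still carrying a
learnable planted signature.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .align import AlignParams
from .community import inverse_simpson, spearman_correlation, turnover_fraction
from .orthology import OrthologMatrix, build_ortholog_matrix
from .scoring import GenusCall, score_genomes
from .signature import SporeSignature, evaluate_signature, mine_signature
from .simulate import SimConfig, holdout_split, simulate_community, simulate_genomes, simulate_timepoints

log = logging.getLogger("sporesig")


@dataclass
class PipelineConfig:
    """Flat configuration for a full synthetic run; every key is overridable."""

    outdir: str = "sporesig_run"
    seed: int = 0
    # simulation profile (pipeline-scale: full BBH stage stays fast)
    n_resistant: int = 10
    n_sensitive: int = 10
    n_holdout_per_class: int = 2
    n_core_families: int = 6
    n_accessory_families: int = 10
    n_signature_families: int = 15
    accessory_presence: float = 0.3
    penetrance_pos: float = 0.95
    penetrance_neg: float = 0.05
    within_family_divergence: float = 0.05
    protein_length_min: int = 60
    protein_length_max: int = 90
    n_samples: int = 6
    n_genera: int = 20
    # thresholds
    conservation_fraction: float = 0.5
    min_identity: float = 40.0
    min_coverage: float = 0.7
    target_size: int = 15
    score_threshold: float = 0.5
    coverage_fold: float = 2.0
    read_cutoff: int = 100
    otu_species_threshold: float = 0.987
    otu_threshold: float = 0.97
    detection_mode: str = "binary"

    def __post_init__(self) -> None:
        if not (0.0 < self.conservation_fraction <= 1.0):
            raise ValueError("conservation_fraction must be in (0, 1]")
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity must be a percentage")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in [0, 1]")
        if not (0.0 < self.otu_species_threshold < 1.0):
            raise ValueError("otu_species_threshold must be in (0, 1)")
        if not (0.0 < self.otu_threshold < 1.0):
            raise ValueError("otu_threshold must be in (0, 1)")
        if self.detection_mode not in ("binary", "fractional"):
            raise ValueError("detection_mode must be 'binary' or 'fractional'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            seed=self.seed,
            n_resistant=self.n_resistant + self.n_holdout_per_class,
            n_sensitive=self.n_sensitive + self.n_holdout_per_class,
            n_core_families=self.n_core_families,
            n_accessory_families=self.n_accessory_families,
            n_signature_families=self.n_signature_families,
            accessory_presence=self.accessory_presence,
            penetrance_pos=self.penetrance_pos,
            penetrance_neg=self.penetrance_neg,
            within_family_divergence=self.within_family_divergence,
            protein_length_range=(self.protein_length_min, self.protein_length_max),
            n_samples=self.n_samples,
            n_genera=self.n_genera,
        )

    def align_params(self) -> AlignParams:
        return AlignParams(min_identity=self.min_identity, min_coverage=self.min_coverage)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def family_representatives(matrix: OrthologMatrix, genomes) -> dict[str, str]:
    """One representative protein per family: the member from the
    lexicographically smallest genome id carrying it (deterministic)."""
    seqs = {gid: dict(g.genes) for gid, g in ((g.genome_id, g) for g in genomes)}
    reps = {}
    for fam, members in matrix.members.items():
        genome_id = min(members)
        reps[fam] = seqs[genome_id][members[genome_id]]
    return reps


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every computational stage; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "warnings": [],
    }
    t_start = time.perf_counter()
    stage = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        sim = config.sim_config()
        genomes, truth = simulate_genomes(sim)
        if truth.warning:
            manifest["warnings"].append(truth.warning)
        train, holdout = holdout_split(genomes, config.n_holdout_per_class, seed=config.seed)
        fasta_paths, meta_path = sio.write_genomes(genomes, outdir / "genomes")
        sio.write_ground_truth(truth, outdir / "ground_truth.json")
        manifest["stages"][stage] = {
            "n_genomes": len(genomes),
            "n_train": len(train),
            "n_holdout": len(holdout),
        }
        log.info("simulated %d genomes", len(genomes))

        # --- orthology ----------------------------------------------------
        stage = "orthology"
        params = config.align_params()
        matrix = build_ortholog_matrix(train, params, config.conservation_fraction)
        member_rows = [
            {"family_id": fam, "genome_id": gid, "gene_id": gene}
            for fam, members in sorted(matrix.members.items())
            for gid, gene in sorted(members.items())
        ]
        sio.write_table(pd.DataFrame(member_rows), outdir / "families.tsv")
        presence_out = matrix.presence.reset_index()
        sio.write_table(presence_out, outdir / "presence_matrix.tsv")
        manifest["stages"][stage] = {
            "n_families": len(matrix.family_ids),
            "n_singletons": len(matrix.singletons),
        }

        # --- mine ---------------------------------------------------------
        stage = "mine"
        labels = truth.genome_phenotypes
        target = min(config.target_size, len(matrix.family_ids))
        if config.target_size > len(matrix.family_ids):
            manifest["warnings"].append(
                f"target_size {config.target_size} exceeds {len(matrix.family_ids)} "
                "retained families; using all positively-oriented families"
            )
        signature = mine_signature(
            matrix, labels, target_size=target, seed=config.seed
        )
        (outdir / "signature.json").write_text(signature.to_json())
        sio.write_table(signature.to_frame(), outdir / "signature.tsv")
        reps = family_representatives(matrix, train)
        sig_reps = {f: reps[f] for f in signature.family_ids}
        sio.write_fasta(sorted(sig_reps.items()), outdir / "signature_representatives.faa")
        manifest["stages"][stage] = {
            "signature_size": len(signature.families),
            "cv_accuracy": signature.metadata["final_cv_accuracy"],
        }

        # --- score (held-out genomes, sequence-level detection) -----------
        stage = "score"
        scores = score_genomes(
            holdout, signature, sig_reps, params,
            mode=config.detection_mode, threshold=config.score_threshold,
        )
        sio.write_table(scores, outdir / "holdout_scores.tsv")
        correct = sum(
            (labels[r.genome_id].value == "resistant") == bool(r.is_spore_former)
            for r in scores.itertuples(index=False)
        )
        holdout_accuracy = correct / len(scores)
        train_eval = evaluate_signature(
            signature, matrix, labels, threshold=config.score_threshold
        )
        manifest["stages"][stage] = {
            "holdout_accuracy": holdout_accuracy,
            "train_accuracy": train_eval["accuracy"],
        }

        # --- community ----------------------------------------------------
        stage = "community"
        t1 = simulate_community(sim, truth)
        t2 = simulate_timepoints(t1, sim)
        sio.write_abundance(t1, outdir / "abundance_t1.tsv")
        sio.write_abundance(t2, outdir / "abundance_t2.tsv")
        genus_flags = {
            sp.split(".")[0]: flag for sp, flag in truth.community_spore_flags.items()
        }
        verdicts = {
            g: GenusCall.SPORE_FORMING if f else GenusCall.NON_SPORE_FORMING
            for g, f in genus_flags.items()
        }
        from .community import spore_fractions

        fr = spore_fractions(t1, verdicts)
        stats_rows = []
        for sample in t1.sample_ids:
            g1 = t1.data[t1.data["sample_id"] == sample].set_index("taxon_id")
            g2 = t2.data[t2.data["sample_id"] == sample].set_index("taxon_id")
            shared = sorted(set(g1.index) & set(g2.index))
            rho = spearman_correlation(
                g1.loc[shared, "abundance"].to_numpy(),
                g2.loc[shared, "abundance"].to_numpy(),
            )
            spore_ab = g1.loc[g1["spore_flag"].astype(bool), "abundance"]
            nonspore_ab = g1.loc[~g1["spore_flag"].astype(bool), "abundance"]
            stats_rows.append(
                {
                    "sample_id": sample,
                    "spearman_rho_t1_t2": rho,
                    "invsimpson_spore": inverse_simpson(spore_ab) if len(spore_ab) else np.nan,
                    "invsimpson_nonspore": inverse_simpson(nonspore_ab) if len(nonspore_ab) else np.nan,
                }
            )
        stats = pd.DataFrame(stats_rows).merge(fr, on="sample_id")
        stats["turnover_spore"] = turnover_fraction(
            t1, t2, truth.community_spore_flags, which="spore"
        ).reindex(stats["sample_id"]).to_numpy()
        stats["turnover_nonspore"] = turnover_fraction(
            t1, t2, truth.community_spore_flags, which="nonspore"
        ).reindex(stats["sample_id"]).to_numpy()
        sio.write_table(stats, outdir / "community_stats.tsv")
        manifest["stages"][stage] = {
            "mean_fraction_of_genera": float(fr["fraction_of_genera"].mean()),
            "mean_fraction_of_abundance": float(fr["fraction_of_abundance"].mean()),
        }
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    manifest["elapsed_s"] = round(time.perf_counter() - t_start, 1)
    text = json.dumps(
        {k: v for k, v in manifest.items() if k != "elapsed_s"},
        indent=2,
        sort_keys=True,
    )
    (outdir / "manifest.json").write_text(text)
    return manifest
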