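"""File formats: FASTA round-tripping, schema-checked TSV tables, JSON.

All tables are tab-separated plain text whose first line is a schema comment
(``# schema: col1 col2 ...``); readers reject files whose schema drifted.
FASTA writing wraps at 80 columns and reading validates the declared
alphabet and id uniqueness.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import validate_nucleotide, validate_protein
from .orthology import GenomeRecord, Phenotype
from .simulate import GroundTruth

FASTA_WRAP = 80


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[tuple[str, str]]:
    """(id, sequence) pairs; validates alphabet and rejects duplicate ids."""
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "protein":
            validate_protein(seq, rec.id)
        else:
            validate_nucleotide(seq, rec.id)
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
        records.append((rec.id, seq))
    if dupes:
        raise ValueError(f"{path}: duplicate sequence ids {sorted(set(dupes))}")
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqs)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with a leading '# schema:' comment naming the columns."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# schema: " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, expected_columns: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# schema:"):
            raise ValueError(f"{path}: missing schema header comment")
        declared = first.removeprefix("# schema:").strip().split("\t")
        df = pd.read_csv(fh, sep="\t")
    if list(df.columns) != declared:
        raise ValueError(
            f"{path}: schema drift — header {list(df.columns)} != declared {declared}"
        )
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise ValueError(
            f"{path}: expected columns {expected_columns}, found {list(df.columns)}"
        )
    return df


def write_genomes(
    genomes: list[GenomeRecord], outdir: str | Path
) -> tuple[list[Path], Path]:
    """One protein FASTA per genome plus the metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_paths = []
    for g in genomes:
        p = outdir / f"{g.genome_id}.faa"
        write_fasta(g.genes, p)
        fasta_paths.append(p)
    meta = pd.DataFrame(
        [
            {
                "genome_id": g.genome_id,
                "species": g.species,
                "genus": g.genus,
                "family": g.family,
                "phenotype": g.phenotype.value,
            }
            for g in genomes
        ]
    )
    meta_path = outdir / "genomes.tsv"
    write_table(meta, meta_path)
    return fasta_paths, meta_path


def read_genomes(metadata_path: str | Path, fasta_dir: str | Path) -> list[GenomeRecord]:
    meta = read_table(metadata_path, ["genome_id", "species", "genus", "family", "phenotype"])
    genomes = []
    for row in meta.itertuples(index=False):
        genes = read_fasta(Path(fasta_dir) / f"{row.genome_id}.faa", "protein")
        genomes.append(
            GenomeRecord(
                genome_id=row.genome_id,
                species=row.species,
                genus=row.genus,
                family=row.family,
                phenotype=Phenotype(row.phenotype),
                genes=genes,
            )
        )
    return genomes


def write_abundance(table, path: str | Path) -> None:
    write_table(table.data, path)


def read_abundance(path: str | Path, mode: str = "relative"):
    from .community import AbundanceTable

    return AbundanceTable(data=read_table(path), mode=mode)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_signature_families": sorted(truth.planted_signature_families),
        "genome_phenotypes": {k: v.value for k, v in truth.genome_phenotypes.items()},
        "community_spore_flags": truth.community_spore_flags,
        "gene_families": truth.gene_families,
        "family_presence": {k: sorted(v) for k, v in truth.family_presence.items()},
        "family_ancestors": truth.family_ancestors,
        "warning": truth.warning,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    obj = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_signature_families=set(obj["planted_signature_families"]),
        genome_phenotypes={
            k: Phenotype(v) for k, v in obj["genome_phenotypes"].items()
        },
        community_spore_flags=obj["community_spore_flags"],
        gene_families=obj["gene_families"],
        family_presence={k: set(v) for k, v in obj["family_presence"].items()},
        family_ancestors=obj.get("family_ancestors", {}),
        warning=obj.get("warning"),
    )
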