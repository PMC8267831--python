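"""Dataset readers and writers.

A dataset directory holds:

    metadata.tsv            strain_id, genus, species, is_type_species,
                            genus_year, environment, nacl_percent[, family]
    genomes/<sid>.fna       genome contigs (FASTA)
    genes/<sid>.ffn         CDS nucleotide sequences (FASTA)
    genes/<sid>.faa         translated proteins (FASTA)
    genes.tsv               strain_id, gene_id, marker_label
    tree.nwk                optional reference/truth tree
    traits.tsv              optional trait table
    truth.tsv, ledger.tsv   synthetic-data truth (optional)

TSV files use exact column-name matching, UTF-8, '.' decimals.  Counts
in equal counts out plus explicitly logged exclusions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (GeneRecord, StrainRecord, Thresholds,
                    check_unique_strain_ids)
from .tree import LabeledTree, read_newick_file, write_newick_file

log = logging.getLogger(__name__)


def _to_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in ("1", "true", "yes", "t")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str})
    missing = [c for c in ("strain_id", "genus", "species", "is_type_species",
                           "genus_year") if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if df["strain_id"].duplicated().any():
        dupes = sorted(df.loc[df["strain_id"].duplicated(), "strain_id"])
        raise ValueError(f"duplicate strain_id in metadata: {dupes}")
    return df


def read_dataset(metadata_file,
                 genome_files: dict[str, Path],
                 cds_files: dict[str, Path],
                 protein_files: dict[str, Path],
                 gene_table: Optional[Path] = None,
                 exclude_plasmids: bool = True) -> list[StrainRecord]:
    """Assemble StrainRecords from explicit per-strain files.

    Genome contigs whose FASTA description mentions 'plasmid' are dropped
    when ``exclude_plasmids`` is set (the exclusion is logged).
    """
    meta = read_metadata(metadata_file)
    markers: dict[tuple[str, str], Optional[str]] = {}
    if gene_table is not None:
        gt = pd.read_csv(gene_table, sep="\t", dtype=str)
        for _, row in gt.iterrows():
            label = row.get("marker_label")
            if pd.isna(label) or label in ("", "none"):
                label = None
            markers[(row["strain_id"], row["gene_id"])] = label

    records = []
    for _, row in meta.iterrows():
        sid = row["strain_id"]
        if sid not in genome_files:
            raise FileNotFoundError(f"no genome file for strain {sid!r}")
        genome = []
        for contig in SeqIO.parse(str(genome_files[sid]), "fasta"):
            if exclude_plasmids and "plasmid" in contig.description.lower():
                log.info("strain %s: excluding plasmid contig %s",
                         sid, contig.id)
                continue
            genome.append(str(contig.seq).upper())

        proteins: dict[str, str] = {}
        if sid in protein_files and Path(protein_files[sid]).exists():
            for rec in SeqIO.parse(str(protein_files[sid]), "fasta"):
                proteins[rec.id] = str(rec.seq).upper()

        genes = []
        if sid in cds_files and Path(cds_files[sid]).exists():
            for rec in SeqIO.parse(str(cds_files[sid]), "fasta"):
                nt = str(rec.seq).upper()
                label = markers.get((sid, rec.id))
                prot = proteins.get(rec.id)
                if prot is None and label != "16S":
                    if len(nt) % 3 != 0:
                        log.warning(
                            "strain %s gene %s: CDS length %d not divisible "
                            "by 3; excluded from codon-aware stages",
                            sid, rec.id, len(nt))
                        prot = None
                    else:
                        prot = str(Seq(nt).translate()).rstrip("*")
                genes.append(GeneRecord(rec.id, nt, prot, label))

        nacl = row.get("nacl_percent")
        records.append(StrainRecord(
            strain_id=sid,
            genome=genome,
            genes=genes,
            genus=str(row["genus"]),
            species=str(row["species"]),
            is_type_species=_to_bool(row["is_type_species"]),
            genus_year=int(row["genus_year"]) if pd.notna(row["genus_year"]) else None,
            environment=str(row.get("environment", "other")),
            nacl_percent=float(nacl) if pd.notna(nacl) else None,
        ))
    check_unique_strain_ids(records)
    return records


def load_dataset(root, exclude_plasmids: bool = True) -> list[StrainRecord]:
    """Read a dataset directory written by write_dataset."""
    root = Path(root)
    meta = read_metadata(root / "metadata.tsv")
    sids = list(meta["strain_id"])
    genome_files = {s: root / "genomes" / f"{s}.fna" for s in sids}
    cds_files = {s: root / "genes" / f"{s}.ffn" for s in sids}
    protein_files = {s: root / "genes" / f"{s}.faa" for s in sids}
    gene_table = root / "genes.tsv"
    return read_dataset(
        root / "metadata.tsv", genome_files, cds_files, protein_files,
        gene_table if gene_table.exists() else None,
        exclude_plasmids=exclude_plasmids,
    )


def write_dataset(records: list[StrainRecord], root,
                  tree: Optional[LabeledTree] = None,
                  traits: Optional[pd.DataFrame] = None,
                  truth: Optional[pd.DataFrame] = None,
                  ledger: Optional[pd.DataFrame] = None,
                  family_of: Optional[dict[str, str]] = None) -> Path:
    root = Path(root)
    (root / "genomes").mkdir(parents=True, exist_ok=True)
    (root / "genes").mkdir(parents=True, exist_ok=True)

    rows = []
    gene_rows = []
    for rec in records:
        rows.append({
            "strain_id": rec.strain_id,
            "genus": rec.genus,
            "species": rec.species,
            "is_type_species": rec.is_type_species,
            "genus_year": rec.genus_year,
            "environment": rec.environment,
            "nacl_percent": rec.nacl_percent,
            "family": (family_of or {}).get(rec.strain_id, ""),
        })
        SeqIO.write(
            [SeqRecord(Seq(s), id=f"{rec.strain_id}_c{i}", description="")
             for i, s in enumerate(rec.genome)],
            str(root / "genomes" / f"{rec.strain_id}.fna"), "fasta")
        SeqIO.write(
            [SeqRecord(Seq(g.nucleotide_seq), id=g.gene_id, description="")
             for g in rec.genes],
            str(root / "genes" / f"{rec.strain_id}.ffn"), "fasta")
        SeqIO.write(
            [SeqRecord(Seq(g.protein_seq), id=g.gene_id, description="")
             for g in rec.genes if g.protein_seq is not None],
            str(root / "genes" / f"{rec.strain_id}.faa"), "fasta")
        for g in rec.genes:
            gene_rows.append({
                "strain_id": rec.strain_id,
                "gene_id": g.gene_id,
                "marker_label": g.marker_label or "none",
            })

    pd.DataFrame(rows).to_csv(root / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(gene_rows).to_csv(root / "genes.tsv", sep="\t", index=False)
    if tree is not None:
        write_newick_file(tree, root / "tree.nwk")
    if traits is not None:
        traits.to_csv(root / "traits.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(root / "truth.tsv", sep="\t", index=False)
    if ledger is not None:
        ledger.to_csv(root / "ledger.tsv", sep="\t", index=False)
    return root


def load_tree(root) -> LabeledTree:
    return read_newick_file(Path(root) / "tree.nwk")


# ----------------------------------------------------------------- config

def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def thresholds_from_config(cfg: dict) -> Thresholds:
    fields = {k: v for k, v in cfg.get("thresholds", {}).items()}
    return Thresholds(**fields)


# ------------------------------------------------------------ TSV outputs

def write_metric_table(metric_records, path) -> None:
    rows = []
    for m in metric_records:
        rows.append({
            "strain_a": m.strain_a, "strain_b": m.strain_b,
            "ani": m.ani, "aai": m.aai, "dddh": m.dddh,
            "cp1": m.cp1, "cp2": m.cp2, "cp3": m.cp3,
            "pd": m.pd, "s16_identity": m.s16_identity,
            "gc_a": m.gc_a, "gc_b": m.gc_b,
        })
    columns = ["strain_a", "strain_b", "ani", "aai", "dddh", "cp1", "cp2",
               "cp3", "pd", "s16_identity", "gc_a", "gc_b"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_qc_table(reports, path) -> None:
    rows = [{
        "strain_id": r.strain_id,
        "completeness": r.completeness,
        "contamination": r.contamination,
        "passed": r.passed,
        "reason": r.reason,
    } for r in reports]
    columns = ["strain_id", "completeness", "contamination", "passed",
               "reason"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_proposals(proposals, path) -> None:
    rows = []
    for p in proposals:
        rows.append({
            "action": p.action,
            "subjects": ";".join(sorted(p.subjects)),
            "destination": p.destination or "",
            "name_changes": p.name_changes,
            "evidence": ";".join(f"{k}={v}" for k, v in sorted(p.evidence.items())),
        })
    columns = ["action", "subjects", "destination", "name_changes",
               "evidence"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
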