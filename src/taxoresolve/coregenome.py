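"""Core-gene identification and concatenated alignments.

Core = present in every kept genome, in exactly one copy.  Clustering is
greedy centroid clustering on protein identity; alignment is the built-in
progressive aligner (see align.py), with nucleotide blocks obtained by
codon-aware back-translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import align
from .model import StrainRecord

log = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.5


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[tuple[str, str]]  # (strain_id, gene_id)
    centroid: tuple[str, str]
    is_core: bool = False

    def strains(self) -> list[str]:
        return [s for s, _ in self.members]


@dataclass
class AlignedBlock:
    """One aligned core-gene: protein rows and back-translated nucleotides."""

    name: str
    protein: dict[str, str]
    nucleotide: dict[str, str]

    @property
    def protein_length(self) -> int:
        return len(next(iter(self.protein.values())))


@dataclass
class ConcatenatedAlignment:
    strain_ids: list[str]
    protein: dict[str, str]
    nucleotide: dict[str, str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)
    # partitions: (block name, start, end) in protein coordinates

    @property
    def n_columns(self) -> int:
        return len(self.protein[self.strain_ids[0]])

    def __post_init__(self) -> None:
        lengths = {len(self.protein[s]) for s in self.strain_ids}
        if len(lengths) > 1:
            raise ValueError("unequal protein row lengths")
        nt_lengths = {len(self.nucleotide[s]) for s in self.strain_ids}
        if nt_lengths != {3 * lengths.pop()}:
            raise ValueError("nucleotide length is not 3x protein length")


def _gene_lookup(records: list[StrainRecord]):
    return {(r.strain_id, g.gene_id): g for r in records for g in r.genes}


def cluster_genes(records: list[StrainRecord],
                  identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                  ) -> list[GeneCluster]:
    """Greedy centroid clustering of all CDS proteins.

    Sequences are processed in decreasing length order (ties broken
    lexicographically by (strain_id, gene_id)); each joins the earliest
    founded centroid with global protein identity >= threshold, else
    founds a new cluster.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity threshold {identity_threshold} outside (0, 1]")
    entries = []
    for rec in records:
        for gene in rec.proteome():
            entries.append((rec.strain_id, gene.gene_id, gene.protein_seq))
    entries.sort(key=lambda e: (-len(e[2]), e[0], e[1]))

    kept_strains = {r.strain_id for r in records}
    clusters: list[GeneCluster] = []
    centroid_seqs: list[str] = []
    centroid_kmers: list[frozenset] = []
    # 3-mer prescreen: at identity p, shared-3-mer containment is ~p^3,
    # while unrelated proteins sit near L^2/8000; a cutoff well below p^3
    # skips only hopeless alignments.
    prescreen = max(0.03, 0.3 * identity_threshold ** 3)
    for strain_id, gene_id, seq in entries:
        kset = align.kmer_set(seq, 3)
        placed = False
        for idx, cseq in enumerate(centroid_seqs):
            if align.kmer_containment(kset, centroid_kmers[idx]) < prescreen:
                continue
            if align.global_identity(seq, cseq, "protein") >= identity_threshold:
                clusters[idx].members.append((strain_id, gene_id))
                placed = True
                break
        if not placed:
            clusters.append(GeneCluster(
                cluster_id=f"cluster_{len(clusters):05d}",
                members=[(strain_id, gene_id)],
                centroid=(strain_id, gene_id),
            ))
            centroid_seqs.append(seq)
            centroid_kmers.append(align.kmer_set(seq, 3))

    for cluster in clusters:
        strains = cluster.strains()
        cluster.is_core = (
            set(strains) == kept_strains and len(strains) == len(kept_strains)
        )
    return clusters


def align_cluster(cluster: GeneCluster,
                  records: list[StrainRecord]) -> AlignedBlock:
    """Align one core cluster; returns protein and codon-aware nt blocks."""
    if not cluster.is_core:
        raise ValueError(f"{cluster.cluster_id} is not a core cluster")
    lookup = _gene_lookup(records)
    members = sorted(cluster.members)
    seqs = []
    usable = []
    for strain_id, gene_id in members:
        gene = lookup[(strain_id, gene_id)]
        if len(gene.nucleotide_seq) != 3 * len(gene.protein_seq):
            log.warning(
                "gene %s/%s: CDS length %d != 3 x protein length %d; "
                "excluded from codon-aware alignment",
                strain_id, gene_id, len(gene.nucleotide_seq),
                len(gene.protein_seq),
            )
            continue
        usable.append((strain_id, gene))
        seqs.append(gene.protein_seq)
    if not usable:
        raise ValueError(f"{cluster.cluster_id}: no alignable members")

    rows = align.progressive_align(seqs)
    protein: dict[str, str] = {}
    nucleotide: dict[str, str] = {}
    for (strain_id, gene), row in zip(usable, rows):
        protein[strain_id] = row
        nucleotide[strain_id] = back_translate(row, gene.nucleotide_seq)
    return AlignedBlock(cluster.cluster_id, protein, nucleotide)


def back_translate(protein_row: str, cds: str) -> str:
    """Replace each aligned residue by its source codon, gaps by '---'."""
    out = []
    pos = 0
    for ch in protein_row:
        if ch == align.GAP:
            out.append("---")
        else:
            out.append(cds[pos:pos + 3])
            pos += 3
    if pos != len(cds):
        raise ValueError("CDS length does not match ungapped protein row")
    return "".join(out)


def concatenate(blocks: list[AlignedBlock],
                strain_order: list[str]) -> ConcatenatedAlignment:
    if not blocks:
        raise ValueError("no blocks to concatenate")
    expected = set(strain_order)
    for block in blocks:
        if set(block.protein) != expected:
            raise ValueError(
                f"block {block.name}: strains do not match the requested order"
            )
    partitions = []
    offset = 0
    prot = {s: [] for s in strain_order}
    nt = {s: [] for s in strain_order}
    for block in blocks:
        length = block.protein_length
        partitions.append((block.name, offset, offset + length))
        offset += length
        for s in strain_order:
            prot[s].append(block.protein[s])
            nt[s].append(block.nucleotide[s])
    return ConcatenatedAlignment(
        strain_ids=list(strain_order),
        protein={s: "".join(v) for s, v in prot.items()},
        nucleotide={s: "".join(v) for s, v in nt.items()},
        partitions=partitions,
    )


def core_alignment(records: list[StrainRecord],
                   identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                   ) -> tuple[list[GeneCluster], ConcatenatedAlignment]:
    """Cluster, align every core cluster, and concatenate."""
    clusters = cluster_genes(records, identity_threshold)
    core = [c for c in clusters if c.is_core]
    if not core:
        raise ValueError("no core gene clusters found")
    order = sorted(r.strain_id for r in records)
    blocks = [align_cluster(c, records) for c in core]
    return clusters, concatenate(blocks, order)
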