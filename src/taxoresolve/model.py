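"""Core domain types shared by every pipeline stage.

All sequence payloads are stored uppercase.  IUPAC ambiguity codes are kept
in storage and treated as mismatches by every identity computation.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field, replace
from typing import Optional

IUPAC_NT = set("ACGTRYSWKMBDHVN")

#: Controlled vocabulary of marker labels a gene may carry.  ``qc-`` prefixed
#: labels denote completeness/contamination markers; the remainder are the
#: phenotype and rRNA markers used by the phenotype and 16S stages.
MARKER_LABELS = {
    "dmdA", "dmdB", "dmdC",
    "dddW", "dddP", "dddQ", "dddD", "dddL", "dddY",
    "luxI", "luxR",
    "16S",
}

DDD_GENES = ("dddW", "dddP", "dddQ", "dddD", "dddL", "dddY")
DMD_GENES = ("dmdA", "dmdB", "dmdC")
QS_GENES = ("luxI", "luxR")


def _valid_marker(label: Optional[str]) -> bool:
    if label is None:
        return True
    return label in MARKER_LABELS or label.startswith("qc-")


@dataclass
class GeneRecord:
    """A single annotated gene: CDS nucleotides plus translated protein.

    ``protein_seq`` is ``None`` for non-coding genes (e.g. the 16S marker).
    """

    gene_id: str
    nucleotide_seq: str
    protein_seq: Optional[str] = None
    marker_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.nucleotide_seq = self.nucleotide_seq.upper()
        if self.protein_seq is not None:
            self.protein_seq = self.protein_seq.upper()
        if not _valid_marker(self.marker_label):
            raise ValueError(
                f"gene {self.gene_id}: marker label {self.marker_label!r} "
                "not in the controlled vocabulary"
            )

    @property
    def is_cds(self) -> bool:
        return self.protein_seq is not None


@dataclass
class StrainRecord:
    """One genome with its annotations and taxonomy metadata."""

    strain_id: str
    genome: list[str] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    genus: str = ""
    species: str = ""
    is_type_species: bool = False
    genus_year: Optional[int] = None
    environment: str = "other"
    nacl_percent: Optional[float] = None

    def __post_init__(self) -> None:
        self.genome = [s.upper() for s in self.genome]
        for seq in self.genome:
            bad = set(seq) - IUPAC_NT
            if bad:
                raise ValueError(
                    f"strain {self.strain_id}: non-IUPAC nucleotide codes {sorted(bad)}"
                )
        if self.genus_year is not None and self.genus_year < 1753:
            raise ValueError(
                f"strain {self.strain_id}: genus_year {self.genus_year} predates 1753"
            )
        if self.nacl_percent is not None and not (0.0 <= self.nacl_percent <= 40.0):
            raise ValueError(
                f"strain {self.strain_id}: nacl_percent {self.nacl_percent} outside [0, 40]"
            )

    def marker_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.genes:
            if g.marker_label is not None:
                counts[g.marker_label] = counts.get(g.marker_label, 0) + 1
        return counts

    def proteome(self) -> list[GeneRecord]:
        """CDS genes usable for protein-level comparisons (16S excluded)."""
        return [g for g in self.genes if g.is_cds and g.marker_label != "16S"]

    def gene_16s(self) -> Optional[GeneRecord]:
        for g in self.genes:
            if g.marker_label == "16S":
                return g
        return None

    def copy(self) -> "StrainRecord":
        return replace(
            self,
            genome=list(self.genome),
            genes=[replace(g) for g in self.genes],
        )


@dataclass
class MetricRecord:
    """One unordered pairwise comparison.  Missing metrics are ``None``."""

    strain_a: str
    strain_b: str
    ani: Optional[float] = None
    aai: Optional[float] = None
    dddh: Optional[float] = None
    cp1: Optional[float] = None
    cp2: Optional[float] = None
    cp3: Optional[float] = None
    pd: Optional[float] = None
    s16_identity: Optional[float] = None
    gc_a: Optional[float] = None
    gc_b: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("ani", "aai", "dddh", "cp1", "cp2", "cp3", "s16_identity",
                     "gc_a", "gc_b"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.pd is not None and self.pd < 0:
            raise ValueError(f"pd={self.pd} negative")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.strain_a, self.strain_b))


@dataclass
class Thresholds:
    """All decision thresholds, with their documented defaults."""

    dddh_species: float = 70.0
    ani_species: float = 95.0
    support_collapse: float = 50.0
    completeness_min: float = 95.0
    contamination_max: float = 5.0
    nacl_high: float = 3.5
    shortlist_k: int = 10
    alpha: float = 0.05
    # Family-lineage detection.
    lineage_support: float = 95.0
    lineage_cover: float = 0.9
    # Reference-range handling for genus-level comparisons: 'minmax',
    # 'quantile' (2.5/97.5) or 'margin' (minmax widened by range_margin).
    range_mode: str = "margin"
    range_margin: float = 0.2
    range_quantiles: tuple = (0.025, 0.975)
    # Number of recorded trait differences at or above which phenotype
    # evidence argues for a separate genus.
    trait_diff_limit: int = 3

    @property
    def dddh_decay(self) -> float:
        """Decay constant of the exponential dDDH calibration curve.

        Anchored so the configured ANI and dDDH species boundaries
        coincide: f(1 - ani_species/100) = dddh_species, f(0) = 100.
        """
        divergence = max(1e-9, 1.0 - self.ani_species / 100.0)
        return math.log(100.0 / self.dddh_species) / divergence

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha outside (0, 1)")
        for name in ("dddh_species", "ani_species", "support_collapse",
                     "completeness_min", "contamination_max"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.shortlist_k < 1:
            raise ValueError("shortlist_k must be >= 1")
        if self.range_mode not in ("minmax", "quantile", "margin"):
            raise ValueError(f"unknown range_mode {self.range_mode!r}")


def check_unique_strain_ids(records: list[StrainRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.strain_id in seen:
            raise ValueError(f"duplicate strain_id {r.strain_id!r}")
        seen.add(r.strain_id)
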