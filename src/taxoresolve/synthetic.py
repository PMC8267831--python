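"""Labeled synthetic datasets with the statistical structure the analysis
assumes: a pure-birth taxonomy tree, genomes of clustered single-copy genes
diverging along it, injected label errors producing para-/polyphyly and
over-split species, and family-conditional Bernoulli traits.

Branch lengths of the emitted tree are in substitutions/site (tree time
multiplied by ``site_mutation_rate``); ``genus_depth`` and
``min_tip_branch`` are on the tree-time scale so a zero mutation rate
remains meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import DDD_GENES, DMD_GENES, GeneRecord, StrainRecord
from .tree import LabeledTree, TreeNode

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# Deterministic stop-codon repair keeps both daughter lineages in frame
# without erasing their shared history.
_STOP_FIX = {"TAA": "TAC", "TAG": "TAC", "TGA": "TGC"}

#: Family-conditional trait probabilities used by default.  Family B plays
#: the salt-adapted lineage; family A the residual one.
DEFAULT_TRAIT_PROBS = {
    "A": {"high_salt": 0.39, "cleavage": 0.37, "demethylation": 0.07,
          "qs": 0.04},
    "B": {"high_salt": 0.89, "cleavage": 0.64, "demethylation": 0.52,
          "qs": 0.56},
}

TRAITS = ("high_salt", "cleavage", "demethylation", "qs")


@dataclass
class InjectionEvent:
    kind: str  # paraphyly | polyphyly | species_split | genus_outlier
    target: Optional[str] = None  # genus (auto-chosen when None)
    detail: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("paraphyly", "polyphyly", "species_split",
                             "genus_outlier"):
            raise ValueError(f"unknown injection kind {self.kind!r}")


@dataclass
class SimulationConfig:
    n_tips: int = 120
    birth_rate: float = 1.0
    genus_depth: float = 1.0          # tree-time units
    n_genes: int = 60
    gene_length_codons: int = 250
    site_mutation_rate: float = 0.025  # substitutions/site per time unit
    accessory_gene_prob: float = 0.0
    accessory_fraction: float = 0.25  # genes eligible for loss
    trait_probs: dict = dc_field(
        default_factory=lambda: {f: dict(p)
                                 for f, p in DEFAULT_TRAIT_PROBS.items()})
    injections: list = dc_field(default_factory=list)
    seed: int = 42
    # Shape parameters.
    min_tip_branch: float = 2.0       # tree-time floor added to terminals
    family_stem: float = 2.0          # extra stem time under each family
    genus_stem: float = 1.0           # extra stem time under each genus
    codon_position_rates: tuple = (0.75, 0.5, 1.75)
    s16_rate_scale: float = 0.25
    s16_length: int = 1200
    n_qc_markers: int = 10
    with_outgroup: bool = True
    outgroup_name: str = "OUTGROUP"

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if not (0.0 <= self.accessory_gene_prob <= 1.0):
            raise ValueError("accessory_gene_prob outside [0, 1]")
        for fam, probs in self.trait_probs.items():
            for trait, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(
                        f"trait prob {fam}/{trait}={p} outside [0, 1]")


# ------------------------------------------------------------------ tree

def simulate_taxonomy_tree(config: SimulationConfig
                           ) -> tuple[LabeledTree, pd.DataFrame]:
    """Pure-birth tree with genus/species/family truth labels.

    Genera are the maximal clades whose crown age (tree-time) is at most
    ``genus_depth``; species are tips; families are the two children of
    the (ingroup) root.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_tips

    root = TreeNode()
    first, second = TreeNode(), TreeNode()
    root.children = [first, second]
    birth_time = {id(root): 0.0, id(first): 0.0, id(second): 0.0}
    active = [first, second]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (config.birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        kids = [TreeNode(), TreeNode()]
        node.children = kids
        for k in kids:
            birth_time[id(k)] = t
        active.extend(kids)
    total = t if t > 0 else 1.0

    # Terminal branches reach the present plus the species-divergence floor.
    scale = config.site_mutation_rate
    split_time: dict[int, float] = {}
    tip_counter = [0]

    def finish(node: TreeNode, parent_split: float) -> None:
        """Assign branch lengths (substitutions/site) and tip names."""
        stem = config.family_stem if node in root.children else 0.0
        if not node.children:
            tip_counter[0] += 1
            node.name = f"T{tip_counter[0]:03d}"
            node.length = (total - parent_split + config.min_tip_branch
                           + stem) * scale
            return
        my_split = birth_time[id(node.children[0])]
        split_time[id(node)] = my_split
        if node is not root:
            node.length = (my_split - parent_split + stem) * scale
        for child in node.children:
            finish(child, my_split)

    finish(root, 0.0)
    root.length = None
    tree = LabeledTree(root)

    # Genus assignment: maximal clades with crown age <= genus_depth.
    sets = tree.tipsets()
    genera: list[frozenset] = []

    def carve(node: TreeNode) -> None:
        if not node.children:
            genera.append(sets[id(node)])
            return
        crown_age = total - split_time[id(node)]
        if crown_age <= config.genus_depth:
            genera.append(sets[id(node)])
            return
        for child in node.children:
            carve(child)

    carve(root)
    if len(genera) <= 1:
        raise ValueError(
            "genus_depth groups every tip into a single genus; "
            "use a smaller cutoff")

    # Lengthen the stem above every genus crown: genera are separated by
    # more divergence than their crowns contain, as in real taxa.
    if config.genus_stem > 0:
        for node in tree.preorder():
            if sets[id(node)] in set(genera):
                node.length = (node.length or 0.0) + \
                    config.genus_stem * scale

    family_a = sets[id(root.children[0])]
    family_b = sets[id(root.children[1])]
    if len(family_a) < len(family_b):
        family_a, family_b = family_b, family_a

    rows = []
    for gi, tips in enumerate(sorted(genera, key=lambda s: sorted(s)[0])):
        genus = f"Genus{gi + 1:02d}"
        for si, tip in enumerate(sorted(tips)):
            rows.append({
                "strain_id": tip,
                "genus": genus,
                "species": f"{genus.lower()}_sp{si + 1:02d}",
                "family": "A" if tip in family_a else "B",
                "is_type_species": si == 0,
                "genus_year": 1900 + gi,
            })
    truth = pd.DataFrame(rows).sort_values("strain_id").reset_index(drop=True)

    if config.with_outgroup:
        og = TreeNode(config.outgroup_name,
                      (total + config.min_tip_branch) * scale * 0.5)
        new_root = TreeNode(children=[root, og])
        root.length = (total + config.min_tip_branch) * scale * 0.25
        tree = LabeledTree(new_root)
    return tree, truth


# --------------------------------------------------------------- genomes

def _random_cds(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    arr = _BASES[rng.integers(0, 4, size=3 * n_codons)].copy()
    return _fix_stops(arr)


def _fix_stops(arr: np.ndarray) -> np.ndarray:
    seq = arr.tobytes().decode()
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    repaired = [_STOP_FIX.get(c, c) for c in codons]
    return np.frombuffer("".join(repaired).encode(), dtype=np.uint8).copy()


def _jc_mutate(arr: np.ndarray, expected_subs: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor resampling: per-site substitution loads in ``expected_subs``."""
    q = 1.0 - np.exp(-4.0 * expected_subs / 3.0)
    hit = rng.random(arr.shape[0]) < q
    out = arr.copy()
    out[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return out


def evolve_genomes(tree: LabeledTree, config: SimulationConfig
                   ) -> list[StrainRecord]:
    """Evolve a root gene set tip-ward under JC-style substitution.

    Branch lengths are expected substitutions/site (at relative rate 1);
    codon positions evolve at ``codon_position_rates`` and the 16S-like
    gene at ``s16_rate_scale``.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_genes = config.n_genes

    genes0 = [_random_cds(rng, config.gene_length_codons)
              for _ in range(n_genes)]
    cds0 = np.concatenate(genes0)
    s16_0 = _BASES[rng.integers(0, 4, size=config.s16_length)].copy()

    pos_rates = np.tile(np.asarray(config.codon_position_rates, dtype=float),
                        cds0.shape[0] // 3)

    n_accessory = int(round(config.accessory_fraction * n_genes))
    accessory_ids = set(range(n_genes - n_accessory, n_genes))

    records: list[StrainRecord] = []

    def descend(node: TreeNode, cds: np.ndarray, s16: np.ndarray) -> None:
        length = node.length or 0.0
        if length > 0:
            cds = _fix_stops(_jc_mutate(cds, length * pos_rates, rng))
            s16 = _jc_mutate(
                s16, np.full(s16.shape[0], length * config.s16_rate_scale),
                rng)
        if node.is_leaf:
            records.append(_make_record(node.name, cds, s16, accessory_ids,
                                        config, rng))
            return
        for child in node.children:
            descend(child, cds, s16)

    descend(tree.root, cds0, s16_0)
    records.sort(key=lambda r: r.strain_id)
    return records


def _make_record(strain_id: str, cds: np.ndarray, s16: np.ndarray,
                 accessory_ids: set, config: SimulationConfig,
                 rng: np.random.Generator) -> StrainRecord:
    gene_len = 3 * config.gene_length_codons
    genes: list[GeneRecord] = []
    genome_parts: list[str] = []
    for gi in range(config.n_genes):
        if gi in accessory_ids and rng.random() < config.accessory_gene_prob:
            continue
        nt = cds[gi * gene_len:(gi + 1) * gene_len].tobytes().decode()
        label = f"qc-m{gi:03d}" if gi < config.n_qc_markers else None
        genes.append(GeneRecord(
            gene_id=f"{strain_id}_g{gi:03d}",
            nucleotide_seq=nt,
            protein_seq=str(Seq(nt).translate()),
            marker_label=label,
        ))
        genome_parts.append(nt)
    s16_seq = s16.tobytes().decode()
    genes.append(GeneRecord(
        gene_id=f"{strain_id}_16S", nucleotide_seq=s16_seq,
        protein_seq=None, marker_label="16S"))
    genome_parts.append(s16_seq)
    return StrainRecord(
        strain_id=strain_id,
        genome=["".join(genome_parts)],
        genes=genes,
    )


def apply_truth_labels(records: list[StrainRecord],
                       truth: pd.DataFrame) -> list[StrainRecord]:
    """Stamp taxonomy labels from the truth table onto the records."""
    by_id = truth.set_index("strain_id")
    out = []
    for rec in records:
        if rec.strain_id not in by_id.index:
            continue  # outgroup tips carry no taxonomy
        row = by_id.loc[rec.strain_id]
        rec.genus = row["genus"]
        rec.species = row["species"]
        rec.is_type_species = bool(row["is_type_species"])
        rec.genus_year = int(row["genus_year"])
        out.append(rec)
    return out


# ---------------------------------------------------------------- traits

def draw_traits(records: list[StrainRecord], trait_probs: dict,
                seed: int, family_of: dict[str, str],
                nacl_high: float = 3.5) -> pd.DataFrame:
    """Family-conditional Bernoulli trait draws; marker genes inserted."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        family = family_of.get(rec.strain_id)
        if family is None:
            continue
        if family not in trait_probs:
            raise ValueError(f"trait probability table missing family {family!r}")
        probs = trait_probs[family]
        draws = {t: bool(rng.random() < probs[t]) for t in TRAITS}

        inserted: list[str] = []
        if draws["demethylation"]:
            inserted.extend(DMD_GENES)
        if draws["cleavage"]:
            k = int(rng.integers(1, len(DDD_GENES) + 1))
            chosen = rng.choice(len(DDD_GENES), size=k, replace=False)
            inserted.extend(DDD_GENES[i] for i in sorted(chosen))
        if draws["qs"]:
            inserted.extend(("luxI", "luxR"))
        for label in inserted:
            nt = _random_cds(rng, 120).tobytes().decode()
            rec.genes.append(GeneRecord(
                gene_id=f"{rec.strain_id}_{label}",
                nucleotide_seq=nt,
                protein_seq=str(Seq(nt).translate()),
                marker_label=label,
            ))
            if rec.genome:
                rec.genome[0] = rec.genome[0] + nt

        if draws["high_salt"]:
            rec.nacl_percent = float(nacl_high + rng.uniform(0.0, 6.5))
            rec.environment = "marine"
        else:
            rec.nacl_percent = float(rng.uniform(0.0, nacl_high - 0.1))
            rec.environment = str(rng.choice(
                ["terrestrial", "freshwater", "other"]))

        rows.append({
            "strain_id": rec.strain_id, "family": family,
            **{t: draws[t] for t in TRAITS},
            "nacl_percent": rec.nacl_percent,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------ injections

def inject_misclassifications(records: list[StrainRecord],
                              tree: LabeledTree,
                              events: list[InjectionEvent],
                              config: SimulationConfig,
                              traits: Optional[pd.DataFrame] = None
                              ) -> pd.DataFrame:
    """Apply label/genome errors in place; returns the truth ledger.

    Each ledger row records the event, the affected tips and the expected
    resolution a correct analysis should propose.
    """
    rng = np.random.default_rng(config.seed + 2)
    used_genera: set[str] = set()
    ledger_rows = []
    for event in events:
        if event.kind == "paraphyly":
            row = _inject_paraphyly(records, tree, event, used_genera, rng,
                                    config)
        elif event.kind == "polyphyly":
            row = _inject_polyphyly(records, tree, event, used_genera, rng,
                                    config)
        elif event.kind == "species_split":
            row = _inject_species_split(records, tree, event, used_genera,
                                        rng, config, traits)
        else:
            row = _inject_genus_outlier(records, tree, event, used_genera,
                                        rng, config)
        ledger_rows.append(row)
    return pd.DataFrame(ledger_rows)


def _genus_map(records) -> dict[str, list[StrainRecord]]:
    out: dict[str, list[StrainRecord]] = {}
    for rec in records:
        out.setdefault(rec.genus, []).append(rec)
    return out


def _pick(rng, items):
    items = sorted(items)
    if not items:
        return None
    return items[int(rng.integers(len(items)))]


def _inject_paraphyly(records, tree, event, used, rng, config) -> dict:
    """Nest a freshly named one-species genus inside an existing genus.

    One member of a within-genus cherry is relabeled as a new,
    later-described genus and its genome is rewritten as a moderately
    diverged copy of its sister, so the intruder reliably re-infers
    inside the host's crown (paraphyly) while staying a distinct species.
    """
    from .phylogeny import patristic_matrix

    genera = _genus_map(records)
    by_id = {r.strain_id: r for r in records}
    scale = config.site_mutation_rate
    d_genus = 2.0 * (config.genus_depth + config.min_tip_branch) * scale

    # Prefer shallow host genera: the intruder's extra divergence plus the
    # host's crown spread must stay inside typical within-genus ranges.
    pdm, names = patristic_matrix(tree)
    index = {n: i for i, n in enumerate(names)}

    def crown_spread(genus: str) -> float:
        ids = [index[r.strain_id] for r in genera[genus]
               if r.strain_id in index]
        if len(ids) < 2:
            return 0.0
        return max(pdm[i, j] for i in ids for j in ids)

    genus_pool = sorted(
        (g for g in genera if g not in used and len(genera[g]) >= 3),
        key=lambda g: (crown_spread(g), g))
    if event.target is not None:
        if event.target in used:
            raise ValueError(f"injection collision on genus {event.target!r}")
        genus_pool = [event.target]
    for genus in genus_pool:
        tips = {r.strain_id for r in genera[genus]}
        cherry = None
        for node in tree.preorder():
            if len(node.children) == 2 and all(c.is_leaf for c in node.children):
                pair = {c.name for c in node.children}
                if pair <= tips:
                    cherry = sorted(pair)
                    break
        if cherry is None:
            continue
        anchor, moved = by_id[cherry[0]], by_id[cherry[1]]
        if moved.is_type_species:
            anchor, moved = moved, anchor
        if moved.is_type_species:
            continue  # both tips anchor names; pick another genus
        # Above the species boundary, but inside typical within-genus
        # divergence even when added to the host's crown spread.
        _overwrite_as_near_copy(anchor, moved, rng,
                                divergence=0.5 * d_genus, config=config)
        new_genus = f"Novo{genus}"
        year = max(r.genus_year or 1900 for r in genera[genus]) + 50
        moved.genus = new_genus
        moved.genus_year = year
        moved.is_type_species = True
        used.add(genus)
        used.add(new_genus)
        return {
            "kind": "paraphyly", "target_genus": genus,
            "subjects": moved.strain_id,
            "expected_action": "merge_genus",
            "expected_destination": genus,
        }
    raise ValueError("no eligible genus for a paraphyly injection")


def _inject_polyphyly(records, tree, event, used, rng, config) -> dict:
    """Relabel a singleton genus as a distant member of another genus.

    The donor keeps its tree position (so the target genus becomes
    polyphyletic) and its genome receives extra divergence so every
    metric against its neighbors is unambiguously between-genus and the
    correct resolution is a fresh genus.
    """
    genera = _genus_map(records)
    sets = tree.tipsets()
    scale = config.site_mutation_rate
    d_genus = 2.0 * (config.genus_depth + config.min_tip_branch) * scale

    donor_pool = [g for g in sorted(genera)
                  if g not in used and len(genera[g]) == 1]
    target_pool = [g for g in sorted(genera)
                   if g not in used and len(genera[g]) >= 2]
    if event.target is not None:
        target_pool = [event.target]

    # Prefer donors from the other side of the root: maximal separation.
    root_sides = [sets[id(c)] for c in tree.root.children]

    for target in target_pool:
        t_tips = frozenset(r.strain_id for r in genera[target])
        t_side = next((s for s in root_sides if t_tips & s), frozenset())
        ordered = sorted(donor_pool, key=lambda g: (
            genera[g][0].strain_id in t_side, g))
        for donor in ordered:
            if donor == target:
                continue
            rec = genera[donor][0]
            joint = t_tips | {rec.strain_id}
            mrca_tips = sets[id(tree.mrca(joint))]
            intruders = mrca_tips - joint
            if not intruders:
                continue
            # The relabeling must yield polyphyly, not mere paraphyly:
            # the intruders' own MRCA has to reach back into the group.
            intruder_mrca = sets[id(tree.mrca(intruders))]
            if not (intruder_mrca & joint):
                continue
            _overwrite_as_near_copy(rec, rec, rng,
                                    divergence=1.2 * d_genus, config=config)
            old_genus = rec.genus
            rec.genus = target
            rec.genus_year = genera[target][0].genus_year
            rec.is_type_species = False
            used.add(target)
            used.add(old_genus)
            return {
                "kind": "polyphyly", "target_genus": target,
                "subjects": rec.strain_id,
                "expected_action": "new_genus",
                "expected_destination": "",
            }
    raise ValueError("no eligible donor/target pair for a polyphyly injection")


def _inject_species_split(records, tree, event, used, rng, config,
                          traits) -> dict:
    genera = _genus_map(records)
    by_id = {r.strain_id: r for r in records}

    pool = [g for g in sorted(genera) if g not in used and len(genera[g]) >= 2]
    if event.target is not None:
        pool = [event.target]
    for genus in pool:
        tips = {r.strain_id for r in genera[genus]}
        cherry = None
        for node in tree.preorder():
            if len(node.children) == 2 and all(c.is_leaf for c in node.children):
                pair = {c.name for c in node.children}
                if pair <= tips:
                    cherry = sorted(pair)
                    break
        if cherry is None:
            continue
        a, b = by_id[cherry[0]], by_id[cherry[1]]
        _overwrite_as_near_copy(a, b, rng, divergence=0.01, config=config)
        if traits is not None and not traits.empty:
            ta = traits["strain_id"] == a.strain_id
            tb = traits["strain_id"] == b.strain_id
            if ta.any() and tb.any():
                for trait in TRAITS:
                    traits.loc[tb, trait] = traits.loc[ta, trait].iloc[0]
        b.nacl_percent = a.nacl_percent
        b.environment = a.environment
        used.add(genus)
        return {
            "kind": "species_split", "target_genus": genus,
            "subjects": ";".join(cherry),
            "expected_action": "merge_species",
            "expected_destination": a.species,
        }
    raise ValueError("no eligible cherry for a species_split injection")


def _overwrite_as_near_copy(src: StrainRecord, dst: StrainRecord,
                            rng, divergence: float,
                            config: Optional[SimulationConfig] = None) -> None:
    """Make dst a mutated copy of src (labels unchanged).

    Mutation loads follow the generator's codon-position rates (and the
    16S rate scale) so the copy is indistinguishable from naturally
    evolved divergence.
    """
    new_genes = []
    parts = []
    for gene in src.genes:
        arr = np.frombuffer(gene.nucleotide_seq.encode(), dtype=np.uint8)
        if gene.marker_label == "16S":
            loads = np.full(arr.shape[0], divergence * (
                config.s16_rate_scale if config else 1.0))
        elif gene.is_cds and config is not None:
            loads = divergence * np.tile(
                np.asarray(config.codon_position_rates, dtype=float),
                arr.shape[0] // 3)
        else:
            loads = np.full(arr.shape[0], divergence)
        mutated = _jc_mutate(arr, loads, rng)
        if gene.is_cds:
            mutated = _fix_stops(mutated)
        nt = mutated.tobytes().decode()
        gene_id = gene.gene_id.replace(src.strain_id, dst.strain_id, 1)
        prot = str(Seq(nt).translate()) if gene.is_cds else None
        new_genes.append(GeneRecord(gene_id, nt, prot, gene.marker_label))
        parts.append(nt)
    dst.genes = new_genes
    dst.genome = ["".join(parts)]


def _inject_genus_outlier(records, tree, event, used, rng, config) -> dict:
    """Turn a singleton-genus strain into a false member of another genus.

    The donor's genome is rewritten as a heavily mutated copy of the
    target genus's type strain, so the inferred tree keeps the expanded
    genus monophyletic while every pairwise metric against it sits at
    between-genus levels.
    """
    genera = _genus_map(records)
    scale = config.site_mutation_rate
    d_genus = 2.0 * (config.genus_depth + config.min_tip_branch) * scale

    target_pool = [g for g in sorted(genera)
                   if g not in used and len(genera[g]) >= 1]
    if event.target is not None:
        target_pool = [event.target]
    donor_pool = [g for g in sorted(genera)
                  if g not in used and len(genera[g]) == 1]
    for genus in target_pool:
        anchor = next((r for r in sorted(genera[genus],
                                         key=lambda r: r.strain_id)
                       if r.is_type_species), None)
        if anchor is None:
            continue
        for donor in donor_pool:
            if donor == genus:
                continue
            rec = genera[donor][0]
            _overwrite_as_near_copy(anchor, rec, rng,
                                    divergence=1.6 * d_genus, config=config)
            old_genus = rec.genus
            rec.genus = genus
            rec.genus_year = anchor.genus_year
            rec.is_type_species = False
            used.add(genus)
            used.add(old_genus)
            return {
                "kind": "genus_outlier", "target_genus": genus,
                "subjects": rec.strain_id,
                "expected_action": "new_genus",
                "expected_destination": "",
            }
    raise ValueError("no eligible donor for a genus_outlier injection")


# ------------------------------------------------------------- generator

def generate_dataset(config: SimulationConfig
                     ) -> tuple[list[StrainRecord], LabeledTree,
                                pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full synthetic dataset: records, truth tree, truth table, traits,
    injection ledger (empty when no injections are configured)."""
    tree, truth = simulate_taxonomy_tree(config)
    records = evolve_genomes(tree, config)
    family_of = dict(zip(truth["strain_id"], truth["family"]))
    labeled = apply_truth_labels(
        [r for r in records if r.strain_id != config.outgroup_name], truth)
    outgroup = [r for r in records if r.strain_id == config.outgroup_name]
    traits = draw_traits(labeled, config.trait_probs, config.seed + 3,
                         family_of)
    if config.injections:
        ingroup_tree = tree.prune([config.outgroup_name]) \
            if config.with_outgroup else tree
        ledger = inject_misclassifications(
            labeled, ingroup_tree, list(config.injections), config, traits)
    else:
        ledger = pd.DataFrame(columns=[
            "kind", "target_genus", "subjects", "expected_action",
            "expected_destination"])
    for rec in outgroup:
        rec.genus = "Outgroup"
        rec.species = "outgroup_sp"
        rec.genus_year = 1850
    return labeled + outgroup, tree, truth, traits, ledger
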