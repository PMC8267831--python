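"""End-to-end orchestration: QC -> core genome -> tree -> metrics ->
phyly -> decision rules -> phenotype contrasts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import coregenome, metrics as metrics_mod, phenotype, phylogeny, qc
from .decisions import (MetricLookup, Proposal, ReferenceDistributions,
                        family_split_test, genus_outlier_scan,
                        resolve_paraphyly, resolve_polyphyly,
                        species_decision)
from .model import MetricRecord, StrainRecord, Thresholds
from .phyly import PhylyReport, classify_genera, two_major_lineages
from .tree import LabeledTree

log = logging.getLogger(__name__)

#: Actions that revise existing names (the clean-null property counts
#: these; a family split on genuinely structured data is a discovery, not
#: a misclassification fix).
RECLASSIFICATION_ACTIONS = ("merge_species", "demote_to_subspecies",
                            "transfer_species", "new_genus", "merge_genus",
                            "flag_inconclusive")


@dataclass
class PipelineResult:
    kept: list[StrainRecord]
    qc_excluded: list
    clusters: list
    alignment: Optional[coregenome.ConcatenatedAlignment]
    tree: Optional[LabeledTree]            # rooted, uncollapsed, no outgroup
    tree_collapsed: Optional[LabeledTree]  # support-collapsed
    metrics: Optional[MetricLookup]
    phyly: dict[str, PhylyReport] = field(default_factory=dict)
    reference: Optional[ReferenceDistributions] = None
    proposals: list[Proposal] = field(default_factory=list)
    family_proposal: Optional[Proposal] = None
    lineages: Optional[tuple] = None
    trait_contrast: Optional[pd.DataFrame] = None

    def reclassification_proposals(self) -> list[Proposal]:
        return [p for p in self.proposals
                if p.action in RECLASSIFICATION_ACTIONS]


def run_pipeline(records: list[StrainRecord],
                 thresholds: Optional[Thresholds] = None,
                 outgroup: Optional[set] = None,
                 traits: Optional[pd.DataFrame] = None,
                 n_bootstrap: int = 100,
                 seed: int = 42,
                 external_tree: Optional[LabeledTree] = None,
                 run_family_test: bool = True,
                 cluster_identity: float = coregenome.DEFAULT_IDENTITY_THRESHOLD
                 ) -> PipelineResult:
    """Run the full analysis over a dataset.

    ``outgroup`` names the rooting strains (required unless an already
    rooted ``external_tree`` is supplied); ANI/dDDH are computed only for
    same-genus pairs inside a shared pure clade, mirroring the species
    workflow.
    """
    thresholds = thresholds or Thresholds()
    outgroup = set(outgroup or ())

    ingroup = [r for r in records if r.strain_id not in outgroup]
    marker_set = sorted({g.marker_label for r in ingroup for g in r.genes
                         if g.marker_label and g.marker_label.startswith("qc-")})
    if marker_set:
        kept, excluded = qc.filter_dataset(ingroup, marker_set, thresholds)
    else:
        kept, excluded = list(ingroup), []
    if len(kept) < 4:
        raise ValueError("fewer than 4 strains pass QC")

    tree_input = kept + [r for r in records if r.strain_id in outgroup]

    clusters, alignment = coregenome.core_alignment(tree_input,
                                                    cluster_identity)

    if external_tree is not None:
        rooted = external_tree
        collapsed = phylogeny.collapse_low_support(
            rooted, thresholds.support_collapse)
    else:
        if not outgroup:
            raise ValueError("an outgroup (or external rooted tree) is required")
        boot = phylogeny.bootstrap_support(
            alignment, n_replicates=n_bootstrap, seed=seed)
        rooted = phylogeny.root_with_outgroup(boot, outgroup)
        collapsed = phylogeny.collapse_low_support(
            rooted, thresholds.support_collapse)
        rooted = rooted.prune(outgroup)
        collapsed = collapsed.prune(outgroup)

    genus_of = {r.strain_id: r.genus for r in kept}
    type_tips = {r.genus: r.strain_id for r in kept if r.is_type_species}
    reports = classify_genera(collapsed, genus_of, type_tips)

    pd_matrix, pd_names = phylogeny.patristic_matrix(rooted)
    pd_index = {n: i for i, n in enumerate(pd_names)}

    # ANI/dDDH are only decisive for same-genus sister pairs (the species
    # rule requires monophyly of the pair), so the costly fragment engine
    # runs on those alone.
    sister_pairs: set[frozenset] = set()
    sets = collapsed.tipsets()
    for node in collapsed.preorder():
        leaves = [c for c in node.children if c.is_leaf]
        if len(node.children) == 2 and len(leaves) == 2:
            a, b = leaves[0].name, leaves[1].name
            if genus_of.get(a) == genus_of.get(b):
                sister_pairs.add(frozenset((a, b)))
    del sets

    by_id = {r.strain_id: r for r in kept}
    sids = sorted(by_id)
    metric_records: list[MetricRecord] = []
    for i in range(len(sids)):
        for j in range(i + 1, len(sids)):
            a, b = by_id[sids[i]], by_id[sids[j]]
            with_ani = frozenset((a.strain_id, b.strain_id)) in sister_pairs
            cp1, cp2, cp3 = metrics_mod.codon_position_similarity(
                alignment, a.strain_id, b.strain_id)
            metric_records.append(MetricRecord(
                strain_a=a.strain_id, strain_b=b.strain_id,
                ani=metrics_mod.ani(a, b) if with_ani else None,
                dddh=metrics_mod.ddd_hybridization(
                    a, b, decay=thresholds.dddh_decay) if with_ani else None,
                aai=metrics_mod.aai(a, b),
                cp1=cp1, cp2=cp2, cp3=cp3,
                pd=float(pd_matrix[pd_index[a.strain_id],
                                   pd_index[b.strain_id]]),
            ))
    lookup = MetricLookup(metric_records)

    reference = ReferenceDistributions.build(lookup, genus_of, reports)

    proposals: list[Proposal] = []

    # --- species level: same-genus pairs within one pure clade
    for genus, report in sorted(reports.items()):
        for clade in report.pure_clades:
            members = sorted(clade)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = by_id[members[i]], by_id[members[j]]
                    rec = lookup.get(a.strain_id, b.strain_id)
                    if rec is None or rec.ani is None:
                        continue
                    prop = species_decision(a, b, rec, collapsed,
                                            thresholds, traits)
                    if prop is not None:
                        proposals.append(prop)

    # --- genus level: outlier scan over monophyletic genera
    has_reference = (reference.within["aai"].size > 0
                     and reference.within["pd"].size > 0)
    if has_reference:
        for genus, report in sorted(reports.items()):
            if report.status != "monophyletic":
                continue
            members = [by_id[t] for t in report.tips if t in by_id]
            if len(members) < 2:
                continue
            proposals.extend(genus_outlier_scan(
                genus, members, lookup, reference, thresholds))

    # --- paraphyletic complexes
    genus_year = {r.genus: r.genus_year or 9999 for r in kept}
    seen_complexes: set[frozenset] = set()
    for genus, report in sorted(reports.items()):
        if report.status != "paraphyletic":
            continue
        clade_tips = report.mrca_tips
        genera_in_clade = sorted({genus_of[t] for t in clade_tips
                                  if t in genus_of})
        key = frozenset(genera_in_clade)
        if key in seen_complexes or len(genera_in_clade) < 2:
            continue
        seen_complexes.add(key)
        if not has_reference:
            continue
        tips_by_genus = {
            g: frozenset(t for t in clade_tips if genus_of.get(t) == g)
            for g in genera_in_clade
        }
        # Only resolve self-contained complexes: a genus reaching outside
        # the clade is somebody else's (polyphyly) problem.
        all_tips_of = {g: {t for t, gg in genus_of.items() if gg == g}
                       for g in genera_in_clade}
        if any(all_tips_of[g] - set(tips_by_genus[g])
               for g in genera_in_clade):
            log.info("paraphyletic complex %s not self-contained; skipped",
                     ",".join(genera_in_clade))
            continue
        proposals.extend(resolve_paraphyly(
            tips_by_genus, lookup, reference, genus_year, thresholds))

    # --- polyphyletic genera
    for genus, report in sorted(reports.items()):
        if report.status != "polyphyletic":
            continue
        if report.primary_clade_index is None:
            log.warning("polyphyletic genus %s has no located type species",
                        genus)
            continue
        if not has_reference:
            continue
        proposals.extend(resolve_polyphyly(
            report, genus, by_id, lookup, reference, reports, genus_of,
            thresholds, traits))

    # --- family level
    family_proposal = None
    lineages = None
    trait_contrast = None
    if run_family_test:
        try:
            lineages = two_major_lineages(
                collapsed, thresholds.lineage_support, thresholds.lineage_cover)
        except ValueError as exc:
            log.info("no family bipartition: %s", exc)
        if lineages is not None:
            try:
                family_proposal = family_split_test(
                    lineages[0], lineages[1], lookup, thresholds)
            except ValueError as exc:
                log.info("family split test not applicable: %s", exc)
            family_of = {}
            for tip in lineages[0]:
                family_of[tip] = "lineage_1"
            for tip in lineages[1]:
                family_of[tip] = "lineage_2"
            profiles = [phenotype.call_pathways(r, thresholds.nacl_high)
                        for r in kept if r.strain_id in family_of]
            try:
                trait_contrast = phenotype.family_trait_contrast(
                    profiles, family_of, thresholds.alpha)
            except ValueError:
                trait_contrast = None

    return PipelineResult(
        kept=kept,
        qc_excluded=excluded,
        clusters=clusters,
        alignment=alignment,
        tree=rooted,
        tree_collapsed=collapsed,
        metrics=lookup,
        phyly=reports,
        reference=reference,
        proposals=proposals,
        family_proposal=family_proposal,
        lineages=lineages,
        trait_contrast=trait_contrast,
    )
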