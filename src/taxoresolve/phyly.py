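"""Mono-/para-/polyphyly classification of label groups on a rooted tree.

Operational rule: given a group of tips, compute the MRCA; the intruders
are the MRCA's tips outside the group.  No intruders = monophyletic.
Intruders forming their own clade free of group tips = paraphyletic.
Anything else = polyphyletic.  This boundary between para- and polyphyly
is a convention (alternatives exist); it reproduces the verbal usage this
package's decision rules were built for: paraphyletic groups sit in one
tree region with a nested foreign clade, polyphyletic groups are split
across the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .tree import LabeledTree


@dataclass
class PhylyReport:
    group: str
    status: str  # monophyletic | paraphyletic | polyphyletic
    mrca_tips: frozenset
    intruders: frozenset
    pure_clades: list[frozenset] = field(default_factory=list)
    primary_clade_index: Optional[int] = None

    @property
    def tips(self) -> frozenset:
        return self.mrca_tips - self.intruders


def classify_group(tree: LabeledTree, group, name: str = "") -> PhylyReport:
    """Classify one tip set; see the module docstring for the rule."""
    group = frozenset(group)
    if not group:
        raise ValueError("empty group")
    all_tips = frozenset(tree.tip_names())
    missing = group - all_tips
    if missing:
        raise ValueError(f"unknown tips: {sorted(missing)}")

    sets = tree.tipsets()
    parents = tree.parent_map()
    mrca = tree.mrca(group)
    mrca_tips = sets[id(mrca)]
    intruders = mrca_tips - group

    if not intruders:
        status = "monophyletic"
    else:
        intruder_mrca_tips = sets[id(tree.mrca(intruders))]
        if intruder_mrca_tips & group:
            status = "polyphyletic"
        else:
            status = "paraphyletic"

    # Maximal subtrees whose tips all belong to the group, in preorder.
    pure: list[frozenset] = []
    for node in tree.preorder():
        s = sets[id(node)]
        if not (s <= group):
            continue
        parent = parents[id(node)]
        if parent is not None and sets[id(parent)] <= group:
            continue
        pure.append(s)

    return PhylyReport(
        group=name or ",".join(sorted(group)),
        status=status,
        mrca_tips=mrca_tips,
        intruders=frozenset(intruders),
        pure_clades=pure,
    )


def find_primary_clade(report: PhylyReport, type_species_tip: str) -> int:
    """Index of the pure clade containing the group's type species."""
    for i, clade in enumerate(report.pure_clades):
        if type_species_tip in clade:
            return i
    raise ValueError(
        f"type species tip {type_species_tip!r} not in any pure clade of "
        f"group {report.group!r}"
    )


def classify_genera(tree: LabeledTree, genus_of: dict[str, str],
                    type_tips: Optional[dict[str, str]] = None
                    ) -> dict[str, PhylyReport]:
    """PhylyReport per genus; type-species tips set the primary clade."""
    groups: dict[str, set] = {}
    for tip, genus in genus_of.items():
        groups.setdefault(genus, set()).add(tip)
    present = set(tree.tip_names())
    reports = {}
    for genus in sorted(groups):
        tips = {t for t in groups[genus] if t in present}
        if not tips:
            continue
        report = classify_group(tree, tips, name=genus)
        if type_tips and genus in type_tips and type_tips[genus] in tips:
            report.primary_clade_index = find_primary_clade(
                report, type_tips[genus])
        reports[genus] = report
    return reports


def two_major_lineages(tree: LabeledTree,
                       min_support: float = 95.0,
                       min_cover: float = 0.9
                       ) -> tuple[frozenset, frozenset, frozenset]:
    """The two largest disjoint well-supported clades covering the tree.

    Nodes without a support value (e.g. the root's children after
    outgroup rooting) are treated as fully supported.  Tips outside both
    lineages are returned as unassigned.
    """
    all_tips = frozenset(tree.tip_names())
    sets = tree.tipsets()
    candidates = []
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        if node.support is not None and node.support < min_support:
            continue
        candidates.append(sets[id(node)])
    candidates.sort(key=lambda s: (-len(s), sorted(s)))

    best: Optional[tuple[frozenset, frozenset]] = None
    best_cover = -1
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            if a & b:
                continue
            cover = len(a | b)
            if cover >= min_cover * len(all_tips) and cover > best_cover:
                best, best_cover = (a, b), cover
    if best is None:
        raise ValueError(
            "no pair of well-supported disjoint clades covers the tree; "
            "assign lineages manually"
        )
    a, b = best
    if len(b) > len(a):
        a, b = b, a
    return a, b, all_tips - a - b
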