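"""Species-, genus-, and family-level decision rules.

The genus-level rules compare candidate pairs against reference
distributions of AAI, PD and codon-position similarities built from
recognized monophyletic genera only.  "Within the expected range" is
formalized as falling inside the within-genus reference interval; the
interval mode is configurable (raw min/max, central quantiles, or min/max
widened by a margin — the default, since raw extremes are sample-size
sensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import MetricRecord, StrainRecord, Thresholds
from .phyly import PhylyReport
from .stats import mann_whitney_u
from .tree import LabeledTree

log = logging.getLogger(__name__)

GENUS_METRICS = ("aai", "pd", "cp1", "cp2", "cp3")
#: Metrics where larger = more similar; PD is the opposite.
SIMILARITY_METRICS = ("aai", "cp1", "cp2", "cp3")

ACTIONS = ("merge_species", "demote_to_subspecies", "transfer_species",
           "new_genus", "merge_genus", "split_family", "flag_inconclusive")


@dataclass
class Proposal:
    action: str
    subjects: list[str]
    destination: Optional[str] = None
    name_changes: int = 0
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if not self.evidence:
            raise ValueError("a proposal requires at least one evidence item")
        if self.action != "flag_inconclusive" and self.name_changes < 1:
            raise ValueError("non-flag proposals entail >= 1 name change")


class MetricLookup:
    """Pair-indexed access to MetricRecords."""

    def __init__(self, records: list[MetricRecord]):
        self._by_pair = {r.pair: r for r in records}

    def get(self, a: str, b: str) -> Optional[MetricRecord]:
        return self._by_pair.get(frozenset((a, b)))

    def records(self) -> list[MetricRecord]:
        return list(self._by_pair.values())


@dataclass
class ReferenceDistributions:
    """Within/between-genus metric values over monophyletic genera."""

    within: dict[str, np.ndarray]
    between: dict[str, np.ndarray]
    within_genus: dict[str, list[str]]  # metric -> genus label per value

    @classmethod
    def build(cls, metrics: MetricLookup, genus_of: dict[str, str],
              reports: dict[str, PhylyReport],
              trim_atypical: bool = True) -> "ReferenceDistributions":
        mono = {g for g, r in reports.items() if r.status == "monophyletic"}
        within_recs = []
        between = {m: [] for m in GENUS_METRICS}
        for rec in metrics.records():
            ga = genus_of.get(rec.strain_a)
            gb = genus_of.get(rec.strain_b)
            if ga is None or gb is None or ga not in mono or gb not in mono:
                continue
            if ga == gb:
                within_recs.append((ga, rec))
            else:
                for m in GENUS_METRICS:
                    v = getattr(rec, m)
                    if v is not None:
                        between[m].append(v)

        # Atypical within-genus pairs (PD far beyond the bulk) are dropped
        # wholesale: a handful of known-aberrant pairs would otherwise
        # stretch the expected range and mask real discordance.
        if trim_atypical and len(within_recs) >= 8:
            pds = np.asarray([r.pd for _, r in within_recs if r.pd is not None])
            if pds.size >= 8:
                q1, q3 = np.quantile(pds, (0.25, 0.75))
                fence = q3 + 2.0 * (q3 - q1)
                kept = []
                for g, rec in within_recs:
                    if rec.pd is not None and rec.pd > fence:
                        log.info("reference: dropping atypical within-genus "
                                 "pair %s/%s (PD %.3f > %.3f)",
                                 rec.strain_a, rec.strain_b, rec.pd, fence)
                        continue
                    kept.append((g, rec))
                if kept:
                    within_recs = kept

        within = {m: [] for m in GENUS_METRICS}
        wg = {m: [] for m in GENUS_METRICS}
        for g, rec in within_recs:
            for m in GENUS_METRICS:
                v = getattr(rec, m)
                if v is not None:
                    within[m].append(v)
                    wg[m].append(g)
        return cls(
            within={m: np.asarray(v, float) for m, v in within.items()},
            between={m: np.asarray(v, float) for m, v in between.items()},
            within_genus=wg,
        )

    def within_values(self, metric: str,
                      exclude_genus: Optional[str] = None) -> np.ndarray:
        vals = self.within[metric]
        if exclude_genus is None:
            return vals
        mask = np.asarray(
            [g != exclude_genus for g in self.within_genus[metric]])
        return vals[mask] if len(vals) else vals

    def bounds(self, metric: str, thresholds: Thresholds,
               exclude_genus: Optional[str] = None
               ) -> tuple[float, float]:
        vals = self.within_values(metric, exclude_genus)
        if vals.size == 0 and exclude_genus is not None:
            vals = self.within_values(metric)  # leave-out emptied the pool
        if vals.size == 0:
            raise ValueError(
                f"empty within-genus reference for metric {metric!r}")
        if thresholds.range_mode == "quantile":
            lo, hi = np.quantile(vals, thresholds.range_quantiles)
        else:
            lo, hi = float(vals.min()), float(vals.max())
            if thresholds.range_mode == "margin":
                # Widen by a fraction of the within/between separation, so
                # the tolerance tracks how far apart the two distributions
                # actually sit rather than the within spread alone.
                btw = self.between.get(metric, np.empty(0))
                if btw.size:
                    sep = abs(float(np.median(btw)) - float(np.median(vals)))
                else:
                    sep = hi - lo
                pad = thresholds.range_margin * max(sep, hi - lo, 1e-9)
                lo -= pad
                hi += pad
        return float(lo), float(hi)

    def is_between_like(self, metric: str, value: float,
                        thresholds: Thresholds,
                        exclude_genus: Optional[str] = None) -> bool:
        """True when the value falls on the between-genus side of the
        within-genus reference interval."""
        lo, hi = self.bounds(metric, thresholds, exclude_genus)
        if metric in SIMILARITY_METRICS:
            return value < lo
        return value > hi

    def is_within_range(self, metric: str, value: float,
                        thresholds: Thresholds,
                        exclude_genus: Optional[str] = None) -> bool:
        lo, hi = self.bounds(metric, thresholds, exclude_genus)
        return lo <= value <= hi


# ------------------------------------------------------------- utilities

def _are_sisters(tree: LabeledTree, a: str, b: str) -> bool:
    sets = tree.tipsets()
    return sets[id(tree.mrca({a, b}))] == frozenset((a, b))


def trait_difference_count(traits, a: str, b: str) -> Optional[int]:
    """Number of recorded traits on which two strains differ."""
    if traits is None or getattr(traits, "empty", True):
        return None
    ra = traits[traits["strain_id"] == a]
    rb = traits[traits["strain_id"] == b]
    if ra.empty or rb.empty:
        return None
    count = 0
    for col in traits.columns:
        if col in ("strain_id", "family", "nacl_percent"):
            continue
        if bool(ra.iloc[0][col]) != bool(rb.iloc[0][col]):
            count += 1
    return count


def _group_trait_difference(traits, tips_a, tips_b) -> Optional[int]:
    """Trait differences between the majority profiles of two tip groups."""
    if traits is None or getattr(traits, "empty", True):
        return None
    cols = [c for c in traits.columns
            if c not in ("strain_id", "family", "nacl_percent")]

    def majority(tips):
        sub = traits[traits["strain_id"].isin(list(tips))]
        if sub.empty:
            return None
        return {c: bool(sub[c].astype(bool).mean() >= 0.5) for c in cols}

    ma, mb = majority(tips_a), majority(tips_b)
    if ma is None or mb is None:
        return None
    return sum(1 for c in cols if ma[c] != mb[c])


# -------------------------------------------------------- species level

def species_decision(rec_a: StrainRecord, rec_b: StrainRecord,
                     metric: Optional[MetricRecord], tree: LabeledTree,
                     thresholds: Thresholds,
                     traits=None) -> Optional[Proposal]:
    """Same-species call: dDDH and ANI thresholds plus tree monophyly.

    Both thresholds must be met AND the pair must be sisters in the tree;
    recorded phenotype differences turn a merge into a subspecies
    demotion.
    """
    if metric is None or metric.dddh is None or metric.ani is None:
        return Proposal(
            action="flag_inconclusive",
            subjects=sorted((rec_a.strain_id, rec_b.strain_id)),
            evidence={"reason": "missing dDDH or ANI"},
        )
    if metric.dddh < thresholds.dddh_species or metric.ani < thresholds.ani_species:
        return None
    if not _are_sisters(tree, rec_a.strain_id, rec_b.strain_id):
        return None
    # The earlier-described name wins; species year is not tracked, so the
    # type species (then alphabetical order) stands in for priority.
    if rec_a.is_type_species or (not rec_b.is_type_species
                                 and rec_a.species <= rec_b.species):
        keeper, other = rec_a, rec_b
    else:
        keeper, other = rec_b, rec_a
    diff = trait_difference_count(traits, rec_a.strain_id, rec_b.strain_id)
    action = "demote_to_subspecies" if diff else "merge_species"
    return Proposal(
        action=action,
        subjects=sorted((rec_a.strain_id, rec_b.strain_id)),
        destination=keeper.species,
        name_changes=1,
        evidence={"dddh": metric.dddh, "ani": metric.ani,
                  "trait_differences": diff,
                  "monophyletic_pair": True},
    )


# ---------------------------------------------------------- genus level

def genus_outlier_scan(genus: str, members: list[StrainRecord],
                       metrics: MetricLookup, ref: ReferenceDistributions,
                       thresholds: Thresholds) -> list[Proposal]:
    """Detect members of a monophyletic genus with between-genus metrics.

    A pair is fully discordant when all five metrics sit on the
    between-genus side of the within-genus reference range; a member all
    of whose pairs are fully discordant is proposed as a new genus.
    Partially discordant pairs (>= 2 of 5 metrics) are flagged.
    """
    if all(v.size == 0 for v in ref.within.values()):
        raise ValueError("empty reference distributions")
    if len(members) < 2:
        return []
    members = sorted(members, key=lambda r: r.strain_id)
    # Inconclusive flags use a doubled margin so marginal excursions of
    # clean deep pairs do not raise alarms; candidate outliers still use
    # the standard bound for all-five discordance.
    from dataclasses import replace as dc_replace
    strict = dc_replace(thresholds, range_margin=2 * thresholds.range_margin)
    n_out: dict[tuple[str, str], int] = {}
    n_strict: dict[tuple[str, str], int] = {}
    values: dict[tuple[str, str], dict] = {}
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            rec = metrics.get(a.strain_id, b.strain_id)
            if rec is None:
                continue
            key = (a.strain_id, b.strain_id)
            count = strict_count = 0
            vals = {}
            for m in GENUS_METRICS:
                v = getattr(rec, m)
                if v is None:
                    continue
                vals[m] = v
                if ref.is_between_like(m, v, thresholds, exclude_genus=genus):
                    count += 1
                if ref.is_between_like(m, v, strict, exclude_genus=genus):
                    strict_count += 1
            n_out[key] = count
            n_strict[key] = strict_count
            values[key] = vals

    proposals: list[Proposal] = []
    flagged_strains = set()
    for rec in members:
        sid = rec.strain_id
        pairs = [k for k in n_out if sid in k]
        if not pairs:
            continue
        if all(n_out[k] == len(GENUS_METRICS) for k in pairs):
            if rec.is_type_species:
                continue  # the type anchors the name; its partner moves
            # An outlier is an outlier only against a coherent genus: for
            # genera of three or more, the remaining members must share at
            # least one concordant pair (otherwise the whole genus is just
            # deep, which is not a misclassification pattern).
            rest_pairs = [k for k in n_out if sid not in k]
            if rest_pairs and all(n_out[k] == len(GENUS_METRICS)
                                  for k in rest_pairs):
                log.info("genus %s: uniformly discordant; %s not treated "
                         "as an outlier", genus, sid)
                continue
            example = values[pairs[0]]
            proposals.append(Proposal(
                action="new_genus",
                subjects=[sid],
                destination=f"NovelGenus_{sid}",
                name_changes=1,
                evidence={"genus": genus, **example,
                          "discordant_metrics": len(GENUS_METRICS)},
            ))
            flagged_strains.add(sid)
    for key, count in sorted(n_out.items()):
        if (n_strict[key] >= 2 and count < len(GENUS_METRICS)
                and not (set(key) & flagged_strains)):
            proposals.append(Proposal(
                action="flag_inconclusive",
                subjects=list(key),
                evidence={"genus": genus, **values[key],
                          "discordant_metrics": count},
            ))
    return proposals


def _cross_pairs_compatible(tips_a, tips_b, metrics: MetricLookup,
                            ref: ReferenceDistributions,
                            thresholds: Thresholds,
                            which=("aai", "pd")) -> Optional[bool]:
    """Mean cross-pair metrics inside the within-genus reference range."""
    values: dict[str, list[float]] = {m: [] for m in which}
    for a in sorted(tips_a):
        for b in sorted(tips_b):
            rec = metrics.get(a, b)
            if rec is None:
                continue
            for m in which:
                v = getattr(rec, m)
                if v is not None:
                    values[m].append(v)
    seen = False
    for m, vals in values.items():
        if not vals:
            continue
        seen = True
        if not ref.is_within_range(m, float(np.mean(vals)), thresholds):
            return False
    return True if seen else None


def resolve_paraphyly(clade_tips_by_genus: dict[str, frozenset],
                      metrics: MetricLookup, ref: ReferenceDistributions,
                      genus_year: dict[str, int],
                      thresholds: Thresholds) -> list[Proposal]:
    """Resolve one paraphyletic complex (one clade, >= 2 genera).

    Candidate resolutions relabel every tip in the clade to one genus;
    metric-compatible candidates are ranked by fewest name changes, then
    by priority (earliest described genus keeps its name), then
    alphabetically.
    """
    genera = sorted(clade_tips_by_genus)
    if len(genera) < 2:
        raise ValueError("a paraphyletic complex needs >= 2 genera")
    candidates = []
    for target in genera:
        moved = [t for g in genera if g != target
                 for t in clade_tips_by_genus[g]]
        compatible = _cross_pairs_compatible(
            clade_tips_by_genus[target], frozenset(moved), metrics, ref,
            thresholds)
        candidates.append({
            "target": target,
            "moved": sorted(moved),
            "name_changes": len(moved),
            "compatible": compatible,
            "year": genus_year.get(target, 9999),
        })
    viable = [c for c in candidates if c["compatible"]]
    if not viable:
        return [Proposal(
            action="flag_inconclusive",
            subjects=sorted(t for g in genera for t in clade_tips_by_genus[g]),
            evidence={"reason": "no metric-compatible resolution",
                      "genera": ",".join(genera)},
        )]
    viable.sort(key=lambda c: (c["name_changes"], c["year"], c["target"]))
    chosen = viable[0]
    return [Proposal(
        action="merge_genus",
        subjects=chosen["moved"],
        destination=chosen["target"],
        name_changes=chosen["name_changes"],
        evidence={
            "genera": ",".join(genera),
            "primary_genus": min(genera, key=lambda g: (genus_year.get(g, 9999), g)),
            "candidate_name_changes": ",".join(
                str(c["name_changes"]) for c in candidates),
        },
    )]


def resolve_polyphyly(report: PhylyReport, genus: str,
                      records_by_id: dict[str, StrainRecord],
                      metrics: MetricLookup, ref: ReferenceDistributions,
                      reports: dict[str, PhylyReport],
                      genus_of: dict[str, str],
                      thresholds: Thresholds,
                      traits=None) -> list[Proposal]:
    """Resolve a polyphyletic genus: the primary clade (type species)
    keeps the name; every other pure clade is merged with its nearest
    metric-compatible neighbor genus or split off as a new genus."""
    if report.status != "polyphyletic":
        raise ValueError(f"{genus} is not polyphyletic")
    if report.primary_clade_index is None:
        raise ValueError(f"type species of {genus} not located")
    mono = {g for g, r in reports.items()
            if r.status == "monophyletic" and g != genus}
    primary = report.pure_clades[report.primary_clade_index]
    proposals: list[Proposal] = []
    for idx, clade in enumerate(report.pure_clades):
        if idx == report.primary_clade_index:
            continue
        # A clade that is metrically indistinguishable from the primary
        # clade already carries the right name: its separation is an
        # unresolved polytomy, not a misclassification.
        own_vals = _group_metric_means(clade, primary, metrics)
        own_checks = [ref.is_within_range(m, v, thresholds,
                                          exclude_genus=genus)
                      for m, v in own_vals.items() if v is not None]
        if own_checks and all(own_checks):
            log.info("polyphyletic %s: clade %d metric-compatible with the "
                     "primary clade; no action", genus, idx)
            continue
        neighbor, neighbor_vals = _nearest_genus(
            clade, mono, reports, metrics)
        evidence = {"genus": genus, "clade_index": idx,
                    "neighbor": neighbor or ""}
        evidence.update(neighbor_vals)
        if neighbor is None:
            proposals.append(Proposal(
                action="new_genus", subjects=sorted(clade),
                destination=f"NovelGenus_{sorted(clade)[0]}",
                name_changes=len(clade),
                evidence={**evidence, "reason": "no neighbor genus"},
            ))
            continue
        neighbor_tips = reports[neighbor].tips
        checks = []
        for m in ("aai", "pd"):
            v = neighbor_vals.get(m)
            if v is None:
                continue
            checks.append(ref.is_within_range(m, v, thresholds))
        between = []
        for m in ("aai", "pd"):
            v = neighbor_vals.get(m)
            if v is None:
                continue
            between.append(ref.is_between_like(m, v, thresholds))
        diff = _group_trait_difference(traits, clade, neighbor_tips)
        if checks and all(checks):
            if diff is not None and diff >= thresholds.trait_diff_limit:
                proposals.append(Proposal(
                    action="new_genus", subjects=sorted(clade),
                    destination=f"NovelGenus_{sorted(clade)[0]}",
                    name_changes=len(clade),
                    evidence={**evidence, "trait_differences": diff,
                              "phenotype_decisive": True},
                ))
            else:
                proposals.append(Proposal(
                    action="merge_genus", subjects=sorted(clade),
                    destination=neighbor, name_changes=len(clade),
                    evidence={**evidence, "trait_differences": diff},
                ))
        elif between and all(between):
            proposals.append(Proposal(
                action="new_genus", subjects=sorted(clade),
                destination=f"NovelGenus_{sorted(clade)[0]}",
                name_changes=len(clade),
                evidence=evidence,
            ))
        else:
            # Metrics inconclusive: phenotype decides when available.
            if diff is None:
                proposals.append(Proposal(
                    action="flag_inconclusive", subjects=sorted(clade),
                    evidence={**evidence,
                              "reason": "metrics inconclusive, no traits"},
                ))
            elif diff >= thresholds.trait_diff_limit:
                proposals.append(Proposal(
                    action="new_genus", subjects=sorted(clade),
                    destination=f"NovelGenus_{sorted(clade)[0]}",
                    name_changes=len(clade),
                    evidence={**evidence, "trait_differences": diff,
                              "phenotype_decisive": True},
                ))
            else:
                proposals.append(Proposal(
                    action="merge_genus", subjects=sorted(clade),
                    destination=neighbor, name_changes=len(clade),
                    evidence={**evidence, "trait_differences": diff,
                              "phenotype_decisive": True},
                ))
    return proposals


def _group_metric_means(tips_a, tips_b, metrics: MetricLookup) -> dict:
    pds, aais = [], []
    for a in tips_a:
        for b in tips_b:
            rec = metrics.get(a, b)
            if rec is None:
                continue
            if rec.pd is not None:
                pds.append(rec.pd)
            if rec.aai is not None:
                aais.append(rec.aai)
    return {
        "pd": float(np.mean(pds)) if pds else None,
        "aai": float(np.mean(aais)) if aais else None,
    }


def _nearest_genus(clade, mono_genera, reports, metrics
                   ) -> tuple[Optional[str], dict]:
    """Nearest monophyletic genus by mean PD (AAI as fallback)."""
    best = None
    best_pd = np.inf
    best_vals: dict = {}
    for g in sorted(mono_genera):
        tips = reports[g].tips
        pds, aais = [], []
        for a in clade:
            for b in tips:
                rec = metrics.get(a, b)
                if rec is None:
                    continue
                if rec.pd is not None:
                    pds.append(rec.pd)
                if rec.aai is not None:
                    aais.append(rec.aai)
        if not pds and not aais:
            continue
        mean_pd = float(np.mean(pds)) if pds else np.inf
        if mean_pd < best_pd:
            best = g
            best_pd = mean_pd
            best_vals = {
                "pd": mean_pd if pds else None,
                "aai": float(np.mean(aais)) if aais else None,
            }
    return best, best_vals


# --------------------------------------------------------- family level

def family_split_test(lineage_a: frozenset, lineage_b: frozenset,
                      metrics: MetricLookup, thresholds: Thresholds
                      ) -> Optional[Proposal]:
    """Propose a family split when all within-vs-between contrasts agree.

    PD must be significantly smaller within lineages than between;
    AAI/CP similarities significantly larger.
    """
    if len(lineage_a) < 2 or len(lineage_b) < 2:
        raise ValueError("each lineage needs >= 2 tips")
    within = {m: [] for m in GENUS_METRICS}
    between = {m: [] for m in GENUS_METRICS}
    for rec in metrics.records():
        a, b = rec.strain_a, rec.strain_b
        in_a = {a, b} <= lineage_a
        in_b = {a, b} <= lineage_b
        cross = (a in lineage_a and b in lineage_b) or \
                (a in lineage_b and b in lineage_a)
        if not (in_a or in_b or cross):
            continue
        for m in GENUS_METRICS:
            v = getattr(rec, m)
            if v is None:
                continue
            (within if (in_a or in_b) else between)[m].append(v)

    evidence = {}
    for m in GENUS_METRICS:
        w, btw = within[m], between[m]
        if not w or not btw:
            return None
        _, p = mann_whitney_u(w, btw, mode="normal")
        direction_ok = (np.mean(w) < np.mean(btw) if m == "pd"
                        else np.mean(w) > np.mean(btw))
        evidence[f"p_{m}"] = p
        if p >= thresholds.alpha or not direction_ok:
            return None
    smaller = min((lineage_a, lineage_b), key=lambda s: (len(s), sorted(s)))
    return Proposal(
        action="split_family",
        subjects=sorted(smaller),
        destination="NovelFamily_01",
        name_changes=len(smaller),
        evidence=evidence,
    )


# ------------------------------------------------------- new genome flow

@dataclass
class PlacementReport:
    query: str
    shortlist: list[str]
    shortlist_size: int
    claimed_genus: Optional[str]
    genus_confirmed: Optional[bool]
    species_assignment: Optional[str]
    recommend_full_analysis: bool
    evidence: dict = field(default_factory=dict)


def place_new_genome(query: StrainRecord, reference: list[StrainRecord],
                     thresholds: Thresholds,
                     k: Optional[int] = None) -> PlacementReport:
    """Shortlist the closest relatives by AAI and verify the placement.

    The top-k references (plus the claimed genus's type species and
    representatives) form a shortlist; a subtree is inferred on it and
    the query's monophyly with the claimed genus is checked.  A reference
    passing both species thresholds against the query yields a species
    assignment.
    """
    from . import metrics as metrics_mod
    from .phylogeny import neighbor_joining
    from .phyly import classify_group

    k = k or thresholds.shortlist_k
    if k < 1:
        raise ValueError("k must be >= 1")
    if not reference:
        raise ValueError("empty reference dataset")

    aais = {}
    for rec in sorted(reference, key=lambda r: r.strain_id):
        value = metrics_mod.aai(query, rec)
        if value is not None:
            aais[rec.strain_id] = value
    if not aais:
        raise ValueError(f"no computable AAI for query {query.strain_id}")

    ranked = sorted(aais, key=lambda s: (-aais[s], s))
    shortlist = ranked[:k]
    claimed = query.genus or None
    by_id = {r.strain_id: r for r in reference}
    if claimed:
        for rec in sorted(reference, key=lambda r: r.strain_id):
            if rec.genus == claimed and rec.strain_id not in shortlist \
                    and rec.strain_id in aais:
                shortlist.append(rec.strain_id)
        if all(by_id[s].genus == claimed for s in shortlist):
            # Monophyly needs at least one outside reference for context.
            outsider = next((s for s in ranked
                             if by_id[s].genus != claimed), None)
            if outsider is not None:
                shortlist.append(outsider)

    # Subtree on the shortlist from AAI distances.
    members = [query] + [by_id[s] for s in shortlist]
    n = len(members)
    genus_confirmed = None
    if n >= 3:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                v = (aais.get(members[j].strain_id)
                     if i == 0 else
                     metrics_mod.aai(members[i], members[j]))
                d = 1.0 - (v or 0.0) / 100.0
                dist[i, j] = dist[j, i] = d
        subtree = neighbor_joining(dist, [m.strain_id for m in members])
        if claimed:
            group = {m.strain_id for m in members
                     if m is query or m.genus == claimed}
            outside = [m.strain_id for m in members
                       if m.strain_id not in group]
            if len(group) > 1 and outside:
                # Root at the most distant outside member; NJ trees are
                # unrooted and monophyly is rooting-dependent.
                from .phylogeny import root_with_outgroup
                root_tip = min(outside,
                               key=lambda s: (aais.get(s, 0.0), s))
                rooted = root_with_outgroup(subtree, {root_tip})
                genus_confirmed = (
                    classify_group(rooted, group).status == "monophyletic")

    species_assignment = None
    evidence: dict = {"top_aai": aais[ranked[0]]}
    best = by_id[ranked[0]]
    ani_v = metrics_mod.ani(query, best)
    dddh_v = metrics_mod.ddd_hybridization(query, best)
    if ani_v is not None and dddh_v is not None:
        evidence.update({"ani": ani_v, "dddh": dddh_v})
        if ani_v >= thresholds.ani_species and dddh_v >= thresholds.dddh_species:
            species_assignment = best.species or best.strain_id
    return PlacementReport(
        query=query.strain_id,
        shortlist=shortlist,
        shortlist_size=len(shortlist),
        claimed_genus=claimed,
        genus_confirmed=genus_confirmed,
        species_assignment=species_assignment,
        recommend_full_analysis=not (genus_confirmed or species_assignment),
        evidence=evidence,
    )
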