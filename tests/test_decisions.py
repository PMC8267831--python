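import numpy as np
import pandas as pd
import pytest

from taxoresolve.decisions import (MetricLookup, Proposal,
                                   ReferenceDistributions, family_split_test,
                                   genus_outlier_scan, place_new_genome,
                                   resolve_paraphyly, resolve_polyphyly,
                                   species_decision, trait_difference_count)
from taxoresolve.model import MetricRecord, StrainRecord, Thresholds
from taxoresolve.phyly import classify_group
from taxoresolve.tree import read_newick

TH = Thresholds()


def metric(a, b, **kw):
    return MetricRecord(strain_a=a, strain_b=b, **kw)


def make_reference(within_aai=(78, 95), within_pd=(0.05, 0.2),
                   within_cp=(80, 98), n=12):
    """Reference distributions with the given within ranges and a clearly
    separated between-genus distribution."""
    rng = np.random.default_rng(0)
    records = []
    genus_of = {}
    reports = {}
    # Six monophyletic two-strain genera give within pairs...
    tree_parts = []
    for g in range(6):
        a, b = f"g{g}a", f"g{g}b"
        genus_of[a] = genus_of[b] = f"G{g}"
        tree_parts.append(f"({a},{b})")
    newick = "(" + ",".join(tree_parts) + ");"
    tree = read_newick(newick)
    for g in range(6):
        reports[f"G{g}"] = classify_group(
            tree, {f"g{g}a", f"g{g}b"}, f"G{g}")
    frac = np.linspace(0, 1, 6)
    for g in range(6):
        t = frac[g]
        records.append(metric(
            f"g{g}a", f"g{g}b",
            aai=within_aai[0] + t * (within_aai[1] - within_aai[0]),
            pd=within_pd[0] + t * (within_pd[1] - within_pd[0]),
            cp1=within_cp[0] + t * (within_cp[1] - within_cp[0]),
            cp2=within_cp[0] + t * (within_cp[1] - within_cp[0]),
            cp3=within_cp[0] + t * (within_cp[1] - within_cp[0]),
        ))
    # Between pairs: well separated.
    for g in range(5):
        records.append(metric(
            f"g{g}a", f"g{g + 1}a",
            aai=55 + g, pd=0.5 + 0.02 * g, cp1=60.0, cp2=62.0, cp3=58.0))
    lookup = MetricLookup(records)
    ref = ReferenceDistributions.build(lookup, genus_of, reports,
                                       trim_atypical=False)
    return ref, lookup


class TestProposal:
    def test_requires_evidence(self):
        with pytest.raises(ValueError, match="evidence"):
            Proposal("merge_species", ["a", "b"], name_changes=1, evidence={})

    def test_non_flag_requires_name_change(self):
        with pytest.raises(ValueError, match="name change"):
            Proposal("merge_species", ["a", "b"], evidence={"x": 1})

    def test_unknown_action(self):
        with pytest.raises(ValueError, match="unknown action"):
            Proposal("rename_everything", ["a"], evidence={"x": 1})


class TestSpeciesDecision:
    def _records(self):
        a = StrainRecord("a", genus="G", species="g_alpha",
                         is_type_species=True)
        b = StrainRecord("b", genus="G", species="g_beta")
        tree = read_newick("((a,b),(c,d));")
        return a, b, tree

    def test_below_thresholds_none(self):
        a, b, tree = self._records()
        m = metric("a", "b", dddh=52.4, ani=91.0)
        assert species_decision(a, b, m, tree, TH) is None

    def test_one_threshold_not_enough(self):
        a, b, tree = self._records()
        m = metric("a", "b", dddh=75.0, ani=94.0)
        assert species_decision(a, b, m, tree, TH) is None

    def test_merge_when_no_trait_differences(self):
        a, b, tree = self._records()
        m = metric("a", "b", dddh=90.0, ani=99.0)
        prop = species_decision(a, b, m, tree, TH)
        assert prop.action == "merge_species"
        assert prop.destination == "g_alpha"  # type species keeps the name
        assert prop.name_changes == 1

    def test_demote_with_recorded_trait_differences(self):
        a, b, tree = self._records()
        traits = pd.DataFrame([
            {"strain_id": "a", "qs": True, "cleavage": False},
            {"strain_id": "b", "qs": False, "cleavage": False},
        ])
        m = metric("a", "b", dddh=100.0, ani=100.0)
        prop = species_decision(a, b, m, tree, TH, traits)
        assert prop.action == "demote_to_subspecies"

    def test_non_sister_pair_none(self):
        a = StrainRecord("a", genus="G", species="g_alpha")
        c = StrainRecord("c", genus="G", species="g_gamma")
        tree = read_newick("((a,b),(c,d));")
        m = metric("a", "c", dddh=90.0, ani=99.0)
        assert species_decision(a, c, m, tree, TH) is None

    def test_missing_metric_flags(self):
        a, b, tree = self._records()
        m = metric("a", "b", dddh=None, ani=99.0)
        prop = species_decision(a, b, m, tree, TH)
        assert prop.action == "flag_inconclusive"


class TestGenusOutlierScan:
    def _members(self):
        return [
            StrainRecord("x1", genus="X", species="x_one",
                         is_type_species=True),
            StrainRecord("x2", genus="X", species="x_two"),
        ]

    def test_fully_discordant_pair_new_genus(self):
        ref, _ = make_reference()
        lookup = MetricLookup([metric(
            "x1", "x2", aai=65.8, pd=0.45, cp1=62.0, cp2=64.0, cp3=59.0)])
        proposals = genus_outlier_scan("X", self._members(), lookup, ref, TH)
        assert len(proposals) == 1
        assert proposals[0].action == "new_genus"
        assert proposals[0].subjects == ["x2"]  # the type species stays

    def test_partial_discordance_flags(self):
        ref, _ = make_reference()
        # cp1/cp2 outside, the rest comfortably inside.
        lookup = MetricLookup([metric(
            "x1", "x2", aai=85.0, pd=0.12, cp1=62.0, cp2=64.0, cp3=90.0)])
        proposals = genus_outlier_scan("X", self._members(), lookup, ref, TH)
        assert len(proposals) == 1
        assert proposals[0].action == "flag_inconclusive"

    def test_typical_pair_no_proposal(self):
        ref, _ = make_reference()
        lookup = MetricLookup([metric(
            "x1", "x2", aai=88.0, pd=0.1, cp1=90.0, cp2=92.0, cp3=88.0)])
        assert genus_outlier_scan("X", self._members(), lookup, ref, TH) == []


class TestResolveParaphyly:
    def test_one_change_beats_priority(self):
        # Intruder genus B (1 tip, younger) nested in genus A (2 tips,
        # older): moving the single B tip costs one name change.
        ref, _ = make_reference()
        lookup = MetricLookup([
            metric("a1", "b1", aai=90.0, pd=0.1),
            metric("a2", "b1", aai=88.0, pd=0.12),
            metric("a1", "a2", aai=92.0, pd=0.08),
        ])
        proposals = resolve_paraphyly(
            {"A": frozenset({"a1", "a2"}), "B": frozenset({"b1"})},
            lookup, ref, {"A": 1990, "B": 2015}, TH)
        assert len(proposals) == 1
        prop = proposals[0]
        assert prop.action == "merge_genus"
        assert prop.subjects == ["b1"]
        assert prop.destination == "A"
        assert prop.name_changes == 1

    def test_smaller_moves_even_into_younger_genus(self):
        # Host genus younger but larger: parsimony wins, priority only
        # breaks ties.
        ref, _ = make_reference()
        lookup = MetricLookup([
            metric("a1", "b1", aai=90.0, pd=0.1),
            metric("a2", "b1", aai=88.0, pd=0.12),
        ])
        proposals = resolve_paraphyly(
            {"A": frozenset({"a1", "a2"}), "B": frozenset({"b1"})},
            lookup, ref, {"A": 2015, "B": 1990}, TH)
        assert proposals[0].destination == "A"
        assert proposals[0].name_changes == 1

    def test_incompatible_metrics_flagged(self):
        ref, _ = make_reference()
        lookup = MetricLookup([
            metric("a1", "b1", aai=55.0, pd=0.6),
            metric("a2", "b1", aai=54.0, pd=0.65),
            metric("a1", "a2", aai=55.0, pd=0.62),
        ])
        proposals = resolve_paraphyly(
            {"A": frozenset({"a1", "a2"}), "B": frozenset({"b1"})},
            lookup, ref, {"A": 1990, "B": 2015}, TH)
        assert proposals[0].action == "flag_inconclusive"

    def test_needs_two_genera(self):
        ref, lookup = make_reference()
        with pytest.raises(ValueError):
            resolve_paraphyly({"A": frozenset({"a1"})}, lookup, ref,
                              {"A": 1990}, TH)


class TestResolvePolyphyly:
    def _setup(self, cross_aai, cross_pd):
        # Genus X split into primary clade {x1,x2} and stray {x3};
        # neighbor genus N = {n1,n2}.
        tree = read_newick("(((x1,x2),(n1,n2)),(x3,(m1,m2)));")
        genus_of = {"x1": "X", "x2": "X", "x3": "X",
                    "n1": "N", "n2": "N", "m1": "M", "m2": "M"}
        report = classify_group(tree, {"x1", "x2", "x3"}, "X")
        report.primary_clade_index = next(
            i for i, c in enumerate(report.pure_clades) if "x1" in c)
        reports = {"X": report,
                   "N": classify_group(tree, {"n1", "n2"}, "N"),
                   "M": classify_group(tree, {"m1", "m2"}, "M")}
        ref, _ = make_reference()
        records = [
            metric("x1", "x3", aai=60.0, pd=0.55),
            metric("x2", "x3", aai=60.0, pd=0.55),
            metric("x3", "m1", aai=cross_aai, pd=cross_pd),
            metric("x3", "m2", aai=cross_aai, pd=cross_pd),
            metric("x3", "n1", aai=58.0, pd=0.7),
            metric("x3", "n2", aai=58.0, pd=0.7),
        ]
        lookup = MetricLookup(records)
        by_id = {s: StrainRecord(s, genus=genus_of[s]) for s in genus_of}
        return report, by_id, lookup, ref, reports, genus_of

    def test_between_range_metrics_new_genus(self):
        report, by_id, lookup, ref, reports, genus_of = \
            self._setup(cross_aai=55.0, cross_pd=0.6)
        proposals = resolve_polyphyly(report, "X", by_id, lookup, ref,
                                      reports, genus_of, TH)
        assert len(proposals) == 1
        assert proposals[0].action == "new_genus"
        assert proposals[0].subjects == ["x3"]

    def test_compatible_neighbor_merge(self):
        report, by_id, lookup, ref, reports, genus_of = \
            self._setup(cross_aai=88.0, cross_pd=0.1)
        proposals = resolve_polyphyly(report, "X", by_id, lookup, ref,
                                      reports, genus_of, TH)
        assert len(proposals) == 1
        assert proposals[0].action == "merge_genus"
        assert proposals[0].destination == "M"

    def test_inconclusive_metrics_traits_decide_new_genus(self):
        # AAI inside the within range, PD on the between side: conflict.
        report, by_id, lookup, ref, reports, genus_of = \
            self._setup(cross_aai=85.0, cross_pd=0.5)
        traits = pd.DataFrame([
            {"strain_id": "x3", "qs": True, "cleavage": True,
             "demethylation": True, "high_salt": True},
            {"strain_id": "m1", "qs": False, "cleavage": False,
             "demethylation": False, "high_salt": False},
            {"strain_id": "m2", "qs": False, "cleavage": False,
             "demethylation": False, "high_salt": False},
        ])
        proposals = resolve_polyphyly(report, "X", by_id, lookup, ref,
                                      reports, genus_of, TH, traits)
        assert proposals[0].action == "new_genus"
        assert proposals[0].evidence.get("phenotype_decisive")

    def test_inconclusive_metrics_no_traits_flagged(self):
        report, by_id, lookup, ref, reports, genus_of = \
            self._setup(cross_aai=85.0, cross_pd=0.5)
        proposals = resolve_polyphyly(report, "X", by_id, lookup, ref,
                                      reports, genus_of, TH, traits=None)
        assert proposals[0].action == "flag_inconclusive"


class TestFamilySplit:
    def _metrics(self, separated=True):
        rng = np.random.default_rng(1)
        lineage_a = frozenset(f"a{i}" for i in range(6))
        lineage_b = frozenset(f"b{i}" for i in range(6))
        records = []
        tips = sorted(lineage_a) + sorted(lineage_b)
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                x, y = tips[i], tips[j]
                same = (x[0] == y[0])
                if separated and not same:
                    pd_v = rng.uniform(0.5, 0.7)
                    aai_v = rng.uniform(55, 62)
                    cp = rng.uniform(55, 65)
                else:
                    pd_v = rng.uniform(0.05, 0.3)
                    aai_v = rng.uniform(75, 95)
                    cp = rng.uniform(78, 95)
                records.append(metric(x, y, aai=aai_v, pd=pd_v,
                                      cp1=cp, cp2=cp, cp3=cp))
        return lineage_a, lineage_b, MetricLookup(records)

    def test_clean_split_detected(self):
        a, b, lookup = self._metrics(separated=True)
        prop = family_split_test(a, b, lookup, TH)
        assert prop is not None
        assert prop.action == "split_family"
        assert all(v < 0.001 for k, v in prop.evidence.items()
                   if k.startswith("p_"))

    def test_unstructured_data_none(self):
        a, b, lookup = self._metrics(separated=False)
        assert family_split_test(a, b, lookup, TH) is None

    def test_shuffled_labels_mostly_none(self):
        rng = np.random.default_rng(5)
        a, b, lookup = self._metrics(separated=True)
        tips = sorted(a | b)
        rejections = 0
        n_perm = 30
        for _ in range(n_perm):
            perm = rng.permutation(tips)
            pa, pb = frozenset(perm[:6]), frozenset(perm[6:])
            if family_split_test(pa, pb, lookup, TH) is not None:
                rejections += 1
        assert rejections / n_perm <= 0.1

    def test_small_lineage_rejected(self):
        _, b, lookup = self._metrics()
        with pytest.raises(ValueError):
            family_split_test(frozenset({"a0"}), b, lookup, TH)


class TestTraitDifferences:
    def test_counts_boolean_columns(self):
        traits = pd.DataFrame([
            {"strain_id": "a", "family": "A", "qs": True, "cleavage": False,
             "nacl_percent": 3.0},
            {"strain_id": "b", "family": "A", "qs": False, "cleavage": False,
             "nacl_percent": 5.0},
        ])
        assert trait_difference_count(traits, "a", "b") == 1

    def test_missing_rows_none(self):
        traits = pd.DataFrame([{"strain_id": "a", "qs": True}])
        assert trait_difference_count(traits, "a", "zz") is None
        assert trait_difference_count(None, "a", "b") is None


@pytest.fixture(scope="module")
def reference_dataset():
    from taxoresolve.synthetic import SimulationConfig, generate_dataset
    cfg = SimulationConfig(n_tips=14, n_genes=8, gene_length_codons=100,
                           seed=71)
    records, *_ = generate_dataset(cfg)
    return [r for r in records if r.strain_id != "OUTGROUP"]


class TestPlacement:
    def test_identical_query_species_assignment(self, reference_dataset):
        query = reference_dataset[0].copy()
        query.strain_id = "QUERY"
        report = place_new_genome(query, reference_dataset, TH, k=5)
        assert report.shortlist[0] == reference_dataset[0].strain_id
        assert report.evidence["ani"] == 100.0
        assert report.evidence["dddh"] == 100.0
        assert report.species_assignment == reference_dataset[0].species
        assert not report.recommend_full_analysis

    def test_member_query_confirms_genus(self, reference_dataset):
        genera = {}
        for r in reference_dataset:
            genera.setdefault(r.genus, []).append(r)
        genus, members = next((g, m) for g, m in sorted(genera.items())
                              if len(m) >= 3)
        query = members[0].copy()
        query.strain_id = "QUERY"
        rest = [r for r in reference_dataset if r.strain_id
                != members[0].strain_id]
        report = place_new_genome(query, rest, TH, k=5)
        assert report.claimed_genus == genus
        assert report.genus_confirmed
        shortlist_genera = {r.genus for r in rest
                            if r.strain_id in report.shortlist}
        assert genus in shortlist_genera
        assert report.shortlist_size < 20

    def test_isolated_query_recommends_full_analysis(self, reference_dataset):
        # A deeply diverged query: no genus confirmed, no species
        # assignment, full analysis recommended.
        rng = np.random.default_rng(5)
        query = reference_dataset[0].copy()
        query.strain_id = "LONER"
        query.genus = ""
        for gene in query.genes:
            arr = list(gene.nucleotide_seq)
            sites = rng.choice(len(arr), size=int(0.35 * len(arr)),
                               replace=False)
            for i in sites:
                arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
            gene.nucleotide_seq = "".join(arr)
            if gene.is_cds:
                from Bio.Seq import Seq
                gene.protein_seq = str(Seq(gene.nucleotide_seq).translate())
        query.genome = ["".join(g.nucleotide_seq for g in query.genes)]
        report = place_new_genome(query, reference_dataset, TH, k=5)
        assert report.species_assignment is None
        assert not report.genus_confirmed
        assert report.recommend_full_analysis

    def test_empty_reference_rejected(self, reference_dataset):
        with pytest.raises(ValueError):
            place_new_genome(reference_dataset[0], [], TH)
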