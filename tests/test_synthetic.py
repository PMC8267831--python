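import numpy as np
import pandas as pd
import pytest

from taxoresolve.phyly import classify_group
from taxoresolve.synthetic import (InjectionEvent, SimulationConfig,
                                   draw_traits, evolve_genomes,
                                   generate_dataset,
                                   inject_misclassifications,
                                   simulate_taxonomy_tree)
from taxoresolve.tree import write_newick


def cfg(**kw):
    base = dict(n_tips=16, n_genes=6, gene_length_codons=80, seed=9)
    base.update(kw)
    return SimulationConfig(**base)


class TestTaxonomyTree:
    def test_tip_count_and_clean_monophyly(self):
        tree, truth = simulate_taxonomy_tree(cfg())
        assert len(truth) == 16
        ingroup = tree.prune(["OUTGROUP"])
        for genus, sub in truth.groupby("genus"):
            report = classify_group(ingroup, set(sub["strain_id"]), genus)
            assert report.status == "monophyletic"

    def test_determinism(self):
        t1, truth1 = simulate_taxonomy_tree(cfg())
        t2, truth2 = simulate_taxonomy_tree(cfg())
        assert write_newick(t1) == write_newick(t2)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_single_genus_cutoff_error(self):
        with pytest.raises(ValueError, match="smaller cutoff"):
            simulate_taxonomy_tree(cfg(genus_depth=1e9))

    def test_replicates_all_monophyletic(self):
        for seed in range(20, 26):
            tree, truth = simulate_taxonomy_tree(cfg(n_tips=40, seed=seed))
            ingroup = tree.prune(["OUTGROUP"])
            for genus, sub in truth.groupby("genus"):
                report = classify_group(ingroup, set(sub["strain_id"]), genus)
                assert report.status == "monophyletic", (seed, genus)

    def test_families_are_root_children(self):
        tree, truth = simulate_taxonomy_tree(cfg(with_outgroup=False))
        sets = tree.tipsets()
        kids = {sets[id(c)] for c in tree.root.children}
        fam = {frozenset(sub["strain_id"])
               for _, sub in truth.groupby("family")}
        assert kids == fam


class TestEvolveGenomes:
    def test_zero_rate_identical_genomes(self):
        tree, truth = simulate_taxonomy_tree(cfg(site_mutation_rate=0.0))
        records = evolve_genomes(tree, cfg(site_mutation_rate=0.0))
        genomes = {r.genome[0] for r in records}
        assert len(genomes) == 1

    def test_jukes_cantor_identity_oracle(self):
        # Two tips at a known path length: observed identity must match
        # the closed-form JC expectation within 3 sigma (binomial).
        config = cfg(n_tips=4, n_genes=20, gene_length_codons=200,
                     codon_position_rates=(1.0, 1.0, 1.0),
                     site_mutation_rate=0.02, min_tip_branch=1.25,
                     family_stem=0.0, with_outgroup=False)
        tree, truth = simulate_taxonomy_tree(config)
        records = evolve_genomes(tree, config)
        by_id = {r.strain_id: r for r in records}
        from taxoresolve.phylogeny import patristic_distance
        tips = tree.tip_names()
        a, b = tips[0], tips[1]
        d = patristic_distance(tree, a, b)
        p_expect = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        seq_a = "".join(g.nucleotide_seq for g in by_id[a].genes
                        if g.marker_label != "16S")
        seq_b = "".join(g.nucleotide_seq for g in by_id[b].genes
                        if g.marker_label != "16S")
        diffs = sum(x != y for x, y in zip(seq_a, seq_b))
        n = len(seq_a)
        sigma = np.sqrt(p_expect * (1 - p_expect) / n)
        # Stop-codon repair perturbs a tiny fraction of third positions.
        assert abs(diffs / n - p_expect) < 3 * sigma + 0.005

    def test_all_genes_core_when_no_accessory_loss(self):
        config = cfg(accessory_gene_prob=0.0)
        records, *_ = generate_dataset(config)
        counts = [len([g for g in r.genes if g.marker_label != "16S"
                       and not (g.marker_label or "").startswith(
                           tuple("dl"))])
                  for r in records]
        # Every strain carries every simulated gene.
        assert len(set(counts)) <= 2  # trait markers vary; core genes do not

    def test_accessory_loss_drops_genes(self):
        config = cfg(accessory_gene_prob=0.9, accessory_fraction=0.5)
        tree, _ = simulate_taxonomy_tree(config)
        records = evolve_genomes(tree, config)
        n_genes = [len([g for g in r.genes if g.marker_label != "16S"])
                   for r in records]
        assert min(n_genes) < config.n_genes

    def test_16s_always_present(self):
        records, *_ = generate_dataset(cfg(accessory_gene_prob=0.9))
        assert all(r.gene_16s() is not None for r in records)


class TestDrawTraits:
    def _records(self, n):
        config = cfg(n_tips=max(8, n))
        tree, truth = simulate_taxonomy_tree(config)
        records = evolve_genomes(tree, config)
        records = [r for r in records if r.strain_id != "OUTGROUP"]
        family_of = dict(zip(truth["strain_id"], truth["family"]))
        return records, family_of

    def test_all_probabilities_one(self):
        records, family_of = self._records(8)
        probs = {f: {t: 1.0 for t in ("high_salt", "cleavage",
                                      "demethylation", "qs")}
                 for f in "AB"}
        table = draw_traits(records, probs, 1, family_of)
        assert table[["high_salt", "cleavage", "demethylation", "qs"]].all().all()
        for rec in records:
            counts = rec.marker_counts()
            assert all(counts.get(m, 0) >= 1 for m in ("dmdA", "dmdB", "dmdC"))
            assert counts.get("luxI", 0) >= 1 and counts.get("luxR", 0) >= 1
            assert rec.nacl_percent >= 3.5

    def test_all_probabilities_zero(self):
        records, family_of = self._records(8)
        probs = {f: {t: 0.0 for t in ("high_salt", "cleavage",
                                      "demethylation", "qs")}
                 for f in "AB"}
        table = draw_traits(records, probs, 1, family_of)
        assert not table[["high_salt", "cleavage", "demethylation",
                          "qs"]].any().any()

    def test_binomial_recovery(self):
        # 500 draws at p=0.6 land within 3 sigma.
        rng = np.random.default_rng(3)
        from taxoresolve.model import StrainRecord
        records = [StrainRecord(f"s{i:04d}") for i in range(500)]
        family_of = {r.strain_id: "A" for r in records}
        probs = {"A": {"high_salt": 0.5, "cleavage": 0.6,
                       "demethylation": 0.5, "qs": 0.5}}
        table = draw_traits(records, probs, 17, family_of)
        p_hat = table["cleavage"].mean()
        assert abs(p_hat - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 500)

    def test_missing_family_row_rejected(self):
        records, family_of = self._records(8)
        with pytest.raises(ValueError, match="missing family"):
            draw_traits(records, {"A": {"high_salt": 1.0, "cleavage": 1.0,
                                        "demethylation": 1.0, "qs": 1.0}},
                        1, family_of)


class TestInjections:
    def _dataset(self, kinds, seed=31, n_tips=40):
        config = cfg(n_tips=n_tips, seed=seed,
                     injections=[InjectionEvent(k) for k in kinds])
        return generate_dataset(config), config

    def test_paraphyly_injection_detected_on_truth_tree(self):
        (records, tree, truth, traits, ledger), config = \
            self._dataset(["paraphyly"])
        assert list(ledger["kind"]) == ["paraphyly"]
        target = ledger.iloc[0]["target_genus"]
        ingroup = tree.prune(["OUTGROUP"])
        tips = {r.strain_id for r in records if r.genus == target}
        report = classify_group(ingroup, tips, target)
        assert report.status == "paraphyletic"
        assert report.intruders == set(ledger.iloc[0]["subjects"].split(";"))

    def test_polyphyly_injection_detected_on_truth_tree(self):
        (records, tree, truth, traits, ledger), config = \
            self._dataset(["polyphyly"])
        target = ledger.iloc[0]["target_genus"]
        ingroup = tree.prune(["OUTGROUP"])
        tips = {r.strain_id for r in records if r.genus == target}
        report = classify_group(ingroup, tips, target)
        assert report.status == "polyphyletic"
        assert len(report.pure_clades) >= 2

    def test_species_split_pair_nearly_identical(self):
        (records, tree, truth, traits, ledger), config = \
            self._dataset(["species_split"])
        a_id, b_id = ledger.iloc[0]["subjects"].split(";")
        by_id = {r.strain_id: r for r in records}
        ga = by_id[a_id].genome[0]
        gb = by_id[b_id].genome[0]
        assert len(ga) == len(gb)
        diff = sum(x != y for x, y in zip(ga, gb)) / len(ga)
        assert diff < 0.03
        assert by_id[a_id].species != by_id[b_id].species

    def test_event_collision_rejected(self):
        config = cfg(n_tips=40, seed=31)
        records, tree, truth, traits, _ = generate_dataset(config)
        ingroup = tree.prune(["OUTGROUP"])
        genus = truth.groupby("genus").size()
        big = genus[genus >= 3].index[0]
        events = [InjectionEvent("paraphyly", target=big),
                  InjectionEvent("paraphyly", target=big)]
        with pytest.raises(ValueError, match="collision"):
            inject_misclassifications(records, ingroup, events, config,
                                      traits)

    def test_zero_events_empty_ledger(self):
        (records, tree, truth, traits, ledger), _ = self._dataset([])
        assert ledger.empty

    def test_each_event_once_in_ledger(self):
        (records, tree, truth, traits, ledger), _ = self._dataset(
            ["paraphyly", "polyphyly", "species_split"], seed=33)
        assert len(ledger) == 3
        assert set(ledger["kind"]) == {"paraphyly", "polyphyly",
                                       "species_split"}
        # Affected taxa exist in the output records.
        ids = {r.strain_id for r in records}
        for subjects in ledger["subjects"]:
            assert set(subjects.split(";")) <= ids


def test_unknown_injection_kind():
    with pytest.raises(ValueError, match="unknown injection kind"):
        InjectionEvent("typo")


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_tips=3)
    with pytest.raises(ValueError):
        SimulationConfig(accessory_gene_prob=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(trait_probs={"A": {"qs": 2.0}})
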