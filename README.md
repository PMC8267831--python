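# taxoresolve

Whole-genome taxonomic revision toolkit for bacterial families. Given
per-strain genomes, gene annotations and taxonomy metadata, it

- screens genome quality from single-copy marker content
  (completeness >= 95%, contamination <= 5%),
- identifies single-copy core genes by greedy protein-identity
  clustering, aligns them (built-in progressive aligner) and builds
  concatenated protein and codon-aware nucleotide matrices,
- infers a neighbor-joining core-genome tree with bootstrap support,
  roots it on an outgroup and collapses nodes below 50% support,
- computes pairwise genomic metrics: ANI (fragment-based), dDDH
  (calibrated from pooled fragment matches), reciprocal-best-hit AAI,
  codon-position similarities, patristic distance, 16S identity, G+C,
- classifies every genus as mono-, para- or polyphyletic and decomposes
  it into maximal pure clades,
- applies species- (dDDH >= 70% AND ANI >= 95% AND pair monophyly),
  genus- (reference distributions of AAI/PD/CP over recognized
  monophyletic genera; priority and parsimony rules for para-/polyphyly)
  and family-level (Mann-Whitney U contrasts of within- vs
  between-lineage metrics) decision rules, emitting an auditable list of
  reclassification proposals,
- predicts phenotypes from marker genes (dmdABC demethylation,
  dddWPQDLY cleavage, luxIR quorum sensing, salinity >= 3.5% NaCl) and
  contrasts trait proportions between families with a two-proportion
  z-test,
- places a new genome against a reference set via an AAI shortlist of
  the closest relatives plus claimed-genus representatives,
- and generates fully labeled synthetic datasets (pure-birth taxonomy
  tree, Jukes-Cantor-style gene evolution, family-conditional Bernoulli
  traits, injectable misclassifications with a truth ledger) so every
  stage is testable without downloads.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (clean-null,
injection recovery, oracle equivalence, metric calibration, statistics,
trait contrasts) at a reduced replicate scale; the rest are unit and
property tests per module.

## CLI

```bash
# generate a labeled synthetic dataset (with optional injected errors)
taxoresolve simulate --out data/ --seed 42 --n-tips 60 --n-genes 20 \
    --paraphyly 1 --polyphyly 1

# individual stages
taxoresolve qc         --data data/ --out qc.tsv
taxoresolve coregenome --data data/ --out core/ --identity 0.35
taxoresolve tree       --data data/ --out tree.nwk --bootstrap 100
taxoresolve metrics    --data data/ --out metrics.tsv
taxoresolve phyly      --data data/ --tree tree.nwk --out phyly.tsv

# full analysis -> proposals.tsv, metrics.tsv, trees, phyly report
taxoresolve decide --data data/ --out results/ --bootstrap 100 \
    --identity 0.35

# new-genome placement and a human-readable summary
taxoresolve place  --data data/ --query T001 --k 10
taxoresolve report --results results/ --out report.md
```

An externally inferred rooted Newick tree can be passed to `decide`
via `--tree` to bypass the built-in NJ inference.

Note on `--identity`: gene clustering defaults to 0.5 protein identity;
the synthetic datasets are generated at a divergence scale where distant
homologs sit near 50%, so synthetic runs use 0.35.

## Dataset directory layout

```
data/
  metadata.tsv     strain_id, genus, species, is_type_species,
                   genus_year, environment, nacl_percent[, family]
  genomes/<id>.fna genome contigs
  genes/<id>.ffn   CDS nucleotide sequences
  genes/<id>.faa   translated proteins
  genes.tsv        strain_id, gene_id, marker_label
  traits.tsv       optional trait table
  tree.nwk         optional reference tree
```

Marker labels drive the QC stage (`qc-*`), the 16S metric (`16S`) and
phenotype prediction (`dmdA..dmdC`, `dddW/P/Q/D/L/Y`, `luxI`, `luxR`).
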