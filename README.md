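# agnostos

Validation, darkness classification, community inference and
ecological/phylogenomic characterization of gene clusters (GCs) from
genomes and metagenomes.

The package operates on standard upstream outputs (predicted proteins in
FASTA, cluster membership TSV, domain-annotation and homology-hit tables,
profile-vs-profile hit tables, per-gene coverage, a rank-labelled Newick
genome tree) and provides:

- **validation** — size flagging, per-cluster sequence similarity networks
  with maximum-spanning-tree trimming, eigenvector-centrality
  representative selection, MSA outlier screening, broken-stick thresholds,
  shadow/spurious-gene filtering and the keep/discard decision;
- **functional** — w-shingling of domain architectures, clan-aware Jaccard
  homogeneity, annotation-frequency Shannon entropy;
- **classification** — consensus domain architectures (weighted
  source-to-sink paths over per-gene architectures), the
  Known / Known-without-Pfam / Genomic-Unknown / Environmental-Unknown
  partition via nested homology voting, remote-homology refinement,
  high-quality cluster selection and the non-redundant architecture set;
- **communities** — profile-homology graphs, an in-package Markov
  clustering implementation, inflation-grid optimization over five
  partition-quality metrics, three-pass orphan rescue;
- **ecology** — TSS abundance profiles, sample selection and grouping
  (Bray-Curtis + silhouette-optimal cut), accumulation curves, quasiswap
  null models and Levins niche-breadth Narrow/Broad/Nonsignificant calls;
- **phylo** — lineage specificity via a clade F1 score, phylogenetic
  conservation (consenTRAIT-style trait depth), known-vs-unknown
  conservation comparison, prophage-presence exclusion;
- **simulate** — a fully seeded generator of every input above with
  planted ground truth, so the entire pipeline is testable offline.

## CLI

The stages chain through a directory of plain-text files:

```sh
agnostos simulate    --preset small --seed 1 --out run/
agnostos validate    --in-dir run --out run
agnostos classify    --in-dir run --out run
agnostos communities --in-dir run --out run
agnostos ecology     --in-dir run --out run --seed 1
agnostos phylo       --in-dir run --out run
```

Every command accepts `--config cfg.yml` (YAML overriding the defaults in
`agnostos.config.DEFAULTS`), `--seed` and `--log-level`. Outputs are TSV
(`validation.tsv`, `homogeneity.tsv`, `categories.tsv`, `communities.tsv`,
`inflation_scan.tsv`, `abundance.tsv`, `accumulation.tsv`,
`distribution_calls.tsv`, `lineage_calls.tsv`) and JSON summaries.

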