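# provirome

Analysis of viral sequences mined from publicly available bacterial and
archaeal genomes. Microbial genome projects are full of viral signal —
integrated prophages, plasmid-like extrachromosomal prophages, chronic
and carrier-state infections assembled outside the host chromosome —
and every such sequence comes with a known host. `provirome` provides
the downstream analysis chain for this kind of data set:

* **curation** of automated viral predictions (control-spike removal,
  confidence and hallmark-gene filters, length floors), replication-mode
  classification (integrated / extrachromosomal / undetermined) and an
  exact rate test for plasmid-partition (ParA/ParB) marker enrichment;
* **gene-sharing clustering**: protein clusters from MCL on the
  reciprocal-best-hit graph, hypergeometric significance of shared gene
  content between genomes, `S = −log10(P·n_pairs)`, MCL again on the
  significance network → virus clusters (VCs ≈ genera), ICCC parameter
  sweeps, and putative-new-genus calling;
* **taxonomy**: strict >75% rank-wise majority affiliation of clusters
  and LCA affiliation of sequences from their relevant gene hits;
* **virus–host network**: VC × host-class incidence matrix, Barber's
  bipartite modularity `Q = (1/m) Σ_ij (A_ij − k_i d_j/m) δ(g_i,g_j)`
  maximised with lp-BRIM, and a 99-permutation null;
* **composition**: k-mer frequency vectors (k = 1..4), MAE distances,
  codon usage tables, CAI, and two-sample K–S comparisons of
  virus–host vs virus–non-host distance distributions, including a
  fragment-size subsampling experiment;
* **host prediction**: nearest genome by tetranucleotide frequency,
  scored per distance bin and taxonomic rank under
  leave-species-out / leave-genus-out exclusion;
* **co-infection** statistics with the terminase-large-subunit
  safeguard against mis-assembled tailed-phage genomes;
* a **synthetic world generator** producing hosts, viruses, gene
  tables, similarity and prediction tables with known ground truth —
  the test bed on which the whole chain is validated.

The intended headline use is the pipeline on a synthetic or real-format
data set; every stage is equally usable as a plain Python function.
See `docs/methods.md` for the full model and parameter account.

## Worked example

Cluster a synthetic world's 64 viral genomes into genus-level virus
clusters (`examples/03_gene_sharing_clusters.py`):

```python
from provirome import SimulationConfig, generate_world
from provirome import network as net

world = generate_world(SimulationConfig(seed=1))
prot2seq = world.protein_to_virus()
pcs = net.protein_clusters(world.similarity, protein_to_genome=prot2seq)
profiles = net.genome_profiles(pcs, prot2seq, world.gene_counts())
network = net.build_genome_network(profiles, sig_threshold=1.0)
clusters, unclustered = net.cluster_genomes(network, inflation=4.0)
```

prints

```
protein clusters: 149
virus clusters:   8 (8 putative new genera, 0 unclustered sequences)
adjusted Rand index vs true genera: 1.000
sweep argmax: threshold 1, inflation 2.00, ICCC 1.000
```

— the 1,152 family-bearing proteins collapse into 149 protein
clusters, the shared-PC significance network splits exactly into the 8
planted genera (ARI 1.0 against truth), every cluster contains a
large/circular member and no reference genome, so all 8 are called
putative new genera, and the ICCC sweep prefers the most permissive
significance threshold.

The virus–host matrix of a larger world
(`examples/05_virus_host_modularity.py`) gives

```
incidence matrix: 8 VCs x 4 host classes
observed Q = 0.750
99 permuted matrices: Q in [0.281, 0.656], mean 0.461
empirical p = 0.01
```

— the observed bipartite modularity exceeds all 99 permuted values:
virus clusters are specific to host classes, the signature of long-term
virus–host coevolution.

Host prediction on a strongly adapted world
(`examples/07_host_prediction.py`) reproduces the characteristic
accuracy gradient: ~100% at tetranucleotide distances below 4×10⁻⁴,
degrading with distance, and genus-level accuracy zero by construction
once the whole host genus is excluded from the reference library.

Each script in `examples/` demonstrates one capability and states what
its numbers mean; `examples/09_full_pipeline.py` runs all seven stages
from a single seed into a bundle of TSV tables plus `summary.json`.

A thin CLI mirrors the stages:

```bash
provirome simulate --seed 1 --out world/
provirome curate --predictions world/predictions.tsv --out curated/
provirome cluster --hits world/similarity.tsv --genes world/genes.gff3 --out vcs/
provirome vhnet --matrix incidence.tsv --perm 99 --seed 42
provirome run-all --seed 42 --out bundle/
```

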