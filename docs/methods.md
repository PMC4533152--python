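# Methods

`provirome` implements an analysis chain for viral sequences mined from
microbial genomes — curation of automated predictions, gene-content
clustering into genus-level virus clusters, taxonomic affiliation,
virus–host network modularity, genome-composition adaptation metrics,
composition-based host prediction, and co-infection statistics — and a
seeded synthetic world with known ground truth on which the whole chain
is exercised and validated. This note records the models, the defaults
and why they are what they are, the numerical choices, and what the
synthetic validation does and does not establish.

## Curation of viral predictions

Automated viral-region detectors report predictions in three confidence
categories, with detection tags (`hallmark`, `refseq`, `noncaudo`,
`vdb`), circularity, and prophage coordinates. The curation filter
keeps only high-confidence, plausibly active viral sequences by
dropping, in this fixed order:

1. PhiX-labelled rows — the Illumina sequencing control, identified here
   by label;
2. category-3 predictions (no hallmark gene and no viral-gene
   enrichment);
3. prophage predictions without a single hallmark gene — likely
   defective prophages whose boundaries are unreliable;
4. linear sequences shorter than 10 kb, except predictions made with
   the non-Caudovirales score, for which the floor is 5 kb because many
   ssDNA viruses have genomes below 10 kb;
5. circular contigs shorter than 3 kb, which are usually short repeat
   regions (the smallest known bacterial/archaeal virus genome is
   ~5 kb);
6. rows on an explicit exclusion list. Manual curation verdicts are an
   *input* (this list), never recomputed.

Only the first violated rule is logged per dropped row, which makes the
rejection accounting reproducible and the filter idempotent. The 5 kb
exception keys on the detection tag (not on the final taxonomic
affiliation); this is the only reading that is decidable at filter
time.

Retained sequences are classified by replication mode: `integrated`
(prophage), `extrachromosomal` (no microbial gene on the contig, and
circular or > 30 kb), else `undetermined` (a short linear contig
without host genes may equally be a poorly assembled prophage). The
module rejects both inconsistent annotations — a prophage without
microbial genes *and* a non-prophage carrying microbial genes — since
the mode definitions presuppose the prophage flag and the microbial
gene content agree.

Draft/complete status of a genome project uses the ">5 sequences"
rule: projects with up to 5 sequences are treated as complete, so
genomes split into a few chromosomes or plasmids are not mislabelled as
drafts.

**ParA/ParB enrichment.** The fraction of sequences carrying
plasmid-partition genes is compared between extrachromosomal sequences
and the rest with an exact conditional rate test (the classical exact
two-sample Poisson test): conditional on the total marker count
`k1 + k2`, `k1` is Binomial(`k1 + k2`, `n1/(n1 + n2)`) under equal
rates, and the reported p-value is the upper tail `P(X >= k1)`. The
test family is standard; the exact conditional construction was chosen
because it is well-defined at the small counts a desk-scale run
produces.

## Gene-sharing network and virus clusters

**Protein clusters (PCs).** Similarity hits below bit score 50 or above
e-value 1e-3 are discarded; reciprocal best hits define an undirected
protein graph (edge weight = mean of the two directed best-hit scores);
Markov clustering (MCL) of that graph yields PCs. When a
protein-to-genome mapping is supplied, the best hit is selected per
subject genome — the standard comparative-genomics RBH construction,
under which a protein family spread over many genomes forms a connected
subgraph. Without the mapping a single global best hit per query is
used; note that mutual *global* best hits form a matching (components
of size 2), so the per-genome mode is what the pipeline uses.
Singleton proteins form no PC and do not count toward repertoires:
shared gene content is defined on PCs.

**MCL numerics** (fixed policy): self-loops of weight 1 are added, the
adjacency is column-normalised, and expansion (matrix square) alternates
with inflation (element-wise power, renormalise) until the matrix
changes by less than 1e-8 or 100 iterations; entries below 1e-6 are
pruned each round. Clusters are the connected components of the limit
matrix's support, so the output is always a partition. Protein-level
inflation defaults to 2.0; genome-level inflation to 4.0. A known MCL
property worth keeping in mind: granularity rises with inflation and
with the edge-to-self-loop weight ratio, so small (3–4 member) cliques
with heavy weights can split into singletons at inflation 4 while
larger cliques hold together.

**Shared-gene significance.** For genomes with `a` and `b` PCs sharing
`c`, against a universe of `n` PCs, the tail probability is

    P = sum_{i=c}^{min(a,b)} C(a,i) C(n-a, b-i) / C(n,b)

and the edge significance is `S = max(0, -log10(P × n_pairs))` with
`n_pairs` the number of genome pairs examined — a Bonferroni-style
correction following the clustering framework this approach derives
from. Shared-PC counting is presence/absence, not copy number. An edge
is drawn when `S` exceeds the significance threshold (default 1).

**Parameter sweep.** The (threshold, inflation) grid is scored by the
intra-cluster clustering coefficient (ICCC): the mean, over nodes of
degree ≥ 1, of the fraction of a node's neighbours sharing its
cluster. Ties go to the lower threshold, then lower inflation. On the
synthetic world the argmax sits at the lowest threshold tested, with
ICCC flat-to-rising in inflation — the same qualitative shape that
motivated the default operating point (significance 1, inflation 4).

**Calling putative new genera.** Virus clusters behave approximately
like genera. A VC is a candidate genus only if at least one member is
circular, a known complete genome, or longer than 30 kb; candidates
without any reference member are *new*. The 30 kb floor deliberately
sacrifices small non-circular genomes to avoid calling short genome
fragments new genera. (Descriptions of this rule sometimes say "more
than 30 predicted genes" instead of ">30 kb"; the length form is
implemented.)

## Taxonomic affiliation

Lineages are ordered rank tuples (`order, family, genus` for viruses;
seven ranks for hosts) in which no assigned rank may sit below an
unassigned one.

* **Groups (profiles, VCs)** take, at each rank top-down, the label held
  by strictly more than 75% of *all* members; members unassigned at the
  rank stay in the denominator (the conservative reading). Exactly 75%
  fails. Descent stops at the first rank without a winner. Two labels
  cannot both exceed 75%.
* **Sequences** are affiliated to the LCA of their relevant hits: the
  absolute best gene hit plus every other gene's best hit scoring
  strictly more than 75% of it. The result is invariant to gene order
  and to positive rescaling of all scores; score ties are broken by
  lexicographic target id. No hits → fully unassigned
  ("unclassified").

## Virus–host network modularity

Rows of the incidence matrix are VCs with strictly more than 10
members (small clusters give unstable host-range signal); columns are
host classes; a cell is 1 when ≥ 1 member virus was found in that
class. Barber's bipartite modularity is

    Q = (1/m) Σ_ij (A_ij − k_i d_j / m) δ(g_i, g_j)

with row/column margins `k_i`, `d_j` and fill `m`. Maximisation uses
lp-BRIM: label-propagation seeding of row/column modules, then BRIM
alternation (columns reassigned optimally given row labels, then the
reverse) until Q stops improving. Implementation details that matter:

* each assignment step offers one fresh empty module, so nodes with
  only negative module affinities can break away (this mirrors the
  exhaustive oracle and is required to reach the optimum on sparse
  matrices);
* restart 1 starts from all-rows-apart; the remaining restarts (20 by
  default; the reference R package's restart policy is not documented)
  use randomised label propagation; the single-module partition is the
  floor, so the returned Q is never below the trivial partition's;
* deterministic given the seed.

Validation is against an exhaustive oracle: for matrices up to 5×4,
every canonical row labelling (up to min(r, c)+1 modules) is
enumerated, and the optimal column assignment decomposes per column
(each column takes the module with the largest summed modularity
contribution, or opts out). lp-BRIM attains this optimum on ≥ 95% of
100 seeded random matrices.

The permutation null scatters the `m` ones uniformly over the grid
(fill preserved; empty rows/columns are kept so Q stays comparable) and
re-runs lp-BRIM on each of 99 permutations; the empirical p-value is
`(1 + #{Q_perm ≥ Q_obs}) / (n_perm + 1)`. A margin-preserving
checkerboard-swap scheme is available behind `scheme="swap"`. Note
that small sparse matrices have high attainable Q under permutation
(the synthetic null mean is ≈ 0.45 on an 8×4 matrix with 8 ones), so
the meaningful statement is `Q_obs > max(Q_perm)`, not the absolute
gap.

## Genome composition and codon usage

* **k-mer vectors** (k = 1..4): overlapping single-strand windows;
  windows containing non-ACGT are skipped; a sequence with no valid
  window is an error. Whether reverse complements should be collapsed
  is ambiguous in common counters, so single-strand counting is the
  default with `canonical=True` available.
* **MAE distance**: mean of absolute frequency differences, `(1/4^k)
  Σ|f1 − f2|`.
* **Codon usage tables**: per-synonymous-family frequencies under the
  standard genetic code; relative adaptiveness `w_c` = family frequency
  divided by the family maximum. Codons never seen in an otherwise
  observed family get `w = 1e-3` (keeps CAI finite and positive);
  fully unobserved families are uninformative and get `w = 1`.
* **CAI**: geometric mean of `w` over a gene's codons, excluding stop
  codons and the single-codon families (ATG, TGG) whose `w` is 1 by
  construction; a gene of only excluded codons is an error. The
  reference implementation's handling of these corners is not
  documented, so the choices are fixed here and tested.
* **K–S statistic**: own ECDF sup-difference implementation
  (cross-checked against an independent library routine in tests).

**Adaptation experiment.** Per virus and metric: the value against the
true host, plus against `n_picks` (default 10) randomly drawn genomes
from each category — same genus (excluding the host), same family
(different genus), different order ("different order" means: genomes
whose order differs from the host's). Categories with fewer candidates
than `n_picks` are skipped with a warning — at desk scale, small worlds
must pass a smaller `n_picks` to populate the same-genus category. Per
stratum (all, by replication mode, by family, by tRNA count…) the K–S
D between the host distribution and each category's pooled distribution
is reported. A Wilcoxon signed-rank utility compares gene-level CAI of
each functional category against the "other" category, paired by
sequence; the category vocabulary is an input column, not hard-coded.

**Subsampling experiment.** Contiguous fragments of viral genomes at
sizes 2–20 kb (genomes shorter than a size are skipped with a warning);
per fragment, distance to the true host and to one random
different-order genome; reported per k as means per size plus the
least-squares slope of distance against size. On the default world the
host/non-host separation persists at 5 kb for k ≤ 2.

## Host prediction

The predicted host is the genome with the smallest tetranucleotide MAE
distance to the virus; ties break lexicographically. Host vectors are
computed on the concatenated genome (per-contig vs concatenated is
unspecified in the field; concatenated is used), with known prophage
regions masked so a prophage is not matched against the genome that
literally contains it. Exclusion modes mimic incomplete reference
databases: none, all genomes of the host species removed, all genomes
of the host genus removed. Accuracy is scored at order/family/genus
rank of the predicted genome's lineage and reported per distance bin —
`d < 4e-4`, `4e-4 ≤ d < 1e-3`, `d ≥ 1e-3` (closed left, open right).
Under genus exclusion, genus-level accuracy is zero by construction.

## Co-infection

A genome project with ≥ 2 curated viral sequences is a candidate
co-infection. When *all* candidates are Caudovirales, it is counted
only if the summed terminase-large-subunit (terL) copies reach 2 —
terL is single-copy and well conserved in Caudovirales, so one copy
spread over several contigs indicates one mis-assembled genome.
Mixed-family candidates are counted regardless, because the
mis-assembly argument is specific to Caudovirales; whether the gate
should also cover mixed Caudovirales/ssDNA genomes is genuinely open,
so `terl_gate_mixed=True` applies it there too. Sequences without a
confident order-level affiliation are treated as non-Caudovirales
(i.e., not gated). Outputs: per-genome records, a viruses-per-genome
histogram over all infected genomes, and unordered family-pair counts
over counted genomes (a counted genome with n viruses contributes
C(n,2) pairs).

## The synthetic world

The generator emulates exactly the statistical structure the analyses
assume, with truth tables for scoring. Study conditions (defaults,
chosen once):

| parameter | default | rationale |
|---|---|---|
| genera | 8 | enough clusters for ARI to be meaningful, small enough for seconds-scale runs |
| hosts per genus | 4 | species-exclusion experiments need ≥ 2; 32 genomes total |
| viruses per host | 2 | every genome is a co-infection candidate; 64 viral genomes |
| host genome | 200 kb | keeps host-side k-mer noise (~1e-4) below the taxonomy signal |
| viral lengths | 5–40 kb | ssDNA-like genera 5–10 kb (circular-heavy), tailed-phage-like 12–40 kb, straddling the 10/30 kb rule boundaries |
| α (adaptation ceiling) | 0.9 | strong but imperfect host amelioration |
| family pool / genes per virus | 40 / 20 | core+accessory repertoires with realistic overlap |
| decoy rate | 0.1 | one countable rule violation per decoy |
| prophage fraction | 0.4 | both replication modes well populated |

**Composition model.** Codon distributions are drawn hierarchically on
the 61 sense codons: an order-level base from Dirichlet(1 per codon)
(orders diverge strongly), a genus perturbation Dirichlet(200·base)
(within-family genera clearly separated), and a species perturbation
Dirichlet(20000·genus) (congeneric species close). Host chromosomes
are i.i.d. codon strings from the species distribution — so nucleotide
bias is induced by codon bias and every in-frame interval is a valid
CDS. The resulting tetramer MAE hierarchy (different order ≈ 2e-3 >
same family ≈ 1e-3 > same genus ≈ 2e-4) mirrors the way real
composition distances recapitulate taxonomy. The concentrations were
calibrated against the generator's own design goals — the distance
hierarchy, occupied distance bins, ≥ 95% genus recovery at α = 0.95 —
and then frozen.

A virus's codon distribution is `α_v · species + (1 − α_v) · uniform`,
with `α_v = α · U(0.4, 1)` per virus: real virus–host adaptation is
strongly heterogeneous (a recently acquired prophage is barely
ameliorated), and this spread is what populates the `d ≥ 1e-3`
distance bin with genuinely harder predictions. α remains the single
knob — it is the ceiling of adaptation strength.

**Gene repertoires.** Each genus owns a pool of protein families; 60%
of a virus's genes come from a conserved genus core (present in every
member), the rest of the family-bearing genes are sampled accessory
families, and ~10% are singletons with no similarity hits (they form no
PC). Phage genera share a conserved core genome; with purely random
family sampling the pairwise overlap is too weak for the significance
threshold and genera shatter. Within-family protein pairs get
reciprocal hits with bit scores uniform in [60, 300] and e-value 1e-20
— comfortably clear of the 50 / 1e-3 thresholds — and no cross-family
hits exist.

**Structure.** A prophage_fraction of viruses are spliced into their
host chromosome at gene-boundary sites (host gene coordinates shifted,
span recorded as truth); the rest are extrachromosomal contigs,
circular with probability 0.9 (ssDNA-like genera) or 0.5. ParA/ParB
flags are set at rate 0.13 on extrachromosomal-looking sequences and
0.01 elsewhere — the empirically observed contrast used as generative
rates. Caudovirales viruses carry one terL gene (hallmark); every
virus's first gene is a hallmark. The prediction table contains one
row per virus plus decoys, each violating exactly one curation rule
(PhiX label, category 3, hallmark-less prophage, short linear, short
circular). A gene-hit table emulates similarity searches against
reference profiles: 95% of family-bearing genes hit their true-lineage
profile (scores 150–300), 5% hit a wrong-lineage profile at lower
score (60–120) — the relevant-hit filter of the LCA affiliation is
what removes these.

**Fragmentation.** `fragment_genomes` cuts each host chromosome at
`ceil(L/target) − 1` uniform breakpoints (or explicit ones), keeping
host-gene counts and prophage overlaps per contig as truth. A contig
made only of prophage sequence, with no host gene, is exactly the case
curation would misread as extrachromosomal; the misclassification rate
of integrated prophages falls monotonically as the size threshold
grows from 10 to 30 kb (the sets are nested by construction; the
experiment shows the 30 kb rate is a small fraction of the 10 kb one,
~0.1–0.3% vs ~10% at a 20 kb target contig length).

**What the synthetic validation does not show.** The generator has no
sequence evolution, no read simulation or assembly, no shared genes
between viral genera (cross-genus similarity is exactly zero, so
cluster recovery is easier than reality), i.i.d. codon sampling (no
local genomic structure: real k-mer distances have heavier tails), and
label-based PhiX identification. Passing tests establish that the
implementations compute their definitions correctly and that the chain
recovers planted structure under realistic noise magnitudes — not that
the specific published accuracies would be reproduced on real data,
which would require the original ~15,000-genome corpus and large-scale
homology searches.

## Pipeline

`run_all` executes curation → clustering → taxonomy → host network →
composition → host prediction → co-infection, writing each stage's
tables before the next starts. All randomness flows from one master
seed through named substreams (`seed × 2654435761 + crc32(stage) mod
2^31−1`), so identical config + seed reproduce the bundle exactly; a
disabled stage makes dependent stages fail fast with the stage names.
Defaults equal the published operating point: score ≥ 50, e-value ≤
1e-3, significance 1, inflation 4, VC size > 10, 99 permutations, bins
4e-4 / 1e-3. The pipeline's demo world uses 6 hosts per genus (96
viruses) so the virus clusters clear the >10-member matrix cut; the
library-level default world keeps 4.

The taxonomy stage consumes the generator's gene-hit table (the
stand-in for reference-database searches); co-infection uses the
stage's sequence affiliations, not truth labels.

## Problem sizes

Default validation runs use 32–48 hosts (6.4–9.6 Mb of sequence),
64–96 viruses, ~1,200 proteins, 99-permutation nulls, 100-replicate
fragmentations and 100-matrix modularity oracles; the full test suite
completes in well under a minute and the acceptance script in
~10 seconds.
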