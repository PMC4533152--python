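"""Measure virus-host genome composition and codon usage adaptation.

For each virus, the k-mer MAE distance (and codon adaptation index) to
its host is compared against 10 random genomes from the same genus, the
same family, and a different order; the separation of the distance
distributions is summarised by a two-sample K-S statistic D.
"""

import warnings

from provirome import SimulationConfig, adaptation_experiment, generate_world

world = generate_world(SimulationConfig(seed=1))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # small categories are skipped
    report = adaptation_experiment(
        world.virus_seqs(), world.host_seqs(), world.truth.virus_host,
        world.host_lineages(), metrics=("k1", "k2", "k3", "k4", "cai"),
        n_picks=3, virus_genes=world.virus_cds(), host_cds=world.host_cds(),
        seed=0,
    )

print(report.pivot(index="metric", columns="category", values="D").round(3))
# D grows with taxonomic distance from the host: distances to
# different-order genomes separate almost perfectly from distances to
# the true host, while same-genus genomes are nearly indistinguishable
# -- the composition signal mirrors the host taxonomy.
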