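"""Generate a synthetic world of hosts and viruses with known truth.

The world carries per-genus codon biases, prophages inserted into host
chromosomes, genus-level viral protein-family pools, a similarity table
and a prediction table with curation decoys.
"""

from provirome import SimulationConfig, generate_world

world = generate_world(SimulationConfig(seed=1))

n_prophages = sum(1 for v in world.viral_sequences if v.prophage_span is not None)
print(f"hosts:            {len(world.hosts)}")
print(f"viral sequences:  {len(world.viral_sequences)} "
      f"({n_prophages} integrated prophages)")
print(f"prediction rows:  {len(world.predictions)} "
      f"({len(world.truth.decoy_ids)} decoys)")
print(f"similarity rows:  {len(world.similarity)}")

v = world.viral_sequences[0]
print(f"\nexample virus {v.virus_id}: {len(v.sequence)} bp, "
      f"{len(v.genes)} genes, lineage {v.lineage}, "
      f"host {world.truth.virus_host[v.virus_id]}")
# The truth tables (virus -> host, virus -> genus, protein -> family)
# are what downstream recovery is scored against.
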