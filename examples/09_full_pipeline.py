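"""Run every stage end to end from one config with one master seed.

Stages: curation -> clustering -> taxonomy -> host network ->
composition -> host prediction -> co-infection.  All outputs are TSV
tables plus a summary JSON; identical config and seed reproduce the
bundle byte for byte.
"""

import json

from provirome import PipelineConfig, run_all

config = PipelineConfig(outdir="pipeline_demo", seed=42)
bundle = run_all(config)

summary = bundle.summary
print(f"outputs in {bundle.outdir}/")
print(f"curation:   {summary['curation']['n_retained']} retained / "
      f"{summary['curation']['n_input']} predictions")
print(f"clustering: {summary['clustering']['n_vcs']} VCs "
      f"({summary['clustering']['n_new']} putative new genera)")
print(f"modularity: Q = {summary['host_network']['q_obs']:.3f} "
      f"(p = {summary['host_network']['p_value']:.2f})")
print("host prediction accuracy:",
      json.dumps(summary['host_prediction']['accuracy']['none']))
print(f"coinfection: {summary['coinfection']['n_counted']} counted")
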