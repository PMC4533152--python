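"""End-to-end orchestration of the analysis stages.

Stages run in order — curation, gene-sharing clustering, taxonomy,
virus-host network, composition, host prediction, co-infection — each
writing its tables before the next starts, all randomness flowing from
one master seed through named per-stage substreams, so the same config
and seed always produce the same bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coinfection as coinf
from . import composition as comp
from . import curation as cur
from . import hostnet
from . import hostpred
from . import io as pio
from . import network as net
from . import taxonomy as tax
from .synthetic import SimulationConfig, generate_world

logger = logging.getLogger("provirome")

STAGES = (
    "curation", "clustering", "taxonomy", "host_network",
    "composition", "host_prediction", "coinfection",
)

STAGE_REQUIRES = {
    "clustering": ("curation",),
    "taxonomy": ("clustering",),
    "host_network": ("clustering",),
    "composition": ("curation",),
    "host_prediction": ("curation",),
    "coinfection": ("taxonomy",),
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    return (master_seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published operating point.

    Score >= 50 and e-value <= 1e-3 for similarity hits, significance
    threshold 1 and inflation 4 for genome clustering, VCs with more
    than 10 sequences in the host matrix, 99 permutations for the
    modularity null, and host-prediction distance bins at 4e-4 / 1e-3.
    """

    # the pipeline demo world uses 6 hosts per genus so virus clusters
    # clear the >10-member cut of the virus-host matrix stage
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(hosts_per_genus=6)
    )
    outdir: str = "provirome_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    min_score: float = 50.0
    max_evalue: float = 1e-3
    protein_inflation: float = 2.0
    sig_threshold: float = 1.0
    genome_inflation: float = 4.0
    min_vc_size: int = 10
    n_perm: int = 99
    n_restarts: int = 20
    n_picks: int = 10
    adaptation_metrics: tuple = ("k1", "k2", "k3", "k4", "cai")
    exclusion_modes: tuple = ("none", "host_species", "host_genus")
    exclusions: tuple = ()  # manually curated sequence ids to drop

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("adaptation_metrics", "exclusion_modes", "exclusions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(simulation=sim, **raw)
        missing = set(STAGES) - set(cfg.stages)
        cfg.stages = {s: cfg.stages.get(s, True) for s in STAGES}
        del missing
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return d


@dataclass
class ReportBundle:
    outdir: Path
    summary: dict
    products: dict


def _require(products: dict, stage: str) -> None:
    for dep in STAGE_REQUIRES.get(stage, ()):
        if dep not in products:
            raise RuntimeError(
                f"stage {stage!r} requires outputs of disabled stage {dep!r}; "
                f"enable it or provide its outputs"
            )


def run_all(config: PipelineConfig) -> ReportBundle:
    """Run every enabled stage on a freshly generated synthetic world."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    summary: dict = {"config": config.to_dict(), "stage_seeds": {}}
    products: dict = {}
    try:
        sim_cfg = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        summary["stage_seeds"]["simulate"] = sim_cfg.seed
        logger.info("simulating world: %s", sim_cfg)
        world = generate_world(sim_cfg)
        pio.write_world(world, outdir / "inputs")
        products["world"] = world
        summary["n_hosts"] = len(world.hosts)
        summary["n_viruses"] = len(world.viral_sequences)
        summary["n_predictions"] = len(world.predictions)

        for stage in STAGES:
            if not config.stages.get(stage, True):
                logger.info("stage %s disabled", stage)
                continue
            _require(products, stage)
            seed = stage_seed(config.seed, stage)
            summary["stage_seeds"][stage] = seed
            logger.info("running stage %s (seed %d)", stage, seed)
            _STAGE_FUNCS[stage](config, world, products, summary, outdir, seed)
    finally:
        logger.removeHandler(handler)
        handler.close()

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    return ReportBundle(outdir=outdir, summary=summary, products=products)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# stage implementations


def _stage_curation(config, world, products, summary, outdir, seed):
    records = pio.predictions_to_records(world.predictions)
    retained, rejections = cur.apply_curation_filters(records, config.exclusions)
    curated = [cur.classify_replication_mode(r) for r in retained]
    pio.records_to_frame(retained).to_csv(outdir / "curated.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sequence_id": r.sequence_id, "rule": r.rule} for r in rejections]
    ).to_csv(outdir / "rejections.tsv", sep="\t", index=False)

    modes = pd.Series([c.replication_mode for c in curated]).value_counts().to_dict()
    extra = [c for c in curated if c.replication_mode == cur.EXTRACHROMOSOMAL]
    rest = [c for c in curated if c.replication_mode != cur.EXTRACHROMOSOMAL]
    k1 = sum(1 for c in extra if c.parA or c.parB)
    k2 = sum(1 for c in rest if c.parA or c.parB)
    p_marker = (
        cur.marker_enrichment_test(k1, len(extra), k2, len(rest))
        if extra and rest
        else None
    )
    products["curation"] = {"retained": retained, "curated": curated,
                            "rejections": rejections}
    summary["curation"] = {
        "n_input": len(records),
        "n_retained": len(retained),
        "n_rejected": len(rejections),
        "replication_modes": modes,
        "parab_extrachromosomal": [k1, len(extra)],
        "parab_other": [k2, len(rest)],
        "parab_p_value": p_marker,
    }
    logger.info("curation: %d retained / %d input", len(retained), len(records))


def _stage_clustering(config, world, products, summary, outdir, seed):
    retained_ids = {r.sequence_id for r in products["curation"]["retained"]}
    prot2seq = {
        p: v for p, v in world.protein_to_virus().items() if v in retained_ids
    }
    sim = world.similarity
    sim = sim[sim["qseqid"].isin(prot2seq) & sim["sseqid"].isin(prot2seq)]
    pcs = net.protein_clusters(
        sim,
        min_score=config.min_score,
        max_evalue=config.max_evalue,
        inflation=config.protein_inflation,
        protein_to_genome=prot2seq,
    )
    gene_counts = {
        vid: n for vid, n in world.gene_counts().items() if vid in retained_ids
    }
    profiles = net.genome_profiles(pcs, prot2seq, gene_counts)
    network = net.build_genome_network(profiles, sig_threshold=config.sig_threshold)
    clusters, unclustered = net.cluster_genomes(
        network, inflation=config.genome_inflation
    )
    vcs, vc_counts = net.classify_vcs(clusters, world.sequence_metadata())

    pd.DataFrame(
        [(pc, p) for pc, members in pcs.items() for p in sorted(members)],
        columns=["pc_id", "protein_id"],
    ).to_csv(outdir / "protein_clusters.tsv", sep="\t", index=False)
    pio.write_edge_list(outdir / "genome_network_edges.tsv", network)
    pd.DataFrame(
        [
            {
                "vc_id": vc.vc_id,
                "n_members": len(vc.members),
                "status": vc.status,
                "members": ",".join(sorted(vc.members)),
            }
            for vc in vcs
        ]
    ).to_csv(outdir / "virus_clusters.tsv", sep="\t", index=False)

    products["clustering"] = {"pcs": pcs, "profiles": profiles,
                              "network": network, "vcs": vcs,
                              "unclustered": unclustered}
    summary["clustering"] = {
        "n_proteins_clustered": sum(len(m) for m in pcs.values()),
        "n_pcs": len(pcs),
        "n_sequences_clustered": sum(len(vc.members) for vc in vcs),
        "n_unclustered": len(unclustered),
        **vc_counts,
    }
    logger.info("clustering: %d PCs, %d VCs", len(pcs), len(vcs))


def _stage_taxonomy(config, world, products, summary, outdir, seed):
    retained_ids = {r.sequence_id for r in products["curation"]["retained"]}
    hits = world.gene_hits
    hits = hits[hits["sequence_id"].isin(retained_ids)]
    seq_affiliations: dict[str, tax.Lineage] = {}
    n_relevant: dict[str, int] = {}
    for seq_id, grp in hits.groupby("sequence_id"):
        gene_hits = [
            tax.GeneHit(
                gene_id=row.gene_id,
                target_id=row.target_id,
                score=float(row.score),
                lineage=tax.Lineage.from_string(row.lineage, tax.VIRUS_RANKS),
            )
            for row in grp.itertuples(index=False)
        ]
        seq_affiliations[str(seq_id)] = tax.affiliate_sequence(gene_hits)
        n_relevant[str(seq_id)] = len(tax.relevant_hits(gene_hits))
    for seq_id in retained_ids - set(seq_affiliations):
        seq_affiliations[seq_id] = tax.Lineage.unassigned(tax.VIRUS_RANKS)
        n_relevant[seq_id] = 0

    vc_affiliations = {}
    for vc in products["clustering"]["vcs"]:
        vc_affiliations[vc.vc_id] = tax.affiliate_vc(
            [seq_affiliations[m] for m in sorted(vc.members)]
        )
    pd.DataFrame(
        [
            {
                "sequence_id": sid,
                "lineage": str(seq_affiliations[sid]),
                "n_relevant_hits": n_relevant[sid],
            }
            for sid in sorted(seq_affiliations)
        ]
    ).to_csv(outdir / "sequence_affiliations.tsv", sep="\t", index=False)
    tax.write_lineages(outdir / "vc_affiliations.tsv", vc_affiliations)
    products["taxonomy"] = {"sequences": seq_affiliations, "vcs": vc_affiliations}
    n_aff = sum(1 for lin in seq_affiliations.values() if not lin.is_unclassified)
    summary["taxonomy"] = {
        "n_sequences_affiliated": n_aff,
        "n_vcs_unclassified": sum(
            1 for lin in vc_affiliations.values() if lin.is_unclassified
        ),
    }
    logger.info("taxonomy: %d/%d sequences affiliated", n_aff, len(seq_affiliations))


def _stage_host_network(config, world, products, summary, outdir, seed):
    vc_members = {
        vc.vc_id: vc.members for vc in products["clustering"]["vcs"]
    }
    host_class = world.virus_host_class()
    try:
        matrix = hostnet.build_incidence(
            vc_members, host_class, min_vc_size=config.min_vc_size
        )
    except ValueError as exc:
        logger.warning("host network skipped: %s", exc)
        summary["host_network"] = {"skipped": str(exc)}
        return
    partition, null = hostnet.permutation_null(
        matrix, n_perm=config.n_perm, seed=seed, n_restarts=config.n_restarts
    )
    pio.write_matrix(outdir / "incidence_matrix.tsv", matrix)
    pd.DataFrame(
        {
            "node": list(matrix.index) + list(matrix.columns),
            "side": ["vc"] * len(matrix.index) + ["host_class"] * len(matrix.columns),
            "module": list(partition.row_modules) + list(partition.col_modules),
        }
    ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    products["host_network"] = {"matrix": matrix, "partition": partition,
                                "null": null}
    summary["host_network"] = {
        "n_vcs": matrix.shape[0],
        "n_host_classes": matrix.shape[1],
        "q_obs": null.q_obs,
        "q_perm_min": null.q_perm_min,
        "q_perm_mean": null.q_perm_mean,
        "q_perm_max": null.q_perm_max,
        "p_value": null.p_value,
    }
    logger.info("host network: Q=%.3f (p=%.3f)", null.q_obs, null.p_value)


def _stage_composition(config, world, products, summary, outdir, seed):
    retained_ids = {r.sequence_id for r in products["curation"]["retained"]}
    viruses = {v: s for v, s in world.virus_seqs().items() if v in retained_ids}
    curated = {c.sequence_id: c for c in products["curation"]["curated"]}
    strata = {v: curated[v].replication_mode for v in viruses}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = comp.adaptation_experiment(
            viruses,
            world.host_seqs(),
            world.truth.virus_host,
            world.host_lineages(),
            metrics=config.adaptation_metrics,
            n_picks=config.n_picks,
            strata=strata,
            virus_genes=world.virus_cds(),
            host_cds=world.host_cds(),
            seed=seed,
        )
    report.to_csv(outdir / "adaptation_report.tsv", sep="\t", index=False)
    products["composition"] = {"report": report}
    summary["composition"] = {
        "n_rows": len(report),
        "ks_by_metric": {
            m: {
                c: float(d)
                for c, d in zip(sub["category"], sub["D"])
            }
            for m, sub in report[report["stratum"] == report["stratum"].iloc[0]]
            .groupby("metric")[["category", "D"]]
        }
        if len(report)
        else {},
    }
    logger.info("composition: %d report rows", len(report))


def _stage_host_prediction(config, world, products, summary, outdir, seed):
    retained_ids = {r.sequence_id for r in products["curation"]["retained"]}
    viruses = {v: s for v, s in world.virus_seqs().items() if v in retained_ids}
    predictions = hostpred.host_prediction_experiment(
        viruses,
        world.host_seqs(mask_prophages=True),
        world.truth.virus_host,
        world.host_lineages(),
        exclusions=config.exclusion_modes,
    )
    evaluation = hostpred.evaluate_predictions(predictions)
    pd.DataFrame(
        [
            {
                "virus_id": p.virus_id,
                "predicted_genome": p.predicted_genome,
                "distance": p.distance,
                "bin": p.bin,
                "exclusion": p.exclusion,
                "correct_order": int(p.correct_order),
                "correct_family": int(p.correct_family),
                "correct_genus": int(p.correct_genus),
            }
            for p in predictions
        ]
    ).to_csv(outdir / "host_predictions.tsv", sep="\t", index=False)
    evaluation.to_csv(outdir / "host_prediction_accuracy.tsv", sep="\t", index=False)
    products["host_prediction"] = {"predictions": predictions,
                                   "evaluation": evaluation}
    acc = {
        mode: {
            rank: hostpred.accuracy_at_rank(predictions, rank, mode)
            for rank in hostpred.RANKS_SCORED
        }
        for mode in config.exclusion_modes
    }
    summary["host_prediction"] = {"accuracy": acc}
    logger.info("host prediction: %s", acc)


def _stage_coinfection(config, world, products, summary, outdir, seed):
    retained = products["curation"]["retained"]
    affiliations = products["taxonomy"]["sequences"]
    table = pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "genome_id": r.genome_id,
                "order": affiliations[r.sequence_id].get("order"),
                "family": affiliations[r.sequence_id].get("family"),
                "terL_count": r.terl_count,
            }
            for r in retained
        ]
    )
    records, hist, pairs = coinf.detect_coinfections(table)
    hist.to_csv(outdir / "coinfection_histogram.tsv", sep="\t", index=False)
    pairs.to_csv(outdir / "coinfection_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "n_viral_sequences": r.n_viral_sequences,
                "terL_total": r.terl_total,
                "counted": int(r.counted),
            }
            for r in records
        ]
    ).to_csv(outdir / "coinfection_records.tsv", sep="\t", index=False)
    products["coinfection"] = {"records": records, "histogram": hist,
                               "pairs": pairs}
    summary["coinfection"] = {
        "n_genomes_with_virus": len(records),
        "n_candidates": sum(1 for r in records if r.n_viral_sequences >= 2),
        "n_counted": sum(1 for r in records if r.counted),
        "n_pairs": int(pairs["n_pairs"].sum()) if len(pairs) else 0,
    }
    logger.info("coinfection: %d counted", summary["coinfection"]["n_counted"])


_STAGE_FUNCS = {
    "curation": _stage_curation,
    "clustering": _stage_clustering,
    "taxonomy": _stage_taxonomy,
    "host_network": _stage_host_network,
    "composition": _stage_composition,
    "host_prediction": _stage_host_prediction,
    "coinfection": _stage_coinfection,
}
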