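"""End-to-end orchestration: simulate -> classify -> DE -> targets ->
networks -> enrichment -> qPCR quantification.

Every stage writes plain-text artifacts into the output directory; the run
finishes with a ``manifest.json`` mapping each artifact to its SHA-256, so
two runs with the same configuration and seed are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import diff_expression as de
from . import enrichment as enr
from . import fragment_typing as ft
from . import network as net
from . import simulate as sim
from . import target_scan as ts
from . import validation as vq
from .trna import read_reference_fasta, write_reference_fasta

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "classify", "de", "targets", "network",
              "enrich", "ddct")
FEATURE_CLASSES = ("mRNA", "miRNA", "tRF")


@dataclass
class Thresholds:
    mrna_fold: float = 2.0
    sncrna_fold: float = 1.2
    alpha: float = 0.05
    target_score: float = 140.0

    def validate(self) -> None:
        if min(self.mrna_fold, self.sncrna_fold, self.alpha,
               self.target_score) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineConfig:
    outdir: str = "trfnet_out"
    seed: int = 0
    simulation: sim.SimulationConfig = field(
        default_factory=sim.SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: Sequence[str] = ALL_STAGES
    adapter: Optional[str] = None
    hub_targets: int = 25
    #: externally supplied inputs (paths); any slot given here replaces the
    #: simulated artifact for downstream stages
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        simc = sim.SimulationConfig(**d.get("simulation", {}))
        thr = Thresholds(**d.get("thresholds", {}))
        cfg = cls(outdir=d.get("outdir", "trfnet_out"),
                  seed=int(d.get("seed", 0)),
                  simulation=simc, thresholds=thr,
                  stages=tuple(d.get("stages", ALL_STAGES)),
                  adapter=d.get("adapter"),
                  hub_targets=int(d.get("hub_targets", 25)),
                  inputs=dict(d.get("inputs", {})))
        cfg.simulation.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        self.thresholds.validate()
        self.simulation.validate()
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()),
        str(path), "fasta")


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


class PipelineRun:
    """Mutable context threaded through the stages."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, dict[str, str]] = {}
        self.truth = sim.GroundTruth()
        self.refs = None
        self.expr: dict[str, pd.DataFrame] = {}
        self.de_results: dict[str, pd.DataFrame] = {}
        self.sncrna_seqs: dict[str, str] = {}
        self.utrs: dict[str, str] = {}
        self.pairs: dict[str, pd.DataFrame] = {}
        self.graphs: dict[str, object] = {}
        self.gene_sets = None

    def record(self, stage: str, *paths: Path) -> None:
        entry = self.manifest.setdefault(stage, {})
        for p in paths:
            entry[p.name] = _sha256(p)


def _stage_simulate(run: PipelineRun) -> None:
    cfg, out = run.config, run.outdir
    scfg = cfg.simulation
    run.refs = sim.make_trna_reference(scfg)
    write_reference_fasta(run.refs, out / "trna_reference.fa")

    reads, read_truth = sim.simulate_reads(run.refs, scfg, adapter=cfg.adapter)
    run.truth.read_classes = read_truth.read_classes
    sim.write_fastq(reads, out / "reads.fastq")

    for cls in FEATURE_CLASSES:
        mat, t = sim.simulate_expression(scfg, cls, refs=run.refs)
        run.expr[cls] = mat
        run.truth.de_direction[cls] = t.de_direction[cls]
        mat.to_csv(out / f"expr_{cls}.tsv", sep="\t")

    snc_ids = [f for c in ("miRNA", "tRF")
               for f, d in run.truth.de_direction[c].items() if d != "null"]
    run.sncrna_seqs = sim.simulate_sncrna_sequences(scfg, snc_ids)
    _write_fasta({k: sim.dna(v) for k, v in run.sncrna_seqs.items()},
                 out / "sncrna.fa")

    mrna_ids = list(run.expr["mRNA"].index)
    de_mrnas = [f for f, d in run.truth.de_direction["mRNA"].items()
                if d != "null"]
    utrs = sim.make_utrs(scfg, mrna_ids)
    utrs, run.truth = sim.plant_target_sites(
        utrs, run.sncrna_seqs, de_mrnas, scfg, run.truth)
    # designate a hub: the first upregulated small RNA, targeting
    # downregulated mRNAs so the anti-correlation rule keeps its edges
    ups = sorted(f for f, d in run.truth.de_direction["tRF"].items()
                 if d == "up" and f in run.sncrna_seqs)
    downs = sorted(f for f, d in run.truth.de_direction["mRNA"].items()
                   if d == "down")
    if ups and downs and cfg.hub_targets > 0:
        hub = ups[0]
        utrs, run.truth = sim.plant_hub_sites(
            utrs, hub, run.sncrna_seqs[hub], downs, cfg.hub_targets,
            scfg, run.truth)
    run.utrs = utrs
    _write_fasta(utrs, out / "utr.fa")

    ct, ct_truth = sim.simulate_ct_table(scfg)
    run.truth.true_ddct = ct_truth.true_ddct
    ct.to_csv(out / "ct.tsv", sep="\t", index=False)

    run.gene_sets = sim.make_gene_sets(scfg, mrna_ids)
    enr.write_gmt(run.gene_sets, out / "gene_sets.gmt")
    (out / "tf_list.txt").write_text(
        "\n".join(sorted(net.default_tf_list())) + "\n")

    run.truth.to_json(out / "ground_truth.json")
    run.record("simulate", *(out / f for f in (
        "trna_reference.fa", "reads.fastq", "expr_mRNA.tsv", "expr_miRNA.tsv",
        "expr_tRF.tsv", "sncrna.fa", "utr.fa", "ct.tsv", "gene_sets.gmt",
        "tf_list.txt", "ground_truth.json")))


def _stage_classify(run: PipelineRun) -> None:
    cfg, out = run.config, run.outdir
    reads_path = cfg.inputs.get("reads", out / "reads.fastq")
    ref_path = cfg.inputs.get("trna_fasta", out / "trna_reference.fa")
    refs = run.refs or read_reference_fasta(ref_path)
    reads = ft.read_small_rna_file(reads_path)
    calls, unmapped = ft.classify_reads(reads, refs, adapter=cfg.adapter)
    calls.to_csv(out / "fragment_calls.tsv", sep="\t", index=False)
    (out / "unmapped.txt").write_text("\n".join(unmapped) + ("\n" if unmapped
                                                             else ""))
    dist = ft.type_distribution(calls)
    dist.overall.rename("fraction").to_csv(out / "type_distribution.tsv",
                                           sep="\t")
    dist.per_ref.to_csv(out / "type_distribution_per_trna.tsv", sep="\t")
    run.record("classify", out / "fragment_calls.tsv", out / "unmapped.txt",
               out / "type_distribution.tsv",
               out / "type_distribution_per_trna.tsv")


def _stage_de(run: PipelineRun) -> None:
    cfg, out = run.config, run.outdir
    thr = cfg.thresholds
    files = []
    for cls in FEATURE_CLASSES:
        if cls in run.expr:
            mat = run.expr[cls]
        else:
            path = cfg.inputs.get(f"expr_{cls}", out / f"expr_{cls}.tsv")
            mat = pd.read_csv(path, sep="\t", index_col=0)
        norm = de.normalize_cpm(mat)
        threshold = thr.mrna_fold if cls == "mRNA" else thr.sncrna_fold
        res = de.de_test(norm, feature_class=cls, alpha=thr.alpha,
                         threshold=threshold)
        run.de_results[cls] = res
        res.to_csv(out / f"de_{cls}.tsv", sep="\t")
        files.append(out / f"de_{cls}.tsv")
    summary = de.summarize_de(run.de_results)
    summary.to_csv(out / "de_summary.tsv", sep="\t")
    run.record("de", *files, out / "de_summary.tsv")


def _stage_targets(run: PipelineRun) -> None:
    cfg, out = run.config, run.outdir
    params = dataclasses.replace(ts.ScanParams(),
                                 threshold=cfg.thresholds.target_score)
    if not run.sncrna_seqs:
        run.sncrna_seqs = {k: sim.rna(v) for k, v in _read_fasta(
            Path(cfg.inputs.get("sncrna_fasta", out / "sncrna.fa"))).items()}
    if not run.utrs:
        run.utrs = ts.read_utr_fasta(
            cfg.inputs.get("utr_fasta", out / "utr.fa"))
    files = []
    for cls in ("miRNA", "tRF"):
        de_res = run.de_results[cls]
        de_ids = de_res.index[de_res["direction"] != "ns"]
        seqs = {i: run.sncrna_seqs[i] for i in de_ids
                if i in run.sncrna_seqs}
        pairs = ts.predict_targets(seqs, run.utrs, params)
        run.pairs[cls] = pairs
        path = out / f"pairs_{cls}.tsv"
        pairs.to_csv(path, sep="\t", index=False)
        files.append(path)
    run.record("targets", *files)


def _stage_network(run: PipelineRun) -> None:
    cfg, out = run.config, run.outdir
    tf_path = cfg.inputs.get("tf_list", out / "tf_list.txt")
    tfs = (net.read_tf_list(tf_path) if Path(tf_path).exists()
           else net.default_tf_list())
    # mRNA symbols double as TF symbols in the simulation: flag any mRNA id
    # listed in the TF file
    files = []
    graphs = {}
    for cls, rtype in (("miRNA", "miRNA"), ("tRF", "tRF/tiRNA")):
        edges = net.pair_filter(run.de_results[cls], run.de_results["mRNA"],
                                run.pairs[cls])
        g = net.build_network(edges, run.de_results[cls],
                              run.de_results["mRNA"], tfs, rtype)
        graphs[cls] = g
        net.write_graphml(g, out / f"network_{cls}.graphml")
        net.write_sif(g, out / f"network_{cls}.sif")
        net.node_table(g).to_csv(out / f"nodes_{cls}.tsv", sep="\t",
                                 index=False)
        files += [out / f"network_{cls}.graphml", out / f"network_{cls}.sif",
                  out / f"nodes_{cls}.tsv"]
    combined = net.merge_networks(graphs["miRNA"], graphs["tRF"])
    graphs["combined"] = combined
    net.write_graphml(combined, out / "network_combined.graphml")
    net.write_sif(combined, out / "network_combined.sif")
    net.node_table(combined).to_csv(out / "nodes_combined.tsv", sep="\t",
                                    index=False)
    hubs = {cls: net.hub_ranking(graphs[cls], k=10)
            for cls in graphs if graphs[cls].number_of_nodes()}
    (out / "hubs.json").write_text(json.dumps(hubs, indent=1, sort_keys=True))
    overlap = sorted(net.tf_overlap(graphs["miRNA"], graphs["tRF"]))
    (out / "tf_overlap.txt").write_text("\n".join(overlap) +
                                        ("\n" if overlap else ""))
    run.graphs = graphs
    run.record("network", *files, out / "network_combined.graphml",
               out / "network_combined.sif", out / "nodes_combined.tsv",
               out / "hubs.json", out / "tf_overlap.txt")


def _stage_enrich(run: PipelineRun) -> None:
    cfg, out = run.config, run.outdir
    gmt_path = cfg.inputs.get("gmt", out / "gene_sets.gmt")
    gene_sets = enr.read_gmt(gmt_path)
    background = list(run.de_results["mRNA"].index)
    combined = run.graphs.get("combined")
    genes = sorted(n for n, d in combined.nodes(data=True)
                   if d["node_type"] == "mRNA") if combined is not None else []
    if not genes:
        logger.warning("no network genes; skipping enrichment")
        return
    table = enr.enrich(genes, gene_sets, background, mode="ease")
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    enr.bubble_table(table, top_n=min(10, len(table))).to_csv(
        out / "enrichment_bubble.tsv", sep="\t", index=False)
    run.record("enrich", out / "enrichment.tsv", out / "enrichment_bubble.tsv")


def _stage_ddct(run: PipelineRun) -> None:
    cfg, out = run.config, run.outdir
    ct_path = cfg.inputs.get("ct", out / "ct.tsv")
    table = vq.read_ct_table(ct_path)
    per_sample, per_group = vq.ddct(table, calibrator_group="control")
    per_sample.to_csv(out / "rq.tsv", sep="\t", index=False)
    per_group.to_csv(out / "rq_groups.tsv", sep="\t", index=False)
    values = {g: v["rq"].tolist() for g, v in per_sample.groupby("group")}
    stats = vq.group_compare(values)
    stats.pop("pairwise", None)
    (out / "rq_stats.json").write_text(json.dumps(stats, indent=1,
                                                  sort_keys=True))
    run.record("ddct", out / "rq.tsv", out / "rq_groups.tsv",
               out / "rq_stats.json")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "de": _stage_de,
    "targets": _stage_targets,
    "network": _stage_network,
    "enrich": _stage_enrich,
    "ddct": _stage_ddct,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return and write
    the artifact manifest."""
    run = PipelineRun(config)
    log_handler = logging.FileHandler(run.outdir / "run.log", mode="w")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("trfnet")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            try:
                _STAGE_FN[stage](run)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", stage,
                        time.perf_counter() - t0)
        (run.outdir / "manifest.json").write_text(
            json.dumps(run.manifest, indent=1, sort_keys=True))
        return run.manifest
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
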