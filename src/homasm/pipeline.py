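"""Two-stage homoeolog-specific assembly pipeline.

Stage 1 runs the assembler in permissive mode over all quality-filtered
reads to produce a deliberately homoeolog-insensitive rough assembly whose
only purpose is to group reads: rough contigs are transitively clustered
by shared canonical 32-mers, reads are assigned to those clusters by the
same criterion, and the rough contigs are then discarded.  Stage 2
re-assembles every cluster independently in strict mode, filters contigs
by length and consensus quality, and de-duplicates contigs that are fully
contained in a contig of another cluster sharing a multi-assigned read.

Cluster assemblies are independent, so the final output is identical
regardless of the order (or concurrency) in which clusters are processed;
the pipeline is deterministic under a fixed seed and configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import asm, cluster as clus, evalhom, readqc
from .align import revcomp
from .synth import Read

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    qc: readqc.QcParams = field(default_factory=readqc.QcParams)
    stage1: asm.AsmParams = field(default_factory=asm.permissive_params)
    stage2: asm.AsmParams = field(default_factory=asm.strict_params)
    cluster_k: int = 32
    #: clusters above this many reads are subsampled (seeded, logged)
    cluster_read_cap: int = 20000
    evaluate: bool = False
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.stage1.min_relative_score
                < self.stage2.min_relative_score):
            raise ValueError("stage-1 must be more permissive than stage-2")


def config_from_yaml(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a nested key/value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "qc" in raw:
        kwargs["qc"] = readqc.QcParams(**raw["qc"])
    if "stage1" in raw:
        kwargs["stage1"] = asm.permissive_params(**raw["stage1"])
    if "stage2" in raw:
        kwargs["stage2"] = asm.strict_params(**raw["stage2"])
    for key in ("cluster_k", "cluster_read_cap", "evaluate", "seed", "outdir"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


@dataclass
class RunResult:
    contigs: list[asm.Contig]
    qc_summary: readqc.QcSummary
    partition: clus.ClusterPartition
    assignment: clus.ReadAssignment
    cluster_stats: pd.DataFrame
    outdir: Optional[Path] = None


def _containment_dedup(contigs: list[asm.Contig],
                       assignment: clus.ReadAssignment) -> list[asm.Contig]:
    """Drop contigs fully contained in another contig they share a
    multi-assigned read with."""
    multi = {rid for rid, cids in assignment.assignments.items()
             if len(cids) > 1}
    members = {c.name: {rid for rid, _, _ in c.members} for c in contigs}
    by_name = {c.name: c for c in contigs}
    # longest first; a contig can only be contained in a longer (or, on
    # ties, lexicographically earlier) one
    names = sorted(by_name, key=lambda n: (-len(by_name[n]), n))
    dropped: set[str] = set()
    for pos, small in enumerate(names):
        shared_pool = members[small] & multi
        if not shared_pool:
            continue
        cs = by_name[small]
        for big in names[:pos]:
            if big in dropped or not (shared_pool & members[big]):
                continue
            cb = by_name[big]
            if cs.consensus in cb.consensus or \
                    revcomp(cs.consensus) in cb.consensus:
                dropped.add(small)
                break
    return [c for c in contigs if c.name not in dropped]


def run_two_stage(reads: Sequence[Read], config: PipelineConfig | None = None,
                  cluster_order: Optional[Sequence[int]] = None) -> RunResult:
    """Run QC, rough assembly, clustering, and per-cluster strict assembly.

    ``cluster_order`` optionally overrides the stage-2 processing order;
    the result is identical for any permutation (order-independence
    contract).  Artifacts are written under ``config.outdir`` when set.
    """
    if config is None:
        config = PipelineConfig()
    t0 = time.time()
    kept, qc_summary = readqc.qc_readset(reads, config.qc)
    if not kept:
        raise RuntimeError("no reads survived quality filtering")
    log.info("QC: kept %d/%d reads (%.1fs)", qc_summary.n_kept,
             qc_summary.n_input, time.time() - t0)

    t0 = time.time()
    rough = asm.assemble_cluster(kept, config.stage1, cluster_id=0)
    rough_map = {c.name: c.consensus for c in rough
                 if len(c) >= config.cluster_k}
    if not rough_map:
        raise RuntimeError("stage-1 rough assembly produced no usable contigs")
    log.info("stage 1: %d rough contigs (%.1fs)", len(rough_map),
             time.time() - t0)

    partition = clus.cluster_contigs(rough_map, config.cluster_k)
    assignment = clus.assign_reads(kept, rough_map, partition,
                                   config.cluster_k)
    stats = clus.cluster_stats(assignment)
    # rough contigs are used only for clustering and then discarded
    del rough, rough_map

    reads_by_id = {r.read_id: r for r in kept}
    cluster_reads: dict[int, list[str]] = {cid: [] for cid in partition.clusters}
    for rid in sorted(assignment.assignments):
        for cid in assignment.assignments[rid]:
            cluster_reads[cid].append(rid)

    order = sorted(partition.clusters) if cluster_order is None \
        else list(cluster_order)
    final: list[asm.Contig] = []
    for cid in order:
        rids = cluster_reads.get(cid, [])
        if not rids:
            continue
        if len(rids) > config.cluster_read_cap:
            rng = np.random.default_rng([config.seed, cid])
            rids = sorted(rng.choice(sorted(rids), size=config.cluster_read_cap,
                                     replace=False))
            log.warning("cluster %d subsampled to %d reads (seed %d)",
                        cid, config.cluster_read_cap, config.seed)
        t0 = time.time()
        contigs = asm.assemble_cluster([reads_by_id[r] for r in sorted(set(rids))],
                                       config.stage2, cluster_id=cid)
        final += asm.filter_contigs(contigs, config.stage2)
        log.info("cluster %d: %d reads -> %d contigs (%.1fs)", cid,
                 len(rids), len(contigs), time.time() - t0)
    final = _containment_dedup(final, assignment)
    final.sort(key=lambda c: c.name)
    result = RunResult(contigs=final, qc_summary=qc_summary,
                       partition=partition, assignment=assignment,
                       cluster_stats=stats)
    if config.outdir:
        result.outdir = Path(config.outdir)
        _write_run(result)
    return result


def _write_run(result: RunResult) -> None:
    out = result.outdir
    out.mkdir(parents=True, exist_ok=True)
    asm.contigs_to_fasta(result.contigs, out / "contigs.fasta")
    asm.contig_table(result.contigs).to_csv(out / "contigs.tsv", sep="\t",
                                            index=False)
    readqc.summary_to_tsv(result.qc_summary, out / "qc_summary.tsv")
    clus.partition_to_tsv(result.partition, out / "clusters.tsv")
    clus.assignment_to_tsv(result.assignment, out / "assignments.tsv")
    result.cluster_stats.to_csv(out / "cluster_stats.tsv", sep="\t",
                                index=False)


# ---------------------------------------------------------------------------
# reporting

def rate_percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage rounded for reporting, e.g. 27/186 -> 14.5."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, digits)


def read_accounting(n_pairs_kept: int, n_singles_kept: int,
                    n_long: int = 0) -> dict:
    """Read totals in the form used for run summaries."""
    short_total = 2 * n_pairs_kept + n_singles_kept
    return {"n_short_reads": short_total, "n_long_reads": n_long,
            "n_total_reads": short_total + n_long}


def length_distribution(lengths: Sequence[int]) -> pd.DataFrame:
    """Cumulative contig-length distribution (number longer than L)."""
    ls = np.sort(np.asarray(lengths))[::-1]
    return pd.DataFrame({"length": ls,
                         "n_at_least": np.arange(1, len(ls) + 1)})


def report(run_dir, references=None) -> dict:
    """Summarise a completed run directory; optionally evaluate against
    a reference homoeolog set (FASTA path or mapping).

    Returns the summary as a dict and writes ``report.txt`` (plus
    evaluation TSVs) into the run directory.
    """
    run_dir = Path(run_dir)
    needed = ["contigs.fasta", "contigs.tsv", "qc_summary.tsv",
              "clusters.tsv", "cluster_stats.tsv"]
    for name in needed:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing run artifact: {name}")
    from Bio import SeqIO

    contigs = {rec.id: str(rec.seq)
               for rec in SeqIO.parse(str(run_dir / "contigs.fasta"), "fasta")}
    qc_row = pd.read_csv(run_dir / "qc_summary.tsv", sep="\t").iloc[0]
    lengths = [len(s) for s in contigs.values()]
    assigned_frac = 0.0
    if (run_dir / "assignments.tsv").exists():
        adf = pd.read_csv(run_dir / "assignments.tsv", sep="\t")
        if len(adf):
            assigned_frac = float(adf["cluster_ids"].notna().mean())
    summary: dict = {
        "n_contigs": len(contigs),
        "n_clusters": int(pd.read_csv(run_dir / "clusters.tsv", sep="\t")
                          ["cluster_id"].nunique()),
        "longest_contig": max(lengths) if lengths else 0,
        "n_contigs_over_1kb": sum(1 for l in lengths if l > 1000),
        "qc": {k: int(qc_row[k]) for k in qc_row.index},
        "assigned_read_fraction": assigned_frac,
    }
    summary.update(read_accounting(int(qc_row["n_pairs_kept"]),
                                   int(qc_row["n_singles_kept"])))
    lines = [
        "homasm run summary",
        f"  contigs: {summary['n_contigs']} "
        f"(>1kb: {summary['n_contigs_over_1kb']}, "
        f"longest: {summary['longest_contig']})",
        f"  clusters: {summary['n_clusters']}",
        f"  reads kept: {summary['qc']['n_kept']} of {summary['qc']['n_input']}"
        f" ({summary['qc']['n_pairs_kept']} pairs + "
        f"{summary['qc']['n_singles_kept']} singles)",
    ]
    if references is not None:
        refs = evalhom.read_reference_fasta(references) \
            if isinstance(references, (str, Path)) \
            else evalhom.flatten_references(references)
        by_family: dict[str, dict[str, str]] = {}
        for rid, seq in refs.items():
            by_family.setdefault(rid.rsplit("|", 1)[0], {})[rid] = seq
        metrics = evalhom.benchmark(contigs, refs)
        hist, peak = evalhom.identity_histogram(contigs)
        cov = evalhom.coverage_profile(refs, contigs)
        summary["benchmark"] = metrics
        summary["chimera_rate_percent"] = rate_percent(
            metrics.n_chimeric, metrics.n_assigned)
        summary["identified_percent"] = rate_percent(
            metrics.n_identified, metrics.n_possible)
        summary["peak"] = peak
        if peak is not None:
            summary["snp_stats"] = evalhom.snp_stats(peak.mean_identity)
        summary["coverage_matched"] = cov.matched_fraction
        evalhom.histogram_to_tsv(hist, run_dir / "identity_histogram.tsv")
        cov.profiles.to_csv(run_dir / "coverage_profile.tsv", sep="\t")
        lines += [
            f"  homoeologs identified: {metrics.n_identified} of "
            f"{metrics.n_possible} ({summary['identified_percent']}%)",
            f"  chimeric contigs: {metrics.n_chimeric} of "
            f"{metrics.n_assigned} ({summary['chimera_rate_percent']}%)",
        ]
        if peak is not None:
            lines.append(
                f"  homoeolog identity peak: {peak.mean_identity:.1f}% "
                f"(sd {peak.sd_identity:.1f}%), excess hits "
                f"{peak.excess_hits:.0f}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    summary["text"] = text
    return summary
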