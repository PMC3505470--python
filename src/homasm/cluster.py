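"""Transitive k-mer clustering of rough contigs and read-to-cluster assignment.

Two contigs belong to the same cluster when they share at least one exact
canonical 32-mer (a shared contiguous 32-base substring on either strand);
the relation is closed transitively with union-find.  Reads then join every
cluster whose contigs they share a canonical 32-mer with, so a read may be
assigned to zero, one, or several clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import revcomp
from .synth import Read

log = logging.getLogger(__name__)

DEFAULT_K = 32


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Canonical (lexicographic min of kmer/revcomp) k-mers, Ns skipped."""
    out: set[str] = set()
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        rc = revcomp(w)
        out.add(w if w <= rc else rc)
    return out


class KmerIndex:
    """Map from canonical k-mer to the set of sequence ids containing it."""

    def __init__(self, k: int = DEFAULT_K):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.k = k
        self.map: dict[str, set[str]] = {}

    def add(self, name: str, seq: str) -> None:
        for w in canonical_kmers(seq, self.k):
            self.map.setdefault(w, set()).add(name)

    def lookup(self, seq: str) -> set[str]:
        found: set[str] = set()
        for w in canonical_kmers(seq, self.k):
            hit = self.map.get(w)
            if hit:
                found |= hit
        return found


@dataclass
class ClusterPartition:
    """Disjoint clusters covering all contigs, numbered deterministically.

    Cluster ids are consecutive integers ordered by the lexicographically
    smallest member contig id.
    """

    clusters: dict[int, frozenset[str]] = field(default_factory=dict)
    contig_to_cluster: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if seen & members:
                raise ValueError("clusters are not disjoint")
            seen |= members
            for m in members:
                if self.contig_to_cluster.get(m) != cid:
                    raise ValueError("inconsistent contig->cluster map")


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _as_items(contigs) -> list[tuple[str, str]]:
    if isinstance(contigs, Mapping):
        return sorted(contigs.items())
    return sorted(contigs)


def cluster_contigs(contigs, k: int = DEFAULT_K) -> ClusterPartition:
    """Partition contigs into transitive shared-k-mer clusters.

    Contigs shorter than k cannot share a k-mer and become singletons
    (logged).
    """
    items = _as_items(contigs)
    if not items:
        raise ValueError("no contigs to cluster")
    short = [name for name, seq in items if len(seq) < k]
    if short:
        log.info("%d contigs shorter than k=%d form singleton clusters",
                 len(short), k)
    uf = _UnionFind()
    index: dict[str, str] = {}  # canonical k-mer -> representative contig id
    for name, seq in items:
        uf.find(name)
        for w in canonical_kmers(seq, k):
            other = index.get(w)
            if other is None:
                index[w] = name
            else:
                uf.union(name, other)
    groups: dict[str, set[str]] = {}
    for name, _ in items:
        groups.setdefault(uf.find(name), set()).add(name)
    partition = ClusterPartition()
    for cid, root in enumerate(sorted(groups, key=lambda r: min(groups[r]))):
        members = frozenset(groups[root])
        partition.clusters[cid] = members
        for m in members:
            partition.contig_to_cluster[m] = cid
    partition.validate()
    return partition


@dataclass
class ReadAssignment:
    """Read id -> set of cluster ids (possibly empty, possibly several)."""

    assignments: dict[str, set[int]] = field(default_factory=dict)

    def assigned_fraction(self) -> float:
        if not self.assignments:
            return 0.0
        return sum(1 for s in self.assignments.values() if s) / len(self.assignments)


def assign_reads(reads: Sequence[Read], contigs, partition: ClusterPartition,
                 k: int = DEFAULT_K) -> ReadAssignment:
    """Assign each read to every cluster it shares a canonical k-mer with."""
    items = _as_items(contigs)
    kmer_to_clusters: dict[str, set[int]] = {}
    for name, seq in items:
        cid = partition.contig_to_cluster[name]
        for w in canonical_kmers(seq, k):
            kmer_to_clusters.setdefault(w, set()).add(cid)
    assignment = ReadAssignment()
    for read in reads:
        found: set[int] = set()
        for w in canonical_kmers(read.sequence, k):
            hit = kmer_to_clusters.get(w)
            if hit:
                found |= hit
        assignment.assignments[read.read_id] = found
    return assignment


def cluster_stats(assignment: ReadAssignment) -> pd.DataFrame:
    """Per-cluster read counts with a cumulative-fraction curve.

    Rows are ordered by descending cluster size; ``cum_fraction`` is the
    cumulative share of assigned read instances (a multi-assigned read
    counts once per cluster).  The frame carries the overall assigned read
    fraction in ``df.attrs['assigned_fraction']``.
    """
    counts: dict[int, int] = {}
    for clusters in assignment.assignments.values():
        for cid in clusters:
            counts[cid] = counts.get(cid, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["cluster_id", "n_reads"],
    )
    total = int(df["n_reads"].sum()) if len(df) else 0
    df["cum_fraction"] = df["n_reads"].cumsum() / total if total else 0.0
    df.attrs["assigned_fraction"] = assignment.assigned_fraction()
    return df


def partition_to_tsv(partition: ClusterPartition, path) -> None:
    rows = sorted(partition.contig_to_cluster.items())
    pd.DataFrame(rows, columns=["contig_id", "cluster_id"]).to_csv(
        path, sep="\t", index=False)


def assignment_to_tsv(assignment: ReadAssignment, path) -> None:
    rows = [
        {"read_id": rid, "cluster_ids": ",".join(map(str, sorted(cids)))}
        for rid, cids in sorted(assignment.assignments.items())
    ]
    pd.DataFrame(rows, columns=["read_id", "cluster_ids"]).to_csv(
        path, sep="\t", index=False)
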