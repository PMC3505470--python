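"""Evaluation of homoeolog-specific assemblies against reference triplets.

Implements the reference-based quality control used throughout the
package: allocation of contigs to individual homoeologs by iteratively
accepting the highest-%ID match, tripartite chimera detection (piece-wise
re-allocation over thirds of each homoeolog), benchmark fractions,
all-vs-all identity-distribution statistics with a background-subtracted
homoeolog peak, SNP-rate conversions, and positional coverage profiling.

Reference homoeolog sets are FASTA files with ``family|genome`` headers
(genomes A/B/D) or in-memory mappings of the same shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignParams, AlignmentHit, all_vs_all, local_align

#: matching parameters emulating a stringent nucleotide database search
DEFAULT_MATCH_PARAMS = AlignParams(min_aligned_length=100, min_pct_id=90.0)
#: piece-wise matching needs shorter alignments (pieces are thirds)
DEFAULT_PIECE_PARAMS = AlignParams(min_aligned_length=50, min_pct_id=90.0)


# ---------------------------------------------------------------------------
# references

def flatten_references(reference_families) -> dict[str, str]:
    """Normalise references to a flat ``{"family|genome": seq}`` mapping.

    Accepts a list of :class:`~homasm.synth.HomoeologFamily`, a nested
    mapping ``{family: {genome: seq}}``, or an already-flat mapping.
    """
    flat: dict[str, str] = {}
    if isinstance(reference_families, Mapping):
        for key, val in reference_families.items():
            if isinstance(val, Mapping):
                for lab, seq in val.items():
                    flat[f"{key}|{lab}"] = seq
            else:
                flat[key] = val
    else:
        for fam in reference_families:
            for lab in fam.genome_labels:
                flat[f"{fam.family_id}|{lab}"] = fam.sequences[lab]
    return flat


def read_reference_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# identity matrix and allocation

def build_identity_matrix(contigs: Mapping[str, str],
                          references: Mapping[str, str],
                          params: AlignParams | None = None,
                          ) -> tuple[pd.DataFrame, dict]:
    """%ID of every qualifying contig-reference alignment.

    Returns the matrix (rows contigs, columns references, NaN where no
    qualifying hit) and the underlying hits keyed ``(contig, reference)``.
    """
    if params is None:
        params = DEFAULT_MATCH_PARAMS
    matrix = pd.DataFrame(np.nan, index=sorted(contigs),
                          columns=sorted(references))
    hits: dict[tuple[str, str], AlignmentHit] = {}
    for cid, rid in _cross_candidates(contigs, references, params):
        hit = local_align(contigs[cid], references[rid], params,
                          query_id=cid, target_id=rid)
        if hit is not None:
            matrix.loc[cid, rid] = hit.pct_id
            hits[(cid, rid)] = hit
    return matrix, hits


def _cross_candidates(contigs: Mapping[str, str],
                      references: Mapping[str, str],
                      params: AlignParams) -> list[tuple[str, str]]:
    """Contig/reference pairs worth aligning (several shared seed words)."""
    from .align import candidate_pairs

    items = [("c::" + k, v) for k, v in contigs.items()] + \
            [("r::" + k, v) for k, v in references.items()]
    min_hits = 3 if params.min_aligned_length >= 100 else 1
    out = []
    for a, b in candidate_pairs(items, params.seed_length, min_hits):
        if a[:3] != b[:3]:
            cid = a[3:] if a.startswith("c::") else b[3:]
            rid = b[3:] if b.startswith("r::") else a[3:]
            out.append((cid, rid))
    return sorted(out)


@dataclass
class Allocation:
    """One-to-one contig-to-homoeolog assignment in acceptance order."""

    order: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def mapping(self) -> dict[str, str]:
        return {c: r for c, r, _ in self.order}

    def validate(self) -> None:
        pcts = [p for _, _, p in self.order]
        if any(a < b for a, b in zip(pcts, pcts[1:])):
            raise ValueError("acceptance %IDs must be non-increasing")
        if len({c for c, _, _ in self.order}) != len(self.order) or \
                len({r for _, r, _ in self.order}) != len(self.order):
            raise ValueError("allocation is not one-to-one")


def iterative_allocation(matrix: pd.DataFrame) -> Allocation:
    """Allocate contigs to homoeologs by repeatedly accepting the globally
    best %ID cell and deleting its row and column.

    Ties are broken by lexicographic (contig, homoeolog) order.  Cells
    without a qualifying hit (NaN) are never accepted.
    """
    if matrix.size == 0:
        raise ValueError("empty identity matrix")
    m = matrix.copy()
    alloc = Allocation()
    while m.size and not m.isna().all().all():
        best = m.max().max()
        rows, cols = np.nonzero(m.values == best)
        cand = sorted((str(m.index[r]), str(m.columns[c]))
                      for r, c in zip(rows, cols))
        contig, hom = cand[0]
        alloc.order.append((contig, hom, float(best)))
        m = m.drop(index=contig, columns=hom)
    alloc.validate()
    return alloc


# ---------------------------------------------------------------------------
# chimera detection

def split_into_pieces(seq: str, n: int = 3) -> list[str]:
    """Split into ``n`` equal pieces; remainder bases go to the last piece."""
    third = len(seq) // n
    return [seq[i * third : (i + 1) * third] for i in range(n - 1)] + \
        [seq[(n - 1) * third :]]


def detect_chimera(contig: str, family_references: Mapping[str, str],
                   params: AlignParams | None = None) -> str:
    """Tripartite consistency check of one contig against a homoeolog set.

    Each reference homoeolog is split into three equal pieces and the
    contig is re-allocated to a homoeolog per piece; pieces without a
    qualifying hit are ignored.  Returns ``"chimeric"`` when the allocated
    homoeolog differs between informative pieces, ``"unassigned"`` when no
    piece is informative, ``"consistent"`` otherwise.
    """
    if len(family_references) < 2:
        raise ValueError("chimera detection needs >= 2 reference homoeologs")
    if params is None:
        params = DEFAULT_PIECE_PARAMS
    assigned: list[str] = []
    for p in range(3):
        pieces = {rid: split_into_pieces(seq)[p]
                  for rid, seq in family_references.items()}
        best: Optional[tuple[float, str]] = None
        for rid in sorted(pieces):
            if not pieces[rid]:
                continue
            hit = local_align(contig, pieces[rid], params)
            if hit is None:
                continue
            if best is None or hit.pct_id > best[0]:
                best = (hit.pct_id, rid)
        if best is not None:
            assigned.append(best[1])
    if not assigned:
        return "unassigned"
    return "chimeric" if len(set(assigned)) > 1 else "consistent"


# ---------------------------------------------------------------------------
# benchmark

@dataclass
class BenchmarkMetrics:
    """Assembly-vs-reference fractions (all in [0, 1])."""

    frac_identified: float
    frac_chimeric: float
    frac_half_length: float
    n_possible: int
    n_identified: int
    n_assigned: int
    n_chimeric: int

    def __post_init__(self) -> None:
        for v in (self.frac_identified, self.frac_chimeric,
                  self.frac_half_length):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def benchmark(contigs: Mapping[str, str], reference_families,
              params: AlignParams | None = None,
              id_threshold: float = 98.0) -> BenchmarkMetrics:
    """Benchmark contigs against curated fully-overlapping homoeolog sets.

    ``frac_identified`` is the fraction of reference homoeologs whose
    allocated contig matches at %ID above ``id_threshold``;
    ``frac_chimeric`` the fraction of allocated contigs with piece-wise
    evidence of chimerism; ``frac_half_length`` the fraction of allocated
    contigs whose alignment spans more than half the homoeolog length.
    """
    refs = flatten_references(reference_families)
    if params is None:
        params = DEFAULT_MATCH_PARAMS
    matrix, hits = build_identity_matrix(contigs, refs, params)
    alloc = iterative_allocation(matrix) if len(matrix) else Allocation()
    n_possible = len(refs)
    n_identified = sum(1 for _, _, p in alloc.order if p > id_threshold)
    by_family: dict[str, dict[str, str]] = {}
    for rid, seq in refs.items():
        fam = rid.rsplit("|", 1)[0]
        by_family.setdefault(fam, {})[rid] = seq
    n_chimeric = 0
    n_half = 0
    for contig, rid, _pct in alloc.order:
        fam = rid.rsplit("|", 1)[0]
        fam_refs = by_family[fam]
        if len(fam_refs) >= 2:
            if detect_chimera(contigs[contig], fam_refs) == "chimeric":
                n_chimeric += 1
        hit = hits[(contig, rid)]
        ts, te = hit.target_interval
        if (te - ts) > 0.5 * len(refs[rid]):
            n_half += 1
    n_assigned = len(alloc.order)
    return BenchmarkMetrics(
        frac_identified=n_identified / n_possible if n_possible else 0.0,
        frac_chimeric=n_chimeric / n_assigned if n_assigned else 0.0,
        frac_half_length=n_half / n_assigned if n_assigned else 0.0,
        n_possible=n_possible, n_identified=n_identified,
        n_assigned=n_assigned, n_chimeric=n_chimeric)


# ---------------------------------------------------------------------------
# identity distribution

@dataclass
class HomoeologPeakEstimate:
    """Background-subtracted homoeolog identity peak."""

    mean_identity: float
    sd_identity: float
    excess_hits: float

    def __post_init__(self) -> None:
        if not (85.0 < self.mean_identity <= 100.0):
            raise ValueError("peak mean outside (85, 100]")
        if self.excess_hits < 0:
            raise ValueError("excess_hits must be >= 0")


def identity_histogram(contigs: Mapping[str, str],
                       params: AlignParams | None = None,
                       bin_width: float = 0.5,
                       background_range: tuple[float, float] = (85.0, 92.0),
                       peak_threshold: float = 93.0,
                       ) -> tuple[pd.DataFrame, Optional[HomoeologPeakEstimate]]:
    """All-vs-all %ID histogram with a homoeolog-peak estimate.

    At most one (best) hit per unordered sequence pair enters the
    histogram.  The background level is the median bin count over
    ``background_range``; the excess above background summed over bins at
    or above ``peak_threshold`` estimates the number of homoeologous
    sequence pairs, and its weighted mean/sd describe the peak.
    """
    if params is None:
        params = AlignParams(min_aligned_length=400)
    hits = all_vs_all(contigs, params)
    edges = np.arange(80.0, 100.0 + 2 * bin_width, bin_width)
    values = [min(h.pct_id, 100.0) for h in hits]
    counts, _ = np.histogram(values, bins=edges)
    starts = edges[:-1]
    bg_mask = (starts >= background_range[0]) & (starts < background_range[1])
    background = float(np.median(counts[bg_mask])) if bg_mask.any() else 0.0
    excess = np.where(starts >= peak_threshold, counts - background, 0.0)
    hist = pd.DataFrame({"bin_start": starts, "count": counts,
                         "background": background, "excess": excess})
    weights = np.clip(excess, 0.0, None)
    total = float(weights.sum())
    estimate = None
    if total >= 3.0:
        centers = np.minimum(starts + bin_width / 2.0, 100.0)
        mean = float(np.average(centers, weights=weights))
        sd = float(math.sqrt(np.average((centers - mean) ** 2, weights=weights)))
        estimate = HomoeologPeakEstimate(
            mean_identity=mean, sd_identity=sd,
            excess_hits=max(float(excess.sum()), 0.0))
    return hist, estimate


# ---------------------------------------------------------------------------
# SNP-rate conversions

def snp_stats(mean_identity: float) -> dict:
    """Convert a pairwise homoeolog %ID into SNP-rate conventions.

    ``per_sequence_snp_freq`` is the divergence of one copy from the
    common ancestor, half the pairwise divergence; spacings are bases per
    SNP under the per-sequence and the pairwise-mismatch conventions.
    """
    if not (0.0 < mean_identity <= 100.0):
        raise ValueError("identity must be in (0, 100]")
    per_seq = (100.0 - mean_identity) / 2.0
    if per_seq == 0.0:
        return {"per_sequence_snp_freq": 0.0,
                "per_sequence_spacing": math.inf,
                "pairwise_mismatch_spacing": math.inf}
    return {
        "per_sequence_snp_freq": per_seq,
        "per_sequence_spacing": round(100.0 / per_seq),
        "pairwise_mismatch_spacing": round(100.0 / (100.0 - mean_identity)),
    }


@dataclass(frozen=True)
class TripletBound:
    raw: float
    rounded_to_hundred: int


def triplet_lower_bound(excess_hits: float) -> TripletBound:
    """Lower bound on homoeolog triplet count from excess pairwise hits.

    Every expressed triplet contributes three pairwise hits to the
    identity-histogram excess, so the bound is ``excess / 3``.
    """
    if excess_hits < 0:
        raise ValueError("excess_hits must be >= 0")
    raw = excess_hits / 3.0
    return TripletBound(raw=raw, rounded_to_hundred=int(round(raw / 100.0) * 100))


# ---------------------------------------------------------------------------
# coverage profiling

@dataclass
class CoverageProfile:
    """Positional coverage of references by contigs at %ID cut-offs."""

    profiles: pd.DataFrame  # n_bins rows, one column per cutoff
    matched_fraction: dict[float, float]
    long_alignment_fraction: dict[float, float]


def coverage_profile(references: Mapping[str, str],
                     contigs: Mapping[str, str],
                     pct_id_cutoffs: Sequence[float] = (90.0, 98.0, 99.0),
                     params: AlignParams | None = None,
                     n_bins: int = 100) -> CoverageProfile:
    """Average positional coverage along references, per %ID cut-off.

    For each cut-off, every reference contributes the fraction of its
    positions covered by at least one qualifying contig alignment, on a
    relative-position axis of ``n_bins`` bins; profiles are averaged over
    all references (uncovered references contribute zeros).  Also reports
    the fraction of references matched at all and the fraction whose best
    single alignment spans more than 80% of the reference length.
    """
    if not references:
        raise ValueError("references must be non-empty")
    if params is None:
        params = AlignParams(min_aligned_length=100)
    ref_hits: dict[str, list[AlignmentHit]] = {rid: [] for rid in references}
    for cid, rid in _cross_candidates(contigs, references, params):
        hit = local_align(contigs[cid], references[rid], params,
                          query_id=cid, target_id=rid)
        if hit is not None:
            ref_hits[rid].append(hit)
    profiles = {}
    matched = {}
    long_frac = {}
    for cutoff in pct_id_cutoffs:
        acc = np.zeros(n_bins)
        n_matched = 0
        n_long = 0
        for rid, seq in references.items():
            L = len(seq)
            covered = np.zeros(L, dtype=bool)
            best_span = 0
            any_hit = False
            for hit in ref_hits[rid]:
                if hit.pct_id < cutoff:
                    continue
                any_hit = True
                ts, te = hit.target_interval
                covered[ts:te] = True
                best_span = max(best_span, te - ts)
            if any_hit:
                n_matched += 1
            if best_span > 0.8 * L:
                n_long += 1
            bins = np.minimum((np.arange(L) * n_bins) // L, n_bins - 1)
            acc += np.bincount(bins, weights=covered, minlength=n_bins) / \
                np.bincount(bins, minlength=n_bins)
        profiles[cutoff] = acc / len(references)
        matched[cutoff] = n_matched / len(references)
        long_frac[cutoff] = n_long / len(references)
    return CoverageProfile(
        profiles=pd.DataFrame(profiles,
                              index=pd.RangeIndex(n_bins, name="bin")),
        matched_fraction=matched, long_alignment_fraction=long_frac)


def histogram_to_tsv(hist: pd.DataFrame, path) -> None:
    hist.to_csv(path, sep="\t", index=False)
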