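"""Seed-and-extend local alignment with banded affine-gap extension.

This is the package's stand-in for BLASTN wherever a percent identity
(%ID) or an alignment length is needed.  Alignments are found by exact
seeding (default word size 11), grouping of seed diagonals into bands, and
banded Smith-Waterman extension over each band; both strands of the target
are searched.  E-value thresholds of database search tools are replaced by
explicit ``(min_aligned_length, min_pct_id, min_score)`` cut-offs, which
are reproducible and database-size independent.

%ID is defined as identical columns divided by total alignment columns,
*including* gap columns, times 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._kernels import NEG, OP_DIAG, banded_align, encode

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignParams:
    """Scoring and filtering parameters for local alignment.

    A gap run of length L is penalised ``gap_open + L * gap_extend``.
    Defaults are BLASTN-like.  ``seed_length`` is the exact-match word size
    used for seeding (>= 11, mirroring BLASTN's nucleotide word size);
    ``band_pad`` is the number of diagonals added on each side of a seed
    diagonal group during banded extension.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -3.0
    gap_extend: float = -2.0
    min_aligned_length: int = 0
    min_pct_id: float = 0.0
    min_score: float = 0.0
    seed_length: int = 11
    band_pad: int = 50

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.seed_length < 11:
            raise ValueError("seed_length must be >= 11")
        if self.band_pad < 1:
            raise ValueError("band_pad must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between a query and a target sequence.

    Intervals are 0-based half-open on the *forward* strand of each
    sequence; for strand '-' the alignment pairs the query with the
    reverse complement of the target.
    """

    query_id: str
    target_id: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    strand: str
    aligned_length: int
    pct_id: float
    score: float
    identities: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_id <= 100.0):
            raise ValueError("pct_id out of range")


def _seed_diagonals(a: str, b: str, k: int) -> list[int]:
    """Diagonals (j - i) of all exact k-mer matches between a and b."""
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        w = a[i : i + k]
        if "N" in w or "n" in w:
            continue
        index.setdefault(w, []).append(i)
    diags: set[int] = set()
    for j in range(len(b) - k + 1):
        hits = index.get(b[j : j + k])
        if hits:
            for i in hits:
                diags.add(j - i)
    return sorted(diags)


def _group_diagonals(diags: list[int], pad: int) -> list[tuple[int, int]]:
    """Split sorted seed diagonals into bands, padding each side."""
    groups: list[tuple[int, int]] = []
    start = prev = diags[0]
    for d in diags[1:]:
        if d - prev > 2 * pad:
            groups.append((start - pad, prev + pad))
            start = d
        prev = d
    groups.append((start - pad, prev + pad))
    return groups


def _extend(a_codes: np.ndarray, b_codes: np.ndarray, lo: int, hi: int,
            params: AlignParams):
    buf = np.empty(a_codes.shape[0] + b_codes.shape[0], dtype=np.int8)
    res = banded_align(
        a_codes, b_codes, lo, hi,
        params.match, params.mismatch, params.gap_open, params.gap_extend,
        True, False, buf,
    )
    return res


def local_align(a: str, b: str, params: AlignParams | None = None, *,
                query_id: str = "query", target_id: str = "target"):
    """Best local alignment of ``a`` against either strand of ``b``.

    Returns an :class:`AlignmentHit` or ``None`` when no seeded alignment
    reaches the configured thresholds.
    """
    if params is None:
        params = AlignParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a_codes = encode(a)
    best = None  # (score, strand, i0, j0, i1, j1, cols, ident, len_b)
    for strand in "+-":
        bs = b if strand == "+" else revcomp(b)
        diags = _seed_diagonals(a, bs, params.seed_length)
        if not diags:
            continue
        b_codes = encode(bs)
        for lo, hi in _group_diagonals(diags, params.band_pad):
            score, i0, j0, i1, j1, n_ops, n_id = _extend(
                a_codes, b_codes, lo, hi, params)
            if score <= NEG / 2:
                continue
            if best is None or score > best[0]:
                best = (score, strand, i0, j0, i1, j1, n_ops, n_id)
    if best is None:
        return None
    score, strand, i0, j0, i1, j1, cols, ident = best
    if strand == "-":
        t_iv = (len(b) - j1, len(b) - j0)
    else:
        t_iv = (j0, j1)
    pct = 100.0 * ident / cols if cols else 0.0
    if (cols < params.min_aligned_length or pct < params.min_pct_id
            or score < params.min_score):
        return None
    return AlignmentHit(
        query_id=query_id, target_id=target_id,
        query_interval=(i0, i1), target_interval=t_iv, strand=strand,
        aligned_length=cols, pct_id=pct, score=score, identities=ident,
    )


def _as_items(seqs) -> list[tuple[str, str]]:
    if isinstance(seqs, Mapping):
        return sorted(seqs.items())
    return sorted(seqs)


def candidate_pairs(items: list[tuple[str, str]], k: int,
                    min_hits: int = 1) -> set[tuple[str, str]]:
    """Unordered id pairs sharing at least ``min_hits`` distinct k-mers on
    either strand."""
    index: dict[str, set[str]] = {}
    for name, seq in items:
        seen = set()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" not in w and w not in seen:
                seen.add(w)
                index.setdefault(w, set()).add(name)
    counts: dict[tuple[str, str], int] = {}
    for name, seq in items:
        for s in (seq, revcomp(seq)):
            seen = set()
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if w in seen:
                    continue
                seen.add(w)
                hit = index.get(w)
                if hit:
                    for other in hit:
                        if other > name:
                            key = (name, other)
                            counts[key] = counts.get(key, 0) + 1
    return {pair for pair, n in counts.items() if n >= min_hits}


def all_vs_all(seqs, params: AlignParams | None = None) -> list[AlignmentHit]:
    """All-vs-all comparison keeping at most one (best) hit per pair.

    Default thresholds follow the whole-assembly diversity analysis: an
    alignment length of at least 400 columns.  Self comparisons are
    excluded and each unordered pair contributes at most one hit.
    """
    items = _as_items(seqs)
    if len(items) < 2:
        raise ValueError("all_vs_all needs at least two sequences")
    if params is None:
        params = AlignParams(min_aligned_length=400)
    lookup = dict(items)
    # an alignment of min_aligned_length columns at qualifying identity
    # shares many seed words; demand a proportional number of distinct
    # shared k-mers before running the DP
    min_hits = max(1, params.min_aligned_length // 100)
    hits = []
    for qid, tid in sorted(candidate_pairs(items, params.seed_length, min_hits)):
        hit = local_align(lookup[qid], lookup[tid], params,
                          query_id=qid, target_id=tid)
        if hit is not None:
            hits.append(hit)
    return hits


def hits_to_tabular(hits: Iterable[AlignmentHit]) -> str:
    """Render hits in the 12-column tab-separated (outfmt-6 style) order.

    Columns: query, target, pct_id, length, mismatches, gap columns,
    qstart, qend, tstart, tend, placeholder evalue ('.'), score.
    Coordinates are 1-based inclusive, target reversed on '-' strand.
    """
    rows = []
    for h in hits:
        qs, qe = h.query_interval
        ts, te = h.target_interval
        if h.strand == "-":
            t1, t2 = te, ts + 1
        else:
            t1, t2 = ts + 1, te
        gaps = h.aligned_length - min(qe - qs, te - ts)
        mism = (min(qe - qs, te - ts)) - h.identities
        rows.append("\t".join(str(x) for x in (
            h.query_id, h.target_id, f"{h.pct_id:.2f}", h.aligned_length,
            max(mism, 0), max(gaps, 0), qs + 1, qe, t1, t2, ".",
            f"{h.score:.1f}")))
    return "\n".join(rows) + ("\n" if rows else "")


def permissive(params: AlignParams, **kw) -> AlignParams:
    """Copy of ``params`` with overrides (convenience for analyses)."""
    return replace(params, **kw)
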