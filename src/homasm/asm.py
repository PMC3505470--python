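"""Homoeolog-sensitive greedy overlap-layout-consensus assembler.

The assembler accepts an overlap between two reads only when its *relative
score* -- alignment score divided by the maximum attainable score for the
overlap length (``match * columns``) -- reaches ``min_relative_score``.
In strict mode (default 0.97) overlaps between reads drawn from distinct
homoeologs (~97% identity, i.e. ~3 substitutions per 100 bases, each worth
``match - mismatch``) fall below the threshold and the copies assemble
apart; in permissive mode (0.90) they merge, emulating the behaviour of a
homoeolog-insensitive first-pass assembler.

Layout is greedy (best overlaps first).  Before two read layouts are
merged, implied overlaps between their other members are re-aligned and
the merge is rejected when observed divergence exceeds
``merge_max_divergence`` -- the package's reconstruction of a multi-pass
assembler learning about possible mis-assemblies.  Consensus is called per
column by quality-weighted plurality over a gap-aware pileup; remaining
high-quality disagreements (conflict columns) trigger a bipartition of the
reads by their alleles and a re-assembly of each part, up to ``max_passes``
rounds.  Mate-pair insert bounds are advisory during layout: violating
merges are deferred behind all compliant ones rather than forbidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from ._kernels import NEG, OP_DIAG, OP_GAP_A, OP_GAP_B, banded_align, encode
from .align import AlignParams, revcomp
from .synth import Read

log = logging.getLogger(__name__)


@dataclass
class AsmParams:
    """Assembly parameters; see :func:`strict_params` / :func:`permissive_params`."""

    min_relative_score: float = 0.97
    min_overlap: int = 40
    insert_min: int = 1
    insert_max: int = 500
    max_passes: int = 3
    min_contig_length: int = 250
    max_mean_error: float = 1e-4
    conflict_min_support: int = 2
    conflict_min_qual: int = 30
    scoring: AlignParams = field(default_factory=AlignParams)
    #: exact seed length for overlap candidate detection
    overlap_seed: int = 14
    #: extra diagonals around seed diagonals for the banded overlap DP
    band_pad: int = 16
    #: maximum pooled divergence (1 - identity fraction, over all validated
    #: implied overlaps) tolerated when merging two layouts
    merge_max_divergence: float = 0.015
    #: implied read pairs re-aligned per attempted layout merge
    n_validate: int = 8
    #: PHRED cap for consensus error probabilities (floor = 10^(-cap/10))
    quality_cap: int = 60
    #: terminal consensus columns with error above this are trimmed
    end_trim_error: float = 1e-3
    #: read-position stride for overlap candidate queries; None = auto
    candidate_stride: Optional[int] = None
    #: slack in bases around the insert bounds for the advisory pair check
    insert_slack: int = 60

    def __post_init__(self) -> None:
        if not (0.0 < self.min_relative_score <= 1.0):
            raise ValueError("min_relative_score must be in (0, 1]")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")
        for v in (self.min_overlap, self.max_passes, self.min_contig_length,
                  self.conflict_min_support, self.conflict_min_qual):
            if v <= 0:
                raise ValueError("thresholds must be positive")


def strict_params(**kw) -> AsmParams:
    """Homoeolog-separating settings (relative score 0.97)."""
    return AsmParams(**kw)


def permissive_params(**kw) -> AsmParams:
    """Homoeolog-insensitive settings for rough/first-pass assembly."""
    kw.setdefault("min_relative_score", 0.90)
    kw.setdefault("merge_max_divergence", 0.05)
    return AsmParams(**kw)


@dataclass(frozen=True)
class Overlap:
    """A dovetail or containment overlap between two reads.

    Coordinates refer to ``a``'s forward sequence and to ``b`` *after*
    orientation ('-' means b is reverse-complemented first).
    """

    a_id: str
    b_id: str
    orientation: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    columns: int
    identities: int
    score: float
    relative_score: float


@dataclass
class Contig:
    name: str
    consensus: str
    per_base_error: np.ndarray
    members: list[tuple[str, int, bool]]  # (read_id, layout offset, flipped)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.per_base_error)) if len(self.per_base_error) else 1.0

    def __len__(self) -> int:
        return len(self.consensus)


# ---------------------------------------------------------------------------
# read cache

class _ReadData:
    __slots__ = ("read", "fwd", "rc", "quals", "rquals", "length", "weights",
                 "rweights")

    def __init__(self, read: Read):
        self.read = read
        self.fwd = encode(read.sequence)
        self.rc = encode(revcomp(read.sequence))
        q = np.asarray(read.qualities, dtype=np.float64)
        self.quals = q
        self.rquals = q[::-1].copy()
        self.length = len(read.sequence)
        w = 1.0 - np.power(10.0, -q / 10.0)
        self.weights = w
        self.rweights = w[::-1].copy()

    def codes(self, flip: bool) -> np.ndarray:
        return self.rc if flip else self.fwd

    def qual(self, flip: bool) -> np.ndarray:
        return self.rquals if flip else self.quals

    def weight(self, flip: bool) -> np.ndarray:
        return self.rweights if flip else self.weights


def _kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer k-mers per start position; -1 where the window contains N."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win @ powers
    vals[(win >= 4).any(axis=1)] = -1
    return vals


# ---------------------------------------------------------------------------
# overlap computation

def _overlap_dp(a_codes, b_codes, lo, hi, scoring: AlignParams):
    buf = np.empty(a_codes.shape[0] + b_codes.shape[0], dtype=np.int8)
    return banded_align(a_codes, b_codes, lo, hi, scoring.match,
                        scoring.mismatch, scoring.gap_open, scoring.gap_extend,
                        False, False, buf)


def compute_overlaps(reads: Sequence[Read],
                     params: AsmParams | None = None) -> list[Overlap]:
    """All acceptable dovetail/containment overlaps between the reads.

    Candidates are seeded by shared exact ``overlap_seed``-mers (both
    orientations) and scored by banded affine DP around the seed
    diagonals; an overlap is kept when it spans at least ``min_overlap``
    columns with relative score >= ``min_relative_score``.  Output order
    is deterministic: score descending, then lexicographic ids.
    """
    if params is None:
        params = AsmParams()
    data = {r.read_id: _ReadData(r) for r in reads}
    ids = sorted(data)
    return _compute_overlaps(ids, data, params)


def _compute_overlaps(ids: list[str], data: dict[str, "_ReadData"],
                      params: AsmParams) -> list[Overlap]:
    k = params.overlap_seed
    stride = params.candidate_stride
    if stride is None:
        stride = 1 if len(ids) <= 100 else 7
    index: dict[int, list[tuple[int, int]]] = {}
    fwd_kmers = []
    for idx, rid in enumerate(ids):
        vals = _kmer_ints(data[rid].fwd, k)
        fwd_kmers.append(vals)
        for pos in range(vals.shape[0]):
            v = vals[pos]
            if v >= 0:
                index.setdefault(int(v), []).append((idx, pos))
    # candidate (lo_idx, hi_idx, orientation) -> [dmin, dmax] in the frame
    # of the DP (a = lower id forward, b = higher id oriented)
    cand: dict[tuple[int, int, str], list[int]] = {}

    def note(i, j, orient, d):
        key = (i, j, orient)
        rng = cand.get(key)
        if rng is None:
            cand[key] = [d, d]
        else:
            if d < rng[0]:
                rng[0] = d
            elif d > rng[1]:
                rng[1] = d

    for jdx, rid in enumerate(ids):
        rd = data[rid]
        vals = fwd_kmers[jdx]
        for pos in range(0, vals.shape[0], stride):
            v = vals[pos]
            if v < 0:
                continue
            for idx, pi in index.get(int(v), ()):
                if idx == jdx:
                    continue
                if idx < jdx:
                    note(idx, jdx, "+", pos - pi)
                else:
                    note(jdx, idx, "+", pi - pos)
        rvals = _kmer_ints(rd.rc, k)
        for pos in range(0, rvals.shape[0], stride):
            v = rvals[pos]
            if v < 0:
                continue
            for idx, pi in index.get(int(v), ()):
                if idx == jdx:
                    continue
                other = data[ids[idx]]
                if idx < jdx:
                    note(idx, jdx, "-", pos - pi)
                else:
                    # match between rc(j) and fwd(i) == fwd(j) and rc(i)
                    pj_f = rd.length - k - pos
                    pir = other.length - k - pi
                    note(jdx, idx, "-", pir - pj_f)
    overlaps: list[Overlap] = []
    pad = params.band_pad
    for (i, j, orient) in sorted(cand):
        dmin, dmax = cand[(i, j, orient)]
        a = data[ids[i]]
        b = data[ids[j]]
        # implied maximal overlap span; skip hopeless candidates
        ov_hi = min(a.length, b.length - dmin) - max(0, -dmax)
        if ov_hi < params.min_overlap:
            continue
        b_codes = b.rc if orient == "-" else b.fwd
        score, i0, j0, i1, j1, cols, ident = _overlap_dp(
            a.fwd, b_codes, dmin - pad, dmax + pad, params.scoring)
        if score <= NEG / 2 or cols < params.min_overlap:
            continue
        rel = score / (params.scoring.match * cols)
        if rel < params.min_relative_score:
            continue
        overlaps.append(Overlap(
            a_id=ids[i], b_id=ids[j], orientation=orient,
            a_start=i0, a_end=i1, b_start=j0, b_end=j1,
            columns=cols, identities=ident, score=float(score),
            relative_score=float(rel)))
    overlaps.sort(key=lambda o: (-o.score, o.a_id, o.b_id, o.orientation))
    return overlaps


# ---------------------------------------------------------------------------
# greedy layout

class _Layouts:
    """Mutable set of read layouts: read -> (offset, flip) per layout."""

    def __init__(self, ids: Iterable[str], data: dict[str, "_ReadData"]):
        self.data = data
        self.of: dict[str, int] = {}
        self.members: dict[int, dict[str, tuple[int, bool]]] = {}
        for n, rid in enumerate(sorted(ids)):
            self.of[rid] = n
            self.members[n] = {rid: (0, False)}

    def placement(self, rid: str) -> tuple[int, bool]:
        return self.members[self.of[rid]][rid]

    def _required_b_placement(self, o: Overlap) -> tuple[int, bool]:
        fa, ea = self.placement(o.a_id)
        la = self.data[o.a_id].length
        lb = self.data[o.b_id].length
        rc = o.orientation == "-"
        if not ea:
            return fa + o.a_start - o.b_start, rc
        return (fa + (la - 1 - o.a_start) - (lb - 1 - o.b_start), not rc)

    def transform(self, o: Overlap):
        """Transform mapping b's current layout onto a's, or None if same."""
        la_id = self.of[o.a_id]
        lb_id = self.of[o.b_id]
        if la_id == lb_id:
            return None
        reqoff, reqflip = self._required_b_placement(o)
        gb, eb = self.members[lb_id][o.b_id]
        lb = self.data[o.b_id].length
        if eb == reqflip:
            return (la_id, lb_id, reqoff - gb, False)
        return (la_id, lb_id, reqoff + gb + lb, True)

    def project(self, rid: str, lb_id: int, shift: int, mirror: bool):
        g, e = self.members[lb_id][rid]
        ln = self.data[rid].length
        if not mirror:
            return g + shift, e
        return shift - (g + ln), not e

    def apply(self, la_id: int, lb_id: int, shift: int, mirror: bool) -> None:
        tgt = self.members[la_id]
        for rid in self.members[lb_id]:
            off, flip = self.project(rid, lb_id, shift, mirror)
            tgt[rid] = (off, flip)
            self.of[rid] = la_id
        del self.members[lb_id]


def _validate_merge(layouts: _Layouts, o: Overlap, tr, params: AsmParams) -> bool:
    """Re-align implied overlaps across the two layouts being merged.

    A sample of reads from one layout is projected into the merged
    coordinate system; for the largest implied overlaps with reads of the
    other layout the observed divergence must stay within
    ``merge_max_divergence``, otherwise the merge is rejected as likely
    mis-assembly.
    """
    import bisect

    la_id, lb_id, shift, mirror = tr

    def proj_b(rid):
        return layouts.project(rid, lb_id, shift, mirror)

    def proj_a(rid):
        return layouts.members[la_id][rid]

    if len(layouts.members[lb_id]) <= len(layouts.members[la_id]):
        iter_ids, iter_proj = sorted(layouts.members[lb_id]), proj_b
        search_ids, search_proj = layouts.members[la_id], proj_a
    else:
        iter_ids, iter_proj = sorted(layouts.members[la_id]), proj_a
        search_ids, search_proj = layouts.members[lb_id], proj_b
    big_sorted = sorted((search_proj(rid)[0], rid) for rid in search_ids)
    max_len = max(layouts.data[rid].length for rid in search_ids)
    if len(iter_ids) > 12:
        step = len(iter_ids) / 12.0
        iter_ids = [iter_ids[int(i * step)] for i in range(12)]
    cands: list[tuple[int, str, str]] = []
    for rid in iter_ids:
        off, _ = iter_proj(rid)
        end = off + layouts.data[rid].length
        pos = bisect.bisect_left(big_sorted, (off - max_len, ""))
        local: list[tuple[int, str, str]] = []
        for boff, brid in big_sorted[pos:]:
            if boff >= end:
                break
            if brid == rid or {rid, brid} == {o.a_id, o.b_id}:
                continue
            bend = boff + layouts.data[brid].length
            ov = min(end, bend) - max(off, boff)
            if ov >= params.min_overlap:
                local.append((ov, rid, brid))
        # several partners per sampled read so that a single clean
        # companion cannot mask divergent evidence from the rest
        local.sort(key=lambda t: (-t[0], t[1], t[2]))
        cands += local[:4]
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    tot_cols = 0
    tot_ident = 0
    for ov, rid, brid in cands[: params.n_validate]:
        off_r, flip_r = iter_proj(rid)
        off_b, flip_b = search_proj(brid)
        a = layouts.data[brid]
        b = layouts.data[rid]
        d = off_b - off_r
        pad = params.band_pad
        score, _i0, _j0, _i1, _j1, cols, ident = _overlap_dp(
            a.codes(flip_b), b.codes(flip_r), d - pad, d + pad, params.scoring)
        if score <= NEG / 2 or cols < min(params.min_overlap, int(0.8 * ov)):
            return False
        tot_cols += cols
        tot_ident += ident
    # pooled divergence over the validated pairs has more statistical power
    # than any single implied overlap
    if tot_cols and (1.0 - tot_ident / tot_cols) > params.merge_max_divergence:
        return False
    return True


def _mate_violation(layouts: _Layouts, o: Overlap, tr,
                    reads_by_id: dict[str, Read], params: AsmParams) -> bool:
    la_id, lb_id, shift, mirror = tr
    lo_b = layouts.members[lb_id]
    lo_a = layouts.members[la_id]
    for rid in lo_b:
        mate = reads_by_id[rid].mate_id
        if mate and mate in lo_a:
            off1, _ = layouts.project(rid, lb_id, shift, mirror)
            off2, _ = lo_a[mate]
            span = (max(off1 + layouts.data[rid].length,
                        off2 + layouts.data[mate].length) - min(off1, off2))
            if not (params.insert_min - params.insert_slack <= span
                    <= params.insert_max + params.insert_slack):
                return True
    return False


def _greedy_layout(ids: list[str], data, overlaps: list[Overlap],
                   reads_by_id, params: AsmParams) -> _Layouts:
    layouts = _Layouts(ids, data)
    deferred: list[Overlap] = []
    # layout pairs that already failed divergence validation; entries become
    # stale (and are purged) when one of the layouts grows by a merge
    rejected: set[tuple[int, int]] = set()
    for stage, batch in enumerate((overlaps, deferred)):
        for o in list(batch):
            tr = layouts.transform(o)
            if tr is None:
                continue
            la_id, lb_id = tr[0], tr[1]
            key = (min(la_id, lb_id), max(la_id, lb_id))
            if key in rejected:
                continue
            if stage == 0 and _mate_violation(layouts, o, tr, reads_by_id, params):
                deferred.append(o)
                continue
            if not _validate_merge(layouts, o, tr, params):
                rejected.add(key)
                continue
            rejected = {k for k in rejected if la_id not in k}
            layouts.apply(*tr)
    return layouts


# ---------------------------------------------------------------------------
# consensus

_GAP = 4  # allele index for a deletion vote


def _align_read_to_draft(rd: _ReadData, flip: bool, off: int,
                         draft: np.ndarray, params: AsmParams):
    """Glocal alignment of the oriented read to a window of the draft.

    Returns (draft start, ops array in forward order) or None.
    """
    pad = 30
    win_start = max(0, off - pad)
    win_end = min(draft.shape[0], off + rd.length + pad)
    if win_end <= win_start:
        return None
    window = draft[win_start:win_end]
    d = off - win_start
    dband = params.band_pad + 8
    buf = np.empty(rd.length + window.shape[0], dtype=np.int8)
    score, i0, j0, i1, j1, n_ops, _ = banded_align(
        rd.codes(flip), window, d - dband, d + dband,
        params.scoring.match, params.scoring.mismatch,
        params.scoring.gap_open, params.scoring.gap_extend,
        False, True, buf)
    if score <= NEG / 2 or n_ops == 0:
        return None
    ops = buf[:n_ops][::-1].copy()
    return win_start + j0, i0, ops


_TIP_MATCH_RUN = 4  # aligned read tips must open with this many matches


def _pileup(placed, data, draft, params: AsmParams):
    """Accumulate quality-weighted votes of every read against the draft.

    Terminal alignment columns of each read up to the first run of
    ``_TIP_MATCH_RUN`` consecutive matches are clipped before voting:
    an indel close to a read end cannot be placed as a gap by the
    aligner and would otherwise smear into spurious terminal mismatches.
    """
    L = draft.shape[0]
    weights = np.zeros((L, 5))
    qsum = np.zeros((L, 5))
    hq = np.zeros((L, 5), dtype=np.int32)
    #: draft column -> {inserted string: [support weight, support qual]}
    inserts: dict[int, dict[str, list]] = {}
    alignments = {}
    for rid, off, flip in placed:
        rd = data[rid]
        res = _align_read_to_draft(rd, flip, off, draft, params)
        if res is None:
            continue
        j0, i0, ops = res
        codes = rd.codes(flip)
        quals = rd.qual(flip)
        w = rd.weight(flip)
        n_ops = ops.shape[0]
        # per-column read/draft positions
        rpos = i0 + np.concatenate(([0], np.cumsum(ops != OP_GAP_A)))[:-1]
        dcol = j0 + np.concatenate(([0], np.cumsum(ops != OP_GAP_B)))[:-1]
        rpos = np.minimum(rpos, rd.length - 1)
        dcol_c = np.minimum(dcol, L - 1)
        is_match = (ops == OP_DIAG) & (codes[rpos] == draft[dcol_c]) & \
            (codes[rpos] < 4)
        # clip read tips up to the first/last clean match run
        kernel = np.ones(_TIP_MATCH_RUN, dtype=int)
        runs = np.convolve(is_match.astype(int), kernel, mode="valid")
        good = np.nonzero(runs == _TIP_MATCH_RUN)[0]
        if good.size == 0:
            continue
        start, stop = int(good[0]), int(good[-1]) + _TIP_MATCH_RUN
        sl = slice(start, stop)
        opw, rp, dc = ops[sl], rpos[sl], dcol[sl]
        diag = (opw == OP_DIAG) & (codes[rp] < 4)
        cols = dc[diag]
        bases = codes[rp[diag]].astype(np.intp)
        qv = quals[rp[diag]]
        np.add.at(weights, (cols, bases), w[rp[diag]])
        np.add.at(qsum, (cols, bases), qv)
        np.add.at(hq, (cols, bases),
                  (qv >= params.conflict_min_qual).astype(np.int32))
        gap = opw == OP_GAP_A
        if gap.any():
            gq = quals[rp[gap]]
            gw = 1.0 - np.power(10.0, -gq / 10.0)
            np.add.at(weights, (dc[gap], _GAP), gw)
            np.add.at(qsum, (dc[gap], _GAP), gq)
            np.add.at(hq, (dc[gap], _GAP),
                      (gq >= params.conflict_min_qual).astype(np.int32))
        # insertions relative to the draft, grouped into contiguous runs so
        # multi-base insertions (e.g. bases missed at a draft junction) are
        # voted on as whole strings
        ins_idx = np.nonzero(opw == OP_GAP_B)[0]
        run_start = 0
        while run_start < ins_idx.shape[0]:
            run_end = run_start
            while (run_end + 1 < ins_idx.shape[0]
                   and ins_idx[run_end + 1] == ins_idx[run_end] + 1):
                run_end += 1
            span = ins_idx[run_start : run_end + 1]
            col = int(dc[span[0]])
            bases = codes[rp[span]]
            if not (bases >= 4).any():
                text = "".join(_DECODE[bases])
                slot = inserts.setdefault(col, {})
                wv = float(np.mean(w[rp[span]]))
                qv = float(np.mean(quals[rp[span]]))
                entry = slot.setdefault(text, [0.0, 0.0])
                entry[0] += wv
                entry[1] += qv
            run_start = run_end + 1
        # allele track for conflict phasing: draft column -> allele code
        keep = diag | gap
        allele_cols = dc[keep]
        allele_vals = np.where(opw[keep] == OP_GAP_A, _GAP, codes[rp[keep]])
        alignments[rid] = (allele_cols, allele_vals)
    return weights, qsum, hq, inserts, alignments


def _call_columns(weights, qsum, inserts, params: AsmParams):
    """Winner allele and error probability per draft column.

    The winning allele maximises the summed support weight
    ``sum(1 - 10^(-q/10))``; its error probability is the likelihood ratio
    against the strongest competing allele, ``10^((Q_lose - Q_win)/10)``,
    clipped to [10^(-quality_cap/10), 0.5].  Unanimous columns are floored
    at ``10^(-min(Q_win, quality_cap)/10)``.
    """
    floor = 10.0 ** (-params.quality_cap / 10.0)
    L = weights.shape[0]
    consensus_codes: list[int] = []
    errors: list[float] = []
    col_map: list[int] = []  # consensus position -> draft column
    for jj in range(L):
        wcol = weights[jj]
        total = wcol.sum()
        if total <= 0:
            continue
        winner = int(np.argmax(wcol))  # ties: A<C<G<T<gap
        if winner != _GAP:
            qw = qsum[jj, winner]
            others = [q for al, q in enumerate(qsum[jj]) if al != winner and
                      weights[jj, al] > 0]
            if others:
                err = 10.0 ** ((max(others) - qw) / 10.0)
            else:
                err = 10.0 ** (-min(qw, params.quality_cap) / 10.0)
            consensus_codes.append(winner)
            errors.append(float(np.clip(err, floor, 0.5)))
            col_map.append(jj)
        ins = inserts.get(jj + 1)
        if ins is not None:
            total_ins = sum(entry[0] for entry in ins.values())
            if total_ins > 0.5 * max(total, 1e-9):
                # plurality inserted string, inserted wholly
                text = max(sorted(ins), key=lambda t: ins[t][0])
                qi = ins[text][1]
                err = 10.0 ** (-min(qi, params.quality_cap) / 10.0)
                err = float(np.clip(err, floor, 0.5))
                for ch in text:
                    consensus_codes.append("ACGT".index(ch))
                    errors.append(err)
                    col_map.append(-1)
    return (np.array(consensus_codes, dtype=np.uint8),
            np.array(errors), col_map)


def call_consensus(layout: Sequence[tuple[Read, int, bool]],
                   params: AsmParams | None = None
                   ) -> tuple[str, np.ndarray]:
    """Quality-weighted consensus over explicitly placed reads.

    ``layout`` is a sequence of ``(read, offset, flipped)`` placements.
    Returns the consensus string and the per-base error probabilities.
    """
    if params is None:
        params = AsmParams()
    if not layout:
        raise ValueError("empty layout")
    data = {r.read_id: _ReadData(r) for r, _, _ in layout}
    placed = [(r.read_id, off, flip) for r, off, flip in layout]
    seq, err, *_ = _consensus_rounds(placed, data, params)
    return seq, err


_DECODE = np.array(list("ACGTN"))


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


def _stack_draft(placed, data) -> np.ndarray:
    """Naive offset-stacked draft: first read covering a column wins."""
    base = min(off for _, off, _ in placed)
    placed = [(rid, off - base, flip) for rid, off, flip in placed]
    L = max(off + data[rid].length for rid, off, _ in placed)
    draft = np.full(L, 4, dtype=np.uint8)
    filled = np.zeros(L, dtype=bool)
    for rid, off, flip in placed:
        codes = data[rid].codes(flip)
        seg = slice(off, off + codes.shape[0])
        take = ~filled[seg]
        draft[seg][take] = codes[take]
        np.copyto(filled[seg], True)
    return draft, placed


def _consensus_rounds(placed, data, params: AsmParams):
    """Two-round draft refinement; returns consensus, errors, pileup state."""
    draft, placed = _stack_draft(placed, data)
    # round 1: realign to the stacked draft and rebuild it gap-aware
    weights, qsum, hq, inserts, aligned = _pileup(placed, data, draft, params)
    codes, errors, col_map1 = _call_columns(weights, qsum, inserts, params)
    if codes.shape[0] == 0:
        codes = draft
        col_map1 = list(range(draft.shape[0]))
    # draft coordinate -> refined consensus coordinate (for read offsets)
    kept_cols = np.array([jj for jj in col_map1 if jj >= 0])
    placed2 = []
    for rid, off, flip in placed:
        new_off = int(np.searchsorted(kept_cols, off)) if kept_cols.size else off
        placed2.append((rid, new_off, flip))
    # round 2: realign to the refined consensus for final calls
    weights, qsum, hq, inserts, aligned = _pileup(placed2, data, codes, params)
    final_codes, errors, col_map = _call_columns(weights, qsum, inserts, params)
    if final_codes.shape[0] == 0:
        # degenerate: fall back to the draft itself
        return _codes_to_str(codes), np.full(codes.shape[0], 0.5), {}, [], {}
    # trim weak contig ends: keep the span between the first and last run
    # of 20 consecutive confident columns, so wobbly low-coverage head and
    # tail regions (not just the outermost columns) are removed
    run = 20
    good = (errors <= params.end_trim_error).astype(int)
    if final_codes.shape[0] >= run:
        sums = np.convolve(good, np.ones(run, dtype=int), mode="valid")
        anchors = np.nonzero(sums == run)[0]
        if anchors.size:
            lo, hi = int(anchors[0]), int(anchors[-1]) + run
            final_codes, errors = final_codes[lo:hi], errors[lo:hi]
            col_map = col_map[lo:hi]
    return (_codes_to_str(final_codes), errors,
            aligned, col_map, {"weights": weights, "qsum": qsum, "hq": hq})


def _conflict_columns(state, col_map, params: AsmParams) -> list[int]:
    """Draft columns where a minority allele has strong support."""
    weights = state["weights"]
    hq = state["hq"]
    out = []
    for cpos, jj in enumerate(col_map):
        if jj < 0:
            continue
        wcol = weights[jj]
        if wcol.sum() <= 0:
            continue
        winner = int(np.argmax(wcol))
        for al in range(5):
            if al != winner and hq[jj, al] >= params.conflict_min_support:
                out.append(jj)
                break
    return out


def _allele_at(alignment, col: int) -> Optional[int]:
    cols, vals = alignment
    idx = np.searchsorted(cols, col)
    if idx < cols.shape[0] and cols[idx] == col:
        v = int(vals[idx])
        return v if v <= _GAP else None
    return None


def _split_reads(member_ids, aligned, data, conflicts, state,
                 params: AsmParams):
    """Bipartition reads by their alleles across linked conflict columns."""
    weights = state["weights"]
    hq = state["hq"]
    # strongest conflict column: maximal high-quality minority support
    def minority_hq(jj):
        winner = int(np.argmax(weights[jj]))
        return max(hq[jj, al] for al in range(5) if al != winner)

    c0 = max(conflicts, key=lambda jj: (minority_hq(jj), -jj))
    winner0 = int(np.argmax(weights[c0]))
    minority0 = max((al for al in range(5) if al != winner0),
                    key=lambda al: (hq[c0, al], weights[c0, al]))
    group_x, group_y, rest = [], [], []
    alleles = {}
    for rid in member_ids:
        alg = aligned.get(rid)
        al = _allele_at(alg, c0) if alg is not None else None
        alleles[rid] = {c0: al} if al is not None else {}
        if al == winner0:
            group_x.append(rid)
        elif al == minority0:
            group_y.append(rid)
        else:
            rest.append(rid)
    if not group_y or not group_x:
        return None
    # plurality allele per group at the other conflict columns
    other = [jj for jj in conflicts if jj != c0]
    prof = {}
    for jj in other:
        for rid in member_ids:
            alg = aligned.get(rid)
            if alg is not None:
                al = _allele_at(alg, jj)
                if al is not None:
                    alleles[rid][jj] = al
        for grp, tag in ((group_x, "x"), (group_y, "y")):
            counts: dict[int, int] = {}
            for rid in grp:
                al = alleles[rid].get(jj)
                if al is not None:
                    counts[al] = counts.get(al, 0) + 1
            if counts:
                prof[(jj, tag)] = max(sorted(counts), key=lambda a: counts[a])
    for rid in rest:
        sx = sum(1 for jj in other
                 if alleles[rid].get(jj) is not None
                 and prof.get((jj, "x")) == alleles[rid][jj])
        sy = sum(1 for jj in other
                 if alleles[rid].get(jj) is not None
                 and prof.get((jj, "y")) == alleles[rid][jj])
        (group_y if sy > sx else group_x).append(rid)
    return sorted(group_x), sorted(group_y)


# ---------------------------------------------------------------------------
# top level assembly

def _assemble(ids: list[str], data, overlaps: list[Overlap], reads_by_id,
              params: AsmParams, passes: int) -> list[tuple]:
    layouts = _greedy_layout(ids, data, overlaps, reads_by_id, params)
    results = []
    for lid in sorted(layouts.members,
                      key=lambda l: min(layouts.members[l])):
        members = layouts.members[lid]
        placed = sorted(((rid, off, flip)
                         for rid, (off, flip) in members.items()),
                        key=lambda t: (t[1], t[0]))
        if len(placed) == 1:
            rid = placed[0][0]
            rd = data[rid]
            err = np.power(10.0, -np.minimum(rd.quals, params.quality_cap) / 10.0)
            results.append((rd.read.sequence, err, [(rid, 0, False)]))
            continue
        seq, err, aligned, col_map, state = _consensus_rounds(
            placed, data, params)
        conflicts = _conflict_columns(state, col_map, params) if state else []
        member_ids = sorted(members)
        if conflicts and passes > 1:
            split = _split_reads(member_ids, aligned, data, conflicts,
                                 state, params)
            if split is not None:
                sub_results = []
                for part in split:
                    part_set = set(part)
                    sub = [o for o in overlaps
                           if o.a_id in part_set and o.b_id in part_set]
                    sub_results += _assemble(part, data, sub, reads_by_id,
                                             params, passes - 1)
                results += sub_results
                continue
        results.append((seq, err,
                        [(rid, off, flip) for rid, off, flip in placed]))
    return results


def assemble_cluster(reads: Sequence[Read], params: AsmParams | None = None,
                     cluster_id: int = 0) -> list[Contig]:
    """Assemble one read cluster into contigs named ``C{cluster}_{index}``.

    Deterministic for a fixed read set (input order does not matter).
    Contigs are *not* filtered here; see :func:`filter_contigs`.
    """
    if params is None:
        params = AsmParams()
    reads = sorted(reads, key=lambda r: r.read_id)
    if not reads:
        raise ValueError("assemble_cluster needs at least one read")
    data = {r.read_id: _ReadData(r) for r in reads}
    reads_by_id = {r.read_id: r for r in reads}
    ids = sorted(data)
    overlaps = _compute_overlaps(ids, data, params)
    raw = _assemble(ids, data, overlaps, reads_by_id, params,
                    params.max_passes)
    raw.sort(key=lambda t: (-len(t[0]), t[0]))
    contigs = []
    for n, (seq, err, members) in enumerate(raw, start=1):
        contigs.append(Contig(name=f"C{cluster_id}_{n}", consensus=seq,
                              per_base_error=np.asarray(err),
                              members=members))
    return contigs


def filter_contigs(contigs: Iterable[Contig],
                   params: AsmParams | None = None) -> list[Contig]:
    """Keep contigs longer than ``min_contig_length`` (strict) with mean
    base error probability below ``max_mean_error`` (strict)."""
    if params is None:
        params = AsmParams()
    return [c for c in contigs
            if len(c) > params.min_contig_length
            and c.mean_error < params.max_mean_error]


# ---------------------------------------------------------------------------
# I/O

def contigs_to_fasta(contigs: Iterable[Contig], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(c.consensus), id=c.name, description="")
                 for c in contigs], str(path), "fasta")


def contig_table(contigs: Iterable[Contig]):
    import pandas as pd

    return pd.DataFrame(
        [{"name": c.name, "length": len(c), "mean_error": c.mean_error,
          "n_reads": len(c.members)} for c in contigs],
        columns=["name", "length", "mean_error", "n_reads"])
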