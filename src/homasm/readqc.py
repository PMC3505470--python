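"""Read trimming and filtering.

Rules, applied in a fixed order per read:

  adapter -> (a) truncate at the first run of more than ``max_run``
  consecutive ambiguous bases or more than ``max_run`` consecutive bases
  below ``min_phred`` -> (b) discard when the median quality of the
  retained bases is below ``min_median_phred`` -> (c) discard when fewer
  than ``min_length`` bases remain.

Truncation scans 5'->3' and removes everything from the start of the first
offending run onwards (3'-degrading chemistry).  An ambiguous base is any
non-ACGT IUPAC symbol.  When one mate of a pair is discarded the surviving
mate is demoted to a single read.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from .synth import Read


@dataclass
class QcParams:
    max_run: int = 3
    min_phred: int = 20
    min_median_phred: int = 20
    min_length: int = 50
    adapter: Optional[str] = None
    adapter_max_mismatch: int = 2
    adapter_min_match: int = 8

    def __post_init__(self) -> None:
        for v in (self.max_run, self.min_phred, self.min_median_phred,
                  self.min_length):
            if v <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class QcVerdict:
    kept: bool
    rule: Optional[str] = None  # 'median' | 'length' when discarded
    trimmed: bool = False


@dataclass
class QcSummary:
    n_input: int = 0
    n_kept: int = 0
    n_discarded_median: int = 0
    n_discarded_length: int = 0
    n_trimmed: int = 0
    n_pairs_kept: int = 0
    n_singles_kept: int = 0

    def validate(self) -> None:
        if self.n_kept + self.n_discarded_median + self.n_discarded_length \
                != self.n_input:
            raise ValueError("QC counts do not add up")
        if 2 * self.n_pairs_kept + self.n_singles_kept != self.n_kept:
            raise ValueError("pair/single accounting does not add up")


_AMBIG = frozenset("ACGT")


def _first_long_run(flags: np.ndarray, max_run: int) -> Optional[int]:
    """Start index of the first run of True longer than ``max_run``."""
    run = 0
    for i, f in enumerate(flags):
        if f:
            run += 1
            if run > max_run:
                return i - run + 1
        else:
            run = 0
    return None


def trim_adapter(read: Read, params: QcParams) -> Read:
    """Remove the longest read suffix matching a prefix of the adapter.

    Up to ``adapter_max_mismatch`` mismatches are tolerated and at least
    ``adapter_min_match`` bases must match; internal adapter occurrences
    are left untouched.  Qualities are trimmed in lockstep.
    """
    adapter = params.adapter
    if not adapter:
        return read
    seq = read.sequence
    for ln in range(min(len(adapter), len(seq)), params.adapter_min_match - 1, -1):
        tail = seq[len(seq) - ln:]
        mism = sum(1 for x, y in zip(tail, adapter[:ln]) if x != y)
        if mism <= params.adapter_max_mismatch:
            return replace(read, sequence=seq[: len(seq) - ln],
                           qualities=list(read.qualities[: len(seq) - ln]))
    return read


def trim_and_filter_read(read: Read,
                         params: QcParams) -> tuple[Optional[Read], QcVerdict]:
    """Apply run-trimming then the median and length filters to one read."""
    seq = read.sequence
    quals = np.asarray(read.qualities)
    cut = len(seq)
    ambig = np.fromiter((c.upper() not in _AMBIG for c in seq), dtype=bool,
                        count=len(seq))
    for flags in (ambig, quals < params.min_phred):
        pos = _first_long_run(flags, params.max_run)
        if pos is not None:
            cut = min(cut, pos)
    trimmed = cut < len(seq)
    if trimmed:
        read = replace(read, sequence=seq[:cut], qualities=list(read.qualities[:cut]))
        quals = quals[:cut]
    if len(read.sequence) == 0:
        return None, QcVerdict(kept=False, rule="length", trimmed=trimmed)
    if float(np.median(quals)) < params.min_median_phred:
        return None, QcVerdict(kept=False, rule="median", trimmed=trimmed)
    if len(read.sequence) < params.min_length:
        return None, QcVerdict(kept=False, rule="length", trimmed=trimmed)
    return read, QcVerdict(kept=True, trimmed=trimmed)


def qc_readset(reads: Iterable[Read],
               params: QcParams | None = None) -> tuple[list[Read], QcSummary]:
    """QC a whole read set, demoting widowed mates to singles.

    Paired reads must carry symmetric mate links; a mismatched link raises
    an error naming the offending read.
    """
    if params is None:
        params = QcParams()
    reads = list(reads)
    by_id = {r.read_id: r for r in reads}
    for r in reads:
        if r.mate_id is not None:
            mate = by_id.get(r.mate_id)
            if mate is None or mate.mate_id != r.read_id:
                raise ValueError(f"asymmetric mate link for read {r.read_id}")
    summary = QcSummary(n_input=len(reads))
    kept_by_id: dict[str, Read] = {}
    for r in reads:
        r2 = trim_adapter(r, params) if params.adapter else r
        adapter_trimmed = r2.sequence != r.sequence
        out, verdict = trim_and_filter_read(r2, params)
        if verdict.trimmed or adapter_trimmed:
            summary.n_trimmed += 1
        if out is None:
            if verdict.rule == "median":
                summary.n_discarded_median += 1
            else:
                summary.n_discarded_length += 1
        else:
            kept_by_id[out.read_id] = out
    kept: list[Read] = []
    for rid in sorted(kept_by_id):
        r = kept_by_id[rid]
        if r.mate_id is not None:
            if r.mate_id in kept_by_id:
                if rid < r.mate_id:
                    summary.n_pairs_kept += 1
                kept.append(r)
            else:
                kept.append(replace(r, mate_id=None))
                summary.n_singles_kept += 1
        else:
            kept.append(r)
            summary.n_singles_kept += 1
    summary.n_kept = len(kept)
    summary.validate()
    return kept, summary


def summary_to_tsv(summary: QcSummary, path) -> None:
    import pandas as pd

    pd.DataFrame([vars(summary)]).to_csv(path, sep="\t", index=False)
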