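"""Ground-truthed synthetic polyploid transcriptome and read simulator.

Emulates the statistical structure of a hexaploid (AABBDD) transcriptome
sequencing experiment: homoeologous gene families of one to three copies
diverged from a shared ancestor at a configurable identity (default mean
97.2%, sd 1.8%), long single-end reads (default mean length 363.2 bases,
homopolymer-indel errors) and short inward-facing read pairs (default
length 108, insert 250-300 bases, substitution errors with 3'-decaying
quality).  Every read carries a truth label so downstream stages can be
audited exactly.  Wet-lab library normalisation is emulated by capping
per-transcript coverage at a multiple of the median expression level.

Coordinates in truth labels are 0-based half-open with strand '+'/'-'.
Quality strings use the Sanger PHRED+33 convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignParams, local_align, revcomp

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic transcriptome and its sequencing."""

    n_families: int = 50
    #: proportions of triplet/doublet/singlet families (sums to 1)
    ploidy_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)
    #: log-normal transcript length model (median in bases, sigma in log space)
    transcript_length_median: float = 1300.0
    transcript_length_sigma: float = 0.35
    transcript_length_min: int = 500
    transcript_length_max: int = 8000
    homoeolog_identity_mean: float = 97.2
    homoeolog_identity_sd: float = 1.8
    #: fraction of divergence events realised as 1-base indels (rest are SNPs)
    indel_fraction_of_variants: float = 0.1
    #: optional inter-cultivar divergence layer, bases per SNP
    cultivar_snp_spacing: Optional[int] = None
    long_read_length_mean: float = 363.2
    long_read_length_sd: float = 60.0
    short_read_length: int = 108
    insert_range: tuple[int, int] = (250, 300)
    long_read_coverage: float = 5.0
    short_read_coverage: float = 25.0
    #: per-eligible-position indel rate inside homopolymer runs (long reads)
    long_homopolymer_indel_rate: float = 0.01
    #: substitution-rate profile along short reads (5' start to 3' end)
    short_sub_rate_start: float = 0.0005
    short_sub_rate_end: float = 0.004
    #: log-normal sigma of per-copy expression and normalisation coverage cap
    expression_sigma: float = 1.0
    normalization_cap: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ploidy_mix) - 1.0) > 1e-9:
            raise ValueError("ploidy_mix must sum to 1")
        if not (85.0 < self.homoeolog_identity_mean <= 100.0):
            raise ValueError("homoeolog identity mean must be in (85, 100]")
        if self.homoeolog_identity_sd < 0:
            raise ValueError("identity sd must be >= 0")
        if self.insert_range[0] > self.insert_range[1]:
            raise ValueError("insert_range min must be <= max")
        for r in (self.indel_fraction_of_variants,
                  self.long_homopolymer_indel_rate,
                  self.short_sub_rate_start, self.short_sub_rate_end):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.n_families < 1:
            raise ValueError("n_families must be positive")


@dataclass(frozen=True)
class TruthLabel:
    family_id: str
    genome_label: str
    start: int
    end: int
    strand: str


@dataclass
class Read:
    read_id: str
    sequence: str
    qualities: list[int]
    platform: str  # 'long' | 'short'
    mate_id: Optional[str] = None
    truth: Optional[TruthLabel] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class HomoeologFamily:
    family_id: str
    genome_labels: tuple[str, ...]
    sequences: dict[str, str]
    #: measured %ID per unordered label pair, e.g. {('A','B'): 97.1}
    realized_pairwise_identity: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.sequences) <= 3:
            raise ValueError("a family holds 1-3 homoeolog copies")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _truncated_normal(rng, mean, sd, low, high) -> float:
    """Normal draw, rejected below ``low`` and censored at ``high``.

    The upper bound is censored (clamped) rather than rejected: identical
    homoeolog copies are biologically meaningful, and rejection at 100%
    would bias the realised identity mean noticeably downward.
    """
    if sd == 0:
        return mean
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x > low:
            return min(x, high)
    raise RuntimeError("truncated normal sampling failed")


def _mutate(rng, seq: str, n_mut: int, indel_fraction: float) -> str:
    """Apply ``n_mut`` divergence events uniformly at random along ``seq``."""
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    n_indel = int(round(indel_fraction * len(positions)))
    chars = list(seq)
    # apply from the 3' end so earlier indices stay valid
    for rank, pos in enumerate(sorted(positions, reverse=True)):
        if rank < n_indel:
            if rng.random() < 0.5:
                chars.insert(pos, str(rng.choice(_BASES)))
            else:
                del chars[pos]
        else:
            alternatives = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = str(rng.choice(np.array(alternatives)))
    return "".join(chars)


def measure_identity(a: str, b: str) -> float:
    """%ID of the best local alignment between two homoeolog copies."""
    hit = local_align(a, b, AlignParams())
    if hit is None:
        return 0.0
    return hit.pct_id


def generate_families(config: SimConfig) -> list[HomoeologFamily]:
    """Generate homoeolog families diverged from shared ancestral transcripts.

    Each family draws a target pairwise identity from a Normal truncated to
    (85, 100]; every genome copy receives half the implied divergence
    independently, so realised pairwise identity matches the target up to
    sampling noise.  Deterministic for a given config seed.
    """
    rng = _rng(config, 0)
    families: list[HomoeologFamily] = []
    labels_all = ("A", "B", "D")
    for i in range(config.n_families):
        ploidy = int(rng.choice([3, 2, 1], p=list(config.ploidy_mix)))
        labels = tuple(sorted(str(x) for x in
                              rng.choice(labels_all, size=ploidy, replace=False)))
        length = int(round(float(rng.lognormal(
            math.log(config.transcript_length_median),
            config.transcript_length_sigma))))
        length = int(np.clip(length, config.transcript_length_min,
                             config.transcript_length_max))
        ancestor = _random_seq(rng, length)
        target = _truncated_normal(
            rng, config.homoeolog_identity_mean, config.homoeolog_identity_sd,
            85.0, 100.0)
        per_copy = max((100.0 - target) / 200.0, 0.0)
        n_mut = int(round(per_copy * length))
        sequences = {lab: _mutate(rng, ancestor, n_mut,
                                  config.indel_fraction_of_variants)
                     for lab in labels}
        if config.cultivar_snp_spacing:
            # shared cultivar haplotype: same extra mutations on every copy
            n_cult = int(round(length / config.cultivar_snp_spacing))
            cult_rng_state = rng.integers(0, 2**31 - 1)
            for lab in labels:
                sub = np.random.default_rng([int(cult_rng_state), 0])
                sequences[lab] = _mutate(sub, sequences[lab], n_cult, 0.0)
        fam = HomoeologFamily(
            family_id=f"F{i:04d}", genome_labels=labels, sequences=sequences)
        for x in range(len(labels)):
            for y in range(x + 1, len(labels)):
                pair = (labels[x], labels[y])
                fam.realized_pairwise_identity[pair] = measure_identity(
                    sequences[pair[0]], sequences[pair[1]])
        families.append(fam)
    return families


def _quality_from_rate(rate: float) -> int:
    if rate <= 0:
        return 41
    return int(np.clip(round(-10.0 * math.log10(rate)), 2, 41))


def _apply_long_errors(rng, seq: str, rate: float) -> tuple[str, int]:
    """Homopolymer 1-base indels; returns mutated sequence and quality."""
    if rate <= 0:
        return seq, 41
    out = []
    n_eligible = 0
    prev = ""
    for c in seq:
        if c == prev:
            n_eligible += 1
            if rng.random() < rate:
                if rng.random() < 0.5:
                    out.append(c)  # duplicated base (insertion)
                    out.append(c)
                # else dropped base (deletion)
                prev = c
                continue
        out.append(c)
        prev = c
    eff = rate * n_eligible / max(len(seq), 1)
    return "".join(out), _quality_from_rate(eff)


def _fragment_start(rng, L: int, ln: int) -> int:
    """Fragment placement emulating a three-population cDNA library:
    5'-terminal, 3'-terminal and internal fragments (terminal fragments
    are amplified separately so transcript ends stay covered)."""
    r = rng.random()
    if r < 0.15:
        return 0
    if r < 0.30:
        return L - ln
    return int(rng.integers(0, L - ln + 1))


def _sample_long_reads(rng, fam, label, seq, cov, config, reads):
    length_mean = config.long_read_length_mean
    n = int(round(cov * len(seq) / max(length_mean, 1.0)))
    for idx in range(n):
        ln = int(round(rng.normal(length_mean, config.long_read_length_sd)))
        ln = int(np.clip(ln, 50, len(seq)))
        start = _fragment_start(rng, len(seq), ln)
        strand = "+" if rng.random() < 0.5 else "-"
        frag = seq[start : start + ln]
        if strand == "-":
            frag = revcomp(frag)
        frag, q = _apply_long_errors(rng, frag, config.long_homopolymer_indel_rate)
        reads.append(Read(
            read_id=f"{fam.family_id}_{label}_L{idx:05d}",
            sequence=frag, qualities=[q] * len(frag), platform="long",
            truth=TruthLabel(fam.family_id, label, start, start + ln, strand)))


def _short_error_profile(config) -> np.ndarray:
    rl = config.short_read_length
    return np.linspace(config.short_sub_rate_start, config.short_sub_rate_end, rl)


def _make_short_read(rng, template: str, profile) -> tuple[str, list[int]]:
    chars = list(template)
    p = profile[: len(chars)]
    quals = [_quality_from_rate(x) for x in p]
    errs = np.nonzero(rng.random(len(chars)) < p)[0]
    for i in errs:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = str(rng.choice(np.array(alternatives)))
    return "".join(chars), quals


def _sample_short_reads(rng, fam, label, seq, cov, config, reads):
    rl = config.short_read_length
    profile = _short_error_profile(config)
    ins_min, ins_max = config.insert_range
    if len(seq) < ins_min:
        log.info("%s|%s shorter than minimum insert; emitting unpaired short reads",
                 fam.family_id, label)
        n = int(round(cov * len(seq) / rl))
        for idx in range(n):
            ln = min(rl, len(seq))
            start = int(rng.integers(0, len(seq) - ln + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            frag = seq[start : start + ln]
            if strand == "-":
                frag = revcomp(frag)
            s, q = _make_short_read(rng, frag, profile)
            reads.append(Read(
                read_id=f"{fam.family_id}_{label}_S{idx:05d}",
                sequence=s, qualities=q, platform="short",
                truth=TruthLabel(fam.family_id, label, start, start + ln, strand)))
        return
    n_pairs = int(round(cov * len(seq) / (2.0 * rl)))
    for idx in range(n_pairs):
        insert = int(rng.integers(ins_min, min(ins_max, len(seq)) + 1))
        start = _fragment_start(rng, len(seq), insert)
        end = start + insert
        flip = rng.random() < 0.5  # fragment orientation on the transcript
        base = f"{fam.family_id}_{label}_P{idx:05d}"
        # inward-facing pair: mate 1 at the 5' end of the fragment, forward;
        # mate 2 at the 3' end, reverse complemented.
        fwd = seq[start : start + rl]
        rev = revcomp(seq[end - rl : end])
        if not flip:
            t1 = (fwd, TruthLabel(fam.family_id, label, start, start + rl, "+"))
            t2 = (rev, TruthLabel(fam.family_id, label, end - rl, end, "-"))
        else:
            t1 = (revcomp(seq[end - rl : end]),
                  TruthLabel(fam.family_id, label, end - rl, end, "-"))
            t2 = (seq[start : start + rl],
                  TruthLabel(fam.family_id, label, start, start + rl, "+"))
        for mate, (tmpl, truth) in enumerate((t1, t2), start=1):
            s, q = _make_short_read(rng, tmpl, profile)
            other = f"{base}/{2 if mate == 1 else 1}"
            reads.append(Read(
                read_id=f"{base}/{mate}", sequence=s, qualities=q,
                platform="short", mate_id=other, truth=truth))


def simulate_reads(families: list[HomoeologFamily],
                   config: SimConfig) -> list[Read]:
    """Sample long and paired short reads from every homoeolog copy.

    Per-copy coverage is modulated by a log-normal expression level capped
    at ``normalization_cap`` times the median (duplex-specific-nuclease
    normalisation emulated as reduced coverage skew).  Deterministic given
    the config seed; every read carries a correct truth label.
    """
    if not families:
        raise ValueError("no families to sequence")
    if config.long_read_coverage < 0 or config.short_read_coverage < 0:
        raise ValueError("coverages must be >= 0")
    if config.long_read_coverage == 0 and config.short_read_coverage == 0:
        raise ValueError("at least one platform needs coverage > 0")
    rng = _rng(config, 1)
    copies = [(fam, lab) for fam in families for lab in fam.genome_labels]
    expr = rng.lognormal(0.0, config.expression_sigma, len(copies))
    med = float(np.median(expr))
    factors = np.minimum(expr, config.normalization_cap * med) / med
    reads: list[Read] = []
    for (fam, lab), factor in zip(copies, factors):
        seq = fam.sequences[lab]
        if config.long_read_coverage > 0:
            _sample_long_reads(rng, fam, lab, seq,
                               config.long_read_coverage * factor, config, reads)
        if config.short_read_coverage > 0:
            _sample_short_reads(rng, fam, lab, seq,
                                config.short_read_coverage * factor, config, reads)
    return reads


@dataclass
class ArtifactParams:
    """Rates for library/sequencing artifacts layered onto clean reads."""

    adapter_fraction: float = 0.0
    adapter_mismatches: int = 0
    n_run_fraction: float = 0.0
    n_run_length: int = 5
    lowq_tail_fraction: float = 0.0
    lowq_tail_length: int = 10
    seed: int = 0


def inject_artifacts(reads: list[Read], adapter: str,
                     params: ArtifactParams) -> list[Read]:
    """Append adapters, ambiguous-base runs, and low-quality tails.

    Each artifact hits an independent configured fraction of reads; truth
    labels are preserved untouched.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 bases")
    rng = np.random.default_rng([params.seed, 2])
    out: list[Read] = []
    for read in reads:
        seq, quals = read.sequence, list(read.qualities)
        if params.adapter_fraction and rng.random() < params.adapter_fraction:
            ad = list(adapter)
            if params.adapter_mismatches:
                for pos in rng.choice(len(ad), size=min(params.adapter_mismatches,
                                                        len(ad)), replace=False):
                    alternatives = [b for b in "ACGT" if b != ad[pos]]
                    ad[pos] = str(rng.choice(np.array(alternatives)))
            seq = seq + "".join(ad)
            quals = quals + [30] * len(ad)
        if params.n_run_fraction and rng.random() < params.n_run_fraction:
            run = params.n_run_length
            if len(seq) > run:
                pos = int(rng.integers(0, len(seq) - run))
                seq = seq[:pos] + "N" * run + seq[pos + run:]
                quals[pos : pos + run] = [2] * run
        if params.lowq_tail_fraction and rng.random() < params.lowq_tail_fraction:
            tail = min(params.lowq_tail_length, len(quals))
            quals[len(quals) - tail:] = [8] * tail
        out.append(replace(read, sequence=seq, qualities=quals))
    return out


# ---------------------------------------------------------------------------
# I/O: FASTA transcripts, FASTQ reads (pairs as _1/_2), TSV truth table

def write_transcripts_fasta(families: Iterable[HomoeologFamily], path) -> None:
    """Write homoeolog copies as FASTA with ``family|genome`` headers."""
    records = []
    for fam in families:
        for lab in fam.genome_labels:
            records.append(SeqRecord(Seq(fam.sequences[lab]),
                                     id=f"{fam.family_id}|{lab}", description=""))
    SeqIO.write(records, str(path), "fasta")


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
    rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def split_pairs(reads: list[Read]) -> tuple[list[Read], list[Read], list[Read]]:
    """Split reads into synchronized mate-1/mate-2 lists plus singles."""
    by_id = {r.read_id: r for r in reads}
    mate1, mate2, singles = [], [], []
    for r in sorted(reads, key=lambda x: x.read_id):
        if r.mate_id and r.mate_id in by_id:
            if r.read_id < r.mate_id:
                mate1.append(r)
                mate2.append(by_id[r.mate_id])
        else:
            singles.append(r)
    return mate1, mate2, singles


def write_reads_fastq(reads: list[Read], prefix) -> list[str]:
    """Write reads under ``prefix``: paired files ``_1/_2`` and ``_single``.

    Returns the list of files written.
    """
    mate1, mate2, singles = split_pairs(reads)
    written = []
    if mate1:
        for tag, batch in (("_1", mate1), ("_2", mate2)):
            path = f"{prefix}{tag}.fastq"
            SeqIO.write([_to_record(r) for r in batch], path, "fastq")
            written.append(path)
    if singles:
        path = f"{prefix}_single.fastq"
        SeqIO.write([_to_record(r) for r in singles], path, "fastq")
        written.append(path)
    return written


def write_truth_tsv(reads: list[Read], path) -> None:
    import pandas as pd

    rows = [
        {"read_id": r.read_id, "family_id": r.truth.family_id,
         "genome_label": r.truth.genome_label, "start": r.truth.start,
         "end": r.truth.end, "strand": r.truth.strand}
        for r in sorted(reads, key=lambda x: x.read_id) if r.truth
    ]
    pd.DataFrame(rows, columns=["read_id", "family_id", "genome_label",
                                "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False)


def read_reads_fastq(path, platform: str = "short") -> list[Read]:
    """Load a FASTQ file as :class:`Read` objects (no mate links)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(Read(read_id=rec.id, sequence=str(rec.seq),
                          qualities=list(rec.letter_annotations["phred_quality"]),
                          platform=platform))
    return reads


def link_pairs(mate1: list[Read], mate2: list[Read]) -> list[Read]:
    """Symmetrically mate-link two synchronized read lists."""
    if len(mate1) != len(mate2):
        raise ValueError("pair files are not synchronized")
    for r1, r2 in zip(mate1, mate2):
        r1.mate_id = r2.read_id
        r2.mate_id = r1.read_id
    return list(mate1) + list(mate2)
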