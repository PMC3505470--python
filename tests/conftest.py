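"""Shared helpers and fixtures for the homasm test suite."""

from __future__ import annotations

import numpy as np
import pytest

from homasm import synth

BASES = np.array(list("ACGT"))


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate_seq(rng: np.random.Generator, seq: str, sub_rate: float,
               indel_rate: float = 0.0) -> str:
    """Independent per-base substitutions and 1-base indels."""
    out = []
    for c in seq:
        r = rng.random()
        if r < sub_rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != c])))
        elif r < sub_rate + indel_rate / 2:
            pass  # deletion
        elif r < sub_rate + indel_rate:
            out.append(c)
            out.append(str(rng.choice(list("ACGT"))))
        else:
            out.append(c)
    return "".join(out)


def make_read(read_id: str, seq: str, qual: int = 30, platform: str = "long",
              mate_id=None) -> synth.Read:
    return synth.Read(read_id=read_id, sequence=seq,
                      qualities=[qual] * len(seq), platform=platform,
                      mate_id=mate_id)


def tile_reads(seq: str, read_len: int, step: int, qual: int = 30,
               prefix: str = "t") -> list[synth.Read]:
    """Error-free reads tiling a sequence on the forward strand."""
    reads = []
    idx = 0
    for start in range(0, max(len(seq) - read_len, 0) + 1, step):
        reads.append(make_read(f"{prefix}{idx:04d}",
                               seq[start : start + read_len], qual))
        idx += 1
    return reads


@pytest.fixture(scope="session")
def triplet_family_reads():
    """One triplet family at ~97% identity with 30x 300-base long reads."""
    cfg = synth.SimConfig(
        n_families=1, ploidy_mix=(1.0, 0.0, 0.0),
        homoeolog_identity_mean=97.0, homoeolog_identity_sd=0.5,
        transcript_length_median=1000.0, transcript_length_sigma=0.0,
        transcript_length_min=500,
        long_read_coverage=30.0, short_read_coverage=0.0,
        long_read_length_mean=300.0, long_read_length_sd=0.0,
        expression_sigma=0.0, seed=101)
    families = synth.generate_families(cfg)
    reads = synth.simulate_reads(families, cfg)
    return families[0], reads
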