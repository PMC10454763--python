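"""Synthetic genomes, mock communities, read simulation, and subsampling.

These generators replicate the validation designs the method is benchmarked
with, at desk scale: random (n-gram-disjoint) genomes with an optional
implanted shared block, even 12-member and staggered 20-member mock
communities, uniform-start paired/single 150 bp reads with i.i.d. substitution
errors, coverage subsampling, and contiguous reference truncation emulating
draft genomes.  Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ngrams as ng
from .errors import InvalidParameterError
from .io import atomic_open, iter_fastq

DEFAULT_READ_LENGTH = 150
DEFAULT_FRAGMENT_LENGTH = 300  # mate-2 is the reverse complement of the far fragment end


@dataclass
class CommunityComposition:
    """Genome proportions of a mock community; must be positive and sum to 1."""

    entries: list[tuple[str, float]]
    label: str = "custom"

    def __post_init__(self):
        props = [p for _g, p in self.entries]
        if not props or any(p <= 0 for p in props):
            raise InvalidParameterError("community proportions must be positive")
        if abs(sum(props) - 1.0) > 1e-9:
            raise InvalidParameterError(f"proportions sum to {sum(props)!r}, expected 1")
        ids = [g for g, _p in self.entries]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("duplicate genome ids in composition")

    @property
    def genome_ids(self) -> list[str]:
        return [g for g, _p in self.entries]

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p for _g, p in self.entries], dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["genome_id", "true_proportion"])


def mock_even(genome_ids: Sequence[str]) -> CommunityComposition:
    """Even 12-genome community (1/12 each), as in the ATCC even gut mix."""
    ids = list(genome_ids)
    if len(ids) != 12:
        raise InvalidParameterError(f"even mock community needs exactly 12 genomes, got {len(ids)}")
    return CommunityComposition([(g, 1.0 / 12.0) for g in ids], label="even")


def mock_staggered(genome_ids: Sequence[str]) -> CommunityComposition:
    """Staggered 20-genome community spanning 0.0002 to 0.18 (raw ratio 900).

    Only the range endpoints are prescribed by the ATCC staggered mix design;
    the per-genome values here are a deterministic geometric ladder between
    them, renormalised to sum to 1 (strictly increasing along the ladder).
    """
    ids = list(genome_ids)
    if len(ids) != 20:
        raise InvalidParameterError(
            f"staggered mock community needs exactly 20 genomes, got {len(ids)}"
        )
    raw = np.geomspace(0.0002, 0.18, num=20)
    props = raw / raw.sum()
    return CommunityComposition(list(zip(ids, props.tolist())), label="staggered")


@dataclass
class ReadSimParams:
    """Read simulator knobs; exactly one of n_reads / target_coverage is set.

    ``n_reads`` counts sequenced fragments (a paired fragment yields two FASTQ
    records).  ``target_coverage`` converts to a fragment count as
    round(coverage * total_genome_length / read_length / (2 if paired else 1)).
    """

    read_length: int = DEFAULT_READ_LENGTH
    n_reads: int | None = None
    target_coverage: float | None = None
    substitution_rate: float = 0.0
    paired: bool = True
    seed: int = 0
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH

    def __post_init__(self):
        if (self.n_reads is None) == (self.target_coverage is None):
            raise InvalidParameterError("set exactly one of n_reads / target_coverage")
        if not (0.0 <= self.substitution_rate <= 0.2):
            raise InvalidParameterError("substitution_rate must be in [0, 0.2]")
        if self.read_length < 1:
            raise InvalidParameterError("read_length must be positive")


@dataclass
class ReadSimReport:
    n_fragments: int
    n_records: int
    per_genome: pd.DataFrame  # genome_id, reads, true_proportion
    paths: list[str] = field(default_factory=list)


def generate_genomes(
    k: int,
    length: int,
    shared_block_fraction: float = 0.0,
    seed: int = 0,
    prefix: str = "g",
    n: int = 21,
) -> list[tuple[str, str]]:
    """k random genomes of i.i.d. uniform bases, optionally sharing one block.

    With ``shared_block_fraction`` > 0 an identical block of that fraction of
    the length is implanted in every genome (at a seeded random position) to
    manufacture common n-grams.  Random 100 kb genomes are n-gram-disjoint at
    n = 21 with overwhelming probability (collision chance < 1e-6 per pair).
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if not (0.0 <= shared_block_fraction <= 1.0):
        raise InvalidParameterError("shared_block_fraction must be in [0, 1]")
    if length < 10 * n:
        raise InvalidParameterError(f"genome length must be >= 10*n = {10 * n}")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(k - 1)))
    block_len = int(round(shared_block_fraction * length))
    block = rng.integers(0, 4, size=block_len, dtype=np.uint8) if block_len else None
    out = []
    for i in range(k):
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        if block is not None and block_len:
            pos = int(rng.integers(0, length - block_len + 1))
            codes[pos : pos + block_len] = block
        out.append((f"{prefix}{i:0{width}d}", ng.codes_to_string(codes)))
    return out


def _resolve_n_fragments(params: ReadSimParams, total_length: int) -> int:
    if params.n_reads is not None:
        return int(params.n_reads)
    per_fragment = params.read_length * (2 if params.paired else 1)
    return int(round(params.target_coverage * total_length / per_fragment))


def simulate_reads(
    genomes: Sequence[tuple[str, str]],
    composition: CommunityComposition,
    params: ReadSimParams,
    out1: str | Path | None = None,
    out2: str | Path | None = None,
    chunk_size: int = 100_000,
) -> ReadSimReport | tuple[ReadSimReport, list[tuple[str, str]], list[tuple[str, str]] | None]:
    """Simulate shotgun reads from a community.

    Per fragment: source genome drawn from the composition, start position
    uniform, strand uniform; mate-1 is the first ``read_length`` bases of the
    (possibly reverse-complemented) fragment, mate-2 the reverse complement of
    the far end.  Substitutions are i.i.d. per base.  With ``out1``/``out2``
    reads are streamed to FASTQ and only the report is returned; otherwise
    (report, mate1_records, mate2_records_or_None) is returned in memory.
    """
    by_id = dict(genomes)
    missing = [g for g in composition.genome_ids if g not in by_id]
    if missing:
        raise InvalidParameterError(f"composition genomes missing from genome set: {missing}")
    gids = composition.genome_ids
    seqs = [by_id[g] for g in gids]
    rl = params.read_length
    for g, s in zip(gids, seqs):
        if rl > len(s):
            raise InvalidParameterError(f"read_length {rl} exceeds genome {g!r} length {len(s)}")
    frag = rl if not params.paired else min(params.fragment_length, min(len(s) for s in seqs))
    frag = max(frag, rl)
    codes = [ng.sequence_codes(s) for s in seqs]
    flat = np.concatenate(codes)
    g_off = np.concatenate(([0], np.cumsum([c.size for c in codes])))[:-1]
    g_len = np.array([c.size for c in codes], dtype=np.int64)
    total_len = int(g_len.sum())
    n_frag = _resolve_n_fragments(params, total_len)
    rng = np.random.default_rng(params.seed)
    props = composition.proportions
    if out1 is not None and params.paired and out2 is None:
        raise InvalidParameterError("paired simulation to files requires out2")

    mate1_records: list[tuple[str, str]] = []
    mate2_records: list[tuple[str, str]] = []
    per_genome = np.zeros(len(gids), dtype=np.int64)
    qual = "I" * rl
    to_base = np.frombuffer(b"ACGT", dtype=np.uint8)

    h1 = atomic_open(out1) if out1 is not None else None
    h2 = atomic_open(out2) if (out2 is not None and params.paired) else None
    f1 = h1.__enter__() if h1 else None
    f2 = h2.__enter__() if h2 else None
    try:
        done = 0
        while done < n_frag:
            count = min(chunk_size, n_frag - done)
            gidx = rng.choice(len(gids), size=count, p=props)
            per_genome += np.bincount(gidx, minlength=len(gids))
            span = np.minimum(frag, g_len[gidx])
            starts = (rng.random(count) * (g_len[gidx] - span + 1)).astype(np.int64)
            idx = (g_off[gidx] + starts)[:, None] + np.arange(frag, dtype=np.int64)[None, :]
            idx = np.minimum(idx, (g_off[gidx] + starts + span - 1)[:, None])
            fragments = flat[idx]
            minus = rng.random(count) < 0.5
            fragments[minus] = 3 - fragments[minus][:, ::-1]
            mate1 = fragments[:, :rl].copy()
            mate2 = (3 - fragments[:, -rl:][:, ::-1]) if params.paired else None

            def corrupt(mat):
                if params.substitution_rate > 0:
                    mask = rng.random(mat.shape) < params.substitution_rate
                    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
                    mat[mask] = (mat[mask] + shift[mask]) % 4
                return mat

            mate1 = corrupt(mate1)
            if mate2 is not None:
                mate2 = corrupt(mate2.astype(np.uint8))
            ids = [f"r{done + i} src={gids[gidx[i]]}" for i in range(count)]
            s1 = [to_base[row].tobytes().decode("ascii") for row in mate1]
            if f1 is not None:
                f1.write("".join(f"@{t}/1\n{s}\n+\n{qual}\n" if params.paired
                                 else f"@{t}\n{s}\n+\n{qual}\n" for t, s in zip(ids, s1)))
            else:
                mate1_records.extend(zip(ids, s1))
            if mate2 is not None:
                s2 = [to_base[row].tobytes().decode("ascii") for row in mate2]
                if f2 is not None:
                    f2.write("".join(f"@{t}/2\n{s}\n+\n{qual}\n" for t, s in zip(ids, s2)))
                elif f1 is None:
                    mate2_records.extend(zip(ids, s2))
            done += count
    finally:
        if h1:
            h1.__exit__(None, None, None)
        if h2:
            h2.__exit__(None, None, None)

    truth = composition.to_frame()
    truth["reads"] = per_genome
    report = ReadSimReport(
        n_fragments=n_frag,
        n_records=n_frag * (2 if params.paired else 1),
        per_genome=truth[["genome_id", "reads", "true_proportion"]],
        paths=[str(p) for p in (out1, out2) if p is not None],
    )
    if out1 is not None:
        return report
    return report, mate1_records, (mate2_records if params.paired else None)


def subsample_reads(
    in1: str | Path,
    out1: str | Path,
    in2: str | Path | None = None,
    out2: str | Path | None = None,
    fraction: float | None = None,
    target_coverage: float | None = None,
    total_genome_length: int | None = None,
    seed: int = 0,
) -> dict:
    """Without-replacement subsampling of a FASTQ (pair), order preserved.

    Mate pairs are kept together (record i of each file).  In coverage mode
    the fraction is target_coverage * total_genome_length / total bases in the
    input.  Two streaming passes; nothing is held in memory.
    """
    if (fraction is None) == (target_coverage is None):
        raise InvalidParameterError("set exactly one of fraction / target_coverage")
    n = 0
    bases = 0
    for _t, seq in iter_fastq(in1):
        n += 1
        bases += len(seq)
    if in2 is not None:
        for _t, seq in iter_fastq(in2):
            bases += len(seq)
    if fraction is None:
        if not total_genome_length:
            raise InvalidParameterError("coverage mode requires total_genome_length")
        fraction = target_coverage * total_genome_length / bases
        fraction = min(1.0, fraction)
    if not (0.0 < fraction <= 1.0):
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    keep = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    selected = np.sort(rng.choice(n, size=keep, replace=False))

    def copy(src, dst):
        sel = set(selected.tolist())
        with atomic_open(dst) as out:
            for i, (title, seq) in enumerate(iter_fastq(src)):
                if i in sel:
                    out.write(f"@{title}\n{seq}\n+\n{'I' * len(seq)}\n")

    copy(in1, out1)
    if in2 is not None:
        if out2 is None:
            raise InvalidParameterError("out2 required when in2 is given")
        copy(in2, out2)
    return {"input_reads": n, "kept_reads": keep, "fraction": float(fraction)}


def degrade_references(
    genomes: Sequence[tuple[str, str]],
    keep_fraction: float,
    seed: int | None = None,
    mode: str = "prefix",
) -> list[tuple[str, str]]:
    """Truncate each genome to a contiguous region of keep_fraction length.

    Emulates incomplete draft assemblies.  ``mode='prefix'`` keeps the leading
    region deterministically; ``mode='window'`` keeps a seeded random window.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise InvalidParameterError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if mode not in ("prefix", "window"):
        raise InvalidParameterError(f"unknown degradation mode {mode!r}")
    if keep_fraction == 1.0:
        return [(g, s) for g, s in genomes]
    rng = np.random.default_rng(seed)
    out = []
    for gid, seq in genomes:
        keep = int(round(keep_fraction * len(seq)))
        start = 0 if mode == "prefix" else int(rng.integers(0, len(seq) - keep + 1))
        out.append((gid, seq[start : start + keep]))
    return out
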