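"""Strain identification: score model genomes against a sample's n-gram set.

The sample's reads are deconstructed into the *distinct* set of n-grams
(multiplicity is deliberately ignored here; it re-enters at quantification
through per-read assignment).  For each genome g the matched n-gram weights
are summed,

    S_g     = sum over sample n-grams present in g of S(m, C)
    nFactor = n_c / n_t          (matched fraction of the genome's n-grams)
    fS_g    = S_g * nFactor

and genomes with fS at or above a calibrated cutoff are called present.
Conceptually S_g is a column sum of the weight matrix W (n-grams x genomes);
the matrix is never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import ngrams as ng
from .errors import ConfigurationError, InvalidParameterError
from .io import iter_fastq_seq_chunks
from .model import SignatureModel, score_weights

_MERGE_LIMIT = 48_000_000  # merge accumulated chunk sets beyond this many values


@dataclass
class SampleNgramSet:
    """Deduplicated n-grams of a whole read collection (sorted uint64)."""

    ngrams: np.ndarray = field(repr=False)
    n: int = 21
    orientation: str = ng.ORIENTATION_CANONICAL
    reads_seen: int = 0
    source_files: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return int(self.ngrams.size)


@dataclass
class GenomeScore:
    genome_id: str
    score_sum: float  # S_g
    n_c: int
    n_t: int
    n_factor: float
    fs: float


@dataclass
class PredictionSet:
    scores: list[GenomeScore]
    cutoff: float
    predicted: list[GenomeScore]

    @property
    def predicted_ids(self) -> list[str]:
        return [g.genome_id for g in self.predicted]


def _accumulate_distinct(chunks: Iterable[list[str]], n: int, orientation: str,
                         revcomp: bool = False) -> tuple[np.ndarray, int]:
    parts: list[np.ndarray] = []
    held = 0
    reads = 0
    for chunk in chunks:
        reads += len(chunk)
        values, _ridx = ng.encode_concatenated(chunk, n, orientation=orientation, revcomp=revcomp)
        if values.size:
            parts.append(np.unique(values))
            held += parts[-1].size
        if held > _MERGE_LIMIT and len(parts) > 1:
            parts = [np.unique(np.concatenate(parts))]
            held = parts[0].size
    if not parts:
        return np.empty(0, dtype=np.uint64), reads
    return np.unique(np.concatenate(parts)) if len(parts) > 1 else parts[0], reads


def sample_from_sequences(
    seqs: Iterable[str],
    mate2_seqs: Iterable[str] | None = None,
    n: int = 21,
    orientation: str = ng.ORIENTATION_CANONICAL,
    chunk_size: int = 50_000,
) -> SampleNgramSet:
    """Build a :class:`SampleNgramSet` from in-memory read sequences.

    In ``as-is`` orientation, mate-2 reads are reverse-complemented to the
    forward direction before extraction; in ``canonical`` orientation each
    n-gram is canonicalised, which makes the mate-2 handling a no-op
    semantically but it is applied uniformly anyway.
    """
    if orientation not in ng.ORIENTATIONS:
        raise InvalidParameterError(f"unknown orientation {orientation!r}")

    def chunked(it):
        buf = []
        for s in it:
            buf.append(s)
            if len(buf) >= chunk_size:
                yield buf
                buf = []
        if buf:
            yield buf

    rc_mate2 = orientation == ng.ORIENTATION_AS_IS
    set1, reads1 = _accumulate_distinct(chunked(seqs), n, orientation)
    if mate2_seqs is not None:
        set2, reads2 = _accumulate_distinct(chunked(mate2_seqs), n, orientation, revcomp=rc_mate2)
        merged = np.unique(np.concatenate((set1, set2)))
        return SampleNgramSet(merged, n, orientation, reads1 + reads2)
    return SampleNgramSet(set1, n, orientation, reads1)


def collect_sample_ngrams(
    fastq_sources: Sequence[str | Path],
    mate2_sources: Sequence[str | Path] | None = None,
    n: int = 21,
    orientation: str = ng.ORIENTATION_CANONICAL,
    chunk_size: int = 50_000,
) -> SampleNgramSet:
    """Collect the distinct n-gram set of one sample from FASTQ files."""
    if orientation not in ng.ORIENTATIONS:
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    rc_mate2 = orientation == ng.ORIENTATION_AS_IS
    set1, reads1 = _accumulate_distinct(
        iter_fastq_seq_chunks(fastq_sources, chunk_size), n, orientation
    )
    reads = reads1
    if mate2_sources:
        set2, reads2 = _accumulate_distinct(
            iter_fastq_seq_chunks(mate2_sources, chunk_size), n, orientation, revcomp=rc_mate2
        )
        reads += reads2
        set1 = np.unique(np.concatenate((set1, set2)))
    files = [str(p) for p in fastq_sources] + [str(p) for p in (mate2_sources or [])]
    return SampleNgramSet(set1, n, orientation, reads, files)


def score_genomes(sample: SampleNgramSet, model: SignatureModel,
                  chunk_size: int = 8_000_000) -> list[GenomeScore]:
    """Score every model genome against a sample n-gram set.

    Output is ordered by descending fS, ties broken by genome_id ascending.
    """
    if sample.n != model.n:
        raise ConfigurationError(f"sample n={sample.n} does not match model n={model.n}")
    if sample.orientation != model.orientation:
        raise ConfigurationError(
            f"sample orientation {sample.orientation!r} does not match "
            f"model orientation {model.orientation!r}"
        )
    g = model.genome_count
    s_sum = np.zeros(g, dtype=np.float64)
    n_c = np.zeros(g, dtype=np.int64)
    values = sample.ngrams
    for lo in range(0, values.size, chunk_size):
        part = values[lo : lo + chunk_size]
        hit, idx = model.lookup(part)
        kidx = idx[hit]
        if not kidx.size:
            continue
        m = model.counts[kidx].astype(np.int64)
        w = score_weights(m, g)
        total = int(m.sum())
        within = np.arange(total, dtype=np.int64) - np.repeat(
            np.concatenate(([0], np.cumsum(m)))[:-1], m
        )
        pos = np.repeat(model.offsets[kidx], m) + within
        ords = model.ordinals[pos]
        s_sum += np.bincount(ords, weights=np.repeat(w, m), minlength=g)
        n_c += np.bincount(ords, minlength=g)

    out = []
    for rec, s, c in zip(model.genomes, s_sum, n_c):
        nf = (c / rec.n_t) if rec.n_t else 0.0
        out.append(
            GenomeScore(rec.genome_id, float(s), int(c), rec.n_t, float(nf), float(s * nf))
        )
    out.sort(key=lambda r: (-r.fs, r.genome_id))
    return out


def apply_cutoff(scores: Sequence[GenomeScore], cutoff: float) -> PredictionSet:
    """Call genomes with fS >= cutoff present (inclusive comparison)."""
    if cutoff < 0:
        raise InvalidParameterError(f"cutoff must be >= 0, got {cutoff}")
    predicted = [s for s in scores if s.fs >= cutoff]
    return PredictionSet(list(scores), float(cutoff), predicted)


def scores_to_frame(scores: Sequence[GenomeScore], cutoff: float | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "genome_id": [s.genome_id for s in scores],
            "S_g": [s.score_sum for s in scores],
            "n_c": [s.n_c for s in scores],
            "n_t": [s.n_t for s in scores],
            "nFactor": [s.n_factor for s in scores],
            "fS": [s.fs for s in scores],
        }
    )
    if cutoff is not None:
        df["predicted"] = (df["fS"] >= cutoff).astype(int)
    return df


def write_scores_tsv(scores: Sequence[GenomeScore], cutoff: float, handle) -> None:
    df = scores_to_frame(scores, cutoff)
    for col in ("S_g", "nFactor", "fS"):
        df[col] = df[col].map(lambda v: f"{v:.6g}")
    df.to_csv(handle, sep="\t", index=False)
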