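"""Read assignment and relative abundance estimation.

Every read (each mate independently) is assigned to at most one of the
genomes that survived the identification cutoff:

Rule 1
    if the read carries unique n-grams (m = 1) of predicted genomes, assign
    to the predicted genome with the most such unique n-grams; a tie falls
    through to Rule 2 restricted to the tied genomes.
Rule 2
    compute the read-genome score R_jg — the sum of the weights S(m, C) of
    the n-grams shared between the read and genome g — and assign to the
    argmax; remaining ties break by genome_id ascending and are flagged.
Rule 3
    a read sharing no n-gram with any predicted genome stays unassigned.

Relative abundance is the assigned-read fraction per predicted genome (no
genome-length normalisation by default; ``length_normalize`` divides counts
by genome length before renormalising).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import ngrams as ng
from .errors import InvalidParameterError
from .identify import PredictionSet
from .io import iter_fastq
from .model import SignatureModel, score_weights

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

RULE_UNIQUE = "unique"
RULE_COMMON = "common-argmax"
RULE_UNASSIGNED = "unassigned"


@dataclass
class ReadAssignment:
    read_id: str
    assigned_genome: str  # genome_id or UNASSIGNED
    rule_used: str
    tie_broken: bool = False


@dataclass
class AbundanceTable:
    """Assigned-read counts and normalised relative abundances.

    Rows cover every predicted genome (zeros included); abundances sum to 1
    whenever at least one read was assigned, else they are reported as 0.
    """

    rows: list[tuple[str, int, float]]
    unassigned_reads: int
    total_reads: int
    length_normalized: bool = False
    assignments: list[ReadAssignment] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["genome_id", "assigned_reads", "relative_abundance"])

    def abundance_of(self, genome_id: str) -> float:
        for gid, _c, rel in self.rows:
            if gid == genome_id:
                return rel
        raise KeyError(genome_id)


class _PredictedIndex:
    """Predicted-genome columns sorted by genome_id (the tie-break order)."""

    def __init__(self, model: SignatureModel, predicted_ids: Sequence[str]):
        if not predicted_ids:
            raise InvalidParameterError("predicted genome set is empty")
        self.model = model
        self.ids = sorted(set(predicted_ids))
        ords = [model.ordinal_of(g) for g in self.ids]
        self.cols = np.array(ords, dtype=np.int64)
        self.ord_to_col = np.full(model.genome_count, -1, dtype=np.int64)
        self.ord_to_col[self.cols] = np.arange(len(self.cols))
        self.lengths = np.array(
            [model.genomes[o].total_length for o in ords], dtype=np.float64
        )


def _match_tables(read_values: np.ndarray, read_index: np.ndarray, n_reads: int,
                  pidx: _PredictedIndex):
    """Dense per-read tables over predicted genomes: unique counts U, scores R,
    and shared-n-gram counts M."""
    model = pidx.model
    p = len(pidx.cols)
    U = np.zeros((n_reads, p), dtype=np.int64)
    R = np.zeros((n_reads, p), dtype=np.float64)
    M = np.zeros((n_reads, p), dtype=np.int64)
    if read_values.size:
        hit, kidx = model.lookup(read_values)
        kidx = kidx[hit]
        ridx = read_index[hit]
        if kidx.size:
            m = model.counts[kidx].astype(np.int64)
            w = score_weights(m, model.genome_count)
            total = int(m.sum())
            within = np.arange(total, dtype=np.int64) - np.repeat(
                np.concatenate(([0], np.cumsum(m)))[:-1], m
            )
            pos = np.repeat(model.offsets[kidx], m) + within
            ords = model.ordinals[pos].astype(np.int64)
            col = pidx.ord_to_col[ords]
            keep = col >= 0
            col = col[keep]
            rr = np.repeat(ridx, m)[keep]
            ww = np.repeat(w, m)[keep]
            uu = np.repeat(m == 1, m)[keep]
            flat = rr * p + col
            size = n_reads * p
            M += np.bincount(flat, minlength=size).reshape(n_reads, p)
            R += np.bincount(flat, weights=ww, minlength=size).reshape(n_reads, p)
            U += np.bincount(flat, weights=uu.astype(np.float64), minlength=size).reshape(
                n_reads, p
            ).astype(np.int64)
    return U, R, M


def _decide(U: np.ndarray, R: np.ndarray, M: np.ndarray):
    """Vectorised Rule 1/2/3 decision per read.

    Returns (winner column, rule code, tie_broken); winner is -1 for
    unassigned reads.  The decision is the lexicographic max of
    (unique-count, R_jg, smallest genome_id), which reproduces the
    rule cascade exactly.
    """
    matched = M.sum(axis=1) > 0
    u_max = U.max(axis=1)
    mask1 = U == u_max[:, None]
    r_masked = np.where(mask1, R, -1.0)
    r_max = r_masked.max(axis=1)
    mask2 = mask1 & (r_masked == r_max[:, None])
    winner = np.argmax(mask2, axis=1)  # first True = smallest genome_id
    tie_broken = (mask2.sum(axis=1) > 1) & matched
    unique_rule = (u_max > 0) & (mask1.sum(axis=1) == 1)
    winner = np.where(matched, winner, -1)
    rules = np.where(matched, np.where(unique_rule, 0, 1), 2)
    return winner, rules, tie_broken


def assign_read(
    read_ngrams: np.ndarray | Iterable[int],
    model: SignatureModel,
    predicted: Sequence[str] | PredictionSet,
    read_id: str = "read",
) -> ReadAssignment:
    """Assign one read from its distinct n-gram set (reference scalar path)."""
    if isinstance(predicted, PredictionSet):
        predicted = predicted.predicted_ids
    pidx = _PredictedIndex(model, predicted)
    values = np.unique(np.asarray(list(read_ngrams) if not isinstance(read_ngrams, np.ndarray)
                                  else read_ngrams, dtype=np.uint64))
    U, R, M = _match_tables(values, np.zeros(values.size, dtype=np.int64), 1, pidx)
    winner, rules, tie = _decide(U, R, M)
    if winner[0] < 0:
        return ReadAssignment(read_id, UNASSIGNED, RULE_UNASSIGNED, False)
    rule = RULE_UNIQUE if rules[0] == 0 else RULE_COMMON
    return ReadAssignment(read_id, pidx.ids[int(winner[0])], rule, bool(tie[0]))


def _assign_batch(seqs: list[str], ids: list[str], model: SignatureModel,
                  pidx: _PredictedIndex, revcomp: bool = False):
    values, ridx = ng.encode_concatenated(
        seqs, model.n, orientation=model.orientation, revcomp=revcomp
    )
    # per-read deduplication: identification and assignment both use distinct
    # n-gram sets
    if values.size:
        order = np.lexsort((values, ridx))
        values = values[order]
        ridx = ridx[order]
        keep = np.concatenate(([True], (values[1:] != values[:-1]) | (ridx[1:] != ridx[:-1])))
        values = values[keep]
        ridx = ridx[keep]
    U, R, M = _match_tables(values, ridx, len(seqs), pidx)
    winner, rules, tie = _decide(U, R, M)
    out = []
    for i, rid in enumerate(ids):
        if winner[i] < 0:
            out.append(ReadAssignment(rid, UNASSIGNED, RULE_UNASSIGNED, False))
        else:
            rule = RULE_UNIQUE if rules[i] == 0 else RULE_COMMON
            out.append(ReadAssignment(rid, pidx.ids[int(winner[i])], rule, bool(tie[i])))
    return out, winner


def quantify_sequences(
    reads: Iterable[tuple[str, str]],
    model: SignatureModel,
    prediction: PredictionSet | Sequence[str],
    mate2: Iterable[tuple[str, str]] | None = None,
    length_normalize: bool = False,
    collect_assignments: bool = False,
    chunk_size: int = 20_000,
) -> AbundanceTable:
    """Quantify from (read_id, sequence) iterables; mates counted independently."""
    predicted_ids = (
        prediction.predicted_ids if isinstance(prediction, PredictionSet) else list(prediction)
    )
    pidx = _PredictedIndex(model, predicted_ids)
    p = len(pidx.cols)
    counts = np.zeros(p, dtype=np.int64)
    unassigned = 0
    total = 0
    assignments: list[ReadAssignment] = []

    def run(stream, revcomp):
        nonlocal unassigned, total
        buf_ids: list[str] = []
        buf_seqs: list[str] = []

        def flush():
            nonlocal unassigned, total
            if not buf_seqs:
                return
            out, winner = _assign_batch(buf_seqs, buf_ids, model, pidx, revcomp)
            assigned = winner[winner >= 0]
            counts[:] += np.bincount(assigned, minlength=p)
            unassigned += int((winner < 0).sum())
            total += len(buf_seqs)
            if collect_assignments:
                assignments.extend(out)
            buf_ids.clear()
            buf_seqs.clear()

        for rid, seq in stream:
            buf_ids.append(rid)
            buf_seqs.append(seq)
            if len(buf_seqs) >= chunk_size:
                flush()
        flush()

    rc_mate2 = model.orientation == ng.ORIENTATION_AS_IS
    run(reads, revcomp=False)
    if mate2 is not None:
        run(mate2, revcomp=rc_mate2)

    weights = counts.astype(np.float64)
    if length_normalize:
        weights = np.divide(weights, pidx.lengths, out=np.zeros_like(weights),
                            where=pidx.lengths > 0)
    denom = weights.sum()
    if counts.sum() == 0:
        logger.warning("no reads could be assigned to any predicted genome")
        rel = np.zeros(p)
    else:
        rel = weights / denom
    rows = [(gid, int(c), float(r)) for gid, c, r in zip(pidx.ids, counts, rel)]
    return AbundanceTable(rows, unassigned, total, length_normalize, assignments)


def quantify_reads(
    fastq_sources: Sequence[str | Path],
    model: SignatureModel,
    prediction: PredictionSet | Sequence[str],
    mate2_sources: Sequence[str | Path] | None = None,
    length_normalize: bool = False,
    collect_assignments: bool = False,
    chunk_size: int = 20_000,
) -> AbundanceTable:
    """Quantify from FASTQ files (optionally paired)."""

    def stream(paths, suffix):
        for path in paths:
            for title, seq in iter_fastq(path):
                yield title.split()[0] + suffix, seq

    mate2 = stream(mate2_sources, "/2") if mate2_sources else None
    return quantify_sequences(
        stream(fastq_sources, "/1" if mate2_sources else ""),
        model,
        prediction,
        mate2=mate2,
        length_normalize=length_normalize,
        collect_assignments=collect_assignments,
        chunk_size=chunk_size,
    )


def abundance_to_tsv(table: AbundanceTable, handle) -> None:
    handle.write("genome_id\tassigned_reads\trelative_abundance\n")
    for gid, c, rel in table.rows:
        handle.write(f"{gid}\t{c}\t{rel:.6g}\n")


def assignments_to_tsv(assignments: Sequence[ReadAssignment], handle) -> None:
    handle.write("read_id\tgenome_id\trule\ttie_broken\n")
    for a in assignments:
        handle.write(f"{a.read_id}\t{a.assigned_genome}\t{a.rule_used}\t{int(a.tie_broken)}\n")
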