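"""Empirical score-cutoff calibration from positive/negative score curves.

The site-specific cutoff is the point where the ascending sorted scores of a
negative (non-site) dataset first exceed the descending sorted scores of a
positive (site) dataset.  Equal-length curves are compared rank by rank; when
the input lists differ in length both are truncated to the shorter one, since
the rank-wise comparison needs aligned ranks.  The cutoff value at a crossing
is the midpoint of the two curve values at that rank; if the curves never
cross and the distributions are fully separated, the midpoint of the gap is
returned instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationError, InvalidParameterError
from .identify import SampleNgramSet, collect_sample_ngrams, score_genomes
from .model import SignatureModel


@dataclass
class ScoreCurve:
    label: str  # "positive" | "negative"
    values: list[float]  # sorted: descending for positive, ascending for negative


@dataclass
class CutoffResult:
    cutoff: float
    crossing_rank: int | None
    positive_curve: ScoreCurve
    negative_curve: ScoreCurve
    separable: bool

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "crossing_rank": self.crossing_rank,
            "separable": self.separable,
            "n_pos": len(self.positive_curve.values),
            "n_neg": len(self.negative_curve.values),
        }


def estimate_cutoff(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> CutoffResult:
    """Locate the crossing of the two sorted score curves.

    crossing_rank is the smallest rank i with neg_asc[i] > pos_desc[i]
    (strict; at-tie ranks do not cross).  Raises :class:`CalibrationError`
    when the negatives dominate at rank 0 or the curves neither cross nor
    separate.
    """
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise InvalidParameterError("both score lists must be non-empty")
    pos_desc = sorted(float(v) for v in pos_scores)[::-1]
    neg_asc = sorted(float(v) for v in neg_scores)
    length = min(len(pos_desc), len(neg_asc))
    pos_desc = pos_desc[:length]
    neg_asc = neg_asc[:length]
    pos_curve = ScoreCurve("positive", pos_desc)
    neg_curve = ScoreCurve("negative", neg_asc)

    crossing = None
    for i in range(length):
        if neg_asc[i] > pos_desc[i]:
            crossing = i
            break
    if crossing == 0:
        raise CalibrationError(
            "negative scores dominate the positive scores at every rank",
            positive_curve=pos_curve,
            negative_curve=neg_curve,
        )
    if crossing is not None:
        cutoff = (neg_asc[crossing] + pos_desc[crossing]) / 2.0
        return CutoffResult(cutoff, crossing, pos_curve, neg_curve, separable=False)
    if max(neg_asc) < min(pos_desc):
        cutoff = (max(neg_asc) + min(pos_desc)) / 2.0
        return CutoffResult(cutoff, None, pos_curve, neg_curve, separable=True)
    raise CalibrationError(
        "score curves neither cross nor separate; cannot calibrate",
        positive_curve=pos_curve,
        negative_curve=neg_curve,
    )


def _as_sample(reads, model: SignatureModel) -> SampleNgramSet:
    if isinstance(reads, SampleNgramSet):
        return reads
    return collect_sample_ngrams(list(reads), n=model.n, orientation=model.orientation)


def calibrate_from_reads(
    model: SignatureModel,
    positive_reads,
    positive_truth: Sequence[str],
    negative_reads,
) -> CutoffResult:
    """Calibrate a cutoff from a positive and a negative read set.

    ``positive_reads``/``negative_reads`` are FASTQ path lists or prebuilt
    :class:`SampleNgramSet` objects.  The positive curve holds the fS scores
    of the known-present (truth) genomes under the positive sample; the
    negative curve holds the fS scores of *all* model genomes under the
    negative sample — those are exactly the false-positive scores the cutoff
    is designed to bound.
    """
    truth = set(positive_truth)
    missing = truth - set(model.genome_ids)
    if missing:
        raise InvalidParameterError(f"truth genomes not in model: {sorted(missing)}")
    pos_scores = score_genomes(_as_sample(positive_reads, model), model)
    neg_scores = score_genomes(_as_sample(negative_reads, model), model)
    pos_curve = [s.fs for s in pos_scores if s.genome_id in truth]
    neg_curve = [s.fs for s in neg_scores]
    return estimate_cutoff(pos_curve, neg_curve)


def curves_to_tsv(result: CutoffResult, handle) -> None:
    """Two-column TSV of the aligned curves, one row per rank (for plotting)."""
    handle.write("rank\tpositive_desc\tnegative_asc\n")
    for i, (p, n) in enumerate(zip(result.positive_curve.values, result.negative_curve.values)):
        handle.write(f"{i}\t{p:.6g}\t{n:.6g}\n")
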