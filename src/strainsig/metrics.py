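"""Confusion counts and sensitivity/specificity/F1 over a closed universe.

The universe of negatives is the model's genome set — the only taxa the
method can name — so TN is countable.  Metrics with a zero denominator are
reported as undefined (None), never as a crash.  An optional strain ->
(species, genus) taxonomy rolls predictions, truth, and universe up to higher
levels before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError

LEVELS = ("strain", "species", "genus")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    counts: ConfusionCounts
    level: str = "strain"

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "TP": self.counts.tp,
            "FP": self.counts.fp,
            "TN": self.counts.tn,
            "FN": self.counts.fn,
        }


def confusion(predicted: Iterable[str], truth: Iterable[str], universe: Iterable[str]) -> ConfusionCounts:
    """Element-wise confusion counts over a closed universe of taxa."""
    predicted, truth, universe = set(predicted), set(truth), set(universe)
    if not predicted <= universe:
        raise ConfigurationError(
            f"predicted ids outside universe: {sorted(predicted - universe)}"
        )
    if not truth <= universe:
        raise ConfigurationError(f"truth ids outside universe: {sorted(truth - universe)}")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def compute_metrics(counts: ConfusionCounts, level: str = "strain") -> MetricsReport:
    """sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), F1 = TP/(TP+(FP+FN)/2)."""
    sens = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else None
    spec = counts.tn / (counts.tn + counts.fp) if (counts.tn + counts.fp) else None
    f1_den = counts.tp + 0.5 * (counts.fp + counts.fn)
    f1 = counts.tp / f1_den if f1_den else None
    return MetricsReport(sens, spec, f1, counts, level)


def read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Parse a strain_id<TAB>species<TAB>genus mapping file."""
    mapping: dict[str, tuple[str, str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected strain<TAB>species<TAB>genus"
                )
            mapping[parts[0]] = (parts[1], parts[2])
    if not mapping:
        raise ConfigurationError(f"taxonomy file {path} is empty")
    return mapping


def rollup(
    strain_ids: Iterable[str],
    taxonomy: Mapping[str, tuple[str, str]],
    level: str,
) -> set[str]:
    """Map a set of strain ids through the taxonomy to species or genus."""
    ids = set(strain_ids)
    if level == "strain":
        return ids
    if level not in LEVELS:
        raise ConfigurationError(f"unknown taxonomic level {level!r}")
    missing = sorted(g for g in ids if g not in taxonomy)
    if missing:
        raise ConfigurationError(f"strains missing from taxonomy mapping: {missing}")
    pos = 0 if level == "species" else 1
    return {taxonomy[g][pos] for g in ids}


def evaluate(
    predicted: Iterable[str],
    truth: Iterable[str],
    universe: Iterable[str],
    taxonomy: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, MetricsReport]:
    """Metrics per taxonomic level (strain always; species/genus with a taxonomy)."""
    predicted, truth, universe = set(predicted), set(truth), set(universe)
    levels: Sequence[str] = LEVELS if taxonomy is not None else ("strain",)
    out = {}
    for level in levels:
        p = rollup(predicted, taxonomy or {}, level)
        t = rollup(truth, taxonomy or {}, level)
        u = rollup(universe, taxonomy or {}, level)
        out[level] = compute_metrics(confusion(p, t, u), level)
    return out
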