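"""DNA signature element models (DSEMs): build, score, survey, serialize.

A signature model indexes every distinct n-gram of a body-site reference
genome set and records which genomes contain it (a posting list).  The
discriminatory weight of an n-gram present in ``m`` of the model's ``C``
genomes is

    S(m, C) = [ln(C / m) / ln(C)]**2

so a unique n-gram (m = 1) scores 1, an n-gram shared by every genome scores
0, and the squared form dampens weights rapidly as n-grams become common.
Weights are never stored; they are recomputed from the posting counts at
query time.
"""

from __future__ import annotations

import logging
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import ngrams as ng
from .errors import (
    ConfigurationError,
    CorruptModelError,
    FastaError,
    InvalidParameterError,
    ModelFormatError,
    ModelTooSmallError,
)
from .io import read_fasta

logger = logging.getLogger(__name__)

MAGIC = b"DSEM"
FORMAT_VERSION = 1
MIN_RECOMMENDED_GENOMES = 50

_ORIENT_TO_BYTE = {ng.ORIENTATION_AS_IS: 0, ng.ORIENTATION_CANONICAL: 1}
_BYTE_TO_ORIENT = {v: k for k, v in _ORIENT_TO_BYTE.items()}


def score_ngram(m: int, c: int) -> float:
    """Weight of an n-gram present in ``m`` of ``c`` model genomes.

    Monotonically decreasing in m for fixed c, with S(1, c) = 1 and
    S(c, c) = 0.
    """
    if c < 2:
        raise ModelTooSmallError(f"a model needs at least 2 genomes, got C={c}")
    if not (1 <= m <= c):
        raise InvalidParameterError(f"genomes-containing count m={m} outside [1, {c}]")
    return (math.log(c / m) / math.log(c)) ** 2


def score_weights(m: np.ndarray, c: int) -> np.ndarray:
    """Vectorised :func:`score_ngram` (inputs assumed in-range)."""
    r = np.log(c / np.asarray(m, dtype=np.float64)) / math.log(c)
    return r * r


@dataclass
class GenomeRecord:
    """Per-genome bookkeeping inside a model.

    ``n_t`` counts the genome's *distinct* n-grams (the index is a set);
    ``unique_count`` of those occur in this genome only.
    """

    genome_id: str
    display_name: str = ""
    total_length: int = 0
    n_t: int = 0
    unique_count: int = 0


@dataclass
class BuildReport:
    total_distinct: int
    unique: int
    common: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class SurveyRow:
    """Unique/common n-gram partition of a genome set at one gram size."""

    n: int
    total_distinct: int
    unique: int
    common: int


class SignatureModel:
    """n-gram -> genome-membership index over a reference genome set.

    Postings are stored CSR-style: ``keys`` (sorted distinct packed n-grams),
    ``counts`` (m per key), ``offsets``/``ordinals`` (concatenated, strictly
    increasing genome ordinals per key).
    """

    def __init__(
        self,
        n: int,
        orientation: str,
        genomes: list[GenomeRecord],
        keys: np.ndarray,
        counts: np.ndarray,
        offsets: np.ndarray,
        ordinals: np.ndarray,
    ):
        if orientation not in ng.ORIENTATIONS:
            raise InvalidParameterError(f"unknown orientation {orientation!r}")
        if len(genomes) < 2:
            raise ModelTooSmallError("a signature model needs at least 2 genomes")
        self.n = int(n)
        self.orientation = orientation
        self.genomes = genomes
        self.keys = np.ascontiguousarray(keys, dtype=np.uint64)
        self.counts = np.ascontiguousarray(counts, dtype=np.uint32)
        self.offsets = np.ascontiguousarray(offsets, dtype=np.int64)
        self.ordinals = np.ascontiguousarray(ordinals, dtype=np.uint32)

    # -- basic introspection -------------------------------------------------

    @property
    def genome_count(self) -> int:
        return len(self.genomes)

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def ordinal_of(self, genome_id: str) -> int:
        try:
            return self.genome_ids.index(genome_id)
        except ValueError:
            raise ConfigurationError(f"genome {genome_id!r} not in model") from None

    @property
    def n_t(self) -> np.ndarray:
        return np.array([g.n_t for g in self.genomes], dtype=np.int64)

    def lookup(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Match packed n-grams against the index.

        Returns ``(hit_mask, key_index)``; ``key_index`` is valid where
        ``hit_mask`` is True.
        """
        values = np.asarray(values, dtype=np.uint64)
        idx = np.searchsorted(self.keys, values)
        idx_c = np.minimum(idx, max(len(self.keys) - 1, 0))
        hit = (
            (idx < len(self.keys)) & (self.keys[idx_c] == values)
            if len(self.keys)
            else np.zeros(values.shape, dtype=bool)
        )
        return hit, idx_c

    def equals(self, other: "SignatureModel") -> bool:
        return (
            self.n == other.n
            and self.orientation == other.orientation
            and self.genomes == other.genomes
            and np.array_equal(self.keys, other.keys)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.offsets, other.offsets)
            and np.array_equal(self.ordinals, other.ordinals)
        )

    def validate(self) -> None:
        """Check structural invariants; raises :class:`CorruptModelError`."""
        if len(self.keys) != len(self.counts) or len(self.offsets) != len(self.keys) + 1:
            raise CorruptModelError("postings arrays are inconsistent")
        if len(self.keys) and np.any(np.diff(self.keys.view(np.uint64)) <= 0):
            raise CorruptModelError("posting keys are not strictly increasing")
        if np.any(self.counts < 1):
            raise CorruptModelError("empty posting list")
        if not np.array_equal(np.diff(self.offsets), self.counts.astype(np.int64)):
            raise CorruptModelError("offsets do not match posting counts")
        if self.ordinals.size and self.ordinals.max() >= self.genome_count:
            raise CorruptModelError("genome ordinal out of range")
        n_t = np.bincount(self.ordinals, minlength=self.genome_count)
        if not np.array_equal(n_t, self.n_t):
            raise CorruptModelError("per-genome n_t does not match postings")

    # -- serialization (documented little-endian binary layout) --------------

    def save(self, path: str | Path) -> None:
        """Write the model in its binary container format.

        Layout (little-endian): magic ``DSEM``, format version u16, n u8,
        orientation u8, genome count u32; per genome an id and display name
        (u16 length-prefixed UTF-8), total_length/n_t/unique_count u64; then
        postings sorted ascending by n-gram, each as n-gram u64, m u32, and m
        delta-encoded genome ordinals u32.
        """
        head = bytearray()
        head += MAGIC
        head += struct.pack("<HBBI", FORMAT_VERSION, self.n,
                            _ORIENT_TO_BYTE[self.orientation], self.genome_count)
        for g in self.genomes:
            for s in (g.genome_id, g.display_name):
                raw = s.encode("utf-8")
                head += struct.pack("<H", len(raw)) + raw
            head += struct.pack("<QQQ", g.total_length, g.n_t, g.unique_count)

        m = self.counts.astype(np.int64)
        n_keys = len(self.keys)
        rec_len = 3 + m  # u32 words per record: key lo, key hi, m, deltas
        rec_off = np.concatenate(([0], np.cumsum(rec_len)))
        buf = np.zeros(int(rec_off[-1]), dtype=np.uint32)
        buf[rec_off[:-1]] = (self.keys & np.uint64(0xFFFFFFFF)).astype(np.uint32)
        buf[rec_off[:-1] + 1] = (self.keys >> np.uint64(32)).astype(np.uint32)
        buf[rec_off[:-1] + 2] = self.counts
        if self.ordinals.size:
            group_start = self.offsets[:-1]
            deltas = self.ordinals.astype(np.int64).copy()
            deltas[1:] -= self.ordinals[:-1].astype(np.int64)
            deltas[group_start] = self.ordinals[group_start]
            within = np.arange(self.ordinals.size, dtype=np.int64) - np.repeat(group_start, m)
            pos = np.repeat(rec_off[:-1] + 3, m) + within
            buf[pos] = deltas.astype(np.uint32)
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_name(path.name + ".tmp")
        with open(tmp, "wb") as out:
            out.write(bytes(head))
            buf.astype("<u4").tofile(out)
        tmp.replace(path)

    @classmethod
    def load(cls, path: str | Path) -> "SignatureModel":
        """Read a model written by :meth:`save`; bit-exact round trip."""
        data = Path(path).read_bytes()
        if len(data) < 12 or data[:4] != MAGIC:
            raise ModelFormatError(f"{path}: not a signature model file (bad magic)")
        version, n, orient_byte, n_genomes = struct.unpack_from("<HBBI", data, 4)
        if version != FORMAT_VERSION:
            raise ModelFormatError(f"{path}: unsupported format version {version}")
        if orient_byte not in _BYTE_TO_ORIENT:
            raise CorruptModelError(f"{path}: unknown orientation byte {orient_byte}")
        off = 12
        genomes = []
        try:
            for _ in range(n_genomes):
                strs = []
                for _s in range(2):
                    (slen,) = struct.unpack_from("<H", data, off)
                    off += 2
                    strs.append(data[off : off + slen].decode("utf-8"))
                    off += slen
                total_length, n_t, unique_count = struct.unpack_from("<QQQ", data, off)
                off += 24
                genomes.append(GenomeRecord(strs[0], strs[1], total_length, n_t, unique_count))
        except struct.error as exc:
            raise CorruptModelError(f"{path}: truncated genome table") from exc
        body = data[off:]
        if len(body) % 4:
            raise CorruptModelError(f"{path}: postings section is not word-aligned")
        words = np.frombuffer(body, dtype="<u4").astype(np.uint32)
        ms = []
        cur = 0
        total = words.size
        while cur < total:
            if cur + 3 > total:
                raise CorruptModelError(f"{path}: truncated posting record")
            m = int(words[cur + 2])
            if m < 1 or cur + 3 + m > total:
                raise CorruptModelError(f"{path}: truncated posting record")
            ms.append(m)
            cur += 3 + m
        counts = np.array(ms, dtype=np.int64)
        rec_off = np.concatenate(([0], np.cumsum(3 + counts)))[:-1].astype(np.int64)
        keys = words[rec_off].astype(np.uint64) | (words[rec_off + 1].astype(np.uint64) << np.uint64(32))
        offsets = np.concatenate(([0], np.cumsum(counts)))
        if counts.size:
            within = np.arange(int(counts.sum()), dtype=np.int64) - np.repeat(offsets[:-1], counts)
            pos = np.repeat(rec_off + 3, counts) + within
            deltas = words[pos].astype(np.int64)
            cs = np.cumsum(deltas)
            group_base = cs[offsets[:-1]] - deltas[offsets[:-1]]
            ordinals = (cs - np.repeat(group_base, counts)).astype(np.uint32)
        else:
            ordinals = np.empty(0, dtype=np.uint32)
        model = cls(n, _BYTE_TO_ORIENT[orient_byte], genomes,
                    keys, counts.astype(np.uint32), offsets, ordinals)
        model.validate()
        return model


# -- construction -------------------------------------------------------------


def filter_plasmids(records: Iterable[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    """Drop FASTA records whose header contains the token 'plasmid' (any case)."""
    return [r for r in records if "plasmid" not in r[1].lower()]


def _genome_distinct(seqs: Sequence[str], n: int, orientation: str) -> np.ndarray:
    parts = []
    for seq in seqs:
        ext = ng.extract_ngrams(seq, n, orientation=orientation)
        if ext.ngrams.size:
            parts.append(ext.ngrams)
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def _check_genome_inputs(genome_seqs: Sequence[tuple[str, Sequence[str] | str]]):
    ids = [gid for gid, _ in genome_seqs]
    if len(genome_seqs) < 2:
        raise ModelTooSmallError("model construction needs at least 2 genomes")
    dupes = {g for g in ids if ids.count(g) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate genome ids: {sorted(dupes)}")


def _as_seq_list(source: Sequence[str] | str) -> list[str]:
    return [source] if isinstance(source, str) else list(source)


def build_model(
    genome_seqs: Sequence[tuple[str, Sequence[str] | str]],
    n: int = 21,
    orientation: str = ng.ORIENTATION_CANONICAL,
    display_names: dict[str, str] | None = None,
) -> tuple[SignatureModel, BuildReport]:
    """Build a signature model from in-memory genomes.

    ``genome_seqs`` is a list of (genome_id, sequence-or-sequences).  Fewer
    than 50 genomes triggers a warning (discriminatory power of the common
    n-gram weights degrades for small genome sets) but never an error.
    """
    _check_genome_inputs(genome_seqs)
    if orientation not in ng.ORIENTATIONS:
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    warnings: list[str] = []
    if len(genome_seqs) < MIN_RECOMMENDED_GENOMES:
        msg = (
            f"model built from only {len(genome_seqs)} genomes; "
            f"at least {MIN_RECOMMENDED_GENOMES} are recommended for stable weights"
        )
        warnings.append(msg)
        logger.warning(msg)

    records: list[GenomeRecord] = []
    all_keys: list[np.ndarray] = []
    all_ords: list[np.ndarray] = []
    for ordinal, (gid, source) in enumerate(genome_seqs):
        seqs = _as_seq_list(source)
        if not seqs or all(len(s) == 0 for s in seqs):
            raise FastaError(f"genome {gid!r} has no sequence data")
        distinct = _genome_distinct(seqs, n, orientation)
        name = (display_names or {}).get(gid, "")
        records.append(
            GenomeRecord(gid, name, total_length=sum(len(s) for s in seqs), n_t=int(distinct.size))
        )
        all_keys.append(distinct)
        all_ords.append(np.full(distinct.size, ordinal, dtype=np.uint32))

    keys_cat = np.concatenate(all_keys) if all_keys else np.empty(0, dtype=np.uint64)
    ords_cat = np.concatenate(all_ords) if all_ords else np.empty(0, dtype=np.uint32)
    order = np.lexsort((ords_cat, keys_cat))
    keys_cat = keys_cat[order]
    ords_cat = ords_cat[order]
    if keys_cat.size:
        new_group = np.concatenate(([True], keys_cat[1:] != keys_cat[:-1]))
        group_start = np.nonzero(new_group)[0]
        keys = keys_cat[group_start]
        counts = np.diff(np.concatenate((group_start, [keys_cat.size]))).astype(np.uint32)
    else:
        keys = keys_cat
        counts = np.empty(0, dtype=np.uint32)
    offsets = np.concatenate(([0], np.cumsum(counts, dtype=np.int64)))

    unique_mask = counts == 1
    uniq_per_genome = np.bincount(
        ords_cat[offsets[:-1][unique_mask]], minlength=len(records)
    ) if keys.size else np.zeros(len(records), dtype=np.int64)
    for rec, u in zip(records, uniq_per_genome):
        rec.unique_count = int(u)

    model = SignatureModel(n, orientation, records, keys, counts, offsets, ords_cat)
    report = BuildReport(
        total_distinct=int(keys.size),
        unique=int(unique_mask.sum()),
        common=int(keys.size - unique_mask.sum()),
        warnings=warnings,
    )
    return model, report


def build_from_fastas(
    entries: Sequence[tuple[str, str | Path]],
    n: int = 21,
    orientation: str = ng.ORIENTATION_CANONICAL,
    plasmid_filter: bool = False,
) -> tuple[SignatureModel, BuildReport]:
    """Build a model from (genome_id, FASTA path) pairs (one file per genome)."""
    genome_seqs = []
    display = {}
    for gid, path in entries:
        records = read_fasta(path)
        if plasmid_filter:
            records = filter_plasmids(records)
        if not records:
            raise FastaError(f"genome {gid!r}: no records left in {path} after plasmid filter")
        display[gid] = records[0][1]
        genome_seqs.append((gid, [seq for _rid, _desc, seq in records]))
    return build_model(genome_seqs, n=n, orientation=orientation, display_names=display)


def ngram_size_survey(
    genome_seqs: Sequence[tuple[str, Sequence[str] | str]],
    n_values: Sequence[int],
    orientation: str = ng.ORIENTATION_CANONICAL,
) -> list[SurveyRow]:
    """Unique/common partition of the genome set for each candidate gram size.

    Used to pick the working n: unique n-grams saturate with growing n while
    index size keeps increasing, so the knee of this table (n = 21 for the
    human-microbiome genome sets this method was designed around) is the
    natural choice.
    """
    if not n_values:
        raise InvalidParameterError("n_values must be non-empty")
    _check_genome_inputs(genome_seqs)
    rows = []
    for n in n_values:
        parts = []
        for _gid, source in genome_seqs:
            parts.append(_genome_distinct(_as_seq_list(source), n, orientation))
        cat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
        if cat.size:
            _keys, counts = np.unique(cat, return_counts=True)
            unique = int((counts == 1).sum())
            total = int(_keys.size)
        else:
            unique, total = 0, 0
        rows.append(SurveyRow(n=int(n), total_distinct=total, unique=unique, common=total - unique))
    return rows


def survey_to_tsv(rows: Sequence[SurveyRow], handle) -> None:
    handle.write("n\ttotal_distinct\tunique\tcommon\n")
    for r in rows:
        handle.write(f"{r.n}\t{r.total_distinct}\t{r.unique}\t{r.common}\n")
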