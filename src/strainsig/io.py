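"""FASTA/FASTQ input, manifest parsing, and atomic output helpers.

FASTA parsing goes through Bio.SeqIO and FASTQ through Biopython's fast
FastqGeneralIterator; both transparently accept ``.gz`` sources.
"""

from __future__ import annotations

import contextlib
import gzip
import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastaError, FastqParseError


def open_text(path: str | Path, mode: str = "rt"):
    """Open plain or gzip-compressed text by suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read all records of a FASTA file as (id, description, sequence) tuples."""
    path = Path(path)
    try:
        with open_text(path) as handle:
            records = [(r.id, r.description, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
    except OSError as exc:
        raise FastaError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise FastaError(f"FASTA {path} contains no records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, 80 columns."""
    with open_text(path, "wt") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (title, sequence) for every FASTQ record, with located errors."""
    path = Path(path)
    index = 0
    try:
        with open_text(path) as handle:
            for title, seq, _qual in FastqGeneralIterator(handle):
                yield title, seq
                index += 1
    except ValueError as exc:  # Biopython signals malformed records this way
        raise FastqParseError(
            f"malformed FASTQ record near index {index} in {path}: {exc}",
            path=str(path),
            record_index=index,
        ) from exc
    except OSError as exc:
        raise FastqParseError(f"cannot read FASTQ {path}: {exc}", path=str(path)) from exc


def iter_fastq_seq_chunks(
    paths: Iterable[str | Path], chunk_size: int = 50_000
) -> Iterator[list[str]]:
    """Yield lists of read sequences across several FASTQ files."""
    buf: list[str] = []
    for path in paths:
        for _title, seq in iter_fastq(path):
            buf.append(seq)
            if len(buf) >= chunk_size:
                yield buf
                buf = []
    if buf:
        yield buf


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Parse a genome manifest: one ``genome_id<TAB>fasta_path`` per line.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    entries: list[tuple[str, Path]] = []
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FastaError(f"{path}:{lineno}: expected 'genome_id<TAB>path', got {line!r}")
            gid, fasta = parts
            fasta_path = Path(fasta)
            if not fasta_path.is_absolute():
                fasta_path = path.parent / fasta_path
            entries.append((gid, fasta_path))
    return entries


@contextlib.contextmanager
def atomic_open(path: str | Path, mode: str = "wt"):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".", suffix=".tmp")
    os.close(fd)
    try:
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(tmp, mode) as handle:
            yield handle
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_json(obj, path: str | Path) -> None:
    with atomic_open(path) as out:
        json.dump(obj, out, indent=2, sort_keys=True)
        out.write("\n")
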