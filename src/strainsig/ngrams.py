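"""Fixed-length DNA n-gram extraction, 2-bit packing, and orientation handling.

An n-gram (k-mer) of length ``n`` is packed most-significant-base-first into an
unsigned 64-bit integer using the fixed code A=00, C=01, G=10, T=11, so any
``1 <= n <= 31`` fits in a single machine word.  Windows containing characters
outside {A, C, G, T} (N, IUPAC ambiguity codes, gaps) are skipped and counted,
never encoded.  Two orientation conventions are supported throughout the
package:

``as-is``
    windows are taken literally from the given strand;
``canonical``
    each window is replaced by the smaller of itself and its reverse
    complement under the unsigned-integer order, making matching
    strand-neutral.

Scalar helpers (:func:`encode`, :func:`decode`, ...) operate on
:class:`EncodedNgram` values and are convenient for tests and small inputs;
the bulk paths used by model building and read scoring work on raw ``uint64``
arrays via :func:`encode_windows` / :func:`canonical_values`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidAlphabetError, InvalidEncodingError, InvalidParameterError

MIN_N = 1
MAX_N = 31  # 2 bits/base in a uint64, with 2 spare bits

BASES = "ACGT"

ORIENTATION_AS_IS = "as-is"
ORIENTATION_CANONICAL = "canonical"
ORIENTATIONS = (ORIENTATION_AS_IS, ORIENTATION_CANONICAL)

# byte -> 2-bit code; 254 marks an invalid character, 255 is reserved as a
# record separator for concatenated multi-read encoding.
_CODE = np.full(256, 254, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i
_SEP = np.uint8(255)

_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

# bit-twiddling masks for reversing the 32 2-bit groups of a uint64
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


def _check_n(n: int) -> int:
    if not (MIN_N <= int(n) <= MAX_N):
        raise InvalidParameterError(f"gram length n must be in [{MIN_N}, {MAX_N}], got {n}")
    return int(n)


@dataclass(frozen=True, order=True)
class EncodedNgram:
    """A 2-bit packed n-gram: ``value`` occupies exactly ``2*n`` bits."""

    value: int
    n: int

    def __post_init__(self):
        _check_n(self.n)
        if not (0 <= self.value < 4 ** self.n):
            raise InvalidEncodingError(
                f"value {self.value} not representable with n={self.n} (needs < {4 ** self.n})"
            )

    def __str__(self) -> str:
        return decode(self)


def encode(window: str) -> EncodedNgram:
    """Pack a base string of length n into an :class:`EncodedNgram`.

    Raises :class:`InvalidAlphabetError` on any character outside ACGT
    (case-insensitive) and :class:`InvalidParameterError` when the length is
    outside [1, 31].
    """
    n = _check_n(len(window))
    value = 0
    for ch in window.upper():
        code = "ACGT".find(ch)
        if code < 0:
            raise InvalidAlphabetError(f"non-ACGT character {ch!r} in window {window!r}")
        value = (value << 2) | code
    return EncodedNgram(value, n)


def decode(g: EncodedNgram | int, n: int | None = None) -> str:
    """Exact inverse of :func:`encode`."""
    if isinstance(g, EncodedNgram):
        value, n = g.value, g.n
    else:
        if n is None:
            raise InvalidParameterError("decode of a bare integer requires n")
        value = int(g)
        _check_n(n)
        if not (0 <= value < 4 ** n):
            raise InvalidEncodingError(f"value {value} not representable with n={n}")
    out = []
    for shift in range(2 * (n - 1), -2, -2):
        out.append(BASES[(value >> shift) & 3])
    return "".join(out)


def revcomp_values(values: np.ndarray, n: int) -> np.ndarray:
    """Vectorised reverse complement of packed n-grams (uint64 array)."""
    v = np.asarray(values, dtype=np.uint64)
    v = v ^ _FULL  # A<->T, C<->G: bitwise complement of every 2-bit code
    v = ((v >> np.uint64(2)) & _M2) | ((v & _M2) << np.uint64(2))
    v = ((v >> np.uint64(4)) & _M4) | ((v & _M4) << np.uint64(4))
    v = v.byteswap()  # reverses the 8 bytes; with the swaps above, all 32 groups
    return v >> np.uint64(64 - 2 * n)


def reverse_complement(g: EncodedNgram) -> EncodedNgram:
    """Reverse complement with base-level semantics identical to strings."""
    out = revcomp_values(np.array([g.value], dtype=np.uint64), g.n)
    return EncodedNgram(int(out[0]), g.n)


def canonical_values(values: np.ndarray, n: int) -> np.ndarray:
    """min(g, revcomp(g)) element-wise under unsigned-integer order."""
    v = np.asarray(values, dtype=np.uint64)
    return np.minimum(v, revcomp_values(v, n))


def canonical(g: EncodedNgram) -> EncodedNgram:
    rc = reverse_complement(g)
    return g if g.value <= rc.value else rc


def sequence_codes(sequence: str | bytes) -> np.ndarray:
    """Map a sequence to per-base 2-bit codes; invalid characters become 254."""
    if isinstance(sequence, str):
        sequence = sequence.encode("latin-1")
    return _CODE[np.frombuffer(sequence, dtype=np.uint8)]


def codes_to_string(codes: np.ndarray) -> str:
    return _TO_BASE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the 2-bit code level; invalid codes stay invalid."""
    c = codes[::-1]
    return np.where(c <= 3, 3 - c, c).astype(np.uint8)


def encode_windows(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-n window of a code array.

    Returns ``(values, valid)`` where ``values`` holds one uint64 per window
    (undefined where invalid) and ``valid`` flags windows free of non-ACGT
    codes.  Windows overlapping separator bytes are invalid by construction.
    """
    _check_n(n)
    codes = np.asarray(codes, dtype=np.uint8)
    w = codes.size - n + 1
    if w <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = codes > 3
    cs = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
    valid = (cs[n:] - cs[:w]) == 0
    c = np.where(bad, 0, codes).astype(np.uint64)
    values = np.zeros(w, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(n):
        values = (values << two) | c[j : j + w]
    return values, valid


@dataclass
class NgramExtraction:
    """The n-grams of one sequence plus window accounting.

    ``windows_total`` is ``max(0, x - n + 1)`` for a length-x sequence and
    ``windows_skipped`` counts windows voided by non-ACGT characters, so for a
    non-distinct extraction ``len(ngrams) + windows_skipped == windows_total``.
    """

    source_id: str | None
    n: int
    ngrams: np.ndarray = field(repr=False)
    windows_total: int = 0
    windows_skipped: int = 0
    distinct: bool = False
    orientation: str = ORIENTATION_AS_IS


def extract_ngrams(
    sequence: str,
    n: int,
    *,
    distinct: bool = False,
    orientation: str = ORIENTATION_AS_IS,
    source_id: str | None = None,
) -> NgramExtraction:
    """Emit all length-n windows of ``sequence`` as packed integers.

    A sequence shorter than n yields an empty extraction (windows_total 0).
    With ``distinct`` the result is the sorted deduplicated set; otherwise
    windows appear in sequence order.
    """
    _check_n(n)
    if orientation not in ORIENTATIONS:
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    codes = sequence_codes(sequence)
    windows_total = max(0, codes.size - n + 1)
    values, valid = encode_windows(codes, n)
    ngrams = values[valid]
    skipped = windows_total - ngrams.size
    if orientation == ORIENTATION_CANONICAL:
        ngrams = canonical_values(ngrams, n)
    if distinct:
        ngrams = np.unique(ngrams)
    return NgramExtraction(
        source_id=source_id,
        n=n,
        ngrams=ngrams,
        windows_total=windows_total,
        windows_skipped=skipped,
        distinct=distinct,
        orientation=orientation,
    )


def encode_concatenated(
    seqs: list[str], n: int, orientation: str = ORIENTATION_AS_IS, revcomp: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Bulk-encode many sequences in one pass.

    Sequences are joined with a separator byte so windows never straddle two
    reads.  Returns ``(values, read_index)`` for all valid windows, where
    ``read_index`` maps each window back to its sequence.  With ``revcomp``
    each sequence is reverse-complemented before extraction (used for mate-2
    reads in ``forward`` model orientation).
    """
    if not seqs:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    big = "\x00".join(seqs)
    codes = _CODE[np.frombuffer(big.encode("latin-1"), dtype=np.uint8)].copy()
    # the NUL separator maps through _CODE to "invalid"; mark it distinctly
    lengths = np.fromiter((len(s) for s in seqs), count=len(seqs), dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(lengths + 1)))[:-1]
    if revcomp:
        parts = []
        for s, ln in zip(starts, lengths):
            parts.append(revcomp_codes(codes[s : s + ln]))
            parts.append(np.array([254], dtype=np.uint8))
        codes = np.concatenate(parts)[:-1]
    values, valid = encode_windows(codes, n)
    pos = np.nonzero(valid)[0]
    values = values[pos]
    read_index = np.searchsorted(starts, pos, side="right") - 1
    if orientation == ORIENTATION_CANONICAL:
        values = canonical_values(values, n)
    return values, read_index
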