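"""Independent brute-force string-level oracles used across the test suite.

Everything here works on plain Python strings, sets, and dicts — no shared
code with the packed-integer implementation under test.
"""

from __future__ import annotations

import math

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp_str(s: str) -> str:
    return s.translate(_COMP)[::-1]


def canonical_str(s: str) -> str:
    rc = revcomp_str(s)
    return s if s <= rc else rc


def windows(seq: str, n: int) -> list[str]:
    """All length-n windows, valid (pure-ACGT) or not, uppercased."""
    seq = seq.upper()
    return [seq[i : i + n] for i in range(max(0, len(seq) - n + 1))]


def valid_windows(seq: str, n: int, canonical: bool = False) -> list[str]:
    out = [w for w in windows(seq, n) if set(w) <= set("ACGT")]
    if canonical:
        out = [canonical_str(w) for w in out]
    return out


def ngram_set(seqs, n: int, canonical: bool = False) -> set[str]:
    """Distinct n-gram strings of one genome (one or more sequences)."""
    if isinstance(seqs, str):
        seqs = [seqs]
    out: set[str] = set()
    for s in seqs:
        out.update(valid_windows(s, n, canonical))
    return out


def posting_map(genomes, n: int, canonical: bool = False) -> dict[str, list[str]]:
    """n-gram string -> sorted list of genome ids containing it."""
    post: dict[str, list[str]] = {}
    for gid, seqs in genomes:
        for w in ngram_set(seqs, n, canonical):
            post.setdefault(w, []).append(gid)
    return {w: sorted(g) for w, g in post.items()}


def weight(m: int, c: int) -> float:
    return (math.log(c / m) / math.log(c)) ** 2


def matrix_w_scores(sample_ngrams: set[str], genomes, n: int, canonical: bool = False):
    """Explicitly materialise the weight matrix W and take column sums.

    ``genomes``: list of (genome_id, sequences).  Returns per-genome dicts
    with S, n_c, n_t, nFactor, fS computed from the full matrix.
    """
    post = posting_map(genomes, n, canonical)
    c = len(genomes)
    gids = [gid for gid, _ in genomes]
    # rows: sample n-grams; columns: genomes; cells: weight if present else 0
    rows = sorted(sample_ngrams)
    matrix = [
        [weight(len(post[w]), c) if (w in post and gid in post[w]) else 0.0 for gid in gids]
        for w in rows
    ]
    out = {}
    for j, (gid, seqs) in enumerate(genomes):
        col = [matrix[i][j] for i in range(len(rows))]
        s = sum(col)
        # n_c counts matched sample n-grams present in this genome (weight may be 0)
        mine = ngram_set(seqs, n, canonical)
        n_c = sum(1 for w in rows if w in mine)
        n_t = len(mine)
        nf = n_c / n_t if n_t else 0.0
        out[gid] = {"S": s, "n_c": n_c, "n_t": n_t, "nFactor": nf, "fS": s * nf}
    return out


def rjg_scores(read_ngrams: set[str], genomes, n: int, canonical: bool = False) -> dict[str, float]:
    """All-pairs read-genome score: sum of shared n-gram weights per genome."""
    post = posting_map(genomes, n, canonical)
    c = len(genomes)
    out = {}
    for gid, seqs in genomes:
        mine = ngram_set(seqs, n, canonical)
        out[gid] = sum(weight(len(post[w]), c) for w in read_ngrams if w in mine)
    return out


def assign_read_oracle(read_ngrams: set[str], genomes, predicted: list[str], n: int,
                       canonical: bool = False):
    """Literal rule-cascade assignment over string sets.

    Returns (genome_id or None, rule, tie_broken).
    """
    post = posting_map(genomes, n, canonical)
    c = len(genomes)
    pred = sorted(predicted)
    by_id = dict((gid, seqs) for gid, seqs in genomes)
    mine = {gid: ngram_set(by_id[gid], n, canonical) for gid in pred}
    shared = {gid: {w for w in read_ngrams if w in mine[gid]} for gid in pred}
    if all(not s for s in shared.values()):
        return None, "unassigned", False
    uniq = {gid: sum(1 for w in shared[gid] if len(post[w]) == 1) for gid in pred}
    umax = max(uniq.values())
    cands = [g for g in pred if uniq[g] == umax] if umax > 0 else pred
    rule = "unique" if (umax > 0 and len(cands) == 1) else "common-argmax"
    if len(cands) > 1 or umax == 0:
        r = {g: sum(weight(len(post[w]), c) for w in shared[g]) for g in cands}
        rmax = max(r.values())
        cands = [g for g in cands if r[g] == rmax]
    tie = len(cands) > 1
    return cands[0], rule, tie
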