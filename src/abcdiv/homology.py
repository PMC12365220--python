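"""Exact-repeat diagnostics between sequence pairs.

Recombination during AAV production is driven by long *identical* stretches
shared between the donor and acceptor coding sequences, so the diagnostics
here are deliberately exact-match based: the longest identical stretch
(LCS), the histogram of maximal exact match (MEM) lengths, and k-mer dot
plots.  Coordinates are 0-based half-open internally; the TSV exports are
1-based as is customary in human-facing reports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

from .codon_core import reverse_complement

__all__ = [
    "MatchSegment",
    "HomologyReport",
    "longest_common_substring",
    "maximal_exact_matches",
    "dotplot",
    "homology_report",
    "write_dotplot_tsv",
    "write_histogram_tsv",
]


@dataclass(frozen=True, order=True)
class MatchSegment:
    """An identical segment: ``a[pos_a:pos_a+length] == b[pos_b:pos_b+length]``.

    ``strand`` is ``'-'`` when the match is against the reverse complement of
    ``b``; ``pos_b`` is then an offset into the reverse-complemented string.
    """

    pos_a: int
    pos_b: int
    length: int
    strand: str = "+"


# ---------------------------------------------------------------------------
# longest common substring via a suffix automaton over `a`

class _SuffixAutomaton:
    __slots__ = ("link", "length", "next", "last")

    def __init__(self, s: str) -> None:
        self.link = [-1]
        self.length = [0]
        self.next: list[dict[str, int]] = [{}]
        self.last = 0
        for ch in s:
            self._extend(ch)

    def _extend(self, ch: str) -> None:
        cur = len(self.length)
        self.length.append(self.length[self.last] + 1)
        self.link.append(-1)
        self.next.append({})
        p = self.last
        while p != -1 and ch not in self.next[p]:
            self.next[p][ch] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
        else:
            q = self.next[p][ch]
            if self.length[p] + 1 == self.length[q]:
                self.link[cur] = q
            else:
                clone = len(self.length)
                self.length.append(self.length[p] + 1)
                self.link.append(self.link[q])
                self.next.append(dict(self.next[q]))
                while p != -1 and self.next[p].get(ch) == q:
                    self.next[p][ch] = clone
                    p = self.link[p]
                self.link[q] = clone
                self.link[cur] = clone
        self.last = cur


def longest_common_substring(a: str, b: str) -> MatchSegment:
    """One witnessing occurrence of a longest shared substring of ``a``, ``b``.

    Returns a zero-length sentinel at (0, 0) when the sequences share no
    character.  Runs in O(|a| + |b|) via a suffix automaton built over ``a``.
    """
    if not a or not b:
        raise ValueError("longest_common_substring requires non-empty sequences")
    sam = _SuffixAutomaton(a)
    # end position of each state's longest string within `a`
    endpos = [0] * len(sam.length)
    v, l = 0, 0
    for i, ch in enumerate(a):
        v = sam.next[v][ch]
        endpos[v] = i + 1
    order = sorted(range(len(sam.length)), key=sam.length.__getitem__, reverse=True)
    for u in order:
        if sam.link[u] >= 0 and not endpos[sam.link[u]]:
            endpos[sam.link[u]] = endpos[u]

    best_len = 0
    best = MatchSegment(0, 0, 0)
    v, l = 0, 0
    for j, ch in enumerate(b):
        while v and ch not in sam.next[v]:
            v = sam.link[v]
            l = sam.length[v]
        if ch in sam.next[v]:
            v = sam.next[v][ch]
            l += 1
        if l > best_len:
            best_len = l
            best = MatchSegment(endpos[v] - l, j + 1 - l, l)
    return best


# ---------------------------------------------------------------------------
# maximal exact matches via diagonal run scanning

_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _diagonal_runs(xa: np.ndarray, xb: np.ndarray, min_len: int):
    """Yield (pos_a, pos_b, length) for every maximal diagonal run >= min_len."""
    n, m = len(xa), len(xb)
    for d in range(-(m - 1), n):
        if d >= 0:
            sa, sb = d, 0
        else:
            sa, sb = 0, -d
        span = min(n - sa, m - sb)
        if span < min_len:
            continue
        eq = xa[sa : sa + span] == xb[sb : sb + span]
        if not eq.any():
            continue
        boundaries = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for k in range(0, len(boundaries), 2):
            start, end = int(boundaries[k]), int(boundaries[k + 1])
            if end - start >= min_len:
                yield (sa + start, sb + start, end - start)


def maximal_exact_matches(a: str, b: str, min_len: int = 1) -> list[MatchSegment]:
    """All maximal exact matches (extendable in neither direction) >= min_len."""
    if not a or not b:
        raise ValueError("maximal_exact_matches requires non-empty sequences")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    xa, xb = encode(a), encode(b)
    return [MatchSegment(pa, pb, l) for pa, pb, l in _diagonal_runs(xa, xb, min_len)]


def dotplot(a: str, b: str, k: int, strand_mode: str = "forward_only") -> list[MatchSegment]:
    """Every position pair (i, j) with ``a[i:i+k] == b[j:j+k]``.

    In ``both`` mode the reverse complement of ``b`` is scanned as well and
    hits are flagged with strand ``'-'`` (``pos_b`` in reverse-complement
    coordinates).
    """
    if not a or not b:
        raise ValueError("dotplot requires non-empty sequences")
    if not 1 <= k <= min(len(a), len(b)):
        raise ValueError(f"k={k} out of range for lengths {len(a)}, {len(b)}")
    if strand_mode not in ("forward_only", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")

    hits: list[MatchSegment] = []
    for strand, bseq in (("+", b), ("-", reverse_complement(b))):
        if strand == "-" and strand_mode == "forward_only":
            continue
        index: dict[str, list[int]] = {}
        for j in range(len(bseq) - k + 1):
            index.setdefault(bseq[j : j + k], []).append(j)
        for i in range(len(a) - k + 1):
            for j in index.get(a[i : i + k], ()):
                hits.append(MatchSegment(i, j, k, strand))
    hits.sort(key=lambda h: (h.strand, h.pos_a, h.pos_b))
    return hits


@dataclass(frozen=True)
class HomologyReport:
    """LCS, MEM length histogram and dot plot for one sequence pair."""

    lcs: MatchSegment
    mem_histogram: dict[int, int]
    dotplot: list[MatchSegment] = field(default_factory=list)
    strand_mode: str = "forward_only"


def homology_report(
    a: str,
    b: str,
    *,
    min_len: int = 1,
    k: int = 12,
    strand_mode: str = "forward_only",
) -> HomologyReport:
    mems = maximal_exact_matches(a, b, min_len)
    hist = dict(sorted(Counter(m.length for m in mems).items()))
    dots = dotplot(a, b, k, strand_mode) if k <= min(len(a), len(b)) else []
    return HomologyReport(
        lcs=longest_common_substring(a, b),
        mem_histogram=hist,
        dotplot=dots,
        strand_mode=strand_mode,
    )


def write_dotplot_tsv(hits: Iterable[MatchSegment], stream: IO[str]) -> None:
    stream.write("pos_a_1based\tpos_b_1based\tstrand\n")
    for h in hits:
        stream.write(f"{h.pos_a + 1}\t{h.pos_b + 1}\t{h.strand}\n")


def write_histogram_tsv(histogram: dict[int, int], stream: IO[str]) -> None:
    stream.write("length_bp\tcount\n")
    for length in sorted(histogram):
        stream.write(f"{length}\t{histogram[length]}\n")
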