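"""The ABCD search: synonymous codon choice minimizing the objective *f*.

Given a protein (or a CDS defining one), a fixed reference DNA context, an
abundance-filtered codon map and a set of forbidden motifs, the diversifier
returns a new CDS for the same protein that is maximally diverse — at the
nucleotide level — from both the reference context and itself.

Search strategy
---------------
The objective *f* is dominated by the longest shared exact runs, so the
search minimizes an exact surrogate that is cheap to maintain incrementally:
a weighted count of shared q-gram pairs (q = 6, 8, 10, 12, 14, weight rising
tenfold per 2 bp), over the full construct ``context || candidate``.  A run
of length L shared with the context or internally contributes through every
q <= L it contains, so the surrogate is monotone-aligned with log10 f.

1. greedy left-to-right construction (per codon slot, the allowed codon with
   the smallest surrogate increment; bounded backtracking when forbidden
   motifs block every codon),
2. simulated-annealing refinement by random synonymous swaps under geometric
   cooling,
3. a repair pass that re-breaks any remaining shared run longer than
   ``m_min + 2`` by the best synonymous substitution inside it.

The reported scores are always full :func:`abcdiv.energy.objective_f`
recomputations; the surrogate never leaks into results.  All randomness flows
from the single task seed, and equal-score codons are resolved by higher
family fraction then alphabetically, so runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .codon_core import (
    AllowedCodonMap,
    CodingSequence,
    ProteinSequence,
    reverse_complement,
    translate,
)
from .energy import (
    EnergyParams,
    FScore,
    _LN10,
    _logsumexp10,
    _stack_prefix,
    blocks_at_offset,
    duplex_blocks,
    objective_f,
    shared_runs,
)
from .homology import longest_common_substring

__all__ = [
    "MotifSet",
    "DiversificationTask",
    "DiversificationResult",
    "ChainResult",
    "InfeasibleMotifError",
    "motif_scan",
    "diversify",
    "diversify_chain",
    "DEFAULT_BUDGET",
]

DEFAULT_BUDGET = 2000

_QGRAM_QS = (6, 8, 10, 12, 14)
_QGRAM_WEIGHTS = {6: 1e2, 8: 1e3, 10: 1e4, 12: 1e5, 14: 1e6}


class InfeasibleMotifError(ValueError):
    """Raised when no motif-free codon assignment was found within budget."""

    def __init__(self, motif: str, window: str):
        self.motif = motif
        self.window = window
        super().__init__(
            f"forbidden motif {motif!r} is unavoidable around ...{window}..."
        )


@dataclass(frozen=True)
class MotifSet:
    """Named DNA motifs that must not occur in a designed sequence."""

    motifs: dict[str, str]
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        for name, m in self.motifs.items():
            if not m or set(m) - set("ACGT"):
                raise ValueError(f"motif {name!r} must be non-empty ACGT: {m!r}")

    @property
    def max_len(self) -> int:
        return max((len(m) for m in self.motifs.values()), default=0)

    def patterns(self) -> list[tuple[str, str, str]]:
        """(name, pattern, strand) pairs to scan on the forward sequence."""
        out = []
        for name, m in sorted(self.motifs.items()):
            out.append((name, m, "+"))
            if self.scan_both_strands:
                out.append((name, reverse_complement(m), "-"))
        return out

    @classmethod
    def empty(cls) -> "MotifSet":
        return cls(motifs={}, scan_both_strands=True)


def motif_scan(seq: str, motifs: MotifSet) -> list[tuple[str, int, str]]:
    """Every occurrence of every motif; reverse-strand hits are positions of
    the motif's reverse complement on the forward sequence."""
    hits: list[tuple[str, int, str]] = []
    for name, pattern, strand in motifs.patterns():
        start = seq.find(pattern)
        while start != -1:
            hits.append((name, start, strand))
            start = seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h[1], h[0], h[2]))
    return hits


@dataclass(frozen=True)
class DiversificationTask:
    target: ProteinSequence | CodingSequence
    reference_context: str = ""
    allowed: AllowedCodonMap = None  # type: ignore[assignment]
    forbidden: MotifSet = field(default_factory=MotifSet.empty)
    seed: int = 0
    budget: int = DEFAULT_BUDGET
    params: EnergyParams = field(default_factory=EnergyParams)

    def __post_init__(self) -> None:
        if self.allowed is None:
            raise ValueError("an AllowedCodonMap is required")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")

    @property
    def protein(self) -> ProteinSequence:
        if isinstance(self.target, CodingSequence):
            return translate(self.target)
        return self.target

    @property
    def stop_codon(self) -> str | None:
        """The terminal stop to copy verbatim to the output, if any."""
        if isinstance(self.target, CodingSequence):
            prot = translate(self.target)
            return self.target.codons[-1] if prot.has_stop else None
        return "TGA" if self.target.has_stop else None


@dataclass(frozen=True)
class DiversificationResult:
    output: CodingSequence
    fscore_vs_reference: FScore
    fscore_internal: FScore
    max_identical_bp: int
    codon_counts: dict[str, int]
    seed: int
    iterations_used: int
    bias: float

    def to_json_dict(self) -> dict:
        return {
            "name": self.output.name,
            "seed": self.seed,
            "bias": self.bias,
            "iterations_used": self.iterations_used,
            "max_identical_bp": self.max_identical_bp,
            "fscore_vs_reference": self.fscore_vs_reference.to_json_dict(),
            "fscore_internal": self.fscore_internal.to_json_dict(),
            "codon_counts": dict(sorted(self.codon_counts.items())),
        }


# ---------------------------------------------------------------------------
# incremental surrogate

class _RepeatSurrogate:
    """Exact weighted shared-q-gram pair count over a mutable char buffer.

    score = sum over q of w_q * (# unordered pairs of equal q-grams).
    Incremental updates are exact; `recompute` rebuilds from scratch and is
    used to assert that in tests.
    """

    def __init__(self, context: str):
        self.chars: list[str] = list(context)
        self.counts: dict[int, defaultdict[str, int]] = {
            q: defaultdict(int) for q in _QGRAM_QS
        }
        self.score = 0.0
        n = len(self.chars)
        s = context
        for q in _QGRAM_QS:
            w = _QGRAM_WEIGHTS[q]
            cnt = self.counts[q]
            for i in range(n - q + 1):
                g = s[i : i + q]
                self.score += w * cnt[g]
                cnt[g] += 1

    def _add(self, q: int, gram: str) -> None:
        c = self.counts[q][gram]
        self.score += _QGRAM_WEIGHTS[q] * c
        self.counts[q][gram] = c + 1

    def _remove(self, q: int, gram: str) -> None:
        c = self.counts[q][gram] - 1
        self.counts[q][gram] = c
        self.score -= _QGRAM_WEIGHTS[q] * c

    def append(self, s: str) -> None:
        for ch in s:
            self.chars.append(ch)
            n = len(self.chars)
            for q in _QGRAM_QS:
                if n >= q:
                    self._add(q, "".join(self.chars[n - q : n]))

    def pop(self, k: int) -> None:
        for _ in range(k):
            n = len(self.chars)
            for q in _QGRAM_QS:
                if n >= q:
                    self._remove(q, "".join(self.chars[n - q : n]))
            self.chars.pop()

    def replace(self, pos: int, s: str) -> None:
        n = len(self.chars)
        spans = {
            q: range(max(0, pos - q + 1), min(n - q, pos + len(s) - 1) + 1)
            for q in _QGRAM_QS
        }
        for q, span in spans.items():
            for i in span:
                self._remove(q, "".join(self.chars[i : i + q]))
        self.chars[pos : pos + len(s)] = list(s)
        for q, span in spans.items():
            for i in span:
                self._add(q, "".join(self.chars[i : i + q]))

    @classmethod
    def recompute_score(cls, full: str) -> float:
        return cls(full).score


def _motif_conflict(
    chars: list[str], lo: int, hi: int, motifs: MotifSet
) -> str | None:
    """Name of a forbidden motif whose occurrence overlaps [lo, hi), else None.

    Occurrences entirely outside the edited span (e.g. pre-existing sites in
    the fixed reference context) are not this edit's fault and are ignored.
    """
    if not motifs.motifs:
        return None
    pad = motifs.max_len - 1
    w_lo = max(0, lo - pad)
    w_hi = min(len(chars), hi + pad)
    window = "".join(chars[w_lo:w_hi])
    rel_lo, rel_hi = lo - w_lo, hi - w_lo
    for name, pattern, _strand in motifs.patterns():
        s = window.find(pattern)
        while s != -1:
            if s < rel_hi and s + len(pattern) > rel_lo:
                return name
            s = window.find(pattern, s + 1)
    return None


# ---------------------------------------------------------------------------
# search phases

def _greedy_build(
    surrogate: _RepeatSurrogate,
    protein: ProteinSequence,
    allowed: AllowedCodonMap,
    motifs: MotifSet,
) -> list[str]:
    ctx_len = len(surrogate.chars)
    n = len(protein)
    chosen: list[str] = []
    rankings: list[list[str]] = []
    indices: list[int] = []
    t = 0
    backtracks = 0
    max_backtracks = max(200, 4 * n)
    last_conflict = "?"
    while t < n:
        if t == len(rankings):
            scored = []
            for codon in allowed[protein.seq[t]]:
                before = surrogate.score
                surrogate.append(codon)
                delta = surrogate.score - before
                surrogate.pop(3)
                scored.append((delta, -allowed.fraction(codon), codon))
            scored.sort()
            rankings.append([c for _, _, c in scored])
            indices.append(0)
        placed = False
        while indices[t] < len(rankings[t]):
            codon = rankings[t][indices[t]]
            surrogate.append(codon)
            pos = ctx_len + 3 * t
            conflict = _motif_conflict(surrogate.chars, pos, pos + 3, motifs)
            if conflict is None:
                chosen.append(codon)
                placed = True
                break
            last_conflict = conflict
            surrogate.pop(3)
            indices[t] += 1
        if placed:
            t += 1
            continue
        # dead end: unwind one slot and advance its candidate
        rankings.pop()
        indices.pop()
        if t == 0 or backtracks >= max_backtracks:
            window = "".join(surrogate.chars[-(motifs.max_len + 6) :])
            raise InfeasibleMotifError(last_conflict, window)
        backtracks += 1
        t -= 1
        surrogate.pop(3)
        chosen.pop()
        indices[t] += 1
    return chosen


def _anneal(
    surrogate: _RepeatSurrogate,
    codons: list[str],
    protein: ProteinSequence,
    allowed: AllowedCodonMap,
    motifs: MotifSet,
    ctx_len: int,
    budget: int,
    rng: np.random.Generator,
) -> int:
    swappable = [t for t in range(len(codons)) if len(allowed[protein.seq[t]]) > 1]
    if not swappable or budget <= 0:
        return 0
    t0, t_end = 3.0 * _QGRAM_WEIGHTS[6], 0.1 * _QGRAM_WEIGHTS[6]
    cool = (t_end / t0) ** (1.0 / budget)
    temp = t0
    moves = 0
    for _ in range(budget):
        temp *= cool
        slot = swappable[int(rng.integers(len(swappable)))]
        choices = allowed[protein.seq[slot]]
        new = choices[int(rng.integers(len(choices)))]
        if new == codons[slot]:
            continue
        pos = ctx_len + 3 * slot
        before = surrogate.score
        old = codons[slot]
        surrogate.replace(pos, new)
        if _motif_conflict(surrogate.chars, pos, pos + 3, motifs) is not None:
            surrogate.replace(pos, old)
            continue
        delta = surrogate.score - before
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            codons[slot] = new
            moves += 1
        else:
            surrogate.replace(pos, old)
    return moves


def _repair(
    surrogate: _RepeatSurrogate,
    codons: list[str],
    protein: ProteinSequence,
    allowed: AllowedCodonMap,
    motifs: MotifSet,
    ctx_len: int,
    m_min: int,
    max_sweeps: int = 6,
) -> int:
    """Break residual shared runs longer than m_min + 2 by the synonymous
    substitution that most reduces the surrogate."""
    break_len = m_min + 2
    out_start, out_end = ctx_len, ctx_len + 3 * len(codons)
    edits = 0
    for _ in range(max_sweeps):
        runs = shared_runs("".join(surrogate.chars), break_len, seq_start=ctx_len)
        runs.sort(key=lambda r: (-r[2], r[0], r[1]))
        if not runs:
            break
        improved = False
        for p, q, l in runs:
            slots: set[int] = set()
            for a, b in ((p, p + l), (q, q + l)):
                lo = max(a, out_start)
                hi = min(b, out_end)
                if lo < hi:
                    slots.update(range((lo - ctx_len) // 3, (hi - 1 - ctx_len) // 3 + 1))
            best: tuple[float, float, str, int] | None = None
            base = surrogate.score
            for slot in sorted(slots):
                for codon in allowed[protein.seq[slot]]:
                    if codon == codons[slot]:
                        continue
                    pos = ctx_len + 3 * slot
                    old = codons[slot]
                    surrogate.replace(pos, codon)
                    ok = _motif_conflict(surrogate.chars, pos, pos + 3, motifs) is None
                    delta = surrogate.score - base
                    surrogate.replace(pos, old)
                    if ok and delta < 0:
                        cand = (delta, -allowed.fraction(codon), codon, slot)
                        if best is None or cand < best:
                            best = cand
            if best is not None:
                _, _, codon, slot = best
                surrogate.replace(ctx_len + 3 * slot, codon)
                codons[slot] = codon
                edits += 1
                improved = True
        if not improved:
            break
    return edits


def _construct_log10_f(construct: str, ctx_len: int, params: EnergyParams) -> float:
    blocks = duplex_blocks(construct, ctx_len, params)
    if not blocks:
        return -math.inf
    terms = np.fromiter((b.energy for b in blocks), dtype=np.float64)
    return _logsumexp10(-terms / (params.rt * _LN10))


def _polish(
    surrogate: _RepeatSurrogate,
    codons: list[str],
    protein: ProteinSequence,
    allowed: AllowedCodonMap,
    motifs: MotifSet,
    ctx_len: int,
    params: EnergyParams,
    rounds: int,
) -> int:
    """Greedy coordinate descent on the true objective.

    The objective chains run energies into per-offset duplex blocks, so runs
    that merge into one block (e.g. bridged matches on the codon-aligned
    frame against the reference) are exponentially worse than the same runs
    spread out — a distinction the q-gram surrogate cannot see.  Each round
    targets the block with the largest Boltzmann term and applies the
    synonymous substitution inside its runs that lowers the full log10 f the
    most.
    """
    out_start, out_end = ctx_len, ctx_len + 3 * len(codons)
    edits = 0
    stale: set[tuple[int, ...]] = set()  # block signatures polish cannot improve
    for _ in range(rounds):
        construct = "".join(surrogate.chars)
        blocks = duplex_blocks(construct, ctx_len, params)
        if not blocks:
            break
        current = _construct_log10_f(construct, ctx_len, params)
        target = None
        for blk in sorted(blocks, key=lambda b: (b.energy, b.offset)):
            sig = (blk.offset, blk.runs[0][0], round(blk.energy, 6))
            if sig not in stale:
                target = (blk, sig)
                break
        if target is None:
            break
        worst, sig = target
        slots: set[int] = set()
        for s, l in worst.runs:
            for a, b in ((s, s + l), (s + worst.offset, s + worst.offset + l)):
                lo, hi = max(a, out_start), min(b, out_end)
                if lo < hi:
                    slots.update(
                        range((lo - ctx_len) // 3, (hi - 1 - ctx_len) // 3 + 1)
                    )
        # cheap local ranking: energy change at the target offset only, with
        # the q-gram surrogate guarding against damage on other offsets
        ranked: list[tuple[float, float, float, str, int]] = []
        for slot in sorted(slots):
            for codon in allowed[protein.seq[slot]]:
                if codon == codons[slot]:
                    continue
                pos = ctx_len + 3 * slot
                old = codons[slot]
                s_before = surrogate.score
                surrogate.replace(pos, codon)
                ok = _motif_conflict(surrogate.chars, pos, pos + 3, motifs) is None
                if ok:
                    trial_construct = "".join(surrogate.chars)
                    codes = np.frombuffer(trial_construct.encode(), dtype=np.uint8)
                    local = blocks_at_offset(
                        codes, _stack_prefix(trial_construct, params.nn_table),
                        worst.offset, ctx_len, params,
                    )
                    local_e = min((b.energy for b in local), default=0.0)
                    gram_delta = surrogate.score - s_before
                    ranked.append(
                        (local_e, gram_delta, -allowed.fraction(codon), codon, slot)
                    )
                surrogate.replace(pos, old)
        ranked.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
        improved = False
        for local_e, _gd, _fr, codon, slot in ranked[:5]:
            pos = ctx_len + 3 * slot
            old = codons[slot]
            surrogate.replace(pos, codon)
            trial = _construct_log10_f("".join(surrogate.chars), ctx_len, params)
            if trial < current - 1e-12:
                codons[slot] = codon
                edits += 1
                improved = True
                break
            surrogate.replace(pos, old)
        if not improved:
            stale.add(sig)
    return edits


# ---------------------------------------------------------------------------

def _validate(output: CodingSequence, task: DiversificationTask) -> None:
    prot = translate(output)
    want = task.protein
    if prot.seq != want.seq:
        raise AssertionError("diversified output does not encode the target protein")
    pad = max(task.forbidden.max_len - 1, 0)
    prefix = task.reference_context[-pad:] if pad and task.reference_context else ""
    joined = prefix + output.seq
    for name, pos, _strand in motif_scan(joined, task.forbidden):
        # ignore occurrences entirely inside the context prefix
        if pos + len(task.forbidden.motifs[name]) > len(prefix):
            raise InfeasibleMotifError(name, joined[max(0, pos - 3) : pos + 9])


def diversify(task: DiversificationTask) -> DiversificationResult:
    """Run the ABCD search for one target; deterministic given ``task.seed``."""
    protein = task.protein
    if len(protein) < 1:
        raise ValueError("empty protein")
    rng = np.random.default_rng(task.seed)

    surrogate = _RepeatSurrogate(task.reference_context)
    ctx_len = len(task.reference_context)
    codons = _greedy_build(surrogate, protein, task.allowed, task.forbidden)
    iterations = _anneal(
        surrogate, codons, protein, task.allowed, task.forbidden,
        ctx_len, task.budget, rng,
    )
    iterations += _repair(
        surrogate, codons, protein, task.allowed, task.forbidden,
        ctx_len, task.params.m_min,
    )
    iterations += _polish(
        surrogate, codons, protein, task.allowed, task.forbidden,
        ctx_len, task.params, rounds=max(8, task.budget // 32),
    )

    body = "".join(codons)
    stop = task.stop_codon
    name = getattr(task.target, "name", "") or "diversified"
    output = CodingSequence(body + (stop or ""), name=f"{name}|abcd")
    _validate(output, task)

    if len(output.seq) >= task.params.m_min:
        f_int = objective_f(output, None, task.params)
        f_ref = (
            objective_f(output, task.reference_context, task.params)
            if task.reference_context
            else f_int
        )
    else:
        f_int = f_ref = FScore(-math.inf, task.params.overflow_log10)
    max_ident = (
        longest_common_substring(output.seq, task.reference_context).length
        if task.reference_context
        else 0
    )
    return DiversificationResult(
        output=output,
        fscore_vs_reference=f_ref,
        fscore_internal=f_int,
        max_identical_bp=max_ident,
        codon_counts=dict(Counter(output.codons)),
        seed=task.seed,
        iterations_used=iterations,
        bias=task.allowed.bias,
    )


@dataclass(frozen=True)
class ChainResult:
    results: list[DiversificationResult]
    labels: list[str]
    max_identical_matrix: list[list[int]]


def diversify_chain(
    targets: Sequence[DiversificationTask], shared_reference: str
) -> ChainResult:
    """Diversify targets sequentially, growing the shared reference.

    Target i is diversified against ``shared_reference || outputs[0..i-1]``,
    so each output ends up diverse from the reference and from every earlier
    output.  Returns all results plus the pairwise longest-identical-stretch
    matrix over {shared_reference, outputs...}.
    """
    if len(targets) < 2:
        raise ValueError("diversify_chain needs at least 2 targets")
    results: list[DiversificationResult] = []
    context = shared_reference
    for template in targets:
        task = dataclasses.replace(template, reference_context=context)
        res = diversify(task)
        results.append(res)
        context = context + res.output.seq

    seqs = ([shared_reference] if shared_reference else []) + [
        r.output.seq for r in results
    ]
    labels = (["reference"] if shared_reference else []) + [
        r.output.name for r in results
    ]
    k = len(seqs)
    matrix = [[0] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            l = longest_common_substring(seqs[i], seqs[j]).length
            matrix[i][j] = matrix[j][i] = l
    return ChainResult(results=results, labels=labels, max_identical_matrix=matrix)
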