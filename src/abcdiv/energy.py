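"""The diversification objective *f*: Boltzmann-aggregated duplex energies.

Recombination needs two stretches of the construct to pair; the propensity of
a construct ``C = context || seq`` to do so is scored by sliding one copy of
``C`` against another at every relative offset ``d > 0``.  At each offset the
perfectly matched runs long enough to nucleate pairing (>= ``m_min`` bases)
can chain into *duplex blocks*: a real duplex tolerates interior loops, at a
free-energy cost that grows with loop length (``loop_open`` plus
``loop_per_nt`` per unpaired base), so two matched runs bridge exactly when
the gained stacking outweighs the loop cost.  Each group of bridgeable runs
(successive gaps <= ``max_loop``) contributes the energy of its *optimal*
contiguous sub-chain — the pairing the strands would actually adopt; runs
further apart, or whose bridging is unprofitable, are independent pairing
events.  Sub-seed matches never contribute: a register that is merely
half-right everywhere is not a duplex.  The objective is

    f = sum over duplex blocks of exp(-E_block / rt),

accumulated in log10 space so that the astronomically large values produced
by near-identical sequence pairs are representable: ``log10_f`` is exact even
when ``f`` itself exceeds the double-precision ceiling of ~1e308, in which
case the score is flagged as overflowed and ``f_capped`` saturates.

Lower *f* means a more diversified sequence; values below ~1e7 have been
adopted in the codon-scrambling literature as safe for repeat-free behaviour.
A >=95 %-identity FP pair forms one essentially sequence-long block (every
gap is a point mismatch) and overflows; a fully diversified CDS only carries
scattered chance hexamers, each its own tiny block.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .codon_core import CodingSequence

__all__ = [
    "NN_STACK_DG37",
    "EnergyParams",
    "FScore",
    "duplex_delta_g",
    "objective_f",
    "pair_f",
    "shared_runs",
    "duplex_blocks",
    "DuplexBlock",
]

#: Unified nearest-neighbor stacking free energies (dG at 37 C, kcal/mol) for
#: the 16 dinucleotide steps, 5'->3' on the top strand of a Watson-Crick duplex.
NN_STACK_DG37: dict[str, float] = {
    "AA": -1.00, "AT": -0.88, "TA": -0.58, "CA": -1.45,
    "GT": -1.44, "CT": -1.28, "GA": -1.30, "CG": -2.17,
    "GC": -2.24, "GG": -1.84, "TT": -1.00, "TG": -1.45,
    "AC": -1.44, "AG": -1.28, "TC": -1.30, "CC": -1.84,
}

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class EnergyParams:
    """Parameters of the objective.

    ``m_min``   minimal perfectly matched run (bp) that nucleates a duplex.
    ``max_loop``  hard cap on interior-loop length (unpaired bases) bridged
                within one duplex block; matches separated further are
                independent.
    ``loop_open`` / ``loop_per_nt``  interior-loop cost (kcal/mol):
                opening term plus a per-unpaired-base term.  Point-mismatch
                loops are nearly free (near-identical sequence pairs zip
                end to end) while bridging tens of bases rarely pays.
    ``rt``      effective Boltzmann factor scale (kcal/mol).  Deliberately a
                free parameter of the score rather than the thermodynamic
                RT at ``temperature``: it sets how many decades of *f* one
                additional matched stack is worth (~0.53 at the default),
                placing fully diversified ~700-bp sequences near 1e5-1e6,
                dissimilar natural pairs tens of decades higher, and
                >=95 %-identity pairs beyond the double-precision ceiling.
    ``temperature``  reference temperature (K) of the stacking table.
    ``overflow_log10``  log10 of the representable ceiling.
    """

    m_min: int = 6
    max_loop: int = 50
    loop_open: float = 1.0
    loop_per_nt: float = 0.5
    rt: float = 1.0
    temperature: float = 310.15
    nn_table: Mapping[str, float] = field(default_factory=lambda: dict(NN_STACK_DG37))
    overflow_log10: float = 308.0

    def __post_init__(self) -> None:
        if self.m_min < 2:
            raise ValueError("m_min must be >= 2")
        if self.max_loop < 0:
            raise ValueError("max_loop must be >= 0")
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.nn_table)
        if missing:
            raise ValueError(f"nn_table is missing stacks: {sorted(missing)}")

    def digest(self) -> str:
        payload = repr(
            (self.m_min, self.max_loop, self.loop_open, self.loop_per_nt,
             self.rt, self.temperature, sorted(self.nn_table.items()),
             self.overflow_log10)
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass(frozen=True)
class FScore:
    """The objective on log10 scale.  ``log10_f`` is -inf when no run >= m_min
    exists anywhere in the construct (nothing to recombine)."""

    log10_f: float
    overflow_log10: float = 308.0

    @property
    def overflowed(self) -> bool:
        return self.log10_f > self.overflow_log10

    @property
    def f_capped(self) -> float:
        if self.log10_f == -math.inf:
            return 0.0
        return 10.0 ** min(self.log10_f, self.overflow_log10)

    def to_json_dict(self, params: EnergyParams | None = None) -> dict:
        out = {
            "log10_f": None if self.log10_f == -math.inf else self.log10_f,
            "overflowed": self.overflowed,
            "f_capped": self.f_capped,
        }
        if params is not None:
            out["params_digest"] = params.digest()
        return out


def _stack_prefix(seq: str, nn_table: Mapping[str, float]) -> np.ndarray:
    """P with P[0] = 0 and P[t] = sum of stack dG over the first t steps, so a
    matched run [k, k+l) contributes P[k+l-1] - P[k]."""
    if len(seq) < 2:
        return np.zeros(max(len(seq), 1))
    steps = np.fromiter(
        (nn_table[seq[t : t + 2]] for t in range(len(seq) - 1)),
        dtype=np.float64,
        count=len(seq) - 1,
    )
    return np.concatenate(([0.0], np.cumsum(steps)))


def shared_runs(seq: str, m_min: int, seq_start: int = 0) -> list[tuple[int, int, int]]:
    """Maximal identical runs ``(p, q, length)`` with ``p < q`` inside ``seq``.

    ``seq[p:p+length] == seq[q:q+length]`` and the run can be extended in
    neither direction.  Runs whose later copy ends at or before ``seq_start``
    (i.e. both copies entirely within a fixed context prefix) are dropped.
    Seeded by exact ``m_min``-gram collisions, so only runs of length >=
    ``m_min`` are reported.
    """
    n = len(seq)
    grams: dict[str, list[int]] = {}
    for i in range(n - m_min + 1):
        grams.setdefault(seq[i : i + m_min], []).append(i)
    runs: list[tuple[int, int, int]] = []
    for positions in grams.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions) - 1):
            p = positions[ai]
            for bi in range(ai + 1, len(positions)):
                q = positions[bi]
                if p > 0 and seq[p - 1] == seq[q - 1]:
                    continue  # not the leftmost seed of its run
                l = m_min
                while q + l < n and seq[p + l] == seq[q + l]:
                    l += 1
                if q + l > seq_start:
                    runs.append((p, q, l))
    return runs


def duplex_delta_g(win_a: str, win_b: str, params: EnergyParams | None = None):
    """Interaction energy (kcal/mol) of two equal-length windows aligned
    end-to-end — the optimal duplex over their matched runs — or None when
    no matched run reaches the seed length."""
    params = params or EnergyParams()
    if len(win_a) != len(win_b):
        raise ValueError(f"window length mismatch: {len(win_a)} vs {len(win_b)}")
    runs: list[tuple[int, int]] = []
    run = 0
    for t in range(len(win_a) + 1):
        if t < len(win_a) and win_a[t] == win_b[t]:
            run += 1
            continue
        if run >= params.m_min:
            runs.append((t - run, run))
        run = 0
    if not runs:
        return None
    stacks = [
        float(sum(params.nn_table[win_a[u : u + 2]] for u in range(s, s + l - 1)))
        for s, l in runs
    ]
    return min(e for e, _i, _j in _chain_runs(runs, stacks, params))


@dataclass(frozen=True)
class DuplexBlock:
    """One pairing event: chained matched runs at a fixed offset.

    ``runs`` holds (start, length) in first-copy coordinates (the partner
    copy of a run starts at ``start + offset``); gaps between consecutive
    runs are <= max_loop; at least one run is >= m_min.
    """

    offset: int
    energy: float
    runs: tuple[tuple[int, int], ...]

    @property
    def max_run(self) -> int:
        return max(l for _, l in self.runs)


def _all_runs_at_offset(
    codes: np.ndarray, d: int, min_len: int = 1
) -> list[tuple[int, int]]:
    """Maximal matched runs (start, length) >= min_len at offset d."""
    eq = codes[: len(codes) - d] == codes[d:]
    if not eq.any():
        return []
    b = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
    starts = b[0::2]
    lens = b[1::2] - starts
    if min_len > 1:
        keep = lens >= min_len
        starts, lens = starts[keep], lens[keep]
    return list(zip(starts.tolist(), lens.tolist()))


def _chain_runs(
    runs: list[tuple[int, int]],
    stacks: list[float],
    params: EnergyParams,
) -> list[tuple[float, int, int]]:
    """Optimal duplex sub-chains over nucleating runs at one register.

    Runs are grouped when successive gaps are <= max_loop; within a group,
    a minimum-sum contiguous sub-chain (run stacking energies, plus the
    interior-loop cost loop_open + loop_per_nt*gap for every bridged gap)
    gives the pairing the strands would adopt.  Returns
    ``(energy, first_run_idx, last_run_idx)`` per group.
    """
    out: list[tuple[float, int, int]] = []
    g_start = 0
    k = len(runs)
    for g_end in range(k):
        last = g_end == k - 1
        gap_next = (
            None if last else runs[g_end + 1][0] - (runs[g_end][0] + runs[g_end][1])
        )
        if not last and gap_next <= params.max_loop:
            continue
        # group is runs[g_start..g_end]: best contiguous sub-chain (Kadane)
        best_val, best_i, best_j = math.inf, g_start, g_start
        cur_val, cur_i = 0.0, g_start
        for t in range(g_start, g_end + 1):
            if t > g_start:
                gap = runs[t][0] - (runs[t - 1][0] + runs[t - 1][1])
                link = params.loop_open + params.loop_per_nt * gap
                if cur_val + link < 0:
                    cur_val = cur_val + link + stacks[t]
                else:
                    cur_val, cur_i = stacks[t], t
            else:
                cur_val, cur_i = stacks[t], t
            if cur_val < best_val:
                best_val, best_i, best_j = cur_val, cur_i, t
        out.append((best_val, best_i, best_j))
        g_start = g_end + 1
    return out


def blocks_at_offset(
    construct_codes: np.ndarray,
    stack_prefix: np.ndarray,
    d: int,
    seq_start: int,
    params: EnergyParams,
) -> list[DuplexBlock]:
    """Viable duplex blocks at one relative offset."""
    runs = _all_runs_at_offset(construct_codes, d, params.m_min)
    if not runs:
        return []
    stacks = [float(stack_prefix[s + l - 1] - stack_prefix[s]) for s, l in runs]
    blocks: list[DuplexBlock] = []
    for energy, i, j in _chain_runs(runs, stacks, params):
        sub = runs[i : j + 1]
        if sub[-1][0] + sub[-1][1] + d > seq_start:
            blocks.append(DuplexBlock(offset=d, energy=energy, runs=tuple(sub)))
    return blocks


def duplex_blocks(
    construct: str, seq_start: int, params: EnergyParams
) -> list[DuplexBlock]:
    """All viable duplex blocks of ``construct`` against itself.

    Candidate offsets are found by seeding on shared m_min-grams; each
    candidate offset is then rescanned for its nucleating runs, which are
    chained into blocks (gap <= max_loop).  A block qualifies if its later
    copy reaches past ``seq_start`` (pairings entirely inside a fixed context
    are not the designed sequence's business).
    """
    seeds = shared_runs(construct, params.m_min, 0)
    offsets = sorted({q - p for p, q, l in seeds})
    if not offsets:
        return []
    codes = np.frombuffer(construct.encode("ascii"), dtype=np.uint8)
    prefix = _stack_prefix(construct, params.nn_table)
    blocks: list[DuplexBlock] = []
    for d in offsets:
        blocks.extend(blocks_at_offset(codes, prefix, d, seq_start, params))
    return blocks


def _log10_terms(
    construct: str, seq_start: int, params: EnergyParams
) -> np.ndarray:
    blocks = duplex_blocks(construct, seq_start, params)
    if not blocks:
        return np.empty(0)
    e = np.fromiter((b.energy for b in blocks), dtype=np.float64)
    return -e / (params.rt * _LN10)


def _logsumexp10(log10_terms: np.ndarray) -> float:
    if log10_terms.size == 0:
        return -math.inf
    m = float(log10_terms.max())
    return m + math.log10(float(np.exp((log10_terms - m) * _LN10).sum()))


def objective_f(
    seq: CodingSequence | str,
    context: str | None = None,
    params: EnergyParams | None = None,
) -> FScore:
    """Score ``seq`` in the fixed DNA ``context`` (which may be empty).

    Only offsets whose matched runs involve ``seq`` contribute; repeats
    entirely internal to the context are its own business and are excluded.
    """
    params = params or EnergyParams()
    s = seq.seq if isinstance(seq, CodingSequence) else str(seq)
    ctx = context or ""
    if len(s) < params.m_min:
        raise ValueError(
            f"sequence length {len(s)} shorter than the seed length {params.m_min}"
        )
    construct = ctx + s
    log10_f = _logsumexp10(_log10_terms(construct, len(ctx), params))
    return FScore(log10_f=log10_f, overflow_log10=params.overflow_log10)


def pair_f(
    donor: CodingSequence | str,
    acceptor: CodingSequence | str,
    params: EnergyParams | None = None,
) -> FScore:
    """Objective for a donor/acceptor pair: the acceptor scored with the donor
    as fixed context (donor-internal repeats do not count)."""
    d = donor.seq if isinstance(donor, CodingSequence) else str(donor)
    a = acceptor.seq if isinstance(acceptor, CodingSequence) else str(acceptor)
    if not d or not a:
        raise ValueError("pair_f requires non-empty sequences")
    return objective_f(a, context=d, params=params)
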