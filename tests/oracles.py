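"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the package's quantities by the most direct
method available (dynamic programming, exhaustive scanning), sharing no code
with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def lcs_length_dp(a: str, b: str) -> int:
    """Longest common substring length by row-wise dynamic programming."""
    if not a or not b:
        return 0
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b), dtype=np.int32)
    best = 0
    for ch in a.encode():
        eq = bv == ch
        cur = np.where(eq, 1, 0).astype(np.int32)
        cur[1:] += np.where(eq[1:], prev[:-1], 0)
        best = max(best, int(cur.max()))
        prev = cur
    return best


def mems_brute(a: str, b: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal exact matches by direct seed extension over every (i, j)."""
    out: set[tuple[int, int, int]] = set()
    for i in range(len(a)):
        for j in range(len(b)):
            if a[i] != b[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # not leftmost
            l = 0
            while i + l < len(a) and j + l < len(b) and a[i + l] == b[j + l]:
                l += 1
            if l >= min_len:
                out.add((i, j, l))
    return out


def dotplot_brute(a: str, b: str, k: int) -> set[tuple[int, int]]:
    return {
        (i, j)
        for i in range(len(a) - k + 1)
        for j in range(len(b) - k + 1)
        if a[i : i + k] == b[j : j + k]
    }


def objective_log10_f_brute(seq: str, context: str, params) -> float:
    """Exhaustive per-register recomputation of the duplex-block objective.

    Scans every offset of C = context + seq with plain character loops,
    groups nucleating runs, and finds each group's optimal sub-chain by
    enumerating all (i, j) sub-chains quadratically.
    """
    construct = (context or "") + seq
    seq_start = len(context or "")
    L = len(construct)
    terms: list[float] = []
    for d in range(1, L):
        span = L - d
        runs: list[tuple[int, int]] = []
        run = 0
        for k in range(span + 1):
            if k < span and construct[k] == construct[k + d]:
                run += 1
                continue
            if run >= params.m_min:
                runs.append((k - run, run))
            run = 0
        if not runs:
            continue
        groups: list[list[tuple[int, int]]] = [[runs[0]]]
        for r in runs[1:]:
            prev = groups[-1][-1]
            if r[0] - (prev[0] + prev[1]) > params.max_loop:
                groups.append([r])
            else:
                groups[-1].append(r)

        def run_energy(s: int, l: int) -> float:
            return sum(
                params.nn_table[construct[u : u + 2]] for u in range(s, s + l - 1)
            )

        for g in groups:
            best = None
            best_sub = None
            for i in range(len(g)):
                for j in range(i, len(g)):
                    e = 0.0
                    for t in range(i, j + 1):
                        e += run_energy(*g[t])
                        if t > i:
                            gap = g[t][0] - (g[t - 1][0] + g[t - 1][1])
                            e += params.loop_open + params.loop_per_nt * gap
                    if best is None or e < best:
                        best, best_sub = e, g[i : j + 1]
            end = best_sub[-1][0] + best_sub[-1][1]
            if end + d <= seq_start:
                continue
            terms.append(-best / (params.rt * math.log(10.0)))
    if not terms:
        return -math.inf
    m = max(terms)
    return m + math.log10(sum(10.0 ** (t - m) for t in terms))
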