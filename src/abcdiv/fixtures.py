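"""Synthetic data generation: homologous FP-like CDS pairs and random proteins.

Fluorescent-protein FRET pairs derived from a common ancestor (the CFP/YFP
family) share >95 % nucleotide identity, which is exactly the regime that
triggers recombination in AAV production; naturally diversified pairs from
different source organisms sit near 50-60 %.  ``make_homolog_pair`` emulates
both regimes: starting from a usage-weighted CDS of a random protein, it
lowers identity codon by codon — synonymous substitutions first, so that at
high identity the two encoded proteins stay essentially the same, then
random codon replacements for the deeply diverged regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_core import (
    GENETIC_CODE,
    SYNONYMOUS_FAMILIES,
    CodingSequence,
    CodonUsageTable,
    ProteinSequence,
)

__all__ = [
    "HomologPairSpec",
    "make_homolog_pair",
    "make_random_protein",
    "GLOBULAR_AA_FREQS",
]

_RESIDUES = sorted({aa for aa in GENETIC_CODE.values()})
_SENSE_CODONS = sorted(GENETIC_CODE)

#: Average amino-acid frequencies of globular proteins (UniProt-style
#: averages, normalized); fluorescent proteins sit close to this profile.
GLOBULAR_AA_FREQS: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0228, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}


def make_random_protein(
    length_aa: int,
    seed: int = 0,
    name: str = "protein",
    composition: str = "uniform",
) -> ProteinSequence:
    """Random i.i.d. residues; deterministic for a given seed.

    ``composition='uniform'`` draws each of the 20 residues equally;
    ``'globular'`` draws from typical globular-protein frequencies;
    ``'fp'`` additionally avoids Leu/Met/Trp triplets, matching fluorescent
    proteins — the substrates of codon diversification — whose sequences
    carry no such runs.  (Met and Trp have a single codon, and at high
    abundance bias leucine can collapse to one codon too, so a Leu/Met/Trp
    triplet is a stretch no synonymous redesign can touch; uniform random
    proteins are unnaturally rich in them.)
    """
    if length_aa < 1:
        raise ValueError("length_aa must be >= 1")
    rng = np.random.default_rng(seed)
    if composition == "uniform":
        seq = "".join(
            _RESIDUES[int(i)] for i in rng.integers(len(_RESIDUES), size=length_aa)
        )
    elif composition in ("globular", "fp"):
        aas = sorted(GLOBULAR_AA_FREQS)
        p = np.array([GLOBULAR_AA_FREQS[a] for a in aas])
        p = p / p.sum()
        out: list[str] = []
        while len(out) < length_aa:
            aa = aas[int(rng.choice(len(aas), p=p))]
            if (
                composition == "fp"
                and len(out) >= 2
                and all(x in "LMW" for x in (out[-2], out[-1], aa))
            ):
                continue
            out.append(aa)
        seq = "".join(out)
    else:
        raise ValueError(f"unknown composition {composition!r}")
    return ProteinSequence(seq, name=name)


@dataclass(frozen=True)
class HomologPairSpec:
    """A pair of equal-length CDSs at a target nucleotide identity."""

    length_aa: int = 239
    identity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.identity <= 1.0:
            raise ValueError("identity target must be in [0.5, 1.0]")
        if self.length_aa < 10:
            raise ValueError("length_aa must be >= 10")


def nucleotide_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _usage_weighted_cds(
    protein: ProteinSequence, usage: CodonUsageTable | None, rng: np.random.Generator
) -> str:
    codons = []
    for aa in protein.seq:
        family = SYNONYMOUS_FAMILIES[aa]
        if usage is not None:
            p = np.array([usage.fraction(c) for c in family])
            p = p / p.sum()
        else:
            p = np.full(len(family), 1.0 / len(family))
        codons.append(family[int(rng.choice(len(family), p=p))])
    return "".join(codons)


def make_homolog_pair(
    spec: HomologPairSpec, usage: CodonUsageTable | None = None
) -> tuple[CodingSequence, CodingSequence]:
    """Two equal-length CDSs with nucleotide identity within +/-1 % of target.

    The second sequence is derived from the first by (1) synonymous codon
    swaps, then — only if the target is out of synonymous reach — (2) random
    codon replacements (never creating stops).  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    protein = make_random_protein(
        spec.length_aa, seed=int(rng.integers(2**31)), composition="fp"
    )
    seq_a = _usage_weighted_cds(protein, usage, rng)
    n = len(seq_a)
    target_diff = round((1.0 - spec.identity) * n)

    codons_b = [seq_a[i : i + 3] for i in range(0, n, 3)]
    slots = list(rng.permutation(spec.length_aa))

    def current_diff() -> int:
        return sum(
            1
            for i in range(spec.length_aa)
            for k in range(3)
            if codons_b[i][k] != seq_a[3 * i + k]
        )

    # phase 1: synonymous point edits — smallest change per codon, spread over
    # many codons, mimicking the scattered point mutations that separate
    # GFP-derived FP variants
    diff = 0
    for slot in slots:
        if diff >= target_diff:
            break
        old = codons_b[slot]
        family = [c for c in SYNONYMOUS_FAMILIES[GENETIC_CODE[old]] if c != old]
        if not family:
            continue
        gains = [(sum(a != b for a, b in zip(c, old)), c) for c in family]
        want = target_diff - diff
        gains.sort()
        gain, codon = gains[0]
        if gain <= want + 1:
            codons_b[slot] = codon
            diff += gain

    # phase 2: arbitrary (non-stop) codon replacements for deep divergence
    guard = 0
    while diff < target_diff - max(1, n // 200) and guard < 20 * spec.length_aa:
        guard += 1
        slot = int(rng.integers(spec.length_aa))
        ref = seq_a[3 * slot : 3 * slot + 3]
        old = codons_b[slot]
        codon = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
        delta = sum(a != b for a, b in zip(codon, ref)) - sum(
            a != b for a, b in zip(old, ref)
        )
        if 0 < delta <= target_diff - diff + 1:
            codons_b[slot] = codon
            diff += delta

    seq_b = "".join(codons_b)
    achieved = nucleotide_identity(seq_a, seq_b)
    if abs(achieved - spec.identity) > 0.01:
        raise ValueError(
            f"identity target {spec.identity:.3f} unreachable: achieved {achieved:.3f}"
        )
    return (
        CodingSequence(seq_a, name=f"homolog_a_id{spec.identity:.2f}"),
        CodingSequence(seq_b, name=f"homolog_b_id{spec.identity:.2f}"),
    )
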