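"""Sequence primitives, genetic code, codon-usage parsing and abundance-bias filtering.

The abundance bias is the heart of ABCD: for every amino acid only the
synonymous codons whose *within-family usage fraction* in the target organism
is at least ``bias`` remain available to the diversifier.  A family whose most
abundant codon still falls below the bias keeps that single codon (fallback),
so any protein stays encodable at any bias in [0, 1].
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "CodingSequence",
    "ProteinSequence",
    "CodonUsageTable",
    "AllowedCodonMap",
    "GENETIC_CODE",
    "STOP_CODONS",
    "AMINO_ACIDS",
    "load_usage_table",
    "write_usage_table",
    "allowed_codons",
    "translate",
    "back_translate",
    "reverse_complement",
]

log = logging.getLogger(__name__)

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Standard genetic code, taken from Biopython's table 1.
_std = _BioCodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_std.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_std.stop_codons)
AMINO_ACIDS: frozenset[str] = frozenset(GENETIC_CODE.values())

#: codons grouped by the residue they encode
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_dna(seq: str, *, what: str = "sequence") -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence (uppercase ACGT, length divisible by 3)."""

    seq: str
    name: str = ""

    def __post_init__(self) -> None:
        s = _normalize_dna(self.seq, what=f"CDS {self.name!r}")
        if len(s) % 3 != 0:
            raise ValueError(
                f"CDS {self.name!r} length {len(s)} is not divisible by 3"
            )
        object.__setattr__(self, "seq", s)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter amino-acid sequence; ``has_stop`` marks a terminal stop."""

    seq: str
    has_stop: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        s = self.seq.upper()
        if not s:
            raise ValueError("empty protein sequence")
        bad = set(s) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"protein {self.name!r} contains non-standard residues: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", s)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon usage for one organism.

    ``entries`` maps each of the 61 sense codons to
    ``(amino_acid, family_fraction, per_thousand)`` where ``family_fraction``
    is the codon's share within its synonymous family (sums to 1 per family).
    """

    organism: str
    entries: Mapping[str, tuple[str, float, float]]
    stop_per_thousand: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = sorted(set(GENETIC_CODE) - set(self.entries))
        if missing:
            raise ValueError(f"usage table is missing sense codons: {missing}")
        extra = sorted(set(self.entries) - set(GENETIC_CODE))
        if extra:
            raise ValueError(f"usage table has unknown/stop codons in entries: {extra}")
        sums: dict[str, float] = {}
        for codon, (aa, frac, per_k) in self.entries.items():
            if GENETIC_CODE[codon] != aa:
                raise ValueError(
                    f"codon {codon} annotated as {aa}, standard code says {GENETIC_CODE[codon]}"
                )
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"family_fraction for {codon} outside [0,1]: {frac}")
            if per_k < 0:
                raise ValueError(f"per_thousand for {codon} negative: {per_k}")
            sums[aa] = sums.get(aa, 0.0) + frac
        for aa, s in sums.items():
            if abs(s - 1.0) > 1e-6:
                raise ValueError(
                    f"family fractions for {aa} sum to {s!r}, expected 1 +/- 1e-6"
                )

    def fraction(self, codon: str) -> float:
        return self.entries[codon][1]

    def family(self, amino_acid: str) -> tuple[str, ...]:
        return SYNONYMOUS_FAMILIES[amino_acid]


@dataclass(frozen=True)
class AllowedCodonMap:
    """Bias-filtered codon choices per amino acid, most abundant first."""

    bias: float
    codons: Mapping[str, tuple[str, ...]]
    fractions: Mapping[str, float] = field(default_factory=dict)
    fallback_residues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError(f"bias outside [0,1]: {self.bias}")
        for aa in AMINO_ACIDS:
            if not self.codons.get(aa):
                raise ValueError(f"amino acid {aa} has no allowed codon")

    def __getitem__(self, amino_acid: str) -> tuple[str, ...]:
        return self.codons[amino_acid]

    def fraction(self, codon: str) -> float:
        return self.fractions[codon]


# ---------------------------------------------------------------------------
# usage-table I/O

_KAZUSA_ENTRY = re.compile(r"([ACGTUacgtu]{3})\s+([0-9]*\.?[0-9]+)\s*\(\s*-?[0-9]+\s*\)")


def load_usage_table(
    stream: IO[str] | Iterable[str],
    dialect: str = "tsv",
    organism: str = "",
) -> CodonUsageTable:
    """Parse a codon-usage table.

    ``tsv``: 4 columns ``codon  amino_acid  family_fraction  per_thousand``
    (header and ``#`` comments allowed; ``-`` for an absent fraction, in which
    case fractions are derived from per_thousand within each family).
    ``kazusa_text``: the classic frequency-table text format with
    ``CODON  per_thousand (count)`` entries.  RNA codons (U) are normalized
    to DNA (T).
    """
    per_k: dict[str, float] = {}
    frac: dict[str, float | None] = {}
    if dialect == "tsv":
        for raw in stream:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0].lower() in ("codon", "triplet"):
                continue
            if len(parts) < 4:
                raise ValueError(f"expected 4 columns, got {len(parts)}: {line!r}")
            codon = _normalize_dna(parts[0], what="codon")
            if len(codon) != 3:
                raise ValueError(f"not a codon: {parts[0]!r}")
            aa = parts[1].upper()
            expected = GENETIC_CODE.get(codon, "*")
            if aa not in (expected, "*", "STOP", "X"):
                raise ValueError(f"codon {codon} annotated {aa}, expected {expected}")
            if codon in per_k:
                raise ValueError(f"duplicate codon {codon}")
            per_k[codon] = float(parts[3])
            frac[codon] = None if parts[2] in ("-", "", "NA") else float(parts[2])
    elif dialect == "kazusa_text":
        text = stream if isinstance(stream, str) else "".join(stream)
        for m in _KAZUSA_ENTRY.finditer(text):
            codon = _normalize_dna(m.group(1), what="codon")
            if codon in per_k:
                raise ValueError(f"duplicate codon {codon}")
            per_k[codon] = float(m.group(2))
            frac[codon] = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    stops = {c: per_k.pop(c) for c in list(per_k) if c in STOP_CODONS}
    for c in STOP_CODONS:
        frac.pop(c, None)
    missing = sorted(set(GENETIC_CODE) - set(per_k))
    if missing:
        raise ValueError(f"usage table is missing sense codons: {missing}")

    entries: dict[str, tuple[str, float, float]] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        fam_sum = sum(per_k[c] for c in family)
        for c in family:
            f = frac.get(c)
            if f is None:
                f = per_k[c] / fam_sum if fam_sum > 0 else 1.0 / len(family)
            entries[c] = (aa, f, per_k[c])
    return CodonUsageTable(organism=organism, entries=entries, stop_per_thousand=stops)


def write_usage_table(table: CodonUsageTable, stream: IO[str]) -> None:
    """Serialize to the canonical 4-column TSV (round-trips with the loader)."""
    stream.write(f"# organism: {table.organism}\n")
    stream.write("codon\tamino_acid\tfamily_fraction\tper_thousand\n")
    for codon in sorted(table.entries):
        aa, f, per_k = table.entries[codon]
        stream.write(f"{codon}\t{aa}\t{f!r}\t{per_k!r}\n")
    for codon in sorted(table.stop_per_thousand):
        stream.write(f"{codon}\t*\t-\t{table.stop_per_thousand[codon]!r}\n")


def allowed_codons(table: CodonUsageTable, bias: float) -> AllowedCodonMap:
    """Codons with family_fraction >= ``bias`` per residue, descending fraction.

    If no codon of a family reaches the bias, the family's single most
    abundant codon is retained (fallback) and a warning is emitted.
    """
    if not 0.0 <= bias <= 1.0:
        raise ValueError(f"bias outside [0,1]: {bias}")
    codons: dict[str, tuple[str, ...]] = {}
    fractions: dict[str, float] = {}
    fallback: set[str] = set()
    for aa, family in SYNONYMOUS_FAMILIES.items():
        ranked = sorted(family, key=lambda c: (-table.fraction(c), c))
        kept = tuple(c for c in ranked if table.fraction(c) >= bias)
        if not kept:
            kept = (ranked[0],)
            fallback.add(aa)
            warnings.warn(
                f"no codon for {aa} reaches bias {bias:.2f}; "
                f"falling back to most abundant codon {ranked[0]}",
                stacklevel=2,
            )
        codons[aa] = kept
        for c in family:
            fractions[c] = table.fraction(c)
    return AllowedCodonMap(
        bias=bias,
        codons=codons,
        fractions=fractions,
        fallback_residues=frozenset(fallback),
    )


def translate(cds: CodingSequence) -> ProteinSequence:
    """Standard-code translation; a stop is only legal as the final codon."""
    residues: list[str] = []
    has_stop = False
    cods = cds.codons
    for i, codon in enumerate(cods):
        if codon in STOP_CODONS:
            if i != len(cods) - 1:
                raise ValueError(
                    f"internal stop codon {codon} at codon {i + 1} of {cds.name!r}"
                )
            has_stop = True
        else:
            residues.append(GENETIC_CODE[codon])
    if not residues:
        raise ValueError("CDS encodes no residues")
    return ProteinSequence("".join(residues), has_stop=has_stop, name=cds.name)


def back_translate(
    protein: ProteinSequence,
    allowed: AllowedCodonMap,
    *,
    rng=None,
    stop_codon: str = "TGA",
    name: str = "",
) -> CodingSequence:
    """Encode a protein using the allowed-codon map.

    Deterministic most-abundant choice when ``rng`` is None (the
    "abundance-greedy" baseline of the diversifier), otherwise a uniform
    draw among allowed codons per residue.
    """
    out: list[str] = []
    for aa in protein.seq:
        choices = allowed[aa]
        out.append(choices[0] if rng is None else choices[int(rng.integers(len(choices)))])
    if protein.has_stop:
        out.append(stop_codon)
    return CodingSequence("".join(out), name=name or protein.name)
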