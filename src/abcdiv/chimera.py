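"""Chimeric-read analysis of recombined AAV pools, plus a matching simulator.

The pipeline mirrors a long-read amplicon experiment on a donor-FP /
acceptor-FP construct: reads are anchored between two flanking stretches,
the insert between the anchors is extracted, identical inserts are grouped,
and each FP-length group is called letter by letter at the positions where
the donor and acceptor coding sequences differ ("C" for donor-like, "Y" for
acceptor-like; any other base means a sequencing error and discards the
whole group).  The count-weighted fraction of "Y" calls at each
discriminating position is the cumulative probability that recombination
happened before that position; under a uniform breakpoint density it grows
linearly with slope ~1/n.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from .codon_core import reverse_complement
from .homology import encode

__all__ = [
    "AnchorPair",
    "ExtractionResult",
    "ReadGroup",
    "DiscriminatingSites",
    "GroupCall",
    "RecombinationProfile",
    "ChimeraSimConfig",
    "extract_inserts",
    "group_inserts",
    "call_group",
    "recombination_profile",
    "simulate_reads",
    "write_profile_tsv",
    "write_truth_tsv",
]


@dataclass(frozen=True)
class AnchorPair:
    """Flanking stretches that must bracket the insert (Hamming matching)."""

    anchor5: str
    anchor3: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if len(self.anchor5) < 10 or len(self.anchor3) < 10:
            raise ValueError("anchors must be at least 10 bp")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


def _hamming_hits(read_codes: np.ndarray, anchor: str, max_mm: int) -> list[int]:
    """All offsets where the anchor matches within max_mm substitutions."""
    k = len(anchor)
    if len(read_codes) < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(read_codes, k)
    mm = (windows != encode(anchor)).sum(axis=1)
    return [int(i) for i in np.flatnonzero(mm <= max_mm)]


@dataclass
class ExtractionResult:
    inserts: list[str]
    n_reads: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)


def extract_inserts(
    reads: Iterable[str | tuple[str, str]], anchors: AnchorPair
) -> ExtractionResult:
    """Extract the sequence between the anchors from each read.

    A read is kept iff each anchor matches exactly once within
    ``max_mismatch`` and the 5' anchor lies upstream of the 3' anchor; when
    forward matching fails the reverse complement of the read is tried.
    Accepts bare sequences or (id, sequence) tuples (e.g. parsed FASTQ).
    """
    result = ExtractionResult(inserts=[])
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else str(item)
        result.n_reads += 1
        reason = None
        insert = None
        for oriented in (seq, reverse_complement(seq)):
            try:
                codes = encode(oriented)
            except ValueError:
                reason = "non_acgt"
                continue
            h5 = _hamming_hits(codes, anchors.anchor5, anchors.max_mismatch)
            h3 = _hamming_hits(codes, anchors.anchor3, anchors.max_mismatch)
            if len(h5) == 1 and len(h3) == 1:
                start = h5[0] + len(anchors.anchor5)
                end = h3[0]
                if end >= start:
                    insert = oriented[start:end]
                    break
                reason = "anchor_order"
            elif len(h5) > 1 or len(h3) > 1:
                reason = "multiple_anchor_hits"
            else:
                reason = reason or "missing_anchor"
        if insert is not None:
            result.inserts.append(insert)
            result.n_kept += 1
        else:
            result.dropped[reason or "missing_anchor"] += 1
    return result


@dataclass(frozen=True)
class ReadGroup:
    insert: str
    count: int


def group_inserts(inserts: Iterable[str]) -> list[ReadGroup]:
    """Group identical inserts; descending count, then lexicographic."""
    counts = Counter(inserts)
    return [
        ReadGroup(insert=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


@dataclass(frozen=True)
class DiscriminatingSites:
    """Positions where equal-length donor and acceptor CDSs differ."""

    donor: str
    acceptor: str
    positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.donor) != len(self.acceptor):
            raise ValueError("donor and acceptor must be the same length")
        pos = tuple(
            i for i in range(len(self.donor)) if self.donor[i] != self.acceptor[i]
        )
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GroupCall:
    """Per-site letters for one group, or a discard with its reason."""

    letters: tuple[str, ...] | None
    discard_reason: str | None = None

    @property
    def discarded(self) -> bool:
        return self.letters is None


def call_group(group: ReadGroup, sites: DiscriminatingSites) -> GroupCall:
    """Assign C (donor base) or Y (acceptor base) at each discriminating
    position; any other base is a sequencing error and discards the group."""
    if len(group.insert) != len(sites.donor):
        return GroupCall(letters=None, discard_reason="length")
    letters = []
    for p in sites.positions:
        base = group.insert[p]
        if base == sites.donor[p]:
            letters.append("C")
        elif base == sites.acceptor[p]:
            letters.append("Y")
        else:
            return GroupCall(letters=None, discard_reason="error")
    return GroupCall(letters=tuple(letters))


@dataclass(frozen=True)
class RecombinationProfile:
    positions: tuple[int, ...]
    n_valid: tuple[int, ...]
    frac_acceptor: tuple[float, ...]
    slope: float
    intercept: float
    r2: float
    chimeric_fraction: float
    error_floor: float = 0.0
    frac_acceptor_floored: tuple[float, ...] | None = None
    n_groups_called: int = 0
    n_groups_discarded_error: int = 0
    n_groups_length_filtered: int = 0

    def summary_json_dict(self) -> dict:
        return {
            "chimeric_fraction": self.chimeric_fraction,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "error_floor": self.error_floor,
            "n_sites": len(self.positions),
            "n_groups_called": self.n_groups_called,
            "n_groups_discarded_error": self.n_groups_discarded_error,
            "n_groups_length_filtered": self.n_groups_length_filtered,
        }


def recombination_profile(
    groups: Sequence[ReadGroup],
    sites: DiscriminatingSites,
    control_profile: RecombinationProfile | None = None,
) -> RecombinationProfile:
    """Count-weighted acceptor fraction per discriminating position.

    ``frac_acceptor(p)`` is the fraction of (read-weighted) valid groups
    calling Y at p — the share of molecules that had recombined before p.
    FP-length groups that fail calling are discarded; groups of a different
    length (full construct, indel-bearing reads) are excluded from calling
    but counted in the chimeric-fraction denominator, the FP-length inserts
    being its numerator.
    """
    n_sites = len(sites.positions)
    acceptor_w = np.zeros(n_sites)
    valid_w = np.zeros(n_sites)
    n_called = n_error = n_length = 0
    total_reads = 0
    fp_length_reads = 0
    for g in groups:
        total_reads += g.count
        if len(g.insert) == len(sites.donor):
            fp_length_reads += g.count
        call = call_group(g, sites)
        if call.discarded:
            if call.discard_reason == "length":
                n_length += 1
            else:
                n_error += 1
            continue
        n_called += 1
        valid_w += g.count
        acceptor_w += g.count * (np.array(call.letters) == "Y")
    if n_called == 0:
        raise ValueError("no valid groups to profile")

    frac = acceptor_w / valid_w
    pos = np.array(sites.positions, dtype=float)
    if n_sites >= 2 and np.ptp(pos) > 0:
        slope, intercept = np.polyfit(pos, frac, 1)
        pred = slope * pos + intercept
        ss_res = float(((frac - pred) ** 2).sum())
        ss_tot = float(((frac - frac.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        slope, intercept, r2 = 0.0, float(frac.mean()) if n_sites else 0.0, 1.0

    error_floor = 0.0
    floored = None
    if control_profile is not None:
        error_floor = max(control_profile.frac_acceptor, default=0.0)
        floored = tuple(max(0.0, f - error_floor) for f in frac)

    return RecombinationProfile(
        positions=tuple(sites.positions),
        n_valid=tuple(int(v) for v in valid_w),
        frac_acceptor=tuple(float(f) for f in frac),
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        chimeric_fraction=fp_length_reads / total_reads if total_reads else 0.0,
        error_floor=float(error_floor),
        frac_acceptor_floored=floored,
        n_groups_called=n_called,
        n_groups_discarded_error=n_error,
        n_groups_length_filtered=n_length,
    )


# ---------------------------------------------------------------------------
# simulator

@dataclass(frozen=True)
class ChimeraSimConfig:
    """Synthetic stand-in for a sequenced AAV amplicon pool.

    With probability ``rho`` a read carries a single-FP chimera
    ``donor[:b] + acceptor[b:]`` (breakpoint b over the full FP span),
    otherwise the intact full construct ``donor + linker + acceptor``.
    Inserts are wrapped in the anchors plus short random pads, hit by i.i.d.
    substitution errors, and half are emitted reverse-complemented.
    """

    donor: str
    acceptor: str
    anchors: AnchorPair
    linker: str = ""
    n_reads: int = 1000
    rho: float = 0.5
    breakpoint_weights: tuple[float, ...] | None = None
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.donor) != len(self.acceptor):
            raise ValueError("donor and acceptor must be the same length")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0,1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.breakpoint_weights is not None and len(self.breakpoint_weights) != len(self.donor) + 1:
            raise ValueError("breakpoint_weights must have length n + 1")

    @property
    def full_construct(self) -> str:
        return self.donor + self.linker + self.acceptor


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    is_chimera: bool
    breakpoint: int | None


def simulate_reads(config: ChimeraSimConfig) -> list[SimulatedRead]:
    """Deterministic (seeded) pool of anchored reads with a truth table."""
    rng = np.random.default_rng(config.seed)
    n = len(config.donor)
    if config.breakpoint_weights is not None:
        w = np.asarray(config.breakpoint_weights, dtype=float)
        bp_p = w / w.sum()
    else:
        bp_p = np.full(n + 1, 1.0 / (n + 1))
    reads: list[SimulatedRead] = []
    for i in range(config.n_reads):
        is_chimera = bool(rng.random() < config.rho)
        if is_chimera:
            b = int(rng.choice(n + 1, p=bp_p))
            insert = config.donor[:b] + config.acceptor[b:]
        else:
            b = None
            insert = config.full_construct
        pad5 = "".join("ACGT"[int(x)] for x in rng.integers(4, size=int(rng.integers(5, 16))))
        pad3 = "".join("ACGT"[int(x)] for x in rng.integers(4, size=int(rng.integers(5, 16))))
        raw = pad5 + config.anchors.anchor5 + insert + config.anchors.anchor3 + pad3
        raw = _mutate(raw, config.error_rate, rng)
        if rng.random() < 0.5:
            raw = reverse_complement(raw)
        reads.append(
            SimulatedRead(read_id=f"read{i:06d}", sequence=raw,
                          is_chimera=is_chimera, breakpoint=b)
        )
    return reads


def write_fastq(reads: Sequence[SimulatedRead], stream: IO[str]) -> None:
    for r in reads:
        stream.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_tsv(reads: Sequence[SimulatedRead], stream: IO[str]) -> None:
    stream.write("read_id\tclass\tbreakpoint_1based\n")
    for r in reads:
        cls = "chimera" if r.is_chimera else "full_construct"
        bp = "" if r.breakpoint is None else str(r.breakpoint + 1)
        stream.write(f"{r.read_id}\t{cls}\t{bp}\n")


def write_profile_tsv(profile: RecombinationProfile, stream: IO[str]) -> None:
    has_floor = profile.frac_acceptor_floored is not None
    header = "position_1based\tn_valid\tfrac_acceptor_raw"
    stream.write(header + ("\tfrac_acceptor_floored\n" if has_floor else "\n"))
    for idx, p in enumerate(profile.positions):
        row = f"{p + 1}\t{profile.n_valid[idx]}\t{profile.frac_acceptor[idx]:.6g}"
        if has_floor:
            row += f"\t{profile.frac_acceptor_floored[idx]:.6g}"
        stream.write(row + "\n")


def write_summary_json(profile: RecombinationProfile, stream: IO[str]) -> None:
    json.dump(profile.summary_json_dict(), stream, indent=2)
    stream.write("\n")
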