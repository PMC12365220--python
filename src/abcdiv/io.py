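"""File I/O: FASTA/FASTQ via Biopython, motif lists, packaged data."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_core import CodonUsageTable, load_usage_table
from .diversifier import MotifSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "load_motifs",
    "packaged_mouse_usage",
    "packaged_restriction_sites",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")  # wraps at 60 columns


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def load_motifs(path: str | Path, scan_both_strands: bool = True) -> MotifSet:
    """Motifs from FASTA, 2-column TSV (name, site) or one-motif-per-line text."""
    text = Path(path).read_text()
    motifs: dict[str, str] = {}
    if text.lstrip().startswith(">"):
        for name, seq in read_fasta(path):
            motifs[name] = seq
    else:
        idx = 0
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) >= 2:
                motifs[parts[0]] = parts[1].upper()
            else:
                idx += 1
                motifs[f"motif{idx}"] = parts[0].upper()
    return MotifSet(motifs=motifs, scan_both_strands=scan_both_strands)


def packaged_mouse_usage() -> CodonUsageTable:
    ref = resources.files("abcdiv.data").joinpath("mouse_codon_usage.tsv")
    with ref.open("r") as fh:
        return load_usage_table(fh, dialect="tsv", organism="mouse")


def packaged_restriction_sites(scan_both_strands: bool = True) -> MotifSet:
    ref = resources.files("abcdiv.data").joinpath("restriction_sites.tsv")
    motifs: dict[str, str] = {}
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name"):
            continue
        name, site = line.split("\t")
        motifs[name] = site
    return MotifSet(motifs=motifs, scan_both_strands=scan_both_strands)
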