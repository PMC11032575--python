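"""File-format helpers shared by the CLI: founder/diploid FASTA and reads."""

from __future__ import annotations

import re
from pathlib import Path

from Bio import SeqIO

from .haplotype_reference import DiploidEntry, DiploidTranscriptome
from .synthetic_data import FounderTranscriptome, TranscriptRecord

_DESC_RE = re.compile(
    r"gene=(?P<gene>\S+)\s+loc=(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)"
)
_DIPLOID_RE = re.compile(
    r"gene=(?P<gene>\S+)\s+allele=(?P<allele>[MP])\s+founder=(?P<founder>[A-H])"
    r"\s+chrom=(?P<chrom>\S+)"
)


def read_founder_fasta(path: Path, founder_code: str) -> FounderTranscriptome:
    """Read one founder transcriptome written by ``write_founder_fasta``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _DESC_RE.search(rec.description)
        if not m:
            raise ValueError(f"{path}: cannot parse header {rec.description!r}")
        records.append(
            TranscriptRecord(
                transcript_id=rec.id,
                gene_id=m["gene"],
                chromosome=m["chrom"],
                start=int(m["start"]),
                end=int(m["end"]),
                sequence=str(rec.seq),
            )
        )
    return FounderTranscriptome(founder_code, tuple(records))


def read_founder_dir(directory: Path, codes) -> dict[str, FounderTranscriptome]:
    """Read ``founder_<code>.fa`` files for every founder code."""
    out = {}
    for code in codes:
        path = directory / f"founder_{code}.fa"
        if not path.exists():
            raise FileNotFoundError(f"missing founder FASTA: {path}")
        out[code] = read_founder_fasta(path, code)
    return out


def read_diploid_fasta(path: Path) -> DiploidTranscriptome:
    """Read a diploid reference written by ``write_diploid_fasta``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _DIPLOID_RE.search(rec.description)
        if not m:
            raise ValueError(f"{path}: cannot parse header {rec.description!r}")
        base_id = rec.id.rsplit("_", 1)[0]
        entries.append(
            DiploidEntry(
                transcript_id=rec.id,
                base_id=base_id,
                gene_id=m["gene"],
                allele=m["allele"],
                source_founder=m["founder"],
                chromosome=m["chrom"],
                sequence=str(rec.seq),
            )
        )
    return DiploidTranscriptome(strain_id="?", maternal_strain="B",
                                entries=tuple(entries))


def read_reads(path: Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (by extension)."""
    fmt = "fastq" if path.suffix in {".fq", ".fastq"} else "fasta"
    return [str(r.seq) for r in SeqIO.parse(str(path), fmt)]
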