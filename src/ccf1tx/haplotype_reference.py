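"""Haplotype-mosaic parsing, CC transcriptome stitching and F1 diploid assembly.

A Collaborative Cross strain's genome is a mosaic of haplotype blocks
inherited from the eight founder strains.  Given the founder transcriptomes
and a strain's mosaic, this module stitches the strain's haploid
transcriptome (each transcript taken from the founder whose blocks best
cover it), combines it with the maternal C57BL/6J copy into an allele-tagged
diploid F1 reference, and reports per-locus founder-of-origin contribution
fractions.

Coordinates are 1-based inclusive throughout, matching the mosaic TSV
dialect (columns ``strain  chromosome  start  end  founder_code``).
The mitochondrial contig is maternal-only: every F1 inherits B6 mitochondria.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import (
    FOUNDER_CODES,
    MT_CHROM,
    REFERENCE_FOUNDER,
    FounderTranscriptome,
    TranscriptRecord,
)

__all__ = [
    "MATERNAL_ONLY_CHROMS",
    "HaplotypeMosaic",
    "HaploidTranscriptome",
    "DiploidEntry",
    "DiploidTranscriptome",
    "parse_mosaic",
    "write_mosaic",
    "build_strain_transcriptome",
    "build_f1_diploid",
    "founder_contribution",
    "write_diploid_fasta",
]

MOSAIC_COLUMNS = ["strain", "chromosome", "start", "end", "founder_code"]

#: Chromosomes inherited exclusively from the dam (B6) in this cross design.
MATERNAL_ONLY_CHROMS = frozenset({MT_CHROM})

MATERNAL_SUFFIX = "_M"
PATERNAL_SUFFIX = "_P"


@dataclass
class HaplotypeMosaic:
    """Ordered founder-labeled blocks per chromosome for one CC strain.

    Blocks within a chromosome must be sorted, non-overlapping and gap-free
    from position 1 to the chromosome end (the last block's end).
    """

    strain_id: str
    blocks: dict[str, list[tuple[int, int, str]]]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for chrom, blks in self.blocks.items():
            if not blks:
                raise ValueError(f"{chrom}: empty block list")
            prev_end = 0
            for start, end, code in blks:
                if code not in FOUNDER_CODES:
                    raise ValueError(
                        f"{chrom}: unknown founder code {code!r} in block "
                        f"({start}, {end})"
                    )
                if start > end:
                    raise ValueError(f"{chrom}: block start {start} > end {end}")
                if start <= prev_end:
                    raise ValueError(
                        f"{chrom}: overlapping blocks at position {start} "
                        f"(previous block ends at {prev_end})"
                    )
                if start != prev_end + 1:
                    raise ValueError(
                        f"{chrom}: gap between positions {prev_end} and {start}"
                    )
                prev_end = end
            if blks[0][0] != 1:
                raise ValueError(f"{chrom}: first block must start at 1")

    def chrom_end(self, chrom: str) -> int:
        return self.blocks[chrom][-1][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.strain_id, chrom, s, e, c)
            for chrom in sorted(self.blocks)
            for s, e, c in self.blocks[chrom]
        ]
        return pd.DataFrame(rows, columns=MOSAIC_COLUMNS)


def parse_mosaic(path) -> HaplotypeMosaic:
    """Parse and validate a mosaic TSV (single strain per file).

    Raises ``ValueError`` for a bad header, multiple strains, unknown founder
    codes, or blocks that overlap or leave gaps (the error names the
    chromosome and offending coordinate).
    """
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "founder_code": str})
    if list(df.columns) != MOSAIC_COLUMNS:
        raise ValueError(
            f"mosaic header must be {MOSAIC_COLUMNS}, got {list(df.columns)}"
        )
    strains = df["strain"].unique()
    if len(strains) != 1:
        raise ValueError(f"expected one strain per mosaic file, found {list(strains)}")
    blocks: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, grp in df.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        blocks[str(chrom)] = [
            (int(r.start), int(r.end), str(r.founder_code)) for r in grp.itertuples()
        ]
    return HaplotypeMosaic(strain_id=str(strains[0]), blocks=blocks)


def write_mosaic(mosaic: HaplotypeMosaic, path) -> None:
    mosaic.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcriptome stitching
# ---------------------------------------------------------------------------

@dataclass
class HaploidTranscriptome:
    """A stitched CC-strain haploid transcript set with per-transcript source."""

    strain_id: str
    transcripts: tuple[TranscriptRecord, ...]
    sources: dict[str, str]  # transcript_id -> founder code

    def by_id(self) -> dict[str, TranscriptRecord]:
        return {t.transcript_id: t for t in self.transcripts}


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def assign_founder(
    mosaic: HaplotypeMosaic, chrom: str, start: int, end: int
) -> str:
    """Founder owning the interval: maximal bp overlap, ties to the founder
    whose earliest overlapping block has the smaller start coordinate."""
    if chrom not in mosaic.blocks:
        raise ValueError(f"chromosome {chrom} not present in mosaic {mosaic.strain_id}")
    per_founder: dict[str, int] = {}
    first_block_start: dict[str, int] = {}
    for b_start, b_end, code in mosaic.blocks[chrom]:
        ov = _overlap(start, end, b_start, b_end)
        if ov > 0:
            per_founder[code] = per_founder.get(code, 0) + ov
            first_block_start.setdefault(code, b_start)
    if not per_founder:
        raise ValueError(
            f"interval {chrom}:{start}-{end} overlaps no block in mosaic "
            f"{mosaic.strain_id}"
        )
    best = max(per_founder.values())
    tied = [c for c, ov in per_founder.items() if ov == best]
    return min(tied, key=lambda c: first_block_start[c])


def build_strain_transcriptome(
    mosaic: HaplotypeMosaic, founders: dict[str, FounderTranscriptome]
) -> HaploidTranscriptome:
    """Stitch a CC strain's haploid transcriptome from the founder set.

    Each transcript's sequence is copied verbatim from the founder whose
    mosaic blocks maximally cover its span (whole-transcript assignment; no
    chimeric per-segment stitching).  Deterministic and idempotent: an
    all-B mosaic reproduces the B transcriptome byte-for-byte.
    """
    missing = [c for c in FOUNDER_CODES if c not in founders]
    if missing:
        raise ValueError(f"missing founder transcriptomes: {missing}")
    skeleton = founders[REFERENCE_FOUNDER].transcripts
    records, sources = [], {}
    for t in skeleton:
        code = assign_founder(mosaic, t.chromosome, t.start, t.end)
        rec = founders[code].by_id().get(t.transcript_id)
        if rec is None:
            raise ValueError(
                f"transcript {t.transcript_id} absent from founder {code}"
            )
        records.append(rec)
        sources[t.transcript_id] = code
    return HaploidTranscriptome(
        strain_id=mosaic.strain_id, transcripts=tuple(records), sources=sources
    )


# ---------------------------------------------------------------------------
# F1 diploid assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiploidEntry:
    """One allele-tagged transcript copy of the F1 diploid reference."""

    transcript_id: str  # suffixed _M or _P
    base_id: str
    gene_id: str
    allele: str  # "M" or "P"
    source_founder: str
    chromosome: str
    sequence: str


@dataclass
class DiploidTranscriptome:
    """Allele-tagged F1 reference: maternal B6 copy + paternal CC-mosaic copy.

    Every transcript appears once with allele M; once with allele P unless it
    lies on a maternal-only chromosome (MT).  The maternal source founder is
    always B.
    """

    strain_id: str
    maternal_strain: str
    entries: tuple[DiploidEntry, ...]

    def by_id(self) -> dict[str, DiploidEntry]:
        return {e.transcript_id: e for e in self.entries}

    def gene_map(self) -> dict[str, str]:
        return {e.base_id: e.gene_id for e in self.entries}


def _as_transcript_map(obj) -> tuple[dict[str, TranscriptRecord], dict[str, str]]:
    """Accept a FounderTranscriptome or HaploidTranscriptome; return
    (transcript map, per-transcript source founder map)."""
    if isinstance(obj, FounderTranscriptome):
        tmap = obj.by_id()
        return tmap, {tid: obj.founder_code for tid in tmap}
    if isinstance(obj, HaploidTranscriptome):
        return obj.by_id(), dict(obj.sources)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a transcript set")


def build_f1_diploid(
    paternal, maternal=None, *, founders: dict[str, FounderTranscriptome] | None = None,
    strain_id: str | None = None,
) -> DiploidTranscriptome:
    """Combine a paternal CC haploid set with the maternal B6 copy.

    ``maternal`` defaults to founder B from ``founders`` when provided.
    Transcript IDs are suffixed ``_M``/``_P``; MT transcripts are emitted
    maternal-only.  Raises on a transcript-skeleton mismatch, listing the
    unmatched IDs.
    """
    if maternal is None:
        if founders is None:
            raise ValueError("provide maternal transcriptome or founders dict")
        maternal = founders[REFERENCE_FOUNDER]
    pat_map, pat_src = _as_transcript_map(paternal)
    mat_map, mat_src = _as_transcript_map(maternal)
    if set(pat_map) != set(mat_map):
        unmatched = sorted(set(pat_map) ^ set(mat_map))
        raise ValueError(f"transcript skeleton mismatch; unmatched ids: {unmatched}")

    entries = []
    for tid in sorted(mat_map):
        m = mat_map[tid]
        entries.append(
            DiploidEntry(
                transcript_id=tid + MATERNAL_SUFFIX,
                base_id=tid,
                gene_id=m.gene_id,
                allele="M",
                source_founder=mat_src[tid],
                chromosome=m.chromosome,
                sequence=m.sequence,
            )
        )
        if m.chromosome in MATERNAL_ONLY_CHROMS:
            continue
        p = pat_map[tid]
        entries.append(
            DiploidEntry(
                transcript_id=tid + PATERNAL_SUFFIX,
                base_id=tid,
                gene_id=p.gene_id,
                allele="P",
                source_founder=pat_src[tid],
                chromosome=p.chromosome,
                sequence=p.sequence,
            )
        )
    sid = strain_id or getattr(paternal, "strain_id", getattr(paternal, "founder_code", "?"))
    return DiploidTranscriptome(
        strain_id=sid, maternal_strain=REFERENCE_FOUNDER, entries=tuple(entries)
    )


# ---------------------------------------------------------------------------
# Founder-of-origin contribution
# ---------------------------------------------------------------------------

def founder_contribution(
    mosaic: HaplotypeMosaic,
    loci: list[tuple[str, str, int, int]],
) -> pd.DataFrame:
    """Per-locus founder contribution fractions.

    ``loci`` are ``(gene_id, chromosome, start, end)`` intervals.  Each row
    gives the fraction of the locus' base pairs covered by each founder's
    blocks; rows sum to 1 and are one-hot whenever the locus does not
    straddle a haplotype breakpoint.  For an all-B6 mosaic the B column is
    1.0 at every locus.
    """
    rows = []
    index = []
    for gene_id, chrom, start, end in loci:
        if chrom not in mosaic.blocks:
            raise ValueError(f"locus {gene_id}: chromosome {chrom} not in mosaic")
        if start < 1 or end > mosaic.chrom_end(chrom) or start > end:
            raise ValueError(
                f"locus {gene_id}: interval {chrom}:{start}-{end} outside "
                f"chromosome span 1-{mosaic.chrom_end(chrom)}"
            )
        total = end - start + 1
        frac = dict.fromkeys(FOUNDER_CODES, 0.0)
        for b_start, b_end, code in mosaic.blocks[chrom]:
            ov = _overlap(start, end, b_start, b_end)
            if ov:
                frac[code] += ov / total
        rows.append(frac)
        index.append(gene_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="gene_id"),
                        columns=list(FOUNDER_CODES))


def write_diploid_fasta(diploid: DiploidTranscriptome, path) -> None:
    """Write the diploid reference as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(
            Seq(e.sequence),
            id=e.transcript_id,
            description=(
                f"gene={e.gene_id} allele={e.allele} founder={e.source_founder} "
                f"chrom={e.chromosome}"
            ),
        )
        for e in diploid.entries
    ]
    SeqIO.write(records, str(path), "fasta")
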