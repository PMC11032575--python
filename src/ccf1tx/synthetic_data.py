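"""Synthetic data generation for the (B6 x CC)F1 analysis pipeline.

Every input the pipeline consumes can be generated here with known ground
truth: the eight Collaborative Cross founder transcriptomes with planted
strain-specific SNPs, recombinant-inbred haplotype mosaics, F1 crosses with
hemizygous transgene segregation, reads drawn from a diploid transcriptome
with known abundances, and expression matrices with planted co-expression
modules, covariate effects and group fold-changes.

The genome model is deliberately small: transcripts are intron-free genomic
intervals, one isoform per gene, autosomes plus an optional maternal-only
mitochondrial contig.  All generators are pure functions of
``(config, seed)``: rerunning with the same configuration yields
byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FOUNDER_CODES",
    "FOUNDER_NAMES",
    "TranscriptRecord",
    "FounderTranscriptome",
    "SimulationConfig",
    "SimRead",
    "ExpressionTruth",
    "gen_founders",
    "gen_mosaic",
    "simulate_cross",
    "simulate_reads",
    "gen_expression",
    "write_founder_fasta",
    "read_transcript_fasta",
    "write_metadata_tsv",
    "read_metadata_tsv",
]

#: Single-letter founder codes used in CC haplotype files.
FOUNDER_CODES = ("A", "B", "C", "D", "E", "F", "G", "H")

#: Standard founder strain names; B (C57BL/6J) is the reference and the
#: maternal strain of every F1 in the breeding scheme modeled here.
FOUNDER_NAMES = {
    "A": "A/J",
    "B": "C57BL/6J",
    "C": "129S1/SvImJ",
    "D": "NOD/ShiLtJ",
    "E": "NZO/HlLtJ",
    "F": "CAST/EiJ",
    "G": "PWK/PhJ",
    "H": "WSB/EiJ",
}

REFERENCE_FOUNDER = "B"
MT_CHROM = "MT"

_BASES = np.array(list("ACGT"))

# Sub-stream tags so that each generator draws from an independent stream of
# the configured seed (adding a generator never perturbs another's output).
_STREAM_FOUNDERS = 0
_STREAM_MOSAIC = 1
_STREAM_CROSS = 2
_STREAM_READS = 3
_STREAM_EXPRESSION = 4


def _rng(config: "SimulationConfig", stream: int, *tags: str) -> np.random.Generator:
    key = [int(config.seed), stream] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(key)


@dataclass(frozen=True)
class TranscriptRecord:
    """One intron-free transcript: its genomic span and sequence."""

    transcript_id: str
    gene_id: str
    chromosome: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    sequence: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span for {self.transcript_id}: [{self.start}, {self.end}]")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != span "
                f"{self.end - self.start + 1}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FounderTranscriptome:
    """Transcript set of one founder strain.

    All eight founders share the same transcript/gene/coordinate skeleton;
    sequences differ only at planted SNP positions.
    """

    founder_code: str
    transcripts: tuple[TranscriptRecord, ...]

    def __post_init__(self):
        if self.founder_code not in FOUNDER_CODES:
            raise ValueError(f"unknown founder code {self.founder_code!r}")

    def by_id(self) -> dict[str, TranscriptRecord]:
        return {t.transcript_id: t for t in self.transcripts}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with an explicit mandatory seed.

    Defaults mirror the structure of the study being emulated: eight founder
    strains, a hemizygous x wildtype cross transmitting the transgene to 50%
    of offspring, 43 bp reads, and ages restricted to 4 and 12 months.
    """

    seed: int
    n_genes: int = 200
    n_chromosomes: int = 2
    chrom_length_bp: int = 200_000
    transcript_length_bp: int = 500
    snp_rate: float = 0.01
    n_blocks_per_chrom: int = 5
    n_offspring: int = 24
    transgene_carrier_prob: float = 0.5
    read_length: int = 43
    n_reads: int = 10_000
    sequencing_error_rate: float = 0.0
    include_mt: bool = False
    n_mt_genes: int = 2
    module_spec: list[tuple[int, float]] = field(default_factory=list)
    covariate_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    n_qc_metrics: int = 8

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_genes", "n_chromosomes", "chrom_length_bp", "transcript_length_bp",
                     "n_blocks_per_chrom", "n_offspring", "read_length", "n_reads",
                     "n_qc_metrics"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("snp_rate", "transgene_carrier_prob", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if sum(size for size, _ in self.module_spec) > self.n_genes:
            raise ValueError("module_spec sizes exceed n_genes")

    @property
    def chromosomes(self) -> list[str]:
        chroms = [f"chr{i + 1}" for i in range(self.n_chromosomes)]
        if self.include_mt:
            chroms.append(MT_CHROM)
        return chroms


# ---------------------------------------------------------------------------
# Founder transcriptomes
# ---------------------------------------------------------------------------

def _transcript_layout(config: SimulationConfig) -> list[tuple[str, str, str, int, int]]:
    """Place genes as evenly spaced non-overlapping intervals on chromosomes.

    Returns (transcript_id, gene_id, chromosome, start, end) tuples.  MT
    genes, when enabled, are counted in addition to ``n_genes`` autosomal
    genes so autosomal module planting is unaffected.
    """
    layout = []
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    spacing = config.chrom_length_bp // per_chrom
    if spacing < config.transcript_length_bp:
        raise ValueError(
            "chromosome too short for requested gene count and transcript length"
        )
    idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for j in range(per_chrom):
            if idx >= config.n_genes:
                break
            start = j * spacing + 1
            end = start + config.transcript_length_bp - 1
            gid = f"gene{idx + 1:05d}"
            layout.append((f"{gid}.t1", gid, chrom, start, end))
            idx += 1
    if config.include_mt:
        spacing_mt = config.chrom_length_bp // config.n_mt_genes
        if spacing_mt < config.transcript_length_bp:
            raise ValueError("MT contig too short for requested MT gene count")
        for j in range(config.n_mt_genes):
            start = j * spacing_mt + 1
            end = start + config.transcript_length_bp - 1
            gid = f"mtgene{j + 1:03d}"
            layout.append((f"{gid}.t1", gid, MT_CHROM, start, end))
    return layout


def gen_founders(
    config: SimulationConfig,
) -> tuple[dict[str, FounderTranscriptome], pd.DataFrame]:
    """Generate the eight founder transcriptomes plus the planted-SNP table.

    Founder B (C57BL/6J) is the reference: its sequences are drawn at
    random, and every other founder differs from it by independent
    substitutions planted at rate ``snp_rate`` per transcript base.

    Returns
    -------
    founders : dict mapping founder code -> FounderTranscriptome
    snp_table : DataFrame with columns founder_code, transcript_id,
        chromosome, position (1-based genomic), offset (0-based within
        transcript), ref, alt — the ground truth for every planted SNP.
    """
    rng = _rng(config, _STREAM_FOUNDERS)
    layout = _transcript_layout(config)

    ref_seqs = {
        tid: "".join(rng.choice(_BASES, size=end - start + 1))
        for tid, _, _, start, end in layout
    }

    snp_rows = []
    founders: dict[str, FounderTranscriptome] = {}
    for code in FOUNDER_CODES:
        records = []
        for tid, gid, chrom, start, end in layout:
            seq = ref_seqs[tid]
            if code != REFERENCE_FOUNDER and config.snp_rate > 0:
                L = len(seq)
                hits = np.flatnonzero(rng.random(L) < config.snp_rate)
                if hits.size:
                    arr = np.array(list(seq))
                    for off in hits:
                        ref_base = arr[off]
                        alt = rng.choice(_BASES[_BASES != ref_base])
                        arr[off] = alt
                        snp_rows.append(
                            (code, tid, chrom, start + int(off), int(off), ref_base, alt)
                        )
                    seq = "".join(arr)
            records.append(TranscriptRecord(tid, gid, chrom, start, end, seq))
        founders[code] = FounderTranscriptome(code, tuple(records))

    snp_table = pd.DataFrame(
        snp_rows,
        columns=["founder_code", "transcript_id", "chromosome", "position",
                 "offset", "ref", "alt"],
    )
    return founders, snp_table


# ---------------------------------------------------------------------------
# Haplotype mosaics and crosses
# ---------------------------------------------------------------------------

def gen_mosaic(config: SimulationConfig, strain_id: str):
    """Simulate a CC strain's haplotype mosaic.

    Each chromosome is split into ``n_blocks_per_chrom`` contiguous blocks
    with uniform random breakpoints; each block is labeled with a founder
    drawn uniformly from the eight codes.  Block-length realism is not
    attempted.  Returns a :class:`~ccf1tx.haplotype_reference.HaplotypeMosaic`.
    """
    from .haplotype_reference import HaplotypeMosaic  # avoid circular import

    rng = _rng(config, _STREAM_MOSAIC, strain_id)
    blocks: dict[str, list[tuple[int, int, str]]] = {}
    for chrom in config.chromosomes:
        n = config.n_blocks_per_chrom
        length = config.chrom_length_bp
        if n > 1:
            cuts = np.sort(rng.choice(np.arange(2, length + 1), size=n - 1, replace=False))
        else:
            cuts = np.array([], dtype=int)
        starts = np.concatenate(([1], cuts))
        ends = np.concatenate((cuts - 1, [length]))
        labels = rng.choice(list(FOUNDER_CODES), size=n)
        blocks[chrom] = [(int(s), int(e), str(l)) for s, e, l in zip(starts, ends, labels)]
    return HaplotypeMosaic(strain_id=strain_id, blocks=blocks)


def simulate_cross(config: SimulationConfig, mosaic) -> pd.DataFrame:
    """Simulate F1 offspring of a hemizygous transgene carrier x CC cross.

    Genotype is Bernoulli(``transgene_carrier_prob``) — the Mendelian 50%
    expectation for a hemizygous parent at the default — sex is
    Bernoulli(0.5), age is drawn from {4, 12} months, and ``line`` is the
    mosaic's strain.  Sequencing QC metrics (used downstream for Seq.PC
    computation) are simulated as correlated Gaussians sharing a planted
    per-sample batch direction.
    """
    rng = _rng(config, _STREAM_CROSS, mosaic.strain_id)
    n = config.n_offspring
    genotype = np.where(rng.random(n) < config.transgene_carrier_prob, "5x", "WT")
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    age = rng.choice([4, 12], size=n)
    meta = pd.DataFrame(
        {
            "sample_id": [f"{mosaic.strain_id}_{i + 1:04d}" for i in range(n)],
            "line": mosaic.strain_id,
            "genotype": genotype,
            "sex": sex,
            "age_months": age,
        }
    )
    # planted batch direction: each QC metric loads on a shared per-sample
    # latent batch score, plus independent measurement noise
    batch = rng.normal(size=n)
    loadings = rng.uniform(0.5, 1.5, size=config.n_qc_metrics)
    for j in range(config.n_qc_metrics):
        meta[f"qc_metric_{j + 1}"] = batch * loadings[j] + rng.normal(
            scale=0.3, size=n
        )
    meta.attrs["batch_score"] = batch
    return meta


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimRead:
    """A simulated single-end read with its ground-truth origin."""

    read_id: str
    sequence: str
    source_transcript: str
    source_allele: str
    start_offset: int  # 0-based offset within the source transcript


def simulate_reads(
    diploid,
    abundances: dict[tuple[str, str], float],
    config: SimulationConfig,
) -> list[SimRead]:
    """Draw error-prone single-end reads from a diploid transcriptome.

    A source (transcript, allele) is picked with probability proportional to
    ``weight x (length - read_length + 1)`` — i.e. weights are molar
    abundances and longer transcripts yield proportionally more fragments —
    then a start position uniform over valid placements, emitting the
    substring.  Per-base substitution errors are applied at
    ``sequencing_error_rate``.  Ground-truth origin is recorded on each read.
    """
    rng = _rng(config, _STREAM_READS)
    L = config.read_length
    entries = {(e.base_id, e.allele): e for e in diploid.entries}
    keys = sorted(abundances)
    missing = [k for k in keys if k not in entries]
    if missing:
        raise KeyError(f"abundance keys not in diploid transcriptome: {missing}")
    weights = np.array([abundances[k] for k in keys], dtype=float)
    if (weights < 0).any():
        raise ValueError("abundance weights must be non-negative")
    if weights.sum() == 0:
        raise ValueError("abundance weights must not all be zero")
    for k in keys:
        if abundances[k] > 0 and len(entries[k].sequence) < L:
            raise ValueError(
                f"read_length {L} exceeds length of transcript "
                f"{entries[k].base_id} allele {entries[k].allele}"
            )
    n_starts = np.array([len(entries[k].sequence) - L + 1 for k in keys], dtype=float)
    p = weights * n_starts
    p /= p.sum()

    src = rng.choice(len(keys), size=config.n_reads, p=p)
    reads = []
    for i, s in enumerate(src):
        entry = entries[keys[s]]
        start = int(rng.integers(0, len(entry.sequence) - L + 1))
        seq = entry.sequence[start : start + L]
        if config.sequencing_error_rate > 0:
            arr = np.array(list(seq))
            errs = np.flatnonzero(rng.random(L) < config.sequencing_error_rate)
            for off in errs:
                arr[off] = rng.choice(_BASES[_BASES != arr[off]])
            seq = "".join(arr)
        reads.append(
            SimRead(f"read{i + 1:07d}", seq, entry.base_id, entry.allele, start)
        )
    return reads


# ---------------------------------------------------------------------------
# Expression matrices with planted structure
# ---------------------------------------------------------------------------

_COVARIATE_CODES = {
    "genotype": {"WT": 0.0, "5x": 1.0},
    "sex": {"F": 0.0, "M": 1.0},
    "age_months": {4: 0.0, 12: 1.0},
}


def _code_covariate(metadata: pd.DataFrame, cov: str) -> np.ndarray:
    if cov not in metadata.columns:
        raise KeyError(f"covariate {cov!r} not in metadata")
    col = metadata[cov]
    if cov in _COVARIATE_CODES:
        return col.map(_COVARIATE_CODES[cov]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


@dataclass
class ExpressionTruth:
    """Ground truth emitted alongside a planted expression matrix."""

    module_labels: pd.Series  # gene -> module index (0 = background)
    factors: pd.DataFrame  # samples x modules latent factors
    loadings: pd.Series  # gene -> loading on its module factor
    covariate_betas: pd.DataFrame  # genes x covariates planted effects


def gen_expression(
    config: SimulationConfig,
    metadata: pd.DataFrame,
    planted_fc: dict[str, dict[str, float]] | None = None,
):
    """Generate a log2-scale expression matrix with planted structure.

    For each planted module ``m`` of ``module_spec`` a latent per-sample
    factor ``f_m ~ N(0, factor_sd)`` is drawn; member genes are
    ``loading * f_m + covariate effects + N(0, noise_sd)``; background genes
    get covariates + noise only.  ``covariate_effects`` maps a covariate name
    to the (mean, sd) of the per-gene effect applied to its 0/1 (or numeric)
    coding; ``planted_fc`` plants targeted effects,
    e.g. ``{"gene00001": {"genotype": 2.0}}`` for a 2-log2-unit carrier shift.

    Returns an :class:`~ccf1tx.preprocess.ExpressionMatrix` (transform
    ``"log2"``) and an :class:`ExpressionTruth`.
    """
    from .preprocess import ExpressionMatrix  # avoid circular import

    rng = _rng(config, _STREAM_EXPRESSION)
    n_samples = len(metadata)
    genes = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    sample_ids = metadata["sample_id"].tolist()

    values = rng.normal(scale=config.noise_sd, size=(config.n_genes, n_samples))

    module_labels = pd.Series(0, index=genes, name="module")
    loadings = pd.Series(0.0, index=genes, name="loading")
    factors = {}
    cursor = 0
    for m, (size, factor_sd) in enumerate(config.module_spec, start=1):
        f = rng.normal(scale=factor_sd, size=n_samples)
        factors[f"module{m}"] = f
        member = genes[cursor : cursor + size]
        load = np.ones(size)
        values[cursor : cursor + size] += np.outer(load, f)
        module_labels.loc[member] = m
        loadings.loc[member] = load
        cursor += size

    betas = pd.DataFrame(0.0, index=genes, columns=sorted(config.covariate_effects))
    for cov, (mean, sd) in sorted(config.covariate_effects.items()):
        code = _code_covariate(metadata, cov)
        b = rng.normal(loc=mean, scale=sd, size=config.n_genes)
        values += np.outer(b, code)
        betas[cov] = b

    if planted_fc:
        for gene, effects in planted_fc.items():
            gi = genes.index(gene)
            for cov, eff in effects.items():
                code = _code_covariate(metadata, cov)
                values[gi] += eff * code
                if cov not in betas.columns:
                    betas[cov] = 0.0
                betas.loc[gene, cov] = betas.loc[gene, cov] + eff

    matrix = pd.DataFrame(values, index=genes, columns=sample_ids)
    truth = ExpressionTruth(
        module_labels=module_labels,
        factors=pd.DataFrame(factors, index=sample_ids),
        loadings=loadings,
        covariate_betas=betas,
    )
    return ExpressionMatrix(values=matrix, transform="log2", metadata=metadata), truth


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_founder_fasta(founder: FounderTranscriptome, path) -> None:
    """Write a founder transcriptome as 60-column-wrapped FASTA."""
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=t.transcript_id,
            description=(
                f"gene={t.gene_id} loc={t.chromosome}:{t.start}-{t.end} "
                f"founder={founder.founder_code}"
            ),
        )
        for t in founder.transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcript_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
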