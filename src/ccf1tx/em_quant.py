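"""Read-to-transcript compatibility mapping, EM quantification and gene TPM.

Reads are assigned to equivalence classes — the set of (transcript, allele)
sequences that contain the read, found by exact substring matching with
k-mer seeding (optional Hamming mismatch tolerance via pigeonhole seeding).
Ambiguous class counts are resolved by a standard multiread EM over
effective-length-normalized transcript abundances, and transcript-allele
abundances are pooled per gene and scaled to transcripts-per-million.

A ``unique_only`` switch drops all multi-member classes before the EM,
reproducing a strict uniquely-aligned-reads quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EquivalenceClassSet",
    "EMResult",
    "compat_map",
    "em_quantify",
    "gene_tpm",
    "quantify_sample",
]

Key = tuple[str, str]  # (transcript_id, allele)


@dataclass
class EquivalenceClassSet:
    """Read counts keyed by sets of compatible (transcript, allele) pairs."""

    classes: dict[frozenset, int]
    transcript_lengths: dict[Key, int]
    read_length: int
    total_reads: int
    n_unmapped: int = 0

    def __post_init__(self):
        for members, count in self.classes.items():
            if count < 1:
                raise ValueError("class counts must be >= 1")
            for key in members:
                if key not in self.transcript_lengths:
                    raise ValueError(f"no length recorded for {key}")
        assigned = sum(self.classes.values())
        if assigned + self.n_unmapped != self.total_reads:
            raise ValueError(
                f"class counts ({assigned}) + unmapped ({self.n_unmapped}) "
                f"!= total reads ({self.total_reads})"
            )

    def effective_lengths(self) -> dict[Key, float]:
        """Number of valid read start positions per transcript, floored at 1."""
        return {
            k: float(max(length - self.read_length + 1, 1))
            for k, length in self.transcript_lengths.items()
        }


def _read_sequences(reads) -> list[str]:
    out = []
    for r in reads:
        out.append(r if isinstance(r, str) else getattr(r, "sequence"))
    return out


def compat_map(reads, diploid, max_mismatches: int = 0) -> EquivalenceClassSet:
    """Map reads to the diploid reference by exact (or near-exact) substring.

    A read's equivalence class is the set of all (transcript, allele) whose
    sequence contains it within ``max_mismatches`` substitutions.  Seeding
    uses the pigeonhole principle: the read is split into
    ``max_mismatches + 1`` segments, at least one of which must match
    exactly; candidate placements from an exact k-mer index are then
    verified by Hamming distance.  Unmapped reads are counted separately.
    """
    entries = list(diploid.entries)
    if not entries:
        raise ValueError("empty diploid index")
    seqs = _read_sequences(reads)
    if not seqs:
        return EquivalenceClassSet({}, {
            (e.base_id, e.allele): len(e.sequence) for e in entries
        }, read_length=0, total_reads=0)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all reads must have equal length")
    min_len = min(len(e.sequence) for e in entries)
    if L > min_len:
        short = min(entries, key=lambda e: len(e.sequence))
        raise ValueError(
            f"read length {L} exceeds shortest transcript "
            f"{short.base_id} allele {short.allele} ({min_len} bp)"
        )

    n_seg = max_mismatches + 1
    k = L // n_seg
    offsets = [i * k for i in range(n_seg)]

    index: dict[str, list[tuple[int, int]]] = {}
    for ei, e in enumerate(entries):
        s = e.sequence
        for pos in range(len(s) - k + 1):
            index.setdefault(s[pos : pos + k], []).append((ei, pos))

    def hamming_le(a: str, b: str, limit: int) -> bool:
        mism = 0
        for x, y in zip(a, b):
            if x != y:
                mism += 1
                if mism > limit:
                    return False
        return True

    classes: dict[frozenset, int] = {}
    n_unmapped = 0
    for s in seqs:
        hits: set[Key] = set()
        seen: set[tuple[int, int]] = set()
        for off in offsets:
            for ei, pos in index.get(s[off : off + k], ()):
                start = pos - off
                if start < 0 or (ei, start) in seen:
                    continue
                seen.add((ei, start))
                e = entries[ei]
                if start + L > len(e.sequence):
                    continue
                if hamming_le(s, e.sequence[start : start + L], max_mismatches):
                    hits.add((e.base_id, e.allele))
        if hits:
            key = frozenset(hits)
            classes[key] = classes.get(key, 0) + 1
        else:
            n_unmapped += 1

    lengths = {(e.base_id, e.allele): len(e.sequence) for e in entries}
    return EquivalenceClassSet(
        classes=classes,
        transcript_lengths=lengths,
        read_length=L,
        total_reads=len(seqs),
        n_unmapped=n_unmapped,
    )


@dataclass
class EMResult:
    """EM output: transcript-allele read-fraction abundances and diagnostics."""

    theta: dict[Key, float]
    n_iter: int
    log_likelihood: float
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(sorted(self.theta), names=["transcript_id", "allele"])
        return pd.Series([self.theta[k] for k in sorted(self.theta)], index=idx)


def em_quantify(
    eq: EquivalenceClassSet,
    tol: float = 1e-8,
    max_iter: int = 1000,
    unique_only: bool = False,
) -> EMResult:
    """Resolve multi-mapping read counts into transcript abundances by EM.

    theta is the fraction of reads originating from each transcript-allele.
    E-step: each class count is split among its members proportionally to
    ``theta_t / eff_len_t``.  M-step: theta is the renormalized total
    assigned fraction.  Iteration stops when the maximum absolute change in
    theta falls below ``tol``; the data log-likelihood is monotone
    non-decreasing.  Non-convergence sets ``converged=False`` rather than
    raising.
    """
    classes = dict(eq.classes)
    if unique_only:
        classes = {m: c for m, c in classes.items() if len(m) == 1}
    if not classes:
        raise ValueError("no equivalence classes to quantify")

    keys = sorted(eq.transcript_lengths)
    key_idx = {k: i for i, k in enumerate(keys)}
    T = len(keys)
    eff = np.array([eq.effective_lengths()[k] for k in keys])

    member_idx = [np.array([key_idx[m] for m in sorted(members)]) for members in classes]
    counts = np.array(list(classes.values()), dtype=float)
    n_total = counts.sum()

    theta = np.full(T, 1.0 / T)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        assigned = np.zeros(T)
        ll = 0.0
        for mi, c in zip(member_idx, counts):
            w = theta[mi] / eff[mi]
            tot = w.sum()
            if tot <= 0:
                w = 1.0 / eff[mi]
                tot = w.sum()
            assigned[mi] += c * w / tot
            ll += c * np.log(tot)
        trace.append(float(ll))
        new_theta = assigned / n_total
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", RuntimeWarning)

    return EMResult(
        theta={k: float(theta[i]) for k, i in key_idx.items()},
        n_iter=n_iter,
        log_likelihood=trace[-1],
        converged=converged,
        loglik_trace=trace,
    )


def gene_tpm(
    em: EMResult | dict[Key, float],
    eq: EquivalenceClassSet,
    gene_map: dict[str, str],
) -> pd.Series:
    """Aggregate transcript-allele abundances to gene-level TPM.

    Read fractions are converted to molar abundances by dividing by the
    effective length, pooled over the M and P alleles of each gene, then
    scaled so the column sums to 1e6.  Raises on a transcript without a gene
    assignment.
    """
    theta = em.theta if isinstance(em, EMResult) else em
    eff = eq.effective_lengths()
    gene_abund: dict[str, float] = {}
    for (tid, allele), th in theta.items():
        gene = gene_map.get(tid)
        if gene is None:
            raise KeyError(f"transcript {tid} has no gene assignment")
        gene_abund[gene] = gene_abund.get(gene, 0.0) + th / eff[(tid, allele)]
    total = sum(gene_abund.values())
    if total <= 0:
        raise ValueError("all abundances are zero; cannot scale to TPM")
    tpm = pd.Series(
        {g: 1e6 * a / total for g, a in sorted(gene_abund.items())}, name="tpm"
    )
    tpm.index.name = "gene_id"
    return tpm


def quantify_sample(
    reads,
    diploid,
    max_mismatches: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    unique_only: bool = False,
) -> tuple[pd.Series, EMResult, EquivalenceClassSet]:
    """Convenience wrapper: reads -> equivalence classes -> EM -> gene TPM."""
    eq = compat_map(reads, diploid, max_mismatches=max_mismatches)
    em = em_quantify(eq, tol=tol, max_iter=max_iter, unique_only=unique_only)
    tpm = gene_tpm(em, eq, diploid.gene_map())
    return tpm, em, eq
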