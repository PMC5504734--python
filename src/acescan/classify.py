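"""Read ingestion, QC, ace pre-filtering, fragment scanning and counting.

The classification core is exact substring matching: a read is susceptible
at a site if it contains that site's susceptible fragment (on either
strand), resistant if it contains a resistant fragment, and ambiguous if it
contains both (ambiguous reads are reported but excluded from the frequency
denominator).  The per-site resistance frequency is

    resistant_reads / (resistant_reads + susceptible_reads)

and is None (not 0) when no read covers the site: absence of evidence is
not evidence of susceptibility.

Before scanning, reads are shortlisted to plausible ace transcripts with a
k-mer membership pre-filter (default: >= 2 shared 15-mers with the reference
CDS set on either strand); pre-mapped SAM input is also accepted, in which
case unmapped records are ignored and reverse-strand records are restored
to read orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from ._seq import reverse_complement
from .fragments import RESISTANT, SUSCEPTIBLE, FragmentIndex
from .reference import AceReference

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"

DEFAULT_Q30_THRESHOLD = 0.85
DEFAULT_K = 15
DEFAULT_MIN_SHARED_KMERS = 2


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; qualities are Phred scores (None for FASTA)."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )


@dataclass(frozen=True)
class QcReport:
    total_reads: int
    total_bases: int
    q30_fraction: float | None  # None when qualities are unavailable
    threshold: float
    passed: bool
    computable: bool


@dataclass(frozen=True)
class SiteCounts:
    site_id: str
    susceptible_reads: int
    resistant_reads: int
    ambiguous_reads: int

    @property
    def resistance_frequency(self) -> float | None:
        return resistance_frequency(self.resistant_reads, self.susceptible_reads)


# ---------------------------------------------------------------------------
# ingestion


def read_fastx(path: str | Path) -> Iterator[ReadRecord]:
    """FASTQ or FASTA, optionally gzip-compressed (Phred+33 qualities)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            quals = entry.get_quality_array()
            yield ReadRecord(
                read_id=entry.name,
                sequence=entry.sequence.upper(),
                qualities=None if quals is None else tuple(quals),
            )


def read_sam(path: str | Path) -> Iterator[ReadRecord]:
    """SAM/BAM records; unmapped entries are skipped, reverse-strand entries
    are reverse-complemented back to read orientation before scanning."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            quals = rec.query_qualities
            if rec.is_reverse:
                seq = reverse_complement(seq)
                quals = quals[::-1] if quals is not None else None
            yield ReadRecord(
                read_id=rec.query_name,
                sequence=seq.upper(),
                qualities=None if quals is None else tuple(quals),
            )


def read_any(path: str | Path, fmt: str = "auto") -> Iterator[ReadRecord]:
    path = Path(path)
    if fmt == "auto":
        suffixes = [s.lower() for s in path.suffixes]
        if suffixes and suffixes[-1] in (".sam", ".bam"):
            fmt = "sam"
        else:
            fmt = "fastx"
    if fmt in ("sam", "bam"):
        return read_sam(path)
    if fmt in ("fastx", "fastq", "fasta"):
        return read_fastx(path)
    raise ValueError(f"unknown read format {fmt!r}")


# ---------------------------------------------------------------------------
# QC


def compute_q30(
    reads: Iterable[ReadRecord], threshold: float = DEFAULT_Q30_THRESHOLD
) -> QcReport:
    """Fraction of bases with Phred >= 30; the dataset passes at >= threshold.

    Reads without qualities contribute bases but no Q30 information; if no
    read carries qualities the report is flagged not computable (the pipeline
    then warns and proceeds).
    """
    total_reads = total_bases = q30_bases = scored_bases = 0
    for read in reads:
        total_reads += 1
        total_bases += len(read.sequence)
        if read.qualities is not None:
            scored_bases += len(read.qualities)
            q30_bases += sum(1 for q in read.qualities if q >= 30)
    if total_reads == 0:
        raise ValueError("no reads")
    if scored_bases == 0:
        return QcReport(total_reads, total_bases, None, threshold, False, False)
    frac = q30_bases / scored_bases
    return QcReport(total_reads, total_bases, frac, threshold, frac >= threshold, True)


# ---------------------------------------------------------------------------
# pre-filter (mapping-stage replacement)


def reference_kmers(references: Iterable[AceReference], k: int = DEFAULT_K) -> set[str]:
    """All k-mers of the reference CDS set, both strands."""
    kmers: set[str] = set()
    for ref in references:
        for seq in (ref.cds, reverse_complement(ref.cds)):
            kmers.update(seq[i : i + k] for i in range(len(seq) - k + 1))
    return kmers


def prefilter_reads(
    reads: Iterable[ReadRecord],
    references: Iterable[AceReference],
    k: int = DEFAULT_K,
    min_shared_kmers: int = DEFAULT_MIN_SHARED_KMERS,
) -> Iterator[ReadRecord]:
    """Shortlist reads sharing >= min_shared_kmers k-mers with the references.

    Stands in for the mapping stage of an aligner-based pipeline: exact
    k-mer membership on either strand, input order preserved.
    """
    kmers = reference_kmers(references, k)
    any_long_enough = False
    for read in reads:
        seq = read.sequence
        if len(seq) < k:
            continue
        any_long_enough = True
        shared = sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] in kmers)
        if shared >= min_shared_kmers:
            yield read
    if not any_long_enough:
        logger.warning("k=%d exceeds every read length; no reads pass the pre-filter", k)


# ---------------------------------------------------------------------------
# scanning and counting


def scan_read(read: ReadRecord, index: FragmentIndex) -> list[tuple[str, str]]:
    """Per-site allele calls for one read by exact fragment containment.

    Both strands are covered because the index stores reverse complements.
    A read containing both alleles of one site is called ambiguous there.
    """
    per_site: dict[str, set[str]] = {}
    seq = read.sequence
    for length in index.fragment_lengths:
        for i in range(len(seq) - length + 1):
            hit = index.lookup(seq[i : i + length])
            if hit is not None:
                site_id, allele = hit
                per_site.setdefault(site_id, set()).add(allele)
    calls = []
    for site_id in sorted(per_site):
        alleles = per_site[site_id]
        calls.append((site_id, AMBIGUOUS if len(alleles) > 1 else next(iter(alleles))))
    return calls


def scan_read_naive(read: ReadRecord, index: FragmentIndex) -> list[tuple[str, str]]:
    """Reference implementation: test every indexed fragment with `in`.

    Kept as an independent cross-check of :func:`scan_read`.
    """
    per_site: dict[str, set[str]] = {}
    for fragment, (site_id, allele) in index.entries.items():
        if fragment in read.sequence:
            per_site.setdefault(site_id, set()).add(allele)
    return [
        (site_id, AMBIGUOUS if len(a) > 1 else next(iter(a)))
        for site_id, a in sorted(per_site.items())
    ]


def count_sites(
    per_read_calls: Iterable[list[tuple[str, str]]],
    site_ids: Iterable[str] | None = None,
) -> list[SiteCounts]:
    """Tally per-site susceptible/resistant/ambiguous reads.

    `site_ids` lists the sites to report (zero-coverage sites then appear
    with frequency None); by default only sites with hits are reported.
    """
    tallies: dict[str, dict[str, int]] = {}
    if site_ids is not None:
        for sid in site_ids:
            tallies[sid] = {SUSCEPTIBLE: 0, RESISTANT: 0, AMBIGUOUS: 0}
    for calls in per_read_calls:
        for site_id, allele in calls:
            site = tallies.setdefault(
                site_id, {SUSCEPTIBLE: 0, RESISTANT: 0, AMBIGUOUS: 0}
            )
            site[allele] += 1
    return [
        SiteCounts(
            site_id=sid,
            susceptible_reads=t[SUSCEPTIBLE],
            resistant_reads=t[RESISTANT],
            ambiguous_reads=t[AMBIGUOUS],
        )
        for sid, t in tallies.items()
    ]


def resistance_frequency(resistant: int, susceptible: int) -> float | None:
    """resistant / (resistant + susceptible); None when the denominator is 0."""
    if resistant < 0 or susceptible < 0:
        raise ValueError("counts must be non-negative")
    denominator = resistant + susceptible
    if denominator == 0:
        return None
    return resistant / denominator


def classify_reads(
    reads: Iterable[ReadRecord],
    index: FragmentIndex,
) -> list[SiteCounts]:
    """Scan a read stream and tally every indexed site (convenience wrapper)."""
    return count_sites((scan_read(r, index) for r in reads), site_ids=index.site_ids)
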