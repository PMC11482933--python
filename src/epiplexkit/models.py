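"""Core data types shared across the pipeline.

Coordinates are 0-based, half-open everywhere in memory; 1-based output formats
(GTF, VCF) convert at the serialization boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Iterable, Optional

Interval = tuple[int, int]

FEATURE_PRECEDENCE = ("3'UTR", "5'UTR", "CDS-exon", "ncRNA-exon", "intron")


def _span_contains(intervals: Iterable[Interval], pos: int) -> bool:
    return any(s <= pos < e for s, e in intervals)


@dataclass(frozen=True)
class Transcript:
    """A transcript with genomic exon structure and inferred UTRs.

    ``exons`` are sorted, non-overlapping genomic intervals.  ``cds``, ``utr5``
    and ``utr3`` are genomic interval lists (empty for non-coding transcripts).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def classify(self, pos: int) -> Optional[str]:
        """Feature label at a genomic position, or None if outside the span."""
        if not (self.start <= pos < self.end):
            return None
        if _span_contains(self.utr3, pos):
            return "3'UTR"
        if _span_contains(self.utr5, pos):
            return "5'UTR"
        in_exon = _span_contains(self.exons, pos)
        if in_exon:
            if self.is_coding:
                # exonic, not UTR -> coding exon
                return "CDS-exon"
            return "ncRNA-exon"
        return "intron"

    def cds_genomic_span(self) -> Optional[Interval]:
        """Genomic [start, end) from first to last CDS base (introns included)."""
        if not self.cds:
            return None
        return (min(s for s, _ in self.cds), max(e for _, e in self.cds))


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_ids: tuple[str, ...]


class TranscriptModel:
    """Gene/transcript/exon/UTR structure used for annotation and profiles."""

    def __init__(self, genes: dict[str, Gene], transcripts: dict[str, Transcript]):
        self.genes = genes
        self.transcripts = transcripts
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self._by_chrom.values():
            glist.sort(key=lambda g: (g.start, g.gene_id))
        self._starts = {c: [g.start for g in gl] for c, gl in self._by_chrom.items()}

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        glist = self._by_chrom.get(chrom, [])
        i = bisect.bisect_right(self._starts.get(chrom, []), pos)
        # genes are short relative to chromosomes here; linear back-scan is fine
        hits = [g for g in glist[:i] if g.start <= pos < g.end]
        return hits

    def transcripts_at(self, chrom: str, pos: int) -> list[Transcript]:
        out = []
        for g in self.genes_at(chrom, pos):
            for tid in g.transcript_ids:
                t = self.transcripts[tid]
                if t.start <= pos < t.end:
                    out.append(t)
        return out

    @classmethod
    def from_gtf(cls, path: str) -> "TranscriptModel":
        from .gtf import load_gtf

        return load_gtf(path)


@dataclass(frozen=True)
class ModificationSite:
    """A planted (or inferred) modified base on the transcript strand."""

    chrom: str
    pos: int  # 0-based genomic position of the modified A
    strand: str
    modification: str  # "m6A" | "inosine" | "standard"
    stoichiometry: float
    transcript_id: str = ""
    context: str = ""  # 5-mer on the transcript strand for m6A sites


@dataclass
class AlignedFragment:
    """A deduplicatable aligned insert with its barcode annotations."""

    ref: str
    start: int
    end: int
    strand: str
    mbc: str  # resolved modification label
    umi: str
    name: str = ""
    sample_role: str = "enrichment"  # enrichment | solution_control
    mean_qual: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"fragment {self.name}: start {self.start} >= end {self.end}")


@dataclass
class TaggedRead:
    """A read pair after MBC/UMI extraction and quality trimming."""

    name: str
    mbc_seq: str
    mbc_label: Optional[str]  # None -> undetermined
    umi: str
    insert_seq: str
    insert_qual: str
    mate_seq: str = ""
    mate_qual: str = ""


@dataclass
class Peak:
    """An enrichment peak for one modification."""

    ref: str
    start: int
    end: int
    summit: int
    modification: str
    raw_enrichment: float
    fold_enrichment: float = 0.0
    depth: int = 0  # deduplicated enrichment fragments covering the summit
    control_depth: int = 0
    strand: str = "."
    name: str = ""
    high_confidence: bool = False
    gene_id: str = ""
    feature: str = ""

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start},{self.end})")

    def overlaps(self, other: "Peak") -> bool:
        return self.ref == other.ref and self.start < other.end and other.start < self.end

    def with_fold(self, factor: float) -> "Peak":
        return replace(self, fold_enrichment=self.raw_enrichment * factor)


@dataclass(frozen=True)
class VariantSite:
    """Per-base A->G evidence (transcript strand) under an inosine peak."""

    chrom: str
    pos: int  # 0-based; VCF output adds 1
    strand: str
    ref_base: str  # genomic (plus-strand) reference base: A on '+', T on '-'
    alt_base: str  # G on '+', C on '-'
    depth: int
    alt_count: int
    peak_name: str

    @property
    def rate(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0
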