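"""Native A-to-G variant detection under inosine peaks.

Inosine base-pairs like guanosine, so edited adenosines are read as G; on the
opposite genomic strand this appears as T-to-C.  A small pileup engine walks
CIGAR-aligned reads restricted to peak intervals, with a configurable depth
cap and base-quality floor, and sites are reported when the transcript-strand
A-to-G rate reaches ``min_rate`` (default 10%) at depth strictly greater than
``min_depth_exclusive`` (default 5).  VCF output is 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

from .models import Peak, VariantSite

log = logging.getLogger(__name__)

DEFAULT_MAX_DEPTH = 20000
DEFAULT_MIN_BASEQ = 13
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGTN"


@dataclass
class PileupColumn:
    ref: str
    pos: int                      # 0-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=dict)  # A/C/G/T/N
    deletions: int = 0
    fwd_counts: dict[str, int] = field(default_factory=dict)
    rev_counts: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values()) + self.deletions


def pileup(reads: Iterable[pysam.AlignedSegment], reference_seqs: dict[str, str],
           regions: list[tuple[str, int, int]],
           max_depth: int = DEFAULT_MAX_DEPTH,
           min_baseq: int = DEFAULT_MIN_BASEQ) -> Iterator[PileupColumn]:
    """Per-base base counts restricted to regions.

    ``reads`` may come from ``pysam.AlignmentFile.fetch`` or any iterable of
    aligned segments.  A read with a malformed/absent CIGAR is skipped and
    counted.  Once a column reaches ``max_depth`` further reads do not add to
    it.  Bases below ``min_baseq`` are ignored.
    """
    regions = sorted(regions)
    masks: dict[str, list[tuple[int, int]]] = {}
    for ref, s, e in regions:
        masks.setdefault(ref, []).append((s, e))

    # per-region count matrices: (length, 5 bases) + deletions + strand splits
    mats = {(ref, s, e): {
        "counts": np.zeros((e - s, 5), dtype=np.int64),
        "dels": np.zeros(e - s, dtype=np.int64),
        "fwd": np.zeros((e - s, 5), dtype=np.int64),
        "depth": np.zeros(e - s, dtype=np.int64),
    } for ref, s, e in regions}

    skipped = 0
    for rec in reads:
        if rec.is_unmapped or rec.reference_name not in masks:
            continue
        try:
            pairs = rec.get_aligned_pairs()
        except (ValueError, TypeError):
            skipped += 1
            continue
        if not pairs:
            skipped += 1
            continue
        seq = rec.query_sequence or ""
        quals = rec.query_qualities
        rev = rec.is_reverse
        for s, e in masks[rec.reference_name]:
            if rec.reference_end <= s or rec.reference_start >= e:
                continue
            m = mats[(rec.reference_name, s, e)]
            for qpos, rpos in pairs:
                if rpos is None or not (s <= rpos < e):
                    continue
                i = rpos - s
                if m["depth"][i] >= max_depth:
                    continue
                if qpos is None:  # deletion in the read
                    m["dels"][i] += 1
                    m["depth"][i] += 1
                    continue
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                bi = _BASE_IDX.get(seq[qpos].upper(), 4)
                m["counts"][i, bi] += 1
                m["depth"][i] += 1
                if not rev:
                    m["fwd"][i, bi] += 1
    if skipped:
        log.warning("pileup: skipped %d read(s) with unusable CIGAR", skipped)

    for ref, s, e in regions:
        m = mats[(ref, s, e)]
        refseq = reference_seqs[ref]
        for i in range(e - s):
            if m["depth"][i] == 0:
                continue
            counts = {b: int(m["counts"][i, j]) for b, j in _BASE_IDX.items()}
            fwd = {b: int(m["fwd"][i, j]) for b, j in _BASE_IDX.items()}
            rev_counts = {b: counts[b] - fwd[b] for b in counts}
            yield PileupColumn(ref=ref, pos=s + i, ref_base=refseq[s + i].upper(),
                               counts=counts, deletions=int(m["dels"][i]),
                               fwd_counts=fwd, rev_counts=rev_counts)


def call_ag_sites(columns: Iterable[PileupColumn], peaks: list[Peak],
                  min_rate: float = 0.10,
                  min_depth_exclusive: int = 5) -> list[VariantSite]:
    """Report transcript-strand A->G sites under inosine peaks.

    A site qualifies when its reference base is A on the peak's transcript
    strand (T on the genomic plus strand for '-' peaks), the alt rate is at
    least ``min_rate`` and the depth strictly exceeds ``min_depth_exclusive``.
    """
    ipeaks = [p for p in peaks if p.modification == "inosine"]
    sites: list[VariantSite] = []
    for col in columns:
        owners = [p for p in ipeaks if p.ref == col.ref and p.start <= col.pos < p.end]
        if not owners:
            continue
        peak = owners[0]
        strand = peak.strand if peak.strand in "+-" else "+"
        ref_base, alt_base = ("A", "G") if strand == "+" else ("T", "C")
        if col.ref_base != ref_base:
            continue
        depth = col.depth
        alt = col.counts.get(alt_base, 0)
        if depth > min_depth_exclusive and depth > 0 and alt / depth >= min_rate:
            sites.append(VariantSite(
                chrom=col.ref, pos=col.pos, strand=strand,
                ref_base=ref_base, alt_base=alt_base,
                depth=depth, alt_count=alt, peak_name=peak.name))
    return sites


def peak_variant_support(peaks: list[Peak], sites: list[VariantSite]
                         ) -> tuple[dict[str, VariantSite | None], float]:
    """Best A->G site per inosine peak and the global support fraction."""
    ipeaks = [p for p in peaks if p.modification == "inosine"]
    best: dict[str, VariantSite | None] = {p.name: None for p in ipeaks}
    for s in sites:
        cur = best.get(s.peak_name)
        if cur is None or s.rate > cur.rate:
            best[s.peak_name] = s
    if not ipeaks:
        return best, 0.0
    frac = sum(v is not None for v in best.values()) / len(ipeaks)
    return best, frac


def write_vcf(sites: list[VariantSite], path: str, contigs: dict[str, int]) -> None:
    """Minimal VCF 4.2 (1-based) with rate/depth/peak INFO fields.

    Sites are reported as A->G on the transcript strand; REF/ALT carry the
    genomic plus-strand bases (T->C for minus-strand peaks), with the strand
    in INFO.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=epiplexkit\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt base count">\n')
        fh.write('##INFO=<ID=RATE,Number=1,Type=Float,Description="Variant rate (alt/depth)">\n')
        fh.write('##INFO=<ID=PEAK,Number=1,Type=String,Description="Owning inosine peak">\n')
        fh.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Transcript strand">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            info = (f"DP={s.depth};AC={s.alt_count};RATE={s.rate:.4f};"
                    f"PEAK={s.peak_name};STRAND={s.strand}")
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref_base}\t{s.alt_base}\t.\tPASS\t{info}\n")
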