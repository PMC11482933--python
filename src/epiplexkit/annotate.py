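"""Peak annotation against gene models, metagene and DRACH motif-shift profiles.

The metagene folds every transcript into a fixed 5'UTR | CDS | 3'UTR axis
(default 30/60/30 bins); intronic summits count within the CDS segment using
the genomic span of the CDS, so intron-resident signal (typical of inosine)
lands in the CDS portion of the profile.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .models import FEATURE_PRECEDENCE, Peak, Transcript, TranscriptModel
from .seq import revcomp

log = logging.getLogger(__name__)

#: DRACH consensus on the sense strand (U written as T): D R A C H.
DRACH_RE = re.compile(r"(?=([AGT][AG]AC[ACT]))")


def drach_scan(sequence: str) -> list[int]:
    """0-based start positions of every (possibly overlapping) DRACH 5-mer."""
    return [m.start() for m in DRACH_RE.finditer(sequence.upper())]


def assign_feature(peak: Peak, model: TranscriptModel) -> tuple[str, str]:
    """(feature label, gene id) for a peak, judged at its summit.

    When the summit hits several transcripts the highest-precedence label wins
    (3'UTR > 5'UTR > CDS-exon > ncRNA-exon > intron); gene-id ties break
    lexicographically.
    """
    hits = []
    for t in model.transcripts_at(peak.ref, peak.summit):
        lab = t.classify(peak.summit)
        if lab is not None:
            hits.append((FEATURE_PRECEDENCE.index(lab), t.gene_id, lab, t.transcript_id))
    if not hits:
        return "intergenic", ""
    hits.sort()
    _, gene_id, label, _tid = hits[0]
    return label, gene_id


def _best_transcript(peak: Peak, model: TranscriptModel) -> tuple[Transcript, str] | None:
    hits = []
    for t in model.transcripts_at(peak.ref, peak.summit):
        lab = t.classify(peak.summit)
        if lab is not None:
            hits.append((FEATURE_PRECEDENCE.index(lab), t.gene_id, t.transcript_id, lab, t))
    if not hits:
        return None
    hits.sort(key=lambda h: h[:3])
    return hits[0][4], hits[0][3]


@dataclass
class MetageneProfile:
    modification: str
    bins: tuple[int, int, int]
    density: np.ndarray  # length sum(bins); sums to 1 when any peak mapped
    n_mapped: int = 0
    n_unmapped: int = 0

    def segment_mass(self, segment: str) -> float:
        b5, bc, b3 = self.bins
        sl = {"5'UTR": slice(0, b5), "CDS": slice(b5, b5 + bc),
              "3'UTR": slice(b5 + bc, b5 + bc + b3)}[segment]
        return float(self.density[sl].sum())


def _segment_fraction(t: Transcript, pos: int, label: str) -> tuple[str, float] | None:
    """Map a genomic position to (segment, fractional position 5'->3')."""
    def frac_in(intervals, p):
        total = sum(e - s for s, e in intervals)
        if total == 0:
            return None
        off = 0
        for s, e in sorted(intervals):
            if s <= p < e:
                off += p - s
                break
            if p >= e:
                off += e - s
        f = off / total
        return f if t.strand == "+" else 1.0 - (off + 1) / total

    if label in ("5'UTR", "3'UTR"):
        f = frac_in(t.utr5 if label == "5'UTR" else t.utr3, pos)
        return (label, f) if f is not None else None
    if label in ("CDS-exon", "intron", "ncRNA-exon"):
        span = t.cds_genomic_span()
        if span is None:  # non-coding: whole transcript counts as the CDS axis
            span = (t.start, t.end)
        s, e = span
        p = min(max(pos, s), e - 1)
        f = (p - s) / (e - s)
        if t.strand == "-":
            f = 1.0 - (p - s + 1) / (e - s)
        return ("CDS", f)
    return None


def metagene(peaks: list[Peak], model: TranscriptModel,
             bins: tuple[int, int, int] = (30, 60, 30),
             modification: str = "") -> MetageneProfile:
    """Density of peak summits over the concatenated 5'UTR|CDS|3'UTR axis."""
    b5, bc, b3 = bins
    counts = np.zeros(b5 + bc + b3)
    n_mapped = n_unmapped = 0
    offsets = {"5'UTR": (0, b5), "CDS": (b5, bc), "3'UTR": (b5 + bc, b3)}
    for p in peaks:
        bt = _best_transcript(p, model)
        if bt is None:
            n_unmapped += 1
            continue
        t, label = bt
        sf = _segment_fraction(t, p.summit, label)
        if sf is None:
            n_unmapped += 1
            continue
        seg, f = sf
        off, nb = offsets[seg]
        counts[off + min(int(f * nb), nb - 1)] += 1
        n_mapped += 1
    total = counts.sum()
    density = counts / total if total > 0 else counts
    return MetageneProfile(modification, bins, density, n_mapped, n_unmapped)


@dataclass
class MotifShiftProfile:
    window: int
    edges: np.ndarray       # histogram bin edges over [-window, window]
    density: np.ndarray     # summit-to-nearest-DRACH distances
    null_density: np.ndarray
    n_peaks: int = 0
    n_null: int = 0

    def central_enrichment(self, halfwidth: int = 10) -> float:
        """Ratio of observed to null mass within |distance| <= halfwidth."""
        centers = (self.edges[:-1] + self.edges[1:]) / 2
        sel = np.abs(centers) <= halfwidth
        obs = self.density[sel].sum()
        null = self.null_density[sel].sum()
        return float(obs / null) if null > 0 else float("inf")


def _nearest_drach_distance(seqs: dict[str, str], chrom: str, pos: int,
                            strand: str, window: int) -> int | None:
    """Signed transcript-strand distance from pos to the nearest DRACH A."""
    seq = seqs[chrom]
    lo, hi = max(0, pos - window - 4), min(len(seq), pos + window + 5)
    sub = seq[lo:hi]
    if strand == "-":
        sub = revcomp(sub)
    best = None
    for m in drach_scan(sub):
        a_local = m + 2  # methylated-A position within the motif
        # map back to genomic coordinates on the scanned strand
        a = lo + a_local if strand == "+" else hi - 1 - a_local
        d = a - pos if strand == "+" else pos - a
        if abs(d) <= window and (best is None or abs(d) < abs(best)):
            best = d
    return best


def motif_shift(peaks: list[Peak], seqs: dict[str, str], model: TranscriptModel,
                window: int = 500, n_null: int = 2000,
                seed: int = 0, bin_width: int = 10) -> MotifShiftProfile:
    """Distance-to-nearest-DRACH profile for peak summits vs a transcriptome null.

    The null draws positions uniformly from gene spans and computes the same
    statistic, so motif clustering at summits shows up as central enrichment
    over the gray-curve baseline.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(-window, window + bin_width, bin_width)

    def profile(points: list[tuple[str, int, str]]) -> tuple[np.ndarray, int]:
        dists = []
        for chrom, pos, strand in points:
            d = _nearest_drach_distance(seqs, chrom, pos, strand, window)
            if d is not None:
                dists.append(d)
        h, _ = np.histogram(dists, bins=edges)
        tot = h.sum()
        return (h / tot if tot else h.astype(float)), len(dists)

    obs_points = []
    for p in peaks:
        strand = p.strand
        if strand == ".":
            genes = model.genes_at(p.ref, p.summit)
            strand = genes[0].strand if genes else "+"
        obs_points.append((p.ref, p.summit, strand))

    genes = sorted(model.genes.values(), key=lambda g: g.gene_id)
    null_points = []
    if genes:
        spans = np.array([g.end - g.start for g in genes], dtype=float)
        pgene = spans / spans.sum()
        gi = rng.choice(len(genes), size=n_null, p=pgene)
        for i in gi:
            g = genes[int(i)]
            null_points.append((g.chrom, int(rng.integers(g.start, g.end)), g.strand))

    density, n_obs = profile(obs_points)
    null_density, n_nul = profile(null_points)
    if n_obs == 0 or n_nul == 0:
        log.warning("motif_shift: empty profile (no DRACH within the window)")
    return MotifShiftProfile(window, edges, density, null_density, n_obs, n_nul)


def write_metagene_tsv(profile: MetageneProfile, path: str) -> None:
    b5, bc, b3 = profile.bins
    labels = ["5'UTR"] * b5 + ["CDS"] * bc + ["3'UTR"] * b3
    with open(path, "w") as fh:
        fh.write("bin\tsegment\tdensity\n")
        for i, (lab, d) in enumerate(zip(labels, profile.density)):
            fh.write(f"{i}\t{lab}\t{d:.6g}\n")


def write_motif_shift_tsv(profile: MotifShiftProfile, path: str) -> None:
    centers = (profile.edges[:-1] + profile.edges[1:]) / 2
    with open(path, "w") as fh:
        fh.write("distance\tdensity\tnull_density\n")
        for c, d, n in zip(centers, profile.density, profile.null_density):
            fh.write(f"{c:.0f}\t{d:.6g}\t{n:.6g}\n")
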