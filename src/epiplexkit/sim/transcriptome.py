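"""Synthetic transcriptome generation.

Builds a single-chromosome genome of ``n_genes`` genes laid end to end with
intergenic gaps.  Each gene has a 5'UTR, a CDS that may be split by introns,
and a 3'UTR; the UTR/CDS partition is applied to the exonic (mature) length and
introns are inserted only inside the CDS so UTRs stay contiguous.  Coordinates
in the emitted FASTA and GTF are mutually consistent.
"""

from __future__ import annotations

import numpy as np

from ..models import Gene, Transcript, TranscriptModel
from .config import SimConfig

BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, length)].tobytes().decode()


def build_transcriptome(config: SimConfig) -> tuple[TranscriptModel, dict[str, str]]:
    """Generate gene models plus the genome sequence they live on.

    Returns the TranscriptModel and a ``{chrom: sequence}`` dict.  Fully
    determined by ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 101)))
    f5, fc, f3 = config.utr_fractions
    chrom = "chr1"

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    cursor = int(rng.integers(*config.intergenic_gap_range))

    for gi in range(config.n_genes):
        gid = f"gene{gi + 1:03d}"
        tid = f"tx{gi + 1:03d}"
        exonic = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        l5 = int(round(f5 * exonic))
        l3 = int(round(f3 * exonic))
        lcds = exonic - l5 - l3
        if lcds < 60:
            raise ValueError("utr_fractions leave too little CDS for this gene length")
        strand = "+" if rng.random() < 0.5 else "-"

        n_exons = int(rng.integers(config.n_exons_range[0], config.n_exons_range[1] + 1))
        n_introns = n_exons - 1
        # intron insertion points, strictly inside the CDS so UTRs stay
        # contiguous; in genomic-left coordinates the upstream block is the
        # 5'UTR on '+' genes and the 3'UTR on '-' genes
        left_utr = l5 if strand == "+" else l3
        if n_introns > 0:
            lo, hi = left_utr + 20, left_utr + lcds - 20
            cuts = np.sort(rng.choice(np.arange(lo, hi), size=n_introns, replace=False))
        else:
            cuts = np.array([], dtype=int)
        intron_lens = [int(rng.integers(*config.intron_length_range)) for _ in range(n_introns)]

        # mature coordinate -> genomic coordinate, walking exon blocks
        block_bounds = [0, *cuts.tolist(), exonic]
        exons: list[tuple[int, int]] = []
        g = cursor
        mature_to_genomic_offsets: list[tuple[int, int, int]] = []  # (m_start, m_end, g_start)
        for bi in range(len(block_bounds) - 1):
            m_s, m_e = block_bounds[bi], block_bounds[bi + 1]
            exons.append((g, g + (m_e - m_s)))
            mature_to_genomic_offsets.append((m_s, m_e, g))
            g += (m_e - m_s)
            if bi < n_introns:
                g += intron_lens[bi]
        gene_start, gene_end = cursor, g

        def project(m_s: int, m_e: int) -> tuple[tuple[int, int], ...]:
            """Project a mature interval onto genomic exon blocks."""
            out = []
            for bm_s, bm_e, bg in mature_to_genomic_offsets:
                s = max(m_s, bm_s)
                e = min(m_e, bm_e)
                if s < e:
                    out.append((bg + (s - bm_s), bg + (e - bm_s)))
            return tuple(out)

        # mature coordinates run 5'->3'; on '-' genes the 5' end is the
        # genomic right, so flip which mature slice is which UTR
        if strand == "+":
            utr5 = project(0, l5)
            cds = project(l5, l5 + lcds)
            utr3 = project(l5 + lcds, exonic)
        else:
            utr3 = project(0, l3)
            cds = project(l3, l3 + lcds)
            utr5 = project(l3 + lcds, exonic)

        transcripts[tid] = Transcript(
            transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
            exons=tuple(exons), cds=cds, utr5=utr5, utr3=utr3)
        genes[gid] = Gene(gid, chrom, strand, gene_start, gene_end, (tid,))
        cursor = gene_end + int(rng.integers(*config.intergenic_gap_range))

    genome_len = cursor
    seqs = {chrom: _random_sequence(rng, genome_len)}
    return TranscriptModel(genes, transcripts), seqs
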