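"""GTF reading/writing for the gene models the pipeline annotates against.

Writing targets the Ensembl dialect (``gene_id``/``transcript_id`` attributes);
reading goes through :mod:`gffutils` so that externally produced GTFs work too.
"""

from __future__ import annotations

import gffutils

from .models import Gene, Transcript, TranscriptModel

_FEATURE_ORDER = {"gene": 0, "transcript": 1, "exon": 2, "CDS": 3,
                  "five_prime_utr": 4, "three_prime_utr": 5}


def write_gtf(model: TranscriptModel, path: str, source: str = "epiplexkit") -> None:
    """Serialize a TranscriptModel as 1-based inclusive GTF."""

    def line(chrom, feat, start, end, strand, attrs):
        a = " ".join(f'{k} "{v}";' for k, v in attrs)
        return f"{chrom}\t{source}\t{feat}\t{start + 1}\t{end}\t.\t{strand}\t.\t{a}\n"

    with open(path, "w") as fh:
        for gid in sorted(model.genes, key=lambda g: (model.genes[g].chrom, model.genes[g].start)):
            g = model.genes[gid]
            fh.write(line(g.chrom, "gene", g.start, g.end, g.strand, [("gene_id", gid)]))
            for tid in g.transcript_ids:
                t = model.transcripts[tid]
                attrs = [("gene_id", gid), ("transcript_id", tid)]
                fh.write(line(t.chrom, "transcript", t.start, t.end, t.strand, attrs))
                for s, e in t.exons:
                    fh.write(line(t.chrom, "exon", s, e, t.strand, attrs))
                for s, e in t.cds:
                    fh.write(line(t.chrom, "CDS", s, e, t.strand, attrs))
                for s, e in t.utr5:
                    fh.write(line(t.chrom, "five_prime_utr", s, e, t.strand, attrs))
                for s, e in t.utr3:
                    fh.write(line(t.chrom, "three_prime_utr", s, e, t.strand, attrs))


def load_gtf(path: str) -> TranscriptModel:
    """Parse a GTF into a TranscriptModel (coordinates converted to 0-based)."""
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, Transcript] = {}
    gene_children: dict[str, list[str]] = {}
    gene_meta: dict[str, tuple[str, str, int, int]] = {}

    for tr in db.features_of_type("transcript"):
        tid = tr.attributes["transcript_id"][0]
        gid = tr.attributes["gene_id"][0]
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(tr, featuretype=("exon", "CDS", "five_prime_utr", "three_prime_utr")):
            iv = (child.start - 1, child.end)
            {"exon": exons, "CDS": cds,
             "five_prime_utr": utr5, "three_prime_utr": utr3}[child.featuretype].append(iv)
        transcripts[tid] = Transcript(
            transcript_id=tid,
            gene_id=gid,
            chrom=tr.seqid,
            strand=tr.strand,
            exons=tuple(sorted(exons)),
            cds=tuple(sorted(cds)),
            utr5=tuple(sorted(utr5)),
            utr3=tuple(sorted(utr3)),
        )
        gene_children.setdefault(gid, []).append(tid)

    for gn in db.features_of_type("gene"):
        gid = gn.attributes["gene_id"][0]
        gene_meta[gid] = (gn.seqid, gn.strand, gn.start - 1, gn.end)

    genes: dict[str, Gene] = {}
    for gid, tids in gene_children.items():
        if gid in gene_meta:
            chrom, strand, s, e = gene_meta[gid]
        else:  # gene row absent: infer from transcripts
            ts = [transcripts[t] for t in tids]
            chrom, strand = ts[0].chrom, ts[0].strand
            s, e = min(t.start for t in ts), max(t.end for t in ts)
        genes[gid] = Gene(gid, chrom, strand, s, e, tuple(sorted(tids)))
    return TranscriptModel(genes, transcripts)
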