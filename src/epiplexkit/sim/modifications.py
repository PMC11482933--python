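"""Planting ground-truth modification sites on a synthetic transcriptome.

m6A sites go on DRACH-matching adenosines (transcript strand) with a
configurable 3'UTR bias; inosine sites go on adenosines in introns and UTRs,
reflecting the intron/UTR-skewed footprint of ADAR editing in enrichment data.
Sites of all modifications are kept at least ``min_site_spacing`` nt apart so
the planted landscape is resolvable by a peak-width assay.
"""

from __future__ import annotations

import logging

import numpy as np

from ..annotate import drach_scan
from ..models import ModificationSite, TranscriptModel
from ..seq import revcomp
from .config import SimConfig

log = logging.getLogger(__name__)


def _transcript_strand_base(seqs, t, pos: int) -> str:
    b = seqs[t.chrom][pos]
    return b if t.strand == "+" else revcomp(b)


def _m6a_candidates(model: TranscriptModel, seqs: dict[str, str],
                    edge: int = 0) -> list[tuple]:
    """(chrom, pos, strand, tid, feature, context) for every exonic DRACH A.

    ``edge`` keeps candidates clear of transcript termini, where coverage
    truncation makes a planted site's summit poorly localizable.
    """
    out = []
    for tid, t in sorted(model.transcripts.items()):
        gseq = seqs[t.chrom]
        sense = gseq[t.start:t.end] if t.strand == "+" else revcomp(gseq[t.start:t.end])
        for m in drach_scan(sense):
            a_sense = m + 2  # modified A sits at position 3 of the 5-mer
            pos = t.start + a_sense if t.strand == "+" else t.end - 1 - a_sense
            if not (t.start + edge <= pos < t.end - edge):
                continue
            feature = t.classify(pos)
            if feature in ("5'UTR", "CDS-exon", "3'UTR", "ncRNA-exon"):
                out.append((t.chrom, pos, t.strand, tid, feature, sense[m:m + 5]))
    return out


def _inosine_candidates(model: TranscriptModel, seqs: dict[str, str],
                        edge: int = 0) -> list[tuple]:
    out = []
    for tid, t in sorted(model.transcripts.items()):
        for pos in range(t.start + edge, t.end - edge):
            feature = t.classify(pos)
            if feature in ("intron", "5'UTR", "3'UTR") and \
                    _transcript_strand_base(seqs, t, pos) == "A":
                out.append((t.chrom, pos, t.strand, tid, feature, ""))
    return out


def _pick(rng, candidates, n, weights_by_feature, chosen_positions, spacing):
    """Draw up to n sites honouring feature weights and minimum spacing."""
    by_feature: dict[str, list] = {}
    for c in candidates:
        by_feature.setdefault(c[4], []).append(c)
    features = sorted(by_feature)
    picked, skipped = [], 0
    for _ in range(n):
        wts = np.array([weights_by_feature.get(f, 0.0) for f in features], dtype=float)
        # fall back to uniform over populated features if weights vanish
        avail = np.array([len(by_feature[f]) > 0 for f in features])
        wts = np.where(avail, wts, 0.0)
        if wts.sum() == 0:
            wts = avail.astype(float)
        if wts.sum() == 0:
            skipped += n - len(picked)
            break
        feat = features[int(rng.choice(len(features), p=wts / wts.sum()))]
        pool = by_feature[feat]
        # try a bounded number of draws to satisfy the spacing constraint
        placed = False
        for _attempt in range(200):
            if not pool:
                break
            i = int(rng.integers(len(pool)))
            cand = pool[i]
            if all(abs(cand[1] - p) >= spacing for p in chosen_positions):
                picked.append(cand)
                chosen_positions.append(cand[1])
                pool.pop(i)
                placed = True
                break
            pool.pop(i)
        if not placed:
            skipped += 1
    return picked, skipped


def plant_modifications(
    model: TranscriptModel,
    seqs: dict[str, str],
    config: SimConfig,
    n_m6a: int | None = None,
    n_inosine: int | None = None,
) -> list[ModificationSite]:
    """Place m6A and inosine sites; returns sites sorted by position.

    Counts default to ``density * exonic kb`` per modification.  Sites that
    cannot be placed (no legal motif/position, or spacing exhausted) are
    skipped with a logged count.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 102)))
    exonic_kb = sum(t.mature_length() for t in model.transcripts.values()) / 1000.0
    if n_m6a is None:
        n_m6a = config.n_m6a_sites if config.n_m6a_sites is not None \
            else int(round(config.m6a_site_density * exonic_kb))
    if n_inosine is None:
        n_inosine = config.n_inosine_sites if config.n_inosine_sites is not None \
            else int(round(config.inosine_site_density * exonic_kb))

    chosen_positions: list[int] = []
    sites: list[ModificationSite] = []

    m6a_weights = {"3'UTR": config.m6a_utr3_bias}
    rest = 1.0 - config.m6a_utr3_bias
    for f in ("5'UTR", "CDS-exon", "ncRNA-exon"):
        m6a_weights[f] = rest / 3.0
    picked, skipped = _pick(rng, _m6a_candidates(model, seqs, config.min_edge_distance), n_m6a,
                            m6a_weights, chosen_positions, config.min_site_spacing)
    if skipped:
        log.warning("m6A planting: %d requested site(s) skipped (no legal DRACH position)", skipped)
    lo, hi = config.stoichiometry_range
    for chrom, pos, strand, tid, _feat, ctx in picked:
        sites.append(ModificationSite(chrom, pos, strand, "m6A",
                                      float(rng.uniform(lo, hi)), tid, ctx))

    picked, skipped = _pick(rng, _inosine_candidates(model, seqs, config.min_edge_distance), n_inosine,
                            dict(config.inosine_feature_weights),
                            chosen_positions, config.min_site_spacing)
    if skipped:
        log.warning("inosine planting: %d requested site(s) skipped", skipped)
    for chrom, pos, strand, tid, _feat, ctx in picked:
        sites.append(ModificationSite(chrom, pos, strand, "inosine",
                                      float(rng.uniform(lo, hi)), tid, ctx))

    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def write_truth_bed(sites: list[ModificationSite], path: str) -> None:
    """BED6+2: chrom, start, end, name, score, strand, modification, stoichiometry."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\tsite{i + 1}\t0\t{s.strand}\t"
                     f"{s.modification}\t{s.stoichiometry:.4f}\n")


def read_truth_bed(path: str) -> list[ModificationSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(ModificationSite(f[0], int(f[1]), f[5], f[6], float(f[7])))
    return sites
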