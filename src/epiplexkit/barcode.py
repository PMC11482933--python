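"""MBC/UMI extraction, demultiplexing, deduplication and MBC-level downsampling.

Read 2 begins with the modification barcode (MBC) followed by the UMI; both
are removed from the sequence and kept as tags.  MBCs are matched against a
whitelist with <=1 Hamming-distance error correction; ambiguous or distant
barcodes route the read to "undetermined".  After alignment, fragments are
deduplicated on (reference, start, strand, MBC, UMI) — position-aware by
default, with a positionless (MBC, UMI) mode behind a flag.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pysam

from .models import AlignedFragment, TaggedRead
from .sim.config import DEFAULT_WHITELIST

log = logging.getLogger(__name__)


@dataclass
class ReadLayout:
    """Where the barcodes sit and how inserts are trimmed."""

    mbc_length: int = 8
    umi_length: int = 10
    min_insert: int = 30          # trimmed inserts shorter than this are removed
    qtrim_window: int = 4         # 3' sliding-window quality trim
    qtrim_min_mean: float = 20.0


@dataclass
class Rejection:
    name: str
    reason: str  # layout_underflow | short


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def correct_mbc(observed: str, whitelist: dict[str, str], max_dist: int = 1) -> str | None:
    """Resolve an observed barcode to a whitelist label, or None.

    The match must be unique at the smallest distance <= max_dist.
    """
    best_label, best_d, ties = None, max_dist + 1, 0
    for bc, label in whitelist.items():
        d = hamming(observed, bc)
        if d < best_d:
            best_label, best_d, ties = label, d, 1
        elif d == best_d:
            ties += 1
    if best_label is None or best_d > max_dist or ties > 1:
        return None
    return best_label


def quality_trim_3p(quals: list[int], window: int = 4, min_mean: float = 20.0) -> int:
    """Return the kept length after 3' sliding-window quality trimming.

    Windows ending at the 3' end are dropped while their mean quality is below
    ``min_mean``; remaining trailing bases individually below the threshold
    are then stripped so the kept read ends on a confident base.
    """
    n = len(quals)
    while n > 0:
        w = quals[max(0, n - window):n]
        if sum(w) / len(w) >= min_mean:
            break
        n -= 1
    while n > 0 and quals[n - 1] < min_mean:
        n -= 1
    return n


def extract_and_trim(read1: tuple[str, str, str], read2: tuple[str, str, str],
                     layout: ReadLayout,
                     whitelist: dict[str, str] | None = None) -> TaggedRead | Rejection:
    """Extract MBC+UMI from read 2 and quality-trim the read-1 insert.

    ``read1``/``read2`` are (name, sequence, quality-string) tuples.
    """
    whitelist = whitelist if whitelist is not None else DEFAULT_WHITELIST
    name, seq1, qual1 = read1
    _, seq2, qual2 = read2
    bc_len = layout.mbc_length + layout.umi_length
    if len(seq2) < bc_len:
        return Rejection(name, "layout_underflow")
    mbc_seq = seq2[:layout.mbc_length]
    umi = seq2[layout.mbc_length:bc_len]
    label = correct_mbc(mbc_seq, whitelist)

    q = [ord(c) - 33 for c in qual1]
    keep = quality_trim_3p(q, layout.qtrim_window, layout.qtrim_min_mean)
    if keep < layout.min_insert:
        return Rejection(name, "short")
    return TaggedRead(
        name=name, mbc_seq=mbc_seq, mbc_label=label, umi=umi,
        insert_seq=seq1[:keep], insert_qual=qual1[:keep],
        mate_seq=seq2[bc_len:], mate_qual=qual2[bc_len:])


def _fastq_pairs(r1_path: str, r2_path: str):
    with pysam.FastxFile(r1_path) as f1, pysam.FastxFile(r2_path) as f2:
        for e1, e2 in zip(f1, f2):
            yield (e1.name, e1.sequence, e1.quality), (e2.name, e2.sequence, e2.quality)


def demux_fastq(r1_path: str, r2_path: str, layout: ReadLayout,
                whitelist: dict[str, str] | None = None,
                out_prefix: str | None = None) -> dict:
    """Demultiplex a FASTQ pair by MBC; optionally write per-label FASTQs.

    Output reads carry the UMI appended to the read name (``name_UMI``); the
    insert written is the trimmed read-1 sequence.  Returns per-label and
    rejection counts.
    """
    whitelist = whitelist if whitelist is not None else DEFAULT_WHITELIST
    counts: Counter = Counter()
    writers = {}
    if out_prefix is not None:
        labels = list(dict.fromkeys(whitelist.values())) + ["undetermined"]
        writers = {lab: gzip.open(f"{out_prefix}.{lab}.fastq.gz", "wt") for lab in labels}
    try:
        for r1, r2 in _fastq_pairs(r1_path, r2_path):
            res = extract_and_trim(r1, r2, layout, whitelist)
            if isinstance(res, Rejection):
                counts[f"rejected_{res.reason}"] += 1
                continue
            lab = res.mbc_label or "undetermined"
            counts[lab] += 1
            if writers:
                writers[lab].write(f"@{res.name}_{res.umi}\n{res.insert_seq}\n+\n{res.insert_qual}\n")
    finally:
        for w in writers.values():
            w.close()
    counts["total"] = sum(v for k, v in counts.items() if not k.startswith("total"))
    return dict(counts)


# --------------------------------------------------------------------------
# aligned-fragment handling

def fragments_from_sam(path: str, sample_role: str = "enrichment",
                       mbc_tag: str = "MB", umi_tag: str = "RX") -> list[AlignedFragment]:
    """Load aligned reads (with barcode tags) as fragments."""
    out = []
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                continue
            quals = rec.query_qualities
            out.append(AlignedFragment(
                ref=rec.reference_name, start=rec.reference_start,
                end=rec.reference_end, strand="-" if rec.is_reverse else "+",
                mbc=str(rec.get_tag(mbc_tag)), umi=str(rec.get_tag(umi_tag)),
                name=rec.query_name, sample_role=sample_role,
                mean_qual=float(np.mean(quals)) if quals is not None else 0.0))
    return out


def _dedup_key(fr: AlignedFragment, position_aware: bool):
    if position_aware:
        return (fr.ref, fr.start, fr.strand, fr.mbc, fr.umi)
    return (fr.mbc, fr.umi)


def deduplicate(fragments: list[AlignedFragment], position_aware: bool = True
                ) -> tuple[list[AlignedFragment], dict]:
    """Collapse PCR duplicates by (reference, start, strand, MBC, UMI).

    The representative is the fragment with the highest mean base quality;
    ties break by lexicographic read name.  The report gives pre/post counts
    per MBC.
    """
    best: dict[tuple, AlignedFragment] = {}
    pre: Counter = Counter()
    for fr in fragments:
        pre[fr.mbc] += 1
        key = _dedup_key(fr, position_aware)
        cur = best.get(key)
        if cur is None or (-fr.mean_qual, fr.name) < (-cur.mean_qual, cur.name):
            best[key] = fr
    unique = sorted(best.values(), key=lambda f: (f.ref, f.start, f.end, f.name))
    post = Counter(f.mbc for f in unique)
    report = {mbc: {"pre": pre[mbc], "post": post[mbc]} for mbc in sorted(pre)}
    return unique, report


def split_by_mbc(fragments: list[AlignedFragment]) -> dict[str, list[AlignedFragment]]:
    """Partition fragments by modification barcode label; counts conserved."""
    out: dict[str, list[AlignedFragment]] = defaultdict(list)
    for fr in fragments:
        out[fr.mbc].append(fr)
    return dict(out)


def downsample_equal_mbc(fragment_sets: dict[str, list[AlignedFragment]],
                         seed: int) -> dict[str, list[AlignedFragment]]:
    """Subsample every sample to the minimum per-MBC count across samples.

    Sampling is without replacement and reproducible for a given seed.  An MBC
    with zero fragments in any sample is downsampled to zero everywhere (with
    a warning).
    """
    if len(fragment_sets) < 2:
        raise ValueError("downsampling requires >= 2 samples")
    mbcs = sorted({fr.mbc for frs in fragment_sets.values() for fr in frs})
    per = {name: split_by_mbc(frs) for name, frs in fragment_sets.items()}
    out: dict[str, list[AlignedFragment]] = {name: [] for name in fragment_sets}
    for mbc in mbcs:
        target = min(len(per[name].get(mbc, [])) for name in fragment_sets)
        if target == 0:
            log.warning("MBC %s has zero fragments in at least one sample; "
                        "downsampled to zero everywhere", mbc)
            continue
        for si, name in enumerate(sorted(fragment_sets)):
            pool = sorted(per[name].get(mbc, []), key=lambda f: f.name)
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(int(seed), 105, si, mbcs.index(mbc))))
            idx = rng.choice(len(pool), size=target, replace=False)
            out[name].extend(pool[int(i)] for i in sorted(idx))
    for name in out:
        out[name].sort(key=lambda f: (f.ref, f.start, f.end, f.name))
    return out
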