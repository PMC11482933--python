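"""Paired enrichment / solution-control library simulation with ground truth.

Fragments are drawn from contiguous gene-span (pre-mRNA) coordinates with
lengths ~ Normal(frag_len_mean, frag_len_sd) truncated at >= 1.  Each molecule
carries, per overlapped modification site, a Bernoulli(stoichiometry)
modification status.  The enrichment library captures molecules with weight
1 + (capture_enrichment - 1) * (#modified sites) and assigns the MBC of the
capturing bead; the solution control samples uniformly and assigns MBCs at
random.  Inosine-carrying molecules read G at the edited A (transcript strand)
with probability ``inosine_editing_rate``.

Randomness is organised as independent counter-keyed streams: one stream per
fragment attribute and one per modification site, all derived from
``SeedSequence`` entropy tuples.  Consequently removing one modification's
sites leaves every other fragment's coordinates, acceptance decision and MBC
unchanged — the two modification channels are decoupled by construction, as
they are in the assay.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pysam

from ..models import ModificationSite, TranscriptModel
from ..seq import FastqWriter, revcomp
from ..spikein import SpikeInReference
from .config import SimConfig

log = logging.getLogger(__name__)

ROLES = ("enrichment", "solution_control")
_ROLE_ID = {"enrichment": 0, "solution_control": 1}
_SRC_ID = {"genome": 0, "spikein": 1}
_STREAMS = {"gene": 0, "len": 1, "pos": 2, "accept": 3, "mbc": 4,
            "umi": 5, "err_r1": 6, "err_r2": 7, "err_sam": 8, "dup": 9}
_LIB_TAG = 104
_BATCH = 32768
_MAX_BATCHES = 512


def _rng(config: SimConfig, replicate: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(config.seed), _LIB_TAG, int(replicate), *map(int, key))))


def _site_rngs(config, replicate, role, src, sites, tag):
    return [_rng(config, replicate, _ROLE_ID[role], _SRC_ID[src], tag, s.pos) for s in sites]


@dataclass
class SimFragment:
    cand_id: int
    ref: str
    start: int
    end: int
    strand: str
    mbc: str
    n_mod: int
    mod_labels: tuple[str, ...] = ()
    edits: tuple[int, ...] = ()  # genomic positions converted A->G (transcript strand)
    source: str = "genome"
    duplicate: bool = False
    name: str = ""


@dataclass
class SimulatedLibrary:
    role: str
    fastq_r1: str
    fastq_r2: str
    sam: str
    truth_tsv: str
    n_fragments: int
    n_reads: int


def _source_tables(model: TranscriptModel, seqs: dict[str, str],
                   spikein: tuple[SpikeInReference, dict[str, str], list[ModificationSite]] | None):
    """Per-source sampling tables: (refs, starts, ends, strands, cum weights)."""
    genes = sorted(model.genes.values(), key=lambda g: g.gene_id)
    gtab = {
        "refs": [g.chrom for g in genes],
        "starts": np.array([g.start for g in genes]),
        "ends": np.array([g.end for g in genes]),
        "strands": np.array([g.strand for g in genes]),
    }
    w = (gtab["ends"] - gtab["starts"]).astype(float)
    gtab["cum"] = np.cumsum(w / w.sum())
    out = {"genome": gtab}
    if spikein is not None:
        ref, sseqs, _ = spikein
        out["spikein"] = {
            "refs": [ref.name],
            "starts": np.array([0]),
            "ends": np.array([ref.length]),
            "strands": np.array(["+"]),
            "cum": np.array([1.0]),
        }
    return out


def sample_fragments(model: TranscriptModel, seqs: dict[str, str],
                     sites: list[ModificationSite], config: SimConfig,
                     role: str = "enrichment", n: int | None = None,
                     replicate: int = 0,
                     spikein=None, source: str = "genome") -> list[SimFragment]:
    """Draw the accepted fragments of one library source (no read synthesis)."""
    config.validate()
    if n is None:
        n = config.n_reads_enrich if role == "enrichment" else config.n_reads_control
    tables = _source_tables(model, seqs, spikein)
    src_sites = [s for s in sites if s.chrom in tables[source]["refs"]] if source == "genome" \
        else [s for s in (spikein[2] if spikein else []) ]
    return _accept_fragments(config, replicate, role, source, tables[source], src_sites, n)


def _accept_fragments(config: SimConfig, replicate: int, role: str, source: str,
                      table: dict, sites: list[ModificationSite], n_target: int
                      ) -> list[SimFragment]:
    if n_target <= 0:
        return []
    rid, sid = _ROLE_ID[role], _SRC_ID[source]
    streams = {name: _rng(config, replicate, rid, sid, tag)
               for name, tag in _STREAMS.items() if name in ("gene", "len", "pos", "accept", "mbc")}
    status_rngs = _site_rngs(config, replicate, role, source, sites, 20)
    edit_rngs = _site_rngs(config, replicate, role, source, sites, 21)

    labels = list(dict.fromkeys(config.whitelist.values()))
    k = config.capture_enrichment
    enriched = role == "enrichment"
    out: list[SimFragment] = []
    offset = 0
    for _batch in range(_MAX_BATCHES):
        B = _BATCH
        gi = np.searchsorted(table["cum"], streams["gene"].random(B), side="right")
        gi = np.clip(gi, 0, len(table["starts"]) - 1)
        gstart, gend = table["starts"][gi], table["ends"][gi]
        span = gend - gstart
        L = np.rint(streams["len"].normal(config.frag_len_mean, config.frag_len_sd, B)).astype(int)
        L = np.maximum(L, 1)
        L = np.minimum(L, span)
        start = gstart + np.floor(streams["pos"].random(B) * (span - L + 1)).astype(int)
        end = start + L

        nmod_by_label = {lab: np.zeros(B, dtype=int) for lab in labels}
        nmod_other = np.zeros(B, dtype=int)  # e.g. the internal-standard mod
        site_mod_masks = []
        for s, st_rng, ed_rng in zip(sites, status_rngs, edit_rngs):
            u = st_rng.random(B)
            ue = ed_rng.random(B)
            cover = (start <= s.pos) & (s.pos < end)
            mod = cover & (u < s.stoichiometry)
            site_mod_masks.append((s, mod, ue))
            if s.modification in nmod_by_label:
                nmod_by_label[s.modification] += mod
            else:
                nmod_other += mod
        nmod_real = sum(nmod_by_label.values())
        nmod_total = nmod_real + nmod_other

        if enriched:
            w = 1.0 + (k - 1.0) * nmod_total
            accept = streams["accept"].random(B) < np.minimum(1.0, w / k)
        else:
            streams["accept"].random(B)  # keep streams aligned across configs
            accept = np.ones(B, dtype=bool)

        u_mbc = streams["mbc"].random(B)
        mbc_idx = np.minimum((u_mbc * len(labels)).astype(int), len(labels) - 1)
        if enriched and labels:
            # modified fragments take the MBC of a capturing bead, chosen
            # proportionally to per-modification modified-site counts
            with np.errstate(invalid="ignore", divide="ignore"):
                cum = np.zeros(B)
                chosen = np.full(B, -1, dtype=int)
                has = nmod_real > 0
                for li, lab in enumerate(labels):
                    cum = cum + np.where(has, nmod_by_label[lab] / np.maximum(nmod_real, 1), 0.0)
                    sel = has & (chosen < 0) & (u_mbc < cum)
                    chosen[sel] = li
                chosen[has & (chosen < 0)] = len(labels) - 1
                mbc_idx = np.where(has, chosen, mbc_idx)

        for i in np.nonzero(accept)[0]:
            if len(out) >= n_target:
                break
            mods, edits = [], []
            for s, mod, ue in site_mod_masks:
                if mod[i]:
                    mods.append(s.modification)
                    if s.modification == "inosine" and ue[i] < config.inosine_editing_rate:
                        edits.append(s.pos)
            out.append(SimFragment(
                cand_id=offset + int(i),
                ref=table["refs"][int(gi[i])],
                start=int(start[i]), end=int(end[i]),
                strand=str(table["strands"][int(gi[i])]),
                mbc=labels[int(mbc_idx[i])],
                n_mod=int(nmod_total[i]),
                mod_labels=tuple(mods), edits=tuple(edits), source=source))
        offset += B
        if len(out) >= n_target:
            return out
    raise RuntimeError(f"could not accept {n_target} fragments in {_MAX_BATCHES} batches")


_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.nonzero(mask)[0]:
        base = chars[i]
        alts = _OTHER.get(base, ["N"])
        chars[i] = alts[int(rng.integers(len(alts)))]
    return "".join(chars)


_B4 = np.frombuffer(b"ACGT", dtype="S1")


def simulate_library(model: TranscriptModel, seqs: dict[str, str],
                     sites: list[ModificationSite],
                     spikein: tuple[SpikeInReference, dict[str, str], list[ModificationSite]],
                     config: SimConfig, outdir: str, replicate: int = 0,
                     prefix: str = "") -> dict[str, SimulatedLibrary]:
    """Simulate both libraries of one replicate and write FASTQ/SAM/truth files."""
    import os

    config.validate()
    os.makedirs(outdir, exist_ok=True)
    spike_ref, spike_seqs, _spike_sites = spikein
    all_seqs = {**seqs, **spike_seqs}
    mbc_by_label = {lab: bc for bc, lab in config.whitelist.items()}
    out: dict[str, SimulatedLibrary] = {}

    for role in ROLES:
        n_target = config.n_reads_enrich if role == "enrichment" else config.n_reads_control
        n_spike = int(round(config.spikein_fraction * n_target))
        n_genomic = n_target - n_spike
        frags = _accept_fragments(config, replicate, role, "genome",
                                  _source_tables(model, seqs, spikein)["genome"],
                                  [s for s in sites], n_genomic)
        frags += _accept_fragments(config, replicate, role, "spikein",
                                   _source_tables(model, seqs, spikein)["spikein"],
                                   list(_spike_sites), n_spike)

        rid = _ROLE_ID[role]
        umi_rng = _rng(config, replicate, rid, 2, _STREAMS["umi"])
        dup_rng = _rng(config, replicate, rid, 2, _STREAMS["dup"])
        err_r1 = _rng(config, replicate, rid, 2, _STREAMS["err_r1"])
        err_r2 = _rng(config, replicate, rid, 2, _STREAMS["err_r2"])
        err_sam = _rng(config, replicate, rid, 2, _STREAMS["err_sam"])

        tag = "e" if role == "enrichment" else "c"
        reads = []  # (frag, name, umi)
        for fr in frags:
            umi = _B4[umi_rng.integers(0, 4, config.umi_length)].tobytes().decode()
            name = f"{prefix}{tag}{replicate}_{fr.source[0]}{fr.cand_id}"
            fr.name = name
            reads.append((fr, name, umi))
            if dup_rng.random() < config.pcr_duplicate_rate:
                reads.append((fr, name + "d", umi))

        base = os.path.join(outdir, f"{prefix}{role}_rep{replicate}")
        paths = SimulatedLibrary(
            role=role,
            fastq_r1=base + "_R1.fastq.gz", fastq_r2=base + "_R2.fastq.gz",
            sam=base + ".sam", truth_tsv=base + "_truth.tsv",
            n_fragments=len(frags), n_reads=len(reads))

        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(s)} for c, s in all_seqs.items()],
        })
        sam_records = []
        with FastqWriter(paths.fastq_r1) as w1, FastqWriter(paths.fastq_r2) as w2, \
                open(paths.truth_tsv, "w", newline="") as tfh:
            tw = csv.writer(tfh, delimiter="\t", lineterminator="\n")
            tw.writerow(["read", "ref", "start", "end", "strand", "mbc", "n_mod",
                         "mods", "edited_positions", "source", "duplicate"])
            for fr, name, umi in reads:
                sense = all_seqs[fr.ref][fr.start:fr.end]
                if fr.strand == "-":
                    sense = revcomp(sense)
                if fr.edits:
                    chars = list(sense)
                    for pos in fr.edits:
                        idx = pos - fr.start if fr.strand == "+" else fr.end - 1 - pos
                        chars[idx] = "G"
                    sense = "".join(chars)
                r1 = _apply_errors(sense[:config.read1_length], err_r1, config.seq_error_rate)
                r2_full = mbc_by_label[fr.mbc] + umi + revcomp(sense)
                r2 = _apply_errors(r2_full[:config.read2_length], err_r2, config.seq_error_rate)
                w1.write(name, r1, "I" * len(r1))
                w2.write(name, r2, "I" * len(r2))

                sam_seq = _apply_errors(sense, err_sam, config.seq_error_rate)
                if fr.strand == "-":
                    sam_seq = revcomp(sam_seq)
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.query_sequence = sam_seq
                a.flag = 16 if fr.strand == "-" else 0
                a.reference_name = fr.ref
                a.reference_start = fr.start
                a.mapping_quality = 60
                a.cigarstring = f"{fr.end - fr.start}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * len(sam_seq))
                a.set_tag("MB", fr.mbc)
                a.set_tag("RX", umi)
                sam_records.append(a)
                tw.writerow([name, fr.ref, fr.start, fr.end, fr.strand, fr.mbc,
                             fr.n_mod, ",".join(fr.mod_labels),
                             ",".join(map(str, fr.edits)), fr.source,
                             int(name.endswith("d"))])

        sam_records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
        with pysam.AlignmentFile(paths.sam, "w", header=header) as sf:
            for a in sam_records:
                sf.write(a)
        out[role] = paths
        log.info("simulated %s rep%d: %d fragments, %d reads",
                 role, replicate, paths.n_fragments, paths.n_reads)
    return out
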