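"""Configured, logged, resumable pipeline runs.

Stages execute in dependency order (simulate -> demux -> align -> dedup ->
spikein -> callpeaks -> filter -> variants -> annotate); each writes a
completion marker, and a re-run skips completed stages until the first stale
one, after which everything downstream is regenerated.  Alignment is
pluggable: supply BAM/SAM files per replicate/role, or let test mode use the
simulator's truth alignments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import shutil
import time
from dataclasses import dataclass, field

import numpy as np
import pysam
import yaml

from . import annotate as anno
from . import confidence, peaks as pk, spikein as spk, variants as var
from .barcode import ReadLayout, deduplicate, demux_fastq, fragments_from_sam, split_by_mbc
from .gtf import write_gtf
from .models import AlignedFragment, Peak, TranscriptModel
from .seq import write_fasta
from .sim import (SimConfig, build_spikein_reference, build_transcriptome,
                  plant_modifications, simulate_library, write_truth_bed)

log = logging.getLogger(__name__)

STAGES = ["simulate", "demux", "align", "dedup", "spikein",
          "callpeaks", "filter", "variants", "annotate"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    layout: ReadLayout = field(default_factory=ReadLayout)
    peak_params: pk.PeakParams = field(default_factory=pk.PeakParams)
    n_replicates: int = 2
    max_fpr: float = confidence.DEFAULT_MAX_FPR
    min_depth: int = confidence.DEFAULT_MIN_DEPTH
    cutoff_grid_size: int = 40
    variant_min_rate: float = 0.10
    variant_min_depth_exclusive: int = 5
    pileup_max_depth: int = var.DEFAULT_MAX_DEPTH
    pileup_min_baseq: int = var.DEFAULT_MIN_BASEQ
    metagene_bins: tuple[int, int, int] = (30, 60, 30)
    alignments: dict = field(default_factory=dict)  # (optional) {"rep0_enrichment": path, ...}

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "RunConfig":
        sim = SimConfig.from_dict(raw.get("sim", {}))
        if seed is not None:
            sim.seed = int(seed)
        layout = ReadLayout(**raw.get("layout", {}))
        ppar = pk.PeakParams(**raw.get("peak_params", {}))
        kwargs = {k: v for k, v in raw.items()
                  if k in cls.__dataclass_fields__ and k not in ("sim", "layout", "peak_params")}
        if "metagene_bins" in kwargs:
            kwargs["metagene_bins"] = tuple(kwargs["metagene_bins"])
        return cls(sim=sim, layout=layout, peak_params=ppar, **kwargs)


# --------------------------------------------------------------------------

class PipelineRun:
    def __init__(self, config: RunConfig, outdir: str):
        self.config = config
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        os.makedirs(self.path("markers"), exist_ok=True)
        self.labels = sorted(set(config.sim.whitelist.values()))
        self._log_fh = None

    # -- paths & bookkeeping
    def path(self, *parts: str) -> str:
        return os.path.join(self.outdir, *parts)

    def stage_dir(self, stage: str) -> str:
        d = self.path(stage if stage != "simulate" else "sim")
        os.makedirs(d, exist_ok=True)
        return d

    def marker(self, stage: str) -> str:
        return self.path("markers", f"{stage}.json")

    def is_done(self, stage: str) -> bool:
        return os.path.exists(self.marker(stage))

    def _mark(self, stage: str, t0: float, stats: dict) -> None:
        with open(self.marker(stage), "w") as fh:
            json.dump({"stage": stage, "elapsed_s": round(time.time() - t0, 2),
                       "stats": stats}, fh, indent=1)
        self._log(f"stage {stage} done: {json.dumps(stats, sort_keys=True)}")

    def _log(self, msg: str) -> None:
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        log.info(msg)
        with open(self.path("run.log"), "a") as fh:
            fh.write(line + "\n")

    # -- shared loaders
    def model(self) -> TranscriptModel:
        return TranscriptModel.from_gtf(self.path("sim", "genes.gtf"))

    def genome(self) -> dict[str, str]:
        out = {}
        with pysam.FastxFile(self.path("sim", "ref.fa")) as fh:
            for rec in fh:
                out[rec.name] = rec.sequence
        return out

    def spike(self):
        return build_spikein_reference(self.config.sim)

    def dedup_fragments(self, rep: int, role: str) -> list[AlignedFragment]:
        path = self.path("dedup", f"fragments_rep{rep}_{role}.tsv")
        out = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                f = line.rstrip("\n").split("\t")
                out.append(AlignedFragment(f[0], int(f[1]), int(f[2]), f[3], f[4], f[5],
                                           name=f[6], sample_role=role, mean_qual=float(f[7])))
        return out

    # -- stages
    def stage_simulate(self) -> dict:
        cfg = self.config.sim
        d = self.stage_dir("simulate")
        model, seqs = build_transcriptome(cfg)
        sites = plant_modifications(model, seqs, cfg)
        spike = self.spike()
        write_fasta({**seqs, **spike[1]}, os.path.join(d, "ref.fa"))
        write_gtf(model, os.path.join(d, "genes.gtf"))
        write_truth_bed(sites, os.path.join(d, "truth_sites.bed"))
        spike[0].write_bed(os.path.join(d, "spikein_segments.bed"))
        stats = {"n_genes": len(model.genes), "n_sites": len(sites)}
        for rep in range(self.config.n_replicates):
            libs = simulate_library(model, seqs, sites, spike, cfg, d, replicate=rep)
            for role, lib in libs.items():
                stats[f"rep{rep}_{role}_reads"] = lib.n_reads
        return stats

    def stage_demux(self) -> dict:
        d = self.stage_dir("demux")
        stats = {}
        for rep in range(self.config.n_replicates):
            for role in ("enrichment", "solution_control"):
                base = self.path("sim", f"{role}_rep{rep}")
                counts = demux_fastq(base + "_R1.fastq.gz", base + "_R2.fastq.gz",
                                     self.config.layout, self.config.sim.whitelist,
                                     out_prefix=os.path.join(d, f"rep{rep}_{role}"))
                with open(os.path.join(d, f"counts_rep{rep}_{role}.json"), "w") as fh:
                    json.dump(counts, fh, indent=1)
                stats[f"rep{rep}_{role}"] = counts
        return stats

    def stage_align(self) -> dict:
        """Pluggable alignment: user-supplied BAM/SAM or the truth alignments."""
        d = self.stage_dir("align")
        stats = {}
        for rep in range(self.config.n_replicates):
            for role in ("enrichment", "solution_control"):
                key = f"rep{rep}_{role}"
                src = self.config.alignments.get(key) or \
                    self.path("sim", f"{role}_rep{rep}.sam")
                if not os.path.exists(src):
                    raise PipelineError(f"missing alignment input: {src}")
                dst = os.path.join(d, f"aligned_{key}.sam")
                shutil.copyfile(src, dst)
                stats[key] = os.path.basename(src)
        return stats

    def stage_dedup(self) -> dict:
        d = self.stage_dir("dedup")
        stats = {}
        for rep in range(self.config.n_replicates):
            for role in ("enrichment", "solution_control"):
                frs = fragments_from_sam(
                    self.path("align", f"aligned_rep{rep}_{role}.sam"), sample_role=role)
                unique, report = deduplicate(frs)
                with open(os.path.join(d, f"fragments_rep{rep}_{role}.tsv"), "w") as fh:
                    fh.write("ref\tstart\tend\tstrand\tmbc\tumi\tname\tmean_qual\n")
                    for fr in unique:
                        fh.write(f"{fr.ref}\t{fr.start}\t{fr.end}\t{fr.strand}\t"
                                 f"{fr.mbc}\t{fr.umi}\t{fr.name}\t{fr.mean_qual:.2f}\n")
                with open(os.path.join(d, f"report_rep{rep}_{role}.json"), "w") as fh:
                    json.dump(report, fh, indent=1)
                stats[f"rep{rep}_{role}"] = {
                    "pre": sum(v["pre"] for v in report.values()),
                    "post": sum(v["post"] for v in report.values())}
        return stats

    def stage_spikein(self) -> dict:
        d = self.stage_dir("spikein")
        ref = self.spike()[0]
        stats = {}
        for rep in range(self.config.n_replicates):
            frames = []
            lib_sizes = {}
            for role in ("enrichment", "solution_control"):
                frs = self.dedup_fragments(rep, role)
                for mbc, sub in split_by_mbc(frs).items():
                    lib_sizes[(role, mbc)] = len(sub)
                spike_frs = [fr for fr in frs if fr.ref == ref.name]
                frames.append(spk.count_spikein(spike_frs, ref))
            import pandas as pd
            counts = pd.concat(frames) if frames else spk.count_spikein([], ref)
            report = spk.SpikeInReport(counts=counts, library_sizes=lib_sizes, ref=ref)
            factors = {}
            for lab in self.labels:
                try:
                    factors[lab] = spk.enrichment_factor(report, lab)
                except spk.SpikeInError as exc:
                    self._log(f"warning: rep{rep} {lab}: {exc}; continuing unscaled")
                    factors[lab] = 1.0
            report.factors = factors
            report.to_json(os.path.join(d, f"report_rep{rep}.json"))
            stats[f"rep{rep}"] = factors
        return stats

    def _factors(self, rep: int) -> dict[str, float]:
        with open(self.path("spikein", f"report_rep{rep}.json")) as fh:
            return json.load(fh)["factors"]

    def stage_callpeaks(self) -> dict:
        d = self.stage_dir("callpeaks")
        model = self.model()
        genome = self.genome()
        spike_name = self.spike()[0].name
        ref_lengths = {c: len(s) for c, s in genome.items() if c != spike_name}
        params = self.config.peak_params
        pk.write_peak_params_json(params, os.path.join(d, "params.json"))
        stats = {}
        for rep in range(self.config.n_replicates):
            factors = self._factors(rep)
            by_role = {}
            for role in ("enrichment", "solution_control"):
                frs = [fr for fr in self.dedup_fragments(rep, role) if fr.ref in ref_lengths]
                by_role[role] = split_by_mbc(frs)
            for lab in self.labels:
                sig_frs = by_role["enrichment"].get(lab, [])
                bg_frs = by_role["solution_control"].get(lab, [])
                sig = pk.build_coverage(sig_frs, ref_lengths)
                bg = pk.build_coverage(bg_frs, ref_lengths)
                all_peaks: list[Peak] = []
                for ref in sorted(ref_lengths):
                    called = pk.call_peaks(sig[ref], bg[ref], params, modification=lab,
                                           name_prefix=f"rep{rep}")
                    all_peaks.extend(called)
                    pk.write_bedgraph(sig[ref], os.path.join(
                        d, f"coverage_rep{rep}_{lab}_{ref}.bedgraph"))
                scaled = pk.scale_peaks(all_peaks, factors)
                # attach transcript strand / gene context from the annotation
                final = []
                for p in scaled:
                    feature, gid = anno.assign_feature(p, model)
                    strand = model.genes[gid].strand if gid else "."
                    final.append(dataclasses.replace(p, strand=strand,
                                                     gene_id=gid, feature=feature))
                pk.write_peaks_bed(final, os.path.join(d, f"peaks_rep{rep}_{lab}.bed"))
                stats[f"rep{rep}_{lab}"] = len(final)
        return stats

    def stage_filter(self) -> dict:
        d = self.stage_dir("filter")
        stats = {}
        for lab in self.labels:
            reps = [pk.read_peaks_bed(self.path("callpeaks", f"peaks_rep{r}_{lab}.bed"))
                    for r in range(self.config.n_replicates)]
            folds = np.array([p.fold_enrichment for ps in reps for p in ps])
            grid = confidence.default_cutoff_grid(folds, n=self.config.cutoff_grid_size)
            cutoff, reason, model = None, "", None
            if self.config.n_replicates >= 2:
                try:
                    points = confidence.fpr_curve(reps[0], reps[1], grid)
                    model = confidence.select_cutoff(
                        confidence.fit_noise_model(points), self.config.max_fpr)
                    cutoff, reason = model.selected_cutoff, model.selection_reason
                except confidence.InsufficientPeaks as exc:
                    self._log(f"warning: {lab}: {exc}; using smallest grid cutoff")
                    cutoff, reason = float(grid[0]), "insufficient_peaks"
                except ValueError as exc:
                    self._log(f"warning: {lab}: noise fit failed ({exc}); smallest cutoff")
                    cutoff, reason = float(grid[0]), "fit_failed"
            else:
                cutoff, reason = float(grid[0]), "single_replicate"
            if model is not None:
                model.to_json(os.path.join(d, f"noise_{lab}.json"))
            else:
                with open(os.path.join(d, f"noise_{lab}.json"), "w") as fh:
                    json.dump({"selected_cutoff": cutoff, "selection_reason": reason}, fh)
            for r, ps in enumerate(reps):
                flagged = confidence.filter_high_confidence(ps, cutoff, self.config.min_depth)
                pk.write_peaks_bed(flagged, os.path.join(d, f"peaks_rep{r}_{lab}.bed"))
                stats[f"rep{r}_{lab}"] = {
                    "cutoff": cutoff, "reason": reason,
                    "high_confidence": sum(p.high_confidence for p in flagged)}
        return stats

    def stage_variants(self) -> dict:
        d = self.stage_dir("variants")
        genome = self.genome()
        peaks = [p for p in pk.read_peaks_bed(self.path("filter", "peaks_rep0_inosine.bed"))
                 if p.high_confidence]
        regions = [(p.ref, p.start, p.end) for p in peaks]
        with pysam.AlignmentFile(self.path("align", "aligned_rep0_enrichment.sam"),
                                 check_sq=False) as af:
            reads = [r for r in af if not r.is_unmapped and
                     str(r.get_tag("MB")) == "inosine"]
        cols = list(var.pileup(reads, genome, regions,
                               max_depth=self.config.pileup_max_depth,
                               min_baseq=self.config.pileup_min_baseq))
        sites = var.call_ag_sites(cols, peaks, self.config.variant_min_rate,
                                  self.config.variant_min_depth_exclusive)
        _best, frac = var.peak_variant_support(peaks, sites)
        var.write_vcf(sites, os.path.join(d, "inosine_ag.vcf"),
                      {c: len(s) for c, s in genome.items()})
        with open(os.path.join(d, "support.json"), "w") as fh:
            json.dump({"n_inosine_peaks": len(peaks), "n_sites": len(sites),
                       "support_fraction": frac}, fh, indent=1)
        return {"n_sites": len(sites), "support_fraction": round(frac, 4)}

    def stage_annotate(self) -> dict:
        d = self.stage_dir("annotate")
        model = self.model()
        genome = self.genome()
        stats = {}
        with open(os.path.join(d, "features.tsv"), "w") as fh:
            fh.write("peak\tmodification\tfeature\tgene_id\tfold_enrichment\thigh_confidence\n")
            for lab in self.labels:
                peaks = pk.read_peaks_bed(self.path("filter", f"peaks_rep0_{lab}.bed"))
                hc = [p for p in peaks if p.high_confidence]
                for p in hc:
                    feature, gid = anno.assign_feature(p, model)
                    fh.write(f"{p.name}\t{lab}\t{feature}\t{gid}\t"
                             f"{p.fold_enrichment:.4g}\t{int(p.high_confidence)}\n")
                prof = anno.metagene(hc, model, self.config.metagene_bins, modification=lab)
                anno.write_metagene_tsv(prof, os.path.join(d, f"metagene_{lab}.tsv"))
                stats[f"{lab}_utr3_mass"] = round(prof.segment_mass("3'UTR"), 4)
                if lab == "m6A":
                    ms = anno.motif_shift(hc, genome, model, seed=self.config.seed)
                    anno.write_motif_shift_tsv(ms, os.path.join(d, "motifshift_m6A.tsv"))
                    stats["m6A_central_motif_enrichment"] = round(ms.central_enrichment(), 3)
        return stats

    # -- driver
    def run(self, force: bool = False, until: str | None = None) -> dict:
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=1, default=str)
        ran_any = force
        results = {}
        for stage in STAGES:
            if until is not None and STAGES.index(stage) > STAGES.index(until):
                break
            if self.is_done(stage) and not ran_any:
                self._log(f"stage {stage}: up to date, skipped")
                continue
            ran_any = True
            if os.path.exists(self.marker(stage)):
                os.remove(self.marker(stage))
            t0 = time.time()
            self._log(f"stage {stage}: running")
            stats = getattr(self, f"stage_{stage}")()
            self._mark(stage, t0, stats)
            results[stage] = stats
        return results


def run_pipeline(config: RunConfig, outdir: str, force: bool = False,
                 until: str | None = None) -> dict:
    return PipelineRun(config, outdir).run(force=force, until=until)
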