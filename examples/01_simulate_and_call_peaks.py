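"""Simulate a toy study and run the full pipeline: simulate -> demux -> dedup
-> spike-in -> peaks -> confidence filter -> variants -> annotation.

Builds a ~50 kb synthetic transcriptome carrying 20 m6A and 10 inosine sites,
sequences paired enrichment/solution-control libraries in two replicates, and
recovers the planted landscape.  Prints per-modification peak counts plus
recall/precision against the planted truth (a summit within 50 nt of a
planted site counts as recovered).
"""

import json
import os
import tempfile

from epiplexkit.peaks import read_peaks_bed
from epiplexkit.pipeline import RunConfig, run_pipeline
from epiplexkit.sim.modifications import read_truth_bed

cfg = RunConfig()
cfg.sim.seed = 1
cfg.sim.n_m6a_sites = 20
cfg.sim.n_inosine_sites = 10

outdir = os.path.join(tempfile.mkdtemp(prefix="epiplex_"), "run")
results = run_pipeline(cfg, outdir)

truth = read_truth_bed(os.path.join(outdir, "sim", "truth_sites.bed"))
print(f"run directory: {outdir}")
for mod in ("m6A", "inosine"):
    planted = [s.pos for s in truth if s.modification == mod]
    peaks = [p for p in read_peaks_bed(os.path.join(outdir, "filter", f"peaks_rep0_{mod}.bed"))
             if p.high_confidence]
    hit = [p for p in peaks if any(abs(p.summit - t) <= 50 for t in planted)]
    recall = sum(any(abs(p.summit - t) <= 50 for p in peaks) for t in planted) / len(planted)
    print(f"{mod:8s} planted={len(planted):3d} high-confidence peaks={len(peaks):3d} "
          f"precision={len(hit) / len(peaks):.2f} recall={recall:.2f}")

with open(os.path.join(outdir, "variants", "support.json")) as fh:
    support = json.load(fh)
print(f"inosine peaks with an A->G site: {support['support_fraction']:.0%} "
      f"({support['n_sites']} sites called)")
print("precision/recall near 1 mean the called summits line up with the "
      "planted sites; the A->G support fraction shows inosine peaks carry "
      "the expected mutation signature.")
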