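"""Compare two conditions: a global 2-fold m6A knockdown versus control.

Condition B carries the same modification landscape as condition A except
every m6A stoichiometry is halved (emulating partial methyltransferase
inhibition).  Peaks are matched across conditions by interval overlap and the
through-origin scatter slope of B versus A summarizes the global change; the
Wilcoxon rank-sum test compares the fold-enrichment distributions.
"""

import dataclasses
import tempfile

from epiplexkit.barcode import deduplicate, fragments_from_sam, split_by_mbc
from epiplexkit.differential import match_peaks, rank_test
from epiplexkit.peaks import build_coverage, call_peaks
from epiplexkit.sim import (SimConfig, build_spikein_reference, build_transcriptome,
                            plant_modifications, simulate_library)

cfg = SimConfig(seed=1, n_m6a_sites=20, n_inosine_sites=10)
model, seqs = build_transcriptome(cfg)
sites_a = plant_modifications(model, seqs, cfg)
sites_b = [dataclasses.replace(s, stoichiometry=s.stoichiometry / 2)
           if s.modification == "m6A" else s for s in sites_a]
spike = build_spikein_reference(cfg)
ref_lengths = {c: len(s) for c, s in seqs.items()}

peak_sets = {}
with tempfile.TemporaryDirectory() as tmp:
    for cond, sites in (("control", sites_a), ("knockdown", sites_b)):
        libs = simulate_library(model, seqs, sites, spike, cfg, f"{tmp}/{cond}")
        by_role = {}
        for role in libs:
            frs, _ = deduplicate(fragments_from_sam(libs[role].sam, role))
            by_role[role] = split_by_mbc([f for f in frs if f.ref in ref_lengths])
        peak_sets[cond] = {}
        for mod in ("m6A", "inosine"):
            sig = build_coverage(by_role["enrichment"].get(mod, []), ref_lengths)
            bg = build_coverage(by_role["solution_control"].get(mod, []), ref_lengths)
            called = call_peaks(sig["chr1"], bg["chr1"], modification=mod)
            for p in called:
                p.fold_enrichment = p.raw_enrichment
            peak_sets[cond][mod] = called

for mod in ("m6A", "inosine"):
    tab = match_peaks({c: peak_sets[c][mod] for c in peak_sets})
    shared = tab[tab["present_control"] & tab["present_knockdown"]]
    x = shared["fe_control"].to_numpy()
    y = shared["fe_knockdown"].to_numpy()
    slope = float((x * y).sum() / (x * x).sum())
    _, p = rank_test(x, y)
    print(f"{mod:8s} shared loci={len(shared):3d} knockdown-vs-control "
          f"slope={slope:.2f} rank-sum p={p:.3g}")
print("a slope well below 1 for m6A with an unchanged inosine slope shows the "
      "knockdown is modification-specific, mirroring a dose-response "
      "inhibitor experiment.")
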