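"""Detect A-to-G editing evidence under inosine peaks with the native pileup.

Inosine base-pairs like G, so edited adenosines appear as A->G mismatches on
the transcript strand (T->C on the opposite genomic strand).  This example
simulates a small library, piles up reads over the planted inosine sites and
reports sites with a variant rate of at least 10% at depth above 5 reads.
"""

import tempfile

import pysam

from epiplexkit.models import Peak
from epiplexkit.sim import (SimConfig, build_spikein_reference, build_transcriptome,
                            plant_modifications, simulate_library)
from epiplexkit.variants import call_ag_sites, peak_variant_support, pileup

cfg = SimConfig(seed=2, n_genes=8, n_reads_enrich=12000, n_reads_control=0)
model, seqs = build_transcriptome(cfg)
sites = plant_modifications(model, seqs, cfg, n_m6a=0, n_inosine=6)
spike = build_spikein_reference(cfg)
with tempfile.TemporaryDirectory() as tmp:
    libs = simulate_library(model, seqs, sites, spike, cfg, tmp)
    with pysam.AlignmentFile(libs["enrichment"].sam, check_sq=False) as af:
        reads = [r for r in af if str(r.get_tag("MB")) == "inosine"]

# stand-in peaks centered on the planted sites (peak calling is shown in
# example 01); strand comes from the owning gene
peaks = [Peak(s.chrom, max(0, s.pos - 75), s.pos + 75, s.pos, "inosine",
              raw_enrichment=1.0, fold_enrichment=10.0, strand=s.strand,
              name=f"ip{i}") for i, s in enumerate(sites)]

columns = pileup(reads, seqs, [(p.ref, p.start, p.end) for p in peaks])
ag_sites = call_ag_sites(columns, peaks)
best, fraction = peak_variant_support(peaks, ag_sites)

print(f"planted inosine sites: {len(sites)}; A->G sites called: {len(ag_sites)}")
for s in ag_sites:
    print(f"  {s.chrom}:{s.pos + 1} {s.ref_base}->{s.alt_base} "
          f"rate={s.rate:.2f} depth={s.depth} (peak {s.peak_name})")
print(f"fraction of inosine peaks with an A->G site: {fraction:.0%}")
print("each reported position is a transcript-strand A read as G in a "
      "stoichiometry-dependent fraction of molecules — the single-base "
      "signature that distinguishes genuine editing from capture noise.")
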