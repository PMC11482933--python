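"""Synthetic spike-in (LMS-style) reference construction.

One reference sequence carrying disjoint segments: one densely modified
segment per modification plus a single internal-standard segment with exactly
one modified base.  The densely modified segments emulate avidity-driven
capture of the spike-in; the internal standard anchors the enrichment-factor
standard curve.
"""

from __future__ import annotations

import numpy as np

from ..models import ModificationSite
from ..spikein import SpikeInReference, SpikeInSegment
from .config import SimConfig
from .transcriptome import _random_sequence

STANDARD_LABEL = "standard"


def build_spikein_reference(
    config: SimConfig,
    ref_name: str = "LMS",
    segment_length: int = 600,
    gap: int = 200,
    site_spacing: int = 30,
) -> tuple[SpikeInReference, dict[str, str], list[ModificationSite]]:
    """Returns (reference with segment map, {name: sequence}, spike-in sites)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, 103)))
    labels = sorted(set(config.whitelist.values()))
    segments: list[SpikeInSegment] = []
    cursor = gap
    for lab in labels:
        segments.append(SpikeInSegment(f"{lab}_segment", cursor, cursor + segment_length, lab))
        cursor += segment_length + gap
    std_len = segment_length // 2
    segments.append(SpikeInSegment("internal_standard", cursor, cursor + std_len, STANDARD_LABEL))
    cursor += std_len + gap
    seq = _random_sequence(rng, cursor)

    sites: list[ModificationSite] = []
    for seg in segments:
        if seg.modification == STANDARD_LABEL:
            mid = (seg.start + seg.end) // 2
            sites.append(ModificationSite(ref_name, mid, "+", STANDARD_LABEL, 1.0))
        else:
            for pos in range(seg.start + site_spacing // 2, seg.end, site_spacing):
                sites.append(ModificationSite(ref_name, pos, "+", seg.modification, 1.0))

    ref = SpikeInReference(
        name=ref_name,
        length=len(seq),
        segments=tuple(segments),
        standard_segment="internal_standard",
        known_stoichiometries={s.name: 1.0 for s in segments if s.modification != STANDARD_LABEL},
    )
    return ref, {ref_name: seq}, sites
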