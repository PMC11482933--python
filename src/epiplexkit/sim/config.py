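"""Simulation configuration.

Defaults emulate the assay's library architecture at desk scale: a ~50 kb toy
transcriptome, ~140 bp fragments, 8 nt modification barcodes (MBC), 10 nt UMIs,
an 8-fold capture boost for modified fragments on beads, and a solution control
that barcodes fragments at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


#: Default MBC whitelist: barcode sequence -> modification label.
DEFAULT_WHITELIST: dict[str, str] = {
    "AACCGGTT": "m6A",
    "TTGGCCAA": "inosine",
}


@dataclass
class SimConfig:
    seed: int = 1
    # transcriptome
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (1200, 2200)  # exonic nt
    utr_fractions: tuple[float, float, float] = (0.10, 0.55, 0.35)  # 5'UTR/CDS/3'UTR
    n_exons_range: tuple[int, int] = (1, 4)
    intron_length_range: tuple[int, int] = (100, 400)
    intergenic_gap_range: tuple[int, int] = (300, 900)
    # modification landscape
    m6a_site_density: float = 0.5      # sites per kb of exonic sequence
    inosine_site_density: float = 0.25
    n_m6a_sites: int | None = None     # explicit counts override the densities
    n_inosine_sites: int | None = None
    m6a_utr3_bias: float = 0.8         # probability an m6A site is drawn from 3'UTRs
    inosine_feature_weights: dict = field(
        default_factory=lambda: {"intron": 0.5, "5'UTR": 0.25, "3'UTR": 0.25})
    stoichiometry_range: tuple[float, float] = (0.5, 1.0)
    min_site_spacing: int = 500        # peak-resolution assay: keep sites separable
    min_edge_distance: int = 200       # keep sites clear of transcript termini, where
                                       # coverage truncation biases summit localization
    # library
    frag_len_mean: float = 140.0
    frag_len_sd: float = 20.0
    mbc_length: int = 8
    umi_length: int = 10
    read1_length: int = 151
    read2_length: int = 71
    n_reads_enrich: int = 40000
    n_reads_control: int = 40000
    capture_enrichment: float = 8.0    # capture-probability multiplier per modified site
    inosine_editing_rate: float = 0.8  # P(read shows G | molecule carries inosine)
    spikein_fraction: float = 0.05
    seq_error_rate: float = 0.001      # uniform substitution rate
    pcr_duplicate_rate: float = 0.15
    whitelist: dict = field(default_factory=lambda: dict(DEFAULT_WHITELIST))

    def validate(self) -> None:
        f5, fc, f3 = self.utr_fractions
        if any(not (0.0 <= f <= 1.0) for f in (f5, fc, f3)) or abs(f5 + fc + f3 - 1.0) > 1e-9:
            raise ValueError("utr_fractions must lie in [0,1] and sum to 1")
        for name in ("m6a_utr3_bias", "inosine_editing_rate", "spikein_fraction",
                     "seq_error_rate", "pcr_duplicate_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.capture_enrichment < 1.0:
            raise ValueError("capture_enrichment must be >= 1")
        lo, hi = self.stoichiometry_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("stoichiometry_range must be within [0,1]")
        if len(set(self.whitelist.values())) != len(self.whitelist):
            raise ValueError("whitelist labels must be unique")
        if any(len(b) != self.mbc_length for b in self.whitelist):
            raise ValueError("whitelist barcodes must match mbc_length")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("gene_length_range", "utr_fractions", "n_exons_range",
                    "intron_length_range", "intergenic_gap_range",
                    "stoichiometry_range"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
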