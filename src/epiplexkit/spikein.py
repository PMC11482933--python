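"""Spike-in (LMS) quantification and per-modification enrichment factors.

The spike-in reference carries modification-specific segments plus one
internal-standard segment with a single modified base.  The enrichment factor
for a modification is a monotone standard curve evaluated at the ratio of
normalized (reads-per-million) counts on its segments to the normalized count
on the internal standard, per sample and MBC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .models import AlignedFragment

log = logging.getLogger(__name__)


class SpikeInError(RuntimeError):
    pass


@dataclass(frozen=True)
class SpikeInSegment:
    name: str
    start: int
    end: int
    modification: str  # modification label, or "standard"


@dataclass(frozen=True)
class SpikeInReference:
    name: str
    length: int
    segments: tuple[SpikeInSegment, ...]
    standard_segment: str
    known_stoichiometries: dict = field(default_factory=dict)

    def __post_init__(self):
        ivs = sorted((s.start, s.end) for s in self.segments)
        for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("spike-in segments must be disjoint")

    def segment_at(self, pos: int) -> str | None:
        """Segment containing pos; midpoints exactly on a boundary belong to
        the left (lower-coordinate) segment by construction of the midpoint."""
        for s in self.segments:
            if s.start <= pos < s.end:
                return s.name
        return None

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for s in self.segments:
                fh.write(f"{self.name}\t{s.start}\t{s.end}\t{s.name}\t0\t+\t{s.modification}\n")


def count_spikein(fragments: Iterable[AlignedFragment],
                  ref: SpikeInReference) -> pd.DataFrame:
    """Count spike-in fragments per (segment, MBC, sample role).

    A fragment straddling two segments is assigned by its midpoint; for
    even-length fragments the midpoint index floors, i.e. ties go left.
    Fragments on an unknown reference raise an error naming the record.
    """
    rows: dict[tuple[str, str, str], int] = {}
    for fr in fragments:
        if fr.ref != ref.name:
            raise SpikeInError(f"fragment {fr.name!r} aligned to unknown spike-in "
                               f"reference {fr.ref!r} (expected {ref.name!r})")
        mid = (fr.start + fr.end - 1) // 2
        seg = ref.segment_at(mid)
        if seg is None:
            continue  # inter-segment filler
        key = (seg, fr.mbc, fr.sample_role)
        rows[key] = rows.get(key, 0) + 1
    idx = pd.MultiIndex.from_tuples(sorted(rows) or [], names=["segment", "mbc", "role"])
    return pd.DataFrame({"count": [rows[k] for k in sorted(rows)]}, index=idx)


# --------------------------------------------------------------------------
# standard curves: pluggable monotone 1-D maps applied to the count ratio

def identity_curve(x: float) -> float:
    return x


def linear_curve(slope: float, intercept: float = 0.0) -> Callable[[float], float]:
    def f(x: float) -> float:
        return slope * x + intercept
    return f


def piecewise_curve_from_tsv(path: str) -> Callable[[float], float]:
    """Two-column TSV (x, y) -> monotone piecewise-linear interpolant."""
    tab = np.loadtxt(path, delimiter="\t", ndmin=2)
    x, y = tab[:, 0], tab[:, 1]
    order = np.argsort(x)
    x, y = x[order], y[order]
    return lambda v: float(np.interp(v, x, y))


@dataclass
class SpikeInReport:
    counts: pd.DataFrame                      # (segment, mbc, role) -> count
    library_sizes: dict[tuple[str, str], int]  # (role, mbc) -> total mapped dedup fragments
    ref: SpikeInReference
    per_mbc: bool = True
    factors: dict = field(default_factory=dict)
    curve_name: str = "identity"

    def normalized(self, segment: str, mbc: str, role: str) -> float:
        """Reads per million mapped deduplicated fragments for the sample."""
        try:
            c = int(self.counts.loc[(segment, mbc, role), "count"])
        except KeyError:
            c = 0
        if self.per_mbc:
            lib = self.library_sizes.get((role, mbc), 0)
        else:
            lib = sum(v for (r, _m), v in self.library_sizes.items() if r == role)
        if lib == 0:
            return 0.0
        return c * 1e6 / lib

    def to_json(self, path: str) -> None:
        payload = {
            "curve": self.curve_name,
            "per_mbc": self.per_mbc,
            "factors": self.factors,
            "counts": [
                {"segment": seg, "mbc": m, "role": r, "count": int(c)}
                for (seg, m, r), c in self.counts["count"].items()
            ],
            "library_sizes": [
                {"role": r, "mbc": m, "size": int(v)}
                for (r, m), v in sorted(self.library_sizes.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def enrichment_factor(report: SpikeInReport, modification: str,
                      curve: Callable[[float], float] = identity_curve,
                      role: str = "enrichment") -> float:
    """Per-modification spike-in scaling factor.

    factor = curve( norm count on mod-specific segments / norm count on the
    internal standard ), computed within the modification's MBC stream.
    Raises SpikeInError("spikein_failed") on zero internal-standard coverage;
    callers may continue unscaled (factor 1) with a warning.
    """
    mod_segments = [s.name for s in report.ref.segments if s.modification == modification]
    if not mod_segments:
        raise SpikeInError(f"no spike-in segment for modification {modification!r}")
    num = sum(report.normalized(seg, modification, role) for seg in mod_segments)
    den = report.normalized(report.ref.standard_segment, modification, role)
    if den <= 0:
        raise SpikeInError("spikein_failed")
    factor = float(curve(num / den))
    if factor <= 0:
        raise SpikeInError(f"standard curve produced non-positive factor {factor}")
    return factor
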