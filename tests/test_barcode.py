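"""Barcode extraction, demultiplexing, deduplication, downsampling."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiplexkit.barcode import (ReadLayout, Rejection, correct_mbc, deduplicate,
                                downsample_equal_mbc, extract_and_trim,
                                quality_trim_3p, split_by_mbc)
from epiplexkit.models import AlignedFragment
from epiplexkit.sim import DEFAULT_WHITELIST, simulate_library

from conftest import small_config

LAYOUT = ReadLayout()
Q40 = "I"


def _read(name, seq, qual=None):
    return (name, seq, qual if qual is not None else Q40 * len(seq))


class TestExtractAndTrim:
    def test_layout_construction_recovers_tags(self):
        insert = "ACGT" * 20
        r2 = "AACCGGTT" + "ACGTACGTAC" + "TTTT"
        res = extract_and_trim(_read("r", insert), _read("r", r2), LAYOUT)
        assert res.mbc_label == "m6A"
        assert res.umi == "ACGTACGTAC"
        assert res.insert_seq == insert
        assert res.mate_seq == "TTTT"

    @pytest.mark.parametrize("keep,kept", [(29, False), (30, True)])
    def test_min_insert_boundary(self, keep, kept):
        # high quality for `keep` bases, then junk that the 3' trimmer removes
        seq = "A" * 50
        qual = Q40 * keep + "#" * (50 - keep)
        r2 = "AACCGGTT" + "ACGTACGTAC" + "T" * 10
        res = extract_and_trim(_read("r", seq, qual), _read("r", r2), LAYOUT)
        if kept:
            assert res.insert_seq == "A" * keep
        else:
            assert isinstance(res, Rejection) and res.reason == "short"

    def test_read2_shorter_than_barcodes_is_layout_underflow(self):
        res = extract_and_trim(_read("r", "A" * 40), _read("r", "ACGT"), LAYOUT)
        assert isinstance(res, Rejection) and res.reason == "layout_underflow"

    def test_quality_trim_keeps_high_quality_prefix(self):
        quals = [40] * 30 + [2] * 10
        assert quality_trim_3p(quals) == 30

    def test_mbc_correction_exhaustive_hamming(self):
        # every 1-substitution neighbour corrects; every 2-substitution
        # neighbour is undetermined (whitelist barcodes are 8 apart)
        for bc, label in DEFAULT_WHITELIST.items():
            assert correct_mbc(bc, DEFAULT_WHITELIST) == label
            for i in range(8):
                for alt in "ACGT":
                    if alt == bc[i]:
                        continue
                    mutated = bc[:i] + alt + bc[i + 1:]
                    assert correct_mbc(mutated, DEFAULT_WHITELIST) == label
            for i, j in itertools.combinations(range(8), 2):
                for ai, aj in itertools.product("ACGT", repeat=2):
                    if ai == bc[i] or aj == bc[j]:
                        continue
                    mutated = list(bc)
                    mutated[i], mutated[j] = ai, aj
                    assert correct_mbc("".join(mutated), DEFAULT_WHITELIST) is None


def _random_fragments(rng, n=500, refs=("chr1", "chr2")):
    out = []
    for i in range(n):
        start = int(rng.integers(0, 50))
        out.append(AlignedFragment(
            ref=str(rng.choice(refs)), start=start, end=start + int(rng.integers(50, 200)),
            strand=str(rng.choice(["+", "-"])),
            mbc=str(rng.choice(["m6A", "inosine"])),
            umi=str(rng.choice(["AAA", "CCC", "GGG"])),
            name=f"r{i}", mean_qual=float(rng.integers(20, 41))))
    return out


class TestDeduplicate:
    def test_identical_key_collapses_to_one(self):
        a = AlignedFragment("chr1", 10, 100, "+", "m6A", "AAA", name="a", mean_qual=30)
        b = AlignedFragment("chr1", 10, 100, "+", "m6A", "AAA", name="b", mean_qual=35)
        unique, report = deduplicate([a, b])
        assert [f.name for f in unique] == ["b"]  # higher mean quality wins
        assert report["m6A"] == {"pre": 2, "post": 1}

    def test_same_position_umi_different_mbc_both_kept(self):
        a = AlignedFragment("chr1", 10, 100, "+", "m6A", "AAA", name="a")
        b = AlignedFragment("chr1", 10, 100, "+", "inosine", "AAA", name="b")
        unique, _ = deduplicate([a, b])
        assert len(unique) == 2

    def test_matches_brute_force_scan(self, rng):
        frags = _random_fragments(rng, n=500)
        unique, _ = deduplicate(frags)
        # O(n^2) oracle: independently group by key, pick best per group
        expected = {}
        for fr in frags:
            key = (fr.ref, fr.start, fr.strand, fr.mbc, fr.umi)
            best = expected.get(key)
            for other in frags:
                okey = (other.ref, other.start, other.strand, other.mbc, other.umi)
                if okey == key and (best is None or
                                    (-other.mean_qual, other.name) < (-best.mean_qual, best.name)):
                    best = other
            expected[key] = best
        assert {f.name for f in unique} == {f.name for f in expected.values()}

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_dedup_is_idempotent(self, seed):
        frags = _random_fragments(np.random.default_rng(seed), n=60)
        once, _ = deduplicate(frags)
        twice, _ = deduplicate(once)
        assert [f.name for f in twice] == [f.name for f in once]


class TestSplitAndDownsample:
    def test_partition_conserves_counts(self, rng):
        frags = _random_fragments(rng, n=120)
        streams = split_by_mbc(frags)
        assert sum(len(v) for v in streams.values()) == 120
        assert set(streams) == {f.mbc for f in frags}

    def test_empty_input_gives_no_streams(self):
        assert split_by_mbc([]) == {}

    def test_partition_is_order_independent(self, rng):
        frags = _random_fragments(rng, n=100)
        shuffled = list(frags)
        rng.shuffle(shuffled)
        a = {k: sorted(f.name for f in v) for k, v in split_by_mbc(frags).items()}
        b = {k: sorted(f.name for f in v) for k, v in split_by_mbc(shuffled).items()}
        assert a == b

    def test_downsample_to_minimum_per_mbc(self, rng):
        sets = {"A": _random_fragments(rng, n=100), "B": _random_fragments(rng, n=80)}
        for f in sets["A"]:
            f.mbc = "m6A"
        for f in sets["B"]:
            f.mbc = "m6A"
        out = downsample_equal_mbc(sets, seed=1)
        assert len(out["A"]) == len(out["B"]) == 80

    def test_downsample_deterministic_and_noop_when_equal(self, rng):
        sets = {"A": _random_fragments(rng, n=90), "B": _random_fragments(rng, n=90)}
        out1 = downsample_equal_mbc(sets, seed=5)
        out2 = downsample_equal_mbc(sets, seed=5)
        assert [f.name for f in out1["A"]] == [f.name for f in out2["A"]]
        for name, frs in sets.items():
            per_mbc_in = {m: len(v) for m, v in split_by_mbc(frs).items()}
            per_mbc_out = {m: len(v) for m, v in split_by_mbc(out1[name]).items()}
            common = {m: min(len(split_by_mbc(sets["A"]).get(m, [])),
                             len(split_by_mbc(sets["B"]).get(m, [])))
                      for m in per_mbc_in}
            assert per_mbc_out == {m: c for m, c in common.items() if c > 0}

    def test_zero_count_mbc_warns_and_empties(self, rng, caplog):
        sets = {"A": _random_fragments(rng, n=40), "B": _random_fragments(rng, n=40)}
        for f in sets["B"]:
            f.mbc = "m6A"  # B has no inosine fragments
        import logging
        with caplog.at_level(logging.WARNING):
            out = downsample_equal_mbc(sets, seed=0)
        assert all(f.mbc != "inosine" for f in out["A"])
        assert any("zero fragments" in r.message for r in caplog.records)


class TestDemuxAccuracy:
    def test_demux_recovers_true_mbc(self, tmp_path, small_world):
        _, model, seqs, sites, spike = small_world
        for err, floor in ((0.0, 1.0), (0.001, 0.99)):
            cfg = small_config(seq_error_rate=err, n_reads_enrich=2500, n_reads_control=0)
            libs = simulate_library(model, seqs, sites, spike, cfg,
                                    str(tmp_path / f"e{err}"))
            lib = libs["enrichment"]
            truth = {}
            with open(lib.truth_tsv) as fh:
                next(fh)
                for line in fh:
                    f = line.rstrip("\n").split("\t")
                    truth[f[0]] = f[5]
            import pysam
            ok = total = 0
            with pysam.FastxFile(lib.fastq_r1) as f1, pysam.FastxFile(lib.fastq_r2) as f2:
                for e1, e2 in zip(f1, f2):
                    res = extract_and_trim((e1.name, e1.sequence, e1.quality),
                                           (e2.name, e2.sequence, e2.quality), LAYOUT)
                    if isinstance(res, Rejection):
                        continue
                    total += 1
                    ok += res.mbc_label == truth[e1.name]
            assert total > 2000
            assert ok / total >= floor
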