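"""Simulator: transcriptome geometry, truth planting, library generation."""

from __future__ import annotations

import gzip
import itertools
import logging

import numpy as np
import pytest
from scipy import stats

from epiplexkit.gtf import write_gtf
from epiplexkit.models import Gene, Transcript, TranscriptModel
from epiplexkit.seq import write_fasta
from epiplexkit.sim import (build_transcriptome, plant_modifications,
                            sample_fragments, simulate_library)

from conftest import small_config


def _file_bytes(path):
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rb") as fh:
        return fh.read()


class TestTranscriptome:
    def test_single_exon_gene_spans_match_fasta(self, tmp_path):
        cfg = small_config(n_genes=1, n_exons_range=(1, 1))
        model, seqs = build_transcriptome(cfg)
        (t,) = model.transcripts.values()
        assert len(t.exons) == 1
        g = model.genes[t.gene_id]
        assert (t.start, t.end) == (g.start, g.end)
        assert t.end <= len(seqs[t.chrom])
        # round-trip through GTF keeps structure
        write_gtf(model, str(tmp_path / "g.gtf"))
        model2 = TranscriptModel.from_gtf(str(tmp_path / "g.gtf"))
        t2 = model2.transcripts[t.transcript_id]
        assert t2.exons == t.exons and t2.cds == t.cds
        assert t2.utr5 == t.utr5 and t2.utr3 == t.utr3

    def test_outputs_byte_identical_for_same_seed(self, tmp_path):
        cfg = small_config(seed=7)
        for d in ("a", "b"):
            model, seqs = build_transcriptome(cfg)
            write_fasta(seqs, str(tmp_path / f"{d}.fa"))
            write_gtf(model, str(tmp_path / f"{d}.gtf"))
        assert _file_bytes(str(tmp_path / "a.fa")) == _file_bytes(str(tmp_path / "b.fa"))
        assert _file_bytes(str(tmp_path / "a.gtf")) == _file_bytes(str(tmp_path / "b.gtf"))

    def test_utr_cds_partition_arithmetic(self):
        # independent arithmetic: fractions (0.1, 0.6, 0.3) of 1000 nt
        cfg = small_config(n_genes=3, gene_length_range=(1000, 1000),
                          utr_fractions=(0.1, 0.6, 0.3))
        model, _ = build_transcriptome(cfg)
        for t in model.transcripts.values():
            l5 = sum(e - s for s, e in t.utr5)
            lc = sum(e - s for s, e in t.cds)
            l3 = sum(e - s for s, e in t.utr3)
            assert (l5, lc, l3) == (100, 600, 300)
            assert t.mature_length() == 1000

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            small_config(utr_fractions=(0.5, 0.6, 0.3))


DRACH_SET = {"".join(p) for p in itertools.product("AGT", "AG", "A", "C", "ACT")}


class TestPlanting:
    def test_planted_m6a_contexts_match_drach_enumeration(self, small_world):
        _, _, _, sites, _ = small_world
        m6a = [s for s in sites if s.modification == "m6A"]
        assert m6a, "expected planted m6A sites"
        for s in m6a:
            assert s.context in DRACH_SET

    def test_inosine_sites_sit_on_transcript_strand_a(self, small_world):
        _, model, seqs, sites, _ = small_world
        for s in sites:
            if s.modification != "inosine":
                continue
            base = seqs[s.chrom][s.pos]
            assert (base == "A") if s.strand == "+" else (base == "T")

    def test_no_drach_available_plants_nothing(self, caplog):
        # hand-built gene over a DRACH-free (all-C) sequence
        t = Transcript("tx1", "g1", "chrC", "+", exons=((0, 600),),
                       cds=((100, 500),), utr5=((0, 100),), utr3=((500, 600),))
        model = TranscriptModel({"g1": Gene("g1", "chrC", "+", 0, 600, ("tx1",))},
                                {"tx1": t})
        cfg = small_config()
        with caplog.at_level(logging.WARNING):
            sites = plant_modifications(model, {"chrC": "C" * 600}, cfg, n_m6a=5, n_inosine=0)
        assert sites == []
        assert any("skipped" in r.message for r in caplog.records)

    def test_full_utr3_bias_puts_all_m6a_in_utr3(self):
        cfg = small_config(m6a_utr3_bias=1.0, min_edge_distance=0, min_site_spacing=100)
        model, seqs = build_transcriptome(cfg)
        sites = plant_modifications(model, seqs, cfg, n_m6a=10, n_inosine=0)
        assert sites
        for s in sites:
            labels = {t.classify(s.pos) for t in model.transcripts_at(s.chrom, s.pos)}
            assert "3'UTR" in labels

    def test_sites_respect_minimum_spacing(self, small_world):
        _, _, _, sites, _ = small_world
        pos = sorted(s.pos for s in sites)
        assert all(b - a >= 500 for a, b in zip(pos, pos[1:]))


class TestLibrary:
    def test_mean_fragment_length_near_140(self, small_world):
        cfg, model, seqs, sites, _ = small_world
        frs = sample_fragments(model, seqs, sites, cfg, role="solution_control", n=10000)
        lens = np.array([f.end - f.start for f in frs])
        sem = lens.std() / np.sqrt(len(lens))
        assert abs(lens.mean() - cfg.frag_len_mean) <= 2 * sem

    def test_zero_editing_rate_leaves_no_edits(self, tmp_path, small_world):
        cfg, model, seqs, sites, spike = small_world
        cfg2 = small_config(inosine_editing_rate=0.0, n_reads_enrich=1500, n_reads_control=0)
        libs = simulate_library(model, seqs, sites, spike, cfg2, str(tmp_path))
        with open(libs["enrichment"].truth_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            col = header.index("edited_positions")
            assert all(line.rstrip("\n").split("\t")[col] == "" for line in fh)

    def test_zero_reads_give_empty_valid_fastq(self, tmp_path, small_world):
        _, model, seqs, sites, spike = small_world
        cfg = small_config(n_reads_enrich=0, n_reads_control=0)
        libs = simulate_library(model, seqs, sites, spike, cfg, str(tmp_path))
        for lib in libs.values():
            assert _file_bytes(lib.fastq_r1) == b""
            assert lib.n_reads == 0

    def test_reads_and_truth_table_conserved(self, tmp_path, small_world):
        cfg, model, seqs, sites, spike = small_world
        cfg = small_config(n_reads_enrich=2000, n_reads_control=2000)
        libs = simulate_library(model, seqs, sites, spike, cfg, str(tmp_path))
        for lib in libs.values():
            with gzip.open(lib.fastq_r1, "rt") as fh:
                fq_names = [l.strip()[1:] for l in itertools.islice(fh, 0, None, 4)]
            with open(lib.truth_tsv) as fh:
                next(fh)
                truth_names = [l.split("\t", 1)[0] for l in fh]
            assert sorted(fq_names) == sorted(truth_names)
            assert len(set(truth_names)) == len(truth_names)

    def test_spikein_fraction_respected(self, tmp_path, small_world):
        cfg, model, seqs, sites, spike = small_world
        cfg = small_config(n_reads_enrich=3000, n_reads_control=0, spikein_fraction=0.1)
        libs = simulate_library(model, seqs, sites, spike, cfg, str(tmp_path))
        with open(libs["enrichment"].truth_tsv) as fh:
            next(fh)
            rows = [l.rstrip("\n").split("\t") for l in fh]
        uniq = {r[0]: r for r in rows if not r[0].endswith("d")}
        n_spike = sum(r[9] == "spikein" for r in uniq.values())
        assert n_spike == round(0.1 * 3000)

    def test_same_seed_gives_byte_identical_fastq(self, tmp_path, small_world):
        _, model, seqs, sites, spike = small_world
        cfg = small_config(n_reads_enrich=800, n_reads_control=800)
        a = simulate_library(model, seqs, sites, spike, cfg, str(tmp_path / "a"))
        b = simulate_library(model, seqs, sites, spike, cfg, str(tmp_path / "b"))
        for role in a:
            assert _file_bytes(a[role].fastq_r1) == _file_bytes(b[role].fastq_r1)
            assert _file_bytes(a[role].fastq_r2) == _file_bytes(b[role].fastq_r2)

    def test_null_capture_makes_libraries_exchangeable(self, small_world):
        # with capture_enrichment = 1 the enrichment library is statistically
        # indistinguishable from the solution control: KS on per-site coverage
        cfg, model, seqs, sites, _ = small_world
        cfg = small_config(capture_enrichment=1.0, n_reads_enrich=6000, n_reads_control=6000)
        cov = {}
        for role in ("enrichment", "solution_control"):
            frs = sample_fragments(model, seqs, sites, cfg, role=role, n=6000)
            cov[role] = [sum(f.start <= s.pos < f.end for f in frs) for s in sites]
        res = stats.ks_2samp(cov["enrichment"], cov["solution_control"])
        assert res.pvalue > 0.01
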