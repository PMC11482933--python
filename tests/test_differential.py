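"""Cross-condition peak matching, correlation, rank test, gene clustering."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epiplexkit.differential import (cluster_gene_scores, correlation,
                                     differential_analysis, gene_scores,
                                     match_peaks, rank_test)
from epiplexkit.models import Peak


def _peak(start, fe, width=100, mod="m6A", gene="", name="p", ref="chr1"):
    return Peak(ref, start, start + width, start + width // 2, mod,
                raw_enrichment=fe, fold_enrichment=fe, gene_id=gene, name=name)


class TestMatchPeaks:
    def test_identical_sets_share_every_locus(self):
        peaks = [_peak(i * 1000, float(i + 1), name=f"p{i}") for i in range(10)]
        tab = match_peaks({"a": peaks, "b": list(peaks)})
        assert len(tab) == 10
        assert tab["present_a"].all() and tab["present_b"].all()
        assert np.allclose(tab["fe_a"], tab["fe_b"])

    def test_disjoint_sets_are_condition_unique(self):
        a = [_peak(i * 1000, 2.0, name=f"a{i}") for i in range(5)]
        b = [_peak(i * 1000 + 500, 3.0, width=100, name=f"b{i}") for i in range(5)]
        tab = match_peaks({"a": a, "b": b})
        assert len(tab) == 10
        assert not (tab["present_a"] & tab["present_b"]).any()

    def test_mixed_modifications_rejected(self):
        with pytest.raises(ValueError):
            match_peaks({"a": [_peak(0, 1.0, mod="m6A")],
                         "b": [_peak(0, 1.0, mod="inosine")]})

    def test_conserves_peak_counts(self, rng):
        sets = {c: [_peak(int(rng.integers(0, 50_000)), float(rng.uniform(1, 10)),
                          width=int(rng.integers(50, 400)), name=f"{c}{i}")
                    for i in range(40)] for c in ("a", "b", "c")}
        tab = match_peaks(sets)
        for c, peaks in sets.items():
            assert tab[f"n_{c}"].sum() == len(peaks)

    def test_matches_brute_force_single_linkage_merge(self, rng):
        sets = {c: [_peak(int(rng.integers(0, 20_000)), 1.0,
                          width=int(rng.integers(50, 300)), name=f"{c}{i}")
                    for i in range(30)] for c in ("a", "b")}
        tab = match_peaks(sets)
        # oracle: union-find over all pairwise overlaps
        all_peaks = [p for ps in sets.values() for p in ps]
        parent = list(range(len(all_peaks)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, p in enumerate(all_peaks):
            for j, q in enumerate(all_peaks):
                if i < j and p.ref == q.ref and p.start < q.end and q.start < p.end:
                    parent[find(i)] = find(j)
        groups = {}
        for i, p in enumerate(all_peaks):
            groups.setdefault(find(i), []).append(p)
        expected = sorted((min(p.start for p in g), max(p.end for p in g))
                          for g in groups.values())
        got = sorted(zip(tab["start"], tab["end"]))
        assert got == expected


class TestCorrelation:
    def test_identical_vectors_give_unit_r_squared(self):
        peaks = [_peak(i * 1000, float(i + 1), name=f"p{i}") for i in range(5)]
        tab = match_peaks({"a": peaks, "b": list(peaks)})
        r, r2 = correlation(tab, "a", "b")
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        a = [_peak(i * 1000, float(i + 1), name=f"a{i}") for i in range(5)]
        b = [_peak(i * 1000, float(5 - i), name=f"b{i}") for i in range(5)]
        tab = match_peaks({"a": a, "b": b})
        r, r2 = correlation(tab, "a", "b")
        assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)

    def test_matches_from_scratch_covariance(self, rng):
        x = rng.uniform(1, 50, 100)
        y = rng.uniform(1, 50, 100)
        a = [_peak(i * 1000, float(v), name=f"a{i}") for i, v in enumerate(x)]
        b = [_peak(i * 1000, float(v), name=f"b{i}") for i, v in enumerate(y)]
        r, _ = correlation(match_peaks({"a": a, "b": b}), "a", "b")
        xm, ym = x - x.mean(), y - y.mean()
        expected = float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_requires_three_shared_loci(self):
        a = [_peak(0, 1.0, name="a0"), _peak(1000, 2.0, name="a1")]
        with pytest.raises(ValueError):
            correlation(match_peaks({"a": a, "b": list(a)}), "a", "b")


class TestRankTest:
    def test_identical_samples_give_p_one(self):
        _, p = rank_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_exact_small_sample_p_value(self):
        # {1,2,3} vs {10,20,30}: the 2 most extreme of C(6,3)=20 arrangements
        _, p = rank_test([1, 2, 3], [10, 20, 30])
        assert p == pytest.approx(0.1)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_common_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=6), r.normal(size=7)
        w1, p1 = rank_test(a, b)
        w2, p2 = rank_test(np.exp(a), np.exp(b))
        assert w1 == w2 and p1 == pytest.approx(p2)

    def test_asymptotic_branch_agrees_with_scipy(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 25)
        _, p = rank_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0])


def _ward_oracle(z: np.ndarray, n_clusters: int) -> list[set[int]]:
    """Brute-force Ward agglomeration via the Lance-Williams recurrence."""
    clusters = {i: {i} for i in range(len(z))}
    d = {(i, j): float(((z[i] - z[j]) ** 2).sum()) / 2.0
         for i in range(len(z)) for j in range(i + 1, len(z))}

    def dist(a, b):
        return d[(a, b) if a < b else (b, a)]

    while len(clusters) > n_clusters:
        (a, b) = min(((i, j) for i in clusters for j in clusters if i < j),
                     key=lambda ij: (dist(*ij), ij))
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters[a] | clusters[b]
        del clusters[b]
        for k in list(clusters):
            if k == a:
                continue
            nk = len(clusters[k])
            new = ((na + nk) * dist(a, k) + (nb + nk) * dist(b, k)
                   - nk * dist(a, b)) / (na + nb + nk)
            d[(min(a, k), max(a, k))] = new
        clusters[a] = merged
    return sorted((sorted(c) for c in clusters.values()))


class TestClustering:
    def _table(self, profiles: dict[str, tuple]):
        peaks = {c: [] for c in ("x", "y", "z")}
        conds = ("x", "y", "z")
        for gi, (gene, vals) in enumerate(sorted(profiles.items())):
            for c, v in zip(conds, vals):
                peaks[c].append(_peak(gi * 5000, float(v), gene=gene,
                                      name=f"{c}{gi}"))
        return match_peaks(peaks)

    def test_identical_profiles_cluster_together(self):
        tab = self._table({"g1": (1, 5, 9), "g2": (1, 5, 9), "g3": (9, 5, 1)})
        out = cluster_gene_scores(tab, ["x", "y", "z"], n_clusters=2)
        assert out.loc["g1", "cluster"] == out.loc["g2", "cluster"]
        assert out.loc["g1", "cluster"] != out.loc["g3", "cluster"]

    def test_k_equals_n_gives_singletons(self):
        tab = self._table({"g1": (1, 2, 3), "g2": (3, 2, 1), "g3": (2, 8, 2)})
        out = cluster_gene_scores(tab, ["x", "y", "z"], n_clusters=3)
        assert len(set(out["cluster"])) == 3

    def test_partition_matches_lance_williams_oracle(self, rng):
        profiles = {f"g{i:02d}": tuple(rng.uniform(1, 20, 3)) for i in range(10)}
        tab = self._table(profiles)
        for k in (2, 3, 4):
            out = cluster_gene_scores(tab, ["x", "y", "z"], n_clusters=k)
            agg = gene_scores(tab, ["x", "y", "z"]).to_numpy()
            mu = agg.mean(axis=1, keepdims=True)
            sd = agg.std(axis=1, keepdims=True)
            z = (agg - mu) / np.where(sd > 0, sd, 1.0)
            expected = _ward_oracle(z, k)
            got = {}
            for i, (g, row) in enumerate(out.iterrows()):
                got.setdefault(row["cluster"], []).append(i)
            assert sorted(sorted(v) for v in got.values()) == expected


def test_differential_analysis_summary(rng):
    a = [_peak(i * 1000, float(rng.uniform(1, 10)), gene=f"g{i % 5}", name=f"a{i}")
         for i in range(20)]
    b = [_peak(i * 1000, float(rng.uniform(1, 10)), gene=f"g{i % 5}", name=f"b{i}")
         for i in range(20)]
    res = differential_analysis({"ctrl": a, "treated": b})
    st_ = res.stats["ctrl_vs_treated"]
    assert st_["n_shared"] == 20
    assert 0.0 <= st_["r_squared"] <= 1.0
    assert 0.0 <= st_["ranksum_p"] <= 1.0


class TestDoseResponseContract:
    def test_halved_m6a_stoichiometry_lowers_scatter_slope(self, tmp_path):
        """Halving every m6A stoichiometry in condition B halves the m6A
        enrichment signal (slope < 1 in the B-vs-A scatter) while leaving the
        inosine channel unchanged (slope ~ 1)."""
        import dataclasses
        from epiplexkit.barcode import deduplicate, fragments_from_sam, split_by_mbc
        from epiplexkit.peaks import build_coverage, call_peaks
        from epiplexkit.sim import (build_spikein_reference, build_transcriptome,
                                    plant_modifications, simulate_library)
        from conftest import toy_config

        cfg = toy_config().sim
        model, seqs = build_transcriptome(cfg)
        sites_a = plant_modifications(model, seqs, cfg, n_m6a=20, n_inosine=10)
        sites_b = [dataclasses.replace(s, stoichiometry=s.stoichiometry / 2)
                   if s.modification == "m6A" else s for s in sites_a]
        spike = build_spikein_reference(cfg)
        ref_lengths = {c: len(s) for c, s in seqs.items()}

        peak_sets: dict[str, dict[str, list]] = {}
        for cond, sites in (("a", sites_a), ("b", sites_b)):
            libs = simulate_library(model, seqs, sites, spike, cfg,
                                    str(tmp_path / cond))
            by_role = {}
            for role in libs:
                frs, _ = deduplicate(fragments_from_sam(libs[role].sam, role))
                by_role[role] = split_by_mbc([f for f in frs if f.ref in ref_lengths])
            peak_sets[cond] = {}
            for mod in ("m6A", "inosine"):
                sig = build_coverage(by_role["enrichment"].get(mod, []), ref_lengths)
                bg = build_coverage(by_role["solution_control"].get(mod, []), ref_lengths)
                called = call_peaks(sig["chr1"], bg["chr1"], modification=mod,
                                    name_prefix=cond)
                for p in called:
                    p.fold_enrichment = p.raw_enrichment
                peak_sets[cond][mod] = called

        slopes = {}
        for mod in ("m6A", "inosine"):
            tab = match_peaks({"a": peak_sets["a"][mod], "b": peak_sets["b"][mod]})
            shared = tab[tab["present_a"] & tab["present_b"]]
            x, y = shared["fe_a"].to_numpy(), shared["fe_b"].to_numpy()
            slopes[mod] = float((x * y).sum() / (x * x).sum())
        assert slopes["m6A"] < 0.9
        assert abs(slopes["inosine"] - 1.0) < 0.3
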