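"""Cross-condition comparison of peak landscapes.

Peaks of one modification are merged across conditions into loci by
single-linkage interval overlap; per-locus fold-enrichment is compared by
Pearson correlation over co-present loci, condition-unique loci are reported
separately, distributions are compared with a Wilcoxon rank-sum test, and
gene-level aggregate z-scores are clustered with Ward-linkage agglomerative
clustering (Euclidean affinity).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .models import Peak


def match_peaks(peak_sets: dict[str, list[Peak]]) -> pd.DataFrame:
    """Merge per-condition peak sets (same modification) into loci.

    Overlapping (>= 1 nt) intervals across conditions join one locus
    (single linkage).  Per locus and condition the fold-enrichment is the max
    over contributing peaks; absent conditions get 0 with presence flag False.
    """
    mods = {p.modification for ps in peak_sets.values() for p in ps}
    if len(mods) > 1:
        raise ValueError(f"match_peaks requires a single modification, got {sorted(mods)}")
    conditions = sorted(peak_sets)
    entries = []  # (ref, start, end, cond, peak)
    for cond in conditions:
        for p in peak_sets[cond]:
            entries.append((p.ref, p.start, p.end, cond, p))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))

    rows = []
    current: list[tuple] = []
    cur_ref, cur_end = None, -1

    def flush():
        if not current:
            return
        row = {
            "ref": current[0][0],
            "start": min(e[1] for e in current),
            "end": max(e[2] for e in current),
            "modification": current[0][4].modification,
        }
        for cond in conditions:
            contrib = [e[4] for e in current if e[3] == cond]
            row[f"fe_{cond}"] = max((p.fold_enrichment for p in contrib), default=0.0)
            row[f"present_{cond}"] = bool(contrib)
            row[f"n_{cond}"] = len(contrib)
        genes = {e[4].gene_id for e in current if e[4].gene_id}
        row["gene_id"] = sorted(genes)[0] if genes else ""
        rows.append(row)

    for e in entries:
        if e[0] != cur_ref or e[1] >= cur_end:
            flush()
            current = [e]
            cur_ref, cur_end = e[0], e[2]
        else:
            current.append(e)
            cur_end = max(cur_end, e[2])
    flush()
    return pd.DataFrame(rows)


def correlation(table: pd.DataFrame, cond_a: str, cond_b: str) -> tuple[float, float]:
    """Pearson r and R^2 of fold-enrichment over loci present in both."""
    sel = table[table[f"present_{cond_a}"] & table[f"present_{cond_b}"]]
    if len(sel) < 3:
        raise ValueError("need >= 3 shared loci for a correlation")
    r = float(stats.pearsonr(sel[f"fe_{cond_a}"], sel[f"fe_{cond_b}"]).statistic)
    return r, r * r


def rank_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test: (rank-sum statistic of a, p-value).

    Exact two-sided p by enumeration (with midrank tie handling) when both
    samples have n <= 8; otherwise the tie-corrected normal approximation
    with continuity correction.  Identical samples give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    w_obs = float(ranks[:n1].sum())
    mean_w = n1 * (n1 + n2 + 1) / 2.0

    if n1 <= 8 and n2 <= 8:
        dev = abs(w_obs - mean_w)
        hits = total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(comb)].sum() - mean_w) >= dev - 1e-9:
                hits += 1
        return w_obs, hits / total

    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w_obs, 1.0
    z = (w_obs - mean_w - math.copysign(0.5, w_obs - mean_w)) / math.sqrt(var_w)
    if w_obs == mean_w:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return w_obs, min(p, 1.0)


def gene_scores(table: pd.DataFrame, conditions: list[str]) -> pd.DataFrame:
    """Per-gene aggregate fold-enrichment: mean over the gene's loci per condition."""
    tab = table[table["gene_id"] != ""]
    agg = tab.groupby("gene_id")[[f"fe_{c}" for c in conditions]].mean()
    agg.columns = conditions
    return agg.sort_index()


def cluster_gene_scores(table: pd.DataFrame, conditions: list[str],
                        n_clusters: int = 2) -> pd.DataFrame:
    """Ward-linkage clustering of per-gene z-scores across conditions.

    Aggregate fold-enrichment per gene and condition is z-scored across
    conditions (row-wise), then clustered with Euclidean affinity and Ward
    linkage.  Deterministic: genes enter in lexicographic order.
    """
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    agg = gene_scores(table, conditions)
    if len(agg) < 2:
        raise ValueError("need >= 2 genes with assigned loci")
    x = agg.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    k = min(n_clusters, len(agg))
    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(z)
    out = agg.copy()
    out["cluster"] = labels
    return out


@dataclass
class DifferentialResult:
    table: pd.DataFrame
    stats: dict

    def unique_to(self, cond: str, conditions: list[str]) -> pd.DataFrame:
        others = [c for c in conditions if c != cond]
        sel = self.table[f"present_{cond}"]
        for o in others:
            sel = sel & ~self.table[f"present_{o}"]
        return self.table[sel]


def differential_analysis(peak_sets: dict[str, list[Peak]],
                          n_clusters: int = 2) -> DifferentialResult:
    """Match -> correlate -> rank-test fold changes across all condition pairs."""
    table = match_peaks(peak_sets)
    conditions = sorted(peak_sets)
    st: dict = {"n_loci": int(len(table))}
    for ca, cb in itertools.combinations(conditions, 2):
        key = f"{ca}_vs_{cb}"
        shared = table[table[f"present_{ca}"] & table[f"present_{cb}"]]
        entry = {"n_shared": int(len(shared)),
                 "n_unique_a": int((table[f"present_{ca}"] & ~table[f"present_{cb}"]).sum()),
                 "n_unique_b": int((table[f"present_{cb}"] & ~table[f"present_{ca}"]).sum())}
        if len(shared) >= 3:
            r, r2 = correlation(table, ca, cb)
            w, p = rank_test(shared[f"fe_{ca}"], shared[f"fe_{cb}"])
            entry.update({"pearson_r": r, "r_squared": r2,
                          "ranksum_w": w, "ranksum_p": p})
        st[key] = entry
    return DifferentialResult(table, st)
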