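"""Sliding-window DMR calling.

The genome is tiled into 100-bp bins at 25-bp offsets.  Within each bin the
per-cytosine methylation levels of the two samples (over jointly covered
sites of one context) are compared with a two-group Kruskal-Wallis rank sum
test; p-values are Benjamini-Hochberg adjusted across all tested windows of
that context genome-wide, windows with q < alpha (optionally also passing a
region fold-change filter) become DMRs, and adjacent same-trend DMRs are
collapsed.  DMRs are finally annotated against gene bodies and their 2-kb
strand-aware flanks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .io import CONTEXTS

WINDOW_COLUMNS = [
    "chrom", "start", "end", "context", "n_sites",
    "mean_a", "mean_b", "h_stat", "p_value", "q_value",
]

DMR_COLUMNS = [
    "chrom", "start", "end", "context", "trend",
    "fold_change", "q_value", "n_windows", "mean_a", "mean_b",
]

REGIONS = ("upstream", "gene_body", "downstream")


def tile_windows(
    chrom_lengths: dict[str, int], size: int = 100, step: int = 25
) -> pd.DataFrame:
    """Window coordinates [s, min(s+size, L)) for s = 0, step, 2*step, ... < L."""
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step must be <= size")
    rows = []
    for chrom, length in sorted(chrom_lengths.items()):
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom}")
        starts = np.arange(0, length, step)
        ends = np.minimum(starts + size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def kruskal_wallis_2group(values_a, values_b) -> tuple[float, float]:
    """Two-group Kruskal-Wallis rank sum test.

    Midranks over the pooled sample, the standard tie-correction divisor,
    and a chi-square upper tail with 1 degree of freedom.  When every pooled
    value is identical the statistic is 0 and p = 1.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(a, b)
    if h <= 0.0:  # numerical round-off can leave a tiny negative statistic
        return 0.0, 1.0
    return float(h), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over ascending-sorted p, capped
    at 1, returned in the original order.  Sorting ties are broken by the
    original index (stable sort) for determinism.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, float)
    q[order] = q_sorted
    return q


def test_windows(
    pair: pd.DataFrame,
    chrom_lengths: dict[str, int],
    context: str,
    size: int = 100,
    step: int = 25,
    min_sites: int = 4,
) -> pd.DataFrame:
    """Run the rank test on every window with enough sites of one context.

    Windows holding fewer than ``min_sites`` jointly covered sites are
    skipped entirely (they never enter the BH family); the BH adjustment
    runs across all tested windows of this context genome-wide.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    sub = pair[pair["context"] == context]
    rows = []
    for chrom, length in sorted(chrom_lengths.items()):
        on_chrom = sub[sub["chrom"] == chrom]
        pos = on_chrom["pos"].to_numpy()
        la = on_chrom["level_a"].to_numpy(float)
        lb = on_chrom["level_b"].to_numpy(float)
        starts = np.arange(0, length, step)
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, np.minimum(starts + size, length), side="left")
        for s, j0, j1 in zip(starts, i0, i1):
            if j1 - j0 < min_sites:
                continue
            wa, wb = la[j0:j1], lb[j0:j1]
            h, p = kruskal_wallis_2group(wa, wb)
            rows.append(
                (chrom, int(s), int(min(s + size, length)), context, int(j1 - j0),
                 float(wa.mean()), float(wb.mean()), h, p)
            )
    windows = pd.DataFrame(rows, columns=WINDOW_COLUMNS[:-1])
    if windows.empty:
        windows = windows.astype({"start": np.int64, "end": np.int64})
        windows["q_value"] = np.array([], float)
        return windows
    windows["q_value"] = bh_adjust(windows["p_value"].to_numpy())
    return windows


def call_dmrs(
    tested_windows: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float | None = 1.2,
) -> pd.DataFrame:
    """Turn significant windows (q < alpha) into pre-merge DMRs.

    The region fold change is ``mean(level_b) / mean(level_a)`` over the
    window's sites (infinite when mean_a = 0); trend is ``hyper`` when the
    fold change exceeds 1, else ``hypo``.  With ``fc_threshold`` set, a
    window must additionally satisfy ``|log(fc)| > log(fc_threshold)``.
    """
    if "q_value" not in tested_windows.columns or tested_windows["q_value"].isna().any():
        raise ValueError("windows must carry q-values")
    sig = tested_windows[tested_windows["q_value"] < alpha].copy()
    mean_a = sig["mean_a"].to_numpy(float)
    mean_b = sig["mean_b"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_a > 0, mean_b / mean_a, np.inf)
    sig["fold_change"] = fc
    sig["trend"] = np.where(fc > 1.0, "hyper", "hypo")
    if fc_threshold is not None:
        keep = (fc > fc_threshold) | (fc < 1.0 / fc_threshold)
        sig = sig.loc[keep]
    sig = sig.assign(n_windows=1)
    return sig[DMR_COLUMNS].reset_index(drop=True)


def merge_adjacent(
    dmrs: pd.DataFrame, pair: pd.DataFrame, max_gap: int = 0
) -> pd.DataFrame:
    """Collapse overlapping-or-abutting same-trend DMRs.

    Opposite-trend neighbours are never merged.  The merged fold change is
    recomputed from all jointly covered sites of the DMR's context inside
    the merged interval; the q-value is the minimum over members.
    """
    if dmrs.empty:
        return dmrs.copy()
    if not (
        pd.MultiIndex.from_arrays([dmrs["chrom"], dmrs["start"]]).is_monotonic_increasing
    ):
        raise ValueError("DMRs must be sorted by (chrom, start)")
    out = []
    for (chrom, context, trend), grp in dmrs.groupby(
        ["chrom", "context", "trend"], sort=True
    ):
        sub = pair[(pair["chrom"] == chrom) & (pair["context"] == context)]
        pos = sub["pos"].to_numpy()
        la = sub["level_a"].to_numpy(float)
        lb = sub["level_b"].to_numpy(float)
        cur = None
        for row in grp.sort_values("start").itertuples(index=False):
            if cur is None or row.start > cur["end"] + max_gap:
                if cur is not None:
                    out.append(cur)
                cur = {
                    "chrom": chrom, "start": row.start, "end": row.end,
                    "context": context, "trend": trend,
                    "q_value": row.q_value, "n_windows": row.n_windows,
                }
            else:
                cur["end"] = max(cur["end"], row.end)
                cur["q_value"] = min(cur["q_value"], row.q_value)
                cur["n_windows"] += row.n_windows
            if cur is not None:
                j0, j1 = np.searchsorted(pos, [cur["start"], cur["end"]])
                ma = float(la[j0:j1].mean()) if j1 > j0 else np.nan
                mb = float(lb[j0:j1].mean()) if j1 > j0 else np.nan
                cur["mean_a"], cur["mean_b"] = ma, mb
                cur["fold_change"] = mb / ma if ma > 0 else np.inf
        if cur is not None:
            out.append(cur)
    merged = pd.DataFrame(out)
    merged = merged.sort_values(["chrom", "start", "end"], kind="mergesort")
    return merged[DMR_COLUMNS].reset_index(drop=True)


def gene_regions(genes: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Expand gene models into body / upstream / downstream intervals.

    Flanks are ``flank`` bp on the strand-aware 5' (upstream) and 3'
    (downstream) sides, clipped at position 0.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    rows = []
    for g in genes.itertuples(index=False):
        rows.append((g.gene_id, g.chrom, g.start, g.end, "gene_body"))
        if g.strand == "+":
            up = (max(0, g.start - flank), g.start)
            dn = (g.end, g.end + flank)
        else:
            up = (g.end, g.end + flank)
            dn = (max(0, g.start - flank), g.start)
        if up[1] > up[0]:
            rows.append((g.gene_id, g.chrom, up[0], up[1], "upstream"))
        if dn[1] > dn[0]:
            rows.append((g.gene_id, g.chrom, dn[0], dn[1], "downstream"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "region"])


def annotate_dmrs(
    dmrs: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every DMR to each (gene, region) it overlaps by >= 1 bp.

    A DMR may annotate several genes and several regions (multi-assignment);
    DMRs overlapping no region are intergenic.  Returns ``(annotations,
    summary)``; the summary reports the percentage of DMRs overlapping any
    gene region and the per-region annotation distribution.
    """
    regions = gene_regions(genes, flank=flank)
    ann_rows = []
    genic = np.zeros(len(dmrs), bool)
    for chrom, reg_chrom in regions.groupby("chrom"):
        d_idx = np.flatnonzero((dmrs["chrom"] == chrom).to_numpy())
        if d_idx.size == 0:
            continue
        d_start = dmrs["start"].to_numpy()[d_idx]
        d_end = dmrs["end"].to_numpy()[d_idx]
        for reg in reg_chrom.itertuples(index=False):
            ov = np.minimum(d_end, reg.end) - np.maximum(d_start, reg.start)
            hit = ov > 0
            genic[d_idx[hit]] = True
            for i, o in zip(d_idx[hit], ov[hit]):
                d = dmrs.iloc[i]
                ann_rows.append(
                    (int(i), d.chrom, int(d.start), int(d.end), d.context, d.trend,
                     reg.gene_id, reg.region, int(o))
                )
    annotations = pd.DataFrame(
        ann_rows,
        columns=["dmr_id", "chrom", "start", "end", "context", "trend",
                 "gene_id", "region", "overlap_bp"],
    )
    n_dmrs = len(dmrs)
    pct_genic = 100.0 * genic.sum() / n_dmrs if n_dmrs else np.nan
    reg_counts = annotations["region"].value_counts() if not annotations.empty else {}
    summary_rows = [("any_gene_region", int(genic.sum()), pct_genic)]
    for region in REGIONS:
        n = int(reg_counts.get(region, 0))
        summary_rows.append(
            (region, n, 100.0 * n / len(annotations) if len(annotations) else np.nan)
        )
    summary = pd.DataFrame(summary_rows, columns=["region", "count", "pct"])
    return annotations, summary


def length_distribution(dmrs: pd.DataFrame, breaks) -> pd.DataFrame:
    """Histogram of DMR lengths over intervals defined by ``breaks``.

    ``breaks`` (strictly increasing) cut the length axis into
    ``[0, b1), [b1, b2), ..., [bk, inf)`` classes.
    """
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    lengths = (dmrs["end"] - dmrs["start"]).to_numpy()
    idx = np.searchsorted(breaks, lengths, side="right")
    edges = [0] + breaks + [np.inf]
    rows = []
    for k in range(len(breaks) + 1):
        n = int((idx == k).sum())
        label = f"[{edges[k]}, {edges[k + 1]})"
        rows.append((label, n, 100.0 * n / len(lengths) if len(lengths) else np.nan))
    return pd.DataFrame(rows, columns=["length_class", "count", "pct"])
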