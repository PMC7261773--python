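"""DMR-type x differential-expression association.

Genes are classified by expression change (increased / decreased at
FDR < 0.05, non-differential, or not expressed at FPKM < 1 in both
samples), grouped by the trend of the DMRs overlapping each gene region
(hyper / hypo / both / none), and the log2 fold-change distributions of the
groups are compared per region among strong (>= 4-fold) DEGs, alongside a
seeded random control group, with pairwise two-sided rank-sum tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .dmr import REGIONS, bh_adjust

EXPRESSION_CLASSES = ("increased", "decreased", "non_diff", "non_expressed")
DMR_GROUPS = ("hyper", "hypo", "both", "none")
GROUP_REGIONS = REGIONS + ("whole_gene",)


def classify_expression(
    records: pd.DataFrame, fdr_alpha: float = 0.05, min_fpkm: float = 1.0
) -> pd.DataFrame:
    """Assign each gene to one of the four expression classes.

    ``non_expressed`` (both FPKM below ``min_fpkm``) takes precedence; then
    ``increased``/``decreased`` by the sign of log2fc at FDR < ``fdr_alpha``;
    everything else is ``non_diff``.  The classes partition the gene set.
    """
    fpkm_low = (records["fpkm_a"] < min_fpkm) & (records["fpkm_b"] < min_fpkm)
    sig = records["fdr"] < fdr_alpha
    cls = np.where(
        fpkm_low,
        "non_expressed",
        np.where(
            sig & (records["log2fc"] > 0),
            "increased",
            np.where(sig & (records["log2fc"] < 0), "decreased", "non_diff"),
        ),
    )
    out = records[["gene_id", "log2fc", "fdr"]].copy()
    out["expr_class"] = cls
    return out


def assign_dmr_groups(genes: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per gene and region, the DMR group implied by overlapping DMR trends.

    ``hyper``/``hypo`` when only that trend overlaps the region, ``both``
    when at least one of each does, ``none`` otherwise.  ``whole_gene`` is
    the union over the three regions.
    """
    out = pd.DataFrame({"gene_id": genes["gene_id"]})
    trend_sets: dict[str, dict[str, set]] = {
        region: {} for region in GROUP_REGIONS
    }
    for ann in annotations.itertuples(index=False):
        trend_sets[ann.region].setdefault(ann.gene_id, set()).add(ann.trend)
        trend_sets["whole_gene"].setdefault(ann.gene_id, set()).add(ann.trend)
    for region in GROUP_REGIONS:
        mapping = trend_sets[region]

        def group_of(gene_id: str) -> str:
            trends = mapping.get(gene_id, set())
            if not trends:
                return "none"
            if trends == {"hyper"}:
                return "hyper"
            if trends == {"hypo"}:
                return "hypo"
            return "both"

        out[region] = out["gene_id"].map(group_of)
    return out


def group_by_dmr(
    genes: pd.DataFrame, annotations: pd.DataFrame, region: str
) -> pd.Series:
    """DMR group of every gene for one region token."""
    if region not in GROUP_REGIONS:
        raise ValueError(f"unknown region {region!r}")
    groups = assign_dmr_groups(genes, annotations)
    return groups.set_index("gene_id")[region]


def foldchange_comparison(
    classes: pd.DataFrame,
    groups: pd.DataFrame,
    min_abs_fc: float = 4.0,
    n_random: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare log2 fold-change distributions across DMR groups.

    For increased- and decreased-DEGs separately, restricted to genes with
    at least ``min_abs_fc``-fold change (|log2fc| >= log2(min_abs_fc)), the
    per-region hyper/hypo/both/none group distributions are summarised
    (n, median, quartiles) together with a seeded random control drawn
    uniformly without replacement from the same DEG set (size ``n_random``,
    default the largest DMR group).  Pairwise two-sided rank-sum tests are
    BH-adjusted within each (direction, region) family.  Deterministic for
    a given seed; changing the seed changes only the random control.
    """
    rng = np.random.default_rng(seed)
    merged = classes.merge(groups, on="gene_id", how="left")
    for region in GROUP_REGIONS:
        merged[region] = merged[region].fillna("none")
    cut = np.log2(min_abs_fc)
    summary_rows, test_rows = [], []
    for direction in ("increased", "decreased"):
        sub = merged[
            (merged["expr_class"] == direction) & (merged["log2fc"].abs() >= cut)
        ]
        for region in GROUP_REGIONS:
            values = {
                g: sub.loc[sub[region] == g, "log2fc"].to_numpy(float)
                for g in DMR_GROUPS
            }
            size = n_random if n_random is not None else max(
                (len(v) for v in values.values()), default=0
            )
            size = min(size, len(sub))
            values["random"] = (
                rng.choice(sub["log2fc"].to_numpy(float), size=size, replace=False)
                if size > 0
                else np.array([], float)
            )
            for g, v in values.items():
                if len(v) == 0:
                    summary_rows.append(
                        (direction, region, g, 0, np.nan, np.nan, np.nan)
                    )
                else:
                    summary_rows.append(
                        (direction, region, g, len(v), float(np.median(v)),
                         float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75)))
                    )
            names = list(values)
            family = []
            for i, g1 in enumerate(names):
                for g2 in names[i + 1:]:
                    v1, v2 = values[g1], values[g2]
                    if len(v1) < 2 or len(v2) < 2:
                        continue  # empty/degenerate group: test skipped
                    stat, p = scipy.stats.mannwhitneyu(
                        v1, v2, alternative="two-sided"
                    )
                    family.append(
                        [direction, region, g1, g2, len(v1), len(v2),
                         float(stat), float(p)]
                    )
            if family:
                qs = bh_adjust([row[7] for row in family])
                for row, q in zip(family, qs):
                    test_rows.append(row + [float(q)])
    summary = pd.DataFrame(
        summary_rows,
        columns=["direction", "region", "group", "n", "median_log2fc", "q25", "q75"],
    )
    tests = pd.DataFrame(
        test_rows,
        columns=["direction", "region", "group1", "group2", "n1", "n2",
                 "u_stat", "p_value", "q_value"],
    )
    return summary, tests


def dmr_gene_percentages(classes: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Percentage of DMR-containing genes (whole-gene region, any trend)
    within each expression class."""
    merged = classes.merge(groups[["gene_id", "whole_gene"]], on="gene_id", how="left")
    merged["whole_gene"] = merged["whole_gene"].fillna("none")
    rows = []
    for cls in EXPRESSION_CLASSES:
        sub = merged[merged["expr_class"] == cls]
        n = len(sub)
        n_dmr = int((sub["whole_gene"] != "none").sum())
        rows.append((cls, n, n_dmr, 100.0 * n_dmr / n if n else np.nan))
    return pd.DataFrame(rows, columns=["expr_class", "n_genes", "n_with_dmr", "pct"])
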