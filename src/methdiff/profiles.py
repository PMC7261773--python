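"""Per-cytosine methylation levels and genome-scale methylome summaries.

Two bisulfite samples are compared on the intersection of cytosines covered
by at least ``min_total_reads`` reads in *both* samples.  The methylation
level of a site is ``n_meth / (n_meth + n_unmeth)``.  On top of the paired
table this module computes methylcytosine (mC) calls and per-context rates,
tiled-bin density/level profiles (50 kb default), per-chromosome
cross-sample correlations of levels and of mC positions, and the
fold-change divergence summary (fraction of mC sites whose level moved by
more than a 1.2-fold ratio between samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CONTEXTS

PAIR_COLUMNS = [
    "chrom", "pos", "strand", "context",
    "n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b",
    "level_a", "level_b",
]


def site_level(n_meth: int, n_unmeth: int) -> float:
    """Methylation level of one cytosine: mC / (mC + un-mC).

    Undefined at zero total coverage; the caller must not invoke it there.
    """
    total = n_meth + n_unmeth
    if total <= 0:
        raise ValueError("site_level undefined at zero coverage")
    return n_meth / total


def _require_sorted(sites: pd.DataFrame, what: str) -> None:
    key = pd.MultiIndex.from_arrays(
        [sites["chrom"], sites["pos"], sites["strand"]]
    )
    if not key.is_monotonic_increasing:
        raise ValueError(f"{what} is not sorted by (chrom, pos, strand)")


def pair_samples(
    sample_a: pd.DataFrame, sample_b: pd.DataFrame, min_total_reads: int = 3
) -> pd.DataFrame:
    """Intersect two site tables on sites covered in both samples.

    Only cytosines with ``n_meth + n_unmeth >= min_total_reads`` in *both*
    samples are retained; per-site levels are computed for each sample.
    Both inputs must be sorted by (chrom, pos, strand).
    """
    _require_sorted(sample_a, "sample_a")
    _require_sorted(sample_b, "sample_b")
    cols = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    merged = pd.merge(
        sample_a[cols], sample_b[cols],
        on=["chrom", "pos", "strand"], how="inner", suffixes=("_a", "_b"),
    )
    if not merged.empty and (merged["context_a"] != merged["context_b"]).any():
        bad = merged.loc[merged["context_a"] != merged["context_b"]].iloc[0]
        raise ValueError(
            f"context disagreement at ({bad.chrom}, {bad.pos}, {bad.strand}): "
            f"{bad.context_a} vs {bad.context_b}"
        )
    total_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    total_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    keep = (total_a >= min_total_reads) & (total_b >= min_total_reads)
    merged = merged.loc[keep].reset_index(drop=True)
    total_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    total_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    merged["level_a"] = np.where(total_a > 0, merged["n_meth_a"] / total_a, np.nan)
    merged["level_b"] = np.where(total_b > 0, merged["n_meth_b"] / total_b, np.nan)
    merged = merged.rename(columns={"context_a": "context"}).drop(columns=["context_b"])
    return merged[PAIR_COLUMNS]


def call_mcs(
    sample: pd.DataFrame, min_total_reads: int = 3, min_meth_reads: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call methylcytosines in one sample.

    A covered site (total reads >= ``min_total_reads``) is an mC iff
    ``n_meth >= min_meth_reads``.  Returns ``(mc_sites, summary)`` where
    summary has one row per context plus ``total`` with covered counts,
    mC counts and the mC rate (mC count / covered count).
    """
    if min_total_reads < 0 or min_meth_reads < 0:
        raise ValueError("thresholds must be >= 0")
    total = sample["n_meth"] + sample["n_unmeth"]
    covered = total >= min_total_reads
    is_mc = covered & (sample["n_meth"] >= min_meth_reads)
    rows = []
    for context in CONTEXTS:
        in_ctx = sample["context"] == context
        n_cov = int((covered & in_ctx).sum())
        n_mc = int((is_mc & in_ctx).sum())
        rows.append((context, n_cov, n_mc, n_mc / n_cov if n_cov else np.nan))
    n_cov = int(covered.sum())
    n_mc = int(is_mc.sum())
    rows.append(("total", n_cov, n_mc, n_mc / n_cov if n_cov else np.nan))
    summary = pd.DataFrame(rows, columns=["context", "n_covered", "n_mc", "mc_rate"])
    return sample.loc[is_mc].reset_index(drop=True), summary


def bin_profiles(
    sample: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 50_000,
    min_total_reads: int = 3,
    min_meth_reads: int = 1,
) -> pd.DataFrame:
    """Tile each chromosome into non-overlapping ``bin_size`` bins (last bin
    truncated) and compute per-bin, per-context profiles.

    ``c_density`` is the density of report cytosines of that context in the
    bin, ``mc_density`` the density of mC calls, both per actual bin length;
    ``mean_level`` is the unweighted average level over covered sites (NaN
    for bins without covered sites).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    for chrom in sample["chrom"].unique():
        if chrom not in chrom_lengths:
            raise ValueError(f"no declared length for chromosome {chrom}")
    pos = sample["pos"].to_numpy()
    lengths = sample["chrom"].map(chrom_lengths).to_numpy()
    if (pos >= lengths).any():
        bad = sample.loc[pos >= lengths].iloc[0]
        raise ValueError(
            f"site at {bad.chrom}:{bad.pos} beyond declared chromosome length"
        )
    total = (sample["n_meth"] + sample["n_unmeth"]).to_numpy()
    covered = total >= min_total_reads
    is_mc = covered & (sample["n_meth"].to_numpy() >= min_meth_reads)
    level = np.where(total > 0, sample["n_meth"].to_numpy() / np.maximum(total, 1), np.nan)

    work = pd.DataFrame(
        {
            "chrom": sample["chrom"],
            "bin": pos // bin_size,
            "context": sample["context"],
            "is_mc": is_mc,
            "covered": covered,
            "cov_level": np.where(covered, level, np.nan),
        }
    )
    rows = []
    for chrom, length in sorted(chrom_lengths.items()):
        n_bins = max(1, -(-length // bin_size))
        on_chrom = work[work["chrom"] == chrom]
        for b in range(n_bins):
            b_start = b * bin_size
            b_end = min(b_start + bin_size, length)
            b_len = b_end - b_start
            in_bin = on_chrom[on_chrom["bin"] == b]
            for context in list(CONTEXTS) + ["total"]:
                sub = in_bin if context == "total" else in_bin[in_bin["context"] == context]
                n_sites = len(sub)
                n_mc = int(sub["is_mc"].sum())
                mean_level = (
                    float(np.nanmean(sub["cov_level"])) if sub["covered"].any() else np.nan
                )
                rows.append(
                    (chrom, b_start, b_end, context, n_sites, n_sites / b_len,
                     n_mc, n_mc / b_len, mean_level)
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "bin_start", "bin_end", "context",
                 "n_sites", "c_density", "n_mc", "mc_density", "mean_level"],
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        return np.nan
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def chromosome_correlations(
    pair: pd.DataFrame, by: str = "level", min_meth_reads: int = 1
) -> pd.DataFrame:
    """Per-chromosome, per-context product-moment correlation between the
    two samples over jointly covered sites.

    ``by="level"`` correlates the per-site levels; ``by="presence"``
    correlates binary mC-call indicators (position concordance).  Chromosome
    x context combinations with fewer than 3 shared sites or zero variance
    are reported as NaN rather than raising.
    """
    if by not in ("level", "presence"):
        raise ValueError(f"unknown correlation mode {by!r}")
    if by == "level":
        xa = pair["level_a"].to_numpy(float)
        xb = pair["level_b"].to_numpy(float)
    else:
        xa = (pair["n_meth_a"].to_numpy() >= min_meth_reads).astype(float)
        xb = (pair["n_meth_b"].to_numpy() >= min_meth_reads).astype(float)
    rows = []
    for chrom in pair["chrom"].unique():
        on_chrom = (pair["chrom"] == chrom).to_numpy()
        for context in list(CONTEXTS) + ["total"]:
            mask = on_chrom if context == "total" else (
                on_chrom & (pair["context"] == context).to_numpy()
            )
            rows.append((chrom, context, int(mask.sum()), _pearson(xa[mask], xb[mask])))
    return pd.DataFrame(rows, columns=["chrom", "context", "n_sites", "r"])


def divergence_summary(
    pair: pd.DataFrame,
    fc_threshold: float = 1.2,
    strong_fc: float = 2.0,
    min_meth_reads: int = 1,
) -> pd.DataFrame:
    """Classify per-site level fold changes between the samples.

    Eligible sites are those called mC in at least one sample.  A site is
    *increased* when ``level_b / level_a > fc_threshold`` (a zero
    denominator with a methylated numerator counts as increased and lands in
    the >= ``strong_fc`` class), *decreased* symmetrically.  All percentages
    share one denominator — the total eligible site count across contexts —
    so the per-context rows are additive shares of the overall divergence.
    """
    eligible = (
        (pair["n_meth_a"] >= min_meth_reads) | (pair["n_meth_b"] >= min_meth_reads)
    ).to_numpy()
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError("no eligible (mC in either sample) sites")
    la = pair["level_a"].to_numpy(float)
    lb = pair["level_b"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_up = np.where(la > 0, lb / la, np.where(lb > 0, np.inf, 1.0))
        ratio_dn = np.where(lb > 0, la / lb, np.where(la > 0, np.inf, 1.0))
    increased = eligible & (ratio_up > fc_threshold)
    decreased = eligible & (ratio_dn > fc_threshold)
    inc_strong = eligible & (ratio_up > strong_fc)
    dec_strong = eligible & (ratio_dn > strong_fc)
    rows = []
    for context in list(CONTEXTS) + ["total"]:
        mask = (
            np.ones(len(pair), bool) if context == "total"
            else (pair["context"] == context).to_numpy()
        )
        pct = lambda m: 100.0 * int((m & mask).sum()) / n_eligible  # noqa: E731
        p_inc, p_dec = pct(increased), pct(decreased)
        rows.append(
            (context, p_inc, p_dec, pct(inc_strong), pct(dec_strong), p_inc + p_dec)
        )
    return pd.DataFrame(
        rows,
        columns=["context", "pct_increased", "pct_decreased",
                 "pct_increased_ge2fold", "pct_decreased_ge2fold", "pct_total_variant"],
    )
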