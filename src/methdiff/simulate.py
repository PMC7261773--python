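"""Synthetic paired methylomes, gene models and expression tables with
planted truth.

The generator emulates the statistical structure of a plant WGBS ploidy
comparison: context-stratified beta-distributed methylation levels (mean
~0.34 CG / ~0.30 CHG / ~0.16 CHH), Poisson read coverage around 12x,
binomial methylated-read counts, sparse planted DMRs concentrated in the
CHH context, and gene expression fold changes coupled to gene-body DMR
direction (a hypo-DMR in the body pushes expression up, a hyper-DMR down).
Outside planted DMRs the two samples share the same true level per site, so
their divergence is pure sampling noise — the null scenario for the caller.

Everything is driven by one integer seed; identical config + seed yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .io import CONTEXTS

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic scenario.

    Defaults describe the standard study conditions: two 1-Mb chromosomes,
    ~12x coverage, 200 planted CHH DMRs with a 0.3 level shift, and a unit
    log2fc coupling from gene-body DMRs to expression.
    """

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    gc_fraction: float = 0.35
    context_means: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.34, "CHG": 0.30, "CHH": 0.16}
    )
    beta_concentration: float = 5.0
    coverage_mean: float = 12.0
    n_planted_dmrs: dict[str, int] = field(
        default_factory=lambda: {"CG": 0, "CHG": 0, "CHH": 200}
    )
    delta_level: float = 0.3
    dmr_length_range: tuple[int, int] = (100, 400)
    dmr_min_sites: int = 5
    dmr_min_separation: int = 500
    dmr_margin: int = 150
    gene_length: int = 2000
    gene_spacing: int = 2000
    gene_offset: int = 1000
    n_genes: int | None = None
    paired_true_levels: bool = True
    deg_fraction: float = 0.5
    non_expressed_fraction: float = 0.15
    deg_log2fc_range: tuple[float, float] = (2.5, 3.0)
    nondiff_log2fc_sd: float = 0.2
    coupling_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        for name, value in self.context_means.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"context mean {name} outside [0, 1]")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    def null(self) -> "SimulationConfig":
        """Copy of this config with no planted effects (global null)."""
        return dataclasses.replace(
            self,
            n_planted_dmrs={c: 0 for c in CONTEXTS},
            coupling_strength=0.0,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth: DMR intervals and per-gene expression labels."""

    dmrs: pd.DataFrame  # chrom, start, end, context, trend, delta_level
    genes: pd.DataFrame | None = None
    gene_truth: pd.DataFrame | None = None


@dataclass
class SimulationBundle:
    config: SimulationConfig
    genome: dict[str, str]
    catalog: pd.DataFrame
    sample_a: pd.DataFrame
    sample_b: pd.DataFrame
    genes: pd.DataFrame
    expression: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome and context catalog


def sequence_contexts(seq: str, chrom: str) -> pd.DataFrame:
    """Cytosine context catalog (both strands) of one sequence.

    Plus-strand C at i: CG if seq[i+1] == G, CHG if seq[i+2] == G, else CHH;
    minus-strand C (a plus-strand G) mirrors this through the reverse
    complement.  Cytosines too close to the sequence end to resolve their
    trinucleotide are classed CHH.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    pad = np.concatenate([[b"N", b"N"], arr, [b"N", b"N"]])
    rows = []

    plus = np.flatnonzero(arr == b"C")
    nxt1 = pad[plus + 3]
    nxt2 = pad[plus + 4]
    ctx_plus = np.where(nxt1 == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
    rows.append(pd.DataFrame({"chrom": chrom, "pos": plus, "strand": "+", "context": ctx_plus}))

    minus = np.flatnonzero(arr == b"G")
    prv1 = pad[minus + 1]
    prv2 = pad[minus]
    ctx_minus = np.where(prv1 == b"C", "CG", np.where(prv2 == b"C", "CHG", "CHH"))
    rows.append(pd.DataFrame({"chrom": chrom, "pos": minus, "strand": "-", "context": ctx_minus}))

    cat = pd.concat(rows, ignore_index=True)
    return cat.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome at the configured GC fraction plus its context catalog."""
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome: dict[str, str] = {}
    catalogs = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        seq = _BASES[rng.choice(4, size=length, p=probs)].tobytes().decode()
        genome[chrom] = seq
        catalogs.append(sequence_contexts(seq, chrom))
    catalog = pd.concat(catalogs, ignore_index=True)
    return genome, catalog


# ---------------------------------------------------------------------------
# gene grid (deterministic layout shared by DMR placement and expression)


def gene_grid(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping genes on alternating strands at a fixed pitch."""
    pitch = config.gene_length + config.gene_spacing
    rows = []
    k = 0
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        start = config.gene_offset
        while start + config.gene_length + config.gene_offset <= length:
            if config.n_genes is not None and k >= config.n_genes:
                break
            rows.append(
                (f"g{k + 1:05d}", chrom, start, start + config.gene_length,
                 "+" if k % 2 == 0 else "-")
            )
            k += 1
            start += pitch
    if config.n_genes is not None and k < config.n_genes:
        raise ValueError(
            f"insufficient space for {config.n_genes} genes (placed {k})"
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _placement_strata(config: SimulationConfig, genes: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Intervals a planted DMR may occupy: inside one gene body or inside
    one intergenic gap, with a margin from every gene edge so the planted
    region (and the calls it provokes) stays within a single stratum."""
    margin = config.dmr_margin
    strata = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        on_chrom = genes[genes["chrom"] == chrom].sort_values("start")
        prev_end = 0
        for g in on_chrom.itertuples(index=False):
            if g.start - margin > prev_end + margin:
                strata.append((chrom, prev_end + margin, g.start - margin))
            if g.end - margin > g.start + margin:
                strata.append((chrom, g.start + margin, g.end - margin))
            prev_end = g.end
        if length - margin > prev_end + margin:
            strata.append((chrom, prev_end + margin, length - margin))
    return strata


def _plant_dmrs(
    config: SimulationConfig,
    catalog: pd.DataFrame,
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    strata = _placement_strata(config, genes)
    weights = np.array([hi - lo for _, lo, hi in strata], float)
    weights /= weights.sum()
    ctx_positions = {
        (chrom, ctx): grp["pos"].to_numpy()
        for (chrom, ctx), grp in catalog.groupby(["chrom", "context"])
    }
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_lengths}
    lo_len, hi_len = config.dmr_length_range
    rows = []
    for context in CONTEXTS:
        for _ in range(config.n_planted_dmrs.get(context, 0)):
            for _attempt in range(1000):
                si = rng.choice(len(strata), p=weights)
                chrom, s_lo, s_hi = strata[si]
                length = int(rng.integers(lo_len, hi_len + 1))
                if s_hi - s_lo < length:
                    continue
                start = int(rng.integers(s_lo, s_hi - length + 1))
                end = start + length
                sep = config.dmr_min_separation
                if any(
                    start < e + sep and end > s - sep for s, e in placed[chrom]
                ):
                    continue
                pos = ctx_positions.get((chrom, context), np.empty(0, int))
                n_sites = int(
                    np.searchsorted(pos, end) - np.searchsorted(pos, start)
                )
                if n_sites < config.dmr_min_sites:
                    continue
                placed[chrom].append((start, end))
                trend = "hyper" if rng.random() < 0.5 else "hypo"
                rows.append((chrom, start, end, context, trend, config.delta_level))
                break
            else:
                raise RuntimeError(
                    f"could not place a {context} DMR after bounded retries"
                )
    truth = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "trend", "delta_level"]
    )
    if truth.empty:
        truth = truth.astype({"start": np.int64, "end": np.int64, "delta_level": float})
    return truth.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylome pair


def simulate_methylome_pair(
    config: SimulationConfig,
    catalog: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw two cytosine reports over a context catalog.

    Per site the true level comes from a beta distribution with the
    context's mean and the configured concentration; sample B inherits
    sample A's true level except inside planted DMRs, where its level is
    redrawn from a beta whose mean is shifted by +-delta_level (clipped
    into [0.02, 0.98] so the distribution stays proper) — a hypo region
    loses methylation across all its sites, a hyper region gains it.
    Coverage is Poisson per sample, methylated counts binomial.
    """
    if catalog.empty:
        raise ValueError("context catalog is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = gene_grid(config)
    truth_dmrs = _plant_dmrs(config, catalog, genes, rng)

    n = len(catalog)
    level_a = np.empty(n, float)
    conc = config.beta_concentration
    for context in CONTEXTS:
        mask = (catalog["context"] == context).to_numpy()
        mu = config.context_means[context]
        level_a[mask] = rng.beta(mu * conc, (1 - mu) * conc, size=int(mask.sum()))
    if config.paired_true_levels:
        # biological pairing: outside planted regions the two samples share
        # one underlying methylation state per site
        level_b = level_a.copy()
    else:
        # exchangeable null: each sample's levels drawn independently from
        # the same per-site (context) distribution
        level_b = np.empty(n, float)
        for context in CONTEXTS:
            mask = (catalog["context"] == context).to_numpy()
            mu = config.context_means[context]
            level_b[mask] = rng.beta(mu * conc, (1 - mu) * conc, size=int(mask.sum()))
    chrom_arr = catalog["chrom"].to_numpy()
    pos_arr = catalog["pos"].to_numpy()
    ctx_arr = catalog["context"].to_numpy()
    for d in truth_dmrs.itertuples(index=False):
        mask = (
            (chrom_arr == d.chrom)
            & (ctx_arr == d.context)
            & (pos_arr >= d.start)
            & (pos_arr < d.end)
        )
        shift = d.delta_level if d.trend == "hyper" else -d.delta_level
        mu_b = float(
            np.clip(config.context_means[d.context] + shift, 0.02, 0.98)
        )
        level_b[mask] = rng.beta(mu_b * conc, (1 - mu_b) * conc, size=int(mask.sum()))

    samples = []
    for level in (level_a, level_b):
        cov = rng.poisson(config.coverage_mean, size=n)
        n_meth = rng.binomial(cov, level)
        df = pd.DataFrame(
            {
                "chrom": catalog["chrom"],
                "pos": catalog["pos"],
                "strand": catalog["strand"],
                "n_meth": n_meth,
                "n_unmeth": cov - n_meth,
                "context": catalog["context"],
            }
        )
        df["covered"] = (df["n_meth"] + df["n_unmeth"]) >= 3
        samples.append(df)
    return samples[0], samples[1], SyntheticTruth(dmrs=truth_dmrs, genes=genes)


# ---------------------------------------------------------------------------
# genes and expression


def simulate_genes_expression(
    config: SimulationConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Expression table coupled to the planted gene-body DMRs.

    Genes are assigned to planted classes (DEG up/down, non-differential,
    non-expressed); DEG baseline |log2fc| is drawn from
    ``deg_log2fc_range``.  A planted hypo-DMR inside a gene body adds
    ``+coupling_strength`` to the gene's log2fc, a hyper-DMR adds the
    negative.  Reported FDRs are small for planted DEGs and uniform
    otherwise (differential-expression testing itself is upstream of this
    pipeline, so its output is emulated, not recomputed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = truth.genes if truth.genes is not None else gene_grid(config)
    lo, hi = config.deg_log2fc_range
    ne_frac = config.non_expressed_fraction
    deg_frac = config.deg_fraction

    body_hypo: dict[str, int] = {}
    body_hyper: dict[str, int] = {}
    for g in genes.itertuples(index=False):
        sub = truth.dmrs[
            (truth.dmrs["chrom"] == g.chrom)
            & (truth.dmrs["end"] > g.start)
            & (truth.dmrs["start"] < g.end)
        ]
        body_hypo[g.gene_id] = int((sub["trend"] == "hypo").sum())
        body_hyper[g.gene_id] = int((sub["trend"] == "hyper").sum())

    rows = []
    for g in genes.itertuples(index=False):
        u = rng.random()
        if u < ne_frac:
            cls = "non_expressed"
        elif u < ne_frac + deg_frac:
            cls = "increased" if rng.random() < 0.5 else "decreased"
        else:
            cls = "non_diff"
        if cls == "non_expressed":
            fpkm_a = float(rng.uniform(0.02, 0.95))
            fpkm_b = float(rng.uniform(0.02, 0.95))
            base = float(np.log2(fpkm_b / fpkm_a))
            increment = 0.0
            log2fc = base
            fdr = float(rng.uniform(0.0, 1.0))
        else:
            if cls == "increased":
                base = float(rng.uniform(lo, hi))
            elif cls == "decreased":
                base = -float(rng.uniform(lo, hi))
            else:
                base = float(rng.normal(0.0, config.nondiff_log2fc_sd))
            increment = config.coupling_strength * (
                (1 if body_hypo[g.gene_id] else 0) - (1 if body_hyper[g.gene_id] else 0)
            )
            log2fc = base + increment
            fpkm_a = 1.0 + float(rng.lognormal(1.0, 1.0))
            fpkm_b = float(fpkm_a * 2.0 ** log2fc)
            fdr = (
                float(rng.uniform(0.0, 0.01))
                if cls in ("increased", "decreased")
                else float(rng.uniform(0.0, 1.0))
            )
        rows.append(
            (g.gene_id, cls, base, increment, log2fc,
             body_hypo[g.gene_id], body_hyper[g.gene_id], fpkm_a, fpkm_b, fdr)
        )
    gene_truth = pd.DataFrame(
        rows,
        columns=["gene_id", "planted_class", "base_log2fc", "coupling_increment",
                 "log2fc", "n_body_hypo", "n_body_hyper", "fpkm_a", "fpkm_b", "fdr"],
    )
    expression = gene_truth[["gene_id", "fpkm_a", "fpkm_b", "log2fc", "fdr"]].copy()
    truth = SyntheticTruth(dmrs=truth.dmrs, genes=genes, gene_truth=gene_truth)
    return genes, expression, truth


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryResult:
    sensitivity: float
    precision: float
    n_planted: int
    n_called: int
    per_context: pd.DataFrame


def evaluate_recovery(
    called_dmrs: pd.DataFrame,
    truth_dmrs: pd.DataFrame,
    min_overlap_fraction: float = 0.5,
    reciprocal: bool = False,
) -> RecoveryResult:
    """Match called DMRs against planted truth (same context and trend).

    A planted DMR is recovered when a same-context, same-trend call covers
    at least ``min_overlap_fraction`` of it (with ``reciprocal=True`` the
    overlap must also cover that fraction of the call).  A call is a true
    positive when it overlaps any planted DMR of its context and trend
    (>= 1 bp, or the reciprocal-fraction rule when ``reciprocal``).
    Precision is NaN when nothing was called.
    """
    matched_planted = np.zeros(len(truth_dmrs), bool)
    matched_called = np.zeros(len(called_dmrs), bool)
    for (chrom, context, trend), t_grp in truth_dmrs.groupby(
        ["chrom", "context", "trend"]
    ):
        c_mask = (
            (called_dmrs["chrom"] == chrom)
            & (called_dmrs["context"] == context)
            & (called_dmrs["trend"] == trend)
        ).to_numpy()
        c_idx = np.flatnonzero(c_mask)
        if c_idx.size == 0:
            continue
        cs = called_dmrs["start"].to_numpy()[c_idx]
        ce = called_dmrs["end"].to_numpy()[c_idx]
        for ti, t in zip(t_grp.index, t_grp.itertuples(index=False)):
            ov = np.minimum(ce, t.end) - np.maximum(cs, t.start)
            t_len = t.end - t.start
            ok_t = ov >= min_overlap_fraction * t_len
            if reciprocal:
                ok_c = ok_t & (ov >= min_overlap_fraction * (ce - cs))
            else:
                ok_c = ov > 0
            if (ok_t & (ok_c if reciprocal else True)).any():
                matched_planted[truth_dmrs.index.get_loc(ti)] = True
            matched_called[c_idx[ok_c]] = True

    rows = []
    for context in CONTEXTS:
        t_ctx = (truth_dmrs["context"] == context).to_numpy()
        c_ctx = (called_dmrs["context"] == context).to_numpy()
        n_t, n_c = int(t_ctx.sum()), int(c_ctx.sum())
        sens = matched_planted[t_ctx].mean() if n_t else np.nan
        prec = matched_called[c_ctx].mean() if n_c else np.nan
        rows.append((context, n_t, n_c, sens, prec))
    per_context = pd.DataFrame(
        rows, columns=["context", "n_planted", "n_called", "sensitivity", "precision"]
    )
    sensitivity = float(matched_planted.mean()) if len(truth_dmrs) else np.nan
    precision = float(matched_called.mean()) if len(called_dmrs) else np.nan
    return RecoveryResult(
        sensitivity, precision, len(truth_dmrs), len(called_dmrs), per_context
    )


# ---------------------------------------------------------------------------
# scenario driver and file output


def simulate_scenario(config: SimulationConfig) -> SimulationBundle:
    """Run the full generator: genome, methylome pair, genes, expression."""
    rng = np.random.default_rng(config.seed)
    genome, catalog = generate_genome(config, rng)
    genes = gene_grid(config)
    sample_a, sample_b, truth = simulate_methylome_pair(config, catalog, genes, rng)
    genes, expression, truth = simulate_genes_expression(config, truth, rng)
    return SimulationBundle(
        config, genome, catalog, sample_a, sample_b, genes, expression, truth
    )


def write_scenario(bundle: SimulationBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle to disk (FASTA, two reports, GFF3, expression TSV,
    chromosome lengths, truth JSON).  Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "report_a": outdir / "sample_a.cx_report.txt",
        "report_b": outdir / "sample_b.cx_report.txt",
        "gff": outdir / "genes.gff3",
        "expression": outdir / "expression.tsv",
        "chrom_lengths": outdir / "chrom_lengths.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["fasta"], "w") as handle:
        for chrom, seq in bundle.genome.items():
            handle.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i:i + 60] + "\n")
    mio.write_cytosine_report(bundle.sample_a, paths["report_a"])
    mio.write_cytosine_report(bundle.sample_b, paths["report_b"])
    mio.write_gene_models(bundle.genes, paths["gff"])
    mio.write_expression_table(bundle.expression, paths["expression"])
    with open(paths["chrom_lengths"], "w") as handle:
        for chrom in sorted(bundle.config.chrom_lengths):
            handle.write(f"{chrom}\t{bundle.config.chrom_lengths[chrom]}\n")
    truth_obj = {
        "dmrs": bundle.truth.dmrs.to_dict(orient="records"),
        "gene_truth": (
            bundle.truth.gene_truth.to_dict(orient="records")
            if bundle.truth.gene_truth is not None
            else None
        ),
    }
    with open(paths["truth"], "w") as handle:
        json.dump(truth_obj, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return paths
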