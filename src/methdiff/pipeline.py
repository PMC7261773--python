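"""Stage orchestration: profile -> dmr -> associate behind one config.

Every output file starts with a provenance header (package version, a hash
of the effective configuration, the seed), so a result can always be traced
back to the exact parameters that produced it.  Re-running with identical
inputs and config reproduces identical output bytes; on a stage failure the
files written so far are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import association as assoc
from . import dmr as dmrmod
from . import io as mio
from . import profiles
from .io import CONTEXTS

log = logging.getLogger("methdiff")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults are the method's standard operating point: joint
    coverage >= 3 reads, 100-bp windows at 25-bp steps, BH q < 0.05 with a
    1.2 region fold-change filter, 2-kb flanks, >=4-fold DEGs, FPKM < 1 as
    not expressed.
    """

    report_a: str | Path
    report_b: str | Path
    outdir: str | Path
    gff: str | Path | None = None
    expression: str | Path | None = None
    chrom_lengths: str | Path | dict[str, int] | None = None

    min_total_reads: int = 3
    window_size: int = 100
    step: int = 25
    min_sites: int = 4
    alpha: float = 0.05
    fc_threshold: float | None = 1.2
    merge_gap: int = 0
    flank: int = 2000
    min_abs_fc: float = 4.0
    min_fpkm: float = 1.0
    fdr_alpha: float = 0.05
    divergence_fc: float = 1.2
    strong_fc: float = 2.0
    bin_size: int = 50_000
    length_breaks: tuple[int, ...] = (200, 400, 600, 800, 1000)
    contexts: tuple[str, ...] = CONTEXTS
    seed: int = 0
    n_random: int | None = None
    write_windows: bool = False

    def validate(self) -> None:
        for context in self.contexts:
            if context not in CONTEXTS:
                raise ValueError(f"unknown context token {context!r}")
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")

    _PATH_FIELDS = ("report_a", "report_b", "outdir", "gff", "expression",
                    "chrom_lengths")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis written to a different location hashes identically)."""
        payload = {
            k: v for k, v in dataclasses.asdict(self).items()
            if k not in self._PATH_FIELDS
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome, length."""
    lengths = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            lengths[chrom] = int(length)
    return lengths


def infer_chrom_lengths(*samples: pd.DataFrame) -> dict[str, int]:
    """Fallback when no lengths table is declared: max position + 1."""
    lengths: dict[str, int] = {}
    for sample in samples:
        for chrom, grp in sample.groupby("chrom"):
            lengths[chrom] = max(lengths.get(chrom, 0), int(grp["pos"].max()) + 1)
    return lengths


class _OutputWriter:
    """Writes provenance-headed outputs and can roll them back on failure."""

    def __init__(self, outdir: Path, cfg: PipelineConfig):
        self.outdir = outdir
        self.header = (
            f"# methdiff v{__version__}\n"
            f"# config_hash={cfg.config_hash()}\n"
            f"# seed={cfg.seed}\n"
        )
        self.written: list[Path] = []

    def table(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        with open(path, "w") as handle:
            handle.write(self.header)
            df.to_csv(handle, sep="\t", index=False, lineterminator="\n")
        self.written.append(path)
        return path

    def custom(self, name: str, writer) -> Path:
        path = self.outdir / name
        with open(path, "w") as handle:
            handle.write(self.header)
            writer(handle)
        self.written.append(path)
        return path

    def rollback(self) -> None:
        for path in self.written:
            path.unlink(missing_ok=True)


def profile_stage(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    pair: pd.DataFrame,
    chrom_lengths: dict[str, int],
    cfg: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    _, mc_a = profiles.call_mcs(sample_a, cfg.min_total_reads)
    _, mc_b = profiles.call_mcs(sample_b, cfg.min_total_reads)
    results = {
        "mc_summary_a": mc_a,
        "mc_summary_b": mc_b,
        "bin_profiles_a": profiles.bin_profiles(
            sample_a, chrom_lengths, cfg.bin_size, cfg.min_total_reads
        ),
        "bin_profiles_b": profiles.bin_profiles(
            sample_b, chrom_lengths, cfg.bin_size, cfg.min_total_reads
        ),
        "correlations_level": profiles.chromosome_correlations(pair, by="level"),
        "correlations_presence": profiles.chromosome_correlations(pair, by="presence"),
        "divergence": profiles.divergence_summary(
            pair, fc_threshold=cfg.divergence_fc, strong_fc=cfg.strong_fc
        ),
    }
    return results


def dmr_stage(
    pair: pd.DataFrame, chrom_lengths: dict[str, int], cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Window testing, calling and merging for every configured context."""
    if not cfg.contexts:
        empty = pd.DataFrame(columns=dmrmod.DMR_COLUMNS)
        return pd.DataFrame(columns=dmrmod.WINDOW_COLUMNS), empty.copy(), empty
    windows_all, premerge_all, merged_all = [], [], []
    for context in cfg.contexts:
        windows = dmrmod.test_windows(
            pair, chrom_lengths, context,
            size=cfg.window_size, step=cfg.step, min_sites=cfg.min_sites,
        )
        log.info("context %s: %d tested windows (BH family size)", context, len(windows))
        premerge = dmrmod.call_dmrs(windows, alpha=cfg.alpha, fc_threshold=cfg.fc_threshold)
        merged = (
            dmrmod.merge_adjacent(premerge, pair, max_gap=cfg.merge_gap)
            if not premerge.empty
            else premerge
        )
        log.info(
            "context %s: %d significant windows, %d merged DMRs",
            context, len(premerge), len(merged),
        )
        windows_all.append(windows)
        premerge_all.append(premerge)
        merged_all.append(merged)
    windows = pd.concat(windows_all, ignore_index=True)
    premerge = pd.concat(premerge_all, ignore_index=True)
    merged = pd.concat(merged_all, ignore_index=True)
    merged = merged.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    return windows, premerge, merged


def associate_stage(
    merged: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    cfg: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    annotations, location_summary = dmrmod.annotate_dmrs(merged, genes, flank=cfg.flank)
    classes = assoc.classify_expression(
        expression, fdr_alpha=cfg.fdr_alpha, min_fpkm=cfg.min_fpkm
    )
    groups = assoc.assign_dmr_groups(genes, annotations)
    summary, tests = assoc.foldchange_comparison(
        classes, groups, min_abs_fc=cfg.min_abs_fc,
        n_random=cfg.n_random, seed=cfg.seed,
    )
    return {
        "dmr_annotations": annotations,
        "dmr_location_summary": location_summary,
        "expression_classes": classes,
        "dmr_groups": groups,
        "association_summary": summary,
        "association_tests": tests,
        "dmr_gene_percentages": assoc.dmr_gene_percentages(classes, groups),
    }


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages; writes TSV/BED outputs under ``cfg.outdir``.

    Raises before any computation when an input is missing or the config is
    invalid; removes partial outputs when a stage fails.
    """
    cfg.validate()
    for name in ("report_a", "report_b", "gff", "expression"):
        path = getattr(cfg, name)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{name}: {path}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    writer = _OutputWriter(outdir, cfg)
    try:
        log.info("methdiff v%s  config_hash=%s seed=%d",
                 __version__, cfg.config_hash(), cfg.seed)
        sample_a = mio.read_cytosine_report(cfg.report_a, cfg.min_total_reads)
        sample_b = mio.read_cytosine_report(cfg.report_b, cfg.min_total_reads)
        if isinstance(cfg.chrom_lengths, dict):
            chrom_lengths = cfg.chrom_lengths
        elif cfg.chrom_lengths is not None:
            chrom_lengths = read_chrom_lengths(cfg.chrom_lengths)
        else:
            chrom_lengths = infer_chrom_lengths(sample_a, sample_b)
        pair = profiles.pair_samples(sample_a, sample_b, cfg.min_total_reads)
        log.info("paired sites covered >=%d in both samples: %d",
                 cfg.min_total_reads, len(pair))

        results = profile_stage(sample_a, sample_b, pair, chrom_lengths, cfg)
        for name, df in results.items():
            writer.table(df, f"{name}.tsv")

        windows, premerge, merged = dmr_stage(pair, chrom_lengths, cfg)
        results.update(
            {"windows": windows, "dmrs_premerge": premerge, "dmrs": merged}
        )
        if cfg.write_windows:
            writer.table(windows, "windows.tsv")
        writer.custom("dmrs_premerge.bed", lambda h: mio.write_dmrs_bed(premerge, h))
        writer.custom("dmrs.bed", lambda h: mio.write_dmrs_bed(merged, h))
        writer.table(
            dmrmod.length_distribution(merged, list(cfg.length_breaks)),
            "dmr_length_distribution.tsv",
        )

        if cfg.gff is not None and cfg.expression is not None:
            genes = mio.read_gene_models(cfg.gff)
            expression = mio.read_expression_table(cfg.expression)
            assoc_results = associate_stage(merged, genes, expression, cfg)
            results.update(assoc_results)
            for name, df in assoc_results.items():
                writer.table(df, f"{name}.tsv")
        log.info("pipeline finished: %d output files", len(writer.written))
        return results
    except Exception:
        log.exception("pipeline failed; removing partial outputs")
        writer.rollback()
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
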