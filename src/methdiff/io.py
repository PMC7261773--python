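"""Readers and writers for the formats the pipeline touches.

Cytosine count reports follow the Bismark cytosine/CX report dialect:
tab-separated ``chrom, pos (1-based), strand, count_methylated,
count_unmethylated, context[, trinucleotide]``.  Gene models come from GFF3,
expression tables from a headered TSV, and DMRs are written as BED6+2.

All coordinates are 0-based half-open in memory; 1-based dialects are
converted at the boundary (and back on write), so the conversion is an
involution.
"""

from __future__ import annotations

import contextlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


@contextlib.contextmanager
def _writable(path_or_handle):
    """Accept a path or an already-open text handle."""
    if hasattr(path_or_handle, "write"):
        yield path_or_handle
    else:
        with open(path_or_handle, "w") as handle:
            yield handle

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: column order of the in-memory cytosine site table
SITE_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "covered"]

EXPRESSION_COLUMNS = ["gene_id", "fpkm_a", "fpkm_b", "log2fc", "fdr"]

DMR_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tfold_change\tq_value"


class ReportParseError(ValueError):
    """Raised when a cytosine report line cannot be interpreted."""


@dataclass(frozen=True)
class CytosineSite:
    """One strand-specific cytosine with read-count evidence.

    ``pos`` is 0-based (internal convention); the report dialect is 1-based.
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative read count")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 0-based half-open, with the strand that defines
    its upstream/downstream flanks."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm_a: float
    fpkm_b: float
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"gene {self.gene_id}: fdr {self.fdr} outside [0, 1]")
        if self.fpkm_a < 0 or self.fpkm_b < 0:
            raise ValueError(f"gene {self.gene_id}: negative FPKM")


# ---------------------------------------------------------------------------
# cytosine reports


def read_cytosine_report(path: str | Path, min_total_reads: int = 0) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a site table.

    Sites with fewer than ``min_total_reads`` total reads are retained but
    flagged ``covered=False`` — coverage filtering is a joint decision made
    later when the two samples are paired.

    Returns a DataFrame with columns :data:`SITE_COLUMNS`, sorted by
    (chrom, pos, strand), positions 0-based.
    """
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    rows = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise ReportParseError(
                    f"line {lineno}: expected 6 or 7 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, nm_s, nu_s, context = fields[:6]
            try:
                pos = int(pos_s)
                n_meth = int(nm_s)
                n_unmeth = int(nu_s)
            except ValueError as exc:
                raise ReportParseError(f"line {lineno}: {exc}") from None
            if pos < 1:
                raise ReportParseError(f"line {lineno}: position {pos} is not 1-based")
            if n_meth < 0 or n_unmeth < 0:
                raise ReportParseError(f"line {lineno}: negative read count")
            if strand not in STRANDS:
                raise ReportParseError(f"line {lineno}: unknown strand {strand!r}")
            if context not in CONTEXTS:
                raise ReportParseError(f"line {lineno}: unknown context {context!r}")
            rows.append((chrom, pos - 1, strand, n_meth, n_unmeth, context))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
    )
    if df.empty:
        df = df.astype({"pos": np.int64, "n_meth": np.int64, "n_unmeth": np.int64})
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ReportParseError(
            f"duplicate site ({first.chrom}, {first.pos + 1}, {first.strand})"
        )
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    df["covered"] = (df["n_meth"] + df["n_unmeth"]) >= min_total_reads
    return df


def write_cytosine_report(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table back to the 1-based report dialect (6 columns)."""
    with _writable(path) as handle:
        for chrom, pos, strand, nm, nu, context in zip(
            sites["chrom"], sites["pos"], sites["strand"],
            sites["n_meth"], sites["n_unmeth"], sites["context"],
        ):
            handle.write(f"{chrom}\t{pos + 1}\t{strand}\t{nm}\t{nu}\t{context}\n")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read ``gene`` features from a GFF3 file.

    GFF3 1-based closed intervals are converted to 0-based half-open.
    Returns a DataFrame with columns gene_id, chrom, start, end, strand.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise ValueError(
                f"gene feature at {feat.seqid}:{feat.start}-{feat.end} lacks an ID attribute"
            )
        gene_id = feat.attributes["ID"][0]
        if feat.end < feat.start:
            raise ValueError(f"gene {gene_id}: end < start")
        model = GeneModel(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand)
        rows.append(
            (model.gene_id, model.chrom, model.start, model.end, model.strand)
        )
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64})
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as a minimal GFF3 (1-based closed intervals)."""
    with _writable(path) as handle:
        handle.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            handle.write(
                f"{row.chrom}\tmethdiff\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-level expression table (TSV, header
    ``gene_id fpkm_a fpkm_b log2fc fdr``) and validate every record."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str}, comment="#",
        float_precision="round_trip",
    )
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    df = df[EXPRESSION_COLUMNS]
    for rec in df.itertuples(index=False):
        ExpressionRecord(*rec)  # invariant validation
    return df.reset_index(drop=True)


def write_expression_table(records: pd.DataFrame, path: str | Path) -> None:
    with _writable(path) as handle:
        handle.write("\t".join(EXPRESSION_COLUMNS) + "\n")
        for row in records.itertuples(index=False):
            handle.write(
                f"{row.gene_id}\t{float(row.fpkm_a)!r}\t{float(row.fpkm_b)!r}\t"
                f"{float(row.log2fc)!r}\t{float(row.fdr)!r}\n"
            )


# ---------------------------------------------------------------------------
# DMR BED


def bed_score(q_value: float) -> int:
    """-10*log10(q), rounded and capped at 1000 (q=0 maps to the cap)."""
    if q_value <= 0.0:
        return 1000
    return int(round(min(1000.0, -10.0 * math.log10(q_value))))


def write_dmrs_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write DMRs as BED6+2 (0-based half-open).

    name = ``context:trend``, score = capped ``-10*log10(q)``, strand is
    ``.`` (regions are unstranded), then fold_change and q_value columns.
    Floats are written with full ``repr`` precision so a write -> read
    round-trip is exact.
    """
    with _writable(path) as handle:
        handle.write(DMR_BED_HEADER + "\n")
        for row in dmrs.itertuples(index=False):
            fc = row.fold_change
            fc_s = "inf" if math.isinf(fc) else repr(float(fc))
            handle.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.context}:{row.trend}\t"
                f"{bed_score(row.q_value)}\t.\t{fc_s}\t{float(row.q_value)!r}\n"
            )


def read_dmrs_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6+2 DMR file back into the in-memory DMR table."""
    rows = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ValueError(f"line {lineno}: expected 8 BED fields")
            chrom, start, end, name, _score, _strand, fc, q = fields
            context, trend = name.split(":", 1)
            rows.append(
                (chrom, int(start), int(end), context, trend, float(fc), float(q))
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "trend", "fold_change", "q_value"],
    )
    if df.empty:
        df = df.astype(
            {"start": np.int64, "end": np.int64, "fold_change": float, "q_value": float}
        )
    return df


def sites_from_records(records: Iterable[CytosineSite]) -> pd.DataFrame:
    """Build a site table from :class:`CytosineSite` records (mainly for tests)."""
    rows = [
        (r.chrom, r.pos, r.strand, r.n_meth, r.n_unmeth, r.context) for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
    )
    df["covered"] = True
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
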