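"""Readers and writers for the pipeline's external formats.

This is the single place on-disk coordinate conventions are translated:
everything downstream sees 0-based half-open intervals (BED-compatible).
The cytosine-report dialect is 1-based on disk; the shift happens here and
nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger("nomepipe")

VALID_CONTEXTS = ("WCG", "GCH", "GCG", "CCG", "OTHER")

#: Column schema for per-cytosine site tables used throughout the pipeline.
SITE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine with strand, trinucleotide context class and call counts."""

    interval: GenomicInterval
    strand: str
    context: str
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise ValueError("CytosineSite interval must have width 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.meth_count < 0 or self.total_count < 0:
            raise ValueError("counts must be non-negative")
        if self.meth_count > self.total_count:
            raise ValueError("meth_count must be <= total_count")


@dataclass(frozen=True)
class GeneRecord:
    """Gene model with biotype and strand-aware TSS/TES.

    ``tss`` is the 5' end of the gene (transcription start), ``tes`` the
    3' end, both as 0-based genomic coordinates; for a minus-strand gene
    ``tss > tes``.  ``length_bp`` is the exonic length used for RPKM when
    exon structure is known, else the TSS-TES span.
    """

    gene_id: str
    biotype: str
    strand: str
    tss: int
    tes: int
    chrom: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.biotype not in ("coding", "lncRNA"):
            raise ValueError(f"biotype must be coding/lncRNA, got {self.biotype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if self.length_bp <= 0:
            raise ValueError(f"gene {self.gene_id}: length_bp must be positive")

    @property
    def span(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi)

    def promoter(self, upstream: int = 1000, downstream: int = 500) -> GenomicInterval:
        """Strand-aware promoter: ``upstream`` bp 5' of the TSS through
        ``downstream`` bp 3' of it (defaults -1 kb/+0.5 kb)."""
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream, self.tss + upstream
        return GenomicInterval(self.chrom, max(0, start), end)


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "lnc_rna": "lncRNA",
}


def read_cytosine_report(path: str | Path, dialect: str = "cytosine_report") -> pd.DataFrame:
    """Read a per-cytosine methylation call table into the site schema.

    Dialects
    --------
    ``cytosine_report``
        Bismark genome-wide cytosine report style: chrom, 1-based position,
        strand, methylated count, unmethylated count, then optional context
        columns. Positions are shifted to 0-based here.
    ``bismark_cov``
        Bismark coverage file: chrom, 1-based start, 1-based end, percent
        methylation, methylated count, unmethylated count.  No strand or
        context: both come back unset ('.' / 'OTHER') and must be annotated
        from the reference before quantification.
    """
    path = Path(path)
    if dialect not in ("cytosine_report", "bismark_cov"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "cytosine_report":
                    chrom, pos1, strand, meth, unmeth = fields[:5]
                    context = fields[5] if len(fields) > 5 else "OTHER"
                    if context not in VALID_CONTEXTS:
                        context = "OTHER"
                    pos = int(pos1) - 1
                else:  # bismark_cov
                    chrom, pos1, _end1, _pct, meth, unmeth = fields[:6]
                    strand, context = ".", "OTHER"
                    pos = int(pos1) - 1
                meth_n, unmeth_n = int(meth), int(unmeth)
                if pos < 0 or meth_n < 0 or unmeth_n < 0:
                    raise ValueError("negative value")
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {line!r} ({exc})"
                ) from None
            rows.append((chrom, pos, strand, context, meth_n, meth_n + unmeth_n))

    if not rows:
        logger.warning("%s: empty cytosine report", path)
        return pd.DataFrame(columns=SITE_COLUMNS)
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


def write_cytosine_report(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table in the ``cytosine_report`` dialect (1-based)."""
    out = sites[SITE_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out["unmeth"] = out["total"] - out["meth"]
    out[["chrom", "pos", "strand", "meth", "unmeth", "context"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read gene models from a GTF (``gene`` feature lines) or BED6+ file.

    BED layout: chrom, start, end, gene_id, biotype, strand[, length_bp].
    TSS/TES are assigned strand-aware: the TSS is the 5' end.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9 and fields[2] != "":
                is_gtf = not fields[1].isdigit()
            else:
                is_gtf = False
            try:
                if is_gtf:
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])  # GTF is 1-based closed
                    strand = fields[6]
                    attrs = _parse_gtf_attributes(fields[8])
                    gene_id = attrs["gene_id"]
                    raw_biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
                else:
                    chrom, start_s, end_s, gene_id, raw_biotype, strand = fields[:6]
                    start, end = int(start_s), int(end_s)
                length = int(fields[6]) if (not is_gtf and len(fields) > 6) else end - start
            except (ValueError, IndexError, KeyError) as exc:
                raise ValueError(
                    f"{path}: malformed gene row at line {lineno}: {line!r} ({exc})"
                ) from None
            if raw_biotype not in _BIOTYPE_MAP:
                continue  # other biotypes out of scope
            if end <= start:
                raise ValueError(f"{path}: gene {gene_id} has zero length")
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    biotype=_BIOTYPE_MAP[raw_biotype],
                    strand=strand,
                    tss=tss,
                    tes=tes,
                    chrom=chrom,
                    length_bp=length,
                )
            )
    return genes


def write_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene models in the BED6+1 layout read_genes accepts."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            fh.write(
                f"{g.chrom}\t{span.start}\t{span.end}\t{g.gene_id}\t"
                f"{g.biotype}\t{g.strand}\t{g.length_bp}\n"
            )


# ---------------------------------------------------------------------------
# region tables (BED)
# ---------------------------------------------------------------------------


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    """Write an interval table as BED (0-based half-open).

    ``regions`` must carry chrom/start/end; any further columns are written
    after column 3 in order, so the matching reader round-trips losslessly.
    """
    required = ["chrom", "start", "end"]
    missing = [c for c in required if c not in regions.columns]
    if missing:
        raise ValueError(f"regions table lacks columns: {missing}")
    extra = [c for c in regions.columns if c not in required]
    out = regions[required + extra].sort_values(
        ["chrom", "start", "end"], kind="stable"
    )
    header = "\t".join(["#chrom", "start", "end"] + extra)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read a BED written by :func:`write_regions` (header names the columns)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.startswith("#"):
        raise ValueError(f"{path}: expected '#chrom\\tstart\\tend...' header")
    names = header.lstrip("#").split("\t")
    names[0] = "chrom"
    df = pd.read_csv(path, sep="\t", skiprows=1, names=names, header=None)
    if df.empty:
        return pd.DataFrame(columns=names)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in intervals],
        columns=["chrom", "start", "end"],
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def validate_sites(sites: pd.DataFrame) -> None:
    """Raise if a site table violates the schema invariants."""
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks columns: {missing}")
    if len(sites) == 0:
        return
    if (sites["pos"] < 0).any():
        raise ValueError("negative positions")
    if (sites["meth"] > sites["total"]).any():
        raise ValueError("meth > total at some sites")
    if (sites["meth"] < 0).any() or (sites["total"] < 0).any():
        raise ValueError("negative counts")
    bad = set(sites["context"].unique()) - set(VALID_CONTEXTS)
    if bad:
        raise ValueError(f"unknown contexts: {sorted(bad)}")
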