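"""Coverage filtering and level computation for sites, regions and profiles.

Both channels go through the same machinery: WCG sites give DNA methylation,
GCH sites give chromatin accessibility.  Per-site level is methylated calls
over total calls; region level is the unweighted mean of per-site levels
(the pooled-count ratio is available behind a flag for sensitivity checks).
Sites need >= 3x depth and regions >= 3 qualifying sites to be reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomicInterval, GeneRecord

logger = logging.getLogger("nomepipe")

MIN_DEPTH = 3
MIN_SITES = 3


@dataclass(frozen=True)
class RegionLevel:
    """Methylation or accessibility level of one region.

    ``level`` is NaN when fewer than ``min_sites`` qualifying sites fall in
    the region (the region is reported but flagged undefined).
    """

    interval: GenomicInterval
    channel: str
    n_sites: int
    level: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.level)


def filter_sites(
    sites: pd.DataFrame, channel: str, min_depth: int = MIN_DEPTH
) -> pd.DataFrame:
    """Retain sites of the requested context class at sufficient depth.

    GCG/CCG/OTHER contexts are always dropped: GCG is ambiguous between the
    two signals and CCG is an M.CviPI off-target context.
    """
    if channel not in ("WCG", "GCH"):
        raise ValueError(f"channel must be WCG or GCH, got {channel!r}")
    keep = (sites["context"] == channel) & (sites["total"] >= min_depth)
    return sites.loc[keep].reset_index(drop=True)


def site_level(meth, total):
    """Per-site level: methylated calls / total calls (scalar or vector)."""
    total_arr = np.asarray(total, dtype=float)
    if np.any(total_arr == 0):
        raise ValueError("site level undefined at zero total count")
    return np.asarray(meth, dtype=float) / total_arr


def region_level(
    sites: pd.DataFrame,
    interval: GenomicInterval,
    channel: str,
    min_sites: int = MIN_SITES,
    pooled: bool = False,
) -> RegionLevel:
    """Level of one region from pre-filtered sites.

    Default is the unweighted mean of per-site levels; ``pooled=True`` uses
    the pooled-count ratio instead.
    """
    sel = sites[
        (sites["chrom"] == interval.chrom)
        & (sites["pos"] >= interval.start)
        & (sites["pos"] < interval.end)
    ]
    n = len(sel)
    if n < min_sites:
        return RegionLevel(interval, channel, n, float("nan"))
    if pooled:
        level = float(sel["meth"].sum()) / float(sel["total"].sum())
    else:
        level = float(np.mean(site_level(sel["meth"], sel["total"])))
    return RegionLevel(interval, channel, n, level)


def global_level(sites: pd.DataFrame, channel: str | None = None) -> float:
    """Genome-wide mean of per-site levels over retained sites.

    Also serves as the whole-genome background estimate for NDR calling.
    """
    if channel is not None:
        sites = sites[sites["context"] == channel]
    if len(sites) == 0:
        raise ValueError("no sites; global level undefined")
    return float(np.mean(site_level(sites["meth"], sites["total"])))


def genome_bins(chrom_sizes: dict[str, int], width: int = 1000) -> pd.DataFrame:
    """Tile each chromosome into fixed-width bins; the last may be short."""
    if width <= 0:
        raise ValueError("width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"{chrom}: size must be positive")
        starts = np.arange(0, size, width)
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def bin_levels(
    sites: pd.DataFrame,
    bins: pd.DataFrame,
    min_sites: int = MIN_SITES,
    pooled: bool = False,
) -> pd.DataFrame:
    """Vectorised region_level over a tiling of bins (one chromosome set).

    Returns the bin table with n_sites and level columns (NaN where fewer
    than ``min_sites`` sites).  Bins must be sorted and non-overlapping per
    chromosome.
    """
    out = bins.copy()
    out["n_sites"] = 0
    out["level"] = np.nan
    lv = site_level(sites["meth"], sites["total"]) if len(sites) else np.array([])
    sites = sites.assign(_level=lv)
    for chrom, chrom_bins in out.groupby("chrom", sort=False):
        csites = sites[sites["chrom"] == chrom].sort_values("pos", kind="stable")
        if csites.empty:
            continue
        pos = csites["pos"].to_numpy()
        levels = csites["_level"].to_numpy()
        meth = csites["meth"].to_numpy(dtype=float)
        total = csites["total"].to_numpy(dtype=float)
        lo = np.searchsorted(pos, chrom_bins["start"].to_numpy())
        hi = np.searchsorted(pos, chrom_bins["end"].to_numpy())
        n = hi - lo
        cl = np.concatenate([[0.0], np.cumsum(levels)])
        cm = np.concatenate([[0.0], np.cumsum(meth)])
        ct = np.concatenate([[0.0], np.cumsum(total)])
        with np.errstate(invalid="ignore", divide="ignore"):
            if pooled:
                val = (cm[hi] - cm[lo]) / (ct[hi] - ct[lo])
            else:
                val = (cl[hi] - cl[lo]) / n
        val[n < min_sites] = np.nan
        out.loc[chrom_bins.index, "n_sites"] = n
        out.loc[chrom_bins.index, "level"] = val
    return out


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

FLANK_BP = 2000
FLANK_BINS = 100
BODY_BINS = 100
TSS_BINS = 200
TSS_BIN_BP = 20


def _per_gene_bin_means(
    pos: np.ndarray, level: np.ndarray, edges: np.ndarray, reverse: bool
) -> np.ndarray:
    """Mean site level per bin given monotone bin edges; NaN where empty."""
    nbins = len(edges) - 1
    idx = np.searchsorted(edges, pos, side="right") - 1
    ok = (idx >= 0) & (idx < nbins) & (pos >= edges[0]) & (pos < edges[-1])
    sums = np.bincount(idx[ok], weights=level[ok], minlength=nbins)
    counts = np.bincount(idx[ok], minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    if reverse:
        means = means[::-1]
    return means


def genebody_profile(
    sites: pd.DataFrame,
    genes: list[GeneRecord],
    channel: str,
    flank_bp: int = FLANK_BP,
    body_bins: int = BODY_BINS,
    flank_bins: int = FLANK_BINS,
) -> np.ndarray:
    """Metagene profile over gene bodies with fixed-width flanks.

    Layout: ``flank_bins`` upstream bins of ``flank_bp/flank_bins`` bp each,
    ``body_bins`` proportional bins over TSS..TES, and the downstream flank —
    300 bins by default, bin 0 always 5'-most.  Per gene the mean site level
    per bin is taken; the profile is the across-gene mean, skipping bins a
    gene does not cover.
    """
    if not genes:
        raise ValueError("empty gene list")
    sites = filter_sites(sites, channel)
    flank_width = flank_bp / flank_bins
    per_gene = []
    for g in genes:
        span = g.span
        if len(span) < 100:
            logger.warning("gene %s shorter than 100 bp; skipped", g.gene_id)
            continue
        csites = sites[sites["chrom"] == g.chrom].sort_values("pos", kind="stable")
        pos = csites["pos"].to_numpy(dtype=float)
        lev = (
            site_level(csites["meth"], csites["total"])
            if len(csites)
            else np.array([])
        )
        up_edges = span.start - flank_bp + flank_width * np.arange(flank_bins + 1)
        body_edges = span.start + (span.end - span.start) * np.linspace(0, 1, body_bins + 1)
        dn_edges = span.end + flank_width * np.arange(flank_bins + 1)
        rows = np.concatenate(
            [
                _per_gene_bin_means(pos, lev, up_edges, reverse=False),
                _per_gene_bin_means(pos, lev, body_edges, reverse=False),
                _per_gene_bin_means(pos, lev, dn_edges, reverse=False),
            ]
        )
        if g.strand == "-":
            rows = rows[::-1]
        per_gene.append(rows)
    if not per_gene:
        raise ValueError("no usable genes for profile")
    stack = np.vstack(per_gene)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)


def tss_profile(
    sites: pd.DataFrame,
    genes: list[GeneRecord],
    channel: str,
    n_bins: int = TSS_BINS,
    bin_bp: int = TSS_BIN_BP,
) -> np.ndarray:
    """Strand-oriented profile of 20-bp bins across +-2 kb around the TSS."""
    if not genes:
        raise ValueError("empty gene list")
    sites = filter_sites(sites, channel)
    half = n_bins * bin_bp // 2
    per_gene = []
    for g in genes:
        csites = sites[sites["chrom"] == g.chrom].sort_values("pos", kind="stable")
        pos = csites["pos"].to_numpy(dtype=float)
        lev = (
            site_level(csites["meth"], csites["total"])
            if len(csites)
            else np.array([])
        )
        edges = g.tss - half + bin_bp * np.arange(n_bins + 1, dtype=float)
        per_gene.append(_per_gene_bin_means(pos, lev, edges, reverse=g.strand == "-"))
    stack = np.vstack(per_gene)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=0)
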