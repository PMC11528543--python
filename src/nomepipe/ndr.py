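"""Nucleosome-depleted region (NDR) calling from GCH accessibility.

M.CviPI methylates GpC cytosines only where chromatin is open, so spans of
elevated GCH level mark nucleosome depletion.  Calling proceeds over 100-bp
windows slid in 20-bp steps: window GCH calls are pooled and tested against
the whole-genome background with a 1-df chi-squared goodness-of-fit test
(plus an explicit level > background direction gate).  Windows passing at
p <= 1e-10 are merged; merged candidates need >= 5 distinct GCH sites and
length >= 140 bp.  Per-sample NDR sets are combined by multi-intersection
semantics, and NDRs overlapping a promoter are proximal, the rest distal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval, GeneRecord
from .quant import MIN_DEPTH, filter_sites, global_level, site_level

WINDOW_WIDTH = 100
WINDOW_STEP = 20
P_MAX = 1e-10
MIN_GCH_SITES = 5
MIN_LENGTH = 140
CONNECT_GAP = 10

NDR_COLUMNS = ["chrom", "start", "end", "n_gch_sites", "level", "background", "chi2_p"]


def sliding_windows(
    chrom_sizes: dict[str, int],
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """Overlapping windows at starts 0, step, 2*step, ...; tail truncated."""
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"{chrom}: size must be positive")
        if size >= width:
            starts = np.arange(0, size - width + step, step)
        else:
            starts = np.array([0])
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def chi2_statistic(meth, total, background):
    """1-df goodness-of-fit statistic of pooled window calls vs background."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    exp_m = background * total
    exp_u = (1.0 - background) * total
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (meth - exp_m) ** 2 / exp_m + ((total - meth) - exp_u) ** 2 / exp_u
    return stat


def window_chi2(meth: int, total: int, background: float) -> float:
    """p-value that pooled window calls deviate from the genomic background.

    Two-sided on the 1-df chi-squared statistic; callers additionally gate
    on observed level > background for one-sided direction.
    """
    if total <= 0:
        raise ValueError("window untestable: zero total coverage")
    if not 0.0 < background < 1.0:
        raise ValueError("background must lie strictly in (0, 1)")
    stat = chi2_statistic(meth, total, background)
    return float(stats.chi2.sf(stat, df=1))


def _merge_touching(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    """Merge sorted windows that overlap or touch into maximal runs."""
    merged: list[tuple[int, int]] = []
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    merged.append((cur_s, cur_e))
    return merged


def call_sample_ndrs(
    sites: pd.DataFrame,
    chrom_sizes: dict[str, int],
    background: float | None = None,
    p_max: float = P_MAX,
    min_sites: int = MIN_GCH_SITES,
    min_length: int = MIN_LENGTH,
    width: int = WINDOW_WIDTH,
    step: int = WINDOW_STEP,
    min_depth: int = MIN_DEPTH,
    candidate_gap: int | None = None,
) -> pd.DataFrame:
    """Call NDRs for one sample.

    ``background`` defaults to the sample's global GCH level over retained
    sites.  Windows are scored on pooled counts; significant windows are
    merged into candidate regions, with runs separated by less than one
    window width (``candidate_gap``, default ``width``) connected — sparse
    GCH stretches inside an open region can interrupt a run of significant
    windows.  Every candidate must then itself satisfy the region criteria:
    chi-squared p <= ``p_max`` against the background over the merged span,
    >= ``min_sites`` distinct GCH sites and length >= ``min_length``; the
    reported region level is the site-mean over the span.
    """
    if candidate_gap is None:
        candidate_gap = width
    gch = filter_sites(sites, "GCH", min_depth=min_depth)
    if background is None:
        if gch.empty:
            raise ValueError("no GCH sites; background not computable")
        background = global_level(gch)
    if not 0.0 < background < 1.0:
        raise ValueError("background must lie strictly in (0, 1)")

    windows = sliding_windows(chrom_sizes, width=width, step=step)
    out_rows = []
    for chrom, cw in windows.groupby("chrom", sort=False):
        csites = gch[gch["chrom"] == chrom].sort_values("pos", kind="stable")
        if csites.empty:
            continue
        pos = csites["pos"].to_numpy()
        meth = csites["meth"].to_numpy(dtype=float)
        total = csites["total"].to_numpy(dtype=float)
        levels = site_level(meth, total)
        cm = np.concatenate([[0.0], np.cumsum(meth)])
        ct = np.concatenate([[0.0], np.cumsum(total)])
        cl = np.concatenate([[0.0], np.cumsum(levels)])

        w_start = cw["start"].to_numpy()
        w_end = cw["end"].to_numpy()
        lo = np.searchsorted(pos, w_start)
        hi = np.searchsorted(pos, w_end)
        w_meth = cm[hi] - cm[lo]
        w_total = ct[hi] - ct[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            w_level = w_meth / w_total
        stat = chi2_statistic(w_meth, w_total, background)
        pvals = stats.chi2.sf(stat, df=1)
        keep = (w_total > 0) & (w_level > background) & (pvals <= p_max)
        if not keep.any():
            continue

        runs = _merge_touching(w_start[keep], w_end[keep])
        candidates = [runs[0]]
        for s, e in runs[1:]:
            if s - candidates[-1][1] < candidate_gap:
                candidates[-1] = (candidates[-1][0], e)
            else:
                candidates.append((s, e))

        for cand_s, cand_e in candidates:
            i0 = int(np.searchsorted(pos, cand_s))
            i1 = int(np.searchsorted(pos, cand_e))
            n_sites = i1 - i0
            if n_sites < min_sites or cand_e - cand_s < min_length:
                continue
            region_meth = cm[i1] - cm[i0]
            region_total = ct[i1] - ct[i0]
            region_level = (cl[i1] - cl[i0]) / n_sites
            region_p = float(
                stats.chi2.sf(chi2_statistic(region_meth, region_total, background), df=1)
            )
            if region_level <= background or region_p > p_max:
                continue
            out_rows.append(
                (chrom, cand_s, cand_e, n_sites, region_level, background, region_p)
            )
    return pd.DataFrame(out_rows, columns=NDR_COLUMNS)


def merge_group_ndrs(
    ndr_sets: list[pd.DataFrame],
    connect_gap: int = CONNECT_GAP,
    min_samples: int = 1,
) -> pd.DataFrame:
    """Combine per-sample NDR sets by multi-intersection semantics.

    The union of all samples' NDRs is partitioned at every interval
    boundary; partition segments covered by >= ``min_samples`` samples are
    retained (default 1 = union) and retained segments separated by
    <= ``connect_gap`` bp are connected.
    """
    if not ndr_sets:
        raise ValueError("need at least one sample NDR set")
    stacked = pd.concat(
        [df.assign(_sample=i) for i, df in enumerate(ndr_sets)], ignore_index=True
    )
    cols = ["chrom", "start", "end"]
    if stacked.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, grp in stacked.groupby("chrom", sort=True):
        edges = np.unique(
            np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()])
        )
        seg_s, seg_e = edges[:-1], edges[1:]
        # coverage = number of distinct samples whose NDRs span the segment
        cover = np.zeros(len(seg_s), dtype=int)
        for _, sgrp in grp.groupby("_sample"):
            hit = np.zeros(len(seg_s), dtype=bool)
            for r in sgrp.itertuples(index=False):
                hit |= (seg_s >= r.start) & (seg_e <= r.end)
            cover += hit
        keep = cover >= min_samples
        if not keep.any():
            continue
        ks, ke = seg_s[keep], seg_e[keep]
        # first merge touching segments, then connect across small gaps
        merged = _merge_touching(ks, ke)
        cur_s, cur_e = merged[0]
        for s, e in merged[1:]:
            if s - cur_e <= connect_gap:
                cur_e = e
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=cols)


def classify_ndrs(
    ndrs: pd.DataFrame,
    genes: list[GeneRecord],
    upstream: int = 1000,
    downstream: int = 500,
) -> pd.DataFrame:
    """Label NDRs proximal (>= 1 bp overlap with a promoter) or distal.

    Promoters are strand-aware: 1 kb upstream through 0.5 kb downstream of
    each TSS.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        prom = g.promoter(upstream=upstream, downstream=downstream)
        trees.setdefault(prom.chrom, IntervalTree()).addi(prom.start, prom.end)
    out = ndrs.copy()
    klass = []
    for r in out.itertuples(index=False):
        tree = trees.get(r.chrom)
        hit = bool(tree is not None and tree.overlap(r.start, r.end))
        klass.append("proximal" if hit else "distal")
    out["klass"] = klass
    return out


def promoters_frame(
    genes: list[GeneRecord], upstream: int = 1000, downstream: int = 500
) -> pd.DataFrame:
    """Promoter intervals for a gene set as a region table."""
    rows = []
    for g in genes:
        prom = g.promoter(upstream=upstream, downstream=downstream)
        rows.append((prom.chrom, prom.start, prom.end, g.gene_id, g.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])
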