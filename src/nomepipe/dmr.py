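"""Differentially methylated window/region calling between two sample groups.

The genome is tiled into 300-bp windows; each window's WCG level is the mean
of per-site levels per sample (>= 3 sites at >= 3x depth, else missing).
Windows are tested with an equal-variance two-sample Student's t test and
BH-adjusted over all tested windows.  A differentially methylated window
(DMW) needs |delta| > 0.20, p <= 0.05 and FDR <= 0.05; same-direction DMWs
within 300 bp are merged into DMRs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .quant import MIN_DEPTH, MIN_SITES, bin_levels, filter_sites, genome_bins

WINDOW_SIZE = 300
DELTA_MIN = 0.20
P_MAX = 0.05
FDR_MAX = 0.05
MERGE_GAP = 300
MIN_GROUP_N = 2  # a t test needs a variance per group


def tile_300bp(chrom_sizes: dict[str, int], width: int = WINDOW_SIZE) -> pd.DataFrame:
    """Non-overlapping 300-bp tiles per chromosome (last may be short)."""
    return genome_bins(chrom_sizes, width=width)


def window_values(
    sites_by_sample: dict[str, pd.DataFrame],
    windows: pd.DataFrame,
    min_sites: int = MIN_SITES,
    min_depth: int = MIN_DEPTH,
) -> pd.DataFrame:
    """Per-sample window WCG levels; NaN where a sample has < 3 WCG sites."""
    out = windows[["chrom", "start", "end"]].copy()
    for sample, sites in sites_by_sample.items():
        wcg = filter_sites(sites, "WCG", min_depth=min_depth)
        out[sample] = bin_levels(wcg, windows, min_sites=min_sites)["level"].to_numpy()
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def test_window(values_g1, values_g2, equal_var: bool = True) -> tuple[float, float]:
    """Effect size and Student's t p-value for one window.

    delta = mean(g1) - mean(g2); identical zero-variance groups come back
    p = 1 (no evidence of difference).  Welch available via equal_var=False.
    """
    a = np.asarray(values_g1, dtype=float)
    b = np.asarray(values_g2, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < MIN_GROUP_N or len(b) < MIN_GROUP_N:
        raise ValueError("each group needs >= 2 non-missing values")
    delta = float(a.mean() - b.mean())
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # zero pooled variance
        p = 1.0 if delta == 0 else 0.0
    return delta, float(p)


def _vectorised_ttest(
    g1: np.ndarray, g2: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t test with per-row NaN dropping.

    Returns (delta, p, testable) over windows (rows).  Matches
    scipy.stats.ttest_ind on each testable row.
    """
    import warnings

    n1 = np.sum(~np.isnan(g1), axis=1)
    n2 = np.sum(~np.isnan(g2), axis=1)
    testable = (n1 >= MIN_GROUP_N) & (n2 >= MIN_GROUP_N)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # all-NaN rows are masked out by `testable` below
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(g1, axis=1)
        m2 = np.nanmean(g2, axis=1)
        v1 = np.nanvar(g1, axis=1, ddof=1)
        v2 = np.nanvar(g2, axis=1, ddof=1)
        delta = m1 - m2
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = delta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = testable & ~np.isfinite(t)
    p[zero_var & (delta == 0)] = 1.0
    p[zero_var & (delta != 0)] = 0.0
    return delta, p, testable


def test_windows(
    values: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Test every window with enough samples per group; BH over tested ones.

    Input is the window_values table; output adds mean_g1/mean_g2/delta/p/q.
    Windows missing in too many samples are dropped (they have no p-value,
    so they do not enter the FDR universe).
    """
    g1 = values[group1].to_numpy(dtype=float)
    g2 = values[group2].to_numpy(dtype=float)
    delta, p, testable = _vectorised_ttest(g1, g2, equal_var)
    out = values.loc[testable, ["chrom", "start", "end"]].copy()
    with np.errstate(invalid="ignore"):
        out["mean_g1"] = np.nanmean(g1[testable], axis=1)
        out["mean_g2"] = np.nanmean(g2[testable], axis=1)
    out["delta"] = delta[testable]
    out["p"] = p[testable]
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.reset_index(drop=True)


def call_dmws(
    tested: pd.DataFrame,
    delta_min: float = DELTA_MIN,
    p_max: float = P_MAX,
    fdr_max: float = FDR_MAX,
) -> pd.DataFrame:
    """Gate tested windows: |delta| strictly > 20 points, p and FDR <= 0.05."""
    keep = (
        (tested["delta"].abs() > delta_min)
        & (tested["p"] <= p_max)
        & (tested["q"] <= fdr_max)
    )
    dmws = tested.loc[keep].copy()
    dmws["direction"] = np.where(dmws["delta"] > 0, "hyper", "hypo")
    return dmws.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def merge_dmrs(dmws: pd.DataFrame, merge_gap: int = MERGE_GAP) -> pd.DataFrame:
    """Merge same-direction DMWs within ``merge_gap`` bp into DMRs.

    Opposite directions never merge.  Output columns: chrom, start, end,
    direction, n_windows, delta (mean of constituent window deltas).
    """
    cols = ["chrom", "start", "end", "direction", "n_windows", "delta"]
    if dmws.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (chrom, direction), grp in dmws.groupby(["chrom", "direction"], sort=False):
        grp = grp.sort_values("start", kind="stable")
        cur_start = cur_end = None
        deltas: list[float] = []
        for r in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, deltas = r.start, r.end, [r.delta]
            elif r.start - cur_end <= merge_gap:
                cur_end = max(cur_end, r.end)
                deltas.append(r.delta)
            else:
                rows.append((chrom, cur_start, cur_end, direction, len(deltas), float(np.mean(deltas))))
                cur_start, cur_end, deltas = r.start, r.end, [r.delta]
        rows.append((chrom, cur_start, cur_end, direction, len(deltas), float(np.mean(deltas))))
    return (
        pd.DataFrame(rows, columns=cols)
        .sort_values(["chrom", "start", "direction"], kind="stable", ignore_index=True)
    )


def call_dmrs(
    group1_sites: dict[str, pd.DataFrame],
    group2_sites: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    window_size: int = WINDOW_SIZE,
    delta_min: float = DELTA_MIN,
    p_max: float = P_MAX,
    fdr_max: float = FDR_MAX,
    merge_gap: int = MERGE_GAP,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full DMR pipeline: tile, quantify, test, gate, merge.

    Returns (tested windows with statistics, merged DMRs).
    """
    windows = tile_300bp(chrom_sizes, width=window_size)
    values = window_values({**group1_sites, **group2_sites}, windows)
    tested = test_windows(
        values, list(group1_sites), list(group2_sites), equal_var=equal_var
    )
    dmws = call_dmws(tested, delta_min=delta_min, p_max=p_max, fdr_max=fdr_max)
    return tested, merge_dmrs(dmws, merge_gap=merge_gap)
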