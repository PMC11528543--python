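"""Expression-side procedures: RPKM, differential expression gating,
lncRNA-coding cis-pairs, isoform ratios, and fetal-program reversal.

The differential test here is a deliberately simple two-group
negative-binomial Wald stand-in (median-of-ratios size factors,
method-of-moments dispersion with a floor) that honours the standard
(log2fc, p) output contract; externally computed per-gene statistics
(e.g. from DESeq2) can be supplied instead wherever a results table is
accepted.  The scientific content downstream of the test — the DEG gates,
the cis-pair criteria, the program set logic — is what this module owns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_fdr
from .io import GeneRecord

LOG2FC_MIN = 0.5
FDR_MAX = 0.05
RPKM_MIN_CODING = 1.0
RPKM_MIN_LNCRNA = 0.1
CIS_MAX_DISTANCE = 100_000
CIS_R_MIN = 0.6
CIS_P_MAX = 0.05
DISPERSION_FLOOR = 0.01


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def rpkm(counts: pd.DataFrame, gene_length_bp: pd.Series, library_size=None) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``counts`` is genes x samples; ``library_size`` defaults to per-sample
    column sums.
    """
    lengths = gene_length_bp.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_size is None:
        library_size = counts.sum(axis=0)
    library_size = pd.Series(library_size, index=counts.columns, dtype=float)
    if (library_size <= 0).any():
        raise ValueError("library size must be positive")
    return counts.div(lengths / 1e3, axis=0).div(library_size / 1e6, axis=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors across samples."""
    logs = np.log(counts.replace(0, np.nan))
    log_geomean = logs.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene expressed in all samples; size factors undefined")
    ratios = logs.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


# ---------------------------------------------------------------------------
# differential test (NB-Wald stand-in)
# ---------------------------------------------------------------------------


def diff_test(counts_g1: pd.DataFrame, counts_g2: pd.DataFrame) -> pd.DataFrame:
    """Two-group negative-binomial Wald test per gene.

    Size factors are estimated over the pooled samples; per-gene dispersion
    by method of moments on normalised counts (pooled within-group, floored
    at 0.01).  log2fc = log2 of normalised group means with pseudocount 1,
    group 1 over group 2.  Returns a frame with gene_id, log2fc, p.
    """
    if counts_g1.shape[1] < 2 or counts_g2.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    if not counts_g1.index.equals(counts_g2.index):
        raise ValueError("gene indexes differ between groups")
    combined = pd.concat([counts_g1, counts_g2], axis=1)
    sf = size_factors(combined)
    norm = combined.div(sf, axis=1)
    n1, n2 = counts_g1.shape[1], counts_g2.shape[1]
    q1 = norm.iloc[:, :n1].to_numpy(dtype=float)
    q2 = norm.iloc[:, n1:].to_numpy(dtype=float)

    mu1 = q1.mean(axis=1)
    mu2 = q2.mean(axis=1)
    log2fc = np.log2((mu1 + 1.0) / (mu2 + 1.0))

    # method-of-moments NB dispersion: var = mu + alpha mu^2, pooled within groups
    v1 = q1.var(axis=1, ddof=1)
    v2 = q2.var(axis=1, ddof=1)
    mu_pooled = (n1 * mu1 + n2 * mu2) / (n1 + n2)
    v_pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (v_pooled - mu_pooled) / mu_pooled**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    # Wald on the log-mean difference; delta-method SE, t reference with
    # within-group df to account for the estimated per-gene variance
    eps = 0.5
    mu1s, mu2s = np.maximum(mu1, eps), np.maximum(mu2, eps)
    se2 = (1.0 / mu1s + alpha) / n1 + (1.0 / mu2s + alpha) / n2
    z = (np.log(mu1s) - np.log(mu2s)) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)

    allzero = (combined.sum(axis=1) == 0).to_numpy()
    log2fc[allzero] = 0.0
    p[allzero] = 1.0
    return pd.DataFrame(
        {"gene_id": combined.index, "log2fc": log2fc, "p": p}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# DEG gating
# ---------------------------------------------------------------------------


def call_degs(
    results: pd.DataFrame,
    biotype: pd.Series,
    mean_rpkm: pd.Series,
    log2fc_min: float = LOG2FC_MIN,
    fdr_max: float = FDR_MAX,
    rpkm_min_coding: float = RPKM_MIN_CODING,
    rpkm_min_lncrna: float = RPKM_MIN_LNCRNA,
) -> pd.DataFrame:
    """Apply the DEG criteria to per-gene (log2fc, p) statistics.

    Coding genes need |log2fc| > 0.5, BH FDR <= 0.05 and mean RPKM > 1;
    lncRNAs the same fold/FDR gates with mean RPKM > 0.1.  FDR is computed
    here over all tested genes.  Fold-change gates are strict inequalities.
    """
    out = results.copy().reset_index(drop=True)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["biotype"] = biotype.reindex(out["gene_id"]).to_numpy()
    out["mean_rpkm"] = mean_rpkm.reindex(out["gene_id"]).to_numpy()
    rpkm_gate = np.where(
        out["biotype"] == "coding", rpkm_min_coding, rpkm_min_lncrna
    )
    passing = (
        (out["log2fc"].abs() > log2fc_min)
        & (out["q"] <= fdr_max)
        & (out["mean_rpkm"] > rpkm_gate)
    )
    out["status"] = "ns"
    out.loc[passing & (out["log2fc"] > 0), "status"] = "up"
    out.loc[passing & (out["log2fc"] < 0), "status"] = "down"
    return out


def deg_sets(degs: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up, down) gene-id sets from a gated DEG table."""
    up = set(degs.loc[degs["status"] == "up", "gene_id"])
    down = set(degs.loc[degs["status"] == "down", "gene_id"])
    return up, down


# ---------------------------------------------------------------------------
# lncRNA-coding cis pairs
# ---------------------------------------------------------------------------


def gene_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Linear distance between gene spans: 0 if overlapping, else the
    nearest-end gap.  Different chromosomes are infinitely far apart."""
    if a.chrom != b.chrom:
        return np.iinfo(np.int64).max
    sa, sb = a.span, b.span
    if sa.overlaps(sb):
        return 0
    return max(sa.start, sb.start) - min(sa.end, sb.end)


def cis_pairs(
    deg_lnc: pd.DataFrame,
    deg_coding: pd.DataFrame,
    rpkm_matrix: pd.DataFrame,
    genes: list[GeneRecord],
    max_distance: int = CIS_MAX_DISTANCE,
    r_min: float = CIS_R_MIN,
    p_max: float = CIS_P_MAX,
) -> pd.DataFrame:
    """Candidate cis-regulatory lncRNA-coding pairs.

    For every same-direction (lncRNA, coding) DEG pair within
    ``max_distance`` bp, the Pearson correlation of their expression across
    all samples of ``rpkm_matrix`` is tested; pairs with r >= 0.6 and
    p <= 0.05 are kept.  Constant expression vectors are skipped.
    """
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for direction in ("up", "down"):
        lncs = deg_lnc.loc[deg_lnc["status"] == direction, "gene_id"]
        codings = deg_coding.loc[deg_coding["status"] == direction, "gene_id"]
        for lnc_id in lncs:
            for coding_id in codings:
                if lnc_id not in by_id or coding_id not in by_id:
                    continue
                dist = gene_distance(by_id[lnc_id], by_id[coding_id])
                if dist > max_distance:
                    continue
                x = rpkm_matrix.loc[lnc_id].to_numpy(dtype=float)
                y = rpkm_matrix.loc[coding_id].to_numpy(dtype=float)
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                r, p = stats.pearsonr(x, y)
                if r >= r_min and p <= p_max:
                    rows.append((lnc_id, coding_id, dist, float(r), float(p), direction))
    return pd.DataFrame(
        rows, columns=["lnc_id", "coding_id", "distance_bp", "r", "p", "direction"]
    )


# ---------------------------------------------------------------------------
# isoform ratio and fetal program
# ---------------------------------------------------------------------------


def isoform_ratio(rpkm_a: pd.Series, rpkm_b: pd.Series) -> pd.Series:
    """Per-sample expression ratio of two genes (e.g. MYH7/MYH6).

    Samples with a zero denominator come back NaN (flagged undefined).
    """
    a = pd.Series(rpkm_a, dtype=float)
    b = pd.Series(rpkm_b, dtype=float).reindex(a.index)
    out = a / b.where(b != 0)
    return out.rename("ratio")


@dataclass
class FetalProgram:
    """Gene sets shared between disease and fetal state, vs the same control.

    ``co_up`` holds genes up in both disease-vs-control and
    fetal-vs-control; ``co_down`` the co-downregulated ones.
    """

    co_up: set[str] = field(default_factory=set)
    co_down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.co_up & self.co_down:
            raise ValueError("co_up and co_down must be disjoint")

    @property
    def size(self) -> int:
        return len(self.co_up) + len(self.co_down)


def fetal_program(
    deg_disease: pd.DataFrame, deg_fetal: pd.DataFrame
) -> FetalProgram:
    """Intersect disease and fetal DEG sets (both vs the same control)."""
    up_d, down_d = deg_sets(deg_disease)
    up_f, down_f = deg_sets(deg_fetal)
    return FetalProgram(co_up=up_d & up_f, co_down=down_d & down_f)


def _percent(numer: int, denom: int) -> int:
    """Integer percentage, rounded half-up."""
    import math

    return int(math.floor(100.0 * numer / denom + 0.5))


def reversal_fraction(
    program: FetalProgram,
    deg_treated_a: pd.DataFrame,
    deg_treated_b: pd.DataFrame,
) -> dict:
    """Fraction of program genes reversed in both treated-vs-disease contrasts.

    A co-upregulated program gene is reversed when it is downregulated in
    both treated groups relative to the untreated disease group (and vice
    versa for co-downregulated genes).  Percentages are integers rounded
    half-up; an empty program side reports NaN (flagged).
    """
    up_a, down_a = deg_sets(deg_treated_a)
    up_b, down_b = deg_sets(deg_treated_b)
    reversed_up = program.co_up & down_a & down_b
    reversed_down = program.co_down & up_a & up_b
    return {
        "program_size": program.size,
        "co_up": len(program.co_up),
        "co_down": len(program.co_down),
        "reversed_up": len(reversed_up),
        "reversed_down": len(reversed_down),
        "reversed_up_genes": sorted(reversed_up),
        "reversed_down_genes": sorted(reversed_down),
        "percent_up": (
            _percent(len(reversed_up), len(program.co_up)) if program.co_up else float("nan")
        ),
        "percent_down": (
            _percent(len(reversed_down), len(program.co_down))
            if program.co_down
            else float("nan")
        ),
    }
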