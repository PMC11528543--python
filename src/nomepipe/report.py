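"""Run-level summaries and genome-element enrichment of region sets.

Enrichment is base-pair based: the fraction of region bp falling in an
element divided by the element's fraction of the genome, so uniformly
placed regions score ~1 everywhere and the whole genome against itself
scores exactly 1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def _merged_bp(df: pd.DataFrame) -> int:
    """Total bp covered by an interval set (overlaps collapsed)."""
    total = 0
    for _, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="stable")
        cur_s = cur_e = None
        for r in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            total += cur_e - cur_s
    return int(total)


def _overlap_bp(regions: pd.DataFrame, element: pd.DataFrame) -> int:
    """Region bp overlapping an element set (element overlaps collapsed)."""
    total = 0
    for chrom, egrp in element.groupby("chrom", sort=False):
        rgrp = regions[regions["chrom"] == chrom]
        if rgrp.empty:
            continue
        estarts = egrp["start"].to_numpy()
        eends = egrp["end"].to_numpy()
        order = np.argsort(estarts, kind="stable")
        estarts, eends = estarts[order], eends[order]
        # collapse element overlaps so shared bp is not double counted
        ms, me = [], []
        for s, e in zip(estarts, eends):
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        ms_a, me_a = np.array(ms), np.array(me)
        for r in rgrp.itertuples(index=False):
            lo = np.searchsorted(me_a, r.start, side="right")
            hi = np.searchsorted(ms_a, r.end, side="left")
            for k in range(lo, hi):
                total += max(0, min(r.end, me_a[k]) - max(r.start, ms_a[k]))
    return int(total)


def element_enrichment(
    regions: pd.DataFrame,
    elements: dict[str, pd.DataFrame],
    genome_bp: int,
) -> pd.DataFrame:
    """Relative bp enrichment of a region set in named genome elements.

    enrichment(e) = (region bp in e / total region bp) / (e bp / genome bp).
    """
    if regions.empty:
        raise ValueError("empty region set; enrichment undefined")
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    region_bp = _merged_bp(regions)
    rows = []
    for name, element in elements.items():
        e_bp = _merged_bp(element)
        o_bp = _overlap_bp(regions, element)
        if e_bp == 0:
            enr = float("nan")
        else:
            enr = (o_bp / region_bp) / (e_bp / genome_bp)
        rows.append((name, o_bp, e_bp, enr))
    return pd.DataFrame(
        rows, columns=["element", "overlap_bp", "element_bp", "enrichment"]
    )


def summarize_run(
    out_dir: str | Path,
    global_levels: dict[str, dict[str, float]] | None = None,
    dmrs: pd.DataFrame | None = None,
    ndrs: pd.DataFrame | None = None,
    reversal: dict | None = None,
    profiles: dict[str, list[float]] | None = None,
) -> dict:
    """Assemble a deterministic JSON + TSV report from stage outputs.

    Missing stages yield explicit null sections rather than being dropped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "global_levels": global_levels,
        "dmr_counts": None,
        "ndr_counts": None,
        "reversal": reversal,
        "profiles": profiles,
    }
    if dmrs is not None:
        report["dmr_counts"] = {
            "total": int(len(dmrs)),
            "hyper": int((dmrs["direction"] == "hyper").sum()) if len(dmrs) else 0,
            "hypo": int((dmrs["direction"] == "hypo").sum()) if len(dmrs) else 0,
        }
        dmrs.to_csv(out_dir / "dmrs.tsv", sep="\t", index=False)
    if ndrs is not None:
        counts = {"total": int(len(ndrs))}
        if "klass" in ndrs.columns and len(ndrs):
            counts["proximal"] = int((ndrs["klass"] == "proximal").sum())
            counts["distal"] = int((ndrs["klass"] == "distal").sum())
        report["ndr_counts"] = counts
        ndrs.to_csv(out_dir / "ndrs.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
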