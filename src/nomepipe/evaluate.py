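"""Recovery metrics: match called regions to planted truth intervals."""

from __future__ import annotations

import pandas as pd


def _reciprocal_match(a_start, a_end, b_start, b_end, min_frac: float) -> bool:
    ov = min(a_end, b_end) - max(a_start, b_start)
    return ov >= min_frac * (a_end - a_start) and ov >= min_frac * (b_end - b_start)


def match_intervals(
    called: pd.DataFrame, truth: pd.DataFrame, min_reciprocal: float = 0.5
) -> tuple[float, float]:
    """(sensitivity, precision) of a called region set against planted truth.

    A truth interval is recovered if some called region overlaps it by at
    least ``min_reciprocal`` of both lengths; a called region is a true
    positive if it matches some truth interval the same way.
    """
    if len(truth) == 0:
        raise ValueError("empty truth set; sensitivity undefined")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in called.itertuples(index=False):
        by_chrom.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    recovered = 0
    for t in truth.itertuples(index=False):
        hits = by_chrom.get(t.chrom, [])
        if any(_reciprocal_match(t.start, t.end, s, e, min_reciprocal) for s, e in hits):
            recovered += 1
    sensitivity = recovered / len(truth)
    if len(called) == 0:
        return sensitivity, float("nan")
    truth_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in truth.itertuples(index=False):
        truth_by_chrom.setdefault(t.chrom, []).append((int(t.start), int(t.end)))
    tp = 0
    for c in called.itertuples(index=False):
        hits = truth_by_chrom.get(c.chrom, [])
        if any(_reciprocal_match(c.start, c.end, s, e, min_reciprocal) for s, e in hits):
            tp += 1
    return sensitivity, tp / len(called)
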