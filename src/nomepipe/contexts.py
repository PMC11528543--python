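"""Trinucleotide context classification for NOMe-seq.

NOMe-seq reads two signals off one molecule: endogenous CpG methylation and
exogenous GpC methylation laid down by M.CviPI on accessible chromatin.  The
two are separable at single-base resolution by the flanking bases of each
cytosine:

* ``WCG`` (W = A/T before CG) — endogenous DNA methylation, free of GpC
  contamination;
* ``GCH`` (GC followed by H = A/T/C) — M.CviPI accessibility signal;
* ``GCG`` — ambiguous (both enzymes can act) and ``CCG`` — prone to M.CviPI
  off-target activity; both are classified here and excluded downstream.

Classification is reference-based: a cytosine at position *i* on the forward
strand is classed from bases (i-1, i, i+1); a reference G is a reverse-strand
cytosine and is classed from the reverse-complement trinucleotide by the same
rule.  Cytosines at contig ends or next to N are OTHER.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONTEXT_CODES = {"OTHER": 0, "WCG": 1, "GCH": 2, "GCG": 3, "CCG": 4}
CODE_TO_CONTEXT = {v: k for k, v in CONTEXT_CODES.items()}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def classify_trinucleotide(prev: str, base: str, nxt: str) -> str:
    """Classify a single cytosine from its flanking reference bases.

    The scalar reference rule; the vectorised :func:`classify_contexts`
    must agree with it on every (prev, next) pair.
    """
    if base != "C":
        raise ValueError(f"center base must be C, got {base!r}")
    if prev in "AT" and nxt == "G":
        return "WCG"
    if prev == "G" and nxt in "ATC":
        return "GCH"
    if prev == "G" and nxt == "G":
        return "GCG"
    if prev == "C" and nxt == "G":
        return "CCG"
    return "OTHER"


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-ACGTN character {chr(arr[pos])!r} at position {pos}")
    return arr


def _classify_strand(prev: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Vectorised context codes for cytosines given flanking base codes."""
    A, C, G, T = (ord(b) for b in "ACGT")
    ctx = np.zeros(prev.shape, dtype=np.uint8)
    w = (prev == A) | (prev == T)
    h = (nxt == A) | (nxt == T) | (nxt == C)
    ctx[w & (nxt == G)] = CONTEXT_CODES["WCG"]
    ctx[(prev == G) & h] = CONTEXT_CODES["GCH"]
    ctx[(prev == G) & (nxt == G)] = CONTEXT_CODES["GCG"]
    ctx[(prev == C) & (nxt == G)] = CONTEXT_CODES["CCG"]
    return ctx


def classify_sequence(seq: str) -> pd.DataFrame:
    """Context map for one sequence: every cytosine on both strands.

    Returns a frame with pos (0-based), strand, context, sorted by position.
    """
    arr = _encode(seq)
    n = len(arr)
    C, G = ord("C"), ord("G")
    frames = []

    # forward strand: reference C, flanks (i-1, i+1)
    fwd = np.flatnonzero(arr == C)
    fwd_inner = fwd[(fwd > 0) & (fwd < n - 1)]
    ctx_f = np.zeros(len(fwd), dtype=np.uint8)
    if len(fwd_inner):
        inner_mask = (fwd > 0) & (fwd < n - 1)
        ctx_f[inner_mask] = _classify_strand(arr[fwd_inner - 1], arr[fwd_inner + 1])
    frames.append(pd.DataFrame({"pos": fwd, "strand": "+", "code": ctx_f}))

    # reverse strand: reference G is a C on the minus strand; its 5' flank is
    # complement(arr[i+1]), its 3' flank complement(arr[i-1])
    rev = np.flatnonzero(arr == G)
    rev_inner = rev[(rev > 0) & (rev < n - 1)]
    ctx_r = np.zeros(len(rev), dtype=np.uint8)
    if len(rev_inner):
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in _COMPLEMENT.items():
            comp[ord(a)] = ord(b)
        inner_mask = (rev > 0) & (rev < n - 1)
        ctx_r[inner_mask] = _classify_strand(comp[arr[rev_inner + 1]], comp[arr[rev_inner - 1]])
    frames.append(pd.DataFrame({"pos": rev, "strand": "-", "code": ctx_r}))

    out = pd.concat(frames, ignore_index=True)
    out["context"] = out["code"].map(CODE_TO_CONTEXT)
    return (
        out.drop(columns="code")
        .sort_values(["pos", "strand"], kind="stable", ignore_index=True)
    )


def classify_contexts(genome: dict[str, str]) -> pd.DataFrame:
    """Context map for a whole genome (dict of chrom -> sequence).

    Returns a frame with chrom, pos, strand, context covering every cytosine
    on both strands; each position/strand appears exactly once (partition).
    """
    frames = []
    for chrom, seq in genome.items():
        df = classify_sequence(seq)
        df.insert(0, "chrom", chrom)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    return pd.concat(frames, ignore_index=True)


def annotate_sites(sites: pd.DataFrame, context_map: pd.DataFrame) -> pd.DataFrame:
    """Attach reference context classes to a site table by (chrom, pos, strand).

    Needed for dialects (bismark coverage) that carry no context on disk.
    Sites absent from the map (e.g. off-reference) come back OTHER.
    """
    merged = sites.drop(columns=["context"]).merge(
        context_map.rename(columns={"context": "ref_context"}),
        on=["chrom", "pos", "strand"],
        how="left",
    )
    merged["context"] = merged.pop("ref_context").fillna("OTHER")
    cols = ["chrom", "pos", "strand", "context", "meth", "total"]
    return merged[cols + [c for c in merged.columns if c not in cols]]


def conversion_rate(spikein_sites: pd.DataFrame) -> float:
    """Bisulfite conversion efficiency from an unmethylated spike-in contig.

    The spike-in (e.g. lambda DNA) carries no methylation, so every
    methylated call is a conversion failure: efficiency = 1 - sum(meth) /
    sum(total) over all spike-in cytosines.
    """
    total = int(spikein_sites["total"].sum())
    if total == 0:
        raise ValueError("spike-in has zero total coverage; conversion rate undefined")
    return 1.0 - float(spikein_sites["meth"].sum()) / total
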