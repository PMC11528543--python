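"""Synthetic data with known truth for every pipeline stage.

The generator emulates the study conditions end to end: a random genome
with realistic trinucleotide composition, binomially sampled per-cytosine
calls at Poisson depth with planted accessible regions (NDRs) and planted
group-wise methylation shifts (DMRs), and negative-binomial expression
counts with planted DEGs, correlated lncRNA-coding cis pairs and a fetal
program shared by the fetal and disease groups and reversed in the treated
groups.  Every dataset ships a TruthTable so recovery tests can compare
caller output to the plants.

Defaults follow the magnitudes of the profiled tissue: background WCG
(endogenous CpG methylation) ~= 0.72, background GCH accessibility ~= 0.15,
NDR-level GCH ~= 0.45, mean depth 10x, six samples per group.  One seed
drives the whole dataset; the same config is byte-identical on re-run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SITE_COLUMNS, GeneRecord

# hand-written trinucleotide truth tables, kept independent of the
# vectorised classifier so the two can cross-check each other
_FWD_CONTEXT = {
    "ACG": "WCG", "TCG": "WCG",
    "GCA": "GCH", "GCT": "GCH", "GCC": "GCH",
    "GCG": "GCG", "CCG": "CCG",
}
_REVCOMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Methylation-channel fields describe one genome shared by all samples;
    expression fields describe the five-group RNA design (control, disease,
    fetal, and two treated groups).
    """

    seed: int = 0
    # genome
    genome_length_bp: int = 200_000
    chrom_name: str = "chrS"
    gc_fraction: float = 0.42
    # methylation calls
    n_samples: int = 6
    depth: float = 10.0
    background_gch_level: float = 0.15
    ndr_gch_level: float = 0.45
    ndr_count: int = 20
    ndr_length_range: tuple[int, int] = (200, 500)
    background_wcg_level: float = 0.72
    dmr_count: int = 10
    dmr_delta: float = 0.30
    dmr_length: int = 900
    plant_spacing: int = 1_000
    # expression
    n_genes: int = 2_000
    n_lncrna: int = 200
    n_expr_samples: int = 6
    nb_dispersion: float = 0.05
    de_fold: float = 4.0
    program_fold: float = 3.0
    n_disease_only: int = 100
    n_fetal_only: int = 40
    program_up_size: int = 88
    program_down_size: int = 275
    reversal_fraction_up: float = 74 / 88
    reversal_fraction_down: float = 217 / 275
    n_cis_pairs: int = 20
    gene_spacing_bp: int = 150_000
    cis_gap_range: tuple[int, int] = (5_000, 50_000)
    expr_base_log_mean: float = float(np.log(100.0))
    expr_base_log_sd: float = 1.0
    de_base_mean: float = 500.0

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "background_gch_level",
            "ndr_gch_level",
            "background_wcg_level",
            "reversal_fraction_up",
            "reversal_fraction_down",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.ndr_gch_level <= self.background_gch_level:
            raise ValueError("ndr_gch_level must exceed background_gch_level")
        if self.genome_length_bp < 10_000:
            raise ValueError("genome must be >= 10 kb")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthTable:
    """Planted features of one simulated dataset."""

    ndrs: pd.DataFrame | None = None
    dmrs: pd.DataFrame | None = None
    program_up: list[str] = field(default_factory=list)
    program_down: list[str] = field(default_factory=list)
    reversed_up: list[str] = field(default_factory=list)
    reversed_down: list[str] = field(default_factory=list)
    disease_up: list[str] = field(default_factory=list)
    disease_down: list[str] = field(default_factory=list)
    fold_changes: dict[str, float] = field(default_factory=dict)
    cis_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ndrs": self.ndrs.to_dict("records") if self.ndrs is not None else None,
            "dmrs": self.dmrs.to_dict("records") if self.dmrs is not None else None,
            "program_up": self.program_up,
            "program_down": self.program_down,
            "reversed_up": self.reversed_up,
            "reversed_down": self.reversed_down,
            "disease_up": self.disease_up,
            "disease_down": self.disease_down,
            "fold_changes": self.fold_changes,
            "cis_pairs": [list(p) for p in self.cis_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        raw = json.loads(Path(path).read_text())
        return cls(
            ndrs=pd.DataFrame(raw["ndrs"]) if raw["ndrs"] is not None else None,
            dmrs=pd.DataFrame(raw["dmrs"]) if raw["dmrs"] is not None else None,
            program_up=raw["program_up"],
            program_down=raw["program_down"],
            reversed_up=raw["reversed_up"],
            reversed_down=raw["reversed_down"],
            disease_up=raw["disease_up"],
            disease_down=raw["disease_down"],
            fold_changes=raw["fold_changes"],
            cis_pairs=[tuple(p) for p in raw["cis_pairs"]],
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def truth_contexts(seq: str) -> pd.DataFrame:
    """Literal-table context classification (the generator's own oracle).

    Walks every cytosine on both strands and looks the trinucleotide up in
    a hand-written table; deliberately simple and independent of the
    vectorised classifier.
    """
    seq = seq.upper()
    rows = []
    n = len(seq)
    for i, base in enumerate(seq):
        if base == "C":
            if 0 < i < n - 1:
                tri = seq[i - 1 : i + 2]
                ctx = _FWD_CONTEXT.get(tri, "OTHER") if "N" not in tri else "OTHER"
            else:
                ctx = "OTHER"
            rows.append((i, "+", ctx))
        elif base == "G":
            if 0 < i < n - 1:
                tri = seq[i - 1 : i + 2]
                if "N" in tri:
                    ctx = "OTHER"
                else:
                    rc = "".join(_REVCOMP[b] for b in reversed(tri))
                    ctx = _FWD_CONTEXT.get(rc, "OTHER")
            else:
                ctx = "OTHER"
            rows.append((i, "-", ctx))
    return pd.DataFrame(rows, columns=["pos", "strand", "context"])


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Random genome at the configured GC fraction (single chromosome)."""
    rng = rng or config.rng()
    p_gc = config.gc_fraction / 2.0
    p_at = (1.0 - config.gc_fraction) / 2.0
    bases = rng.choice(
        np.array(["A", "C", "G", "T"]),
        size=config.genome_length_bp,
        p=[p_at, p_gc, p_gc, p_at],
    )
    return {config.chrom_name: "".join(bases)}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# methylation calls with planted NDRs / DMRs
# ---------------------------------------------------------------------------


def _plant_intervals(
    genome_length: int,
    count: int,
    length_range: tuple[int, int],
    spacing: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping plant intervals with >= ``spacing`` bp between them.

    Drawn by spreading plants over evenly sized slots with random jitter so
    placement stays feasible at high plant counts.
    """
    lo, hi = length_range
    if count == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    slot = genome_length // count
    if slot < hi + spacing:
        raise ValueError("genome too small for requested plants")
    lengths = rng.integers(lo, hi + 1, size=count)
    offsets = rng.integers(0, slot - hi - spacing + 1, size=count)
    starts = np.arange(count) * slot + spacing // 2 + offsets
    return starts, starts + lengths


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership index of each position in sorted disjoint intervals
    (-1 where outside)."""
    if len(starts) == 0:
        return np.full(len(pos), -1)
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    return np.where(inside, idx, -1)


def simulate_calls(
    config: SimulationConfig,
    genome: dict[str, str],
    contexts: pd.DataFrame,
    rng: np.random.Generator | None = None,
    plant_ndrs: bool = True,
    plant_dmrs: bool = True,
) -> tuple[dict[str, dict[str, pd.DataFrame]], TruthTable]:
    """Per-sample cytosine call tables for two sample groups.

    Per site and sample, depth ~ Poisson(config.depth) and methylated calls
    ~ Binomial(depth, level); sites with zero depth are unobserved.  GCH
    level is elevated inside planted NDRs (all samples); WCG level is
    shifted by +-dmr_delta in group 1 inside planted DMRs; GCG/CCG sites
    run at the WCG background so their downstream exclusion is exercised.
    """
    rng = rng or config.rng()
    chrom = config.chrom_name
    glen = len(genome[chrom])
    ctx = contexts[contexts["context"] != "OTHER"].reset_index(drop=True)
    if "chrom" in ctx.columns:
        ctx = ctx[ctx["chrom"] == chrom].reset_index(drop=True)
    pos = ctx["pos"].to_numpy()

    if plant_ndrs and config.ndr_count:
        ndr_s, ndr_e = _plant_intervals(
            glen, config.ndr_count, config.ndr_length_range, config.plant_spacing, rng
        )
    else:
        ndr_s = ndr_e = np.array([], dtype=int)
    if plant_dmrs and config.dmr_count:
        # offset DMR slots from NDR slots by drawing from a fresh region of rng
        dmr_s, dmr_e = _plant_intervals(
            glen,
            config.dmr_count,
            (config.dmr_length, config.dmr_length),
            config.plant_spacing,
            rng,
        )
        dmr_dir = rng.choice([1, -1], size=config.dmr_count)
    else:
        dmr_s = dmr_e = np.array([], dtype=int)
        dmr_dir = np.array([], dtype=int)

    is_gch = (ctx["context"] == "GCH").to_numpy()
    is_wcg = (ctx["context"] == "WCG").to_numpy()
    ndr_idx = _in_intervals(pos, ndr_s, ndr_e)
    dmr_idx = _in_intervals(pos, dmr_s, dmr_e)

    # baseline level per site (group 2 / unshifted)
    base = np.full(len(ctx), config.background_wcg_level)
    base[is_gch] = config.background_gch_level
    base[is_gch & (ndr_idx >= 0)] = config.ndr_gch_level

    # group 1: WCG levels shifted inside planted DMRs
    g1_level = base.copy()
    in_dmr = is_wcg & (dmr_idx >= 0)
    shift = np.zeros(len(ctx))
    if len(dmr_s):
        shift[in_dmr] = dmr_dir[dmr_idx[in_dmr]] * config.dmr_delta
    g1_level = np.clip(g1_level + shift, 0.02, 0.98)

    def draw_group(level: np.ndarray, names: list[str]) -> dict[str, pd.DataFrame]:
        out = {}
        for name in names:
            depth = rng.poisson(config.depth, size=len(ctx))
            meth = rng.binomial(depth, level)
            keep = depth > 0
            out[name] = pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "strand": ctx["strand"].to_numpy()[keep],
                    "context": ctx["context"].to_numpy()[keep],
                    "meth": meth[keep],
                    "total": depth[keep],
                }
            )[SITE_COLUMNS]
        return out

    g1 = draw_group(g1_level, [f"g1_s{i}" for i in range(config.n_samples)])
    g2 = draw_group(base, [f"g2_s{i}" for i in range(config.n_samples)])

    truth = TruthTable(
        ndrs=pd.DataFrame({"chrom": chrom, "start": ndr_s, "end": ndr_e}),
        dmrs=pd.DataFrame(
            {
                "chrom": chrom,
                "start": dmr_s,
                "end": dmr_e,
                "direction": np.where(dmr_dir > 0, "hyper", "hypo"),
            }
        ),
    )
    return {"g1": g1, "g2": g2}, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

EXPR_GROUPS = ("control", "disease", "fetal", "treated_A", "treated_B")


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_null_counts(
    n_genes: int,
    n_per_group: int,
    dispersion: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two groups drawn from identical NB distributions (null contrast)."""
    base = np.exp(rng.normal(np.log(100.0), 1.0, size=n_genes))
    idx = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")

    def draw(prefix: str) -> pd.DataFrame:
        cols = {}
        for j in range(n_per_group):
            cols[f"{prefix}_{j}"] = _nb_draw(rng, base, dispersion)
        return pd.DataFrame(cols, index=idx)

    return draw("a"), draw("b")


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]], list[GeneRecord], TruthTable]:
    """Five-group NB count matrix with planted structure.

    Returns (counts genes x samples, group -> sample names, gene models,
    truth).  Planted structure:

    * a fetal program: ``program_up_size`` genes up and ``program_down_size``
      genes down (fold ``program_fold``) in both disease and fetal groups
      vs control; a configured fraction of each side returns to the control
      mean in both treated groups (the "reversed" genes), the rest stay at
      the disease mean;
    * disease-only DEGs at ``de_fold`` (half up, half down) for fold-change
      recovery checks, plus fetal-only DEGs as negative controls;
    * ``n_cis_pairs`` lncRNA-coding pairs placed within 100 kb that share a
      per-sample latent factor (and a common disease upshift), so their
      expression is strongly correlated across samples;
    * MYH7/MYH6 style isoform switch: the beta-type gene up, the alpha-type
      gene down in disease and fetal groups.
    """
    rng = rng or config.rng()
    n_coding = config.n_genes - config.n_lncrna
    gene_ids = [f"G{i:05d}" for i in range(n_coding)] + [
        f"L{i:05d}" for i in range(config.n_lncrna)
    ]
    biotypes = ["coding"] * n_coding + ["lncRNA"] * config.n_lncrna
    # MYH genes live among the coding ids
    gene_ids[0], gene_ids[1] = "MYH7", "MYH6"

    # gene placement: one synthetic chromosome, genes far apart by default;
    # cis-pair partners are moved next to each other below
    starts = np.arange(config.n_genes) * config.gene_spacing_bp
    lengths = rng.integers(1_000, 10_000, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)

    coding_pool = [i for i in range(2, n_coding)]  # exclude MYH7/MYH6
    lnc_pool = list(range(n_coding, config.n_genes))
    rng.shuffle(coding_pool)
    rng.shuffle(lnc_pool)

    def take(pool: list[int], k: int) -> list[int]:
        picked, rest = pool[:k], pool[k:]
        pool[:] = rest
        return picked

    # MYH7 (index 0) joins the program-up side and MYH6 (index 1) the down
    # side: the beta/alpha myosin switch is itself part of the fetal program
    prog_up = [0] + take(coding_pool, config.program_up_size - 1)
    prog_down = [1] + take(coding_pool, config.program_down_size - 1)
    n_half = config.n_disease_only // 2
    disease_up_only = take(coding_pool, n_half)
    disease_down_only = take(coding_pool, config.n_disease_only - n_half)
    fetal_only = take(coding_pool, config.n_fetal_only)
    cis_coding = take(coding_pool, config.n_cis_pairs)
    cis_lnc = take(lnc_pool, config.n_cis_pairs)

    # reversed program genes: the first round(fraction * size) of each side
    n_rev_up = int(round(config.reversal_fraction_up * len(prog_up)))
    n_rev_down = int(round(config.reversal_fraction_down * len(prog_down)))
    rev_up, rev_down = prog_up[:n_rev_up], prog_down[:n_rev_down]

    # move each cis lnc next to its coding partner (gap <= 100 kb)
    for lnc_i, cod_i in zip(cis_lnc, cis_coding):
        gap = rng.integers(*config.cis_gap_range)
        starts[lnc_i] = starts[cod_i] + lengths[cod_i] + gap

    # per-group fold-change matrix (genes x groups), control = 1
    fold = np.ones((config.n_genes, len(EXPR_GROUPS)))
    col = {g: k for k, g in enumerate(EXPR_GROUPS)}
    up_f, down_f = config.program_fold, 1.0 / config.program_fold

    for i in prog_up:
        fold[i, col["disease"]] = fold[i, col["fetal"]] = up_f
        fold[i, col["treated_A"]] = fold[i, col["treated_B"]] = up_f
    for i in rev_up:
        fold[i, col["treated_A"]] = fold[i, col["treated_B"]] = 1.0
    for i in prog_down:
        fold[i, col["disease"]] = fold[i, col["fetal"]] = down_f
        fold[i, col["treated_A"]] = fold[i, col["treated_B"]] = down_f
    for i in rev_down:
        fold[i, col["treated_A"]] = fold[i, col["treated_B"]] = 1.0
    for i in disease_up_only:
        fold[i, col["disease"]] = config.de_fold
        fold[i, col["treated_A"]] = fold[i, col["treated_B"]] = config.de_fold
    for i in disease_down_only:
        fold[i, col["disease"]] = 1.0 / config.de_fold
        fold[i, col["treated_A"]] = fold[i, col["treated_B"]] = 1.0 / config.de_fold
    for i in fetal_only:
        fold[i, col["fetal"]] = config.de_fold
    for lnc_i, cod_i in zip(cis_lnc, cis_coding):
        for i in (lnc_i, cod_i):
            fold[i, col["disease"]] = up_f
            fold[i, col["treated_A"]] = fold[i, col["treated_B"]] = up_f
    base_mu = np.exp(
        rng.normal(config.expr_base_log_mean, config.expr_base_log_sd, size=config.n_genes)
    )
    # fold-change plants used for log2fc recovery sit at high expression,
    # where the fold estimate is limited by biological noise, not counting noise
    de_idx = disease_up_only + disease_down_only + cis_lnc + cis_coding
    base_mu[de_idx] = np.exp(
        rng.normal(np.log(config.de_base_mean), 0.3, size=len(de_idx))
    )
    counts = {}
    groups: dict[str, list[str]] = {}
    for g in EXPR_GROUPS:
        names = [f"{g}_{j}" for j in range(config.n_expr_samples)]
        groups[g] = names
        for name in names:
            lib = np.exp(rng.normal(0.0, 0.1))
            mu = base_mu * fold[:, col[g]] * lib
            # shared latent factor couples each cis pair within this sample
            latent = np.exp(rng.normal(0.0, 0.5, size=config.n_cis_pairs))
            for k, (lnc_i, cod_i) in enumerate(zip(cis_lnc, cis_coding)):
                mu[lnc_i] *= latent[k]
                mu[cod_i] *= latent[k]
            counts[name] = _nb_draw(rng, mu, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    genes = [
        GeneRecord(
            gene_id=gene_ids[i],
            biotype=biotypes[i],
            strand=str(strands[i]),
            tss=int(starts[i]) if strands[i] == "+" else int(starts[i] + lengths[i]),
            tes=int(starts[i] + lengths[i]) if strands[i] == "+" else int(starts[i]),
            chrom="chrE",
            length_bp=int(lengths[i]),
        )
        for i in range(config.n_genes)
    ]
    ids = np.array(gene_ids)
    truth = TruthTable(
        program_up=sorted(ids[prog_up]),
        program_down=sorted(ids[prog_down]),
        reversed_up=sorted(ids[rev_up]),
        reversed_down=sorted(ids[rev_down]),
        disease_up=sorted(
            set(ids[prog_up]) | set(ids[disease_up_only])
            | set(ids[cis_lnc]) | set(ids[cis_coding])
        ),
        disease_down=sorted(set(ids[prog_down]) | set(ids[disease_down_only])),
        fold_changes={str(ids[i]): config.de_fold for i in disease_up_only},
        cis_pairs=[(str(ids[l]), str(ids[c])) for l, c in zip(cis_lnc, cis_coding)],
    )
    return counts_df, groups, genes, truth


def config_to_json(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=1, sort_keys=True))
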