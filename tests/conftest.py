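import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import nomepipe as nm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_sites(rows):
    """Site table from (chrom, pos, strand, context, meth, total) tuples."""
    return pd.DataFrame(rows, columns=nm.io.SITE_COLUMNS)


@pytest.fixture(scope="session")
def small_sim():
    """A 200 kb simulated dataset with planted NDRs and DMRs, shared
    across tests that only read from it."""
    config = nm.SimulationConfig(
        seed=101, genome_length_bp=200_000, depth=20.0, ndr_count=15, dmr_count=8
    )
    rng = config.rng()
    genome = nm.simulate_genome(config, rng)
    ctx = nm.classify_sequence(genome[config.chrom_name])
    ctx.insert(0, "chrom", config.chrom_name)
    calls, truth = nm.simulate_calls(config, genome, ctx, rng)
    return {
        "config": config,
        "genome": genome,
        "contexts": ctx,
        "calls": calls,
        "truth": truth,
        "chrom_sizes": {config.chrom_name: config.genome_length_bp},
    }


@pytest.fixture(scope="session")
def expr_sim():
    """A five-group expression dataset with planted program and cis pairs."""
    config = nm.SimulationConfig(seed=202)
    counts, groups, genes, truth = nm.simulate_expression(config)
    lengths = pd.Series({g.gene_id: g.length_bp for g in genes})
    biotype = pd.Series({g.gene_id: g.biotype for g in genes})
    rpkm = nm.rpkm(counts, lengths)
    return {
        "config": config,
        "counts": counts,
        "groups": groups,
        "genes": genes,
        "truth": truth,
        "lengths": lengths,
        "biotype": biotype,
        "rpkm": rpkm,
    }
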