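"""Shared fixtures: one small ground-truthed simulation reused session-wide."""

import numpy as np
import pandas as pd
import pytest

from apakit.atlas import THREE_PRIME, UPSTREAM
from apakit.quantify import CountTable
from apakit.simulate import (
    SimulationConfig,
    build_toy_genome,
    plan_truth,
    simulate_sample_reads,
    write_fixture_bundle,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=3,
        n_genes=30,
        samples=(("ctrl_rep1", "ctrl", 8000), ("kd_rep1", "kd", 8000)),
    )


@pytest.fixture(scope="session")
def small_assets(small_config):
    return build_toy_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_assets):
    return plan_truth(small_assets, small_config)


@pytest.fixture(scope="session")
def small_reads(small_config, small_assets, small_truth):
    reads = {}
    for i, (sample_id, condition, n_reads) in enumerate(small_config.samples):
        reads[sample_id] = simulate_sample_reads(
            small_assets,
            small_truth,
            condition,
            n_reads,
            seed=small_config.seed + 100 + i,
            config=small_config,
        )
    return reads


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config, small_assets, small_truth, small_reads):
    out = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_bundle(
        small_assets, small_truth, small_reads, out, small_config
    )
    return out, manifest


def table_from_truth_counts(truth, counts_frame) -> CountTable:
    """Build a CountTable directly from truth PAS rows and drawn counts."""
    merged = counts_frame.merge(
        truth.pas[["gene_id", "pas_index", "position", "region"]],
        on=["gene_id", "pas_index"],
    )
    strands = truth.genes.set_index("gene_id")["strand"]
    region_map = {"three_prime_exon": THREE_PRIME, "extended": THREE_PRIME,
                  "upstream": UPSTREAM}
    index = merged["gene_id"] + ":" + merged["pas_index"].astype(str)
    counts = pd.DataFrame(
        {
            cond[len("count_"):]: merged[cond].to_numpy()
            for cond in merged.columns
            if cond.startswith("count_")
        },
        index=index,
    )
    meta = pd.DataFrame(
        {
            "gene_id": merged["gene_id"].to_numpy(),
            "region": merged["region"].map(region_map).to_numpy(),
            "position": merged["position"].to_numpy(),
            "strand": merged["gene_id"].map(strands).to_numpy(),
            "contig": "chr1",
            "biotype": "mRNA",
        },
        index=index,
    )
    return CountTable(counts, meta)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
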