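"""Shared fixtures: small synthetic datasets built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from parallelpeaks import sim, windows
from parallelpeaks.genome import Genome


def two_transect_config(seed=0, features=None, chrom_length=500_000,
                        n_chromosomes=2, sites_per_kb=4.0, n_diploids=4):
    """A minimal two-transect study: one side of the barrier, two replicate
    transect trios, a donor lineage and an outgroup."""
    pops, tips = [], {}
    alt = {"high": 1200.0, "low": 360.0, "low_distant": 95.0}
    t_nodes = []
    for t in ("t1", "t2"):
        leaves = []
        for cls in ("high", "low", "low_distant"):
            pid = f"{t}_{cls}"
            pops.append(sim.PopulationSpec(pid, t, "west", cls, alt[cls], n_diploids))
            leaves.append(sim.DriftNode(pid, f=0.02))
        t_nodes.append(sim.DriftNode(t, f=0.02, children=leaves))
    pops.append(sim.PopulationSpec("donor", "donor", "east", "donor", 1500.0,
                                   n_diploids, species="specialist"))
    pops.append(sim.PopulationSpec("outgroup", "outgroup", "east", "outgroup",
                                   500.0, 2, species="outgroup", outgroup=True))
    root = sim.DriftNode("root", children=[
        sim.DriftNode("ingroup", f=0.02, children=t_nodes),
        sim.DriftNode("donor", f=0.25),
        sim.DriftNode("outgroup", f=0.3),
    ])
    n_sites = int(n_chromosomes * chrom_length / 1000 * sites_per_kb)
    return sim.SimConfig(
        n_chromosomes=n_chromosomes, chrom_length=chrom_length,
        n_sites=n_sites, populations=pops, drift_tree=root,
        planted_features=features or [], seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A neutral (no planted feature) two-transect dataset."""
    cfg = two_transect_config(seed=11)
    table = sim.simulate_frequencies(cfg)
    geno, samples = sim.sample_genotypes(table, cfg)
    popmap = sim.popmap_frame(cfg)
    counts = windows.allele_counts(table.chrom, table.pos, geno, samples, popmap)
    return {"config": cfg, "table": table, "geno": geno, "samples": samples,
            "popmap": popmap, "counts": counts, "genome": cfg.genome()}


@pytest.fixture(scope="session")
def sweep_dataset():
    """Two-transect dataset with a strong sweep shared by both highlands
    and an introgression tract from the donor into one highland."""
    feats = [
        sim.PlantedFeature("sweep", "chr1", 150_000, 300_000,
                           ["t1_high", "t2_high"], 0.9),
        sim.PlantedFeature("introgression", "chr2", 100_000, 250_000,
                           ["t1_high"], 0.9, donor_population="donor"),
    ]
    cfg = two_transect_config(seed=7, features=feats, chrom_length=1_000_000)
    table = sim.simulate_frequencies(cfg)
    geno, samples = sim.sample_genotypes(table, cfg)
    popmap = sim.popmap_frame(cfg)
    counts = windows.allele_counts(table.chrom, table.pos, geno, samples, popmap)
    return {"config": cfg, "table": table, "geno": geno, "samples": samples,
            "popmap": popmap, "counts": counts, "genome": cfg.genome()}


@pytest.fixture(scope="session")
def toy_genome():
    return Genome({"chr1": 2_000_000, "chr2": 1_500_000})
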