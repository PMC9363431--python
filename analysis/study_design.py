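"""The synthetic study design shared by the numbered analysis scripts.

Four altitudinal transect trios (two per side of a dispersal barrier), a
highland-specialist donor species and an outgroup, with planted signals
for each mechanism of repeated adaptation:

* two sweeps shared by all four highland populations (allopatric
  parallelism),
* three sweeps replicated in the two western highlands only,
* one ancestrally shared standing variant in every highland population,
* one introgression tract from the donor into the western highlands,
* one inversion-like divergent haplotype block segregating in the two
  eastern highland populations.
"""

from __future__ import annotations

from pathlib import Path

from parallelpeaks import sim, windows

SEED = 17
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "study"
RESULTS = Path(__file__).resolve().parent.parent / "results"

ALL_HIGH = ["t1_high", "t2_high", "t3_high", "t4_high"]
WEST_HIGH = ["t1_high", "t2_high"]
EAST_HIGH = ["t3_high", "t4_high"]
LAYOUT = {"t1": "west", "t2": "west", "t3": "east", "t4": "east"}


def features() -> list[sim.PlantedFeature]:
    return [
        sim.PlantedFeature("sweep", "chr1", 200_000, 350_000, ALL_HIGH, 0.9),
        sim.PlantedFeature("sweep", "chr2", 800_000, 950_000, ALL_HIGH, 0.9),
        sim.PlantedFeature("sweep", "chr3", 400_000, 550_000, WEST_HIGH, 0.9),
        sim.PlantedFeature("sweep", "chr3", 1_500_000, 1_650_000, WEST_HIGH, 0.9),
        sim.PlantedFeature("sweep", "chr4", 600_000, 750_000, WEST_HIGH, 0.9),
        sim.PlantedFeature("shared_standing", "chr4", 1_200_000, 1_350_000,
                           ALL_HIGH, 0.8),
        sim.PlantedFeature("introgression", "chr4", 200_000, 350_000,
                           WEST_HIGH, 0.9, donor_population="donor"),
        sim.PlantedFeature("inversion_block", "chr1", 2_200_000, 2_600_000,
                           EAST_HIGH, 0.5),
    ]


def config() -> sim.SimConfig:
    return sim.default_study_config(seed=SEED, chrom_length=3_000_000,
                                    features=features())


def dataset():
    """Simulate (deterministically) and return the working objects."""
    cfg = config()
    table = sim.simulate_frequencies(cfg)
    geno, samples = sim.sample_genotypes(table, cfg)
    popmap = sim.popmap_frame(cfg)
    counts = windows.allele_counts(table.chrom, table.pos, geno, samples,
                                   popmap)
    return cfg, table, geno, samples, popmap, counts


def scan_all(cfg, counts):
    """Selection-statistic tracks and HDR sets for all four transects."""
    from parallelpeaks import intervals

    tracks, hdr_sets = {}, {}
    for t in LAYOUT:
        trio = windows.TransectTrio(f"{t}_high", f"{t}_low", f"{t}_low_distant")
        tracks[t] = windows.transect_scan(cfg.genome(), counts, trio)
        outl = intervals.call_outliers(tracks[t])
        hdr_sets[t] = intervals.build_hdrs(cfg.genome(), outl,
                                           source_transect=t)
    return tracks, hdr_sets
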