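"""Generate the synthetic study dataset and write it to disk.

Writes the full VCF / population map / truth BED / config to scratch/
(bulky, regenerable) and a population and planted-feature summary to
results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd
import study_design as sd

from parallelpeaks import sim


def main():
    cfg, table, geno, samples, popmap, _ = sd.dataset()
    sd.RESULTS.mkdir(exist_ok=True)
    paths = sim.write_dataset(geno, samples, table, cfg, sd.SCRATCH)
    print(f"wrote dataset ({table.n_sites} sites x {len(samples)} samples) "
          f"to {sd.SCRATCH}")

    pops = (popmap.groupby(["transect", "side", "population",
                            "altitude_class", "altitude_m"])
            .size().rename("n_samples").reset_index())
    pops.to_csv(sd.RESULTS / "01_populations.tsv", sep="\t", index=False)

    feats = pd.DataFrame([
        {"kind": f.kind, "chrom": f.chrom, "start": f.start, "end": f.end,
         "targets": ",".join(f.target_populations), "intensity": f.intensity,
         "donor": f.donor_population or ""}
        for f in cfg.planted_features
    ])
    feats.to_csv(sd.RESULTS / "01_planted_features.tsv", sep="\t", index=False)
    print(f"{len(pops)} populations, {len(feats)} planted features "
          f"({feats['kind'].value_counts().to_dict()})")


if __name__ == "__main__":
    main()
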