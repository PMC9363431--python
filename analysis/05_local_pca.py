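"""Local PCA of each shared HDR: does altitude predict the first local
component beyond neutral structure? Also clusters karyotypes along PC1 of
the planted inversion block."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd
import study_design as sd

from parallelpeaks import intervals, pca
from parallelpeaks.genome import IntervalSet


def side_columns(popmap, samples, transects):
    keep = set(popmap.loc[popmap["transect"].isin(transects), "sample"])
    cols = [j for j, s in enumerate(samples) if s in keep]
    return cols, [samples[j] for j in cols]


def main():
    cfg, table, geno, samples, popmap, counts = sd.dataset()
    genome = cfg.genome()
    tracks, hdr_sets = sd.scan_all(cfg, counts)
    classified = intervals.classify_sharing(hdr_sets, sd.LAYOUT)
    sd.RESULTS.mkdir(exist_ok=True)
    alt = popmap.set_index("sample")["altitude_m"]

    all_hdr = IntervalSet.from_linear(
        genome,
        np.concatenate([h.lin_start for h in hdr_sets.values()]),
        np.concatenate([h.lin_end for h in hdr_sets.values()]))

    rows = []
    for side, transects in (("west", ["t1", "t2"]), ("east", ["t3", "t4"])):
        cols, side_samples = side_columns(popmap, samples, transects)
        gp = pca.global_pca(geno[:, cols], side_samples, table.chrom,
                            table.pos, exclude_intervals=all_hdr, seed=sd.SEED)
        for t in transects:
            shared = classified[t][classified[t]["sharing_class"] != "private"]
            for _, region in shared.iterrows():
                sel = ((table.chrom == region["chrom"])
                       & (table.pos >= region["start"])
                       & (table.pos < region["end"]))
                if sel.sum() < 2:
                    continue
                lp = pca.local_pca(geno[np.ix_(np.flatnonzero(sel), cols)],
                                   side_samples)
                a = pca.altitude_association(
                    lp.scores["PC1"].to_numpy(),
                    alt.loc[lp.scores.index].to_numpy(),
                    gp.scores["PC1"].loc[lp.scores.index].to_numpy())
                rows.append({"transect": t, "chrom": region["chrom"],
                             "start": region["start"], "end": region["end"],
                             "pc1_var_pct": 100 * lp.explained_variance_ratio[0],
                             **a})
    assoc = pd.DataFrame(rows)
    assoc.to_csv(sd.RESULTS / "05_altitude_association.tsv", sep="\t",
                 index=False)
    sig = (assoc["altitude_p"] < 0.05).sum()
    print(f"altitude significantly predicts local PC1 in {sig} of "
          f"{len(assoc)} SHDR local PCAs "
          f"(median partial R^2 = {assoc['partial_r2_altitude'].median():.2f})")

    # karyotype clustering along the planted inversion block
    inv = [f for f in cfg.planted_features if f.kind == "inversion_block"][0]
    cols, side_samples = side_columns(popmap, samples, ["t3", "t4"])
    sel = ((table.chrom == inv.chrom) & (table.pos >= inv.start)
           & (table.pos < inv.end))
    lp = pca.local_pca(geno[np.ix_(np.flatnonzero(sel), cols)], side_samples)
    k = pca.karyotype_cluster(lp.scores["PC1"].to_numpy())
    karyo = pd.DataFrame({"sample": lp.scores.index,
                          "pc1": lp.scores["PC1"].to_numpy(),
                          "karyotype": k["labels"]})
    karyo.to_csv(sd.RESULTS / "05_inversion_karyotypes.tsv", sep="\t",
                 index=False)
    counts_by = karyo["karyotype"].value_counts().to_dict()
    print(f"inversion local PCA: silhouette {k['silhouette']:.2f}, "
          f"karyotype counts {counts_by}")


if __name__ == "__main__":
    main()
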