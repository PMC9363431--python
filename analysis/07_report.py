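"""Assemble the stage tables under results/ into a single markdown
summary of the synthetic study."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd
import study_design as sd


def read(name):
    path = sd.RESULTS / name
    return pd.read_csv(path, sep="\t") if path.exists() else None


def main():
    lines = ["# Synthetic parallel-adaptation study: summary", ""]
    sharing = read("03_hdr_sharing.tsv")
    if sharing is not None:
        lines += ["## HDR sharing across transects", "",
                  sharing.round(4).to_markdown(index=False), ""]
    ev = read("04_shdr_evidence.tsv")
    if ev is not None:
        tally = (ev.groupby(["transect", "n_outlier_stats_total"])
                 .size().rename("n_shdrs").reset_index())
        lines += ["## Corroborating selection statistics per SHDR", "",
                  tally.to_markdown(index=False), ""]
    assoc = read("05_altitude_association.tsv")
    if assoc is not None:
        sig = (assoc["altitude_p"] < 0.05).sum()
        lines += ["## Altitude association of SHDR local PC1", "",
                  f"Altitude is a significant predictor (p < 0.05) in "
                  f"{sig}/{len(assoc)} SHDR local PCAs; median altitude "
                  f"partial R^2 = "
                  f"{assoc['partial_r2_altitude'].median():.2f}.", ""]
    fdm = read("06_fdm_summary.tsv")
    if fdm is not None:
        lines += ["## Excess allele sharing at SHDRs (f_dM)", "",
                  fdm.round(4).to_markdown(index=False), ""]
    out = sd.RESULTS / "report.md"
    out.write_text("\n".join(lines))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
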