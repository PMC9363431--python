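"""End-to-end orchestration of the parallel-adaptation scan.

A single :class:`RunConfig` drives the stage order

    simulate (optional) -> windows -> hdr -> share -> enrich -> pca -> fdm
    -> report

with one master seed expanded into per-stage seeds via a counter, so any
stochastic stage can be re-run in isolation and reproduce its files. A
JSON manifest records inputs, seeds, the config hash and the stage list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, intervals, introgression, pca, sim, vcfio, windows
from .genome import Genome, IntervalSet

STAGES = ["simulate", "windows", "hdr", "share", "enrich", "pca", "fdm", "report"]


@dataclass
class RunConfig:
    out_dir: str
    vcf: str | None = None
    popmap: str | None = None
    simulate: dict | None = None  # SimConfig dict; generates inputs when set
    trios: dict[str, dict] = field(default_factory=dict)  # transect -> {high, low, low_distant}
    layout: dict[str, str] = field(default_factory=dict)  # transect -> side
    quartets: list[dict] = field(default_factory=list)  # {p1, p2, p3, outgroup}
    window: int = windows.DEFAULT_WINDOW
    step: int = windows.DEFAULT_STEP
    min_sites: int = windows.DEFAULT_MIN_SITES
    z_threshold: float = intervals.DEFAULT_Z_THRESHOLD
    buffer: int = intervals.DEFAULT_BUFFER
    n_perm_share: int = 10_000
    n_perm_enrich: int = 10_000
    n_perm_fdm: int = 1_000
    fdm_window: int = introgression.DEFAULT_FDM_WINDOW
    fdm_min_informative: int = introgression.DEFAULT_MIN_INFORMATIVE
    jackknife_block: int = 1_000_000
    exclude_chroms: list[str] = field(default_factory=list)
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str) -> int:
        # master seed expanded by stage index; kept below 2**31
        return (self.master_seed * 1000 + STAGES.index(stage)) % (2**31 - 1)

    def config_hash(self) -> str:
        # out_dir does not affect results, so it is not part of the hash
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _log(stage: str, msg: str, fh=None):
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{stage}\t{msg}"
    print(line, file=sys.stderr)
    if fh is not None:
        fh.write(line + "\n")


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the artifact directory.

    Any stage failure aborts with the stage name; files written by earlier
    stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_fh = open(out / "run.log", "a")
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stages": [],
        "inputs": {"vcf": config.vcf, "popmap": config.popmap},
        "seeds": {s: config.stage_seed(s) for s in STAGES},
    }
    stage = "validate"
    try:
        vcf_path, popmap_path = config.vcf, config.popmap
        if config.simulate is None:
            for name, p in (("vcf", vcf_path), ("popmap", popmap_path)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing {name} input: {p}")

        # --- simulate -------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            _log(stage, "generating synthetic dataset", log_fh)
            sc = sim.SimConfig.from_dict({**config.simulate,
                                          "seed": config.simulate.get(
                                              "seed", config.stage_seed("simulate"))})
            table = sim.simulate_frequencies(sc)
            geno, samples = sim.sample_genotypes(table, sc)
            paths = sim.write_dataset(geno, samples, table, sc, out / "sim")
            vcf_path = str(paths["vcf"])
            popmap_path = str(paths["popmap"])
            manifest["inputs"] = {"vcf": "sim/sim.vcf", "popmap": "sim/popmap.tsv"}
            manifest["stages"].append("simulate")

        # --- load inputs ----------------------------------------------
        stage = "windows"
        chrom, pos, geno, samples = vcfio.read_vcf(vcf_path)
        popmap = vcfio.read_popmap(popmap_path)
        contigs = _contig_lengths(config, chrom, pos)
        genome = Genome(contigs)
        counts = windows.allele_counts(chrom, pos, geno, samples, popmap)
        _log(stage, f"{pos.size} sites, {len(samples)} samples,"
                    f" {len(config.trios)} transects", log_fh)
        tracks: dict[str, pd.DataFrame] = {}
        for name, trio_d in config.trios.items():
            trio = windows.TransectTrio(**trio_d)
            tr = windows.transect_scan(genome, counts, trio,
                                       config.window, config.step, config.min_sites)
            tr.to_csv(out / f"windows_{name}.tsv", sep="\t", index=False)
            tracks[name] = tr
        manifest["stages"].append("windows")

        # --- hdr ------------------------------------------------------
        stage = "hdr"
        hdr_sets: dict[str, IntervalSet] = {}
        for name, tr in tracks.items():
            outl = intervals.call_outliers(tr, config.z_threshold)
            hdrs = intervals.build_hdrs(genome, outl, config.buffer, name)
            hdr_sets[name] = hdrs
            df = hdrs.to_frame()
            df["name"] = df.get("source_transect", name)
            df["score"] = df.get("max_z", np.nan)
            df["strand"] = "."
            vcfio.write_bed(out / f"hdr_{name}.bed", df)
            _log(stage, f"{name}: {len(hdrs)} HDRs "
                        f"({hdrs.genome_fraction():.3%} of genome)", log_fh)
        manifest["stages"].append("hdr")

        # --- share ----------------------------------------------------
        stage = "share"
        share_rows = []
        classified = intervals.classify_sharing(hdr_sets, config.layout) \
            if len(hdr_sets) >= 2 else {}
        for name, df in classified.items():
            df.to_csv(out / f"shdr_{name}.tsv", sep="\t", index=False)
            same, other = intervals._side_partners(config.layout, name)
            partners = [hdr_sets[t] for t in same]
            if partners and len(hdr_sets[name]):
                perm = intervals.overlap_permutation_null(
                    genome, hdr_sets[name], partners,
                    n_perm=config.n_perm_share, seed=config.stage_seed("share"))
                jk = intervals.jackknife_ci(genome, hdr_sets[name], partners,
                                            block_size=config.jackknife_block)
                share_rows.append({
                    "transect": name, "n_hdrs": len(hdr_sets[name]),
                    "shared_within_side": float((df["sharing_class"] != "private").mean()),
                    "shared_allopatric": float((df["sharing_class"] == "shdr_allopatric").mean()),
                    "perm_p": perm["p"], "perm_null_mean": perm["null_mean"],
                    "jackknife_se": jk["se"],
                    "ci_low": jk["ci"][0], "ci_high": jk["ci"][1],
                })
        share_df = pd.DataFrame(share_rows)
        share_df.to_csv(out / "sharing.tsv", sep="\t", index=False)
        manifest["stages"].append("share")

        # --- enrich ---------------------------------------------------
        stage = "enrich"
        enrich_frames = []
        for name, df in classified.items():
            shared = df[df["sharing_class"] != "private"]
            if not len(shared):
                continue
            shdrs = IntervalSet(genome, shared["chrom"].to_numpy(),
                                shared["start"].to_numpy(), shared["end"].to_numpy())
            obs = enrichment.shdr_extrema(genome, shdrs, tracks[name])
            nulls = enrichment.permuted_extrema_null(
                genome, tracks[name], shdrs.sizes(),
                n_perm=max(1, config.n_perm_enrich // max(1, len(shdrs))),
                seed=config.stage_seed("enrich"))
            ev = enrichment.classify_outliers(obs, nulls)
            ev.insert(0, "transect", name)
            enrich_frames.append(ev)
        if enrich_frames:
            pd.concat(enrich_frames).to_csv(out / "enrichment.tsv", sep="\t",
                                            index=False)
        manifest["stages"].append("enrich")

        # --- pca ------------------------------------------------------
        stage = "pca"
        all_hdr = None
        for name, h in hdr_sets.items():
            all_hdr = h if all_hdr is None else IntervalSet.from_linear(
                genome, np.concatenate([all_hdr.lin_start, h.lin_start]),
                np.concatenate([all_hdr.lin_end, h.lin_end]))
        # neutral structure among transect samples only (the donor species
        # and outgroup would otherwise dominate PC1)
        transect_classes = {"high", "low", "low_distant"}
        in_transects = popmap[popmap["altitude_class"].isin(transect_classes)]
        keep_samples = set(in_transects["sample"])
        cols = [j for j, s in enumerate(samples) if s in keep_samples]
        sub_samples = [samples[j] for j in cols]
        gp = pca.global_pca(geno[:, cols], sub_samples, chrom, pos,
                            exclude_intervals=all_hdr,
                            exclude_chroms=config.exclude_chroms,
                            seed=config.stage_seed("pca"))
        gp.scores.to_csv(out / "global_pca.tsv", sep="\t")
        assoc_rows = []
        alt = popmap.set_index("sample")["altitude_m"]
        sample_transect = popmap.set_index("sample")["transect"]
        for name, df in classified.items():
            shared = df[df["sharing_class"] != "private"].reset_index()
            same, _ = intervals._side_partners(config.layout, name)
            wanted = {name, *same}
            lcols = [j for j in cols
                     if sample_transect.get(samples[j]) in wanted]
            lsamples = [samples[j] for j in lcols]
            if len(lsamples) < 4:
                continue
            for _, region in shared.iterrows():
                sel = ((chrom == region["chrom"]) & (pos >= region["start"])
                       & (pos < region["end"]))
                if sel.sum() < 2:
                    continue
                lp = pca.local_pca(geno[np.ix_(np.flatnonzero(sel), lcols)],
                                   lsamples)
                a = pca.altitude_association(
                    lp.scores["PC1"].to_numpy(),
                    alt.loc[lp.scores.index].to_numpy(),
                    gp.scores["PC1"].loc[lp.scores.index].to_numpy())
                assoc_rows.append({"transect": name, "chrom": region["chrom"],
                                   "start": region["start"], "end": region["end"],
                                   **{k: v for k, v in a.items()}})
        pd.DataFrame(assoc_rows).to_csv(out / "altitude_association.tsv",
                                        sep="\t", index=False)
        manifest["stages"].append("pca")

        # --- fdm ------------------------------------------------------
        stage = "fdm"
        fdm_rows = []
        for q in config.quartets:
            quartet = introgression.QuartetConfig(**q)
            track = introgression.fdm_track(genome, counts, quartet,
                                            config.fdm_window,
                                            config.fdm_min_informative)
            tag = f"{quartet.p2}_vs_{quartet.p3}"
            track.to_csv(out / f"fdm_{tag}.tsv", sep="\t", index=False)
            row = {"quartet": tag,
                   "pattersons_d": introgression.pattersons_d(counts, quartet),
                   "mean_fdm": float(np.nanmean(track["fdm"]))}
            # SHDRs of the transect containing P2, if any
            for name, df in classified.items():
                shared = df[df["sharing_class"] != "private"]
                if not len(shared):
                    continue
                shdrs = IntervalSet(genome, shared["chrom"].to_numpy(),
                                    shared["start"].to_numpy(),
                                    shared["end"].to_numpy())
                res = introgression.shdr_fdm_outliers(genome, track, shdrs)
                row[f"pct_outlier_{name}"] = res["percent_flagged"]
            fdm_rows.append(row)
        pd.DataFrame(fdm_rows).to_csv(out / "fdm_summary.tsv", sep="\t",
                                      index=False)
        manifest["stages"].append("fdm")

        # --- report ---------------------------------------------------
        stage = "report"
        manifest["stages"].append("report")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        report(out)
    except Exception as e:
        log_fh.close()
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    log_fh.close()
    return out


def _contig_lengths(config: RunConfig, chrom, pos) -> dict[str, int]:
    if config.simulate is not None:
        sc = config.simulate
        return dict.fromkeys([f"chr{i + 1}" for i in range(sc["n_chromosomes"])],
                             sc["chrom_length"])
    # infer from VCF header if possible, else from max position
    from cyvcf2 import VCF

    lengths = {}
    v = VCF(config.vcf)
    for line in v.raw_header.splitlines():
        if line.startswith("##contig"):
            fields = dict(kv.split("=") for kv in
                          line[len("##contig=<"):-1].split(","))
            lengths[fields["ID"]] = int(fields["length"])
    if lengths:
        return lengths
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    return {c: int(pos[chrom == c].max()) + 1 for c in dict.fromkeys(chrom.tolist())}


def _read_tsv(path: Path) -> pd.DataFrame | None:
    if not path.exists():
        return None
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def report(artifact_dir) -> Path:
    """Human-readable markdown summary of a completed run."""
    out = Path(artifact_dir)
    lines = ["# Parallel-adaptation scan report", ""]
    df = _read_tsv(out / "sharing.tsv")
    if df is not None:
        lines.append("## HDR sharing across transects\n")
        if len(df):
            lines.append(df.to_markdown(index=False))
        else:
            lines.append("No high-differentiation regions were called.")
        lines.append("")
    df = _read_tsv(out / "enrichment.tsv")
    if df is not None and len(df):
        lines.append("## Selection-statistic support in SHDRs\n")
        tally = df.groupby(["transect", "n_outlier_stats_total"]).size()
        lines.append(tally.rename("n_shdrs").reset_index().to_markdown(index=False))
        lines.append("")
    df = _read_tsv(out / "altitude_association.tsv")
    if df is not None:
        lines.append("## Altitude association of local PC1\n")
        if len(df):
            sig = (df["altitude_p"] < 0.05).sum()
            lines.append(f"{sig} of {len(df)} SHDR local PCAs have altitude as a "
                         f"significant predictor (p < 0.05).")
        else:
            lines.append("No SHDRs were available for local PCA.")
        lines.append("")
    df = _read_tsv(out / "fdm_summary.tsv")
    if df is not None:
        lines.append("## Excess allele sharing (f_dM)\n")
        if len(df):
            lines.append(df.to_markdown(index=False))
        else:
            lines.append("No quartets configured.")
        lines.append("")
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
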