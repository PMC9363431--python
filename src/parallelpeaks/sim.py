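"""Synthetic genotype datasets with planted adaptive signals.

The generator produces per-population allele frequencies under a
hierarchical Balding-Nichols drift model: an ancestral frequency is drawn
per site from a Beta distribution and each branch of a rooted population
tree replaces the parent frequency p by a draw from
Beta(p(1-F)/F, (1-p)(1-F)/F), where F in [0,1) is the branch's drift
coefficient (F=0 copies the parent exactly). On top of the neutral drift
structure, four kinds of features can be planted in genomic intervals:

* ``sweep`` - shifts the target populations' derived frequency toward
  fixation by ``intensity`` (p' = p + intensity*(1-p)), and optionally
  thins intermediate-frequency sites inside the interval to induce the
  rare-allele excess (negative Tajima's D) a hard sweep leaves behind;
* ``shared_standing`` - sets one identical elevated derived frequency in
  all target populations, emulating a shared ancestral standing variant;
* ``introgression`` - mixes the donor population's frequency into the
  targets (p' = (1-intensity)*p + intensity*p_donor);
* ``inversion_block`` - a divergent non-recombining haplotype segregating
  at frequency ``intensity`` in the target populations; carriers receive
  a fixed diverged allele sequence, so local PCA of the block shows the
  three karyotype clusters a real inversion produces.

Diploid genotypes are then drawn Binomial(2, p) per sample, and the whole
dataset (VCF, population map, truth BED, config YAML) can be written out
and read back losslessly. Identical configs (including the seed) give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import Genome

__all__ = [
    "PopulationSpec",
    "PlantedFeature",
    "DriftNode",
    "SimConfig",
    "FrequencyTable",
    "simulate_frequencies",
    "sample_genotypes",
    "write_dataset",
    "read_dataset",
    "default_study_config",
]

FEATURE_KINDS = ("sweep", "shared_standing", "introgression", "inversion_block")


@dataclass
class PopulationSpec:
    id: str
    transect: str
    side: str
    altitude_class: str  # high | low | low_distant | donor | outgroup
    altitude_m: float
    n_diploids: int
    species: str = "simulated"
    outgroup: bool = False

    def __post_init__(self):
        if self.n_diploids < 2:
            raise ValueError(f"population {self.id!r} needs >= 2 diploids")


@dataclass
class PlantedFeature:
    kind: str
    chrom: str
    start: int
    end: int
    target_populations: list[str]
    intensity: float
    donor_population: str | None = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must be in [0, 1]")
        if self.kind == "introgression" and self.donor_population is None:
            raise ValueError("introgression features require a donor population")
        if self.end <= self.start:
            raise ValueError("feature interval is empty or inverted")


@dataclass
class DriftNode:
    """A node of the rooted drift tree; ``f`` is the drift coefficient of
    the branch ABOVE this node (ignored at the root)."""

    name: str
    f: float = 0.0
    children: list["DriftNode"] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"branch F must be in [0, 1); got {self.f} at {self.name!r}")

    def leaves(self) -> list["DriftNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "f": float(self.f),
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriftNode":
        return cls(
            name=d["name"],
            f=float(d.get("f", 0.0)),
            children=[cls.from_dict(c) for c in d.get("children", [])],
        )


@dataclass
class SimConfig:
    n_chromosomes: int
    chrom_length: int
    n_sites: int
    populations: list[PopulationSpec]
    drift_tree: DriftNode
    ancestral_beta: tuple[float, float] = (0.8, 2.0)
    planted_features: list[PlantedFeature] = field(default_factory=list)
    seed: int = 0
    position_jitter: bool = False
    sweep_thin_fraction: float = 0.8  # of intermediate-frequency sweep sites
    missing_rate: float = 0.0

    def __post_init__(self):
        pop_ids = [p.id for p in self.populations]
        if len(set(pop_ids)) != len(pop_ids):
            raise ValueError("duplicate population ids")
        leaf_names = {l.name for l in self.drift_tree.leaves()}
        for p in self.populations:
            if p.id not in leaf_names:
                raise ValueError(f"population {p.id!r} is not a leaf of the drift tree")
        a, b = self.ancestral_beta
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError("ancestral Beta parameters must be finite and positive")
        known = set(pop_ids)
        chroms = set(self.chrom_names())
        for f in self.planted_features:
            for t in f.target_populations:
                if t not in known:
                    raise ValueError(f"feature targets unknown population {t!r}")
            if f.donor_population is not None and f.donor_population not in known:
                raise ValueError(f"unknown donor population {f.donor_population!r}")
            if f.chrom not in chroms:
                raise ValueError(f"feature on unknown chromosome {f.chrom!r}")
            if f.start < 0 or f.end > self.chrom_length:
                raise ValueError("feature interval outside chromosome bounds")
        # same-kind features may not overlap
        by_kind: dict[str, list[PlantedFeature]] = {}
        for f in self.planted_features:
            by_kind.setdefault(f.kind, []).append(f)
        for kind, feats in by_kind.items():
            feats = sorted(feats, key=lambda f: (f.chrom, f.start))
            for a_, b_ in zip(feats, feats[1:]):
                if a_.chrom == b_.chrom and b_.start < a_.end:
                    raise ValueError(f"overlapping {kind!r} features")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def genome(self) -> Genome:
        return Genome({c: self.chrom_length for c in self.chrom_names()})

    def pop_index(self) -> dict[str, int]:
        return {p.id: i for i, p in enumerate(self.populations)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift_tree"] = self.drift_tree.to_dict()
        d["ancestral_beta"] = list(self.ancestral_beta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["populations"] = [PopulationSpec(**p) for p in d["populations"]]
        d["planted_features"] = [PlantedFeature(**f) for f in d.get("planted_features", [])]
        d["drift_tree"] = DriftNode.from_dict(d["drift_tree"])
        d["ancestral_beta"] = tuple(d["ancestral_beta"])
        return cls(**d)


@dataclass
class FrequencyTable:
    """Per-site, per-population derived-allele frequencies."""

    chrom: np.ndarray  # object array of chromosome names
    pos: np.ndarray  # 0-based positions
    freqs: np.ndarray  # (n_sites, n_populations)
    populations: list[str]
    # background (pre-feature) frequencies and the diverged haplotype state,
    # kept only at inversion_block sites so genotype sampling can model
    # karyotypes explicitly
    inversion_data: list[dict] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.pos.size


def _balding_nichols(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of drift: Beta(p(1-F)/F, (1-p)(1-F)/F) draw per site."""
    if f == 0.0:
        return p.copy()
    out = p.copy()
    seg = (p > 0.0) & (p < 1.0)  # fixed sites stay fixed
    k = (1.0 - f) / f
    out[seg] = rng.beta(p[seg] * k, (1.0 - p[seg]) * k)
    return out


def simulate_frequencies(config: SimConfig) -> FrequencyTable:
    """Simulate the per-population derived-allele frequency matrix."""
    ss = np.random.SeedSequence(config.seed)
    rng_freq, _rng_geno, rng_aux = [np.random.default_rng(s) for s in ss.spawn(3)]

    # ~uniform site placement across the genome
    chroms = config.chrom_names()
    per_chrom = np.full(config.n_chromosomes, config.n_sites // config.n_chromosomes)
    per_chrom[: config.n_sites % config.n_chromosomes] += 1
    chrom_arr, pos_arr = [], []
    for c, n in zip(chroms, per_chrom):
        spacing = config.chrom_length / n
        pos = np.floor(spacing * (np.arange(n) + 0.5)).astype(np.int64)
        if config.position_jitter:
            jitter = rng_aux.integers(-int(spacing // 3), int(spacing // 3) + 1, size=n)
            pos = np.clip(pos + jitter, 0, config.chrom_length - 1)
            pos = np.unique(pos)
        chrom_arr.append(np.full(pos.size, c, dtype=object))
        pos_arr.append(pos)
    chrom = np.concatenate(chrom_arr)
    pos = np.concatenate(pos_arr)
    n_sites = pos.size

    a, b = config.ancestral_beta
    p0 = rng_freq.beta(a, b, size=n_sites)

    # depth-first drift down the tree; leaves collect their frequency vector
    leaf_freqs: dict[str, np.ndarray] = {}

    def descend(node: DriftNode, p: np.ndarray):
        if not node.children:
            leaf_freqs[node.name] = p
            return
        for child in node.children:
            descend(child, _balding_nichols(p, child.f, rng_freq))

    descend(config.drift_tree, p0)

    pops = [p.id for p in config.populations]
    freqs = np.column_stack([leaf_freqs[p] for p in pops])
    for i, spec in enumerate(config.populations):
        if spec.outgroup:
            freqs[:, i] = 0.0  # outgroup carries the ancestral state

    pidx = config.pop_index()
    table = FrequencyTable(chrom=chrom, pos=pos, freqs=freqs, populations=pops)

    drop_mask = np.zeros(n_sites, dtype=bool)
    for feat in config.planted_features:
        in_feat = (chrom == feat.chrom) & (pos >= feat.start) & (pos < feat.end)
        cols = [pidx[t] for t in feat.target_populations]
        if feat.kind == "sweep":
            for c in cols:
                p = freqs[in_feat, c]
                freqs[in_feat, c] = p + feat.intensity * (1.0 - p)
            if config.sweep_thin_fraction > 0:
                # remove a fraction of intermediate-frequency sites inside the
                # sweep to mimic the SFS skew of a hard sweep
                mean_t = freqs[:, cols].mean(axis=1)
                inter = in_feat & (mean_t >= 0.25) & (mean_t <= 0.75)
                u = rng_aux.random(n_sites)
                drop_mask |= inter & (u < config.sweep_thin_fraction)
        elif feat.kind == "shared_standing":
            freqs[np.ix_(in_feat, cols)] = feat.intensity
        elif feat.kind == "introgression":
            donor = freqs[in_feat, pidx[feat.donor_population]]
            for c in cols:
                freqs[in_feat, c] = (1 - feat.intensity) * freqs[in_feat, c] + feat.intensity * donor
        elif feat.kind == "inversion_block":
            # diverged haplotype: a fixed allele sequence far from the
            # background, segregating at frequency `intensity`
            background = freqs[in_feat][:, cols].copy()
            hap = (rng_aux.random(int(in_feat.sum())) < 0.5).astype(np.int8)
            table.inversion_data.append(
                {
                    "feature": feat,
                    "site_mask": in_feat,
                    "haplotype": hap,
                    "background": background,
                }
            )
            for j, c in enumerate(cols):
                freqs[in_feat, c] = (
                    (1 - feat.intensity) * background[:, j] + feat.intensity * hap
                )

    if np.any(drop_mask):
        keep = ~drop_mask
        table.chrom = table.chrom[keep]
        table.pos = table.pos[keep]
        table.freqs = freqs[keep]
        for inv in table.inversion_data:
            old = inv["site_mask"]
            kept_within = keep[old]
            inv["haplotype"] = inv["haplotype"][kept_within]
            inv["background"] = inv["background"][kept_within]
            inv["site_mask"] = old[keep]
    else:
        table.freqs = freqs
    return table


def sample_genotypes(table: FrequencyTable, config: SimConfig) -> tuple[np.ndarray, list[str]]:
    """Draw diploid dosages (sites x samples, values 0/1/2; -1 missing).

    Genotypes are Binomial(2, p) per sample, except inside inversion blocks
    in target populations, where each sample first draws a karyotype
    k ~ Binomial(2, intensity) and then carries k copies of the diverged
    haplotype allele plus 2-k draws from the background frequency.
    """
    if np.any((table.freqs < 0) | (table.freqs > 1)):
        raise ValueError("frequencies outside [0, 1]")
    ss = np.random.SeedSequence(config.seed)
    _, rng, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    sample_ids: list[str] = []
    cols = []
    pidx = config.pop_index()
    for spec in config.populations:
        n = spec.n_diploids
        p = table.freqs[:, pidx[spec.id]]
        g = rng.binomial(2, p[:, None], size=(table.n_sites, n)).astype(np.int8)
        for inv in table.inversion_data:
            feat: PlantedFeature = inv["feature"]
            if spec.id not in feat.target_populations:
                continue
            j = feat.target_populations.index(spec.id)
            mask = inv["site_mask"]
            k = rng.binomial(2, feat.intensity, size=n)  # per-sample karyotype
            bg = inv["background"][:, j]
            hap = inv["haplotype"]
            for s in range(n):
                rest = rng.binomial(2 - k[s], bg).astype(np.int8)
                g[mask, s] = k[s] * hap + rest
        cols.append(g)
        sample_ids.extend(f"{spec.id}_{i}" for i in range(n))
    geno = np.concatenate(cols, axis=1)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = -1
    return geno, sample_ids


def popmap_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    for spec in config.populations:
        for i in range(spec.n_diploids):
            rows.append(
                {
                    "sample": f"{spec.id}_{i}",
                    "population": spec.id,
                    "transect": spec.transect,
                    "side": spec.side,
                    "altitude_class": spec.altitude_class,
                    "altitude_m": spec.altitude_m,
                    "species": spec.species,
                }
            )
    return pd.DataFrame(rows)


def write_dataset(
    genotypes: np.ndarray,
    sample_ids: list[str],
    table: FrequencyTable,
    config: SimConfig,
    out_dir,
) -> dict[str, Path]:
    """Write VCF + population map + truth BED + config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "sim.vcf",
        "popmap": out / "popmap.tsv",
        "truth_bed": out / "truth.bed",
        "config": out / "sim_config.yaml",
    }
    from .vcfio import write_vcf

    write_vcf(paths["vcf"], table.chrom, table.pos, genotypes, sample_ids,
              contigs=dict.fromkeys(config.chrom_names(), config.chrom_length))
    popmap_frame(config).to_csv(paths["popmap"], sep="\t", index=False)
    with open(paths["truth_bed"], "w") as fh:
        for feat in config.planted_features:
            name = f"{feat.kind}:{','.join(feat.target_populations)}"
            fh.write(f"{feat.chrom}\t{feat.start}\t{feat.end}\t{name}\t"
                     f"{feat.intensity:g}\t.\n")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return paths


def read_dataset(out_dir):
    """Read back a written dataset; inverse of :func:`write_dataset`."""
    from .vcfio import read_popmap, read_vcf

    out = Path(out_dir)
    chrom, pos, geno, samples = read_vcf(out / "sim.vcf")
    popmap = read_popmap(out / "popmap.tsv")
    with open(out / "sim_config.yaml") as fh:
        config = SimConfig.from_dict(yaml.safe_load(fh))
    return chrom, pos, geno, samples, popmap, config


def default_study_config(
    seed: int = 0,
    n_chromosomes: int = 4,
    chrom_length: int = 2_000_000,
    sites_per_kb: float = 4.0,
    n_diploids: int = 6,
    features: list[PlantedFeature] | None = None,
    f_pop: float = 0.02,
    f_transect: float = 0.02,
    f_side: float = 0.05,
    f_donor: float = 0.25,
    sweep_thin_fraction: float = 0.8,
) -> SimConfig:
    """The default replicated-transect study design.

    Two sides of a dispersal barrier, each with two replicate transects;
    each transect samples a highland (~1200 m), nearby lowland (~360 m) and
    distant lowland (~95 m) population. A divergent highland-specialist
    donor species and a distant outgroup (fixed for the ancestral state)
    complete the sampling, mirroring a replicated altitudinal study design.
    """
    pops: list[PopulationSpec] = []
    tips: dict[str, DriftNode] = {}
    sides = {"west": ["t1", "t2"], "east": ["t3", "t4"]}
    alt = {"high": 1200.0, "low": 360.0, "low_distant": 95.0}
    side_nodes = []
    for side, transects in sides.items():
        t_nodes = []
        for t in transects:
            leaf_nodes = []
            for cls in ("high", "low", "low_distant"):
                pid = f"{t}_{cls}"
                pops.append(
                    PopulationSpec(
                        id=pid, transect=t, side=side, altitude_class=cls,
                        altitude_m=alt[cls], n_diploids=n_diploids,
                    )
                )
                node = DriftNode(pid, f=f_pop)
                tips[pid] = node
                leaf_nodes.append(node)
            t_nodes.append(DriftNode(t, f=f_transect, children=leaf_nodes))
        side_nodes.append(DriftNode(side, f=f_side, children=t_nodes))
    pops.append(
        PopulationSpec(
            id="donor", transect="donor", side="east", altitude_class="donor",
            altitude_m=1500.0, n_diploids=n_diploids, species="specialist",
        )
    )
    pops.append(
        PopulationSpec(
            id="outgroup", transect="outgroup", side="east", altitude_class="outgroup",
            altitude_m=500.0, n_diploids=max(2, n_diploids // 2),
            species="outgroup", outgroup=True,
        )
    )
    ingroup = DriftNode("ingroup", f=0.02, children=side_nodes)
    donor = DriftNode("donor", f=f_donor)
    root = DriftNode(
        "root",
        children=[DriftNode("split", f=0.0, children=[ingroup, donor]),
                  DriftNode("outgroup", f=0.3)],
    )
    n_sites = int(n_chromosomes * chrom_length / 1000 * sites_per_kb)
    return SimConfig(
        n_chromosomes=n_chromosomes,
        chrom_length=chrom_length,
        n_sites=n_sites,
        populations=pops,
        drift_tree=root,
        planted_features=features or [],
        seed=seed,
        sweep_thin_fraction=sweep_thin_fraction,
    )
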