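"""Seeded synthetic bisulfite count data for the 2x2x3 factorial design.

The generator produces a complete input bundle — region FASTA, region table,
one cytosine report per sample, manifest, and a ground-truth table — that
emulates the structure of a targeted bisulfite study of temperature epitypes:

* two growth-temperature conditions (cool 18C, warm 28C) x two embryo parts
  (apical, basal) x three replicates of pooled material = 12 samples;
* context-specific base methylation, high for CpG, intermediate for CHG and
  low for CHH;
* a spatial profile over each 3 kb region: elevated promoter methylation
  declining linearly toward the TSS, with a low flat plateau over the 1 kb
  gene body;
* multiplicative hypermethylation of the warm condition, with an optional
  extra factor for the warm-basal cell;
* optional planted window-level differences ("planted DMRs") for power and
  recovery studies.

Each site's true methylation probability is

    p = base_level[context] * spatial(position) * condition/part factors

clipped to [0, 1]; per replicate, coverage is drawn per site (Poisson or
fixed) and the methylated read count is Binomial(coverage, p).  The two
strands of a CpG dyad are simulated independently — the analysis treats
strands as independent observations, so coupling them would only flatter the
caller.  An optional bisulfite conversion-failure rate folds false-positive
methylation into p (default 0).  The seed fully determines the bundle.

In a planted window the condition/part factors are suppressed and the warm
groups get ``p_cool + delta`` instead, so the true between-condition
difference in that window equals the planted delta exactly (pre-clipping).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .regions import TargetRegion, enumerate_sites_many, write_regions_fasta

CONDITIONS = ("cool", "warm")
PARTS = ("apical", "basal")


@dataclass(frozen=True)
class PlantedDMR:
    """One planted window-level methylation difference (warm minus cool)."""

    gene_id: str
    window_index: int
    context: str
    delta: float  # true probability difference added to the warm groups


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the factorial design and the qualitative methylation
    structure of a targeted temperature-epitype experiment; base levels per
    context sit inside realistic per-context ranges (CpG well above CHG,
    CHH lowest).
    """

    n_genes: int = 50
    region_length: int = 3000
    tss_offset: int = 2000
    gc_content: float = 0.40
    n_fraction: float = 0.0  # probability of an N base
    base_level: dict = field(
        default_factory=lambda: {"CpG": 0.35, "CHG": 0.12, "CHH": 0.03}
    )
    # constitutively unmethylated sites (p = 0 in every group), drawn once per
    # site and shared across groups; real methylomes are dominated by such
    # sites, CHH most of all
    unmethylated_site_fraction: dict = field(
        default_factory=lambda: {"CpG": 0.3, "CHG": 0.5, "CHH": 0.7}
    )
    # per-group probability that a site's silenced/active status flips,
    # drawn independently for each (condition, part); makes methylated and
    # unmethylated site sets differ between groups as they do in real data
    epimutation_rate: float = 0.1
    promoter_profile: str = "linear_decline"  # or "constant"
    promoter_start_multiplier: float = 1.6
    promoter_end_multiplier: float = 0.4
    body_level_multiplier: float = 0.3
    condition_effect: float = 1.4  # multiplicative warm hypermethylation
    part_effect: float = 1.2  # extra factor for the warm-basal cell
    conversion_failure_rate: float = 0.0
    planted_dmrs: list = field(default_factory=list)
    mean_coverage: float = 30.0
    coverage_model: str = "poisson"  # or "fixed"
    n_replicates: int = 3
    window_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.n_fraction < 1.0:
            raise ValueError("n_fraction must be in [0, 1)")
        if self.promoter_profile not in ("linear_decline", "constant"):
            raise ValueError(f"unknown promoter_profile {self.promoter_profile!r}")
        if self.coverage_model not in ("poisson", "fixed"):
            raise ValueError(f"unknown coverage_model {self.coverage_model!r}")
        if self.region_length % self.window_size != 0:
            raise ValueError("window_size must divide region_length")
        if not 0 < self.tss_offset < self.region_length:
            raise ValueError("tss_offset must lie inside the region")
        for ctx, lvl in self.base_level.items():
            if not 0.0 <= lvl <= 1.0:
                raise ValueError(f"base_level[{ctx}] must be in [0, 1]")
        for ctx, frac in self.unmethylated_site_fraction.items():
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"unmethylated_site_fraction[{ctx}] must be in [0, 1)")
        if not 0.0 <= self.epimutation_rate < 0.5:
            raise ValueError("epimutation_rate must be in [0, 0.5)")
        self.planted_dmrs = [
            p if isinstance(p, PlantedDMR) else PlantedDMR(*p) for p in self.planted_dmrs
        ]
        n_windows = self.region_length // self.window_size
        for p in self.planted_dmrs:
            if not 0 <= p.window_index < n_windows:
                raise ValueError(f"planted window {p.window_index} outside [0, {n_windows})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_dmrs"] = [list(dataclasses.astuple(p)) for p in self.planted_dmrs]
        return d


def _gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:04d}" for i in range(n)]


def simulate_sequences(config: SimulationConfig, rng: np.random.Generator) -> dict[str, TargetRegion]:
    """Draw i.i.d. sequences at the configured GC content (and N fraction)."""
    gc = config.gc_content
    probs = np.array(
        [
            (1 - config.n_fraction) * (1 - gc) / 2,  # A
            (1 - config.n_fraction) * gc / 2,  # C
            (1 - config.n_fraction) * gc / 2,  # G
            (1 - config.n_fraction) * (1 - gc) / 2,  # T
            config.n_fraction,  # N
        ]
    )
    alphabet = np.array(list("ACGTN"))
    regions = {}
    for gene in _gene_ids(config.n_genes):
        bases = rng.choice(alphabet, size=config.region_length, p=probs)
        regions[gene] = TargetRegion(gene, "".join(bases), config.tss_offset)
    return regions


def _spatial_multiplier(positions: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Promoter decline / body plateau multiplier at each position."""
    pos = np.asarray(positions, dtype=float)
    tss = config.tss_offset
    if config.promoter_profile == "constant":
        prom = np.ones_like(pos)
    else:
        s, e = config.promoter_start_multiplier, config.promoter_end_multiplier
        # linear from s at position 0 to e at the last promoter base (TSS-1)
        prom = s + (e - s) * pos / max(tss - 1, 1)
    return np.where(pos < tss, prom, config.body_level_multiplier)


def _silencing_mask(config: SimulationConfig, sites: pd.DataFrame) -> np.ndarray:
    """Deterministic per-site mask of constitutively unmethylated sites.

    Seeded from the config alone so every group sees the same mask.
    """
    rng = np.random.default_rng([config.seed % (2**31), 0xC0])
    frac = sites["context"].map(config.unmethylated_site_fraction).to_numpy(dtype=float)
    return rng.uniform(size=len(sites)) < frac


def methylation_surface(
    config: SimulationConfig, sites: pd.DataFrame, condition: str, part: str
) -> np.ndarray:
    """True methylation probability for every (unambiguous) site in one group."""
    base = sites["context"].map(config.base_level).to_numpy(dtype=float)
    p_raw = base * _spatial_multiplier(sites["position"].to_numpy(), config)
    silenced = _silencing_mask(config, sites)
    if config.epimutation_rate:
        group_index = CONDITIONS.index(condition) * 2 + PARTS.index(part)
        rng = np.random.default_rng([config.seed % (2**31), 0xE1, group_index])
        flip = rng.uniform(size=len(sites)) < config.epimutation_rate
        silenced = silenced ^ flip
    p = np.where(silenced, 0.0, p_raw)
    factor = np.ones(len(sites))
    if condition == "warm":
        factor *= config.condition_effect
        if part == "basal":
            factor *= config.part_effect
    p_effect = p * factor
    if config.planted_dmrs:
        win = sites["position"].to_numpy() // config.window_size
        for planted in config.planted_dmrs:
            mask = (
                (sites["gene_id"].to_numpy() == planted.gene_id)
                & (win == planted.window_index)
                & (sites["context"].to_numpy() == planted.context)
            )
            # suppress group factors and silencing so the true between-group
            # difference in the planted window is exactly delta at every site
            p_effect[mask] = p_raw[mask] + (planted.delta if condition == "warm" else 0.0)
    if config.conversion_failure_rate:
        p_effect = p_effect + (1.0 - p_effect) * config.conversion_failure_rate
    return np.clip(p_effect, 0.0, 1.0)


@dataclass
class SimulatedBundle:
    """In-memory result of a simulation run."""

    config: SimulationConfig
    regions: dict[str, TargetRegion]
    sites: pd.DataFrame  # unambiguous sites only
    manifest: pd.DataFrame  # without counts_path until written
    counts: dict[str, pd.DataFrame]  # sample_id -> SiteCounts frame
    ground_truth: pd.DataFrame  # per-site true p per (condition, part)

    def long_counts(self) -> pd.DataFrame:
        """Stack per-sample counts with sample metadata (as after loading)."""
        frames = []
        for r in self.manifest.itertuples(index=False):
            c = self.counts[r.sample_id].copy()
            c.insert(0, "sample_id", r.sample_id)
            c.insert(1, "condition", r.condition)
            c.insert(2, "part", r.part)
            c.insert(3, "replicate", r.replicate)
            frames.append(c)
        return pd.concat(frames, ignore_index=True)


def simulate_counts(config: SimulationConfig) -> SimulatedBundle:
    """Generate the full synthetic bundle (sequences, surfaces, counts).

    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    regions = simulate_sequences(config, rng)
    sites = enumerate_sites_many(list(regions.values()), drop_ambiguous=True)

    truth = sites[["gene_id", "position", "strand", "context", "region"]].copy()
    surfaces = {}
    for cond in CONDITIONS:
        for part in PARTS:
            p = methylation_surface(config, sites, cond, part)
            surfaces[(cond, part)] = p
            truth[f"p_{cond}_{part}"] = p

    manifest_rows = []
    counts: dict[str, pd.DataFrame] = {}
    n_sites = len(sites)
    for cond in CONDITIONS:
        for part in PARTS:
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{cond}_{part}_r{rep}"
                if config.coverage_model == "poisson":
                    cov = rng.poisson(config.mean_coverage, size=n_sites)
                else:
                    cov = np.full(n_sites, int(round(config.mean_coverage)))
                meth = rng.binomial(cov, surfaces[(cond, part)])
                counts[sample_id] = pd.DataFrame(
                    {
                        "gene_id": sites["gene_id"],
                        "position": sites["position"],
                        "strand": sites["strand"],
                        "meth": meth,
                        "unmeth": cov - meth,
                    }
                )
                manifest_rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": cond,
                        "part": part,
                        "replicate": rep,
                        "counts_path": f"{sample_id}.cx.tsv",
                    }
                )
    manifest = pd.DataFrame(manifest_rows)
    return SimulatedBundle(config, regions, sites, manifest, counts, truth)


def write_bundle(bundle: SimulatedBundle, outdir) -> dict[str, str]:
    """Write the bundle as a ready-to-analyze input directory.

    Emits ``regions.fasta``, ``regions.tsv``, one ``<sample>.cx.tsv`` per
    sample, ``manifest.tsv``, ``ground_truth.tsv`` and the resolved
    ``sim_config.yaml``; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(outdir / "regions.fasta"),
        "regions": str(outdir / "regions.tsv"),
        "manifest": str(outdir / "manifest.tsv"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
        "config": str(outdir / "sim_config.yaml"),
    }
    write_regions_fasta(bundle.regions, paths["fasta"], paths["regions"])
    for r in bundle.manifest.itertuples(index=False):
        mio.write_cx_report(
            bundle.counts[r.sample_id], outdir / r.counts_path, annotation=bundle.sites
        )
    bundle.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    bundle.ground_truth.to_csv(
        paths["ground_truth"], sep="\t", index=False, float_format="%.10g"
    )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=False)
    planted = pd.DataFrame(
        [dataclasses.asdict(p) for p in bundle.config.planted_dmrs],
        columns=["gene_id", "window_index", "context", "delta"],
    )
    paths["planted"] = str(outdir / "planted_dmrs.tsv")
    planted.to_csv(paths["planted"], sep="\t", index=False)
    return paths


def simulate_bundle(config: SimulationConfig, outdir=None) -> SimulatedBundle:
    """Simulate and, if ``outdir`` is given, write the bundle to disk."""
    bundle = simulate_counts(config)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle
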