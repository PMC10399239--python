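"""End-to-end orchestration: inputs -> sites -> statistics -> windows -> calls.

``run_pipeline`` consumes a :class:`RunConfig` (paths plus the analysis
constants: 50-bp windows, alpha 0.05, >20 percentage-point effect threshold)
and writes a fixed set of TSV result tables, each with a comment header that
echoes the configuration so every output is self-describing.  The comparisons
mirror the study design: warm vs cool within each embryo part, and basal vs
apical within each condition.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from . import stats, windows
from .regions import CONTEXTS, count_context_sites, enumerate_sites_many, read_regions

logger = logging.getLogger(__name__)

#: (name, group A (condition, part), group B) — delta is B minus A
def _comparison_pairs(kind: str) -> list[tuple[str, tuple[str, str], tuple[str, str]]]:
    if kind == "between-conditions-within-part":
        return [
            (f"warm_vs_cool_{part}", ("cool", part), ("warm", part))
            for part in mio.PARTS
        ]
    if kind == "between-parts-within-condition":
        return [
            (f"basal_vs_apical_{cond}", (cond, "apical"), (cond, "basal"))
            for cond in mio.CONDITIONS
        ]
    raise ValueError(f"unknown comparison kind {kind!r}")


@dataclass
class RunConfig:
    """Configuration of one analysis run; every field is echoed into outputs."""

    fasta: str
    regions: str
    manifest: str
    outdir: str
    window_size: int = 50
    alpha: float = 0.05
    delta_threshold: float = 20.0
    min_coverage: int = 1
    context_mean_mode: str = "weighted"  # or "literal"
    denominator_mode: str = "union"  # or "either_group_mean"
    comparisons: tuple = (
        "between-conditions-within-part",
        "between-parts-within-condition",
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def header(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparisons"] = ",".join(self.comparisons)
        return d


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full analysis and write all result tables.

    Returns a map from table name to written path.  Fails before any
    computation if the inputs are mutually inconsistent (e.g. a manifest
    report naming a gene absent from the FASTA).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()

    regions = read_regions(config.fasta, config.regions)
    lengths = {g: r.length for g, r in regions.items()}
    manifest = mio.read_manifest(config.manifest)
    sites = enumerate_sites_many(list(regions.values()))
    n_ambiguous = int((sites["context"] == "ambiguous").sum())
    logger.info(
        "%d regions, %d cytosine sites (%d ambiguous, excluded)",
        len(regions), len(sites), n_ambiguous,
    )

    long_counts = mio.load_sample_counts(manifest)
    annotated = mio.annotate_counts(long_counts, sites)
    interrogated = (annotated["meth"] + annotated["unmeth"]) >= max(config.min_coverage, 1)
    logger.info(
        "%d count rows, %d interrogated at min_coverage=%d",
        len(annotated), int(interrogated.sum()), config.min_coverage,
    )

    paths: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        mio.write_table(df, path, header)
        paths[name] = str(path)

    # per-window context-site abundance (site counts, methylation-agnostic)
    abundance = []
    for gene, region in sorted(regions.items()):
        tab = count_context_sites(region, config.window_size)
        tab = tab.reset_index().assign(gene_id=gene)
        abundance.append(tab)
    abundance_df = pd.concat(abundance, ignore_index=True)
    mean_abundance = (
        abundance_df.groupby("window_index", sort=True)[list(CONTEXTS)].mean().reset_index()
    )
    _write("context_site_abundance", mean_abundance)

    # group-pooled counts and site classification
    group_counts = stats.aggregate_group_counts(annotated)
    classified = stats.classify_sites(group_counts, min_coverage=config.min_coverage)

    _write(
        "gene_methylation",
        stats.gene_methylation_table(
            group_counts, mode=config.context_mean_mode, min_coverage=config.min_coverage
        ),
    )
    _write(
        "context_decomposition",
        stats.context_fraction_decomposition(classified, min_coverage=config.min_coverage),
    )

    # metaprofiles per group: global and per context
    profiles = []
    for ctx in (None, *CONTEXTS):
        profiles.append(
            windows.metaprofile(annotated, lengths, config.window_size, context=ctx)
        )
    _write("metaprofile", pd.concat(profiles, ignore_index=True))

    # shared-context percentages + DMR calls per comparison
    shared_rows, call_frames, dmg_frames = [], [], []
    for kind in config.comparisons:
        for name, (cond_a, part_a), (cond_b, part_b) in _comparison_pairs(kind):
            cls_a = classified[
                (classified["condition"] == cond_a) & (classified["part"] == part_a)
            ]
            cls_b = classified[
                (classified["condition"] == cond_b) & (classified["part"] == part_b)
            ]
            shared = stats.shared_context_percentages(
                cls_a, cls_b, denominator_mode=config.denominator_mode
            )
            shared.insert(0, "comparison", name)
            shared.insert(1, "kind", kind)
            shared_rows.append(shared)

            ann_a = annotated[
                (annotated["condition"] == cond_a) & (annotated["part"] == part_a)
            ]
            ann_b = annotated[
                (annotated["condition"] == cond_b) & (annotated["part"] == part_b)
            ]
            comp_calls = []
            for ctx in (*CONTEXTS, None):
                win_a = windows.aggregate_window_counts(
                    ann_a, lengths, config.window_size, context=ctx, by=["condition"]
                ).drop(columns=["condition"])
                win_b = windows.aggregate_window_counts(
                    ann_b, lengths, config.window_size, context=ctx, by=["condition"]
                ).drop(columns=["condition"])
                calls = windows.call_dmrs(
                    win_a, win_b, alpha=config.alpha, delta_threshold=config.delta_threshold
                )
                comp_calls.append(calls)
            comp_calls = pd.concat(comp_calls, ignore_index=True)
            comp_calls.insert(0, "comparison", name)
            w = config.window_size
            comp_calls.insert(3, "window_start", comp_calls["window_index"] * w)
            comp_calls.insert(4, "window_end", (comp_calls["window_index"] + 1) * w)
            call_frames.append(comp_calls)

            dmg = windows.summarize_dmgs(comp_calls)
            dmg.insert(0, "comparison", name)
            dmg_frames.append(dmg)
            logger.info(
                "comparison %s: %d DMR windows, %d/%d DMGs (any context)",
                name,
                int(comp_calls["is_dmr"].sum()),
                int(dmg["is_dmg_any"].sum()),
                len(dmg),
            )

    _write("shared_contexts", pd.concat(shared_rows, ignore_index=True))
    _write("dmr_calls", pd.concat(call_frames, ignore_index=True))
    dmg_all = pd.concat(dmg_frames, ignore_index=True)
    _write("dmg_summary", dmg_all)

    dmg_fracs = (
        dmg_all.groupby("comparison", sort=True)["is_dmg_any"].mean().mul(100).reset_index()
    )
    dmg_fracs.columns = ["comparison", "dmg_any_pct"]
    _write("dmg_fractions", dmg_fracs)

    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    paths["run_config"] = str(outdir / "run_config.yaml")
    return paths
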