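"""Shared fixtures: seeded synthetic bundles reused across the suite.

All bundles are generated in-session by the package's own simulator — the
suite carries no data files.
"""

from __future__ import annotations

import pytest

from methwin import io as mio
from methwin.pipeline import RunConfig, run_pipeline
from methwin.simulate import PlantedDMR, SimulationConfig, simulate_counts, write_bundle

#: window indices used for planting: spread over promoter and body
PLANTED_WINDOWS = (5, 11, 17, 23, 29, 35, 41, 47, 53, 59)
N_PLANTED_GENES = 50
N_NULL_GENES = 20
PLANTED_DELTA = 0.30


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    """Study-default simulation: factorial design, spatial profile, warm effect."""
    return SimulationConfig(n_genes=24, mean_coverage=15, seed=11)


@pytest.fixture(scope="session")
def default_bundle(default_cfg):
    return simulate_counts(default_cfg)


@pytest.fixture(scope="session")
def default_annotated(default_bundle):
    """Long per-sample counts annotated with recomputed context/region labels."""
    return mio.annotate_counts(default_bundle.long_counts(), default_bundle.sites)


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    """Full pipeline run on the default bundle; returns (config, paths)."""
    root = tmp_path_factory.mktemp("default_run")
    write_bundle(default_bundle, root / "bundle")
    cfg = RunConfig(
        fasta=str(root / "bundle" / "regions.fasta"),
        regions=str(root / "bundle" / "regions.tsv"),
        manifest=str(root / "bundle" / "manifest.tsv"),
        outdir=str(root / "out"),
    )
    paths = run_pipeline(cfg)
    return cfg, paths


@pytest.fixture(scope="session")
def null_bundle():
    """No condition/part effects: both conditions share identical surfaces."""
    cfg = SimulationConfig(
        n_genes=34,
        mean_coverage=8,
        condition_effect=1.0,
        part_effect=1.0,
        epimutation_rate=0.0,
        seed=29,
    )
    return simulate_counts(cfg)


def make_planted_cfg(seed: int = 17) -> SimulationConfig:
    """50 genes x 10 planted CpG windows (delta 0.30) plus 20 null genes."""
    planted = [
        PlantedDMR(f"g{g + 1:04d}", w, "CpG", PLANTED_DELTA)
        for g in range(N_PLANTED_GENES)
        for w in PLANTED_WINDOWS
    ]
    return SimulationConfig(
        n_genes=N_PLANTED_GENES + N_NULL_GENES,
        gc_content=0.5,
        mean_coverage=25,
        condition_effect=1.0,
        part_effect=1.0,
        epimutation_rate=0.0,
        planted_dmrs=planted,
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_bundle():
    return simulate_counts(make_planted_cfg())


@pytest.fixture(scope="session")
def planted_annotated(planted_bundle):
    return mio.annotate_counts(planted_bundle.long_counts(), planted_bundle.sites)
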