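"""Plain-text and figure summary of a pipeline run.

Every number in the report is read back from the result TSVs — the tables are
the single source of truth; the report never recomputes statistics.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import io as mio
from .regions import CONTEXTS

logger = logging.getLogger(__name__)

_TABLES = (
    "metaprofile",
    "context_decomposition",
    "dmr_calls",
    "dmg_summary",
    "dmg_fractions",
    "shared_contexts",
)


def _plot_metaprofiles(profile: pd.DataFrame, outdir: Path, window_size: int) -> list[str]:
    written = []
    for ctx in ("all", *CONTEXTS):
        sub = profile[profile["context"] == ctx]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        for (cond, part), curve in sub.groupby(["condition", "part"]):
            color = "tab:red" if cond == "warm" else "tab:blue"
            style = "-" if part == "apical" else "--"
            ax.plot(
                curve["window_index"] * window_size,
                curve["mean_pct"],
                style,
                color=color,
                label=f"{cond} {part}",
            )
        ax.set_xlabel("position in region (bp)")
        ax.set_ylabel("mean methylation (%)")
        ax.set_title(f"Metaprofile ({ctx} context)" if ctx != "all" else "Metaprofile (all contexts)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"metaprofile_{ctx}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written


def _plot_decomposition(decomp: pd.DataFrame, outdir: Path) -> list[str]:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, col, title in zip(
        axes,
        ("unmethylated_share_pct", "methylated_share_pct"),
        ("Unmethylated sites", "Methylated sites"),
    ):
        pivot = decomp.pivot_table(
            index=["condition", "part", "region"], columns="context", values=col
        )
        pivot.plot.bar(stacked=True, ax=ax, legend=False)
        ax.set_title(title)
        ax.set_ylabel("share of sites (%)")
        ax.tick_params(axis="x", labelsize=7)
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    path = outdir / "context_decomposition.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [str(path)]


def render_report(outdir, window_size: int = 50) -> str:
    """Render ``report.txt`` plus figures from the tables in ``outdir``.

    Missing tables are listed in the report but do not abort it.
    """
    outdir = Path(outdir)
    tables: dict[str, pd.DataFrame] = {}
    missing = []
    for name in _TABLES:
        path = outdir / f"{name}.tsv"
        if path.exists():
            tables[name] = mio.read_table(path)
        else:
            missing.append(name)

    lines = ["Methylation analysis report", "=" * 28, ""]
    if missing:
        lines += ["Missing tables: " + ", ".join(missing), ""]

    if "dmr_calls" in tables:
        calls = tables["dmr_calls"]
        lines.append("DMR windows per comparison and context:")
        if calls["is_dmr"].sum() == 0:
            lines.append("  zero DMRs called")
        else:
            counts = (
                calls[calls["is_dmr"]]
                .groupby(["comparison", "context"])
                .size()
                .reset_index(name="n_dmr")
            )
            for r in counts.itertuples(index=False):
                lines.append(f"  {r.comparison:>24s}  {r.context:>4s}  {r.n_dmr}")
        lines.append("")

    if "dmg_fractions" in tables:
        lines.append("DMG fraction (any context) per comparison:")
        for r in tables["dmg_fractions"].itertuples(index=False):
            lines.append(f"  {r.comparison:>24s}  {r.dmg_any_pct:.1f}%")
        lines.append("")

    if "shared_contexts" in tables:
        lines.append("Shared-context percentages (first rows):")
        head = tables["shared_contexts"].head(12)
        lines.append(head.to_string(index=False))
        lines.append("")

    figures = []
    if "metaprofile" in tables:
        figures += _plot_metaprofiles(tables["metaprofile"], outdir, window_size)
    if "context_decomposition" in tables and not tables["context_decomposition"].empty:
        figures += _plot_decomposition(tables["context_decomposition"], outdir)
    if figures:
        lines.append("Figures written:")
        lines += [f"  {f}" for f in figures]
        lines.append("")

    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    logger.info("report written to %s", report_path)
    return str(report_path)
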