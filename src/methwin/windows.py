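"""Window tiling, metaprofiles, and Fisher-exact DMR/DMG calling.

Each target region is tiled into consecutive, non-overlapping 50-bp windows
(60 windows for the default 3 kb geometry).  For two groups being compared,
the methylated and unmethylated read observations in a window are pooled
across sites (both strands) and replicates, giving a 2x2 contingency table

        methylated   unmethylated
    A      m_A           u_A
    B      m_B           u_B

tested with a two-tailed Fisher's exact test.  A window is a differentially
methylated region (DMR) when p < alpha (0.05) and the absolute methylation
difference exceeds ``delta_threshold`` percentage points (strictly > 20 by
default).  A gene with at least one DMR in a context is a differentially
methylated gene (DMG) for that context; "any context" rolls the three up.

The two-sided p-value uses the standard hypergeometric rule: the sum of the
probabilities of all tables with the observed margins whose point probability
does not exceed that of the observed table (a relative guard of 1e-7 absorbs
floating-point ties).  Any zero margin gives p = 1: such a table carries no
information about association.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .regions import CONTEXTS, TargetRegion
from .stats import GROUP_COLS

logger = logging.getLogger(__name__)

_TIE_GUARD = 1.0 + 1e-7


def tile_windows(length: int, window_size: int = 50) -> pd.DataFrame:
    """Tile ``[0, length)`` into consecutive half-open windows.

    ``window_size`` must divide ``length`` exactly; window ``k`` spans
    ``[k*w, (k+1)*w)``.  Returns columns ``window_index, start, end``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if length % window_size != 0:
        raise ValueError(f"window_size {window_size} does not divide region length {length}")
    n = length // window_size
    idx = np.arange(n)
    return pd.DataFrame(
        {"window_index": idx, "start": idx * window_size, "end": (idx + 1) * window_size}
    )


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    p = fisher_exact_many(np.array([a]), np.array([b]), np.array([c]), np.array([d]))
    return float(p[0])


def _pvalues_for_margins(n1: int, n2: int, m1: int) -> np.ndarray:
    """Two-sided p for every table with row sums (n1, n2) and first-column sum m1.

    Returns the p-value indexed by k = the first cell, for k over the
    hypergeometric support ``[max(0, m1-n2), min(n1, m1)]``.
    """
    kmin = max(0, m1 - n2)
    kmax = min(n1, m1)
    support = np.arange(kmin, kmax + 1)
    if len(support) == 1:  # a zero margin: single possible table
        return np.ones(1)
    pmf = hypergeom.pmf(support, n1 + n2, n1, m1)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * _TIE_GUARD, side="right")
    return np.minimum(cum[idx - 1], 1.0)


def fisher_exact_many(
    meth_a: np.ndarray, unmeth_a: np.ndarray, meth_b: np.ndarray, unmeth_b: np.ndarray
) -> np.ndarray:
    """Vectorized two-tailed Fisher exact test over many 2x2 tables.

    Tables sharing margins share one hypergeometric evaluation, which keeps
    genome-scale window sweeps fast.
    """
    a = np.asarray(meth_a, dtype=np.int64)
    b = np.asarray(unmeth_a, dtype=np.int64)
    c = np.asarray(meth_b, dtype=np.int64)
    d = np.asarray(unmeth_b, dtype=np.int64)
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("contingency-table counts must be non-negative")
    n1 = a + b
    n2 = c + d
    m1 = a + c
    out = np.empty(len(a), dtype=float)
    cache: dict[tuple[int, int, int], np.ndarray] = {}
    for i in range(len(a)):
        key = (int(n1[i]), int(n2[i]), int(m1[i]))
        pvals = cache.get(key)
        if pvals is None:
            pvals = _pvalues_for_margins(*key)
            cache[key] = pvals
        kmin = max(0, key[2] - key[1])
        out[i] = pvals[int(a[i]) - kmin]
    return out


def aggregate_window_counts(
    annotated: pd.DataFrame,
    lengths: dict[str, int],
    window_size: int = 50,
    context: str | None = None,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Pool read counts per (group, gene, window), both strands, all replicates.

    ``annotated`` is a long counts frame with context/region labels and the
    grouping columns in ``by`` (default condition+part).  ``context`` of None
    pools all three contexts ("all").  Every window of every gene appears in
    the output, including empty ones (0, 0, NaN mean).
    """
    by = list(by) if by is not None else GROUP_COLS
    sub = annotated if context is None else annotated[annotated["context"] == context]
    sub = sub.copy()
    sub["window_index"] = sub["position"] // window_size
    agg = sub.groupby(by + ["gene_id", "window_index"], as_index=False, sort=True)[
        ["meth", "unmeth"]
    ].sum()

    # complete the grid: groups x genes x all windows of each gene
    groups = annotated[by].drop_duplicates()
    gene_windows = pd.concat(
        [
            pd.DataFrame(
                {"gene_id": gene, "window_index": np.arange(length // window_size)}
            )
            for gene, length in sorted(lengths.items())
        ],
        ignore_index=True,
    )
    grid = groups.merge(gene_windows, how="cross")
    full = grid.merge(agg, on=by + ["gene_id", "window_index"], how="left").fillna(
        {"meth": 0, "unmeth": 0}
    )
    full[["meth", "unmeth"]] = full[["meth", "unmeth"]].astype(np.int64)
    cov = full["meth"] + full["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        full["mean_pct"] = np.where(cov > 0, 100.0 * full["meth"] / cov, np.nan)
    full["context"] = context if context is not None else "all"
    return full.sort_values(by + ["gene_id", "window_index"], kind="stable").reset_index(
        drop=True
    )


def call_dmrs(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    alpha: float = 0.05,
    delta_threshold: float = 20.0,
) -> pd.DataFrame:
    """Per-window Fisher tests and DMR calls for two groups on one window grid.

    ``windows_a``/``windows_b`` come from :func:`aggregate_window_counts` for
    the two groups (same genes, same grid, same context) — mismatched grids
    are an error.  ``delta_pct`` is group B minus group A.  Windows where
    either group has zero coverage are not testable: ``tested`` is False and
    no call is made.  A Benjamini-Hochberg column is provided for reference
    but never drives ``is_dmr``.
    """
    keys = ["gene_id", "window_index", "context"]
    a = windows_a.sort_values(keys, kind="stable").reset_index(drop=True)
    b = windows_b.sort_values(keys, kind="stable").reset_index(drop=True)
    if len(a) != len(b) or not a[keys].equals(b[keys]):
        raise ValueError("the two groups are not aggregated on the same window grid")
    out = a[keys].copy()
    out["meth_a"], out["unmeth_a"] = a["meth"], a["unmeth"]
    out["meth_b"], out["unmeth_b"] = b["meth"], b["unmeth"]
    cov_a = out["meth_a"] + out["unmeth_a"]
    cov_b = out["meth_b"] + out["unmeth_b"]
    out["pct_a"] = a["mean_pct"]
    out["pct_b"] = b["mean_pct"]
    out["delta_pct"] = out["pct_b"] - out["pct_a"]
    tested = (cov_a > 0) & (cov_b > 0)
    out["tested"] = tested.to_numpy()
    pvals = np.full(len(out), np.nan)
    if tested.any():
        t = out[tested.to_numpy()]
        pvals[tested.to_numpy()] = fisher_exact_many(
            t["meth_a"].to_numpy(),
            t["unmeth_a"].to_numpy(),
            t["meth_b"].to_numpy(),
            t["unmeth_b"].to_numpy(),
        )
    out["p_value"] = pvals
    padj = np.full(len(out), np.nan)
    if tested.any():
        padj[tested.to_numpy()] = false_discovery_control(pvals[tested.to_numpy()], method="bh")
    out["p_adj_bh"] = padj
    out["is_dmr"] = (
        out["tested"]
        & (out["p_value"] < alpha)
        & (out["delta_pct"].abs() > delta_threshold)
    )
    n_nocall = int((~out["tested"]).sum())
    if n_nocall:
        logger.info("%d window(s) untestable (zero coverage in a group)", n_nocall)
    return out


def summarize_dmgs(calls: pd.DataFrame) -> pd.DataFrame:
    """Roll window-level DMR calls up to per-gene DMG status.

    ``calls`` may span several contexts (typically CpG/CHG/CHH and "all");
    a gene is a DMG in a context iff it has >= 1 DMR window there, and a DMG
    overall iff DMG in at least one of the three single contexts.
    """
    contexts = [c for c in calls["context"].unique()]
    per_gene = (
        calls.groupby(["gene_id", "context"], sort=True)["is_dmr"].sum().unstack(fill_value=0)
    )
    out = pd.DataFrame({"gene_id": per_gene.index})
    for ctx in contexts:
        out[f"n_dmr_{ctx}"] = per_gene[ctx].to_numpy(dtype=int)
        out[f"is_dmg_{ctx}"] = per_gene[ctx].to_numpy() > 0
    single = [c for c in CONTEXTS if c in contexts]
    out["is_dmg_any"] = np.column_stack(
        [out[f"is_dmg_{c}"].to_numpy() for c in single]
    ).any(axis=1) if single else False
    return out.reset_index(drop=True)


def dmg_fraction(dmg_summary: pd.DataFrame) -> float:
    """Fraction of genes that are DMGs in at least one context."""
    if dmg_summary.empty:
        return float("nan")
    return float(dmg_summary["is_dmg_any"].mean())


def metaprofile(
    annotated: pd.DataFrame,
    lengths: dict[str, int],
    window_size: int = 50,
    context: str | None = None,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """TSS-anchored mean-methylation curve per group.

    For every group and window position: each replicate's window methylation
    percentage is averaged across genes (windows without coverage in a gene
    are excluded from that gene's contribution, not counted as zero), then the
    replicate curves are averaged.  Returns one row per (group, window) with
    ``mean_pct`` and ``n_genes`` (the per-window mean across replicates of
    contributing genes).
    """
    by = list(by) if by is not None else GROUP_COLS
    per_rep = aggregate_window_counts(
        annotated, lengths, window_size=window_size, context=context, by=by + ["replicate"]
    )
    gene_level = per_rep.dropna(subset=["mean_pct"])
    rep_curves = gene_level.groupby(by + ["replicate", "window_index"], sort=True).agg(
        mean_pct=("mean_pct", "mean"), n_genes=("gene_id", "nunique")
    )
    curves = (
        rep_curves.groupby(by + ["window_index"], sort=True)
        .agg(mean_pct=("mean_pct", "mean"), n_genes=("n_genes", "mean"))
        .reset_index()
    )
    curves["context"] = context if context is not None else "all"
    return curves


def windows_to_bed(region: TargetRegion, window_size: int = 50) -> pd.DataFrame:
    """Window grid of one region as BED-style rows (0-based half-open)."""
    tiles = tile_windows(region.length, window_size)
    return pd.DataFrame(
        {
            "chrom": region.gene_id,
            "start": tiles["start"],
            "end": tiles["end"],
            "name": [f"{region.gene_id}_w{i}" for i in tiles["window_index"]],
        }
    )
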