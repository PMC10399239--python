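"""Methylation-level summary statistics.

Three levels of aggregation are provided, all on read counts:

* per-site methylation fraction: methylated reads / total reads, undefined
  ("missing", not zero) below the coverage threshold;
* per-gene mean: the read-weighted mean over all interrogated sites in scope,
  i.e. total methylated read observations over total read observations;
* per-context mean: the read-weighted mean restricted to one context
  (default), or a "literal" variant that additionally divides by the number
  of context sites in the gene — kept as an explicit reproduction mode
  because the two readings differ whenever a gene has more than one site of
  the context (see the package methods note).

Site classification follows the methylated/unmethylated dichotomy on
group-pooled counts: any methylated read makes a site "methylated"
(methylation level > 0); an interrogated site with zero methylated reads is
"unmethylated"; below-threshold coverage is "uninterrogated".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .regions import BODY, CONTEXTS, PROMOTER

logger = logging.getLogger(__name__)

UNMETHYLATED = "unmethylated"
METHYLATED = "methylated"
UNINTERROGATED = "uninterrogated"

GROUP_COLS = ["condition", "part"]
SITE_KEYS = ["gene_id", "position", "strand"]


def site_methylation_fraction(meth, unmeth, min_coverage: int = 1):
    """Per-site methylation fraction in [0, 1]; NaN below ``min_coverage``.

    Accepts scalars or aligned arrays.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    cov = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cov >= max(min_coverage, 1), meth / cov, np.nan)
    if frac.ndim == 0:
        return float(frac)
    return frac


def _scope_mask(df: pd.DataFrame, scope: str) -> pd.Series:
    if scope == "both":
        return pd.Series(True, index=df.index)
    if scope in (PROMOTER, BODY):
        return df["region"] == scope
    raise ValueError(f"unknown scope {scope!r}; expected 'promoter', 'body' or 'both'")


def gene_mean_methylation(df: pd.DataFrame, scope: str = "both", min_coverage: int = 1) -> float:
    """Read-weighted mean methylation over interrogated sites in scope, percent.

    ``sum(meth) / sum(meth + unmeth) * 100``; NaN when no site is interrogated.
    """
    sub = df[_scope_mask(df, scope)]
    cov = sub["meth"] + sub["unmeth"]
    sub = sub[cov >= max(min_coverage, 1)]
    total = float((sub["meth"] + sub["unmeth"]).sum())
    if total == 0:
        return float("nan")
    return 100.0 * float(sub["meth"].sum()) / total


def context_mean_methylation(
    df: pd.DataFrame,
    context: str,
    mode: str = "weighted",
    scope: str = "both",
    min_coverage: int = 1,
) -> float:
    """Mean methylation for one context, percent.

    ``weighted`` (default): read-weighted mean over interrogated sites of the
    context.  ``literal``: total methylated observations divided by (total
    observations x number of interrogated context sites), a reproduction-mode
    formula that shrinks with the site count.
    """
    if mode not in ("weighted", "literal"):
        raise ValueError(f"unknown mode {mode!r}; expected 'weighted' or 'literal'")
    sub = df[_scope_mask(df, scope) & (df["context"] == context)]
    cov = sub["meth"] + sub["unmeth"]
    sub = sub[cov >= max(min_coverage, 1)]
    total = float((sub["meth"] + sub["unmeth"]).sum())
    if total == 0:
        return float("nan")
    pct = 100.0 * float(sub["meth"].sum()) / total
    if mode == "literal":
        pct /= len(sub)
    return pct


def aggregate_group_counts(long_counts: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Sum replicate read counts per site within each (condition, part) cell."""
    by = list(by) if by is not None else GROUP_COLS
    agg = (
        long_counts.groupby(by + SITE_KEYS + ["context", "region"], as_index=False, sort=True)[
            ["meth", "unmeth"]
        ]
        .sum()
    )
    return agg


def classify_sites(
    group_counts: pd.DataFrame,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Label each group-pooled site unmethylated / methylated / uninterrogated.

    Input must already be aggregated within groups (replicates summed); a
    methylated read count of zero at interrogated coverage means unmethylated,
    any methylated read means methylated.
    """
    out = group_counts.copy()
    cov = out["meth"] + out["unmeth"]
    state = np.where(
        cov < max(min_coverage, 1),
        UNINTERROGATED,
        np.where(out["meth"] > 0, METHYLATED, UNMETHYLATED),
    )
    out["state"] = state
    return out


def classify_sites_consensus(
    long_counts: pd.DataFrame,
    min_replicates: int = 2,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Replicate-consensus classification: methylated iff methylated in
    >= ``min_replicates`` replicates of the group (sensitivity-analysis mode;
    pooled classification is the default elsewhere)."""
    per_rep = classify_sites(
        long_counts.rename(columns={})[
            GROUP_COLS + ["replicate"] + SITE_KEYS + ["context", "region", "meth", "unmeth"]
        ],
        min_coverage=min_coverage,
    )
    def _consensus(states: pd.Series) -> str:
        interrogated = states[states != UNINTERROGATED]
        if interrogated.empty:
            return UNINTERROGATED
        n_meth = (interrogated == METHYLATED).sum()
        return METHYLATED if n_meth >= min_replicates else UNMETHYLATED

    grouped = (
        per_rep.groupby(GROUP_COLS + SITE_KEYS + ["context", "region"], sort=True)["state"]
        .apply(_consensus)
        .reset_index()
    )
    return grouped


def gene_methylation_table(
    group_counts: pd.DataFrame,
    mode: str = "weighted",
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Per-(group, gene, scope) methylation summary table.

    One row per group x gene x scope (promoter/body/both) with the global
    read-weighted mean, per-context means and per-context interrogated-site
    counts.  Missing strata carry NaN, never zero.
    """
    rows = []
    for (cond, part, gene), sub in group_counts.groupby(GROUP_COLS + ["gene_id"], sort=True):
        for scope in (PROMOTER, BODY, "both"):
            row = {
                "condition": cond,
                "part": part,
                "gene_id": gene,
                "scope": scope,
                "global_mean_pct": gene_mean_methylation(sub, scope, min_coverage),
            }
            for ctx in CONTEXTS:
                row[f"{ctx}_mean_pct"] = context_mean_methylation(
                    sub, ctx, mode=mode, scope=scope, min_coverage=min_coverage
                )
                in_scope = sub[_scope_mask(sub, scope) & (sub["context"] == ctx)]
                cov = in_scope["meth"] + in_scope["unmeth"]
                row[f"{ctx}_n_sites"] = int((cov >= max(min_coverage, 1)).sum())
            rows.append(row)
    return pd.DataFrame(rows)


def context_fraction_decomposition(
    classified: pd.DataFrame,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Per-(group, region) context decomposition of site states.

    Within each (condition, part, region) stratum: the share of unmethylated
    sites falling in each context (summing to 100 across CpG/CHG/CHH), the
    same for methylated sites, and the per-context read-weighted mean
    methylation.  Strata with zero interrogated sites are skipped and logged.
    """
    rows = []
    for (cond, part, reg), sub in classified.groupby(GROUP_COLS + ["region"], sort=True):
        interrogated = sub[sub["state"] != UNINTERROGATED]
        if interrogated.empty:
            logger.info("stratum (%s, %s, %s): no interrogated sites, skipped", cond, part, reg)
            continue
        n_unmeth = (interrogated["state"] == UNMETHYLATED).sum()
        n_meth = (interrogated["state"] == METHYLATED).sum()
        for ctx in CONTEXTS:
            ctx_sub = interrogated[interrogated["context"] == ctx]
            rows.append(
                {
                    "condition": cond,
                    "part": part,
                    "region": reg,
                    "context": ctx,
                    "unmethylated_share_pct": (
                        100.0 * (ctx_sub["state"] == UNMETHYLATED).sum() / n_unmeth
                        if n_unmeth
                        else float("nan")
                    ),
                    "methylated_share_pct": (
                        100.0 * (ctx_sub["state"] == METHYLATED).sum() / n_meth
                        if n_meth
                        else float("nan")
                    ),
                    "mean_pct": context_mean_methylation(
                        sub, ctx, mode="weighted", min_coverage=min_coverage
                    ),
                    "n_sites": len(ctx_sub),
                }
            )
    return pd.DataFrame(rows)


def shared_context_percentages(
    classified_a: pd.DataFrame,
    classified_b: pd.DataFrame,
    denominator_mode: str = "union",
) -> pd.DataFrame:
    """Percentage of context sites sharing methylation state between two groups.

    Sites uninterrogated in either group are excluded entirely.  For each
    (context, region): shared methylated = sites methylated in both groups,
    divided by — ``union`` mode (default) — sites methylated in at least one
    group, or — ``either_group_mean`` mode — the mean of the two groups'
    methylated-site totals; same for unmethylated.  Returns NaN (logged) for
    empty denominators.
    """
    if denominator_mode not in ("union", "either_group_mean"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    keys = SITE_KEYS + ["context", "region"]
    merged = classified_a[keys + ["state"]].merge(
        classified_b[keys + ["state"]], on=keys, suffixes=("_a", "_b")
    )
    merged = merged[
        (merged["state_a"] != UNINTERROGATED) & (merged["state_b"] != UNINTERROGATED)
    ]
    rows = []
    for (ctx, reg), sub in merged.groupby(["context", "region"], sort=True):
        row = {"context": ctx, "region": reg, "n_sites": len(sub)}
        for state, col in ((UNMETHYLATED, "pct_shared_unmethylated"), (METHYLATED, "pct_shared_methylated")):
            in_a = sub["state_a"] == state
            in_b = sub["state_b"] == state
            both = float((in_a & in_b).sum())
            if denominator_mode == "union":
                denom = float((in_a | in_b).sum())
            else:
                denom = (float(in_a.sum()) + float(in_b.sum())) / 2.0
            if denom == 0:
                logger.info("shared %s (%s, %s): empty denominator", state, ctx, reg)
                row[col] = float("nan")
            else:
                row[col] = 100.0 * both / denom
        rows.append(row)
    return pd.DataFrame(rows)
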