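"""Count-level input/output: cytosine reports, sample manifests, result tables.

The count input dialect follows the Bismark cytosine report ("CX report"):
one tab-separated line per strand-resolved cytosine with

    gene_id  position(1-based)  strand(+/-)  count_methylated  count_unmethylated  [context  trinucleotide]

Positions are 1-based on disk and 0-based everywhere in memory.  The context
and trinucleotide columns are ignored on read — contexts are always recomputed
from the region sequence, so a report paired with the wrong FASTA is caught
rather than silently trusted.  Files ending in ``.gz`` are read and written
gzip-compressed.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("cool", "warm")
PARTS = ("apical", "basal")

_CX_COLUMNS = ["gene_id", "position", "strand", "meth", "unmeth"]


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_cx_report(path) -> pd.DataFrame:
    """Read a per-sample cytosine report into a counts DataFrame.

    Returns columns ``gene_id, position, strand, meth, unmeth`` with 0-based
    positions.  Zero-coverage rows are retained (they are "not interrogated"
    and filtered downstream by the coverage threshold).  Malformed lines,
    negative counts, bad strands and duplicate ``(gene, position, strand)``
    keys raise ``ValueError`` with the offending line number.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 tab-separated fields")
            gene, pos_s, strand, meth_s, unmeth_s = fields[:5]
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position {pos} is not 1-based positive")
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            rows.append((gene, pos - 1, strand, meth, unmeth))
    counts = pd.DataFrame(rows, columns=_CX_COLUMNS)
    if counts.empty:
        return counts
    dup = counts.duplicated(subset=["gene_id", "position", "strand"])
    if dup.any():
        r = counts[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate site ({r.gene_id}, {r.position + 1}, {r.strand})"
        )
    return counts


def write_cx_report(counts: pd.DataFrame, path, annotation: pd.DataFrame | None = None) -> None:
    """Write counts in the CX dialect (1-based positions), sorted for diffability.

    ``annotation``, if given, supplies ``context``/``trinucleotide`` columns
    keyed by ``(gene_id, position, strand)``; otherwise both are written
    as ``.``.
    """
    out = counts.sort_values(["gene_id", "position", "strand"], kind="stable").copy()
    if annotation is not None:
        keys = ["gene_id", "position", "strand"]
        cols = [c for c in ("context", "trinucleotide") if c in annotation.columns]
        out = out.merge(annotation[keys + cols], on=keys, how="left")
    if "context" not in out.columns:
        out["context"] = "."
    if "trinucleotide" not in out.columns:
        out["trinucleotide"] = "."
    out["context"] = out["context"].fillna(".")
    out["trinucleotide"] = out["trinucleotide"].fillna(".")
    with _open_text(path, "wt") as fh:
        for r in out.itertuples(index=False):
            fh.write(
                f"{r.gene_id}\t{r.position + 1}\t{r.strand}\t{r.meth}\t{r.unmeth}"
                f"\t{r.context}\t{r.trinucleotide}\n"
            )


def read_manifest(path, expected_replicates: int = 3) -> pd.DataFrame:
    """Read the sample manifest: TSV with header
    ``sample_id, condition, part, replicate, counts_path``.

    Validates the two-condition x two-part factorial design: unknown
    condition/part tokens and duplicate sample ids or design cells are errors;
    a ``(condition, part)`` cell with fewer than ``expected_replicates``
    replicates is only warned about.  Relative ``counts_path`` entries are
    resolved against the manifest's directory.
    """
    path = Path(path)
    m = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "counts_path": str})
    required = {"sample_id", "condition", "part", "replicate", "counts_path"}
    missing = required - set(m.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    for col, allowed in (("condition", CONDITIONS), ("part", PARTS)):
        bad = set(m[col]) - set(allowed)
        if bad:
            raise ValueError(
                f"manifest {path}: unknown {col} value(s) {sorted(bad)}; allowed: {list(allowed)}"
            )
    if m["sample_id"].duplicated().any():
        dup = m.loc[m["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"manifest {path}: duplicate sample_id {dup!r}")
    m["replicate"] = m["replicate"].astype(int)
    if (m["replicate"] < 1).any():
        raise ValueError(f"manifest {path}: replicate numbers must be >= 1")
    key = m[["condition", "part", "replicate"]]
    if key.duplicated().any():
        r = m[key.duplicated()].iloc[0]
        raise ValueError(
            f"manifest {path}: duplicate design cell ({r.condition}, {r.part}, rep {r.replicate})"
        )
    for cond in CONDITIONS:
        for part in PARTS:
            n = ((m["condition"] == cond) & (m["part"] == part)).sum()
            if n < expected_replicates:
                logger.warning(
                    "manifest %s: cell (%s, %s) has %d replicate(s), expected %d",
                    path, cond, part, n, expected_replicates,
                )
    m["counts_path"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p) for p in m["counts_path"]
    ]
    return m.reset_index(drop=True)


def load_sample_counts(manifest: pd.DataFrame) -> pd.DataFrame:
    """Read every sample's report and stack them into one long frame.

    Adds ``sample_id, condition, part, replicate`` to each counts row.
    """
    frames = []
    for r in manifest.itertuples(index=False):
        counts = read_cx_report(r.counts_path)
        counts.insert(0, "sample_id", r.sample_id)
        counts.insert(1, "condition", r.condition)
        counts.insert(2, "part", r.part)
        counts.insert(3, "replicate", r.replicate)
        logger.info("sample %s: %d sites read", r.sample_id, len(counts))
        frames.append(counts)
    return pd.concat(frames, ignore_index=True)


def annotate_counts(counts: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Attach context and region labels (recomputed from sequence) to counts.

    Counts at coordinates that are not cytosine sites of the stated strand
    indicate a sequence/report mismatch and raise ``ValueError``.  Ambiguous-
    context sites are dropped, as are their count rows.
    """
    keys = ["gene_id", "position", "strand"]
    merged = counts.merge(sites[keys + ["context", "region"]], on=keys, how="left")
    unmatched = merged["context"].isna()
    if unmatched.any():
        r = merged[unmatched].iloc[0]
        raise ValueError(
            f"count row at ({r.gene_id}, {r.position}, {r.strand}) does not match any "
            "cytosine site in the region sequences; report/FASTA mismatch?"
        )
    n_amb = int((merged["context"] == "ambiguous").sum())
    if n_amb:
        logger.info("dropping %d count rows at ambiguous-context sites", n_amb)
    merged = merged[merged["context"] != "ambiguous"].reset_index(drop=True)
    return merged


def write_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write a result TSV with ``#`` comment lines recording configuration."""
    with _open_text(path, "wt") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a result TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
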