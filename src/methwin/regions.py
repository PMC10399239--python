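"""Target-region geometry and strand-resolved cytosine context annotation.

Each analyzed gene is an independent mini-contig: a fixed-length span (by
default 3 kb = 2 kb promoter + 1 kb gene body) anchored at the transcriptional
start site (TSS).  Every cytosine on either strand is classified into one of
the three plant methylation contexts by reading two bases downstream on the
site's own strand:

    CpG : C followed by G
    CHG : C, H, G        (H = A, C or T)
    CHH : C, H, H

Coordinates are 0-based half-open throughout; the TSS is the first base of the
gene-body span.  Sites whose 2-nt downstream window runs off the region end,
or touches an N, are labeled ``ambiguous`` and excluded from all statistics:
targets are extracted subsequences, so the flanking genome is not available to
resolve them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

CONTEXTS = ("CpG", "CHG", "CHH")
AMBIGUOUS = "ambiguous"
PROMOTER = "promoter"
BODY = "body"

_VALID_BASES = frozenset(b"ACGTN")


@dataclass(frozen=True)
class TargetRegion:
    """One gene's analyzed span with its promoter/body partition.

    Parameters
    ----------
    gene_id : str
        Identifier; must match the FASTA record and count-report rows.
    sequence : str
        Forward-strand DNA over ``{A, C, G, T, N}`` (case-insensitive).
    tss_offset : int
        0-based offset of the TSS within the region.  ``[0, tss_offset)`` is
        the promoter span, ``[tss_offset, len)`` the gene-body span.
    """

    gene_id: str
    sequence: str
    tss_offset: int = 2000

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
        if bad.any():
            off = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"invalid base {seq[off]!r} at offset {off} in region {self.gene_id!r}"
            )
        if not 0 < self.tss_offset < len(seq):
            raise ValueError(
                f"region {self.gene_id!r}: tss_offset {self.tss_offset} outside (0, {len(seq)})"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def promoter_span(self) -> tuple[int, int]:
        return (0, self.tss_offset)

    @property
    def body_span(self) -> tuple[int, int]:
        return (self.tss_offset, len(self.sequence))


def _context_codes(base1: np.ndarray, base2: np.ndarray) -> np.ndarray:
    """Context of a C given the next two bases on its own strand.

    Returns an index into ``(CpG, CHG, CHH, ambiguous)``.
    """
    G, N = ord("G"), ord("N")
    ctx = np.full(base1.shape, 3, dtype=np.int8)  # ambiguous
    b1_h = (base1 != G) & (base1 != N)
    ctx[base1 == G] = 0  # CpG
    ctx[b1_h & (base2 == G)] = 1  # CHG
    ctx[b1_h & (base2 != G) & (base2 != N)] = 2  # CHH
    return ctx


def enumerate_sites(region: TargetRegion, drop_ambiguous: bool = False) -> pd.DataFrame:
    """Enumerate every strand-resolved cytosine site in a region.

    Forward-strand C's become ``+`` sites; forward-strand G's become ``-``
    sites (a C on the reverse complement at the same forward coordinate).
    Context is read downstream on the site's own strand.

    Returns a DataFrame with columns ``gene_id, position, strand, context,
    region`` sorted by position then strand; ambiguous-context rows are kept
    unless ``drop_ambiguous``.
    """
    seq = np.frombuffer(region.sequence.encode("ascii"), dtype=np.uint8)
    L = len(seq)
    C, G, N = ord("C"), ord("G"), ord("N")
    # pad so the two downstream lookups are branch-free; N forces ambiguous
    padded = np.concatenate([np.full(2, N, np.uint8), seq, np.full(2, N, np.uint8)])

    plus_pos = np.flatnonzero(seq == C)
    plus_ctx = _context_codes(padded[plus_pos + 3], padded[plus_pos + 4])

    # a '-' site reads downstream toward lower forward coordinates, complemented;
    # complement(x) == G iff x == C, and complement in {A,C,T} iff x in {A,G,T}
    minus_pos = np.flatnonzero(seq == G)
    down1 = padded[minus_pos + 1]  # forward base at position-1
    down2 = padded[minus_pos + 0]  # forward base at position-2
    comp = np.full(256, N, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    minus_ctx = _context_codes(comp[down1], comp[down2])

    labels = np.array(list(CONTEXTS) + [AMBIGUOUS])
    frame = pd.DataFrame(
        {
            "gene_id": region.gene_id,
            "position": np.concatenate([plus_pos, minus_pos]),
            "strand": np.repeat(["+", "-"], [len(plus_pos), len(minus_pos)]),
            "context": labels[np.concatenate([plus_ctx, minus_ctx])],
        }
    )
    frame["region"] = np.where(frame["position"] < region.tss_offset, PROMOTER, BODY)
    frame = frame.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)
    if drop_ambiguous:
        frame = frame[frame["context"] != AMBIGUOUS].reset_index(drop=True)
    return frame


def enumerate_sites_many(regions: list[TargetRegion], drop_ambiguous: bool = False) -> pd.DataFrame:
    """Concatenate :func:`enumerate_sites` over several regions."""
    frames = [enumerate_sites(r, drop_ambiguous=drop_ambiguous) for r in regions]
    if not frames:
        return pd.DataFrame(columns=["gene_id", "position", "strand", "context", "region"])
    return pd.concat(frames, ignore_index=True)


def count_context_sites(region: TargetRegion, window_size: int = 50) -> pd.DataFrame:
    """Per-window abundance of CpG/CHG/CHH sites, both strands pooled.

    The region is tiled into ``length / window_size`` half-open windows
    (``window_size`` must divide the length exactly); ambiguous sites are
    excluded.  Returns a DataFrame indexed by ``window_index`` with one column
    per context.
    """
    if region.length % window_size != 0:
        raise ValueError(
            f"window_size {window_size} does not divide region length {region.length}"
        )
    n_windows = region.length // window_size
    sites = enumerate_sites(region, drop_ambiguous=True)
    sites["window_index"] = sites["position"] // window_size
    table = (
        sites.pivot_table(
            index="window_index", columns="context", values="position", aggfunc="count"
        )
        .reindex(index=range(n_windows), columns=list(CONTEXTS))
        .fillna(0)
        .astype(int)
    )
    table.columns.name = None
    return table


def read_region_table(path) -> pd.DataFrame:
    """Read the region table: TSV with header ``gene_id, length, tss_offset``."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "length", "tss_offset"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"region table {path} missing columns: {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in region table")
    return table


def read_regions(fasta_path, table_path) -> dict[str, TargetRegion]:
    """Load target regions from a FASTA plus the region table.

    Every table row must have a FASTA record of the stated length; FASTA
    records absent from the table are ignored.
    """
    table = read_region_table(table_path)
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    regions: dict[str, TargetRegion] = {}
    for row in table.itertuples(index=False):
        if row.gene_id not in records:
            raise ValueError(f"gene {row.gene_id!r} in region table but not in FASTA")
        seq = records[row.gene_id]
        if len(seq) != row.length:
            raise ValueError(
                f"gene {row.gene_id!r}: FASTA length {len(seq)} != table length {row.length}"
            )
        regions[row.gene_id] = TargetRegion(row.gene_id, seq, int(row.tss_offset))
    return regions


def write_regions_fasta(regions: dict[str, TargetRegion], fasta_path, table_path) -> None:
    """Write regions as FASTA plus the matching region table."""
    with open(fasta_path, "w") as fh:
        for r in regions.values():
            fh.write(f">{r.gene_id}\n")
            for i in range(0, r.length, 80):
                fh.write(r.sequence[i : i + 80] + "\n")
    table = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in regions.values()],
            "length": [r.length for r in regions.values()],
            "tss_offset": [r.tss_offset for r in regions.values()],
        }
    )
    table.to_csv(table_path, sep="\t", index=False)
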