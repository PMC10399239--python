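"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths of the package under test: the site
scan uses regular expressions over both literal strands, and the Fisher
oracle computes hypergeometric point probabilities from a log-factorial
table and sums them by the definitional rule.
"""

from __future__ import annotations

import re

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
_CTX_RE = re.compile(r"(?=(CG|C[ACT]G|C[ACT][ACT]))")

TIE_GUARD = 1.0 + 1e-7


def regex_site_scan(sequence: str) -> set[tuple[int, str, str]]:
    """All unambiguous cytosine sites of both strands via regex.

    Returns ``{(forward_position, strand, context)}``; sites whose
    trinucleotide runs off the end or touches an N simply do not match.
    """
    seq = sequence.upper()
    rc = seq.translate(_COMP)[::-1]
    L = len(seq)
    sites = set()
    for strand, s in (("+", seq), ("-", rc)):
        for m in _CTX_RE.finditer(s):
            tri = m.group(1)
            ctx = "CpG" if tri == "CG" else ("CHG" if tri.endswith("G") else "CHH")
            pos = m.start() if strand == "+" else L - 1 - m.start()
            sites.add((pos, strand, ctx))
    return sites


def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])


_LF_CACHE: dict[int, np.ndarray] = {}


def _lf(n: int) -> np.ndarray:
    size = max(1024, n + 1)
    for cached in _LF_CACHE:
        if cached >= n + 1:
            return _LF_CACHE[cached]
    table = _log_factorials(size)
    _LF_CACHE.clear()
    _LF_CACHE[size] = table
    return table


def fisher_oracle_margins(n1: int, n2: int, m1: int) -> np.ndarray:
    """Two-sided p for every first-cell value over the hypergeometric support.

    Brute force: every table with the given margins is enumerated, its point
    probability computed from log factorials, and for each observed table the
    probabilities of all tables at most (1 + 1e-7) times as likely are summed.
    """
    lf = _lf(n1 + n2)
    kmin, kmax = max(0, m1 - n2), min(n1, m1)
    k = np.arange(kmin, kmax + 1)
    logs = (
        lf[n1] - lf[k] - lf[n1 - k]
        + lf[n2] - lf[m1 - k] - lf[n2 - m1 + k]
        + lf[m1] + lf[n1 + n2 - m1] - lf[n1 + n2]
    )
    pmf = np.exp(logs)
    include = pmf[None, :] <= pmf[:, None] * TIE_GUARD
    return np.minimum((include * pmf[None, :]).sum(axis=1), 1.0)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for one table, by brute-force enumeration."""
    n1, n2, m1 = a + b, c + d, a + c
    kmin = max(0, m1 - n2)
    return float(fisher_oracle_margins(n1, n2, m1)[a - kmin])
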